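"""Incidence-based chemical diversity: Hill numbers, coverage, rarefaction.

The sampling unit is a species; the "abundance" of a compound within a
family is its incidence frequency Y_i, the number of that family's species
in which it occurs.  With U = sum(Y_i) and p_i = Y_i / U, the Hill numbers
are

    q = 0: richness S_obs
    q = 1: exp(-sum p_i ln p_i)           (Shannon-effective diversity)
    q = 2: 1 / sum p_i^2                  (Simpson-effective diversity)

and chemical evenness is the Hill ratio q1/q0.

Sampling-effort standardization uses coverage-based rarefaction and
extrapolation: expected richness at t <= T sampling units is

    S(t) = S_obs - sum_i C(T - Y_i, t) / C(T, t)

with Chao2-based extrapolation beyond T, and sample coverage is estimated
with the incidence Good-Turing correction.  Diversity is reported at the
(real-valued) number of sampling units whose estimated coverage hits the
target (default 0.95), capped at 2T.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import pearsonr

__all__ = [
    "IncidenceFrequencies",
    "HillProfile",
    "hill_numbers",
    "hill_profile",
    "sample_coverage",
    "rarefied_richness",
    "expected_frequency_spectrum",
    "coverage_at",
    "hill_at",
    "chao2_richness",
    "coverage_rarefy",
    "plasticity_index",
]


@dataclass(frozen=True)
class IncidenceFrequencies:
    """Incidence frequency counts for one family.

    ``T`` sampling units (species) and per-compound incidence counts ``y``
    with ``1 <= y_i <= T``.
    """

    T: int
    y: np.ndarray

    @classmethod
    def from_incidence(cls, incidence) -> "IncidenceFrequencies":
        """From a binary species x compound matrix (rows = species)."""
        mat = np.asarray(incidence, dtype=float)
        if mat.ndim != 2:
            raise ValueError("incidence must be 2-D (species x compound)")
        y = mat.sum(axis=0)
        return cls(T=mat.shape[0], y=y[y > 0].astype(float))

    def __post_init__(self):
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "y", y)
        if len(y) and (y.min() < 1 or y.max() > self.T):
            raise ValueError("incidence frequencies must satisfy 1 <= Y_i <= T")

    @property
    def S_obs(self) -> int:
        return len(self.y)

    @property
    def U(self) -> float:
        return float(self.y.sum())

    def Q(self, k: int) -> int:
        """Number of compounds observed in exactly k sampling units."""
        return int(np.sum(self.y == k))


@dataclass(frozen=True)
class HillProfile:
    q0: float
    q1: float
    q2: float
    evenness: float
    coverage_standardized: bool = False
    target_coverage: float | None = None


def hill_numbers(freqs: IncidenceFrequencies, q: int) -> float:
    """Hill number of order q in {0, 1, 2} from incidence frequencies."""
    if freqs.S_obs == 0:
        raise ValueError("no compounds")
    if q == 0:
        return float(freqs.S_obs)
    p = freqs.y / freqs.U
    if q == 1:
        return float(np.exp(-np.sum(p * np.log(p))))
    if q == 2:
        return float(1.0 / np.sum(p**2))
    raise ValueError(f"unsupported Hill order q={q}; only q in {{0, 1, 2}}")


def hill_profile(freqs: IncidenceFrequencies) -> HillProfile:
    q0, q1, q2 = (hill_numbers(freqs, q) for q in (0, 1, 2))
    return HillProfile(q0=q0, q1=q1, q2=q2, evenness=q1 / q0)


def sample_coverage(freqs: IncidenceFrequencies) -> float:
    """Good-Turing incidence coverage estimate of the full sample."""
    if freqs.U == 0:
        raise ValueError("no incidences")
    if freqs.T < 2:
        raise ValueError("need at least 2 sampling units")
    Q1, Q2, T, U = freqs.Q(1), freqs.Q(2), freqs.T, freqs.U
    if Q1 == 0:
        return 1.0
    A = (T - 1) * Q1 / ((T - 1) * Q1 + 2 * Q2)
    return float(1.0 - (Q1 / U) * A)


def _log_choose(n, k):
    """log C(n, k) with C(n, k) = 0 handled by the caller (n >= k assumed)."""
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def _choose_ratio(n: np.ndarray, t: int, total: int) -> np.ndarray:
    """C(n, t) / C(total, t) with zero where n < t, numerically stable."""
    n = np.asarray(n, dtype=float)
    out = np.zeros_like(n)
    ok = n >= t
    if ok.any():
        out[ok] = np.exp(_log_choose(n[ok], t) - _log_choose(total, t))
    return out


def rarefied_richness(freqs: IncidenceFrequencies, t: int) -> float:
    """Expected richness in t of the T sampling units (interpolation)."""
    if not 1 <= t <= freqs.T:
        raise ValueError("t must be in [1, T]")
    return float(freqs.S_obs - _choose_ratio(freqs.T - freqs.y, t, freqs.T).sum())


def chao2_richness(freqs: IncidenceFrequencies) -> float:
    """Chao2 asymptotic richness (bias-corrected fallback when Q2 = 0)."""
    Q1, Q2, T = freqs.Q(1), freqs.Q(2), freqs.T
    if Q2 > 0:
        extra = (T - 1) / T * Q1**2 / (2 * Q2)
    else:
        extra = (T - 1) / T * Q1 * (Q1 - 1) / 2
    return float(freqs.S_obs + extra)


def _extrapolated_richness(freqs: IncidenceFrequencies, t_star: int) -> float:
    Q0_hat = chao2_richness(freqs) - freqs.S_obs
    Q1 = freqs.Q(1)
    if Q0_hat <= 0 or Q1 == 0:
        return float(freqs.S_obs)
    return float(
        freqs.S_obs + Q0_hat * (1.0 - (1.0 - Q1 / (Q1 + freqs.T * Q0_hat)) ** t_star)
    )


def expected_frequency_spectrum(freqs: IncidenceFrequencies, t: int) -> np.ndarray:
    """E[Q_k(t)] for k = 1..t under subsampling t of T units without replacement.

    Entry ``k-1`` is the expected number of compounds with incidence exactly
    k in a random subsample of t sampling units (hypergeometric).
    """
    if not 1 <= t <= freqs.T:
        raise ValueError("t must be in [1, T]")
    T, y = freqs.T, freqs.y
    ks = np.arange(1, t + 1)
    log_ct = _log_choose(T, t)
    spectrum = np.zeros(t)
    for idx, k in enumerate(ks):
        ok = (y >= k) & (T - y >= t - k)
        if ok.any():
            terms = _log_choose(y[ok], k) + _log_choose(T - y[ok], t - k) - log_ct
            spectrum[idx] = np.exp(terms).sum()
    return spectrum


def coverage_at(freqs: IncidenceFrequencies, t: int) -> float:
    """Estimated sample coverage of a t-unit sample (interp/extrapolation)."""
    T, U, y = freqs.T, freqs.U, freqs.y
    if t < 1:
        raise ValueError("t must be >= 1")
    if t < T:
        ok = T - y >= t
        s = 0.0
        if ok.any():
            terms = np.log(y[ok] / U) + _log_choose(T - y[ok], t) - _log_choose(T - 1, t)
            s = np.exp(terms).sum()
        return float(1.0 - s)
    if t == T:
        return sample_coverage(freqs)
    Q1, Q2 = freqs.Q(1), freqs.Q(2)
    if Q1 == 0:
        return 1.0
    A = (T - 1) * Q1 / ((T - 1) * Q1 + 2 * Q2)
    return float(1.0 - (Q1 / U) * A ** (t - T + 1))


def hill_at(freqs: IncidenceFrequencies, t: int) -> tuple[float, float, float]:
    """Hill numbers (q0, q1, q2) of a t-unit sample.

    For t <= T the expected rarefied frequency spectrum is plugged into the
    Hill formulas; for t > T richness is extrapolated (Chao2-based) while
    q1/q2 are held at their observed, near-asymptotic values.
    """
    if t >= freqs.T:
        q0 = (
            float(freqs.S_obs) if t == freqs.T else _extrapolated_richness(freqs, t - freqs.T)
        )
        return q0, hill_numbers(freqs, 1), hill_numbers(freqs, 2)
    spectrum = expected_frequency_spectrum(freqs, t)
    ks = np.arange(1, t + 1, dtype=float)
    U_t = float((ks * spectrum).sum())
    q0 = float(spectrum.sum())
    p = ks / U_t
    nz = spectrum > 0
    q1 = float(np.exp(-np.sum(spectrum[nz] * p[nz] * np.log(p[nz]))))
    q2 = float(1.0 / np.sum(spectrum * p**2))
    return q0, q1, q2


def _coverage_target_t(freqs: IncidenceFrequencies, target: float) -> tuple[float, bool]:
    """Real-valued t at which estimated coverage reaches ``target``.

    Linear interpolation between integer-t coverages; returns (t, capped)
    where ``capped`` flags families whose coverage never reaches the target
    within the 2T extrapolation bound.
    """
    t_max = 2 * freqs.T
    prev_c = coverage_at(freqs, 1)
    if prev_c >= target:
        return 1.0, False
    for t in range(2, t_max + 1):
        c = coverage_at(freqs, t)
        if c >= target:
            if c == prev_c:
                return float(t), False
            frac = (target - prev_c) / (c - prev_c)
            return (t - 1) + float(frac), False
        prev_c = c
    return float(t_max), True


def coverage_rarefy(
    incidence_by_family: dict[str, "np.ndarray | pd.DataFrame"],
    target_coverage: float = 0.95,
) -> pd.DataFrame:
    """Coverage-standardized Hill profiles per family.

    ``incidence_by_family`` maps family name to its binary species x
    compound matrix.  Each family's diversity is reported at the number of
    sampling units (possibly fractional, interpolated between integers)
    whose estimated coverage equals ``target_coverage``.
    """
    if not 0 < target_coverage <= 1:
        raise ValueError("target_coverage must be in (0, 1]")
    rows = []
    for family, inc in incidence_by_family.items():
        freqs = IncidenceFrequencies.from_incidence(inc)
        if freqs.T < 2:
            raise ValueError(f"family {family!r} has fewer than 2 sampling units")
        t_star, capped = _coverage_target_t(freqs, target_coverage)
        lo, hi = int(np.floor(t_star)), int(np.ceil(t_star))
        h_lo = hill_at(freqs, lo)
        h_hi = hill_at(freqs, hi) if hi != lo else h_lo
        frac = t_star - lo
        q0, q1, q2 = (a + frac * (b - a) for a, b in zip(h_lo, h_hi))
        rows.append(
            {
                "family": family,
                "q0": q0,
                "q1": q1,
                "q2": q2,
                "evenness": q1 / q0,
                "coverage_observed": sample_coverage(freqs),
                "t_at_target": t_star,
                "T": freqs.T,
                "extrapolated": t_star > freqs.T,
                "coverage_capped": capped,
            }
        )
    return pd.DataFrame(rows)


def plasticity_index(class_counts: pd.DataFrame) -> tuple[pd.DataFrame, float, float]:
    """Biosynthetic plasticity: Shannon diversity of chemical classes.

    For each family (row of the family x class count matrix), H' =
    -sum p_c ln p_c over its class proportions.  Also returns log10 compound
    richness per family and the Pearson correlation (r, p) between
    plasticity and log-richness across families.  Families with no
    classified compounds are excluded.
    """
    counts = class_counts.loc[class_counts.sum(axis=1) > 0]
    if counts.empty:
        raise ValueError("no classified compounds in any family")
    p = counts.div(counts.sum(axis=1), axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    h = -plogp.sum(axis=1)
    out = pd.DataFrame(
        {
            "family": counts.index,
            "plasticity": h,
            "richness": counts.sum(axis=1).astype(int),
            "log10_richness": np.log10(counts.sum(axis=1)),
        }
    ).reset_index(drop=True)
    if len(out) >= 3 and out["plasticity"].nunique() > 1:
        r, pval = pearsonr(out["log10_richness"], out["plasticity"])
    else:
        r, pval = float("nan"), float("nan")
    return out, float(r), float(pval)
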