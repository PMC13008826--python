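"""Pairwise beta-diversity partitioning into turnover and nestedness.

Given the incidence components of one pair of units — a shared compounds,
b exclusive to the first and c exclusive to the second — total pairwise
dissimilarity decomposes additively (Baselga's framework):

Jaccard family::

    beta_jac = (b + c) / (a + b + c)
    beta_jtu = 2 min(b, c) / (a + 2 min(b, c))    # turnover (replacement)
    beta_jne = beta_jac - beta_jtu                # nestedness-resultant

Sorensen family::

    beta_sor = (b + c) / (2a + b + c)
    beta_sim = min(b, c) / (a + min(b, c))
    beta_sne = beta_sor - beta_sim

The *turnover ratio* beta_jtu / beta_jac measures the share of total
dissimilarity due to compound replacement; 1 for disjoint pairs, 0 for
perfectly nested pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import kruskal

__all__ = [
    "PairCounts",
    "BetaPartition",
    "pair_counts",
    "jaccard_partition",
    "sorensen_partition",
    "partition",
    "pairwise_family_partitions",
    "turnover_summary",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PairCounts:
    a: int  # shared
    b: int  # exclusive to first unit
    c: int  # exclusive to second unit

    def __post_init__(self):
        if min(self.a, self.b, self.c) < 0:
            raise ValueError("a, b, c must be >= 0")
        if self.a + self.b + self.c < 1:
            raise ValueError("a + b + c must be >= 1")


@dataclass(frozen=True)
class BetaPartition:
    beta_jac: float
    beta_jtu: float
    beta_jne: float
    beta_sor: float
    beta_sim: float
    beta_sne: float

    @property
    def turnover_ratio(self) -> float:
        """Share of Jaccard dissimilarity due to turnover (NaN when beta_jac = 0)."""
        if self.beta_jac == 0:
            return float("nan")
        return self.beta_jtu / self.beta_jac


def pair_counts(set_a: Iterable, set_b: Iterable) -> PairCounts:
    """Incidence components of a pair of compound sets."""
    A, B = set(set_a), set(set_b)
    if not A and not B:
        raise ValueError("both sets are empty")
    return PairCounts(a=len(A & B), b=len(A - B), c=len(B - A))


def jaccard_partition(counts: PairCounts) -> tuple[float, float, float]:
    """(beta_jac, beta_jtu, beta_jne) of one pair."""
    a, b, c = counts.a, counts.b, counts.c
    total = a + b + c
    beta_jac = (b + c) / total
    m = min(b, c)
    beta_jtu = 2 * m / (a + 2 * m) if m > 0 else 0.0
    return beta_jac, beta_jtu, beta_jac - beta_jtu


def sorensen_partition(counts: PairCounts) -> tuple[float, float, float]:
    """(beta_sor, beta_sim, beta_sne) of one pair."""
    a, b, c = counts.a, counts.b, counts.c
    beta_sor = (b + c) / (2 * a + b + c)
    m = min(b, c)
    beta_sim = m / (a + m) if m > 0 else 0.0
    return beta_sor, beta_sim, beta_sor - beta_sim


def partition(counts: PairCounts) -> BetaPartition:
    """Full Jaccard + Sorensen partition of one pair."""
    jac, jtu, jne = jaccard_partition(counts)
    sor, sim, sne = sorensen_partition(counts)
    return BetaPartition(jac, jtu, jne, sor, sim, sne)


def pairwise_family_partitions(core) -> pd.DataFrame:
    """Beta partition for every unordered pair of family-pooled compound sets.

    ``core`` is a :class:`~phylochem.core_filter.ChemicalCore` (or anything
    exposing ``family_compound_sets()``).  Families whose core set is empty
    are excluded with a warning.
    """
    sets = {f: s for f, s in core.family_compound_sets().items() if len(s) > 0}
    dropped = set(core.family_compound_sets()) - set(sets)
    if dropped:
        logger.warning("families with empty core sets excluded from pairs: %s",
                       sorted(dropped))
    if len(sets) < 2:
        raise ValueError("need at least 2 families with nonempty compound sets")
    rows = []
    for fam_i, fam_j in combinations(sorted(sets), 2):
        pc = pair_counts(sets[fam_i], sets[fam_j])
        bp = partition(pc)
        rows.append(
            {
                "family_i": fam_i, "family_j": fam_j,
                "a": pc.a, "b": pc.b, "c": pc.c,
                "beta_jac": bp.beta_jac, "beta_jtu": bp.beta_jtu, "beta_jne": bp.beta_jne,
                "beta_sor": bp.beta_sor, "beta_sim": bp.beta_sim, "beta_sne": bp.beta_sne,
                "turnover_ratio": bp.turnover_ratio,
            }
        )
    return pd.DataFrame(rows)


def _pair_group(clade_i: str, clade_j: str) -> str:
    return f"within-{clade_i}" if clade_i == clade_j else "between-clade"


def turnover_summary(
    partitions: pd.DataFrame,
    clade_map: Mapping[str, str] | None = None,
    n_bins: int = 20,
) -> dict:
    """Summary statistics of the turnover share across family pairs.

    Reports mean/median of the turnover ratio and of beta_jtu; groups pairs
    as within-clade (per clade) or between-clade; runs a tie-corrected
    Kruskal-Wallis test across the within-clade groups (groups with fewer
    than 2 pairs are dropped with a warning); and bins the turnover ratio
    into a histogram.
    """
    if len(partitions) < 2:
        raise ValueError("need at least 2 pairs")
    ratio = partitions["turnover_ratio"].dropna()
    out: dict = {
        "mean_turnover_ratio": float(ratio.mean()),
        "median_turnover_ratio": float(ratio.median()),
        "mean_beta_jtu": float(partitions["beta_jtu"].mean()),
        "median_beta_jtu": float(partitions["beta_jtu"].median()),
        "n_pairs": int(len(partitions)),
    }
    counts, edges = np.histogram(ratio, bins=n_bins, range=(0.0, 1.0))
    out["turnover_ratio_histogram"] = {
        "bin_edges": edges.tolist(), "counts": counts.tolist()
    }
    if clade_map:
        groups = [
            _pair_group(clade_map[r.family_i], clade_map[r.family_j])
            for r in partitions.itertuples()
        ]
        parts = partitions.assign(pair_group=groups)
        out["group_means"] = (
            parts.groupby("pair_group")["turnover_ratio"].mean().to_dict()
        )
        within = parts[parts["pair_group"] != "between-clade"]
        samples, labels = [], []
        for grp, sub in within.groupby("pair_group"):
            if len(sub) < 2:
                logger.warning("group %s has < 2 pairs; dropped from the test", grp)
                continue
            samples.append(sub["turnover_ratio"].to_numpy())
            labels.append(grp)
        if len(samples) >= 2:
            try:
                H, p = kruskal(*samples)
            except ValueError:  # all values identical across groups
                H, p = 0.0, 1.0
            out["kruskal_wallis"] = {"H": float(H), "p_value": float(p),
                                     "groups": labels}
        out["pair_groups"] = parts["pair_group"].tolist()
    return out
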