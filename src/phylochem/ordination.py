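"""Species-level ordination and permutation statistics.

Species x compound incidence matrices (standardized to at most ``n_max``
species per family by uniform subsampling) feed Jaccard distance matrices,
principal coordinates analysis (Gower double-centering, negative
eigenvalues reported rather than corrected), PERMANOVA with free
whole-label permutations, and multivariate dispersion (distance to group
centroid in the full PCoA embedding, with the standard real/imaginary
split for non-Euclidean distances).

Monte-Carlo p-values use the plus-one rule and are therefore never zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .core_filter import ChemicalCore

__all__ = [
    "DistanceMatrix",
    "PcoaResult",
    "PermanovaResult",
    "DispersionResult",
    "subsample_species",
    "jaccard_distance_matrix",
    "pcoa",
    "permanova",
    "betadisper",
    "dispersion_stability",
]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric nonnegative distance matrix with unit labels."""

    data: np.ndarray
    ids: tuple[str, ...]
    metric: str = "jaccard"

    def __post_init__(self):
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(d) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(d < 0):
            raise ValueError("distances must be nonnegative")
        object.__setattr__(self, "data", d)
        object.__setattr__(self, "ids", tuple(self.ids))

    @property
    def n(self) -> int:
        return self.data.shape[0]


@dataclass(frozen=True)
class PcoaResult:
    coordinates: np.ndarray      # n x n_pos, scaled by sqrt(eigenvalue)
    eigenvalues: np.ndarray      # all n, descending (negatives reported)
    neg_coordinates: np.ndarray  # axes with negative eigenvalues, |lambda|-scaled
    ids: tuple[str, ...]


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_F: float
    R2: float
    p_value: float
    n_perm: int
    seed: int


@dataclass(frozen=True)
class DispersionResult:
    distances: pd.Series         # per-unit distance to its group centroid
    group_means: pd.Series
    F: float
    p_value: float
    n_perm: int
    seed: int


def subsample_species(
    core: ChemicalCore, n_max: int = 200, seed: int = 0
) -> ChemicalCore:
    """Standardize sampling depth: at most ``n_max`` species per family.

    Families above the cap get a uniform random sample without replacement;
    families at or below it are kept whole (no upsampling).
    """
    if n_max < 2:
        raise ValueError("n_max must be >= 2")
    rng = np.random.default_rng(seed)
    keep: list[str] = []
    for fam in core.families:
        species = sorted(core.records.loc[core.records["family"] == fam, "species"].unique())
        if len(species) > n_max:
            idx = rng.choice(len(species), size=n_max, replace=False)
            species = [species[i] for i in sorted(idx)]
        keep.extend(species)
    sub = core.records[core.records["species"].isin(set(keep))]
    return ChemicalCore.from_records(sub)


def jaccard_distance_matrix(incidence: pd.DataFrame) -> DistanceMatrix:
    """Pairwise Jaccard dissimilarity between rows of a binary matrix."""
    mat = (np.asarray(incidence, dtype=float) > 0)
    row_sums = mat.sum(axis=1)
    if np.any(row_sums == 0):
        empty = [str(incidence.index[i]) for i in np.flatnonzero(row_sums == 0)]
        raise ValueError(f"units with no compounds: {empty[:5]}")
    d = squareform(pdist(mat, metric="jaccard"))
    ids = tuple(str(i) for i in incidence.index)
    return DistanceMatrix(data=d, ids=ids, metric="jaccard")


def pcoa(D: DistanceMatrix) -> PcoaResult:
    """Principal coordinates analysis by Gower double-centering.

    B = -1/2 J D^2 J is eigendecomposed; coordinates on axes with positive
    eigenvalues are scaled by sqrt(lambda).  Negative eigenvalues (possible
    for non-Euclidean dissimilarities like Jaccard) are reported and their
    axes returned separately (|lambda|-scaled) for dispersion corrections.
    """
    n = D.n
    if n < 3:
        raise ValueError("need at least 3 units for PCoA")
    d2 = D.data**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ d2 @ J
    eigval, eigvec = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    pos = eigval > 1e-10
    neg = eigval < -1e-10
    coords = eigvec[:, pos] * np.sqrt(eigval[pos])
    neg_coords = eigvec[:, neg] * np.sqrt(-eigval[neg])
    return PcoaResult(coordinates=coords, eigenvalues=eigval,
                      neg_coordinates=neg_coords, ids=D.ids)


def _group_indices(groups) -> tuple[np.ndarray, list]:
    labels = pd.Series(list(groups))
    uniq = sorted(labels.unique())
    codes = labels.map({g: i for i, g in enumerate(uniq)}).to_numpy()
    return codes, uniq


def _permanova_F(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> tuple[float, float]:
    n = d2.shape[0]
    ss_t = d2[np.triu_indices(n, 1)].sum() / n
    ss_w = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        sub = d2[np.ix_(idx, idx)]
        ss_w += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ss_a = ss_t - ss_w
    if ss_w == 0:  # perfect within-group coincidence
        return (np.inf if ss_a > 0 else 0.0), (ss_a / ss_t if ss_t > 0 else 0.0)
    F = (ss_a / (n_groups - 1)) / (ss_w / (n - n_groups))
    return F, ss_a / ss_t


def permanova(
    D: DistanceMatrix, groups, n_perm: int = 999, seed: int = 0
) -> PermanovaResult:
    """One-factor PERMANOVA on a distance matrix.

    SS_total = (1/N) sum_{i<j} d_ij^2, SS_within pools the per-group
    analogues, and significance comes from free permutation of the group
    labels (plus-one rule).
    """
    codes, uniq = _group_indices(groups)
    if len(codes) != D.n:
        raise ValueError("groups length must match distance matrix size")
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    counts = np.bincount(codes)
    if counts.min() < 2:
        raise ValueError("every group needs at least 2 units")
    d2 = D.data**2
    F_obs, R2 = _permanova_F(d2, codes, len(uniq))
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        F_perm, _ = _permanova_F(d2, perm, len(uniq))
        if F_perm >= F_obs:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return PermanovaResult(pseudo_F=float(F_obs), R2=float(R2), p_value=float(p),
                           n_perm=n_perm, seed=seed)


def _dispersion_distances(D: DistanceMatrix, codes: np.ndarray) -> np.ndarray:
    """Distance of each unit to its group centroid in the PCoA embedding.

    Squared distances on negative-eigenvalue ("imaginary") axes subtract
    from those on positive axes; the result is floored at zero before the
    square root (standard treatment for non-Euclidean dissimilarities).
    """
    res = pcoa(D)
    pos, neg = res.coordinates, res.neg_coordinates
    n = D.n
    d2 = np.zeros(n)
    for g in np.unique(codes):
        idx = np.flatnonzero(codes == g)
        c_pos = pos[idx].mean(axis=0)
        real = ((pos[idx] - c_pos) ** 2).sum(axis=1)
        imag = np.zeros(len(idx))
        if neg.shape[1]:
            c_neg = neg[idx].mean(axis=0)
            imag = ((neg[idx] - c_neg) ** 2).sum(axis=1)
        d2[idx] = np.maximum(real - imag, 0.0)
    return np.sqrt(d2)


def _anova_F(values: np.ndarray, codes: np.ndarray) -> float:
    grand = values.mean()
    ss_b = ss_w = 0.0
    n_groups = 0
    for g in np.unique(codes):
        sub = values[codes == g]
        ss_b += len(sub) * (sub.mean() - grand) ** 2
        ss_w += ((sub - sub.mean()) ** 2).sum()
        n_groups += 1
    df_b, df_w = n_groups - 1, len(values) - n_groups
    if ss_w == 0:
        return np.inf if ss_b > 0 else 0.0
    return (ss_b / df_b) / (ss_w / df_w)


def betadisper(
    D: DistanceMatrix, groups, n_perm: int = 999, seed: int = 0
) -> DispersionResult:
    """Multivariate dispersion: distance to group centroid + permutation F."""
    codes, uniq = _group_indices(groups)
    if len(codes) != D.n:
        raise ValueError("groups length must match distance matrix size")
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    if np.bincount(codes).min() < 2:
        raise ValueError("every group needs at least 2 units")
    dist = _dispersion_distances(D, codes)
    F_obs = _anova_F(dist, codes)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        F_perm = _anova_F(dist, rng.permutation(codes))
        if F_perm >= F_obs:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    labels = pd.Series(list(groups))
    series = pd.Series(dist, index=list(D.ids), name="dist_to_centroid")
    means = series.groupby(labels.to_numpy()).mean()
    return DispersionResult(distances=series, group_means=means, F=float(F_obs),
                            p_value=float(p), n_perm=n_perm, seed=seed)


def dispersion_stability(
    core: ChemicalCore,
    n_grid=(20, 50, 100, 200, 500, 1000),
    reps: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Stability of per-family dispersion under species subsampling.

    For each subsample cap n and each replicate, species are subsampled per
    family (capped at family size), distances recomputed and per-family mean
    dispersion recorded; output is the mean +- sd across replicates per n.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for n in n_grid:
        for rep in range(reps):
            sub = subsample_species(core, n_max=max(int(n), 2),
                                    seed=int(rng.integers(2**31)))
            inc = sub.species_incidence()
            fam_of = sub.records.drop_duplicates("species").set_index("species")["family"]
            groups = [fam_of[sp] for sp in inc.index]
            D = jaccard_distance_matrix(inc)
            disp = betadisper(D, groups, n_perm=0 + 1, seed=0)
            for fam, val in disp.group_means.items():
                rows.append({"n": int(n), "rep": rep, "family": fam,
                             "dispersion": float(val)})
    table = pd.DataFrame(rows)
    summary = (
        table.groupby(["family", "n"])["dispersion"]
        .agg(["mean", "std"])
        .reset_index()
        .rename(columns={"mean": "dispersion_mean", "std": "dispersion_sd"})
    )
    return summary
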