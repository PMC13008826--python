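"""Chemotaxonomic drivers, network structure and phylogenetic signal.

* Chemical-class profile matrices (family- or species-level compound counts
  per class) with Hellinger / z-score / log1p transforms.
* Ward (ward.D2) clustering of transformed class profiles with ordinary
  bootstrap support over resampled class columns.
* Random-forest classification of clades from species-level profiles with
  permutation ("mean decrease accuracy"-style) variable importance, and the
  per-family share of top-driver chemistry.
* Bipartite family x class metrics on the log1p matrix: the H2'
  specialization index (two-dimensional Shannon entropy standardized by its
  margin-constrained extrema) and Barber's bipartite modularity Q via a
  seeded greedy label-move optimizer with restarts.
* A phenetic UPGMA tree from chemical distances, and Blomberg's K with a
  tip-permutation test for phylogenetic signal of biosynthetic traits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage

from .ordination import DistanceMatrix

__all__ = [
    "class_profile_matrix",
    "hellinger",
    "WardResult",
    "ward_cluster",
    "RfDriverResult",
    "rf_drivers",
    "BipartiteMetrics",
    "bipartite_metrics",
    "upgma_tree",
    "PhyloSignalResult",
    "blomberg_k",
    "tree_covariance",
    "simulate_brownian",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# class profiles and transforms
# ---------------------------------------------------------------------------

def class_profile_matrix(
    core, level: str = "family", class_col: str = "class",
    include_unclassified: bool = False,
) -> pd.DataFrame:
    """Counts of core compounds per unit (family/species) per chemical class.

    Compounds lacking a class label are pooled into an ``unclassified``
    column, which is dropped unless ``include_unclassified``.
    """
    rec = core.records.copy()
    if class_col not in rec.columns:
        raise ValueError(f"core has no class column {class_col!r}")
    unit = "family" if level == "family" else "species"
    rec[class_col] = rec[class_col].replace("", np.nan).fillna("unclassified")
    rec = rec.drop_duplicates([unit, "inchikey"])
    mat = pd.crosstab(rec[unit], rec[class_col])
    if not include_unclassified and "unclassified" in mat.columns:
        mat = mat.drop(columns="unclassified")
    if mat.to_numpy().sum() == 0:
        raise ValueError("no classified compounds")
    return mat


def hellinger(matrix: pd.DataFrame) -> pd.DataFrame:
    """Row-wise Hellinger transform: sqrt(x_ij / row_sum_i)."""
    arr = np.asarray(matrix, dtype=float)
    if (arr < 0).any():
        raise ValueError("negative entries")
    sums = arr.sum(axis=1)
    if (sums == 0).any():
        zero = [str(matrix.index[i]) for i in np.flatnonzero(sums == 0)]
        raise ValueError(f"all-zero rows: {zero}")
    out = np.sqrt(arr / sums[:, None])
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


# ---------------------------------------------------------------------------
# Ward clustering with bootstrap support
# ---------------------------------------------------------------------------

@dataclass
class WardResult:
    linkage: np.ndarray
    labels: tuple[str, ...]
    support: dict[frozenset, float]   # bipartition (leaf set) -> bootstrap frequency
    newick: str


def _linkage_bipartitions(Z: np.ndarray, labels) -> list[frozenset]:
    n = len(labels)
    members: dict[int, frozenset] = {i: frozenset([labels[i]]) for i in range(n)}
    parts = []
    for k, (i, j, _, _) in enumerate(Z[:, :4]):
        merged = members[int(i)] | members[int(j)]
        members[n + k] = merged
        parts.append(merged)
    return parts


def _linkage_to_newick(Z: np.ndarray, labels, height_scale: float = 1.0) -> str:
    """Newick string with ultrametric branch lengths (node height = h * scale)."""
    n = len(labels)
    height = {i: 0.0 for i in range(n)}
    node: dict[int, str] = {i: str(labels[i]).replace(" ", "_") for i in range(n)}
    for k, (i, j, h, _) in enumerate(Z[:, :4]):
        i, j = int(i), int(j)
        h = float(h) * height_scale
        bi = h - height[i]
        bj = h - height[j]
        node[n + k] = f"({node[i]}:{bi:.10g},{node[j]}:{bj:.10g})"
        height[n + k] = h
    return node[2 * n - 2] + ";"


def ward_cluster(
    matrix: pd.DataFrame, bootstrap_n: int = 1000, seed: int = 0
) -> WardResult:
    """Ward.D2 dendrogram of class profiles with bootstrap branch support.

    The raw count matrix is Hellinger-transformed then column z-scored;
    constant columns after the transform are dropped with a warning.
    Support is the fraction of column-resampled bootstrap replicates in
    which each original bipartition recurs (ordinary bootstrap probability).
    """
    if len(matrix) < 3:
        raise ValueError("need at least 3 rows to cluster")
    hel = hellinger(matrix)
    sd = hel.std(ddof=1)
    keep = sd > 0
    if (~keep).any():
        logger.warning("constant columns dropped before clustering: %s",
                       list(hel.columns[~keep]))
    hel = hel.loc[:, keep]
    z = (hel - hel.mean()) / hel.std(ddof=1)
    X = z.to_numpy()
    Z = linkage(X, method="ward")
    labels = tuple(str(i) for i in matrix.index)
    original = _linkage_bipartitions(Z, labels)
    counts = {p: 0 for p in original}
    rng = np.random.default_rng(seed)
    for _ in range(bootstrap_n):
        cols = rng.integers(0, X.shape[1], size=X.shape[1])
        Zb = linkage(X[:, cols], method="ward")
        found = set(_linkage_bipartitions(Zb, labels))
        for p in counts:
            if p in found:
                counts[p] += 1
    support = {p: c / bootstrap_n for p, c in counts.items()} if bootstrap_n else {}
    return WardResult(linkage=Z, labels=labels, support=support,
                      newick=_linkage_to_newick(Z, labels, height_scale=0.5))


# ---------------------------------------------------------------------------
# random-forest drivers
# ---------------------------------------------------------------------------

@dataclass
class RfDriverResult:
    importance: pd.DataFrame        # class, importance, importance_sd, rank
    oob_accuracy: float
    family_shares: pd.DataFrame | None
    top_k: int
    seed: int


def rf_drivers(
    species_profiles: pd.DataFrame,
    clade_labels,
    n_trees: int = 2000,
    seed: int = 0,
    top_k: int = 25,
    family_class_counts: pd.DataFrame | None = None,
    n_repeats: int = 5,
) -> RfDriverResult:
    """Random-forest clade classification and chemical-class importance.

    A forest of ``n_trees`` is trained on species-level class-count
    profiles to predict clade membership; variable importance is
    permutation-based (accuracy decrease averaged over ``n_repeats``
    shuffles), the mean-decrease-accuracy analogue.  If a family x class
    count matrix is supplied, each family's share of diagnostic chemistry
    is its class counts restricted to the top ``top_k`` drivers, normalized
    to 100% per family.
    """
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.inspection import permutation_importance

    y = pd.Series(list(clade_labels))
    if y.nunique() < 2:
        raise ValueError("need at least 2 clades")
    if y.value_counts().min() < 10:
        raise ValueError("need at least 10 species per clade")
    X = species_profiles.to_numpy(dtype=float)
    model = RandomForestClassifier(
        n_estimators=n_trees, oob_score=True, random_state=seed, n_jobs=1
    )
    model.fit(X, y.to_numpy())
    perm = permutation_importance(
        model, X, y.to_numpy(), n_repeats=n_repeats, random_state=seed, n_jobs=1
    )
    importance = (
        pd.DataFrame(
            {
                "class": species_profiles.columns,
                "importance": perm.importances_mean,
                "importance_sd": perm.importances_std,
            }
        )
        .sort_values("importance", ascending=False, kind="mergesort")
        .reset_index(drop=True)
    )
    importance["rank"] = np.arange(1, len(importance) + 1)

    shares = None
    if family_class_counts is not None:
        top = list(importance["class"].head(top_k))
        sub = family_class_counts.reindex(columns=top, fill_value=0).astype(float)
        totals = sub.sum(axis=1)
        shares = sub.div(totals.where(totals > 0), axis=0) * 100.0
    return RfDriverResult(importance=importance, oob_accuracy=float(model.oob_score_),
                          family_shares=shares, top_k=top_k, seed=seed)


# ---------------------------------------------------------------------------
# bipartite specialization and modularity
# ---------------------------------------------------------------------------

@dataclass
class BipartiteMetrics:
    H2_prime: float
    H2: float
    H2_max: float
    H2_min: float
    Q: float
    row_modules: dict[str, int]
    col_modules: dict[str, int]
    seed: int
    restarts: int


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def _h2_min(row_m: np.ndarray, col_m: np.ndarray) -> float:
    """Minimum entropy under fixed margins by greedy mass concentration."""
    r, c = row_m.copy(), col_m.copy()
    h = 0.0
    while r.sum() > 1e-12 and c.sum() > 1e-12:
        i, j = int(np.argmax(r)), int(np.argmax(c))
        m = min(r[i], c[j])
        if m <= 0:
            break
        h -= m * np.log(m)
        r[i] -= m
        c[j] -= m
    return h


def _barber_Q(A: np.ndarray, row_lab: np.ndarray, col_lab: np.ndarray) -> float:
    m = A.sum()
    k = A.sum(axis=1)
    d = A.sum(axis=0)
    q = 0.0
    for mod in np.unique(np.concatenate([row_lab, col_lab])):
        ri = row_lab == mod
        cj = col_lab == mod
        q += A[np.ix_(ri, cj)].sum() - k[ri].sum() * d[cj].sum() / m
    return float(q / m)


def _greedy_modules(A: np.ndarray, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, float]:
    n_r, n_c = A.shape
    n_mod = max(2, min(n_r, n_c))
    row_lab = rng.integers(0, n_mod, size=n_r)
    col_lab = rng.integers(0, n_mod, size=n_c)
    best = _barber_Q(A, row_lab, col_lab)
    improved = True
    while improved:
        improved = False
        for side, lab in (("row", row_lab), ("col", col_lab)):
            n_nodes = n_r if side == "row" else n_c
            for i in rng.permutation(n_nodes):
                current = lab[i]
                for mod in range(n_mod):
                    if mod == current:
                        continue
                    lab[i] = mod
                    q = _barber_Q(A, row_lab, col_lab)
                    if q > best + 1e-12:
                        best = q
                        current = mod
                        improved = True
                    else:
                        lab[i] = current
    return row_lab, col_lab, best


def bipartite_metrics(
    family_class_counts: pd.DataFrame, seed: int = 0, restarts: int = 20
) -> BipartiteMetrics:
    """H2' specialization and Barber modularity of the family x class network.

    The count matrix is log1p-transformed.  H2 is the two-dimensional
    Shannon entropy of the normalized matrix; H2max is the entropy of the
    margin-product (independence) table and H2min the greedy
    margin-concentrating minimum, so H2' = (H2max - H2)/(H2max - H2min) is
    0 for margin-independent matrices and 1 at maximal specialization.  Q
    is maximized by greedy label moves from ``restarts`` random starts (the
    single-module partition, Q = 0, is always a candidate).
    """
    A = np.log1p(np.asarray(family_class_counts, dtype=float))
    if A.sum() <= 0:
        raise ValueError("zero interaction matrix")
    if A.shape[0] < 2 or A.shape[1] < 2:
        raise ValueError("need at least 2 rows and 2 columns")
    P = A / A.sum()
    h2 = _entropy(P.ravel())
    row_m, col_m = P.sum(axis=1), P.sum(axis=0)
    h2_max = _entropy(row_m) + _entropy(col_m)
    h2_min = _h2_min(row_m, col_m)
    if h2_max - h2_min > 1e-12:
        h2_prime = (h2_max - h2) / (h2_max - h2_min)
    else:
        h2_prime = 0.0
    h2_prime = float(np.clip(h2_prime, 0.0, 1.0))

    rng = np.random.default_rng(seed)
    best_q = 0.0  # single-module baseline
    best_rows = np.zeros(A.shape[0], dtype=int)
    best_cols = np.zeros(A.shape[1], dtype=int)
    for _ in range(restarts):
        rows, cols, q = _greedy_modules(A, rng)
        if q > best_q:
            best_q, best_rows, best_cols = q, rows.copy(), cols.copy()
    return BipartiteMetrics(
        H2_prime=h2_prime, H2=h2, H2_max=h2_max, H2_min=h2_min, Q=float(best_q),
        row_modules={str(r): int(m) for r, m in zip(family_class_counts.index, best_rows)},
        col_modules={str(c): int(m) for c, m in zip(family_class_counts.columns, best_cols)},
        seed=seed, restarts=restarts,
    )


# ---------------------------------------------------------------------------
# UPGMA tree and Blomberg's K
# ---------------------------------------------------------------------------

def upgma_tree(D: DistanceMatrix) -> str:
    """UPGMA phenetic tree (newick, ultrametric) from a distance matrix."""
    if D.n < 3:
        raise ValueError("need at least 3 taxa")
    if np.isnan(D.data).any():
        raise ValueError("NaN distances")
    from scipy.spatial.distance import squareform

    Z = linkage(squareform(D.data, checks=False), method="average")
    return _linkage_to_newick(Z, D.ids, height_scale=0.5)


@dataclass
class PhyloSignalResult:
    K: float
    p_value: float
    tree: str
    trait: str
    n_perm: int
    seed: int


def tree_covariance(tree) -> tuple[np.ndarray, list[str]]:
    """Shared-path (Brownian) covariance matrix of a tree's tips.

    ``tree`` is a newick string or a dendropy Tree.  V_ij is the root-to-MRCA
    path length for tips i, j; V_ii the root-to-tip distance.
    """
    import dendropy

    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    root_dist = {}
    for leaf in tree.leaf_node_iter():
        root_dist[leaf.taxon] = leaf.distance_from_root()
    n = len(taxa)
    V = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            if i == j:
                V[i, i] = root_dist[taxa[i]]
            else:
                d = pdm.patristic_distance(taxa[i], taxa[j])
                V[i, j] = V[j, i] = 0.5 * (root_dist[taxa[i]] + root_dist[taxa[j]] - d)
    return V, [t.label for t in taxa]


def _k_statistic(x: np.ndarray, Vinv: np.ndarray, expected_ratio: float,
                 ones: np.ndarray) -> float:
    a_hat = float(ones @ Vinv @ x) / float(ones @ Vinv @ ones)
    resid = x - a_hat
    mse0 = float(resid @ resid)
    mse = float(resid @ Vinv @ resid)
    return (mse0 / mse) / expected_ratio


def blomberg_k(
    tree, trait_values, n_perm: int = 999, seed: int = 0, trait_name: str = "trait"
) -> PhyloSignalResult:
    """Blomberg's K with a tip-permutation significance test.

    K compares the observed ratio of trait variance to its
    phylogenetically-corrected (GLS) counterpart against the ratio expected
    under Brownian motion on the tree; K ~ 1 indicates Brownian-like
    signal, K -> 0 no signal.  The p-value is the plus-one-rule proportion
    of tip permutations with K_perm >= K_obs.
    """
    V, labels = tree_covariance(tree) if not isinstance(tree, tuple) else tree
    if isinstance(trait_values, pd.Series):
        x = trait_values.reindex(labels).to_numpy(dtype=float)
    elif isinstance(trait_values, dict):
        x = np.array([trait_values[l] for l in labels], dtype=float)
    else:
        x = np.asarray(trait_values, dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 tips")
    if np.isnan(x).any():
        raise ValueError("missing trait values")
    if np.allclose(x, x[0]):
        raise ValueError("constant trait; K undefined")
    try:
        Vinv = np.linalg.inv(V)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular tree covariance matrix") from exc
    ones = np.ones(n)
    expected = (np.trace(V) - n / float(ones @ Vinv @ ones)) / (n - 1)
    K_obs = _k_statistic(x, Vinv, expected, ones)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        K_perm = _k_statistic(rng.permutation(x), Vinv, expected, ones)
        if K_perm >= K_obs:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    newick = tree if isinstance(tree, str) else ""
    return PhyloSignalResult(K=float(K_obs), p_value=float(p), tree=newick,
                             trait=trait_name, n_perm=n_perm, seed=seed)


def simulate_brownian(V: np.ndarray, n_reps: int, seed: int = 0) -> np.ndarray:
    """Brownian-motion trait replicates on a tree with covariance ``V``."""
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(V + 1e-12 * np.eye(len(V)))
    return (L @ rng.standard_normal((len(V), n_reps))).T
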