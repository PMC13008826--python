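"""Class profiles, Ward clustering, RF drivers, bipartite metrics, K."""

import itertools

import numpy as np
import pandas as pd
import pytest

from phylochem.drivers import (
    _barber_Q,
    bipartite_metrics,
    blomberg_k,
    class_profile_matrix,
    hellinger,
    rf_drivers,
    simulate_brownian,
    tree_covariance,
    upgma_tree,
    ward_cluster,
)
from phylochem.ordination import DistanceMatrix


# ---- profiles and Hellinger ------------------------------------------------

def test_class_profile_counts(small_core):
    core, _, _ = small_core
    fam = class_profile_matrix(core, "family")
    sp = class_profile_matrix(core, "species")
    per_species = core.records.drop_duplicates(["species", "inchikey"]) \
        .groupby("species").size()
    assert (sp.sum(axis=1) == per_species.reindex(sp.index)).all()
    assert set(fam.index) == set(core.families)


def test_planted_allocation_recovered(small_dataset, small_core):
    occ, truth = small_dataset
    # recovery on the compounds drawn from each family's own allocation
    own = occ.drop_duplicates("inchikey")
    own = own[own["inchikey"].map(truth.roles) == "family_core"]
    for family, grp in own.groupby("family"):
        marker = truth.diagnostic_class[family]
        prop = (grp["class"] == marker).mean()
        se = np.sqrt(0.35 * 0.65 / len(grp))
        assert prop == pytest.approx(0.35, abs=3 * se + 0.01)
    # and on the filtered core the planted marker stays the modal class
    core, _, _ = small_core
    fam = class_profile_matrix(core, "family")
    for family, marker in truth.diagnostic_class.items():
        props = fam.loc[family] / fam.loc[family].sum()
        assert props[marker] == props.max()


def test_hellinger_values_and_invariances():
    m = pd.DataFrame([[1.0, 3.0], [2.0, 6.0], [5.0, 0.0]])
    h = hellinger(m)
    np.testing.assert_allclose(h.iloc[0], [0.5, np.sqrt(0.75)], atol=1e-12)
    np.testing.assert_allclose(h.iloc[0], h.iloc[1], atol=1e-12)  # scale invariant
    np.testing.assert_allclose((h**2).sum(axis=1), 1.0, atol=1e-12)
    assert hellinger(pd.DataFrame([[7.0]])).iloc[0, 0] == 1.0
    with pytest.raises(ValueError):
        hellinger(pd.DataFrame([[0.0, 0.0]]))


# ---- Ward clustering -------------------------------------------------------

def _ward_d2_oracle(X):
    """Independent Lance-Williams recursion for Ward.D2 merge heights."""
    from scipy.spatial.distance import pdist, squareform

    d = squareform(pdist(X))
    active = {i: 1 for i in range(len(X))}
    heights = []
    current = {i: i for i in range(len(X))}
    while len(active) > 1:
        items = sorted(active)
        best = None
        for i, j in itertools.combinations(items, 2):
            if best is None or d[i, j] < best[0]:
                best = (d[i, j], i, j)
        h, i, j = best
        heights.append(h)
        ni, nj = active.pop(i), active.pop(j)
        new = max(current.values()) + 1
        d = np.pad(d, ((0, 1), (0, 1)))
        for k in active:
            nk = active[k]
            d[new, k] = d[k, new] = np.sqrt(
                ((ni + nk) * d[i, k] ** 2 + (nj + nk) * d[j, k] ** 2
                 - nk * h ** 2) / (ni + nj + nk)
            )
        active[new] = ni + nj
        current[new] = new
    return heights


def test_ward_heights_match_lance_williams_oracle():
    rng = np.random.default_rng(0)
    counts = pd.DataFrame(rng.integers(1, 30, size=(4, 6)).astype(float))
    res = ward_cluster(counts, bootstrap_n=0, seed=0)
    # replicate the internal transform to drive the independent oracle
    h = hellinger(counts)
    z = (h - h.mean()) / h.std(ddof=1)
    oracle = _ward_d2_oracle(z.to_numpy())
    np.testing.assert_allclose(res.linkage[:, 2], oracle, rtol=1e-10)


def test_ward_identical_rows_merge_first_at_zero():
    counts = pd.DataFrame([[5.0, 5], [5, 5], [1, 20], [20, 1]],
                          index=["a", "a2", "b", "c"])
    res = ward_cluster(counts, bootstrap_n=20, seed=1)
    first = res.linkage[0]
    assert first[2] == pytest.approx(0.0, abs=1e-12)
    assert {int(first[0]), int(first[1])} == {0, 1}
    assert (np.diff(res.linkage[:, 2]) >= -1e-12).all()  # heights nondecreasing
    assert frozenset({"a", "a2"}) in res.support
    assert res.support[frozenset({"a", "a2"})] >= 0.95


def test_ward_collinear_points_merge_nearest():
    # one informative column after transform: rows at 0, 1, 10
    counts = pd.DataFrame([[1.0, 0.0], [0.8, 0.2], [0.1, 0.9]])
    res = ward_cluster(counts, bootstrap_n=0, seed=0)
    assert {int(res.linkage[0, 0]), int(res.linkage[0, 1])} == {0, 1}


# ---- random forest ---------------------------------------------------------

def _profiles(rng, n_per_clade=30):
    rows, labels = [], []
    for clade in ("A", "B", "C"):
        for _ in range(n_per_clade):
            row = {f"noise{k}": rng.poisson(3) for k in range(6)}
            row["diag_A"] = rng.poisson(5) if clade == "A" else 0
            rows.append(row)
            labels.append(clade)
    return pd.DataFrame(rows).fillna(0), labels


def test_clade_exclusive_class_ranks_first():
    rng = np.random.default_rng(0)
    X, y = _profiles(rng)
    res = rf_drivers(X, y, n_trees=300, seed=1)
    assert res.importance.loc[0, "class"] == "diag_A"


def test_shuffled_labels_give_chance_accuracy():
    rng = np.random.default_rng(1)
    X, y = _profiles(rng)
    y_shuffled = list(rng.permutation(y))
    res = rf_drivers(X, y_shuffled, n_trees=300, seed=1)
    assert abs(res.oob_accuracy - 1 / 3) < 0.15


def test_family_shares_normalize_to_100(small_core):
    core, _, _ = small_core
    sp = class_profile_matrix(core, "species")
    fam = class_profile_matrix(core, "family")
    clades = core.records.drop_duplicates("species").set_index("species")["clade"] \
        .reindex(sp.index)
    res = rf_drivers(sp, clades, n_trees=100, seed=1,
                     family_class_counts=fam, top_k=fam.shape[1])
    np.testing.assert_allclose(res.family_shares.sum(axis=1), 100.0, atol=1e-9)


def test_rf_requires_two_clades():
    X = pd.DataFrame(np.ones((20, 3)))
    with pytest.raises(ValueError):
        rf_drivers(X, ["A"] * 20, n_trees=10)


# ---- bipartite metrics -----------------------------------------------------

def test_h2prime_extremes():
    diag = pd.DataFrame(np.eye(4) * 5.0)
    assert bipartite_metrics(diag, seed=0, restarts=5).H2_prime == pytest.approx(1.0, abs=1e-9)
    # independent margins after log1p: counts = expm1(outer product)
    r = np.array([0.2, 0.5, 0.8, 1.1])
    c = np.array([0.3, 0.6, 1.0])
    rank_one = pd.DataFrame(np.expm1(np.outer(r, c)))
    assert bipartite_metrics(rank_one, seed=0, restarts=5).H2_prime < 0.02


def test_h2prime_monotone_under_diagonal_concentration():
    rng = np.random.default_rng(2)
    base = np.full((4, 4), 1.0)
    previous = -1.0
    for w in (1.0, 3.0, 9.0, 27.0):
        m = base.copy()
        np.fill_diagonal(m, w)
        h2p = bipartite_metrics(pd.DataFrame(m), seed=0, restarts=3).H2_prime
        assert h2p >= previous - 1e-9
        previous = h2p


def _set_partitions(items):
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def _exhaustive_Q(A):
    n_r, n_c = A.shape
    nodes = [("r", i) for i in range(n_r)] + [("c", j) for j in range(n_c)]
    best = -np.inf
    for part in _set_partitions(nodes):
        row_lab = np.zeros(n_r, dtype=int)
        col_lab = np.zeros(n_c, dtype=int)
        for m, block in enumerate(part):
            for side, idx in block:
                (row_lab if side == "r" else col_lab)[idx] = m
        best = max(best, _barber_Q(A, row_lab, col_lab))
    return best


def test_modularity_matches_exhaustive_search():
    counts = pd.DataFrame([[8.0, 7, 0], [6, 9, 0], [0, 0, 12]])
    res = bipartite_metrics(counts, seed=3, restarts=20)
    A = np.log1p(counts.to_numpy())
    assert res.Q == pytest.approx(_exhaustive_Q(A), abs=1e-9)
    # two-block structure recovered
    assert res.row_modules["0"] == res.row_modules["1"] != res.row_modules["2"]
    assert res.Q >= 0.0  # never below the single-module baseline


def test_zero_matrix_rejected():
    with pytest.raises(ValueError):
        bipartite_metrics(pd.DataFrame(np.zeros((3, 3))))


# ---- UPGMA and Blomberg's K ------------------------------------------------

def _dm(d, ids):
    return DistanceMatrix(np.asarray(d, dtype=float), tuple(ids))


def test_upgma_three_taxa_heights():
    D = _dm([[0, 2, 6], [2, 0, 6], [6, 6, 0]], ["A", "B", "C"])
    newick = upgma_tree(D)
    V, labels = tree_covariance(newick)
    r = {lab: V[i, i] for i, lab in enumerate(labels)}
    assert r["A"] == pytest.approx(3.0, abs=1e-9)  # root height 3
    i, j = labels.index("A"), labels.index("B")
    assert V[i, j] == pytest.approx(2.0, abs=1e-9)  # A,B diverge at height 1
    k = labels.index("C")
    assert V[i, k] == pytest.approx(0.0, abs=1e-9)


def test_upgma_is_ultrametric_and_recovers_ultrametric_input():
    rng = np.random.default_rng(3)
    pts = rng.normal(size=(7, 3))
    from scipy.cluster.hierarchy import average, cophenet
    from scipy.spatial.distance import pdist, squareform

    Z = average(pdist(pts))
    ultra = squareform(cophenet(Z))
    ids = [f"t{i}" for i in range(7)]
    newick = upgma_tree(_dm(ultra, ids))
    V, labels = tree_covariance(newick)
    roots = np.diag(V)
    assert np.allclose(roots, roots[0], atol=1e-9)  # ultrametric
    for i, j in itertools.combinations(range(len(labels)), 2):
        patristic = roots[i] + roots[j] - 2 * V[i, j]
        a, b = ids.index(labels[i]), ids.index(labels[j])
        assert patristic == pytest.approx(ultra[a, b], abs=1e-8)


def test_star_phylogeny_K_is_one():
    V = np.eye(8)
    labels = [f"t{i}" for i in range(8)]
    rng = np.random.default_rng(0)
    for _ in range(5):
        x = rng.normal(size=8)
        res = blomberg_k((V, labels), x, n_perm=19, seed=0)
        assert res.K == pytest.approx(1.0, rel=1e-10)


@pytest.fixture(scope="module")
def random_tree_cov():
    rng = np.random.default_rng(8)
    pts = rng.normal(size=(16, 4))
    from scipy.cluster.hierarchy import average
    from scipy.spatial.distance import pdist

    Z = average(pdist(pts))
    from phylochem.drivers import _linkage_to_newick

    newick = _linkage_to_newick(Z, [f"t{i}" for i in range(16)], 0.5) + ";"
    return tree_covariance(newick)


def test_brownian_traits_give_K_near_one(random_tree_cov):
    V, labels = random_tree_cov
    traits = simulate_brownian(V, n_reps=300, seed=2)
    ks = [blomberg_k((V, labels), x, n_perm=0 + 1, seed=0).K for x in traits]
    assert 0.85 <= np.mean(ks) <= 1.15


def test_shuffled_traits_lose_signal(random_tree_cov):
    V, labels = random_tree_cov
    rng = np.random.default_rng(4)
    traits = simulate_brownian(V, n_reps=100, seed=5)
    ks_bm, ks_null, pvals = [], [], []
    for x in traits:
        ks_bm.append(blomberg_k((V, labels), x, n_perm=1, seed=0).K)
        shuffled = rng.permutation(x)
        res = blomberg_k((V, labels), shuffled, n_perm=49, seed=1)
        ks_null.append(res.K)
        pvals.append(res.p_value)
    assert np.mean(ks_null) < np.mean(ks_bm)
    assert 0.3 < np.mean(pvals) < 0.7  # p roughly uniform under the null


def test_blomberg_input_validation(random_tree_cov):
    V, labels = random_tree_cov
    with pytest.raises(ValueError):
        blomberg_k((V, labels), np.ones(len(labels)), n_perm=9)  # constant trait
    with pytest.raises(ValueError):
        blomberg_k((V[:3, :3], labels[:3]), np.arange(3.0), n_perm=9)  # too few tips
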