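"""Jaccard distances, PCoA geometry, PERMANOVA/betadisper behavior."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from phylochem.ordination import (
    DistanceMatrix,
    betadisper,
    jaccard_distance_matrix,
    pcoa,
    permanova,
    subsample_species,
)


def _euclidean_dm(points, ids=None):
    d = squareform(pdist(points))
    ids = ids or [f"u{i}" for i in range(len(points))]
    return DistanceMatrix(d, tuple(ids), metric="euclidean")


# ---- subsampling -----------------------------------------------------------

def test_subsample_caps_and_keeps(small_core):
    core, _, _ = small_core
    sub = subsample_species(core, n_max=20, seed=5)
    counts = sub.records.groupby("family")["species"].nunique()
    full = core.records.groupby("family")["species"].nunique()
    for fam in full.index:
        assert counts[fam] == min(full[fam], 20)


def test_subsample_is_seed_reproducible(small_core):
    core, _, _ = small_core
    s1 = subsample_species(core, n_max=15, seed=42)
    s2 = subsample_species(core, n_max=15, seed=42)
    pd.testing.assert_frame_equal(s1.records, s2.records)
    with pytest.raises(ValueError):
        subsample_species(core, n_max=1)


# ---- Jaccard distances -----------------------------------------------------

def test_jaccard_distance_values():
    inc = pd.DataFrame(
        [[1, 1, 0], [0, 1, 1], [1, 1, 0], [1, 0, 0]],
        index=["xy", "yz", "xy2", "x"], columns=["x", "y", "z"],
    )
    D = jaccard_distance_matrix(inc)
    assert D.data[0, 2] == 0.0                      # identical repertoires
    assert D.data[0, 1] == pytest.approx(2 / 3)     # {x,y} vs {y,z}
    assert D.data[1, 3] == 1.0                      # disjoint


def test_jaccard_rejects_empty_unit():
    inc = pd.DataFrame([[1, 0], [0, 0]], index=["a", "empty_unit"])
    with pytest.raises(ValueError, match="empty_unit"):
        jaccard_distance_matrix(inc)


# ---- PCoA ------------------------------------------------------------------

def test_pcoa_equilateral_triangle():
    d = np.ones((3, 3)) - np.eye(3)
    res = pcoa(DistanceMatrix(d, ("a", "b", "c")))
    pos = res.eigenvalues[res.eigenvalues > 1e-10]
    assert len(pos) == 2 and pos[0] == pytest.approx(pos[1], rel=1e-9)
    rec = squareform(pdist(res.coordinates))
    assert np.allclose(rec, d, atol=1e-10)


def test_pcoa_reconstructs_euclidean_distances():
    rng = np.random.default_rng(0)
    pts = rng.normal(size=(15, 4))
    D = _euclidean_dm(pts)
    res = pcoa(D)
    assert (res.eigenvalues > -1e-8).all()
    rec = squareform(pdist(res.coordinates))
    assert np.max(np.abs(rec - D.data)) < 1e-8


def test_pcoa_duplicated_points_coincide():
    pts = np.array([[0.0, 0], [1, 0], [1, 0], [0, 3]])
    res = pcoa(_euclidean_dm(pts))
    assert np.allclose(res.coordinates[1], res.coordinates[2], atol=1e-9)


def test_pcoa_agrees_with_reference_implementation():
    skbio = pytest.importorskip("skbio")
    from skbio.stats.ordination import pcoa as skbio_pcoa

    rng = np.random.default_rng(1)
    inc = pd.DataFrame((rng.random((10, 25)) < 0.4).astype(int))
    inc = inc.loc[inc.sum(axis=1) > 0]
    D = jaccard_distance_matrix(inc)
    ours = pcoa(D)
    ref = skbio_pcoa(skbio.DistanceMatrix(D.data, [str(i) for i in D.ids]))
    np.testing.assert_allclose(
        np.sort(ours.eigenvalues)[::-1][:5], ref.eigvals.to_numpy()[:5], atol=1e-8
    )


# ---- PERMANOVA -------------------------------------------------------------

def test_permanova_identical_groups_nonsignificant():
    pts = np.tile(np.array([[0.0, 0], [1, 0], [0, 1], [1, 1]]), (2, 1))
    D = _euclidean_dm(pts)
    res = permanova(D, ["g1"] * 4 + ["g2"] * 4, n_perm=199, seed=0)
    assert res.R2 == pytest.approx(0.0, abs=1e-9)
    assert res.p_value > 0.5


def test_permanova_perfect_separation():
    pts = np.array([[0.0, 0]] * 4 + [[10.0, 0]] * 4)
    D = _euclidean_dm(pts)
    res = permanova(D, ["a"] * 4 + ["b"] * 4, n_perm=199, seed=0)
    assert res.R2 == pytest.approx(1.0, rel=1e-9)
    # permutations reproducing the same 4/4 split tie on F, so p is bounded
    # below by the plus-one minimum but need not attain it
    assert 1 / 200 <= res.p_value <= 0.05


def test_permanova_agrees_with_reference_implementation():
    skbio = pytest.importorskip("skbio")
    from skbio.stats.distance import permanova as skbio_permanova

    rng = np.random.default_rng(2)
    pts = rng.normal(size=(18, 3))
    pts[:9] += 0.8
    D = _euclidean_dm(pts)
    groups = ["a"] * 9 + ["b"] * 9
    ours = permanova(D, groups, n_perm=499, seed=3)
    ref = skbio_permanova(skbio.DistanceMatrix(D.data, list(D.ids)),
                          grouping=groups, permutations=499)
    assert ours.pseudo_F == pytest.approx(ref["test statistic"], rel=1e-9)
    assert abs(ours.p_value - ref["p-value"]) < 0.05


def test_permanova_errors():
    D = _euclidean_dm(np.random.default_rng(0).normal(size=(5, 2)))
    with pytest.raises(ValueError):
        permanova(D, ["a"] * 5)
    with pytest.raises(ValueError):
        permanova(D, ["a", "a", "a", "a", "b"])  # singleton group


def test_planted_clade_structure_detected(small_core):
    core, _, _ = small_core
    sub = subsample_species(core, n_max=10, seed=1)
    inc = sub.species_incidence()
    fam_of = sub.records.drop_duplicates("species").set_index("species")["family"]
    D = jaccard_distance_matrix(inc)
    res = permanova(D, [fam_of[s] for s in inc.index], n_perm=999, seed=1)
    assert res.p_value <= 0.005


# ---- dispersion ------------------------------------------------------------

def test_dispersion_zero_for_coincident_group():
    pts = np.array([[0.0, 0]] * 3 + [[3.0, 0], [5, 0], [4, 2]])
    D = _euclidean_dm(pts)
    res = betadisper(D, ["tight"] * 3 + ["loose"] * 3, n_perm=99, seed=0)
    assert res.group_means["tight"] == pytest.approx(0.0, abs=1e-9)
    assert res.group_means["loose"] > 0


def test_dispersion_ratio_of_scaled_groups():
    rng = np.random.default_rng(4)
    base = rng.normal(size=(20, 3))
    base -= base.mean(axis=0)
    pts = np.vstack([base, 2 * base + 10])
    D = _euclidean_dm(pts)
    res = betadisper(D, ["g1"] * 20 + ["g2"] * 20, n_perm=99, seed=0)
    assert res.group_means["g2"] / res.group_means["g1"] == pytest.approx(2.0, rel=1e-9)


def test_monte_carlo_p_values_never_zero():
    pts = np.array([[0.0, 0]] * 4 + [[10.0, 0]] * 4)
    D = _euclidean_dm(pts)
    for n_perm in (9, 99, 999):
        assert permanova(D, ["a"] * 4 + ["b"] * 4, n_perm=n_perm, seed=0).p_value > 0
        assert betadisper(D, ["a"] * 4 + ["b"] * 4, n_perm=n_perm, seed=0).p_value > 0


def test_distance_matrix_validation():
    with pytest.raises(ValueError):
        DistanceMatrix(np.array([[0.0, 1], [2, 0]]), ("a", "b"))  # asymmetric
    with pytest.raises(ValueError):
        DistanceMatrix(np.array([[1.0, 0], [0, 1]]), ("a", "b"))  # nonzero diag


def test_dispersion_stability_no_variance_without_sampling(small_core):
    from phylochem.ordination import dispersion_stability

    core, _, _ = small_core
    max_size = core.records.groupby("family")["species"].nunique().max()
    table = dispersion_stability(core, n_grid=(int(max_size), 8), reps=3, seed=2)
    assert set(table.columns) == {"family", "n", "dispersion_mean", "dispersion_sd"}
    # at n >= every family size nothing is subsampled, so replicates coincide
    full = table[table["n"] == max_size]
    assert np.allclose(full["dispersion_sd"], 0.0)
    assert (table["dispersion_mean"] >= 0).all()
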