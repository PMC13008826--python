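"""Hill numbers, coverage estimation, rarefaction oracle, plasticity."""

from itertools import combinations

import numpy as np
import pytest

from phylochem.diversity import (
    IncidenceFrequencies,
    chao2_richness,
    coverage_at,
    coverage_rarefy,
    expected_frequency_spectrum,
    hill_at,
    hill_numbers,
    hill_profile,
    plasticity_index,
    rarefied_richness,
    sample_coverage,
)

import pandas as pd


def _freqs(y, T):
    return IncidenceFrequencies(T=T, y=np.asarray(y, dtype=float))


# ---- Hill numbers ----------------------------------------------------------

def test_uniform_incidences_all_hill_orders_equal():
    f = _freqs([1, 1, 1, 1, 1], T=3)
    prof = hill_profile(f)
    assert prof.q0 == 5
    assert prof.q1 == pytest.approx(5, rel=1e-12)
    assert prof.q2 == pytest.approx(5, rel=1e-12)
    assert prof.evenness == pytest.approx(1.0, rel=1e-12)


def test_single_compound_diversity_is_one():
    f = _freqs([2], T=3)
    assert all(hill_numbers(f, q) == 1 for q in (0, 1, 2))


def test_hand_computed_hill_values():
    f = _freqs([4, 1, 1], T=6)
    assert hill_numbers(f, 0) == 3
    expected_q1 = np.exp(-(4 / 6 * np.log(4 / 6) + 2 * (1 / 6) * np.log(1 / 6)))
    assert hill_numbers(f, 1) == pytest.approx(expected_q1, rel=1e-12)
    assert hill_numbers(f, 1) == pytest.approx(2.3811, abs=1e-4)
    assert hill_numbers(f, 2) == pytest.approx(2.0, rel=1e-12)


def test_unsupported_order_rejected():
    with pytest.raises(ValueError):
        hill_numbers(_freqs([1, 2], T=3), 3)


def test_hill_monotonic_in_order_on_random_data():
    rng = np.random.default_rng(1)
    for _ in range(200):
        T = int(rng.integers(2, 20))
        y = rng.integers(1, T + 1, size=rng.integers(1, 30))
        f = _freqs(y, T)
        q0, q1, q2 = (hill_numbers(f, q) for q in (0, 1, 2))
        assert q0 >= q1 - 1e-9 and q1 >= q2 - 1e-9


# ---- coverage --------------------------------------------------------------

def test_coverage_is_one_without_uniques():
    assert sample_coverage(_freqs([2, 3, 2], T=5)) == 1.0


def test_coverage_formula_arithmetic():
    # T=10, Q1=5, Q2=5, U=50: C = 1 - (5/50) * (45 / (45 + 10))
    y = [1] * 5 + [2] * 5 + [7] * 5
    f = _freqs(y, T=10)
    assert f.U == 50
    assert sample_coverage(f) == pytest.approx(1 - (5 / 50) * (45 / 55), rel=1e-12)
    assert sample_coverage(f) == pytest.approx(0.9182, abs=1e-4)


def test_coverage_increases_with_duplicates():
    base = [1] * 5 + [3] * 5
    more_q2 = [1] * 5 + [2] * 3 + [3] * 5
    f1 = _freqs(base + [2] * 1, T=10)
    f2 = _freqs(more_q2, T=10)
    assert sample_coverage(f2) > sample_coverage(f1)


# ---- rarefaction oracle ----------------------------------------------------

def _brute_force_mean_richness(matrix, t):
    """Average richness over all C(T, t) species subsets (exhaustive)."""
    T = matrix.shape[0]
    vals = [
        (matrix[list(idx)].sum(axis=0) > 0).sum()
        for idx in combinations(range(T), t)
    ]
    return float(np.mean(vals))


def _brute_force_spectrum(matrix, t, k):
    T = matrix.shape[0]
    vals = [
        (matrix[list(idx)].sum(axis=0) == k).sum()
        for idx in combinations(range(T), t)
    ]
    return float(np.mean(vals))


@pytest.mark.parametrize("T, S", [(4, 6), (5, 8), (6, 10)])
def test_rarefied_richness_matches_exhaustive_enumeration(T, S):
    rng = np.random.default_rng(T * 100 + S)
    matrix = (rng.random((T, S)) < 0.5).astype(int)
    matrix[:, matrix.sum(axis=0) == 0] = 1  # every compound observed
    f = IncidenceFrequencies.from_incidence(matrix)
    for t in range(1, T + 1):
        assert rarefied_richness(f, t) == pytest.approx(
            _brute_force_mean_richness(matrix, t), rel=1e-10
        )
    assert rarefied_richness(f, T) == pytest.approx(f.S_obs, rel=1e-12)


def test_expected_spectrum_matches_exhaustive_enumeration():
    rng = np.random.default_rng(5)
    matrix = (rng.random((5, 7)) < 0.6).astype(int)
    matrix[:, matrix.sum(axis=0) == 0] = 1
    f = IncidenceFrequencies.from_incidence(matrix)
    for t in (2, 3, 4):
        spec = expected_frequency_spectrum(f, t)
        for k in range(1, t + 1):
            assert spec[k - 1] == pytest.approx(
                _brute_force_spectrum(matrix, t, k), rel=1e-10
            )


def test_rarefaction_curve_monotone_and_concave():
    rng = np.random.default_rng(11)
    matrix = (rng.random((12, 40)) < 0.3).astype(int)
    matrix[:, matrix.sum(axis=0) == 0] = 1
    f = IncidenceFrequencies.from_incidence(matrix)
    s = np.array([rarefied_richness(f, t) for t in range(1, 13)])
    diffs = np.diff(s)
    assert (diffs >= -1e-9).all()
    assert (np.diff(diffs) <= 1e-9).all()


def test_extrapolated_coverage_continuous_at_T():
    rng = np.random.default_rng(3)
    matrix = (rng.random((8, 30)) < 0.3).astype(int)
    matrix[:, matrix.sum(axis=0) == 0] = 1
    f = IncidenceFrequencies.from_incidence(matrix)
    assert coverage_at(f, f.T) == pytest.approx(sample_coverage(f), rel=1e-12)
    assert coverage_at(f, 2 * f.T) >= coverage_at(f, f.T)


def test_chao2_fallback_without_doubletons():
    f = _freqs([1, 1, 1, 3], T=4)  # Q1=3, Q2=0
    assert chao2_richness(f) == pytest.approx(4 + (3 / 4) * 3 * 2 / 2)


def test_coverage_standardized_richness_not_above_observed(small_core):
    core, _, _ = small_core
    inc = {f: core.species_incidence(f).to_numpy() for f in core.families}
    prof = coverage_rarefy(inc, target_coverage=0.95)
    interpolated = prof[~prof["extrapolated"]]
    obs = {f: (m.sum(axis=0) > 0).sum() for f, m in inc.items()}
    for row in interpolated.itertuples():
        assert row.q0 <= obs[row.family] + 1e-9


def test_evenness_invariant_under_unit_duplication():
    rng = np.random.default_rng(2)
    matrix = (rng.random((6, 15)) < 0.5).astype(int)
    matrix[:, matrix.sum(axis=0) == 0] = 1
    f1 = IncidenceFrequencies.from_incidence(matrix)
    f2 = IncidenceFrequencies.from_incidence(np.vstack([matrix, matrix]))
    p1, p2 = hill_profile(f1), hill_profile(f2)
    assert p1.evenness == pytest.approx(p2.evenness, rel=1e-12)


def test_bad_target_coverage_rejected(small_core):
    core, _, _ = small_core
    inc = {f: core.species_incidence(f).to_numpy() for f in core.families}
    with pytest.raises(ValueError):
        coverage_rarefy(inc, target_coverage=1.5)


# ---- plasticity ------------------------------------------------------------

def test_plasticity_shannon_values():
    counts = pd.DataFrame(
        {
            "c1": [10, 25, 50],
            "c2": [0, 25, 30],
            "c3": [0, 25, 20],
            "c4": [0, 25, 0],
        },
        index=["mono", "uniform4", "paper_example"],
    )
    table, _, _ = plasticity_index(counts)
    h = table.set_index("family")["plasticity"]
    assert h["mono"] == 0.0
    assert h["uniform4"] == pytest.approx(np.log(4), rel=1e-12)
    assert h["paper_example"] == pytest.approx(1.0297, abs=1e-4)


def test_plasticity_excludes_unclassified_family():
    counts = pd.DataFrame({"c1": [3, 0], "c2": [1, 0]}, index=["A", "B"])
    table, _, _ = plasticity_index(counts)
    assert list(table["family"]) == ["A"]
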