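import numpy as np
import pytest

from hypersample import ahels
from hypersample.covariates import extract_table
from hypersample.errors import OutOfBoundsError, PartialAllocationWarning
from hypersample.synthetic import LandscapeSpec, make_landscape, make_legacy

from conftest import stack_from_arrays


class TestQuantileMatrix:
    def test_quartiles_match_quantile_oracle(self):
        vals = np.arange(1, 101, dtype=float).reshape(10, 10)
        stack = stack_from_arrays([vals])
        qm = ahels.quantile_matrix(stack, 4)
        np.testing.assert_allclose(qm.edges[:, 0],
                                   np.quantile(vals, [0, 0.25, 0.5, 0.75, 1.0]))

    def test_s1_min_max(self):
        stack = stack_from_arrays([np.arange(16, dtype=float).reshape(4, 4)])
        qm = ahels.quantile_matrix(stack, 1)
        assert qm.edges.shape == (2, 1)
        np.testing.assert_allclose(qm.edges[:, 0], [0.0, 15.0])

    def test_two_covariates_two_columns(self):
        rng = np.random.default_rng(0)
        stack = stack_from_arrays([rng.normal(size=(6, 6)), rng.normal(size=(6, 6))])
        qm = ahels.quantile_matrix(stack, 3)
        assert qm.k == 2 and qm.edges.shape == (4, 2)

    def test_first_last_rows_are_min_max(self, plain_landscape):
        qm = ahels.quantile_matrix(plain_landscape, 5)
        for j, name in enumerate(qm.names):
            vals = plain_landscape[name].values[plain_landscape.mask]
            assert qm.edges[0, j] == vals.min()
            assert qm.edges[-1, j] == vals.max()


class TestDensities:
    def test_toy_hand_tally(self):
        # r = 20 cells with values 1..20, o = 4 legacy at values {1, 2, 3, 11}
        vals = np.arange(1, 21, dtype=float).reshape(4, 5)
        stack = stack_from_arrays([vals])
        legacy = extract_table(stack, cells=[(0, 0), (0, 1), (0, 2), (2, 0)])
        qm = ahels.quantile_matrix(stack, 2)
        tables = ahels.densities(stack, legacy, qm)
        # strata split at the median 10.5: 10 cells each side
        np.testing.assert_allclose(tables.grid_density[:, 0], [0.5, 0.5])
        np.testing.assert_allclose(tables.data_density[:, 0], [0.75, 0.25])
        np.testing.assert_allclose(tables.ratio[:, 0], [1.5, 0.5])

    def test_density_columns_sum_to_one(self, plain_landscape):
        stack = plain_landscape
        legacy = make_legacy(stack, 50, bias="none", seed=1)
        tables = ahels.densities(stack, legacy, ahels.quantile_matrix(stack, 10))
        np.testing.assert_allclose(tables.grid_density.sum(axis=0), 1.0, atol=1e-9)
        np.testing.assert_allclose(tables.data_density.sum(axis=0), 1.0, atol=1e-9)

    def test_proportional_legacy_ratio_near_one(self, plain_landscape):
        stack = plain_landscape
        legacy = make_legacy(stack, 1200, bias="none", seed=2)
        tables = ahels.densities(stack, legacy, ahels.quantile_matrix(stack, 4))
        assert np.all(np.abs(tables.ratio - 1.0) < 0.35)

    def test_empty_stratum_ratio_zero(self):
        vals = np.arange(1, 21, dtype=float).reshape(4, 5)
        stack = stack_from_arrays([vals])
        legacy = extract_table(stack, cells=[(0, 0), (0, 1)])  # all low values
        tables = ahels.densities(stack, legacy, ahels.quantile_matrix(stack, 2))
        assert tables.ratio[1, 0] == 0.0

    def test_off_mask_legacy_errors(self):
        vals = np.arange(16, dtype=float).reshape(4, 4)
        vals[0, 0] = np.nan
        stack = stack_from_arrays([vals])
        legacy = extract_table(stack, cells=[(1, 1)])
        legacy.cells = np.array([[0, 0]])
        with pytest.raises(OutOfBoundsError):
            ahels.densities(stack, legacy, ahels.quantile_matrix(stack, 2))


class TestRankStrata:
    def test_ranking_is_permutation_with_deterministic_ties(self):
        vals = np.arange(1, 21, dtype=float).reshape(4, 5)
        stack = stack_from_arrays([vals, vals[::-1].copy()])
        legacy = extract_table(stack, cells=[(0, 0), (3, 4)])
        tables = ahels.densities(stack, legacy, ahels.quantile_matrix(stack, 4))
        ranking = ahels.rank_strata(tables)
        assert len(ranking) == 4 * 2
        assert len({tuple(rc) for rc in ranking.tolist()}) == 8
        ratios = tables.ratio[ranking[:, 0], ranking[:, 1]]
        assert np.all(np.diff(ratios) >= -1e-12)
        # within equal ratios, (col, row) order
        for i in range(len(ranking) - 1):
            if ratios[i] == ratios[i + 1]:
                assert (ranking[i, 1], ranking[i, 0]) < (ranking[i + 1, 1], ranking[i + 1, 0])


@pytest.fixture(scope="module")
def biased_setup():
    stack = make_landscape(LandscapeSpec(shape=(60, 60), n_continuous=3,
                                         ranges=5.0, seed=40))
    legacy = make_legacy(stack, 120, bias="covariate_low_tail", seed=41)
    return stack, legacy


class TestAllocate:

    def test_budget_conserved_exactly(self, biased_setup):
        stack, legacy = biased_setup
        result = ahels.allocate(stack, legacy, 50, seed=1)
        assert result.design.n == 50
        assert len(result.assignments) == 50

    def test_no_duplicate_cells(self, biased_setup):
        stack, legacy = biased_setup
        result = ahels.allocate(stack, legacy, 80, seed=2)
        cells = {tuple(c) for c in result.design.cells.tolist()}
        assert len(cells) == result.design.n
        legacy_cells = {tuple(c) for c in legacy.cells.tolist()}
        assert not cells & legacy_cells

    def test_sites_fall_in_their_strata(self, biased_setup):
        stack, legacy = biased_setup
        result = ahels.allocate(stack, legacy, 30, seed=3)
        for (_, rec), cell in zip(result.assignments.iterrows(), result.design.cells):
            j = result.qm.names.index(rec["covariate"])
            lo = result.qm.edges[int(rec["stratum_row"]), j]
            hi = result.qm.edges[int(rec["stratum_row"]) + 1, j]
            v = stack[rec["covariate"]].values[cell[0], cell[1]]
            assert lo <= v <= hi

    def test_underfilled_upper_tail_targeted(self, biased_setup):
        stack, legacy = biased_setup
        wins = 0
        for seed in range(10):
            result = ahels.allocate(stack, legacy, 60, seed=seed)
            frac = (result.assignments["legacy_ratio"] < 1.0).mean()
            wins += frac >= 0.8
        assert wins >= 8

    def test_min_ratio_never_decreases(self, biased_setup):
        stack, legacy = biased_setup
        result = ahels.allocate(stack, legacy, 60, seed=5)
        combined_cells = np.vstack([legacy.cells, result.design.cells])
        combined = extract_table(stack, cells=combined_cells)
        before = ahels.densities(stack, legacy, result.qm)
        after = ahels.densities(stack, combined, result.qm)
        assert after.ratio.min() >= before.ratio.min() - 1e-12

    def test_seeded_determinism(self, biased_setup):
        stack, legacy = biased_setup
        a = ahels.allocate(stack, legacy, 25, seed=9)
        b = ahels.allocate(stack, legacy, 25, seed=9)
        np.testing.assert_array_equal(a.design.cells, b.design.cells)

    def test_unfillable_budget_partial_with_warning(self):
        vals = np.arange(16, dtype=float).reshape(4, 4)
        stack = stack_from_arrays([vals])
        legacy = extract_table(stack, cells=[(0, 0)])
        with pytest.warns(PartialAllocationWarning):
            result = ahels.allocate(stack, legacy, 16, seed=0)
        assert result.design.n == 15  # every non-legacy cell

    def test_literal_m_formula_flag(self, biased_setup):
        stack, legacy = biased_setup
        lit = ahels.allocate(stack, legacy, 30, seed=4, subtract_existing=False)
        assert lit.design.n == 30
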