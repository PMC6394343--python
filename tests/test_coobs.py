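import numpy as np
import pytest

from hypersample import coobs
from hypersample.covariates import extract_table
from hypersample.distance import population_factor
from hypersample.errors import DegenerateStackError
from hypersample.synthetic import LandscapeSpec, make_landscape, make_legacy

from conftest import stack_from_arrays


def coobs_oracle(stack, legacy, threshold):
    """Brute-force double loop over pixels and legacy points."""
    factor = population_factor(stack)
    cells = stack.valid_cells()
    pix = stack.continuous_matrix(cells)
    leg = legacy.table[stack.continuous_names].to_numpy(dtype=float)
    counts = np.full(stack.shape, -1, dtype=int)
    magpd = np.full(stack.shape, np.nan)
    for i, cell in enumerate(cells):
        dists_all = factor.distances(pix, pix[i])
        m = dists_all.max()
        magpd[cell[0], cell[1]] = m
        c = 0
        for j in range(len(leg)):
            dd = factor.distances(leg[j][None, :], pix[i])[0]
            if m == 0:
                c += dd == 0
            elif 1.0 - dd / m >= threshold:
                c += 1
        counts[cell[0], cell[1]] = c
    return counts, magpd


class TestMagpd:
    def test_constant_stack_degenerate(self):
        stack = stack_from_arrays([np.full((3, 3), 2.0)])
        with pytest.raises(DegenerateStackError):
            coobs.magpd_map(stack, coobs.CoobsConfig(mode="exact"))

    def test_single_covariate_hand_values(self):
        # values 0, 1, 2 with sample sd sigma: middle cell's farthest point
        # is at distance 1/sigma
        vals = np.array([[0.0, 1.0, 2.0]])
        stack = stack_from_arrays([vals])
        m = coobs.magpd_map(stack, coobs.CoobsConfig(mode="exact"))
        sigma = np.std([0, 1, 2], ddof=1)
        np.testing.assert_allclose(m[0], [2 / sigma, 1 / sigma, 2 / sigma], atol=1e-12)

    def test_approximate_full_subset_equals_exact(self, small_landscape):
        stack = small_landscape
        exact = coobs.magpd_map(stack, coobs.CoobsConfig(mode="exact"))
        approx = coobs.magpd_map(stack, coobs.CoobsConfig(mode="approximate",
                                                          approx_sample=stack.r, seed=0))
        np.testing.assert_allclose(exact[stack.mask], approx[stack.mask], atol=1e-12)

    def test_approximate_biased_low(self, small_landscape):
        stack = small_landscape
        exact = coobs.magpd_map(stack, coobs.CoobsConfig(mode="exact"))
        approx = coobs.magpd_map(stack, coobs.CoobsConfig(mode="approximate",
                                                          approx_sample=50, seed=3))
        assert np.all(approx[stack.mask] <= exact[stack.mask] + 1e-12)


@pytest.fixture(scope="module")
def toy():
    rng = np.random.default_rng(50)
    stack = stack_from_arrays([rng.normal(size=(5, 5)), rng.normal(size=(5, 5))])
    legacy = extract_table(stack, cells=[(0, 0), (2, 3), (4, 4)])
    return stack, legacy


class TestCoobsMap:

    def test_matches_brute_force_oracle(self, toy):
        stack, legacy = toy
        cfg = coobs.CoobsConfig(mode="exact", similarity_threshold=0.8)
        cm = coobs.coobs_map(stack, legacy, cfg)
        oracle_counts, oracle_magpd = coobs_oracle(stack, legacy, 0.8)
        np.testing.assert_array_equal(cm.coobs, oracle_counts)
        np.testing.assert_allclose(cm.magpd[stack.mask], oracle_magpd[stack.mask], atol=1e-9)

    def test_pixel_equal_to_legacy_counted(self, toy):
        stack, legacy = toy
        cfg = coobs.CoobsConfig(mode="exact", similarity_threshold=0.999)
        cm = coobs.coobs_map(stack, legacy, cfg)
        for cell in legacy.cells:
            assert cm.coobs[cell[0], cell[1]] >= 1

    def test_farthest_legacy_never_counted(self, toy):
        stack, legacy = toy
        factor = population_factor(stack)
        pix = stack.continuous_matrix()
        cells = stack.valid_cells()
        cfg = coobs.CoobsConfig(mode="exact", similarity_threshold=1e-9)
        cm = coobs.coobs_map(stack, legacy, cfg)
        # a legacy point at a pixel's exact magpd location has sdd = 0
        for i, cell in enumerate(cells):
            d = factor.distances(legacy.table[stack.continuous_names].to_numpy(dtype=float),
                                 pix[i])
            m = cm.magpd[cell[0], cell[1]]
            exact_far = np.isclose(d, m).sum()
            assert cm.coobs[cell[0], cell[1]] <= legacy.n - exact_far

    def test_monotone_in_threshold(self, toy):
        stack, legacy = toy
        lo = coobs.coobs_map(stack, legacy, coobs.CoobsConfig(mode="exact",
                                                              similarity_threshold=0.7))
        hi = coobs.coobs_map(stack, legacy, coobs.CoobsConfig(mode="exact",
                                                              similarity_threshold=0.95))
        assert np.all(hi.coobs[stack.mask] <= lo.coobs[stack.mask])

    def test_monotone_in_legacy_count(self, toy):
        stack, _ = toy
        few = extract_table(stack, cells=[(0, 0), (2, 3)])
        more = extract_table(stack, cells=[(0, 0), (2, 3), (4, 4), (1, 1)])
        cfg = coobs.CoobsConfig(mode="exact", similarity_threshold=0.8)
        cm_few = coobs.coobs_map(stack, few, cfg)
        cm_more = coobs.coobs_map(stack, more, cfg)
        assert np.all(cm_more.coobs[stack.mask] >= cm_few.coobs[stack.mask])

    def test_exact_geq_approximate(self, small_landscape):
        stack = small_landscape
        legacy = make_legacy(stack, 30, seed=6)
        cfg_e = coobs.CoobsConfig(mode="exact", similarity_threshold=0.9)
        cfg_a = coobs.CoobsConfig(mode="approximate", approx_sample=60,
                                  similarity_threshold=0.9, seed=1)
        exact = coobs.coobs_map(stack, legacy, cfg_e)
        approx = coobs.coobs_map(stack, legacy, cfg_a)
        assert np.all(exact.coobs[stack.mask] >= approx.coobs[stack.mask])

    def test_counts_bounded_by_o(self, small_landscape):
        stack = small_landscape
        legacy = make_legacy(stack, 20, seed=7)
        cm = coobs.coobs_map(stack, legacy, coobs.CoobsConfig(mode="exact",
                                                              similarity_threshold=0.5))
        on = cm.coobs[stack.mask]
        assert on.min() >= 0 and on.max() <= legacy.n


class TestCrosstab:
    def test_all_low_coverage(self, small_landscape):
        stack = small_landscape
        legacy = make_legacy(stack, 10, seed=8)
        cm = coobs.coobs_map(stack, legacy, coobs.CoobsConfig(mode="exact"))
        sites = extract_table(stack, cells=stack.valid_cells()[::50])
        table = coobs.coverage_crosstab(cm, sites)
        assert table.sum() == pytest.approx(1.0, abs=1e-9)
        if np.all(cm.coobs[stack.mask] < 5):
            assert table.iloc[0] == pytest.approx(1.0)

    def test_class_labels(self, small_landscape):
        stack = small_landscape
        legacy = make_legacy(stack, 10, seed=8)
        cm = coobs.coobs_map(stack, legacy, coobs.CoobsConfig(mode="exact"))
        sites = extract_table(stack, cells=stack.valid_cells()[:5])
        table = coobs.coverage_crosstab(cm, sites)
        assert list(table.index) == ["0-5", "5-10", "10-20", "20-40", ">40"]

    def test_ahels_sites_concentrate_in_low_coverage(self):
        """New sites land in lower-coverage pixels than random sites do."""
        from hypersample import ahels

        wins = 0
        for seed in range(10):
            stack = make_landscape(LandscapeSpec(shape=(30, 30), n_continuous=3,
                                                 ranges=4.0, seed=200 + seed))
            legacy = make_legacy(stack, 80, bias="covariate_low_tail", seed=300 + seed)
            cm = coobs.coobs_map(stack, legacy,
                                 coobs.CoobsConfig(mode="exact", similarity_threshold=0.9))
            new = ahels.allocate(stack, legacy, 30, seed=400 + seed).design
            rng = np.random.default_rng(500 + seed)
            cells = stack.valid_cells()
            rand = extract_table(stack, cells=cells[rng.choice(stack.r, 30, replace=False)])
            mean_new = cm.coobs[new.cells[:, 0], new.cells[:, 1]].mean()
            mean_rand = cm.coobs[rand.cells[:, 0], rand.cells[:, 1]].mean()
            wins += mean_new <= mean_rand
        assert wins >= 8
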