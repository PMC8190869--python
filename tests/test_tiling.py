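import numpy as np
import pandas as pd
import pytest
from scipy.stats import fisher_exact

from methdmr import (ParameterError, ValidationError, adjust_fdr, dmr_table,
                     dmr_test, filter_dmrs, tile_windows)

from conftest import make_window_matrix


def _cov(chrom, pos, meth, unmeth):
    return pd.DataFrame({"chrom": chrom, "pos": pos, "meth_count": meth,
                         "unmeth_count": unmeth})


class TestTileWindows:
    def test_grid_assignment_is_phase_anchored_at_one(self):
        sites = {"s": _cov(["chr11", "chr11"], [1861001, 1861000],
                           [5, 5], [5, 5])}
        wm = tile_windows(sites)
        spans = list(zip(wm.windows["start"], wm.windows["end"]))
        assert (1861001, 1862000) in spans       # x001 starts a window
        assert (1860001, 1861000) in spans       # x000 ends the previous one

    def test_window_sums_and_level(self):
        sites = {"s": _cov(["chr1", "chr1"], [50, 900], [3, 5], [7, 5])}
        wm = tile_windows(sites)
        assert wm.meth[0, 0] == 8 and wm.cov[0, 0] == 20
        assert wm.levels[0, 0] == pytest.approx(0.4)
        assert wm.n_sites[0, 0] == 2

    def test_shallow_sites_excluded_by_coverage_floor(self):
        sites = {"s": _cov(["chr1", "chr1"], [10, 20], [1, 4], [0, 4])}
        wm = tile_windows(sites, min_site_coverage=2)
        assert wm.cov[0, 0] == 8      # the coverage-1 site contributes nothing
        wm2 = tile_windows(sites, min_site_coverage=1)
        assert wm2.cov[0, 0] == 9

    def test_invalid_window_size(self):
        with pytest.raises(ParameterError):
            tile_windows({}, window_size=0)


class TestDmrTest:
    def test_identical_groups_are_null(self):
        res = dmr_test({"a": (5, 10), "b": (5, 10)}, ["a"], ["b"])
        assert res["meth_diff"] == 0
        assert res["p"] >= 0.99

    def test_p_tracks_fisher_exact_on_extreme_2x2(self):
        # the asymptotic chi-square tail of the LRT and the exact
        # hypergeometric tail diverge in deep tails; order-of-magnitude
        # agreement is what the approximation guarantees here
        res = dmr_test({"a": (18, 20), "b": (5, 20)}, ["a"], ["b"])
        fp = fisher_exact([[18, 2], [5, 15]], alternative="two-sided")[1]
        assert res["direction"] == "hyper"
        assert fp / 10 <= res["p"] <= fp * 10

    def test_p_tracks_fisher_exact_at_moderate_tables(self):
        res = dmr_test({"a": (14, 20), "b": (8, 20)}, ["a"], ["b"])
        fp = fisher_exact([[14, 6], [8, 12]], alternative="two-sided")[1]
        assert fp / 3 <= res["p"] <= fp * 3

    def test_complete_separation_is_finite(self):
        res = dmr_test({"a": (20, 20), "b": (0, 20)}, ["a"], ["b"])
        assert res["meth_diff"] == pytest.approx(100.0)
        assert res["direction"] == "hyper"
        assert 0 <= res["p"] < 1e-6

    def test_label_swap_flips_sign_keeps_p(self):
        rng = np.random.default_rng(5)
        cov = rng.integers(5, 40, size=(30, 8))
        meth = rng.binomial(cov, 0.4)
        wm = make_window_matrix(meth, cov)
        a, b = wm.samples[:4], wm.samples[4:]
        t1 = dmr_table(wm, a, b)
        t2 = dmr_table(wm, b, a)
        np.testing.assert_allclose(t1["p"], t2["p"], rtol=1e-10)
        np.testing.assert_allclose(t1["meth_diff"], -t2["meth_diff"],
                                   rtol=1e-10)

    def test_matches_statsmodels_binomial_glm(self):
        """Closed-form LRT equals an iterative GLM fit (independent route)."""
        import statsmodels.api as sm

        rng = np.random.default_rng(7)
        cov = rng.integers(8, 40, size=(12, 10))
        meth = rng.binomial(cov, rng.uniform(0.2, 0.8, size=(12, 1)))
        wm = make_window_matrix(meth, cov)
        table = dmr_table(wm, wm.samples[:5], wm.samples[5:])
        x = sm.add_constant(np.r_[np.ones(5), np.zeros(5)])
        for i in range(12):
            endog = np.c_[meth[i], cov[i] - meth[i]]
            full = sm.GLM(endog, x, family=sm.families.Binomial()).fit()
            null = sm.GLM(endog, np.ones((10, 1)),
                          family=sm.families.Binomial()).fit()
            lrt_p = 1 - __import__("scipy").stats.chi2.cdf(
                2 * (full.llf - null.llf), 1)
            assert table["p"].iloc[i] == pytest.approx(lrt_p, abs=1e-6)

    def test_uncovered_group_untestable(self):
        wm = make_window_matrix([[3, 0]], [[10, 0]])
        t = dmr_table(wm, [wm.samples[0]], [wm.samples[1]])
        assert bool(t["untestable"].iloc[0])
        assert np.isnan(t["p"].iloc[0])

    def test_overlapping_groups_rejected(self):
        wm = make_window_matrix([[3, 4]], [[10, 10]])
        with pytest.raises(ParameterError):
            dmr_table(wm, [wm.samples[0]], list(wm.samples))


class TestAdjustFdr:
    def test_single_p_is_identity(self):
        assert adjust_fdr([0.03])[0] == pytest.approx(0.03)

    def test_hand_applied_step_up(self):
        np.testing.assert_allclose(adjust_fdr([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_null_batch(self):
        assert (adjust_fdr([1.0, 1.0, 1.0]) == 1.0).all()

    def test_na_passthrough(self):
        q = adjust_fdr([0.01, np.nan, 0.5])
        assert np.isnan(q[1]) and not np.isnan(q[[0, 2]]).any()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            adjust_fdr([0.5, 1.5])

    def test_matches_brute_force_bh(self):
        """q_i = min over j >= i (sorted) of m*p_(j)/j, capped at 1."""
        rng = np.random.default_rng(42)
        for _ in range(25):
            m = int(rng.integers(1, 51))
            p = rng.random(m)
            order = np.argsort(p)
            q_expect = np.empty(m)
            running = 1.0
            for rank in range(m, 0, -1):
                i = order[rank - 1]
                running = min(running, m * p[i] / rank)
                q_expect[i] = running
            q = adjust_fdr(p)
            np.testing.assert_allclose(q, q_expect, rtol=1e-12)
            assert (q >= p - 1e-12).all()      # BH never lowers a p-value


@pytest.mark.parametrize("q,diff,kept", [
    (0.04, 12.0, True),
    (0.04, -12.0, True),     # absolute effect size
    (0.06, 50.0, False),     # q gate
    (0.04, 9.0, False),      # effect gate
])
def test_filter_dmrs_gates(q, diff, kept):
    df = pd.DataFrame({"chrom": ["chr1"], "start": [1], "end": [1000],
                       "meth_diff": [diff], "p": [0.001], "q": [q]})
    out = filter_dmrs(df, q_max=0.05, min_abs_diff=10)
    assert (len(out) == 1) is kept
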