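"""FHB / FHC / FastFHC smoothing, pooled estimation, DMR calling."""

import numpy as np
import pandas as pd
import pytest
from conftest import enum_posterior, make_table

from fethmm import (
    HmmParams,
    StrategyConfig,
    ValidationError,
    binarize,
    build_emission_from_pvalues,
    call_dmrs,
    detect,
    estep_only,
    estimate_pooled_params,
    run_fastfhc,
    run_fhb,
    run_fhc,
    smooth_results,
)
from fethmm.strategies import DetectionResult


def _signal_table(n=12, lo=2, hi=8, base=60, bump=300):
    """One site with a strong treated-IP gain on bins [lo, hi)."""
    x0 = np.full(n, base)
    y0 = np.full(n, base)
    x1 = np.full(n, base)
    y1 = np.full(n, base)
    y1[lo:hi] = bump
    return make_table({"siteA": (x0, y0, x1, y1)})


class TestBinarize:
    def test_threshold_is_strict(self):
        np.testing.assert_array_equal(
            binarize(np.array([0.2, 0.01, 0.04, 0.05]), 0.05), [0, 1, 1, 0]
        )

    def test_near_one_threshold_marks_everything(self):
        fdr = np.array([0.2, 0.9, 0.5])
        assert binarize(fdr, 1 - 1e-12).all()

    def test_degenerate_bins_never_marked(self):
        assert not binarize(np.array([1.0, 1.0]), 0.05).any()

    def test_bad_threshold_rejected(self):
        with pytest.raises(ValidationError):
            binarize(np.array([0.5]), 1.5)


class TestEmissionFromPvalues:
    def test_uninformative_half(self):
        em = build_emission_from_pvalues([0.5])
        np.testing.assert_allclose(em.rows, [[0.5, 0.5]])

    def test_degenerate_p_one_clipped(self):
        em = build_emission_from_pvalues([1.0])
        np.testing.assert_allclose(em.rows, [[1 - 1e-10, 1e-10]])

    def test_row_structure(self):
        em = build_emission_from_pvalues([0.01, 0.99])
        np.testing.assert_allclose(em.rows, [[0.01, 0.99], [0.99, 0.01]])

    def test_rejects_zero_p(self):
        with pytest.raises(ValidationError):
            build_emission_from_pvalues([0.0])


class TestPooledParams:
    def test_hand_counted_example(self):
        pooled = estimate_pooled_params([np.array([0, 0, 1, 1])], pseudocount=0)
        np.testing.assert_allclose(pooled.pi, [0.5, 0.5])
        np.testing.assert_allclose(pooled.A, [[0.5, 0.5], [0.0, 1.0]])

    def test_all_zero_bins_with_smoothing(self):
        pooled = estimate_pooled_params([np.zeros(10, dtype=int)], pseudocount=1)
        np.testing.assert_allclose(pooled.pi, [1.0, 0.0])
        np.testing.assert_allclose(pooled.A.sum(axis=1), [1.0, 1.0])
        assert np.all(pooled.A > 0)

    def test_single_bin_sites_have_no_transitions(self):
        pooled = estimate_pooled_params(
            [np.array([1]), np.array([0]), np.array([1])], pseudocount=1
        )
        np.testing.assert_allclose(pooled.A, [[0.5, 0.5], [0.5, 0.5]])
        np.testing.assert_allclose(pooled.pi, [1 / 3, 2 / 3])

    def test_transitions_not_counted_across_sites(self):
        # sites [1] and [0, 0]: a cross-site 1->0 must not be counted
        pooled = estimate_pooled_params(
            [np.array([1]), np.array([0, 0])], pseudocount=0
        )
        np.testing.assert_allclose(pooled.A[1], [0.5, 0.5])  # untouched row

    def test_no_bins_rejected(self):
        with pytest.raises(ValidationError):
            estimate_pooled_params([], pseudocount=1)


class TestFhb:
    def test_run_of_signal_raises_posterior_inside(self, balanced_sizes):
        cfg = StrategyConfig(strategy="fhb", seed=0)
        res = run_fhb(_signal_table(), balanced_sizes, cfg)
        post = res.bins["posterior"].to_numpy()
        assert np.all(post[3:7] >= 0.5)
        assert post[0] < 0.5 and post[-1] < 0.5

    def test_null_table_stays_below_half(self, balanced_sizes):
        n = 10
        flat = np.full(n, 50)
        table = make_table({"s": (flat, flat, flat, flat)})
        res = run_fhb(table, balanced_sizes, StrategyConfig(strategy="fhb", seed=1))
        assert np.all(res.bins["posterior"].to_numpy() <= 0.5 + 1e-9)

    def test_short_site_falls_back_to_one_minus_p(self, balanced_sizes):
        flat = np.full(3, 40)
        table = make_table({"tiny": (flat, flat, flat, flat)})
        res = run_fhb(table, balanced_sizes, StrategyConfig(strategy="fhb"))
        assert res.bins["em_fallback"].all()
        np.testing.assert_allclose(
            res.bins["posterior"], 1.0 - res.bins["p_value"], atol=0
        )

    def test_posterior_invariant_to_subthreshold_pvalue_changes(self):
        # two results tables whose p/fdr differ but binarise identically
        base = pd.DataFrame(
            {
                "site_id": "s",
                "bin_index": np.arange(8),
                "p_value": [0.5, 0.6, 1e-6, 1e-6, 1e-6, 0.7, 0.8, 0.9],
                "fdr": [0.9, 0.9, 1e-5, 1e-5, 1e-5, 0.9, 0.9, 0.9],
            }
        )
        jitter = base.copy()
        jitter["p_value"] = [0.4, 0.7, 1e-8, 1e-7, 2e-6, 0.6, 0.95, 0.99]
        jitter["fdr"] = [0.8, 0.95, 1e-6, 1e-6, 4e-5, 0.8, 0.99, 1.0]
        cfg = StrategyConfig(strategy="fhb", seed=3)
        a = smooth_results(base, cfg).bins["posterior"]
        b = smooth_results(jitter, cfg).bins["posterior"]
        np.testing.assert_array_equal(a.to_numpy(), b.to_numpy())


class TestFhc:
    def test_uniform_pvalues_give_constant_posterior(self):
        # p = 0.5 everywhere makes the likelihood parameter-free; from a
        # symmetric start the posterior is the flat chain marginal 0.5
        from fethmm import baum_welch

        emission = build_emission_from_pvalues(np.full(6, 0.5))
        init = HmmParams(
            pi=np.array([0.5, 0.5]),
            A=np.array([[0.8, 0.2], [0.2, 0.8]]),
            emission=emission,
        )
        fit = baum_welch(init, max_iter=50)
        np.testing.assert_allclose(fit.track.gamma1, 0.5, atol=1e-9)

    def test_tiny_pvalues_everywhere_give_posterior_near_one(self):
        res = smooth_results(
            pd.DataFrame(
                {
                    "site_id": "s",
                    "bin_index": np.arange(8),
                    "p_value": 1e-8,
                    "fdr": 1e-7,
                }
            ),
            StrategyConfig(strategy="fhc", seed=0),
        )
        assert np.all(res.bins["posterior"].to_numpy() > 0.99)

    def test_posterior_matches_enumeration_at_fitted_params(self, balanced_sizes):
        cfg = StrategyConfig(strategy="fhc", seed=5)
        table = _signal_table(n=8, lo=2, hi=6)
        res = run_fhc(table, balanced_sizes, cfg)
        params = res.site_params["siteA"]
        g_ref, _, _ = enum_posterior(params.pi, params.A, params.emission.rows)
        np.testing.assert_allclose(
            res.bins["posterior"].to_numpy(), g_ref[:, 1], atol=1e-8
        )

    def test_pvalue_continuity(self):
        # small p perturbations move the posterior only slightly
        base = pd.DataFrame(
            {
                "site_id": "s",
                "bin_index": np.arange(6),
                "p_value": [0.3, 0.2, 0.01, 0.02, 0.4, 0.6],
                "fdr": 0.5,
            }
        )
        cfg = StrategyConfig(strategy="fhc", seed=2)
        a = smooth_results(base, cfg).bins["posterior"].to_numpy()
        pert = base.copy()
        pert["p_value"] = base["p_value"] * 1.01
        b = smooth_results(pert, cfg).bins["posterior"].to_numpy()
        assert np.max(np.abs(a - b)) < 0.05


class TestFastFhc:
    def test_single_site_equals_estep_with_pooled_params(self, balanced_sizes):
        cfg = StrategyConfig(strategy="fastfhc")
        table = _signal_table(n=10, lo=3, hi=7)
        res = run_fastfhc(table, balanced_sizes, cfg)
        emission = build_emission_from_pvalues(res.bins["p_value"].to_numpy())
        manual = estep_only(
            HmmParams(pi=res.pooled.pi, A=res.pooled.A, emission=emission)
        )
        np.testing.assert_array_equal(
            res.bins["posterior"].to_numpy(), manual.gamma1
        )

    def test_identical_sites_get_identical_tracks(self, balanced_sizes):
        n = 8
        x = np.full(n, 50)
        y1 = x.copy()
        y1[2:5] = 250
        table = make_table({"a": (x, x, x, y1), "b": (x, x, x, y1)})
        res = run_fastfhc(table, balanced_sizes, StrategyConfig(strategy="fastfhc"))
        post = res.bins["posterior"].to_numpy()
        np.testing.assert_array_equal(post[:n], post[n:])

    def test_posterior_matches_enumeration_at_pooled_params(self, balanced_sizes):
        table = _signal_table(n=7, lo=2, hi=5)
        res = run_fastfhc(table, balanced_sizes, StrategyConfig(strategy="fastfhc"))
        emission = build_emission_from_pvalues(res.bins["p_value"].to_numpy())
        g_ref, _, _ = enum_posterior(res.pooled.pi, res.pooled.A, emission.rows)
        np.testing.assert_allclose(
            res.bins["posterior"].to_numpy(), g_ref[:, 1], atol=1e-8
        )

    def test_pooled_params_invariant_to_subthreshold_pvalue_changes(self):
        base = pd.DataFrame(
            {
                "site_id": "s",
                "bin_index": np.arange(6),
                "p_value": [0.5, 1e-6, 1e-6, 0.6, 0.7, 0.8],
                "fdr": [0.9, 1e-5, 1e-5, 0.9, 0.9, 0.9],
            }
        )
        jitter = base.copy()
        jitter["fdr"] = [0.7, 1e-6, 3e-5, 0.99, 0.6, 0.95]
        cfg = StrategyConfig(strategy="fastfhc")
        a = smooth_results(base, cfg).pooled
        b = smooth_results(jitter, cfg).pooled
        np.testing.assert_array_equal(a.pi, b.pi)
        np.testing.assert_array_equal(a.A, b.A)


class TestDetectDispatch:
    @pytest.mark.parametrize("strategy", ["fhb", "fhc", "fastfhc"])
    def test_dispatch_matches_direct_runner(self, balanced_sizes, strategy):
        table = _signal_table()
        cfg = StrategyConfig(strategy=strategy, seed=11)
        direct = {"fhb": run_fhb, "fhc": run_fhc, "fastfhc": run_fastfhc}[strategy]
        a = detect(table, balanced_sizes, cfg)
        b = direct(table, balanced_sizes, cfg)
        np.testing.assert_array_equal(
            a.bins["posterior"].to_numpy(), b.bins["posterior"].to_numpy()
        )


class TestCallDmrs:
    def _result(self, posteriors, site="s"):
        n = len(posteriors)
        bins = pd.DataFrame(
            {
                "site_id": site,
                "bin_index": np.arange(n),
                "p_value": np.linspace(0.01, 0.5, n),
                "log2_or": np.ones(n),
                "posterior": posteriors,
            }
        )
        return DetectionResult(bins=bins, strategy="fhc")

    def test_two_runs_split_by_low_bin(self):
        dmrs = call_dmrs(self._result([0.95, 0.96, 0.1, 0.92]), cutoff=0.9)
        assert len(dmrs) == 2
        assert dmrs.iloc[0][["bin_first", "bin_last"]].tolist() == [0, 1]
        assert dmrs.iloc[1][["bin_first", "bin_last"]].tolist() == [3, 3]
        assert (dmrs["direction"] == 1).all()

    def test_no_bins_above_cutoff(self):
        dmrs = call_dmrs(self._result([0.1, 0.2, 0.3]), cutoff=0.9)
        assert dmrs.empty

    def test_cutoff_zero_spans_each_site(self):
        dmrs = call_dmrs(self._result([0.1, 0.2, 0.3]), cutoff=0.0)
        assert len(dmrs) == 1
        assert dmrs.iloc[0]["n_bins"] == 3

    def test_intervals_never_cross_site_boundaries(self):
        bins = pd.concat(
            [
                self._result([0.95, 0.95], site="a").bins,
                self._result([0.95, 0.95], site="b").bins,
            ],
            ignore_index=True,
        )
        dmrs = call_dmrs(DetectionResult(bins=bins, strategy="fhc"), cutoff=0.9)
        assert len(dmrs) == 2
        assert set(dmrs["site_id"]) == {"a", "b"}
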