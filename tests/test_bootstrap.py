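"""Paired bootstrap, confidence intervals, stability selection, first-drop."""

import numpy as np
import pandas as pd
import pytest

from stutterconn.bootstrap import (
    BootstrapConfig,
    BootstrapResult,
    build_selection_report,
    coefficient_ci,
    first_drop_cutoff,
    paired_bootstrap_indices,
    run_bootstrap,
    stability_select,
    write_selection_report,
)
from stutterconn.connectivity import DesignMatrix
from stutterconn.lasso import LassoConfig, lasso_fit


def _design(n=40, p=10, beta1=2.0, noise=0.5, seed=0, null=False):
    rng = np.random.default_rng(seed)
    X = np.column_stack([rng.standard_normal((n, p - 1)),
                         rng.integers(0, 2, n).astype(float)])
    y = rng.normal(0, 1, n) if null else beta1 * X[:, 0] + rng.normal(0, noise, n)
    y = y - y.min() + 0.1  # keep on a rate-like positive scale
    labels = tuple([f"c{i}" for i in range(p - 1)] + ["site"])
    return DesignMatrix(X=X, y=y, column_labels=labels,
                        site_column_index=p - 1,
                        subject_ids=tuple(f"P{i}" for i in range(n)))


def _fake_result(draws, labels=None):
    draws = np.asarray(draws, float)
    labels = labels or tuple(f"c{i}" for i in range(draws.shape[1]))
    return BootstrapResult(labels=tuple(labels), coef_draws=draws,
                           lambdas=np.ones(draws.shape[0]),
                           degenerate=np.zeros(draws.shape[0], bool), seed=0)


class TestPairedIndices:
    def test_shape_range_determinism(self):
        idx = paired_bootstrap_indices(20, 50, seed=3)
        assert idx.shape == (50, 20)
        assert idx.min() >= 0 and idx.max() < 20
        np.testing.assert_array_equal(idx, paired_bootstrap_indices(20, 50, seed=3))

    def test_distinct_row_count_matches_binomial_expectation(self):
        # E[#distinct] = n(1 - (1-1/n)^n) ~= 12.83 for n=20
        idx = paired_bootstrap_indices(20, 1000, seed=0)
        distinct = np.array([len(set(row.tolist())) for row in idx])
        assert 12.2 <= distinct.mean() <= 13.4

    def test_too_few_subjects(self):
        with pytest.raises(ValueError):
            paired_bootstrap_indices(1, 10, seed=0)


class TestRunBootstrap:
    def test_planted_effect_recovered(self):
        design = _design(seed=1)
        res = run_bootstrap(design, LassoConfig(), BootstrapConfig(n_boot=200, seed=1))
        assert res.mean_coef[0] > 0
        assert res.selection_freq[0] >= 0.9

    def test_null_outcome_coefficients_small(self):
        # under a pure-noise outcome the bootstrap-mean coefficients sit at the
        # chance-correlation scale: small on average relative to SD(y).  (The
        # per-predictor maximum can reach ~0.3 SD(y) at n=40 through a single
        # chance correlation, so the bound is on the average magnitude.)
        for seed in (2, 3, 4):
            design = _design(seed=seed, null=True)
            res = run_bootstrap(design, LassoConfig(seed=seed),
                                BootstrapConfig(n_boot=100, seed=seed))
            assert np.abs(res.mean_coef).mean() < 0.2 * design.y.std()

    def test_reproducible_draws(self):
        design = _design(n=15, seed=3)
        cfg = BootstrapConfig(n_boot=2, seed=9)
        r1 = run_bootstrap(design, LassoConfig(), cfg)
        r2 = run_bootstrap(design, LassoConfig(), cfg)
        assert r1.coef_draws.tobytes() == r2.coef_draws.tobytes()

    def test_degenerate_draws_recorded_as_zero(self):
        rng = np.random.default_rng(4)
        X = np.column_stack([rng.standard_normal((3, 2)), [1.0, 0.0, 0.0]])
        design = DesignMatrix(X=X, y=np.array([1.0, 1.0, 4.0]),
                              column_labels=("a", "b", "site"), site_column_index=2,
                              subject_ids=("p1", "p2", "p3"))
        res = run_bootstrap(design, LassoConfig(), BootstrapConfig(n_boot=40, seed=5))
        assert res.degenerate.any()
        assert np.all(res.coef_draws[res.degenerate] == 0.0)
        assert np.isnan(res.lambdas[res.degenerate]).all()

    def test_constant_outcome_hard_error(self):
        design = _design(n=10, seed=6)
        flat = DesignMatrix(X=design.X, y=np.full(10, 2.0),
                            column_labels=design.column_labels,
                            site_column_index=design.site_column_index,
                            subject_ids=design.subject_ids)
        with pytest.raises(RuntimeError, match="degenerate"):
            run_bootstrap(flat, LassoConfig(), BootstrapConfig(n_boot=20, seed=0))

    def test_avg_lambda_excludes_degenerate(self):
        res = BootstrapResult(labels=("c0",), coef_draws=np.array([[1.0], [0.0]]),
                              lambdas=np.array([0.5, np.nan]),
                              degenerate=np.array([False, True]), seed=0)
        assert res.avg_lambda == pytest.approx(0.5)


class TestCoefficientCI:
    def test_hand_computed_normal_interval(self):
        # draws engineered to mean 1.0, SD 0.1 exactly (B=2)
        d = 0.1 / np.sqrt(2)
        res = _fake_result(np.array([[1.0 - d], [1.0 + d]]))
        lo, hi, sig = coefficient_ci(res, BootstrapConfig(bonferroni_m=1))
        assert lo[0] == pytest.approx(0.804, abs=5e-4)
        assert hi[0] == pytest.approx(1.196, abs=5e-4)
        assert sig[0]

    def test_degenerate_zero_predictor_not_significant(self):
        res = _fake_result(np.zeros((5, 2)))
        lo, hi, sig = coefficient_ci(res, BootstrapConfig())
        assert not sig.any()
        assert lo[0] == hi[0] == 0.0

    def test_width_monotone_in_bonferroni_m(self):
        rng = np.random.default_rng(7)
        res = _fake_result(rng.normal(0.5, 0.2, size=(100, 3)))
        widths = []
        for m in (1, 3, 59):
            lo, hi, _ = coefficient_ci(res, BootstrapConfig(bonferroni_m=m))
            widths.append((hi - lo).mean())
        assert widths[0] < widths[1] < widths[2]

    def test_width_monotone_in_sd(self):
        res = _fake_result(np.column_stack([
            np.linspace(-0.1, 0.1, 50), np.linspace(-0.5, 0.5, 50)]))
        lo, hi, _ = coefficient_ci(res, BootstrapConfig())
        assert hi[1] - lo[1] > hi[0] - lo[0]

    def test_percentile_method(self):
        rng = np.random.default_rng(8)
        draws = rng.normal(1.0, 0.1, size=(2000, 1))
        res = _fake_result(draws)
        cfg = BootstrapConfig(bonferroni_m=1, ci_method="percentile")
        lo, hi, sig = coefficient_ci(res, cfg)
        assert lo[0] == pytest.approx(np.quantile(draws, 0.025), abs=1e-12)
        assert sig[0]

    def test_conditional_on_selection_variant(self):
        draws = np.array([[0.0], [2.0], [2.0], [0.0]])
        res = _fake_result(draws)
        lo, hi, sig = coefficient_ci(
            res, BootstrapConfig(condition_on_selection=True, bonferroni_m=1))
        assert lo[0] == hi[0] == pytest.approx(2.0)  # nonzero draws constant
        assert sig[0]


class TestStabilitySelection:
    def test_ranking_and_tie_breaks(self):
        # c0 selected 3x, c1 and c2 tied at 2 with |mean| deciding, c3 never
        draws = np.array([
            [1.0, 0.5, -2.0, 0.0],
            [1.0, 0.5, -2.0, 0.0],
            [1.0, 0.0, 0.0, 0.0],
        ])
        df = stability_select(_fake_result(draws))
        assert list(df["predictor"]) == ["c0", "c2", "c1", "c3"]
        assert list(df["selection_count"]) == [3, 2, 2, 0]

    def test_label_lexicographic_final_tie(self):
        draws = np.array([[1.0, -1.0], [1.0, -1.0]])
        df = stability_select(_fake_result(draws, labels=("zeta", "alpha")))
        assert list(df["predictor"]) == ["alpha", "zeta"]

    def test_input_order_invariance(self):
        rng = np.random.default_rng(9)
        draws = (rng.random((50, 6)) < 0.4) * rng.normal(size=(50, 6))
        labels = tuple(f"c{i}" for i in range(6))
        perm = rng.permutation(6)
        a = stability_select(_fake_result(draws, labels))
        b = stability_select(_fake_result(draws[:, perm], tuple(labels[i] for i in perm)))
        assert list(a["predictor"]) == list(b["predictor"])

    def test_selection_count_monotone_in_lambda(self):
        # refitting every draw at a larger fixed penalty never increases counts
        design = _design(n=30, seed=10)
        idx = paired_bootstrap_indices(30, 40, seed=11)
        counts = {}
        for lam in (0.05, 0.5):
            draws = np.vstack([
                lasso_fit(design.X[rows], design.y[rows], lam).coefficients
                for rows in idx])
            counts[lam] = np.count_nonzero(draws, axis=0)
        assert np.all(counts[0.5] <= counts[0.05])


class TestFirstDropCutoff:
    @pytest.mark.parametrize("counts,expected", [
        ([990, 985, 980, 400, 390], 3),
        ([1000, 0], 1),
        ([10, 4, 4, 4], 1),
        ([5, 5, 3, 3], 2),  # tie on equal drops goes to the earliest
    ])
    def test_examples(self, counts, expected):
        assert first_drop_cutoff(counts) == expected

    def test_all_equal_warns_empty(self):
        with pytest.warns(UserWarning, match="equal"):
            assert first_drop_cutoff([500, 500, 500]) == 0

    def test_input_validation(self):
        with pytest.raises(ValueError):
            first_drop_cutoff([5])
        with pytest.raises(ValueError):
            first_drop_cutoff([1, 5, 3])


class TestSelectionReport:
    def test_report_consistency(self):
        design = _design(seed=12)
        boot = BootstrapConfig(n_boot=50, seed=12)
        res = run_bootstrap(design, LassoConfig(), boot)
        rep = build_selection_report(res, boot)
        # significance flag must equal the zero-exclusion rule
        for j in range(len(rep.labels)):
            assert rep.significant[j] == (rep.ci_lower[j] > 0 or rep.ci_upper[j] < 0)
        assert len(rep.stable_set) == rep.cutoff_index
        # stable set is the top of the ranking
        assert list(rep.stable_set) == list(rep.ranking["predictor"][: rep.cutoff_index])

    def test_mean_matches_independent_recomputation(self):
        design = _design(n=20, seed=13)
        res = run_bootstrap(design, LassoConfig(), BootstrapConfig(n_boot=30, seed=13))
        np.testing.assert_allclose(
            res.mean_coef, res.coef_draws.sum(axis=0) / res.n_boot, atol=1e-12)
        np.testing.assert_array_equal(
            res.selection_count, (res.coef_draws != 0).sum(axis=0))

    def test_fixed_threshold_rule(self):
        draws = np.array([[1.0, 1.0, 0.0]] * 8 + [[1.0, 0.0, 0.0]] * 2)
        res = _fake_result(draws)
        rep = build_selection_report(
            res, BootstrapConfig(cutoff_rule="fixed_threshold", threshold=0.9))
        assert rep.stable_set == ("c0",)

    def test_writer_round_trip_and_determinism(self, tmp_path):
        design = _design(n=15, seed=14)
        boot = BootstrapConfig(n_boot=20, seed=14)
        res = run_bootstrap(design, LassoConfig(), boot)
        rep = build_selection_report(res, boot)
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_selection_report(rep, res, boot, p1, tmp_path / "a.json")
        write_selection_report(rep, res, boot, p2)
        assert p1.read_bytes() == p2.read_bytes()
        df = pd.read_csv(p1)
        assert set(df.columns) >= {"predictor", "mean_coef", "sd_coef", "ci_lower",
                                   "ci_upper", "significant", "selection_count",
                                   "stability_rank", "in_stable_set"}
        meta = (tmp_path / "a.json").read_text()
        assert "config_hash" in meta
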