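"""Staged least-squares inference: residuals, recovery, summary, holdout."""

import numpy as np
import pytest

from doublebind.fitting import (
    FitConfig,
    FitResult,
    StagingError,
    STAGE_FREE_PARAMS,
    fit_replicate,
    holdout_validate,
    residuals,
    staged_fit,
    summarize,
)
from doublebind.model_core import Condition, ParameterSet
from doublebind.synthetic_data import (
    ExperimentDesign,
    NoiseModel,
    TimeSeriesDataset,
    generate_dataset,
)

UT_FIXED = {"r_N": 0.0, "K_N": 1.0, "lambda_SN": 0.0, "lambda_RN": 0.0}


class TestResiduals:
    def test_zero_at_generating_truth(self, table1, noiseless_ds, one_rep_design):
        r = residuals(table1["UT"], noiseless_ds.subset("UT", 1),
                      one_rep_design, "UT")
        assert r.shape == (7 * 26 * 2,)
        assert np.max(np.abs(r)) < 1e-6

    def test_perturbation_gives_positive_loss(self, table1, noiseless_ds,
                                              one_rep_design):
        p = table1["UT"].with_values(r_S=table1["UT"].r_S * 1.1)
        r = residuals(p, noiseless_ds.subset("UT", 1), one_rep_design, "UT")
        assert np.sum(r ** 2) > 1e-4

    def test_time_grid_mismatch_is_data_error(self, noiseless_ds, table1,
                                              one_rep_design):
        sl = noiseless_ds.subset("UT", 1)
        df = sl.data.copy()
        df.loc[df.index[:26], "f"] = 0.3  # misaligned duplicate fraction
        df = df.iloc[5:]
        with pytest.raises(ValueError):
            residuals(table1["UT"], TimeSeriesDataset(df), one_rep_design, "UT")


class TestFitReplicate:
    def test_noiseless_recovery_within_one_percent(self, table1, staged_noiseless):
        truth = table1["UT"]
        fit = staged_noiseless[Condition.UT][0]
        for name in STAGE_FREE_PARAMS[Condition.UT]:
            est, tv = getattr(fit.params, name), getattr(truth, name)
            assert est == pytest.approx(tv, rel=0.01), name

    def test_untreated_holds_nk_terms_at_zero(self, staged_noiseless):
        p = staged_noiseless[Condition.UT][0].params
        assert p.lambda_SN == 0.0 and p.lambda_RN == 0.0 and p.r_N == 0.0
        assert {"lambda_SN", "lambda_RN", "r_N", "K_N"} <= set(p.fixed)

    def test_estimates_respect_bounds(self, staged_noiseless):
        cfg = FitConfig()
        for fits in staged_noiseless.values():
            for fit in fits:
                for name in ("r_S", "r_R", "r_N"):
                    lo, hi = cfg.rate_bounds
                    assert lo <= getattr(fit.params, name) <= hi
                for name in ("alpha_SR", "alpha_RS", "lambda_SN", "lambda_RN"):
                    lo, hi = cfg.interaction_bounds
                    assert lo <= getattr(fit.params, name) <= hi

    def test_deterministic_given_seed(self, noiseless_ds, one_rep_design):
        cfg = FitConfig(n_multistart=2, seed=11)
        fits = [
            fit_replicate(noiseless_ds.subset("UT", 1), "UT", cfg, UT_FIXED,
                          one_rep_design)
            for _ in range(2)
        ]
        assert fits[0].params == fits[1].params
        assert fits[0].loss == fits[1].loss

    def test_multistart_never_hurts_best_loss(self, noiseless_ds, one_rep_design):
        losses = {}
        for n in (1, 3):
            cfg = FitConfig(n_multistart=n, seed=0)
            fit = fit_replicate(noiseless_ds.subset("UT", 1), "UT", cfg,
                                UT_FIXED, one_rep_design)
            losses[n] = fit.loss
        assert losses[3] <= losses[1] + 1e-12

    def test_incomplete_fixed_set_rejected(self, noiseless_ds, one_rep_design):
        with pytest.raises(ValueError, match="staging"):
            fit_replicate(noiseless_ds.subset("UT", 1), "UT", FitConfig(),
                          {"K_N": 1.0}, one_rep_design)


class TestStagedFit:
    def test_treated_arms_carry_untreated_capacity_means(self, staged_noiseless):
        ut = staged_noiseless[Condition.UT]
        K_S = np.mean([r.params.K_S for r in ut if r.converged])
        K_R = np.mean([r.params.K_R for r in ut if r.converged])
        for cond in (Condition.RT, Condition.NK, Condition.RTNK):
            for fit in staged_noiseless[cond]:
                assert fit.params.K_S == pytest.approx(K_S, abs=1e-12)
                assert fit.params.K_R == pytest.approx(K_R, abs=1e-12)
                assert {"K_S", "K_R", "K_N"} <= set(fit.params.fixed)

    def test_one_result_per_replicate_per_condition(self, staged_noiseless,
                                                    noiseless_ds):
        n = len(noiseless_ds.replicates)
        assert set(staged_noiseless) == set(Condition)
        for fits in staged_noiseless.values():
            assert len(fits) == n

    def test_ut_only_dataset_yields_single_key(self, noiseless_ds):
        ds = noiseless_ds.subset("UT")
        out = staged_fit(ds, FitConfig(n_multistart=1))
        assert list(out) == [Condition.UT]

    def test_missing_ut_is_staging_error(self, noiseless_ds):
        ds = noiseless_ds.subset("RT")
        with pytest.raises(StagingError):
            staged_fit(ds, FitConfig(n_multistart=1))


def _result(cond, rep, converged=True, **overrides):
    base = dict(r_S=0.032, r_R=0.0357, r_N=0.0, K_S=1.27, K_R=0.779, K_N=1.0,
                alpha_SR=1.54, alpha_RS=0.3, lambda_SN=0.0, lambda_RN=0.0)
    base.update(overrides)
    params = ParameterSet(**base, fixed=frozenset(UT_FIXED))
    return FitResult(condition=Condition(cond), replicate=rep, params=params,
                     loss=0.0, converged=converged)


class TestSummarize:
    def test_sem_is_sample_sd_over_sqrt_n(self):
        results = {Condition.UT: [_result("UT", 1, r_S=0.03),
                                  _result("UT", 2, r_S=0.04)]}
        s = summarize(results)
        assert s.value("UT", "r_S") == pytest.approx(0.035)
        assert s.value("UT", "r_S", "sem") == pytest.approx(0.005)
        assert s.value("UT", "r_S", "n") == 2

    def test_identical_replicates_have_zero_sem(self):
        results = {Condition.UT: [_result("UT", i) for i in range(1, 13)]}
        s = summarize(results)
        for name in ("r_S", "K_S", "alpha_SR"):
            assert s.value("UT", name, "sem") == pytest.approx(0.0, abs=1e-15)

    def test_fixed_parameters_flagged_with_zero_sem(self):
        results = {Condition.UT: [_result("UT", 1), _result("UT", 2)]}
        s = summarize(results)
        row = s.table.query("condition == 'UT' and parameter == 'K_N'").iloc[0]
        assert row["mean"] == 1.0 and row["sem"] == 0.0 and bool(row["fixed"])

    def test_nonconverged_replicates_dropped(self):
        results = {Condition.UT: [_result("UT", 1, r_S=0.03),
                                  _result("UT", 2, r_S=0.9, converged=False)]}
        s = summarize(results)
        assert s.value("UT", "r_S") == pytest.approx(0.03)
        assert s.value("UT", "r_S", "n") == 1

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            summarize({})

    def test_json_round_trip(self, tmp_path):
        results = {Condition.UT: [_result("UT", 1), _result("UT", 2, r_S=0.04)]}
        s = summarize(results)
        path = tmp_path / "summary.json"
        s.to_json(path)
        from doublebind.fitting import FitSummary
        back = FitSummary.from_json(path)
        assert back.value("UT", "r_S") == s.value("UT", "r_S")
        assert back.replicate_values == s.replicate_values

    def test_mean_params_reconstruct_parameterset(self):
        results = {Condition.UT: [_result("UT", 1), _result("UT", 2)]}
        p = summarize(results).mean_params("UT")
        assert p.r_S == pytest.approx(0.032)
        assert "K_N" in p.fixed


@pytest.fixture(scope="module")
def two_rep_ut(table1):
    design = ExperimentDesign(n_replicates=2, conditions=(Condition.UT,))
    return generate_dataset(table1.as_truth(), design,
                            NoiseModel(law="none", seed=2))


class TestHoldout:
    def test_noiseless_validation_loss_near_zero(self, two_rep_ut):
        report = holdout_validate(two_rep_ut, [1], FitConfig(n_multistart=1))
        assert report["UT"]["validation_loss"] < 1e-10
        assert report["UT"]["n_train"] == 1 and report["UT"]["n_validation"] == 1

    def test_degenerate_splits_rejected(self, two_rep_ut):
        with pytest.raises(ValueError, match="degenerate"):
            holdout_validate(two_rep_ut, [1, 2], FitConfig(n_multistart=1))
        with pytest.raises(ValueError):
            holdout_validate(two_rep_ut, 1.2, FitConfig(n_multistart=1))
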