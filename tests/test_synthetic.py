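"""Synthetic biodistribution generator and TIAC recovery experiments."""

import numpy as np
import pytest

from augerdose.biokinetics import apply_physical_decay, fit_tail_exponential, time_integrated_activity
from augerdose.synthetic import (
    KineticModel,
    default_study_presets,
    generate_biodistribution,
    recovery_experiment,
    series_to_frame,
)


def _monoexp_model(cv=0.0):
    return KineticModel(
        tissue="washout",
        a1_pct_per_g=40.0,
        lambda1_per_h=0.003,
        a2_pct_per_g=0.0,
        noise_cv=cv,
        schedule_h=(1.0, 24.0, 48.0, 72.0, 168.0, 336.0, 504.0),
    )


class TestGenerator:
    def test_zero_cv_reproduces_model_means(self, spectrum):
        model = _monoexp_model(cv=0.0)
        series, _ = generate_biodistribution(model, spectrum, seed=1)
        expected = model.mean_pct_id_per_g(np.array(model.schedule_h))
        got = series[0].concentrations()
        assert np.allclose(got, expected)

    def test_same_seed_identical_tables(self, spectrum):
        presets = default_study_presets()
        f1 = series_to_frame(generate_biodistribution(presets, spectrum, seed=9)[0])
        f2 = series_to_frame(generate_biodistribution(presets, spectrum, seed=9)[0])
        assert f1.equals(f2)

    def test_different_seed_differs(self, spectrum):
        presets = default_study_presets()
        f1 = series_to_frame(generate_biodistribution(presets, spectrum, seed=9)[0])
        f2 = series_to_frame(generate_biodistribution(presets, spectrum, seed=10)[0])
        assert not f1.equals(f2)

    def test_lognormal_noise_is_mean_unbiased(self, spectrum):
        model = KineticModel(
            tissue="flat",
            a1_pct_per_g=10.0,
            lambda1_per_h=1e-6,
            noise_cv=0.2,
            n_animals=4000,
            schedule_h=(24.0,),
        )
        series, _ = generate_biodistribution(model, spectrum, seed=2)
        assert series[0].concentrations()[0] == pytest.approx(
            float(model.mean_pct_id_per_g(24.0)), rel=0.02
        )

    def test_empty_schedule_rejected(self):
        with pytest.raises(ValueError):
            KineticModel(
                tissue="x", a1_pct_per_g=1.0, lambda1_per_h=0.01, schedule_h=()
            )


class TestPresets:
    def test_kidney_anchors(self):
        kidney = default_study_presets()["kidney"]
        assert float(kidney.mean_pct_id_per_g(336.0)) == pytest.approx(12.8, rel=0.02)
        assert float(kidney.mean_pct_id_per_g(2016.0)) == pytest.approx(0.2, rel=0.02)

    def test_tumor_to_kidney_ratio_two_to_three(self):
        presets = default_study_presets()
        for t in (48.0, 168.0, 336.0, 504.0):
            ratio = float(
                presets["pip_tumor"].mean_pct_id_per_g(t)
                / presets["kidney"].mean_pct_id_per_g(t)
            )
            assert 2.0 <= ratio <= 3.0

    def test_flu_uptake_minimal(self):
        flu = default_study_presets()["flu_tumor"]
        t = np.linspace(0.1, 504.0, 2000)
        assert float(np.max(flu.mean_pct_id_per_g(t))) <= 1.4

    def test_all_presets_positive_everywhere(self):
        t = np.linspace(0.1, 2016.0, 500)
        for model in default_study_presets().values():
            assert np.all(model.mean_pct_id_per_g(t) > 0)

    def test_kidney_early_points_censored(self, spectrum):
        series, _ = generate_biodistribution(
            default_study_presets(), spectrum, seed=3
        )
        kidney = {s.tissue: s for s in series}["kidney"]
        assert [g.time_h for g in kidney.gaps] == [1.0, 24.0]


class TestTruth:
    def test_truth_matches_analytic_biexponential_integral(self, spectrum):
        model = KineticModel(
            tissue="biexp",
            a1_pct_per_g=30.0,
            lambda1_per_h=0.02,
            a2_pct_per_g=73.5,
            lambda2_per_h=0.0024755,
        )
        lam_p = spectrum.decay_constant_per_hour
        expected = 0.30 / (0.02 + lam_p) + 0.735 / (0.0024755 + lam_p)
        assert model.true_tiac(spectrum) == pytest.approx(expected, rel=1e-12)

    def test_uptake_reduces_truth(self, spectrum):
        base = _monoexp_model()
        with_uptake = KineticModel(
            tissue="washout",
            a1_pct_per_g=40.0,
            lambda1_per_h=0.003,
            uptake_tau_h=20.0,
            schedule_h=base.schedule_h,
        )
        assert with_uptake.true_tiac(spectrum) < base.true_tiac(spectrum)


class TestRecovery:
    def test_zero_noise_recovery_within_quadrature_error(self, spectrum):
        result = recovery_experiment(
            _monoexp_model(cv=0.0), spectrum, replicates=1, seed=1
        )
        assert abs(result["bias"]) < 0.01

    def test_noisy_recovery_small_bias(self, spectrum):
        model = KineticModel(
            tissue="pip_like",
            a1_pct_per_g=30.0,
            lambda1_per_h=0.02,
            a2_pct_per_g=73.5,
            uptake_tau_h=20.0,
            noise_cv=0.2,
            n_animals=5,
        )
        result = recovery_experiment(model, spectrum, replicates=50, seed=1)
        assert abs(result["bias"]) < 0.10
        assert result["rmse"] < 0.20

    def test_recovered_lambda_within_ten_percent(self, spectrum):
        # parameter recovery at default noise on a slow washout
        model = KineticModel(
            tissue="slow",
            a1_pct_per_g=30.0,
            lambda1_per_h=0.0024755,
            noise_cv=0.2,
            n_animals=5,
            schedule_h=(48.0, 168.0, 336.0, 672.0, 1008.0, 1344.0, 2016.0),
        )
        lam_p = spectrum.decay_constant_per_hour
        lam_eff = []
        for rep in range(30):
            series, _ = generate_biodistribution(model, spectrum, seed=100 + rep)
            physical = apply_physical_decay(series[0], spectrum, "to_physical")
            lam_eff.append(fit_tail_exponential(physical).lambda_eff_per_h)
        assert np.mean(lam_eff) == pytest.approx(
            model.lambda1_per_h + lam_p, rel=0.10
        )

    def test_replicate_count_validated(self, spectrum):
        with pytest.raises(ValueError):
            recovery_experiment(_monoexp_model(), spectrum, replicates=0)

    def test_pipeline_failure_carries_context(self, spectrum):
        # two quantified points cannot support a three-point tail fit
        model = KineticModel(
            tissue="short",
            a1_pct_per_g=10.0,
            lambda1_per_h=0.01,
            schedule_h=(24.0, 48.0),
        )
        with pytest.raises(RuntimeError, match="replicate 0"):
            recovery_experiment(model, spectrum, replicates=1)
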