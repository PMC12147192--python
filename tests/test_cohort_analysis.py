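import numpy as np
import pytest
from scipy import stats

from comtransfer.cohort_analysis import (
    InsufficientDataError,
    asymmetry_evolution,
    cfo_prediction_mae,
    fp_share_of_final_asymmetry,
    phase_contributions,
    stepwise_control_correlation,
    summarize_participant,
    summary_table,
    transfer_variability,
    velocity_offset_for_fp,
    work_vs_delta_regression,
)
from comtransfer.pipeline import analyze_trial
from comtransfer.step_metrics import StepMetrics
from comtransfer.synthetic_data import SyntheticConfig, simulate_trial


def make_step(direction, proj_ic=-0.10, proj_cfo=-0.09, final=-0.089,
              work=1.0, i=0, side=None):
    side = side or ("left" if direction == "paretic" else "right")
    return StepMetrics(
        step_index=i, leading_side=side, transfer_direction=direction,
        fp_ic=proj_ic * 1.05, v_ic=0.15, proj_ic=proj_ic, proj_cfo=proj_cfo,
        final_mag=final, delta_ds=proj_cfo - proj_ic, delta_ess=final - proj_cfo,
        work_ds=work, avg_power_ds=work / 0.2, avg_mlgrf_ds=50.0, avg_vel_ds=0.1,
        ds_duration=0.2, ess_duration=0.15, fp_component=proj_ic * 1.1,
        v_component=-proj_ic * 0.1, fp_coefficient=1.05, v_coefficient=0.10,
    )


class TestAsymmetryEvolution:
    def test_sign_rule_greater_transfer_toward_non_paretic(self):
        """Non-paretic final mean -0.08, paretic -0.12 gives +0.04: positive
        asymmetry means more transfer toward the non-paretic side."""
        steps = ([make_step("non_paretic", final=-0.08)] * 4
                 + [make_step("paretic", final=-0.12)] * 4)
        _, _, asym_final = asymmetry_evolution(steps)
        assert asym_final == pytest.approx(0.04)

    def test_symmetric_distributions_near_zero(self):
        rng = np.random.default_rng(0)
        steps = []
        for i in range(60):
            d = "paretic" if i % 2 else "non_paretic"
            steps.append(make_step(d, final=-0.09 + rng.normal(0, 0.01)))
        _, _, asym = asymmetry_evolution(steps)
        se = 0.01 * np.sqrt(2 / 30)
        assert abs(asym) < 2 * se + 1e-9

    def test_insufficient_side_flagged(self):
        steps = [make_step("paretic")] * 2 + [make_step("non_paretic")] * 5
        with pytest.raises(InsufficientDataError):
            asymmetry_evolution(steps)

    def test_prescribed_paretic_deficit_recovered(self):
        """A trial generated with wider paretic foot placement shows a
        positive IC asymmetry."""
        trial, _ = simulate_trial(SyntheticConfig(seed=41))
        _, metrics = analyze_trial(trial)
        asym_ic, asym_cfo, asym_final = asymmetry_evolution(metrics)
        assert asym_ic > 0
        assert asym_final > 0


class TestPhaseContributions:
    def test_all_at_ic(self):
        assert phase_contributions(0.04, 0.04, 0.04) == pytest.approx((100, 0, 0))

    def test_worked_arithmetic(self):
        a = 0.05
        c = phase_contributions(0.54 * a, 0.92 * a, a)
        assert c == pytest.approx((54, 38, 8))

    def test_sum_is_always_100(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            ic, cfo, final = rng.normal(0.02, 0.02, 3)
            if abs(final) < 1e-6:
                continue
            assert sum(phase_contributions(ic, cfo, final)) == pytest.approx(100.0, abs=1e-9)

    def test_degenerate_final_rejected(self):
        with pytest.raises(ValueError):
            phase_contributions(0.01, 0.01, 1e-9)


class TestPredictionMae:
    def test_perfect_prediction_zero(self):
        steps = [make_step(d, proj_cfo=-0.09, final=-0.09)
                 for d in ("paretic", "non_paretic") for _ in range(4)]
        assert cfo_prediction_mae(steps) == (0.0, 0.0)

    def test_noise_scale_mae(self, noisy_analyzed):
        """At ~1 mm kinematic noise the per-side MAE sits at the
        millimeter scale of marker-based motion capture."""
        _, _, _, metrics = noisy_analyzed
        mae_p, mae_np = cfo_prediction_mae(metrics)
        assert 0.5e-3 <= mae_p <= 3e-3
        assert 0.5e-3 <= mae_np <= 3e-3


class TestStepwiseControl:
    def test_perfect_compensation_r_minus_one(self):
        steps = []
        rng = np.random.default_rng(2)
        for i in range(20):
            d = "paretic" if i % 2 else "non_paretic"
            pic = -0.10 + rng.normal(0, 0.01)
            delta = -(pic - (-0.09))
            steps.append(make_step(d, proj_ic=pic, proj_cfo=pic + delta))
        r_p, r_np = stepwise_control_correlation(steps)
        assert r_p == pytest.approx(-1.0, abs=1e-6)
        assert r_np == pytest.approx(-1.0, abs=1e-6)

    def test_compensating_generator_recovers_negative_r(self):
        cfg = SyntheticConfig(seed=43, compensation_gain_p=1.0,
                              compensation_gain_np=1.0, work_sd=0.0,
                              noise_pos_sd=0.0, noise_grf_sd=0.0)
        trial, _ = simulate_trial(cfg)
        _, metrics = analyze_trial(trial)
        r_p, r_np = stepwise_control_correlation(metrics)
        assert r_p < -0.85
        assert r_np < -0.85

    def test_independent_changes_give_null_scale_r(self):
        """When the double-support change is statistically independent of
        the IC projection, r stays within the null sampling bound."""
        rng = np.random.default_rng(3)
        steps = []
        for i in range(200):
            d = "paretic" if i % 2 else "non_paretic"
            pic = -0.10 + rng.normal(0, 0.01)
            steps.append(make_step(d, proj_ic=pic,
                                   proj_cfo=pic + abs(rng.normal(0.012, 0.004))))
        r_p, r_np = stepwise_control_correlation(steps)
        assert abs(r_p) < 3 / np.sqrt(100)
        assert abs(r_np) < 3 / np.sqrt(100)

    def test_partial_compensation_recovers_negative_sign(self):
        """Partial compensation (gain 0.5) with work noise still shows up
        as a negative step-to-step correlation."""
        hits = 0
        for seed in range(10):
            cfg = SyntheticConfig(seed=seed, compensation_gain_p=0.5,
                                  compensation_gain_np=0.5, work_sd=0.15)
            trial, _ = simulate_trial(cfg)
            _, metrics = analyze_trial(trial)
            r_p, r_np = stepwise_control_correlation(metrics)
            hits += (r_p < 0) and (r_np < 0)
        assert hits >= 9


class TestVariability:
    def test_identical_steps_zero_sd(self):
        steps = [make_step(d) for d in ("paretic", "non_paretic") for _ in range(5)]
        assert transfer_variability(steps) == (0.0, 0.0, 0.0, 0.0)

    def test_fp_sd_propagates_through_coefficient(self):
        """With a prescribed 1.5 cm placement SD and no velocity spread,
        the SD of the IC projection lands inside the chi-distribution 95%
        interval around 1.5 cm x fp_coefficient."""
        cfg = SyntheticConfig(seed=45, n_steps=40, fp_sd_p=0.015, fp_sd_np=0.015,
                              v_ic_sd=0.0, noise_pos_sd=0.0, noise_grf_sd=0.0,
                              fp_centering_gain=0.0)
        trial, _ = simulate_trial(cfg)
        _, metrics = analyze_trial(trial)
        sd_ic_p, sd_ic_np, _, _ = transfer_variability(metrics)
        for side, sd in (("paretic", sd_ic_p), ("non_paretic", sd_ic_np)):
            ms = [m for m in metrics if m.transfer_direction == side]
            n = len(ms)
            c_fp = np.mean([m.fp_coefficient for m in ms])
            target = 0.015 * c_fp
            lo = target * np.sqrt(stats.chi2.ppf(0.025, n - 1) / (n - 1))
            hi = target * np.sqrt(stats.chi2.ppf(0.975, n - 1) / (n - 1))
            assert lo <= sd <= hi

    def test_compensation_reduces_final_variability(self):
        cfg = SyntheticConfig(seed=46, compensation_gain_p=1.0,
                              compensation_gain_np=1.0, work_sd=0.0,
                              noise_pos_sd=0.0, noise_grf_sd=0.0)
        trial, _ = simulate_trial(cfg)
        _, metrics = analyze_trial(trial)
        sd_ic_p, sd_ic_np, sd_f_p, sd_f_np = transfer_variability(metrics)
        assert sd_f_p < sd_ic_p
        assert sd_f_np < sd_ic_np


class TestWorkRegression:
    def test_exact_linear_relation(self):
        steps = []
        for i in range(20):
            d = "paretic" if i % 2 else "non_paretic"
            w = 0.5 + 0.05 * i
            steps.append(make_step(d, proj_ic=-0.10, proj_cfo=-0.10 + 0.01 * w, work=w))
        for slope, intercept, r2 in work_vs_delta_regression(steps).values():
            assert r2 == pytest.approx(1.0)
            assert slope == pytest.approx(0.01)

    def test_work_only_variation_high_r2(self):
        cfg = SyntheticConfig(seed=47, fp_sd_p=0.0, fp_sd_np=0.0, v_ic_sd=0.0,
                              work_sd=0.8, noise_pos_sd=0.0, noise_grf_sd=0.0)
        trial, _ = simulate_trial(cfg)
        _, metrics = analyze_trial(trial)
        for _, _, r2 in work_vs_delta_regression(metrics).values():
            assert r2 > 0.95

    def test_r2_degrades_with_state_noise(self):
        r2s = []
        for fp_sd in (0.0, 0.008, 0.02):
            cfg = SyntheticConfig(seed=48, fp_sd_p=fp_sd, fp_sd_np=fp_sd,
                                  v_ic_sd=fp_sd / 2, work_sd=0.8,
                                  noise_pos_sd=0.0, noise_grf_sd=0.0)
            trial, _ = simulate_trial(cfg)
            _, metrics = analyze_trial(trial)
            fits = work_vs_delta_regression(metrics)
            r2s.append(np.mean([f[2] for f in fits.values()]))
        assert r2s[0] > r2s[1] > r2s[2]


class TestWorkedExampleCalculators:
    def test_velocity_offset_zero(self):
        assert velocity_offset_for_fp(0.0, 1.05, 0.10) == 0.0

    def test_velocity_offset_printed_coefficients(self):
        """A 1 cm wider foot placement needs ~0.1 m/s more CoM velocity at
        the cohort-typical coefficients."""
        v = velocity_offset_for_fp(0.01, 1.05, 0.10)
        assert round(v, 1) == 0.1

    def test_velocity_offset_linearity(self):
        assert velocity_offset_for_fp(0.02, 1.05, 0.10) == pytest.approx(
            2 * velocity_offset_for_fp(0.01, 1.05, 0.10))

    def test_fp_share_printed_example(self):
        assert round(fp_share_of_final_asymmetry(53.9, 10.0), 1) == 49.0

    def test_fp_share_limits(self):
        assert fp_share_of_final_asymmetry(53.9, 1e9) == pytest.approx(53.9, abs=1e-6)
        assert fp_share_of_final_asymmetry(40.0, 1.0) == pytest.approx(20.0)


class TestParticipantSummary:
    def test_summary_consistency(self, noisy_analyzed):
        _, _, _, metrics = noisy_analyzed
        s = summarize_participant("P01", metrics)
        assert s.n_steps_p + s.n_steps_np == len(metrics)
        assert s.contrib_ic + s.contrib_ds + s.contrib_ess == pytest.approx(100.0, abs=1e-9)
        assert -1 <= s.r_p <= 1 and -1 <= s.r_np <= 1
        assert min(s.sd_ic_p, s.sd_ic_np, s.sd_final_p, s.sd_final_np) >= 0
        assert s.mae_p >= 0 and s.mae_np >= 0
        df = summary_table([s])
        assert len(df) == 1
        assert df.loc[0, "asym_ic"] == s.asym_ic
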