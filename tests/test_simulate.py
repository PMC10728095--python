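import numpy as np
import pytest

from ctldyn.model import CheckpointMode, SystemState
from ctldyn.simulate import (CLAMP_MM3, ClinicalLabel, classify_clinical,
                             default_initial_state, grid_response, integrate,
                             low_antigen_fraction, p2_threshold_for_reduction)


def logistic_volume(v0_mm3, rate, K_mm3, t):
    return K_mm3 / (1 + (K_mm3 / v0_mm3 - 1) * np.exp(-rate * t))


class TestIntegrate:
    def test_logistic_limit_matches_closed_form(self, baseline):
        """With no immune compartment the total tumor is exactly logistic."""
        p = baseline.with_updates(mu=0.0)
        init = SystemState(N=5e5, M=5e5, T=0.0)
        tr = integrate(p, init, CheckpointMode.BLOCKED, 150.0)
        expected = logistic_volume(1.0, p.alpha_n, 5000.0, tr.times)
        rel_err = np.abs(tr.volumes_mm3 - expected) / expected
        assert rel_err.max() < 1e-6

    def test_active_baseline_reaches_carrying_capacity_by_day_150(self,
                                                                  baseline):
        tr = integrate(baseline, default_initial_state(baseline),
                       CheckpointMode.ACTIVE, 150.0)
        assert tr.volume_at(150.0) == pytest.approx(5000.0, rel=0.02)

    def test_clamp_freezes_reported_volume(self, baseline):
        # strong uniform fast killing drives the tumor under the limit
        p = baseline.with_updates(p_1=1.0, p_2=1.0, delta_nf=1e-6,
                                  delta_mf=1e-6)
        init = default_initial_state(p, T0=p.mu / p.delta_t)
        tr = integrate(p, init, CheckpointMode.BLOCKED, 150.0)
        assert tr.clamped
        after = tr.times >= tr.clamped_at
        assert np.all(tr.volumes_mm3[after] == CLAMP_MM3)
        assert tr.label_at(150.0) is ClinicalLabel.CLINICAL_ELIMINATION

    def test_clamp_at_start_for_subthreshold_inoculum(self, baseline):
        init = SystemState(N=2.5e4, M=2.5e4, T=0.0)  # 0.05 mm3
        tr = integrate(baseline, init, CheckpointMode.ACTIVE, 10.0)
        assert tr.clamped_at == 0.0
        assert np.all(tr.volumes_mm3 == CLAMP_MM3)

    def test_post_clamp_T_relaxes_to_homeostasis(self, baseline):
        p = baseline.with_updates(p_1=1.0, p_2=1.0, delta_nf=1e-6,
                                  delta_mf=1e-6)
        init = default_initial_state(p, T0=p.mu / p.delta_t)
        tr = integrate(p, init, CheckpointMode.BLOCKED, 400.0)
        assert tr.clamped
        assert tr.T[-1] == pytest.approx(p.mu / p.delta_t, rel=1e-3)

    def test_readout_invariant_to_sampling_resolution(self, baseline):
        coarse = integrate(baseline, default_initial_state(baseline),
                           CheckpointMode.BLOCKED, 150.0,
                           t_eval=np.array([0.0, 25.0, 150.0]))
        fine = integrate(baseline, default_initial_state(baseline),
                         CheckpointMode.BLOCKED, 150.0)
        for day in (25.0, 150.0):
            assert coarse.volume_at(day) == pytest.approx(
                fine.volume_at(day), rel=1e-6)
            assert classify_clinical(coarse.volume_at(day)) is \
                classify_clinical(fine.volume_at(day))

    def test_readout_invariant_to_tolerance_tightening(self, baseline):
        init = default_initial_state(baseline)
        for mode in CheckpointMode:
            v1 = integrate(baseline, init, mode, 25.0).volume_at(25.0)
            v2 = integrate(baseline, init, mode, 25.0,
                           rtol=1e-9, atol=1e-3).volume_at(25.0)
            assert v1 == pytest.approx(v2, rel=1e-4)

    def test_trajectory_stays_nonnegative(self, baseline):
        p = baseline.with_updates(p_1=1.0, p_2=1.0, delta_nf=1e-6,
                                  delta_mf=1e-6)
        tr = integrate(p, default_initial_state(p, T0=1e6),
                       CheckpointMode.BLOCKED, 150.0)
        for arr in (tr.N, tr.M, tr.T):
            assert np.all(arr >= 0)

    def test_invalid_horizon(self, baseline):
        with pytest.raises(ValueError):
            integrate(baseline, default_initial_state(baseline),
                      CheckpointMode.ACTIVE, 0.0)


class TestClassifyClinical:
    @pytest.mark.parametrize("volume,label", [
        (0.0, ClinicalLabel.CLINICAL_ELIMINATION),
        (0.05, ClinicalLabel.CLINICAL_ELIMINATION),
        (0.1, ClinicalLabel.DORMANCY),       # boundary included in dormancy
        (500.0, ClinicalLabel.DORMANCY),
        (500.01, ClinicalLabel.ESCAPE),
        (600.0, ClinicalLabel.ESCAPE),
    ])
    def test_thresholds(self, volume, label):
        assert classify_clinical(volume) is label

    def test_clamped_readout_counts_as_eliminated(self):
        assert classify_clinical(0.1, clamped=True) is \
            ClinicalLabel.CLINICAL_ELIMINATION

    def test_negative_volume_rejected(self):
        with pytest.raises(ValueError):
            classify_clinical(-0.1)


class TestLowAntigenFraction:
    def test_even_split(self):
        assert low_antigen_fraction(SystemState(5e5, 5e5, 0)) == 0.5

    def test_pure_high_antigen(self):
        assert low_antigen_fraction(SystemState(1e6, 0, 0)) == 0.0

    def test_empty_tumor_is_undefined(self):
        assert np.isnan(low_antigen_fraction(SystemState(0, 0, 1e5)))


class TestGridResponse:
    def test_checkpoint_benefit_at_baseline(self, baseline):
        df = grid_response([baseline.p_1], [baseline.p_2], baseline,
                           days=[25.0])
        by_mode = df.set_index("mode")
        assert by_mode.loc["blocked", "volume_mm3"] < \
            by_mode.loc["active", "volume_mm3"]
        assert by_mode.loc["blocked", "percent_reduction"] >= 0.7

    def test_relapse_after_early_response(self, baseline):
        """Printed relapse coordinate: strong day-25 shrinkage under
        blockade, escape again by day 150."""
        df = grid_response([0.85], [0.36], baseline, days=[25.0, 150.0])
        b = df[df["mode"] == "blocked"].set_index("day")
        assert b.loc[25.0, "percent_reduction"] > 0.5
        assert b.loc[150.0, "volume_mm3"] > 500.0

    def test_low_antigen_takeover_when_p1_exceeds_p2(self, baseline):
        df = grid_response([0.92], [0.33], baseline, days=[150.0])
        b = df[df["mode"] == "blocked"]
        assert float(b.low_antigen_fraction.iloc[0]) > 0.95

    def test_rejects_out_of_range_probabilities(self, baseline):
        with pytest.raises(ValueError):
            grid_response([1.2], [0.5], baseline)


class TestP2Threshold:
    def test_trivial_target_is_zero(self, baseline):
        assert p2_threshold_for_reduction(1.0, 0.0, baseline) == 0.0

    def test_unattainable_target_returns_none(self, baseline):
        # with killing essentially disabled no reduction level is reachable
        p = baseline.with_updates(delta_nf=1e-8, delta_mf=1e-8,
                                  delta_ns=1.0, delta_ms=1.0, mu=5e3)
        assert p2_threshold_for_reduction(0.0, 0.99, p) is None

    def test_threshold_found_by_bisection_matches_grid_scan(self, baseline):
        """Bisection agrees with a direct scan of the reduction curve."""
        from ctldyn.simulate import _reduction_at
        target = 0.9
        star = p2_threshold_for_reduction(1.0, target, baseline, tol=1e-3)
        assert star is not None
        assert _reduction_at(min(star + 0.01, 1.0), 1.0, baseline, 25.0) \
            >= target
        assert _reduction_at(max(star - 0.01, 0.0), 1.0, baseline, 25.0) \
            < target
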