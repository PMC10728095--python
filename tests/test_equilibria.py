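import numpy as np
import pytest

from ctldyn.equilibria import (Branch, NoStableEquilibriumError, Stability,
                               SteadyOutcome, bifurcation_sweep,
                               classify_by_simulation, classify_steady_state,
                               find_equilibria, jacobian,
                               tumor_free_equilibrium)
from ctldyn.model import CheckpointMode
from ctldyn.simulate import integrate
from ctldyn.model import SystemState

B = CheckpointMode.BLOCKED
A = CheckpointMode.ACTIVE


class TestTumorFree:
    def test_homeostatic_T_level(self, baseline):
        eq = tumor_free_equilibrium(baseline, B)
        assert (eq.N, eq.M) == (0.0, 0.0)
        assert eq.T == pytest.approx(2e4 / 0.0412)  # ~4.854e5 cells
        assert eq.residual == pytest.approx(0.0, abs=1e-6)

    def test_closed_form_matches_numerical_jacobian(self, baseline):
        for mode in (A, B):
            eq = tumor_free_equilibrium(baseline, mode)
            J = jacobian(np.array([0.0, 0.0, eq.T]), baseline, mode)
            num = np.sort_complex(np.linalg.eigvals(J))
            ana = np.sort_complex(np.array(eq.eigenvalues))
            assert np.allclose(num, ana, rtol=1e-8)

    def test_no_immune_system_leaves_tumor_free_unstable(self, baseline):
        p = baseline.with_updates(mu=0.0)
        eq = tumor_free_equilibrium(p, B)
        assert eq.T == 0.0
        assert max(e.real for e in eq.eigenvalues) == pytest.approx(p.alpha_n)
        assert eq.stability is Stability.UNSTABLE


class TestFindEquilibria:
    def test_baseline_blocked_has_stable_escape_state(self, baseline):
        eqs = find_equilibria(baseline, B, n_starts=100, seed=1)
        stable = [e for e in eqs if e.stability is Stability.STABLE]
        assert any(e.total_tumor_mm3 >= 500 for e in stable)
        # the persistent tumor is purely low-antigen (p1 > p2)
        escape = max(stable, key=lambda e: e.total_tumor_mm3)
        assert escape.branch is Branch.M_ONLY

    def test_deterministic_under_fixed_seed(self, baseline):
        a = find_equilibria(baseline, B, n_starts=50, seed=7)
        b = find_equilibria(baseline, B, n_starts=50, seed=7)
        assert [(e.N, e.M, e.T) for e in a] == [(e.N, e.M, e.T) for e in b]

    def test_residual_bound_holds(self, baseline):
        for e in find_equilibria(baseline, B, n_starts=60, seed=3):
            scale = max(1.0, np.linalg.norm([e.N, e.M, e.T]))
            assert e.residual <= 1e-6 * scale

    def test_no_recruitment_recovers_logistic_fixed_points(self, baseline):
        p = baseline.with_updates(mu=0.0)
        eqs = find_equilibria(p, B, n_starts=40, seed=2)
        coords = {(round(e.N, 3), round(e.M, 3), round(e.T, 3)) for e in eqs}
        assert (0.0, 0.0, 0.0) in coords
        assert (p.K, 0.0, 0.0) in coords and (0.0, p.K, 0.0) in coords

    def test_stable_state_attracts_perturbations(self, baseline):
        eqs = find_equilibria(baseline, B, n_starts=100, seed=1)
        stable = [e for e in eqs if e.stability is Stability.STABLE]
        for e in stable:
            y0 = SystemState(N=e.N * 1.01, M=e.M * 1.01, T=e.T * 1.01)
            tr = integrate(baseline, y0, B, 2000.0,
                           t_eval=np.array([0.0, 2000.0]))
            final = np.array([tr.N[-1], tr.M[-1], tr.T[-1]])
            ref = np.array([e.N, e.M, e.T])
            assert np.linalg.norm(final - ref) <= 1e-3 * np.linalg.norm(ref)


class TestClassification:
    def test_baseline_blocked_escapes_with_certainty(self, baseline):
        res = classify_steady_state(baseline, B, n_starts=100, seed=1)
        assert res.outcomes == frozenset({SteadyOutcome.ESCAPE})
        assert not res.bistable
        assert res.composition == "low_antigen_dominant"

    def test_swap_symmetry_flips_composition(self, baseline):
        res = classify_steady_state(
            baseline.with_updates(p_1=0.33, p_2=0.92), B,
            n_starts=100, seed=1)
        assert res.outcomes == frozenset({SteadyOutcome.ESCAPE})
        assert res.composition == "high_antigen_dominant"

    def test_high_recruitment_opens_elimination_escape_bistability(
            self, baseline):
        """Raising T-cell recruitment creates initial-condition-dependent
        elimination alongside escape (adoptive-transfer scenario)."""
        p = baseline.with_updates(mu=8e4, p_1=1.0, p_2=0.9)
        res = classify_steady_state(p, B, n_starts=150, seed=1)
        assert SteadyOutcome.ELIMINATION in res.outcomes
        assert SteadyOutcome.ESCAPE in res.outcomes
        assert res.bistable

    def test_cytokine_boost_enables_dormancy_near_4x_baseline(self, baseline):
        """Dormancy requires roughly a four-fold increase of antigen-driven
        CTL proliferation over baseline (checkpoint blocked)."""
        def dormant(amt):
            res = classify_steady_state(
                baseline.with_updates(alpha_mt=amt), B, n_starts=120, seed=4)
            return SteadyOutcome.DORMANCY in res.outcomes

        assert not dormant(0.15)  # baseline: escape only
        lo, hi = 0.15, 1.0
        assert dormant(hi)
        for _ in range(12):
            mid = 0.5 * (lo + hi)
            if dormant(mid):
                hi = mid
            else:
                lo = mid
        fold = hi / 0.15
        assert 3.0 <= fold <= 5.0  # "approximately four times", +/- 25%

    def test_unstable_only_draw_raises_and_simulation_fallback_works(
            self, baseline):
        # symmetric diagonal: neutral direction leaves attractors marginal
        p = baseline.with_updates(p_1=0.0, p_2=0.0, mu=8e4)
        with pytest.raises(NoStableEquilibriumError):
            classify_steady_state(p, B, n_starts=60, seed=2)
        sim = classify_by_simulation(p, B)
        assert SteadyOutcome.ESCAPE in sim


class TestBifurcationSweep:
    def test_cytokine_slices_expand_bistable_dormancy_region(self, baseline):
        grids = np.linspace(0.05, 0.95, 5)
        counts = {}
        for amt in (0.05, 0.5):
            df = bifurcation_sweep("p_1", grids, "p_2", grids, B,
                                   slice_param="alpha_mt",
                                   slice_values=[amt], n_starts=40, seed=2)
            counts[amt] = (df.outcome_set == "dormancy+escape").sum()
        assert counts[0.5] > counts[0.05]

    def test_recruitment_slice_contains_elimination_escape_region(
            self, baseline):
        grids = np.linspace(0.05, 0.95, 5)
        df = bifurcation_sweep("p_1", grids, "p_2", grids, B,
                               slice_param="mu", slice_values=[8e4],
                               n_starts=40, seed=2)
        assert (df.outcome_set == "elimination+escape").any()
        assert not (df.outcome_set == "failed").any()

    def test_unknown_parameter_rejected(self):
        with pytest.raises(KeyError):
            bifurcation_sweep("nope", [0.1], "p_2", [0.1], B)
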