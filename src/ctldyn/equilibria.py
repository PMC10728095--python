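"""Steady states, stability, bistability, and bifurcation region maps.

Steady-state outcomes use the bifurcation thresholds (distinct from the
clinical ones): elimination means literally no tumor cells, dormancy a
persistent tumor below 500 mm³, escape at or above 500 mm³. Bistability is
the coexistence of two or more stable outcomes, selected by initial
conditions. Persistent tumors are single-phenotype at steady state (the
faster-killed compartment is competitively excluded), so composition is
reported as high- or low-antigen dominant.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .model import CELLS_PER_MM3, CheckpointMode, checkpoint_factor, rhs_array
from .parameters import PARAMETER_NAMES, ParameterSet
from .simulate import DORMANCY_UPPER_MM3

__all__ = [
    "Branch",
    "Stability",
    "SteadyOutcome",
    "Equilibrium",
    "SteadyStateOutcome",
    "NoStableEquilibriumError",
    "jacobian",
    "tumor_free_equilibrium",
    "find_equilibria",
    "classify_steady_state",
    "classify_by_simulation",
    "bifurcation_sweep",
]

#: Eigenvalue tolerance (per day) separating stable/unstable from marginal.
TOL_EIG: float = 1e-8
#: Relative residual bound every reported equilibrium must satisfy.
RESIDUAL_RTOL: float = 1e-6


class Branch(enum.Enum):
    TUMOR_FREE = "tumor_free"
    N_ONLY = "N_only"
    M_ONLY = "M_only"
    INTERIOR = "interior"


class Stability(enum.Enum):
    STABLE = "stable"
    UNSTABLE = "unstable"
    MARGINAL = "marginal"


class SteadyOutcome(enum.Enum):
    ELIMINATION = "elimination"   # no tumor cells at all
    DORMANCY = "dormancy"         # persistent tumor < 500 mm³
    ESCAPE = "escape"             # tumor >= 500 mm³


class NoStableEquilibriumError(RuntimeError):
    """No stable equilibrium located; fall back to simulation from a grid of
    initial conditions (classify_by_simulation)."""


@dataclass(frozen=True)
class Equilibrium:
    """A fixed point (N*, M*, T*) with its local stability."""

    N: float
    M: float
    T: float
    residual: float
    eigenvalues: tuple[complex, complex, complex]
    stability: Stability
    branch: Branch

    @property
    def total_tumor_mm3(self) -> float:
        return (self.N + self.M) / CELLS_PER_MM3

    def outcome(self) -> SteadyOutcome:
        if self.N + self.M == 0:
            return SteadyOutcome.ELIMINATION
        if self.total_tumor_mm3 < DORMANCY_UPPER_MM3:
            return SteadyOutcome.DORMANCY
        return SteadyOutcome.ESCAPE


@dataclass(frozen=True)
class SteadyStateOutcome:
    """Union of outcomes over all stable equilibria of one parameter set."""

    outcomes: frozenset[SteadyOutcome]
    bistable: bool
    composition: str  # high_antigen_dominant | low_antigen_dominant | none


def jacobian(y: np.ndarray, params: ParameterSet, mode: CheckpointMode,
             rel_step: float = 6e-6) -> np.ndarray:
    """Central finite-difference Jacobian of the right-hand side at ``y``."""
    y = np.asarray(y, dtype=float)
    J = np.empty((3, 3))
    for j in range(3):
        h = rel_step * max(abs(y[j]), 1e3)
        yp, ym = y.copy(), y.copy()
        yp[j] += h
        ym[j] -= h
        J[:, j] = (rhs_array(0.0, yp, params, mode)
                   - rhs_array(0.0, ym, params, mode)) / (2 * h)
    return J


def _classify_eigs(eigs: np.ndarray) -> Stability:
    re = np.real(eigs)
    if np.all(re < -TOL_EIG):
        return Stability.STABLE
    if np.any(re > TOL_EIG):
        return Stability.UNSTABLE
    return Stability.MARGINAL


def _make_equilibrium(y: np.ndarray, params: ParameterSet,
                      mode: CheckpointMode, branch: Branch,
                      eigs: np.ndarray | None = None) -> Equilibrium:
    resid = float(np.max(np.abs(rhs_array(0.0, y, params, mode))))
    if eigs is None:
        eigs = np.linalg.eigvals(jacobian(y, params, mode))
    eigs = eigs[np.argsort(-np.real(eigs))]
    return Equilibrium(N=float(y[0]), M=float(y[1]), T=float(y[2]),
                       residual=resid,
                       eigenvalues=tuple(complex(e) for e in eigs),
                       stability=_classify_eigs(eigs), branch=branch)


def tumor_free_equilibrium(params: ParameterSet,
                           mode: CheckpointMode) -> Equilibrium:
    """The tumor-free state (0, 0, mu/delta_t) with closed-form eigenvalues.

    The Jacobian there is lower triangular: lambda_T = -delta_t, and each
    tumor phenotype's invasion eigenvalue is its per-capita net growth rate
    against the homeostatic effector level,
    lambda_N = alpha_n - F*·[p_1 delta_nf T* + (1-p_1) slow(T*)].
    """
    if params.delta_t <= 0:
        raise ValueError("tumor-free equilibrium requires delta_t > 0")
    T_star = params.mu / params.delta_t
    y = np.array([0.0, 0.0, T_star])
    F = checkpoint_factor(params, y, mode)
    slow = params.kappa_1 * T_star / (params.kappa_0 + params.kappa_1 * T_star)
    lam_N = params.alpha_n - F * (params.p_1 * params.delta_nf * T_star
                                  + (1 - params.p_1) * params.delta_ns * slow)
    lam_M = params.alpha_m - F * (params.p_2 * params.delta_mf * T_star
                                  + (1 - params.p_2) * params.delta_ms * slow)
    eigs = np.array([lam_N, lam_M, -params.delta_t], dtype=complex)
    return _make_equilibrium(y, params, mode, Branch.TUMOR_FREE, eigs=eigs)


_BRANCH_FREE = {
    Branch.N_ONLY: (0, 2),
    Branch.M_ONLY: (1, 2),
    Branch.INTERIOR: (0, 1, 2),
}


def _branch_residual(z: np.ndarray, free: tuple[int, ...],
                     params: ParameterSet, mode: CheckpointMode) -> np.ndarray:
    """Per-capita residuals on a branch, in log coordinates (positivity is
    built in; the trivial zero roots are removed by dividing by N, M, T)."""
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        y = np.zeros(3)
        y[list(free)] = np.exp(z)
        d = rhs_array(0.0, y, params, mode)
        return np.array([d[i] / y[i] for i in free])


def find_equilibria(params: ParameterSet, mode: CheckpointMode,
                    n_starts: int = 200, seed: int = 0) -> list[Equilibrium]:
    """Multistart root finding on each invariant branch.

    Starts are log-uniform over [1, 10 K] per free coordinate; solutions are
    deduplicated at relative distance 1e-6 and must satisfy the residual
    bound. The tumor-free equilibrium (closed form) is always included; a
    branch with no converged roots contributes nothing.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    rng = np.random.default_rng(seed)
    found: list[np.ndarray] = []
    branches: list[Branch] = []

    if params.delta_t > 0:
        tf = tumor_free_equilibrium(params, mode)
        out = [tf]
        found.append(np.array([0.0, 0.0, tf.T]))
        branches.append(Branch.TUMOR_FREE)
    else:
        out = []

    if params.mu == 0:
        # With no baseline recruitment the T-free plane is invariant:
        # (0,0,0) plus each phenotype resting at carrying capacity.
        for y in (np.zeros(3), np.array([params.K, 0.0, 0.0]),
                  np.array([0.0, params.K, 0.0])):
            out.append(_make_equilibrium(y, params, mode,
                                         Branch.TUMOR_FREE if y[0] + y[1] == 0
                                         else (Branch.N_ONLY if y[1] == 0
                                               else Branch.M_ONLY)))
            found.append(y)
            branches.append(out[-1].branch)

    hi = np.log(10 * params.K)
    for branch, free in _BRANCH_FREE.items():
        k = len(free)
        z0s = rng.uniform(0.0, hi, size=(n_starts, k))
        for z0 in z0s:
            sol = root(_branch_residual, z0, args=(free, params, mode),
                       method="hybr", options={"xtol": 1e-12})
            if not sol.success:
                continue
            y = np.zeros(3)
            y[list(free)] = np.exp(sol.x)
            if not np.all(np.isfinite(y)) or np.any(y[list(free)] > 100 * params.K):
                continue
            resid = np.max(np.abs(rhs_array(0.0, y, params, mode)))
            if resid > RESIDUAL_RTOL * max(1.0, float(np.linalg.norm(y))):
                continue
            scale = max(1.0, float(np.linalg.norm(y)))
            if any(np.linalg.norm(y - f) <= 1e-6 * max(scale, 1.0,
                                                       float(np.linalg.norm(f)))
                   for f in found):
                continue
            found.append(y)
            branches.append(branch)
            out.append(_make_equilibrium(y, params, mode, branch))
    return out


def _composition(stable_persistent: list[Equilibrium]) -> str:
    if not stable_persistent:
        return "none"
    comps = set()
    for eq in stable_persistent:
        if eq.branch is Branch.N_ONLY:
            comps.add("high_antigen_dominant")
        elif eq.branch is Branch.M_ONLY:
            comps.add("low_antigen_dominant")
        else:
            comps.add("mixed")
    if comps == {"high_antigen_dominant"}:
        return "high_antigen_dominant"
    if comps == {"low_antigen_dominant"}:
        return "low_antigen_dominant"
    return "none"


def classify_steady_state(params: ParameterSet, mode: CheckpointMode,
                          n_starts: int = 200, seed: int = 0,
                          equilibria: list[Equilibrium] | None = None,
                          ) -> SteadyStateOutcome:
    """Outcome set over all stable equilibria, with bistability flag and the
    composition of the persistent (nonzero) state."""
    eqs = equilibria if equilibria is not None else find_equilibria(
        params, mode, n_starts=n_starts, seed=seed)
    stable = [e for e in eqs if e.stability is Stability.STABLE]
    if not stable:
        raise NoStableEquilibriumError(
            "no stable equilibrium found; classify by simulation from a grid "
            "of initial conditions (classify_by_simulation)")
    outcomes = frozenset(e.outcome() for e in stable)
    persistent = [e for e in stable if e.N + e.M > 0]
    return SteadyStateOutcome(outcomes=outcomes,
                              bistable=len(outcomes) >= 2,
                              composition=_composition(persistent))


def classify_by_simulation(params: ParameterSet, mode: CheckpointMode,
                           t_end: float = 2000.0,
                           tumor_grid: tuple[float, ...] = (1e4, 1e7, 5e9),
                           T_grid: tuple[float, ...] = (1e4, 3e5, 1e7),
                           ) -> frozenset[SteadyOutcome]:
    """Long-run outcomes reached by unclamped integration from a grid of
    initial conditions (the simulation counterpart of the equilibrium map)."""
    labels = set()
    for N0, M0, T0 in itertools.product(tumor_grid, tumor_grid, T_grid):
        sol = solve_ivp(rhs_array, (0.0, t_end), [N0, M0, T0],
                        method="LSODA", args=(params, mode),
                        rtol=1e-8, atol=1e-2)
        if not sol.success:
            continue
        tot = max(sol.y[0, -1] + sol.y[1, -1], 0.0)
        if tot < 1.0:  # below one cell: eliminated
            labels.add(SteadyOutcome.ELIMINATION)
        elif tot / CELLS_PER_MM3 < DORMANCY_UPPER_MM3:
            labels.add(SteadyOutcome.DORMANCY)
        else:
            labels.add(SteadyOutcome.ESCAPE)
    return frozenset(labels)


def bifurcation_sweep(param_x: str, grid_x, param_y: str, grid_y,
                      mode: CheckpointMode,
                      slice_param: str | None = None, slice_values=None,
                      n_starts: int = 60, seed: int = 0,
                      params: ParameterSet | None = None) -> pd.DataFrame:
    """Classify the steady-state outcome set over a 2-D parameter plane,
    optionally repeated at several values of a third parameter.

    Emits a long-format table (param names/values, slice, outcome set as a
    '+'-joined sorted string, bistable flag, composition); per-point failures
    are recorded with outcome_set='failed' and the sweep continues.
    """
    for name in filter(None, (param_x, param_y, slice_param)):
        if name not in PARAMETER_NAMES:
            raise KeyError(f"unknown parameter {name!r}")
    base = params if params is not None else ParameterSet.baseline()
    slices = [None] if slice_param is None else list(slice_values)
    rows = []
    for s in slices:
        for vx in grid_x:
            for vy in grid_y:
                updates = {param_x: float(vx), param_y: float(vy)}
                if slice_param is not None:
                    updates[slice_param] = float(s)
                row = dict(param_x=param_x, x=vx, param_y=param_y, y=vy,
                           slice_param=slice_param, slice=s)
                try:
                    pset = base.with_updates(**updates)
                    res = classify_steady_state(pset, mode,
                                                n_starts=n_starts, seed=seed)
                    row.update(outcome_set="+".join(
                                   sorted(o.value for o in res.outcomes)),
                               bistable=res.bistable,
                               composition=res.composition,
                               method="equilibria")
                except NoStableEquilibriumError:
                    # e.g. the symmetric p1 = p2 diagonal, where a neutral
                    # direction leaves every attractor marginal
                    sim = classify_by_simulation(pset, mode)
                    row.update(outcome_set="+".join(
                                   sorted(o.value for o in sim)),
                               bistable=len(sim) >= 2, composition="none",
                               method="simulation")
                except Exception:
                    row.update(outcome_set="failed", bistable=False,
                               composition="none", method="failed")
                rows.append(row)
    return pd.DataFrame(rows)
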