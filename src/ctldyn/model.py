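"""Core model: state, checkpoint suppression, killing responses, and the ODE
right-hand side.

The system tracks high-antigen tumor cells N, low-antigen tumor cells M and
cytotoxic T cells T (all in cells; time in days):

    dN/dt = alpha_n N (1 - (N+M)/K) - F [ p_1 delta_nf T + (1-p_1) S_ns ] N
    dM/dt = alpha_m M (1 - (N+M)/K) - F [ p_2 delta_mf T + (1-p_2) S_ms ] M
    dT/dt = mu + [ alpha_nt N/(kappa_2+N) + alpha_mt M/(kappa_2+M) ] T
            - delta_t T - delta_n N T - delta_m M T

with the slow (FasL) kill rate a Beddington–DeAngelis functional response

    S_s = delta_s kappa_1 T / (kappa_0 + kappa_1 T + N + M),

which saturates at the maximum rate delta_s as effectors accumulate and is
diluted by tumor bulk (effectors are shared over targets). The fast
(perforin) kill is mass action, delta_f·T per target cell.

F is the PD-1/PD-L1 suppression factor: with the checkpoint active,
F = 1 / (1 + P·L / k_TQ) where P = rho_p·T is total PD-1 and
L = rho_l·(T + eps_c·(N+M)) total PD-L1; with the checkpoint blocked, F = 1.
p_1, p_2 interpolate each tumor compartment's loss between the pure slow
(saturating, FasL) and pure fast (mass-action, perforin) killing mechanisms.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

from .parameters import ParameterSet

__all__ = [
    "CheckpointMode",
    "SystemState",
    "CELLS_PER_MM3",
    "mm3_to_cells",
    "cells_to_mm3",
    "checkpoint_factor",
    "slow_kill_rate",
    "rhs",
    "rhs_array",
]

#: Volume convention used package-wide: 1 mm³ of tumor = 1e6 cells, the
#: standard solid-tumor bookkeeping (places the 5e9-cell carrying capacity
#: at 5000 mm³ and a 1 mm³ inoculum at 1e6 cells).
CELLS_PER_MM3: float = 1e6


class CheckpointMode(enum.Enum):
    """PD-1/PD-L1 checkpoint status: ``active`` (suppression F < 1 whenever
    PD-1 and PD-L1 are both present) or ``blocked`` (ideal blockade, F ≡ 1)."""

    ACTIVE = "active"
    BLOCKED = "blocked"


@dataclass(frozen=True)
class SystemState:
    """Cell counts (N, M, T) at time t (days)."""

    N: float
    M: float
    T: float
    t: float = 0.0

    def __post_init__(self) -> None:
        for name in ("N", "M", "T", "t"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")

    @property
    def total_tumor_cells(self) -> float:
        return self.N + self.M

    @property
    def total_tumor_mm3(self) -> float:
        return cells_to_mm3(self.N + self.M)

    def as_array(self) -> np.ndarray:
        return np.array([self.N, self.M, self.T], dtype=float)


def mm3_to_cells(volume_mm3: float) -> float:
    """Convert tumor volume (mm³) to a cell count."""
    if volume_mm3 < 0:
        raise ValueError(f"volume must be >= 0, got {volume_mm3}")
    return volume_mm3 * CELLS_PER_MM3


def cells_to_mm3(cells: float) -> float:
    """Convert a tumor cell count to volume (mm³)."""
    if cells < 0:
        raise ValueError(f"cell count must be >= 0, got {cells}")
    return cells / CELLS_PER_MM3


def checkpoint_factor(
    params: ParameterSet,
    state: SystemState | np.ndarray,
    mode: CheckpointMode,
) -> float:
    """PD-1/PD-L1 suppression factor F in (0, 1].

    F multiplies the two CTL kill terms only; blockade pins F at 1.
    """
    if mode is CheckpointMode.BLOCKED:
        return 1.0
    if isinstance(state, SystemState):
        N, M, T = state.N, state.M, state.T
    else:
        N, M, T = state
    P = params.rho_p * T
    L = params.rho_l * (T + params.eps_c * (N + M))
    return 1.0 / (1.0 + P * L / params.k_TQ)


def slow_kill_rate(T: float, delta_s: float, kappa_0: float,
                   kappa_1: float, tumor_cells: float = 0.0) -> float:
    """Per-capita tumor death rate from slow (FasL) killing by T effectors.

    rate = delta_s·kappa_1·T / (kappa_0 + kappa_1·T + tumor_cells): a
    Beddington–DeAngelis response, linear in T when effectors are scarce,
    saturating at the maximum rate delta_s as effectors accumulate, and
    diluted by tumor bulk (a fixed effector pool is shared over targets).
    """
    if T < 0:
        raise ValueError(f"T must be >= 0, got {T}")
    if tumor_cells < 0:
        raise ValueError(f"tumor_cells must be >= 0, got {tumor_cells}")
    if T == 0:
        return 0.0
    denom = kappa_0 + kappa_1 * T + tumor_cells
    if denom <= 0:
        raise ValueError(
            "degenerate slow-kill parameters: kappa_0 + kappa_1*T + tumor "
            "must be > 0")
    return delta_s * kappa_1 * T / denom


def rhs_array(t: float, y: np.ndarray, params: ParameterSet,
              mode: CheckpointMode) -> np.ndarray:
    """Right-hand side on a raw (N, M, T) array; the solver-facing form.

    Accepts (transient, solver-internal) slightly negative coordinates; the
    algebraic forms remain well defined there.
    """
    N, M, T = float(y[0]), float(y[1]), float(y[2])
    p = params

    if mode is CheckpointMode.BLOCKED:
        F = 1.0
    else:
        P = p.rho_p * T
        L = p.rho_l * (T + p.eps_c * (N + M))
        F = 1.0 / (1.0 + P * L / p.k_TQ)

    crowding = 1.0 - (N + M) / p.K
    # shared Beddington-DeAngelis response (without the delta_s factor)
    slow = p.kappa_1 * T / (p.kappa_0 + p.kappa_1 * T + N + M)
    kill_n = p.p_1 * p.delta_nf * T + (1.0 - p.p_1) * p.delta_ns * slow
    kill_m = p.p_2 * p.delta_mf * T + (1.0 - p.p_2) * p.delta_ms * slow

    dN = p.alpha_n * N * crowding - F * kill_n * N
    dM = p.alpha_m * M * crowding - F * kill_m * M
    stim = p.alpha_nt * N / (p.kappa_2 + N) + p.alpha_mt * M / (p.kappa_2 + M)
    dT = p.mu + stim * T - p.delta_t * T - p.delta_n * N * T - p.delta_m * M * T
    return np.array([dN, dM, dT])


def rhs(state: SystemState, params: ParameterSet,
        mode: CheckpointMode) -> tuple[float, float, float]:
    """Time derivatives (dN/dt, dM/dt, dT/dt) in cells/day."""
    d = rhs_array(state.t, state.as_array(), params, mode)
    if not np.all(np.isfinite(d)):
        raise FloatingPointError(f"non-finite derivative at state {state}")
    return float(d[0]), float(d[1]), float(d[2])
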