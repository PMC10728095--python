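"""Virtual cohorts: Latin hypercube sampling of tumor-immune landscapes,
checkpoint-blockade outcome simulation, and parameter-outcome statistics.

Each virtual mouse is one LHS draw of all model parameters over their
published ranges (uniform on each range) plus two initial conditions: the
low-antigen fraction of a fixed 1 mm³ inoculum (uniform on [0, 1]) and the
initial effector-to-tumor-cell ratio (log-uniform over the standard 1:10 to
10:1 effector:target window). Both checkpoint modes are simulated from the
same draw, and day-25/150 volumes are classified as clinical elimination,
dormancy or escape.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde, qmc

from .model import CheckpointMode, SystemState, mm3_to_cells
from .parameters import PARAMETER_NAMES, RANGES, SAMPLING_SCALE, ParameterSet
from .simulate import ClinicalLabel, IntegrationError, classify_clinical, integrate

logger = logging.getLogger(__name__)

__all__ = [
    "CohortSpec",
    "CohortResult",
    "sample_cohort",
    "run_cohort",
    "outcome_probabilities",
    "binned_outcome_rates",
    "outcome_conditioned_summary",
]

_LABELS = [lab.value for lab in ClinicalLabel]


@dataclass(frozen=True)
class CohortSpec:
    """Design of a virtual cohort.

    ``ranges``/``scales`` default to the published parameter table (uniform
    sampling); entries may be overridden per symbol. Initial tumor volume is
    fixed (the standard 1 mm³ inoculum); initial composition and the
    effector:tumor ratio are sampled.
    """

    n: int = 30000
    seed: int = 0
    ranges: dict[str, tuple[float, float]] = field(default_factory=dict)
    scales: dict[str, str] = field(default_factory=dict)
    init_tumor_volume_mm3: float = 1.0
    init_low_fraction_range: tuple[float, float] = (0.0, 1.0)
    init_T_to_tumor_ratio_range: tuple[float, float] = (0.1, 10.0)
    init_T_to_tumor_ratio_scale: str = "log"

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("cohort size n must be >= 1")
        for name, (lo, hi) in self.ranges.items():
            if name not in RANGES:
                raise KeyError(f"unknown parameter {name!r}")
            full_lo, full_hi = RANGES[name]
            if not (full_lo <= lo <= hi <= full_hi):
                raise ValueError(
                    f"range for {name} must lie within published bounds "
                    f"[{full_lo}, {full_hi}], got [{lo}, {hi}]")
        for name, sc in self.scales.items():
            if sc not in ("linear", "log"):
                raise ValueError(f"scale for {name} must be linear|log")
        lo, hi = self.init_low_fraction_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError("init_low_fraction_range must lie within [0, 1]")

    def range_of(self, name: str) -> tuple[float, float]:
        return self.ranges.get(name, RANGES[name])

    def scale_of(self, name: str) -> str:
        return self.scales.get(name, SAMPLING_SCALE[name])


#: Sampled dimensions beyond the model parameters.
_EXTRA_DIMS = ("init_low_fraction", "init_T_to_tumor_ratio")


def _transform(u: np.ndarray, lo: float, hi: float, scale: str) -> np.ndarray:
    if lo == hi:
        return np.full_like(u, lo)
    if scale == "log":
        if lo <= 0:
            raise ValueError("log scale requires a positive lower bound")
        return 10 ** (math.log10(lo) + (math.log10(hi) - math.log10(lo)) * u)
    return lo + (hi - lo) * u


def sample_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Latin hypercube sample of the cohort: one row per virtual mouse.

    Every sampled dimension is stratified — exactly one draw falls in each of
    the n equal-probability strata on its sampling scale — and the table is
    reproducible under a fixed seed. Degenerate ranges (low == high) hold the
    dimension constant with a logged notice.
    """
    dims = list(PARAMETER_NAMES) + list(_EXTRA_DIMS)
    u = qmc.LatinHypercube(d=len(dims), seed=spec.seed).random(spec.n)
    cols: dict[str, np.ndarray] = {}
    for j, name in enumerate(dims):
        if name == "init_low_fraction":
            lo, hi = spec.init_low_fraction_range
            scale = "linear"
        elif name == "init_T_to_tumor_ratio":
            lo, hi = spec.init_T_to_tumor_ratio_range
            scale = spec.init_T_to_tumor_ratio_scale
        else:
            lo, hi = spec.range_of(name)
            scale = spec.scale_of(name)
        if lo == hi:
            logger.info("dimension %s held constant at %g", name, lo)
        cols[name] = _transform(u[:, j], lo, hi, scale)
    df = pd.DataFrame(cols)
    df.insert(0, "mouse", np.arange(spec.n))
    return df


def _initial_state(row: pd.Series, volume_mm3: float) -> SystemState:
    cells = mm3_to_cells(volume_mm3)
    lf = float(row["init_low_fraction"])
    return SystemState(N=(1 - lf) * cells, M=lf * cells,
                       T=float(row["init_T_to_tumor_ratio"]) * cells)


@dataclass(frozen=True)
class CohortResult:
    """Per-mouse outcomes of a cohort run under both checkpoint modes."""

    table: pd.DataFrame          # one row per mouse: inputs + readouts
    days: tuple[float, ...]
    n_failed: int
    spec: CohortSpec | None = None

    def ok(self) -> pd.DataFrame:
        return self.table[self.table["status"] == "ok"]


def run_cohort(cohort: pd.DataFrame,
               days: tuple[float, ...] = (25.0, 150.0),
               modes: tuple[CheckpointMode, ...] = (CheckpointMode.ACTIVE,
                                                    CheckpointMode.BLOCKED),
               init_tumor_volume_mm3: float = 1.0,
               spec: CohortSpec | None = None,
               max_failure_fraction: float = 0.01) -> CohortResult:
    """Simulate every virtual mouse under each checkpoint mode and record
    day-25/150 volume, composition and clinical label.

    Integration failures are flagged and excluded from downstream statistics;
    more than ``max_failure_fraction`` failures aborts (it indicates solver
    misconfiguration rather than isolated stiffness).
    """
    days = tuple(sorted(float(d) for d in days))
    t_end = max(days)
    t_eval = np.union1d([0.0], days)
    records = []
    n_failed = 0
    for _, row in cohort.iterrows():
        params = ParameterSet.from_dict(
            {k: float(row[k]) for k in PARAMETER_NAMES})
        init = _initial_state(row, init_tumor_volume_mm3)
        rec = dict(row)
        status = "ok"
        for mode in modes:
            try:
                tr = integrate(params, init, mode, t_end, t_eval=t_eval)
            except IntegrationError:
                status = "failed"
                for day in days:
                    key = f"{mode.value}_day{day:g}"
                    rec[f"{key}_volume_mm3"] = np.nan
                    rec[f"{key}_low_fraction"] = np.nan
                    rec[f"{key}_label"] = "failed"
                continue
            for day in days:
                key = f"{mode.value}_day{day:g}"
                rec[f"{key}_volume_mm3"] = tr.volume_at(day)
                rec[f"{key}_low_fraction"] = tr.low_fraction_at(day)
                rec[f"{key}_label"] = tr.label_at(day).value
        rec["status"] = status
        n_failed += status == "failed"
        records.append(rec)
    if n_failed > max_failure_fraction * len(cohort):
        raise RuntimeError(
            f"{n_failed}/{len(cohort)} integrations failed "
            f"(> {max_failure_fraction:.0%}); check solver configuration")
    if n_failed:
        logger.warning("%d cohort integrations failed and were excluded",
                       n_failed)
    return CohortResult(table=pd.DataFrame(records), days=days,
                        n_failed=n_failed, spec=spec)


def _label_column(result: CohortResult, mode: CheckpointMode,
                  day: float) -> pd.Series:
    col = f"{mode.value}_day{day:g}_label"
    if col not in result.table.columns:
        raise KeyError(f"no stored readout for mode={mode.value}, day={day}")
    return result.ok()[col]


def outcome_probabilities(result: CohortResult, mode: CheckpointMode,
                          day: float) -> pd.DataFrame:
    """Fractions of each clinical outcome (with binomial standard errors)
    among successfully simulated mice."""
    labels = _label_column(result, mode, day)
    n = len(labels)
    if n == 0:
        raise ValueError("cohort result is empty")
    rows = []
    for lab in _LABELS:
        p = float((labels == lab).mean())
        rows.append(dict(label=lab, probability=p,
                         se=math.sqrt(p * (1 - p) / n), n=n))
    return pd.DataFrame(rows)


def binned_outcome_rates(result: CohortResult, parameter: str,
                         mode: CheckpointMode, day: float,
                         n_bins: int = 5,
                         scale: str | None = None) -> pd.DataFrame:
    """Outcome probabilities within equal-width bins of one sampled
    parameter (width taken on the parameter's sampling scale).

    Empty bins report NaN probabilities. Returns bin edges, counts and the
    per-label fractions (each non-empty bin's fractions sum to 1).
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    tab = result.ok()
    if parameter not in tab.columns:
        raise KeyError(f"parameter {parameter!r} was not sampled")
    if scale is None:
        scale = (SAMPLING_SCALE.get(parameter, "linear")
                 if result.spec is None else
                 (result.spec.scale_of(parameter)
                  if parameter in RANGES else "linear"))
    x = tab[parameter].to_numpy(dtype=float)
    labels = _label_column(result, mode, day).to_numpy()
    if scale == "log":
        edges = np.geomspace(x.min(), x.max(), n_bins + 1)
    else:
        edges = np.linspace(x.min(), x.max(), n_bins + 1)
    idx = np.clip(np.digitize(x, edges) - 1, 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        sel = labels[idx == b]
        row = dict(bin=b, lo=edges[b], hi=edges[b + 1], count=len(sel))
        for lab in _LABELS:
            row[lab] = float((sel == lab).mean()) if len(sel) else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def outcome_conditioned_summary(result: CohortResult, parameter: str,
                                mode: CheckpointMode, day: float,
                                min_rows: int = 10,
                                grid_size: int = 128) -> pd.DataFrame:
    """Distribution of a sampled parameter conditioned on each outcome:
    median, quartiles and a Gaussian-kernel density sketch on a fixed grid
    (the tabular counterpart of a violin plot). Labels with fewer than
    ``min_rows`` mice are omitted with a notice."""
    tab = result.ok()
    if parameter not in tab.columns:
        raise KeyError(f"parameter {parameter!r} was not sampled")
    labels = _label_column(result, mode, day)
    x_all = tab[parameter].to_numpy(dtype=float)
    grid = np.linspace(x_all.min(), x_all.max(), grid_size)
    rows = []
    for lab in _LABELS:
        x = x_all[(labels == lab).to_numpy()]
        if len(x) < min_rows:
            logger.info("label %s has %d rows (< %d); summary omitted",
                        lab, len(x), min_rows)
            continue
        q1, med, q3 = np.percentile(x, [25, 50, 75])
        try:
            dens = gaussian_kde(x)(grid)
        except np.linalg.LinAlgError:  # degenerate (constant) sample
            dens = np.full_like(grid, np.nan)
        rows.append(dict(label=lab, n=len(x), median=med, q1=q1, q3=q3,
                         grid=grid.copy(), density=dens))
    return pd.DataFrame(rows)
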