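"""Model parameters: baseline values, admissible ranges, and sampling scales.

All rates are per day; cell quantities are absolute cell counts; PD-1/PD-L1
concentrations are in μM. ``mu_PA`` (the anti-PD-1 blocking rate, per-hour
units as published) is carried for completeness but drives no dynamics here:
checkpoint blockade is idealized as the suppression factor F being pinned
at 1, not as a drug compartment.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, fields, replace
from pathlib import Path
from typing import Iterator

import yaml

logger = logging.getLogger(__name__)

__all__ = ["ParameterSet", "PARAMETER_NAMES", "RANGES", "SAMPLING_SCALE"]

#: Admissible range [low, high] for each parameter, as published.
RANGES: dict[str, tuple[float, float]] = {
    "alpha_n": (0.05, 0.6),
    "alpha_m": (0.05, 0.6),
    "K": (3e9, 6e9),
    "delta_ns": (1.0, 12.0),
    "delta_ms": (1.0, 12.0),
    "delta_nf": (1e-8, 1e-6),
    "delta_mf": (1e-8, 1e-6),
    "kappa_0": (1e6, 1e8),
    "kappa_1": (0.01, 1.0),
    "kappa_2": (1e6, 1e8),
    "delta_t": (0.0, 0.5),
    "mu": (5e3, 1.5e5),
    "delta_n": (1e-11, 1e-9),
    "delta_m": (1e-11, 1e-9),
    "p_1": (0.0, 1.0),
    "p_2": (0.0, 1.0),
    "alpha_nt": (0.0, 0.5),
    "alpha_mt": (0.0, 0.5),
    "rho_p": (1e-12, 1e-10),
    "rho_l": (1e-12, 2e-10),
    "eps_c": (1.0, 50.0),
    "mu_PA": (6.45, 273.0),
    "k_TQ": (1e-10, 1e-8),
}

#: Sampling scale per parameter for cohort generation. Virtual cohorts use
#: plain uniform Latin hypercube sampling over every published range; a "log"
#: entry switches a dimension to log-uniform if a study calls for it.
SAMPLING_SCALE: dict[str, str] = {name: "linear" for name in RANGES}

_BASELINE: dict[str, float] = {
    "alpha_n": 0.337,
    "alpha_m": 0.337,
    "K": 5e9,
    "delta_ns": 4.0,
    "delta_ms": 4.0,
    "delta_nf": 2.5e-7,
    "delta_mf": 2.5e-7,
    "kappa_0": 2e7,
    "kappa_1": 0.5,
    "kappa_2": 2.019e7,
    "delta_t": 0.0412,
    "mu": 2e4,
    "delta_n": 3.422e-10,
    "delta_m": 3.422e-10,
    "p_1": 0.92,
    "p_2": 0.33,
    "alpha_nt": 0.15,
    "alpha_mt": 0.15,
    "rho_p": 1.259e-11,
    "rho_l": 2.510e-11,
    "eps_c": 10.0,
    "mu_PA": 8.945,
    "k_TQ": 1.296e-9,
}

# Parameters whose published range has lower bound 0, plus mu (mu = 0 is the
# immune-free limit used by the logistic-growth oracle); zero is accepted for
# these, as an admissible if degenerate value of the model.
_MAY_BE_ZERO = frozenset({"delta_t", "alpha_nt", "alpha_mt", "p_1", "p_2",
                          "mu"})


@dataclass(frozen=True)
class ParameterSet:
    """The full parameter vector of the tumor-immune model.

    Tumor compartments: high-antigen cells N and low-antigen cells M share a
    logistic growth law (rates ``alpha_n``/``alpha_m``, joint capacity ``K``)
    and are killed by CTLs through a fast, perforin-mediated mass-action term
    (coefficients ``delta_nf``/``delta_mf``, engaged with probability
    ``p_1``/``p_2``) and a slow, FasL-mediated saturating term (maximum rates
    ``delta_ns``/``delta_ms``, shape ``kappa_0``/``kappa_1``). CTLs are
    recruited at rate ``mu``, proliferate in response to antigen
    (``alpha_nt``/``alpha_mt``, half-saturation ``kappa_2``), die at rate
    ``delta_t`` plus tumor-contact losses ``delta_n``/``delta_m``. PD-1/PD-L1
    engagement (``rho_p``, ``rho_l``, ``eps_c``, ``k_TQ``) suppresses killing
    while the checkpoint is active.
    """

    alpha_n: float
    alpha_m: float
    K: float
    delta_ns: float
    delta_ms: float
    delta_nf: float
    delta_mf: float
    kappa_0: float
    kappa_1: float
    kappa_2: float
    delta_t: float
    mu: float
    delta_n: float
    delta_m: float
    p_1: float
    p_2: float
    alpha_nt: float
    alpha_mt: float
    rho_p: float
    rho_l: float
    eps_c: float
    mu_PA: float
    k_TQ: float

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v):
                raise ValueError(f"parameter {f.name} is not finite: {v!r}")
            if f.name in ("p_1", "p_2"):
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"{f.name} must lie in [0, 1], got {v}")
            elif f.name in _MAY_BE_ZERO:
                if v < 0.0:
                    raise ValueError(f"{f.name} must be >= 0, got {v}")
            elif v <= 0.0:
                raise ValueError(f"{f.name} must be > 0, got {v}")

    @classmethod
    def baseline(cls) -> "ParameterSet":
        """The published baseline parameterization (mouse)."""
        return cls(**_BASELINE)

    @staticmethod
    def range_of(name: str) -> tuple[float, float]:
        """Admissible [low, high] range of a parameter."""
        try:
            return RANGES[name]
        except KeyError:
            raise KeyError(f"unknown parameter {name!r}") from None

    @staticmethod
    def scale_of(name: str) -> str:
        """Cohort sampling scale of a parameter: 'linear' or 'log'."""
        if name not in SAMPLING_SCALE:
            raise KeyError(f"unknown parameter {name!r}")
        return SAMPLING_SCALE[name]

    def with_updates(self, **updates: float) -> "ParameterSet":
        unknown = set(updates) - set(PARAMETER_NAMES)
        if unknown:
            raise KeyError(f"unknown parameter(s): {sorted(unknown)}")
        return replace(self, **updates)

    def to_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def __iter__(self) -> Iterator[tuple[str, float]]:
        return iter(self.to_dict().items())

    # -- flat key/value config I/O -------------------------------------

    @classmethod
    def from_dict(cls, values: dict[str, float]) -> "ParameterSet":
        """Build from a flat mapping; unknown keys error, missing keys fall
        back to baseline with a logged notice."""
        unknown = set(values) - set(PARAMETER_NAMES)
        if unknown:
            raise KeyError(
                f"unknown parameter key(s) in config: {sorted(unknown)}")
        merged = dict(_BASELINE)
        missing = set(PARAMETER_NAMES) - set(values)
        if missing:
            logger.info("parameters missing from config, using baseline: %s",
                        ", ".join(sorted(missing)))
        merged.update({k: float(v) for k, v in values.items()})
        return cls(**merged)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ParameterSet":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config {path} must be a flat key: value map")
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


PARAMETER_NAMES: tuple[str, ...] = tuple(f.name for f in fields(ParameterSet))
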