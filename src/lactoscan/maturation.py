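"""The milk maturation percent (MM%) score.

MM% maps calibrated milk conductivity onto a 0-100 scale spanning the full
dynamic range from initial colostrum (electrolyte-rich, high conductivity,
MM% = 0) to fully mature milk (MM% = 100).  Early milk is rich in sodium and
chloride, so conductivity falls as secretory activation progresses and MM%
is monotone *decreasing* in conductivity.

The production system computes MM% with an empirical equation that is not
public; this module provides a documented, configurable surrogate — linear
interpolation between two conductivity anchors by default, with an optional
logistic shape.  Every downstream stage (reference charts, classification,
threshold screening) depends only on monotonicity and the [0, 100] range,
not on the exact functional form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

#: Default anchors in mS/cm.  Chosen to be consistent with the synthetic
#: cohort generator; they are surrogate values, not device constants.
DEFAULT_SIGMA_COLOSTRUM = 6.0
DEFAULT_SIGMA_MATURE = 3.0


@dataclass(frozen=True)
class MaturationModel:
    """Conductivity -> MM% mapping.

    ``sigma_colostrum`` (mS/cm) maps to 0%, ``sigma_mature`` to 100%.  With
    ``shape='logistic'`` the unit interval between the anchors is warped by a
    logistic rescaled so the anchors still map exactly to 0 and 100;
    ``logistic_steepness`` (> 0) controls the warp strength.
    """

    sigma_colostrum: float = DEFAULT_SIGMA_COLOSTRUM
    sigma_mature: float = DEFAULT_SIGMA_MATURE
    shape: str = "linear"
    logistic_steepness: float = 6.0

    def __post_init__(self):
        if not self.sigma_colostrum > self.sigma_mature > 0:
            raise ValidationError(
                "anchors must satisfy sigma_colostrum > sigma_mature > 0, got "
                f"{self.sigma_colostrum} and {self.sigma_mature}"
            )
        if self.shape not in ("linear", "logistic"):
            raise ValidationError(f"shape must be linear|logistic, got {self.shape!r}")
        if self.logistic_steepness <= 0:
            raise ValidationError(f"logistic_steepness must be > 0, got {self.logistic_steepness}")


@dataclass(frozen=True)
class MMResult:
    mm_percent: float
    conductivity_25C: float
    clipped: bool


def _warp(u: np.ndarray | float, model: MaturationModel):
    """Map progress u = (sigma_c - sigma)/(sigma_c - sigma_m) to [0, 1]."""
    if model.shape == "linear":
        return u
    k = model.logistic_steepness
    f = lambda x: 1.0 / (1.0 + np.exp(-k * (x - 0.5)))  # noqa: E731
    f0, f1 = f(0.0), f(1.0)
    return (f(u) - f0) / (f1 - f0)


def _unwarp(w: float, model: MaturationModel) -> float:
    if model.shape == "linear":
        return w
    k = model.logistic_steepness
    f = lambda x: 1.0 / (1.0 + np.exp(-k * (x - 0.5)))  # noqa: E731
    f0, f1 = f(0.0), f(1.0)
    y = f0 + w * (f1 - f0)
    return 0.5 + np.log(y / (1.0 - y)) / k


def mm_from_conductivity(conductivity_25C: float, model: MaturationModel) -> MMResult:
    """Score a calibrated conductivity on the 0-100 maturation scale.

    Values outside [0, 100] (sensor noise beyond the anchors) are clipped and
    flagged rather than rejected.
    """
    if not np.isfinite(conductivity_25C) or conductivity_25C <= 0:
        raise ValidationError(f"conductivity must be positive and finite, got {conductivity_25C}")
    span = model.sigma_colostrum - model.sigma_mature
    u = (model.sigma_colostrum - conductivity_25C) / span
    clipped = not 0.0 <= u <= 1.0
    u_clipped = min(max(u, 0.0), 1.0)
    mm = 100.0 * float(_warp(u_clipped, model))
    return MMResult(mm_percent=mm, conductivity_25C=conductivity_25C, clipped=clipped)


def conductivity_from_mm(mm_percent: float, model: MaturationModel) -> float:
    """Inverse of the unclipped forward map (needed by the simulator)."""
    if not 0.0 <= mm_percent <= 100.0:
        raise ValidationError(f"mm_percent must be in [0, 100], got {mm_percent}")
    u = float(_unwarp(mm_percent / 100.0, model))
    return model.sigma_colostrum - u * (model.sigma_colostrum - model.sigma_mature)


def mm_array(conductivities: np.ndarray, model: MaturationModel) -> np.ndarray:
    """Vectorised MM% with clipping, for batch pipelines (no flags)."""
    sigma = np.asarray(conductivities, dtype=float)
    span = model.sigma_colostrum - model.sigma_mature
    u = np.clip((model.sigma_colostrum - sigma) / span, 0.0, 1.0)
    return 100.0 * np.asarray(_warp(u, model), dtype=float)
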