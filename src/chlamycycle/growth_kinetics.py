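"""Light-driven exponential growth of single-cell volume.

During the interdivision phase a Chlamydomonas cell grows exponentially,

    V(t) = V(0) * exp(mu * t),

with a specific volume growth rate ``mu`` (h^-1) set by the photosynthetically
active radiation (PAR, umol m^-2 s^-1) it receives.  This module provides the
growth law itself, the endpoint estimator mu = (1/T) ln(V(T)/V(0)), a
least-squares fit of the law to sampled trajectories, and a saturating
light-response curve mapping PAR to mu.

The light response is a shifted rectangular hyperbola

    mu(P) = mu_max * (P - P0) / (K + P - P0)   for P > P0, else 0,

where P0 is the compensation irradiance below which no net growth occurs.
The packaged default calibration is pinned so that mu(200)/mu(10) = 8 (the
observed factor between interdivision durations at those intensities) and the
interdivision duration at PAR 200 is 10 h.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np

__all__ = [
    "GrowthCalibration",
    "GrowthSegment",
    "volume_at",
    "mu_from_endpoints",
    "growth_rate",
    "fit_exponential",
]


@dataclass(frozen=True)
class GrowthCalibration:
    """Parameters of the PAR -> growth-rate response.

    Attributes
    ----------
    mu_max : float
        Asymptotic growth rate at saturating light (h^-1).
    K : float
        Half-saturation constant of the shifted hyperbola (umol m^-2 s^-1).
    par_compensation : float
        Compensation irradiance; mu = 0 at or below it (umol m^-2 s^-1).
    """

    mu_max: float
    K: float
    par_compensation: float = 0.2

    def __post_init__(self) -> None:
        if not self.mu_max > 0:
            raise ValueError(f"mu_max must be positive, got {self.mu_max}")
        if not self.K > 0:
            raise ValueError(f"K must be positive, got {self.K}")
        if self.par_compensation < 0:
            raise ValueError(
                f"par_compensation must be >= 0, got {self.par_compensation}"
            )

    @classmethod
    def default(cls) -> "GrowthCalibration":
        """Packaged default calibration (see module docstring)."""
        return _DEFAULT_CALIBRATION

    @classmethod
    def from_dict(cls, d: dict) -> "GrowthCalibration":
        return cls(**d)

    def to_dict(self) -> dict:
        return {
            "mu_max": self.mu_max,
            "K": self.K,
            "par_compensation": self.par_compensation,
        }


def _load_default() -> GrowthCalibration:
    text = resources.files("chlamycycle.data").joinpath(
        "default_calibration.json"
    ).read_text()
    return GrowthCalibration.from_dict(json.loads(text))


_DEFAULT_CALIBRATION = _load_default()


@dataclass(frozen=True)
class GrowthSegment:
    """One constant-rate stretch of exponential growth."""

    t_start: float
    t_end: float
    mu: float
    v_start: float

    def __post_init__(self) -> None:
        if not self.t_end > self.t_start:
            raise ValueError("t_end must exceed t_start")
        if not self.v_start > 0:
            raise ValueError("v_start must be positive")
        if self.mu < 0:
            raise ValueError("mu must be non-negative")

    def volume_at(self, t: float) -> float:
        """Volume at absolute time ``t`` within this segment."""
        if not (self.t_start <= t <= self.t_end):
            raise ValueError(f"t={t} outside segment [{self.t_start}, {self.t_end}]")
        return volume_at(self.v_start, self.mu, t - self.t_start)


def volume_at(v0: float, mu: float, t: float) -> float:
    """Volume after growing for time ``t`` at rate ``mu`` from volume ``v0``.

    Parameters are the initial volume (um^3), the specific growth rate (h^-1)
    and the elapsed time (h).
    """
    if not v0 > 0:
        raise ValueError(f"v0 must be positive, got {v0}")
    if t < 0:
        raise ValueError(f"t must be non-negative, got {t}")
    if mu < 0:
        raise ValueError(f"mu must be non-negative, got {mu}")
    return v0 * math.exp(mu * t)


def mu_from_endpoints(v0: float, vT: float, T: float) -> float:
    """Growth rate from the two endpoint volumes: mu = (1/T) ln(vT / v0)."""
    if not v0 > 0:
        raise ValueError(f"v0 must be positive, got {v0}")
    if not T > 0:
        raise ValueError(f"T must be positive, got {T}")
    if vT < v0:
        raise ValueError(
            f"vT={vT} < v0={v0}: shrinkage is not exponential growth"
        )
    return math.log(vT / v0) / T


def growth_rate(par: float, calib: GrowthCalibration | None = None) -> float:
    """Specific growth rate (h^-1) at irradiance ``par`` (umol m^-2 s^-1)."""
    if par < 0:
        raise ValueError(f"par must be non-negative, got {par}")
    c = calib if calib is not None else GrowthCalibration.default()
    if par <= c.par_compensation:
        return 0.0
    x = par - c.par_compensation
    return c.mu_max * x / (c.K + x)


def fit_exponential(
    points: Sequence[tuple[float, float]] | np.ndarray,
) -> tuple[float, float, float]:
    """Fit V(t) = v0 * exp(mu t) by ordinary least squares on log volume.

    Parameters
    ----------
    points : sequence of (time, volume)
        At least three samples with strictly increasing times and positive
        volumes.

    Returns
    -------
    (mu, v0, r_squared)
        Slope, exp-transformed intercept, and coefficient of determination of
        the log-linear regression.  On a flat series mu = 0 and r_squared is
        reported as 1 (the model reproduces the data exactly).
    """
    arr = np.asarray(points, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("need at least 3 (time, volume) points")
    t, v = arr[:, 0], arr[:, 1]
    if np.any(v <= 0):
        raise ValueError("all volumes must be positive")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    y = np.log(v)
    slope, intercept = np.polyfit(t, y, 1)
    resid = y - (slope * t + intercept)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return float(slope), float(np.exp(intercept)), r2
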