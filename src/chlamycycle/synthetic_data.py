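"""Synthetic single-cell data with known ground truth.

No micrographs or trajectories were deposited with the original on-chip
experiments, so every input of the analysis pipeline is emulated here:

* cohorts of noisy volume trajectories under the four illumination
  conditions (LL, LD, LDL, L1L2), produced by running the cycle simulator
  per cell and sampling its volume path with multiplicative measurement
  noise, plus the shrinkage-and-plateau signature of the division phase that
  the division detector keys on;
* grayscale raster images of single elliptical cells with exact geometric
  ground truth, for the volumetry stage.

Between-cell variability defaults reproduce the reported dispersions: initial
volume 79.7 +/- 12.6 um^3 and a growth-rate CV that places the cohort CV of
the interdivision duration in the observed 21-38% band.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .cycle_model import (
    CycleParams,
    CycleResult,
    LightSchedule,
    _lognormal_multiplier,
    simulate_cycle,
)
from .image_volumetry import CellImage, spheroid_volume
from .trajectory_analysis import VolumeTrajectory

__all__ = [
    "CohortSpec",
    "build_schedule",
    "volume_path",
    "generate_trajectory",
    "generate_cohort",
    "generate_cell_image",
]

#: fractional volume lost over the shrinkage subphase (rendering convention
#: for detector testing, not a measured value)
SHRINK_FRACTION = 0.10


@dataclass
class CohortSpec:
    """Recipe for one synthetic cohort.

    ``schedule_params`` holds the condition-specific schedule arguments
    (``par``/``t_off``/``t_on`` or ``par1``/``t_switch``/``par2``); any value
    may be a sequence, in which case it is cycled across cells so a cohort
    can span, e.g., several light-off times.
    """

    condition: str  # LL | LD | LDL | L1L2
    n_cells: int
    schedule_params: dict
    params: CycleParams = field(default_factory=CycleParams)
    sampling_interval: float = 1.0 / 120.0  # 30 s, as recorded on-chip
    seed: int = 0
    #: sampling horizon after the last schedule event for undivided cells (h)
    undivided_horizon: float = 48.0
    #: hard cap on simulated time (h)
    t_max: float = 1000.0

    def __post_init__(self) -> None:
        if self.condition not in ("LL", "LD", "LDL", "L1L2"):
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if not self.sampling_interval > 0:
            raise ValueError("sampling_interval must be positive")


_SCHEDULE_KEYS = {
    "LL": ("par",),
    "LD": ("par", "t_off"),
    "LDL": ("par", "t_off", "t_on"),
    "L1L2": ("par1", "t_switch", "par2"),
}


def build_schedule(condition: str, schedule_params: dict) -> LightSchedule:
    """Light schedule for one cell of a given condition."""
    keys = _SCHEDULE_KEYS.get(condition)
    if keys is None:
        raise ValueError(f"unknown condition {condition!r}")
    missing = [k for k in keys if k not in schedule_params]
    if missing:
        raise ValueError(f"{condition} schedule needs {missing}")
    args = [schedule_params[k] for k in keys]
    return getattr(LightSchedule, condition)(*args)


def _cell_schedule_params(spec: CohortSpec, i: int) -> dict:
    out = {}
    for k in _SCHEDULE_KEYS[spec.condition]:
        v = spec.schedule_params[k]
        if isinstance(v, (list, tuple, np.ndarray)):
            out[k] = float(v[i % len(v)])
        else:
            out[k] = float(v)
    return out


def volume_path(result: CycleResult, times: np.ndarray, params: CycleParams) -> np.ndarray:
    """Noise-free volume at each time, including the division-phase signature.

    During the interdivision phase the path follows the simulator's
    piecewise-exponential growth segments.  From division-phase entry the
    volume ramps down by ``SHRINK_FRACTION`` over the shrinkage subphase and
    then plateaus until mitosis completion (hatching).
    """
    times = np.asarray(times, dtype=float)
    v = np.empty_like(times)
    v[:] = np.nan
    for seg in result.growth_segments:
        m = (times >= seg.t_start) & (times <= seg.t_end)
        v[m] = seg.v_start * np.exp(seg.mu * (times[m] - seg.t_start))
    if result.t_division_entry is not None:
        t_e = result.t_division_entry
        shrink = params.subphase_durations["shrinkage"]
        v_lo = result.v_final * (1.0 - SHRINK_FRACTION)
        after = times >= t_e
        if shrink > 0:
            frac = np.clip((times[after] - t_e) / shrink, 0.0, 1.0)
        else:
            frac = 1.0
        v[after] = result.v_final - (result.v_final - v_lo) * frac
    # anything before the first segment or after the last event holds steady
    if np.isnan(v).any():
        filled = np.flatnonzero(~np.isnan(v))
        if filled.size == 0:
            raise ValueError("no growth segments overlap the sample times")
        v = np.interp(times, times[filled], v[filled])
    return v


def generate_trajectory(
    cell_id: str,
    schedule: LightSchedule,
    params: CycleParams,
    rng: np.random.Generator,
    sampling_interval: float,
    undivided_horizon: float,
    t_max: float,
) -> VolumeTrajectory:
    """One noisy trajectory with ground-truth annotations."""
    v0 = params.v0_mean * _lognormal_multiplier(rng, params.v0_cv)
    result = simulate_cycle(schedule, params, v0, t_max=t_max, _rng=rng)
    if result.t_division_entry is not None:
        t_end = result.t_division_entry + params.division_phase_duration
    else:
        finite = [b for _a, b, _p in schedule.segments if math.isfinite(b)]
        t_end = min((max(finite) if finite else 0.0) + undivided_horizon, t_max)
    times = np.arange(0.0, t_end + sampling_interval / 2, sampling_interval)
    clean = volume_path(result, times, params)
    if params.cv_measurement > 0:
        sigma = math.sqrt(math.log(1.0 + params.cv_measurement**2))
        noise = np.exp(rng.normal(-sigma**2 / 2.0, sigma, size=times.shape))
    else:
        noise = 1.0
    ann = result.to_dict()
    ann["cell_id"] = cell_id
    return VolumeTrajectory(
        cell_id=cell_id,
        times=times,
        volumes=clean * noise,
        schedule=schedule,
        annotations=ann,
    )


def generate_cohort(spec: CohortSpec) -> list[VolumeTrajectory]:
    """Seeded cohort of noisy trajectories; identical spec -> identical data."""
    rng = np.random.default_rng(spec.seed)
    out = []
    for i in range(spec.n_cells):
        schedule = build_schedule(spec.condition, _cell_schedule_params(spec, i))
        out.append(
            generate_trajectory(
                cell_id=f"{spec.condition}_{i:03d}",
                schedule=schedule,
                params=spec.params,
                rng=rng,
                sampling_interval=spec.sampling_interval,
                undivided_horizon=spec.undivided_horizon,
                t_max=spec.t_max,
            )
        )
    return out


def generate_cell_image(
    La: float,
    Lb: float,
    orientation: float = 0.0,
    pixel_size: float = 0.05,
    noise_sd: float = 0.0,
    seed: int | None = None,
    shape: tuple[int, int] | None = None,
    background: float = 0.2,
    foreground: float = 0.9,
) -> CellImage:
    """Render one elliptical cell on a darker background.

    ``La``/``Lb`` are full axis lengths in um; ``orientation`` is the angle
    of the long axis from the image x (column) axis.  Edges are anti-aliased
    by 3x3 subpixel supersampling and Gaussian pixel noise of standard
    deviation ``noise_sd`` (intensity units) is added with the given seed.
    The ground truth carries the axes, orientation and spheroid volume.
    """
    if not Lb > 0 or La < Lb:
        raise ValueError(f"need La >= Lb > 0, got La={La}, Lb={Lb}")
    a, b = La / 2.0, Lb / 2.0
    if shape is None:
        half_extent = a + 10 * pixel_size
        n = int(math.ceil(2 * half_extent / pixel_size))
        shape = (n, n)
    H, W = shape
    # the rotated ellipse must fit with a small margin
    if 2 * a > (min(H, W) - 4) * pixel_size:
        raise ValueError("cell larger than raster")

    rows = (np.arange(H) - (H - 1) / 2.0) * pixel_size
    cols = (np.arange(W) - (W - 1) / 2.0) * pixel_size
    sub = (np.arange(3) - 1.0) / 3.0 * pixel_size
    cover = np.zeros((H, W))
    c, s = math.cos(orientation), math.sin(orientation)
    for dy in sub:
        for dx in sub:
            y = (rows + dy)[:, None]
            x = (cols + dx)[None, :]
            u = c * x + s * y
            w = -s * x + c * y
            cover += ((u / a) ** 2 + (w / b) ** 2) <= 1.0
    cover /= len(sub) ** 2
    img = background + (foreground - background) * cover
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    return CellImage(
        pixels=img,
        pixel_size=pixel_size,
        ground_truth={
            "La": La,
            "Lb": Lb,
            "orientation": orientation,
            "true_volume": spheroid_volume(La, Lb),
        },
    )
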