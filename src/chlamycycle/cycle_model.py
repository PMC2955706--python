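"""Forward simulator of the Chlamydomonas cell cycle under arbitrary light.

The model couples exponential volume growth (``growth_kinetics``) to three
decision rules observed in single-cell experiments:

* **interdivision timer** — a dimensionless accumulator ``s(t)`` triggers entry
  into the division phase when it reaches a fixed threshold (default
  ln(4.1) ~ 1.41).  Before commitment the accumulator runs at the current
  instantaneous growth rate, so s = ln(V/V0) exactly and it pauses in
  darkness.  After commitment it runs at the growth rate memorised at the
  moment of commitment, even in darkness — a light-deprived committed cell
  still divides "on schedule".
* **commitment sizer** — a cell commits to dividing once it has doubled its
  initial volume (V/V0 >= 2) under illumination.  An uncommitted cell placed
  in darkness arrests indefinitely.
* **mitotic sizer** — the final/initial volume ratio at division-phase entry
  sets the daughter number: below ~2 no division, up to ~2.9 one fission
  (2 daughters), above that two fissions (4 daughters).  Odd daughter
  numbers never occur.

The division phase itself is a fixed, light-independent sequence of
subphases (shrinkage, rotation, two mitoses, completion).

Integration is event-driven and closed-form within each constant-PAR segment
of the light schedule; no numerical ODE stepping is involved, so noiseless
runs satisfy the model identities (e.g. mu * T = threshold under continuous
light) to machine precision.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .growth_kinetics import GrowthCalibration, GrowthSegment, growth_rate

__all__ = [
    "LightSchedule",
    "CycleParams",
    "CycleResult",
    "accrue_timer",
    "commitment_check",
    "mitotic_sizer",
    "simulate_cycle",
    "simulate_lineage",
    "DEFAULT_SUBPHASE_DURATIONS",
]

#: Irradiance at or below which a schedule segment counts as "dark" when
#: labelling conditions (matches the default compensation irradiance).
DARK_PAR = 0.2

#: Division-subphase durations in hours.  The subphases and their light
#: independence are observed; these magnitudes are calibration choices.
DEFAULT_SUBPHASE_DURATIONS = {
    "shrinkage": 0.3,
    "rotation": 0.3,
    "first_mitosis": 0.5,
    "second_mitosis": 0.5,
    "mitosis_completion": 0.4,
}

SUBPHASE_ORDER = (
    "shrinkage",
    "rotation",
    "first_mitosis",
    "second_mitosis",
    "mitosis_completion",
)


@dataclass(frozen=True)
class LightSchedule:
    """Piecewise-constant PAR over time.

    ``segments`` is an ordered list of ``(t_start, t_end, par)`` with
    contiguous, non-overlapping spans starting at t = 0; the final segment may
    be open-ended (``t_end = inf``).
    """

    segments: tuple[tuple[float, float, float], ...]

    def __init__(self, segments: Sequence[Sequence[float]]):
        segs = tuple((float(a), float(b), float(p)) for a, b, p in segments)
        if not segs:
            raise ValueError("schedule needs at least one segment")
        if segs[0][0] != 0.0:
            raise ValueError("first segment must start at t = 0")
        for i, (a, b, p) in enumerate(segs):
            if not b > a:
                raise ValueError(f"segment {i}: t_end must exceed t_start")
            if p < 0:
                raise ValueError(f"segment {i}: par must be non-negative")
            if i and segs[i - 1][1] != a:
                raise ValueError(f"segment {i}: segments must be contiguous")
        object.__setattr__(self, "segments", segs)

    # -- constructors for the four experimental conditions -----------------

    @classmethod
    def LL(cls, par: float) -> "LightSchedule":
        """Continuous light."""
        return cls([(0.0, math.inf, par)])

    @classmethod
    def LD(cls, par: float, t_off: float) -> "LightSchedule":
        """Light until ``t_off``, then darkness."""
        return cls([(0.0, t_off, par), (t_off, math.inf, 0.0)])

    @classmethod
    def LDL(cls, par: float, t_off: float, t_on: float) -> "LightSchedule":
        """Light, a dark interval [t_off, t_on), then light again (same PAR)."""
        if not t_on > t_off:
            raise ValueError("t_on must exceed t_off")
        return cls(
            [(0.0, t_off, par), (t_off, t_on, 0.0), (t_on, math.inf, par)]
        )

    @classmethod
    def L1L2(cls, par1: float, t_switch: float, par2: float) -> "LightSchedule":
        """A PAR step (typically down) at ``t_switch``, no darkness."""
        return cls([(0.0, t_switch, par1), (t_switch, math.inf, par2)])

    # -- queries ------------------------------------------------------------

    @property
    def t_end(self) -> float:
        return self.segments[-1][1]

    def par_at(self, t: float) -> float:
        """PAR at time ``t`` (right-continuous; last segment extends)."""
        if t < 0:
            raise ValueError("t must be non-negative")
        for a, b, p in self.segments:
            if a <= t < b:
                return p
        return self.segments[-1][2]

    def light_periods(self, dark_par: float = DARK_PAR):
        """Merged illuminated spans, as a list of (t_start, t_end, par)."""
        out = []
        for a, b, p in self.segments:
            if p > dark_par:
                if out and out[-1][1] == a and out[-1][2] == p:
                    out[-1] = (out[-1][0], b, p)
                else:
                    out.append((a, b, p))
        return out

    def dark_duration(self, t_from: float, t_to: float, dark_par: float = DARK_PAR) -> float:
        """Total dark time inside the window [t_from, t_to]."""
        total = 0.0
        for a, b, p in self.segments:
            if p <= dark_par:
                total += max(0.0, min(b, t_to) - max(a, t_from))
        return total

    def condition_label(self, dark_par: float = DARK_PAR) -> str:
        """LL / LD / LDL / L1L2 classification of the schedule shape."""
        kinds = []
        for a, b, p in self.segments:
            k = ("D", None) if p <= dark_par else ("L", p)
            if not kinds or kinds[-1] != k:
                kinds.append(k)
        tags = [k for k, _ in kinds]
        pars = [p for _, p in kinds]
        if tags == ["L"]:
            return "LL"
        if tags == ["L", "D"]:
            return "LD"
        if tags == ["L", "D", "L"]:
            return "LDL" if pars[0] == pars[2] else "custom"
        if tags == ["L", "L"]:
            return "L1L2"
        return "custom"

    # -- serialisation -------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "segments": [
                {
                    "t_start": a,
                    "t_end": None if math.isinf(b) else b,
                    "par": p,
                }
                for a, b, p in self.segments
            ]
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LightSchedule":
        segs = [
            (
                s["t_start"],
                math.inf if s.get("t_end") is None else s["t_end"],
                s["par"],
            )
            for s in d["segments"]
        ]
        return cls(segs)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "LightSchedule":
        return cls.from_dict(json.loads(text))


@dataclass(frozen=True)
class CycleParams:
    """All model constants for one simulation.

    ``timer_threshold`` is the accrued mu*t at which the division phase is
    entered (default ln(4.1)); ``commitment_ratio`` the V/V0 doubling gate;
    the mitotic cutpoints map the final/initial ratio to 0/2/4 daughters.
    Noise CVs act multiplicatively (lognormal, unit mean) on the per-cell
    growth rate and timer threshold, and on each volume measurement.
    """

    timer_threshold: float = math.log(4.1)
    commitment_ratio: float = 2.0
    mitotic_cutpoint_low: float = 2.0
    mitotic_cutpoint_high: float = 2.9
    calib: GrowthCalibration = field(default_factory=GrowthCalibration.default)
    subphase_durations: dict = field(
        default_factory=lambda: dict(DEFAULT_SUBPHASE_DURATIONS)
    )
    cv_mu: float = 0.25
    cv_threshold: float = 0.10
    cv_measurement: float = 0.03
    v0_mean: float = 79.7
    v0_cv: float = 12.6 / 79.7
    #: when true, mitotic_sizer draws its cutpoints per cell from the
    #: indeterminate bands [1.8, 2.2] and [2.7, 3.1]
    stochastic_bands: bool = False

    def __post_init__(self) -> None:
        if not self.commitment_ratio > 1:
            raise ValueError("commitment_ratio must exceed 1")
        if not self.timer_threshold > math.log(self.commitment_ratio):
            raise ValueError("timer_threshold must exceed ln(commitment_ratio)")
        if not (
            self.commitment_ratio
            < self.mitotic_cutpoint_high
            <= math.exp(self.timer_threshold) + 1e-12
        ):
            raise ValueError(
                "mitotic_cutpoint_high must lie between commitment_ratio and "
                "exp(timer_threshold)"
            )
        if self.mitotic_cutpoint_low <= 0:
            raise ValueError("mitotic_cutpoint_low must be positive")
        for name in SUBPHASE_ORDER:
            if name not in self.subphase_durations:
                raise ValueError(f"missing subphase duration: {name}")
            if self.subphase_durations[name] < 0:
                raise ValueError(f"subphase duration {name} must be >= 0")
        for cv in (self.cv_mu, self.cv_threshold, self.cv_measurement, self.v0_cv):
            if cv < 0:
                raise ValueError("noise CVs must be >= 0")

    @property
    def division_phase_duration(self) -> float:
        return float(sum(self.subphase_durations[k] for k in SUBPHASE_ORDER))

    def to_dict(self) -> dict:
        return {
            "timer_threshold": self.timer_threshold,
            "commitment_ratio": self.commitment_ratio,
            "mitotic_cutpoint_low": self.mitotic_cutpoint_low,
            "mitotic_cutpoint_high": self.mitotic_cutpoint_high,
            "calib": self.calib.to_dict(),
            "subphase_durations": dict(self.subphase_durations),
            "cv_mu": self.cv_mu,
            "cv_threshold": self.cv_threshold,
            "cv_measurement": self.cv_measurement,
            "v0_mean": self.v0_mean,
            "v0_cv": self.v0_cv,
            "stochastic_bands": self.stochastic_bands,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CycleParams":
        d = dict(d)
        if "calib" in d:
            d["calib"] = GrowthCalibration.from_dict(d["calib"])
        return cls(**d)


@dataclass
class CycleResult:
    """Outcome of one simulated cell cycle."""

    v_initial: float
    t_division_entry: float | None
    v_final: float
    mu_initial_light: float
    mu_second_light: float | None
    committed: bool
    t_commitment: float | None
    division_number: int
    daughter_volumes: list[float]
    subphase_times: list[float]
    growth_segments: list[GrowthSegment]
    #: piecewise-linear breakpoints (t, s) of the timer accumulator
    timer_trace: list[tuple[float, float]]
    t_simulated: float

    @property
    def ratio_final(self) -> float:
        return self.v_final / self.v_initial

    @property
    def interdivision_duration(self) -> float | None:
        return self.t_division_entry

    def to_dict(self) -> dict:
        return {
            "v_initial": self.v_initial,
            "t_division_entry": self.t_division_entry,
            "v_final": self.v_final,
            "mu_initial_light": self.mu_initial_light,
            "mu_second_light": self.mu_second_light,
            "committed": self.committed,
            "t_commitment": self.t_commitment,
            "division_number": self.division_number,
            "daughter_volumes": list(self.daughter_volumes),
            "subphase_times": list(self.subphase_times),
            "timer_trace": [list(p) for p in self.timer_trace],
            "t_simulated": self.t_simulated,
        }


def commitment_check(v: float, v0: float, params: CycleParams | None = None) -> bool:
    """True once the cell has reached the commitment size V/V0 >= ratio."""
    p = params if params is not None else CycleParams()
    if not v0 > 0:
        raise ValueError("v0 must be positive")
    if v < v0:
        raise ValueError(f"v={v} < v0={v0}: volume cannot shrink before division")
    return v / v0 >= p.commitment_ratio


def mitotic_sizer(
    ratio: float,
    params: CycleParams | None = None,
    rng: np.random.Generator | None = None,
) -> int:
    """Daughter number (0, 2 or 4) from the final/initial volume ratio.

    In the default deterministic mode the cutpoints are fixed at
    ``mitotic_cutpoint_low`` and ``mitotic_cutpoint_high``.  With
    ``params.stochastic_bands`` and an ``rng``, each cutpoint is drawn
    uniformly from the empirically indeterminate bands [1.8, 2.2] and
    [2.7, 3.1], emulating the observed cell-to-cell variability at the band
    edges.  Asymmetric division (odd daughter numbers) never occurs.
    """
    p = params if params is not None else CycleParams()
    if not ratio > 0:
        raise ValueError(f"ratio must be positive, got {ratio}")
    low, high = p.mitotic_cutpoint_low, p.mitotic_cutpoint_high
    if p.stochastic_bands and rng is not None:
        low = float(rng.uniform(1.8, 2.2))
        high = float(rng.uniform(2.7, 3.1))
    if ratio < low:
        return 0
    if ratio < high:
        return 2
    return 4


def _lognormal_multiplier(rng: np.random.Generator, cv: float) -> float:
    """Unit-mean lognormal multiplier with coefficient of variation ``cv``."""
    if cv == 0:
        return 1.0
    sigma2 = math.log(1.0 + cv * cv)
    return float(rng.lognormal(mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2)))


def _integrate(
    schedule: LightSchedule,
    params: CycleParams,
    v0: float,
    mu_mult: float,
    thr_mult: float,
    t_max: float,
):
    """Event-driven walk through the schedule.

    Returns ``(t_entry, ln_ratio, committed, t_commit, mu_mem, growth_segments,
    timer_trace, t_stop)``; ``t_entry`` is None when the timer never fires
    within ``t_max``.
    """
    thr = params.timer_threshold * thr_mult
    ln_commit = math.log(params.commitment_ratio)
    t = 0.0
    lnv = 0.0  # ln(V/V0)
    s = 0.0  # timer accumulator; equals lnv until commitment
    committed = False
    mu_mem = 0.0
    t_commit: float | None = None
    segments: list[GrowthSegment] = []
    trace: list[tuple[float, float]] = [(0.0, 0.0)]

    def record(t0: float, t1: float, mu: float, lnv0: float) -> None:
        if t1 > t0:
            segments.append(
                GrowthSegment(t0, t1, mu, v0 * math.exp(lnv0))
            )

    for a, b, par in schedule.segments:
        if t >= t_max:
            break
        mu = mu_mult * growth_rate(par, params.calib)
        b_eff = min(b, t_max)
        while t < b_eff:
            if not committed:
                if mu <= 0.0:
                    # darkness before commitment: volume and timer both frozen
                    record(t, b_eff, 0.0, lnv)
                    trace.append((b_eff, s))
                    t = b_eff
                    break
                t_c = t + (ln_commit - lnv) / mu
                if t_c <= b_eff:
                    record(t, t_c, mu, lnv)
                    lnv = ln_commit
                    s = ln_commit
                    trace.append((t_c, s))
                    committed = True
                    mu_mem = mu
                    t_commit = t_c
                    t = t_c
                    continue
                record(t, b_eff, mu, lnv)
                lnv += mu * (b_eff - t)
                s = lnv
                trace.append((b_eff, s))
                t = b_eff
            else:
                # timer runs on the memorised rate, volume on the actual one
                t_f = t + (thr - s) / mu_mem
                if t_f <= b_eff:
                    record(t, t_f, mu, lnv)
                    lnv += mu * (t_f - t)
                    s = thr
                    trace.append((t_f, s))
                    return t_f, lnv, committed, t_commit, mu_mem, segments, trace, t_f
                record(t, b_eff, mu, lnv)
                lnv += mu * (b_eff - t)
                s += mu_mem * (b_eff - t)
                trace.append((b_eff, s))
                t = b_eff
    return None, lnv, committed, t_commit, mu_mem, segments, trace, min(t, t_max)


def accrue_timer(
    schedule: LightSchedule, params: CycleParams, t: float
) -> float:
    """Timer accumulator s(t) for a noiseless cell under ``schedule``.

    Before commitment s equals ln(V/V0) (zero accrual in darkness); after
    commitment it accrues at the memorised commitment-time growth rate even
    in darkness.  After the timer fires, s stays at the threshold.
    """
    if t < 0:
        raise ValueError("t must be non-negative")
    _, _, _, _, _, _, trace, _ = _integrate(
        schedule, params, v0=1.0, mu_mult=1.0, thr_mult=1.0, t_max=t
    )
    # trace is piecewise linear; t lies at or before the last breakpoint
    ts = [p[0] for p in trace]
    ss = [p[1] for p in trace]
    return float(np.interp(t, ts, ss))


def simulate_cycle(
    schedule: LightSchedule,
    params: CycleParams | None = None,
    v0: float | None = None,
    rng_seed: int | None = None,
    *,
    t_max: float = 500.0,
    _rng: np.random.Generator | None = None,
) -> CycleResult:
    """Simulate one cell cycle.

    With ``rng_seed`` (or an explicit generator) the per-cell growth rate and
    timer threshold receive unit-mean lognormal multipliers with CVs
    ``params.cv_mu`` and ``params.cv_threshold``; without either the run is
    noiseless and fully deterministic.  ``t_max`` bounds the simulated horizon
    for cells that never divide (e.g. uncommitted cells in permanent
    darkness); such runs return ``division_number = 0`` with
    ``t_division_entry = None``.
    """
    p = params if params is not None else CycleParams()
    v0_ = p.v0_mean if v0 is None else float(v0)
    if not v0_ > 0:
        raise ValueError("v0 must be positive")
    rng = _rng
    if rng is None and rng_seed is not None:
        rng = np.random.default_rng(rng_seed)
    mu_mult = _lognormal_multiplier(rng, p.cv_mu) if rng is not None else 1.0
    thr_mult = (
        _lognormal_multiplier(rng, p.cv_threshold) if rng is not None else 1.0
    )

    t_entry, lnv, committed, t_commit, mu_mem, segs, trace, t_stop = _integrate(
        schedule, p, v0_, mu_mult, thr_mult, t_max
    )

    lights = schedule.light_periods()
    mu_first = mu_mult * growth_rate(lights[0][2], p.calib) if lights else 0.0
    mu_second = (
        mu_mult * growth_rate(lights[1][2], p.calib) if len(lights) > 1 else None
    )

    v_final = v0_ * math.exp(lnv)
    if t_entry is None:
        return CycleResult(
            v_initial=v0_,
            t_division_entry=None,
            v_final=v_final,
            mu_initial_light=mu_first,
            mu_second_light=mu_second,
            committed=committed,
            t_commitment=t_commit,
            division_number=0,
            daughter_volumes=[],
            subphase_times=[],
            growth_segments=segs,
            timer_trace=trace,
            t_simulated=t_stop,
        )

    n = mitotic_sizer(v_final / v0_, p, rng=rng if p.stochastic_bands else None)
    daughters = [v_final / n] * n if n else []
    boundaries = [t_entry]
    for name in SUBPHASE_ORDER:
        boundaries.append(boundaries[-1] + p.subphase_durations[name])
    return CycleResult(
        v_initial=v0_,
        t_division_entry=t_entry,
        v_final=v_final,
        mu_initial_light=mu_first,
        mu_second_light=mu_second,
        committed=committed,
        t_commitment=t_commit,
        division_number=n,
        daughter_volumes=daughters,
        subphase_times=boundaries,
        growth_segments=segs,
        timer_trace=trace,
        t_simulated=boundaries[-1],
    )


def simulate_lineage(
    schedule: LightSchedule,
    params: CycleParams | None = None,
    generations: int = 1,
    rng_seed: int | None = None,
    v0: float | None = None,
    *,
    t_max: float = 500.0,
) -> list[CycleResult]:
    """Follow one daughter per generation, as in a microchamber experiment.

    Each daughter starts at ``v_final / division_number`` of its mother (a
    quarter after two fissions, a half after one) and experiences the same
    schedule from t = 0.  A generation that never divides truncates the
    lineage; its (division-free) result is still included.
    """
    if generations < 1:
        raise ValueError("generations must be >= 1")
    p = params if params is not None else CycleParams()
    seeds = (
        np.random.SeedSequence(rng_seed).spawn(generations)
        if rng_seed is not None
        else [None] * generations
    )
    results: list[CycleResult] = []
    v = p.v0_mean if v0 is None else float(v0)
    for g in range(generations):
        rng = np.random.default_rng(seeds[g]) if seeds[g] is not None else None
        res = simulate_cycle(schedule, p, v, t_max=t_max, _rng=rng)
        results.append(res)
        if res.division_number == 0:
            break
        v = res.v_final / res.division_number
    return results
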