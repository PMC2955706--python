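"""File formats and the end-to-end analysis pipeline.

Trajectories travel as RFC-4180 CSV with the fixed header
``cell_id,time_h,volume_um3``; light schedules and cohort reports as JSON.
``run_pipeline`` ties the stages together: read a cohort, analyse every cell,
and write per-cell records plus a cohort summary that embeds the fully
resolved configuration, so a report is reproducible from its own contents.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cycle_model import CycleParams, LightSchedule
from .trajectory_analysis import (
    CellRecord,
    VolumeTrajectory,
    analyse_trajectory,
    summarise_cohort,
)

__all__ = [
    "PipelineConfig",
    "read_trajectories",
    "write_trajectories",
    "read_schedule",
    "write_schedule",
    "write_records",
    "run_pipeline",
]

logger = logging.getLogger("chlamycycle")

TRAJECTORY_COLUMNS = ["cell_id", "time_h", "volume_um3"]

RECORD_COLUMNS = [
    "cell_id",
    "condition",
    "T_h",
    "mu_first_per_h",
    "muT",
    "ratio_final",
    "dark_adjusted_muT",
    "additive_accrual",
    "division_number",
]


@dataclass
class PipelineConfig:
    """Everything the pipeline needs, round-trippable through JSON."""

    params: CycleParams = field(default_factory=CycleParams)
    drop_fraction: float = 0.05
    min_samples: int = 5
    #: median pre-filter width for division detection; None = auto (~0.25 h)
    smooth_window: int | None = None
    use_annotations: bool = False
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "drop_fraction": self.drop_fraction,
            "min_samples": self.min_samples,
            "smooth_window": self.smooth_window,
            "use_annotations": self.use_annotations,
            "seed": self.seed,
            "log_level": self.log_level,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "params" in d:
            d["params"] = CycleParams.from_dict(d["params"])
        return cls(**d)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        return cls.from_dict(json.loads(text))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _parse_error(path, row, message) -> ValueError:
    return ValueError(f"{path}: row {row}: {message}")


def read_trajectories(
    path, schedule: LightSchedule | None = None
) -> list[VolumeTrajectory]:
    """Read and validate a trajectory CSV; one trajectory per cell_id.

    Rows may arrive in any order; they are sorted by time within each cell.
    Malformed rows (missing column, non-numeric field, non-positive volume,
    duplicate (cell_id, time)) raise a parse error naming the file and row.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"cell_id": str})
    missing = [c for c in TRAJECTORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    for col in ("time_h", "volume_um3"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(vals.isna() & df[col].notna() | df[col].isna())
        if bad.size:
            raise _parse_error(path, int(bad[0]) + 2, f"non-numeric {col}")
        df[col] = vals
    bad = np.flatnonzero((df["volume_um3"] <= 0).to_numpy())
    if bad.size:
        raise _parse_error(path, int(bad[0]) + 2, "volume_um3 must be positive")
    dup = df.duplicated(subset=["cell_id", "time_h"])
    if dup.any():
        raise _parse_error(
            path, int(np.flatnonzero(dup)[0]) + 2, "duplicate (cell_id, time_h)"
        )
    out = []
    for cell_id, grp in df.groupby("cell_id", sort=True):
        grp = grp.sort_values("time_h")
        out.append(
            VolumeTrajectory(
                cell_id=str(cell_id),
                times=grp["time_h"].to_numpy(),
                volumes=grp["volume_um3"].to_numpy(),
                schedule=schedule,
            )
        )
    return out


def write_trajectories(trajectories, path) -> None:
    """Write trajectories as CSV with 6-significant-digit floats."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        fh.write(",".join(TRAJECTORY_COLUMNS) + "\r\n")
        for traj in trajectories:
            for t, v in zip(traj.times, traj.volumes):
                fh.write(f"{traj.cell_id},{t:.6g},{v:.6g}\r\n")


def read_schedule(path) -> LightSchedule:
    return LightSchedule.from_json(Path(path).read_text())


def write_schedule(schedule: LightSchedule, path) -> None:
    Path(path).write_text(schedule.to_json())


def _record_row(r: CellRecord) -> dict:
    return {
        "cell_id": r.cell_id,
        "condition": r.condition_label,
        "T_h": r.T,
        "mu_first_per_h": r.mu_first,
        "muT": r.muT,
        "ratio_final": r.ratio_final,
        "dark_adjusted_muT": r.dark_adjusted_muT,
        "additive_accrual": r.additive_accrual,
        "division_number": r.division_number,
    }


def write_records(records, path) -> None:
    """Per-cell records as CSV with fixed column order."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        fh.write(",".join(RECORD_COLUMNS) + "\r\n")
        for r in records:
            row = _record_row(r)
            cells = []
            for col in RECORD_COLUMNS:
                v = row[col]
                if v is None:
                    cells.append("")
                elif isinstance(v, float):
                    cells.append(f"{v:.6g}")
                else:
                    cells.append(str(v))
            fh.write(",".join(cells) + "\r\n")


def run_pipeline(
    config: PipelineConfig,
    trajectories_path,
    schedule_path,
    records_out=None,
    summary_out=None,
) -> dict:
    """Analyse a cohort end to end and return (and optionally write) a report.

    The report JSON embeds the resolved configuration and its hash, the
    cohort summary, and the per-cell records.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    schedule = read_schedule(schedule_path)
    trajectories = read_trajectories(trajectories_path, schedule=schedule)
    if not trajectories:
        raise ValueError(f"{trajectories_path}: empty cohort")
    logger.info(
        "analysing %d cells (config %s, seed %d)",
        len(trajectories),
        config.config_hash(),
        config.seed,
    )
    records = [
        analyse_trajectory(
            t,
            params=config.params,
            drop_fraction=config.drop_fraction,
            min_samples=config.min_samples,
            use_annotations=config.use_annotations,
            smooth_window=config.smooth_window,
        )
        for t in trajectories
    ]
    summary = summarise_cohort(records)
    report = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_cells": len(records),
        "summary": summary.to_dict(),
        "records": [_record_row(r) for r in records],
    }
    if records_out is not None:
        write_records(records, records_out)
    if summary_out is not None:
        Path(summary_out).write_text(json.dumps(report, indent=1, sort_keys=True))
    return report
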