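"""Read and write colony metadata, worker trajectories, and colony summaries.

All files are plain CSV. Positions are stored in millimetres with a
bottom-left origin; an optional ``px_per_mm`` conversion factor can be
applied at read time for trajectory files digitised in pixels.

Schemas
-------
colonies
    ``colony_id,n_total,n_tracked,mass_g,metabolic_rate_mW,enclosure_mm,duration_s,frame_rate,sample_stride``
    (the last four columns are optional and default to 248, 30, 15, 5).
trajectories
    ``colony_id,worker_id,t_s,x_mm,y_mm``, one row per position sample.
summaries
    ``colony_id,n_total,n_tracked,L_mm,L_median_mm,n_active,E,mean_degree,area_mm2,a_star,i_star``.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .records import ColonyRecord, ColonySummary, Trajectory, ValidationError

logger = logging.getLogger(__name__)

COLONY_COLUMNS = [
    "colony_id", "n_total", "n_tracked", "mass_g", "metabolic_rate_mW",
    "enclosure_mm", "duration_s", "frame_rate", "sample_stride",
]
_COLONY_DEFAULTS = {"enclosure_mm": 248.0, "duration_s": 30.0, "frame_rate": 15.0,
                    "sample_stride": 5}
TRAJECTORY_COLUMNS = ["colony_id", "worker_id", "t_s", "x_mm", "y_mm"]
SUMMARY_COLUMNS = [
    "colony_id", "n_total", "n_tracked", "L_mm", "L_median_mm", "n_active",
    "E", "mean_degree", "area_mm2", "a_star", "i_star",
]


def read_colonies(path: str | Path) -> list[ColonyRecord]:
    """Load colony metadata, validating every row.

    Raises :class:`~antscale.records.ValidationError` naming the offending
    row for missing columns, non-positive quantities, or duplicate ids.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    required = COLONY_COLUMNS[:5]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required column(s) {missing}")
    for col, default in _COLONY_DEFAULTS.items():
        if col not in df.columns:
            df[col] = default
        else:
            df[col] = df[col].fillna(default)
    if df["colony_id"].duplicated().any():
        dupes = df.loc[df["colony_id"].duplicated(), "colony_id"].tolist()
        raise ValidationError(f"{path}: duplicate colony_id(s) {dupes}")
    records = []
    for i, row in df.iterrows():
        try:
            records.append(
                ColonyRecord(
                    colony_id=str(row["colony_id"]),
                    n_total=int(row["n_total"]),
                    n_tracked=int(row["n_tracked"]),
                    mass_g=float(row["mass_g"]),
                    metabolic_rate_mw=float(row["metabolic_rate_mW"]),
                    enclosure_mm=float(row["enclosure_mm"]),
                    duration_s=float(row["duration_s"]),
                    frame_rate=float(row["frame_rate"]),
                    sample_stride=int(row["sample_stride"]),
                )
            )
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"{path}: row {i}: {exc}") from exc
    return records


def write_colonies(records: Sequence[ColonyRecord], path: str | Path) -> None:
    """Write colony metadata; inverse of :func:`read_colonies`."""
    if not records:
        raise ValidationError("cannot write an empty colony collection")
    df = pd.DataFrame(
        {
            "colony_id": [r.colony_id for r in records],
            "n_total": [r.n_total for r in records],
            "n_tracked": [r.n_tracked for r in records],
            "mass_g": [r.mass_g for r in records],
            "metabolic_rate_mW": [r.metabolic_rate_mw for r in records],
            "enclosure_mm": [r.enclosure_mm for r in records],
            "duration_s": [r.duration_s for r in records],
            "frame_rate": [r.frame_rate for r in records],
            "sample_stride": [r.sample_stride for r in records],
        }
    )
    df.to_csv(path, index=False)


def read_trajectories(
    path: str | Path,
    colonies: Sequence[ColonyRecord],
    *,
    mode: str = "strict",
    px_per_mm: float | None = None,
) -> list[Trajectory]:
    """Load per-worker trajectories and validate them against their colonies.

    Parameters
    ----------
    mode
        ``"strict"`` rejects out-of-enclosure positions; ``"lenient"`` clips
        them to the enclosure with a warning.
    px_per_mm
        If given, raw coordinates are divided by this factor (input in
        pixels) before bounds checks.

    Rows are grouped by (colony_id, worker_id) and sorted by time, so input
    row order is immaterial. Workers with fewer samples than the colony's
    nominal grid are kept and flagged ``partial``.
    """
    if mode not in ("strict", "lenient"):
        raise ValueError(f"mode must be 'strict' or 'lenient', got {mode!r}")
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in TRAJECTORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required column(s) {missing}")
    by_id = {c.colony_id: c for c in colonies}
    orphans = set(df["colony_id"].astype(str)) - set(by_id)
    if orphans:
        raise ValidationError(f"{path}: colony_id(s) {sorted(orphans)} not in metadata")
    if px_per_mm is not None:
        df = df.assign(x_mm=df["x_mm"] / px_per_mm, y_mm=df["y_mm"] / px_per_mm)

    trajs: list[Trajectory] = []
    for (cid, wid), grp in df.groupby(["colony_id", "worker_id"], sort=True):
        cid, wid = str(cid), str(wid)
        record = by_id[cid]
        grp = grp.sort_values("t_s")
        t = grp["t_s"].to_numpy(dtype=float)
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValidationError(
                f"{path}: worker {wid} (colony {cid}): non-monotone sample times"
            )
        xy = grp[["x_mm", "y_mm"]].to_numpy(dtype=float)
        side = record.enclosure_mm
        out = (xy < 0) | (xy > side)
        if out.any():
            if mode == "strict":
                bad = np.nonzero(out.any(axis=1))[0][0]
                raise ValidationError(
                    f"{path}: worker {wid} (colony {cid}): position "
                    f"({xy[bad, 0]:g}, {xy[bad, 1]:g}) mm outside [0, {side:g}]"
                )
            warnings.warn(
                f"worker {wid} (colony {cid}): clipped {int(out.any(axis=1).sum())} "
                f"out-of-enclosure sample(s)",
                stacklevel=2,
            )
            xy = np.clip(xy, 0.0, side)
        trajs.append(
            Trajectory(
                colony_id=cid,
                worker_id=wid,
                times=t,
                xy=xy,
                partial=t.size < record.n_samples_expected,
            )
        )
    for cid in by_id:
        workers = [t.worker_id for t in trajs if t.colony_id == cid]
        if len(workers) != len(set(workers)):
            raise ValidationError(f"{path}: duplicate worker_id within colony {cid}")
    return trajs


def write_trajectories(trajs: Iterable[Trajectory], path: str | Path) -> None:
    """Write trajectories; inverse of :func:`read_trajectories`."""
    trajs = list(trajs)
    if not trajs:
        raise ValidationError("cannot write an empty trajectory collection")
    frames = [
        pd.DataFrame(
            {
                "colony_id": tr.colony_id,
                "worker_id": tr.worker_id,
                "t_s": tr.times,
                "x_mm": tr.xy[:, 0],
                "y_mm": tr.xy[:, 1],
            }
        )
        for tr in trajs
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_summaries(summaries: Sequence[ColonySummary], path: str | Path) -> None:
    """Write per-colony summaries to CSV (lossless round-trip)."""
    if not summaries:
        raise ValidationError("cannot write an empty summary collection")
    df = pd.DataFrame(
        {
            "colony_id": [s.colony_id for s in summaries],
            "n_total": [s.n_total for s in summaries],
            "n_tracked": [s.n_tracked for s in summaries],
            "L_mm": [s.l_mean_mm for s in summaries],
            "L_median_mm": [s.l_median_mm for s in summaries],
            "n_active": [s.n_active for s in summaries],
            "E": [s.e_mean for s in summaries],
            "mean_degree": [s.mean_degree for s in summaries],
            "area_mm2": [s.area_mm2 for s in summaries],
            "a_star": [s.a_star for s in summaries],
            "i_star": [s.i_star for s in summaries],
        }
    )
    df.to_csv(path, index=False)


def read_summaries(path: str | Path) -> list[ColonySummary]:
    """Load per-colony summaries written by :func:`write_summaries`."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in SUMMARY_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required column(s) {missing}")
    out = []
    for i, row in df.iterrows():
        try:
            out.append(
                ColonySummary(
                    colony_id=str(row["colony_id"]),
                    n_total=int(row["n_total"]),
                    n_tracked=int(row["n_tracked"]),
                    l_mean_mm=float(row["L_mm"]),
                    l_median_mm=float(row["L_median_mm"]),
                    n_active=int(row["n_active"]),
                    e_mean=float(row["E"]),
                    mean_degree=float(row["mean_degree"]),
                    area_mm2=float(row["area_mm2"]),
                    a_star=float(row["a_star"]),
                    i_star=float(row["i_star"]),
                )
            )
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"{path}: row {i}: {exc}") from exc
    return out
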