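"""Per-worker path lengths, speeds, and active/inactive classification.

A worker counts as active when its average speed over the observation
exceeds 0.1 mm/s — for a 30 s video, a travelled distance of more than
3 mm. The comparison is strict, so a worker at exactly the threshold is
inactive. Path length is the sum of Euclidean displacements between the
tracked positions (3 Hz sampling; no interpolation to the full frame rate).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .records import ColonyRecord, Trajectory

#: Average-speed threshold separating active from inactive workers (mm/s).
SPEED_THRESHOLD_MM_S = 0.1


@dataclass
class KinematicSummary:
    """Path length, mean speed, and activity label for one worker."""

    worker_id: str
    path_length: float  # mm
    mean_speed: float  # mm/s
    active: bool
    partial: bool = False


def path_length(traj: Trajectory) -> float:
    """Total distance travelled along the sampled positions, in mm.

    Zero for a single-sample trajectory.
    """
    if traj.n_samples < 2:
        return 0.0
    steps = np.diff(traj.xy, axis=0)
    return float(np.hypot(steps[:, 0], steps[:, 1]).sum())


def classify_active(
    traj: Trajectory,
    duration: float,
    speed_threshold: float = SPEED_THRESHOLD_MM_S,
) -> KinematicSummary:
    """Label one worker active/inactive from its average speed.

    ``duration`` is the nominal observation length; partially tracked
    workers are scored over their own observed time span instead, so a
    worker visible for 10 s is not diluted to a 30 s average.
    """
    if duration <= 0:
        raise ValueError(f"duration must be positive, got {duration}")
    length = path_length(traj)
    if traj.partial and traj.observed_duration > 0:
        effective = traj.observed_duration
    else:
        effective = duration
    speed = length / effective
    return KinematicSummary(
        worker_id=traj.worker_id,
        path_length=length,
        mean_speed=speed,
        active=speed > speed_threshold,
        partial=traj.partial,
    )


def colony_kinematics(
    trajs: Sequence[Trajectory],
    record: ColonyRecord,
    speed_threshold: float = SPEED_THRESHOLD_MM_S,
) -> tuple[float, float, int]:
    """Aggregate worker kinematics for one colony.

    Returns ``(L_mean, L_median, n_active)``: mean and median per-worker
    path length (mm) and the number of active workers A, all over tracked
    workers only.
    """
    trajs = [t for t in trajs if t.colony_id == record.colony_id]
    if not trajs:
        raise ValueError(f"no trajectories for colony {record.colony_id}")
    summaries = [classify_active(t, record.duration_s, speed_threshold) for t in trajs]
    lengths = np.array([s.path_length for s in summaries])
    n_active = int(sum(s.active for s in summaries))
    return float(lengths.mean()), float(np.median(lengths)), n_active
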