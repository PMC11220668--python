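"""Core record types shared across the pipeline.

A colony is described by its census metadata (:class:`ColonyRecord`), the
tracked workers' positional data (:class:`Trajectory`), and the derived
per-colony quantities (:class:`ColonySummary`) that every downstream model
consumes: mean/median path length L, active count A, time-averaged edge
count E, mean degree ⟨k⟩ = 2E/N, spanned area, and the whole-colony scaled
counts A* = A·N*/N and I* = N* − A*.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np


class ValidationError(ValueError):
    """Raised when an input record violates a structural invariant."""


@dataclass
class ColonyRecord:
    """Census and recording metadata for one colony.

    Parameters
    ----------
    colony_id
        Unique colony identifier.
    n_total
        Total worker count N* (from the colony census).
    n_tracked
        Number of visually trackable workers N (N ≤ N*).
    mass_g
        Colony wet mass M in grams.
    metabolic_rate_mw
        Whole-colony metabolic rate B in milliwatts.
    enclosure_mm
        Side length of the square nest enclosure in mm.
    duration_s
        Length of the video observation in seconds.
    frame_rate
        Video frame rate in frames per second.
    sample_stride
        Frames between consecutive tracked positions (positions are
        annotated every ``sample_stride`` frames).
    """

    colony_id: str
    n_total: int
    n_tracked: int
    mass_g: float
    metabolic_rate_mw: float
    enclosure_mm: float = 248.0
    duration_s: float = 30.0
    frame_rate: float = 15.0
    sample_stride: int = 5

    def __post_init__(self) -> None:
        if self.n_total < 1:
            raise ValidationError(f"colony {self.colony_id}: n_total must be >= 1")
        if not 1 <= self.n_tracked <= self.n_total:
            raise ValidationError(
                f"colony {self.colony_id}: need 1 <= n_tracked <= n_total, "
                f"got n_tracked={self.n_tracked}, n_total={self.n_total}"
            )
        for name in ("mass_g", "metabolic_rate_mw", "enclosure_mm", "duration_s", "frame_rate"):
            if getattr(self, name) <= 0:
                raise ValidationError(
                    f"colony {self.colony_id}: {name} must be strictly positive"
                )
        if self.sample_stride < 1:
            raise ValidationError(f"colony {self.colony_id}: sample_stride must be >= 1")

    @property
    def n_samples_expected(self) -> int:
        """Number of position samples per fully tracked worker."""
        return math.floor(self.duration_s * self.frame_rate / self.sample_stride)

    @property
    def sample_times(self) -> np.ndarray:
        """Nominal sample-time grid in seconds (0-based)."""
        dt = self.sample_stride / self.frame_rate
        return np.arange(self.n_samples_expected) * dt


@dataclass
class Trajectory:
    """One tracked worker's time-stamped 2-D positions (mm, bottom-left origin)."""

    colony_id: str
    worker_id: str
    times: np.ndarray  # shape (n,), seconds, strictly increasing
    xy: np.ndarray  # shape (n, 2), mm
    partial: bool = False  # fewer samples than the colony's nominal grid

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.xy = np.asarray(self.xy, dtype=float)
        if self.times.ndim != 1 or self.xy.shape != (self.times.size, 2):
            raise ValidationError(
                f"worker {self.worker_id}: times must be (n,), xy must be (n, 2)"
            )
        if self.times.size == 0:
            raise ValidationError(f"worker {self.worker_id}: empty trajectory")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValidationError(
                f"worker {self.worker_id}: sample times must be strictly increasing"
            )

    @property
    def n_samples(self) -> int:
        return self.times.size

    @property
    def observed_duration(self) -> float:
        """Time spanned by the observed samples, in seconds."""
        return float(self.times[-1] - self.times[0])


@dataclass
class ColonySummary:
    """Derived per-colony quantities feeding the scaling and metabolic models."""

    colony_id: str
    n_total: int
    n_tracked: int
    l_mean_mm: float
    l_median_mm: float
    n_active: int
    e_mean: float  # time-averaged proximity edge count E
    mean_degree: float  # ⟨k⟩ = 2E/N
    area_mm2: float  # spanned area
    a_star: float  # A·N*/N
    i_star: float  # N* − A*

    def __post_init__(self) -> None:
        if self.n_tracked < 1:
            raise ValidationError(f"colony {self.colony_id}: n_tracked must be >= 1")
        if self.n_active < 0 or self.n_active > self.n_tracked:
            raise ValidationError(
                f"colony {self.colony_id}: need 0 <= n_active <= n_tracked"
            )
        for name in ("l_mean_mm", "l_median_mm", "e_mean", "area_mm2"):
            if getattr(self, name) < 0:
                raise ValidationError(f"colony {self.colony_id}: {name} must be >= 0")
        if not math.isclose(self.a_star + self.i_star, self.n_total, rel_tol=1e-9, abs_tol=1e-6):
            raise ValidationError(
                f"colony {self.colony_id}: a_star + i_star must equal n_total"
            )
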