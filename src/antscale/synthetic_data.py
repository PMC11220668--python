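"""Synthetic colonies with the statistical structure the analysis assumes.

Two modes:

* **summary mode** — draws per-colony derived quantities directly from the
  generating scaling laws (E = E0·N^βE, Area = Area0·N^βArea, the balance
  relation for A, the Cobb–Douglas law for B) with multiplicative
  lognormal noise. Sharp parameter-recovery tests run here.
* **trajectory mode** — emits full positional data: workers aggregate
  around a few attractor sites with heavy-tailed weights (ants cluster at
  corners, brood pile, food), inactive workers jitter sub-threshold around
  their site, active workers perform correlated random walks with
  size-independent mean path length. End-to-end pipeline tests and
  qualitative (hypermetric/hypometric) checks run here; the emergent
  exponents are not guaranteed to equal the summary-mode targets.

Randomness uses one root seed with per-colony child streams
(``numpy.random.SeedSequence.spawn``), so appending a colony never
perturbs earlier ones.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .records import ColonyRecord, ColonySummary, Trajectory

_TWO_PI = 2.0 * np.pi


@dataclass
class GeneratorConfig:
    """Generating parameters; scaling-law defaults are the fitted values
    from the 16-colony harvester-ant dataset."""

    n_colonies: int = 16
    n_range: tuple[int, int] = (40, 400)  # N* bounds, log-uniform
    tracked_fraction: float = 0.85
    beta_e: float = 1.47
    e0: float = 0.0944
    beta_area: float = 0.51
    area0: float = 3050.0  # mm²
    q: float = 0.519
    alpha_b: float = 0.85
    b0: float = 0.0301  # mW
    noise_sigma_log: float = 0.2
    # trajectory mode
    n_clusters: int = 4
    cluster_sd_mm: float = 15.0
    active_fraction_override: float | None = None
    # auxiliary scales (see docs/methods.md)
    mean_path_mm: float = 77.0  # size-independent mean path length L
    path_sigma_log: float = 0.3
    mass_per_worker_g: float = 0.008
    mass_sigma_log: float = 0.1
    jitter_mm: float = 0.005  # inactive-worker positional noise per sample
    # enclosure / recording protocol
    enclosure_mm: float = 248.0
    duration_s: float = 30.0
    frame_rate: float = 15.0
    sample_stride: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_colonies < 1:
            raise ValueError("n_colonies must be >= 1")
        if not 0 < self.tracked_fraction <= 1:
            raise ValueError("tracked_fraction must be in (0, 1]")
        if self.n_range[0] < 1 or self.n_range[1] < self.n_range[0]:
            raise ValueError(f"invalid n_range {self.n_range}")
        for name in ("e0", "area0", "q", "b0", "mean_path_mm", "mass_per_worker_g",
                     "enclosure_mm", "duration_s", "frame_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.noise_sigma_log < 0:
            raise ValueError("noise_sigma_log must be >= 0")
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "n_range" in data:
            data["n_range"] = tuple(data["n_range"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["n_range"] = list(data["n_range"])
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def _colony_streams(config: GeneratorConfig) -> list[np.random.Generator]:
    root = np.random.SeedSequence(config.seed)
    return [np.random.default_rng(child) for child in root.spawn(config.n_colonies)]


def _draw_census(rng: np.random.Generator, config: GeneratorConfig) -> tuple[int, int]:
    lo, hi = config.n_range
    n_total = int(round(np.exp(rng.uniform(np.log(lo), np.log(hi)))))
    n_total = max(1, n_total)
    n_tracked = max(1, int(round(config.tracked_fraction * n_total)))
    return n_total, min(n_tracked, n_total)


def balance_active_count(q: float, n: int, e: float) -> float:
    """Active count solving the balance ⟨k⟩A²/N = qN for the colony's own E.

    With ⟨k⟩ = 2E/N the solution is A = N·sqrt(qN/(2E)), capped at N.
    """
    a = n * np.sqrt(q * n / (2.0 * e))
    return float(min(a, n))


def generate_summaries(
    config: GeneratorConfig,
) -> tuple[list[ColonyRecord], list[ColonySummary]]:
    """Draw per-colony summaries directly from the generating laws."""
    records: list[ColonyRecord] = []
    summaries: list[ColonySummary] = []
    for j, rng in enumerate(_colony_streams(config)):
        n_total, n = _draw_census(rng, config)
        sig = config.noise_sigma_log
        e = config.e0 * n**config.beta_e * rng.lognormal(0.0, sig)
        area = config.area0 * n**config.beta_area * rng.lognormal(0.0, sig)
        a = int(round(balance_active_count(config.q, n, e)))
        a = min(max(a, 0), n)
        a_star = a * n_total / n
        i_star = n_total - a_star
        b = (
            config.b0
            * max(a_star, 1e-12) ** config.alpha_b
            * max(i_star, 1e-12) ** (1.0 - config.alpha_b)
            * rng.lognormal(0.0, sig)
        )
        mass = config.mass_per_worker_g * n_total * rng.lognormal(0.0, config.mass_sigma_log)
        l_mean = rng.lognormal(np.log(config.mean_path_mm), config.path_sigma_log)
        cid = f"syn{j + 1:02d}"
        records.append(
            ColonyRecord(
                colony_id=cid, n_total=n_total, n_tracked=n, mass_g=mass,
                metabolic_rate_mw=b, enclosure_mm=config.enclosure_mm,
                duration_s=config.duration_s, frame_rate=config.frame_rate,
                sample_stride=config.sample_stride,
            )
        )
        summaries.append(
            ColonySummary(
                colony_id=cid, n_total=n_total, n_tracked=n,
                l_mean_mm=l_mean, l_median_mm=0.9 * l_mean, n_active=a,
                e_mean=e, mean_degree=2.0 * e / n, area_mm2=area,
                a_star=a_star, i_star=i_star,
            )
        )
    return records, summaries


def _simulate_worker(
    rng: np.random.Generator,
    active: bool,
    sites: np.ndarray,
    site_idx: int,
    config: GeneratorConfig,
    n_samples: int,
) -> np.ndarray:
    side = config.enclosure_mm
    anchor = sites[site_idx] + rng.normal(0.0, config.cluster_sd_mm, size=2)
    anchor = np.clip(anchor, 0.0, side)
    if not active:
        xy = anchor + rng.normal(0.0, config.jitter_mm, size=(n_samples, 2))
        return np.clip(xy, 0.0, side)
    # correlated random walk drifting between attractor sites; step length
    # calibrated so the total path is size-independent around mean_path_mm
    total = rng.lognormal(np.log(config.mean_path_mm), config.path_sigma_log)
    step = total / max(n_samples - 1, 1)
    target = site_idx
    heading = rng.uniform(0.0, _TWO_PI)
    xy = np.empty((n_samples, 2))
    xy[0] = anchor
    for k in range(1, n_samples):
        if rng.random() < 0.03:
            target = int(rng.integers(len(sites)))
        to_site = sites[target] - xy[k - 1]
        bias = np.arctan2(to_site[1], to_site[0])
        # relax heading toward the target, with angular noise
        heading += 0.3 * np.angle(np.exp(1j * (bias - heading))) + rng.normal(0.0, 0.6)
        pos = xy[k - 1] + step * np.array([np.cos(heading), np.sin(heading)])
        # reflect at the walls
        for axis in range(2):
            if pos[axis] < 0:
                pos[axis] = -pos[axis]
            elif pos[axis] > side:
                pos[axis] = 2 * side - pos[axis]
        xy[k] = np.clip(pos, 0.0, side)
    return xy


def generate_trajectories(
    config: GeneratorConfig,
) -> tuple[list[ColonyRecord], list[Trajectory]]:
    """Emit full positional data for every tracked worker.

    Workers cluster around ``n_clusters`` attractor sites with
    Dirichlet(0.7) weights. The active fraction follows the balance
    prediction sqrt(q/(2E0))·N^((1−βE)/2) (capped at 0.95) unless
    ``active_fraction_override`` is set. Colony mass and metabolic rate in
    the metadata are generated consistently with the realised active
    count, so the trajectory world feeds the full pipeline.
    """
    records: list[ColonyRecord] = []
    trajectories: list[Trajectory] = []
    for j, rng in enumerate(_colony_streams(config)):
        n_total, n = _draw_census(rng, config)
        cid = f"syn{j + 1:02d}"
        side = config.enclosure_mm
        margin = 0.12 * side
        sites = rng.uniform(margin, side - margin, size=(config.n_clusters, 2))
        weights = rng.dirichlet(np.full(config.n_clusters, 0.7))
        assignment = rng.choice(config.n_clusters, size=n, p=weights)
        if config.active_fraction_override is not None:
            f = config.active_fraction_override
        else:
            f = min(
                0.95,
                np.sqrt(config.q / (2.0 * config.e0))
                * n ** ((1.0 - config.beta_e) / 2.0),
            )
        active = rng.random(n) < f
        n_samples = int(np.floor(config.duration_s * config.frame_rate / config.sample_stride))
        times = np.arange(n_samples) * config.sample_stride / config.frame_rate
        for w in range(n):
            xy = _simulate_worker(rng, bool(active[w]), sites, int(assignment[w]),
                                  config, n_samples)
            trajectories.append(
                Trajectory(colony_id=cid, worker_id=f"{cid}_w{w + 1:03d}",
                           times=times.copy(), xy=xy)
            )
        a = int(active.sum())
        a_star = a * n_total / n
        i_star = n_total - a_star
        b = (
            config.b0
            * max(a_star, 1e-12) ** config.alpha_b
            * max(i_star, 1e-12) ** (1.0 - config.alpha_b)
            * rng.lognormal(0.0, config.noise_sigma_log)
        )
        mass = config.mass_per_worker_g * n_total * rng.lognormal(0.0, config.mass_sigma_log)
        records.append(
            ColonyRecord(
                colony_id=cid, n_total=n_total, n_tracked=n, mass_g=mass,
                metabolic_rate_mw=b, enclosure_mm=side,
                duration_s=config.duration_s, frame_rate=config.frame_rate,
                sample_stride=config.sample_stride,
            )
        )
    return records, trajectories
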