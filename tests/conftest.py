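import numpy as np
import pytest

from antscale.records import ColonyRecord, ColonySummary, Trajectory


def make_trajectory(points, colony_id="c1", worker_id="w1", dt=1 / 3, times=None,
                    partial=False):
    """Build a Trajectory from a list of (x, y) positions on a regular grid."""
    xy = np.asarray(points, dtype=float)
    if times is None:
        times = np.arange(len(xy)) * dt
    return Trajectory(colony_id=colony_id, worker_id=worker_id,
                      times=np.asarray(times, dtype=float), xy=xy, partial=partial)


@pytest.fixture
def record():
    return ColonyRecord(colony_id="c1", n_total=100, n_tracked=85,
                        mass_g=0.8, metabolic_rate_mw=1.2)


@pytest.fixture
def summary():
    return ColonySummary(colony_id="c1", n_total=100, n_tracked=85,
                         l_mean_mm=40.0, l_median_mm=35.0, n_active=40,
                         e_mean=80.0, mean_degree=2 * 80.0 / 85, area_mm2=20000.0,
                         a_star=40 * 100 / 85, i_star=100 - 40 * 100 / 85)
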