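"""The generator's stated world: determinism, recovery, emergent structure."""

import numpy as np
import pytest

from antscale import kinematics
from antscale.contagion_model import estimate_q
from antscale.metabolic_model import ScaledCounts, fit_cobb_douglas
from antscale.occupancy import spanned_area
from antscale.scaling_fits import fit_power_law
from antscale.synthetic_data import (
    GeneratorConfig,
    balance_active_count,
    generate_summaries,
    generate_trajectories,
)


class TestConfig:
    def test_defaults_are_the_fitted_constants(self):
        cfg = GeneratorConfig()
        assert (cfg.beta_e, cfg.e0, cfg.beta_area, cfg.area0) == (1.47, 0.0944, 0.51, 3050.0)
        assert (cfg.q, cfg.alpha_b, cfg.b0) == (0.519, 0.85, 0.0301)
        assert cfg.n_colonies == 16 and cfg.n_range == (40, 400)
        assert cfg.tracked_fraction == 0.85

    @pytest.mark.parametrize(
        "kwargs", [dict(tracked_fraction=0.0), dict(n_range=(0, 10)),
                   dict(q=-1.0), dict(n_colonies=0), dict(noise_sigma_log=-0.1)]
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            GeneratorConfig(**kwargs)

    def test_yaml_round_trip(self, tmp_path):
        cfg = GeneratorConfig(seed=9, noise_sigma_log=0.3, n_clusters=6)
        p = tmp_path / "gen.yaml"
        cfg.to_yaml(p)
        assert GeneratorConfig.from_yaml(p) == cfg


class TestSummaryMode:
    def test_seed_determinism(self):
        a = generate_summaries(GeneratorConfig(seed=13))
        b = generate_summaries(GeneratorConfig(seed=13))
        assert a == b
        c = generate_summaries(GeneratorConfig(seed=14))
        assert a != c

    def test_child_streams_stable_under_appended_colony(self):
        five = generate_summaries(GeneratorConfig(n_colonies=5, seed=3))
        six = generate_summaries(GeneratorConfig(n_colonies=6, seed=3))
        assert five[0] == six[0][:5]
        assert five[1] == six[1][:5]

    def test_noise_free_world_recovers_exponents(self):
        """σ = 0: E and Area fits reproduce the generating laws exactly;
        q and αB inherit only the integer rounding of the active count."""
        records, summaries = generate_summaries(GeneratorConfig(noise_sigma_log=0.0, seed=1))
        n = np.array([s.n_tracked for s in summaries], float)
        e_fit = fit_power_law(n, [s.e_mean for s in summaries])
        area_fit = fit_power_law(n, [s.area_mm2 for s in summaries])
        assert e_fit.exponent == pytest.approx(1.47, abs=1e-10)
        assert e_fit.prefactor == pytest.approx(0.0944, rel=1e-10)
        assert area_fit.exponent == pytest.approx(0.51, abs=1e-10)
        _, params = estimate_q(summaries, e_fit)
        assert params.q == pytest.approx(0.519, rel=0.02)
        cd, _ = fit_cobb_douglas(
            [ScaledCounts(s.a_star, s.i_star) for s in summaries],
            [r.metabolic_rate_mw for r in records],
        )
        assert cd.alpha_b == pytest.approx(0.85, abs=0.02)

    def test_default_world_recovers_interaction_exponent(self):
        _, summaries = generate_summaries(GeneratorConfig(seed=7, noise_sigma_log=0.3))
        n = [s.n_tracked for s in summaries]
        fit = fit_power_law(n, [s.e_mean for s in summaries])
        assert fit.exponent == pytest.approx(1.47, abs=0.40)

    def test_balance_consistency_of_active_counts(self):
        """Generated A is the (rounded) solution of ⟨k⟩A²/N = qN at the colony's own E."""
        _, summaries = generate_summaries(GeneratorConfig(seed=21))
        for s in summaries:
            a_exact = balance_active_count(0.519, s.n_tracked, s.e_mean)
            assert s.n_active == round(a_exact) or s.n_active == s.n_tracked

    def test_summary_invariants(self):
        records, summaries = generate_summaries(GeneratorConfig(seed=4))
        for r, s in zip(records, summaries):
            assert 40 <= r.n_total <= 400
            assert r.n_tracked == round(0.85 * r.n_total) or r.n_tracked == 1
            assert s.a_star + s.i_star == pytest.approx(s.n_total)
            assert s.mean_degree == pytest.approx(2 * s.e_mean / s.n_tracked)


class TestTrajectoryMode:
    def test_seed_determinism(self):
        ra, ta = generate_trajectories(GeneratorConfig(n_colonies=3, seed=5))
        rb, tb = generate_trajectories(GeneratorConfig(n_colonies=3, seed=5))
        assert ra == rb
        for x, y in zip(ta, tb):
            np.testing.assert_array_equal(x.xy, y.xy)

    def test_positions_stay_in_enclosure_on_sample_grid(self):
        _, trajs = generate_trajectories(GeneratorConfig(n_colonies=3, seed=8))
        for tr in trajs:
            assert tr.n_samples == 90
            assert np.all((tr.xy >= 0) & (tr.xy <= 248))
            assert np.allclose(np.diff(tr.times), 1 / 3)

    def test_zero_active_fraction_classifies_all_inactive(self):
        cfg = GeneratorConfig(n_colonies=2, active_fraction_override=0.0, seed=6)
        records, trajs = generate_trajectories(cfg)
        for record in records:
            _, _, n_active = kinematics.colony_kinematics(
                [t for t in trajs if t.colony_id == record.colony_id], record
            )
            assert n_active == 0

    def test_activity_fraction_concentrates_on_override(self):
        """n_active/N approaches the generating fraction (binomial concentration)."""
        cfg = GeneratorConfig(n_colonies=2, n_range=(350, 400),
                              active_fraction_override=0.4, seed=10)
        records, trajs = generate_trajectories(cfg)
        for record in records:
            _, _, n_active = kinematics.colony_kinematics(
                [t for t in trajs if t.colony_id == record.colony_id], record
            )
            assert n_active / record.n_tracked == pytest.approx(0.4, abs=0.08)

    def test_collapsed_clusters_limit_spanned_area(self):
        """Spread → 0 pins all workers to the attractor sites."""
        cfg = GeneratorConfig(n_colonies=2, cluster_sd_mm=0.0,
                              active_fraction_override=0.0, n_clusters=4, seed=12)
        records, trajs = generate_trajectories(cfg)
        for record in records:
            grid = spanned_area(
                [t for t in trajs if t.colony_id == record.colony_id], record
            )
            assert len(grid.visited) <= 4
            assert grid.area <= 4 * grid.cell_length**2

    def test_active_worker_path_length_is_size_independent(self):
        """Per active worker the walk statistics do not depend on colony size
        (the colony-wide mean still declines with N because the active
        fraction does)."""
        cfg = GeneratorConfig(n_colonies=8, seed=2)
        records, trajs = generate_trajectories(cfg)
        l_active, sizes = [], []
        for record in records:
            lengths = [
                s.path_length
                for t in trajs
                if t.colony_id == record.colony_id
                and (s := kinematics.classify_active(t, record.duration_s)).active
            ]
            l_active.append(np.mean(lengths))
            sizes.append(record.n_tracked)
        # active-worker paths scatter around the generating 77 mm scale with
        # no systematic size trend
        assert abs(np.corrcoef(sizes, l_active)[0, 1]) < 0.7
        assert 50 < np.mean(l_active) < 110
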