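"""Cobb–Douglas fitting, marginal products, and the size→metabolism prediction."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from antscale import metabolic_model as mm
from antscale.contagion_model import ContagionParams, predict_active
from antscale.records import ColonyRecord, ColonySummary

CG = ContagionParams(q=0.519, e0=0.0944, beta_e=1.47)
CD = mm.CobbDouglasParams(b0=0.0301, alpha_b=0.85)


class TestScaleCounts:
    def test_worked_example(self):
        record = ColonyRecord("c1", 100, 80, 0.5, 1.0)
        summary = ColonySummary("c1", 100, 80, 40, 35, 40, 50, 1.25, 1e4,
                                a_star=50.0, i_star=50.0)
        counts = mm.scale_counts(summary, record)
        assert (counts.a_star, counts.i_star) == (50.0, 50.0)

    def test_no_active_workers(self):
        record = ColonyRecord("c1", 120, 100, 0.5, 1.0)
        summary = ColonySummary("c1", 120, 100, 1, 1, 0, 10, 0.2, 1e4,
                                a_star=0.0, i_star=120.0)
        counts = mm.scale_counts(summary, record)
        assert counts.a_star == 0.0 and counts.i_star == 120.0

    @settings(deadline=None, max_examples=50)
    @given(data=st.data())
    def test_conservation(self, data):
        n_total = data.draw(st.integers(2, 400))
        n_tracked = data.draw(st.integers(1, n_total))
        n_active = data.draw(st.integers(0, n_tracked))
        record = ColonyRecord("c1", n_total, n_tracked, 0.5, 1.0)
        a_star = n_active * n_total / n_tracked
        summary = ColonySummary("c1", n_total, n_tracked, 1, 1, n_active, 10, 0.2,
                                1e4, a_star=a_star, i_star=n_total - a_star)
        counts = mm.scale_counts(summary, record)
        assert counts.a_star + counts.i_star == pytest.approx(n_total)


class TestFitCobbDouglas:
    def _exact_world(self, b0=0.03, alpha=0.8, n=10, seed=0):
        rng = np.random.default_rng(seed)
        a = rng.uniform(5, 200, n)
        i = rng.uniform(5, 300, n)
        b = b0 * a**alpha * i ** (1 - alpha)
        return [mm.ScaledCounts(x, y) for x, y in zip(a, i)], b

    def test_exact_model_recovered_to_high_precision(self):
        counts, rates = self._exact_world()
        params, fit = mm.fit_cobb_douglas(counts, rates)
        assert params.alpha_b == pytest.approx(0.8, rel=1e-11)
        assert params.b0 == pytest.approx(0.03, rel=1e-11)
        assert fit.r2_raw == pytest.approx(1.0)

    def test_noisy_recovery_within_printed_band(self):
        """16 colonies at αB = 0.85, B0 = 0.0301 with σ = 0.2 noise: α̂B within ±0.15."""
        rng = np.random.default_rng(0)
        n = np.exp(rng.uniform(np.log(40), np.log(400), 16))
        frac = np.clip(math.sqrt(0.519 / (2 * 0.0944)) * n ** (-0.235), 0, 0.95)
        a, i = frac * n, (1 - frac) * n
        b = 0.0301 * a**0.85 * i**0.15 * rng.lognormal(0, 0.2, 16)
        params, fit = mm.fit_cobb_douglas(
            [mm.ScaledCounts(x, y) for x, y in zip(a, i)], b
        )
        assert params.alpha_b == pytest.approx(0.85, abs=0.15)
        assert fit.dof == 14

    def test_proportional_inputs_rejected(self):
        a = np.array([10.0, 20.0, 40.0, 80.0])
        counts = [mm.ScaledCounts(x, 2 * x) for x in a]
        with pytest.raises(ValueError, match="unidentifiable|zero variance"):
            mm.fit_cobb_douglas(counts, 0.03 * a)

    def test_zero_counts_excluded_then_error_below_three(self):
        counts, rates = self._exact_world(n=4)
        counts[0] = mm.ScaledCounts(0.0, 50.0)
        with pytest.warns(UserWarning, match="excluding"):
            params, _ = mm.fit_cobb_douglas(counts, rates)
        assert 0 < params.alpha_b < 1
        counts[1] = mm.ScaledCounts(0.0, 50.0)
        with pytest.warns(UserWarning, match="excluding"):
            with pytest.raises(ValueError, match=">= 3"):
                mm.fit_cobb_douglas(counts, rates)


class TestMarginalProducts:
    def test_worked_arithmetic(self):
        # αB·B/A* with B forced to 1 mW at A* = 50
        params = mm.CobbDouglasParams(b0=1.0, alpha_b=0.85)
        counts = mm.ScaledCounts(50.0, 30.0)
        b = mm.cobb_douglas_rate(params, counts)
        mp_a, mp_i = mm.marginal_products(params, counts)
        assert mp_a == pytest.approx(0.85 * b / 50.0)
        assert mp_a / mp_i == pytest.approx((0.85 / 50) / (0.15 / 30))

    def test_symmetric_at_equal_elasticities_and_counts(self):
        params = mm.CobbDouglasParams(b0=0.5, alpha_b=0.5)
        mp_a, mp_i = mm.marginal_products(params, mm.ScaledCounts(70.0, 70.0))
        assert mp_a == pytest.approx(mp_i)

    @settings(deadline=None, max_examples=50)
    @given(
        alpha=st.floats(0.05, 0.95),
        b0=st.floats(0.001, 1.0),
        a=st.floats(1.0, 500.0),
        i=st.floats(1.0, 500.0),
    )
    def test_euler_identity(self, alpha, b0, a, i):
        """Degree-one homogeneity: A*·MP(A*) + I*·MP(I*) = B exactly."""
        params = mm.CobbDouglasParams(b0=b0, alpha_b=alpha)
        counts = mm.ScaledCounts(a, i)
        mp_a, mp_i = mm.marginal_products(params, counts)
        assert a * mp_a + i * mp_i == pytest.approx(
            mm.cobb_douglas_rate(params, counts), rel=1e-12
        )

    def test_homogeneity_doubling_inputs_doubles_output(self):
        counts = mm.ScaledCounts(40.0, 90.0)
        doubled = mm.ScaledCounts(80.0, 180.0)
        assert mm.cobb_douglas_rate(CD, doubled) == pytest.approx(
            2 * mm.cobb_douglas_rate(CD, counts), rel=1e-12
        )


class TestPredictMetabolicRate:
    def test_equals_composition_of_activity_and_cobb_douglas(self):
        """Closed form ≡ Cobb–Douglas evaluated at the contagion-predicted counts."""
        for n in (30, 100, 351, 1000):
            n_total = round(n / 0.85)
            a_star = predict_active(CG, n) * n_total / n
            composed = mm.cobb_douglas_rate(
                CD, mm.ScaledCounts(a_star, n_total - a_star)
            )
            direct = mm.predict_metabolic_rate(CD, CG, n, n_total)
            assert direct == pytest.approx(composed, rel=1e-12)

    def test_alpha_one_limit_inactive_workers_costless(self):
        cd = mm.CobbDouglasParams(b0=0.03, alpha_b=1.0 - 1e-15)
        n, n_total = 100, 118
        frac = predict_active(CG, n) / n
        assert mm.predict_metabolic_rate(cd, CG, n, n_total) == pytest.approx(
            0.03 * n_total * frac, rel=1e-9
        )

    def test_domain_error_below_validity_bound(self):
        # predicted active fraction reaches 1 at n = (2E0/q)^(1/(1−βE)) ≈ 8.6
        with pytest.raises(mm.DomainError, match="active fraction"):
            mm.predict_metabolic_rate(CD, CG, 5, 6)
        mm.predict_metabolic_rate(CD, CG, 10, 12)  # just inside the domain

    def test_asymptotic_slope_matches_derived_exponent(self):
        """For large N (M ∝ N) the log-log slope approaches (1−βE)αB/2 + 1."""
        n = np.array([1e3, 1e4, 1e6, 1e8])
        b = [mm.predict_metabolic_rate(CD, CG, x, x) for x in n]
        slopes = np.diff(np.log(b)) / np.diff(np.log(n))
        target = mm.derived_exponent(CG, CD)
        assert slopes[-1] == pytest.approx(target, abs=2e-3)
        # convergence is monotone from below the isometric line
        assert abs(slopes[-1] - target) < abs(slopes[0] - target)


class TestDerivedExponent:
    def test_printed_value(self):
        assert round(mm.derived_exponent(CG, CD), 2) == 0.80

    def test_isometric_limit(self):
        cg = ContagionParams(q=0.519, e0=0.0944, beta_e=1.0 + 1e-15)
        assert mm.derived_exponent(cg, CD) == pytest.approx(1.0)

    def test_no_activity_dependence(self):
        cd = mm.CobbDouglasParams(b0=0.03, alpha_b=1e-15)
        assert mm.derived_exponent(CG, cd) == pytest.approx(1.0)
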