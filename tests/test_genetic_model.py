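"""Trait mixture model, heritability algebra, and cut-point solving."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad
from scipy.stats import norm

from bsadesign import (
    PoolSpec,
    PopulationKind,
    PopulationSpec,
    QTLEffectModel,
    effects_from_heritability,
    heritability_from_effects,
    mixture_cdf,
    mixture_pdf,
    population_b_t,
    solve_cut_points,
)


class TestPopulationBT:
    @pytest.mark.parametrize(
        "kind,k,expected",
        [
            ("F2", None, (0.25, 1)),
            ("F3", None, (0.375, 1)),
            ("F4", None, (0.4375, 1)),
            (PopulationKind.F_SELFING, 2, (0.25, 1)),
            (PopulationKind.F_SELFING, 3, (0.375, 1)),
            ("H", None, (0.5, 0)),
            ("DH", None, (0.5, 0)),
            ("RIL", None, (0.5, 0)),
        ],
    )
    def test_homozygote_frequency_and_ploidy_exponent(self, kind, k, expected):
        assert population_b_t(kind, k) == pytest.approx(expected)

    def test_selfing_limit_is_permanent_population(self):
        b, t = population_b_t(PopulationKind.F_SELFING, 50)
        assert b == pytest.approx(0.5, abs=1e-12)
        assert t == 1

    def test_invalid_generation_rejected(self):
        with pytest.raises(ValueError):
            population_b_t(PopulationKind.F_SELFING, 1)
        with pytest.raises(ValueError):
            population_b_t(PopulationKind.F_SELFING, None)
        with pytest.raises(ValueError):
            PopulationKind.parse("F1x")


class TestHeritability:
    def test_null_qtl_has_zero_heritability(self):
        assert heritability_from_effects(0.0, 0.0, 0.25) == (0.0, 0.0, 0.0)

    def test_dominance_vanishes_in_permanent_population(self):
        h2_a, h2_d, h2 = heritability_from_effects(1.0, 5.0, 0.5)
        assert (h2_a, h2_d, h2) == pytest.approx((0.5, 0.0, 0.5))

    def test_known_additive_point(self):
        # a0 = 0.3244 in an F2 explains ~5% of the variance
        _, _, h2 = heritability_from_effects(0.3244, 0.0, 0.25)
        assert h2 == pytest.approx(0.05, abs=2e-4)

    def test_inversion_closed_form(self):
        a0, d0 = effects_from_heritability(0.03, 0.0, 0.5)
        assert a0 == pytest.approx(math.sqrt((0.03 / 0.97) / 1.0), rel=1e-12)
        assert a0 == pytest.approx(0.1759, abs=1e-4)
        assert d0 == 0.0

    def test_h2_half_permanent_gives_unit_effect(self):
        a0, _ = effects_from_heritability(0.5, 0.7, 0.5)
        assert a0 == pytest.approx(1.0, rel=1e-12)

    def test_invalid_heritability_rejected(self):
        with pytest.raises(ValueError):
            effects_from_heritability(1.0, 0.0, 0.25)
        with pytest.raises(ValueError):
            effects_from_heritability(-0.1, 0.0, 0.25)

    @pytest.mark.parametrize("b", [0.25, 0.375, 0.4375, 0.5])
    @pytest.mark.parametrize("r_d", [0.0, 0.5, 1.0])
    @pytest.mark.parametrize("h2", [0.005, 0.03, 0.1, 0.3])
    def test_round_trip(self, h2, r_d, b):
        a0, d0 = effects_from_heritability(h2, r_d, b)
        h2_a, h2_d, h2_back = heritability_from_effects(a0, d0, b)
        assert h2_back == pytest.approx(h2, abs=1e-10)
        a0_back, d0_back = effects_from_heritability(h2_back, r_d, b)
        assert a0_back == pytest.approx(a0, abs=1e-10)
        assert d0_back == pytest.approx(d0, abs=1e-10)

    def test_empirical_variance_decomposition(self, rng):
        """Genotype-class simulation of the mixture reproduces h2_a, h2_d."""
        b, h2, r_d, n = 0.25, 0.1, 0.5, 1_000_000
        model = QTLEffectModel.from_heritability(h2, r_d, b)
        geno = rng.choice(3, size=n, p=[b, 1 - 2 * b, b])
        means = np.array([-model.a0, model.d0, model.a0])[geno]
        pheno = means + rng.standard_normal(n)
        h2_hat = np.var(means) / np.var(pheno)
        # MC standard error of the variance ratio is ~4e-4 at this n
        assert h2_hat == pytest.approx(h2, abs=3 * 4e-4)
        class_means = np.array([means[geno == g].mean() for g in range(3)])
        # additive part from the homozygote-class contrast
        a0_hat = (class_means[2] - class_means[0]) / 2
        assert a0_hat == pytest.approx(model.a0, abs=0.01)


class TestMixture:
    def test_null_is_standard_normal(self):
        x = np.linspace(-3, 3, 7)
        np.testing.assert_allclose(mixture_cdf(x, 0, 0, 0.25), norm.cdf(x))

    def test_symmetric_when_additive(self):
        assert mixture_cdf(0.0, 0.7, 0.0, 0.25) == pytest.approx(0.5)
        assert mixture_cdf(1.3, 0.7, 0.0, 0.25) == pytest.approx(
            1 - mixture_cdf(-1.3, 0.7, 0.0, 0.25)
        )

    @pytest.mark.parametrize(
        "a0,d0,b", [(0.3244, 0.0, 0.25), (0.5, 0.4, 0.375), (1.2, -0.6, 0.4375)]
    )
    def test_cdf_integrates_density(self, a0, d0, b):
        for x in (-1.0, 0.3, 0.692, 2.0):
            oracle, _ = quad(mixture_pdf, -np.inf, x, args=(a0, d0, b))
            assert mixture_cdf(x, a0, d0, b) == pytest.approx(oracle, abs=1e-9)

    def test_quadrature_point_from_f2_model(self):
        # F2, h2 ~ 0.05: third quartile of the mixture is near 0.692
        assert mixture_cdf(0.692, 0.3244, 0.0, 0.25) == pytest.approx(0.75, abs=1e-3)

    @settings(derandomize=True, max_examples=50)
    @given(
        x1=st.floats(-6, 6),
        x2=st.floats(-6, 6),
        a0=st.floats(0, 2),
        d0=st.floats(-2, 2),
        b=st.floats(0.25, 0.5),
    )
    def test_cdf_monotone(self, x1, x2, a0, d0, b):
        lo, hi = min(x1, x2), max(x1, x2)
        assert mixture_cdf(lo, a0, d0, b) <= mixture_cdf(hi, a0, d0, b) + 1e-12


class TestCutPoints:
    def test_standard_normal_quartiles(self):
        pool = PoolSpec(p=0.25, gamma=1.0)
        effect = QTLEffectModel.from_effects(0.0, 0.0, 0.25)
        pop = PopulationSpec.make("F2")
        xH, xL = solve_cut_points(pool, effect, pop)
        assert xH == pytest.approx(norm.isf(0.25), abs=1e-8)
        assert xL == pytest.approx(-norm.isf(0.25), abs=1e-8)

    def test_half_pools_meet_at_median(self):
        pool = PoolSpec(p=0.5, gamma=1.0)
        effect = QTLEffectModel.from_effects(0.8, 0.0, 0.25)
        pop = PopulationSpec.make("F2")
        xH, xL = solve_cut_points(pool, effect, pop)
        assert xH == pytest.approx(0.0, abs=1e-8)
        assert xL == pytest.approx(0.0, abs=1e-8)

    def test_haploid_quartile_cut(self):
        # haploid minor QTL: the cut sits slightly outside the normal quartile
        pool = PoolSpec(p=0.25, gamma=1.0)
        pop = PopulationSpec.make("H")
        effect = QTLEffectModel.from_heritability(0.03, 0.0, pop.b)
        xH, xL = solve_cut_points(pool, effect, pop)
        assert xH == pytest.approx(0.685, abs=1e-3)
        assert xL == pytest.approx(-xH, abs=1e-8)  # gamma=1, d0=0 symmetry

    def test_empirical_quantile_oracle(self, rng):
        """Cut points agree with empirical quantiles of simulated draws."""
        pop = PopulationSpec.make("H")
        effect = QTLEffectModel.from_heritability(0.03, 0.0, pop.b)
        pool = PoolSpec(p=0.25, gamma=1.0)
        n = 2_000_000
        geno = rng.integers(0, 2, n)  # 1 = P1 allele
        x = np.where(geno == 1, -effect.a0, effect.a0) + rng.standard_normal(n)
        xH, xL = solve_cut_points(pool, effect, pop)
        assert xH == pytest.approx(np.quantile(x, 0.75), abs=3e-3)
        assert xL == pytest.approx(np.quantile(x, 0.25), abs=3e-3)

    @pytest.mark.parametrize("p,gamma", [(0.25, 1.0), (0.1, 2.0), (0.4, 0.5)])
    def test_round_trip_through_cdf(self, p, gamma, f2_design):
        pool = PoolSpec(p=p, gamma=gamma)
        xH, xL = solve_cut_points(pool, f2_design.effect, f2_design.pop)
        b, a0, d0 = f2_design.pop.b, f2_design.effect.a0, f2_design.effect.d0
        assert 1 - mixture_cdf(xH, a0, d0, b) == pytest.approx(pool.pH, abs=1e-8)
        assert mixture_cdf(xL, a0, d0, b) == pytest.approx(pool.pL, abs=1e-8)
        assert xL <= xH

    def test_invalid_pool_spec_rejected(self):
        with pytest.raises(ValueError):
            PoolSpec(p=0.0, gamma=1.0)
        with pytest.raises(ValueError):
            PoolSpec(p=0.25, gamma=0.0)
        with pytest.raises(ValueError):
            PoolSpec(p=0.6, gamma=1.0)  # pools would exceed the population
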