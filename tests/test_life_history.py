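"""Life table, Keyfitz entropy and the nine derived traits."""

import numpy as np
import pytest

from debipm import (Environment, KernelSet, LifeTable, Mesh, age_at_maturity,
                    build_kernels, core_demography, degree_of_iteroparity,
                    derived_traits, growth_directionality, keyfitz_entropy,
                    life_table, mature_life_expectancy, mean_life_expectancy,
                    mean_recruitment)
from conftest import two_stage_toy


def single_state(s: float, f: float = 0.0) -> KernelSet:
    mesh = Mesh(n_bins=1, lower=0, upper=1)
    return KernelSet(mesh=mesh, S_diag=np.array([s]), G=np.ones((1, 1)),
                     R_diag=np.array([f]), D=np.ones((1, 1)) * (f > 0),
                     adult_mask=np.array([True]), birth_index=0,
                     puberty_index=0)


class TestLifeTable:
    def test_single_state_survivorship_is_geometric(self):
        s = 0.8
        lt = life_table(single_state(s, f=1.0), tol=1e-6)
        np.testing.assert_allclose(lt.l_x, s ** lt.ages, rtol=1e-12)
        assert lt.l_x[0] == 1.0
        assert np.all(np.diff(lt.l_x) <= 0)

    def test_two_stage_lifetime_reproduction_matches_R0_oracle(self):
        p, s, f = 0.3, 0.6, 2.0
        lt = life_table(two_stage_toy(p, s, f), tol=1e-12)
        assert (lt.l_x * lt.m_x).sum() == pytest.approx(p * f / (1 - s),
                                                        rel=1e-9)

    def test_truncation_contract(self):
        lt = life_table(single_state(0.5, f=1.0), tol=1e-3)
        assert lt.l_x[-1] >= 1e-3
        assert 0.5 * lt.l_x[-1] < 1e-3  # the next age would fall below tol

    def test_rejects_bad_tolerance(self, shark_kernels):
        with pytest.raises(ValueError):
            life_table(shark_kernels, tol=0.0)


class TestKeyfitzEntropy:
    def test_constant_mortality_gives_unit_entropy(self):
        # l_x = exp(-0.05 x): the exponential survivorship reference
        ages = np.arange(0, 600)
        lt = LifeTable(ages=ages.astype(float), l_x=np.exp(-0.05 * ages),
                       m_x=np.zeros_like(ages, dtype=float),
                       cohort_init=np.array([1.0]))
        assert keyfitz_entropy(lt) == pytest.approx(1.0, rel=0.03)

    def test_front_loaded_mortality_exceeds_one(self):
        # steep early decline then a long flat plateau: mortality falls
        l = np.concatenate([[1.0], np.full(30, 0.05)])
        lt = LifeTable(ages=np.arange(len(l), dtype=float), l_x=l,
                       m_x=np.zeros_like(l), cohort_init=np.array([1.0]))
        assert keyfitz_entropy(lt) > 1.0

    def test_plateau_then_death_approaches_zero(self):
        # no deaths until a wall of mortality: entropy -> 0 as the
        # plateau lengthens (direct summation oracle)
        def H(n):
            l = np.ones(n)
            lt = LifeTable(ages=np.arange(n, dtype=float), l_x=l,
                           m_x=np.zeros(n), cohort_init=np.array([1.0]))
            return keyfitz_entropy(lt)

        assert H(100) == pytest.approx(0.0, abs=1e-12)

    def test_rising_mortality_below_one(self):
        # Gompertz-like acceleration of mortality with age
        ages = np.arange(0, 100, dtype=float)
        l = np.exp(-0.001 * np.exp(0.15 * ages).cumsum())
        lt = LifeTable(ages=ages, l_x=l, m_x=np.zeros_like(l),
                       cohort_init=np.array([1.0]))
        assert keyfitz_entropy(lt) < 1.0

    def test_degenerate_table_is_flagged(self):
        lt = LifeTable(ages=np.array([0.0]), l_x=np.array([1.0]),
                       m_x=np.array([0.0]), cohort_init=np.array([1.0]))
        assert np.isnan(keyfitz_entropy(lt))


class TestAgeAtMaturity:
    def test_geometric_waiting_time_without_mortality(self):
        # juvenile matures w.p. p each year, never dies: mean wait 1/p
        p = 0.25
        mesh = Mesh(n_bins=2, lower=0, upper=2)
        k = KernelSet(mesh=mesh, S_diag=np.array([1.0, 0.5]),
                      G=np.array([[1 - p, 0.0], [p, 1.0]]),
                      R_diag=np.array([0.0, 1.0]),
                      D=np.array([[0.0, 1.0], [0.0, 0.0]]),
                      adult_mask=np.array([False, True]),
                      birth_index=0, puberty_index=1)
        assert age_at_maturity(k) == pytest.approx(1 / p, rel=1e-9)
        assert age_at_maturity(k, conditional=False) == pytest.approx(
            1 / p, rel=1e-9)

    def test_one_step_maturation(self, shark_traits):
        env = Environment(E_Y=0.9, sigma_Y=0.0)
        fast = shark_traits.replace(r_B=5.0)  # crosses L_p in one year
        k = build_kernels(fast, env)
        assert age_at_maturity(k) == pytest.approx(1.0)

    def test_finite_whenever_a_maturation_path_exists(self, fixture_table):
        env = Environment(E_Y=0.9)
        for t in fixture_table.records[:10]:
            k = build_kernels(t, env)
            assert np.isfinite(age_at_maturity(k))

    def test_conditional_no_larger_than_unconditional(self, shark_kernels):
        # deaths truncate juvenile careers, shrinking the raw mean
        assert age_at_maturity(shark_kernels, conditional=False) <= \
            age_at_maturity(shark_kernels) + 1e-9


class TestLifeExpectancies:
    def test_single_adult_state_geometric(self):
        s = 0.7
        assert mature_life_expectancy(single_state(s)) == pytest.approx(
            1 / (1 - s), rel=1e-12)

    def test_pure_adult_survival_closed_form(self, shark_traits):
        env = Environment(E_Y=0.9, sigma_Y=0.0)
        k = build_kernels(shark_traits, env)
        expect = 1 / (1 - np.exp(-shark_traits.mu_a))
        assert mature_life_expectancy(k) == pytest.approx(expect, rel=0.02)

    def test_decomposition_into_maturity_plus_mature_expectancy(
            self, fixture_table):
        env = Environment(E_Y=0.9)
        for t in fixture_table.records[:15]:
            k = build_kernels(t, env)
            eta = mean_life_expectancy(k)
            decomposed = age_at_maturity(k) + mature_life_expectancy(k)
            assert eta == pytest.approx(decomposed, rel=0.05)


class TestGrowthDirectionality:
    def test_deterministic_growth_never_shrinks(self, shark_traits):
        env = Environment(E_Y=0.9, sigma_Y=0.0)
        k = build_kernels(shark_traits, env)
        core = core_demography(k)
        gamma, rho = growth_directionality(k, core.w)
        assert rho == 0.0

    def test_identity_growth_is_pure_stasis(self):
        k = single_state(0.5, f=1.0)
        gamma, rho = growth_directionality(k, np.array([1.0]))
        assert gamma == 0.0 and rho == 0.0

    def test_probabilities_bounded(self, shark_kernels):
        core = core_demography(shark_kernels)
        gamma, rho = growth_directionality(shark_kernels, core.w)
        assert 0 <= gamma <= 1 and 0 <= rho <= 1
        assert gamma + rho <= 1 + 1e-12


class TestMeanRecruitment:
    def test_zero_without_reproduction(self):
        k = single_state(0.5)
        assert mean_recruitment(k, np.array([1.0])) == 0.0

    def test_single_adult_bin_reduces_to_fecundity(self):
        f = 3.5
        k = single_state(0.5, f=f)
        assert mean_recruitment(k, np.array([1.0])) == pytest.approx(f)

    def test_linear_in_max_reproduction_at_fixed_structure(self, shark_traits,
                                                           env_high):
        k1 = build_kernels(shark_traits, env_high)
        k2 = build_kernels(shark_traits.replace(R_m=2 * shark_traits.R_m),
                           env_high)
        w = core_demography(k1).w  # held fixed across both
        assert mean_recruitment(k2, w) == pytest.approx(
            2 * mean_recruitment(k1, w), rel=1e-9)


class TestIteroparity:
    def test_single_age_reproduction_is_semelparous(self):
        lt = LifeTable(ages=np.arange(5, dtype=float),
                       l_x=np.array([1, 0.9, 0.8, 0.7, 0.6]),
                       m_x=np.array([0, 0, 4.0, 0, 0]),
                       cohort_init=np.array([1.0]))
        assert degree_of_iteroparity(lt) == 0.0

    def test_two_point_distribution_by_hand(self):
        # equal reproductive weight at ages 1 and 3: mean 2, var 1, S = 0.5
        lt = LifeTable(ages=np.arange(4, dtype=float),
                       l_x=np.array([1.0, 0.5, 0.25, 0.125]),
                       m_x=np.array([0.0, 2.0, 0.0, 8.0]),
                       cohort_init=np.array([1.0]))
        assert degree_of_iteroparity(lt) == pytest.approx(0.5, rel=1e-12)

    def test_spreading_reproduction_raises_S(self):
        def S(m):
            lt = LifeTable(ages=np.arange(len(m), dtype=float),
                           l_x=np.ones(len(m)), m_x=np.asarray(m, float),
                           cohort_init=np.array([1.0]))
            return degree_of_iteroparity(lt)

        concentrated = S([0, 0, 1.0, 0, 0])
        spread = S([0, 0.5, 0, 0.5, 0])  # same mean age 2
        assert spread > concentrated

    def test_sterile_cohort_is_flagged(self):
        lt = LifeTable(ages=np.arange(3, dtype=float),
                       l_x=np.array([1, 0.5, 0.25]), m_x=np.zeros(3),
                       cohort_init=np.array([1.0]))
        assert np.isnan(degree_of_iteroparity(lt))


class TestDerivedTraits:
    def test_two_stage_toy_closed_forms(self):
        p, s, f = 0.3, 0.6, 2.0
        res = derived_traits(two_stage_toy(p, s, f))
        assert res.R0 == pytest.approx(p * f / (1 - s), rel=1e-9)
        assert res.R0_lifetable == pytest.approx(res.R0, rel=1e-6)
        assert res.L_omega == pytest.approx(1 / (1 - s), rel=1e-9)
        assert res.L_alpha == pytest.approx(1.0, rel=1e-9)  # matures or dies
        for val in (res.T, res.H, res.gamma, res.rho, res.phi, res.S_itero,
                    res.eta_e, res.lam, res.damping):
            assert np.isfinite(val)

    def test_dual_R0_definitions_agree(self, fixture_table):
        env = Environment(E_Y=0.9)
        for t in fixture_table.records[:15]:
            k = build_kernels(t, env)
            res = derived_traits(k)
            assert np.isclose(res.R0_lifetable, res.R0, rtol=0.01, atol=1e-6)

    def test_maturation_accelerates_with_feeding_level(self, fixture_table):
        # faster growth toward a larger ultimate length crosses the fixed
        # puberty length sooner
        for t in fixture_table.records[:8]:
            ages = []
            for env in (Environment(E_Y=0.5), Environment(E_Y=0.9)):
                if t.L_m * env.E_Y / t.kappa < t.L_p:
                    continue
                ages.append(age_at_maturity(build_kernels(t, env)))
            # NaN marks a level where growth tops out below L_p and no
            # maturation path exists despite the starvation check passing
            if len(ages) == 2 and all(np.isfinite(a) for a in ages):
                assert ages[1] <= ages[0] * (1 + 1e-6)
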