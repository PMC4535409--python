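import dataclasses

import numpy as np
import pytest
from hypothesis import given, strategies as st

from pihna import (AAEffect, PihnaParameters, RadialGrid, RadiotherapyPlan,
                   aa_transform_parameters, alpha_from_rho, effective_oer,
                   gtr_resect, radiation_cell_kill, simulate, spherical_count)
from pihna.imaging import ImagingThresholds

from conftest import make_state

K = 2.39e5


def rt_plan(**kw):
    defaults = dict(alpha_slope=0.003, alpha_intercept=0.025)
    defaults.update(kw)
    return RadiotherapyPlan(**defaults)


class TestAATransform:
    def test_identity_effect_is_bitwise_noop(self, aggressive_params):
        out = aa_transform_parameters(aggressive_params, AAEffect.identity())
        assert out == aggressive_params

    def test_identity_applied_twice_is_still_identity(self, aggressive_params):
        ident = AAEffect.identity()
        once = aa_transform_parameters(aggressive_params, ident)
        twice = aa_transform_parameters(once, ident)
        assert twice == aggressive_params

    def test_action_factor_two_doubles_exactly_the_halfsat_constants(
            self, aggressive_params):
        effect = AAEffect(angiogenic_action_factor=2.0,
                          h_to_c_multiplier=1.0, c_to_h_multiplier=1.0)
        out = aa_transform_parameters(aggressive_params, effect)
        changed = {"a_halfsat", "a_destabilization_halfsat"}
        for f in dataclasses.fields(PihnaParameters):
            before = getattr(aggressive_params, f.name)
            after = getattr(out, f.name)
            if f.name in changed:
                assert after == 2.0 * before
            else:
                assert after == before

    def test_conversion_multipliers_rescale_the_two_rates(self,
                                                          aggressive_params):
        effect = AAEffect(angiogenic_action_factor=1.0,
                          h_to_c_multiplier=3.0, c_to_h_multiplier=0.25)
        out = aa_transform_parameters(aggressive_params, effect)
        assert out.reoxygenation_rate == 3.0 * aggressive_params.reoxygenation_rate
        assert out.hypoxia_rate == 0.25 * aggressive_params.hypoxia_rate

    def test_hypoxia_diminishes_under_treatment(self, coarse_grid,
                                                coarse_settings,
                                                grown_hypoxic,
                                                moderate_params):
        # fourteen days from the same hypoxic state: the treated tumour
        # must carry fewer hypoxic cells than the untreated control
        state, _ = grown_hypoxic
        treated_params = aa_transform_parameters(moderate_params, AAEffect())
        h_treated = simulate(state, treated_params, coarse_grid, 14.0,
                             coarse_settings).final.h
        h_control = simulate(state, moderate_params, coarse_grid, 14.0,
                             coarse_settings).final.h
        assert spherical_count(h_treated, coarse_grid) \
            < spherical_count(h_control, coarse_grid)

    def test_invalid_effects_rejected(self):
        with pytest.raises(ValueError):
            AAEffect(angiogenic_action_factor=0.5)
        with pytest.raises(ValueError):
            AAEffect(h_to_c_multiplier=-1.0)


class TestGtrResect:
    @pytest.fixture(scope="class")
    def grid(self):
        return RadialGrid.uniform(r_max=60.0, dr=0.5)

    def test_compact_tumour_fully_resected(self, grid):
        c = np.where(grid.r <= 15.0, 0.9 * K, 0.0)
        h = np.where(grid.r <= 10.0, 0.1 * K, 0.0)
        state = make_state(grid, c=c, h=h)
        post, r = gtr_resect(state, grid, K=K)
        assert r >= 15.0
        assert spherical_count(post.h, grid) == 0.0
        assert spherical_count(post.c, grid) == 0.0

    def test_subthreshold_tumour_is_a_noop(self, grid):
        state = make_state(grid, c=np.full(grid.n, 0.5 * K))
        post, r = gtr_resect(state, grid, K=K)
        assert r == 0.0 and post is state

    def test_shell_additivity_of_hypoxic_counts(self, grid):
        rng = np.random.default_rng(23)
        c = 0.9 * K * np.exp(-((grid.r / 20.0) ** 2))
        h = 0.2 * K * rng.uniform(0.3, 1.0, grid.n) * np.exp(-grid.r / 25.0)
        state = make_state(grid, c=c, h=h)
        post, r = gtr_resect(state, grid, K=K)
        assert r > 0
        removed = spherical_count(state.h - post.h, grid)
        h_pre = spherical_count(state.h, grid)
        h_post = spherical_count(post.h, grid)
        assert h_pre == pytest.approx(h_post + removed, rel=1e-12)

    def test_never_increases_counts_and_leaves_outside_untouched(self, grid):
        c = 0.9 * K * np.exp(-((grid.r / 20.0) ** 2))
        state = make_state(grid, c=c, h=0.05 * K, n=0.01 * K, v=0.05 * K, a=1.0)
        post, r = gtr_resect(state, grid, K=K)
        outside = grid.r > r
        for f in "chn":
            assert spherical_count(getattr(post, f), grid) \
                <= spherical_count(getattr(state, f), grid) + 1e-9
            np.testing.assert_array_equal(getattr(post, f)[outside],
                                          getattr(state, f)[outside])
        np.testing.assert_array_equal(post.v, state.v)
        np.testing.assert_array_equal(post.a, state.a)

    def test_requires_carrying_capacity(self, grid):
        with pytest.raises(ValueError, match="K"):
            gtr_resect(make_state(grid), grid, ImagingThresholds())


class TestAlphaFromRho:
    def test_zero_rho_returns_intercept(self):
        assert alpha_from_rho(0.0, rt_plan()) == 0.025

    def test_alpha_increasing_in_rho(self):
        plan = rt_plan()
        alphas = [alpha_from_rho(r, plan) for r in (1.0, 10.0, 50.0, 83.0)]
        assert all(b > a for a, b in zip(alphas, alphas[1:]))

    def test_beta_identity(self):
        plan = rt_plan(alpha_beta_ratio=10.0)
        alpha = alpha_from_rho(42.0, plan)
        beta = alpha / plan.alpha_beta_ratio
        assert beta * plan.alpha_beta_ratio == pytest.approx(alpha, rel=1e-15)

    def test_nonphysical_alpha_rejected(self):
        plan = rt_plan(alpha_intercept=0.0, alpha_slope=0.0)
        with pytest.raises(ValueError, match="nonphysical|alpha"):
            alpha_from_rho(10.0, plan)


class TestEffectiveOer:
    def test_pure_normoxic_is_one(self):
        assert effective_oer(100.0, 0.0, rt_plan()) == 1.0

    def test_pure_hypoxic_is_oer_max(self):
        assert effective_oer(0.0, 100.0, rt_plan()) == 3.0

    def test_equal_mix_is_arithmetic_mean(self):
        assert effective_oer(5.0, 5.0, rt_plan()) == pytest.approx(2.0)

    def test_no_viable_cells_degenerate_return(self):
        assert effective_oer(0.0, 0.0, rt_plan()) == 1.0

    @given(c=st.floats(0, 1e9), h=st.floats(0, 1e9))
    def test_bounded_between_one_and_oer_max(self, c, h):
        oer = effective_oer(c, h, rt_plan())
        assert 1.0 <= oer <= 3.0

    def test_oer_max_bounds_enforced(self):
        with pytest.raises(ValueError):
            rt_plan(oer_max=5.0)


class TestRadiationCellKill:
    @pytest.fixture(scope="class")
    def grid(self):
        return RadialGrid.uniform(r_max=40.0, dr=0.5)

    def test_zero_dose_kills_nothing(self, grid):
        state = make_state(grid, c=0.5 * K, h=0.1 * K)
        out = radiation_cell_kill(state, grid, 20.0,
                                  rt_plan(dose_per_fraction=0.0))
        assert out.cells_killed == 0.0
        np.testing.assert_array_equal(out.post_state.c, state.c)
        np.testing.assert_array_equal(out.post_state.h, state.h)

    def test_normoxic_uniform_matches_lq_closed_form(self, grid):
        # alpha = 0.05/Gy, 30 x 2 Gy, alpha/beta = 10:
        # F_CK = 1 - exp(-30 (0.05*2 + 0.005*4)) = 1 - exp(-3.6)
        plan = rt_plan(alpha_slope=0.0, alpha_intercept=0.05)
        state = make_state(grid, c=0.5 * K)
        out = radiation_cell_kill(state, grid, 20.0, plan)
        assert out.kill_fraction == pytest.approx(1 - np.exp(-3.6), rel=1e-9)

    def test_hypoxic_uniform_matches_oer_scaled_closed_form(self, grid):
        plan = rt_plan(alpha_slope=0.0, alpha_intercept=0.05)
        state = make_state(grid, h=0.5 * K)
        out = radiation_cell_kill(state, grid, 20.0, plan)
        assert out.kill_fraction == pytest.approx(1 - np.exp(-1.2), rel=1e-9)
        # hypoxia shields: strictly less kill than the normoxic tumour
        normox = radiation_cell_kill(make_state(grid, c=0.5 * K), grid, 20.0,
                                     plan)
        assert out.kill_fraction < normox.kill_fraction

    def test_necrotic_compartment_unaffected(self, grid):
        state = make_state(grid, c=0.3 * K, h=0.2 * K, n=0.25 * K)
        out = radiation_cell_kill(state, grid, 20.0, rt_plan())
        np.testing.assert_array_equal(out.post_state.n, state.n)

    def test_replacing_hypoxic_with_normoxic_cannot_reduce_kill(self, grid):
        plan = rt_plan()
        mixed = make_state(grid, c=0.3 * K, h=0.3 * K)
        swapped = make_state(grid, c=0.6 * K, h=0.0)
        kill_mixed = radiation_cell_kill(mixed, grid, 20.0, plan)
        kill_swapped = radiation_cell_kill(swapped, grid, 20.0, plan)
        assert kill_swapped.cells_killed >= kill_mixed.cells_killed

    @given(d=st.sampled_from([0.5, 1.0, 2.0, 3.0]),
           n=st.sampled_from([1, 10, 30]))
    def test_kill_fraction_valid_and_monotone_in_course(self, grid, d, n):
        plan = rt_plan(dose_per_fraction=d, n_fractions=n)
        state = make_state(grid, c=0.4 * K, h=0.2 * K)
        out = radiation_cell_kill(state, grid, 20.0, plan)
        assert 0.0 <= out.kill_fraction <= 1.0
        viable = spherical_count(state.viable_density, grid)
        assert out.cells_killed <= viable
        bigger = radiation_cell_kill(
            state, grid, 20.0,
            rt_plan(dose_per_fraction=d, n_fractions=n + 1))
        assert bigger.cells_killed >= out.cells_killed
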