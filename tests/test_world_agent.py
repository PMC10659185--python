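"""Boundary-updating agent: class-state deduction, likelihood algebra, posterior."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import norm

from critlearn import (
    CORRECT, INCORRECT, LARGE, SMALL,
    BoundaryBelief, FixedAgent, FixedParams, WorldAgent, WorldParams,
    boundary_likelihood, decide, deduce_class_state,
    make_run_schedules, posterior_update, propagate_prior,
    simulate_agent_session,
)

PARAMS = WorldParams(sigma_m=0.8, sigma_mprime=0.6, sigma_s=1.0)  # sigma_M = 1


class TestClassState:
    @pytest.mark.parametrize("choice,feedback,expected", [
        (LARGE, CORRECT, LARGE),
        (SMALL, INCORRECT, LARGE),
        (LARGE, INCORRECT, SMALL),
        (SMALL, CORRECT, SMALL),
    ])
    def test_deduction_rule(self, choice, feedback, expected):
        assert deduce_class_state(choice, feedback) == expected


class TestDecide:
    def test_measurement_at_boundary_is_a_tie_broken_by_coin(self, rng):
        belief = BoundaryBelief(0.4, 0.2)
        choices = {decide(0.4, belief, 1.0, rng)[0] for _ in range(200)}
        assert choices == {SMALL, LARGE}
        assert decide(0.4, belief, 1.0, rng)[1] == pytest.approx(0.5)

    def test_one_sigma_above_boundary(self, rng):
        choice, p_l = decide(1.4, BoundaryBelief(0.4, 0.2), 1.0, rng)
        assert choice == LARGE
        assert p_l == pytest.approx(0.8413447, abs=1e-6)

    def test_probability_decreases_as_boundary_shifts_up(self, rng):
        ps = [decide(0.5, BoundaryBelief(b, 0.1), 1.0, rng)[1]
              for b in (-0.5, 0.0, 0.5, 1.0)]
        assert all(a > b for a, b in zip(ps, ps[1:]))


class TestBoundaryLikelihood:
    def test_class_states_marginalize_to_gaussian(self):
        b = np.linspace(-5, 5, 50)
        sd = np.sqrt(PARAMS.sigma_s ** 2 + PARAMS.sigma_M2)
        for m_prime in np.linspace(-5, 5, 50):
            total = (boundary_likelihood(b, m_prime, SMALL, PARAMS)
                     + boundary_likelihood(b, m_prime, LARGE, PARAMS))
            assert np.abs(total - norm.pdf(m_prime, b, sd)).max() < 1e-10

    def test_boundary_at_measurement_splits_mass_equally(self):
        ls = boundary_likelihood(np.array([0.7]), 0.7, SMALL, PARAMS)
        ll = boundary_likelihood(np.array([0.7]), 0.7, LARGE, PARAMS)
        assert ls == pytest.approx(ll)

    def test_closed_form_matches_numeric_integration(self):
        # marginalize the generative chain over the stimulus by quadrature
        def integrand(s, b):
            return (norm.pdf(1.0, s, np.sqrt(PARAMS.sigma_M2))
                    * norm.pdf(s, b, PARAMS.sigma_s))

        num, _ = quad(integrand, 0.0, np.inf, args=(0.0,))
        cf = boundary_likelihood(np.array([0.0]), 1.0, LARGE, PARAMS)[0]
        assert abs(num - cf) < 1e-8

    def test_degenerate_widths_rejected(self):
        with pytest.raises(ValueError):
            WorldParams(sigma_s=0.0)           # zero stimulus spread
        with pytest.raises(ValueError):
            # sigma_s^2 underflows to zero: the closed form is undefined
            boundary_likelihood(np.zeros(3), 0.0, LARGE, WorldParams(sigma_s=1e-300))


class TestPosterior:
    def test_grid_density_normalizes(self):
        post = posterior_update(BoundaryBelief(0.0, 1.0), 0.5, LARGE, PARAMS)
        x, dens = post.grid
        assert np.trapezoid(dens, x) == pytest.approx(1.0, abs=1e-6)

    def test_sharp_prior_dominates(self):
        post = posterior_update(BoundaryBelief(0.3, 1e-6), 2.0, LARGE, PARAMS)
        assert post.mean == pytest.approx(0.3, abs=1e-2)

    def test_moments_match_fine_grid_oracle(self):
        prior = BoundaryBelief(-0.2, 0.8)
        post = posterior_update(prior, 1.3, SMALL, PARAMS)
        oracle = posterior_update(prior, 1.3, SMALL, PARAMS, n_grid=100_001)
        assert abs(post.mean - oracle.mean) < 1e-4
        assert abs(post.var - oracle.var) < 1e-4

    def test_compiled_kernel_matches_reference_grid_path(self):
        from critlearn.world_agent import posterior_moments_fast
        rng = np.random.default_rng(5)
        worst = 0.0
        for _ in range(60):
            prior = BoundaryBelief(rng.normal(0, 1), 10 ** rng.uniform(-3, 0.5))
            mp = rng.normal(0, 2.5)
            cl = LARGE if rng.random() < 0.5 else SMALL
            ref = posterior_update(prior, mp, cl, PARAMS, n_grid=501,
                                   keep_grid=False)
            fast = posterior_moments_fast(prior, mp, cl, PARAMS, n_grid=501)
            worst = max(worst, abs(ref.mean - fast.mean), abs(ref.var - fast.var))
        assert worst < 1e-10

    def test_posterior_mean_increases_with_measurement(self):
        prior = BoundaryBelief(0.0, 1.0)
        means = [posterior_update(prior, mp, LARGE, PARAMS).mean
                 for mp in np.linspace(-2, 2, 9)]
        assert all(a < b for a, b in zip(means, means[1:]))

    def test_informed_class_state_pushes_boundary_opposite(self):
        # weak measurement: the class-state push dominates
        prior = BoundaryBelief(0.0, 1.0)
        assert posterior_update(prior, 0.05, LARGE, PARAMS).mean < 0.0
        assert posterior_update(prior, -0.05, SMALL, PARAMS).mean > 0.0
        # strong measurement: the attraction toward it dominates
        assert posterior_update(prior, 2.0, LARGE, PARAMS).mean > 0.0


class TestPropagate:
    def test_zero_posterior_variance_keeps_mean(self):
        p = WorldParams(mu0=0.5, sigma_0=1.0, sigma_diffusion=0.2)
        out = propagate_prior(BoundaryBelief(1.7, 0.0), p)
        assert out.mean == pytest.approx(1.7)
        assert out.var == pytest.approx(0.04)

    def test_huge_posterior_variance_reverts_to_attractor(self):
        p = WorldParams(mu0=-0.3, sigma_0=1.0, sigma_diffusion=0.0)
        out = propagate_prior(BoundaryBelief(5.0, 1e12), p)
        assert out.mean == pytest.approx(-0.3, abs=1e-6)

    def test_decay_arithmetic(self):
        p = WorldParams(mu0=0.0, sigma_0=1.0, sigma_diffusion=np.sqrt(0.1))
        out = propagate_prior(BoundaryBelief(2.0, 1.0), p)
        assert out.mean == pytest.approx(1.0)
        assert out.var == pytest.approx(0.6)


class TestAgent:
    def test_session_is_deterministic_under_seed(self):
        def run(seed):
            rng = np.random.default_rng(seed)
            agent = WorldAgent(WorldParams(sigma_m=1.2), n_grid=501)
            return simulate_agent_session(agent, make_run_schedules(1, rng), rng)

        a, b = run(3), run(3)
        assert np.allclose(a[["m", "m_prime", "b_mean", "b_var"]],
                           b[["m", "m_prime", "b_mean", "b_var"]])

    def test_pinned_decay_reduces_to_fixed_agent(self, rng):
        # sigma_0 -> 0 forces lambda -> 0: the boundary snaps back to mu0
        # every trial, so choices must be distributed like the Fixed agent's
        wp = WorldParams(mu0=0.4, sigma_m=1.2, sigma_0=0.01, sigma_diffusion=0.05)
        world = WorldAgent(wp, n_grid=501)
        fixed = FixedAgent(FixedParams(mu0=0.4, sigma_m=1.2))
        scheds = make_run_schedules(20, rng, freeze=True)
        tw = simulate_agent_session(world, scheds, rng, record_latents=False)
        tf = simulate_agent_session(fixed, scheds, rng, record_latents=False)
        n = 20 * 34
        for s in (-2, -1, 0, 1, 2):
            pw = tw[tw.stimulus == s].choice.mean()
            pf = tf[tf.stimulus == s].choice.mean()
            se = np.sqrt(2 * max((pw + pf) / 2 * (1 - (pw + pf) / 2), 1e-9) / n)
            assert abs(pw - pf) < 4 * se + 0.01
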