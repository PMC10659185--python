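"""Reference agents spanning the model space: Base, Fixed, and Hybrid.

Base fixes the class boundary at 0 and learns nothing (1 free parameter,
``sigma_m``); Fixed allows an arbitrary constant boundary ``mu0`` (2 free
parameters); Hybrid composes the boundary-updating and value-updating
algorithms (9 free parameters).  Base and Fixed use the argmax readout on the
class probability -- their choice stochasticity comes entirely from the
sensory measurement -- matching their 1- and 2-parameter counts.

All agents expose the same interface (``start_run`` / ``draw_choice`` /
``update`` / ``latents``) so simulation and fitting are model-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .task import CORRECT, LARGE, SMALL
from .value_agent import belief_state, expected_values, softmax_prob_large, value_update
from .world_agent import (BoundaryBelief, WorldParams, decide,
                          posterior_moments_fast, propagate_prior)


@dataclass(frozen=True)
class FixedParams:
    mu0: float = 0.0
    sigma_m: float = 1.0

    def __post_init__(self):
        if self.sigma_m <= 0:
            raise ValueError("sigma_m must be > 0")


@dataclass(frozen=True)
class HybridParams:
    """Union of the boundary-updating and value-updating parameter sets."""

    mu0: float = 0.0
    sigma_m: float = 1.0
    sigma_s: float = 2.2
    sigma_0: float = 2.0
    sigma_mprime: float = 0.8
    sigma_diffusion: float = 0.4
    alpha: float = 0.2
    beta: float = 4.0
    v_init: float = 1.0

    def world(self) -> WorldParams:
        return WorldParams(self.mu0, self.sigma_m, self.sigma_s, self.sigma_0,
                           self.sigma_mprime, self.sigma_diffusion)


class FixedAgent:
    """Constant-boundary agent: choice = large iff m > mu0 (ties by coin)."""

    name = "fixed"

    def __init__(self, params: FixedParams):
        self.params = params
        self._belief = BoundaryBelief(params.mu0, 0.0)

    def start_run(self) -> None:
        pass

    def latents(self) -> dict:
        return {"b_mean": self.params.mu0, "b_var": 0.0}

    def prob_large_given_m(self, m: float) -> float:
        return 1.0 if m > self.params.mu0 else (0.5 if m == self.params.mu0 else 0.0)

    def draw_choice(self, stimulus: float, rng: np.random.Generator) -> tuple[int, float]:
        m = rng.normal(stimulus, self.params.sigma_m)
        choice, _ = decide(m, self._belief, self.params.sigma_m, rng)
        return choice, m

    def update(self, m, choice, feedback, rng) -> dict:
        return {}


class BaseAgent(FixedAgent):
    """Unbiased non-learning agent: boundary pinned at 0."""

    name = "base"

    def __init__(self, sigma_m: float = 1.0):
        super().__init__(FixedParams(mu0=0.0, sigma_m=sigma_m))


class HybridAgent:
    """Composition of boundary updating and value updating in one agent.

    The class probability is computed against the boundary inferred by the
    world-updating algorithm, multiplied by learned values, and read out by a
    softmax.  After feedback, the value update and the boundary update are
    both applied from the same episode; the two updates are independent given
    the episode, so their order is irrelevant.
    """

    name = "hybrid"

    def __init__(self, params: HybridParams, n_grid: int = 2001):
        self.params = params
        self.world_params = params.world()
        self.n_grid = n_grid
        self.belief = BoundaryBelief(params.mu0, params.sigma_0 ** 2)
        self.v_small = params.v_init
        self.v_large = params.v_init

    def start_run(self) -> None:
        self.belief = BoundaryBelief(self.params.mu0, self.params.sigma_0 ** 2)
        self.v_small = self.params.v_init
        self.v_large = self.params.v_init

    def latents(self) -> dict:
        return {"b_mean": self.belief.mean, "b_var": self.belief.var,
                "v_small": self.v_small, "v_large": self.v_large}

    def prob_large_given_m(self, m: float) -> float:
        p_l = belief_state(m, self.belief.mean, self.params.sigma_m)
        q_s, q_l = expected_values(p_l, self.v_small, self.v_large)
        return softmax_prob_large(q_s, q_l, self.params.beta)

    def draw_choice(self, stimulus: float, rng: np.random.Generator) -> tuple[int, float]:
        m = rng.normal(stimulus, self.params.sigma_m)
        p = self.prob_large_given_m(m)
        choice = LARGE if rng.random() < p else SMALL
        return choice, m

    def update(self, m: float, choice: int, feedback: int,
               rng: np.random.Generator) -> dict:
        # value update from the belief state at decision time
        p_l = belief_state(m, self.belief.mean, self.params.sigma_m)
        p_c = p_l if choice == LARGE else 1.0 - p_l
        r = 1 if feedback == CORRECT else 0
        self.v_small, self.v_large, _ = value_update(
            self.v_small, self.v_large, choice, p_c, r, self.params.alpha)
        # boundary update from the mnemonic measurement and informed class state
        if self.params.sigma_mprime > 0:
            m_prime = rng.normal(m, self.params.sigma_mprime)
        else:
            m_prime = m
        cl = choice if feedback == CORRECT else (SMALL if choice == LARGE else LARGE)
        post = posterior_moments_fast(self.belief, m_prime, cl, self.world_params,
                                      n_grid=self.n_grid)
        self.belief = propagate_prior(post, self.world_params)
        return {"m_prime": m_prime}
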