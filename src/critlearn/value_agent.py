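"""Belief-based reinforcement-learning ("value-updating") agent.

The agent treats corrective feedback as reward.  Given a noisy sensory
measurement ``m`` of the stimulus, it computes the belief state
``p_L = Phi((m - mu0) / sigma_m)`` -- the probability that the stimulus lies
above a constant class boundary ``mu0`` -- multiplies the class probabilities
by learned choice values to form expected values ``Q``, chooses by a softmax
over the ``Q``s, and after feedback updates the chosen option's value by the
confidence-weighted reward prediction error

    delta = r - p_C * V_C,      V_C <- V_C + alpha * delta,

with reward ``r = 1`` for *correct* and ``r = 0`` for *incorrect* feedback.
Because ``delta`` shrinks as decision confidence ``p_C`` grows but never
changes sign (until ``Q_C`` reaches the maximal reward), feedback effects
under this agent diminish with sensory evidence but are never reversed.
No temporal discounting; rewards are exactly {0, 1}; values are not clipped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr

from .task import CORRECT, LARGE, SMALL


@dataclass(frozen=True)
class ValueParams:
    """Parameters of the value-updating agent.

    mu0
        Constant class boundary (level units).
    sigma_m
        Sensory noise SD (> 0).
    alpha
        Learning rate in [0, 1].
    beta
        Softmax inverse temperature (>= 0).
    v_init
        Initial value of both choices.
    """

    mu0: float = 0.0
    sigma_m: float = 1.0
    alpha: float = 0.2
    beta: float = 4.0
    v_init: float = 1.0

    def __post_init__(self):
        if self.sigma_m <= 0:
            raise ValueError("sigma_m must be > 0")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")


def belief_state(m: float, boundary: float, sigma_m: float) -> float:
    """P(stimulus > boundary | m) with p(S|m) = N(S; m, sigma_m**2).

    Equals ``Phi((m - boundary) / sigma_m)``; the *small*-class probability is
    the complement.
    """
    if sigma_m <= 0:
        raise ValueError("sigma_m must be > 0")
    if not np.isfinite(m):
        raise ValueError("measurement m must be finite")
    return float(ndtr((m - boundary) / sigma_m))


def expected_values(p_large: float, v_small: float, v_large: float) -> tuple[float, float]:
    """Expected values (Q_small, Q_large) = ((1-p_L)*V_S, p_L*V_L)."""
    if not 0.0 <= p_large <= 1.0:
        raise ValueError("p_large must be a probability")
    return (1.0 - p_large) * v_small, p_large * v_large


def softmax_prob_large(q_small: float, q_large: float, beta: float) -> float:
    """Softmax choice probability of *large*, computed overflow-safely."""
    if beta < 0:
        raise ValueError("beta must be >= 0")
    # logistic of the value difference; clip the exponent to avoid overflow
    z = np.clip(beta * (q_large - q_small), -700.0, 700.0)
    return float(1.0 / (1.0 + np.exp(-z)))


def value_update(v_small: float, v_large: float, choice: int, p_chosen: float,
                 reward: int, alpha: float) -> tuple[float, float, float]:
    """One reward-prediction-error update of the chosen value.

    Returns ``(v_small, v_large, delta)`` with only the chosen option changed:
    ``delta = reward - p_chosen * V_C`` and ``V_C <- V_C + alpha * delta``.
    """
    if reward not in (0, 1):
        raise ValueError("reward must be 0 or 1")
    v_c = v_large if choice == LARGE else v_small
    delta = reward - p_chosen * v_c
    v_c = v_c + alpha * delta
    if choice == LARGE:
        return v_small, v_c, delta
    return v_c, v_large, delta


class ValueAgent:
    """Stateful value-updating agent with the simulation/fitting interface.

    ``start_run`` resets both values to ``v_init`` (per-run reset mirroring
    the per-run reference display); ``draw_choice`` samples a measurement and
    a softmax choice without touching state; ``update`` applies the value
    update given the episode.
    """

    name = "value"

    def __init__(self, params: ValueParams):
        self.params = params
        self.v_small = params.v_init
        self.v_large = params.v_init

    def start_run(self) -> None:
        self.v_small = self.params.v_init
        self.v_large = self.params.v_init

    def latents(self) -> dict:
        return {"v_small": self.v_small, "v_large": self.v_large}

    def prob_large_given_m(self, m: float) -> float:
        p_l = belief_state(m, self.params.mu0, self.params.sigma_m)
        q_s, q_l = expected_values(p_l, self.v_small, self.v_large)
        return softmax_prob_large(q_s, q_l, self.params.beta)

    def draw_choice(self, stimulus: float, rng: np.random.Generator) -> tuple[int, float]:
        m = rng.normal(stimulus, self.params.sigma_m)
        p = self.prob_large_given_m(m)
        choice = LARGE if rng.random() < p else SMALL
        return choice, m

    def update(self, m: float, choice: int, feedback: int,
               rng: np.random.Generator) -> dict:
        p_l = belief_state(m, self.params.mu0, self.params.sigma_m)
        p_c = p_l if choice == LARGE else 1.0 - p_l
        r = 1 if feedback == CORRECT else 0
        self.v_small, self.v_large, delta = value_update(
            self.v_small, self.v_large, choice, p_c, r, self.params.alpha)
        return {}
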