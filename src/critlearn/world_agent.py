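"""Bayesian boundary-updating ("world-updating") agent.

The agent treats corrective feedback as evidence about the state of the
world.  Its learned generative model assumes stimuli are drawn from
``N(B, sigma_s**2)`` around a latent class boundary ``B``; the class state is
*large* iff the stimulus exceeds ``B``; the sensory measurement ``m`` is
``N(S, sigma_m**2)`` and its later mnemonic recall ``m'`` is
``N(m, sigma_mprime**2)``.

Decisions use only the current boundary belief mean ``B_hat``:
``p_L = Phi((m - B_hat) / sigma_m)``, choosing *large* when ``p_L > 0.5``.
After feedback, the informed class state ``CL`` is deduced from choice x
feedback, and the boundary belief is updated by Bayes' rule with the
closed-form likelihood

    L_small(b) = Phi((b - w(b)) / sqrt(v)) * N(m'; b, sigma_M**2 + sigma_s**2)
    L_large(b) = Phi(-(b - w(b)) / sqrt(v)) * N(m'; b, sigma_M**2 + sigma_s**2)

where ``sigma_M**2 = sigma_mprime**2 + sigma_m**2``,
``w(b) = (b*sigma_M**2 + m'*sigma_s**2) / (sigma_M**2 + sigma_s**2)`` and
``v = sigma_M**2 * sigma_s**2 / (sigma_M**2 + sigma_s**2)``.  The mnemonic
measurement attracts the boundary toward the previous stimulus while the
informed class state pushes it the other way; their balance produces the
stimulus-dependent bias reversal that distinguishes this agent from the
value-updating one.

The posterior is evaluated on a dense grid and summarized by its mean and
variance; on recall as the next trial's prior it decays toward the long-run
attractor ``mu0`` with rate ``lambda = sigma_0**2 / (sigma_0**2 + var_post)``
and picks up diffusion noise ``sigma_diffusion**2``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import ndtr

from .task import CORRECT, LARGE, SMALL

_SQRT_2PI = np.sqrt(2.0 * np.pi)


@dataclass(frozen=True)
class WorldParams:
    """Parameters of the boundary-updating agent.

    mu0
        Long-run boundary attractor (level units).
    sigma_m
        Sensory noise SD (> 0).
    sigma_s
        Believed stimulus-distribution SD (> 0).
    sigma_0
        Baseline prior SD governing the decay rate lambda (> 0).
    sigma_mprime
        Memory (mnemonic recall) noise SD (>= 0).
    sigma_diffusion
        Belief diffusion SD added on recall (>= 0).
    """

    mu0: float = 0.0
    sigma_m: float = 1.0
    sigma_s: float = 2.2
    sigma_0: float = 2.0
    sigma_mprime: float = 0.8
    sigma_diffusion: float = 0.4

    def __post_init__(self):
        for name in ("sigma_m", "sigma_s", "sigma_0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("sigma_mprime", "sigma_diffusion"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def sigma_M2(self) -> float:
        """Combined measurement-chain variance sigma_mprime**2 + sigma_m**2."""
        return self.sigma_mprime ** 2 + self.sigma_m ** 2


@dataclass
class BoundaryBelief:
    """Gaussian summary (mean, variance) of the boundary belief.

    ``grid`` optionally carries the most recent gridded posterior as a
    ``(support, density)`` pair whose trapezoid integral is 1.
    """

    mean: float
    var: float
    grid: Optional[tuple[np.ndarray, np.ndarray]] = None

    def __post_init__(self):
        if self.var < 0:
            raise ValueError("belief variance must be >= 0")


def deduce_class_state(choice: int, feedback: int) -> int:
    """Informed class state CL from choice x feedback.

    *large* iff (large, correct) or (small, incorrect); *small* otherwise.
    """
    if feedback == CORRECT:
        return choice
    return SMALL if choice == LARGE else LARGE


def decide(m: float, belief: BoundaryBelief, sigma_m: float,
           rng: Optional[np.random.Generator] = None) -> tuple[int, float]:
    """Choice from the p-computation against the inferred boundary.

    ``p_L = Phi((m - B_hat) / sigma_m)``; *large* iff ``p_L > 0.5``; an exact
    tie is broken by a fair coin.
    """
    if sigma_m <= 0:
        raise ValueError("sigma_m must be > 0")
    p_l = float(ndtr((m - belief.mean) / sigma_m))
    if p_l > 0.5:
        choice = LARGE
    elif p_l < 0.5:
        choice = SMALL
    else:
        coin = (rng.random() if rng is not None else 0.5) < 0.5
        choice = LARGE if coin else SMALL
    return choice, p_l


def boundary_likelihood(b, m_prime: float, cl: int, params: WorldParams) -> np.ndarray:
    """Closed-form likelihood of boundary values given (m', CL).

    Vectorized over ``b``.  The two class states sum to the marginal
    ``N(m'; b, sigma_s**2 + sigma_M**2)``, which serves as the normalization
    identity in tests.
    """
    s_m2 = params.sigma_M2
    s_s2 = params.sigma_s ** 2
    if s_m2 <= 0 or s_s2 <= 0:
        raise ValueError("sigma_M and sigma_s must be nonzero for the closed form")
    b = np.asarray(b, dtype=float)
    tot = s_m2 + s_s2
    w = (b * s_m2 + m_prime * s_s2) / tot
    v = s_m2 * s_s2 / tot
    z = (b - w) / np.sqrt(v)
    gauss = np.exp(-((b - m_prime) ** 2) / (2.0 * tot)) / (_SQRT_2PI * np.sqrt(tot))
    if cl == SMALL:
        return ndtr(z) * gauss
    return ndtr(-z) * gauss


def _make_grid(prior: BoundaryBelief, m_prime: float, params: WorldParams,
               n_grid: int, span: float) -> np.ndarray:
    sd_prior = np.sqrt(prior.var)
    sd_marg = np.sqrt(params.sigma_s ** 2 + params.sigma_M2)
    lo = min(prior.mean - span * sd_prior, m_prime - span * sd_marg)
    hi = max(prior.mean + span * sd_prior, m_prime + span * sd_marg)
    return np.linspace(lo, hi, n_grid)


def posterior_update(prior: BoundaryBelief, m_prime: float, cl: int,
                     params: WorldParams, n_grid: int = 2001,
                     span: float = 8.0, keep_grid: bool = True) -> BoundaryBelief:
    """Gridded Bayesian update of the boundary belief from one episode.

    The posterior density ``L_CL(b) * N(b; prior.mean, prior.var)`` is
    normalized by trapezoid integration on a grid spanning at least
    ``span`` combined SDs around both the prior and the mnemonic measurement
    (default 2001 points).  The returned belief carries the grid mean and
    variance; if the normalizer underflows the grid is widened once before
    failing.
    """
    if prior.var <= 0:
        raise ValueError("prior variance must be > 0")
    if n_grid < 3:
        raise ValueError("n_grid must be >= 3")

    def density_on(x):
        like = boundary_likelihood(x, m_prime, cl, params)
        log_prior = -((x - prior.mean) ** 2) / (2.0 * prior.var)
        return like * np.exp(log_prior - log_prior.max())

    for attempt_span in (span, 2.0 * span):
        x = _make_grid(prior, m_prime, params, n_grid, attempt_span)
        dens = density_on(x)
        # if the mass sits in a small fraction of the grid (e.g. a prior far
        # sharper than the grid spacing), re-grid onto the occupied region so
        # the trapezoid moments stay resolved
        occupied = np.flatnonzero(dens > dens.max() * 1e-14)
        if occupied.size and occupied.size < 0.2 * n_grid:
            lo = x[max(occupied[0] - 1, 0)]
            hi = x[min(occupied[-1] + 1, n_grid - 1)]
            if hi > lo:
                x = np.linspace(lo, hi, n_grid)
                dens = density_on(x)
        # trapezoid rule on the uniform grid, written as direct sums
        dx = (x[-1] - x[0]) / (n_grid - 1)
        z = (dens.sum() - 0.5 * (dens[0] + dens[-1])) * dx
        if z > 0 and np.isfinite(z):
            dens = dens / z
            xd = x * dens
            mean = (xd.sum() - 0.5 * (xd[0] + xd[-1])) * dx
            x2d = (x - mean) ** 2 * dens
            var = (x2d.sum() - 0.5 * (x2d[0] + x2d[-1])) * dx
            return BoundaryBelief(float(mean), max(float(var), 0.0),
                                  grid=(x, dens) if keep_grid else None)
    raise FloatingPointError(
        "posterior normalizer underflowed even after widening the grid; "
        "prior and measurement are numerically incompatible")


try:  # compiled posterior-moment kernel; the gridded numpy path is the reference
    import math as _math

    from numba import njit as _njit

    @_njit(cache=False)
    def _posterior_moments_jit(prior_mean, prior_var, m_prime, cl_large,
                               s_m2, s_s2, n_grid, span):
        """Same algorithm as :func:`posterior_update`, returning (mean, var, ok)."""
        tot = s_m2 + s_s2
        inv_sqrt_v = 1.0 / np.sqrt(s_m2 * s_s2 / tot)
        sd_prior = np.sqrt(prior_var)
        sd_marg = np.sqrt(tot)
        x = np.empty(n_grid)
        dens = np.empty(n_grid)
        for widen in range(2):
            sp = span * (1.0 + widen)
            lo = min(prior_mean - sp * sd_prior, m_prime - sp * sd_marg)
            hi = max(prior_mean + sp * sd_prior, m_prime + sp * sd_marg)
            for regrid in range(2):
                dx = (hi - lo) / (n_grid - 1)
                # shift exponents by the prior's best achievable log-density
                # so sharp priors cannot underflow the whole product
                bstar = min(max(prior_mean, lo), hi)
                shift = ((bstar - prior_mean) ** 2) / (2.0 * prior_var)
                dmax = 0.0
                for i in range(n_grid):
                    b = lo + i * dx
                    z = (b - m_prime) * s_s2 / tot * inv_sqrt_v
                    if cl_large:
                        z = -z
                    phi = 0.5 * (1.0 + _math.erf(z / 1.4142135623730951))
                    g = np.exp(-((b - m_prime) ** 2) / (2.0 * tot)
                               - ((b - prior_mean) ** 2) / (2.0 * prior_var)
                               + shift)
                    x[i] = b
                    dens[i] = phi * g
                    if dens[i] > dmax:
                        dmax = dens[i]
                if dmax <= 0.0:
                    break
                first, last = -1, -1
                thresh = dmax * 1e-14
                n_occ = 0
                for i in range(n_grid):
                    if dens[i] > thresh:
                        n_occ += 1
                        if first < 0:
                            first = i
                        last = i
                if regrid == 0 and n_occ > 0 and n_occ < 0.2 * n_grid:
                    lo2 = x[max(first - 1, 0)]
                    hi2 = x[min(last + 1, n_grid - 1)]
                    if hi2 > lo2:
                        lo, hi = lo2, hi2
                        continue
                break
            if dmax <= 0.0:
                continue
            dx = (x[n_grid - 1] - x[0]) / (n_grid - 1)
            zsum = (dens.sum() - 0.5 * (dens[0] + dens[n_grid - 1])) * dx
            if zsum > 0.0 and np.isfinite(zsum):
                m1 = 0.0
                for i in range(n_grid):
                    wgt = dens[i]
                    if i == 0 or i == n_grid - 1:
                        wgt *= 0.5
                    m1 += x[i] * wgt
                m1 *= dx / zsum
                m2 = 0.0
                for i in range(n_grid):
                    wgt = dens[i]
                    if i == 0 or i == n_grid - 1:
                        wgt *= 0.5
                    m2 += (x[i] - m1) ** 2 * wgt
                m2 *= dx / zsum
                return m1, max(m2, 0.0), True
        return 0.0, 0.0, False

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional accelerator
    _HAVE_NUMBA = False


def posterior_moments_fast(prior: BoundaryBelief, m_prime: float, cl: int,
                           params: WorldParams, n_grid: int = 2001,
                           span: float = 8.0) -> BoundaryBelief:
    """Posterior mean/variance via the compiled kernel when available.

    Falls back to :func:`posterior_update`; both paths implement the same
    grid algorithm and agree to numerical round-off (asserted in tests).
    """
    if _HAVE_NUMBA:
        if prior.var <= 0:
            raise ValueError("prior variance must be > 0")
        mean, var, ok = _posterior_moments_jit(
            prior.mean, prior.var, m_prime, cl == LARGE,
            params.sigma_M2, params.sigma_s ** 2, n_grid, span)
        if ok:
            return BoundaryBelief(mean, var)
        raise FloatingPointError(
            "posterior normalizer underflowed even after widening the grid; "
            "prior and measurement are numerically incompatible")
    return posterior_update(prior, m_prime, cl, params, n_grid=n_grid,
                            span=span, keep_grid=False)


def propagate_prior(post: BoundaryBelief, params: WorldParams) -> BoundaryBelief:
    """Recall the posterior as the next trial's prior, with decay and diffusion.

    ``lambda = sigma_0**2 / (sigma_0**2 + var_post)``;
    mean ``lambda * mean_post + (1 - lambda) * mu0``;
    variance ``lambda * var_post + sigma_diffusion**2``.
    """
    s02 = params.sigma_0 ** 2
    lam = s02 / (s02 + post.var)
    mean = lam * post.mean + (1.0 - lam) * params.mu0
    var = lam * post.var + params.sigma_diffusion ** 2
    return BoundaryBelief(mean, var)


class WorldAgent:
    """Stateful boundary-updating agent with the simulation/fitting interface.

    ``start_run`` resets the belief to ``N(mu0, sigma_0**2)``;
    ``draw_choice`` samples a measurement and decides against the current
    belief without touching state; ``update`` recalls the measurement with
    memory noise, deduces the class state, performs the gridded posterior
    update and propagates the recalled prior for the next trial.

    ``n_grid`` controls the posterior grid resolution (default 2001; smaller
    grids trade accuracy for speed in simulation-based fitting).
    """

    name = "world"

    def __init__(self, params: WorldParams, n_grid: int = 2001):
        self.params = params
        self.n_grid = n_grid
        self.belief = BoundaryBelief(params.mu0, params.sigma_0 ** 2)

    def start_run(self) -> None:
        self.belief = BoundaryBelief(self.params.mu0, self.params.sigma_0 ** 2)

    def latents(self) -> dict:
        return {"b_mean": self.belief.mean, "b_var": self.belief.var}

    def prob_large_given_m(self, m: float) -> float:
        return float(ndtr((m - self.belief.mean) / self.params.sigma_m))

    def draw_choice(self, stimulus: float, rng: np.random.Generator) -> tuple[int, float]:
        m = rng.normal(stimulus, self.params.sigma_m)
        choice, _ = decide(m, self.belief, self.params.sigma_m, rng)
        return choice, m

    def update(self, m: float, choice: int, feedback: int,
               rng: np.random.Generator) -> dict:
        if self.params.sigma_mprime > 0:
            m_prime = rng.normal(m, self.params.sigma_mprime)
        else:
            m_prime = m
        cl = deduce_class_state(choice, feedback)
        post = posterior_moments_fast(self.belief, m_prime, cl, self.params,
                                      n_grid=self.n_grid)
        self.belief = propagate_prior(post, self.params)
        return {"m_prime": m_prime}
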