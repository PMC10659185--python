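"""Simulation-based maximum-likelihood fitting of agents to choice sequences.

The log likelihood of a sequential simulator model is estimated without bias
by inverse binomial sampling (IBS): for each trial, simulated choices are
drawn from the model until one matches the observed choice; if the match
occurs on draw K the trial contributes ``-sum_{j=1}^{K-1} 1/j``.  Between
trials the agent's latent state is propagated using the *observed* choice and
feedback (clamped to data), with the matching draw's measurement feeding the
memory/update step, so the per-trial emission stays consistent with the
conditioning event.

Optimization uses Latin-hypercube multistart with a bounded derivative-free
search; each start evaluates the IBS objective under common random numbers
(a frozen per-start noise seed), which makes the objective deterministic
within a start, and the winning candidate is re-evaluated on fresh noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import qmc

from .psychometrics import fit_psychometric, _level_counts
from .reference_agents import BaseAgent, FixedAgent, FixedParams, HybridAgent, HybridParams
from .task import LARGE, SMALL
from .value_agent import ValueAgent, ValueParams
from .world_agent import WorldAgent, WorldParams

SIGMA_BOUNDS = (0.01, 10.0)
DEFAULT_BOUNDS = {
    "mu0": (-2.0, 2.0),
    "sigma_m": SIGMA_BOUNDS,
    "sigma_s": SIGMA_BOUNDS,
    "sigma_0": SIGMA_BOUNDS,
    "sigma_mprime": SIGMA_BOUNDS,
    "sigma_diffusion": SIGMA_BOUNDS,
    "alpha": (0.0, 1.0),
    "beta": (0.0, 50.0),
    "v_init": (0.0, 5.0),
}


@dataclass(frozen=True)
class ModelSpec:
    """A named agent family: parameter names, box bounds and a factory."""

    name: str
    param_names: tuple[str, ...]
    factory: Callable[..., object]

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def bounds(self, overrides: Optional[dict] = None) -> list[tuple[float, float]]:
        overrides = overrides or {}
        return [overrides.get(p, DEFAULT_BOUNDS[p]) for p in self.param_names]

    def make(self, theta: Sequence[float], n_grid: int = 2001):
        kw = dict(zip(self.param_names, map(float, theta)))
        return self.factory(kw, n_grid)


MODELS: dict[str, ModelSpec] = {
    "base": ModelSpec("base", ("sigma_m",),
                      lambda kw, g: BaseAgent(kw["sigma_m"])),
    "fixed": ModelSpec("fixed", ("mu0", "sigma_m"),
                       lambda kw, g: FixedAgent(FixedParams(**kw))),
    "value": ModelSpec("value", ("mu0", "sigma_m", "alpha", "beta", "v_init"),
                       lambda kw, g: ValueAgent(ValueParams(**kw))),
    "world": ModelSpec("world", ("mu0", "sigma_m", "sigma_s", "sigma_0",
                                 "sigma_mprime", "sigma_diffusion"),
                       lambda kw, g: WorldAgent(WorldParams(**kw), n_grid=g)),
    "hybrid": ModelSpec("hybrid", ("mu0", "sigma_m", "sigma_s", "sigma_0",
                                   "sigma_mprime", "sigma_diffusion",
                                   "alpha", "beta", "v_init"),
                        lambda kw, g: HybridAgent(HybridParams(**kw), n_grid=g)),
}


def estimate_lapse_rate(trials: pd.DataFrame) -> float:
    """Session-level lapse probability from the grand-mean psychometric curve.

    Fits the 4-parameter cumulative Gaussian (guess and lapse rates free) to
    all trials pooled and returns ``(guess + lapse) / 2``; a non-identifiable
    grand fit returns 0.
    """
    levels, n, k = _level_counts(trials)
    fit = fit_psychometric(levels, n, k, include_lapse=True)
    if not fit.identifiable:
        return 0.0
    return float(np.clip((fit.guess + fit.lapse) / 2.0, 0.0, 0.5))


@dataclass
class IBSResult:
    loglik: float
    n_trials: int
    n_capped: int


def ibs_loglik(agent, trials: pd.DataFrame,
               rng: "np.random.Generator | int",
               lapse_rate: float = 0.0, max_draws: int = 10_000) -> IBSResult:
    """Unbiased IBS estimate of the log likelihood of observed choices.

    ``trials`` must be ordered (run, trial).  The per-draw emission is a
    lapse mixture: with probability ``lapse_rate`` the simulated choice is a
    fair coin (scoring designated lapse behavior and bounding the match
    probability away from 0).  Trials whose match takes more than
    ``max_draws`` draws have their contribution floored at
    ``-sum_{j=1}^{max_draws-1} 1/j`` and are counted in ``n_capped``.

    ``rng`` may be an integer seed instead of a generator; each trial then
    draws from its own (seed, trial)-keyed substream.  Estimates produced
    this way are distributionally identical, but two models scored under the
    same seed see the same noise per trial, so their log-likelihood
    *difference* is estimated with far lower variance (common random
    numbers) -- the mode used for model-comparison evidence.
    """
    if not 0.0 <= lapse_rate <= 1.0:
        raise ValueError("lapse_rate must be a probability")
    crn_seed = int(rng) if isinstance(rng, (int, np.integer)) else None
    if crn_seed is not None:
        # one counter-based bit generator, re-keyed per trial: trial i reads
        # from counter lane (0, i, 0, 0), so substreams never overlap
        _philox = np.random.Philox(key=np.uint64(crn_seed))
        _state = _philox.state
        _gen = np.random.Generator(_philox)

        def _trial_rng(i):
            _state["state"]["counter"][:] = 0
            _state["state"]["counter"][1] = i
            _state["buffer_pos"] = 4
            _philox.state = _state
            return _gen
    stim = trials["stimulus"].to_numpy()
    obs_choice = trials["choice"].to_numpy()
    obs_fb = trials["feedback"].to_numpy()
    runs = trials["run"].to_numpy()
    harm = np.concatenate([[0.0], np.cumsum(1.0 / np.arange(1, max_draws + 1))])
    ll = 0.0
    n_capped = 0
    prev_run = None
    for i in range(len(stim)):
        if runs[i] != prev_run:
            agent.start_run()
            prev_run = runs[i]
        if crn_seed is not None:
            rng = _trial_rng(i)
        s, c_obs = stim[i], obs_choice[i]
        k = 0
        m_match = None
        while True:
            k += 1
            if k > max_draws:
                n_capped += 1
                ll -= harm[max_draws - 1]
                # propagate with a fresh measurement despite the cap
                m_match = rng.normal(s, getattr(agent, "params").sigma_m) \
                    if m_match is None else m_match
                break
            if lapse_rate > 0.0 and rng.random() < lapse_rate:
                c_sim = LARGE if rng.random() < 0.5 else SMALL
                m = rng.normal(s, getattr(agent, "params").sigma_m)
            else:
                c_sim, m = agent.draw_choice(s, rng)
            if c_sim == c_obs:
                ll -= harm[k - 1]
                m_match = m
                break
        agent.update(m_match, c_obs, obs_fb[i], rng)
    return IBSResult(float(ll), len(stim), n_capped)


def ibs_loglik_repeated(make_agent, trials: pd.DataFrame, seeds: Sequence[int],
                        lapse_rate: float = 0.0, max_draws: int = 10_000,
                        per_trial_crn: bool = False) -> float:
    """Average of independent IBS estimates over the given noise seeds.

    With ``per_trial_crn`` each seed is passed through to per-trial
    substreams, making estimates comparable across models (see
    :func:`ibs_loglik`).
    """
    vals = [ibs_loglik(make_agent(), trials,
                       int(s) if per_trial_crn else np.random.default_rng(int(s)),
                       lapse_rate, max_draws).loglik for s in seeds]
    return float(np.mean(vals))


def _log_scale_mask(spec: "ModelSpec") -> np.ndarray:
    """Scale parameters (sigmas) are searched in log space."""
    return np.array([p.startswith("sigma") for p in spec.param_names])


def _informed_start(spec: "ModelSpec", trials: pd.DataFrame,
                    box: np.ndarray) -> Optional[np.ndarray]:
    """Data-driven start point: sigma_m from the grand psychometric slope,
    mu0 from its PSE, remaining parameters at neutral mid-range values."""
    levels, n, k = _level_counts(trials)
    fit = fit_psychometric(levels, n, k)
    if not fit.identifiable or not np.isfinite(fit.pse):
        return None
    guess = {"mu0": fit.pse, "sigma_m": fit.slope_sd, "sigma_s": 1.5,
             "sigma_0": 1.0, "sigma_mprime": 1.0, "sigma_diffusion": 0.5,
             "alpha": 0.2, "beta": 5.0, "v_init": 1.0}
    theta = np.array([guess[p] for p in spec.param_names])
    return np.clip(theta, box[:, 0], box[:, 1])


@dataclass
class StartResult:
    theta0: np.ndarray
    theta: np.ndarray
    loglik: float
    converged: bool


@dataclass
class FitResult:
    """Best-fitting parameters and per-start provenance for one model/dataset."""

    model: str
    params: dict[str, float]
    loglik: float
    n_trials: int
    lapse_rate: float
    starts: list[StartResult] = field(default_factory=list)
    success: bool = True

    def to_dict(self) -> dict:
        return {"model": self.model, "params": self.params,
                "loglik": self.loglik, "n_trials": self.n_trials,
                "lapse_rate": self.lapse_rate, "success": self.success,
                "starts": [{"theta0": s.theta0.tolist(), "theta": s.theta.tolist(),
                            "loglik": s.loglik, "converged": s.converged}
                           for s in self.starts]}


def fit_model(model: str | ModelSpec, trials: pd.DataFrame,
              rng: np.random.Generator, n_starts: int = 20,
              lapse_rate: Optional[float] = None,
              bounds: Optional[dict] = None,
              n_reps_search: int = 1, n_reps_refine: int = 8,
              n_reps_final: int = 100,
              max_draws: int = 10_000, maxfev: int = 200,
              maxfev_refine: Optional[int] = None,
              n_reps_polish: int = 0, maxfev_polish: int = 48,
              n_grid: int = 2001,
              final_seeds: Optional[Sequence[int]] = None) -> FitResult:
    """Latin-hypercube multistart maximum-likelihood fit via IBS.

    Start points are a Latin-hypercube sample within the box bounds; each is
    optimized by bounded Powell search on the IBS objective under common
    random numbers (``n_reps_search`` frozen seeds per start).  Because a
    single IBS replicate is noisy, the search is noise-aware: every start's
    optimum is re-scored under one shared ``n_reps_refine``-seed set, the
    best candidate is re-optimized under that re-averaged objective, and the
    winner is finally re-evaluated on ``n_reps_final`` fresh seeds for the
    reported log likelihood.  When ``lapse_rate`` is None it is estimated
    from the grand-mean psychometric curve.

    ``final_seeds`` overrides the fresh seeds of the final evaluation and
    switches it to per-trial common random numbers; supplying the same seeds
    to fits of competing models makes their evidence differences far less
    noisy (used by model recovery).
    """
    spec = MODELS[model] if isinstance(model, str) else model
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    if lapse_rate is None:
        lapse_rate = estimate_lapse_rate(trials)
    box = np.array(spec.bounds(bounds))
    # scale parameters are searched in log space: better conditioned, and
    # Latin-hypercube starts spread sensibly over orders of magnitude
    log_mask = _log_scale_mask(spec)
    tbox = box.copy()
    tbox[log_mask] = np.log(np.maximum(box[log_mask], 1e-12))

    def from_internal(u):
        theta = np.asarray(u, dtype=float).copy()
        theta[log_mask] = np.exp(theta[log_mask])
        return np.clip(theta, box[:, 0], box[:, 1])

    def to_internal(theta):
        u = np.asarray(theta, dtype=float).copy()
        u[log_mask] = np.log(np.maximum(u[log_mask], 1e-12))
        return np.clip(u, tbox[:, 0], tbox[:, 1])

    sampler = qmc.LatinHypercube(d=spec.n_params, seed=int(rng.integers(2 ** 31)))
    unit = sampler.random(n_starts)
    u0s = tbox[:, 0] + unit * (tbox[:, 1] - tbox[:, 0])
    informed = _informed_start(spec, trials, box)
    if informed is not None:
        u0s[0] = to_internal(informed)

    starts: list[StartResult] = []
    for u0 in u0s:
        seeds = rng.integers(2 ** 31, size=n_reps_search)

        def objective(u):
            # per-trial substreams keep the frozen-noise surface locally
            # smooth in theta, which Powell needs on a stochastic objective
            return -ibs_loglik_repeated(
                lambda: spec.make(from_internal(u), n_grid), trials, seeds,
                lapse_rate, max_draws, per_trial_crn=True)

        try:
            res = minimize(objective, u0, method="Powell",
                           bounds=[tuple(b) for b in tbox],
                           options={"maxfev": maxfev, "xtol": 1e-3, "ftol": 1e-3})
            starts.append(StartResult(from_internal(u0), from_internal(res.x),
                                      -float(res.fun), True))
        except Exception:
            starts.append(StartResult(from_internal(u0), from_internal(u0),
                                      -np.inf, False))

    converged = [s for s in starts if s.converged and np.isfinite(s.loglik)]
    if not converged:
        return FitResult(spec.name, {}, -np.inf, len(trials), lapse_rate,
                         starts, success=False)

    # noise-aware selection and refinement under a shared re-averaged objective
    refine_seeds = rng.integers(2 ** 31, size=n_reps_refine)

    def refined_objective(u):
        return -ibs_loglik_repeated(
            lambda: spec.make(from_internal(u), n_grid), trials,
            refine_seeds, lapse_rate, max_draws, per_trial_crn=True)

    best = max(converged, key=lambda s: -refined_objective(to_internal(s.theta)))
    theta_best = best.theta
    if maxfev_refine is None:
        maxfev_refine = max(maxfev // 4, 10 * spec.n_params)
    if maxfev_refine > 0:
        try:
            res = minimize(refined_objective, to_internal(theta_best),
                           method="Powell", bounds=[tuple(b) for b in tbox],
                           options={"maxfev": maxfev_refine,
                                    "xtol": 1e-3, "ftol": 1e-3})
            theta_best = from_internal(res.x)
        except Exception:
            pass  # keep the unrefined candidate

    if n_reps_polish > 0:
        # short high-precision pass: shallow likelihood ridges (e.g. the
        # sigma_m/beta trade-off) are only a few log units deep, below the
        # refine stage's noise floor, so resolve them with many repetitions
        polish_seeds = rng.integers(2 ** 31, size=n_reps_polish)

        def polish_objective(u):
            return -ibs_loglik_repeated(
                lambda: spec.make(from_internal(u), n_grid), trials,
                polish_seeds, lapse_rate, max_draws, per_trial_crn=True)

        try:
            res = minimize(polish_objective, to_internal(theta_best),
                           method="Powell", bounds=[tuple(b) for b in tbox],
                           options={"maxfev": maxfev_polish,
                                    "xtol": 1e-3, "ftol": 1e-4})
            theta_best = from_internal(res.x)
        except Exception:
            pass

    crn = final_seeds is not None
    if final_seeds is None:
        final_seeds = rng.integers(2 ** 31, size=n_reps_final)
    ll_final = ibs_loglik_repeated(lambda: spec.make(theta_best, n_grid),
                                   trials, final_seeds, lapse_rate, max_draws,
                                   per_trial_crn=crn)
    params = dict(zip(spec.param_names, map(float, theta_best)))
    return FitResult(spec.name, params, ll_final, len(trials), lapse_rate, starts)
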