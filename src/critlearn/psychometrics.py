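"""Episode-conditioned history-effect analysis via psychometric PSE estimation.

The point of subjective equality (PSE) is the stimulus level at which a
cumulative-Gaussian psychometric function predicts 50% *large* choices;
negative PSE means a bias toward *large*.  History effects of a decision
episode (stimulus, choice, feedback) are quantified by fitting psychometric
curves to the trials immediately preceding (retrospective, toi-1) and
following (prospective, toi+1) every occurrence of that episode, estimating
the PSE by averaging over binomial bootstrap refits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import ndtr

from .task import Episode, LARGE, STIM_LEVELS

_BOUNDS_2P = [(-10.0, 10.0), (1e-3, 50.0)]
_BOUNDS_4P = _BOUNDS_2P + [(0.0, 0.5), (0.0, 0.5)]


@dataclass
class PsychometricFit:
    """Cumulative-Gaussian fit psi(x) = gamma + (1 - gamma - lapse) * F(x; mu, sigma).

    ``pse`` is the fitted ``mu`` (NaN when the fit is non-identifiable, e.g.
    all responses identical).  Bootstrap statistics are attached by
    :func:`bootstrap_pse`.
    """

    pse: float
    slope_sd: float
    guess: float = 0.0
    lapse: float = 0.0
    nll: float = np.nan
    identifiable: bool = True
    n_boot: int = 0
    boot_mean_pse: float = np.nan
    boot_sd_pse: float = np.nan
    boot_dropped: int = 0
    boot_flagged: bool = False


def _nll(theta, x, n, k, with_lapse):
    if with_lapse:
        mu, sigma, gamma, lam = theta
    else:
        mu, sigma = theta
        gamma = lam = 0.0
    p = gamma + (1.0 - gamma - lam) * ndtr((x - mu) / sigma)
    p = np.clip(p, 1e-10, 1.0 - 1e-10)
    return -np.sum(k * np.log(p) + (n - k) * np.log1p(-p))


def _start_mu(x, n, k):
    with np.errstate(invalid="ignore"):
        prop = np.where(n > 0, k / np.maximum(n, 1), np.nan)
    order = np.argsort(x)
    xs, ps = x[order], prop[order]
    crossing = np.interp(0.5, np.clip(ps, 0.0, 1.0), xs) if np.nanmax(ps) > 0.5 >= np.nanmin(ps) else np.nanmean(xs)
    return float(np.clip(crossing, xs.min() - 2, xs.max() + 2))


def fit_psychometric(levels: Sequence[float], n_trials: Sequence[int],
                     n_large: Sequence[int],
                     include_lapse: bool = False,
                     start: Optional[Sequence[float]] = None) -> PsychometricFit:
    """Maximum-likelihood binomial fit of the cumulative Gaussian.

    ``levels``/``n_trials``/``n_large`` give, per stimulus level, the trial
    count and the number of *large* responses.  With ``include_lapse``, guess
    and lapse rates (each bounded in [0, 0.5]) are fitted as well.  A table
    whose responses are all identical is flagged non-identifiable (PSE NaN)
    rather than extrapolated.  ``start`` supplies a single warm start
    (mu, sigma[, guess, lapse]) and skips the multistart (used by the
    bootstrap, which refits near the point estimate).
    """
    x = np.asarray(levels, dtype=float)
    n = np.asarray(n_trials, dtype=float)
    k = np.asarray(n_large, dtype=float)
    use = n > 0
    x, n, k = x[use], n[use], k[use]
    if x.size < 2:
        raise ValueError("need >= 2 stimulus levels with trials")
    if np.any(k < 0) or np.any(k > n):
        raise ValueError("n_large must lie in [0, n_trials] per level")
    if k.sum() == 0 or k.sum() == n.sum():
        return PsychometricFit(np.nan, np.nan, identifiable=False)

    bounds = _BOUNDS_4P if include_lapse else _BOUNDS_2P
    if start is not None:
        starts = [tuple(start)]
    else:
        mu0 = _start_mu(x, n, k)
        spread = max(0.5, (x.max() - x.min()) / 4.0)
        extra = (0.01, 0.01) if include_lapse else ()
        starts = [(mu0, spread) + extra, (mu0, 2.0 * spread) + extra,
                  (0.0, spread) + extra]
    best = None
    for theta0 in starts:
        theta0 = np.clip(theta0, [b[0] for b in bounds], [b[1] for b in bounds])
        res = minimize(_nll, theta0, args=(x, n, k, include_lapse),
                       method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    mu, sigma = best.x[0], best.x[1]
    gamma, lam = (best.x[2], best.x[3]) if include_lapse else (0.0, 0.0)
    return PsychometricFit(float(mu), float(sigma), float(gamma), float(lam),
                           nll=float(best.fun))


def bootstrap_pse(levels: Sequence[float], n_trials: Sequence[int],
                  n_large: Sequence[int], n_boot: int = 5000,
                  rng: Optional[np.random.Generator] = None,
                  include_lapse: bool = False,
                  max_drop_frac: float = 0.2) -> PsychometricFit:
    """Bootstrap-averaged PSE estimate.

    Per-level successes are resampled binomially at the observed proportions
    (the binomial random process), each resample is refitted, and the mean
    PSE over identifiable resamples is the reported estimate, with their SD
    as its uncertainty.  Resamples with non-identifiable fits are dropped and
    counted; the estimate is flagged when more than ``max_drop_frac`` drop.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    fit = fit_psychometric(levels, n_trials, n_large, include_lapse)
    x = np.asarray(levels, dtype=float)
    n = np.asarray(n_trials, dtype=int)
    k = np.asarray(n_large, dtype=float)
    use = n > 0
    x, n, k = x[use], n[use], k[use]
    prop = k / n
    warm = None
    if fit.identifiable and np.isfinite(fit.pse):
        warm = (fit.pse, fit.slope_sd) + ((fit.guess, fit.lapse)
                                          if include_lapse else ())
    pses = []
    dropped = 0
    for _ in range(n_boot):
        k_star = rng.binomial(n, prop)
        refit = fit_psychometric(x, n, k_star, include_lapse, start=warm)
        if refit.identifiable and np.isfinite(refit.pse):
            pses.append(refit.pse)
        else:
            dropped += 1
    fit.n_boot = n_boot
    fit.boot_dropped = dropped
    fit.boot_flagged = dropped > max_drop_frac * n_boot
    if pses:
        fit.boot_mean_pse = float(np.mean(pses))
        fit.boot_sd_pse = float(np.std(pses, ddof=1)) if len(pses) > 1 else 0.0
    return fit


# -- episode conditioning ----------------------------------------------------

def condition_on_episode(trials: pd.DataFrame, episode: Episode,
                         offset: int) -> pd.DataFrame:
    """Trials at position toi+offset for every toi matching ``episode``.

    ``offset`` is -1 (retrospective) or +1 (prospective).  Trials of interest
    at a run edge contribute nothing in that direction.  An empty selection
    returns an empty frame, not an exception.
    """
    if offset not in (-1, 1):
        raise ValueError("offset must be -1 or +1")
    t = trials
    toi = ((t["stimulus"].to_numpy() == episode.stimulus)
           & (t["choice"].to_numpy() == episode.choice)
           & (t["feedback"].to_numpy() == episode.feedback))
    if "valid" in t.columns:
        toi &= t["valid"].to_numpy().astype(bool)
    idx = np.flatnonzero(toi) + offset
    ok = (idx >= 0) & (idx < len(t))
    idx = idx[ok]
    # the shifted row must belong to the same run
    same_run = t["run"].to_numpy()[idx] == t["run"].to_numpy()[idx - offset]
    return t.iloc[idx[same_run]]


def _level_counts(sub: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    levels = np.array(STIM_LEVELS, dtype=float)
    n = np.zeros(len(levels), dtype=int)
    k = np.zeros(len(levels), dtype=int)
    stim = sub["stimulus"].to_numpy()
    ch = sub["choice"].to_numpy()
    for i, lv in enumerate(STIM_LEVELS):
        sel = stim == lv
        n[i] = sel.sum()
        k[i] = (ch[sel] == LARGE).sum()
    return levels, n, k


def history_effect_table(trials: pd.DataFrame,
                         episodes: Optional[Iterable[Episode]] = None,
                         n_boot: int = 1000,
                         min_trials: int = 50,
                         include_lapse: bool = False,
                         directions: Sequence[str] = ("retrospective",
                                                      "prospective"),
                         rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Retrospective/prospective/subtractive PSE table over episodes.

    Returns one tidy row per episode x direction with columns ``stimulus``,
    ``choice``, ``feedback``, ``direction`` ('retrospective', 'prospective' or
    'subtractive'), ``pse``, ``se``, ``n`` and ``flagged``.  Episode cells
    with fewer than ``min_trials`` conditioned trials, or non-identifiable
    fits, carry NaN PSEs rather than imputed values.  With ``n_boot = 0`` the
    point fit is reported without bootstrap statistics.  ``directions``
    restricts the analysis; the subtractive row is emitted only when both
    directions are computed.
    """
    rng = np.random.default_rng() if rng is None else rng
    episodes = list(episodes) if episodes is not None else Episode.all_episodes()
    offsets = {"retrospective": -1, "prospective": 1}
    rows = []
    for ep in episodes:
        cell = {}
        for direction in directions:
            sub = condition_on_episode(trials, ep, offsets[direction])
            n_cond = len(sub)
            pse, se, flagged = np.nan, np.nan, False
            if n_cond >= max(min_trials, 1):
                levels, n, k = _level_counts(sub)
                if (n > 0).sum() >= 2 and 0 < k.sum() < n.sum():
                    if n_boot > 0:
                        fit = bootstrap_pse(levels, n, k, n_boot, rng, include_lapse)
                        pse, se, flagged = fit.boot_mean_pse, fit.boot_sd_pse, fit.boot_flagged
                    else:
                        fit = fit_psychometric(levels, n, k, include_lapse)
                        pse = fit.pse
            cell[direction] = (pse, se, n_cond, flagged)
            rows.append({"stimulus": ep.stimulus, "choice": ep.choice,
                         "feedback": ep.feedback, "direction": direction,
                         "pse": pse, "se": se, "n": n_cond, "flagged": flagged})
        if "retrospective" in cell and "prospective" in cell:
            retro, pro = cell["retrospective"], cell["prospective"]
            sub_se = (np.sqrt(retro[1] ** 2 + pro[1] ** 2)
                      if np.isfinite(retro[1]) and np.isfinite(pro[1]) else np.nan)
            rows.append({"stimulus": ep.stimulus, "choice": ep.choice,
                         "feedback": ep.feedback, "direction": "subtractive",
                         "pse": pro[0] - retro[0], "se": sub_se,
                         "n": min(retro[2], pro[2]),
                         "flagged": retro[3] or pro[3]})
    return pd.DataFrame(rows)


def episode_pair_map(trials: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """20x20 conditional episode-pair frequency maps, one per direction.

    Entry (row = episode at toi+-1, column = episode at toi) is
    ``P(episode at toi+-1 | episode at toi)``; each observed column sums to 1.
    Unobserved conditioning episodes give all-NaN columns.
    """
    eps = Episode.all_episodes()
    labels = [e.label for e in eps]
    code = {(e.stimulus, e.choice, e.feedback): i for i, e in enumerate(eps)}
    stim = trials["stimulus"].to_numpy()
    ch = trials["choice"].to_numpy()
    fb = trials["feedback"].to_numpy()
    run = trials["run"].to_numpy()
    ep_idx = np.array([code[(s, c, f)] for s, c, f in zip(stim, ch, fb)])
    maps = {}
    for direction, offset in (("retrospective", -1), ("prospective", 1)):
        counts = np.zeros((20, 20))
        idx = np.arange(len(trials))
        shifted = idx + offset
        ok = (shifted >= 0) & (shifted < len(trials))
        ok[ok] &= run[shifted[ok]] == run[idx[ok]]
        np.add.at(counts, (ep_idx[shifted[ok]], ep_idx[idx[ok]]), 1)
        col_tot = counts.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            cond = counts / col_tot
        cond[:, col_tot == 0] = np.nan
        maps[direction] = pd.DataFrame(cond, index=labels, columns=labels)
    return maps
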