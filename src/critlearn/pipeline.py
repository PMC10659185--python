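"""Orchestration of the package's computational experiments.

Three experiment kinds are supported, each fully determined by a config plus
a seed:

ex ante
    Simulate the value-updating and world-updating agents over a grid of
    sensory-noise levels ``sigma_m`` (default 25 levels uniformly spaced on
    [0.15, 3.27]) with no lapses and no arbitrary bias, on frozen trial
    schedules shared by both agents, and tabulate retrospective/prospective
    PSE history effects per episode.  This previews each model's predicted
    stimulus-dependent feedback effects before any fitting.

ex post
    Same machinery, but each simulated agent uses a supplied (e.g. fitted)
    parameter set and lapse rate, and the output additionally includes
    episode-pair frequency maps and an optional per-cell statistical
    comparison against a reference table.

recovery
    See :func:`critlearn.comparison.model_recovery`; a thin config-driven
    wrapper is provided here.

The non-``sigma_m`` ex ante defaults are chosen so that simulated task
accuracy lands in the observed human range (about 61-74% correct).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .psychometrics import Episode, episode_pair_map, history_effect_table
from .reference_agents import HybridAgent, HybridParams
from .task import make_run_schedules, simulate_agent_session
from .value_agent import ValueAgent, ValueParams
from .world_agent import WorldAgent, WorldParams

#: sigma_m grid used for ex ante simulation (25 uniform levels).
SIGMA_M_GRID = tuple(np.linspace(0.15, 3.27, 25))

#: Ex ante defaults for the non-sigma_m parameters (no arbitrary bias:
#: mu0 = 0 for both agents).  Chosen once to put simulated accuracy in the
#: human range; see docs/methods.md.
EX_ANTE_VALUE_DEFAULTS = {"mu0": 0.0, "alpha": 0.2, "beta": 4.0, "v_init": 1.0}
EX_ANTE_WORLD_DEFAULTS = {"mu0": 0.0, "sigma_s": 2.2, "sigma_0": 2.0,
                          "sigma_mprime": 0.8, "sigma_diffusion": 0.4}


def make_agent(model: str, params: dict, n_grid: int = 2001):
    """Instantiate a simulation agent by model name from a parameter dict."""
    from .fitting import MODELS
    spec = MODELS[model]
    theta = [params[p] for p in spec.param_names]
    return spec.make(theta, n_grid)


@dataclass
class ExAnteConfig:
    """Configuration of an ex ante simulation experiment."""

    sigma_m_grid: Sequence[float] = SIGMA_M_GRID
    n_runs: int = 30
    n_reps: int = 100
    models: Sequence[str] = ("value", "world")
    value_defaults: dict = field(default_factory=lambda: dict(EX_ANTE_VALUE_DEFAULTS))
    world_defaults: dict = field(default_factory=lambda: dict(EX_ANTE_WORLD_DEFAULTS))
    episodes: Optional[Sequence[Episode]] = None
    n_boot: int = 0
    min_trials: int = 50
    n_grid: int = 2001
    directions: Sequence[str] = ("retrospective", "prospective")
    seed: int = 0


def _agent_for(model: str, sigma_m: float, cfg: ExAnteConfig):
    if model == "value":
        return ValueAgent(ValueParams(sigma_m=sigma_m, **cfg.value_defaults))
    if model == "world":
        return WorldAgent(WorldParams(sigma_m=sigma_m, **cfg.world_defaults),
                          n_grid=cfg.n_grid)
    if model == "hybrid":
        return HybridAgent(HybridParams(sigma_m=sigma_m, **cfg.value_defaults,
                                        **cfg.world_defaults), n_grid=cfg.n_grid)
    raise ValueError(f"unknown ex ante model {model!r}")


def run_ex_ante(cfg: ExAnteConfig) -> dict[str, pd.DataFrame]:
    """Ex ante history-effect tables per model.

    For every ``sigma_m`` grid level and repetition, frozen schedules
    (identical stimulus sequences and virtual-criterion draws) drive each
    model agent; trials are pooled over repetitions within a grid level and
    one history-effect table is computed per (model, grid level).  Returns a
    tidy frame per model with a ``sigma_m`` column, plus an ``accuracy``
    frame under key ``"_accuracy"``.
    """
    rng = np.random.default_rng(cfg.seed)
    tables: dict[str, list] = {m: [] for m in cfg.models}
    acc_rows = []
    for sigma_m in cfg.sigma_m_grid:
        pooled: dict[str, list] = {m: [] for m in cfg.models}
        for rep in range(cfg.n_reps):
            schedules = make_run_schedules(cfg.n_runs, rng, freeze=True)
            for model in cfg.models:
                agent = _agent_for(model, float(sigma_m), cfg)
                t = simulate_agent_session(agent, schedules, rng,
                                           record_latents=False)
                t["run"] = t["run"] + rep * cfg.n_runs   # keep runs distinct
                pooled[model].append(t)
        for model in cfg.models:
            trials = pd.concat(pooled[model], ignore_index=True)
            acc_rows.append({"model": model, "sigma_m": sigma_m,
                             "accuracy": float(trials["feedback"].mean())})
            tab = history_effect_table(trials, episodes=cfg.episodes,
                                       n_boot=cfg.n_boot,
                                       min_trials=cfg.min_trials,
                                       directions=cfg.directions, rng=rng)
            tab.insert(0, "sigma_m", sigma_m)
            tables[model].append(tab)
    out = {m: pd.concat(v, ignore_index=True) for m, v in tables.items()}
    out["_accuracy"] = pd.DataFrame(acc_rows)
    return out


@dataclass
class ExPostConfig:
    """Configuration of an ex post simulation from per-agent parameters."""

    model: str
    agent_params: Sequence[dict]          # one parameter dict per simulated agent
    lapse_rates: Optional[Sequence[float]] = None
    n_runs: int = 30
    n_reps: int = 1
    episodes: Optional[Sequence[Episode]] = None
    n_boot: int = 0
    min_trials: int = 50
    n_grid: int = 2001
    seed: int = 0


def run_ex_post(cfg: ExPostConfig) -> dict:
    """Ex post per-agent history-effect tables and episode-pair maps.

    Each agent is simulated with its own parameter set (and lapse rate, when
    given) on fresh schedules; per-agent tables are stacked with an ``agent``
    column so that :func:`report_stats` can run paired per-cell tests against
    a reference table of the same shape.
    """
    if not cfg.agent_params:
        raise ValueError("agent_params must contain at least one parameter set")
    rng = np.random.default_rng(cfg.seed)
    lapses = cfg.lapse_rates or [0.0] * len(cfg.agent_params)
    if len(lapses) != len(cfg.agent_params):
        raise ValueError("lapse_rates must align with agent_params")
    tabs, maps = [], []
    for i, (params, lapse) in enumerate(zip(cfg.agent_params, lapses)):
        pooled = []
        for rep in range(cfg.n_reps):
            agent = make_agent(cfg.model, params, cfg.n_grid)
            schedules = make_run_schedules(cfg.n_runs, rng, freeze=True)
            t = simulate_agent_session(agent, schedules, rng, lapse_rate=lapse,
                                       record_latents=False)
            t["run"] = t["run"] + rep * cfg.n_runs
            pooled.append(t)
        trials = pd.concat(pooled, ignore_index=True)
        tab = history_effect_table(trials, episodes=cfg.episodes,
                                   n_boot=cfg.n_boot,
                                   min_trials=cfg.min_trials, rng=rng)
        tab.insert(0, "agent", i)
        tabs.append(tab)
        maps.append(episode_pair_map(trials))
    return {"history": pd.concat(tabs, ignore_index=True), "pair_maps": maps}


_CELL_KEYS = ["stimulus", "choice", "feedback", "direction"]


def report_stats(table_a: pd.DataFrame, table_b: pd.DataFrame,
                 alpha: float = 0.05, method: str = "ttest") -> pd.DataFrame:
    """Per-cell paired tests between two stacked per-agent PSE tables.

    Both tables must carry ``agent`` plus the episode/direction key columns
    and a ``pse`` column and cover the same agents and cells.  Cells are
    compared by paired two-sided t tests (or Wilcoxon signed-rank with
    ``method='wilcoxon'``); the significance threshold is Bonferroni-adjusted
    to ``alpha / n_cells`` over the non-missing cells.
    """
    a = table_a.set_index(["agent"] + _CELL_KEYS)["pse"]
    b = table_b.set_index(["agent"] + _CELL_KEYS)["pse"]
    if not a.index.sort_values().equals(b.index.sort_values()):
        raise ValueError("tables are misaligned: agent/cell keys differ")
    b = b.reindex(a.index)
    frame = pd.DataFrame({"a": a, "b": b}).reset_index()
    rows = []
    for keys, grp in frame.groupby(_CELL_KEYS, sort=False):
        paired = grp.dropna(subset=["a", "b"])
        if len(paired) < 2 or np.allclose(paired["a"], paired["b"]):
            stat, p = np.nan, np.nan
            if len(paired) >= 2:   # identical values: no deviation
                stat, p = 0.0, 1.0
        elif method == "wilcoxon":
            stat, p = stats.wilcoxon(paired["a"], paired["b"])
        else:
            stat, p = stats.ttest_rel(paired["a"], paired["b"])
        rows.append(dict(zip(_CELL_KEYS, keys),
                         n_agents=len(paired), stat=stat, p=p))
    out = pd.DataFrame(rows)
    n_cells = int(out["p"].notna().sum())
    threshold = alpha / max(n_cells, 1)
    out["threshold"] = threshold
    out["significant"] = out["p"] < threshold
    return out


def bonferroni_threshold(alpha: float, n_cells: int) -> float:
    """Bonferroni-corrected per-cell threshold alpha / n_cells."""
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    return alpha / n_cells
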