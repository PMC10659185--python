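"""Task simulator for feedback-driven binary classification.

Emulates a ring-size classification experiment: on each trial the agent sees
one of five stimulus levels (integer units ``-2..2``), classifies it as
*small* or *large*, and receives corrective feedback.  Feedback is stochastic:
correctness is judged against a "virtual" criterion drawn per trial from
``N(mu_true, sigma_true**2)``, so feedback is occasionally nonveridical.  This
covers the full 3-D episode space (stimulus x choice x feedback, 20 cells)
that the history-effect analyses condition on.

Design defaults mirror the study conditions: 170 trials per run, stimulus
levels randomized within blocks of 5, ``sigma_true = 1.28``, and a per-run
criterion mean that starts at 0 and switches to one of {-0.4, 0, +0.4} after
40-50 trials.  Stimulus units are the internal integer levels; physical sizes
are metadata only and never enter any computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

# -- fixed encodings ---------------------------------------------------------

SMALL, LARGE = 0, 1              # choice / class encoding
INCORRECT, CORRECT = 0, 1        # feedback encoding

STIM_LEVELS = (-2, -1, 0, 1, 2)
N_TRIALS_PER_RUN = 170
BLOCK_SIZE = 5
SIGMA_TRUE = 1.28
MU_TRUE_VALUES = (-0.4, 0.0, 0.4)
SWITCH_TRIAL_RANGE = (40, 50)    # inclusive bounds for the criterion switch
N_RUNS_DEFAULT = 30

#: Column order of a serialized trial table.
TRIAL_COLUMNS = (
    "run", "trial", "stimulus", "choice", "feedback", "valid", "lapse",
    "m", "m_prime", "b_mean", "b_var", "v_small", "v_large",
)

CHOICE_NAMES = {SMALL: "small", LARGE: "large"}
FEEDBACK_NAMES = {INCORRECT: "incorrect", CORRECT: "correct"}


@dataclass(frozen=True)
class Episode:
    """A (stimulus, choice, feedback) triple indexing one of the 20 episode cells.

    Encoding: choice small=0 / large=1; feedback incorrect=0 / correct=1.
    """

    stimulus: int
    choice: int
    feedback: int

    def __post_init__(self):
        if self.stimulus not in STIM_LEVELS:
            raise ValueError(f"stimulus must be one of {STIM_LEVELS}, got {self.stimulus}")
        if self.choice not in (SMALL, LARGE):
            raise ValueError(f"choice must be {SMALL} (small) or {LARGE} (large)")
        if self.feedback not in (INCORRECT, CORRECT):
            raise ValueError(f"feedback must be {INCORRECT} (incorrect) or {CORRECT} (correct)")

    @property
    def label(self) -> str:
        return (f"S={self.stimulus:+d},C={CHOICE_NAMES[self.choice]},"
                f"F={FEEDBACK_NAMES[self.feedback]}")

    @staticmethod
    def all_episodes() -> list["Episode"]:
        """The 20 distinct episodes in canonical (stimulus, choice, feedback) order."""
        return [Episode(s, c, f)
                for s in STIM_LEVELS for c in (SMALL, LARGE) for f in (INCORRECT, CORRECT)]


@dataclass
class RunSchedule:
    """Per-run design: trial count, criterion drift and (optionally) frozen draws.

    The criterion mean is 0 for trials before ``switch_trial`` and ``mu_true``
    from then on.  ``stimuli`` and ``criteria`` may be materialized with
    :meth:`freeze` so that several agents experience identical trial sequences
    and identical correct answers.
    """

    mu_true: float = 0.0
    n_trials: int = N_TRIALS_PER_RUN
    sigma_true: float = SIGMA_TRUE
    switch_trial: int = 45
    block_size: int = BLOCK_SIZE
    stimuli: Optional[np.ndarray] = None
    criteria: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.sigma_true < 0:
            raise ValueError("sigma_true must be >= 0")
        if not (SWITCH_TRIAL_RANGE[0] <= self.switch_trial <= SWITCH_TRIAL_RANGE[1]):
            raise ValueError(
                f"switch_trial must lie in {SWITCH_TRIAL_RANGE}, got {self.switch_trial}")

    def mu_at(self, trial: int) -> float:
        """Criterion mean in effect on trial ``trial`` (0-based)."""
        return 0.0 if trial < self.switch_trial else self.mu_true

    def freeze(self, rng: np.random.Generator) -> "RunSchedule":
        """Materialize the stimulus sequence and virtual-criterion draws."""
        stimuli = make_stimulus_sequence(self.n_trials, self.block_size, rng)
        mus = np.array([self.mu_at(t) for t in range(self.n_trials)])
        criteria = rng.normal(mus, self.sigma_true)
        return replace(self, stimuli=stimuli, criteria=criteria)


def make_stimulus_sequence(n_trials: int, block_size: int,
                           rng: np.random.Generator) -> np.ndarray:
    """Stimulus levels randomized within every block of ``block_size`` trials.

    Each consecutive window of ``block_size`` trials is an independent uniform
    permutation of the distinct levels, so every level occurs exactly
    ``n_trials / block_size`` times.
    """
    if block_size != len(STIM_LEVELS):
        raise ValueError(f"block_size must equal the number of levels ({len(STIM_LEVELS)})")
    if n_trials % block_size != 0:
        raise ValueError(
            f"n_trials ({n_trials}) must be divisible by block_size ({block_size})")
    levels = np.array(STIM_LEVELS)
    blocks = [rng.permutation(levels) for _ in range(n_trials // block_size)]
    return np.concatenate(blocks)


def generate_feedback(stimulus: float, choice: int, mu_true: float,
                      sigma_true: float, rng: np.random.Generator,
                      criterion: Optional[float] = None) -> int:
    """Stochastic feedback from a virtual criterion ``b ~ N(mu_true, sigma_true**2)``.

    The true class is *large* iff ``stimulus > b``; feedback is *correct* iff
    the choice matches the true class.  ``sigma_true = 0`` gives the degenerate
    deterministic criterion ``b = mu_true`` (useful in tests).  A pre-drawn
    ``criterion`` overrides the sampling (used for frozen schedules).
    """
    if sigma_true < 0:
        raise ValueError("sigma_true must be >= 0")
    b = criterion if criterion is not None else rng.normal(mu_true, sigma_true)
    true_class = LARGE if stimulus > b else SMALL
    return CORRECT if choice == true_class else INCORRECT


def make_run_schedules(n_runs: int = N_RUNS_DEFAULT,
                       rng: Optional[np.random.Generator] = None,
                       mu_values: Sequence[float] = MU_TRUE_VALUES,
                       sigma_true: float = SIGMA_TRUE,
                       n_trials: int = N_TRIALS_PER_RUN,
                       freeze: bool = False) -> list[RunSchedule]:
    """Session-level schedule: runs split evenly over criterion means, shuffled.

    ``n_runs`` is split as evenly as possible over ``mu_values`` (10/10/10 at
    the default 30) and the assignment order is shuffled.  The switch trial is
    drawn uniformly in the inclusive range 40..50 per run.  With ``freeze``,
    stimulus sequences and criterion draws are materialized immediately.
    """
    rng = np.random.default_rng() if rng is None else rng
    reps = [n_runs // len(mu_values) + (1 if i < n_runs % len(mu_values) else 0)
            for i in range(len(mu_values))]
    mus = np.repeat(mu_values, reps)
    rng.shuffle(mus)
    schedules = []
    for mu in mus:
        sw = int(rng.integers(SWITCH_TRIAL_RANGE[0], SWITCH_TRIAL_RANGE[1] + 1))
        sched = RunSchedule(mu_true=float(mu), n_trials=n_trials,
                            sigma_true=sigma_true, switch_trial=sw)
        schedules.append(sched.freeze(rng) if freeze else sched)
    return schedules


def simulate_agent_session(agent, schedules: Iterable[RunSchedule],
                           rng: np.random.Generator,
                           lapse_rate: float = 0.0,
                           reset_each_run: bool = True,
                           record_latents: bool = True) -> pd.DataFrame:
    """Drive an agent through a session of runs and log a trial table.

    Per trial: the agent draws a measurement and a choice; with probability
    ``lapse_rate`` the choice is overridden by a fair coin (the agent is not
    told it lapsed); feedback is generated from the run's virtual criterion;
    the agent updates its latent state from its own measurement, the emitted
    choice, and the feedback.  Latent traces (measurement ``m``, mnemonic
    recall ``m_prime``, boundary belief, choice values) are logged per trial
    where the agent produces them.

    Agent state is re-initialized at each run start when ``reset_each_run``
    (the default, mirroring the per-run reference display).
    """
    if not 0.0 <= lapse_rate <= 1.0:
        raise ValueError("lapse_rate must be a probability")
    rows = []
    if not reset_each_run:
        agent.start_run()
    for run_id, sched in enumerate(schedules):
        if reset_each_run:
            agent.start_run()
        stimuli = sched.stimuli if sched.stimuli is not None else \
            make_stimulus_sequence(sched.n_trials, sched.block_size, rng)
        for t in range(sched.n_trials):
            s = int(stimuli[t])
            try:
                pre = agent.latents() if record_latents else {}
                choice, m = agent.draw_choice(s, rng)
                lapsed = lapse_rate > 0.0 and rng.random() < lapse_rate
                if lapsed:
                    choice = LARGE if rng.random() < 0.5 else SMALL
                crit = sched.criteria[t] if sched.criteria is not None else None
                feedback = generate_feedback(s, choice, sched.mu_at(t),
                                             sched.sigma_true, rng, criterion=crit)
                post = agent.update(m, choice, feedback, rng)
            except Exception as err:
                raise RuntimeError(
                    f"agent failed at run {run_id}, trial {t}: {err}") from err
            row = {"run": run_id, "trial": t, "stimulus": s, "choice": choice,
                   "feedback": feedback, "valid": True, "lapse": lapsed, "m": m}
            if record_latents:
                row.update(pre)
                row.update(post or {})
            rows.append(row)
    table = pd.DataFrame(rows)
    for col in TRIAL_COLUMNS:
        if col not in table.columns:
            table[col] = np.nan
    return table[list(TRIAL_COLUMNS)]
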