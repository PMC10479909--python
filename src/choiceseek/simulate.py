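"""Synthetic-subject generator for the two-stage task.

Produces complete per-subject trial logs — training phase (scheduled
stage-1 cues, agent-chosen free stage-2 actions, mandated forced actions)
followed by the test phase (softmax stage-1 choices) for every block — from
any TD-RL agent of the factorial family, or from one of four heuristic
stay/switch strategy agents used to interpret stay behaviour under
degraded controllability.

All randomness derives from a single seed; sub-seeds for cohort members
are split with numpy's SeedSequence (a splitmix-style stream split), so a
cohort is bit-reproducible from its master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .task import (A1, A2, FREE, FORCED, BlockSpec, ConfigurationError,
                   TaskConfig, draw_outcome, training_schedule)
from .agents import (ModelSpec, Params, QTable, ResolvedParams,
                     action_probabilities, step_trial)

TRAIN = "train"
TEST = "test"

STRATEGIES = ("reward_based", "swap_avoidance", "model_based",
              "control_maintenance")

#: Default probability of choosing the free cue at stage 1 for strategy
#: agents (the strategies only specify stage-2 behaviour); matches the
#: fully coherent block's mean free-choice preference.
DEFAULT_STRATEGY_P_FREE = 0.69

TRIAL_COLUMNS = ("subject_id", "experiment", "block_index", "phase",
                 "trial_index", "stage1_option", "stage1_is_choice",
                 "stage2_action", "displayed_target", "coherent", "reward")


@dataclass(frozen=True)
class TrialRecord:
    subject_id: str
    experiment: str
    block_index: int
    phase: str                # "train" | "test"
    trial_index: int          # 0-based within phase
    stage1_option: str        # "free" | "forced"
    stage1_is_choice: bool    # True only in the test phase
    stage2_action: str        # emitted action, "a1" | "a2"
    displayed_target: str     # after a possible swap
    coherent: bool
    reward: int

    def __post_init__(self) -> None:
        if self.phase == TRAIN and self.stage1_is_choice:
            raise ValueError("training trials have no stage-1 choice")
        if self.coherent != (self.stage2_action == self.displayed_target):
            raise ValueError("coherent flag inconsistent with targets")


def records_to_frame(records: list[TrialRecord]) -> pd.DataFrame:
    df = pd.DataFrame([asdict(r) for r in records], columns=TRIAL_COLUMNS)
    df["coherent"] = df["coherent"].astype(bool)
    df["stage1_is_choice"] = df["stage1_is_choice"].astype(bool)
    return df


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _stage2_free_action(q: QTable, block_index: int, spec, params,
                        rng) -> str:
    p = action_probabilities(q, (FREE, block_index), None, 2, spec, params)
    return A1 if rng.random() < p[0] else A2


def simulate_subject(config: TaskConfig, spec: ModelSpec,
                     params: Params | ResolvedParams,
                     subject_id: str = "sim", seed=0,
                     share_stage1: bool = True) -> list[TrialRecord]:
    """Full synthetic log of one TD-RL agent.

    Training values carry into the test phase of the same block; stage-1
    cue values are shared across blocks by default.  Deterministic given
    (seed, spec, params, config).
    """
    if isinstance(params, Params):
        params = params.resolve(spec)
    rng = _rng(seed)
    q = QTable(config, spec.q_init, share_stage1=share_stage1)
    two_forced = config.n_forced_actions == 2
    records: list[TrialRecord] = []

    for block in config.blocks:
        b = block.block_index
        for ti, option in enumerate(training_schedule(block, rng)):
            if option == FREE:
                action = _stage2_free_action(q, b, spec, params, rng)
            else:
                action = None  # mandated; uniform draw in exp3
            out = draw_outcome(block, option, action, rng,
                               two_forced_targets=two_forced)
            rec = TrialRecord(subject_id, config.experiment, b, TRAIN, ti,
                              option, False, out.action, out.displayed_target,
                              out.coherent, out.reward)
            step_trial(q, rec, spec, params, prev_stage1_choice=None)
            records.append(rec)

        prev_choice = None  # stickiness resets at the first test trial
        s1 = q.stage1_state(b)
        free_idx = q.actions(s1).index(FREE)
        for ti in range(block.n_test):
            p1 = action_probabilities(q, s1, prev_choice, 1, spec, params)
            option = FREE if rng.random() < p1[free_idx] else FORCED
            if option == FREE:
                action = _stage2_free_action(q, b, spec, params, rng)
            else:
                action = None
            out = draw_outcome(block, option, action, rng,
                               two_forced_targets=two_forced)
            rec = TrialRecord(subject_id, config.experiment, b, TEST, ti,
                              option, True, out.action, out.displayed_target,
                              out.coherent, out.reward)
            step_trial(q, rec, spec, params, prev_stage1_choice=prev_choice)
            records.append(rec)
            prev_choice = option
    return records


# ---------------------------------------------------------------------------
# Heuristic strategy agents (stay/switch rules over free trials)
# ---------------------------------------------------------------------------

def _strategy_says_stay(strategy: str, rewarded: bool, coherent: bool) -> bool:
    if strategy == "reward_based":
        return rewarded
    if strategy == "swap_avoidance":
        return coherent
    if strategy == "model_based":
        return rewarded == coherent
    if strategy == "control_maintenance":
        # outcomes from incoherent trials are ignored: always repeat;
        # coherent outcomes are used: stay iff rewarded
        return (not coherent) or rewarded
    raise ConfigurationError(f"unknown strategy {strategy!r}")


def simulate_strategy_subject(config: TaskConfig, strategy: str,
                              adherence: float = 1.0,
                              subject_id: str = "strat", seed=0,
                              p_free_stage1: float = DEFAULT_STRATEGY_P_FREE,
                              ) -> list[TrialRecord]:
    """Log of a value-free agent following a stay/switch rule at stage 2.

    On free trials with a preceding free trial in the same block, the
    agent repeats its previous emitted action with probability
    ``adherence`` when the strategy's rule says stay and ``1 - adherence``
    when it says switch (conditioning on the most recent free trial's
    reward and coherence); otherwise it chooses uniformly.  At stage 1 of
    test trials it picks free with fixed probability ``p_free_stage1``.
    """
    if strategy not in STRATEGIES:
        raise ConfigurationError(
            f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")
    if not 0.5 <= adherence <= 1.0:
        raise ConfigurationError("adherence must be in [0.5, 1]")
    rng = _rng(seed)
    two_forced = config.n_forced_actions == 2
    records: list[TrialRecord] = []

    for block in config.blocks:
        b = block.block_index
        last_free = None  # (action, rewarded, coherent) of most recent free trial

        def free_action() -> str:
            if last_free is None:
                return A1 if rng.random() < 0.5 else A2
            action, rewarded, coherent = last_free
            stay = _strategy_says_stay(strategy, rewarded, coherent)
            p_stay = adherence if stay else 1.0 - adherence
            if rng.random() < p_stay:
                return action
            return A2 if action == A1 else A1

        for ti, option in enumerate(training_schedule(block, rng)):
            action = free_action() if option == FREE else None
            out = draw_outcome(block, option, action, rng,
                               two_forced_targets=two_forced)
            records.append(TrialRecord(
                subject_id, config.experiment, b, TRAIN, ti, option, False,
                out.action, out.displayed_target, out.coherent, out.reward))
            if option == FREE:
                last_free = (out.action, bool(out.reward), out.coherent)

        for ti in range(block.n_test):
            option = FREE if rng.random() < p_free_stage1 else FORCED
            action = free_action() if option == FREE else None
            out = draw_outcome(block, option, action, rng,
                               two_forced_targets=two_forced)
            records.append(TrialRecord(
                subject_id, config.experiment, b, TEST, ti, option, True,
                out.action, out.displayed_target, out.coherent, out.reward))
            if option == FREE:
                last_free = (out.action, bool(out.reward), out.coherent)
    return records


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

def simulate_cohort(config: TaskConfig, spec: ModelSpec,
                    params: Params | None = None,
                    n_subjects: int = 10, seed: int = 0,
                    draw_from_priors: bool = False,
                    priors=None, share_stage1: bool = True,
                    clip_inv_tau: bool = True,
                    ) -> tuple[list[list[TrialRecord]], pd.DataFrame]:
    """Independent synthetic subjects with split sub-seeds.

    With ``draw_from_priors`` each subject's parameters are drawn from
    the fitting priors (1/tau clipped at its 99th prior percentile for
    identifiability when ``clip_inv_tau``); otherwise ``params`` is used
    for every subject.  Returns the logs and the generating-parameter
    table (one row per subject).
    """
    if n_subjects < 1:
        raise ConfigurationError("n_subjects must be >= 1")
    if not draw_from_priors and params is None:
        raise ConfigurationError("provide params or set draw_from_priors")
    if draw_from_priors and priors is None:
        from .fitting import PriorSet
        priors = PriorSet()
    children = np.random.SeedSequence(seed).spawn(n_subjects)
    logs, rows = [], []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        sid = f"sub{i:03d}"
        if draw_from_priors:
            p = priors.draw_params(spec, rng, clip_inv_tau=clip_inv_tau)
        else:
            p = params
        resolved = p.resolve(spec) if isinstance(p, Params) else p
        logs.append(simulate_subject(config, spec, resolved, sid, rng,
                                     share_stage1=share_stage1))
        rows.append({"subject_id": sid, **asdict(resolved)})
    return logs, pd.DataFrame(rows)
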