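"""Task structure for the two-stage free/forced choice paradigm.

Every trial has two stages.  At stage 1 the subject faces (training) or
chooses (test) one of two cues: the *free* cue, which leads to a terminal
state offering a self-determined choice between two fractal targets, or the
*forced* cue, whose terminal action is mandated by the computer.  Extrinsic
reward (0/1) follows the terminal action with a probability attached to the
displayed target.

Three experiments share this skeleton:

* Experiment 1 (variants 1a/1b) varies the overall reward probability P per
  block, with the best free target and the forced target equally rewarded
  (P and 1-P on the two free targets).
* Experiment 2 keeps the free targets at 0.75/0.25 and raises the forced
  probability across blocks (0.75, 0.85, 0.95), the equal-probability block
  always coming first.
* Experiment 3 fixes all probabilities at 0.75 and manipulates
  *incoherence*: with some probability the displayed target is swapped
  relative to the emitted action, for both the free and (now two-target)
  forced terminal states.  The no-swap block always comes first.

States are abstract: stage-1 actions are ``free``/``forced``; stage-2
actions are ``a1``/``a2``.  Screen side is not modelled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

FREE = "free"
FORCED = "forced"
A1 = "a1"
A2 = "a2"

EXPERIMENTS = ("exp1a", "exp1b", "exp2", "exp3")


class ConfigurationError(ValueError):
    """Invalid experiment name or malformed task configuration."""


@dataclass(frozen=True)
class BlockSpec:
    """Reward schedule and trial counts of one block.

    ``p_forced`` applies to every forced terminal target (one target in
    experiments 1-2, two in experiment 3).  ``incoherence`` is the
    probability that the displayed stage-2 target is swapped relative to
    the emitted action; it must be 0 outside experiment 3 and below 0.5 so
    coherent feedback remains the majority outcome.
    """

    block_index: int
    p_forced: float
    p_free_a1: float
    p_free_a2: float
    incoherence: float = 0.0
    n_train_free: int = 48
    n_train_forced: int = 48
    n_test: int = 48

    def __post_init__(self) -> None:
        for name in ("p_forced", "p_free_a1", "p_free_a2"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name}={p} outside [0, 1]")
        if not 0.0 <= self.incoherence < 0.5:
            raise ConfigurationError(
                f"incoherence={self.incoherence} outside [0, 0.5)")
        if self.n_train_free != self.n_train_forced:
            raise ConfigurationError(
                "training must expose free and forced options equally")

    def p_free(self, action: str) -> float:
        return self.p_free_a1 if action == A1 else self.p_free_a2


@dataclass(frozen=True)
class TaskConfig:
    """One experiment: an ordered list of blocks plus its ordering rule."""

    experiment: str
    blocks: tuple[BlockSpec, ...]
    seed: int = 0
    fixed_first_block: bool = False

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENTS:
            raise ConfigurationError(
                f"unknown experiment {self.experiment!r}; "
                f"expected one of {EXPERIMENTS}")

    @property
    def n_states(self) -> int:
        """6 states in experiments 1-2; the 7th (second forced terminal
        target) exists only in experiment 3."""
        return 7 if self.experiment == "exp3" else 6

    @property
    def n_forced_actions(self) -> int:
        return 2 if self.experiment == "exp3" else 1

    def to_dict(self) -> dict:
        return {
            "experiment": self.experiment,
            "seed": self.seed,
            "blocks": [
                {k: v for k, v in asdict(b).items() if k != "block_index"}
                for b in self.blocks
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TaskConfig":
        blocks = tuple(
            BlockSpec(block_index=i, **blk) for i, blk in enumerate(d["blocks"])
        )
        return cls(experiment=d["experiment"], blocks=blocks,
                   seed=int(d.get("seed", 0)))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "TaskConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _permute_blocks(blocks: list[BlockSpec], seed: int,
                    fixed_first: bool) -> tuple[BlockSpec, ...]:
    rng = np.random.default_rng(seed)
    if fixed_first:
        head, tail = blocks[:1], blocks[1:]
    else:
        head, tail = [], blocks
    order = rng.permutation(len(tail))
    return tuple(head + [tail[i] for i in order])


def build_config(experiment: str, seed: int = 0) -> TaskConfig:
    """Canonical published schedule for one experiment.

    Block *identity* (the set of reward schedules) is fixed; the order in
    which a subject experiences the non-fixed blocks is permuted by
    ``seed``.  Experiment 2 always starts with the equal-probability block
    (p_forced = 0.75) and experiment 3 with the fully coherent block.
    """
    if experiment == "exp1a":
        ps = [0.5, 0.75, 1.0]
        blocks = [
            BlockSpec(i, p_forced=p, p_free_a1=p, p_free_a2=round(1 - p, 2),
                      n_train_free=24 if p == 1.0 else 48,
                      n_train_forced=24 if p == 1.0 else 48,
                      n_test=48)
            for i, p in enumerate(ps)
        ]
        fixed_first = False
    elif experiment == "exp1b":
        ps = [0.5, 0.67, 0.83, 1.0]
        blocks = [
            BlockSpec(i, p_forced=p, p_free_a1=p, p_free_a2=round(1 - p, 2),
                      n_train_free=24 if p == 1.0 else 48,
                      n_train_forced=24 if p == 1.0 else 48,
                      n_test=48)
            for i, p in enumerate(ps)
        ]
        fixed_first = False
    elif experiment == "exp2":
        blocks = [
            BlockSpec(i, p_forced=pf, p_free_a1=0.75, p_free_a2=0.25,
                      n_train_free=40, n_train_forced=40, n_test=40)
            for i, pf in enumerate([0.75, 0.85, 0.95])
        ]
        fixed_first = True
    elif experiment == "exp3":
        blocks = [
            BlockSpec(i, p_forced=0.75, p_free_a1=0.75, p_free_a2=0.75,
                      incoherence=inc,
                      n_train_free=40, n_train_forced=40, n_test=40)
            for i, inc in enumerate([0.0, 0.15, 0.3])
        ]
        fixed_first = True
    else:
        raise ConfigurationError(
            f"unknown experiment {experiment!r}; expected one of {EXPERIMENTS}")
    ordered = _permute_blocks(blocks, seed, fixed_first)
    return TaskConfig(experiment=experiment, blocks=ordered, seed=seed,
                      fixed_first_block=fixed_first)


@dataclass(frozen=True)
class Outcome:
    """Result of one stage-2 action draw."""

    action: str           # action emitted by the subject
    displayed_target: str  # target shown after a possible swap
    coherent: bool
    reward: int


def draw_outcome(block: BlockSpec, option: str, action: str | None,
                 rng: np.random.Generator, *,
                 two_forced_targets: bool = False) -> Outcome:
    """Draw the displayed target and reward for one stage-2 action.

    For the forced option with two terminal targets (experiment 3) the
    mandated action is drawn uniformly when ``action`` is None.  With
    probability ``block.incoherence`` the displayed target is the
    non-emitted one and the trial is flagged incoherent.  Reward is
    Bernoulli with the probability attached to the *displayed* target.
    """
    if option == FORCED:
        if two_forced_targets:
            if action is None:
                action = A1 if rng.random() < 0.5 else A2
        else:
            if action is None:
                action = A1
            elif action != A1:
                raise ConfigurationError(
                    "forced option admits only a1 in experiments 1-2")
    elif action is None:
        raise ConfigurationError("free option requires an explicit action")

    swapped = block.incoherence > 0 and rng.random() < block.incoherence
    displayed = (A2 if action == A1 else A1) if swapped else action

    if option == FREE:
        p = block.p_free(displayed)
    else:
        p = block.p_forced
    reward = int(rng.random() < p)
    return Outcome(action=action, displayed_target=displayed,
                   coherent=not swapped, reward=reward)


def training_schedule(block: BlockSpec,
                      rng: np.random.Generator) -> list[str]:
    """Random interleaving of free- and forced-type training trials with
    equal counts per option."""
    options = [FREE] * block.n_train_free + [FORCED] * block.n_train_forced
    order = rng.permutation(len(options))
    return [options[i] for i in order]
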