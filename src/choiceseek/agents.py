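"""Temporal-difference RL model family for the two-stage task.

A trial is modelled as two chained state-action updates.  The prediction
error is

    delta_t = r_{t+1} + Z(s_{t+1}, a_{t+1}) - Q(s_t, a_t)

with reward delivered only after the terminal (stage-2) action, and the
future-value term Z taking one of three forms:

* ``sarsa``            -- Q(s', a'), the value of the action actually taken;
* ``q_learning``       -- max_a' Q(s', a');
* ``beta_pessimistic`` -- beta * max_a' Q(s', a') + (1 - beta) * min_a' Q(s', a'),
  a risk-sensitive mixture of the best and worst next action values that
  reduces to Q-learning at beta = 1.

Values are updated by Q <- Q + alpha * delta with separate (optional)
learning rates and softmax temperatures per stage.  Two further features
capture choice-seeking: a *free-choice bonus* rho added to every stage-2
outcome obtained through the free option (entering subsequent value
updates), and a *stickiness* kappa added to the stage-1 softmax utility of
repeating the previous trial's stage-1 selection.  A supplementary
alternative to the bonus is a *static bias* b on the free cue's stage-1
utility, which never enters value updates.

The factorial family (3 targets x bonus x 1/2 alpha x 1/2 tau x stickiness)
contains exactly 48 models; the static-bias variants sit outside it.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np

from .task import A1, A2, FREE, FORCED, TaskConfig

SARSA = "sarsa"
Q_LEARNING = "q_learning"
BETA_PESSIMISTIC = "beta_pessimistic"
TARGETS = (SARSA, Q_LEARNING, BETA_PESSIMISTIC)

_TARGET_SHORT = {SARSA: "sarsa", Q_LEARNING: "q", BETA_PESSIMISTIC: "pess"}
_SHORT_TARGET = {v: k for k, v in _TARGET_SHORT.items()}


class ParameterError(ValueError):
    """Parameter outside its admissible range."""


class ContractError(ValueError):
    """An operation was called outside its contract."""


# ---------------------------------------------------------------------------
# Model specification and parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    target: str = Q_LEARNING
    has_bonus: bool = False
    n_alpha: int = 1
    n_tau: int = 1
    has_stickiness: bool = False
    has_static_bias: bool = False
    q_init: float = 0.0

    def __post_init__(self) -> None:
        if self.target not in TARGETS:
            raise ParameterError(f"unknown target {self.target!r}")
        if self.n_alpha not in (1, 2) or self.n_tau not in (1, 2):
            raise ParameterError("n_alpha and n_tau must be 1 or 2")
        if self.q_init not in (0.0, 0.5):
            raise ParameterError("q_init must be 0 or 0.5")

    @property
    def free_param_names(self) -> tuple[str, ...]:
        names = ["alpha1"]
        if self.n_alpha == 2:
            names.append("alpha2")
        names.append("inv_tau1")
        if self.n_tau == 2:
            names.append("inv_tau2")
        if self.target == BETA_PESSIMISTIC:
            names.append("beta")
        if self.has_bonus:
            names.append("rho")
        if self.has_stickiness:
            names.append("kappa")
        if self.has_static_bias:
            names.append("bias")
        return tuple(names)

    @property
    def n_free_params(self) -> int:
        return len(self.free_param_names)

    @property
    def name(self) -> str:
        parts = [_TARGET_SHORT[self.target]]
        if self.has_bonus:
            parts.append("bonus")
        parts.append(f"{self.n_alpha}alpha")
        parts.append(f"{self.n_tau}tau")
        if self.has_stickiness:
            parts.append("sticky")
        if self.has_static_bias:
            parts.append("bias")
        qi = "0" if self.q_init == 0.0 else "0.5"
        return "+".join(parts) + f"@qinit{qi}"

    @classmethod
    def from_name(cls, name: str) -> "ModelSpec":
        body, _, qi = name.partition("@qinit")
        parts = body.split("+")
        target = _SHORT_TARGET[parts[0]]
        return cls(
            target=target,
            has_bonus="bonus" in parts[1:],
            n_alpha=2 if "2alpha" in parts else 1,
            n_tau=2 if "2tau" in parts else 1,
            has_stickiness="sticky" in parts,
            has_static_bias="bias" in parts,
            q_init=float(qi) if qi else 0.0,
        )

    def with_q_init(self, q_init: float) -> "ModelSpec":
        return replace(self, q_init=q_init)


def enumerate_family() -> list[ModelSpec]:
    """The full 48-model factorial family (static-bias variants excluded).

    Each spec is enumerated at q_init = 0; fitting evaluates both q_init
    hyperparameter values.
    """
    return [
        ModelSpec(target=t, has_bonus=b, n_alpha=na, n_tau=nt,
                  has_stickiness=st)
        for t, b, na, nt, st in itertools.product(
            TARGETS, (False, True), (1, 2), (1, 2), (False, True))
    ]


@dataclass(frozen=True)
class Params:
    """Numeric parameter vector.

    Units: Q-values and rho are in reward units (1 = one reward symbol);
    tau is a softmax temperature in the same units; kappa and bias are
    softmax utility increments.
    """

    alpha1: float = 0.5
    alpha2: float | None = None
    tau1: float = 0.5
    tau2: float | None = None
    beta: float = 1.0
    rho: float = 0.0
    kappa: float = 0.0
    bias: float = 0.0

    def resolve(self, spec: ModelSpec) -> "ResolvedParams":
        """Tie shared parameters and neutralise switched-off features."""
        alpha2 = self.alpha1 if spec.n_alpha == 1 else (
            self.alpha1 if self.alpha2 is None else self.alpha2)
        tau2 = self.tau1 if spec.n_tau == 1 else (
            self.tau1 if self.tau2 is None else self.tau2)
        rp = ResolvedParams(
            alpha1=self.alpha1,
            alpha2=alpha2,
            tau1=self.tau1,
            tau2=tau2,
            beta=self.beta if spec.target == BETA_PESSIMISTIC else 1.0,
            rho=self.rho if spec.has_bonus else 0.0,
            kappa=self.kappa if spec.has_stickiness else 0.0,
            bias=self.bias if spec.has_static_bias else 0.0,
        )
        rp.validate()
        return rp


@dataclass(frozen=True)
class ResolvedParams:
    alpha1: float
    alpha2: float
    tau1: float
    tau2: float
    beta: float
    rho: float
    kappa: float
    bias: float

    def validate(self) -> None:
        for name in ("alpha1", "alpha2"):
            a = getattr(self, name)
            if not 0.0 <= a <= 1.0:
                raise ParameterError(f"{name}={a} outside [0, 1]")
        for name in ("tau1", "tau2"):
            t = getattr(self, name)
            if not t > 0.0:
                raise ParameterError(f"{name}={t} must be positive")
        if not 0.0 <= self.beta <= 1.0:
            raise ParameterError(f"beta={self.beta} outside [0, 1]")


# ---------------------------------------------------------------------------
# Value table
# ---------------------------------------------------------------------------

STAGE1 = "stage1"


class QTable:
    """Look-up table of state-action values for one subject.

    Stage-2 states are per block (fractal targets are unique per block);
    the stage-1 cue values are shared across blocks by default (the same
    coloured cues are reused), switchable via ``share_stage1``.
    """

    def __init__(self, config: TaskConfig, q_init: float = 0.0,
                 share_stage1: bool = True):
        self.config = config
        self.share_stage1 = share_stage1
        self._actions: dict[object, tuple[str, ...]] = {}
        self._q: dict[tuple[object, str], float] = {}
        forced_actions = (A1, A2) if config.n_forced_actions == 2 else (A1,)
        if share_stage1:
            self._actions[STAGE1] = (FREE, FORCED)
        for b in config.blocks:
            i = b.block_index
            if not share_stage1:
                self._actions[(STAGE1, i)] = (FREE, FORCED)
            self._actions[(FREE, i)] = (A1, A2)
            self._actions[(FORCED, i)] = forced_actions
        for s, acts in self._actions.items():
            for a in acts:
                self._q[(s, a)] = q_init

    def stage1_state(self, block_index: int):
        return STAGE1 if self.share_stage1 else (STAGE1, block_index)

    def actions(self, state) -> tuple[str, ...]:
        try:
            return self._actions[state]
        except KeyError:
            raise ContractError(f"unknown state {state!r}") from None

    def __getitem__(self, key: tuple[object, str]) -> float:
        try:
            return self._q[key]
        except KeyError:
            raise ContractError(f"unknown state-action {key!r}") from None

    def __setitem__(self, key: tuple[object, str], value: float) -> None:
        if key not in self._q:
            raise ContractError(f"unknown state-action {key!r}")
        self._q[key] = value

    def values_at(self, state) -> list[float]:
        return [self._q[(state, a)] for a in self.actions(state)]

    def copy(self) -> "QTable":
        new = object.__new__(QTable)
        new.config = self.config
        new.share_stage1 = self.share_stage1
        new._actions = self._actions
        new._q = dict(self._q)
        return new


# ---------------------------------------------------------------------------
# Core operations
# ---------------------------------------------------------------------------

def future_value(target: str, q: QTable, next_state, next_action: str | None,
                 beta: float = 1.0) -> float:
    """Z(s', a'): the future-value term of the prediction error.

    Returns 0 when ``next_state`` is None (end of trial: no further value).
    """
    if next_state is None:
        return 0.0
    if target == SARSA:
        if next_action is None:
            raise ContractError("sarsa requires the next action")
        return q[(next_state, next_action)]
    vals = q.values_at(next_state)
    if target == Q_LEARNING:
        return max(vals)
    if target == BETA_PESSIMISTIC:
        return beta * max(vals) + (1.0 - beta) * min(vals)
    raise ParameterError(f"unknown target {target!r}")


def effective_reward(extrinsic: float, option: str, rho: float) -> float:
    """r + rho on free-option outcomes (rewarded or not), r otherwise."""
    return extrinsic + rho if option == FREE else float(extrinsic)


def prediction_error(q: QTable, s, a: str, r_effective: float,
                     next_state, next_action: str | None,
                     spec: ModelSpec, params: ResolvedParams) -> float:
    """delta = r_eff + Z(s', a') - Q(s, a)."""
    z = future_value(spec.target, q, next_state, next_action, params.beta)
    return r_effective + z - q[(s, a)]


def apply_update(q: QTable, s, a: str, delta: float, alpha: float) -> QTable:
    """Q(s, a) <- Q(s, a) + alpha * delta, in place; returns the table."""
    if not 0.0 <= alpha <= 1.0:
        raise ParameterError(f"alpha={alpha} outside [0, 1]")
    q[(s, a)] = q[(s, a)] + alpha * delta
    return q


def softmax_pair(u1: float, u2: float, tau: float) -> np.ndarray:
    if not tau > 0.0:
        raise ParameterError(f"tau={tau} must be positive")
    # max-stabilised two-point softmax
    m = max(u1, u2)
    e1 = math.exp((u1 - m) / tau)
    e2 = math.exp((u2 - m) / tau)
    z = e1 + e2
    return np.array([e1 / z, e2 / z])


def action_probabilities(q: QTable, s, prev_stage1_choice: str | None,
                         stage: int, spec: ModelSpec,
                         params: ResolvedParams) -> np.ndarray:
    """Softmax policy over the two actions available in ``s``.

    At stage 1 the utilities include the stickiness increment kappa for
    repeating the previous trial's stage-1 choice (0 on the first test
    trial of a block) and, for static-bias variants, the constant b on
    the free cue.
    """
    acts = q.actions(s)
    if len(acts) != 2:
        raise ContractError(f"state {s!r} does not offer a choice")
    tau = params.tau1 if stage == 1 else params.tau2
    us = []
    for a in acts:
        u = q[(s, a)]
        if stage == 1:
            if prev_stage1_choice is not None and a == prev_stage1_choice:
                u += params.kappa
            if spec.has_static_bias and a == FREE:
                u += params.bias
        us.append(u)
    return softmax_pair(us[0], us[1], tau)


def step_trial(q: QTable, trial, spec: ModelSpec, params: ResolvedParams,
               prev_stage1_choice: str | None = None) -> dict[str, float]:
    """Replay one trial against the table, in place.

    Emits the policy probability of each modelled free decision (stage-1
    choice in test; stage-2 choice on free-type trials in both phases)
    computed from pre-update values, then applies the stage-1 backup
    (using pre-update stage-2 values) followed by the stage-2 update with
    the effective reward.  Forced key presses contribute no probability
    but still drive updates.  On incoherent trials the stage-2 update
    credits the *emitted* action with the reward as delivered.

    Returns a dict with keys among {"stage1", "stage2"} mapping to the
    probability of the decision actually taken.
    """
    option = trial.stage1_option
    block = trial.block_index
    s1 = q.stage1_state(block)
    s2 = (option, block)
    action = trial.stage2_action
    probs: dict[str, float] = {}

    if trial.stage1_is_choice:
        p1 = action_probabilities(q, s1, prev_stage1_choice, 1, spec, params)
        probs["stage1"] = float(p1[q.actions(s1).index(option)])
    if option == FREE:
        p2 = action_probabilities(q, s2, None, 2, spec, params)
        probs["stage2"] = float(p2[q.actions(s2).index(action)])

    # stage-1 backup from pre-update stage-2 values (one-step, no reward yet)
    d1 = prediction_error(q, s1, option, 0.0, s2, action, spec, params)
    apply_update(q, s1, option, d1, params.alpha1)

    # stage-2 outcome update; terminal, so Z = 0
    r_eff = effective_reward(trial.reward, option, params.rho)
    d2 = prediction_error(q, s2, action, r_eff, None, None, spec, params)
    apply_update(q, s2, action, d2, params.alpha2)
    return probs
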