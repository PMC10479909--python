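"""Trial-level likelihood and MAP estimation.

A single parameter set is fit to one subject's complete log: every block's
training phase followed by its test phase, with learned values carried
from training into test.  The modelled decisions are

* the stage-2 choice on every free-type trial (training and test), and
* the stage-1 free/forced choice on every test trial;

forced key presses are mandated and contribute no likelihood term (but
still drive value updates).  The log-likelihood is the sum of log softmax
probabilities of those decisions under an exact replay of the agent's
update equations.

Estimation is maximum a posteriori: L-BFGS-B on the penalised
log-likelihood, optimising on the inverse-temperature scale (1/tau bounded
below at 0; alpha and beta in [0, 1]; rho, kappa, bias unbounded), with
restarts drawn from the priors

    alpha  ~ Beta(1.1, 1.1)       1/tau ~ Gamma(shape=1.2, scale=5)
    beta   ~ Beta(1.1, 1.1)       rho, kappa, bias ~ Normal(0, 1)

The BIC reported for model comparison is k * ln(n_obs) - 2 * logL at the
MAP estimate, with n_obs the number of modelled decisions.

The replay core is compiled with numba; the heavy loops run over integer
per-trial arrays encoded once per subject.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats

from .task import FREE, TaskConfig
from .agents import (BETA_PESSIMISTIC, Q_LEARNING, SARSA, ModelSpec, Params,
                     ResolvedParams)
from .simulate import TrialRecord, records_to_frame

try:
    from numba import njit
except ImportError:  # pragma: no cover - numba is a hard dependency
    def njit(*args, **kwargs):
        def wrap(f):
            return f
        return wrap if not (args and callable(args[0])) else args[0]


class DataError(ValueError):
    """Malformed or degenerate trial log."""


class FitError(RuntimeError):
    """No optimizer restart converged."""


# ---------------------------------------------------------------------------
# Log encoding
# ---------------------------------------------------------------------------

_TARGET_CODE = {SARSA: 0, Q_LEARNING: 1, BETA_PESSIMISTIC: 2}


@dataclass(frozen=True)
class EncodedLog:
    """One subject's log as flat per-trial arrays (chronological order)."""

    block: np.ndarray     # int64, block_index
    phase: np.ndarray     # int64, 0 train / 1 test
    option: np.ndarray    # int64, 0 free / 1 forced
    action: np.ndarray    # int64, emitted stage-2 action, 0 = a1
    reward: np.ndarray    # float64
    n_blocks: int
    n_forced_actions: int

    @property
    def n_trials(self) -> int:
        return int(self.block.shape[0])

    @property
    def n_obs(self) -> int:
        """Count of modelled decisions: free stage-2 + test stage-1."""
        return int((self.option == 0).sum() + (self.phase == 1).sum())


def encode_log(log, config: TaskConfig) -> EncodedLog:
    """Validate and flatten a trial log (records or DataFrame)."""
    if isinstance(log, pd.DataFrame):
        df = log
    else:
        df = records_to_frame(list(log))
    if len(df) == 0:
        raise DataError("empty trial log")
    block = df["block_index"].to_numpy(dtype=np.int64)
    known = {b.block_index for b in config.blocks}
    bad = set(np.unique(block)) - known
    if bad:
        raise DataError(f"log references unknown blocks {sorted(bad)}")
    phase = (df["phase"].to_numpy() == "test").astype(np.int64)
    option = (df["stage1_option"].to_numpy() == "forced").astype(np.int64)
    action = (df["stage2_action"].to_numpy() == "a2").astype(np.int64)
    reward = df["reward"].to_numpy(dtype=np.float64)
    n_blocks = max(known) + 1
    return EncodedLog(block, phase, option, action, reward,
                      n_blocks, config.n_forced_actions)


# ---------------------------------------------------------------------------
# Replay core
# ---------------------------------------------------------------------------

@njit(cache=False)
def _log_sigmoid(d):
    # log(1 / (1 + exp(-d))), overflow-safe
    if d < -35.0:
        return d
    return -math.log1p(math.exp(-d))


@njit(cache=False)
def _replay(block, phase, option, action, reward,
            n_blocks, n_forced, target, q_init, share_stage1,
            alpha1, alpha2, it1, it2, beta, rho, kappa, bias,
            logp1, logp2):
    """Replay one subject's log; fills per-trial decision log-probabilities
    (NaN where the decision is not modelled) and returns (logL, n_obs)."""
    n1 = 1 if share_stage1 else n_blocks
    q1 = np.full((n1, 2), q_init)          # [:, 0]=free cue, [:, 1]=forced cue
    q2f = np.full((n_blocks, 2), q_init)   # free terminal targets
    q2F = np.full((n_blocks, 2), q_init)   # forced terminal target(s)
    loglik = 0.0
    n_obs = 0
    prev_choice = -1
    prev_block = -1
    prev_phase = -1
    for t in range(block.shape[0]):
        b = block[t]
        ph = phase[t]
        op = option[t]
        a = action[t]
        if b != prev_block or ph != prev_phase:
            prev_choice = -1  # no previous stage-1 choice at block start
            prev_block = b
            prev_phase = ph
        bi = 0 if share_stage1 else b

        if op == 0:
            v0 = q2f[b, 0]
            v1 = q2f[b, 1]
        else:
            v0 = q2F[b, 0]
            v1 = q2F[b, 1] if n_forced == 2 else v0

        if ph == 1:
            u_free = q1[bi, 0] + bias
            u_forced = q1[bi, 1]
            if prev_choice == 0:
                u_free += kappa
            elif prev_choice == 1:
                u_forced += kappa
            d1 = (u_free - u_forced) * it1
            lp = _log_sigmoid(d1) if op == 0 else _log_sigmoid(-d1)
            logp1[t] = lp
            loglik += lp
            n_obs += 1
            prev_choice = op

        if op == 0:
            d2 = (v0 - v1) * it2
            lp = _log_sigmoid(d2) if a == 0 else _log_sigmoid(-d2)
            logp2[t] = lp
            loglik += lp
            n_obs += 1

        # future value of the visited terminal state (pre-update)
        if op == 1 and n_forced == 1:
            z = v0
        else:
            va = v0 if a == 0 else v1
            if target == 0:      # sarsa
                z = va
            else:
                mx = v0 if v0 >= v1 else v1
                mn = v1 if v0 >= v1 else v0
                if target == 1:  # q-learning
                    z = mx
                else:            # beta-pessimistic
                    z = beta * mx + (1.0 - beta) * mn

        q1[bi, op] += alpha1 * (z - q1[bi, op])

        r_eff = reward[t] + rho if op == 0 else reward[t]
        if op == 0:
            q2f[b, a] += alpha2 * (r_eff - q2f[b, a])
        else:
            q2F[b, a] += alpha2 * (r_eff - q2F[b, a])
    return loglik, n_obs


def _run_replay(enc: EncodedLog, spec: ModelSpec, rp: ResolvedParams,
                share_stage1: bool):
    logp1 = np.full(enc.n_trials, np.nan)
    logp2 = np.full(enc.n_trials, np.nan)
    loglik, n_obs = _replay(
        enc.block, enc.phase, enc.option, enc.action, enc.reward,
        enc.n_blocks, enc.n_forced_actions, _TARGET_CODE[spec.target],
        spec.q_init, share_stage1,
        rp.alpha1, rp.alpha2, 1.0 / rp.tau1, 1.0 / rp.tau2,
        rp.beta, rp.rho, rp.kappa, rp.bias, logp1, logp2)
    return loglik, n_obs, logp1, logp2


def log_likelihood(log, spec: ModelSpec, params: Params | ResolvedParams,
                   config: TaskConfig,
                   share_stage1: bool = True) -> tuple[float, int]:
    """Summed log-probability of all modelled decisions, and their count."""
    rp = params.resolve(spec) if isinstance(params, Params) else params
    enc = log if isinstance(log, EncodedLog) else encode_log(log, config)
    loglik, n_obs, _, _ = _run_replay(enc, spec, rp, share_stage1)
    return float(loglik), int(n_obs)


def decision_log_probabilities(log, spec, params, config,
                               share_stage1: bool = True):
    """Per-trial (stage-1, stage-2) decision log-probabilities; NaN where
    a decision is not modelled (training stage 1, forced stage 2)."""
    rp = params.resolve(spec) if isinstance(params, Params) else params
    enc = log if isinstance(log, EncodedLog) else encode_log(log, config)
    _, _, logp1, logp2 = _run_replay(enc, spec, rp, share_stage1)
    return logp1, logp2


# ---------------------------------------------------------------------------
# Priors
# ---------------------------------------------------------------------------

_LN_2PI = math.log(2.0 * math.pi)


def _log_beta_pdf(x: float, a: float, b: float) -> float:
    if x <= 0.0 or x >= 1.0:
        return -math.inf
    lnB = math.lgamma(a) + math.lgamma(b) - math.lgamma(a + b)
    return (a - 1.0) * math.log(x) + (b - 1.0) * math.log1p(-x) - lnB


def _log_gamma_pdf(x: float, shape: float, scale: float) -> float:
    if x <= 0.0:
        return -math.inf
    return ((shape - 1.0) * math.log(x) - x / scale
            - math.lgamma(shape) - shape * math.log(scale))


def _log_normal_pdf(x: float, sd: float) -> float:
    return -0.5 * (x / sd) ** 2 - math.log(sd) - 0.5 * _LN_2PI


@dataclass(frozen=True)
class PriorSet:
    """Independent priors over the free parameters (on the fitting scale:
    temperatures are parameterised as inverse temperatures)."""

    alpha_shape1: float = 1.1
    alpha_shape2: float = 1.1
    inv_tau_shape: float = 1.2
    inv_tau_scale: float = 5.0
    beta_shape1: float = 1.1
    beta_shape2: float = 1.1
    rho_sd: float = 1.0
    kappa_sd: float = 1.0
    bias_sd: float = 1.0

    def log_prior_one(self, name: str, value: float) -> float:
        if name in ("alpha1", "alpha2"):
            return _log_beta_pdf(value, self.alpha_shape1, self.alpha_shape2)
        if name in ("inv_tau1", "inv_tau2"):
            return _log_gamma_pdf(value, self.inv_tau_shape,
                                  self.inv_tau_scale)
        if name == "beta":
            return _log_beta_pdf(value, self.beta_shape1, self.beta_shape2)
        if name == "rho":
            return _log_normal_pdf(value, self.rho_sd)
        if name == "kappa":
            return _log_normal_pdf(value, self.kappa_sd)
        if name == "bias":
            return _log_normal_pdf(value, self.bias_sd)
        raise KeyError(name)

    def log_prior(self, spec: ModelSpec, x: np.ndarray) -> float:
        """Sum of log prior densities over the spec's free parameters."""
        total = 0.0
        for name, v in zip(spec.free_param_names, x):
            total += self.log_prior_one(name, float(v))
        return total

    def draw_one(self, name: str, rng: np.random.Generator) -> float:
        if name in ("alpha1", "alpha2"):
            return float(rng.beta(self.alpha_shape1, self.alpha_shape2))
        if name in ("inv_tau1", "inv_tau2"):
            return float(rng.gamma(self.inv_tau_shape, self.inv_tau_scale))
        if name == "beta":
            return float(rng.beta(self.beta_shape1, self.beta_shape2))
        if name == "rho":
            return float(rng.normal(0.0, self.rho_sd))
        if name == "kappa":
            return float(rng.normal(0.0, self.kappa_sd))
        if name == "bias":
            return float(rng.normal(0.0, self.bias_sd))
        raise KeyError(name)

    def draw_vector(self, spec: ModelSpec,
                    rng: np.random.Generator) -> np.ndarray:
        return np.array([self.draw_one(n, rng)
                         for n in spec.free_param_names])

    def inv_tau_cap(self, q: float = 0.99) -> float:
        return float(scipy.stats.gamma.ppf(q, self.inv_tau_shape,
                                           scale=self.inv_tau_scale))

    def draw_params(self, spec: ModelSpec, rng: np.random.Generator,
                    clip_inv_tau: bool = True) -> Params:
        """Draw a generating Params from the priors (for simulation)."""
        x = self.draw_vector(spec, rng)
        if clip_inv_tau:
            cap = self.inv_tau_cap()
            for i, n in enumerate(spec.free_param_names):
                if n.startswith("inv_tau"):
                    x[i] = min(max(x[i], 1e-3), cap)
        return vector_to_params(spec, x)


def vector_to_params(spec: ModelSpec, x: np.ndarray) -> Params:
    d = dict(zip(spec.free_param_names, (float(v) for v in x)))
    return Params(
        alpha1=d["alpha1"],
        alpha2=d.get("alpha2"),
        tau1=1.0 / d["inv_tau1"] if d["inv_tau1"] > 0 else math.inf,
        tau2=(1.0 / d["inv_tau2"] if d["inv_tau2"] > 0 else math.inf)
        if "inv_tau2" in d else None,
        beta=d.get("beta", 1.0),
        rho=d.get("rho", 0.0),
        kappa=d.get("kappa", 0.0),
        bias=d.get("bias", 0.0),
    )


def _vector_to_core_args(spec: ModelSpec, x: np.ndarray):
    d = dict(zip(spec.free_param_names, (float(v) for v in x)))
    alpha1 = d["alpha1"]
    alpha2 = d.get("alpha2", alpha1)
    it1 = d["inv_tau1"]
    it2 = d.get("inv_tau2", it1)
    return (alpha1, alpha2, it1, it2, d.get("beta", 1.0),
            d.get("rho", 0.0), d.get("kappa", 0.0), d.get("bias", 0.0))


def params_to_vector(spec: ModelSpec, params: Params) -> np.ndarray:
    rp = params.resolve(spec) if isinstance(params, Params) else params
    full = {"alpha1": rp.alpha1, "alpha2": rp.alpha2,
            "inv_tau1": 1.0 / rp.tau1, "inv_tau2": 1.0 / rp.tau2,
            "beta": rp.beta, "rho": rp.rho, "kappa": rp.kappa,
            "bias": rp.bias}
    return np.array([full[n] for n in spec.free_param_names])


def log_posterior(log, spec: ModelSpec, params: Params | ResolvedParams,
                  priors: PriorSet, config: TaskConfig,
                  share_stage1: bool = True) -> float:
    """log-likelihood plus log prior density of the spec's free parameters
    (the temperature prior evaluated on the 1/tau scale)."""
    ll, _ = log_likelihood(log, spec, params, config, share_stage1)
    if isinstance(params, ResolvedParams):
        x = params_to_vector(spec, params)
    else:
        x = params_to_vector(spec, params.resolve(spec))
    return ll + priors.log_prior(spec, x)


# ---------------------------------------------------------------------------
# MAP estimation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FitResult:
    spec: ModelSpec
    params_hat: Params
    log_likelihood: float
    log_posterior: float
    n_obs: int
    n_params: int
    bic: float
    n_restarts_converged: int
    subject_id: str = ""

    def to_row(self) -> dict:
        rp = self.params_hat.resolve(self.spec)
        row = {"subject_id": self.subject_id, "spec": self.spec.name,
               "q_init": self.spec.q_init}
        free = set(self.spec.free_param_names)
        for name, val in asdict(rp).items():
            key = {"tau1": "inv_tau1", "tau2": "inv_tau2"}.get(name, name)
            row[name] = val if (key in free or name in free) else None
        row.update(log_lik=self.log_likelihood, log_post=self.log_posterior,
                   n_obs=self.n_obs, bic=self.bic)
        return row


def _bounds_for(spec: ModelSpec) -> list[tuple]:
    bounds = []
    for name in spec.free_param_names:
        if name in ("alpha1", "alpha2", "beta"):
            bounds.append((0.0, 1.0))
        elif name.startswith("inv_tau"):
            bounds.append((0.0, None))
        else:
            bounds.append((None, None))
    return bounds


def fit_map(log, spec: ModelSpec, priors: PriorSet | None = None,
            config: TaskConfig | None = None, n_restarts: int = 10,
            seed: int = 0, share_stage1: bool = True,
            subject_id: str = "") -> FitResult:
    """Bounded multi-start MAP fit of one spec to one subject's log.

    Starts are drawn from the priors; the best restart that the optimizer
    reports as converged wins.  Deterministic given the seed.
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    if priors is None:
        priors = PriorSet()
    if config is None:
        raise ValueError("config is required")
    enc = log if isinstance(log, EncodedLog) else encode_log(log, config)
    if enc.n_obs == 0:
        raise DataError("log contains no modelled decisions")
    target = _TARGET_CODE[spec.target]
    logp1 = np.full(enc.n_trials, np.nan)
    logp2 = np.full(enc.n_trials, np.nan)

    def neg_log_post(x: np.ndarray) -> float:
        lp = priors.log_prior(spec, x)
        if not math.isfinite(lp):
            return 1e12
        core = _vector_to_core_args(spec, x)
        ll, _ = _replay(enc.block, enc.phase, enc.option, enc.action,
                        enc.reward, enc.n_blocks, enc.n_forced_actions,
                        target, spec.q_init, share_stage1, *core,
                        logp1, logp2)
        val = ll + lp
        return -val if math.isfinite(val) else 1e12

    rng = np.random.default_rng(seed)
    bounds = _bounds_for(spec)
    best = None
    n_converged = 0
    messages = []
    for _ in range(n_restarts):
        x0 = priors.draw_vector(spec, rng)
        res = scipy.optimize.minimize(neg_log_post, x0, method="L-BFGS-B",
                                      bounds=bounds)
        if res.success:
            n_converged += 1
            if best is None or res.fun < best.fun:
                best = res
        else:
            messages.append(str(res.message))
    if best is None:
        raise FitError(
            f"all {n_restarts} restarts failed for {spec.name}: "
            f"{messages[:3]}")
    if n_converged < n_restarts:
        warnings.warn(
            f"{n_restarts - n_converged}/{n_restarts} restarts did not "
            f"converge for {spec.name}", RuntimeWarning, stacklevel=2)

    x_hat = best.x
    params_hat = vector_to_params(spec, x_hat)
    core = _vector_to_core_args(spec, x_hat)
    ll, n_obs = _replay(enc.block, enc.phase, enc.option, enc.action,
                        enc.reward, enc.n_blocks, enc.n_forced_actions,
                        target, spec.q_init, share_stage1, *core,
                        logp1, logp2)
    k = spec.n_free_params
    bic = k * math.log(n_obs) - 2.0 * ll
    return FitResult(spec=spec, params_hat=params_hat,
                     log_likelihood=float(ll),
                     log_posterior=float(-best.fun), n_obs=int(n_obs),
                     n_params=k, bic=float(bic),
                     n_restarts_converged=n_converged,
                     subject_id=subject_id)


def fits_to_frame(fits: list[FitResult]) -> pd.DataFrame:
    return pd.DataFrame([f.to_row() for f in fits])
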