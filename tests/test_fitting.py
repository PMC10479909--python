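"""Likelihood replay, priors, and MAP estimation."""

import math

import numpy as np
import pytest
import scipy.stats

import choiceseek as cs
from choiceseek.fitting import DataError, params_to_vector
from conftest import random_trial_log


# ---------------------------------------------------------------------------
# Independent straight-line likelihood oracle (dict-based, no shared code
# with the fitting module's array replay)
# ---------------------------------------------------------------------------

def oracle_log_likelihood(records, spec, params, config, share_stage1=True):
    rp = params.resolve(spec) if isinstance(params, cs.Params) else params
    nf = config.n_forced_actions
    q = {}
    for b in config.blocks:
        i = b.block_index
        key1 = "s1" if share_stage1 else ("s1", i)
        q.setdefault((key1, "free"), spec.q_init)
        q.setdefault((key1, "forced"), spec.q_init)
        q[("free", i, "a1")] = spec.q_init
        q[("free", i, "a2")] = spec.q_init
        q[("forced", i, "a1")] = spec.q_init
        if nf == 2:
            q[("forced", i, "a2")] = spec.q_init

    def soft(u_chosen, u_other, tau):
        return math.exp(u_chosen / tau) / (
            math.exp(u_chosen / tau) + math.exp(u_other / tau))

    total = 0.0
    n_obs = 0
    prev_choice = None
    prev_ctx = None
    for r in records:
        b = r.block_index
        if (b, r.phase) != prev_ctx:
            prev_choice = None
            prev_ctx = (b, r.phase)
        key1 = "s1" if share_stage1 else ("s1", b)
        opt = r.stage1_option
        act = r.stage2_action
        if r.phase == "test":
            u = {}
            for o in ("free", "forced"):
                u[o] = q[(key1, o)]
                if prev_choice == o:
                    u[o] += rp.kappa
                if o == "free":
                    u[o] += rp.bias
            other = "forced" if opt == "free" else "free"
            total += math.log(soft(u[opt], u[other], rp.tau1))
            n_obs += 1
            prev_choice = opt
        if opt == "free":
            other = "a2" if act == "a1" else "a1"
            total += math.log(soft(q[("free", b, act)],
                                   q[("free", b, other)], rp.tau2))
            n_obs += 1
        # future value of the visited stage-2 state, pre-update
        if opt == "forced" and nf == 1:
            z = q[("forced", b, "a1")]
        else:
            vals = [q[(opt, b, "a1")], q[(opt, b, "a2")]]
            if spec.target == "sarsa":
                z = q[(opt, b, act)]
            elif spec.target == "q_learning":
                z = max(vals)
            else:
                z = rp.beta * max(vals) + (1 - rp.beta) * min(vals)
        q[(key1, opt)] += rp.alpha1 * (z - q[(key1, opt)])
        r_eff = r.reward + rp.rho if opt == "free" else r.reward
        q[(opt, b, act)] += rp.alpha2 * (r_eff - q[(opt, b, act)])
    return total, n_obs


ORACLE_SPECS = [
    cs.ModelSpec(target="sarsa"),
    cs.ModelSpec(target="q_learning", has_bonus=True, n_alpha=2),
    cs.ModelSpec(target="beta_pessimistic", n_tau=2, has_stickiness=True),
    cs.ModelSpec(target="beta_pessimistic", has_bonus=True,
                 has_stickiness=True, has_static_bias=True, q_init=0.5),
]


@pytest.mark.parametrize("spec", ORACLE_SPECS, ids=lambda s: s.name)
@pytest.mark.parametrize("experiment", ["exp1a", "exp3"])
def test_likelihood_matches_oracle_on_random_logs(spec, experiment):
    config = cs.build_config(experiment, seed=0)
    rng = np.random.default_rng(42)
    params = cs.Params(alpha1=0.7, alpha2=0.3, tau1=0.4, tau2=0.8,
                       beta=0.25, rho=0.6, kappa=-0.4, bias=0.3)
    for rep in range(10):
        log = random_trial_log(config, n_trials=5, rng=rng)
        ll, n = cs.log_likelihood(log, spec, params, config)
        oll, on = oracle_log_likelihood(log, spec, params, config)
        assert n == on
        assert ll == pytest.approx(oll, abs=1e-12)


def test_likelihood_matches_oracle_on_full_simulated_log(
        exp1a, q_bonus_spec, moderate_params, small_log):
    ll, n = cs.log_likelihood(small_log, q_bonus_spec, moderate_params,
                              exp1a)
    oll, on = oracle_log_likelihood(small_log, q_bonus_spec,
                                    moderate_params, exp1a)
    assert n == on
    assert ll == pytest.approx(oll, abs=1e-10)


def test_simulation_and_likelihood_paths_agree(exp1a, q_bonus_spec,
                                               moderate_params, small_log):
    """The per-trial probabilities emitted while simulating (Python path)
    equal the likelihood replay's (compiled path)."""
    from choiceseek.fitting import decision_log_probabilities
    rp = moderate_params.resolve(q_bonus_spec)
    q = cs.QTable(exp1a, q_bonus_spec.q_init)
    logp1, logp2 = decision_log_probabilities(small_log, q_bonus_spec,
                                              moderate_params, exp1a)
    prev_choice = None
    prev_ctx = None
    for t, r in enumerate(small_log):
        if (r.block_index, r.phase) != prev_ctx:
            prev_choice = None
            prev_ctx = (r.block_index, r.phase)
        probs = cs.step_trial(q, r, q_bonus_spec, rp,
                              prev_stage1_choice=prev_choice)
        if "stage1" in probs:
            assert math.log(probs["stage1"]) == pytest.approx(
                logp1[t], abs=1e-10)
        else:
            assert np.isnan(logp1[t])
        if "stage2" in probs:
            assert math.log(probs["stage2"]) == pytest.approx(
                logp2[t], abs=1e-10)
        if r.phase == "test":
            prev_choice = r.stage1_option


def test_flat_policy_limit(exp1a, q_bonus_spec, small_log):
    """tau -> infinity: every modelled decision has probability 1/2."""
    params = cs.Params(alpha1=0.5, tau1=1e12, rho=0.5)
    ll, n = cs.log_likelihood(small_log, q_bonus_spec, params, exp1a)
    assert ll == pytest.approx(n * math.log(0.5), rel=1e-9)


def test_beta_one_pessimist_reproduces_q_learning(exp1a, moderate_params,
                                                  small_log):
    q_spec = cs.ModelSpec(target="q_learning", has_bonus=True)
    p_spec = cs.ModelSpec(target="beta_pessimistic", has_bonus=True)
    p1 = cs.Params(alpha1=0.5, tau1=0.3, rho=0.5, beta=1.0)
    ll_q, _ = cs.log_likelihood(small_log, q_spec, moderate_params, exp1a)
    ll_p, _ = cs.log_likelihood(small_log, p_spec, p1, exp1a)
    assert ll_p == pytest.approx(ll_q, abs=1e-12)


class TestPriors:
    def test_alpha_prior_closed_form(self):
        pr = cs.PriorSet()
        expected = scipy.stats.beta.logpdf(0.5, 1.1, 1.1)
        assert pr.log_prior_one("alpha1", 0.5) == pytest.approx(expected,
                                                                abs=1e-12)

    def test_inv_tau_prior_closed_form(self):
        pr = cs.PriorSet()
        expected = scipy.stats.gamma.logpdf(2.0, 1.2, scale=5.0)
        assert pr.log_prior_one("inv_tau1", 2.0) == pytest.approx(
            expected, abs=1e-12)

    def test_rho_prior_at_zero(self):
        pr = cs.PriorSet()
        assert pr.log_prior_one("rho", 0.0) == pytest.approx(
            -0.5 * math.log(2 * math.pi), abs=1e-12)

    def test_outside_support_is_minus_infinity(self):
        pr = cs.PriorSet()
        assert pr.log_prior_one("alpha1", -0.1) == -math.inf
        assert pr.log_prior_one("inv_tau1", 0.0) == -math.inf

    def test_log_posterior_adds_only_free_parameter_priors(
            self, exp1a, small_log):
        spec = cs.ModelSpec(target="q_learning")  # free: alpha1, inv_tau1
        pr = cs.PriorSet()
        params = cs.Params(alpha1=0.4, tau1=0.5)
        ll, _ = cs.log_likelihood(small_log, spec, params, exp1a)
        lp = cs.log_posterior(small_log, spec, params, pr, exp1a)
        expected = (ll + pr.log_prior_one("alpha1", 0.4)
                    + pr.log_prior_one("inv_tau1", 2.0))
        assert lp == pytest.approx(expected, abs=1e-10)


class TestFitMap:
    def test_fit_deterministic(self, exp1a, q_bonus_spec, moderate_params,
                               small_log):
        kw = dict(priors=cs.PriorSet(), config=exp1a, n_restarts=3, seed=7)
        f1 = cs.fit_map(small_log, q_bonus_spec, **kw)
        f2 = cs.fit_map(small_log, q_bonus_spec, **kw)
        assert f1 == f2

    def test_n_obs_counts_modelled_decisions(self, exp1a, q_bonus_spec,
                                             moderate_params, small_log):
        _, n = cs.log_likelihood(small_log, q_bonus_spec, moderate_params,
                                 exp1a)
        expected = (sum(r.stage1_option == cs.FREE for r in small_log)
                    + sum(r.phase == "test" for r in small_log))
        assert n == expected

    def test_bic_definition(self, exp1a, q_bonus_spec, small_log):
        fit = cs.fit_map(small_log, q_bonus_spec, cs.PriorSet(), exp1a,
                         n_restarts=3, seed=1)
        assert fit.n_params == q_bonus_spec.n_free_params
        assert fit.bic == pytest.approx(
            fit.n_params * math.log(fit.n_obs) - 2 * fit.log_likelihood)
        assert fit.log_posterior <= fit.log_likelihood + 2.0

    def test_recovers_generating_parameters_roughly(self, exp1a,
                                                    q_bonus_spec):
        truth = cs.Params(alpha1=0.5, alpha2=0.6, tau1=0.3, rho=0.5)
        spec = cs.ModelSpec(target="q_learning", has_bonus=True, n_alpha=2)
        log = cs.simulate_subject(exp1a, spec, truth, seed=31)
        fit = cs.fit_map(log, spec, cs.PriorSet(), exp1a, n_restarts=5,
                         seed=2)
        assert fit.params_hat.alpha2 == pytest.approx(0.6, abs=0.25)
        assert fit.params_hat.rho == pytest.approx(0.5, abs=0.4)

    def test_degenerate_log_rejected(self, exp1a, q_bonus_spec):
        # forced-type training trials only: no modelled decision exists
        recs = [cs.TrialRecord("s", "exp1a", 0, "train", i, cs.FORCED,
                               False, cs.A1, cs.A1, True, 1)
                for i in range(10)]
        with pytest.raises(DataError):
            cs.fit_map(recs, q_bonus_spec, cs.PriorSet(), exp1a, seed=0)

    def test_unknown_block_rejected(self, exp1a, q_bonus_spec):
        recs = [cs.TrialRecord("s", "exp1a", 9, "test", 0, cs.FREE, True,
                               cs.A1, cs.A1, True, 1)]
        with pytest.raises(DataError):
            cs.log_likelihood(recs, q_bonus_spec,
                              cs.Params(alpha1=0.5, tau1=1.0), exp1a)


def test_params_vector_round_trip():
    spec = cs.ModelSpec(target="beta_pessimistic", has_bonus=True,
                        n_alpha=2, n_tau=2, has_stickiness=True)
    params = cs.Params(alpha1=0.2, alpha2=0.8, tau1=0.5, tau2=2.0,
                       beta=0.3, rho=-0.7, kappa=1.1)
    vec = params_to_vector(spec, params)
    from choiceseek.fitting import vector_to_params
    back = params_to_vector(spec, vector_to_params(spec, vec))
    assert vec == pytest.approx(back, abs=1e-12)
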