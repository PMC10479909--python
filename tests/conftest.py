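import numpy as np
import pytest
from hypothesis import settings

import choiceseek as cs

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def exp1a():
    return cs.build_config("exp1a", seed=0)


@pytest.fixture(scope="session")
def exp3():
    return cs.build_config("exp3", seed=0)


@pytest.fixture(scope="session")
def q_bonus_spec():
    return cs.ModelSpec(target=cs.Q_LEARNING, has_bonus=True)


@pytest.fixture(scope="session")
def moderate_params():
    return cs.Params(alpha1=0.5, tau1=0.3, rho=0.5)


@pytest.fixture(scope="session")
def small_log(exp1a, q_bonus_spec, moderate_params):
    """One simulated subject on the full exp1a schedule."""
    return cs.simulate_subject(exp1a, q_bonus_spec, moderate_params,
                               subject_id="s0", seed=11)


def random_trial_log(config, n_trials, rng, subject_id="rnd"):
    """Arbitrary (not behaviourally generated) log consistent with the
    task graph, for likelihood oracle checks."""
    records = []
    counters = {}
    for _ in range(n_trials):
        block = config.blocks[rng.integers(len(config.blocks))]
        b = block.block_index
        phase = "test" if rng.random() < 0.5 else "train"
        option = cs.FREE if rng.random() < 0.6 else cs.FORCED
        if option == cs.FREE or config.n_forced_actions == 2:
            action = cs.A1 if rng.random() < 0.5 else cs.A2
        else:
            action = cs.A1
        if block.incoherence > 0 and rng.random() < block.incoherence:
            displayed = cs.A2 if action == cs.A1 else cs.A1
        else:
            displayed = action
        ti = counters.get((b, phase), 0)
        counters[(b, phase)] = ti + 1
        records.append(cs.TrialRecord(
            subject_id=subject_id, experiment=config.experiment,
            block_index=b, phase=phase, trial_index=ti,
            stage1_option=option, stage1_is_choice=(phase == "test"),
            stage2_action=action, displayed_target=displayed,
            coherent=action == displayed,
            reward=int(rng.random() < 0.5)))
    return records
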