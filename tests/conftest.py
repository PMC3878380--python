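import numpy as np
import pytest
from hypothesis import settings

from expertrack import ability, task

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def session():
    """One generated (unbet) session with the default design."""
    return task.generate_session(seed=101)


@pytest.fixture(scope="session")
def q_filter(session):
    """Volatility-filter asset beliefs for the shared session."""
    return ability.default_asset_beliefs(session)


@pytest.fixture(scope="session")
def seq_subject(session, q_filter):
    """The shared session completed by a sequential-model subject."""
    return task.simulate_subject("sequential", {"beta": 4.45}, session, seed=202, q=q_filter)


def simulate_cohort(model, params, seed, n_subjects, config=None):
    """Seeded cohort of completed sessions with cached filter beliefs."""
    cfg = config or task.TaskConfig()
    out = []
    for child in np.random.SeedSequence(seed).spawn(n_subjects):
        s_sess, s_subj = (int(v % 2**31) for v in child.generate_state(2))
        sess = task.generate_session(cfg, seed=s_sess)
        q = ability.default_asset_beliefs(sess)
        done = task.simulate_subject(model, params, sess, seed=s_subj, q=q)
        done.attrs["q_filter"] = q
        out.append((done, q))
    return out
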