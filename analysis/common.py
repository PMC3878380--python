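"""Shared helpers for the numbered analysis drivers.

The study cohort is regenerated deterministically from a fixed master seed,
so every driver can be run independently and in any order.
"""

from pathlib import Path

import numpy as np

from expertrack import ability, task

COHORT_SEED = 20130

#: study conditions: 25 subjects following the sequential model
N_SUBJECTS = 25
SEQ_PARAMS = {"beta": 4.45}

#: asymmetric eight-rate generator used for the learning-asymmetry analyses:
#: people credited more on agree-correct trials, algorithms penalized more
#: on agree-incorrect trials
ASYM_RATES = dict(
    gamma_p=0.15, eta_p=0.10, phi_p=0.05, lambda_p=0.10,
    gamma_a=0.05, eta_a=0.10, phi_a=0.15, lambda_a=0.10, beta=7.0,
)

RESULTS = Path(__file__).resolve().parent.parent / "results"


def simulate_cohort(model, params, seed=COHORT_SEED, n_subjects=N_SUBJECTS):
    """Seeded cohort of completed sessions, with filter beliefs attached."""
    out = []
    for child in np.random.SeedSequence(seed).spawn(n_subjects):
        s_sess, s_subj = (int(v % 2**31) for v in child.generate_state(2))
        sess = task.generate_session(seed=s_sess)
        q = ability.default_asset_beliefs(sess)
        done = task.simulate_subject(model, params, sess, seed=s_subj, q=q)
        done.attrs["q_filter"] = q
        out.append((done, q))
    return out


def results_dir() -> Path:
    RESULTS.mkdir(exist_ok=True)
    return RESULTS
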