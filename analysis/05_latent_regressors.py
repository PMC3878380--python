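"""Construct the model-derived latent regressors and check their structure.

For every cohort subject the sequential model supplies trial-wise expected
value, reward prediction error, expertise estimates, and signed/unsigned
ability prediction errors (aPEs) at the two update slots. Two structural
checks: the pairwise correlation matrix among the regressors entering the
same design matrix (they need to be distinguishable), and the within-session
correlation between unsigned aPEs and the surprisal of the judged event
(expected near 0.98: for binary events |g - m| = 1 - P(g) is an
almost-linear function of -log2 P(g) over the beliefs this task produces).

Writes results/regressor_correlations.tsv, ape_surprisal.tsv, and a figure
under scratch/.
"""

import time
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from common import SEQ_PARAMS, results_dir, simulate_cohort
from expertrack.choice import compute_latent_regressors, regressor_correlations

out = results_dir()
t0 = time.time()

cohort = simulate_cohort("sequential", SEQ_PARAMS)
corrs, rs = [], []
example = None
for done, q in cohort:
    lat = compute_latent_regressors("sequential", SEQ_PARAMS, done, q=q)
    corrs.append(regressor_correlations(lat))
    ape = np.concatenate([lat.ape_sim_unsigned.dropna(), lat.ape_ev_unsigned.dropna()])
    sur = np.concatenate([lat.surprise_sim.dropna(), lat.surprise_ev.dropna()])
    rs.append(np.corrcoef(ape, sur)[0, 1])
    example = example if example is not None else (ape, sur)

mean_corr = sum(corrs) / len(corrs)
mean_corr.to_csv(out / "regressor_correlations.tsv", sep="\t", float_format="%.3f")
pd.DataFrame({"subject": range(len(rs)), "r_ape_surprisal": rs}).to_csv(
    out / "ape_surprisal.tsv", sep="\t", index=False, float_format="%.4f"
)

print("mean regressor correlation matrix (25 sequential-model subjects):")
print(mean_corr.to_string(float_format="%.3f"))
print(
    f"\nmean within-session correlation between unsigned aPE and surprisal: "
    f"{np.mean(rs):.3f} (range {np.min(rs):.3f}-{np.max(rs):.3f})"
)

scratch = Path(__file__).resolve().parent.parent / "scratch"
scratch.mkdir(exist_ok=True)
fig, ax = plt.subplots(figsize=(4, 4))
ax.scatter(example[0], example[1], s=8, alpha=0.5)
ax.set_xlabel("unsigned aPE  |g - m|")
ax.set_ylabel("surprisal  -log2 P(g)  [bits]")
ax.set_title("subject 0: update magnitude vs surprise")
fig.tight_layout()
fig.savefig(scratch / "ape_vs_surprisal.png", dpi=120)
print(f"figure written to {scratch / 'ape_vs_surprisal.png'}")
print(f"total time {time.time() - t0:.0f}s")
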