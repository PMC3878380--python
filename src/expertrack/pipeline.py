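"""End-to-end pipeline: simulate -> fit -> compare -> analyze -> regressors.

Each stage is a thin orchestration over the library modules; all randomness
flows from one master seed so a fixed configuration reproduces byte-identical
outputs. A JSON manifest records the configuration, seeds, and output hashes.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import ability as ability_mod
from . import behavior as behavior_mod
from . import choice as choice_mod
from . import fit as fit_mod
from . import io as io_mod
from .task import TaskConfig, generate_session, simulate_subject

logger = logging.getLogger("expertrack")

DEFAULT_STAGES = ("simulate", "fit", "compare", "analyze", "regressors")


def run_pipeline(config: dict, out_dir: str | Path) -> dict:
    """Run the requested stages and return the manifest.

    Config keys: ``task`` (TaskConfig fields), ``n_subjects``, ``seed``,
    ``model`` and ``params`` (generator for simulated subjects), ``models``
    (candidate list for comparison), ``stages`` (subset of
    :data:`DEFAULT_STAGES`).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    task_cfg: TaskConfig = config.get("task_config") or TaskConfig(**config.get("task", {}))
    n_subjects = int(config.get("n_subjects", 25))
    seed = int(config.get("seed", 0))
    gen_model = config.get("model", "sequential")
    gen_params = dict(config.get("params", {"beta": 4.45}))
    models = list(config.get("models", ["sequential", "evidence", "simulation", "rl_sequential_2p"]))
    stages = tuple(config.get("stages", DEFAULT_STAGES))

    outputs: list[Path] = []
    sessions: list[pd.DataFrame] = []
    q_list: list[np.ndarray] = []
    stage = None
    try:
        stage = "simulate"
        if "simulate" in stages:
            logger.info("stage simulate: %d subjects, model=%s", n_subjects, gen_model)
            ss = np.random.SeedSequence(seed)
            for i, child in enumerate(ss.spawn(n_subjects)):
                s_sess, s_subj = (int(v % (2**31)) for v in child.generate_state(2))
                sess = generate_session(task_cfg, seed=s_sess)
                q = ability_mod.default_asset_beliefs(sess)
                done = simulate_subject(gen_model, gen_params, sess, seed=s_subj, q=q)
                done.attrs["q_filter"] = q
                sessions.append(done)
                q_list.append(q)
                p = out_dir / f"session_{i:02d}.tsv"
                io_mod.write_session(done, p)
                outputs.append(p)

        if "fit" in stages or "compare" in stages:
            stage = "compare"
            logger.info("stage compare: models=%s", models)
            table = fit_mod.compare_models(models, sessions, q_list)
            p = out_dir / "model_comparison.tsv"
            table.to_csv(p, sep="\t", index=False, float_format="%.4f")
            outputs.append(p)

        if "analyze" in stages:
            stage = "analyze"
            logger.info("stage analyze: lagged regressions")
            results = [
                behavior_mod.agreement_split_regression(s, q=q) for s, q in zip(sessions, q_list)
            ]
            inter = behavior_mod.interaction_contrast(results)
            p = out_dir / "interaction_contrast.tsv"
            inter.per_subject.to_csv(p, sep="\t", index=False, float_format="%.4f")
            outputs.append(p)
            stats_p = out_dir / "group_stats.txt"
            stats_p.write_text(
                f"interaction contrast mean {inter.contrast_mean:.4f}\n"
                f"t({len(inter.per_subject) - 1}) = {inter.t_stat:.3f}, "
                f"F = {inter.f_stat:.3f}, p = {inter.p_value:.4f}\n"
            )
            outputs.append(stats_p)

        if "regressors" in stages:
            stage = "regressors"
            logger.info("stage regressors: latent-variable tables")
            for i, (s, q) in enumerate(zip(sessions, q_list)):
                lat = choice_mod.compute_latent_regressors(gen_model, gen_params, s, q=q)
                p = out_dir / f"latents_{i:02d}.tsv"
                lat.to_csv(p, sep="\t", index=False, na_rep="NA", float_format="%.6f")
                outputs.append(p)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc

    manifest = io_mod.write_manifest(
        out_dir / "manifest.json",
        config={k: v for k, v in config.items()},
        seeds={"master": seed},
        outputs=outputs,
    )
    return manifest
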