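"""Reading and writing trial tables and run configuration.

Trial tables are TSV with a fixed header (see
:data:`expertrack.task.SESSION_COLUMNS`), UTF-8, with ``NA`` as the only
missing-value token; agent fields are NA on asset-prediction trials.
Configuration files are YAML mappings mirroring TaskConfig fields plus
pipeline options.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .task import AGENT_BET, ASSET_PREDICT, SESSION_COLUMNS, TaskConfig

__all__ = ["write_session", "load_session_table", "load_config", "file_sha256", "write_manifest"]

_INT_COLS = ("block", "trial", "outcome")
_BINARY_CODES = {0, 1}


def write_session(session: pd.DataFrame, path: str | Path) -> None:
    """Write a trial table as TSV with NA for missing agent fields."""
    out = session[SESSION_COLUMNS].copy()
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


def _err(row: int, msg: str) -> ValueError:
    return ValueError(f"row {row}: {msg}")


def load_session_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a TSV trial table into the session schema.

    Schema violations raise ``ValueError`` naming the offending (1-based,
    header-exclusive) row.
    """
    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)
    missing = [c for c in SESSION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    df = df[SESSION_COLUMNS]
    for i, row in enumerate(df.itertuples(index=False), start=1):
        if row.condition not in (AGENT_BET, ASSET_PREDICT):
            raise _err(i, f"unknown condition {row.condition!r}")
        for col in _INT_COLS:
            v = getattr(row, col)
            if pd.isna(v) or float(v) != int(v):
                raise _err(i, f"non-integer {col}={v!r}")
        if int(row.outcome) not in _BINARY_CODES:
            raise _err(i, f"non-binary outcome {row.outcome!r}")
        if row.condition == ASSET_PREDICT:
            if not (pd.isna(row.agent_id) and pd.isna(row.agent_prediction)):
                raise _err(i, "asset trials must have NA agent fields")
        else:
            if pd.isna(row.agent_id) or pd.isna(row.agent_prediction) or pd.isna(row.correctness):
                raise _err(i, "agent trial with NA agent fields")
            if int(row.agent_prediction) not in _BINARY_CODES:
                raise _err(i, f"non-binary agent_prediction {row.agent_prediction!r}")
            if int(row.correctness) != int(int(row.agent_prediction) == int(row.outcome)):
                raise _err(i, "correctness inconsistent with prediction and outcome")
    # restore typed columns: ints where defined, None for missing object fields
    for col in ("agent_prediction", "correctness"):
        df[col] = df[col].astype(object).where(df[col].notna(), None)
        df[col] = df[col].map(lambda v: int(v) if v is not None else None)
    for col in ("agent_id", "category", "bet"):
        df[col] = df[col].astype(object).where(df[col].notna(), None)
    df["outcome"] = df["outcome"].astype(int)
    df["block"] = df["block"].astype(int)
    df["trial"] = df["trial"].astype(int)
    return df


def load_config(path: str | Path) -> dict:
    """Load a YAML run configuration; TaskConfig fields under ``task``."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if "task" in cfg:
        task_kwargs = dict(cfg["task"])
        if "drift_clip" in task_kwargs:
            task_kwargs["drift_clip"] = tuple(task_kwargs["drift_clip"])
        cfg["task_config"] = TaskConfig(**task_kwargs)
    return cfg


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(path: str | Path, *, config: dict, seeds: dict, outputs: list[str | Path]) -> dict:
    """Record a run's configuration, seeds, and output hashes as JSON."""
    from . import __version__

    manifest = {
        "package_version": __version__,
        "config": {k: v for k, v in config.items() if k != "task_config"},
        "seeds": seeds,
        "outputs": {str(p): file_sha256(p) for p in outputs},
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
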