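"""Result tables: CSV output with a JSON run-metadata sidecar."""

from __future__ import annotations

import json
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import pandas as pd

from .config import ExperimentConfig


def _software_version() -> str:
    try:
        return version("pazquant")
    except PackageNotFoundError:  # pragma: no cover
        return "unknown"


def write_table(df: pd.DataFrame, path, cfg: ExperimentConfig | None = None, **extra):
    """Write a result table to CSV (UTF-8, header row) plus a ``.meta.json``
    sidecar recording the config hash, seed and software version."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, encoding="utf-8")
    meta = {
        "software": "pazquant",
        "version": _software_version(),
        "n_rows": int(len(df)),
        **extra,
    }
    if cfg is not None:
        meta["config_hash"] = cfg.hash()
        meta["seed"] = cfg.rng_seed
        meta["config"] = cfg.to_dict()
    with open(path.with_suffix(path.suffix + ".meta.json"), "w") as fh:
        json.dump(meta, fh, indent=1, default=str)
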