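"""TSV output with a provenance header and a JSON sidecar.

Every table the pipeline writes carries ``#``-prefixed header lines
recording the tool version, a hash of the effective configuration, and the
seed, so reruns are attributable; the same metadata is mirrored to a
machine-readable ``<name>.meta.json`` sidecar.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from . import __version__

__all__ = ["config_hash", "write_table", "read_table"]


def config_hash(params: dict) -> str:
    canon = json.dumps(params, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    params: dict | None = None,
    seed: int | None = None,
    index: bool = True,
) -> None:
    path = Path(path)
    meta = {
        "tool": "microjxn",
        "version": __version__,
        "config_hash": config_hash(params or {}),
        "seed": seed,
    }
    with open(path, "w") as fh:
        for key, value in meta.items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, sep="\t", index=index)
    with open(path.with_suffix(path.suffix + ".meta.json"), "w") as fh:
        json.dump({**meta, "params": params or {}}, fh, indent=1, default=str)


def read_table(path: str | Path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)
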