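"""Delimited-text tables and YAML provenance sidecars."""

from __future__ import annotations

import hashlib
from pathlib import Path

import pandas as pd
import yaml

from . import __version__

__all__ = ["read_table", "write_table", "write_table_with_sidecar", "write_sidecar"]


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path, force: bool = True) -> Path:
    path = Path(path)
    if path.exists() and not force:
        raise FileExistsError(f"{path} exists; pass force=True to overwrite")
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    return path


def write_sidecar(path, metadata: dict) -> Path:
    """YAML sidecar (`<path>.meta.yaml`) with a config hash and version."""
    path = Path(path)
    payload = dict(metadata)
    payload["version"] = __version__
    payload["config_sha256"] = hashlib.sha256(
        yaml.safe_dump(metadata, sort_keys=True).encode()
    ).hexdigest()
    sidecar = path.with_suffix(path.suffix + ".meta.yaml")
    sidecar.write_text(yaml.safe_dump(payload, sort_keys=True))
    return sidecar


def write_table_with_sidecar(df: pd.DataFrame, path, metadata: dict, force: bool = True) -> Path:
    out = write_table(df, path, force=force)
    write_sidecar(out, metadata)
    return out
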