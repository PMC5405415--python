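"""Delimited-text writers with provenance headers.

All tabular artifacts are comma-separated with a header row, preceded by
``#``-prefixed provenance comments (package version, seed, config hash)
so every output is auditable against its inputs.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Mapping

import pandas as pd

__all__ = ["write_table", "read_table", "config_hash"]


def config_hash(payload: str | bytes) -> str:
    """Short stable hash of a serialized configuration."""
    if isinstance(payload, str):
        payload = payload.encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def write_table(path, frame: pd.DataFrame, meta: Mapping[str, object] | None = None) -> Path:
    """Write a DataFrame as CSV with '#' provenance comment lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, value in (meta or {}).items():
            fh.write(f"# {key}: {value}\n")
        frame.to_csv(fh, index=False, lineterminator="\n")
    return path


def read_table(path) -> pd.DataFrame:
    """Read a CSV written by :func:`write_table`, reporting bad lines by number."""
    try:
        return pd.read_csv(path, comment="#")
    except pd.errors.ParserError as exc:  # surface the line number pandas reports
        raise ValueError(f"corrupted readout file {path}: {exc}") from exc
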