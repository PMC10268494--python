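"""Delimited-table I/O with provenance headers.

One tabular dialect throughout: UTF-8 plain text, one header row, comma on
write, comma or tab autodetected on read.  Every written table starts with
``#``-prefixed metadata lines recording the package version and a hash of
the effective configuration, so reruns are verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__


def config_hash(config: Mapping) -> str:
    """Stable short hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_table(df: pd.DataFrame, path, config: Mapping | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# butyrogen version: {__version__}\n")
        fh.write(f"# config hash: {config_hash(config or {})}\n")
        df.to_csv(fh, index=False)


def read_table(path) -> pd.DataFrame:
    """Read a delimited table, skipping ``#`` comment lines; sep autodetected."""
    return pd.read_csv(path, sep=None, engine="python", comment="#",
                       encoding="utf-8")
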