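"""Result serialization: CSV tables and JSON records with provenance sidecars.

Numeric CSV output uses 17 significant digits so that values round-trip
exactly through text; every file gets a ``.meta.json`` sidecar carrying the
resolved configuration, the master seed, and the package version.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__

FLOAT_FORMAT = "%.17g"


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_table(df: pd.DataFrame, path, meta: dict | None = None) -> Path:
    """Write a CSV table plus a JSON provenance sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)
    if meta is not None:
        write_meta(path, meta)
    return path


def write_json(record: dict, path, meta: dict | None = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(_jsonable(record), indent=2) + "\n")
    if meta is not None:
        write_meta(path, meta)
    return path


def write_meta(path: Path, meta: dict) -> Path:
    side = path.with_suffix(path.suffix + ".meta.json")
    payload = {"version": __version__, **_jsonable(meta)}
    side.write_text(json.dumps(payload, indent=2) + "\n")
    return side
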