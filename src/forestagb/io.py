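"""Readers/writers for the package's plain-text interchange formats.

Point clouds travel as CSV tables with columns ``x,y,z,pulse,class``;
plot, tree and feature tables as CSV with their documented column names;
comparison grids, filter reports and survey geometry as JSON.  Every
artifact written by the CLI is accompanied by a manifest recording the
master seed and a hash of the configuration, so a run can be audited and
reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError
from .features import POINT_COLUMNS


def write_point_csv(cloud: pd.DataFrame, path) -> None:
    missing = [c for c in POINT_COLUMNS if c not in cloud.columns]
    if missing:
        raise SchemaError(f"point table is missing columns {missing}")
    cloud.loc[:, POINT_COLUMNS].to_csv(path, index=False, float_format="%.3f")


def read_point_csv(path) -> pd.DataFrame:
    cloud = pd.read_csv(path)
    missing = [c for c in POINT_COLUMNS if c not in cloud.columns]
    if missing:
        raise SchemaError(f"{path}: point table is missing columns {missing}")
    return cloud


def write_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def write_json(payload: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping."""
    canon = json.dumps(config, sort_keys=True, default=_jsonable)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def write_manifest(out_dir, config: dict, seed: int, outputs: list[str]) -> Path:
    path = Path(out_dir) / "manifest.json"
    write_json({"seed": seed, "config_hash": config_hash(config),
                "config": config, "outputs": sorted(outputs)}, path)
    return path
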