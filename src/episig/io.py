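"""Readers and writers for the plain-text interchange formats.

All tabular data are TSV/CSV with a header row; reports are JSON.
The beta matrix TSV has ``probe_id`` as its first column, the manifest
is a BED-like TSV with 0-based half-open coordinates.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import BetaMatrix, validate_sample_sheet


def write_beta_tsv(beta: BetaMatrix, path) -> None:
    df = beta.values.copy()
    df.index.name = "probe_id"
    df.to_csv(path, sep="\t", float_format="%.6g")


def read_beta_tsv(path, manifest=None, samples=None) -> BetaMatrix:
    df = pd.read_csv(path, sep="\t", index_col="probe_id")
    return BetaMatrix(df, manifest, samples)


def write_sample_sheet(samples: pd.DataFrame, path) -> None:
    df = samples.copy()
    df.index.name = "sample_id"
    df.to_csv(path)


def read_sample_sheet(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col="sample_id")
    return validate_sample_sheet(df)


def write_manifest(manifest: pd.DataFrame, path) -> None:
    df = manifest.reset_index(names="probe_id")
    cols = ["chrom", "start", "end", "probe_id"] + [
        c for c in df.columns if c not in ("chrom", "start", "end", "probe_id")
    ]
    df[cols].to_csv(path, sep="\t", index=False)


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return df.set_index("probe_id")


def write_reference_profiles(ref: pd.DataFrame, path) -> None:
    df = ref.copy()
    df.index.name = "probe_id"
    df.to_csv(path, sep="\t", float_format="%.6g")


def read_reference_profiles(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="probe_id")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [_jsonable(v) for v in sorted(obj)] if isinstance(obj, set) else [
            _jsonable(v) for v in obj
        ]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, pd.Index):
        return list(obj)
    return obj


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(_jsonable(obj), indent=2, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
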