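"""Table and report input/output with canonical-header validation."""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .features.names import FEATURE_NAMES, REFERENCE_NAMES


def write_feature_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=True, index_label="recording_id")


def read_feature_table(path, expected: str | None = "automated", task: str | None = None) -> pd.DataFrame:
    """Read a recordings x features CSV, checking the canonical header.

    ``expected`` is "automated" (the 53-name set), "reference" (task-specific
    reference names; requires ``task``) or None to skip validation. A header
    mismatch raises with the offending names listed.
    """
    df = pd.read_csv(path, index_col=0)
    if expected == "automated":
        canonical = list(FEATURE_NAMES)
    elif expected == "reference":
        if task is None:
            raise ValueError("task required to validate a reference table header")
        canonical = list(REFERENCE_NAMES[task])
    elif expected is None:
        return df
    else:
        raise ValueError(f"unknown expectation {expected!r}")
    got = list(df.columns)
    if got != canonical:
        missing = sorted(set(canonical) - set(got))
        extra = sorted(set(got) - set(canonical))
        raise ValueError(
            f"{path}: header does not match the canonical feature names; "
            f"missing={missing}, unexpected={extra}"
        )
    return df


def write_clinical_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=True, index_label="participant_id")


def read_clinical_table(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return {"index": obj.index.tolist(), "columns": obj.columns.tolist(), "data": obj.to_numpy().tolist()}
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(_jsonable(obj), fh, indent=2, sort_keys=True, allow_nan=True)


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
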