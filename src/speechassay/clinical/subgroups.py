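"""Severity subgrouping of clinical measures.

Six clinical measures are split into less-severe / more-severe subgroups at
the study thresholds (strictly below the threshold means more severe): FRS
total < 35/48, FRS-resp < 10/12, FRS-bulb < 11/12, SIT rate < 160 WPM, SIT
intelligibility < 96%, FVC < 80% predicted. Sex (male = 1, female = 2) and
site of onset (bulbar / spinal) enter as their natural binary groupings,
giving the eight measures used throughout clinical validation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

SEVERITY_THRESHOLDS = {
    "frs_total": 35.0,
    "frs_resp": 10.0,
    "frs_bulb": 11.0,
    "sit_rate": 160.0,
    "sit_intell": 96.0,
    "fvc_pct": 80.0,
}

MEASURES = ("sex_code", "onset_site", *SEVERITY_THRESHOLDS)

MORE, LESS = "more-severe", "less-severe"


def assign_subgroups(clinical: pd.DataFrame) -> pd.DataFrame:
    """Binary group labels per participant for the eight measures.

    Clinical measures map to {more-severe, less-severe} (strict '<' at the
    threshold); sex and onset site keep their categories. Missing values
    propagate as missing. Unknown columns in the threshold table raise.
    """
    for measure in SEVERITY_THRESHOLDS:
        if measure not in clinical.columns:
            raise KeyError(f"clinical table lacks measure {measure!r}")
    out = pd.DataFrame(index=clinical.index)
    sex = clinical["sex_code"]
    out["sex_code"] = sex.map({1: "male", 2: "female"})
    if out["sex_code"].isna().any() and sex.notna().any():
        bad = sorted(set(sex.dropna()) - {1, 2})
        if bad:
            raise ValueError(f"sex_code must be encoded male=1/female=2; got {bad}")
    out["onset_site"] = clinical["onset_site"]
    for measure, threshold in SEVERITY_THRESHOLDS.items():
        vals = clinical[measure].astype(float)
        lab = np.where(vals < threshold, MORE, LESS)
        out[measure] = pd.Series(lab, index=clinical.index).where(vals.notna())
    return out


def subgroup_sizes(subgroups: pd.DataFrame) -> pd.DataFrame:
    """Per-measure category counts (mirrors more/less-severe accounting)."""
    rows = {}
    for measure in subgroups.columns:
        rows[measure] = subgroups[measure].value_counts(dropna=True).to_dict()
    return pd.DataFrame(rows).T.fillna(0).astype(int)
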