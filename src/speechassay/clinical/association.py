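"""Cramér's V association mapping between clinical subgroups and
feature-level predictions, with hierarchical clustering for display."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.stats import chi2_contingency

from .discretize import jenks_discretize

V_FLOOR = 0.35  # large-effect threshold at df = 2 (Kim 2017 convention)
V_CEILING = 0.50


@dataclass
class AssociationMatrix:
    """Cramér's V for every clinical measure x acoustic feature pair."""

    values: pd.DataFrame  # measures x features
    row_order: list = field(default_factory=list)
    col_order: list = field(default_factory=list)
    display: pd.DataFrame | None = None
    floor: float = V_FLOOR
    ceiling: float = V_CEILING


def cramers_v(labels_a, labels_b) -> float:
    """Cramér's V = sqrt(chi2 / (n * (min(r, c) - 1))), uncorrected chi2.

    Pairs with a missing label on either side are dropped; a degenerate
    table (a single category on either margin) yields NaN.
    """
    a = pd.Series(labels_a).reset_index(drop=True)
    b = pd.Series(labels_b).reset_index(drop=True)
    if len(a) != len(b):
        raise ValueError("label vectors must have equal length")
    ok = a.notna() & b.notna()
    a, b = a[ok], b[ok]
    if a.nunique() < 2 or b.nunique() < 2:
        return float("nan")
    table = pd.crosstab(a, b)
    chi2 = chi2_contingency(table.to_numpy(), correction=False).statistic
    n = table.to_numpy().sum()
    r, c = table.shape
    return float(np.sqrt(chi2 / (n * (min(r, c) - 1))))


def association_matrix(
    predictions: pd.DataFrame,
    subgroups: pd.DataFrame,
    k_range: tuple = (2, 4),
    gof_min: float = 0.90,
) -> AssociationMatrix:
    """V for every measure x feature combination.

    ``predictions`` are the continuous feature-level model outputs (rows =
    participants); each column is Jenks-discretized before association.
    ``subgroups`` holds the categorical clinical groupings (same index).
    Missing pairs are dropped per cell.
    """
    if not predictions.index.equals(subgroups.index):
        raise ValueError("predictions and subgroups must share the participant index")
    disc = {}
    for feat in predictions.columns:
        res = jenks_discretize(predictions[feat].to_numpy(), k_range, gof_min)
        lab = res.labels.astype(float)
        lab[lab < 0] = np.nan
        disc[feat] = lab
    vals = np.full((subgroups.shape[1], predictions.shape[1]), np.nan)
    for i, measure in enumerate(subgroups.columns):
        m = subgroups[measure]
        for j, feat in enumerate(predictions.columns):
            vals[i, j] = cramers_v(m.to_numpy(), disc[feat])
    return AssociationMatrix(
        values=pd.DataFrame(vals, index=subgroups.columns, columns=predictions.columns)
    )


def cluster_association_matrix(matrix: AssociationMatrix) -> AssociationMatrix:
    """Order rows and columns by average-linkage Euclidean clustering and
    attach the thresholded display copy (cells <= floor blanked to 0, cells
    >= ceiling saturated). NaN counts as 0 for clustering and display."""
    vals = matrix.values.fillna(0.0)
    if vals.shape[0] > 1:
        row_link = hierarchy.linkage(vals.to_numpy(), method="average", metric="euclidean")
        row_order = hierarchy.leaves_list(row_link).tolist()
    else:
        row_order = [0]
    if vals.shape[1] > 1:
        col_link = hierarchy.linkage(vals.to_numpy().T, method="average", metric="euclidean")
        col_order = hierarchy.leaves_list(col_link).tolist()
    else:
        col_order = [0]
    disp = vals.to_numpy().copy()
    disp[disp <= matrix.floor] = 0.0
    disp = np.minimum(disp, matrix.ceiling)
    display = pd.DataFrame(disp, index=vals.index, columns=vals.columns)
    display = display.iloc[row_order, col_order]
    return AssociationMatrix(
        values=matrix.values,
        row_order=[vals.index[i] for i in row_order],
        col_order=[vals.columns[j] for j in col_order],
        display=display,
        floor=matrix.floor,
        ceiling=matrix.ceiling,
    )
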