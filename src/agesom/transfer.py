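"""Cross-cohort comparison on a frozen primary map.

A secondary cohort (for example tumor methylomes) is projected onto the
primary aging map by extension-SOM, after which its samples can be
compared with the primary cohort: a rectangular portrait-correlation
matrix, and a "river flow" assignment of every secondary sample to the
best-correlating primary age group.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .schemes import AgeGroupScheme

__all__ = ["FlowTable", "cross_cohort_pcm", "flow_assignment"]


@dataclass
class FlowTable:
    """Secondary-group x primary-age-group sample flow.

    ``counts``: contingency table of assignments; ``by_secondary`` and
    ``by_primary``: the two row-normalized views; ``assignments``: per-
    sample best-matching group and its correlation.
    """

    counts: pd.DataFrame
    by_secondary: pd.DataFrame
    by_primary: pd.DataFrame
    assignments: pd.DataFrame


def _pearson_columns(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson correlation between every column of ``a`` and of ``b``."""
    a = a - a.mean(axis=0, keepdims=True)
    b = b - b.mean(axis=0, keepdims=True)
    sa = np.sqrt((a**2).sum(axis=0))
    sb = np.sqrt((b**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (a.T @ b) / np.outer(sa, sb)
    r[sa == 0, :] = np.nan
    r[:, sb == 0] = np.nan
    return r


def cross_cohort_pcm(
    primary_portraits: pd.DataFrame,
    secondary_portraits: pd.DataFrame,
    primary_order: Optional[Sequence[str]] = None,
    secondary_order: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Rectangular Pearson matrix between primary and secondary portraits.

    Rows are primary samples, columns secondary samples, each axis sorted
    by its supplied (group) order when given. Zero-variance portraits give
    missing entries.
    """
    p_cols = list(primary_order) if primary_order is not None else list(primary_portraits.columns)
    s_cols = list(secondary_order) if secondary_order is not None else list(secondary_portraits.columns)
    r = _pearson_columns(
        primary_portraits[p_cols].to_numpy(float),
        secondary_portraits[s_cols].to_numpy(float),
    )
    return pd.DataFrame(r, index=p_cols, columns=s_cols)


def flow_assignment(
    secondary_portraits: pd.DataFrame,
    group_portraits: pd.DataFrame,
    scheme: AgeGroupScheme,
    secondary_groups: Optional[Mapping[str, str]] = None,
) -> FlowTable:
    """Assign each secondary sample to its best-correlating primary age group.

    Ties are broken toward the younger group. When ``secondary_groups``
    (sample -> subtype label) is given, counts are aggregated into a
    subtype x age-group flow table with both row normalizations; otherwise
    all samples share one "secondary" row.
    """
    age_labels = [g for g in scheme.labels if g in group_portraits.columns]
    r = _pearson_columns(
        secondary_portraits.to_numpy(float),
        group_portraits[age_labels].to_numpy(float),
    )
    rows = []
    for i, s in enumerate(secondary_portraits.columns):
        corrs = r[i]
        best = int(np.nanargmax(corrs))  # argmax; ties resolve to younger group
        rows.append(
            {
                "sample": s,
                "best_group": age_labels[best],
                "correlation": float(corrs[best]),
                "secondary_group": (
                    secondary_groups[s] if secondary_groups is not None else "secondary"
                ),
            }
        )
    assign = pd.DataFrame(rows).set_index("sample")
    counts = (
        assign.groupby(["secondary_group", "best_group"]).size().unstack(fill_value=0)
    )
    counts = counts.reindex(columns=age_labels, fill_value=0)
    by_secondary = counts.div(counts.sum(axis=1), axis=0)
    by_primary = counts.T.div(counts.T.sum(axis=1).replace(0, np.nan), axis=0)
    return FlowTable(counts, by_secondary, by_primary, assign)
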