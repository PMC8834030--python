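"""Spot-module segmentation on the metagene grid.

A "spot" is an 8-connected region of grid nodes that are jointly
over-expressed (or hyper-methylated) in at least one age group, together
with the genes assigned to those nodes. Spots are detected on the
over-expression summary map (node-wise maximum over group-mean portraits)
by percentile thresholding, restricted to populated nodes (a spot is a
cluster of genes; interpolated empty nodes carry none). Labels are
assigned alphabetically by the age of each spot's peak group, so "A" is
the earliest-peaking module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Set, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from .preprocess import OmicsMatrix
from .schemes import AgeGroupScheme
from .som import SOMPortrayal

__all__ = ["Spot", "SpotSet", "detect_spots", "spot_profiles"]

log = logging.getLogger(__name__)

_CONN8 = np.ones((3, 3), dtype=int)


@dataclass
class Spot:
    label: str
    nodes: Set[int]
    genes: List[str]
    peak_group: str


@dataclass
class SpotSet:
    """Labeled, disjoint, 8-connected spot modules of one data layer."""

    layer: str
    spots: Dict[str, Spot]
    summary: np.ndarray  # rows x cols summary map
    mask: np.ndarray  # rows x cols boolean mask
    polarity: str = "over"

    def membership(self) -> pd.Series:
        """Gene -> spot label for all member genes."""
        out = {}
        for lab, spot in self.spots.items():
            for g in spot.genes:
                out[g] = lab
        return pd.Series(out, name="spot")

    def report(self) -> pd.DataFrame:
        rows = [
            {
                "spot": lab,
                "n_nodes": len(s.nodes),
                "n_genes": len(s.genes),
                "peak_group": s.peak_group,
            }
            for lab, s in self.spots.items()
        ]
        return pd.DataFrame(rows)


def _letters(n: int) -> List[str]:
    out = []
    for i in range(n):
        lab = ""
        k = i
        while True:
            lab = chr(ord("A") + k % 26) + lab
            k = k // 26 - 1
            if k < 0:
                break
        out.append(lab)
    return out


def _masked_components(
    mask_grid: np.ndarray, gp: np.ndarray, corr_min: float
) -> list:
    """Spot candidates: metagene clustering within the mask.

    Masked nodes are first clustered by their group profiles
    (complete-linkage on correlation distance, cut so that every pair of
    nodes within a cluster correlates at r >= corr_min); each cluster is
    then split into its 8-connected grid components. The complete-linkage
    gate prevents differently-timed modules from chaining together through
    intermediate boundary nodes.
    """
    from scipy.cluster.hierarchy import fcluster, linkage
    from scipy.spatial.distance import pdist

    nodes = np.flatnonzero(mask_grid.ravel())
    if len(nodes) == 0:
        return []
    out = []
    if len(nodes) == 1:
        profile_labels = np.array([1])
    else:
        centered = gp[nodes] - gp[nodes].mean(axis=1, keepdims=True)
        norms = np.linalg.norm(centered, axis=1)
        safe = np.where(norms > 0, norms, 1.0)
        d = pdist(centered / safe[:, None], metric="cosine")  # 1 - r
        profile_labels = fcluster(
            linkage(d, method="complete"), t=1.0 - corr_min, criterion="distance"
        )
    for lab in np.unique(profile_labels):
        members = nodes[profile_labels == lab]
        sub = np.zeros(mask_grid.size, dtype=bool)
        sub[members] = True
        labeled, n_comp = ndimage.label(
            sub.reshape(mask_grid.shape), structure=_CONN8
        )
        labeled = labeled.ravel()
        for comp in range(1, n_comp + 1):
            out.append(np.flatnonzero(labeled == comp))
    return out


def detect_spots(
    model: SOMPortrayal,
    group_portraits: pd.DataFrame,
    scheme: AgeGroupScheme,
    q: float = 75.0,
    min_size: int = 4,
    layer: str = "expression",
    polarity: str = "over",
    require_populated: bool = True,
    corr_min: float = 0.6,
) -> SpotSet:
    """Segment over-expression (or, with ``polarity="under"``, under-
    expression) spot modules from group-mean portraits.

    The summary map is the node-wise maximum over group portraits (minimum,
    sign-flipped, for under-expression). Nodes above the ``q``-th
    percentile of the summary values — restricted to populated nodes,
    since a spot is a cluster of genes and interpolated empty nodes carry
    none — form the mask. Spots are the connected components of the graph
    whose edges join 8-adjacent masked nodes with positively correlated
    group profiles (Pearson r >= ``corr_min``); the profile gate keeps
    adjacent but differently-timed modules from fusing into one region.
    Components below ``min_size`` nodes are discarded. Each spot's member
    genes are the genes whose best-matching node lies in the spot, and its
    peak group is the group with the highest mean portrait value over the
    spot's nodes.
    """
    shape = (model.rows, model.cols)
    gp = group_portraits[list(scheme.labels)].to_numpy(float)
    if polarity == "over":
        summary = gp.max(axis=1)
    elif polarity == "under":
        summary = -gp.min(axis=1)
    else:
        raise ValueError(f"unknown polarity {polarity!r}")
    if q >= 100:  # percentile edge: only the maxima survive
        mask = summary >= summary.max()
    else:
        mask = summary >= np.percentile(summary, q)
    if require_populated:
        mask = mask & model.populated_
    mask_grid = mask.reshape(shape)
    components = _masked_components(mask_grid, gp, corr_min)

    candidates = []
    for nodes in components:
        if len(nodes) < min_size:
            continue
        means = gp[nodes].mean(axis=0)
        peak_idx = int(np.argmax(means)) if polarity == "over" else int(np.argmin(means))
        candidates.append((peak_idx, int(nodes.min()), nodes))
    candidates.sort(key=lambda c: (c[0], c[1]))

    node_of_gene = model.assignment_
    spots: Dict[str, Spot] = {}
    for lab, (peak_idx, _, nodes) in zip(_letters(len(candidates)), candidates):
        node_set = set(int(n) for n in nodes)
        genes = [g for g, nd in node_of_gene.items() if nd in node_set]
        spots[lab] = Spot(
            label=lab,
            nodes=node_set,
            genes=genes,
            peak_group=scheme.labels[peak_idx],
        )
    if not spots:
        log.warning("spot detection produced an empty mask (q=%s)", q)
    return SpotSet(
        layer=layer,
        spots=spots,
        summary=summary.reshape(shape),
        mask=mask_grid,
        polarity=polarity,
    )


def spot_profiles(
    spotset: SpotSet,
    matrix: OmicsMatrix,
    groups: Mapping[str, str],
    scheme: AgeGroupScheme,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Per-group and per-sample mean differential value of each spot.

    For every spot, the per-sample profile is the mean centralized value
    (delta-e or delta-m) over its member genes, and the per-group profile
    averages those over the group's samples. Returns ``(per_group,
    per_sample)`` frames indexed by spot label.
    """
    if not matrix.centralized:
        raise ValueError("spot profiles are defined on a centralized matrix")
    per_sample_rows = {}
    for lab, spot in spotset.spots.items():
        members = [g for g in spot.genes if g in matrix.values.index]
        if not members:
            raise ValueError(f"spot {lab!r} has no member genes in the matrix")
        per_sample_rows[lab] = matrix.values.loc[members].mean(axis=0)
    per_sample = pd.DataFrame(per_sample_rows).T
    group_of = pd.Series({s: groups[s] for s in per_sample.columns})
    per_group = pd.DataFrame(
        {
            lab: per_sample.loc[:, group_of[group_of == lab].index].mean(axis=1)
            for lab in scheme.labels
            if (group_of == lab).any()
        }
    )
    return per_group, per_sample
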