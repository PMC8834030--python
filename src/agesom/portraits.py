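"""Sample-level portrait analyses.

Group-mean portraits, the pairwise correlation map (PCM) between sample
portraits, the sample similarity net, supporting maps (population,
variance, significance, entropy, weighted topological overlap between spot
profiles, invariant-gene region) and per-sample summary statistics whose
age course exhibits the "hourglass" shape on lifespan cohorts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .preprocess import OmicsMatrix
from .schemes import AgeGroupScheme
from .som import SOMPortrayal

__all__ = [
    "CorrelationMap",
    "SupportingMaps",
    "group_mean_portraits",
    "pairwise_correlation_map",
    "similarity_net",
    "supporting_maps",
    "sample_summary_stats",
    "shannon_entropy",
]

log = logging.getLogger(__name__)

_CONN8 = np.ones((3, 3), dtype=int)


@dataclass
class CorrelationMap:
    """Symmetric Pearson-correlation matrix between flattened portraits."""

    samples: list
    matrix: pd.DataFrame


@dataclass
class SupportingMaps:
    """Per-node and per-sample diagnostic maps of a trained model."""

    population: np.ndarray  # rows x cols gene counts
    variance: np.ndarray  # rows x cols variance over samples
    significance: Optional[np.ndarray]  # rows x cols two-sided p vs 0
    entropy: pd.Series  # per-sample portrait entropy (bits)
    wto: Optional[pd.DataFrame]  # spot x spot weighted topological overlap
    invariant_region: np.ndarray  # node indices of the low-variance region


def shannon_entropy(values: np.ndarray, bins: int = 25) -> float:
    """Shannon entropy (bits) of values discretized into equal-width bins."""
    v = np.asarray(values, float).ravel()
    v = v[np.isfinite(v)]
    if v.size == 0 or v.max() == v.min():
        return 0.0
    counts, _ = np.histogram(v, bins=bins)
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())


def group_mean_portraits(
    portraits: pd.DataFrame,
    groups: Mapping[str, str],
    scheme: AgeGroupScheme,
) -> pd.DataFrame:
    """Node-wise mean portrait per age group, in scheme order.

    ``portraits`` is a nodes x samples frame; ``groups`` maps each sample to
    its group label. A scheme group without any sample is rejected.
    """
    out = {}
    for lab in scheme.labels:
        members = [s for s in portraits.columns if groups[s] == lab]
        if not members:
            raise ValueError(f"age group {lab!r} has no samples")
        out[lab] = portraits[members].mean(axis=1)
    return pd.DataFrame(out)


def pairwise_correlation_map(
    portraits: pd.DataFrame,
    ages: Optional[Mapping[str, float]] = None,
    order_by_age: bool = True,
) -> CorrelationMap:
    """Pearson correlations between all pairs of flattened portraits.

    Samples are ordered by increasing age when ``ages`` is supplied and
    ``order_by_age`` is true. A zero-variance portrait yields missing
    (NaN) correlations, reported as such.
    """
    if portraits.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    cols = list(portraits.columns)
    if order_by_age and ages is not None:
        cols = sorted(cols, key=lambda s: ages[s])
    vals = portraits[cols].to_numpy(float)
    sd = vals.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(vals, rowvar=False)
    corr[sd == 0, :] = np.nan
    corr[:, sd == 0] = np.nan
    np.fill_diagonal(corr, np.where(sd > 0, 1.0, np.nan))
    if np.any(sd == 0):
        log.warning("%d zero-variance portraits in PCM", int((sd == 0).sum()))
    return CorrelationMap(cols, pd.DataFrame(corr, index=cols, columns=cols))


def similarity_net(
    portraits: pd.DataFrame, threshold: float = 0.5
) -> nx.Graph:
    """Sample similarity graph: correlation edges plus a maximum spanning tree.

    Edges are kept where the portrait correlation is >= ``threshold``; the
    maximum-spanning tree over correlations is always included so the graph
    stays connected even under a strict threshold.
    """
    pcm = pairwise_correlation_map(portraits, order_by_age=False)
    corr = pcm.matrix
    g = nx.Graph()
    g.add_nodes_from(pcm.samples)
    full = nx.Graph()
    full.add_nodes_from(pcm.samples)
    for i, a in enumerate(pcm.samples):
        for b in pcm.samples[i + 1:]:
            r = corr.loc[a, b]
            if np.isnan(r):
                continue
            full.add_edge(a, b, weight=float(r))
            if r >= threshold:
                g.add_edge(a, b, weight=float(r))
    mst = nx.maximum_spanning_tree(full, weight="weight")
    g.add_edges_from(mst.edges(data=True))
    return g


def _wto(profiles: pd.DataFrame) -> pd.DataFrame:
    """Weighted topological overlap between spot profiles.

    Adjacency is the absolute Pearson correlation between per-sample spot
    profiles; the overlap of spots i, j is the soft count of shared
    neighbors normalized by the smaller connectivity:
    ``w_ij = (sum_{u != i,j} a_iu * a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)``.
    """
    a = np.abs(np.corrcoef(profiles.to_numpy(float)))
    np.fill_diagonal(a, 0.0)
    n = a.shape[0]
    k = a.sum(axis=1)
    l = a @ a  # l_ij includes u = i and u = j terms, both zero since a_ii = 0
    w = np.ones((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                w[i, j] = (l[i, j] + a[i, j]) / (min(k[i], k[j]) + 1.0 - a[i, j])
    return pd.DataFrame(w, index=profiles.index, columns=profiles.index)


def supporting_maps(
    model: SOMPortrayal,
    spots=None,
    bins: int = 25,
    variance_percentile: float = 20.0,
) -> SupportingMaps:
    """Population, variance, significance, entropy, wTO and invariant region.

    Significance is a two-sided one-sample t-test of each node's values
    against zero (omitted with fewer than 3 samples; constant nodes NaN).
    The invariant region is the largest 8-connected set of nodes below the
    ``variance_percentile``-th percentile of node variance.
    """
    shape = (model.rows, model.cols)
    population = model.node_counts_.reshape(shape)
    cb = model.codebook_
    variance = cb.var(axis=1, ddof=1).reshape(shape)

    significance = None
    if cb.shape[1] >= 3:
        p = np.full(cb.shape[0], np.nan)
        varying = cb.std(axis=1) > 0
        if varying.any():
            res = stats.ttest_1samp(cb[varying], 0.0, axis=1)
            p[varying] = res.pvalue
        significance = p.reshape(shape)

    entropy = pd.Series(
        {s: shannon_entropy(cb[:, j], bins=bins) for j, s in enumerate(model.sample_ids_)},
        name="entropy",
    )

    wto = None
    if spots is not None and len(spots.spots) >= 2:
        profiles = {}
        for lab, spot in spots.spots.items():
            profiles[lab] = cb[sorted(spot.nodes)].mean(axis=0)
        wto = _wto(pd.DataFrame(profiles).T)

    thr = np.percentile(variance, variance_percentile)
    mask = variance <= thr
    labeled, n_comp = ndimage.label(mask, structure=_CONN8)
    invariant = np.array([], dtype=int)
    if n_comp:
        sizes = ndimage.sum_labels(mask, labeled, index=np.arange(1, n_comp + 1))
        best = 1 + int(np.argmax(sizes))
        invariant = np.flatnonzero((labeled == best).ravel())
    return SupportingMaps(population, variance, significance, entropy, wto, invariant)


def sample_summary_stats(
    matrix: OmicsMatrix,
    groups: Mapping[str, str],
    scheme: AgeGroupScheme,
    bins: int = 25,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample mean, variance and entropy over genes, grouped by age.

    Returns the per-sample table and per-group quartile summaries (in
    scheme group order). On lifespan cohorts dominated by developmental and
    aging programs these statistics trace an hourglass: extremal in
    mid-life, wide at both ends of life.
    """
    if not matrix.centralized:
        raise ValueError("summary statistics are defined on a centralized matrix")
    vals = matrix.values
    per_sample = pd.DataFrame(
        {
            "mean": vals.mean(axis=0),
            "variance": vals.var(axis=0, ddof=0),
            "entropy": [shannon_entropy(vals[c].to_numpy(), bins=bins) for c in vals.columns],
        }
    )
    per_sample["group"] = [groups[s] for s in per_sample.index]
    rows = []
    for lab in scheme.labels:
        sub = per_sample[per_sample["group"] == lab]
        if sub.empty:
            continue
        for stat in ("mean", "variance", "entropy"):
            q1, med, q3 = np.percentile(sub[stat], [25, 50, 75])
            rows.append(
                {"group": lab, "statistic": stat, "q25": q1, "median": med, "q75": q3}
            )
    return per_sample, pd.DataFrame(rows)
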