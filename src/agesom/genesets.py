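"""Gene-set analysis on omics portraits.

Covers set-vs-spot overrepresentation (one-sided Fisher exact with
Benjamini-Hochberg adjustment across all set x spot pairs), sample-wise
gene-set Z (GSZ) profiles, smoothed gene-density maps on the grid,
cross-map "spot melting" scores (entropy-based dispersal of a set that is
compact in one map when located in the other), and classification of
expression-methylation coupling from group-ordered mean trajectories.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .preprocess import OmicsMatrix
from .schemes import AgeGroupScheme
from .som import SOMPortrayal

__all__ = [
    "GeneSetCollection",
    "CouplingCall",
    "read_gmt",
    "write_gmt",
    "overrepresentation",
    "enrich_spots",
    "gsz_profile",
    "gene_density_map",
    "melting_score",
    "coupling_classify",
]

log = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named gene lists (GMT-style) with a provenance tag."""

    sets: Dict[str, List[str]]
    provenance: str = ""

    def __post_init__(self) -> None:
        empty = [k for k, v in self.sets.items() if not v]
        for k in empty:
            log.warning("dropping empty gene set %r", k)
            del self.sets[k]

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> List[str]:
        return self.sets[name]

    def items(self):
        return self.sets.items()


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file (name TAB description TAB gene ...).

    Lines with fewer than three fields are skipped with a warning;
    duplicate genes within a set are kept once (first occurrence).
    """
    sets: Dict[str, List[str]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\r\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                log.warning("%s line %d: fewer than 3 fields, skipped", path, ln)
                continue
            name = fields[0]
            genes = list(dict.fromkeys(g for g in fields[2:] if g))
            sets[name] = genes
    return GeneSetCollection(sets, provenance=str(path))


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.items():
            fh.write("\t".join([name, collection.provenance or "na", *genes]) + "\n")


# ------------------------------------------------------------ enrichment


def overrepresentation(
    gene_set: Iterable[str],
    spot_genes: Iterable[str],
    universe: Iterable[str],
) -> Tuple[int, float]:
    """One-sided Fisher exact test for set/spot overlap within a universe.

    Returns ``(overlap, p)`` where ``p = P(X >= overlap)`` under the
    hypergeometric null. Degenerate tables report p = 1.
    """
    uni = set(universe)
    s = set(gene_set) & uni
    sp = set(spot_genes) & uni
    if (set(gene_set) | set(spot_genes)) - uni:
        raise ValueError("universe must contain all set and spot genes")
    if not s:
        raise ValueError("gene set does not intersect the universe")
    overlap = len(s & sp)
    table = [
        [overlap, len(s) - overlap],
        [len(sp) - overlap, len(uni) - len(s) - len(sp) + overlap],
    ]
    if len(s) == len(uni) or len(sp) == len(uni) or len(sp) == 0:
        return overlap, 1.0
    _, p = stats.fisher_exact(table, alternative="greater")
    return overlap, float(min(p, 1.0))


def enrich_spots(
    collection: GeneSetCollection,
    spot_membership: Mapping[str, Sequence[str]],
    universe: Iterable[str],
) -> pd.DataFrame:
    """Fisher overrepresentation of every set in every spot, BH-adjusted.

    The BH family is all set x spot pairs of this invocation. Returns a
    tidy frame with columns set, spot, overlap, p, p_adj.
    """
    uni = set(universe)
    rows = []
    for name, genes in collection.items():
        genes_u = [g for g in genes if g in uni]
        if not genes_u:
            continue
        for spot, members in spot_membership.items():
            ov, p = overrepresentation(genes_u, [m for m in members if m in uni], uni)
            rows.append({"set": name, "spot": spot, "overlap": ov, "p": p})
    out = pd.DataFrame(rows)
    if not out.empty:
        out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


# ------------------------------------------------------------------- GSZ


def gsz_profile(
    gene_set: Iterable[str],
    matrix: OmicsMatrix,
    groups: Optional[Mapping[str, str]] = None,
    scheme: Optional[AgeGroupScheme] = None,
) -> Tuple[pd.Series, Optional[pd.Series]]:
    """Gene-set Z score per sample (and per group when a scheme is given).

    For sample ``s`` with centralized values ``d(g, s)``:
    ``GSZ(s) = (mean_set d - mean_all d) / (sd_all d / sqrt(n_set))``.
    A sample with zero overall standard deviation yields a missing score.
    """
    genes = [g for g in dict.fromkeys(gene_set) if g in matrix.values.index]
    if len(genes) < 2:
        raise ValueError("need at least 2 set genes present in the matrix")
    vals = matrix.values.to_numpy(float)
    sub = matrix.values.loc[genes].to_numpy(float)
    mean_all = vals.mean(axis=0)
    sd_all = vals.std(axis=0, ddof=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (sub.mean(axis=0) - mean_all) / (sd_all / np.sqrt(len(genes)))
    z = np.where(sd_all == 0, np.nan, z)
    per_sample = pd.Series(z, index=matrix.values.columns, name="gsz")
    per_group = None
    if groups is not None and scheme is not None:
        glab = pd.Series({s: groups[s] for s in per_sample.index})
        per_group = pd.Series(
            {
                lab: per_sample[glab[glab == lab].index].mean()
                for lab in scheme.labels
                if (glab == lab).any()
            },
            name="gsz",
        )
    return per_sample, per_group


# ----------------------------------------------------------- density map


def gene_density_map(
    gene_set: Iterable[str], model: SOMPortrayal, bandwidth: float = 1.5
) -> np.ndarray:
    """Gaussian-smoothed 2-D histogram of a set's best-matching nodes.

    The map integrates (sums) to the number of mapped set genes within
    1e-6; smoothing uses a normalized Gaussian kernel evaluated on the
    grid, so no mass escapes the map.
    """
    genes = [g for g in gene_set if g in model.assignment_.index]
    if not genes:
        raise ValueError("no set gene is present in the model")
    nodes = model.assignment_.loc[genes].to_numpy()
    hist = np.bincount(nodes, minlength=model.n_nodes).astype(float)
    ii, jj = np.meshgrid(np.arange(model.rows), np.arange(model.cols), indexing="ij")
    coords = np.column_stack([ii.ravel(), jj.ravel()]).astype(float)
    d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
    kernel = np.exp(-d2 / (2.0 * bandwidth**2))
    kernel /= kernel.sum(axis=0, keepdims=True)  # column-normalized: mass conserved
    density = kernel @ hist
    return density.reshape(model.rows, model.cols)


# --------------------------------------------------------------- melting


def melting_score(
    gene_set: Iterable[str],
    model_src: SOMPortrayal,
    model_dst: SOMPortrayal,
) -> Tuple[float, float, float]:
    """Entropy-based dispersal of a set between two independently trained maps.

    ``H`` is the Shannon entropy of the set's node-occupancy distribution,
    normalized by ``log2(min(n_set, n_nodes))`` so it lies in [0, 1].
    The melting ratio ``H_dst / H_src`` exceeds 1 when the set is more
    dispersed in the destination map — the "spot melting" signature of
    expression-methylation decoupling. Degenerate conventions: both
    entropies 0 -> ratio 1; only the source 0 -> ratio capped at 100.
    """
    genes = [
        g
        for g in dict.fromkeys(gene_set)
        if g in model_src.assignment_.index and g in model_dst.assignment_.index
    ]
    if len(genes) < 5:
        raise ValueError("melting score needs at least 5 shared set genes")

    def _norm_entropy(model: SOMPortrayal) -> float:
        nodes = model.assignment_.loc[genes].to_numpy()
        counts = np.bincount(nodes)
        p = counts[counts > 0] / counts.sum()
        h = -(p * np.log2(p)).sum()
        return float(h / np.log2(min(len(genes), model.n_nodes)))

    h_src = _norm_entropy(model_src)
    h_dst = _norm_entropy(model_dst)
    if h_src == 0.0:
        ratio = 1.0 if h_dst == 0.0 else 100.0
    else:
        ratio = min(h_dst / h_src, 100.0)
    return h_src, h_dst, ratio


# -------------------------------------------------------------- coupling


@dataclass
class CouplingCall:
    """Expression-methylation coupling category of one set/spot/gene."""

    ident: str
    r: float
    slope: float
    category: str  # repressed | de_repressed_RC | decoupled
    degenerate: bool = False


def coupling_classify(
    e_means: Sequence[float],
    m_means: Sequence[float],
    ident: str = "",
    threshold: float = 0.5,
) -> CouplingCall:
    """Classify a group-ordered (methylation, expression) trajectory.

    Pearson r over the group-ordered pairs: ``r <= -threshold`` means
    methylation represses expression ("repressed"); ``r >= +threshold``
    suggests repressive-complex-like positive coupling
    ("de_repressed_RC"); otherwise the pair is "decoupled". Constant
    series are flagged degenerate and reported decoupled.
    """
    e = np.asarray(e_means, float)
    m = np.asarray(m_means, float)
    if e.shape != m.shape or e.size < 3:
        raise ValueError("need >= 3 groups with both expression and methylation means")
    if np.std(e) == 0 or np.std(m) == 0:
        return CouplingCall(ident, np.nan, np.nan, "decoupled", degenerate=True)
    r = float(np.corrcoef(m, e)[0, 1])
    slope = float(np.polyfit(m, e, 1)[0])
    if r <= -threshold:
        cat = "repressed"
    elif r >= threshold:
        cat = "de_repressed_RC"
    else:
        cat = "decoupled"
    return CouplingCall(ident, r, slope, cat)
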