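"""Preprocessing of expression and promoter-methylation matrices.

The pipeline consumes already-normalized measurements: log-scale expression
intensities (genes x samples) and methylation beta values (CpGs x samples)
with a CpG -> (gene, TSS offset) annotation. Preprocessing comprises

1. restriction of CpGs to the promoter window around the TSS and averaging
   of beta values per gene,
2. rescaling of beta (fraction methylated) to the log2 ratio of methylated
   to unmethylated signal (the "M-value" logit transform),
3. removal of sex-chromosome genes, and
4. gene-wise centralization, yielding differential values (delta-e for
   expression, delta-m for methylation) whose per-gene mean over samples
   is zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .schemes import AgeGroupScheme, assign_age_group  # noqa: F401  (re-export)

__all__ = [
    "OmicsMatrix",
    "MethylationInput",
    "beta_to_mratio",
    "mratio_to_beta",
    "aggregate_promoter",
    "filter_autosomal",
    "centralize",
    "collapse_probes",
    "PROMOTER_WINDOW",
]

log = logging.getLogger(__name__)

#: Closed promoter window around the TSS, in bp: [-1500, +500].
PROMOTER_WINDOW: Tuple[int, int] = (-1500, 500)


@dataclass
class OmicsMatrix:
    """Gene x sample numeric matrix with a layer tag.

    ``layer`` is ``"expression"`` (log2 intensities, delta-e once
    centralized) or ``"methylation_log_ratio"`` (log2 methylated/unmethylated
    odds, delta-m once centralized).
    """

    values: pd.DataFrame
    layer: str = "expression"
    centralized: bool = False

    def __post_init__(self) -> None:
        if self.layer not in ("expression", "methylation_log_ratio"):
            raise ValueError(f"unknown layer {self.layer!r}")
        if self.values.index.has_duplicates:
            raise ValueError("duplicated feature ids in matrix")
        if self.centralized:
            means = np.nanmean(self.values.to_numpy(float), axis=1)
            if np.nanmax(np.abs(means), initial=0.0) > 1e-9:
                raise ValueError("matrix flagged centralized but row means exceed 1e-9")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def subset_genes(self, genes) -> "OmicsMatrix":
        return replace(self, values=self.values.loc[genes])


@dataclass
class MethylationInput:
    """CpG-level beta matrix plus CpG annotation.

    ``annotation`` must contain columns ``gene_id``, ``tss_offset`` and
    optionally ``chromosome``, indexed by CpG id.
    """

    beta: pd.DataFrame
    annotation: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.beta.to_numpy(float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("beta values must lie in [0, 1]")
        missing = self.beta.index.difference(self.annotation.index)
        if len(missing):
            raise ValueError(
                f"{len(missing)} CpGs lack annotation rows (e.g. {missing[0]!r})"
            )


def beta_to_mratio(beta, eps: float = 1e-3):
    """Rescale beta values to log2 methylated/unmethylated ratios.

    ``log2(b / (1 - b))`` with ``b`` clamped to ``[eps, 1 - eps]`` so the
    boundary values 0 and 1 stay finite. Strictly increasing in beta on the
    unclamped range; ``beta_to_mratio(0.5) == 0``.
    """
    if not 0 < eps < 0.5:
        raise ValueError(f"eps must be in (0, 0.5), got {eps}")
    arr = np.asarray(beta, dtype=float)
    mask = np.isfinite(arr)
    if np.any((arr[mask] < 0) | (arr[mask] > 1)):
        bad = arr[mask][(arr[mask] < 0) | (arr[mask] > 1)][0]
        raise ValueError(f"beta value outside [0, 1]: {bad}")
    clamped = np.clip(arr, eps, 1 - eps)
    out = np.log2(clamped / (1.0 - clamped))
    if isinstance(beta, pd.DataFrame):
        return pd.DataFrame(out, index=beta.index, columns=beta.columns)
    if isinstance(beta, pd.Series):
        return pd.Series(out, index=beta.index)
    if np.isscalar(beta):
        return float(out)
    return out


def mratio_to_beta(m):
    """Inverse of :func:`beta_to_mratio` on the unclamped range."""
    arr = np.asarray(m, dtype=float)
    out = 1.0 / (1.0 + np.exp2(-arr))
    if np.isscalar(m):
        return float(out)
    return out


def aggregate_promoter(
    data: MethylationInput,
    window: Tuple[int, int] = PROMOTER_WINDOW,
) -> Tuple[pd.DataFrame, list]:
    """Average beta over each gene's promoter-window CpGs.

    CpGs with TSS offset inside the closed window are averaged per gene
    (unweighted mean, NaNs ignored). Returns the gene x sample beta matrix
    and the list of genes dropped for lacking in-window CpGs.
    """
    if data.beta.size == 0:
        raise ValueError("empty beta matrix")
    lo, hi = window
    annot = data.annotation.loc[data.beta.index]
    offsets = annot["tss_offset"].astype(float)
    in_window = (offsets >= lo) & (offsets <= hi)
    all_genes = pd.unique(annot["gene_id"])
    kept = data.beta.loc[in_window.to_numpy()]
    genes = annot.loc[in_window.to_numpy(), "gene_id"].to_numpy()
    agg = kept.groupby(genes, sort=False).mean()
    dropped = sorted(set(all_genes) - set(agg.index))
    if dropped:
        log.info("aggregate_promoter: dropped %d genes without in-window CpGs", len(dropped))
    return agg, dropped


_SEX_CHROMS = {"x", "y", "chrx", "chry", "23", "24"}


def filter_autosomal(
    matrix: pd.DataFrame, chromosome: Mapping[str, str]
) -> pd.DataFrame:
    """Drop rows on chromosomes X/Y (case-insensitive, 'chr' prefix optional).

    Genes without a chromosome label are retained and logged. Row order of
    the remaining genes is preserved.
    """
    keep = []
    n_missing = 0
    for g in matrix.index:
        chrom = chromosome.get(g)
        if chrom is None:
            n_missing += 1
            keep.append(g)
        elif str(chrom).strip().lower() not in _SEX_CHROMS:
            keep.append(g)
    if n_missing:
        log.info("filter_autosomal: %d genes lack chromosome labels; retained", n_missing)
    return matrix.loc[keep]


def centralize(matrix, layer: str = "expression") -> OmicsMatrix:
    """Subtract each gene's mean over samples (idempotent).

    Accepts a DataFrame or an :class:`OmicsMatrix`; returns a centralized
    :class:`OmicsMatrix` whose row means are zero within 1e-9. Isolated
    missing values are imputed with the row mean before centering.
    """
    if isinstance(matrix, OmicsMatrix):
        layer = matrix.layer
        df = matrix.values
    else:
        df = matrix
    if df.shape[1] < 2:
        raise ValueError("centralization needs at least 2 samples")
    vals = df.to_numpy(float).copy()
    all_nan = np.all(~np.isfinite(vals), axis=1)
    if all_nan.any():
        bad = df.index[all_nan][0]
        raise ValueError(f"gene {bad!r} has no finite values")
    row_means = np.nanmean(vals, axis=1, keepdims=True)
    nan_mask = ~np.isfinite(vals)
    if nan_mask.any():
        vals[nan_mask] = np.broadcast_to(row_means, vals.shape)[nan_mask]
    centered = vals - vals.mean(axis=1, keepdims=True)
    out = pd.DataFrame(centered, index=df.index, columns=df.columns)
    return OmicsMatrix(values=out, layer=layer, centralized=True)


def collapse_probes(
    matrix: pd.DataFrame, probe_to_gene: Mapping[str, str]
) -> pd.DataFrame:
    """Optional probe->gene collapse keeping the highest-variance probe."""
    gene = pd.Series({p: probe_to_gene.get(p, p) for p in matrix.index})
    variances = matrix.var(axis=1)
    order = variances.sort_values(ascending=False).index
    seen: dict = {}
    for probe in order:
        seen.setdefault(gene[probe], probe)
    chosen = [seen[g] for g in pd.unique(gene[matrix.index])]
    out = matrix.loc[chosen]
    out.index = [gene[p] for p in chosen]
    return out
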