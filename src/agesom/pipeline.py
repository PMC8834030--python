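"""End-to-end pipeline driver.

Ties the stages together for one data layer: input (or simulation) ->
preprocessing -> SOM training -> group portraits -> spot modules -> spot
profiles -> summary statistics (-> gene-set enrichment when a GMT is
supplied), writing TSV outputs and the verbatim run configuration into
the output directory.
"""

from __future__ import annotations

import logging
import pathlib
from dataclasses import dataclass
from typing import Optional

import pandas as pd

from . import io as aio
from .genesets import enrich_spots, read_gmt
from .portraits import (
    group_mean_portraits,
    pairwise_correlation_map,
    sample_summary_stats,
    similarity_net,
    supporting_maps,
)
from .preprocess import (
    MethylationInput,
    OmicsMatrix,
    aggregate_promoter,
    beta_to_mratio,
    centralize,
    filter_autosomal,
)
from .schemes import EXPRESSION_SCHEME, METHYLATION_SCHEME, AgeGroupScheme
from .simulate import cohort_spec_from_dict, generate_cohort
from .som import SOMPortrayal
from .spots import SpotSet, detect_spots, spot_profiles

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    matrix: OmicsMatrix
    model: SOMPortrayal
    group_portraits: pd.DataFrame
    spotset: SpotSet
    metadata: pd.DataFrame
    scheme: AgeGroupScheme


def prepare_layer(config: aio.RunConfig) -> tuple:
    """Load or simulate inputs and return (centralized matrix, metadata, scheme)."""
    scheme = EXPRESSION_SCHEME if config.scheme == "expression" else METHYLATION_SCHEME
    if config.simulate is not None:
        spec = cohort_spec_from_dict({**config.simulate, "scheme": config.scheme})
        cohort = generate_cohort(spec)
        meta = cohort.metadata
        if config.scheme == "expression":
            matrix = centralize(cohort.expression)
        else:
            agg, _ = aggregate_promoter(
                MethylationInput(cohort.beta, cohort.cpg_annotation)
            )
            matrix = centralize(beta_to_mratio(agg), layer="methylation_log_ratio")
        return matrix, meta, scheme
    meta = aio.read_metadata(config.metadata)
    if "group" not in meta.columns:
        meta["group"] = [scheme.assign(a) for a in meta["age_years"]]
    if config.scheme == "expression":
        raw = aio.read_matrix(config.expression)
        layer = "expression"
    else:
        beta = aio.read_matrix(config.beta)
        annot = pd.read_csv(config.cpg_annotation, sep="\t", index_col=0)
        raw, _ = aggregate_promoter(MethylationInput(beta, annot))
        if "chromosome" in annot.columns:
            chrom = dict(zip(annot["gene_id"], annot["chromosome"]))
            raw = filter_autosomal(raw, chrom)
        raw = beta_to_mratio(raw)
        layer = "methylation_log_ratio"
    matrix = centralize(raw, layer=layer)
    return matrix, meta, scheme


def run_pipeline(config: aio.RunConfig) -> PipelineResult:
    """Run the full portrayal pipeline for one layer and write outputs."""
    out = pathlib.Path(config.out)
    out.mkdir(parents=True, exist_ok=True)
    config.dump(out)
    matrix, meta, scheme = prepare_layer(config)
    groups = meta["group"].to_dict()
    ages = meta["age_years"].to_dict()
    log.info("matrix: %d genes x %d samples", *matrix.values.shape)

    model = SOMPortrayal(**config.som).fit(matrix)
    portraits = model.portraits()
    gp = group_mean_portraits(portraits, groups, scheme)
    spotset = detect_spots(
        model,
        gp,
        scheme,
        q=float(config.spots.get("q", 75.0)),
        min_size=int(config.spots.get("min_size", 4)),
        layer=matrix.layer,
    )
    per_group, per_sample_prof = spot_profiles(spotset, matrix, groups, scheme)
    pcm = pairwise_correlation_map(portraits, ages=ages)
    net = similarity_net(portraits)
    maps = supporting_maps(model, spots=spotset)
    stats_sample, stats_group = sample_summary_stats(matrix, groups, scheme)

    portraits.to_csv(out / "portraits.tsv", sep="\t")
    gp.to_csv(out / "group_portraits.tsv", sep="\t")
    pcm.matrix.to_csv(out / "pcm.tsv", sep="\t")
    pd.DataFrame(
        [(a, b, d["weight"]) for a, b, d in net.edges(data=True)],
        columns=["sample_a", "sample_b", "correlation"],
    ).to_csv(out / "similarity_net_edges.tsv", sep="\t", index=False)
    spotset.report().to_csv(out / "spots.tsv", sep="\t", index=False)
    spotset.membership().to_csv(out / "spot_membership.tsv", sep="\t")
    per_group.to_csv(out / "spot_profiles_by_group.tsv", sep="\t")
    per_sample_prof.to_csv(out / "spot_profiles_by_sample.tsv", sep="\t")
    aio.write_grid(spotset.summary, out / "summary_map.tsv")
    aio.write_grid(spotset.mask.astype(int), out / "spot_mask.tsv")
    aio.write_grid(maps.population, out / "population_map.tsv")
    aio.write_grid(maps.variance, out / "variance_map.tsv")
    if maps.significance is not None:
        aio.write_grid(maps.significance, out / "significance_map.tsv")
    maps.entropy.to_csv(out / "sample_entropy.tsv", sep="\t")
    if maps.wto is not None:
        maps.wto.to_csv(out / "spot_wto.tsv", sep="\t")
    stats_sample.to_csv(out / "sample_summary_stats.tsv", sep="\t")
    stats_group.to_csv(out / "group_summary_stats.tsv", sep="\t", index=False)
    model.training_log_.to_csv(out / "training_log.tsv", sep="\t", index=False)

    if config.gene_sets:
        sets = read_gmt(config.gene_sets)
        membership = {lab: s.genes for lab, s in spotset.spots.items()}
        enr = enrich_spots(sets, membership, matrix.values.index)
        enr.to_csv(out / "spot_enrichment.tsv", sep="\t", index=False)
    return PipelineResult(matrix, model, gp, spotset, meta, scheme)
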