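"""Chromatin-state strata across developmental stages.

Genes carry one chromatin state per developmental stage (fetal or adult
brain): active or poised promoters (TssA, TssP), transcription (Tx),
enhancer-like states (Enh, EnhG, EnhP), zinc-finger (ZNF), quiescent
(Quies), heterochromatin (Het, HetRpts) and polycomb-repressed states
(RepPC, RepPCWk). For each state, genes split into three strata: those
holding the state in the fetal stage only, in the adult stage only, or in
both ("overlap"). Each stratum is then profiled as a gene set (GSZ) on the
expression and methylation layers, and its joint trajectory is classified
for expression-methylation coupling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Set, Tuple

import pandas as pd

from .genesets import coupling_classify, gsz_profile
from .preprocess import OmicsMatrix
from .schemes import AgeGroupScheme

__all__ = [
    "CHROMATIN_STATES",
    "StateAssignment",
    "StateStrata",
    "read_state_table",
    "build_strata",
    "strata_profiles",
    "states_from_segments",
]

log = logging.getLogger(__name__)

CHROMATIN_STATES = (
    "TssA", "TssP", "Tx", "Enh", "EnhG", "EnhP", "ZNF",
    "Quies", "Het", "HetRpts", "RepPC", "RepPCWk",
)

STRATA = ("fetal_only", "overlap", "adult_only")


@dataclass
class StateAssignment:
    """Gene -> chromatin state for one developmental stage."""

    stage: str  # fetal | adult
    states: Dict[str, str]
    collapse_weak: bool = False

    def __post_init__(self) -> None:
        if self.stage not in ("fetal", "adult"):
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.collapse_weak:
            self.states = {
                g: ("RepPC" if s == "RepPCWk" else s) for g, s in self.states.items()
            }
        bad = sorted({s for s in self.states.values() if s not in CHROMATIN_STATES})
        if bad:
            raise ValueError(f"unknown chromatin state labels: {bad}")


@dataclass
class StateStrata:
    """Per-state fetal-only / overlap / adult-only gene sets."""

    strata: Dict[str, Dict[str, Set[str]]]

    def counts(self) -> pd.DataFrame:
        rows = [
            {"state": st, **{k: len(v) for k, v in groups.items()}}
            for st, groups in self.strata.items()
        ]
        return pd.DataFrame(rows).set_index("state")


def read_state_table(path, stage: str, collapse_weak: bool = False) -> StateAssignment:
    """Read a two-column gene_id TAB state TSV (header optional)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if str(df.iloc[0, 1]) not in CHROMATIN_STATES:  # header row
        df = df.iloc[1:]
    states = dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
    return StateAssignment(stage=stage, states=states, collapse_weak=collapse_weak)


def build_strata(fetal: StateAssignment, adult: StateAssignment) -> StateStrata:
    """Split each state's genes into fetal-only / overlap / adult-only.

    Genes absent from a stage's table are simply absent from that stage's
    side (they are not treated as quiescent).
    """
    if fetal.stage != "fetal" or adult.stage != "adult":
        raise ValueError("expected one fetal and one adult assignment")
    states = sorted(set(fetal.states.values()) | set(adult.states.values()))
    strata: Dict[str, Dict[str, Set[str]]] = {}
    for st in states:
        fset = {g for g, s in fetal.states.items() if s == st}
        aset = {g for g, s in adult.states.items() if s == st}
        strata[st] = {
            "fetal_only": fset - aset,
            "overlap": fset & aset,
            "adult_only": aset - fset,
        }
    return StateStrata(strata)


def strata_profiles(
    strata: StateStrata,
    expression: OmicsMatrix,
    methylation: OmicsMatrix,
    groups_e: Mapping[str, str],
    groups_m: Mapping[str, str],
    scheme_e: AgeGroupScheme,
    scheme_m: AgeGroupScheme,
) -> Tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """GSZ age profiles of every stratum on both layers, plus coupling calls.

    Returns ``(profiles, couplings, counts)``: tidy per-(state, stratum,
    layer, group) GSZ values; per-(state, stratum) coupling classification
    of the group-ordered (methylation, expression) trajectory restricted to
    the groups the two schemes share; and the strata count table. Strata
    with fewer than two genes on a layer are skipped with a warning.
    """
    prof_rows = []
    coup_rows = []
    for st, groups in strata.strata.items():
        for stratum, genes in groups.items():
            per_layer = {}
            for layer, matrix, glab, scheme in (
                ("expression", expression, groups_e, scheme_e),
                ("methylation", methylation, groups_m, scheme_m),
            ):
                present = [g for g in genes if g in matrix.values.index]
                if len(present) < 2:
                    log.warning(
                        "stratum %s/%s: <2 genes on %s layer, skipped", st, stratum, layer
                    )
                    continue
                _, per_group = gsz_profile(present, matrix, glab, scheme)
                per_layer[layer] = per_group
                for grp, val in per_group.items():
                    prof_rows.append(
                        {
                            "state": st,
                            "stratum": stratum,
                            "layer": layer,
                            "group": grp,
                            "gsz": val,
                        }
                    )
            if len(per_layer) == 2:
                shared = [
                    g
                    for g in scheme_e.labels
                    if g in per_layer["expression"].index
                    and g in per_layer["methylation"].index
                ]
                if len(shared) >= 3:
                    call = coupling_classify(
                        per_layer["expression"][shared],
                        per_layer["methylation"][shared],
                        ident=f"{st}:{stratum}",
                    )
                    coup_rows.append(
                        {
                            "state": st,
                            "stratum": stratum,
                            "r": call.r,
                            "slope": call.slope,
                            "category": call.category,
                        }
                    )
    return pd.DataFrame(prof_rows), pd.DataFrame(coup_rows), strata.counts()


def states_from_segments(
    segments: pd.DataFrame,
    tss: pd.DataFrame,
    stage: str,
    collapse_weak: bool = False,
) -> StateAssignment:
    """Derive gene states from genomic state segments (optional importer).

    ``segments`` has columns chrom, start, end (half-open, 0-based as in
    BED), state; ``tss`` is indexed by gene id with columns chrom and tss
    (and optionally strand, already applied to the tss coordinate). A
    gene's state is the state of the segment overlapping its TSS; when
    several segments touch it, the longest overlap wins.
    """
    states: Dict[str, str] = {}
    by_chrom = {c: df.sort_values("start") for c, df in segments.groupby("chrom")}
    for gene, row in tss.iterrows():
        segs = by_chrom.get(row["chrom"])
        if segs is None:
            continue
        pos = int(row["tss"])
        hit = segs[(segs["start"] <= pos) & (pos < segs["end"])]
        if hit.empty:
            continue
        if len(hit) > 1:
            hit = hit.assign(length=hit["end"] - hit["start"]).sort_values(
                "length", ascending=False
            )
        states[gene] = str(hit.iloc[0]["state"])
    return StateAssignment(stage=stage, states=states, collapse_weak=collapse_weak)
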