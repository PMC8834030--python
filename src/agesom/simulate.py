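"""Synthetic paired expression/methylation cohorts with planted aging modes.

The generator emulates a lifespan brain cohort: gene modules ("modes")
follow canonical age courses (monotone rise/decay, U / inverse-U reversal,
early or late peaks) over an ordered age-group scheme, and each module's
promoter methylation is coupled to its expression — antagonistically
(methylation represses transcription), positively (repressive-complex-like
co-gain), or not at all (decoupled). Coupling acts on the log2-odds (logit)
scale so beta values stay inside (0, 1). Every generated gene and sample is
recorded in a ground-truth table, which is what downstream recovery tests
are scored against.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .preprocess import OmicsMatrix, mratio_to_beta
from .schemes import EXPRESSION_SCHEME, METHYLATION_SCHEME, AgeGroupScheme

__all__ = [
    "ModeSpec",
    "CohortSpec",
    "SimulatedCohort",
    "mode_profile",
    "generate_cohort",
    "expression_fixture_spec",
    "methylation_fixture_spec",
    "coupling_fixture_spec",
    "hourglass_fixture_spec",
    "cohort_spec_from_dict",
    "load_cohort_spec",
    "write_cohort",
]

SHAPES = ("monotone_up", "monotone_down", "U", "inverse_U",
          "early_peak", "late_peak", "peak", "flat")

_PEAK_SIGMA = 0.15


def mode_profile(
    shape: str,
    scheme: AgeGroupScheme,
    peak_center: Optional[float] = None,
    peak_sigma: Optional[float] = None,
) -> np.ndarray:
    """Canonical per-group age course for a planted mode.

    Profiles are parameterized on the normalized group index ``t`` in
    ``[0, 1]``: monotone courses are linear in ``t``, U / inverse-U are
    quadratic with their extremum at the middle group, and peak shapes are
    Gaussian bumps (sigma 0.15) centered at ``t = 0.15`` (early), ``0.85``
    (late) or an explicit ``peak_center``. The returned vector has zero mean
    over groups and maximum absolute value 1; ``flat`` is all zeros.
    """
    n = scheme.n_groups
    if n < 3:
        raise ValueError("mode profiles need a scheme with >= 3 groups")
    t = np.linspace(0.0, 1.0, n)
    if shape == "flat":
        return np.zeros(n)
    if shape == "monotone_up":
        v = 2 * t - 1
    elif shape == "monotone_down":
        v = 1 - 2 * t
    elif shape in ("U", "inverse_U"):
        v = 2 * (2 * t - 1) ** 2 - 1
        if shape == "inverse_U":
            v = -v
    elif shape in ("early_peak", "late_peak", "peak"):
        if shape == "early_peak":
            c = 0.15 if peak_center is None else peak_center
        elif shape == "late_peak":
            c = 0.85 if peak_center is None else peak_center
        else:
            if peak_center is None:
                raise ValueError("shape 'peak' requires peak_center")
            c = peak_center
        sigma = _PEAK_SIGMA if peak_sigma is None else peak_sigma
        v = np.exp(-((t - c) ** 2) / (2 * sigma**2))
    else:
        raise ValueError(f"unknown mode shape {shape!r}")
    v = v - v.mean()
    return v / np.max(np.abs(v))


@dataclass(frozen=True)
class ModeSpec:
    """One planted gene module.

    ``layer`` selects on which data layer the shape is planted directly;
    the other layer follows through the coupling. ``coupling_strength`` is
    the fraction of the amplitude transmitted to the coupled layer.
    """

    shape: str
    amplitude: float
    n_genes: int
    coupling: str = "antagonistic"
    coupling_strength: float = 1.0
    layer: str = "expression"
    peak_center: Optional[float] = None
    peak_sigma: Optional[float] = None

    def __post_init__(self) -> None:
        if self.shape not in SHAPES:
            raise ValueError(f"unknown mode shape {self.shape!r}")
        if not np.isfinite(self.amplitude) or self.amplitude < 0:
            raise ValueError("amplitude must be finite and >= 0")
        if self.shape == "flat" and self.amplitude != 0:
            raise ValueError("flat modes must have amplitude 0")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.coupling not in ("antagonistic", "positive", "decoupled"):
            raise ValueError(f"unknown coupling {self.coupling!r}")
        if not 0.0 <= self.coupling_strength <= 1.0:
            raise ValueError("coupling_strength must be in [0, 1]")
        if self.layer not in ("expression", "methylation"):
            raise ValueError(f"unknown layer {self.layer!r}")


@dataclass(frozen=True)
class CohortSpec:
    """Full recipe for one paired cohort."""

    scheme: AgeGroupScheme
    n_per_group: int
    modes: Tuple[ModeSpec, ...]
    n_background_genes: int
    noise_sd: float = 0.3
    baseline_beta: float = 0.3
    baseline_expression: float = 7.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "modes", tuple(self.modes))
        for name in ("noise_sd", "baseline_beta", "baseline_expression"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 < self.baseline_beta < 1:
            raise ValueError("baseline_beta must be in (0, 1)")
        if self.n_per_group < 1 or self.n_background_genes < 0:
            raise ValueError("invalid cohort sizes")

    @property
    def n_genes(self) -> int:
        return sum(m.n_genes for m in self.modes) + self.n_background_genes


@dataclass
class SimulatedCohort:
    """Generator output: data layers, annotation, metadata and ground truth."""

    expression: OmicsMatrix
    beta: pd.DataFrame
    cpg_annotation: pd.DataFrame
    metadata: pd.DataFrame
    truth: pd.DataFrame
    spec: CohortSpec

    @property
    def scheme(self) -> AgeGroupScheme:
        return self.spec.scheme


def _logit2(b: float) -> float:
    return float(np.log2(b / (1.0 - b)))


def _random_decoupled_profile(
    rng: np.random.Generator, reference: np.ndarray, scheme: AgeGroupScheme
) -> np.ndarray:
    """Independent random mode whose course is uncorrelated with ``reference``.

    Draws shape and sign until |Pearson r| with the reference profile is
    below 0.3, so "decoupled" genes are genuinely decoupled rather than
    coupled by a chance draw.
    """
    candidates = [s for s in SHAPES if s not in ("flat", "peak")]
    for _ in range(200):
        shape = candidates[rng.integers(len(candidates))]
        sign = 1.0 if rng.random() < 0.5 else -1.0
        prof = sign * mode_profile(shape, scheme)
        r = np.corrcoef(prof, reference)[0, 1]
        if abs(r) < 0.3:
            return prof
    raise RuntimeError("could not draw a decoupled profile")  # pragma: no cover


def generate_cohort(spec: CohortSpec) -> SimulatedCohort:
    """Generate a paired expression/methylation cohort from a spec.

    Deterministic under a fixed spec (including its seed): expression values
    are baseline + amplitude * mode profile + Gaussian noise; promoter CpG
    beta values are the inverse (base-2) logit of the gene's methylation
    course around its baseline log-odds, with noise added on the logit
    scale; each gene emits 1-5 CpGs at TSS offsets inside [-1500, +500].
    """
    rng = np.random.default_rng(spec.seed)
    scheme = spec.scheme

    # --- samples: ages drawn uniformly inside each group's (clipped) range
    sample_ids: List[str] = []
    ages: List[float] = []
    groups: List[str] = []
    for lab in scheme.labels:
        lo, hi = scheme.ranges[lab]
        lo = max(lo, -0.75)
        hi = min(hi, 90.0)
        a = np.sort(rng.uniform(lo, hi, size=spec.n_per_group))
        for k, age in enumerate(a):
            sample_ids.append(f"S_{lab}_{k:02d}")
            ages.append(float(age))
            groups.append(lab)
    n_samples = len(sample_ids)
    group_idx = np.array([scheme.index(g) for g in groups])

    # --- per-gene expression/methylation courses (per group, in log2 units)
    gene_ids: List[str] = []
    mode_of_gene: List[int] = []
    coupling_of_gene: List[str] = []
    shape_of_gene: List[str] = []
    e_courses: List[np.ndarray] = []
    m_courses: List[np.ndarray] = []
    zero = np.zeros(scheme.n_groups)
    for mi, mode in enumerate(spec.modes):
        prof = mode.amplitude * mode_profile(mode.shape, scheme, mode.peak_center, mode.peak_sigma)
        for gi in range(mode.n_genes):
            gene_ids.append(f"g_m{mi}_{gi:04d}")
            mode_of_gene.append(mi)
            coupling_of_gene.append(mode.coupling)
            shape_of_gene.append(mode.shape)
            if mode.coupling == "antagonistic":
                coupled = -mode.coupling_strength * prof
            elif mode.coupling == "positive":
                coupled = mode.coupling_strength * prof
            elif mode.amplitude == 0:
                coupled = zero
            else:  # decoupled: independent random mode on the other layer
                ref = mode_profile(mode.shape, scheme, mode.peak_center, mode.peak_sigma)
                coupled = mode.amplitude * _random_decoupled_profile(rng, ref, scheme)
            if mode.layer == "expression":
                e_courses.append(prof)
                m_courses.append(coupled)
            else:
                m_courses.append(prof)
                e_courses.append(coupled)
    for gi in range(spec.n_background_genes):
        gene_ids.append(f"g_bg_{gi:04d}")
        mode_of_gene.append(-1)
        coupling_of_gene.append("background")
        shape_of_gene.append("flat")
        e_courses.append(zero)
        m_courses.append(zero)
    n_genes = len(gene_ids)
    e_course_mat = np.vstack(e_courses)  # genes x groups
    m_course_mat = np.vstack(m_courses)

    # --- expression matrix
    expr = (
        spec.baseline_expression
        + e_course_mat[:, group_idx]
        + rng.normal(0.0, spec.noise_sd, size=(n_genes, n_samples))
    )
    expression = OmicsMatrix(
        values=pd.DataFrame(expr, index=gene_ids, columns=sample_ids),
        layer="expression",
        centralized=False,
    )

    # --- methylation: per-gene baseline log-odds, 1-5 CpGs per gene
    base_logit = _logit2(spec.baseline_beta) + rng.normal(0.0, 0.5, size=n_genes)
    chroms = rng.integers(1, 23, size=n_genes)
    n_cpgs = rng.integers(1, 6, size=n_genes)
    cpg_rows: List[np.ndarray] = []
    cpg_ids: List[str] = []
    annot_rows: List[Tuple[str, str, int, str]] = []
    for g in range(n_genes):
        gene_track = base_logit[g] + m_course_mat[g, group_idx]
        offsets = rng.integers(-1500, 501, size=n_cpgs[g])
        for c in range(n_cpgs[g]):
            cpg_id = f"cg_{gene_ids[g]}_{c}"
            noise = rng.normal(0.0, spec.noise_sd, size=n_samples)
            cpg_rows.append(mratio_to_beta(gene_track + noise))
            cpg_ids.append(cpg_id)
            annot_rows.append((cpg_id, gene_ids[g], int(offsets[c]), f"chr{chroms[g]}"))
    beta = pd.DataFrame(np.vstack(cpg_rows), index=cpg_ids, columns=sample_ids)
    annotation = pd.DataFrame(
        annot_rows, columns=["cpg_id", "gene_id", "tss_offset", "chromosome"]
    ).set_index("cpg_id")

    metadata = pd.DataFrame(
        {"sample_id": sample_ids, "age_years": ages, "group": groups}
    ).set_index("sample_id")
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "mode": mode_of_gene,
            "coupling": coupling_of_gene,
            "shape": shape_of_gene,
            "chromosome": [f"chr{c}" for c in chroms],
        }
    ).set_index("gene_id")
    return SimulatedCohort(
        expression=expression,
        beta=beta,
        cpg_annotation=annotation,
        metadata=metadata,
        truth=truth,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# default fixtures


def _load_yaml_spec(name: str, seed: int) -> CohortSpec:
    text = (
        importlib.resources.files("agesom.data").joinpath(name).read_text()
    )
    cfg = yaml.safe_load(text)
    cfg["seed"] = seed
    return cohort_spec_from_dict(cfg)


def expression_fixture_spec(seed: int = 1) -> CohortSpec:
    """Default expression cohort: seven planted modules with age-swept peaks."""
    return _load_yaml_spec("expression_fixture.yaml", seed)


def methylation_fixture_spec(seed: int = 1) -> CohortSpec:
    """Default methylation cohort: five hyper-methylation modules, 7 groups."""
    return _load_yaml_spec("methylation_fixture.yaml", seed)


def coupling_fixture_spec(seed: int = 1) -> CohortSpec:
    """Cohort with one module per coupling class, for coupling recovery."""
    return CohortSpec(
        scheme=EXPRESSION_SCHEME,
        n_per_group=6,
        modes=(
            ModeSpec("monotone_down", 2.0, 200, coupling="antagonistic"),
            ModeSpec("inverse_U", 2.0, 200, coupling="positive"),
            ModeSpec("late_peak", 2.0, 200, coupling="decoupled"),
        ),
        n_background_genes=1000,
        noise_sd=0.3,
        seed=seed,
    )


def hourglass_fixture_spec(seed: int = 1) -> CohortSpec:
    """Monotone-modes cohort whose gene variance is minimal at mid-life."""
    return CohortSpec(
        scheme=EXPRESSION_SCHEME,
        n_per_group=6,
        modes=(
            ModeSpec("monotone_down", 2.0, 200, coupling="antagonistic"),
            ModeSpec("monotone_up", 2.0, 200, coupling="antagonistic"),
        ),
        n_background_genes=600,
        noise_sd=0.3,
        seed=seed,
    )


_SCHEMES = {"expression": EXPRESSION_SCHEME, "methylation": METHYLATION_SCHEME}


def cohort_spec_from_dict(cfg: dict) -> CohortSpec:
    """Build a CohortSpec from a plain dict (YAML config contents)."""
    scheme = cfg["scheme"]
    if isinstance(scheme, str):
        scheme = _SCHEMES[scheme]
    modes = tuple(ModeSpec(**m) for m in cfg["modes"])
    return CohortSpec(
        scheme=scheme,
        n_per_group=int(cfg["n_per_group"]),
        modes=modes,
        n_background_genes=int(cfg["n_background_genes"]),
        noise_sd=float(cfg.get("noise_sd", 0.3)),
        baseline_beta=float(cfg.get("baseline_beta", 0.3)),
        baseline_expression=float(cfg.get("baseline_expression", 7.0)),
        seed=int(cfg.get("seed", 0)),
    )


def load_cohort_spec(path, seed: Optional[int] = None) -> CohortSpec:
    """Read a cohort spec from a YAML file; ``seed`` overrides the file's."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if seed is not None:
        cfg["seed"] = seed
    return cohort_spec_from_dict(cfg)


def write_cohort(cohort: SimulatedCohort, outdir) -> None:
    """Write the cohort as TSV files (expression, beta, annotation, meta, truth)."""
    import pathlib

    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.expression.values.to_csv(out / "expression.tsv", sep="\t")
    cohort.beta.to_csv(out / "beta.tsv", sep="\t")
    cohort.cpg_annotation.to_csv(out / "cpg_annotation.tsv", sep="\t")
    cohort.metadata.to_csv(out / "metadata.tsv", sep="\t")
    cohort.truth.to_csv(out / "truth.tsv", sep="\t")
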