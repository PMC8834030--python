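"""Tabular readers/writers and run configuration.

All matrices are TSV with a header row of sample ids and feature ids in
the first column; grids are written row-major with row/col indices so
every output diffs cleanly.
"""

from __future__ import annotations

import logging
import pathlib
from dataclasses import asdict, dataclass, field
from typing import Dict, Optional

import numpy as np
import pandas as pd
import yaml

__all__ = ["RunConfig", "read_matrix", "read_metadata", "write_grid", "setup_logging"]

log = logging.getLogger(__name__)


def read_matrix(path, max_missing_fraction: float = 0.2) -> pd.DataFrame:
    """Read a feature x sample TSV matrix.

    The first column holds feature ids, the header row sample ids.
    Duplicated feature ids are rejected; non-numeric cells raise an error
    naming the offending row and column; rows with more than
    ``max_missing_fraction`` missing values are rejected.
    """
    path = pathlib.Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise ValueError(f"{path}: empty matrix")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicated feature id {dup!r}")
    for col in df.columns:
        if df[col].dtype == object:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[coerced.isna() & df[col].notna()]
            if len(bad):
                raise ValueError(
                    f"{path}: non-numeric value at row {bad[0]!r}, column {col!r}"
                )
            df[col] = coerced
    frac_missing = df.isna().mean(axis=1)
    if (frac_missing > max_missing_fraction).any():
        bad = frac_missing.idxmax()
        raise ValueError(
            f"{path}: row {bad!r} exceeds missing-value fraction "
            f"{max_missing_fraction}"
        )
    return df.astype(float)


def read_metadata(path) -> pd.DataFrame:
    """Read a sample metadata TSV (sample_id, age_years, optional group)."""
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns:
        df = df.rename(columns={df.columns[0]: "sample_id"})
    return df.set_index("sample_id")


def write_grid(grid: np.ndarray, path) -> None:
    """Write a rows x cols grid as TSV with row/col indices."""
    pd.DataFrame(
        grid,
        index=pd.RangeIndex(grid.shape[0], name="row"),
        columns=pd.RangeIndex(grid.shape[1]),
    ).to_csv(path, sep="\t")


@dataclass
class RunConfig:
    """Validated configuration of a full pipeline run."""

    expression: Optional[str] = None
    beta: Optional[str] = None
    cpg_annotation: Optional[str] = None
    metadata: Optional[str] = None
    simulate: Optional[dict] = None  # cohort spec dict; replaces file inputs
    scheme: str = "expression"
    som: Dict[str, int] = field(
        default_factory=lambda: {"rows": 40, "cols": 40, "epochs": 50, "seed": 0}
    )
    spots: Dict[str, float] = field(
        default_factory=lambda: {"q": 75.0, "min_size": 4}
    )
    gene_sets: Optional[str] = None  # GMT path
    out: str = "agesom_out"

    def __post_init__(self) -> None:
        if self.scheme not in ("expression", "methylation"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.simulate is None and (self.expression is None or self.metadata is None):
            raise ValueError("config needs either 'simulate' or expression+metadata paths")
        if not 0 < self.spots.get("q", 75.0) <= 100:
            raise ValueError("spot quantile q must be in (0, 100]")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        return cls(**cfg)

    def dump(self, outdir) -> None:
        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "run_config.yaml", "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def setup_logging(outdir: Optional[str] = None) -> None:
    handlers = [logging.StreamHandler()]
    if outdir is not None:
        pathlib.Path(outdir).mkdir(parents=True, exist_ok=True)
        handlers.append(logging.FileHandler(pathlib.Path(outdir) / "run.log"))
    logging.basicConfig(
        level=logging.INFO,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )
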