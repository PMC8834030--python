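"""Batch self-organizing map for gene-level omics portrayal.

Genes (features) are clustered into "metagenes" arranged on a planar
rectangular grid (default 40 x 40). Each grid node carries a prototype
profile over samples (the codebook); a sample's "portrait" is the grid of
codebook values at that sample, i.e. its expression or methylation
landscape image. Training is batch mode: per epoch every gene is assigned
to its best-matching node (minimal Euclidean distance) and the codebook is
recomputed as Gaussian-neighborhood-weighted means under an exponentially
shrinking radius, which makes the fit deterministic and independent of
gene order. After the schedule a final zero-radius step replaces each
populated node's prototype by the plain mean of its assigned genes (empty
nodes are distance-interpolated), so node values equal the mean profile of
their member genes.

Secondary cohorts are projected onto a trained map without retraining
("extension SOM"): each secondary sample's portrait value at a node is the
mean of that sample's values over the genes assigned to the node, leaving
the primary codebook and assignment untouched.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .preprocess import OmicsMatrix

__all__ = ["SOMPortrayal", "Portrait", "train_som", "extend_som"]

log = logging.getLogger(__name__)


@dataclass
class Portrait:
    """One sample's metagene landscape: a rows x cols grid of node values."""

    sample: str
    grid: np.ndarray

    @property
    def flat(self) -> np.ndarray:
        return self.grid.ravel()


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, OmicsMatrix):
        return X.values
    if isinstance(X, pd.DataFrame):
        return X
    raise TypeError("expected an OmicsMatrix or a genes x samples DataFrame")


class SOMPortrayal(BaseEstimator):
    """Batch SOM over gene profiles with portrait and extension support.

    Parameters
    ----------
    rows, cols:
        Grid dimensions (the canonical portrayal uses 40 x 40).
    epochs:
        Number of batch epochs of the annealing schedule.
    radius_start, radius_end:
        Gaussian neighborhood radius at the first and last epoch; the
        radius decays exponentially between them. ``radius_start=None``
        uses ``max(rows, cols) / 2``.
    seed:
        Stored for provenance; training itself is deterministic (principal-
        component initialization, batch updates, index-ordered tie breaks).

    Attributes
    ----------
    codebook_ : ndarray of shape (rows * cols, n_samples)
        Node prototype profiles (row-major node order).
    assignment_ : pandas.Series
        Gene id -> node index of each gene's best-matching unit.
    node_counts_ : ndarray of shape (rows * cols,)
        Number of genes assigned to each node.
    training_log_ : pandas.DataFrame
        Per-epoch radius and quantization error.
    """

    def __init__(
        self,
        rows: int = 40,
        cols: int = 40,
        epochs: int = 50,
        radius_start: Optional[float] = None,
        radius_end: float = 0.5,
        seed: int = 0,
    ):
        self.rows = rows
        self.cols = cols
        self.epochs = epochs
        self.radius_start = radius_start
        self.radius_end = radius_end
        self.seed = seed

    # ------------------------------------------------------------------ fit

    @property
    def n_nodes(self) -> int:
        return self.rows * self.cols

    def _grid_coords(self) -> np.ndarray:
        ii, jj = np.meshgrid(np.arange(self.rows), np.arange(self.cols), indexing="ij")
        return np.column_stack([ii.ravel(), jj.ravel()]).astype(float)

    def _pca_init(self, X: np.ndarray) -> np.ndarray:
        """Linear codebook init spanning the top two principal components."""
        mean = X.mean(axis=0)
        Xc = X - mean
        # deterministic SVD; fix component signs by largest-loading convention
        _, s, vt = np.linalg.svd(Xc, full_matrices=False)
        comps = vt[:2]
        for k in range(comps.shape[0]):
            j = np.argmax(np.abs(comps[k]))
            if comps[k, j] < 0:
                comps[k] = -comps[k]
        sd = s[:2] / np.sqrt(max(X.shape[0] - 1, 1))
        if len(sd) < 2:  # degenerate: fewer than 2 singular values
            sd = np.pad(sd, (0, 2 - len(sd)))
            comps = np.vstack([comps, np.zeros((2 - comps.shape[0], X.shape[1]))])
        coords = self._grid_coords()
        u = coords[:, 0] / max(self.rows - 1, 1) - 0.5
        v = coords[:, 1] / max(self.cols - 1, 1) - 0.5
        return (
            mean
            + np.outer(2.0 * sd[0] * u, comps[0])
            + np.outer(2.0 * sd[1] * v, comps[1])
        )

    def fit(self, X: Union[OmicsMatrix, pd.DataFrame], y=None) -> "SOMPortrayal":
        df = _as_frame(X)
        if isinstance(X, OmicsMatrix) and not X.centralized:
            warnings.warn("training on a non-centralized matrix")
        vals = df.to_numpy(float)
        if not np.all(np.isfinite(vals)):
            raise ValueError("matrix contains non-finite entries")
        n_genes, n_samples = vals.shape
        if n_genes < self.n_nodes:
            warnings.warn(
                f"{n_genes} genes for {self.n_nodes} nodes; grid may be underpopulated"
            )
        coords = self._grid_coords()
        node_d2 = (
            (coords[:, None, :] - coords[None, :, :]) ** 2
        ).sum(-1)  # n_nodes x n_nodes squared grid distances

        codebook = self._pca_init(vals)
        r0 = self.radius_start if self.radius_start is not None else max(self.rows, self.cols) / 2.0
        r1 = self.radius_end
        log_rows = []
        bmu = None
        for epoch in range(self.epochs):
            frac = epoch / max(self.epochs - 1, 1)
            radius = r0 * (r1 / r0) ** frac
            d2 = self._sq_distances(vals, codebook)
            bmu = np.argmin(d2, axis=1)
            qe = float(np.sqrt(d2[np.arange(n_genes), bmu]).mean())
            log_rows.append({"epoch": epoch, "radius": radius, "quantization_error": qe})
            # batch update: neighborhood-weighted means
            counts = np.bincount(bmu, minlength=self.n_nodes).astype(float)
            sums = np.zeros((self.n_nodes, n_samples))
            np.add.at(sums, bmu, vals)
            w = np.exp(-node_d2 / (2.0 * radius**2))
            denom = w @ counts
            numer = w @ sums
            ok = denom > 0
            codebook[ok] = numer[ok] / denom[ok, None]

        # final zero-radius step: populated nodes become plain member means
        # under the final assignment, which is kept, so that each node's
        # prototype is exactly the mean profile of its member genes
        d2 = self._sq_distances(vals, codebook)
        bmu = np.argmin(d2, axis=1)
        counts = np.bincount(bmu, minlength=self.n_nodes).astype(float)
        sums = np.zeros((self.n_nodes, n_samples))
        np.add.at(sums, bmu, vals)
        populated = counts > 0
        codebook[populated] = sums[populated] / counts[populated, None]
        codebook[~populated] = self._interpolate_empty(
            codebook, populated, node_d2
        )
        # quantization error w.r.t. the kept assignment
        qe = float(
            np.sqrt(((vals - codebook[bmu]) ** 2).sum(axis=1)).mean()
        )
        log_rows.append(
            {"epoch": self.epochs, "radius": 0.0, "quantization_error": qe}
        )

        self.codebook_ = codebook
        self.assignment_ = pd.Series(bmu, index=df.index, name="node")
        self.node_counts_ = np.bincount(bmu, minlength=self.n_nodes)
        self.populated_ = self.node_counts_ > 0
        self.sample_ids_ = list(df.columns)
        self.gene_ids_ = list(df.index)
        self.training_log_ = pd.DataFrame(log_rows)
        return self

    @staticmethod
    def _sq_distances(X: np.ndarray, codebook: np.ndarray) -> np.ndarray:
        d2 = (
            (X**2).sum(1)[:, None]
            - 2.0 * X @ codebook.T
            + (codebook**2).sum(1)[None, :]
        )
        np.maximum(d2, 0.0, out=d2)
        return d2

    @staticmethod
    def _interpolate_empty(
        codebook: np.ndarray, populated: np.ndarray, node_d2: np.ndarray
    ) -> np.ndarray:
        """Inverse-squared-grid-distance mean of populated nodes, per empty node."""
        if populated.all():
            return codebook[~populated]
        w = 1.0 / node_d2[np.ix_(~populated, populated)]
        return (w @ codebook[populated]) / w.sum(1)[:, None]

    # ----------------------------------------------------------- inference

    def _check_fitted(self) -> None:
        if not hasattr(self, "codebook_"):
            raise RuntimeError("SOMPortrayal instance is not fitted")

    def predict(self, X) -> np.ndarray:
        """Best-matching node index for each row profile of ``X``."""
        self._check_fitted()
        df = _as_frame(X) if not isinstance(X, np.ndarray) else None
        vals = df.to_numpy(float) if df is not None else np.atleast_2d(X)
        if vals.shape[1] != len(self.sample_ids_):
            raise ValueError(
                f"profile length {vals.shape[1]} != model samples {len(self.sample_ids_)}"
            )
        d2 = self._sq_distances(vals, self.codebook_)
        return np.argmin(d2, axis=1)

    def best_matching_unit(self, profile: Sequence[float]) -> int:
        """Node index minimizing Euclidean distance; ties -> lowest index."""
        return int(self.predict(np.asarray(profile, float)[None, :])[0])

    def portrait(self, sample: str) -> Portrait:
        """The stored codebook column for ``sample``, reshaped to the grid."""
        self._check_fitted()
        if sample not in self.sample_ids_:
            raise KeyError(f"unknown sample {sample!r}")
        j = self.sample_ids_.index(sample)
        return Portrait(sample, self.codebook_[:, j].reshape(self.rows, self.cols))

    def portraits(self) -> pd.DataFrame:
        """All portraits as a nodes x samples frame (row-major node order)."""
        self._check_fitted()
        return pd.DataFrame(
            self.codebook_.copy(),
            index=pd.RangeIndex(self.n_nodes, name="node"),
            columns=self.sample_ids_,
        )

    def transform(self, X) -> pd.DataFrame:
        """Alias for :meth:`extend` (secondary-cohort projection)."""
        return self.extend(X)

    # ------------------------------------------------------------- exSOM

    def extend(self, secondary: Union[OmicsMatrix, pd.DataFrame]) -> pd.DataFrame:
        """Project a secondary cohort onto the frozen map (extension SOM).

        The secondary matrix must share gene ids with the training matrix
        and be centralized over its own samples. Returns a nodes x
        secondary-samples portrait frame; the primary codebook and
        assignment are not modified. Node values are means over the node's
        assigned genes present in the secondary matrix; nodes without any
        such gene are filled by distance-weighted interpolation.
        """
        self._check_fitted()
        df = _as_frame(secondary)
        common = [g for g in self.gene_ids_ if g in set(df.index)]
        if not common:
            raise ValueError("no overlapping genes between model and secondary matrix")
        frac = len(common) / len(self.gene_ids_)
        if frac < 0.5:
            warnings.warn(
                f"only {frac:.0%} of model genes present in the secondary matrix"
            )
        sec = df.loc[common].to_numpy(float)
        nodes = self.assignment_.loc[common].to_numpy()
        counts = np.bincount(nodes, minlength=self.n_nodes).astype(float)
        sums = np.zeros((self.n_nodes, sec.shape[1]))
        np.add.at(sums, nodes, sec)
        filled = counts > 0
        out = np.empty_like(sums)
        out[filled] = sums[filled] / counts[filled, None]
        coords = self._grid_coords()
        node_d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
        if not filled.all():
            w = 1.0 / node_d2[np.ix_(~filled, filled)]
            out[~filled] = (w @ out[filled]) / w.sum(1)[:, None]
        return pd.DataFrame(
            out, index=pd.RangeIndex(self.n_nodes, name="node"), columns=df.columns
        )


    # -------------------------------------------------------- persistence

    def save(self, path) -> None:
        """Serialize the fitted model to a single .npz archive."""
        self._check_fitted()
        np.savez_compressed(
            path,
            codebook=self.codebook_,
            assignment=self.assignment_.to_numpy(),
            gene_ids=np.array(self.gene_ids_, dtype=object),
            sample_ids=np.array(self.sample_ids_, dtype=object),
            dims=np.array([self.rows, self.cols]),
            params=np.array(
                [self.epochs, self.radius_end, self.seed], dtype=float
            ),
            log_epoch=self.training_log_["epoch"].to_numpy(),
            log_radius=self.training_log_["radius"].to_numpy(),
            log_qe=self.training_log_["quantization_error"].to_numpy(),
        )

    @classmethod
    def load(cls, path) -> "SOMPortrayal":
        with np.load(path, allow_pickle=True) as z:
            rows, cols = (int(x) for x in z["dims"])
            model = cls(
                rows=rows,
                cols=cols,
                epochs=int(z["params"][0]),
                radius_end=float(z["params"][1]),
                seed=int(z["params"][2]),
            )
            model.codebook_ = z["codebook"]
            model.gene_ids_ = list(z["gene_ids"])
            model.sample_ids_ = list(z["sample_ids"])
            model.assignment_ = pd.Series(
                z["assignment"], index=model.gene_ids_, name="node"
            )
            model.node_counts_ = np.bincount(
                model.assignment_.to_numpy(), minlength=model.n_nodes
            )
            model.populated_ = model.node_counts_ > 0
            model.training_log_ = pd.DataFrame(
                {
                    "epoch": z["log_epoch"],
                    "radius": z["log_radius"],
                    "quantization_error": z["log_qe"],
                }
            )
        return model


# ----------------------------------------------------------- thin wrappers


def train_som(
    matrix: Union[OmicsMatrix, pd.DataFrame],
    rows: int = 40,
    cols: int = 40,
    epochs: int = 50,
    seed: int = 0,
    **kwargs,
) -> SOMPortrayal:
    """Fit a :class:`SOMPortrayal` on a centralized gene x sample matrix."""
    return SOMPortrayal(
        rows=rows, cols=cols, epochs=epochs, seed=seed, **kwargs
    ).fit(matrix)


def extend_som(model: SOMPortrayal, secondary) -> pd.DataFrame:
    """Project secondary samples onto a trained map (see ``SOMPortrayal.extend``)."""
    return model.extend(secondary)
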