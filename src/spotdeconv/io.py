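"""Domain containers and file I/O.

Two measurement modalities feed the deconvolution problem:

* a single-cell RNA-seq *reference* — a cells x genes count matrix in which
  every row (a "prototype") carries a cell-type label, several prototypes
  per type;
* a *spatial* expression matrix — spots x genes counts, each spot a capture
  location whose measured expression mixes an unknown blend of cell types,
  with planar (x, y) coordinates.

Both are accepted from ``h5ad`` (counts in ``X``, label / coordinate columns
in ``.obs``) or from delimited text (counts table with a header row of gene
identifiers plus a sibling metadata table sharing the row index).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import anndata as ad
import numpy as np
import pandas as pd

__all__ = [
    "ReferenceProfile",
    "SpatialExpression",
    "PrototypeWeights",
    "CellTypeProportions",
    "CVReport",
    "load_reference",
    "load_spatial",
    "write_reference",
    "write_spatial",
    "align_genes",
]


def _as_dense_float(X) -> np.ndarray:
    if hasattr(X, "toarray"):  # sparse
        X = X.toarray()
    return np.asarray(X, dtype=float)


def _check_counts(counts: np.ndarray, what: str) -> None:
    if counts.ndim != 2:
        raise ValueError(f"{what} counts must be 2-dimensional, got {counts.ndim}")
    if not np.all(np.isfinite(counts)):
        raise ValueError(f"{what} counts contain non-finite values")
    if np.any(counts < 0):
        raise ValueError(f"{what} counts contain negative entries")


def _check_gene_ids(gene_ids: np.ndarray, n_genes: int) -> None:
    if gene_ids.shape[0] != n_genes:
        raise ValueError(
            f"gene_ids length {gene_ids.shape[0]} does not match gene dimension {n_genes}"
        )
    if len(set(gene_ids.tolist())) != gene_ids.shape[0]:
        dup = pd.Index(gene_ids)[pd.Index(gene_ids).duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene identifiers: {dup[:5]}")


@dataclass
class ReferenceProfile:
    """Single-cell reference: prototypes (rows) x genes, with per-cell type labels."""

    counts: np.ndarray
    gene_ids: np.ndarray
    cell_types: np.ndarray
    cell_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = _as_dense_float(self.counts)
        self.gene_ids = np.asarray(self.gene_ids, dtype=str)
        self.cell_types = np.asarray(self.cell_types, dtype=str)
        _check_counts(self.counts, "reference")
        _check_gene_ids(self.gene_ids, self.counts.shape[1])
        if self.cell_types.shape[0] != self.counts.shape[0]:
            raise ValueError(
                f"{self.cell_types.shape[0]} cell-type labels for "
                f"{self.counts.shape[0]} cells"
            )
        if self.cell_ids is None:
            self.cell_ids = np.array([f"cell_{i}" for i in range(self.n_cells)])
        else:
            self.cell_ids = np.asarray(self.cell_ids, dtype=str)

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def type_names(self) -> np.ndarray:
        """Sorted unique cell-type names (deterministic column order downstream)."""
        return np.unique(self.cell_types)

    @property
    def n_types(self) -> int:
        return self.type_names.shape[0]


@dataclass
class SpatialExpression:
    """Spatial expression: spots (rows) x genes, with per-spot planar coordinates."""

    counts: np.ndarray
    gene_ids: np.ndarray
    coordinates: np.ndarray
    spot_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = _as_dense_float(self.counts)
        self.gene_ids = np.asarray(self.gene_ids, dtype=str)
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        _check_counts(self.counts, "spatial")
        _check_gene_ids(self.gene_ids, self.counts.shape[1])
        if self.coordinates.shape != (self.counts.shape[0], 2):
            raise ValueError(
                f"coordinates shape {self.coordinates.shape} incompatible with "
                f"{self.counts.shape[0]} spots (expected (n_spots, 2))"
            )
        if self.spot_ids is None:
            self.spot_ids = np.array([f"spot_{i}" for i in range(self.n_spots)])
        else:
            self.spot_ids = np.asarray(self.spot_ids, dtype=str)

    @property
    def n_spots(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]


@dataclass
class PrototypeWeights:
    """Estimated spot-by-prototype weight matrix M (the regression coefficients).

    OLS weights may be negative; NNLS weights are elementwise non-negative.
    """

    weights: np.ndarray
    estimator: str  # "OLS" | "NNLS"
    lambda_used: float | None = None
    pinv_fallback: bool = False
    objective_trace: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.estimator not in ("OLS", "NNLS"):
            raise ValueError(f"estimator must be 'OLS' or 'NNLS', got {self.estimator!r}")
        if self.estimator == "NNLS" and np.any(self.weights < 0):
            raise ValueError("NNLS weights must be non-negative")


@dataclass
class CellTypeProportions:
    """Spot-by-type proportion matrix; every row lies on the probability simplex."""

    proportions: np.ndarray
    type_names: np.ndarray
    spot_ids: np.ndarray | None = None
    fallback_spots: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def __post_init__(self) -> None:
        self.proportions = np.asarray(self.proportions, dtype=float)
        self.type_names = np.asarray(self.type_names, dtype=str)
        if self.proportions.ndim != 2:
            raise ValueError("proportions must be 2-dimensional")
        if self.type_names.shape[0] != self.proportions.shape[1]:
            raise ValueError("one type name per proportion column required")
        if np.any(self.proportions < 0):
            raise ValueError("proportions contain negative entries")
        row_sums = self.proportions.sum(axis=1)
        if not np.allclose(row_sums, 1.0, atol=1e-9, rtol=0):
            bad = np.flatnonzero(np.abs(row_sums - 1.0) > 1e-9)
            raise ValueError(f"rows off the probability simplex: {bad[:5].tolist()}")
        if self.spot_ids is not None:
            self.spot_ids = np.asarray(self.spot_ids, dtype=str)

    @property
    def n_spots(self) -> int:
        return self.proportions.shape[0]

    def to_frame(self) -> pd.DataFrame:
        index = self.spot_ids if self.spot_ids is not None else pd.RangeIndex(self.n_spots)
        return pd.DataFrame(self.proportions, index=index, columns=self.type_names)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CellTypeProportions":
        return cls(
            proportions=df.to_numpy(dtype=float),
            type_names=df.columns.to_numpy(dtype=str),
            spot_ids=df.index.to_numpy(dtype=str),
        )


@dataclass
class CVReport:
    """Held-out-gene cross-validation table for the ridge parameter.

    ``fold_mse[i, j]`` is the validation error of grid value ``lambda_grid[i]``
    on fold ``j``; ``selected_lambda`` minimizes the per-lambda mean (ties
    broken toward the smallest lambda).
    """

    lambda_grid: np.ndarray
    fold_mse: np.ndarray
    mean_mse: np.ndarray
    selected_lambda: float

    def __post_init__(self) -> None:
        self.lambda_grid = np.asarray(self.lambda_grid, dtype=float)
        self.fold_mse = np.asarray(self.fold_mse, dtype=float)
        self.mean_mse = np.asarray(self.mean_mse, dtype=float)
        if np.any(self.fold_mse < 0):
            raise ValueError("validation errors must be non-negative")
        best = self.lambda_grid[np.argmin(self.mean_mse)]
        where = np.flatnonzero(self.lambda_grid == self.selected_lambda)
        if where.size == 0:
            raise ValueError(f"selected_lambda {self.selected_lambda} not on the grid")
        if self.mean_mse[where[0]] > self.mean_mse.min():
            raise ValueError(
                f"selected_lambda {self.selected_lambda} does not minimize the mean "
                f"validation error (argmin at {best})"
            )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.fold_mse,
            index=pd.Index(self.lambda_grid, name="lambda"),
            columns=[f"fold_{j}" for j in range(self.fold_mse.shape[1])],
        )
        df["mean"] = self.mean_mse
        return df


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_DELIMITED = {".csv": ",", ".tsv": "\t", ".txt": "\t"}


def _default_metadata_path(path: Path) -> Path:
    return path.with_name(path.stem + "_metadata" + path.suffix)


def _read_tables(path: Path, metadata_path: Path | None) -> tuple[pd.DataFrame, pd.DataFrame]:
    sep = _DELIMITED[path.suffix]
    counts = pd.read_csv(path, index_col=0, sep=sep)
    meta_path = metadata_path or _default_metadata_path(path)
    if not Path(meta_path).exists():
        raise FileNotFoundError(f"metadata table not found: {meta_path}")
    meta = pd.read_csv(meta_path, index_col=0, sep=_DELIMITED[Path(meta_path).suffix])
    meta = meta.reindex(counts.index)
    if meta.isna().all(axis=1).any():
        missing = meta.index[meta.isna().all(axis=1)][:5].tolist()
        raise ValueError(f"metadata rows missing for: {missing}")
    return counts, meta


def load_reference(
    path: str | Path,
    cell_type_key: str = "cell_type",
    metadata_path: str | Path | None = None,
) -> ReferenceProfile:
    """Read a single-cell reference with per-cell type labels.

    ``path`` may be an ``.h5ad`` file (labels in ``.obs[cell_type_key]``) or a
    delimited counts table (rows = cells, header = gene ids) paired with a
    metadata table (``<stem>_metadata.<ext>`` by default, or ``metadata_path``).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"reference file not found: {path}")
    if path.suffix == ".h5ad":
        adata = ad.read_h5ad(path)
        if cell_type_key not in adata.obs.columns:
            raise KeyError(
                f"cell_type_key {cell_type_key!r} not in metadata columns "
                f"{adata.obs.columns.tolist()}"
            )
        return ReferenceProfile(
            counts=_as_dense_float(adata.X),
            gene_ids=adata.var_names.to_numpy(dtype=str),
            cell_types=adata.obs[cell_type_key].to_numpy(dtype=str),
            cell_ids=adata.obs_names.to_numpy(dtype=str),
        )
    if path.suffix in _DELIMITED:
        counts, meta = _read_tables(path, Path(metadata_path) if metadata_path else None)
        if cell_type_key not in meta.columns:
            raise KeyError(
                f"cell_type_key {cell_type_key!r} not in metadata columns "
                f"{meta.columns.tolist()}"
            )
        return ReferenceProfile(
            counts=counts.to_numpy(dtype=float),
            gene_ids=counts.columns.to_numpy(dtype=str),
            cell_types=meta[cell_type_key].to_numpy(dtype=str),
            cell_ids=counts.index.to_numpy(dtype=str),
        )
    raise ValueError(f"unsupported reference format: {path.suffix!r}")


def load_spatial(
    path: str | Path,
    metadata_path: str | Path | None = None,
    x_key: str = "x",
    y_key: str = "y",
) -> SpatialExpression:
    """Read spatial expression with per-spot x/y coordinates.

    For ``.h5ad``, coordinates come from ``.obs[[x_key, y_key]]`` or, failing
    that, from ``.obsm["spatial"]``. Spot order is preserved from the file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"spatial file not found: {path}")
    if path.suffix == ".h5ad":
        adata = ad.read_h5ad(path)
        if x_key in adata.obs.columns and y_key in adata.obs.columns:
            coords = adata.obs[[x_key, y_key]].to_numpy(dtype=float)
        elif "spatial" in adata.obsm:
            coords = np.asarray(adata.obsm["spatial"], dtype=float)[:, :2]
        else:
            raise KeyError(
                f"spatial coordinates not found: need obs columns "
                f"({x_key!r}, {y_key!r}) or obsm['spatial']"
            )
        return SpatialExpression(
            counts=_as_dense_float(adata.X),
            gene_ids=adata.var_names.to_numpy(dtype=str),
            coordinates=coords,
            spot_ids=adata.obs_names.to_numpy(dtype=str),
        )
    if path.suffix in _DELIMITED:
        counts, meta = _read_tables(path, Path(metadata_path) if metadata_path else None)
        for key in (x_key, y_key):
            if key not in meta.columns:
                raise KeyError(
                    f"coordinate column {key!r} not in metadata columns "
                    f"{meta.columns.tolist()}"
                )
        return SpatialExpression(
            counts=counts.to_numpy(dtype=float),
            gene_ids=counts.columns.to_numpy(dtype=str),
            coordinates=meta[[x_key, y_key]].to_numpy(dtype=float),
            spot_ids=counts.index.to_numpy(dtype=str),
        )
    raise ValueError(f"unsupported spatial format: {path.suffix!r}")


def write_reference(ref: ReferenceProfile, path: str | Path, cell_type_key: str = "cell_type") -> Path:
    """Write a reference to ``.h5ad`` or delimited text (counts + metadata pair)."""
    path = Path(path)
    if path.suffix == ".h5ad":
        adata = ad.AnnData(
            X=ref.counts.copy(),
            obs=pd.DataFrame({cell_type_key: ref.cell_types}, index=ref.cell_ids),
            var=pd.DataFrame(index=pd.Index(ref.gene_ids, name="gene_id")),
        )
        adata.write_h5ad(path)
        return path
    if path.suffix in _DELIMITED:
        sep = _DELIMITED[path.suffix]
        pd.DataFrame(ref.counts, index=ref.cell_ids, columns=ref.gene_ids).to_csv(path, sep=sep)
        pd.DataFrame({cell_type_key: ref.cell_types}, index=ref.cell_ids).to_csv(
            _default_metadata_path(path), sep=sep
        )
        return path
    raise ValueError(f"unsupported reference format: {path.suffix!r}")


def write_spatial(spatial: SpatialExpression, path: str | Path) -> Path:
    """Write spatial expression to ``.h5ad`` or delimited text."""
    path = Path(path)
    meta = pd.DataFrame(
        {"x": spatial.coordinates[:, 0], "y": spatial.coordinates[:, 1]},
        index=spatial.spot_ids,
    )
    if path.suffix == ".h5ad":
        adata = ad.AnnData(
            X=spatial.counts.copy(),
            obs=meta,
            var=pd.DataFrame(index=pd.Index(spatial.gene_ids, name="gene_id")),
        )
        adata.obsm["spatial"] = spatial.coordinates.copy()
        adata.write_h5ad(path)
        return path
    if path.suffix in _DELIMITED:
        sep = _DELIMITED[path.suffix]
        pd.DataFrame(spatial.counts, index=spatial.spot_ids, columns=spatial.gene_ids).to_csv(
            path, sep=sep
        )
        meta.to_csv(_default_metadata_path(path), sep=sep)
        return path
    raise ValueError(f"unsupported spatial format: {path.suffix!r}")


def align_genes(
    ref: ReferenceProfile, spatial: SpatialExpression
) -> tuple[ReferenceProfile, SpatialExpression]:
    """Restrict both datasets to their shared genes, sorted lexicographically.

    Matching is by exact (case-sensitive) identifier; the sorted order makes
    the result independent of input column order. Idempotent.
    """
    shared = np.intersect1d(ref.gene_ids, spatial.gene_ids)  # sorted, unique
    if shared.size == 0:
        raise ValueError("reference and spatial data share no gene identifiers")
    ref_idx = _index_of(ref.gene_ids, shared)
    sp_idx = _index_of(spatial.gene_ids, shared)
    ref_out = ReferenceProfile(
        counts=ref.counts[:, ref_idx],
        gene_ids=shared,
        cell_types=ref.cell_types,
        cell_ids=ref.cell_ids,
    )
    sp_out = SpatialExpression(
        counts=spatial.counts[:, sp_idx],
        gene_ids=shared,
        coordinates=spatial.coordinates,
        spot_ids=spatial.spot_ids,
    )
    return ref_out, sp_out


def _index_of(haystack: np.ndarray, needles: Sequence[str]) -> np.ndarray:
    lookup = {g: i for i, g in enumerate(haystack.tolist())}
    return np.array([lookup[g] for g in needles], dtype=int)
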