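"""Reference preprocessing: depth normalization, rare-type removal, marker selection.

The pipeline applies three ordered steps to a gene-aligned reference/spatial
pair:

1. divide each reference cell by its total count (library-size normalization),
2. drop cell types represented by fewer than ``cellcount_min`` cells,
3. rank genes one-vs-rest per cell type and keep the union of each type's
   top ``gene_top`` markers; both datasets are restricted to that union.

Spatial counts are never normalized here — the linear mixing model regresses
raw spot counts on the normalized prototype profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ReferenceProfile, SpatialExpression

__all__ = [
    "PreprocessConfig",
    "normalize_cells",
    "filter_rare_celltypes",
    "rank_genes_one_vs_rest",
    "select_marker_genes",
    "top_markers_per_type",
    "preprocess",
]


@dataclass
class PreprocessConfig:
    cellcount_norm: bool = True
    cellcount_min: int = 2
    gene_top: int = 200
    de_method: str = "wilcoxon"  # or "ttest"

    def __post_init__(self) -> None:
        if self.cellcount_min < 1:
            raise ValueError("cellcount_min must be >= 1")
        if self.gene_top < 1:
            raise ValueError("gene_top must be >= 1")
        if self.de_method not in ("wilcoxon", "ttest"):
            raise ValueError(f"unknown de_method {self.de_method!r}")


def normalize_cells(ref: ReferenceProfile) -> ReferenceProfile:
    """Divide every cell by its total count so each row sums to 1.

    Cells with zero total are dropped first (with a warning); if none remain,
    an error is raised.
    """
    totals = ref.counts.sum(axis=1)
    keep = totals > 0
    if not keep.any():
        raise ValueError("all cells have zero total counts")
    if not keep.all():
        dropped = np.flatnonzero(~keep)
        warnings.warn(
            f"dropping {dropped.size} zero-total cells: indices {dropped[:10].tolist()}",
            stacklevel=2,
        )
    counts = ref.counts[keep] / totals[keep, None]
    return ReferenceProfile(
        counts=counts,
        gene_ids=ref.gene_ids,
        cell_types=ref.cell_types[keep],
        cell_ids=ref.cell_ids[keep],
    )


def filter_rare_celltypes(ref: ReferenceProfile, min_cells: int) -> ReferenceProfile:
    """Remove cell types with fewer than ``min_cells`` cells (order preserved)."""
    types, counts_per_type = np.unique(ref.cell_types, return_counts=True)
    keep_types = set(types[counts_per_type >= min_cells].tolist())
    if not keep_types:
        raise ValueError(f"no cell type has >= {min_cells} cells")
    removed = sorted(set(types.tolist()) - keep_types)
    if removed:
        warnings.warn(f"removing rare cell types: {removed}", stacklevel=2)
    keep = np.array([t in keep_types for t in ref.cell_types.tolist()])
    return ReferenceProfile(
        counts=ref.counts[keep],
        gene_ids=ref.gene_ids,
        cell_types=ref.cell_types[keep],
        cell_ids=ref.cell_ids[keep],
    )


def _tie_term(values: np.ndarray) -> np.ndarray:
    """Sum of t^3 - t over tied groups, per gene column."""
    out = np.zeros(values.shape[1])
    for j in range(values.shape[1]):
        _, t = np.unique(values[:, j], return_counts=True)
        out[j] = float((t**3 - t).sum())
    return out


def rank_genes_one_vs_rest(ref: ReferenceProfile, method: str = "wilcoxon") -> pd.DataFrame:
    """Per-gene differential-expression score of each type against the rest.

    Returns a genes x types DataFrame of standardized statistics; larger
    values mean higher expression in the type than in the rest.

    ``wilcoxon``: tie-corrected Mann-Whitney/rank-sum z statistic computed on
    log1p-transformed expression (the rank statistic itself is invariant to
    the monotone transform; the transform matters only for ``ttest``).
    ``ttest``: Welch t statistic on log1p expression.
    """
    if ref.n_types < 2:
        raise ValueError("one-vs-rest ranking requires at least 2 cell types")
    vals = np.log1p(ref.counts)
    types = ref.type_names
    scores = np.empty((ref.n_genes, types.size))
    if method == "wilcoxon":
        ranks = stats.rankdata(vals, axis=0)
        n = ref.n_cells
        tie = _tie_term(vals)
        for k, t in enumerate(types):
            mask = ref.cell_types == t
            n1 = int(mask.sum())
            n2 = n - n1
            r1 = ranks[mask].sum(axis=0)
            u = r1 - n1 * (n1 + 1) / 2.0
            mu = n1 * n2 / 2.0
            var = n1 * n2 / 12.0 * ((n + 1) - tie / (n * (n - 1)))
            with np.errstate(divide="ignore", invalid="ignore"):
                z = (u - mu) / np.sqrt(var)
            scores[:, k] = np.where(var > 0, z, 0.0)
    elif method == "ttest":
        for k, t in enumerate(types):
            mask = ref.cell_types == t
            with np.errstate(divide="ignore", invalid="ignore"):
                tstat, _ = stats.ttest_ind(vals[mask], vals[~mask], equal_var=False)
            scores[:, k] = np.nan_to_num(tstat, nan=0.0)
    else:
        raise ValueError(f"unknown de_method {method!r}")
    return pd.DataFrame(scores, index=ref.gene_ids, columns=types)


def top_markers_per_type(
    ref: ReferenceProfile, gene_top: int, method: str = "wilcoxon"
) -> dict[str, list[str]]:
    """Each type's ``gene_top`` highest-scoring genes (ties broken by gene id)."""
    scores = rank_genes_one_vs_rest(ref, method)
    gene_ids = scores.index.to_numpy()
    out: dict[str, list[str]] = {}
    for t in scores.columns:
        col = scores[t].to_numpy()
        # primary key: descending score; secondary: ascending gene id
        order = np.lexsort((gene_ids, -col))
        out[t] = gene_ids[order[:gene_top]].tolist()
    return out


def select_marker_genes(
    ref: ReferenceProfile, gene_top: int, method: str = "wilcoxon"
) -> np.ndarray:
    """Union over types of per-type top markers, sorted by gene id."""
    per_type = top_markers_per_type(ref, gene_top, method)
    union: set[str] = set()
    for genes in per_type.values():
        union.update(genes)
    return np.array(sorted(union))


def preprocess(
    ref: ReferenceProfile,
    spatial: SpatialExpression,
    cfg: PreprocessConfig | None = None,
) -> tuple[ReferenceProfile, SpatialExpression]:
    """Run the three ordered steps and restrict both datasets to the marker set.

    Inputs must already be gene-aligned (see :func:`spotdeconv.io.align_genes`).
    """
    cfg = cfg or PreprocessConfig()
    if ref.n_genes != spatial.n_genes or not np.array_equal(ref.gene_ids, spatial.gene_ids):
        raise ValueError("inputs must be gene-aligned before preprocessing")
    if cfg.cellcount_norm:
        ref = normalize_cells(ref)
    ref = filter_rare_celltypes(ref, cfg.cellcount_min)
    markers = select_marker_genes(ref, cfg.gene_top, cfg.de_method)
    lookup = {g: i for i, g in enumerate(ref.gene_ids.tolist())}
    idx = np.array([lookup[g] for g in markers.tolist()], dtype=int)
    ref_out = ReferenceProfile(
        counts=ref.counts[:, idx],
        gene_ids=markers,
        cell_types=ref.cell_types,
        cell_ids=ref.cell_ids,
    )
    sp_out = SpatialExpression(
        counts=spatial.counts[:, idx],
        gene_ids=markers,
        coordinates=spatial.coordinates,
        spot_ids=spatial.spot_ids,
    )
    return ref_out, sp_out
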