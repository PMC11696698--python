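"""Turn prototype weights into cell-type proportions; end-to-end runners.

A cell type is represented by several prototypes (reference cells), so the
estimated spot-by-prototype weight matrix is aggregated per type:

* NNLS route — weights are already non-negative; the proportion of type k
  at spot i is the sum of that type's prototype weights divided by the
  spot's total weight.
* SLS (soft-thresholding least squares) route — OLS weights may be
  negative; each *per-type sum* is clamped at zero before normalization
  (the clamp acts on the type sums, not on individual prototype entries).

Spots whose denominator vanishes (all-zero, or all type sums non-positive)
get a uniform row and a warning; this keeps every output row on the
probability simplex.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass

import numpy as np

from .io import CellTypeProportions, CVReport, PrototypeWeights, ReferenceProfile, SpatialExpression
from .solvers import SolverConfig, cross_validate_lambda, nnls_estimate, ols_estimate

__all__ = ["DeconvResult", "aggregate_nnls", "aggregate_sls", "run_sls", "run_nnls"]


@dataclass
class DeconvResult:
    """Proportions plus the solver wall time and the ordered type names."""

    proportions: CellTypeProportions
    elapsed_seconds: float
    type_names: np.ndarray
    weights: PrototypeWeights | None = None
    cv_report: CVReport | None = None


def _type_indicator(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-grouping matrix T (n_cells x K) for sorted unique type names."""
    labels = np.asarray(labels, dtype=str)
    types = np.unique(labels)
    T = (labels[:, None] == types[None, :]).astype(float)
    return T, types


def _normalize_rows(sums: np.ndarray, types: np.ndarray, spot_ids=None) -> CellTypeProportions:
    denom = sums.sum(axis=1)
    degenerate = np.flatnonzero(denom <= 0)
    if degenerate.size:
        warnings.warn(
            f"{degenerate.size} spot(s) with no positive type weight get a uniform "
            f"row: indices {degenerate[:10].tolist()}",
            stacklevel=3,
        )
        sums = sums.copy()
        sums[degenerate] = 1.0
        denom = sums.sum(axis=1)
    return CellTypeProportions(
        proportions=sums / denom[:, None],
        type_names=types,
        spot_ids=spot_ids,
        fallback_spots=degenerate,
    )


def aggregate_nnls(M: PrototypeWeights, labels: np.ndarray, spot_ids=None) -> CellTypeProportions:
    """Sum non-negative prototype weights per type and normalize each spot."""
    W = M.weights if isinstance(M, PrototypeWeights) else np.asarray(M, dtype=float)
    if np.any(W < 0):
        raise ValueError("aggregate_nnls expects non-negative weights")
    labels = np.asarray(labels, dtype=str)
    if labels.shape[0] != W.shape[1]:
        raise ValueError("one label per weight column required")
    T, types = _type_indicator(labels)
    return _normalize_rows(W @ T, types, spot_ids)


def aggregate_sls(M: PrototypeWeights, labels: np.ndarray, spot_ids=None) -> CellTypeProportions:
    """Clamp per-type OLS weight sums at zero, then normalize each spot."""
    W = M.weights if isinstance(M, PrototypeWeights) else np.asarray(M, dtype=float)
    labels = np.asarray(labels, dtype=str)
    if labels.shape[0] != W.shape[1]:
        raise ValueError("one label per weight column required")
    T, types = _type_indicator(labels)
    sums = np.maximum(W @ T, 0.0)
    return _normalize_rows(sums, types, spot_ids)


def run_sls(
    ref: ReferenceProfile,
    spatial: SpatialExpression,
    cfg: SolverConfig | None = None,
) -> DeconvResult:
    """Soft-thresholding least squares deconvolution (tuning-free, closed form).

    Inputs must be gene-aligned (and typically preprocessed). The reported
    time covers the solve and aggregation only.
    """
    _require_aligned(ref, spatial)
    t0 = time.perf_counter()
    M = ols_estimate(spatial.counts, ref.counts)
    P = aggregate_sls(M, ref.cell_types, spot_ids=spatial.spot_ids)
    elapsed = time.perf_counter() - t0
    return DeconvResult(proportions=P, elapsed_seconds=elapsed, type_names=P.type_names, weights=M)


def run_nnls(
    ref: ReferenceProfile,
    spatial: SpatialExpression,
    cfg: SolverConfig | None = None,
) -> DeconvResult:
    """Non-negative least squares deconvolution.

    If ``cfg.ridge_lambda`` is a sequence with more than one value, the ridge
    penalty is first selected by gene-split cross-validation and the model is
    refit on the full gene set with the winner.
    """
    cfg = cfg or SolverConfig()
    _require_aligned(ref, spatial)
    t0 = time.perf_counter()
    report = None
    grid = cfg.lambda_grid
    if grid.size > 1:
        report = cross_validate_lambda(spatial.counts, ref.counts, cfg)
        lam = report.selected_lambda
    else:
        lam = float(grid[0])
    M = nnls_estimate(spatial.counts, ref.counts, cfg, lam=lam)
    P = aggregate_nnls(M, ref.cell_types, spot_ids=spatial.spot_ids)
    elapsed = time.perf_counter() - t0
    return DeconvResult(
        proportions=P,
        elapsed_seconds=elapsed,
        type_names=P.type_names,
        weights=M,
        cv_report=report,
    )


def _require_aligned(ref: ReferenceProfile, spatial: SpatialExpression) -> None:
    if not np.array_equal(ref.gene_ids, spatial.gene_ids):
        raise ValueError("reference and spatial gene sets differ; run align_genes first")
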