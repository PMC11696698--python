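"""Accuracy metrics for estimated cell-type proportions.

With ground truth available: root-mean-square error pooled over all
spot x type entries, and the per-spot Jensen-Shannon divergence (log base 2,
so 0 <= JSD <= 1) averaged over spots. Without ground truth: the Pearson
correlation, across spots, between each type's estimated proportion and the
mean expression of that type's marker genes on depth-normalized spot counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.spatial.distance import jensenshannon

from .io import CellTypeProportions, SpatialExpression

__all__ = ["EvaluationResult", "rmse", "jsd", "pcc_markers", "evaluate"]

#: Conventions fixed by this package (recorded on every result).
_CONVENTIONS = {
    "rmse": "pooled over all spot x type entries",
    "jsd": "per-spot, log base 2, averaged over spots",
    "pcc": "per type: corr(proportion, mean marker expression on "
    "depth-normalized spot counts); mean over defined types",
}


@dataclass
class EvaluationResult:
    rmse: float | None = None
    jsd: float | None = None
    pcc_per_type: dict[str, float] = field(default_factory=dict)
    pcc_mean: float | None = None
    conventions: dict[str, str] = field(default_factory=lambda: dict(_CONVENTIONS))

    def to_dict(self) -> dict:
        out: dict = {"conventions": self.conventions}
        if self.rmse is not None:
            out["rmse"] = self.rmse
        if self.jsd is not None:
            out["jsd"] = self.jsd
        if self.pcc_per_type:
            out["pcc_per_type"] = {
                k: (None if np.isnan(v) else v) for k, v in self.pcc_per_type.items()
            }
            out["pcc_mean"] = self.pcc_mean
        return out


def _pair(P, Q) -> tuple[np.ndarray, np.ndarray]:
    A = P.proportions if isinstance(P, CellTypeProportions) else np.asarray(P, dtype=float)
    B = Q.proportions if isinstance(Q, CellTypeProportions) else np.asarray(Q, dtype=float)
    if A.shape != B.shape:
        raise ValueError(f"shape mismatch: {A.shape} vs {B.shape}")
    if (
        isinstance(P, CellTypeProportions)
        and isinstance(Q, CellTypeProportions)
        and not np.array_equal(P.type_names, Q.type_names)
    ):
        raise ValueError("type-name columns differ between the two proportion matrices")
    return A, B


def rmse(P, P_true) -> float:
    """Root-mean-square error over all spot x type entries."""
    A, B = _pair(P, P_true)
    return float(np.sqrt(np.mean((A - B) ** 2)))


def jsd(P, P_true) -> float:
    """Mean per-spot Jensen-Shannon divergence, log base 2 (in [0, 1])."""
    A, B = _pair(P, P_true)
    for name, mat in (("first", A), ("second", B)):
        if np.any(mat < -1e-6) or not np.allclose(mat.sum(axis=1), 1.0, atol=1e-6, rtol=0):
            raise ValueError(f"{name} argument has rows off the probability simplex")
    A = np.clip(A, 0.0, None)
    B = np.clip(B, 0.0, None)
    # scipy returns the JS *distance* (sqrt of the divergence); identical rows
    # can hit sqrt of a tiny negative and come back nan
    with np.errstate(invalid="ignore"):
        dist = jensenshannon(A, B, base=2, axis=1)
    div = np.square(np.nan_to_num(dist, nan=0.0))  # identical rows give nan -> 0
    return float(np.mean(div))


def pcc_markers(
    P: CellTypeProportions,
    spatial: SpatialExpression,
    markers: dict[str, list[str]],
) -> EvaluationResult:
    """Marker-based concordance when truth is unknown.

    For each type, spot counts are normalized by their totals, the type's
    marker genes are averaged per spot, and the Pearson correlation with the
    type's estimated proportion column is taken across spots. Types whose
    proportion or marker signal is constant across spots are marked undefined
    (NaN) and excluded from ``pcc_mean``.
    """
    if spatial.n_spots < 2:
        raise ValueError("at least 2 spots required for correlation")
    if P.n_spots != spatial.n_spots:
        raise ValueError("proportions and spatial data disagree on spot count")
    lookup = {g: i for i, g in enumerate(spatial.gene_ids.tolist())}
    totals = spatial.counts.sum(axis=1)
    totals[totals == 0] = 1.0
    norm = spatial.counts / totals[:, None]
    per_type: dict[str, float] = {}
    for k, t in enumerate(P.type_names.tolist()):
        if t not in markers:
            raise KeyError(f"no marker list for cell type {t!r}")
        missing = [g for g in markers[t] if g not in lookup]
        if missing:
            raise KeyError(f"marker genes absent from spatial data: {missing[:5]}")
        idx = np.array([lookup[g] for g in markers[t]], dtype=int)
        signal = norm[:, idx].mean(axis=1)
        prop = P.proportions[:, k]
        if np.ptp(signal) == 0 or np.ptp(prop) == 0:
            warnings.warn(f"constant column for type {t!r}; PCC undefined", stacklevel=2)
            per_type[t] = float("nan")
            continue
        per_type[t] = float(stats.pearsonr(prop, signal).statistic)
    defined = [v for v in per_type.values() if not np.isnan(v)]
    mean = float(np.mean(defined)) if defined else float("nan")
    return EvaluationResult(pcc_per_type=per_type, pcc_mean=mean)


def evaluate(
    P: CellTypeProportions,
    P_true: CellTypeProportions | None = None,
    spatial: SpatialExpression | None = None,
    markers: dict[str, list[str]] | None = None,
) -> EvaluationResult:
    """Compute whichever metrics the provided inputs allow."""
    result = EvaluationResult()
    if P_true is not None:
        result.rmse = rmse(P, P_true)
        result.jsd = jsd(P, P_true)
    if spatial is not None and markers is not None:
        frag = pcc_markers(P, spatial, markers)
        result.pcc_per_type = frag.pcc_per_type
        result.pcc_mean = frag.pcc_mean
    return result
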