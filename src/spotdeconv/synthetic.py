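"""Synthetic reference + spatial data with known mixing proportions.

The generator instantiates the linear mixing model directly: K cell types
get distinct gene-expression *signatures* (probability vectors over genes,
drawn from a sparse Dirichlet so types are well separated); reference cells
are noisy draws from their type's signature; each spot's expected profile is
a proportion-weighted mixture of the signatures at a chosen sequencing
depth, with the true proportions drawn from a Dirichlet on the simplex.

With ``noise_model="none"`` every draw is replaced by its expectation, which
makes the mixing model exact — both estimators must then recover the truth
to numerical precision. ``noise_model="poisson"`` draws independent Poisson
counts around the expected profiles.

Ground truth is defined at the *type* level; the implied prototype-level
weights split each type's mass equally among its prototypes (any split with
the same type sums is observationally equivalent under the aggregation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io import CellTypeProportions, ReferenceProfile, SpatialExpression

__all__ = ["SimulationConfig", "type_signatures", "generate_reference", "generate_spots", "generate_dataset"]


@dataclass
class SimulationConfig:
    """Study conditions for the simulator.

    signature_strength is the Dirichlet concentration for the type
    signatures: small values give sparse, well-separated expression programs.
    proportion_prior is the Dirichlet concentration for the true per-spot
    compositions (1.0 = uniform on the simplex). sequencing_depth is the
    expected total count per cell and per spot.
    """

    n_types: int = 3
    cells_per_type: int = 50
    n_genes: int = 300
    n_spots: int = 100
    signature_strength: float = 0.1
    sequencing_depth: float = 10_000.0
    noise_model: str = "poisson"  # "none" | "poisson"
    proportion_prior: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_types", "cells_per_type", "n_genes", "n_spots"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.signature_strength <= 0 or self.proportion_prior <= 0:
            raise ValueError("concentrations must be positive")
        if self.noise_model not in ("none", "poisson"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")

    @property
    def type_names(self) -> np.ndarray:
        width = len(str(self.n_types - 1))
        return np.array([f"type_{k:0{width}d}" for k in range(self.n_types)])

    @property
    def gene_ids(self) -> np.ndarray:
        width = max(4, len(str(self.n_genes - 1)))
        return np.array([f"g{j:0{width}d}" for j in range(self.n_genes)])


def _rng(cfg: SimulationConfig, stream: int) -> np.random.Generator:
    # independent streams per stage so reference and spots can be regenerated separately
    return np.random.default_rng(np.random.SeedSequence([int(cfg.seed), stream]))


def type_signatures(cfg: SimulationConfig) -> np.ndarray:
    """K x n_genes matrix of gene-probability signatures (rows sum to 1)."""
    rng = _rng(cfg, 0)
    alpha = np.full(cfg.n_genes, cfg.signature_strength)
    sigs = rng.dirichlet(alpha, size=cfg.n_types)
    # keep every gene representable so Poisson expectations are never exactly 0
    sigs = sigs + 1e-12
    return sigs / sigs.sum(axis=1, keepdims=True)


def generate_reference(
    cfg: SimulationConfig, signatures: np.ndarray | None = None
) -> ReferenceProfile:
    """Draw ``cells_per_type`` reference cells per type from the signatures."""
    if signatures is None:
        signatures = type_signatures(cfg)
    rng = _rng(cfg, 1)
    expected = np.repeat(signatures, cfg.cells_per_type, axis=0) * cfg.sequencing_depth
    if cfg.noise_model == "none":
        counts = expected
    else:
        counts = rng.poisson(expected).astype(float)
    labels = np.repeat(cfg.type_names, cfg.cells_per_type)
    return ReferenceProfile(counts=counts, gene_ids=cfg.gene_ids, cell_types=labels)


def generate_spots(
    signatures: np.ndarray,
    cfg: SimulationConfig,
    proportions: np.ndarray | None = None,
) -> tuple[SpatialExpression, CellTypeProportions]:
    """Mix the signatures into spots; return counts plus the true proportions.

    Spots are laid out on a square grid (unit spacing); the expected count
    vector of spot i is ``depth * sum_k p_ik * signature_k``. Pass an explicit
    ``proportions`` matrix (n_spots x K, rows on the simplex) to hold the
    truth fixed while redrawing noise under a different seed.
    """
    rng = _rng(cfg, 2)
    if proportions is None:
        props = rng.dirichlet(np.full(cfg.n_types, cfg.proportion_prior), size=cfg.n_spots)
    else:
        props = np.asarray(proportions, dtype=float)
        if props.shape != (cfg.n_spots, cfg.n_types):
            raise ValueError(f"proportions shape {props.shape} != ({cfg.n_spots}, {cfg.n_types})")
    expected = cfg.sequencing_depth * (props @ signatures)
    if cfg.noise_model == "none":
        counts = expected
    else:
        counts = rng.poisson(expected).astype(float)
    side = math.ceil(math.sqrt(cfg.n_spots))
    idx = np.arange(cfg.n_spots)
    coords = np.column_stack([idx % side, idx // side]).astype(float)
    spatial = SpatialExpression(counts=counts, gene_ids=cfg.gene_ids, coordinates=coords)
    truth = CellTypeProportions(
        proportions=props, type_names=cfg.type_names, spot_ids=spatial.spot_ids
    )
    return spatial, truth


def generate_dataset(
    cfg: SimulationConfig,
) -> tuple[ReferenceProfile, SpatialExpression, CellTypeProportions]:
    """Convenience wrapper: signatures -> reference + spots + ground truth."""
    sigs = type_signatures(cfg)
    ref = generate_reference(cfg, sigs)
    spatial, truth = generate_spots(sigs, cfg)
    return ref, spatial, truth
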