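"""Batch self-organizing map on a hexagonal grid.

Genes (rows of a z-scaled tissue x condition profile matrix) are clustered
onto a small hexagonal grid (default 3 rows x 4 columns, 12 units).  Each
batch epoch assigns every gene to its best-matching unit (BMU, minimal
Euclidean distance, ties to the lowest unit index) and replaces every
codebook vector by the neighborhood-weighted mean of the assigned data.
The Gaussian neighborhood is truncated at the current radius, which decays
linearly from two-thirds of the grid diameter to 0.5; since the hexagonal
unit spacing is 1.0, the final epochs update BMUs only (exact Lloyd
steps), so the quantization error is non-increasing once the radius is
frozen.  Training is deterministic given the seed and invariant to the row
order of the input.
"""

from __future__ import annotations

import logging
import math
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .setsim import SetPair, similarity_matrix
from .types import DimensionError, SetSimilarityResult, SOMModel

logger = logging.getLogger("orthocompare")


def hex_positions(rows: int, cols: int) -> np.ndarray:
    """Offset hexagonal coordinates: row r, col c -> (c + 0.5*(r%2), r*sqrt(3)/2).

    Nearest neighbors are equidistant with unit spacing 1.0.  Unit index =
    r * cols + c.
    """
    pos = np.empty((rows * cols, 2))
    for r in range(rows):
        for c in range(cols):
            pos[r * cols + c] = (c + 0.5 * (r % 2), r * math.sqrt(3.0) / 2.0)
    return pos


def _quantization_error(X: np.ndarray, codebook: np.ndarray, bmu: np.ndarray) -> float:
    return float(np.sum((X - codebook[bmu]) ** 2))


def train_som(
    zmatrix: pd.DataFrame,
    rows: int = 3,
    cols: int = 4,
    epochs: int = 100,
    seed: int = 0,
    radius_start: Optional[float] = None,
    radius_end: float = 0.5,
    n_restarts: int = 4,
) -> SOMModel:
    """Train a batch SOM on a genes x features z-profile matrix.

    Runs ``n_restarts`` trainings from different seeded initializations
    and keeps the one with the lowest final quantization error (batch SOM
    shares k-means' sensitivity to initialization); fully deterministic
    given ``seed``.
    """
    best: Optional[SOMModel] = None
    for k in range(max(n_restarts, 1)):
        model = _train_som_once(
            zmatrix, rows=rows, cols=cols, epochs=epochs,
            seed=seed + 7919 * k, radius_start=radius_start, radius_end=radius_end,
        )
        if best is None or model.quantization_errors[-1] < best.quantization_errors[-1]:
            best = model
    assert best is not None
    return best


def _train_som_once(
    zmatrix: pd.DataFrame,
    rows: int,
    cols: int,
    epochs: int,
    seed: int,
    radius_start: Optional[float],
    radius_end: float,
) -> SOMModel:
    if zmatrix.isna().to_numpy().any():
        raise DimensionError("z-profile matrix contains missing values")
    n_units = rows * cols
    if zmatrix.shape[0] < n_units:
        raise DimensionError(
            f"{zmatrix.shape[0]} genes < {n_units} units; cannot train"
        )
    # canonical gene order makes the partition invariant to input row order
    order = np.argsort(zmatrix.index.to_numpy())
    genes = zmatrix.index.to_numpy()[order]
    X = zmatrix.to_numpy(dtype=float)[order]

    positions = hex_positions(rows, cols)
    grid_d = cdist(positions, positions)
    if radius_start is None:
        radius_start = (2.0 / 3.0) * float(grid_d.max()) if n_units > 1 else radius_end

    rng = np.random.default_rng(seed)
    _, first_idx = np.unique(X, axis=0, return_index=True)
    distinct = np.sort(first_idx)
    if distinct.size < n_units:
        raise DimensionError(
            f"only {distinct.size} distinct profiles for {n_units} units"
        )
    init_idx = rng.choice(distinct, size=n_units, replace=False)
    codebook = X[init_idx].copy()

    qe_history = []
    bmu = np.zeros(X.shape[0], dtype=int)
    for epoch in range(epochs):
        frac = epoch / (epochs - 1) if epochs > 1 else 1.0
        radius = radius_start + (radius_end - radius_start) * frac
        d = cdist(X, codebook)
        bmu = np.argmin(d, axis=1)  # argmin takes the lowest index on ties
        qe_history.append(_quantization_error(X, codebook, bmu))
        h = np.exp(-(grid_d**2) / (2.0 * radius**2))
        h[grid_d > radius] = 0.0  # truncated neighborhood
        weights = h[bmu]  # gene x unit
        denom = weights.sum(axis=0)
        numer = weights.T @ X
        nonempty = denom > 1e-12
        codebook[nonempty] = numer[nonempty] / denom[nonempty, None]
        if not nonempty.all():
            # dead-unit repair: relocate each empty unit onto the gene
            # currently worst-represented by its BMU (cannot raise the
            # quantization error, so the frozen-radius phase stays monotone)
            resid = np.sum((X - codebook[bmu]) ** 2, axis=1)
            order = np.argsort(-resid, kind="stable")
            for k, u in enumerate(np.flatnonzero(~nonempty)):
                codebook[u] = X[order[k % len(order)]]
            logger.debug("train_som: epoch %d, relocated %d empty unit(s)",
                         epoch, int((~nonempty).sum()))
    d = cdist(X, codebook)
    bmu = np.argmin(d, axis=1)
    qe_history.append(_quantization_error(X, codebook, bmu))
    logger.info("train_som: %d genes on %dx%d hex grid, %d epochs, final QE %.4g",
                X.shape[0], rows, cols, epochs, qe_history[-1])
    return SOMModel(
        rows=rows,
        cols=cols,
        topology="hexagonal",
        unit_positions=positions,
        codebook=codebook,
        assignment=pd.Series(bmu, index=genes, name="unit"),
        feature_names=tuple(str(c) for c in zmatrix.columns),
        epochs=epochs,
        radius_start=float(radius_start),
        radius_end=float(radius_end),
        seed=seed,
        quantization_errors=tuple(qe_history),
    )


def cluster_profiles(model: SOMModel, zmatrix: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Per-unit mean z-profile over member genes, plus member counts."""
    sub = zmatrix.loc[model.assignment.index]
    units = model.assignment.to_numpy()
    profiles = np.zeros((model.n_units, sub.shape[1]))
    counts = np.zeros(model.n_units, dtype=int)
    X = sub.to_numpy(dtype=float)
    for u in range(model.n_units):
        mask = units == u
        counts[u] = int(mask.sum())
        if counts[u]:
            profiles[u] = X[mask].mean(axis=0)
    prof = pd.DataFrame(profiles, index=range(model.n_units), columns=sub.columns)
    return prof, pd.Series(counts, index=range(model.n_units), name="n_members")


def cluster_orthogroup_sets(
    assignment: pd.Series,
    gene_to_group: Mapping[str, str],
    n_units: int,
) -> tuple[dict[int, frozenset], set[str]]:
    """Each cluster's orthogroup set (groups with >= 1 member gene).

    Returns the per-unit sets and the universe (all orthogroups touched by
    any clustered gene).  Unmapped genes are excluded and logged.
    """
    sets: dict[int, set[str]] = {u: set() for u in range(n_units)}
    universe: set[str] = set()
    n_unmapped = 0
    for gene, unit in assignment.items():
        gid = gene_to_group.get(gene)
        if gid is None:
            n_unmapped += 1
            continue
        sets[int(unit)].add(gid)
        universe.add(gid)
    if n_unmapped:
        logger.info("cluster_orthogroup_sets: %d clustered genes unmapped to any orthogroup",
                    n_unmapped)
    return {u: frozenset(s) for u, s in sets.items()}, universe


def match_clusters(
    assign_a: pd.Series,
    assign_b: pd.Series,
    gene_to_group_a: Mapping[str, str],
    gene_to_group_b: Mapping[str, str],
    n_units_a: int = 12,
    n_units_b: int = 12,
    n_perm: int = 10000,
    seed: int = 0,
    label_a: str = "A",
    label_b: str = "B",
) -> list[SetSimilarityResult]:
    """Jaccard permutation tests for all cluster pairs of two species.

    Each species' universe is the set of hierarchical orthogroups with at
    least one clustered gene; all of a species' cluster sets are mapped
    through one bijection per draw.  BH correction spans the whole cluster-
    pair matrix.
    """
    sets_a, uni_a = cluster_orthogroup_sets(assign_a, gene_to_group_a, n_units_a)
    sets_b, uni_b = cluster_orthogroup_sets(assign_b, gene_to_group_b, n_units_b)
    pairs = [
        SetPair(
            label=f"{label_a}{ua} x {label_b}{ub}",
            side_a=f"som:{label_a}",
            side_b=f"som:{label_b}",
            set_a=sets_a[ua],
            set_b=sets_b[ub],
        )
        for ua in range(n_units_a)
        for ub in range(n_units_b)
    ]
    universes = {f"som:{label_a}": sorted(uni_a), f"som:{label_b}": sorted(uni_b)}
    return similarity_matrix(pairs, universes, n_perm=n_perm, seed=seed)
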