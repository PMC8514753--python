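"""Gaussian interaction profile kernels and similarity kernel fusion.

Two similarity sources are produced or combined here:

* The **GIP kernel**: for side entities with interaction profiles
  ``K(x_i)`` (rows or columns of the association matrix), the kernel is
  ``exp(-rho * ||K(x_i) - K(x_j)||^2)`` with the effective bandwidth
  ``rho = rho' / mean_i ||K(x_i)||^2``, i.e. the base bandwidth
  normalized by the average number of verified associations per entity.

* **Similarity kernel fusion (SKF)**: a cross-diffusion of several
  kernels of the same side.  Each input kernel contributes a
  column-normalized form ``P_n`` and a KNN-restricted row-normalized
  "neighbor-constraint" kernel ``C_n``.  The ``P_n`` are iterated
  synchronously,

      P_n <- beta * C_n @ mean_{t != n}(P_t) @ C_n.T
             + (1 - beta) * mean_{t != n}(P_t^0),

  until the largest elementwise change falls below a tolerance.  The
  iterates are averaged into an overall kernel, masked elementwise by a
  mutual-k-nearest-neighbor weight matrix W in {0, 0.5, 1} to suppress
  similarities between entities that are not close in the fused
  geometry, and symmetrized.

An average-fusion baseline (plain elementwise mean) is included for
comparison experiments.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .core_data import (
    AlignmentError,
    AssociationMatrix,
    DegenerateBandwidthError,
    FusionParams,
    GipParams,
    NeighborIndex,
    NeighborWeightMatrix,
    NormalizationError,
    Side,
    SimilarityKernel,
    StochasticKernel,
    ValidationError,
)

logger = logging.getLogger("ilpmda")


# ---------------------------------------------------------------------------
# Gaussian interaction profile kernel
# ---------------------------------------------------------------------------

def _profiles(A: AssociationMatrix, side: Side) -> np.ndarray:
    return A.values if side == "disease" else A.values.T


def gip_bandwidth(A: AssociationMatrix, side: Side, params: GipParams | None = None) -> float:
    """Effective GIP bandwidth rho = rho' / mean squared profile norm."""
    params = params or GipParams()
    profiles = _profiles(A, side)
    mean_sq = float((profiles ** 2).sum(axis=1).mean())
    if mean_sq == 0.0:
        raise DegenerateBandwidthError(
            f"all {side} interaction profiles are zero; GIP bandwidth undefined"
        )
    base = (params.base_bandwidth_disease if side == "disease"
            else params.base_bandwidth_mirna)
    return base / mean_sq


def gip_kernel(A: AssociationMatrix, side: Side, params: GipParams | None = None) -> SimilarityKernel:
    """Gaussian interaction profile kernel for one side of A.

    Symmetric, unit diagonal, entries in (0, 1].  Raises
    :class:`DegenerateBandwidthError` when A has no associations.
    """
    rho = gip_bandwidth(A, side, params)
    profiles = _profiles(A, side)
    sq_dists = squareform(pdist(profiles, metric="sqeuclidean"))
    K = np.exp(-rho * sq_dists)
    np.fill_diagonal(K, 1.0)
    return SimilarityKernel(K, A.labels_for(side), side)


# ---------------------------------------------------------------------------
# normalizations and neighborhoods
# ---------------------------------------------------------------------------

def normalize_kernel(K: SimilarityKernel) -> StochasticKernel:
    """Column-stochastic normalization P(i, j) = K(i, j) / sum_k K(k, j)."""
    col_sums = K.values.sum(axis=0)
    zero = np.flatnonzero(col_sums == 0.0)
    if zero.size:
        raise NormalizationError(
            f"cannot normalize: all-zero similarity column for "
            f"{[K.labels[i] for i in zero[:5]]}"
        )
    return StochasticKernel(K.values / col_sums, list(K.labels), "column")


def neighbor_sets(K: SimilarityKernel, k: int, include_self: bool = True) -> NeighborIndex:
    """The k most similar entities per entity, in descending similarity.

    Ties are broken by ascending index.  With ``include_self`` the entity
    itself is forced into its own set (and counts toward k); otherwise it
    is excluded from the candidates.  k larger than the candidate pool is
    clipped with a warning.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    n = K.n
    available = n if include_self else n - 1
    if k > available:
        warnings.warn(
            f"k={k} exceeds the {available} available neighbors; clipping",
            stacklevel=2,
        )
        k = available
    idx = np.arange(n)
    out: list[list[int]] = []
    for i in range(n):
        # ascending (-similarity, index): highest similarity first, index tiebreak
        order = np.lexsort((idx, -K.values[i]))
        others = order[order != i]
        if include_self:
            out.append([i] + others[: k - 1].tolist())
        else:
            out.append(others[:k].tolist())
    return NeighborIndex(out, k, include_self)


def neighbor_constraint_kernel(K: SimilarityKernel, nbrs: NeighborIndex) -> StochasticKernel:
    """Row-normalize K over each entity's neighbor set, zero elsewhere.

    ``nbrs`` is expected to be built from K with ``include_self=True``.
    Rows whose neighbor mass is zero stay all-zero (with a warning).
    """
    C = np.zeros_like(K.values)
    for i, sel in enumerate(nbrs.neighbors):
        sel = np.asarray(sel, dtype=int)
        mass = K.values[i, sel].sum()
        if mass == 0.0:
            warnings.warn(
                f"entity {K.labels[i]!r}: zero similarity mass over its "
                f"neighbor set; emitting a zero row",
                stacklevel=2,
            )
            continue
        C[i, sel] = K.values[i, sel] / mass
    return StochasticKernel(C, list(K.labels), "row")


def mutual_neighbor_weights(nbrs: NeighborIndex, n: int) -> NeighborWeightMatrix:
    """Mutual-KNN mask: 1 for mutual neighbors, 0.5 one-way, 0 neither."""
    member = np.zeros((n, n), dtype=bool)
    for i, sel in enumerate(nbrs.neighbors):
        member[i, sel] = True
    W = np.where(member & member.T, 1.0, np.where(member | member.T, 0.5, 0.0))
    return NeighborWeightMatrix(W)


# ---------------------------------------------------------------------------
# fusion
# ---------------------------------------------------------------------------

@dataclass
class FusionResult:
    kernel: SimilarityKernel
    iterations: int
    converged: bool


def _check_same_entities(kernels: Sequence[SimilarityKernel]) -> tuple[Side, list[str]]:
    if not kernels:
        raise ValidationError("at least one kernel is required")
    side, labels = kernels[0].side, kernels[0].labels
    for i, K in enumerate(kernels[1:], start=1):
        if K.side != side:
            raise AlignmentError(f"kernel #{i} has side {K.side!r}, expected {side!r}")
        if K.labels != labels:
            raise AlignmentError(f"kernel #{i} labels do not match kernel #0")
    return side, labels


def skf_fuse(kernels: Sequence[SimilarityKernel], params: FusionParams | None = None) -> FusionResult:
    """Fuse kernels of one side by iterative cross-diffusion.

    A single input kernel is a degenerate case: its column-normalized,
    symmetrized form is returned without iteration.
    """
    params = params or FusionParams()
    side, labels = _check_same_entities(kernels)
    m = len(kernels)
    if m == 1:
        P = normalize_kernel(kernels[0]).values
        sym = (P + P.T) / 2.0
        return FusionResult(SimilarityKernel(sym, labels, side), 0, True)

    P0 = [normalize_kernel(K).values for K in kernels]
    C = [
        neighbor_constraint_kernel(K, neighbor_sets(K, params.k_neighbors, include_self=True)).values
        for K in kernels
    ]
    total0 = np.sum(P0, axis=0)
    cross0 = [(total0 - P0[n]) / (m - 1) for n in range(m)]

    P = [p.copy() for p in P0]
    iterations = 0
    converged = False
    for it in range(1, params.max_iterations + 1):
        total = np.sum(P, axis=0)
        new_P = [
            params.beta * (C[n] @ ((total - P[n]) / (m - 1)) @ C[n].T)
            + (1.0 - params.beta) * cross0[n]
            for n in range(m)
        ]
        delta = max(np.abs(new_P[n] - P[n]).max() for n in range(m))
        P = new_P
        iterations = it
        if delta < params.tolerance:
            converged = True
            break
    if not converged:
        logger.warning("SKF did not converge in %d iterations", params.max_iterations)

    overall = np.mean(P, axis=0)
    overall = (overall + overall.T) / 2.0
    fused_kernel = SimilarityKernel(overall, labels, side)
    nbrs = neighbor_sets(fused_kernel, params.k_neighbors, include_self=True)
    W = mutual_neighbor_weights(nbrs, fused_kernel.n)
    masked = W.values * overall
    masked = (masked + masked.T) / 2.0
    return FusionResult(SimilarityKernel(masked, labels, side), iterations, converged)


def average_fuse(kernels: Sequence[SimilarityKernel]) -> SimilarityKernel:
    """Average-fusion baseline: the elementwise mean of the kernels."""
    side, labels = _check_same_entities(kernels)
    return SimilarityKernel(np.mean([K.values for K in kernels], axis=0), labels, side)
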