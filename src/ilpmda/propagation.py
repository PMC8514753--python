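"""KNN local affinities, bidirectional label propagation, full pipeline.

Each fused similarity kernel is sparsified into a row-stochastic *local
affinity* restricted to every entity's k nearest neighbors (self
excluded — self-retention is handled by the (1 - gamma) term of the
propagation itself).

Propagation runs independently in both directions.  On the disease
side, with affinity ``sd`` and source labels ``Y = A`` (the
WKNKN-updated association matrix), the default (``as_printed``) update
is

    X^t = gamma * sd @ Y + (1 - gamma) * X^(t-1),      X^0 = Y.

The inhomogeneous term is constant, so the iteration is an affine
contraction with factor (1 - gamma) and closed form

    X^t = (1 - gamma)^t * Y + (1 - (1 - gamma)^t) * sd @ Y,

converging geometrically for any gamma > 0.  A ``recurrent`` mode is
also provided, implementing the conventional propagation
``X^t = gamma * sd @ X^(t-1) + (1 - gamma) * Y`` in which labels
diffuse through multi-step neighborhoods.  Iteration stops when the
largest elementwise change drops below a tolerance; the side score is
the running sum X^0 + X^1 + ... + X^k including the final iterate.

The miRNA side runs the same recursion with ``sm`` and ``Y = A.T``;
the two score matrices are blended as F = alpha * F_d + (1 - alpha) * F_m.T.

``ilpmda_predict`` orchestrates the whole pipeline: GIP kernels from
the association matrix, fusion of [provided kernels + GIP] per side,
WKNKN densification, local affinities, bidirectional propagation,
ensemble.  Entities are internally sorted by label and restored to the
caller's order afterwards, so predictions are exactly independent of
input row/column ordering.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core_data import (
    AssociationMatrix,
    PipelineConfig,
    PropagationParams,
    Side,
    SimilarityKernel,
    StochasticKernel,
    ValidationError,
    align_inputs,
    _check_labels,
)
from .similarity import average_fuse, gip_kernel, neighbor_sets, skf_fuse
from .wknkn import wknkn_update

logger = logging.getLogger("ilpmda")


@dataclass
class ScoreMatrix:
    """Real-valued prediction scores with row/column entity labels."""

    values: np.ndarray
    row_labels: list[str]
    col_labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.row_labels = _check_labels(self.row_labels, "score row")
        self.col_labels = _check_labels(self.col_labels, "score column")
        if self.values.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValidationError("score matrix shape does not match labels")
        if not np.isfinite(self.values).all():
            raise ValidationError("score matrix contains non-finite entries")


@dataclass
class LabelState:
    """Final propagation iterate plus convergence diagnostics."""

    labels: np.ndarray
    iteration: int
    converged: bool
    initial_change: float
    final_change: float


def local_affinity(K: SimilarityKernel, k: int) -> StochasticKernel:
    """Row-stochastic affinity over each entity's k nearest neighbors.

    Self is excluded, so the diagonal is always zero.  Rows with zero
    neighbor similarity mass stay all-zero.
    """
    nbrs = neighbor_sets(K, k, include_self=False)
    aff = np.zeros_like(K.values)
    for i, sel in enumerate(nbrs.neighbors):
        sel = np.asarray(sel, dtype=int)
        mass = K.values[i, sel].sum()
        if mass > 0.0:
            aff[i, sel] = K.values[i, sel] / mass
    return StochasticKernel(aff, list(K.labels), "row")


def propagate_side(
    aff: StochasticKernel,
    A: AssociationMatrix,
    side: Side,
    params: PropagationParams | None = None,
) -> tuple[ScoreMatrix, LabelState]:
    """Propagate association labels over one side's affinity graph.

    Returns the accumulated score matrix (nd x nm for the disease side,
    nm x nd for the miRNA side) and the final label state.
    """
    params = params or PropagationParams()
    if aff.orientation != "row":
        raise ValidationError("propagation requires a row-stochastic affinity")
    if aff.labels != A.labels_for(side):
        raise ValidationError(f"{side} affinity labels are not aligned with the association matrix")

    Y = A.values if side == "disease" else A.values.T
    gamma = params.gamma
    source = aff.values @ Y  # constant inhomogeneous term in as_printed mode

    X = Y.copy()
    score = Y.copy()
    initial_change = np.nan
    final_change = np.nan
    converged = False
    iteration = 0
    for t in range(1, params.max_iterations + 1):
        if params.mode == "as_printed":
            X_new = gamma * source + (1.0 - gamma) * X
        else:
            X_new = gamma * (aff.values @ X) + (1.0 - gamma) * Y
        final_change = float(np.abs(X_new - X).max(initial=0.0))
        if t == 1:
            initial_change = final_change
        score += X_new
        X = X_new
        iteration = t
        if final_change < params.tolerance:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"{side} propagation did not converge within {params.max_iterations} "
            f"iterations (last change {final_change:g})",
            stacklevel=2,
        )

    if side == "disease":
        rows, cols = A.disease_labels, A.mirna_labels
    else:
        rows, cols = A.mirna_labels, A.disease_labels
    state = LabelState(X, iteration, converged, initial_change, final_change)
    return ScoreMatrix(score, list(rows), list(cols)), state


def ensemble_scores(
    Fd: ScoreMatrix, Fm: ScoreMatrix, params: PropagationParams | None = None
) -> ScoreMatrix:
    """Blend the two directional scores: F = alpha * Fd + (1 - alpha) * Fm.T."""
    params = params or PropagationParams()
    if Fd.row_labels != Fm.col_labels or Fd.col_labels != Fm.row_labels:
        raise ValidationError("Fd and Fm label orientations do not match")
    values = params.alpha * Fd.values + (1.0 - params.alpha) * Fm.values.T
    return ScoreMatrix(values, list(Fd.row_labels), list(Fd.col_labels))


def ilpmda_predict(
    A: AssociationMatrix,
    disease_kernels: Sequence[SimilarityKernel],
    mirna_kernels: Sequence[SimilarityKernel],
    config: PipelineConfig | None = None,
) -> ScoreMatrix:
    """Full prediction pipeline: GIP -> fusion -> WKNKN -> propagation -> ensemble.

    Deterministic given the configuration, and exactly invariant to the
    ordering of rows/columns in the inputs (entities are canonically
    sorted by label internally).
    """
    config = config or PipelineConfig()
    if A.values.sum() == 0:
        raise ValidationError("association matrix has no known associations")

    # canonical entity order: predictions must not depend on input ordering
    od = np.argsort(np.asarray(A.disease_labels, dtype=object))
    om = np.argsort(np.asarray(A.mirna_labels, dtype=object))
    A_c = AssociationMatrix(
        A.values[np.ix_(od, om)],
        [A.disease_labels[i] for i in od],
        [A.mirna_labels[j] for j in om],
    )
    aligned = align_inputs(A_c, disease_kernels, mirna_kernels)

    gip_d = gip_kernel(A_c, "disease", config.gip)
    gip_m = gip_kernel(A_c, "mirna", config.gip)
    dks = list(aligned.disease_kernels) + [gip_d]
    mks = list(aligned.mirna_kernels) + [gip_m]

    if config.fusion.method == "average":
        SD = average_fuse(dks)
        SM = average_fuse(mks)
    else:
        SD = skf_fuse(dks, config.fusion).kernel
        SM = skf_fuse(mks, config.fusion).kernel

    A_dense = wknkn_update(A_c, SD, SM, config.wknkn)

    sd = local_affinity(SD, config.propagation.k_neighbors)
    sm = local_affinity(SM, config.propagation.k_neighbors)
    Fd, _ = propagate_side(sd, A_dense, "disease", config.propagation)
    Fm, _ = propagate_side(sm, A_dense, "mirna", config.propagation)
    F_c = ensemble_scores(Fd, Fm, config.propagation)

    inv_d = np.argsort(od)
    inv_m = np.argsort(om)
    return ScoreMatrix(
        F_c.values[np.ix_(inv_d, inv_m)],
        list(A.disease_labels),
        list(A.mirna_labels),
    )
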