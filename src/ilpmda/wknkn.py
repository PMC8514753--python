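"""Weighted k-nearest known neighbor (WKNKN) densification.

The binary association matrix is extremely sparse, which starves the
propagation stage of labels.  WKNKN replaces unknown entries with
similarity-weighted averages of the profiles of each entity's K nearest
*verified* neighbors — entities with at least one known association.

For entity r with selected neighbors i = 1..K (descending similarity,
index tiebreak, self excluded), the reconstructed profile is

    profile(r) = sum_i decay^(i-1) * S(i, r) * profile_i  /  sum_i S(i, r)

Note the normalizer sums the raw similarities without the decay, so
with decay < 1 the reconstruction is deliberately shrunk toward zero
for the lower-ranked neighbors.  The disease-side and miRNA-side
reconstructions are blended with weights (delta_disease, delta_mirna)
and the original matrix is updated by an elementwise maximum, so known
associations are always preserved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core_data import (
    AlignmentError,
    AssociationMatrix,
    Side,
    SimilarityKernel,
    ValidationError,
    WknknParams,
)

logger = logging.getLogger("ilpmda")


@dataclass
class WknknProfiles:
    """Intermediate reconstructions: disease-side, miRNA-side, combined."""

    AD: np.ndarray
    AM: np.ndarray
    A_md: np.ndarray


def known_entities(A: AssociationMatrix, side: Side) -> np.ndarray:
    """Indices of entities with at least one known association."""
    profiles = A.values if side == "disease" else A.values.T
    return np.flatnonzero(profiles.sum(axis=1) > 0)


def side_profiles(
    A: AssociationMatrix,
    S: SimilarityKernel,
    side: Side,
    params: WknknParams | None = None,
) -> np.ndarray:
    """Reconstruct every entity's profile from its K nearest verified neighbors.

    Returns an nd x nm matrix regardless of side.  Entities with no
    verified neighbor (or zero similarity to all of them) get a zero
    profile.
    """
    params = params or WknknParams()
    if S.side != side:
        raise AlignmentError(f"kernel side {S.side!r} does not match requested {side!r}")
    if S.labels != A.labels_for(side):
        raise AlignmentError(f"{side} kernel labels are not aligned with the association matrix")

    profiles = A.values if side == "disease" else A.values.T
    n = profiles.shape[0]
    verified = known_entities(A, side)
    out = np.zeros_like(profiles)
    idx = np.arange(n)
    for r in range(n):
        cands = verified[verified != r]
        if cands.size == 0:
            continue
        order = np.lexsort((idx[cands], -S.values[cands, r]))
        sel = cands[order][: params.k]
        if sel.size < params.k:
            logger.debug(
                "entity %r: only %d verified neighbors available (K=%d)",
                S.labels[r], sel.size, params.k,
            )
        sims = S.values[sel, r]
        norm = sims.sum()
        if norm == 0.0:
            continue
        weights = params.decay ** np.arange(sel.size) * sims
        out[r] = weights @ profiles[sel] / norm
    # convex-ish combinations of [0,1] profiles; clip float spill past 1
    np.clip(out, 0.0, 1.0, out=out)
    return out if side == "disease" else out.T


def combine_profiles(AD: np.ndarray, AM: np.ndarray, params: WknknParams | None = None) -> np.ndarray:
    """Blend the two side reconstructions: (d1*AD + d2*AM) / (d1 + d2)."""
    params = params or WknknParams()
    AD = np.asarray(AD, dtype=float)
    AM = np.asarray(AM, dtype=float)
    if AD.shape != AM.shape:
        raise ValidationError(f"profile shapes differ: {AD.shape} vs {AM.shape}")
    d1, d2 = params.delta_disease, params.delta_mirna
    return (d1 * AD + d2 * AM) / (d1 + d2)


def wknkn_profiles(
    A: AssociationMatrix,
    SD: SimilarityKernel,
    SM: SimilarityKernel,
    params: WknknParams | None = None,
) -> WknknProfiles:
    params = params or WknknParams()
    AD = side_profiles(A, SD, "disease", params)
    AM = side_profiles(A, SM, "mirna", params)
    return WknknProfiles(AD, AM, combine_profiles(AD, AM, params))


def wknkn_update(
    A: AssociationMatrix,
    SD: SimilarityKernel,
    SM: SimilarityKernel,
    params: WknknParams | None = None,
) -> AssociationMatrix:
    """Densify A: elementwise max of A and the blended reconstruction.

    Output dominates A elementwise and stays in [0, 1]; known
    associations are preserved exactly.
    """
    prof = wknkn_profiles(A, SD, SM, params)
    values = np.maximum(A.values, prof.A_md)
    return AssociationMatrix(values, list(A.disease_labels), list(A.mirna_labels))
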