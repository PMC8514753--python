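"""Synthetic benchmark generator with planted low-rank structure.

Emulates the statistical situation the predictor assumes: functionally
similar miRNAs associate with similar diseases.  Nonnegative latent
factors U (diseases) and V (miRNAs) define a planted score matrix
P = U @ V.T; the binary association matrix marks the top ``density``
fraction of P.  Each similarity kernel is the cosine similarity of the
side's latent factors plus symmetric zero-mean Gaussian noise, clipped
to [0, 1] with a forced unit diagonal — so the kernels are informative
about the planted structure but not identical to it.

Everything is reproducible from the spec's seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core_data import AssociationMatrix, SimilarityKernel, ValidationError
from .propagation import ScoreMatrix

logger = logging.getLogger("ilpmda")


@dataclass
class SyntheticSpec:
    """Benchmark dimensions and noise level (defaults are the study conditions)."""

    nd: int = 60
    nm: int = 80
    rank: int = 4
    density: float = 0.08
    kernel_noise_sd: float = 0.1
    kernels_per_side: int = 3
    seed: int = 42

    def __post_init__(self) -> None:
        if not 0.0 < self.density < 1.0:
            raise ValidationError("density must lie in (0, 1)")
        if self.rank < 1:
            raise ValidationError("rank must be >= 1")
        if self.nd < self.rank or self.nm < self.rank:
            raise ValidationError("nd and nm must be >= rank")
        if self.kernel_noise_sd < 0:
            raise ValidationError("kernel_noise_sd must be nonnegative")
        if self.kernels_per_side < 1:
            raise ValidationError("kernels_per_side must be >= 1")


@dataclass
class SyntheticBenchmark:
    association: AssociationMatrix
    disease_kernels: list[SimilarityKernel]
    mirna_kernels: list[SimilarityKernel]
    planted: ScoreMatrix


def _cosine_similarity(X: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    S = (X / norms) @ (X / norms).T
    np.clip(S, 0.0, 1.0, out=S)
    np.fill_diagonal(S, 1.0)
    return (S + S.T) / 2.0


def _noisy_kernels(
    base: np.ndarray, labels: list[str], side: str, count: int,
    noise_sd: float, rng: np.random.Generator,
) -> list[SimilarityKernel]:
    kernels = []
    for _ in range(count):
        noise = rng.normal(0.0, noise_sd, base.shape) if noise_sd > 0 else np.zeros(base.shape)
        noise = (noise + noise.T) / 2.0
        K = np.clip(base + noise, 0.0, 1.0)
        np.fill_diagonal(K, 1.0)
        kernels.append(SimilarityKernel(K, labels, side))
    return kernels


def generate_benchmark(spec: SyntheticSpec | None = None) -> SyntheticBenchmark:
    """Draw a planted-structure benchmark.

    The positive set is the ``density`` fraction of pairs with the
    highest planted scores, except that every disease's and every
    miRNA's single top-scoring pair is always included first — real
    association databases only list entities with at least one verified
    association, and pure global thresholding of a low-rank score
    matrix would leave low-norm entities empty.
    """
    spec = spec or SyntheticSpec()
    rng = np.random.default_rng(spec.seed)
    n_pos = max(1, round(spec.density * spec.nd * spec.nm))

    # Gamma(2, 1) latent factors: nonnegative, continuous, informative cosines
    U = rng.gamma(2.0, 1.0, size=(spec.nd, spec.rank))
    V = rng.gamma(2.0, 1.0, size=(spec.nm, spec.rank))
    P = U @ V.T

    flat = np.zeros(spec.nd * spec.nm)
    row_best = np.argmax(P, axis=1) + np.arange(spec.nd) * spec.nm
    col_best = np.argmax(P, axis=0) * spec.nm + np.arange(spec.nm)
    seeded = np.union1d(row_best, col_best)
    if seeded.size > n_pos:
        raise ValidationError(
            f"density {spec.density} yields {n_pos} positives, fewer than the "
            f"{seeded.size} needed to give every entity one association"
        )
    flat[seeded] = 1.0
    remaining = n_pos - seeded.size
    for idx in np.argsort(-P.ravel(), kind="stable"):
        if remaining == 0:
            break
        if flat[idx] == 0.0:
            flat[idx] = 1.0
            remaining -= 1
    A = flat.reshape(spec.nd, spec.nm)
    assert A.sum(axis=1).all() and A.sum(axis=0).all()

    width = max(3, len(str(max(spec.nd, spec.nm) - 1)))
    disease_labels = [f"disease_{i:0{width}d}" for i in range(spec.nd)]
    mirna_labels = [f"mirna_{j:0{width}d}" for j in range(spec.nm)]

    disease_kernels = _noisy_kernels(
        _cosine_similarity(U), disease_labels, "disease",
        spec.kernels_per_side, spec.kernel_noise_sd, rng,
    )
    mirna_kernels = _noisy_kernels(
        _cosine_similarity(V), mirna_labels, "mirna",
        spec.kernels_per_side, spec.kernel_noise_sd, rng,
    )
    return SyntheticBenchmark(
        AssociationMatrix(A, disease_labels, mirna_labels),
        disease_kernels,
        mirna_kernels,
        ScoreMatrix(P, disease_labels, mirna_labels),
    )


def mask_positives(
    A: AssociationMatrix, fraction: float, seed: int
) -> tuple[AssociationMatrix, np.ndarray]:
    """Zero a uniformly random subset of the known pairs.

    Returns the training matrix and the held-out (i, j) pair array.  At
    least one pair is always masked; masking everything is an error.
    """
    if not 0.0 < fraction < 1.0:
        raise ValidationError("fraction must lie in (0, 1)")
    positives = A.positive_pairs()
    n_mask = max(1, int(round(fraction * len(positives))))
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(positives), size=n_mask, replace=False)
    held_out = positives[np.sort(chosen)]
    train = A.copy()
    train.values[held_out[:, 0], held_out[:, 1]] = 0.0
    if train.values.sum() == 0:
        raise ValidationError("masking removed every known association")
    return train, held_out
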