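"""Leak-free cross-validation, ROC/AUC, and per-disease candidate ranking.

Both protocols hold out known associations, zero them in a *training*
copy of the association matrix, and rerun the entire pipeline — GIP
kernels, fusion and WKNKN are recomputed from the training matrix only,
so no information about a held-out pair can leak through the
interaction-profile kernels.  The precomputed input kernels are left
unchanged.  Candidate (negative) scores are the scores of all pairs
unknown in the *full* matrix, taken from the same runs.

* **Global LOOCV**: one pipeline run per known association; held-out
  scores are ranked against the candidate scores pooled globally.
* **Repeated k-fold CV**: per repeat, the known associations are
  partitioned uniformly at random; each fold is zeroed and scored in
  one run; an AUC is computed per repeat and summarized as mean +/- sd.

AUC is the rank (Mann-Whitney) statistic — the probability that a
held-out positive outranks a random candidate, ties credited one half —
and the ROC curve comes from a threshold sweep over the unique scores.
"""

from __future__ import annotations

import logging
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.stats import rankdata

from .core_data import (
    AssociationMatrix,
    IlpmdaError,
    PipelineConfig,
    SimilarityKernel,
    ValidationError,
)
from .propagation import ScoreMatrix, ilpmda_predict

logger = logging.getLogger("ilpmda")


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

@dataclass
class RocResult:
    """Threshold sweep (FPR/TPR, both anchored at 0 and ending at 1) plus AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    n_positive: int
    n_negative: int


@dataclass
class CvPlan:
    """Cross-validation scheme: global LOOCV or seeded repeated k-fold."""

    scheme: str = "kfold"
    folds: int = 5
    repeats: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scheme not in ("global_loocv", "kfold"):
            raise ValidationError("scheme must be 'global_loocv' or 'kfold'")
        if self.scheme == "kfold" and self.folds < 2:
            raise ValidationError("kfold requires folds >= 2")
        if self.repeats < 1:
            raise ValidationError("repeats must be >= 1")


@dataclass
class CvSummary:
    """Per-repeat AUCs with their mean and standard deviation."""

    aucs: np.ndarray
    auc_mean: float
    auc_sd: float
    rocs: list[RocResult] = field(default_factory=list)


def roc_auc(scores: np.ndarray, is_positive: np.ndarray) -> RocResult:
    """Rank-statistic AUC and threshold-sweep ROC curve.

    Requires at least one positive and one negative score.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    is_positive = np.asarray(is_positive, dtype=bool).ravel()
    if scores.shape != is_positive.shape:
        raise ValidationError("scores and positive mask must have the same length")
    n_pos = int(is_positive.sum())
    n_neg = int((~is_positive).sum())
    if n_pos == 0 or n_neg == 0:
        raise IlpmdaError("AUC undefined: need at least one positive and one negative")

    ranks = rankdata(scores)  # average ranks -> ties credited 0.5
    auc = (ranks[is_positive].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)

    order = np.argsort(-scores, kind="mergesort")
    sorted_scores = scores[order]
    sorted_pos = is_positive[order].astype(int)
    # last index of each tie group = one ROC point per unique threshold
    boundaries = np.r_[np.flatnonzero(np.diff(sorted_scores)), scores.size - 1]
    tps = np.cumsum(sorted_pos)[boundaries]
    fps = boundaries + 1 - tps
    fpr = np.r_[0.0, fps / n_neg]
    tpr = np.r_[0.0, tps / n_pos]
    return RocResult(fpr, tpr, float(auc), n_pos, n_neg)


# ---------------------------------------------------------------------------
# leak-free CV harnesses
# ---------------------------------------------------------------------------

PredictFn = Callable[..., ScoreMatrix]


def _held_out_run(
    A: AssociationMatrix,
    disease_kernels: Sequence[SimilarityKernel],
    mirna_kernels: Sequence[SimilarityKernel],
    config: PipelineConfig,
    test_pairs: np.ndarray,
    candidate_mask: np.ndarray,
    predict_fn: PredictFn,
) -> tuple[np.ndarray, np.ndarray]:
    """Zero the test positives, rerun the pipeline, return (test, candidate) scores."""
    train = A.copy()
    train.values[test_pairs[:, 0], test_pairs[:, 1]] = 0.0
    # leak audit: no test positive may survive in the training matrix
    if train.values[test_pairs[:, 0], test_pairs[:, 1]].any():
        raise IlpmdaError("leak audit failed: test positives present in training matrix")
    F = predict_fn(train, disease_kernels, mirna_kernels, config)
    test_scores = F.values[test_pairs[:, 0], test_pairs[:, 1]]
    return test_scores, F.values[candidate_mask]


def _run_batches(tasks, max_workers: int):
    if max_workers <= 1:
        return [task() for task in tasks]
    with ProcessPoolExecutor(max_workers=max_workers) as pool:
        futures = [pool.submit(_call_task, task) for task in tasks]
        return [f.result() for f in futures]  # submission order => worker-count independent


def _call_task(task):
    return task()


class _HeldOutTask:
    """Picklable closure over one held-out pipeline run."""

    def __init__(self, A, dks, mks, config, test_pairs, candidate_mask, predict_fn):
        self.args = (A, dks, mks, config, test_pairs, candidate_mask, predict_fn)

    def __call__(self):
        return _held_out_run(*self.args)


def global_loocv(
    A: AssociationMatrix,
    disease_kernels: Sequence[SimilarityKernel],
    mirna_kernels: Sequence[SimilarityKernel],
    config: PipelineConfig | None = None,
    max_workers: int = 1,
    predict_fn: PredictFn | None = None,
) -> RocResult:
    """Global leave-one-out CV over every known association.

    Each known pair is zeroed in turn and the whole pipeline rerun; its
    score is ranked against the scores of all never-known pairs pooled
    from the same runs.  Cost: one full pipeline run per positive.
    """
    config = config or PipelineConfig()
    predict_fn = predict_fn or ilpmda_predict
    A.require_binary()
    positives = A.positive_pairs()
    if len(positives) < 2:
        raise ValidationError("global LOOCV needs at least 2 known associations")
    candidate_mask = A.values == 0

    tasks = [
        _HeldOutTask(A, disease_kernels, mirna_kernels, config,
                     positives[i : i + 1], candidate_mask, predict_fn)
        for i in range(len(positives))
    ]
    results = _run_batches(tasks, max_workers)
    pos_scores = np.concatenate([r[0] for r in results])
    neg_scores = np.concatenate([r[1] for r in results])
    scores = np.r_[pos_scores, neg_scores]
    labels = np.r_[np.ones(pos_scores.size, bool), np.zeros(neg_scores.size, bool)]
    return roc_auc(scores, labels)


def kfold_cv(
    A: AssociationMatrix,
    disease_kernels: Sequence[SimilarityKernel],
    mirna_kernels: Sequence[SimilarityKernel],
    config: PipelineConfig | None = None,
    plan: CvPlan | None = None,
    max_workers: int = 1,
    predict_fn: PredictFn | None = None,
) -> CvSummary:
    """Seeded repeated k-fold CV over the known associations.

    Per repeat, the positives are partitioned uniformly at random into
    ``plan.folds`` folds; each fold is zeroed in a training copy and
    scored by one full pipeline run.  Held-out and candidate scores are
    pooled within the repeat into one AUC; the summary reports the mean
    and standard deviation over repeats.
    """
    config = config or PipelineConfig()
    plan = plan or CvPlan()
    predict_fn = predict_fn or ilpmda_predict
    A.require_binary()
    positives = A.positive_pairs()
    if plan.folds > len(positives):
        raise ValidationError(
            f"cannot split {len(positives)} positives into {plan.folds} folds"
        )
    candidate_mask = A.values == 0

    rng = np.random.default_rng(plan.seed)
    fold_pairs: list[list[np.ndarray]] = []
    for _ in range(plan.repeats):
        perm = rng.permutation(len(positives))
        fold_pairs.append([positives[ix] for ix in np.array_split(perm, plan.folds)])

    tasks = [
        _HeldOutTask(A, disease_kernels, mirna_kernels, config,
                     test_pairs, candidate_mask, predict_fn)
        for folds in fold_pairs
        for test_pairs in folds
    ]
    results = _run_batches(tasks, max_workers)

    aucs = []
    rocs = []
    for rep in range(plan.repeats):
        chunk = results[rep * plan.folds : (rep + 1) * plan.folds]
        pos_scores = np.concatenate([r[0] for r in chunk])
        neg_scores = np.concatenate([r[1] for r in chunk])
        scores = np.r_[pos_scores, neg_scores]
        labels = np.r_[np.ones(pos_scores.size, bool), np.zeros(neg_scores.size, bool)]
        roc = roc_auc(scores, labels)
        rocs.append(roc)
        aucs.append(roc.auc)
    aucs = np.asarray(aucs)
    sd = float(aucs.std(ddof=1)) if aucs.size > 1 else 0.0
    return CvSummary(aucs, float(aucs.mean()), sd, rocs)


# ---------------------------------------------------------------------------
# candidate ranking
# ---------------------------------------------------------------------------

def rank_candidates(
    F: ScoreMatrix,
    A: AssociationMatrix,
    disease_label: str,
    top_n: int = 50,
) -> list[tuple[str, float]]:
    """Top candidate miRNAs for one disease, by descending predicted score.

    Only miRNAs with no known association to the disease are candidates;
    ties are broken by ascending miRNA label.  Returns at most ``top_n``
    (label, score) pairs, fewer when the candidate pool is smaller.
    """
    if disease_label not in A.disease_labels:
        raise ValidationError(f"unknown disease label {disease_label!r}")
    if F.row_labels != A.disease_labels or F.col_labels != A.mirna_labels:
        raise ValidationError("score matrix labels are not aligned with the association matrix")
    i = A.disease_labels.index(disease_label)
    candidates = [
        (A.mirna_labels[j], float(F.values[i, j]))
        for j in np.flatnonzero(A.values[i] == 0)
    ]
    candidates.sort(key=lambda pair: (-pair[1], pair[0]))
    return candidates[:top_n]
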