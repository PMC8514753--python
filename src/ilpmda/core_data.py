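"""Labeled matrices, TSV I/O, input alignment and pipeline configuration.

The central object is the binary disease x miRNA adjacency matrix ``A``
(``nd x nm``): ``A[i, j] = 1`` when disease ``i`` has a verified
association with miRNA ``j``.  Row ``i`` is the interaction profile of
disease ``d_i`` and column ``j`` the interaction profile of miRNA
``m_j``.  Around it live square, symmetric similarity kernels for each
side (semantic / functional / sequence similarities are consumed as
files, never computed here) and their row- or column-normalized
stochastic forms used by the fusion and propagation stages.

Every matrix carries ordered entity labels.  Labels are opaque strings;
no miRNA or disease nomenclature is parsed.  All on-disk exchange uses
labeled TSV: one header row of column labels, first column of row
labels, values written with 12 significant digits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("ilpmda")

#: tolerance for symmetry checks on similarity kernels
SYMMETRY_TOL = 1e-10
#: tolerance for row/column sums of stochastic kernels
STOCHASTIC_TOL = 1e-10

Side = Literal["disease", "mirna"]
SIDES = ("disease", "mirna")


# ---------------------------------------------------------------------------
# errors
# ---------------------------------------------------------------------------

class IlpmdaError(Exception):
    """Base class for all package errors."""


class MatrixParseError(IlpmdaError):
    """A TSV cell could not be parsed as a finite number."""


class ValidationError(IlpmdaError):
    """A domain invariant was violated."""


class AlignmentError(IlpmdaError):
    """Kernel labels do not cover the association matrix labels."""


class DegenerateBandwidthError(IlpmdaError):
    """GIP bandwidth is undefined (all-zero association matrix)."""


class NormalizationError(IlpmdaError):
    """A kernel cannot be normalized (all-zero column)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

def _check_labels(labels: Sequence[str], what: str) -> list[str]:
    labels = [str(x) for x in labels]
    if len(set(labels)) != len(labels):
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        raise ValidationError(f"duplicate {what} labels: {dupes[:10]}")
    return labels


def _check_side(side: str) -> str:
    if side not in SIDES:
        raise ValidationError(f"side must be one of {SIDES}, got {side!r}")
    return side


@dataclass
class AssociationMatrix:
    """Disease x miRNA association matrix with entity labels.

    Binary on ingest; WKNKN densification yields real values in [0, 1].
    """

    values: np.ndarray
    disease_labels: list[str]
    mirna_labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("association matrix must be 2-dimensional")
        self.disease_labels = _check_labels(self.disease_labels, "disease")
        self.mirna_labels = _check_labels(self.mirna_labels, "miRNA")
        if self.values.shape != (len(self.disease_labels), len(self.mirna_labels)):
            raise ValidationError(
                f"association shape {self.values.shape} does not match "
                f"{len(self.disease_labels)} disease / {len(self.mirna_labels)} miRNA labels"
            )
        if not np.isfinite(self.values).all():
            raise ValidationError("association matrix contains non-finite entries")
        if self.values.min(initial=0.0) < 0.0 or self.values.max(initial=0.0) > 1.0:
            raise ValidationError("association entries must lie in [0, 1]")

    @property
    def nd(self) -> int:
        return self.values.shape[0]

    @property
    def nm(self) -> int:
        return self.values.shape[1]

    def is_binary(self) -> bool:
        return bool(np.isin(self.values, (0.0, 1.0)).all())

    def require_binary(self) -> None:
        if not self.is_binary():
            raise ValidationError("a binary {0,1} association matrix is required here")

    def positive_pairs(self) -> np.ndarray:
        """Indices (i, j) of known associations, row-major order."""
        return np.argwhere(self.values > 0)

    def copy(self) -> "AssociationMatrix":
        return AssociationMatrix(
            self.values.copy(), list(self.disease_labels), list(self.mirna_labels)
        )

    def labels_for(self, side: Side) -> list[str]:
        return self.disease_labels if _check_side(side) == "disease" else self.mirna_labels


@dataclass
class SimilarityKernel:
    """Square symmetric similarity matrix over one side's entities."""

    values: np.ndarray
    labels: list[str]
    side: Side

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = _check_labels(self.labels, f"{self.side} kernel")
        _check_side(self.side)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValidationError(
                f"kernel shape {self.values.shape} does not match {n} labels"
            )
        if not np.isfinite(self.values).all():
            raise ValidationError("kernel contains non-finite entries")
        if self.values.min(initial=0.0) < 0.0:
            raise ValidationError("kernel entries must be nonnegative")
        asym = np.abs(self.values - self.values.T).max(initial=0.0)
        if asym > SYMMETRY_TOL:
            raise ValidationError(f"kernel is asymmetric (max |K - K.T| = {asym:g})")

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class StochasticKernel:
    """Row- or column-normalized kernel.

    Vectors along the stochastic orientation sum to 1 within
    ``STOCHASTIC_TOL`` or are entirely zero (isolated entity).
    """

    values: np.ndarray
    labels: list[str]
    orientation: Literal["row", "column"]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = _check_labels(self.labels, "stochastic kernel")
        if self.orientation not in ("row", "column"):
            raise ValidationError(f"orientation must be 'row' or 'column', got {self.orientation!r}")
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValidationError("stochastic kernel must be square over its labels")
        if not np.isfinite(self.values).all():
            raise ValidationError("stochastic kernel contains non-finite entries")
        if self.values.min(initial=0.0) < 0.0:
            raise ValidationError("stochastic kernel entries must be nonnegative")
        axis = 1 if self.orientation == "row" else 0
        sums = self.values.sum(axis=axis)
        bad = ~(np.isclose(sums, 1.0, rtol=0.0, atol=STOCHASTIC_TOL) | (sums == 0.0))
        if bad.any():
            raise ValidationError(
                f"{self.orientation} sums must be 1 or 0; offending entities: "
                f"{[self.labels[i] for i in np.flatnonzero(bad)[:5]]}"
            )

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class NeighborIndex:
    """Per-entity ordered nearest-neighbor index lists."""

    neighbors: list[list[int]]
    k: int
    include_self: bool

    def __post_init__(self) -> None:
        for i, nb in enumerate(self.neighbors):
            if len(set(nb)) != len(nb):
                raise ValidationError(f"duplicate neighbors for entity {i}")
            if self.include_self != (i in nb):
                raise ValidationError(
                    f"entity {i}: self membership inconsistent with include_self={self.include_self}"
                )


@dataclass
class NeighborWeightMatrix:
    """Mutual-neighborhood weight mask W with entries in {0, 0.5, 1}."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.isin(self.values, (0.0, 0.5, 1.0)).all():
            raise ValidationError("neighbor weights must be in {0, 0.5, 1}")
        if not np.array_equal(self.values, self.values.T):
            raise ValidationError("neighbor weight matrix must be symmetric")


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

def read_matrix_frame(path: str | Path) -> tuple[np.ndarray, list[str], list[str]]:
    """Read a labeled TSV matrix into (values, row_labels, col_labels).

    Raises :class:`MatrixParseError` naming the first offending cell when a
    value is missing or non-numeric, and :class:`ValidationError` on
    duplicate labels.
    """
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\r\n").split("\t")
    col_labels = _check_labels(header[1:], f"column ({path.name})")
    df = pd.read_csv(path, sep="\t", index_col=0, header=0, dtype=object)
    if df.shape[1] != len(col_labels):
        raise MatrixParseError(f"{path}: ragged rows (header has {len(col_labels)} columns)")
    row_labels = _check_labels(df.index, f"row ({path.name})")
    values = np.empty(df.shape, dtype=float)
    for j in range(df.shape[1]):
        coerced = pd.to_numeric(df.iloc[:, j], errors="coerce").to_numpy(dtype=float)
        bad = ~np.isfinite(coerced)
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise MatrixParseError(
                f"{path}: non-numeric or missing value at row '{row_labels[i]}', "
                f"column '{col_labels[j]}'"
            )
        values[:, j] = coerced
    return values, row_labels, col_labels


def read_labeled_matrix(
    path: str | Path, expect_square: bool = False, side: Side = "disease"
) -> "AssociationMatrix | SimilarityKernel":
    """Parse a labeled TSV into the appropriate domain type.

    With ``expect_square`` the file must be a square matrix with identical
    row and column labels and is returned as a :class:`SimilarityKernel`
    for ``side``; otherwise an :class:`AssociationMatrix` is returned.
    """
    values, rows, cols = read_matrix_frame(path)
    if expect_square:
        if rows != cols:
            raise ValidationError(
                f"{path}: square matrix expected but row and column labels differ"
            )
        return SimilarityKernel(values, rows, side)
    return AssociationMatrix(values, rows, cols)


def write_labeled_matrix(
    path: str | Path,
    values: np.ndarray,
    row_labels: Sequence[str],
    col_labels: Sequence[str],
) -> None:
    """Write a labeled matrix as TSV with 12 significant digits."""
    df = pd.DataFrame(np.asarray(values, dtype=float), index=list(row_labels),
                      columns=list(col_labels))
    df.to_csv(path, sep="\t", float_format="%.12g", index_label="")


def write_association(path: str | Path, A: AssociationMatrix) -> None:
    write_labeled_matrix(path, A.values, A.disease_labels, A.mirna_labels)


def write_kernel(path: str | Path, K: SimilarityKernel) -> None:
    write_labeled_matrix(path, K.values, K.labels, K.labels)


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------

@dataclass
class AlignedInputs:
    """Association matrix plus kernels reordered to its label order."""

    association: AssociationMatrix
    disease_kernels: list[SimilarityKernel]
    mirna_kernels: list[SimilarityKernel]
    #: labels present in a kernel but absent from A, keyed "side[i]"
    dropped: dict[str, list[str]] = field(default_factory=dict)


def _align_kernel(K: SimilarityKernel, labels: Sequence[str]) -> tuple[SimilarityKernel, list[str]]:
    pos = {lab: i for i, lab in enumerate(K.labels)}
    missing = [lab for lab in labels if lab not in pos]
    if missing:
        raise AlignmentError(
            f"{K.side} kernel is missing labels required by the association "
            f"matrix: {missing[:10]}" + (" ..." if len(missing) > 10 else "")
        )
    keep = set(labels)
    dropped = [lab for lab in K.labels if lab not in keep]
    ix = np.array([pos[lab] for lab in labels], dtype=int)
    aligned = SimilarityKernel(K.values[np.ix_(ix, ix)], list(labels), K.side)
    return aligned, dropped


def align_inputs(
    A: AssociationMatrix,
    disease_kernels: Sequence[SimilarityKernel],
    mirna_kernels: Sequence[SimilarityKernel],
) -> AlignedInputs:
    """Reorder (and subset) every kernel to A's entity order.

    Each kernel's label set must be a superset of the corresponding A
    labels; extra labels are dropped and reported in ``dropped``.
    Idempotent: aligning aligned inputs is the identity.
    """
    dropped: dict[str, list[str]] = {}
    dks, mks = [], []
    for i, K in enumerate(disease_kernels):
        if K.side != "disease":
            raise AlignmentError(f"disease kernel #{i} has side {K.side!r}")
        aligned, drop = _align_kernel(K, A.disease_labels)
        if drop:
            dropped[f"disease[{i}]"] = drop
            logger.info("disease kernel #%d: dropped %d labels absent from A", i, len(drop))
        dks.append(aligned)
    for i, K in enumerate(mirna_kernels):
        if K.side != "mirna":
            raise AlignmentError(f"miRNA kernel #{i} has side {K.side!r}")
        aligned, drop = _align_kernel(K, A.mirna_labels)
        if drop:
            dropped[f"mirna[{i}]"] = drop
            logger.info("miRNA kernel #%d: dropped %d labels absent from A", i, len(drop))
        mks.append(aligned)
    return AlignedInputs(A, dks, mks, dropped)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class GipParams:
    """Base bandwidths rho' for the Gaussian interaction profile kernel.

    The effective bandwidth is rho = rho' / (mean squared profile norm);
    rho' = 1 is the established GIP convention.
    """

    base_bandwidth_disease: float = 1.0
    base_bandwidth_mirna: float = 1.0

    def __post_init__(self) -> None:
        if self.base_bandwidth_disease <= 0 or self.base_bandwidth_mirna <= 0:
            raise ValidationError("GIP base bandwidths must be > 0")


@dataclass
class FusionParams:
    """Similarity kernel fusion hyperparameters.

    ``beta`` balances the cross-diffusion term against the initial
    kernels; ``k_neighbors`` sizes the neighbor-constraint kernels and
    the mutual-neighborhood mask (clipped to n at use).
    """

    beta: float = 0.5
    k_neighbors: int = 20
    max_iterations: int = 20
    tolerance: float = 1e-6
    method: Literal["skf", "average"] = "skf"

    def __post_init__(self) -> None:
        if not 0.0 < self.beta < 1.0:
            raise ValidationError("fusion beta must lie in (0, 1)")
        if self.k_neighbors < 1:
            raise ValidationError("fusion k_neighbors must be >= 1")
        if self.max_iterations < 1:
            raise ValidationError("fusion max_iterations must be >= 1")
        if self.tolerance <= 0:
            raise ValidationError("fusion tolerance must be > 0")
        if self.method not in ("skf", "average"):
            raise ValidationError("fusion method must be 'skf' or 'average'")


@dataclass
class WknknParams:
    """Weighted k-nearest known neighbor hyperparameters.

    ``k`` verified neighbors per entity, geometric decay ``decay`` in
    [0, 1] on the similarity weights, and side weights ``delta_disease``
    / ``delta_mirna`` for combining the two reconstructed profiles.
    """

    k: int = 10
    decay: float = 0.7
    delta_disease: float = 0.5
    delta_mirna: float = 0.5

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValidationError("wknkn k must be >= 1")
        if not 0.0 <= self.decay <= 1.0:
            raise ValidationError("wknkn decay must lie in [0, 1]")
        if self.delta_disease < 0 or self.delta_mirna < 0:
            raise ValidationError("wknkn deltas must be nonnegative")
        if self.delta_disease + self.delta_mirna <= 0:
            raise ValidationError("wknkn deltas must not both be zero")


@dataclass
class PropagationParams:
    """Label propagation hyperparameters.

    ``gamma`` balances absorbing labels from neighbors against retaining
    previous labels; ``alpha`` weights the disease-side score matrix in
    the final ensemble.  Defaults are the tuned values gamma=0.2,
    alpha=0.3.
    """

    gamma: float = 0.2
    alpha: float = 0.3
    k_neighbors: int = 20
    tolerance: float = 1e-6
    max_iterations: int = 1000
    mode: Literal["as_printed", "recurrent"] = "as_printed"

    def __post_init__(self) -> None:
        if not 0.0 <= self.gamma <= 1.0:
            raise ValidationError("propagation gamma must lie in [0, 1]")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValidationError("propagation alpha must lie in [0, 1]")
        if self.k_neighbors < 1:
            raise ValidationError("propagation k_neighbors must be >= 1")
        if self.tolerance <= 0:
            raise ValidationError("propagation tolerance must be > 0")
        if self.max_iterations < 1:
            raise ValidationError("propagation max_iterations must be >= 1")
        if self.mode not in ("as_printed", "recurrent"):
            raise ValidationError("propagation mode must be 'as_printed' or 'recurrent'")


@dataclass
class PipelineConfig:
    """All pipeline hyperparameters plus the base random seed."""

    gip: GipParams = field(default_factory=GipParams)
    fusion: FusionParams = field(default_factory=FusionParams)
    wknkn: WknknParams = field(default_factory=WknknParams)
    propagation: PropagationParams = field(default_factory=PropagationParams)
    seed: int = 0

    _SECTIONS = {
        "gip": GipParams,
        "fusion": FusionParams,
        "wknkn": WknknParams,
        "propagation": PropagationParams,
    }

    @classmethod
    def from_mapping(cls, mapping: Mapping) -> "PipelineConfig":
        kwargs: dict = {}
        for key, value in mapping.items():
            if key == "seed":
                kwargs["seed"] = int(value)
            elif key in cls._SECTIONS:
                section_cls = cls._SECTIONS[key]
                known = {f.name for f in fields(section_cls)}
                unknown = set(value) - known
                if unknown:
                    raise ValidationError(f"unknown {key} options: {sorted(unknown)}")
                kwargs[key] = section_cls(**value)
            else:
                raise ValidationError(f"unknown config section: {key!r}")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, Mapping):
            raise ValidationError(f"{path}: config file must contain a mapping")
        return cls.from_mapping(data)

    def to_mapping(self) -> dict:
        out: dict = {"seed": self.seed}
        for key, section_cls in self._SECTIONS.items():
            section = getattr(self, key)
            out[key] = {f.name: getattr(section, f.name) for f in fields(section_cls)}
        return out
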