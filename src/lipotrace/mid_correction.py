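"""Natural-abundance correction of 13C-traced isotopologue intensities.

A measured GC/MS isotopologue envelope mixes two signals: tracer-derived
13C on the palmitate backbone, and naturally occurring heavy isotopes
(13C, 2H, 18O, 29/30Si, ...) everywhere in the derivatized fragment. The
correction models the measured envelope as ``measured = M @ true`` where
column j of the correction matrix M is the theoretical envelope of a
molecule carrying exactly j tracer-derived carbons, and recovers the true
mass isotopomer distribution (MID) by non-negative least squares.

The default fragment ``C18H37O2Si`` is a TBDMS-palmitate-consistent ion
with 16 tracer-eligible backbone carbons; both are configuration, not
fixed chemistry.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .isotope_chem import (
    ElementalFormula,
    IsotopePattern,
    IsotopeTable,
    default_isotope_table,
    natural_pattern,
    parse_formula,
)

__all__ = [
    "CorrectionSpec",
    "RawMID",
    "CorrectedMID",
    "CorrectionError",
    "build_correction_matrix",
    "correct_mid",
    "forward_measure",
    "DEFAULT_FRAGMENT",
    "PALMITATE_CARBONS",
]

logger = logging.getLogger(__name__)

#: TBDMS-palmitate-consistent fragment; the monitored ion is configurable.
DEFAULT_FRAGMENT = "C18H37O2Si"
#: Palmitate backbone length: 16 carbons, all potentially tracer-derived.
PALMITATE_CARBONS = 16


class CorrectionError(ValueError):
    """Raised for invalid correction configuration or unusable input."""


@dataclass(frozen=True)
class CorrectionSpec:
    """Configuration of the natural-abundance correction.

    Parameters
    ----------
    fragment
        Elemental composition of the full derivatized fragment.
    tracer_element
        Element carrying the label (``"C"`` for [U-13C]glucose).
    tracer_count
        Number of backbone positions that can carry tracer label
        (16 for palmitate).
    tracer_purity
        Isotopic enrichment of the tracer source: probability that a
        tracer-derived position actually is 13C.
    correct_tracer_natural
        Whether the (tracer_count - j) unlabeled backbone positions
        contribute natural 13C to column j.
    """

    fragment: ElementalFormula = field(
        default_factory=lambda: parse_formula(DEFAULT_FRAGMENT)
    )
    tracer_element: str = "C"
    tracer_count: int = PALMITATE_CARBONS
    tracer_purity: float = 0.99
    correct_tracer_natural: bool = True
    isotope_table: IsotopeTable | None = None

    def __post_init__(self) -> None:
        if self.tracer_count <= 0:
            raise CorrectionError("tracer_count must be positive")
        if self.fragment[self.tracer_element] < self.tracer_count:
            raise CorrectionError(
                f"fragment has {self.fragment[self.tracer_element]} "
                f"{self.tracer_element} atoms, fewer than tracer_count="
                f"{self.tracer_count}"
            )
        if not 0.0 < self.tracer_purity <= 1.0:
            raise CorrectionError("tracer_purity must be in (0, 1]")

    @property
    def table(self) -> IsotopeTable:
        return self.isotope_table if self.isotope_table is not None else default_isotope_table()

    def default_n_rows(self) -> int:
        """Rows retained by default: tracer_count + 4 extra natural-shift channels."""
        return self.tracer_count + 4 + 1


@dataclass(frozen=True)
class RawMID:
    """Measured isotopologue intensities over m+0 ... m+K (arbitrary units)."""

    intensities: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.intensities, dtype=float)
        if v.ndim != 1 or v.size == 0:
            raise ValueError("intensities must be a non-empty 1-D vector")
        if np.any(v < 0):
            raise ValueError("intensities must be non-negative")
        if not np.any(v > 0):
            raise ValueError("intensities must contain a positive entry")
        object.__setattr__(self, "intensities", v)
        self.intensities.setflags(write=False)

    def __len__(self) -> int:
        return len(self.intensities)


@dataclass(frozen=True)
class CorrectedMID:
    """Corrected isotopomer fractions p0 ... p_n summing to 1, plus fit residual."""

    fractions: np.ndarray = field(repr=False)
    residual: float = 0.0

    def __post_init__(self) -> None:
        p = np.asarray(self.fractions, dtype=float)
        if np.any(p < 0):
            raise ValueError("fractions must be non-negative")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"fractions sum to {p.sum()!r}, expected 1")
        if self.residual < 0:
            raise ValueError("residual must be non-negative")
        object.__setattr__(self, "fractions", p)
        self.fractions.setflags(write=False)

    def __len__(self) -> int:
        return len(self.fractions)


def _base_pattern(spec: CorrectionSpec, n_unlabeled: int) -> IsotopePattern:
    """Natural envelope of all atoms that are not tracer-labeled in a column.

    Covers every non-tracer atom, plus ``n_unlabeled`` backbone positions
    when the spec corrects natural 13C at unlabeled tracer positions.
    """
    n_backbone_natural = n_unlabeled if spec.correct_tracer_natural else 0
    remove = spec.tracer_count - n_backbone_natural
    counts = dict(spec.fragment.counts)
    if remove:
        if counts[spec.tracer_element] == remove:
            del counts[spec.tracer_element]
        else:
            counts[spec.tracer_element] -= remove
    if not counts:  # every atom is a labeled tracer position
        return IsotopePattern(np.array([1.0]))
    return natural_pattern(ElementalFormula(counts), spec.table)


def _purity_pattern(j: int, purity: float) -> IsotopePattern:
    """Binomial mass-shift distribution of j labeled positions at given purity."""
    if j == 0:
        return IsotopePattern(np.array([1.0]))
    return IsotopePattern(stats.binom.pmf(np.arange(j + 1), j, purity))


def build_correction_matrix(spec: CorrectionSpec, n_rows: int | None = None) -> np.ndarray:
    """Correction matrix M with ``n_rows`` rows and ``tracer_count + 1`` columns.

    Column j is the theoretical measured envelope of a molecule with exactly
    j tracer-derived carbons: the convolution of the natural pattern of all
    non-labeled atoms with the binomial purity pattern of the j labeled
    positions, truncated to ``n_rows`` channels.
    """
    if n_rows is None:
        n_rows = spec.default_n_rows()
    if n_rows < spec.tracer_count + 1:
        raise CorrectionError(
            f"n_rows={n_rows} must cover m+0..m+{spec.tracer_count}"
        )
    M = np.zeros((n_rows, spec.tracer_count + 1))
    for j in range(spec.tracer_count + 1):
        base = _base_pattern(spec, n_unlabeled=spec.tracer_count - j)
        column = np.convolve(base.probs, _purity_pattern(j, spec.tracer_purity).probs)
        M[:, j] = column[:n_rows] if len(column) >= n_rows else np.pad(
            column, (0, n_rows - len(column))
        )
    return M


def forward_measure(true_fractions: np.ndarray, matrix: np.ndarray) -> RawMID:
    """Forward model: the envelope a given true MID would measure as.

    This is the independent oracle for :func:`correct_mid` — a plain
    matrix-vector product, no inversion involved.
    """
    x = np.asarray(true_fractions, dtype=float)
    if x.ndim != 1 or x.size != matrix.shape[1]:
        raise ValueError(
            f"true MID length {x.size} does not match matrix columns {matrix.shape[1]}"
        )
    return RawMID(matrix @ x)


def correct_mid(raw: RawMID, matrix: np.ndarray) -> CorrectedMID:
    """Invert the measured envelope into a corrected, normalized MID.

    Solves ``min ||M x - raw||`` subject to ``x >= 0`` (non-negative least
    squares), then normalizes ``x`` to sum 1. The residual is the fit norm
    before normalization. Raw vectors longer than the matrix are truncated
    (with a warning); shorter ones are zero-padded.
    """
    n_rows, n_cols = matrix.shape
    if np.linalg.matrix_rank(matrix) < n_cols:
        raise CorrectionError(
            "correction matrix is rank deficient; check the correction spec "
            "(fragment, tracer_count, purity)"
        )
    b = raw.intensities
    if len(b) > n_rows:
        logger.warning(
            "raw vector has %d channels; truncating to the matrix's %d rows",
            len(b), n_rows,
        )
        b = b[:n_rows]
    elif len(b) < n_rows:
        b = np.pad(b, (0, n_rows - len(b)))
    if not np.any(b > 0):
        raise CorrectionError("raw intensities are all zero after truncation")
    x, residual = optimize.nnls(matrix, b)
    total = x.sum()
    if total <= 0:
        raise CorrectionError("non-negative fit returned an all-zero MID")
    return CorrectedMID(fractions=x / total, residual=float(residual))
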