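"""Chemical formulas and theoretical natural-abundance isotope patterns.

A molecule's isotope envelope at unit (nominal-mass) resolution is the
discrete convolution of one single-atom isotope distribution per atom.
For a GC/MS fragment such as TBDMS-derivatized palmitate this envelope is
what natural-abundance correction removes, so the forward model here is
the foundation of the correction matrix in :mod:`lipotrace.mid_correction`.

Only nominal mass shifts are modeled (m+0, m+1, ...); fine isotope
structure is out of scope for a unit-resolution GC/MS workflow.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "ElementalFormula",
    "IsotopeTable",
    "IsotopePattern",
    "FormulaError",
    "parse_formula",
    "natural_pattern",
    "convolve",
    "default_isotope_table",
    "load_isotope_table",
]

#: Hill-order convention: C first, H second, then remaining elements
#: alphabetically.
_HILL_HEAD = ("C", "H")


class FormulaError(ValueError):
    """Raised for malformed or chemically invalid formula strings."""


@dataclass(frozen=True)
class ElementalFormula:
    """Element -> atom-count mapping for a molecule or fragment.

    Counts must be positive; elements with zero atoms are simply absent.
    """

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        if not self.counts:
            raise FormulaError("formula must contain at least one atom")
        for element, n in self.counts.items():
            if not isinstance(n, (int, np.integer)) or n <= 0:
                raise FormulaError(
                    f"invalid count {n!r} for element {element!r}; "
                    "counts must be positive integers"
                )
        object.__setattr__(self, "counts", dict(self.counts))

    @property
    def n_atoms(self) -> int:
        return sum(self.counts.values())

    def __getitem__(self, element: str) -> int:
        return self.counts.get(element, 0)

    def without(self, element: str, n: int) -> "ElementalFormula":
        """Return a copy with ``n`` atoms of ``element`` removed."""
        have = self[element]
        if n > have:
            raise FormulaError(
                f"cannot remove {n} {element} atoms from a formula with {have}"
            )
        counts = dict(self.counts)
        if n == have:
            del counts[element]
        else:
            counts[element] = have - n
        if not counts:
            raise FormulaError("removal would leave an empty formula")
        return ElementalFormula(counts)

    def hill_string(self) -> str:
        """Canonical Hill-order string, e.g. ``C18H37O2Si``."""
        parts = []
        rest = sorted(e for e in self.counts if e not in _HILL_HEAD)
        for element in (*_HILL_HEAD, *rest):
            n = self.counts.get(element, 0)
            if n == 1:
                parts.append(element)
            elif n > 1:
                parts.append(f"{element}{n}")
        return "".join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.hill_string()


@dataclass(frozen=True)
class IsotopeTable:
    """Per-element single-atom isotope distributions.

    ``shifts[element]`` holds strictly increasing nominal mass shifts and
    ``abundances[element]`` the matching probabilities, summing to 1.
    """

    shifts: Mapping[str, Sequence[int]]
    abundances: Mapping[str, Sequence[float]]

    def __post_init__(self) -> None:
        shifts = {}
        abund = {}
        for element in self.shifts:
            s = tuple(int(x) for x in self.shifts[element])
            a = tuple(float(x) for x in self.abundances[element])
            if len(s) != len(a) or not s:
                raise ValueError(f"inconsistent isotope rows for {element!r}")
            if any(x < 0 for x in s) or any(s[i] >= s[i + 1] for i in range(len(s) - 1)):
                raise ValueError(
                    f"mass shifts for {element!r} must be non-negative and "
                    "strictly increasing"
                )
            if any(x < 0 for x in a):
                raise ValueError(f"negative abundance for {element!r}")
            if abs(sum(a) - 1.0) > 1e-12:
                raise ValueError(
                    f"abundances for {element!r} sum to {sum(a)!r}, expected 1"
                )
            shifts[element] = s
            abund[element] = a
        object.__setattr__(self, "shifts", shifts)
        object.__setattr__(self, "abundances", abund)

    def elements(self) -> tuple[str, ...]:
        return tuple(self.shifts)

    def single_atom_pattern(self, element: str) -> "IsotopePattern":
        """The isotope distribution of one atom of ``element`` as a dense vector."""
        if element not in self.shifts:
            raise KeyError(f"element {element!r} not in isotope table")
        s = self.shifts[element]
        probs = np.zeros(s[-1] + 1)
        probs[list(s)] = self.abundances[element]
        return IsotopePattern(probs)


@dataclass(frozen=True)
class IsotopePattern:
    """Probability vector over nominal mass shifts m+0 ... m+K.

    Entries are non-negative and sum to at most 1; a sum below 1 indicates
    truncation of the high-mass tail.
    """

    probs: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 1 or p.size == 0:
            raise ValueError("pattern must be a non-empty 1-D vector")
        if np.any(p < -1e-15):
            raise ValueError("pattern entries must be non-negative")
        p = np.clip(p, 0.0, None)
        if p.sum() > 1.0 + 1e-9:
            raise ValueError(f"pattern mass {p.sum()!r} exceeds 1")
        object.__setattr__(self, "probs", p)
        self.probs.setflags(write=False)

    def __len__(self) -> int:
        return len(self.probs)

    @property
    def total_mass(self) -> float:
        """Retained probability mass (1 minus truncation loss)."""
        return float(self.probs.sum())

    def truncated(self, max_shift: int) -> "IsotopePattern":
        if max_shift < 0:
            raise ValueError("max_shift must be >= 0")
        return IsotopePattern(self.probs[: max_shift + 1])


_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str, *, known_elements: Sequence[str] | None = None) -> ElementalFormula:
    """Parse a Hill-style formula string like ``"C18H37O2Si"``.

    Grammar: one or more ``Element[Count]`` tokens; a missing count means 1.
    Repeated element symbols accumulate. Zero counts are rejected, as are
    element symbols outside ``known_elements`` (default: the elements of the
    packaged isotope table).
    """
    if not isinstance(text, str) or not text.strip():
        raise FormulaError("empty formula string")
    text = text.strip()
    if known_elements is None:
        known_elements = default_isotope_table().elements()
    known = set(known_elements)
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None or m.start() != pos or not m.group(1):
            raise FormulaError(
                f"malformed formula {text!r}: unexpected token at {text[pos:]!r}"
            )
        element, digits = m.group(1), m.group(2)
        if element not in known:
            raise FormulaError(f"unknown element symbol {element!r} in {text!r}")
        n = int(digits) if digits else 1
        if n == 0:
            raise FormulaError(f"zero atom count for {element!r} in {text!r}")
        counts[element] = counts.get(element, 0) + n
        pos = m.end()
    return ElementalFormula(counts)


def convolve(a: IsotopePattern, b: IsotopePattern) -> IsotopePattern:
    """Discrete convolution of two patterns (combining independent atoms).

    Output length is ``len(a) + len(b) - 1``; total mass multiplies.
    """
    return IsotopePattern(np.convolve(a.probs, b.probs))


def _element_power(single: IsotopePattern, n: int) -> IsotopePattern:
    """n-fold self-convolution by binary exponentiation."""
    result = IsotopePattern(np.array([1.0]))
    base = single
    while n > 0:
        if n & 1:
            result = convolve(result, base)
        base = convolve(base, base)
        n >>= 1
    return result


def natural_pattern(
    formula: ElementalFormula,
    table: IsotopeTable | None = None,
    max_shift: int | None = None,
) -> IsotopePattern:
    """Theoretical natural-abundance envelope of ``formula``.

    Convolves each atom's single-atom distribution from ``table`` (default:
    standard terrestrial abundances). With ``max_shift`` set, the tail above
    m+max_shift is truncated; the retained mass is available as
    ``pattern.total_mass``.
    """
    if table is None:
        table = default_isotope_table()
    pattern = IsotopePattern(np.array([1.0]))
    for element, n in formula.counts.items():
        single = table.single_atom_pattern(element)
        pattern = convolve(pattern, _element_power(single, n))
    if max_shift is not None:
        pattern = pattern.truncated(max_shift)
    return pattern


def load_isotope_table(path) -> IsotopeTable:
    """Load an isotope table from a YAML mapping element -> [[shift, abundance], ...]."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    return _table_from_mapping(raw)


def _table_from_mapping(raw: Mapping) -> IsotopeTable:
    shifts = {e: [row[0] for row in rows] for e, rows in raw.items()}
    abund = {e: [row[1] for row in rows] for e, rows in raw.items()}
    return IsotopeTable(shifts=shifts, abundances=abund)


_DEFAULT_TABLE: IsotopeTable | None = None


def default_isotope_table() -> IsotopeTable:
    """Standard terrestrial isotope abundances packaged with lipotrace."""
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        ref = resources.files("lipotrace").joinpath("data/isotopes.yaml")
        raw = yaml.safe_load(ref.read_text(encoding="utf-8"))
        _DEFAULT_TABLE = _table_from_mapping(raw)
    return _DEFAULT_TABLE


def monoisotopic_table(elements: Sequence[str] = ("C", "H", "N", "O", "Si", "S")) -> IsotopeTable:
    """A degenerate table with all abundance at m+0 (useful for tests/limits)."""
    return IsotopeTable(
        shifts={e: [0] for e in elements},
        abundances={e: [1.0] for e in elements},
    )
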