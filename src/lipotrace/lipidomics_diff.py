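"""Differential untargeted lipidomics with chain-length stratification.

Lipid species arrive as shorthand names — class abbreviation plus total
acyl carbons and double bonds, e.g. ``TG(52:2)`` or ``PC 37:4`` — over a
species x sample relative-abundance matrix. The differential procedure is
the field-standard two-group recipe: per-species t-test and fold change,
Benjamini-Hochberg correction across species, significance at adjusted
p < 0.05, followed by per-class carbon-number bin summaries (e.g. long-chain
PC C37-C42 versus shorter PC C24-C33, which respond in opposite directions
when lipogenesis is suppressed).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


__all__ = [
    "LipidSpecies",
    "AbundanceTable",
    "DiffResult",
    "LipidNameError",
    "parse_lipid_name",
    "differential",
    "bh_adjust",
    "chain_length_summary",
    "KNOWN_CLASSES",
    "DEFAULT_PC_BINS",
]

logger = logging.getLogger(__name__)

#: Recognized lipid class abbreviations (longest matched first at parse time).
KNOWN_CLASSES = ("LysoPC", "MG", "DG", "TG", "PC", "PE", "CL", "SM", "Cer", "FA")

#: Default carbon-number bins for PC chain-length stratification (inclusive).
DEFAULT_PC_BINS = ((24, 33), (37, 42))


class LipidNameError(ValueError):
    """Raised when a lipid shorthand name has no parsable carbons:bonds pair."""


@dataclass(frozen=True)
class LipidSpecies:
    """Parsed lipid shorthand: class, total acyl carbons, double bonds."""

    raw_name: str
    lipid_class: str
    total_carbons: int
    double_bonds: int

    def __post_init__(self) -> None:
        if self.total_carbons <= 0:
            raise ValueError("total_carbons must be positive")
        if not 0 <= self.double_bonds < self.total_carbons:
            raise ValueError("double_bonds must be in [0, total_carbons)")

    def canonical_name(self) -> str:
        return f"{self.lipid_class}({self.total_carbons}:{self.double_bonds})"


_NAME = re.compile(
    r"""^\s*
        (?P<cls>[A-Za-z]+)          # class token
        [\s(]*                      # optional space / opening paren
        C?                          # optional C prefix, as in TG(C52:2)
        (?P<carbons>\d+)
        :
        (?P<bonds>\d+)
        \)?\s*$""",
    re.VERBOSE,
)


def parse_lipid_name(name: str) -> LipidSpecies:
    """Parse shorthand like ``"TG(52:2)"``, ``"TG(C52:2)"`` or ``"PC 37:4"``.

    The class token is matched case-sensitively against the known classes;
    unknown tokens fall back to class ``"other"`` with a warning. A name
    without a ``carbons:bonds`` pair is a parse error.
    """
    if not name or not name.strip():
        raise LipidNameError("empty lipid name")
    m = _NAME.match(name)
    if m is None:
        raise LipidNameError(f"no carbons:double-bonds pair found in {name!r}")
    cls = m.group("cls")
    if cls not in KNOWN_CLASSES:
        logger.warning("unknown lipid class %r in %r; treated as 'other'", cls, name)
        cls = "other"
    return LipidSpecies(
        raw_name=name.strip(),
        lipid_class=cls,
        total_carbons=int(m.group("carbons")),
        double_bonds=int(m.group("bonds")),
    )


@dataclass(frozen=True)
class AbundanceTable:
    """Species x sample relative abundances with a sample -> group mapping."""

    values: pd.DataFrame  # index: species names, columns: sample ids
    groups: Mapping[str, str]  # sample id -> group label

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate species names: {dupes[:5]}")
        missing = [s for s in self.values.columns if s not in self.groups]
        if missing:
            raise ValueError(f"samples without group labels: {missing[:5]}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("abundances must be non-negative")
        object.__setattr__(self, "groups", dict(self.groups))

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] == group]


@dataclass(frozen=True)
class DiffResult:
    """Per-species two-group comparison result."""

    species: LipidSpecies
    log2_fc: float
    t_stat: float
    p_raw: float
    p_adj: float
    significant: bool
    zero_denominator: bool = False


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    Sort ascending, scale p_(i) by m/i, enforce monotonicity from the
    largest rank down, cap at 1. Empty input yields an empty output.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum(np.minimum.accumulate(scaled[::-1])[::-1], 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def differential(
    table: AbundanceTable,
    group_a: str,
    group_b: str,
    *,
    alpha: float = 0.05,
    welch: bool = True,
    log_transform: bool = True,
) -> list[DiffResult]:
    """Two-group differential analysis across all species in the table.

    Per species: two-sample t-test (Welch by default) on log2-transformed
    abundances (offset: half the smallest nonzero value in the table), and
    ``log2_fc = log2(mean_b / mean_a)`` on the raw scale with the same
    offset guarding zero denominators. BH correction runs across all tested
    species; significance is adjusted p < ``alpha``.
    """
    a_samples = table.samples_in_group(group_a)
    b_samples = table.samples_in_group(group_b)
    if len(a_samples) < 2 or len(b_samples) < 2:
        raise ValueError(
            f"both groups need >= 2 samples; got {len(a_samples)} in "
            f"{group_a!r} and {len(b_samples)} in {group_b!r}"
        )
    values = table.values.to_numpy(dtype=float)
    nonzero = values[values > 0]
    offset = float(nonzero.min()) / 2.0 if nonzero.size else 1e-12

    a = table.values[a_samples].to_numpy(dtype=float)
    b = table.values[b_samples].to_numpy(dtype=float)
    test_a = np.log2(a + offset) if log_transform else a
    test_b = np.log2(b + offset) if log_transform else b

    n_species = values.shape[0]
    t_stats = np.zeros(n_species)
    p_raw = np.ones(n_species)
    for i in range(n_species):
        xa, xb = test_a[i], test_b[i]
        if np.ptp(xa) == 0 and np.ptp(xb) == 0 and xa[0] == xb[0]:
            continue  # no variation anywhere: t = 0, p = 1
        t, p = stats.ttest_ind(xb, xa, equal_var=not welch)
        if np.isnan(t):
            continue
        t_stats[i], p_raw[i] = t, p

    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    zero_denominator = mean_a <= 0
    log2_fc = np.log2((mean_b + offset * zero_denominator)
                      / np.where(zero_denominator, offset, mean_a))
    if zero_denominator.any():
        logger.warning(
            "%d species have an all-zero denominator group; fold change "
            "computed against the offset guard", int(zero_denominator.sum()),
        )
    p_adj = bh_adjust(p_raw)

    results = []
    for i, name in enumerate(table.values.index):
        results.append(
            DiffResult(
                species=parse_lipid_name(str(name)),
                log2_fc=float(log2_fc[i]),
                t_stat=float(t_stats[i]),
                p_raw=float(p_raw[i]),
                p_adj=float(p_adj[i]),
                significant=bool(p_adj[i] < alpha),
                zero_denominator=bool(zero_denominator[i]),
            )
        )
    return results


@dataclass(frozen=True)
class ChainLengthBin:
    """Summary of one carbon-number bin within a lipid class."""

    lipid_class: str
    carbon_min: int
    carbon_max: int
    n_species: int
    n_significant: int
    median_log2_fc: float
    consensus: str  # "increased" | "decreased" | "mixed" | "none"


def chain_length_summary(
    results: Sequence[DiffResult],
    class_filter: str,
    bins: Sequence[tuple[int, int]] | None = None,
) -> list[ChainLengthBin]:
    """Bin a class's species by total carbons and summarize direction.

    Each bin is an inclusive carbon-number range (defaults: the PC ranges
    C24-C33 and C37-C42). Consensus is the sign shared by every significant
    species in the bin ("increased"/"decreased"), "mixed" when significant
    species disagree, "none" with no significant species. An absent class
    returns an empty summary with a warning.
    """
    if not results:
        raise ValueError("no differential results supplied")
    if bins is None:
        bins = DEFAULT_PC_BINS
    in_class = [r for r in results if r.species.lipid_class == class_filter]
    if not in_class:
        logger.warning("no species of class %r in results", class_filter)
        return []
    summaries = []
    for lo, hi in bins:
        members = [r for r in in_class if lo <= r.species.total_carbons <= hi]
        if not members:
            summaries.append(ChainLengthBin(class_filter, lo, hi, 0, 0, float("nan"), "none"))
            continue
        sig = [r for r in members if r.significant]
        signs = {np.sign(r.log2_fc) for r in sig if r.log2_fc != 0}
        if not sig or not signs:
            consensus = "none"
        elif signs == {1.0}:
            consensus = "increased"
        elif signs == {-1.0}:
            consensus = "decreased"
        else:
            consensus = "mixed"
        summaries.append(
            ChainLengthBin(
                lipid_class=class_filter,
                carbon_min=lo,
                carbon_max=hi,
                n_species=len(members),
                n_significant=len(sig),
                median_log2_fc=float(np.median([r.log2_fc for r in members])),
                consensus=consensus,
            )
        )
    return summaries
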