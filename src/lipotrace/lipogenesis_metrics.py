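"""De novo lipogenesis metrics from corrected palmitate MIDs.

Palmitate (16 carbons) is assembled from 8 two-carbon acetyl units, so
[U-13C]glucose label enters in m+2 increments: the even isotopologues
m+2, m+4, ..., m+16 carry the lipogenic signal, while odd channels are
measurement noise under this tracer. Two summaries are computed:

* the atom percent of glucose-derived palmitate,
  ``sum_k(p_k * k) / ((sum_k p_k + p0) * 16)`` over even k = 2..16 — the
  fraction of all palmitate carbon that came from labeled glucose;
* an isotopomer-spectral-analysis (ISA) style mixture fit, modeling the
  palmitate pool as a fraction ``g`` newly synthesized during labeling
  (each new molecule drawing its 8 acetyl units from a pool with labeled
  fraction ``D``) plus ``1 - g`` pre-existing unlabeled molecules.

For noiseless data the two agree analytically: atom percent equals g*D.

Group statistics mirror the tracing figure's convention: one-way ANOVA on
the m+0 fraction, two-way ANOVA (isotopologue x treatment group) on
m+2 .. m+16.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "PalmitateMID",
    "AtomPercentResult",
    "IsaFit",
    "AnovaResult",
    "TwoWayAnovaResult",
    "atom_percent",
    "total_de_novo",
    "fit_isa",
    "anova_one_way",
    "anova_two_way",
    "EVEN_K",
    "N_ACETYL_UNITS",
]

#: Even isotopologue indices carrying acetyl-unit label.
EVEN_K: tuple[int, ...] = (2, 4, 6, 8, 10, 12, 14, 16)
#: Acetyl (two-carbon) units per palmitate molecule.
N_ACETYL_UNITS = 8


@dataclass(frozen=True)
class PalmitateMID:
    """Corrected palmitate isotopomer fractions p0 ... p16."""

    p: np.ndarray = field(repr=False)
    n_carbons: int = 16

    def __post_init__(self) -> None:
        v = np.asarray(self.p, dtype=float)
        if v.ndim != 1 or v.size != self.n_carbons + 1:
            raise ValueError(
                f"expected {self.n_carbons + 1} fractions p0..p{self.n_carbons}, "
                f"got {v.size}"
            )
        if np.any(v < -1e-12):
            raise ValueError("fractions must be non-negative")
        v = np.clip(v, 0.0, None)
        if abs(v.sum() - 1.0) > 1e-9:
            raise ValueError(f"fractions sum to {v.sum()!r}, expected 1")
        object.__setattr__(self, "p", v)
        self.p.setflags(write=False)

    @property
    def even_k(self) -> tuple[int, ...]:
        return EVEN_K

    @property
    def p0(self) -> float:
        return float(self.p[0])

    def even_fractions(self) -> np.ndarray:
        """Fractions at k = 2, 4, ..., 16 (label-carrying channels)."""
        return self.p[list(EVEN_K)]


@dataclass(frozen=True)
class AtomPercentResult:
    """Fraction of palmitate carbon derived from labeled glucose, in [0, 1]."""

    atom_percent: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.atom_percent <= 1.0 + 1e-12:
            raise ValueError("atom_percent must lie in [0, 1]")


@dataclass(frozen=True)
class IsaFit:
    """ISA mixture-model estimates.

    ``g``: fraction of the palmitate pool synthesized de novo during labeling.
    ``D``: labeled fraction of the lipogenic acetyl pool.
    ``sse``: residual sum of squares of the fit over the 9 doublet channels.
    ``d_identifiable``: False when g is (near) zero, where D drops out of the
    model and its value is arbitrary.
    """

    g: float
    D: float
    sse: float
    d_identifiable: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.g <= 1.0 and 0.0 <= self.D <= 1.0):
            raise ValueError("g and D must lie in [0, 1]")


def atom_percent(mid: PalmitateMID) -> AtomPercentResult:
    """Atom percent of glucose-derived palmitate.

    Returns ``sum_k(p_k * k) / ((sum_k p_k + p0) * n)`` with the sums over
    even k = 2..16 and n = 16 carbons. Odd-channel mass (noise under a
    glucose tracer) is excluded from numerator and denominator.
    """
    even = mid.even_fractions()
    denom = (even.sum() + mid.p0) * mid.n_carbons
    if denom <= 0:
        raise ValueError(
            "atom percent undefined: no mass on p0 or any even isotopologue"
        )
    numer = float(np.dot(even, EVEN_K))
    return AtomPercentResult(atom_percent=numer / denom)


def total_de_novo(mid: PalmitateMID) -> float:
    """Fraction of palmitate molecules carrying any label, on even-k support.

    Computed as ``1 - p0 / (p0 + sum of even-k fractions)`` — the labeled
    share of the even-channel pool. A molecule-level companion to the
    carbon-level :func:`atom_percent`.
    """
    even_sum = float(mid.even_fractions().sum())
    denom = mid.p0 + even_sum
    if denom <= 0:
        raise ValueError("total de novo undefined: no even-channel mass")
    return even_sum / denom


def isa_doublet_model(g: float, d: float) -> np.ndarray:
    """Model doublet-count distribution q_j, j = 0..8 labeled acetyl units.

    ``q_j = (1-g)*[j==0] + g * Binomial(8, D).pmf(j)``; q_j corresponds to
    the m+2j isotopologue.
    """
    q = g * stats.binom.pmf(np.arange(N_ACETYL_UNITS + 1), N_ACETYL_UNITS, d)
    q[0] += 1.0 - g
    return q


def _isa_sse(params: np.ndarray, observed: np.ndarray) -> float:
    g, d = np.clip(params, 0.0, 1.0)
    return float(np.sum((isa_doublet_model(g, d) - observed) ** 2))


def fit_isa(mid: PalmitateMID, grid_size: int = 101) -> IsaFit:
    """Fit the ISA mixture model (g, D) to the even-channel MID.

    Least squares over the 9 doublet channels (p0, p2, ..., p16) via an
    exhaustive ``grid_size x grid_size`` scan of [0,1]^2 followed by
    Nelder-Mead polish from the grid optimum. Deterministic; ties broken by
    the first minimum in row-major grid order.
    """
    observed = np.concatenate(([mid.p0], mid.even_fractions()))
    if observed.sum() <= 0:
        raise ValueError("ISA fit undefined: no mass on p0 or even isotopologues")
    grid = np.linspace(0.0, 1.0, grid_size)
    j = np.arange(N_ACETYL_UNITS + 1)
    # pmf matrix: grid_size x 9, row per candidate D
    pmf = stats.binom.pmf(j[None, :], N_ACETYL_UNITS, grid[:, None])
    best = (np.inf, 0.0, 0.0)
    for g in grid:
        q = g * pmf
        q[:, 0] += 1.0 - g
        sse = np.sum((q - observed[None, :]) ** 2, axis=1)
        i = int(np.argmin(sse))
        if sse[i] < best[0] - 1e-18:
            best = (float(sse[i]), float(g), float(grid[i]))
    res = optimize.minimize(
        _isa_sse,
        x0=np.array(best[1:]),
        args=(observed,),
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-16, "maxiter": 2000},
    )
    g_hat, d_hat = np.clip(res.x, 0.0, 1.0)
    sse = _isa_sse(np.array([g_hat, d_hat]), observed)
    if sse > best[0]:  # polish must never lose to the grid
        sse, g_hat, d_hat = best
    identifiable = g_hat > 1e-6
    if not identifiable:
        d_hat = 0.0
    return IsaFit(g=float(g_hat), D=float(d_hat), sse=float(sse),
                  d_identifiable=bool(identifiable))


# --------------------------------------------------------------------------
# Group statistics (tracing-figure conventions)

@dataclass(frozen=True)
class AnovaResult:
    F: float
    p: float
    df_between: int
    df_within: int
    zero_within_variance: bool = False


@dataclass(frozen=True)
class TwoWayAnovaResult:
    """Fixed-effects two-factor decomposition with interaction."""

    F_a: float
    p_a: float
    F_b: float
    p_b: float
    F_interaction: float
    p_interaction: float
    df: Mapping[str, int]


def anova_one_way(values_by_group: Mapping[str, Sequence[float]]) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA.

    Requires at least two groups of at least two observations each. When
    within-group variance is exactly zero but means differ, F is infinite
    and p = 0, flagged via ``zero_within_variance``.
    """
    groups = [np.asarray(v, dtype=float) for v in values_by_group.values()]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("every group needs at least two observations")
    all_values = np.concatenate(groups)
    grand = all_values.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(float(np.sum((g - g.mean()) ** 2)) for g in groups)
    df_b = len(groups) - 1
    df_w = len(all_values) - len(groups)
    if ss_within == 0.0:
        if ss_between == 0.0:
            return AnovaResult(F=0.0, p=1.0, df_between=df_b, df_within=df_w)
        return AnovaResult(F=np.inf, p=0.0, df_between=df_b, df_within=df_w,
                           zero_within_variance=True)
    F = (ss_between / df_b) / (ss_within / df_w)
    p = float(stats.f.sf(F, df_b, df_w))
    return AnovaResult(F=float(F), p=p, df_between=df_b, df_within=df_w)


def anova_two_way(table: pd.DataFrame,
                  factor_a: str = "isotopologue",
                  factor_b: str = "group",
                  value: str = "value") -> TwoWayAnovaResult:
    """Balanced complete two-way fixed-effects ANOVA with interaction.

    ``table`` holds one observation per row with two categorical factor
    columns and a value column; every factor-level combination must appear
    with the same number (>= 2) of replicates. Unbalanced or incomplete
    designs are rejected.
    """
    for col in (factor_a, factor_b, value):
        if col not in table.columns:
            raise ValueError(f"missing column {col!r}")
    counts = table.groupby([factor_a, factor_b], observed=True)[value].count()
    a_levels = table[factor_a].nunique()
    b_levels = table[factor_b].nunique()
    if len(counts) != a_levels * b_levels or counts.nunique() != 1:
        raise ValueError("design must be balanced and complete")
    n = int(counts.iloc[0])
    if n < 2:
        raise ValueError("need at least two replicates per cell")

    y = table[value].to_numpy(dtype=float)
    grand = y.mean()
    cell_means = table.groupby([factor_a, factor_b], observed=True)[value].mean()
    a_means = table.groupby(factor_a, observed=True)[value].mean()
    b_means = table.groupby(factor_b, observed=True)[value].mean()

    ss_a = b_levels * n * float(((a_means - grand) ** 2).sum())
    ss_b = a_levels * n * float(((b_means - grand) ** 2).sum())
    interaction_dev = (
        cell_means
        - a_means.reindex(cell_means.index.get_level_values(0)).to_numpy()
        - b_means.reindex(cell_means.index.get_level_values(1)).to_numpy()
        + grand
    )
    ss_ab = n * float((interaction_dev ** 2).sum())
    fitted = cell_means.loc[
        list(zip(table[factor_a], table[factor_b]))
    ].to_numpy()
    ss_e = float(np.sum((y - fitted) ** 2))

    df_a, df_b = a_levels - 1, b_levels - 1
    df_ab = df_a * df_b
    df_e = a_levels * b_levels * (n - 1)

    def f_and_p(ss: float, df: int) -> tuple[float, float]:
        if ss_e == 0.0:
            return (0.0, 1.0) if ss <= 1e-24 else (np.inf, 0.0)
        F = (ss / df) / (ss_e / df_e)
        return float(F), float(stats.f.sf(F, df, df_e))

    F_a, p_a = f_and_p(ss_a, df_a)
    F_b, p_b = f_and_p(ss_b, df_b)
    F_ab, p_ab = f_and_p(ss_ab, df_ab)
    return TwoWayAnovaResult(
        F_a=F_a, p_a=p_a, F_b=F_b, p_b=p_b,
        F_interaction=F_ab, p_interaction=p_ab,
        df={"a": df_a, "b": df_b, "interaction": df_ab, "error": df_e},
    )
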