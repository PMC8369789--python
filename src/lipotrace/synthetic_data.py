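"""Ground-truthed simulators for the tracing and lipidomics analyses.

Two generators produce the inputs every downstream stage consumes, with
sidecar tables recording the simulation truth so recovery can be checked:

* palmitate GC/MS isotopologue intensities: each replicate's true MID is an
  ISA mixture — a fraction ``g`` of molecules newly synthesized from 8
  acetyl units drawn from a pool with labeled fraction ``D``, the rest
  pre-existing and unlabeled — pushed through the natural-abundance
  correction matrix (the forward model) and degraded with multiplicative
  lognormal noise;
* lipid abundance matrices: lognormal species baselines with class- and
  carbon-range-dependent group effects on the log2 scale, emulating the
  pattern where long-chain PC/DG species fall and some shorter-chain
  PC/TG species rise when lipogenesis is suppressed.

The default tracing groups mirror a conditional-oncogene experiment
(vehicle with the highest de novo fraction; doxycycline and two TOFA doses
progressively suppressed). All values are simulator configuration, not
measured quantities.

Determinism: one seeded generator per call, consumed in documented order
(groups sorted, replicates/species in index order) so equal seeds give
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .lipogenesis_metrics import EVEN_K, isa_doublet_model
from .mid_correction import CorrectionSpec, build_correction_matrix

__all__ = [
    "TracingSimConfig",
    "LipidSimConfig",
    "LipidEffect",
    "simulate_palmitate_raw",
    "simulate_lipid_table",
    "true_mid_from_isa",
    "DEFAULT_TRACING_GROUPS",
    "DEFAULT_LIPID_EFFECTS",
]

#: Vehicle highest de novo fraction; dox and TOFA doses progressively lower.
DEFAULT_TRACING_GROUPS: dict[str, tuple[float, float]] = {
    "vehicle": (0.55, 0.45),
    "dox": (0.25, 0.35),
    "tofa3": (0.15, 0.30),
    "tofa10": (0.05, 0.25),
}


@dataclass(frozen=True)
class TracingSimConfig:
    """Configuration of the palmitate tracing simulator.

    ``g_by_group`` / ``d_by_group`` map group label to the de novo fraction
    and acetyl-pool enrichment; ``noise_cv`` is the coefficient of variation
    of multiplicative lognormal measurement noise per channel.
    """

    g_by_group: Mapping[str, float] = field(
        default_factory=lambda: {k: v[0] for k, v in DEFAULT_TRACING_GROUPS.items()}
    )
    d_by_group: Mapping[str, float] = field(
        default_factory=lambda: {k: v[1] for k, v in DEFAULT_TRACING_GROUPS.items()}
    )
    n_replicates: int = 6
    noise_cv: float = 0.02
    correction_spec: CorrectionSpec = field(default_factory=CorrectionSpec)
    total_intensity: float = 1e6
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.g_by_group) != set(self.d_by_group):
            raise ValueError("g_by_group and d_by_group must share group labels")
        for grp in self.g_by_group:
            g, d = self.g_by_group[grp], self.d_by_group[grp]
            if not (0.0 <= g <= 1.0 and 0.0 <= d <= 1.0):
                raise ValueError(f"g and D for group {grp!r} must lie in [0, 1]")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")


def true_mid_from_isa(g: float, d: float, n_carbons: int = 16) -> np.ndarray:
    """True (pre-measurement) MID p0..p16 implied by ISA parameters.

    All mass sits on even isotopologues: p_{2j} = q_j with q the doublet
    model; odd channels are exactly zero.
    """
    q = isa_doublet_model(g, d)
    p = np.zeros(n_carbons + 1)
    p[0] = q[0]
    p[list(EVEN_K)] = q[1:]
    return p


def _lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-mean multiplicative lognormal factors with the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=size)


def simulate_palmitate_raw(
    config: TracingSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate raw palmitate isotopologue intensities plus a truth sidecar.

    Returns ``(raw, truth)``: ``raw`` has columns ``sample_id, group,
    m0..mK`` (K set by the correction spec's row count); ``truth`` records
    per sample the generating ``g``, ``D`` and the true MID ``p0..p16``.
    """
    spec = config.correction_spec
    matrix = build_correction_matrix(spec)
    n_rows = matrix.shape[0]
    rng = np.random.default_rng(config.seed)

    raw_records, truth_records = [], []
    for group in sorted(config.g_by_group):
        g, d = config.g_by_group[group], config.d_by_group[group]
        true_mid = true_mid_from_isa(g, d, spec.tracer_count)
        expected = matrix @ true_mid * config.total_intensity
        for rep in range(config.n_replicates):
            sample_id = f"{group}_{rep + 1}"
            measured = expected * _lognormal_noise(rng, config.noise_cv, n_rows)
            raw_records.append(
                {"sample_id": sample_id, "group": group,
                 **{f"m{k}": measured[k] for k in range(n_rows)}}
            )
            truth_records.append(
                {"sample_id": sample_id, "group": group, "g": g, "D": d,
                 **{f"p{k}": true_mid[k] for k in range(spec.tracer_count + 1)}}
            )
    return pd.DataFrame(raw_records), pd.DataFrame(truth_records)


@dataclass(frozen=True)
class LipidEffect:
    """Group effect on one (class, carbon-range) stratum, log2 scale."""

    lipid_class: str
    carbon_min: int
    carbon_max: int
    log2_mean: float
    log2_sd: float


#: Long-chain PC/DG suppressed, short-chain PC and TG mildly increased in
#: every treated group, echoing the chain-length-dependent response of the
#: lipidome to lipogenesis inhibition.
DEFAULT_LIPID_EFFECTS: dict[str, tuple[LipidEffect, ...]] = {
    group: (
        LipidEffect("PC", 37, 42, -1.5, 0.2),
        LipidEffect("PC", 24, 33, +0.8, 0.2),
        LipidEffect("DG", 34, 44, -1.2, 0.2),
        LipidEffect("TG", 40, 54, +0.6, 0.3),
    )
    for group in ("dox", "tofa3", "tofa10")
}


@dataclass(frozen=True)
class LipidSimConfig:
    """Configuration of the lipid abundance-table simulator."""

    n_species_per_class: Mapping[str, int] = field(
        default_factory=lambda: {"PC": 40, "DG": 20, "TG": 30, "PE": 15, "LysoPC": 10}
    )
    effects_by_group: Mapping[str, Sequence[LipidEffect]] = field(
        default_factory=lambda: dict(DEFAULT_LIPID_EFFECTS)
    )
    carbon_range_by_class: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: {
            "PC": (24, 44), "DG": (28, 44), "TG": (40, 60),
            "PE": (30, 44), "LysoPC": (14, 22),
        }
    )
    reference_group: str = "vehicle"
    n_samples_per_group: int = 6
    within_group_cv: float = 0.15
    baseline_log_mean: float = 10.0
    baseline_log_sd: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples_per_group < 2:
            raise ValueError("n_samples_per_group must be >= 2")
        if self.within_group_cv < 0:
            raise ValueError("within_group_cv must be >= 0")


def _species_effect(species_class: str, carbons: int,
                    effects: Sequence[LipidEffect],
                    rng: np.random.Generator) -> float:
    for eff in effects:
        if eff.lipid_class == species_class and eff.carbon_min <= carbons <= eff.carbon_max:
            return float(rng.normal(eff.log2_mean, eff.log2_sd))
    return 0.0


def simulate_lipid_table(
    config: LipidSimConfig,
) -> tuple[pd.DataFrame, Mapping[str, str], pd.DataFrame]:
    """Simulate a lipid abundance matrix plus group map and truth sidecar.

    Returns ``(values, groups, truth)``: ``values`` is species x sample,
    ``groups`` maps sample id to group, and ``truth`` records each species'
    true log2 effect per treated group (zero rows are true nulls).
    """
    rng = np.random.default_rng(config.seed)
    all_groups = [config.reference_group, *sorted(config.effects_by_group)]

    species: list[tuple[str, str, int]] = []  # name, class, carbons
    for cls in sorted(config.n_species_per_class):
        lo, hi = config.carbon_range_by_class.get(cls, (24, 44))
        seen = set()
        for _ in range(config.n_species_per_class[cls]):
            while True:
                carbons = int(rng.integers(lo, hi + 1))
                bonds = int(rng.integers(0, min(7, carbons)))
                name = f"{cls}({carbons}:{bonds})"
                if name not in seen:
                    seen.add(name)
                    break
            species.append((name, cls, carbons))

    baselines = rng.lognormal(config.baseline_log_mean, config.baseline_log_sd,
                              size=len(species))
    effects = {
        group: np.array([
            _species_effect(cls, carbons, config.effects_by_group[group], rng)
            for (_, cls, carbons) in species
        ])
        for group in sorted(config.effects_by_group)
    }

    groups: dict[str, str] = {}
    columns: dict[str, np.ndarray] = {}
    for group in all_groups:
        log2_shift = effects.get(group, np.zeros(len(species)))
        group_mean = baselines * np.exp2(log2_shift)
        for i in range(config.n_samples_per_group):
            sample_id = f"{group}_{i + 1}"
            groups[sample_id] = group
            columns[sample_id] = group_mean * _lognormal_noise(
                rng, config.within_group_cv, len(species)
            )

    values = pd.DataFrame(columns, index=[name for name, _, _ in species])
    truth = pd.DataFrame(
        {"species": [name for name, _, _ in species],
         "lipid_class": [cls for _, cls, _ in species],
         "total_carbons": [c for _, _, c in species],
         **{f"log2_effect_{g}": effects[g] for g in sorted(effects)}}
    )
    return values, groups, truth
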