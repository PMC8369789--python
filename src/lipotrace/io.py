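"""CSV/YAML readers and writers, run configuration, and the pipeline driver.

Interchange is plain CSV throughout (the inputs are post-integration
intensity and abundance tables, not raw spectra): UTF-8, ``.`` decimal,
header required. Each pipeline run writes its outputs next to a YAML
manifest echoing the configuration, seed and package version.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .lipidomics_diff import (
    AbundanceTable,
    DiffResult,
    chain_length_summary,
    differential,
)
from .lipogenesis_metrics import (
    PalmitateMID,
    anova_one_way,
    anova_two_way,
    atom_percent,
    fit_isa,
    total_de_novo,
)
from .mid_correction import CorrectionSpec, RawMID, build_correction_matrix, correct_mid
from .isotope_chem import parse_formula

__all__ = [
    "RunConfig",
    "PipelineError",
    "read_intensity_csv",
    "read_abundance_csv",
    "read_sample_map_csv",
    "write_corrected_csv",
    "write_metrics_csv",
    "write_diff_csv",
    "correct_table",
    "metrics_table",
    "diff_to_frame",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

_MCOL = re.compile(r"^m(\d+)$")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


def read_intensity_csv(path) -> pd.DataFrame:
    """Read a raw isotopologue intensity table.

    Expects columns ``sample_id, group, m0..mK`` with contiguous m-columns
    from 0. Non-numeric or negative cells and duplicate sample ids are
    rejected with coordinates.
    """
    df = pd.read_csv(path)
    for col in ("sample_id", "group"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    mcols = sorted(
        (int(m.group(1)), c) for c in df.columns if (m := _MCOL.match(c))
    )
    if not mcols:
        raise ValueError(f"{path}: no intensity columns m0..mK found")
    if [k for k, _ in mcols] != list(range(len(mcols))):
        raise ValueError(f"{path}: intensity columns must be contiguous from m0")
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"{path}: duplicate sample ids {dupes}")
    for _, col in mcols:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() | (numeric < 0)
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"{path}: non-numeric or negative intensity at "
                f"row {row} (sample {df['sample_id'].iloc[row]!r}), column {col!r}"
            )
        df[col] = numeric
    return df[["sample_id", "group", *(c for _, c in mcols)]]


def read_abundance_csv(path) -> pd.DataFrame:
    """Read a lipid abundance matrix: first column species names, rest samples."""
    df = pd.read_csv(path, index_col=0)
    if df.empty:
        raise ValueError(f"{path}: empty abundance table")
    return df


def read_sample_map_csv(path) -> dict[str, str]:
    """Read a sample-to-group map with columns ``sample_id, group``."""
    df = pd.read_csv(path)
    for col in ("sample_id", "group"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    if df["sample_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate sample ids in sample map")
    return dict(zip(df["sample_id"].astype(str), df["group"].astype(str)))


def correct_table(raw_df: pd.DataFrame, spec: CorrectionSpec) -> pd.DataFrame:
    """Natural-abundance-correct every sample row of an intensity table."""
    mcols = [c for c in raw_df.columns if _MCOL.match(c)]
    matrix = build_correction_matrix(spec, n_rows=max(len(mcols), spec.default_n_rows()))
    records = []
    for _, row in raw_df.iterrows():
        corrected = correct_mid(RawMID(row[mcols].to_numpy(dtype=float)), matrix)
        records.append(
            {"sample_id": row["sample_id"], "group": row["group"],
             **{f"p{k}": corrected.fractions[k] for k in range(len(corrected))},
             "residual": corrected.residual}
        )
    return pd.DataFrame(records)


def metrics_table(mid_df: pd.DataFrame, n_carbons: int = 16) -> pd.DataFrame:
    """Per-sample lipogenesis metrics from a corrected-MID table."""
    pcols = [f"p{k}" for k in range(n_carbons + 1)]
    records = []
    for _, row in mid_df.iterrows():
        p = row[pcols].to_numpy(dtype=float)
        mid = PalmitateMID(p / p.sum(), n_carbons=n_carbons)
        isa = fit_isa(mid)
        records.append(
            {"sample_id": row["sample_id"], "group": row["group"],
             "atom_percent": atom_percent(mid).atom_percent,
             "total_de_novo": total_de_novo(mid),
             "g": isa.g, "D": isa.D, "isa_sse": isa.sse,
             "d_identifiable": isa.d_identifiable}
        )
    return pd.DataFrame(records)


def tracing_group_stats(mid_df: pd.DataFrame) -> dict:
    """Tracing-figure statistics: one-way ANOVA on m+0, two-way on m+2..m+16."""
    one_way = anova_one_way(
        {g: sub["p0"].to_numpy(dtype=float) for g, sub in mid_df.groupby("group")}
    )
    long_rows = []
    for _, row in mid_df.iterrows():
        for k in range(2, 17, 2):
            long_rows.append(
                {"isotopologue": f"m{k}", "group": row["group"],
                 "value": float(row[f"p{k}"])}
            )
    two_way = anova_two_way(pd.DataFrame(long_rows))
    return {
        "m0_one_way": {"F": one_way.F, "p": one_way.p},
        "labeled_two_way": {
            "isotopologue": {"F": two_way.F_a, "p": two_way.p_a},
            "group": {"F": two_way.F_b, "p": two_way.p_b},
            "interaction": {"F": two_way.F_interaction, "p": two_way.p_interaction},
        },
    }


def diff_to_frame(results: list[DiffResult]) -> pd.DataFrame:
    """Tidy differential results: one row per species."""
    return pd.DataFrame(
        [{"name": r.species.raw_name, "lipid_class": r.species.lipid_class,
          "total_carbons": r.species.total_carbons,
          "double_bonds": r.species.double_bonds,
          "log2_fc": r.log2_fc, "t_stat": r.t_stat,
          "p_raw": r.p_raw, "p_adj": r.p_adj, "significant": r.significant}
         for r in results]
    )


def write_corrected_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def write_metrics_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def write_diff_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


@dataclass
class RunConfig:
    """End-to-end pipeline configuration.

    ``mode`` selects the tracing pipeline (correct -> metrics -> group
    statistics) or the lipidomics pipeline (differential -> chain-length
    summary).
    """

    mode: str  # "tracing" | "lipidomics"
    input_path: Path
    output_dir: Path
    sample_map_path: Path | None = None
    fragment: str = "C18H37O2Si"
    tracer_count: int = 16
    tracer_purity: float = 0.99
    group_a: str | None = None
    group_b: str | None = None
    welch: bool = True
    log_transform: bool = True
    alpha: float = 0.05
    pc_bins: tuple[tuple[int, int], ...] = ((24, 33), (37, 42))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("tracing", "lipidomics"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        self.input_path = Path(self.input_path)
        self.output_dir = Path(self.output_dir)

    def correction_spec(self) -> CorrectionSpec:
        return CorrectionSpec(
            fragment=parse_formula(self.fragment),
            tracer_count=self.tracer_count,
            tracer_purity=self.tracer_purity,
        )


def _write_manifest(config: RunConfig, outputs: list[str]) -> None:
    manifest = {
        "lipotrace_version": __version__,
        "mode": config.mode,
        "seed": config.seed,
        "config": {
            k: (str(v) if isinstance(v, Path) else v)
            for k, v in vars(config).items()
        },
        "outputs": outputs,
    }
    with open(config.output_dir / "run_manifest.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured pipeline and write all declared outputs.

    Returns a report dict naming the written files and headline statistics.
    Any stage failure raises :class:`PipelineError` naming the stage.
    """
    if not config.input_path.exists():
        raise PipelineError(f"input: {config.input_path} does not exist")
    config.output_dir.mkdir(parents=True, exist_ok=True)
    outputs: list[str] = []

    if config.mode == "tracing":
        try:
            raw_df = read_intensity_csv(config.input_path)
        except Exception as exc:
            raise PipelineError(f"read-intensities: {exc}") from exc
        try:
            mid_df = correct_table(raw_df, config.correction_spec())
        except Exception as exc:
            raise PipelineError(f"correct: {exc}") from exc
        try:
            met_df = metrics_table(mid_df, n_carbons=config.tracer_count)
            stats_report = tracing_group_stats(mid_df)
        except Exception as exc:
            raise PipelineError(f"metrics: {exc}") from exc
        mid_path = config.output_dir / "corrected_mid.csv"
        met_path = config.output_dir / "metrics.csv"
        stats_path = config.output_dir / "group_stats.yaml"
        write_corrected_csv(mid_df, mid_path)
        write_metrics_csv(met_df, met_path)
        with open(stats_path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(stats_report, fh)
        outputs += [mid_path.name, met_path.name, stats_path.name]
        report = {"outputs": outputs, "group_stats": stats_report,
                  "n_samples": len(mid_df)}
    else:
        if config.sample_map_path is None or config.group_a is None or config.group_b is None:
            raise PipelineError(
                "config: lipidomics mode needs sample_map_path, group_a and group_b"
            )
        try:
            values = read_abundance_csv(config.input_path)
            groups = read_sample_map_csv(config.sample_map_path)
        except Exception as exc:
            raise PipelineError(f"read-abundances: {exc}") from exc
        labels = set(groups.values())
        for g in (config.group_a, config.group_b):
            if g not in labels:
                raise PipelineError(f"config: group {g!r} absent from sample map")
        try:
            table = AbundanceTable(values=values, groups=groups)
            results = differential(
                table, config.group_a, config.group_b,
                alpha=config.alpha, welch=config.welch,
                log_transform=config.log_transform,
            )
            summary = chain_length_summary(results, "PC", bins=config.pc_bins)
        except Exception as exc:
            raise PipelineError(f"differential: {exc}") from exc
        diff_df = diff_to_frame(results)
        diff_path = config.output_dir / "differential.csv"
        write_diff_csv(diff_df, diff_path)
        summary_df = pd.DataFrame([vars(b) for b in summary])
        summary_path = config.output_dir / "chain_length_summary.csv"
        summary_df.to_csv(summary_path, index=False)
        outputs += [diff_path.name, summary_path.name]
        report = {"outputs": outputs,
                  "n_significant": int(diff_df["significant"].sum()),
                  "n_species": len(diff_df)}

    _write_manifest(config, outputs)
    return report
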