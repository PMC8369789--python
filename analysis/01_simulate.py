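#!/usr/bin/env python
"""Generate the study's synthetic inputs: tracing and lipidomics datasets.

Simulates (i) palmitate GC/MS isotopologue intensities for four treatment
groups (vehicle / dox / TOFA 3 / TOFA 10, de novo synthesis progressively
suppressed) and (ii) a lipid abundance matrix with chain-length-dependent
group effects. Ground-truth sidecars are written next to each dataset.
"""

from pathlib import Path

import pandas as pd

from lipotrace.synthetic_data import (
    LipidSimConfig,
    TracingSimConfig,
    simulate_lipid_table,
    simulate_palmitate_raw,
)

OUT = Path(__file__).resolve().parent.parent / "results" / "data"
SEED = 20260923


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    tracing = TracingSimConfig(seed=SEED)
    raw, truth = simulate_palmitate_raw(tracing)
    raw.to_csv(OUT / "tracing_raw.csv", index=False)
    truth.to_csv(OUT / "tracing_truth.csv", index=False)
    print(f"tracing: {len(raw)} samples over groups "
          f"{sorted(raw['group'].unique())} -> {OUT / 'tracing_raw.csv'}")

    lipids = LipidSimConfig(seed=SEED)
    values, groups, lipid_truth = simulate_lipid_table(lipids)
    values.to_csv(OUT / "lipid_abundances.csv")
    pd.DataFrame({"sample_id": list(groups), "group": list(groups.values())}
                 ).to_csv(OUT / "lipid_sample_map.csv", index=False)
    lipid_truth.to_csv(OUT / "lipid_truth.csv", index=False)
    print(f"lipidomics: {values.shape[0]} species x {values.shape[1]} samples "
          f"-> {OUT / 'lipid_abundances.csv'}")


if __name__ == "__main__":
    main()
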