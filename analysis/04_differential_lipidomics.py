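#!/usr/bin/env python
"""Differential lipidomics: each treated group versus vehicle.

Welch t-tests on log2 abundances with Benjamini-Hochberg control per
comparison, followed by PC chain-length bin summaries. Writes one tidy
results table per comparison and prints the significant-species counts
and the direction of the long- versus short-chain PC bins.
"""

from pathlib import Path

import pandas as pd

from lipotrace.io import diff_to_frame, read_abundance_csv, read_sample_map_csv
from lipotrace.lipidomics_diff import AbundanceTable, chain_length_summary, differential

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    values = read_abundance_csv(RESULTS / "data" / "lipid_abundances.csv")
    groups = read_sample_map_csv(RESULTS / "data" / "lipid_sample_map.csv")
    table = AbundanceTable(values=values, groups=groups)

    for treated in ("dox", "tofa3", "tofa10"):
        results = differential(table, "vehicle", treated)
        frame = diff_to_frame(results)
        out = RESULTS / f"differential_vehicle_vs_{treated}.csv"
        frame.to_csv(out, index=False)
        n_sig = int(frame["significant"].sum())
        print(f"vehicle vs {treated}: {n_sig}/{len(frame)} species at adj p < 0.05")
        for b in chain_length_summary(results, "PC"):
            print(f"  PC C{b.carbon_min}-C{b.carbon_max}: {b.n_significant}/"
                  f"{b.n_species} significant, median log2FC "
                  f"{b.median_log2_fc:+.2f} ({b.consensus})")

    summaries = []
    for treated in ("dox", "tofa3", "tofa10"):
        for b in chain_length_summary(
            differential(table, "vehicle", treated), "PC"
        ):
            summaries.append({"comparison": f"vehicle_vs_{treated}", **vars(b)})
    pd.DataFrame(summaries).to_csv(RESULTS / "pc_chain_length_summary.csv",
                                   index=False)


if __name__ == "__main__":
    main()
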