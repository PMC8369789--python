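# lipotrace

Tools for quantifying **de novo lipogenesis** from [U-¹³C]glucose tracing of
palmitate, and for **differential untargeted lipidomics** — the two
measurement workflows used to ask whether an oncogene (or a direct
acetyl-CoA-carboxylase inhibitor such as TOFA) shuts down fatty-acid
synthesis in lymphoid tumor cells.

It is written for metabolism researchers who have post-integration tables in
hand — GC/MS isotopologue intensities for a palmitate fragment, or an LC/MS
lipid species × sample abundance matrix — and want a tested, scriptable path
from those tables to corrected mass isotopomer distributions (MIDs),
lipogenesis metrics, and FDR-controlled differential lipid calls.

## What it computes

**Natural-abundance correction.** A measured isotopologue envelope mixes
tracer-derived ¹³C with naturally occurring heavy isotopes throughout the
derivatized fragment (default `C18H37O2Si`, a TBDMS-palmitate-consistent
ion). The measured vector is modeled as `raw = M·p`, where column *j* of the
correction matrix **M** is the theoretical envelope of a molecule with
exactly *j* tracer carbons (natural-abundance convolution of all unlabeled
atoms × a binomial tracer-purity pattern). The corrected MID
`p = (p₀, …, p₁₆)` is recovered by non-negative least squares and
normalized to sum 1.

**Atom percent of glucose-derived palmitate.** Palmitate (16 carbons) is
built from 8 acetyl units, so glucose label arrives in m+2 steps; with even
k = 2, 4, …, 16:

```
atom% = Σₖ pₖ·k / ((Σₖ pₖ + p₀) · 16)
```

**ISA mixture model.** The palmitate pool is modeled as a fraction *g*
newly synthesized during labeling, each new molecule drawing its 8 acetyl
units from a pool with labeled fraction *D*:

```
q_j = (1−g)·𝟙[j=0] + g·C(8,j)·D^j·(1−D)^(8−j),   p_{2j} = q_j
```

Least-squares fitting of (g, D) gives the total de novo synthesis fraction;
on noiseless data the two summaries agree analytically (atom% = g·D).

**Group statistics.** One-way ANOVA on the m+0 fraction and balanced
two-way ANOVA (isotopologue × treatment group) on m+2…m+16.

**Differential lipidomics.** Lipid shorthand names (`TG(52:2)`,
`TG(C52:2)`, `PC 37:4`) are parsed into class / total carbons / double
bonds; each treated group is compared to vehicle by Welch t-tests on log2
abundances, Benjamini-Hochberg corrected, significant at adjusted p < 0.05,
then summarized in carbon-number bins per class (defaults: PC C24–C33 and
C37–C42).

A seeded synthetic-data module generates ground-truthed inputs for both
workflows, so the whole pipeline is testable without instrument data.

## Worked example

Run the numbered drivers from the repository root:

```bash
python analysis/01_simulate.py
python analysis/02_correct_mids.py
python analysis/03_lipogenesis_metrics.py
python analysis/04_differential_lipidomics.py
```

The third step prints, for the default simulated experiment (vehicle / dox /
TOFA 3 / TOFA 10, six replicates, 2 % measurement noise):

```
group means (atom percent, labeled fraction, ISA g and D):
         atom_percent  total_de_novo       g       D
group
dox            0.0872         0.2401  0.2506  0.3521
tofa10         0.0124         0.0443  0.0514  0.2544
tofa3          0.0449         0.1405  0.1511  0.3031
vehicle        0.2482         0.5462  0.5523  0.4506

m+0 one-way ANOVA: F = 5227.32, p = 4.16e-29
m+2..m+16 two-way ANOVA, group effect: F = 25944.80, p = 9.33e-215
```

Reading this: in the vehicle group about 25 % of all palmitate carbon came
from glucose during the 24 h label, and the ISA fit attributes that to ~55 %
of the pool being newly synthesized (g) with ~45 % acetyl-pool enrichment
(D); suppressing lipogenesis (dox, TOFA) drives both down, and the fitted g
matches the simulation's ground truth (0.55 / 0.25 / 0.15 / 0.05) to two
decimals. The fourth step reports the chain-length pattern, e.g. for
vehicle vs dox: long-chain PCs (C37–C42) all significantly decreased
(median log2FC −1.47) while short-chain PCs (C24–C33) increased (+0.78).

The same operations are available as a CLI (`lipotrace simulate`, `correct`,
`atom-percent`, `isa-fit`, `lipid-diff`, `report`) — see `lipotrace --help`.

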