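# Methods

## Isotope model

All isotope arithmetic is at unit (nominal-mass) resolution: a molecule's
envelope is the discrete convolution of one single-atom distribution per
atom, computed by binary exponentiation per element. Fine isotope structure
is irrelevant at GC/MS unit resolution and is not modeled. The packaged
isotope table (`src/lipotrace/data/isotopes.yaml`) holds standard
terrestrial abundances (¹³C 0.0107, ²H 0.000115, ¹⁵N 0.00364, ¹⁷O/¹⁸O
0.00038/0.00205, ²⁹Si/³⁰Si 0.04685/0.03092, ³³S/³⁴S/³⁶S
0.0075/0.0425/0.0001) and can be overridden by a YAML file of the same
shape, since tracing studies occasionally assume slightly different values.

## Correction matrix and inversion

For a fragment with formula F, tracer element C, and `tracer_count` = 16
labelable backbone positions, column *j* of the correction matrix is the
envelope of a molecule with exactly *j* tracer-derived carbons:

* the natural envelope of every non-tracer atom, plus — when
  `correct_tracer_natural` is on (default) — the 16 − j unlabeled backbone
  positions;
* convolved with Binomial(j, purity), each labeled position being ¹³C with
  probability `tracer_purity` (default 0.99) and ¹²C otherwise.

Defaults the data cannot pin down are explicit configuration: the monitored
fragment ion is set to `C18H37O2Si` (consistent with MTBSTFA/TBDMS
derivatization of palmitate, [M−57]-type composition) and purity to 0.99,
both overridable per run. Matrices keep `tracer_count + 4 + 1` rows by
default; that retains > 99.99 % of column mass for fragments of this size.

Inversion is non-negative least squares (`scipy.optimize.nnls`) rather than
a matrix inverse: with noisy, near-zero high-mass channels an unconstrained
solve routinely produces negative fractions. The fit residual is reported
before the final normalization to Σp = 1. Raw vectors longer than the
matrix are truncated with a warning, shorter ones zero-padded; an all-zero
vector and a rank-deficient matrix are hard errors. Correction is exactly
scale-invariant, so intensity units never matter.

## Lipogenesis metrics

`atom_percent` implements the even-k formula
Σₖ pₖ·k / ((Σₖ pₖ + p₀)·16), k ∈ {2,…,16}. Odd-channel mass — which under a
[U-¹³C]glucose tracer can only be measurement noise — is excluded from both
numerator and denominator rather than folded in; that is the formula as
stated, and it makes the metric invariant to small odd-channel
contamination (renormalizing over even channels only).

The "total de novo" quantity is deliberately reported two ways, since a
single pool-level number can be defined at the carbon or the molecule
level: (i) the atom percent above, and (ii) `total_de_novo` = labeled share
of the even-channel pool (1 − p₀ restricted to even-k support). On the ISA
model the first equals g·D and the second g·(1 − (1−D)⁸); both are emitted
so the reader can pick the definition that matches their comparison.

`fit_isa` fits q_j = (1−g)·𝟙[j=0] + g·Binomial(8, D) to (p₀, p₂, …, p₁₆) by
sum-of-squares over a 101×101 grid on [0,1]², then Nelder–Mead polish from
the grid optimum (ties: first minimum in row-major order; the polish is
discarded if it ever does worse than the grid). The fit is deterministic.
When ĝ ≤ 1e−6 the acetyl enrichment D drops out of the model; the result is
flagged `d_identifiable = False` and D reported as 0.

Identity used as a test oracle throughout: a noiseless ISA-generated MID
satisfies atom% = g·D exactly (each de novo molecule carries 16·D labeled
carbons in expectation; pre-existing molecules carry none).

## ANOVA

One-way and two-way fixed-effects ANOVA are computed from the classical
sums-of-squares decompositions with exact F CDF p-values. They are written
out directly (rather than through a model-fitting API) because the required
edge semantics are pinned: groups of < 2 observations are errors, zero
within-group variance with unequal means reports F = ∞, p = 0 with a flag,
and the two-way routine accepts only balanced complete designs — the
tracing design (fixed isotopologue set × treatment arms, equal replicates)
is balanced, and Type I/II/III distinctions for unbalanced data are out of
scope. Both routines are verified against independent oracles
(`scipy.stats.f_oneway`; `statsmodels` `anova_lm` and a direct
sums-of-squares enumeration) to 1e−9 in F.

## Differential lipidomics

The two-group procedure is per-species t-test + fold change, BH correction
across species, significance at adjusted p < 0.05, run separately for each
treated group against vehicle (no omnibus model). Two choices the procedure
itself leaves open are made explicit and switchable:

* **Welch** (unequal-variance) t-test by default — the safer default for
  relative MS abundances with group-dependent spread; Student's form is a
  flag.
* Abundances are **log2-transformed** before testing, with offset = half
  the smallest nonzero value in the table guarding zeros; relative MS
  abundances are right-skewed and the t-test is better calibrated on the
  log scale. Fold changes are computed on the raw scale with the same
  offset guard, and all-zero denominator groups are flagged.

BH adjustment is the explicit step-up construction (sort, scale by m/rank,
running minimum from the top, cap at 1), matching the reference loop bit
for bit; `statsmodels.multipletests` serves as an independent cross-check
in the tests (it agrees to 1 ulp, not exactly, due to operation order).

Chain-length summaries bin a class's species by inclusive total-carbon
ranges (defaults PC C24–C33 and C37–C42, configurable), reporting count,
significant count, median log2 fold change, and a sign consensus over the
significant species ("increased" / "decreased" / "mixed" / "none").

## Synthetic data

The tracing simulator draws, per group, a true MID from the ISA model
(mass only on even isotopologues), pushes it through the correction matrix
— the exact forward model of the correction — and applies per-channel
multiplicative lognormal noise with configurable CV (unit mean;
scale-proportional noise is the standard MS intensity model; an additive
floor is not simulated). Default conditions: four groups (vehicle g = 0.55,
D = 0.45; dox 0.25/0.35; TOFA-3 0.15/0.30; TOFA-10 0.05/0.25 — vehicle
highest, inhibition progressively stronger), six replicates, CV 2 %. These
mirror the qualitative group ordering of a conditional-oncogene experiment
and are configuration, not measured values.

The lipid simulator draws lognormal species baselines, then applies
per-(class, carbon-range) log2 effects with per-species jitter (defaults:
PC C37–C42 −1.5, PC C24–C33 +0.8, DG long-chain −1.2, TG +0.6 in every
treated group), 15 % within-group CV, six samples per group. Species names
are emitted in shorthand and unique per class.

Both simulators consume a single seeded generator in documented order
(groups sorted, replicates/species in index order), so equal seeds give
byte-identical files. What the simulators do **not** emulate: chromatographic
peak integration errors, co-eluting isobars, adducts, missing values, or
heavy-tailed outliers — passing tests demonstrate correctness of the
computations under the stated noise model, not robustness to every artifact
of real spectra.

## Problem sizes and numerics

Test and acceptance workloads use desk-scale sizes chosen to exercise the
statistics without waste: 500 random MIDs for round-trips, 100 simulated
experiments × 20 replicates for ISA recovery, 200 random balanced designs
per ANOVA oracle, 1000 random vectors for BH, 500 true-null species for the
type-I check. Key tolerances: noiseless round-trip max error < 1e−8
(observed ~1e−16), enumeration agreement 1e−10, atom%/g·D identity 1e−9,
ANOVA oracle agreement 1e−9, ISA recovery MAE < 0.02 (observed ~7e−4).

## Known limitations

* Single tracer element only; no multi-tracer or high-resolution
  (fine-structure) correction.
* The ISA model assumes a single acetyl pool at steady enrichment and no
  chain elongation of pre-existing species; g and D are pool-level
  summaries, not fluxes.
* Balanced designs only for the two-way ANOVA.
* The lipid name parser covers the class + C:D shorthand dialects, not
  full structure-resolved nomenclature (e.g. `PC(18:0/20:4)` sn-resolved
  forms are out of scope).
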