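# Methods

This note documents the models implemented in effluxkit, the parameter
choices that matter, what the synthetic-data generators do and do not
emulate, and the numerical decisions a maintainer would want to know.

## Dose–response (4PL) fitting

T/C (treated-over-control) viability is modelled as

    f(c) = bottom + (top − bottom) / (1 + (c / IC50)^h)

and fitted by unweighted least squares in log10(concentration), the
standard parameterisation for sigmoid dose–response. The reported IC50
is the *relative* IC50 — the inflection point halfway between the
fitted plateaus — not the absolute 50%-of-control concentration.
Replicate wells are averaged on the T/C scale before fitting, matching
duplicate-per-condition plate designs.

Numerical choices:

* **Initialisation**: top/bottom from the observed extremes, IC50 from
  linear interpolation of the midpoint crossing, multi-start over Hill
  slopes {0.5, 1, 2, 4}. Sigmoid fits started far from the true
  steepness find local minima; four starts were always enough in
  simulation.
* **Bounds**: bottom ∈ [−0.1, 0.5]·hi, top ∈ [0.5, 1.2]·hi (hi = max
  observed T/C), IC50 ∈ [Cmin/100, Cmax·100], hill ∈ [0.1, 10]. On
  partial curves unbounded plateaus run away; these bounds keep the
  parameters interpretable without binding on complete curves.
* **Censoring**: if the fitted midpoint lies outside the tested range,
  or the observed response span is below 0.2 (no resolvable curve),
  the result is censored and the boundary concentration reported with
  a comparator (`> 30.0000`), the convention used in results tables for
  inactive single agents. A censored IC50 refuses to enter a
  resistance ratio; callers must report a bound instead.
* Fits are invariant to rescaling the raw signal, since T/C
  normalisation cancels units.

Recovery under the study conditions (10 half-log concentrations,
duplicates, 10% CV multiplicative noise): IC50 within ±25% of truth in
≈ 94% of 200 seeded runs; noiseless data recover all four parameters
within 1%.

## Bliss-independence synergy

With T/C as fraction unaffected, the Bliss expectation of a
combination is the product of the measured single-agent effects from
the same plate, `E12 = E1·E2`, and the Bliss index is
`BI = E12 − T/C(combo)`. E1/E2 come from the plate's single-agent
row/column rather than fitted curves, so plate-level biases cancel.
T/C values above 1 (apparent stimulation) are used as-is in the
algebra and clipped to [0, 1] only in heat-map exports.

Per-cell flags use `BI ≥ 0.15` (synergy) and `BI ≤ −0.15`
(antagonism); ties count as flagged. The assay-level call counts
flagged cells against `k = ceil(0.12 · n_total)`: more than k ⇒
synergy/antagonism, exactly k ⇒ the "slight" call, and additive when
neutral cells exceed `n_total − k − 1`. On a 25-cell checkerboard this
is the familiar >3/25, =3/25, >22/25 counting rule; the fractional
form lets 8×2 layouts (16 cells, k = 2) be classified by the same
logic. If synergy and antagonism counts both exceed k the call is
`mixed` rather than guessing a precedence; if no rule fires (possible
only in rare split configurations) the call falls back to additive.
Combination cells that lost one replicate use the surviving one; cells
with no data are excluded from `n_total` and logged.

## Caco-2 bidirectional transport

Apparent permeability from single-timepoint sampling:
`Papp = (dQ/dT)/(A·C0)` with dQ the receiver-side amount (pmol), dT
the incubation (s), A the insert area (0.7 cm² by default, overridable
per record) and C0 the donor concentration (pmol/cm³). Efflux ratio
`ER = Papp(B-A)/Papp(A-B)`; `ER > 2` together with
`Papp(B-A) > Papp(A-B)` calls an efflux substrate, and an inhibitor
arm with `ER < 2` calls inhibition. Recovery
`R = 100·(Q_apical + Q_basolateral + Q_cells)/Q0` audits mass balance.

Because ER is a ratio of noisy means, two aggregations are reported:
the ratio of mean Papps (display default) and the mean of
per-replicate ERs (detail output); at ≤ 10% replicate CV they agree
within 5%. Papp uncertainty is the SEM over replicates; ER uncertainty
uses first-order error propagation. Wells failing monolayer QC
(Lucifer-Yellow flag in the input) are excluded with a logged reason —
the QC threshold itself is upstream instrument territory, so the
toolkit only honours the pass/fail flag.

## Expression screen

**QC.** Four per-sample outlier statistics on log-CPM
(`log2(1e6·(count+0.5)/(lib+1))`): summed Euclidean distance to the
other samples; Hoeffding's D between the sample and the per-gene
median pseudo-reference (a common consensus-profile choice); mean
Pearson correlation with the other samples (constant vectors are
excluded from the mean, logged); and the two-sample KS statistic
against the pooled distribution of the remaining samples. A sample is
flagged when a statistic deviates > 3 robust z-units (median ± 3
scaled-MAD) in its suspicious direction **and** the deviation is
material: ≥ 0.1 absolute for the three bounded statistics, ≥ 25%
relative for the distance sum. The floor exists because with ~12
near-identical samples the MAD is minuscule and a bare z-rule flags
trivial fluctuations (~30% of clean runs in simulation); with the
floor, clean runs flag nothing (0/100 seeds) while a
permuted-across-genes sample is always caught by the correlation and
Hoeffding statistics.

**Hoeffding's D** is computed from joint ranks (mid-ranks for ties)
with the classical `30·[(n−2)(n−3)D1 + D2 − 2(n−2)D3]/(n…(n−4))`
normalisation: D = 1 for monotone dependence without ties, ≈ 0 under
independence. The test suite checks it exactly against a brute-force
degree-5 U-statistic oracle on all permutations of n = 5–7.

**Differential expression** is a deliberate stand-in for count-model
pipelines (TMM normalisation and voom precision weights are out of
scope): per-gene tests on log-CPM with BH FDR control and the DEG
conjunction `q < 0.05 and |fold| ≥ 2` (symmetric up/down). The default
statistic is an empirical-Bayes **moderated t**: pooled per-gene
variances are shrunk toward a lowess trend of log-variance on mean
abundance, with the prior degrees of freedom fitted by trigamma
moments. Moderation is not optional seasoning here — with triplicates
the per-gene test has ~4 degrees of freedom, and no single gene can
survive FDR control over thousands of tests without borrowing
variance information (the plain Welch t, available as
`method="welch"`, bottoms out near p ≈ 1e-4). A development
cross-check against the Bioconductor moderated-t implementation on the
same log-CPM matrix gave Spearman 0.998 agreement on p-values and
log-fold-changes within 0.03. Under the study conditions, a true
8-fold gene (3 vs 3, NB dispersion 0.05) is detected in ≈ 99% of
seeded runs, null data yield ~0% DEGs, and a 3000-fold
transporter-like gene is the top-fold DEG in every run. Biological DEG
*lists* from real experiments are not reproducible with this stand-in,
and no claim about them is made.

## Synthetic-data generators

All generators attach a `SyntheticTruth` record and draw from one
seeded generator per dataset; regeneration from (truth, seed) is
byte-identical. Noise is multiplicative log-normal with unit mean
(plate-reader error scales with signal); default CV 10% for viability
wells, 5% for checkerboards and transwell replicates.

**Viability/checkerboard mechanism.** Cell kill follows the parental
4PL of the *effective* concentration
`C_eff = c_drug / (1 + E·occ)`, `occ = 1 − c_inh/(c_inh + Ki)`, times
the inhibitor's own 4PL survival. E = 0 produces exact Bliss-null
behaviour; E ≫ 1 produces resistance that collapses back to parental
potency at saturating inhibitor. Defaults (chosen once from the
study's endpoints): parental docetaxel IC50 1 nM, hill 1.5, top 1,
bottom 0; E = 21.3 (a 22.3-fold resistant line); inhibitor Ki = 2 µM
(10 µM ritonavir nearly fully reverses resistance) and intrinsic
ritonavir IC50 25 µM (prostate-line range 16–29 µM). The generator
targets observed endpoint patterns, not transporter kinetics — Km/Vmax
modelling is out of scope.

**Transwell.** `Papp(A-B) = p/(1 + M·occ)`, `Papp(B-A) = p·(1 + M·occ)`,
so the noiseless ER is `(1 + M·occ)²`. Defaults p = 3.7×10⁻⁶ cm/s and
M = 4.7 give ER ≈ 32.5 for the substrate alone; per-condition Ki
overrides encode inhibitor potency (valspodar 0.05 µM, ritonavir
1.2 µM, back-solved once from the ER-collapse endpoints). Compartment
quantities are mass-conserving, so noiseless recovery is exactly 100%.

**Counts.** Negative-binomial counts (dispersion 0.05) around a
log-normal baseline (log-mean 3, log-sd 1.5) shared between cell lines
up to a per-line log-normal wobble (sd 0.2) — fully independent
baselines would give unrealistic near-zero cross-line correlations.
Differentially expressed genes are modelled silent-vs-expressed
(expressed mean ~200 counts; the transporter-like gene 2000): a
3000-fold gene with a large baseline would dominate the library and
its replicate noise would distort every other gene's CPM, which both
misrepresents the biology (the transporter is undetectable in parental
cells) and manufactures spurious QC outliers. Default sizes are 2,000
genes and triplicates per group — large enough for stable FDR
behaviour, small enough that the full suite runs in well under a
minute per stage. The generators do not emulate read-level sequencing,
batch effects, GC/length bias, or colony-image data, so passing tests
say nothing about those failure modes in real data.

## Pipeline and configuration

`RunConfig` (pydantic-validated, YAML-serialisable) carries the
thresholds: BI cutoff 0.15 with flag fraction 0.12, ER cutoff 2,
insert area 0.7 cm², DEG fold 2 / FDR 0.05, outlier z-cutoff 3. Every
output directory receives the serialised config, and the summary
embeds its SHA-256 hash and the seed, so runs with equal hashes are
byte-identical. The pipeline preserves partial results and reports
schema errors with context; the CLI exits non-zero on any failure.

## Known limitations

* The DEG stage is a moderated-t stand-in, not a count-model fit;
  absolute p-values differ from dedicated RNA-seq pipelines even
  though rankings agree closely.
* The Bliss machinery makes no statistical inference on BI (no
  confidence intervals); calls are threshold counts by design.
* Loewe additivity, HSA, ZIP and response-surface synergy models are
  out of scope, as are absolute IC50s, transporter kinetics and
  LC-MS/MS bioanalysis.
* `classify_assay` can in principle reach a configuration where no
  counting rule fires (e.g. 2 synergy + 2 antagonism + 21 neutral of
  25); it falls back to additive, the weakest claim.
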