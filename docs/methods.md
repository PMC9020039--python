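# Methods

## The analysis model

The pipeline targets a case–control methylation-array design: a small
series of affected individuals (default n₁ = 17) against a large
population control cohort (default n₂ = 350), with per-probe methylation
summarised as β ∈ [0, 1]. Probes are tested marginally — no covariate
adjustment, cell-type deconvolution, or inflation-factor correction —
which matches the intended use: epimutations at promoter CpG islands are
large, localised effects (Δβ ≈ 0.3–0.5) for which a plain two-sample
*t* test is decisive, and the island-level concordance requirement does
the specificity work that genome-wide covariate modelling would
otherwise carry.

Per probe, the EWAS reports the group mean β values, Δβ = mean(cases) −
mean(controls), the *t* statistic, the two-sided nominal *P*, the
Bonferroni-corrected *P*, −log10 *P*, and a smoothed −log10 *P*. Missing
β values are excluded pairwise; a probe is tested only if each group
retains at least two non-missing values, otherwise it is kept in the
output flagged `tested=False` and excluded from the Bonferroni factor.
The Bonferroni factor is the number of probes actually tested in the
current run, not a fixed array size: the correction is then exact for
the family of tests actually performed.

### t-test variant

The default is Welch's unequal-variance test: cases are diseased-tissue
samples and controls a separate cohort, so equal variances should not be
assumed. The classical pooled-variance form is available
(`variant="student"`, CLI `--t-test student`). On a *homoscedastic* null
(both groups drawn from one distribution) the pooled test is the exactly
calibrated one; Welch carries a small finite-sample anti-conservatism
from the Welch–Satterthwaite approximation at n₁ = 17 (measured ≈ 0.0504
at nominal 0.05 on symmetric data), and a substantially larger one on
strongly skewed bounded data (≈ 0.07 on a Beta null with mean 0.03, see
*Calibration*, below). Neither variant is robust to heavy skew at small
n₁; this is a property of *t* statistics, not of the implementation.

### Smoothed P-values

Smoothing operates on the −log10 scale: for probe *i*, the smoothed
value is the arithmetic mean of −log10 *P* over probes *i − r .. i + r*
on the same chromosome, with the window truncated at chromosome ends
(edge windows average fewer probes) and radius r = 3 by default (a
7-probe window; radius 0 is the identity). Untested probes neither
receive nor contribute values. The smoothed track is reported alongside —
never replacing — the nominal and Bonferroni *P*; its purpose is
visual: a single-probe fluke dilutes by 1/(2r+1), while a genuine
island signature keeps its height across neighbours. The moving-mean
form is this package's documented choice; the statistic and scale are
deliberately simple and the radius is exposed as a parameter.

### PCA QC

Sample-level PCA is computed on probe-centered β values after imputing
missing cells with the probe mean, via an exact SVD (top k = 10
components, labelled EV1..EV10, eigenvalues non-increasing). A
chromosome-restricted run (e.g. chromosome 1 only) is supported for
checking that a locus-scale signal, not genome-wide structure, drives a
component. On simulated data with sex-differential probes, one of the
top components separates the sexes — the standard array QC signature.

## Three-state classification and island calls

β < 0.2 → fully unmethylated; 0.2 ≤ β ≤ 0.6 → hemimethylated; β > 0.6 →
fully methylated. The boundary values are taken *closed into the
hemimethylated band*: the thresholds are conventional round numbers and
a probe sitting exactly on one is intermediate evidence, so the
intermediate class is the conservative home for it. Classification
operates on group-mean β (the level the epigram plots show); a
per-sample majority mode would be a straightforward extension but is not
currently wired into the caller.

An island call considers all probes mapped to the island, *flank probes
included* (default flank window 250 bp, symmetric/strand-agnostic — the
data motivating this package label probes downstream in genome
coordinates as "upstream 5′ end" of a minus-strand gene, and no distance
is part of the published record, so the window is a parameter rather
than a biological constant). A probe is *concordant* when controls are
fully unmethylated and cases hemimethylated **or** fully methylated
(a bi-allelic epimutation pushes case β above 0.6). The verdict is
`epimutated` iff:

- n probes considered ≥ `min_probes` (default 3; fewer →
  `insufficient_probes`),
- concordant fraction ≥ `min_fraction_concordant` (default 1.0 — the
  motivating signature is concordant at every probe; relax for noisier
  data),
- at least `require_significant` probes (default 1) have Bonferroni
  *P* < α (default 0.05). Whether the original analyses required
  per-probe significance at every probe is not documented; one
  significant probe plus full concordance is the package's default, and
  the count is a parameter.

Genome scans emit one call per island with ≥ 1 mapped probe, sorted by
the island's minimum nominal *P*; the result is invariant to the input
order of the island table.

## Coordinates and I/O

Internal coordinates are 1-based inclusive (the convention of array
manifests and printed tables); island files are BED (0-based half-open)
and converted on read/write, preserving interval length exactly. All
tabular artifacts are TSV (CSV via a flag) with a `#` header comment
carrying the tool version and genome-build label; β matrices parse empty
cells as missing, never 0, and reject values outside [0, 1] naming the
offending probe and sample.

## The synthetic-data generator

β values are drawn from a Beta(μκ, (1−μ)κ) family — mean μ and
concentration κ — which has the right [0, 1] support without clipping;
μ ∈ {0, 1} is rejected as having no valid parameterisation. Defaults:

| parameter | default | meaning |
|---|---|---|
| n_cases / n_controls | 17 / 350 | the emulated study design |
| case_effect | 0.45 | mean case β at epimutated probes (hemimethylated) |
| control_level | 0.03 | mean control β at those probes (unmethylated) |
| noise_concentration κ | 50 | SD ≈ 0.07 at μ = 0.45, ≈ 0.024 at μ = 0.03 |
| background | mixture | open-sea probes: 60% unmethylated (μ 0.05), 30% methylated (μ 0.85), 10% hemimethylated (μ 0.45) |
| sex_effect_probes | 0 | probes with sex-specific μ (F 0.70 / M 0.20) |

Hemimethylation in cases is a unimodal distribution around 0.45, not a
per-allele mixture: the array reports one β per probe. Islands are laid
out with probes every 50 bp, flank probes every 40 bp past the island
edge, and open-sea probes every 10 kb; positions strictly increase
within a chromosome, and a multi-chromosome layout (for per-chromosome
PCA and smoothing-boundary tests) is available. Everything is
deterministic under a fixed seed.

What the generator does **not** emulate: probe-type (Infinium I/II)
chemistry bias, SWAN-style normalisation artifacts, batch effects,
platform harmonisation between 450k and EPIC, spatial correlation of
background probes, or cell-composition heterogeneity. Passing tests on
synthetic data therefore demonstrate the statistical machinery under the
declared noise model, not robustness to array artifacts — real inputs
are assumed to arrive already normalised.

The alignment-record generator produces, per query, either a candidate
satisfying all five assignment criteria (optionally with shorter decoys)
or a single-criterion violator, cycling criteria i–v, together with a
truth table; criterion ii's violator is a query whose
highest-alignment-length hit is spurious while a clean shorter hit
exists, i.e. a failure attributable to the selection rule itself.

## Calibration and power (repeated-simulation studies)

- **Type-I**: under a zero-effect simulation the per-probe false-positive
  rate at α = 0.05 is checked against 0.05 within 3 Monte-Carlo standard
  errors of the estimated mean (SD of per-rep fractions / √reps). The
  null study uses the pooled-variance variant and the hemimethylated
  (symmetric) background — the homoscedastic, near-normal condition under
  which a *t* test is calibrated. This is deliberate: on the skewed
  unmethylated background the Welch test's true type-I error is ≈ 0.07
  at n₁ = 17 (pooled: ≈ 0.048), so calibration on strongly asymmetric
  nulls should not be expected of any *t*-based EWAS at this sample
  size; the island-level concordance filter is the guard against those
  probe-level false positives. The island family-wise call rate under
  the null is also checked (≤ α; in practice ≈ 0).
- **Power**: with the epimutated-island effect at Δβ = 0.4 over a 0.03
  control level and default noise, the planted island is recovered in
  ≥ 95% of repetitions (measured: 100%).

Problem sizes used: 200 reps × 10,000 probes (tests) or 100 reps
(acceptance script) for the null; 200 reps × 1,000 probes for power —
sizes chosen so each study pins its rate to ±0.005 or better while the
whole suite runs in a couple of minutes.

## Transcript assignment, TPM, and ΔΔCq

Criterion order is biotype filter first, then best-candidate selection
by alignment length ("highest among candidates" reads most naturally as
among biotype-eligible candidates); the alternative order is available
via `biotype_first=False`. Ties on alignment length break by higher bit
score, then lower e-value, then lexicographic subject id — an invented
but documented chain that makes assignment invariant to candidate order.
"Maximum number of gaps = 1" is interpreted as **gap openings ≤ 1**, the
semantics of the standard 12-column tabular `gapopen` field; the bound
is configurable. Criterion iii is strict: subject length must equal the
alignment length *and* exceed 300 nt, so a 300-nt perfect hit fails.

Gene TPM is the sum of assigned transcript TPM, with unassigned mass
reported under `unassigned` so totals are conserved. Relative expression
uses ΔCq = Cq(target) − mean(Cq over reference genes) — the arithmetic
mean of reference Cq corresponds to the geometric mean of reference
quantities — and fold change = E^−(ΔCq − ΔCq_calibrator) with
amplification efficiency E = 2.0 by default (per-gene efficiencies can
be passed); the calibrator group has fold change 1 by construction, one
cycle less is a two-fold increase, and a constant per-sample Cq offset
(plate effect) cancels.

## Numerical choices and degenerate inputs

- *P*-values are reported in (0, 1]: a zero-variance probe with equal
  group means gets (t = 0, P = 1); with unequal means, P is floored at
  the smallest positive double rather than 0.
- Identical nominal *P* ties in sorted outputs are broken by
  (chromosome, position).
- Probe→island mapping ties (equidistant islands) resolve to the
  lexicographically first island id; the mapping partitions probes —
  exactly one relation each.
- Unsorted input to the smoother (position inversions, or a chromosome
  split into non-adjacent blocks) is an error, not a silent bridge.
- The run manifest hashes all analysis and simulation parameters but not
  the output path, so identical configurations produce byte-identical
  run directories wherever they are written.

## Known limitations

Welch's skew-driven anti-conservatism at n₁ = 17 (above); no FDR
alternative to Bonferroni (by design — the target effect sizes make
Bonferroni affordable); no covariate or batch adjustment; classification
thresholds 0.2/0.6 are fixed conventions, exposed as parameters but with
no data-driven estimation; the caller assumes hypermethylation-type
epimutations (control-unmethylated → case-methylated) and would need a
mirrored concordance rule for loss-of-methylation events.
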