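# Methods

`synscav` analyses two-compound antioxidant mixtures measured by DPPH and
ABTS radical-scavenging assays: it converts plate absorbances to
scavenging rates, estimates half-maximal scavenging concentrations
(IC50) by linear inverse prediction, tests for synergy against the Loewe
additivity null model, and correlates downstream microbiota abundances
with biomarker expression. This note records the models, the defaults,
and the choices made where the design was open.

## Scavenging rates

DPPH wells carry a blank, a measure well and a color-control well:

    scavenging % = 100 · [A_blank − (A_measure − A_control)] / A_blank

ABTS has two circulating denominator conventions:

    as_printed:  100 · (A_blank − A_sample) / A_sample
    standard:    100 · (A_blank − A_sample) / A_blank

The `as_printed` form (division by the sample absorbance) is nonstandard
— it reports 100% when the sample merely halves the absorbance — but it
is what some assay write-ups print. Whether it is a typo cannot be
decided from the data, so both conventions are implemented behind a
config switch (default `as_printed`), and every report records which was
used. The downstream synergy analysis consumes tabulated rates, so none
of its results depend on this choice.

Replicates (three technical replicates per concentration by default) are
averaged to one rate per concentration *before* curve fitting; each
sample well is paired with the blank of its own replicate, so shared
blank error cancels within a replicate. Negative rates from noisy
low-dose wells are retained, not clipped: clipping would bias fits near
zero dose.

## IC50 estimation

Dose-effect curves are fitted as straight lines, y = a + b·x, by
ordinary least squares — the model used for the data this package
targets, which are linear to R² > 0.99 over the tested ranges. For
fixed-ratio mixtures the x axis is the concentration of the
lower-proportion component (the per-component concentration for 1:1).
The IC50 is the inverse prediction (50 − a)/b; a crossing outside the
tested range is flagged `extrapolated`, not rejected. A slope ≤ 0 or a
non-positive crossing is an error.

The confidence interval is Fieller's theorem for the abscissa of the
50% crossing, with Student-t on n − 2 df:

    g = t² s² / (b² Sxx),
    limits = x̄ + [ (x̂₀ − x̄) ± (t s / b) √( (x̂₀−x̄)²/Sxx + (1−g)/n ) ] / (1 − g)

Fieller is the standard interval for a ratio of correlated normal
estimates and degrades gracefully as the slope loses significance: at
g ≥ 1 the set is unbounded, reported as infinite limits with a flag
rather than a fabricated finite interval. A first-order delta-method
interval, x̂₀ ± t·SE, is available for comparison; the two agree closely
whenever the slope t-statistic is large (> 20 gives < 1% relative width
difference). Perfectly collinear data collapse the interval to the
point estimate. IC50s are carried at full precision and displayed at 4
significant figures.

No sigmoidal (4PL/log-logistic) model is offered in the estimation path;
a Hill curve exists only in the simulator as a stress-test truth model
(see below).

## Loewe additivity and the interaction index

With single-agent IC50s `IC50_A`, `IC50_B` and mass fractions
(k_A, k_B), the additive prediction on the total-concentration scale is

    R = IC50_A / IC50_B
    IC50_add = IC50_A / (k_A + R·k_B)

a dose-weighted harmonic-type mean that always lies between the two
single-agent values. The observed mixture IC50 enters the interaction
index

    γ = k_A·IC50_mix / IC50_A + k_B·IC50_mix / IC50_B

with γ < 1 synergy, γ ≈ 1 additivity, γ > 1 antagonism. A sham
combination (a compound mixed with itself) gives γ = 1 identically for
any ratio, which is property-tested.

Two readings of the mixture IC50 coexist deliberately. The fit produces
`ic50_mix_axis`, on the lower-proportion-component axis; γ and the
per-component doses are defined on `ic50_mix_total`, the same number
read as total mixture concentration and split by (k_A, k_B). This
total-scale reading is the one that makes the interaction indices of the
packaged dataset internally consistent, and both numbers appear in every
report with the conversion stated.

When the single-agent IC50s carry finite confidence intervals, the
classifier is geometric: the additive isobole is the segment from
(IC50_A, 0) to (0, IC50_B); its 95% envelope connects the CI-bound
intercepts (endpoint-connected, the simplest band consistent with the
interval estimates — a pointwise band is not constructible from
interval endpoints alone). The mixture's dose point (d_A, d_B) is
synergistic if it lies below the lower-bound line
(d_A/ciLow_A + d_B/ciLow_B < 1), antagonistic above the upper-bound
line, additive between. Without CIs a γ-only fallback is used with an
absolute tolerance of 0.05 (configurable) so that synergy is never
declared from rounding noise. The normalized-dose sum the classifier
computes is identically γ, and the two code paths are cross-checked to
1e-12.

Known data caveat: in the packaged dataset the printed ABTS additive
IC50s (92.17, 88.17, 84.51 μg/mL) are not reproducible from the printed
single-compound ABTS IC50s (78.03, 94.77 μg/mL) under the additivity
formula, which yields 88.45, 85.59, 82.91; the DPPH cells are exactly
reproducible. Likewise the tabulated ABTS 1:2 and 2:1 interaction
indices (0.34, 0.33) come out as 0.343 and 0.336 (the 2:1 cell rounding
to 0.34, not 0.33). The pipeline therefore recomputes these quantities
from first principles and flags any user-supplied expectation that
disagrees by more than 1%, rather than asserting the irreproducible
cells.

## Synthetic data

The simulator emulates the measurement process, not just its summary:
noise lives on absorbance. Blanks draw from Normal(0.70, 0.0255) AU
(0.70 ± 0.05 read as a ~95% range); a true scavenging rate is inverted
through the configured convention to an expected sample absorbance, and
Normal(0, `noise_sd_abs`) is added there. The default
`noise_sd_abs` = 0.005 AU is a realistic plate-reader noise level chosen
to make fits with R² > 0.99 typical of simulated plates (median R² at
the default design is 0.9999); it is not derived from any replicate
variance, since none is published for the target dataset. Absorbances
driven below zero are clipped and counted. Every well has its own
counter-derived substream of one root seed, so well order is irrelevant
and identical seeds give bit-identical plates. A zero-noise plate
round-trips exactly: recomputed rates equal the true curve to 1e-9.

Truth models are `linear` (mirrors the estimator; used for calibration
checks) and `logistic` (Hill). A Hill curve with its IC50 inside a
geometric 12-fold concentration grid is visibly curved there (R² ≈ 0.94
for hill = 1), so the linear estimator converges to the noiseless
line's 50% crossing — a pseudo-true value ~25% above the Hill IC50 for
hill = 1 on the default grid — not to the Hill IC50 itself. The test
suite measures exactly that: interval coverage is checked where the
model is correctly specified (linear truth: 94–95% empirical coverage
of 95% Fieller intervals over 500 seeded plates), and the logistic run
documents the model-misspecification bias instead of pretending it away.
Passing tests therefore certify calibration under the stated model, not
robustness to strongly saturating dose-response shapes.

Fixed-ratio designs (1:2, 1:1, 2:1) are generated from the axis grid of
the lower-proportion component and reproduce the packaged concentration
pairs exactly. The association-table generator produces log-normal
taxon abundances and positive marker expressions with planted strictly
monotone links: at zero noise a planted link has Spearman ρ = ±1, and
with no links the p ≤ 0.05 edge rule fires at its nominal rate
(measured 0.054 over 200 simulations at n = 15). It does not emulate
compositionality, sparsity/zero-inflation, or sequencing depth — results
on it say nothing about those features of real 16S data.

## Correlation network and F/B ratio

Spearman's ρ is the Pearson correlation of midranks (average ranks on
ties). Two-sided significance defaults to `auto`: for n ≤ 8 the exact
permutation null over all n! orderings of untied ranks is enumerated
(count |ρ_perm| ≥ |ρ_obs|, with a 1e-12 tolerance on the comparison);
for larger n the t approximation t = ρ√((n−2)/(1−ρ²)) on n − 2 df is
used; |ρ| = 1 under the t method returns the smallest positive float
rather than 0. Edges are kept at p ≤ α (boundary inclusive, α = 0.05
default) without multiplicity adjustment by default, matching the
common practice for these networks; Benjamini–Hochberg is available via
`adjust="bh"` and is the recommended setting when the network is used
inferentially rather than descriptively. Pairs with a constant vector
are skipped (correlation undefined). Edge order is deterministic
(taxon, then marker, lexicographic).

The Firmicutes/Bacteroidota ratio is computed per sample from a
phylum-rank table; matching is case-insensitive and accepts the older
"Bacteroidetes" name. A sample with zero Bacteroidota yields NaN
(flagged undefined), never a crash; a missing phylum row is an error.
The ratio is scale-invariant, so raw counts and relative abundances give
the same answer.

## Numerical conventions and edge cases

- OLS via `scipy.stats.linregress`; diagnostics (Sxx, x̄, residual SE)
  recomputed explicitly. Constant-y data define R² = 1 (the flat line
  fits exactly); R² is clamped to [0, 1] against rounding.
- Spearman ρ within 1e-12 of ±1 is snapped to ±1 (perfect monotonicity
  up to floating-point rank rounding).
- Mixture fractions must be interior (0 < k < 1); pure-compound
  boundaries are rejected everywhere, and the pure limit is exercised in
  tests as k → 1.
- 1:1 mixtures tie-break the axis component to compound A (numerically
  irrelevant).
- Table parsing autodetects comma vs tab, requires a header, reports
  line numbers on bad cells, and round-trips numeric fields bitwise via
  repr.

## Problem sizes

The packaged analysis is desk-scale (six 5-point series) and runs in
milliseconds. Monte-Carlo checks use 500 plates for interval coverage,
200 table pairs for the null edge rate, 100 plates for the
misspecification-bias check, and 20,000 permutation draws for the
t-approximation cross-check; the full suite completes in well under a
minute on one CPU.
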