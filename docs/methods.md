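# Methods

## The synthetic study

The generator emulates a three-group, four-matrix rodent NMR metabolomics
design: groups `control`, `SMFY`, `GMFS` (the two treatment arms of the
emulated design), n = 8 per group, matrices serum, urine, cortex and
stomach extract. For each matrix it draws per-sample metabolite amounts,
renders them as a spectrum, and records the ground truth used by the
recovery tests.

**Forward model.** Each metabolite template is a set of resonances with a
chemical-shift position, multiplet fine structure (line offsets in Hz and
weights), a linewidth and an area share; shares and weights each sum
to 1. A resonance line is a unit-area Lorentzian
L(x) = (1/π)·h/((x−c)² + h²) with HWHM h = linewidth/2 converted to ppm at
600 MHz (default linewidth 1 Hz; 2.5 Hz for unresolved multiplets, 4–8 Hz
for broad protein/lipoprotein signals). Spectra are rendered on a uniform
grid from −0.25 to 10.0 ppm with step 0.0005 ppm (8 points per 0.004 ppm
bucket). The grid extends below 0 ppm so the TSP reference singlet at
δ 0.000 is available to the referencing step; all analysed ranges start at
0.5 ppm. Intensity is linear in concentration and in the per-sample
dilution factor.

**Statistical structure.** Control concentrations are log-normal around
each template's baseline with log-SD 0.15 (multiplicative biology);
treated groups multiply affected metabolites by 2^(log₂ effect); the
internal standard (TSP) has no biological variation. Dilution factors are
log-normal with log-SD 0.30 for urine and 0.05 for the other matrices.
Detector noise is additive Gaussian (default SD 0.5 intensity units,
about three orders of magnitude below major peak heights — high-field
NMR is a high-SNR technique and detectability here is governed by
biological variance, not noise). Per-sample-type RNG streams are spawned
from a single seed, so regeneration is bit-identical.

**Planted effects.** Each matrix has ten affected metabolites per
treatment arm: a shared core changed in the same direction in both arms,
arm-specific changes, and serum methionine planted *down* in SMFY and
*up* in GMFS (the opposite-direction pattern). Magnitudes span
0.5–1.5 on the log₂ scale. The bundled library holds 73 compounds at
standard 600 MHz positions; most are present in every matrix, with
gut-microbial aromatics (hippurate, benzoate, urocanate, aminohippurate,
…) urinary, GABA cortex-only and the broad LDL resonance serum-only, so
each matrix quantifies 54–65 metabolites. Library positions were curated
so that each metabolite in each matrix retains at least one resonance
whose surrounding window contains no other compound's line — the
"least-overlapping peak" needed for interval quantification (verified by
a test).

**What the generator does not emulate** — and hence what passing tests do
not demonstrate about real data: peak-position jitter (pH/ionic-strength
shifts) and the alignment step it would require, baseline roll and phase
errors, J-coupling roofing effects, spectral crowding beyond the curated
overlaps, and correlated metabolite physiology (each compound varies
independently). Recovery statistics on this generator are best read as
an upper bound for equally sized real studies.

## Preprocessing

Referencing translates the ppm axis by an integer number of grid steps so
the reference apex sits on its nominal value: the TSP singlet apex
(searched in −0.05..0.05 ppm) to 0.000, or, for serum, the left
(lower-ppm) split of the lactate methyl doublet (searched in
1.30..1.36 ppm) to 1.336. An apex must exceed a robust noise floor
(median + 10·MAD). Synthetic pipelines default to no re-referencing since
the generator's axis is exact.

Exclusions remove points outside the retained range (serum 0.5–9.0,
urine 0.5–10.0, cortex 0.5–8.5, stomach 0.5–9.2 ppm) and inside half-open
excluded windows: residual water (serum 4.7–5.0, urine 4.76–5.06, cortex
4.97–5.02, stomach 4.95–5.04) and urea 5.60–6.35, applied to all
matrices.

Bucketing lays half-open 0.004 ppm buckets ascending from the start of
the retained range; a bucket's value is the rectangle-rule integral over
its member points (the grid is fine enough that trapezoid integration
changes nothing testable). Buckets intersecting an excluded gap are
dropped whole rather than truncated — conservative, and it avoids area
bias at gap borders; a trailing partial bucket narrower than half a width
is dropped. The serum range yields 2125 buckets before exclusions.

Normalization is constant-sum to 100 followed by PQN: the reference
spectrum is the element-wise median over control-group rows (falling back
to all rows), quotients are taken over buckets where the reference
exceeds its own 5th percentile (a floor that excludes noise-only
buckets), and each row is divided by its median quotient. The product of
a sample's constant-sum factor and its PQN quotient estimates its
dilution factor up to a common scale; on urine-like simulations this
estimate correlates with the true factors at r > 0.99. PQN applied to an
already-normalized matrix is a no-op (the state machine makes the step
idempotent).

## Chemometric models

All models are NIPALS-based and deterministic: every component's sign is
fixed by making its largest-magnitude loading element positive.

*PCA* is power iteration with deflation on centred data (tolerance 1e−14,
effectively machine precision on the small matrices used here); it
matches an SVD to 1e−8 and truncates with a warning past the matrix rank.
*PLS-DA* is classical NIPALS with X- and Y-deflation; Y is one-hot for
three-group score plots or ±1 for pairwise models. *OPLS-DA* follows the
standard sequence — w ∝ Xᵀy, t = Xw, p = Xᵀt/tᵀt, orthogonal weight
w_o ∝ p − (wᵀp)w, deflation by t_o p_oᵀ — and keeps adding orthogonal
components while 7-fold cross-validated Q² improves by more than 0.01,
capped at 5 (the heuristic family used by commercial chemometrics
software; the choice is exposed as `n_orth`).

Cross-validation is stratified: within each class, samples are shuffled
with a seeded RNG and dealt round-robin with a counter running across
classes, so an 8 + 8 design over 7 folds gives sizes {3,3,2,2,2,2,2}.
Q² = 1 − PRESS/TSS with each test residual referenced to the
training-fold mean of y. The permutation test redraws any permutation
that reproduces the observed label vector — not merely the identity
permutation — because in a balanced 8 + 8 design about one random
permutation in 13 000 recreates the labels exactly and would count the
observed Q² among its own nulls. Permuted models reuse the observed
model's orthogonal rank.

VIP is computed from the single predictive component,
VIP_j = √K·|w_j|/‖w‖, so ΣVIP² = K holds identically; this weights
exactly the class-discriminating direction. Correlation loadings are
Pearson correlations between the predictive score and each scaled
variable, with r = 0 assigned to constant columns.

## Quantification and selection

Metabolites are quantified as bucket-sum integrals over one
least-overlapping resonance, expressed as a percentage of the sample's
total bucket sum (relative concentration). The bundled regions are
chosen automatically: each peak of a metabolite is scored by the
clearance between its multiplet span and the nearest foreign line in
that matrix (zero if a foreign line falls inside the span); the winning
span is widened by half its clearance, clamped to 0.006–0.02 ppm, and
peaks inside excluded windows are ineligible.

Group comparison uses the two-sided pooled-variance Student's t-test with
Bonferroni adjustment over the metabolites of one comparison and sample
type, and fold-change = mean(treated)/mean(control) of the quantified
percentages. VIP and |r| are lifted to the metabolite as the maximum over
its quantification buckets (a metabolite is flagged if any resolved
resonance discriminates), and VIP categories are cut at the empirical
0.95/0.90/0.80 quantiles, boundary-inclusive; an all-equal VIP vector is
assigned wholly to the rest-80% bin. Selection requires all four
criteria: |r| ≥ 0.6, VIP category in the top 20%, adjusted p ≤ 0.05 and
|log₂FC| ≥ 0.1. The p and fold-change cut-offs are deliberate defaults
(configurable): 0.1 on the log₂ scale admits a reproducible 0.9-fold
decrease, the weakest effect the workflow is meant to catch.

## Power analysis

Effect size is Cohen's d with the pooled (n−1) SD — the two-sample
default of standard power software; the test is two-sided, matching the
volcano's t-tests. Power is exact noncentral-t:
P(|T| > t₁₋α/2,2n−2) with noncentrality d·√(n/2); the lower-tail term is
set to zero when the noncentral CDF underflows at extreme noncentrality.
`required_sample_size` inverts this by bisection over n. The per-marker
report evaluates d from the quantified concentrations and power at the
study's n and α = 0.01. A pilot-data, FDR-calibrated power analysis is
out of scope here (it requires real pilot spectra); the α-level analysis
is the package's a-priori tool.

## Pathway impact

Enrichment combines the hypergeometric upper tail P(X ≥ k) over a
compound universe (by default the union of all compounds in the loaded
pathway set — reproducible without external databases) with topological
impact: betweenness centralities normalized to sum 1 within each pathway,
summed over the hit compounds. Pathways with no intermediate node (all
betweenness zero) fall back to uniform centrality so impact stays
defined. The significance rule is impact ≥ 0.4 and −log₁₀(p) ≥ 2; the
log base is taken as 10, consistent with the volcano axis. The bundled
ten-pathway demo set is hand-built from library compounds (4–12 nodes
each, connected) and is a synthetic fixture for exercising the statistic,
not curated biochemistry; with the default universe of ~40 compounds and
marker lists of 20–30, hypergeometric p-values rarely clear the
significance bar, which is the expected behaviour of the rule at this
universe size.

## Pipeline, seeding and problem sizes

A single seed drives everything: the study simulation uses it directly
and each (sample type, comparison) model derives its own sub-2³¹ seed by
a fixed affine rule, so partial re-runs through the CLI reproduce the
full run exactly. Stage outputs are plain TSV/JSON with a checksummed
manifest. Degenerate configurations still run: with fewer samples than
folds the fold count drops to the sample count, and designs with fewer
than three samples per group trigger a warning that power estimates are
uninterpretable.

The shipped validation suite uses the sizes the package itself considers
adequate for its claims: 25 simulated studies for marker recovery,
10 for the power floor, 20 label shuffles with 200 permutations each for
null calibration, 10⁴ replicates for t-test calibration and 2×10⁵
simulated tests per grid point for the Monte-Carlo power oracle.

## Known limitations

- No peak alignment: real spectra with pH-driven position jitter would
  need an alignment step before bucketing.
- Bonferroni is the only multiplicity correction; an FDR option is a
  natural extension but is not implemented.
- The VIP top-20% rule caps the number of selectable markers at 20% of
  the quantified metabolites per panel by construction; panels expecting
  more true markers need a larger quantified panel or a relaxed
  `vip_top_fraction`.
- OPLS-DA assumes a balanced (or near-balanced) two-class design; class
  weights are not implemented.
- The demo pathway graphs are illustrative topology, not curated
  metabolic networks; impact values on them should not be interpreted
  biologically.
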