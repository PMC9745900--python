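# Methods

## Scope and data model

The package implements the analysis layer of a targeted-drug viability
screen on a small cell-line panel: everything downstream of raw plate
luminescence, annotated variant calls, and summarized phospho-flow
medians. Alignment, variant calling and annotation, and cytometry gating
are upstream of the package boundary and are consumed as columns of the
input tables.

## Normalization

Viability is anchored per plate to the means of the negative (vehicle,
100%) and positive (full kill, 0%) control wells; the median is available
as a robust alternative. Values outside [0, 100] are retained and flagged
rather than clipped: clipping before curve fitting would bias asymptote
estimates, and the scoring stage clips inside its own integrand anyway.
Inverted or missing controls abort with the plate named. Replicates are
summarized by mean and sample SD (n−1); a single replicate yields a
flagged, undefined SD.

## Dose-response fitting

The four-parameter log-logistic model (slope b, lower asymptote c, upper
asymptote d, inflection e in nM) is fitted by Levenberg–Marquardt with
initialization d₀ = max response, c₀ = min response, e₀ = the tested dose
nearest the half-response, b₀ = 1. A fit counts as non-converged when the
optimizer fails, a parameter is non-finite, or e leaves
[min dose/10⁴, max dose·10⁴]; the profile is then refitted with a logistic
on the log10-dose axis (L4), whose location parameter is a log10 value and
is only required to be finite. The two families are reparameterizations of
each other; the fallback matters exactly when the nM-scale parameterization
runs away (full kill below the lowest dose, or near-flat drifts pushing e
to extremes). The fallback itself multi-starts over a few slope/location
initializations, and if plain Levenberg–Marquardt still stalls — typical
when the response drops before the second dose, leaving the upper
asymptote unidentifiable — a bounded trust-region fit pins the parameters
to a sane box; the scoring stage clips predicted viability anyway, so a
boundary-pinned asymptote cannot distort the score. Constant profiles
short-circuit to a degenerate fit (b = 0, c = d = mean) that downstream
scoring marks low-confidence. Optimizer tolerances are 1e-12; tighter
settings make LM exhaust its evaluation budget without improving the
solution.

## Sensitivity scoring

The score integrates 100 − max(v(x), t) over x = log10 dose across the
tested range, with v clipped to [0, 100] inside the integrand and
t = 10% viability; the normalizer is (100 − t)(x_max − x_min) with no
additional logarithmic term, and the result is clamped to [0, 100].
Saturating the integrand at 100 − t beyond the threshold crossing is the
window semantics used by default: truncating the integral there instead
(available as `window="truncate"`) would score a maximally potent drug
near zero, inverting the scale's meaning. Integration uses the composite
trapezoid on a fixed grid of 1000 points per decade; against an adaptive
quadrature oracle with kink isolation, the worst relative error over
random curve draws is below 1e-7, comfortably inside the 1e-6 target.

## Variant triage

The cascade drops variants with 1000 Genomes phase-3 MAF > 1% or ESP MAF
> 0.1% in any population (strict inequalities; a boundary value stays),
then dbSNP-138 variants lacking ClinVar associations, then everything that
is not a coding-class variant (missense, stop-gain/loss, frameshift,
non-frameshift, splice donor/acceptor) in a COSMIC-census gene. Missing
MAFs mean "absent from the population database" and never exclude.
PolyPhen-2 damaging calls annotate a priority flag without dropping rows,
because the downstream mutation matrix covers more genes than the
damaging-and-druggable subset. All three drop filters are row-wise
predicates, so they commute; the tests verify this on a fixture covering
every branch. The matrix is binary per gene × cell line with a provenance
list of contributing protein changes.

## Phospho-flow transform

Readouts become asinh(signal/cofactor) − asinh(isotype/cofactor) with
cofactor 150 (conventional for fluorescence cytometry; configurable — its
choice washes out after standardization). Each analyte row is standardized
to mean 0 / sample SD 1 across cell lines before modelling;
constant analytes become zero rows and are flagged.

## Tree-guided group lasso

For features X (samples × p) and scores Y (samples × q) the model
minimizes ½‖Y − XB‖²_F + Λ·Ω(B). Both X and Y are column-centered
internally and the per-drug means return as intercepts; binary mutation
covariates are otherwise left on their 0/1 scale, while protein covariates
arrive already standardized.

The penalty follows the recursive tree-guided construction: the drug tree
is built on 1 − Pearson distance between DSS profiles with complete
linkage (configurable), merge heights normalized to put the root at 1 and
leaves at 0, then clamped at h_cut = 0.7. Clamping (rather than pruning
above the cutoff) keeps the joint root-level group active, which is what
lets weak but concordant effects borrow strength across the whole library.
Each internal node's clamped height s_v mixes separate-child selection
(s_v → 1) against joint selection (s_v → 0); expanding the recursion gives
group weights (1 − s_v)·∏ ancestor s for internal nodes and ∏ ancestor s
for leaves, which telescopes to total weight exactly 1 along every
root-to-leaf path — no extra normalization is needed. Setting every s to 1
reproduces the plain lasso and every s to 0 a single all-drug group; both
reductions are asserted to 1e-10 in the tests.

Optimization: the internal-node group norms are Nesterov-smoothed with
μ = 1e-4 and the leaf-level L1 handled exactly by soft-thresholding,
inside a monotone accelerated proximal-gradient loop (momentum restarts on
any non-monotone step, so the objective trace never increases). The step
size is a backtracking estimate of local curvature capped by the analytic
bound σ_max(XᵀX) + Λ²·max_j Σ_{v∋j} w_v² / μ; using the analytic bound
directly would shrink steps by up to ~10⁷ away from the origin, where the
smoothed norms are nearly linear. Convergence requires five consecutive
iterations with relative objective change below tol (default 1e-8,
max_iter 20,000).

Because the group family is laminar, the proximal operator of the exact
(unsmoothed) penalty is the children-first composition of per-group
soft-thresholdings; `method="prox"` uses it with full 1/σ_max steps. It
solves the exact objective, agrees with SPG to within the smoothing gap
(≤ Λμ·#groups/2), and is roughly an order of magnitude faster, so the
leave-one-out CV paths use it by default while single fits default to SPG.

Λ is tuned on a log-spaced grid under the pure-lasso null bound
Λ_max = max|XᵀY| (library default 30 points over three decades; the
pipeline and the bundled experiments use shorter grids, 10–20 points over
two decades, which the CV curves show is where all the structure lives).
Each LOO fold holds out one cell line; held-out squared errors are pooled
per (sample, drug) entry. The selected Λ is the smallest grid value whose
MSE is within 2% of the minimum over itself and all larger values — an
operationalization of "where the CV curve becomes essentially flat".
On pure-noise responses this rule collapses roughly two thirds of runs to
the exactly-null model and most of the rest to within one or two grid
points of it; the property test asserts the measured level, not an ideal
one. Fold fits run at tol 1e-6 / max_iter 3000 — the CV curve needs far
less precision than a final fit — and the final model is refitted on all
samples at the selected Λ with default tolerances.

R² = 1 − RSS/TSS is pooled over every (sample, drug) entry, with TSS
around per-drug means, so an intercept-only model scores 0. For display,
feature rows are dropped when all-zero or when, for every drug, the
absolute coefficient is strictly below 5% of that drug's total absolute
coefficient mass.

## Association statistics

Welch's t (unequal variances, Welch–Satterthwaite df, two-sided) compares
score means between carrier and wild-type groups; drug-class tests pool
every drug × cell-line observation of the class by default (a
per-cell-line-mean mode is available). Pearson r significance uses the
exact t transform with n − 2 df; per-pair p-values are reported without
multiple-testing adjustment — on panels this small, FDR control across
~10³ pairs removes everything, which is precisely why the joint tree-lasso
is the primary inference route — with an optional Benjamini–Hochberg
column for context. Cell-line columns cluster under Euclidean distance and
Ward linkage with no row scaling. A consistency check computes the
fraction of nonzero coefficients whose sign matches the marginal
feature-drug correlation; for standardized covariates the two carry
analogous interpretations. That interpretation is a property of the
heavily-penalized (sparse) regime, where coefficients behave like
soft-thresholded marginal covariances: there the agreement is essentially
perfect, while near the CV optimum the model also carries many tiny
noise-absorbing coefficients whose partial-effect signs legitimately
decouple from marginal correlations. The bundled consistency experiments
therefore evaluate sparse fits (Λ = Λ_max/2).

## Synthetic study design

The generator produces every pipeline input with ground truth attached.
Defaults mirror the screen design the package targets: 9 cell lines, 33
drugs, five concentrations from 1 to 10,000 nM, triplicate plates with 16
negative and 16 positive control wells (a realistic 384-well layout), and
additive Gaussian plate noise of 5 percent-viability units on the
luminescence scale. Drug-sensitivity targets are baseline (uniform 8–55)
plus planted effects — four causal genes (e.g. NRAS → +28 on the four-drug
MEK-inhibitor class, PIK3CA → +24 on the six-drug PI3K class) among eight
decoy genes, and four causal analytes in a 31-analyte panel — plus
residual noise (SD 4), clipped to [1, 96]. Each target is inverted into a
log-logistic curve (bisection on log e; slope drawn 1.0–2.2, full-kill
asymptotes), so the simulated screen, after normalization, fitting and
scoring, reproduces the planted effect structure. The variant table is
constructed so the triage survivors rebuild the planted mutation matrix
exactly, with decoys exercising each exclusion branch; phospho signals are
back-transformed through the arcsinh so standardization recovers the
planted covariates exactly.

What the generator does not emulate: plate spatial/edge artifacts,
heteroscedastic or non-Gaussian reader noise, correlated replicate
failures, subclonal variant allele fractions, or biological nonlinearity
in the feature → response map. Passing tests therefore demonstrate that
the pipeline recovers the truth under its own modelling assumptions at
realistic noise, not that those assumptions hold for any particular real
screen.

The feature-recovery experiment (the hardest test) plants 5 causal binary
features among 50, each boosting one four-drug class by +25 score units,
over 60 samples at residual SD 5 with 16 drugs; recovery is judged on the
rows surviving the 5% display filter, and succeeds when all five causal
features appear with positive coefficients on their class drugs and at
most five non-causal features survive. With twelve Λ values over two
decades this holds in ≥ 90% of 50 seeded runs at a few seconds per run.

## Numerical choices and degenerate inputs

Trapezoid grid 1000 points/decade (score error < 1e-7 relative);
LM tolerances 1e-12; inflection validity window min dose/10⁴ to max
dose·10⁴; degenerate (constant) profiles scored from their mean with a
low-confidence flag; identical drug profiles merge at height 0 and a fully
degenerate tree keeps all heights at 0; zero-variance analytes become zero
rows; MAF fields outside [0, 0.5] are rejected rather than coerced. All
generators and the pipeline are pure functions of their seed; tables are
written tab-separated with full float precision, which is what makes
same-seed reruns byte-identical. Bit-level identity additionally assumes a
single-threaded linear-algebra backend (multi-threaded BLAS reductions are
order-dependent); the bundled reproduction script pins the backend to one
thread accordingly.

## Known limitations

Λ is implementation-scaled: its numerical value depends on the penalty
normalization and response units, so tuned values are not transferable
between implementations. LOO-CV on 9 cell lines is noisy; the flat-rule
selection inherits that noise. The pooled drug-class test treats class
members as exchangeable observations, understating within-cell-line
correlation; the per-cell-line-mean mode is the conservative alternative.
Penalized coefficients carry no p-values by design.
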