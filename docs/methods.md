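# Methods

## Behavioral measures

Each participant contributes up to three coded speech samples
(conversation, phone call, reading passage).  A sample's rate for a
disfluency type is `100 * count / total_syllables`; the participant-level
rate is the unweighted mean of the per-sample rates, so each task counts
equally regardless of its syllable total (samples are averaged, never
pooled).  All values are kept at full precision internally and rounded to
two decimals only when serialized.  The packaged demographics table pools
the three samples into combined counts, which the data model admits via a
`combined` task label; records with fewer than three samples are averaged
over what is present, with a logged warning.

Two percentage cells in the packaged table are internally inconsistent with
their own printed count and total (off by one unit in the second decimal
under any rounding rule); the counts and totals are treated as
authoritative and the discrepancy is documented in the test fixtures.

Inter-rater reliability uses the single-measure, two-way random-effects,
absolute-agreement intraclass correlation ICC(2,1), computed from the
two-way ANOVA decomposition.  Absolute agreement is the defensible default
when multiple raters score the same items and systematic rater offsets
should count against reliability; the consistency form ICC(3,1) is
selectable.  Zero between-item variance leaves the ICC undefined and
returns 0 with a warning.

## Connectivity predictors

Predictors are Fisher z-transformed Pearson correlations between ROI-pair
time series, z = arctanh(r).  Correlations with |r| ≥ 1 − 1e−7 are clipped
to that bound before the transform (with a warning) so degenerate series
cannot produce infinities; real BOLD data never approaches the bound.  The
58-pair DIVA/GODIVA connection list ships as configuration
(`data/diva_godiva_connections.yaml`) and is an explicit reconstruction
from the network logic and ROI vocabulary of the source figures — the
original pair enumeration is not published, so numeric agreement with the
original z-values is out of reach by design and nothing downstream depends
on it.  Users may bypass time series entirely and supply a subject ×
connection z-table.  The scanner covariate is one binary column (MGH = 1,
BU = 0); cohorts with more than two sites are rejected.

## LASSO core

The solver minimizes `(1/2n)·RSS + λ·Σ|β_j|` by cyclic coordinate descent
with soft-thresholding, operating on the Gram matrix `G = X̃'X̃/n`
(covariance updates), so a sweep costs O(p²) independent of n; the hot loop
is numba-compiled with a pure-Python mirror used as a reference and debug
engine (the debug engine asserts the objective never increases across
sweeps).  After each full sweep the solver iterates only the currently
nonzero coordinates until stable, then re-checks with a full sweep —
convergence is always certified by a full sweep.

Predictors are centered and scaled to unit population (1/n) variance by
default; coefficients are reported on the original scale and the intercept
is unpenalized.  Constant columns get coefficient exactly 0.  The
regularization path is geometric with 100 values from
`λ_max = max_j |⟨x̃_j, y − ȳ⟩|/n` (the smallest penalty with an all-zero
solution) down to `λ_max · r`, with `r = 0.01` when n < p and `1e−4`
otherwise.  Cross-validation uses 10 folds (reduced to n when n < 10)
assigned by a seeded shuffle, scores every fold on the shared path, and
picks the λ minimizing mean validation MSE, breaking ties toward the
larger (sparser) λ.  A training fold with a constant outcome degenerates to
an intercept-only model and is still scored; if every fold degenerates the
fit errors out.  These defaults follow the conventions of the standard
cross-validated LASSO implementations; all are configurable.

The stopping rule is the glmnet-style weighted squared-change criterion:
a sweep cycle terminates when `max_j v_j·(Δβ_j)² < tol` with `tol = 1e−7`
(v_j the standardized column variance).  This targets coefficient precision
of order 3e−4 on the standardized scale — ample for cross-validation and
bootstrap aggregation; oracle comparisons in the test suite tighten `tol`
to drive the solver to numerical convergence.

The scanner covariate is penalized like any other predictor by default
(it enters the model as an ordinary column); an unpenalized option exists.

## Bootstrap inference and stability selection

The subjects are resampled with replacement B = 1000 times (predictor rows
and outcome jointly).  Iteration b derives its randomness from
`seed XOR b` — both the resample indices and the CV fold assignment —
so any iteration is reproducible in isolation and folds are repartitioned
independently per resample.  Bootstrap duplicates may co-occur in training
and validation folds; no deduplication is applied, matching the plain
per-resample cross-validation the procedure describes.  A resample with a
constant outcome cannot be fit: its coefficients are recorded as all-zero
and logged, and more than 50% such draws aborts the run.

Aggregation uses raw coefficients, zeros included (a
condition-on-selection variant is available).  Confidence intervals are
normal-approximation `mean ± z·SD` using the bootstrap SD as the standard
error, at the Bonferroni-adjusted level α′ = (1 − 0.95)/m with m = the
number of predictors in the model including the site column (59 by
default); percentile intervals and other m are configurable.  Both the
bootstrap SD and SD/√B are reported, since "standard error" is ambiguous
between them.  Stability selection counts nonzero draws per predictor,
ranks descending (ties: |mean coefficient| descending, then label), and the
first-drop cutoff places the stable/unstable boundary at the largest gap
`count_i − count_{i+1}`, ties to the earliest i, returning i as the number
of stable predictors; all-equal counts yield an empty stable set with a
warning.  "First prominent drop" and "largest drop" are reconciled as the
largest gap with earliest tie-break; a fixed-frequency threshold rule is
available as an alternative.  The procedure provides no formal
false-discovery control; it trades that for reproducibility of the
selected set under resampling.

## Site diagnostics

Levene's test (one-way ANOVA on absolute deviations from the group center)
screens each connection for MGH-vs-BU variance differences.  The classic
mean-centered form is the default — it has higher power than the
median-centered Brown–Forsythe variant under approximate normality, which
z-transformed correlations satisfy — with the median form selectable.
Flags are reported at the raw α with no multiplicity adjustment, mirroring
the screen's descriptive role; if the deviations are constant within every
group the statistic degenerates (0 with p = 1 when groups agree, ∞ with
p = 0 when they differ).

## Synthetic cohorts

The generator emulates the study's statistical structure with known ground
truth.  Connectivity rows are multivariate normal with block-exchangeable
correlation ρ = 0.3 in blocks of 6 consecutive connections, marginal mean
0.4 and SD 0.3 (the typical resting-state Fisher-z scale), plus a +0.1
z-shift for MGH subjects (55% of the cohort).  The outcome is
`y = max(0, μ + Σ_k effect_k·z_k + ε)` with ε ~ N(0, 1) percent and μ set
so the pre-truncation mean is 3.7% (the block-rate scale); each outcome is
then zeroed with probability 0.15, reproducing the exact zeros real
cohorts show for rarer disfluency types without claiming a hurdle-model
mechanism.  Three planted effects (+0.2, −0.18, +0.17 percent per z-unit)
sit on connections chosen to mirror the kind of stable set the analysis
targets: a feedback-map connection (L_vMC~R_vPMC), a cerebellar–thalamic
feedforward connection (R_aCb~L_VL, negative), and a planning-loop
connection (L_pIFS~L_preSMA).  The behavioral table is back-computed from
the simulated rates: three samples per subject with syllable totals uniform
on [200, 1100] and integer counts `round(rate·total/100)`, so the
behavioral module reproduces the simulated outcome to within the
count-rounding bound 50/min(total).  Repetition and prolongation companion
rates are null (no planted effects) at their typical cohort scales.  All
draws are pure functions of (config, seed).

These defaults put the planted signal at roughly 1% explained variance at
n = 20 — a deliberate stress regime.  What passing tests show is therefore
calibrated behavior under weak signal (correct signs for whatever enters
the stable set, no recurrent null intrusions, near-nominal error rates),
not that the procedure recovers the exact support at this sample size; it
does not, and neither would any method.  The generator also omits several
features of real data — BOLD autocorrelation and preprocessing artifacts,
non-Gaussian connectivity tails, site effects beyond a mean shift — so
numerical agreement with any particular empirical cohort is not implied.

## Numerical and design notes

- Fold assignment, bootstrap indices and all simulation draws use
  `numpy.random.default_rng` seeded explicitly; identical inputs and seeds
  give byte-identical report CSVs (floats are rounded to 10 decimals at
  serialization to keep text output stable).
- λ-selection ties prefer the larger λ (parsimony).
- Bonferroni m defaults to per-model comparisons (59); whether the original
  analysis corrected across the three outcome models is unknowable from the
  text, so cross-model correction is left to configuration.
- The average optimal λ reported per outcome excludes degenerate draws.
- Known limitations: no elastic-net mixing or non-Gaussian families; no
  1-SE λ rule (MSE-minimizing only); no harmonization (the screen's verdict
  is advisory); stability selection here is the simple selection-frequency
  variant, not complementary-pairs with error control.
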