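# Methods

## Data model

A *study* bundles four plain-text tables.  `trials.csv` has one row per
old/new test trial: subject, test position, clip id, target/foil, encoding
time (seconds from session start; clip onset marks the event), yes/no
response, correctness, and an optional repeat-group id linking the two
presentations of a covertly repeated clip.  `annotations.csv` holds
long-format categorical content labels per clip against a vocabulary declared
in `study.yaml`; `fixations.csv` flags, per target clip and content category,
whether any fixation landed on that content, along with saccade count and
mean saccade duration; `cv_features.csv` carries a fixed-dimension numeric
vector per clip (surrogate visual features by default — any per-clip vectors,
e.g. activations of a pretrained vision network, can be substituted through
the same table).

Foil clips come from a *donor* subject's session; their encoding times live
on the donor's timeline and are retained (the trial-type column flags them),
because the lag analysis can optionally be run in an `all_trials` sensitivity
mode.  Fixation records exist only for target clips: the donor's gaze is not
relevant to the subject's memory.  All performance statistics use first
presentations only; repeats would otherwise be double-counted and move chance
off 50%.

## Generative model of a synthetic subject

Familiarity of a presented clip is Gaussian with unit total variance
(variances in familiarity-SD units):

    f = mu(type) + sqrt(w_g) * g(t) + clip_persistent + sqrt(w_eps) * eps

with `mu(target) − mu(foil) = d'` and response *yes* iff `f > c`.

* `g(t)` is a stationary Ornstein–Uhlenbeck process with autocovariance
  `exp(−Δt/τ_gen)`, simulated *exactly* at the irregular clip onsets via the
  conditional AR(1) recursion `g_{i+1} = φ g_i + sqrt(1−φ²) ξ`,
  `φ = exp(−Δt_i/τ_gen)`.  There is no discretization error, so τ recovery
  tests the estimator, not the simulator.  `g` exists only on the subject's
  own encoding timeline; foil clips receive an iid clip-level term of equal
  variance so the marginal distributions match.
* `clip_persistent = content effects + η` is drawn once per clip and shared
  by repeat presentations.  Content effects are centred so they do not move
  d′.
* `eps` is trial-unique and is the only component redrawn on a covert
  repeat.

Clip onsets are cumulative sums of inter-onset intervals drawn from a normal
truncated below at 0.5 s (defaults 7.07 ± 0.89 s outdoors, 7.50 ± 0.32 s
indoors) up to the session duration (59 min outdoors, ~55 min indoors),
giving ≈ 470–500 clips per session.  Between-subject heterogeneity is
Gaussian: `d'_s ~ N(d', sd_d)` clipped at 0, `c_s ~ N(c, sd_c)`.  The master
seed spawns one `numpy` `SeedSequence` per subject
(`SeedSequence(master, spawn_key=(k,))`), so any subject regenerates in
isolation.

### Calibration identities

Two free variance shares are solved from the targeted binary statistics,
using exact bivariate normal orthant probabilities (Owen's T function):

* **Temporal share `w_g`.**  The normalized conditional curve obeys
  `y(Δ) = 1 + ρ_C(Δ)(1−p)/p`, where `ρ_C` is the Pearson correlation of the
  two correctness indicators and `p` the marginal probability correct.  A
  target amplitude α therefore fixes `ρ_C(0) = α p/(1−p)`; `w_g` is the
  latent correlation whose dichotomization yields that `ρ_C(0)`
  (numerically inverted; at p = ½ the closed form is `sin(π ρ_C/2)`).
* **Trial-noise share `w_eps`.**  The two presentations of a repeat share
  everything but `eps`, so their latent correlation is `1 − w_eps`, and
  expected agreement is `2Φ₂(z,z;ρ) + 2p_yes − 1`.  The generator solves for
  the *cohort-mean* agreement: the closed form is averaged over the two
  trial types (target and foil yes-rates differ) and over the subject
  (d′, c) distribution by Gauss–Hermite quadrature, then inverted.
  Calibrating at a single pooled yes-rate would overshoot the cohort mean
  because agreement is convex in the threshold.

The remaining share `w_clip = 1 − w_g − w_eps` absorbs content-effect
variance plus η; a configuration whose targets need `w_g + w_eps > 1` is
rejected as infeasible with a diagnostic.

Dichotomizing an exponential latent correlation slightly *steepens* the
binary correlation (arcsine-type concavity), so the fitted τ of simulated
cohorts runs ~5–10% below τ_gen at the outdoor operating point.  The
calibration intentionally targets the zero-lag amplitude and keeps the
latent timescale at τ_gen; the distortion is measured by the
dichotomized-process oracle test and is well inside the recovery tolerances.

### Cohort presets

Three presets encode the study conditions as package defaults:
`experiment_i()` (outdoor, 1-day: d′ = 0.29, c = 0.065, sd_d = 0.19,
sd_c = 0.35, α = 0.32, τ = 28.4 s, consistency 78.1%, 25 repeat pairs per
type, no fixations — these reproduce hit ≈ 53%, correct rejection ≈ 58%,
overall ≈ 55.7%, yes-rate ≈ 47%); `experiment_i_3month()` (d′ = 0.41,
c = 0.18, α = 0.375, τ = 37.6 s); `experiment_ii()` (indoor, with
fixations: d′ = 0.67, c = 0.106, sd_d = 0.41, sd_c = 0.27, α = 0.13,
τ = 10.8 s, consistency 74.9%, 18 repeat pairs per type).  Criterion spreads
are chosen so the implied yes-rate SDs are ~14% and ~11%.

## Estimators

**Signal detection.**  d′ and criterion use the log-linear correction
`p* = (x+0.5)/(n+1)` applied always, not only at 0/1 rates, keeping the
estimator continuous in the counts.  Percent correct uses raw counts.
Self-consistency is the fraction of repeat pairs with identical responses
and is reported as *absent* (not zero) when a study has no repeats.  Group
dispersion is SD for performance and SEM for self-consistency, always
labeled.  A pooled-cohort d′ is emitted separately from the mean of
per-subject d′ values; the two conventions are not interchangeable.  QC
flags: `yes_bias` for yes-rates beyond 90%/10% and `accuracy_outlier` for
percent correct more than 5 MADs above the cohort median (the signature of a
subject recognizing their clips from an incidental global cue).

**Lag curve.**  Over all ordered within-subject pairs of first-presentation
target trials with encoding-time difference in a bin (default 5 s bins up to
120 s), the fraction of successor-correct pairs among predecessor-correct
pairs, divided by that subject's own marginal probability correct; subjects
are pooled weighted by conditioning-pair counts.  Per-subject normalization
matters: pooling subjects with different marginal rates before normalizing
manufactures lag-independent excess.  Bins with fewer than 30 conditioning
pairs are dropped, not zeroed.  Bin centers are pair-weighted mean lags —
with ~7 s clip spacing the pairs cluster near multiples of the interval, and
nominal midpoints would bias τ.  The fit of `y = 1 + α exp(−Δ/τ)` is bounded
least squares (α ∈ [0,5], τ ∈ [1,600] s) multi-started over
τ₀ ∈ {5,10,20,40,80,160} s; `tau_identifiable` is false below α = 0.02.
Pair-count weighting (`weights="pair_counts"`) is recommended and used by
the recovery pipeline: the shortest-lag bins hold few pairs and dominate an
unweighted fit's variance (measured single-cohort sd(α̂): 0.15 unweighted vs
0.033 weighted at the outdoor conditions).  The test-order control applies
the identical estimator with lag measured in test positions.

**Parameter recovery.**  Even weighted, one 16-subject cohort estimates the
indoor amplitude (α = 0.13) with sd ≈ 0.06, so recovery is assessed on the
curve pooled over 12–16 replicate cohorts (each at the full study size,
independent seeds).  This is the procedure behind `scripts/acceptance.py`
and the recovery tests; problem sizes are stated in each output.

**Content and fixation splits.**  Cell performance pools trials (counts
reported per cell); error bars are SEMs of per-subject cell means, and the
rank-sum unit is the subject.  Both comparison families are emitted and
labeled — target-vs-foil within a content level, and level-vs-level within a
trial type — since a bar-plot star can refer to either.  Groups of ≤ 10 use
the exhaustive permutation distribution of the Mann–Whitney statistic
(exact even under ties); larger groups use the tie-corrected normal
approximation.  No multiple-testing correction by default (per-panel flags
at p < 0.01); a Benjamini–Hochberg option exists.

**Memorability model.**  Per subject, AdaBoost over depth-1 trees (default
100 rounds; an RBF-kernel SVM behind a switch) with stratified k-fold CV
(default 10 folds), standardization fitted inside each training fold.  The
reported metric is **balanced accuracy** (mean per-class recall): correctness
base rates sit at 55–65%, so raw accuracy has a majority-class null at the
base rate, whereas balanced accuracy is 50% under any label shuffle.  Raw
accuracy is emitted alongside.  Fold assignments depend only on
(seed, subject, labels), making feature-group ablations paired.  A fold
where boosting cannot beat the base rate falls back to the training majority
class.  Fold count, rounds and depth are reported with every result.

One structural property worth knowing: a content effect that shifts
familiarity *symmetrically* raises hits and false alarms together, so its
effect on pooled-trial correctness cancels to first order.  Content signal
is therefore detectable mainly on target-only rows; `assemble_features`
exposes `trial_scope="targets"` (the eye groups force it anyway, since
fixations exist only for targets).

## What the simulator does and does not emulate

It reproduces: balanced designs at ~50% yes-rates, barely-above-chance
sensitivity with realistic between-subject spread, calibrated repeat
agreement, exponential encoding-time correlation of correctness with no
test-order dependence, configurable content/fixation effect sizes, and a
planted low-dimensional direction in the surrogate visual features.

It does not emulate: dependence between annotation features (e.g. a gender
label on a clip without faces), nonstationarity over the hour (fatigue,
primacy), non-Gaussian familiarity, criterion drift during the test,
rehearsal between encoding and test, or the content statistics of real
video.  Passing tests therefore certify the estimators under the stated
model, not the behavior of any real cohort; real tables plug into the same
`trial_io` surface.

## Numerical choices

Orthant probabilities via Owen's T (machine precision; diagonal closed form
`Φ(z) − 2T(z, sqrt((1−ρ)/(1+ρ)))`, limit `¼ + arcsin(ρ)/2π` at z = 0);
calibration inversions by Brent's method at 1e−10…1e−12 tolerance, cached;
decay fits with xtol = ftol = 1e−14 so noiseless recovery is exact to 1e−6;
degenerate inputs raise typed errors (zero-variance t-test, empty rank-sum
group, all-correct subjects skipped with a warning).  CSV writing is sorted
and format-pinned so identical configurations produce byte-identical tables.

Test-suite problem sizes are scaled-down study conditions (e.g. 3–8 subjects
at 10–20 min sessions for pipeline and classifier checks, 12–16 replicate
cohorts for recovery, 10⁶-draw Monte-Carlo oracles for the orthant
identities); each test states its own size and tolerance.

## Known limitations

The α ≥ 0 fit bound truncates noise at the boundary, slightly inflating mean
α̂ on weak-amplitude cohorts; τ̂ carries the ~5–10% dichotomization bias noted
above.  The exact rank-sum path enumerates up to C(20,10) assignments and is
not meant for larger groups (the asymptotic path takes over).  The 3-month
preset reuses the 1-day self-consistency level, which that retest did not
re-measure.  The CLI covers the simulate→analyze→report loop; multi-session
(retest) linkage is representable in the tables (session label in
`study.yaml`) but no cross-session analysis is provided.
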