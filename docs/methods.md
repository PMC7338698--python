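# Methods

## Models

Recognition confidence ratings (1 = *sure new* … 6 = *sure old*) are
modelled as arising from a unidimensional memory-strength variable
compared against five ordered criteria `c1 < … < c5` (with `c0 = −∞`,
`c6 = +∞`). New-item strengths are standard normal (`μ_n = 0`,
`σ_n = 1`; fixed, not configurable). Three accounts of the old-item
distribution are implemented:

* **UVSD** — old strengths `N(d, σ_o)`. Hit probability at criterion c
  is `Φ((d − c)/σ_o)`; false-alarm probability is `Φ(−c)`. The z-ROC is
  exactly linear with slope `1/σ_o`, so the commonly observed slope of
  ~0.8 corresponds to old-item SD ≈ 1.25.
* **DPSD** — with probability `R` an old item is recollected and always
  rated 6; otherwise an equal-variance familiarity process `N(d′, 1)`
  responds. Hit probability `R + (1 − R)Φ(d′ − c)`. The recollection
  mass is assigned wholly to the top confidence category (the standard
  reading of "judged old with the highest degree of confidence"); no
  graded-recollection variant is offered. Because the model leaves the
  recollection distribution's shape unspecified, `old_item_variance`
  deliberately rejects DPSD parameters.
* **MSD** — old strengths are a two-component normal mixture:
  `N(d_A, 1)` with probability `λ` (attended), else `N(d_A′, 1)`. The
  default pipeline fixes `d_A′ = 0`, which equates the free-parameter
  count (7) with the other two models; a nonzero `d_A′` can be set
  explicitly on `MSDParams` but is untested against any empirical
  anchor. With `d_A′ = 0` the old-item variance is
  `1 + λ(1 − λ)d_A²` — equal to 1 at `λ ∈ {0, 1}` (the EVSD reductions)
  and maximal at `λ = 0.5`.

All three models reduce to the equal-variance model when
`σ_o = 1`, `R = 0`, or `λ = 1`, and the package tests that the three
reductions produce identical category probabilities to 1e-12.

Category probabilities are obtained by differencing the cumulative
("old" response) curves across adjacent criteria. The normal CDF is
`scipy.special.ndtr` (complementary-error-function based); no lookup
tables.

## Likelihood and fitting

The likelihood of a 2 × 6 count table is multinomial over the 12 cells
(multinomial coefficient omitted). Predicted cell probabilities are
floored at 1e-10 and renormalized before logs are taken: extreme
criteria can otherwise produce exactly-zero cells and −∞ likelihoods
mid-optimization, and the floor does not materially move any optimum.

Estimation maximizes the likelihood over an unconstrained transform:
criteria as `(c1, log-increments)` (enforcing strict ordering), `σ_o`
as log (bounds [0.1, 10]), `R`/`λ` via logit, and `d`/`d′`/`d_A`
box-bounded in [−5, 25]. The MSD model has a known degeneracy in which
`d_A → ∞` with a compensating `λ`; rather than let the optimizer
wander, fits reaching the bound are flagged (`boundary=True`) and
treated as "> 10" outliers by the exclusion rule below. The optimizer
is L-BFGS-B (max 2,000 iterations per start, loglik tolerance ~1e-8)
with seeded multi-start (default 20): the first start sets the criteria
from the probit of the observed new-item cumulative proportions and the
strength parameter from the probit hit/FA difference at the scale
midpoint; the remaining starts jitter that point with seeded Gaussian
noise. DPSD/MSD likelihoods are multimodal; UVSD rarely needs more than
a few starts. Fits are bit-reproducible given the seed. The recovery
harnesses default to 5 starts per fit — spot checks against 20-start
fits show identical optima on these well-identified simulated tables,
and the harnesses run hundreds of fits.

Goodness of fit is `G² = 2 Σ O ln(O/E)` over the 12 cells (zero-count
cells contribute 0), with df = 2·(6 − 1) − 7 = 3 and p from the
chi-square distribution. Because the same floored probabilities enter
the likelihood and the expected counts, `G²` equals
`2(loglik_saturated − loglik_model)` identically. Model comparison uses
raw G² (all three models have 7 free parameters); ties within 1e-6 are
split fractionally between the tied models, since no published rule
exists. Participants with an MSD `d_A > 10` in either condition are
excluded listwise from paired and correlational MSD analyses.

Aggregate-level fits pool counts across participants within a condition
before fitting.

## ROC analysis

Empirical ROC point k is the proportion of ratings strictly above k for
old (hit) and new (false alarm) items, k = 1…5. Cumulative proportions
of exactly 0 or 1 are replaced by `1/(2N)` and `1 − 1/(2N)` so the
probit transform is defined (flagged with a warning). The z-ROC slope
is the ordinary least-squares line of `z(hit)` on `z(fa)` — the
convention under which the literature's 0.8 value equals `1/σ_o`.

## Synthetic experiments

The generator reproduces the statistical structure of three
within-subject encoding-variability manipulations:

1. **Study duration** — fixed 3,000 ms vs. durations drawn from
   N(3000, 1100) ms truncated to [500, 5500] with (a) the sum
   constrained to the fixed-condition total (390,000 ms over 130
   trials) and (b) composite Kolmogorov–Smirnov and Anderson–Darling
   normality checks (both p > .05 against a normal with
   sample-estimated mean/SD; the composite form matches how the
   checks are reported with sample df). Sum enforcement
   rejection-samples a candidate set, spreads the deficit additively
   with re-clipping, applies an exact residual correction to the value
   with the most slack, re-tests, and retries with a fresh sub-seed
   (up to 1,000 attempts). A zero-SD spec degenerates to constant
   durations with the normality check skipped.
2. **Attention (one-back task)** — inter-digit intervals: fixed
   3,500 ms (synchronised with trials) vs. N(3500, 1100) ms on
   [1000, 6000] summing to 455,000 ms. Digit onsets are cumulative
   interval sums from session start; trial i owns the half-open window
   `(i·L, (i+1)·L]`, so the synchronised condition yields exactly one
   digit per trial and onsets landing on a boundary belong to the
   earlier trial. The per-trial digit count (0–3) is the attentional
   covariate; the one-back response process itself is not modelled.
3. **Word frequency** — Zipf scores (`log10(per-million) + 3`): low
   variance (mean 3.48, bounds 3.41–3.59; parent SD 0.05, roughly half
   the bound half-width, since only mean and bounds are reported for
   these sets) vs. high variance (mean 3.5, SD 1, bounds 1.17–5.84,
   truncated-normal shaped, KS/AD-checked). For the high-variance sets
   the reported SD is the *realised* SD inside bounds of ±2.3 SD, so
   the sampler solves for the parent SD whose truncated distribution
   has the requested SD (a parent SD of 1 truncated there would realise
   ≈ 0.935). New items carry a matched frequency distribution, as in
   the experimental design.

Under the encoding-variability construction an old item's strength is
`B + Y` with `B ~ N(μ_B, σ_B)`, `Y ~ N(μ_Y, σ_Y)` and correlation ρ,
giving old-item variance `σ_B² + σ_Y² + 2ρσ_Yσ_B`; new items are
baseline-only draws. Cohorts draw each participant's parameters once
from normal population distributions (defaults: the fixed/low-variance
condition means and SDs of the participant-level fits, e.g.
σ_o = 1.47 ± 0.41), truncated to valid ranges (σ_o ≥ 0.1, R/λ clipped
to [0, 1], criteria re-sorted with 1e-3 minimum gaps) and reused in
both conditions — a null cohort, since the empirical manipulations did
not move the parameters. The covariate set is frozen per condition
(one sample serves all participants, as in the experiments) and its
assignment to trials is shuffled per participant, since trial order
was randomised per participant.

Covariates influence strength through a centred link added to the
old-item mean. The duration link is saturating,
`gain · (1 − exp(−t/τ))` with τ = 1,500 ms, reflecting the negatively
accelerated relation between study time and accuracy; the word-
frequency link is linear. The gains are calibrated by simulation
(10 cohorts × 40 participants) to the observed weak covariate–rating
correlations: gain 0.8 gives a mean per-participant duration–rating
r ≈ .05, slope −0.155 gives a Zipf–rating r ≈ −.10. The cohort-to-
cohort SD of those mean correlations is ~0.02, so single-cohort checks
use a ±0.03 tolerance.

What the generator does *not* emulate: serial-position and fatigue
effects, counterbalancing order effects, the retention-interval task,
response times, and any participant-level violation of the generating
model family. Passing tests therefore show that the pipeline recovers
what it assumes — they cannot certify the models against real data.

## Recovery harnesses

Parameter recovery simulates N replicate experiments from a known
parameter set, refits, and reports per-parameter bias and RMSE
(excluding fit failures and, optionally, boundary/outlier fits). At
130 + 130 trials the UVSD σ_o bias is ≲ 0.02 for generating σ_o in
[1.0, 1.5] (RMSE ≈ 0.13–0.18 over 200 replicates).

Model recovery cross-fits all three models to data from each generator
and tallies the G² winner into a 3 × 3 confusion matrix (fractional
ties). Two generator triples are provided. `default_generators()` uses
the cohort means — empirically plausible, but at 260 trials the UVSD
and MSD models are then nearly equivalent: the asymptotic G² separation
between UVSD(d ≈ 1.3, σ_o ≈ 1.5) and its best mixture approximation is
only ~0.2 per experiment, far below sampling noise, so the UVSD row of
the matrix is close to a coin flip (consistent with the mixed best-fit
percentages seen on real data). `separable_generators()` raises the
UVSD generator to σ_o = 1.75 — still well inside the observed
participant distribution — chosen as the smallest σ_o whose asymptotic
G² gap (~1.5 per experiment) exceeds sampling noise; there the
confusion matrix is diagonally dominant and the suite asserts it. At
the exact EVSD coincidence (σ_o = 1) no model can win reliably, but the
winner shares are *not* uniform: the DPSD and MSD boundary parameters
(R = 0, λ = 1) remove one direction of noise-chasing flexibility in
about half the samples, while σ_o = 1 is interior for UVSD, which
therefore wins a plurality. The test asserts only that every model
keeps a substantial share.

## Statistics

Paired t tests are two-sided with df = n − 1, a 95% CI on the mean
difference and Cohen's `d_z = mean(diff)/sd(diff)`. The Wilcoxon
statistic is V, the sum of positive-difference ranks (zero differences
dropped; exact p for n ≤ 25 without ties, normal approximation above).
Pearson correlations report df = n − 2 and a Fisher-z 95% CI. The
2 × 2 within-subjects ANOVA is computed by direct sums-of-squares
decomposition with each effect tested against its own effect-by-subject
interaction, F(1, n − 1), and partial eta squared
`SS_effect/(SS_effect + SS_error)`; for a two-level factor the
main-effect F equals the squared paired t on the marginal means
(asserted to 1e-8).

The JZS Bayes factor integrates the noncentral-t likelihood over a
Cauchy(0, r) prior on the standardised effect size
(`BF10 = ∫ f_nct(t; δ√n, ν) Cauchy(δ; r) dδ / f_t(t; ν)`), by adaptive
quadrature with an explicit error check. The default scale
`r = √2/2` is the conventional "medium" prior; with it the fixture
t(39) = 3.54 gives BF10 ≈ 29.15 (reported: 29.10 — the software
version behind the published value and hence its exact prior scale is
unknown, so BF agreement is checked to ~10%).

## Numerical choices and problem sizes

* Probability floor 1e-10 (see above); category probabilities are
  clipped at 0 and renormalized to absorb ~1e-17 cancellation error.
* Degenerate ROC proportions replaced by `1/(2N)`.
* Ties in model comparison split fractionally at 1e-6.
* Monte-Carlo equivalence tests use 1e6 samples per class and a 3-SE
  band per cell; variance identities use 1e6 draws with an absolute
  0.02 tolerance.
* The recovery suites run 200 replicates (parameter recovery) and
  100 replicates per row (model recovery) at 130 + 130 trials with
  5 optimizer starts per fit; the EVSD-coincidence check runs 150
  replicates with 3 starts. These sizes put the simulation SE well
  below every asserted tolerance.
* Type-I error of the paired t test is checked on 2,000 null
  simulations at n = 40 (band [0.03, 0.07]).

## Known limitations

* The MSD `d_A` blow-up is handled by bounding at 25 and flagging, not
  by reparameterisation; the flagged fits are excluded rather than
  interpreted.
* `old_item_variance` is undefined for DPSD by design (unspecified
  recollection distribution).
* Aggregate ROCs pool counts rather than averaging proportions; with
  heterogeneous participants the two differ.
* The Wilcoxon exact path requires untied absolute differences;
  continuous data make ties measure-zero, but heavily rounded inputs
  fall back to the normal approximation.
* No hierarchical/Bayesian fitting and no AIC/BIC (the three models
  share a parameter count, so raw G² comparison is the intended rule).
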