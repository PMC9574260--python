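# Methods

## Task and data model

Each 8000 ms trial shows a fixation point (0–1000 ms absolute), then two
pictures — target and distractor — from 1000 to 7000 ms while a sentence
plays. All analyses run on *relative* time (0 = picture onset): the verb
starts at 2000 ms, the noun at 4000 ms, picture offset is 6000 ms. The two
areas of interest are the screen halves of a 1920×1080 reference display
(960×1080 boxes centred at 480×540 and 1440×540), rescaled to each
participant's screen by independent width and height factors applied to box
size and centre alike; a 1600×1200 screen therefore carries 800×1200 boxes
centred at 400×600 and 1200×600.

Each participant's session holds 28 trials — 7 closely related verb (CV),
7 moderately related (MV), 14 unrelated (UV) — drawn from a 56-sentence
inventory (14 CV, 14 MV, 28 UV). UV sentences reuse the image pairs of the
predictive items, so the design splits the predictive items into two
complementary halves across four counterbalancing orders: the half heard
predictively and the half heard as UV alternate, every image pair appears
exactly once per participant, and all 56 sentences are used across the
rotation. Target side is balanced 14 left / 14 right by a seeded RNG; side
counterbalancing is an assumption of this implementation, not a documented
property of the original procedure.

## Synthetic gaze generator

The generator emulates a webcam eye-tracker: irregular timestamps (period
jittered around 16.7 ms, sd 2.5 ms), isotropic Gaussian positional noise
(default sd 100 px), a probability `off_aoi_p` (default 0.08) of looking
outside both AOIs, and missing runs that start with per-sample probability
`gap_rate` (default 0.01) and have geometric length with mean `gap_mean_ms`
(default 80 ms).

The target-fixation probability follows a logistic time course

    p(t) = baseline + (asymptote − baseline) / (1 + exp(−(t − c)/s)),

with crossover `c = crossover_ms + onset_shift_ms` and scale `s`
(default 300 ms) on relative time. Chance is 0.5 before the disambiguating
word. Group × condition defaults encode the qualitative profiles the task
is designed around: adults and TD children anticipate in CV and MV (CV
earlier/stronger), the DS profile anticipates in CV only and 200 ms later
than TD, and every UV curve has its crossover anchored after noun onset
(4000 ms). The published record motivates the orderings and the 200 ms
delay; curve amplitudes are unpublished, so the asymptotes (0.72–0.80) were
chosen once as realistic for a two-alternative display and are not tuned to
any table. Per-subject Gaussian effects on the crossover (sd 150 ms) and on
the logit asymptote (sd 0.3), shared across conditions, supply the
between-subject variance the mixed models assume. One seed sequence is
split per subject, so cohorts are reproducible under subsetting.

What the generator does *not* model: saccade dynamics, pupil data,
calibration drift, item-level variation in effect size (association
strength modulates nothing beyond the condition split), and any dependence
of gaze on sentence content beyond the three-condition logistic profile.
Passing calibration tests on this generator therefore show that the
*pipeline* is correct and calibrated for data with this covariance
structure, not that any substantive claim about real populations holds.

## Preprocessing

Fixed order: smoothing → interpolation/resampling → AOI coding → binning →
exclusion.

- **Smoothing.** Gaussian kernel, σ = 5 interpreted in samples at the
  native rate (the unit is not documented in the original description;
  a millisecond interpretation can be configured via the sample period).
  The kernel is truncated at 4σ and renormalised over valid neighbours, so
  missing samples stay missing and gaps neither shrink nor receive values.
  Smoothing precedes interpolation, following the documented processing
  order; because it is gap-aware it cannot bridge runs that the
  interpolation rule will refuse.
- **Interpolation/resampling.** Linear interpolation onto a 20 ms grid
  (multiples of the period in relative time). Grid points strictly inside a
  run between valid samples spaced more than 150 ms apart stay missing; a
  run of exactly 150 ms is interpolated (strict inequality). No
  extrapolation beyond the first/last valid sample.
- **AOI coding.** A grid point scores 1 for the AOI containing it, else 0;
  box edges are half-open (left/top inside) so ties are deterministic.
  Overlapping boxes are a configuration error.
- **Binning.** Half-open 100 ms bins; per bin F = target hits, N = target +
  distractor hits. N counts only AOI samples — not all valid samples — so
  that chance level of p = F/N is exactly 0.5 in a two-AOI display;
  off-AOI looks reduce N. (The original wording is ambiguous on this point;
  this choice is flagged because it changes what p measures.)
- **Exclusion.** A trial is dropped when its looking fraction — AOI samples
  in [0, 6000) over the 300 grid slots the window holds at 20 ms — is
  strictly below 25%.

A consequence of smoothing positions *before* AOI coding is worth noting:
when the eye alternates between the two picture centres, the smoothed
position approaches the screen midline and the coded series behaves like a
local majority vote over the kernel span. Under the null this is symmetric
(chance stays 0.5); under signal it sharpens binned curves relative to the
generating logistic. Parameter-recovery tests therefore check ordering and
sign of recovered parameters, not amplitude equality.

## Growth curve analysis

Bins inside the analysis window (default 4000–6000 ms relative, the printed
window; the surrounding text suggests the verb onset at 2000 ms, so the
window is configurable) are modelled on the empirical log-odds scale
log((F + c)/(N − F + c)), with boundary correction c = 0.5 by default
(c = 0 reproduces the uncorrected log F/(N−F)). Time is carried by
orthonormal polynomial contrasts of degrees 1–3 (QR of the monomial basis;
columns sum to zero, unit norm, deterministic sign). Fixed effects are all
time terms × condition (× group when two groups are present), treatment
coded with UV and TD as references.

Estimation uses statsmodels MixedLM with subject time-slope random effects
and an item variance component, as a reproducible stand-in for a
penalised-quasi-likelihood binomial fit. Two approximations are documented
rather than hidden: (1) MixedLM accepts no observation weights, so per-bin
N weighting is exact only in the final no-random-effects rung (weighted
least squares); at 50 Hz with 100 ms bins N ≤ 5 and nearly constant, so the
weighting is almost flat. (2) MixedLM supports one grouping factor, so item
intercepts enter as a variance component nested in subjects rather than
crossed with them. When a structure fails to converge, a deterministic
ladder drops the cubic, quadratic, then linear subject slope, then all
slopes, then falls back to WLS; the structure used and the attempts are
reported. p-values use the residual-df t distribution (normal beyond
df 1000); df conventions differ across estimators and are not a comparison
surface. Bins with N = 0 are dropped, not imputed.

At the default generator settings the sign of the CV × group interaction in
the post-noun window is not determined by the design (both groups' CV
curves are saturated there and the contrast is dominated by the UV
crossover difference); tests assert the robust pattern only — positive
CV/MV main effects and a negative MV × group interaction.

## Cluster-mass permutation test

Subject-level curves (mean of per-trial p per 100 ms bin over [0, 6000))
are the exchangeable unit. Per bin: a paired t on subject differences
(CV or MV against UV) or a one-sample t against chance 0.5, with pairwise
deletion per bin; a bin with fewer than two complete subjects or zero
variance has no t and breaks cluster contiguity. Clusters are maximal
contiguous same-sign runs with |t| above the two-tailed α = 0.05 Student
critical value, df = n − 1 (≈2.09 at n = 21, ≈2.02 at n = 39); a literal
override is accepted for reproducing published critical values whatever
their df convention. Cluster mass is Σt over the run; both signs are kept
because effects in either direction are interpretable.

The permutation null swaps condition labels (equivalently, flips the sign
of the per-subject difference) for paired contrasts and flips the sign of
(curve − 0.5) for one-sample tests, records the maximum |mass| over all
clusters per iteration (100,000 by default; calibration suites use 2,000),
and assigns each observed cluster p = (1 + #{perm max ≥ |mass|}) /
(n_perm + 1) — the add-one estimator never returns exactly zero.
Because a sign flip leaves each subject's squared values unchanged, every
permutation's t series is a function of the sign-weighted sums alone, which
makes the null fully vectorisable. Exactness was checked against exhaustive
2^n enumeration at n = 3, and the empirical type-I rate on 500 null
cohorts (flat chance curves, 21 subjects) was 5.4%.

## Prediction-window models

Counts are summed per trial over the half-open window [2500, 4000) ms —
after the verb, before the noun; the half-open edge avoids double-counting
the 4000 ms bin against the growth-curve window. The reference model is a
binomial GLMM on F of N with logit link: condition fixed effects (UV
reference), condition slopes by subject, item intercepts — fit with
lme4::glmer through Rscript, since no frequentist GLMM exists in the Python
stack and glmer is the canonical estimator for this model. A deterministic
ladder simplifies the random structure on convergence failure, and a
cluster-robust binomial GLM backend is available where R is not.
Aggregated counts are likelihood-equivalent to per-sample binary responses
up to a constant, so the aggregated form is the default.

Candidate moderators — chronological age, mental age, production score
(per subject) and association strength (per item) — are min-max normalised
to [−0.5, 0.5] and enter one at a time as a main effect plus condition
interactions. Judgement combines the likelihood-ratio statistic
(−2ΔlogLik) against χ²(df = 3: one main effect + two interaction dummies)
and the BIC-approximated Bayes factor exp((BIC_ref − BIC_ext)/2), read as
null support below 1/3 and alternative support above 3.

## Stimulus norming

Association strength is 100 × (matching responses)/(respondents) for a cue
word; matching case-folds and strips diacritics but does not lemmatise (a
pluggable matcher allows stricter or looser rules). The packaged item table
(28 image pairs × target/distractor × predictive/unrelated strengths, in
percent) drives the condition contrasts: tie-corrected Kruskal–Wallis
across conditions and Mann–Whitney post-hocs whose continuity and
tie-correction flags both default to on — the convention that reproduces
the published CV-vs-MV z to three decimals, and the distractor-strength H
exactly. The published target-strength H and MV-vs-UV z are not
reproducible from the item table under any single correction convention
(they may have been computed respondent-level); they are treated as soft
cross-checks, not assertions.

## Problem sizes and numerical choices

Calibration suites run at the sizes the design implies — 21 subjects × 28
trials per cohort — with 500 replicates at 2,000 permutations for the
type-I rate and 100 replicates for the prediction-window pattern recovery;
the acceptance script reports the same quantities at 150 and 40 replicates
respectively. Variances below 1e-24 make a t statistic undefined rather
than infinite. The exact-enumeration oracle is only feasible for n ≤ ~10
subjects and is run at n = 3. All randomness flows from explicit seeds;
cluster permutations are drawn in chunks of 20,000 to bound memory.

## Known limitations

- The growth-curve estimator is a weighted/unweighted LMM on empirical
  log-odds, not a quasi-binomial fit; coefficient scales are comparable but
  not identical to PQL output, and its item effects are nested, not
  crossed.
- The generator's missing-data process is stationary; real webcam data show
  drift and blocks of loss correlated with posture and lighting.
- Exclusion rates at the default gap parameters are near zero; raising
  `gap_rate`/`gap_mean_ms` exercises the exclusion rule.
- One-sample tests against chance assume no persistent subject-level side
  or target preference under the null; the generator's subject asymptote
  effects violate this by design (they model real heterogeneity), so
  type-I calibration uses the paired contrast.
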