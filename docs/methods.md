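# Methods

## Model

The analysis object is a first-order multilevel vector autoregression
over k = 7 momentary variables. For subject i, outcome j and beep t,

    y_ij(t) = b_0j + u_ij + Σ_k B[j,k] x̃_ik(t−1) + e_ij(t),

estimated nodewise: each outcome gets its own mixed-effects regression on
all k lagged predictors with a per-subject random intercept u_ij.
Predictors are centered on the subject's own mean over the included lag
pairs (within-person centering), so B captures within-subject temporal
coupling, not trait-level differences. Lag-1 pairs are formed only
between consecutive beeps within the same day — overnight intervals
violate the equal-spacing premise of a lag-1 model, and the generator
restarts each day's latent series from the stationary distribution for
the same reason. Variables are z-standardized per group (after the
nonparanormal transform) before fitting so coefficients are comparable
across edges; the network edges are therefore standardized lagged
regression coefficients.

Assumptions: stationarity of each series (screened, below), monotone
marginal distortions (handled by the transform), missingness unrelated to
the process (the generator's MCAR matches this), and subjects independent.

## Estimator

The default backend uses a closed-form identity: when every predictor
column sums to zero within each subject, the GLS fixed-effect slopes of
the random-intercept model are invariant to the intercept-variance ratio
and equal pooled least squares on the centered predictors, with slope
covariance σ_e²(Xcᵀ Xc)⁻¹. σ_e² is estimated from the within-subject
residual sum of squares on n − S − k degrees of freedom (n pairs, S
subjects, k predictors); p-values are two-sided t. The test suite checks
this backend against statsmodels `MixedLM` (REML), which agrees to
machine precision on the slopes; `backend="mixedlm"` is also available
directly and adds optional *uncorrelated* random slopes — the
full correlated random-effects VAR is deliberately out of reach at k = 7,
matching standard practice for networks of this size.

Two consequences of the closed form matter:

- **Speed.** A permutation refit only re-aggregates per-subject
  cross-products and solves k small systems, so 10⁵ refits are feasible.
  Standardization per permuted group is applied as the exact rescaling
  B_std[j,k] = B_raw[j,k]·s_k/s_j with group SDs recomputed from the
  permuted membership; the tests verify this equals fitting on z-scored
  data through the ordinary path.
- **Known finite-T attenuation.** Centering lagged predictors on the
  subject's own mean biases autoregressive estimates downward by roughly
  (1+3ρ)/T (T ≈ 49 pairs/subject here, i.e. ≈ −0.02 to −0.04 on the
  diagonal). This is a property of the within-person-centered estimator
  family itself, not of this implementation; recovery tests therefore
  evaluate estimates averaged over replicate simulated datasets, so that
  Monte-Carlo noise is not stacked on top of the attenuation, and the
  combined error stays inside the stated 0.05 band. Group *comparisons*
  are unaffected (both groups attenuate equally).

## Nonparanormal transformation

Each variable is mapped through its truncated empirical CDF to
standard-normal quantiles (ranks with ties averaged, scaled by 1/n,
Winsorized at δ_n = 1/(4 n^{1/4} √(π log n)), then Φ⁻¹). The transform is
fitted per group over pooled observations (a per-subject option exists);
missing values pass through untouched. Rank preservation is strict except
at the Winsorized tails, where the extreme order statistics tie by
construction — the brute-force oracle in the tests reproduces this
exactly. Physical activity is transformed like every other variable.

## Stationarity screens

*Inertia*: per variable and group, a two-level AR(1) (random intercept,
day-respecting lags) whose fixed-effect coefficient is the
moment-to-moment inertia; > 1 flags nonstationarity outright and > 0.9 a
borderline warning band (a unit root estimated with this estimator's
attenuation lands near 0.9, hence the band). *KPSS*: level-stationarity
test per (subject, variable) on the non-missing sequence, constant-only
null, automatic lag truncation, α = .05; series shorter than 10 points or
constant are skipped and counted. At 56-beep lengths the battery retains
only moderate power against random walks (~70% rejection), which the
acceptance checks reflect.

## Permutation comparison

The two stages are independent samples, so the exchangeable unit is the
subject. Each permutation reassigns whole subjects (group sizes
preserved, series intact), refits both networks with the observed
estimator settings, and records raw differences (group 1 − group 2) of:
all k² edges, 2k strengths, and overall connectivity. Two-sided p-values
use the add-one rule p = (1 + #{|d*| ≥ |d|})/(1 + n_perm); for small
groups `exhaustive=True` enumerates all splits and returns exact
proportions. Defaults: 2,000 permutations (a `--full` CLI flag runs
100,000); failed refits (singular pooled design) are redrawn and counted,
with an error above a 5% failure rate. The rank gaussianization is fitted
once on the observed grouping and held fixed across permutations:
refitting it per relabeling would change values only through the tail
Winsorization while multiplying cost a hundredfold. Uncorrected p-values
are reported (an FDR column can be added downstream); the many-comparisons
caveat transfers to interpretation.

Strength centrality uses absolute edge weights with self-loops excluded
(signed and self-loop-including variants are flags); overall connectivity
is Σ|B| with self-loops included by default. These conventions are
declared, not derived — networks carry negative edges and signed sums
would let edges cancel.

## Synthetic data

The generator emulates the study design: two groups of 130 subjects
(configurable), 7 days × 8 beeps randomized uniformly within 105-minute
blocks between 08:00 and 22:00 (whole-second resolution), ~17.5% of
prompts missed completely at random with a per-subject cap of 50%
(redrawn otherwise), and a thin independent dropout (0.8%) of the
activity value emulating nonwear exclusion. Generating networks draw
autoregressions uniform on (0.13, 0.37) — the inertia range typical of
momentary items — and off-diagonal edges Bernoulli(sparsity) with
magnitudes 0.05–0.15 and random signs, rescaled below a spectral cap of
0.9; a group difference is injected as an exact single-edge offset, with
redraws if it breaks the cap. Subject heterogeneity: entrywise-normal
coefficient noise (SD 0.05, resampled until stationary) and latent trait
means with SD 1 (one innovation SD), i.e. an intraclass correlation near
0.5, typical of EMA items. Observed scales come from strictly monotone
maps: logistic into (0, 100) for the five visual-analog items, empirical
septile discretization for the 7-point social-contact item, and
exponentiation (exp(3.5 + 0.35 z), median ≈ 33 mg) for physical activity
— chosen precisely to create the nonnormal marginals the nonparanormal
transform exists to undo.

Raw accelerometry: rest segments place 1 g along a random orientation
re-drawn every 2 minutes plus 5 mg noise (so wear windows never mimic
stillness); activity segments add 0.5–3 Hz sinusoidal bursts of 50–300 mg;
nonwear segments hold one orientation with 2 mg noise clipped at 4σ,
below the detector's thresholds by construction. The generator does not
emulate: autocorrelated missingness (bursty missed prompts), response-time
behavior, device calibration error, seasonal or time-of-day effects, or
floor/ceiling clumping beyond what the logistic map induces — passing
tests therefore certify the pipeline's statistical machinery under the
model's own assumptions, not robustness to every artifact of field data.

## Actigraphy defaults

ENMO per sample = √(x²+y²+z²) − 1000 mg, negatives truncated to zero
(configurable), averaged in 5 s epochs. Nonwear: 60-minute windows in
15-minute steps; an axis is "still" when its SD < 13 mg *and* its range
< 50 mg; the window score counts still axes and windows scoring above 1
are excluded. Pre-beep activity is the mean ENMO over [t − 3600 s, t)
restricted to wear epochs, returned missing when wear coverage is below
50% (a coverage rule prevents one-epoch "hours"). Exclusion operates at
the beep-window level. Inputs are assumed calibrated in milligravity;
device autocalibration is out of scope.

## Problem sizes and determinism

Default analyses: 130 subjects/group and 2,000 permutations. The test
suite's simulation studies use 20–60 subjects/group, 200 permutations and
100–200 replicate datasets; the acceptance script uses 1,000 permutations
for the cohort analysis and 5–100 replicates for the validation battery —
sizes chosen so the full battery runs in minutes on one core while
keeping Monte-Carlo error well inside the asserted bands. All randomness
flows from explicit integer seeds through numpy Generators; identical
configuration and seed reproduce byte-identical artifacts, which the
suite asserts at the pipeline level.

## Known limitations

- Edges are standardized lagged regression coefficients; "partial
  correlation" readings of such networks differ by a scale factor per
  node pair.
- The within-person-centering attenuation above affects absolute
  autoregression estimates at short series lengths.
- MCAR missingness and the subject-level permutation scheme assume
  missingness and group assignment are unrelated to the process; neither
  a paired/within-subject permutation scheme nor studentized permutation
  statistics are implemented.
- KPSS decisions at 56 points are low-powered; the battery's proportion
  is a screen, not a test of the model.
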