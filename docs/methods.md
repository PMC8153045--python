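# Methods

This note documents the models, conventions and numerical choices behind
`entroprint`, and what the synthetic cohort does and does not emulate.

## Dispersion entropy

Dispersion entropy summarises the symbolic dynamics of a univariate signal.
Each sample is mapped through the normal CDF parameterised by the signal's
own mean and standard deviation, θᵢ = Φ((sᵢ − M)/D), and quantised into one
of `c` classes, zᵢ = round(c·θᵢ + 0.5); consecutive labels are embedded into
length-`m` patterns with within-pattern spacing `τ` (pattern start indices
always advance by one sample), and EN = −Σ pₖ ln pₖ over the empirical
pattern distribution. Defaults are c = 3, m = 2, τ = 1; the natural
logarithm is used throughout, so EN ∈ [0, ln cᵐ] (ln 9 ≈ 2.197 at the
defaults). The upper bound is attained when all patterns are equiprobable
(white noise); a periodic signal approaches the lower bound.

Conventions that the tests pin down:

* **Standard deviation**: population convention (divide by *n*). The class
  labels are invariant under positive affine transforms of the signal either
  way, because M and D rescale with it.
* **Rounding**: round half away from zero, with labels clamped to [1, c] to
  guard the θ → 1 float edge.
* **Degenerate input**: a constant signal (D = 0) is a hard error, never a
  silent zero.
* **Implementation**: the label of a sample only depends on which of the
  c − 1 fixed boundaries Φ⁻¹(k/c) its normalised value crosses, so the
  production path compares against precomputed boundaries instead of
  evaluating the CDF per sample; a single-pass compiled kernel (numba, with
  a numpy fallback) handles the tens of thousands of subject × run × ROI
  signals of a cohort. Equality with an explicit census oracle to 1e-12 is
  enforced in the tests.

**Run handling.** Entropy is computed per run and averaged over the two runs
of a session; the "two-day" profile used for prediction is the mean of the
two session matrices. Whether one should instead concatenate runs is not
determinable from the study design we mirror; concatenation is available via
`run_aggregation="concatenate"`, and a rank-stability check (Spearman
correlation of group-mean profiles across (c, m, τ) settings) verifies that
the spatial ordering of ROIs is insensitive to the parameter choice.

## Fingerprint identification and differentiation power

Identification predicts target subject *i* as the database subject *j*
maximising the Pearson correlation of their profiles. Ties (measure zero on
real data) break towards the lowest database index with a warning. The
permutation null shuffles the target identities (500 permutations with each
day as database, pooled to 1000); each direction's observed accuracy is
compared against the pooled null with `P = #{null ≥ observed}/1000`.
Bootstrap CIs resample target subjects. Accuracy above the conventional
60 % criterion counts as satisfactory; significance alone does not (the
null rarely exceeds a few percent accuracy).

Differentiation power z-scores each profile across ROIs (per subject — the
convention implied by decomposing the Pearson correlation into element-wise
products of z-scored vectors), forms φᵢⱼ(n) = zENᵢ^d1(n)·zENⱼ^d2(n), counts
how often cross-subject products beat the within-subject product, and
reports DP(n) = −ln(meanᵢ Pᵢ(n)). The mean (rather than sum) inside the log
only shifts DP by the constant ln N, so rankings are unchanged; when the
mean probability is exactly zero it is replaced by ε = 1/(2N(N−1)), the
smallest attainable nonzero value.

## Reliability screening

Per-ROI test–retest reliability is the across-subject Pearson correlation
between the two days. The entropy null is built by temporally shuffling
each first-session run once per subject × ROI (more repetitions are
configurable), computing entropy through the same run-averaging path. The
thresholds are the 5th percentiles (linear interpolation between order
statistics) of the per-ROI reliability distribution and the permuted null;
an ROI is flagged only when it fails *both* (low reliability AND
ceiling-level entropy). The grand-mean entropy uses both days while the
null uses day 1 only — an asymmetry kept deliberately from the procedure we
mirror. Flagged ROIs are excluded from all reliable-profile analyses.

## Ridge / LOFOV prediction

The linear model Y = bX + k is fitted in closed form,
b̃ = (XᵀX + λI)⁻¹XᵀY, on data centred and z-scored *within each training
fold* (leakage hygiene; the alternative of one global z-scoring would mix
test information into training). λ = 0 reduces exactly to OLS and raises a
clear error on collinear designs. Folds are families: all siblings are held
out together. The outcome is z-scored on the training fold and predictions
are mapped back through the fold's mean/sd; the intercept is handled by
centring. λ is selected from a logarithmic grid (10⁻² … 10⁵ by default) as
the maximiser of the LOFOV observed-predicted correlation — the same
quantity that is reported, a mild optimism that is documented rather than
corrected, since it mirrors the procedure under study. A negative
correlation is clamped to zero. Significance uses the t transform
t = r√((n−2)/(1−r²)); CIs are 1000-replicate percentile bootstraps over
subjects. Per-ROI importance is the mean |weight| across folds (weights are
comparable because predictors are z-scored). Optional univariate feature
screening (train-fold Pearson p < p_th) exists but is off by default.
Per-network predictions repeat the fit on each network's retained ROIs and
are BH-FDR corrected across the full network × outcome family; networks
left with fewer than 2 ROIs after screening are skipped with a warning.

## Structural analyses

Directed connective probabilities are symmetrised by reciprocal averaging,
w_ij = (p_ij + p_ji)/2, and thresholded at 0.001 (configurable; the default
retains roughly 10 % of links in the synthetic networks). Strength is the
row sum, degree the suprathreshold link count; reprocessing a processed
matrix is a no-op.

Blueprint correlations relate the group-mean entropy profile to each
property's group-mean profile across retained ROIs; bootstrap CIs resample
ROIs (the observation unit of that correlation), and cross-individual
analyses resample subjects. The structure → entropy prediction uses one
property at a time — a simple per-ROI univariate OLS under the same LOFOV
folds — because the per-property specificity comparison is the scientific
point; ROIs whose regressor is constant in a training fold fall back to the
training-mean prediction with a warning. Predicted profiles are scored two
ways: per-subject similarity (Pearson over ROIs) and identification with
the predictions as database. Similarity is driven by *blueprint* coupling —
any property that tracks the shared spatial profile reconstructs every
subject's profile shape about equally well — whereas identification
specificity requires *individual-deviation* coupling. This dissociation is
exercised explicitly in the acceptance suite.

## Statistical primitives

Pearson p-values use the exact t transform with n − 2 degrees of freedom
(scipy's implementation); |r| = 1 is reported as p = 0. Confidence
intervals are percentile bootstraps (the simplest defensible reading of
"1000 bootstrap samples"); a resample on which the statistic fails is
redrawn with a warning. Identification-accuracy bootstraps resample target
subjects. Multiple testing uses Benjamini–Hochberg step-up via statsmodels.

## The synthetic cohort

The generator emulates the *statistical* structure of a two-session,
two-run, family-structured resting-state cohort; it makes no attempt at
hemodynamics, spatial smoothness, motion artefacts or imaging formats.

Per subject *i* and ROI *n*, a latent irregularity
a_{i,n} = blueprint_sd·A_n + Σ_p ic_p·dev_{i,n,p} + subject_sd·ξ_{i,n}
combines a shared blueprint A_n (itself a weighted sum of six structural
property blueprints with configurable couplings bc_p, z-scored so couplings
read as correlations) with stable individual deviations. Each deviation
field is low-rank + noise: six shared spatial modes carry 80 % of its
variance, with per-property bases and partial sibling sharing (50 %). This
reflects that individual differences in real cortical maps are dominated by
a few global and network-level modes rather than ROI-independent noise —
and it is what makes the planted cognitive signal recoverable near its
theoretical ceiling by a ridge model at n ≈ 300. The per-property bases are
deliberately *not* shared across properties, so a property with zero
individual coupling carries no systematic individual entropy signal — the
premise of the blueprint/fingerprint dissociation.

Session-level jitter (sd 0.25) perturbs a, and the AR(1) coefficient is
φ = 0.95·σ(−a/1.5) ∈ (0, 0.95): higher irregularity ⇒ smaller φ ⇒ higher
entropy, monotone by construction and quasi-linear over the operating range
(φ roughly 0.2–0.75), keeping planted couplings approximately equal to
measured correlations. Time series are stationary AR(1) with unit-variance
innovations, fresh per run. Five percent of ROIs (placed in the limbic-like
network, overflowing to the salience network) are pure white noise with no
subject effect: they sit within 0.05 nats of the ln 9 ceiling with
near-zero reliability, which is exactly what the screening rule targets.
The default scales (subject_sd 0.6 vs jitter 0.25) put per-ROI test–retest
reliability around 0.85 — a clean-data regime; real scanner noise would
push it lower without changing any qualitative behaviour.

Connectivity: a base weight matrix w⁰_ij = 0.001·exp(β(u_ij − u_q)) with
u_ij = conn_i + conn_j + pair jitter places exactly the top 10 % of pairs
above the 0.001 threshold; per-subject directed probabilities multiply w⁰
by node-level individual factors and log-normal directional noise. Strength
and degree blueprints both derive from the single connectivity propensity
and are therefore strongly correlated, as in real structural networks —
planted couplings on them combine through that correlation.

Cognition: each outcome is √R²·s + √(1−R²)·noise with s a sparse
(20 % of ROIs) weighting of the structured component of the stable subject
residual, standardised empirically so R² is the population value; the noise
shares 30 % of its variance within families. Family sizes are drawn from
(0.55, 0.30, 0.15) over sizes 1–3.

**What passing tests do and do not show.** The generator provides exact
ground truth, so the tests demonstrate that every stage recovers what was
planted under known conditions — estimator correctness, fold hygiene,
screening sensitivity, the dissociation logic, determinism. They do not
demonstrate robustness to physiological confounds, preprocessing choices or
non-AR temporal structure, and absolute numbers (identification accuracy
near 100 %, reliability ≈ 0.85) are cleaner than real data would give.

## Problem sizes and determinism

Simulation sizes in the test and acceptance suites (e.g. 200 subjects ×
100 ROIs for screening, 20 cohorts of 300 subjects for prediction recovery,
1000-sample runs throughout) were chosen as the smallest scales at which
the targeted statistical properties are stable across seeds. One seed
drives every stochastic step of a pipeline run; reports serialise floats at
full precision with sorted keys, so identical config + seed reproduces
byte-identical JSON. On-disk cohorts round-trip exactly (text matrices at
17 significant digits; reading uses round-trip float parsing).

## Known limitations

* AR(1) is the minimal stationary process with a scalar irregularity knob;
  the generator interface is pluggable but no richer process ships.
* The entropy–φ transform is only approximately linear; planted couplings
  are recovered to ~±0.05 near the operating point, degrading toward the
  entropy ceiling.
* Multiscale or frequency-resolved entropy variants are out of scope, as is
  FC-profile fingerprinting.
* The λ-selection optimism noted above means reported prediction r is an
  upper-ish estimate; nested selection would cost another CV layer.
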