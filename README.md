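# entroprint

Individual cortical **entropy profiles** from resting-state fMRI: how
irregular is the BOLD signal in each parcel of a person's cortex, how stable
is that spatial pattern across scan days, what does it predict, and what
anatomy underlies it?

`entroprint` is a Python package for researchers in computational
neuroimaging and brain-dynamics biostatistics who work with parcellated
resting-state time series (e.g. HCP-style multi-session scans). It
implements an end-to-end analysis of per-subject entropy profiles —

1. **Dispersion entropy** of every ROI time series. A signal
   *S = s₁ … s_T* is quantised through the normal CDF fitted to its own mean
   *M* and standard deviation *D*,
   θᵢ = Φ((sᵢ − M)/D), zᵢ = round(c·θᵢ + 0.5) ∈ {1, …, c}, and embedded into
   dispersion patterns (zᵢ, z_{i+τ}, …, z_{i+(m−1)τ}); the entropy is the
   Shannon entropy of the empirical pattern distribution,
   EN = −Σₖ pₖ ln pₖ ∈ [0, ln cᵐ]   (defaults c = 3, m = 2, τ = 1).
2. **Fingerprint identification**: each subject's day-2 identity is
   predicted as argmaxⱼ corr(EN⃗ᵢ^d1, EN⃗ⱼ^d2) over the day-1 database, with
   a permutation null, bootstrap CIs, a fixed 60 % success criterion, and
   per-ROI **differentiation power** DP(n) = −ln(meanᵢ Pᵢ(n)).
3. **Reliability screening**: per-ROI test–retest correlation across
   subjects, the empirical entropy null of temporally permuted signals, and
   the conjunction rule (r below the 5th-percentile reliability threshold AND
   entropy above the 5th percentile of the permuted null) that flags
   noise-dominated ROIs.
4. **Cognition prediction**: closed-form ridge regression
   b̃ = (XᵀX + λI)⁻¹Xᵀy on z-scored reliable profiles under
   leave-one-family-out cross-validation (LOFOV; siblings never straddle
   train/test), with observed-vs-predicted correlation clamped at zero,
   per-network predictions, and BH-FDR correction.
5. **Structural basis**: connectivity matrix processing
   (w_ij = (p_ij + p_ji)/2, thresholded at 0.001; node strength and degree),
   cross-ROI *blueprint* correlations, cross-individual per-ROI
   correlations, and per-ROI OLS prediction of entropy profiles from one
   structural property, scored by per-subject similarity and by
   identification specificity — the dissociation that separates what shapes
   the shared profile from what makes it individual.

Because the source cohort is access-restricted, the package ships a fully
specified **synthetic cohort generator** with known ground truth (latent
irregularity, noise-ROI mask, planted couplings and weights) so that every
stage is testable end to end without any download.

## Worked example

```python
import entroprint as ep

cohort = ep.generate_cohort(ep.CohortConfig(n_subjects=150, n_rois=80, seed=7))
p1 = ep.entropy_profiles(cohort.timeseries, session="REST1")
p2 = ep.entropy_profiles(cohort.timeseries, session="REST2")

print(ep.FingerprintIdentification(p1, p2).fit(seed=0).summary())
fit = ep.CognitiveAbilityRidge(p1.averaged_with(p2), cohort.scores,
                               outcome="g").fit(seed=0)
print(fit.summary())
```

prints

```
Fingerprint identification
==========================================================
direction   accuracy    perm p              95% CI   pass
R1->R2        1.0000    0.0000      [1.000, 1.000]    yes
R2->R1        1.0000    0.0000      [1.000, 1.000]    yes
criterion: accuracy > 60%; null pooled over 1000 permutations

Ridge LOFOV prediction of 'g'
====================================================
subjects: 150   families (folds): 93   predictors: 80
accuracy r (clamped at 0): 0.4626   p = 2.52e-09   95% CI [0.343, 0.576]
selected lambda: 1000  (grid 0.01 ... 100000)
top ROIs by mean |weight|: R072 (0.033), R005 (0.033), R024 (0.032), ...
```

Every subject is re-identified from their day-2 profile (the synthetic
cohort's stable subject effects dominate its session jitter), and the
reliable entropy profile predicts the general cognitive factor *g* out of
sample at r ≈ 0.46 — close to the √R² ≈ 0.55 ceiling implied by the
generator's planted R² = 0.3, attenuated by estimation and measurement
noise. `fit.plot_predictions()` draws the observed-vs-predicted scatter.

The same analyses are available from the shell:

```bash
entroprint simulate --seed 7 --out data/
entroprint run-all --seed 7 --out reports/
```

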