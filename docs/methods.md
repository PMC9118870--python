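# Methods

This note documents the models, estimators and design choices behind
`restspectra`, the assumptions they rest on, and what the synthetic
validation does and does not demonstrate.

## Synthetic cohort generator

The generator emulates the *structure* of a multi-site resting-state
case–control study so every downstream stage can be validated against
known ground truth. Per subject it draws covariates and synthesizes a
multichannel recording; all randomness flows from one seed through
per-subject substreams (`numpy` `SeedSequence.spawn`), so cohorts are
bit-reproducible and invariant to generation order. A covariate-only
mode (`signals=False`) draws the same subject-level parameters without
synthesizing EEG, for calibration studies needing hundreds of cohorts.

Defaults (the emulated study conditions):

| parameter | default | meaning |
|---|---|---|
| recording | 8 × 30 s blocks, EO/EC alternating | 4 min total, 2 min per condition |
| channels | 61-label 10-10 montage (23-label reduced set for demos) | includes O1, O2, Oz, PO3, PO4, POz |
| age | uniform [6, 32] years | inclusion range |
| sex | 72% male | cohort margin |
| IQ | N(106, 14) truncated > 75 | inclusion rule IQ > 75 |
| sites | 3, cyclic assignment per group | every site holds both groups |
| background | 1/f^χ Gaussian noise, χ = 1, 8 µV RMS | inverse-FFT spectral shaping |
| alpha | 1 Hz-band filtered noise at f_p(age), 6 µV RMS EC | narrowband noise, not a sine, so envelopes are defined |
| f_p(age) | 8 + 0.1·(age − 6) Hz, capped at 11 | a positive age slope; the exact trajectory is a placeholder, not an empirical claim |
| reactivity | R = 0.45 + slope_group·(age − 19) + N(0, 0.1), clipped to [0.02, 0.95] | EO alpha amplitude = EC·√(1 − R) |
| group effects | mean shift `effect_mean` (in subject-SD units) and SD ratio `effect_variance_ratio` on log alpha power | ASD relative to NT |
| site offsets | ±0.15 on log power | additive site biases |

Each occipital channel receives an *independent* alpha realization of
equal amplitude: averaging the occipital spectrum then suppresses
envelope sampling noise, keeping the per-subject reactivity estimate
within a few hundredths of its target over 2 minutes per condition
(with one shared oscillator the Monte-Carlo error would be ~0.1).
Coupled channel pairs share a narrowband analytic signal; the second
channel is rotated by the requested phase lag and mixed with an
independent component to set the envelope correlation below 1. The
coupled component's amplitude scales with `snr` and can differ between
groups (`group_snr_delta`), injecting a group contrast on one link.

The generator deliberately omits volume conduction, ocular/muscle
artifacts, electrode drifts and head-geometry variability. Passing
tests therefore show the *pipeline machinery* is correct and calibrated
under its statistical assumptions — not that it is robust to real-world
artifact structure. The synthetic leadfield likewise uses an
infinite-homogeneous-medium dipole potential on a 1.5 cm
cubic-diamond-style grid (mirror-symmetric about x = 0, odd counts
completed with midline points), a stand-in for an MRI-derived forward
model whose only purpose is exercising the beamformer algebra.

## Preprocessing

The band-pass is an order-2000 Hamming-window FIR (1–32 Hz), applied
per resting-state block with 2 s of padding on each side (neighbouring
samples where available, reflection at recording edges). The kernel is
symmetric and applied with centred convolution, giving an exactly
zero-phase response: any phase handling that differed between
conditions or channels would bias the phase-based connectivity metrics
downstream. Resampling is polyphase with anti-alias filtering. Epochs
are 2.5 s, tiled from each block start, never crossing block
boundaries, dropped when they intersect an artifact-mask interval;
block tails shorter than one epoch are discarded.

Subject inclusion applies three criteria: ≥15 clean epochs per
condition; ≥51 usable channels and no contiguous patch of more than 3
bad neighbouring channels (operationalised as the largest connected
component of bad channels within 5 cm); and (good channels − artifact
ICs) ≥ 35. Independent-component artifact removal itself is a
human-in-the-loop step and enters only through the IC count. Bad
channels are repaired by spherical-spline interpolation.

## Spectral estimation

Welch spectra use 2.5 s Hann windows with 75% overlap (0.4 Hz
resolution, density scaling, so integrated power equals variance). The
wavelet grid is the 27-point dyadic sequence 2^(1+0.15k), k = 0…26; the
endpoint choice (last exponent 4.9 ≤ 5) is the only count consistent
with the feature-space identities 365×27×2 = 19,710 and
1225×27×2 = 66,150. Wavelets have Gaussian envelopes with
σ_t = 1/(2π σ_f), σ_f = f/4.88, window length 5σ_t, step 10% of the
window, windows dropped at epoch edges (no padding). Amplitude is
normalised so a unit sinusoid at centre frequency yields |coeff|² = 0.5;
at the lowest frequency (2 Hz) the window is 1.94 s and still fits a
2.5 s epoch. The 90% overlap is of the full 5σ_t window. Relative
power divides each space×condition spectrum by its unweighted sum over
the 27 grid points (a config choice; trapezoidal integration would
weight interior points differently), removing the depth-dependent
amplitude bias of beamformer estimates.

## Source projection

LCMV filters are built from the joint EO+EC sensor covariance with
diagonal loading of 5% of the mean trace. Per source the unit-gain
three-orientation filter is W = C⁻¹L(LᵀC⁻¹L)⁻¹; the retained
orientation is the dominant eigenvector of the source output-power
matrix (LᵀC⁻¹L)⁻¹ — the max-power convention — and the final scalar
filter satisfies wᵀLθ = 1. ROIs: k-means on folded coordinates
(|x|, y, z) yields 25 clusters, instantiated separately per hemisphere
(midline sources balance the two mirror ROIs of their cluster); ROI
adjacency requires at least one cross pair of sources within the grid
26-neighbourhood (≤1.5× spacing). Each ROI is summarised by the first
principal component of its member series, sign-fixed to correlate
positively with the member mean — PCA signs are otherwise arbitrary and
would break reproducibility.

## Connectivity

All metrics are computed from pooled epoch×window wavelet coefficients
per condition, except wPLI. wPLI = |mean Im X| / mean |Im X| over
cross-spectral samples X = c_i·conj(c_j); its unsigned form keeps values
in [0, 1], which the x^0.11 normalising transform presumes. Because
wPLI is positively biased at small sample sizes, subjects with
different amounts of clean data are made comparable by the subsampled
estimator: draw 15 epochs without replacement, compute wPLI, repeat 100
times, average. Orthogonalized power correlation removes the component
of one signal in phase with the other per sample
(y⊥ = Im(c_j conj(c_i))/|c_i|) and correlates log power with log
residual power, averaged over both directions; log (not raw) envelopes
are used for both orthPowCorr and PowCorr. Degenerate
orthogonalization (identical signals) returns exactly 0 — residual
power below a relative rounding-noise floor is clamped so numerical
noise cannot masquerade as correlation. A zero-lag common signal
(volume conduction) creates no spurious wPLI or iCOH between otherwise
independent channels, while inflating COH and PLV; this, not sample-level
invariance of wPLI (whose |Im| denominator does change), is the
robustness property the tests assert.

## Group statistics

Models 1–3 are fit by direct likelihood maximisation: for fixed
variance ratios λ = σ²_site/σ² and δ (ASD/NT residual SD ratio) the
per-site covariance is diagonal-plus-rank-one, so solves and
determinants use the Sherman–Morrison identity and β and σ² are
profiled out, leaving a 1–2 parameter Nelder–Mead search with warm
starts (model 2 starts at model 1's variance ratio, model 3 at model
2's with δ = 1), which also enforces the likelihood nesting
ll₁ ≤ ll₂ ≤ ll₃ numerically. Age and IQ are z-scored, sex coded M = 0.
The implementation agrees with an independent mixed-model fitter to
~1e-5 in log-likelihood on models 1–2 (test suite); model 3 has no
off-the-shelf single-call equivalent, which is why the likelihood is
authored here. The χ² reference distributions are used as stated for
the LLR tests; their anticonservativeness at small n is real (the
variance test's null 95th percentile is ≈5.2 at n = 120 but ≈3.6–3.9 at
n = 400) and is mitigated by confirmatory REML F tests with
between-within denominator degrees of freedom (n − n_sites − (p − 1)).
Transform selection standardizes each candidate's output and picks the
largest Kolmogorov–Smirnov p against the standard normal. The x⁴
reactivity transform is applied to raw R including negatives, as
specified upstream, with a warning: it destroys sign information for
R < 0.

## Cluster-based permutation correction

Features form a graph: spatial neighbours at the same frequency,
consecutive grid frequencies at the same space, no edges across
conditions. For links, (a,b) and (a,c) are neighbours iff ROIs b and c
are adjacent. Clusters are connected components of nodes with
uncorrected p < 0.05; cluster mass is node count (a statistic-sum
option exists). Under permutation the group labels are shuffled and
all covariates stay with their subjects. The corrected p is the
proportion of permutations whose maximal cluster is **at least as
large** as the observed cluster. The strict "larger than" version was
measured to inflate the family-wise error to ≈18% at nominal 5% in the
null calibration (integer sizes are heavily tied, and the strict rule
is anticonservative by one probability-mass step); the inclusive
Monte-Carlo convention restores calibration (measured FWER 2.3%,
slightly conservative, again because of ties). Per-node tests inside
the permutation loop default to the exact mixed-model LLR; a
vectorised OLS analogue (site as fixed effect) is provided as fast
mode — it tracks the exact p values to ≈0.08 absolute in the mid-range
and matches α = 0.05 decisions in the validation test, and is what the
calibration simulations and the demo use.

## Classification

Features are residualized per column against the covariate-only mixed
model (fixed effects plus site BLUP), reduced by PCA to the components
explaining 98% of variance, and classified by one of: L2 linear SVC
(C ∈ 10⁻³…10²), elastic-net logistic regression (C ∈ 10⁻³…10²,
l1-ratio {0.1, 0.5, 0.9}), or a Boruta-style shadow-feature selection
(100-tree forests, 50 iterations, one-sided binomial confirmation at
α = 0.05, falling back to all features when nothing is confirmed) in
front of an RBF SVC (C ∈ 10⁻¹…10², kernel width at {0.5, 1, 2}× the
median heuristic). These grids are this package's choices and
config-overridable. Evaluation: 15 stratified 80/20 splits, inner
10-fold cross-validated grid search maximising S1, unweighted mean of
rates across splits; single-point grids skip the inner search.
Residualization and PCA are fit on the full sample before splitting
(replicate mode, matching the upstream procedure); note this leaks
marginal feature structure across splits — refitting inside each fold
would be the strict alternative. The permutation p is the proportion
of label-shuffled datasets whose aggregated S1 reaches the observed one.

## Replication statistics

Stratified 70/30 splits randomize within site × age group (children
6–11, adolescents 12–17, adults 18+) × diagnosis strata,
round(0.7·n) to training, singletons to training with a warning.
Prediction intervals use Fisher-z variances 1/(n−3) per study for
correlations (bounds mapped back through tanh, hence always inside
(−1, 1)) and the large-sample variance
(n₁+n₂)/(n₁n₂) + d²/(2(n₁+n₂)) for standardized mean differences, with
a normal quantile: with the documented inputs (r = 0.10, 183 → 212)
this reproduces the printed lower bound −0.10; the upper bound computes
to 0.29 where 0.30 is printed, and no tested variant (t quantiles,
alternative n choices) reproduces that rounding exactly. Analytic
two-sample power uses the noncentral t distribution; mixed-model power
is by simulation through the full test and is not claimed to reproduce
any externally printed power figures, whose derivation details are not
available.

## Validation problem sizes

Test-suite and acceptance-script simulation sizes were chosen for
desk-scale runtime as the package's own defaults: cluster-test
family-wise error over 400 null datasets (n = 60, 24 nodes, 200
permutations; 200 datasets in the acceptance script); variance-LLR null
quantile over 400 simulated features at n = 400 (250 in the script);
mixed-model parameter recovery over 200 replicates at n = 400;
prediction-interval coverage over 5000 simulated pairs; classifier-p
calibration over 60 experiments × 60 permutations; end-to-end demo
with 40 subjects, 23 channels, 256 Hz, 400 cluster permutations. The
demo injects a deliberately strong link coupling (wPLI near 1 on the
coupled link) and reactivity interaction so that detection is expected,
demonstrating sensitivity of the chain rather than a power claim.

## Known limitations

- No artifact simulation or automatic artifact detection; ICA is
  represented only by its component count.
- The synthetic forward model is not a volume conductor; source-space
  and sensor-space analyses are exercised on separate fixtures.
- The OLS fast mode of the permutation test treats site as a fixed
  effect; with very few subjects per site its p values drift from the
  exact mixed-model values.
- The x⁴ reactivity transform is not monotone over negative reactivity
  values; results for subjects with R < 0 conflate sign and magnitude.
- Prediction intervals use normal quantiles; for very small replication
  samples t-based intervals would be wider.
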