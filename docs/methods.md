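# Methods

This note records the models, defaults and numerical choices behind
`spectrocycle`, and what the synthetic study does and does not establish.

## Spectral forward model

Every image channel is an (excitation line, emission band) pair.  A
fluorophore is modelled as Gaussian mixtures over excitation and emission
wavelength; its response in a channel is

    brightness × Σᵢ wᵢ N(ex_channel; exᵢ, σᵢ² + σ_ex²) / N(0;0,·)
               × Σⱼ wⱼ overlap(emⱼ, σⱼ; band)

where the excitation factor is the peak Gaussian convolved with the ±5 nm
band Gaussian evaluated at the line centre, and the emission factor is the
overlap integral with the ±20 nm bandpass transmission (or the emission
mass above the cut-on for long-pass filters).  Band half-widths are
half-widths at half-maximum (σ = HWHM/√(2 ln 2)).  Real filter
transmission curves and detector quantum efficiency are out of scope; the
Gaussian stand-in is smooth and keeps every response differentiable in the
wavelengths.

Endmember parameters: free NAD(P)H excitation 290/351 nm, emission
440/460 nm, brightness 1; bound NAD(P)H shares the excitation peaks with
emission blue-shifted 15 nm and brightness 2 — distinguishable from the
free form but collinear enough to stress the unmixing; FAD 450 → 535 nm,
brightness 0.9; PPIX Soret 405 nm (weak Q-bands at 505–630 nm), emission
635 nm with a 705 nm shoulder, brightness 0.7.  The resulting 34×4
endmember matrix has full rank (smallest singular value ≈ 0.19 after
column normalisation); columns are stored unit-norm with their scales so
physical abundances can be recovered.

## Synthetic study design

The generator emulates fields of view of plated cells from three cancer
lines under the 34-channel layout.  Defaults define the study conditions:

- **Groups**: 3 lines × 4 phases × 50 cells, one 384×384 field of view per
  (line, phase) group; ellipse semi-axes 6–11 px, rejection-sampled
  non-overlapping placement (error after 10 000 rejections).
- **Abundances**: per-cell lognormal draws (CV 0.18) around line baselines
  scaled by phase multipliers.  Line baselines differ strongly —
  HeLa (1.0, 0.45, 0.6, 0.08), MIA-PaCa-2 (3.4, 1.05, 2.5, 0.05),
  PANC1 (0.6, 1.9, 0.22, 0.18) in the order (free, bound, FAD, PPIX) —
  so that the between-line mean-spectrum distance exceeds 5× the
  within-line between-phase distance (measured ratio 5.5 on the noiseless
  means).  Phase multipliers are weak (≤ 1.4×) and encode the qualitative
  effect directions the pipeline should detect: bound NAD(P)H S > G1 in
  MIA-PaCa-2 and PANC1; PPIX M > G1 in HeLa and PANC1; redox ratio and
  bound/free ratio G1 > M in HeLa and PANC1.  A design-time power analysis
  sized these multipliers so the named contrasts reach ≥ 80 % power at
  n = 50/group under Mann–Whitney testing (measured 0.94–1.00).
- **Texture**: each cell carries a positive unit-mean multiplicative field
  (exponentiated Gaussian random field, strength 0.25) whose correlation
  length shrinks with phase (G1 2.2 px → M 1.5 px), giving texture
  features some class signal.  The contrast is deliberately mild: a
  steeper schedule made GLCM homogeneity so discriminative that one
  stage's training clusters became fully separable (1-SD IoU = 0), outside
  the intended regime in which all cell-cycle cluster pairs overlap while
  origin clusters are disjoint.  Unit mean preserves the linear mixing
  model on cell means exactly.
- **Artefacts**: background 25 DN, quadratic vignette (~±12 %), dead and
  saturated sensor sites at rates 1e-4 and 5e-5 (applied at the same
  pixel site across all channels, as for a real sensor), Poisson shot
  noise at photon_scale 1000, 16-bit quantisation.  `poisson=False`
  renders the real-valued noiseless photon rate for forward-model tests.
- **M-phase** cells are generated (needed for phase-wise abundance
  comparisons) but merged into G2+M for classification, M-phase cells
  being too rare in practice to model separately.

What the generator does **not** emulate: optical PSF blur, 3-D structure,
photobleaching, spectral channel cross-talk, cell-shape irregularity,
cell–cell contact, or any within-line heterogeneity beyond lognormal
abundance scatter.  Passing tests therefore show the pipeline's
correctness and calibration under the linear mixing model with realistic
noise — not classifier performance on real microscope data.

## Preparation

Order: defective-pixel repair → flat-field → background subtraction →
variance stabilisation.  Repair must precede any fit; the flat-field
polynomial is fitted *before* the pedestal is removed because the
background level is precisely what reveals the illumination shape — fitting
it to pedestal-subtracted residuals (which hover near zero) would
catastrophically amplify the normalised correction field.  Stabilisation
runs last so every fit sees raw counts.

Choices: dead = value 0, saturated ≥ full scale; repaired by the median of
valid 8-neighbours, iterated ≤ 5 passes.  Background = per-channel 5th
percentile, clamped at zero.  Flat field = order-2 (configurable 1–3)
bivariate polynomial least-squares fitted to background pixels, normalised
to unit mean, clipped at 0.05, divided out.  Shot noise: Anscombe
transform 2√(x+3/8), Gaussian smoothing σ = 1 px, algebraic inverse
clamped at zero.  Every step is channel-separable, deterministic and
switchable.

## Features

731 features per cell: 34 masked channel means; 561 unordered channel
ratios meanᵢ/max(meanⱼ, 10⁻⁶) (unordered to avoid duplicated reciprocal
information, floored to stay finite); per-channel population standard
deviation and Fisher–Pearson skewness (biased moments; skewness defined 0
when the variance is below 10⁻¹²); per-channel GLCM entropy and
homogeneity.  The GLCM uses per-cell min–max quantisation to 32 equal
bins, counts only pixel pairs with both members inside the mask, is
symmetrised, normalised per offset and averaged over the four unit offsets
(0,1), (1,0), (1,1), (1,−1).  Cells under 20 px are rejected; texture
needs at least 2 co-occurring pairs.  Scaling all pixels by k > 0 scales
means and standard deviations by k and leaves every other feature
unchanged.

## Classification

Per stage: features are z-scored with training-fold statistics (ratio and
texture features live on incommensurate scales); one-way ANOVA keeps
features with p < 0.005, ranked by F, at most 13 (ties broken
lexicographically); Fisher's discriminant direction is computed in
within-class-scatter-whitened coordinates with a 10⁻⁶ ridge on the scatter.
Two-class Fisher analysis yields a single axis, so the second canonical
variable is defined as the leading principal component of the whitened
within-class residuals orthogonalised against axis 1 — deterministic,
orthogonal to axis 1 in the whitened metric, and harmless to the
classifier, which uses both coordinates through a pooled-covariance linear
discriminant with an equal-priors midpoint bias (the study's class balance
is configurable, so no prior is privileged).  Stratified 10-fold
cross-validation performs selection, standardisation and fitting inside
each training split; a class with fewer members than folds triggers
leave-one-out with a warning.  Stage accuracies are reported conditional on
true stage membership (stage 2 is evaluated on true S/G2/M cells), matching
how per-stage performance is usually tabulated; end-to-end three-class
predictions are available through `predict_two_stage`.

ROC/AUC: threshold sweep over unique scores with trapezoidal integration;
ties receive half credit, making the AUC identical to the rank
(Mann–Whitney) statistic — asserted against an independent rank-based
implementation in the tests.

## Cluster overlap

A projected cluster is summarised by its mean and population covariance;
the "SD ellipse" is the Mahalanobis-distance-1 contour (~39 % of a
Gaussian's mass; a scale parameter k generalises to k-SD).  Intersection
area integrates the overlap of the two per-abscissa y-intervals on a
doubling midpoint grid until successive estimates agree to 10⁻⁴ relative,
clamped by the smaller ellipse's area; coincident ellipses short-circuit
exactly.  The integrator agrees with a 10⁶-sample Monte-Carlo oracle
within three standard errors on randomised pairs.  Exact conic–conic
algebra was rejected in favour of the (cross-checked) numeric rule for
robustness near tangency.

## Unmixing and statistics

Per-cell mean spectra (after preparation, so background-corrected) are
unmixed by active-set NNLS against the unit-norm endmember matrix;
coefficients are rescaled by the stored column norms to physical
abundances and normalised to fractions.  Whether to unmix per pixel and
average, or per cell-mean spectrum, is an open choice; per-cell-mean is
the default (it is the lower-noise estimator under the unit-mean texture
model) and per-pixel unmixing can be built from `nnls_unmix` directly.
Ratios: redox = FAD/free, bound/free = bound/free, both floored at 10⁻⁹.

Mann–Whitney U: exact enumeration when nx+ny ≤ 16 without ties, otherwise
the normal approximation with tie and continuity corrections.  The exact
route matters: below about five cells per group the normal approximation
misstates two-sided p-values by up to ~0.13, so small-sample comparisons
must never take the asymptotic path.  Phase comparisons are flagged at
unadjusted p < 0.05 — matching the usual presentation of per-panel
significance letters — and a Holm-adjusted column is emitted alongside for
family-wise control.  Under null (no phase effect) generator settings the
pipeline flags 5.4 % of tests at α = 0.05 across 1000 simulated tables
(tests within a table share cells, hence the mild excess over the nominal
binomial band).

An unsupervised mode (`estimate_endmembers_nmf`, best of 50 random-restart
NMF factorisations, columns matched to reference fluorophores by optimal
spectral-correlation assignment) stands in for robust unsupervised
unmixing.  It recovers the three dominant fluorophores (spectral
correlation > 0.8) but not PPIX, whose ~5 % signal share is absorbed into
other components — supervised NNLS with the known endmember matrix is the
default for this reason.

## Known limitations

- Performance figures quantify the synthetic study only; the generator's
  simplifications (above) mean real-data accuracy will differ.
- The canonical second axis is a package convention; any rotation of the
  residual subspace would serve equally.
- IoU is reported without confidence intervals, and only for cluster
  pairs.
- The 44-vs-34 discrepancy in contemporary descriptions of this channel
  layout is resolved in favour of the enumerable 34-channel list; the
  builtin constant is that list.
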