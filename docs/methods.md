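# Methods

## Model and assumptions

The pipeline assumes a two-group cohort described at three levels: voxels
(gray-matter values), ROIs (mean gray-matter value over the voxels of an
atlas region inside a network mask), and networks (mean over all mask
voxels). ROI features inside one brain network are assumed to carry shared,
interregional covariate information; networks are treated as (approximately)
independent blocks. All classifiers downstream are linear, so whatever the
representation does not make linearly visible is lost: this single fact
drives most of the design analysis below.

### Intra-network coupling

Each ROI feature is expanded to its elementwise powers 1..E₁ after per-feature
min–max scaling. Pearson correlations between all pairs of expanded columns
within a network form the coupling weight matrices; a correlation whose
two-sided p-value (exact t-transform, M−2 df) exceeds α = 0.05 is revised to
exactly 0, so the stored weights are sparse and every nonzero entry is
statistically supported. The coupled vector of ROI k weights its own powers
by R_intra(k) and the other ROIs' powers by R_inter(k), each damped by the
Taylor-like factors ω_e = 1/e!, which geometrically suppress high powers so
the expansion behaves like a truncated series rather than a raw polynomial
blow-up. The E₁ = 1 case bypasses coupling entirely and returns the scaled
original features. Coupling is strictly per network: the implementation
guarantees (and the tests verify) that perturbing one network can never
change another network's block.

The ⊙/⊗ combination in the coupled-vector formula is implemented as
"elementwise Taylor damping followed by a vector–matrix product", the only
dimensionally consistent reading; an independent triple-loop reference in the
test suite freezes this interpretation.

### Inter-network coupling

For each unordered pair of networks, canonical correlations between their ROI
blocks are computed as singular values of the whitened cross-covariance
C₁₁^(−1/2) C₁₂ C₂₂^(−1/2) with a ridge of 1e−8 on each within-block
covariance (robust at n = 3 with small training folds), clipped to [0, 1],
descending. The top E₂ values are retained, zero-padded when the spectrum is
shorter (with n ROIs per network only n correlations exist, so E₂ > n adds
exact zeros — a warning, not an error). Network l's inter-coupled feature
sums the Taylor-damped powers of the *other* networks' scaled network-level
features, each power weighted by the corresponding retained canonical
correlation. The source formula never pins down its V_EFM term; of the two
defensible readings (power expansion of network features vs. no expansion
with pair-indexed weights) the power-expansion reading is implemented, as the
exact parallel of the ROI-level formula; the alternative is noted here and
not implemented.

### Classifier

One sequential AdaBoost pass over the feature blocks in fixed order (networks
ascending, inter block last; a `rounds` option repeats passes). Base learners
are sample-weighted linear SVMs (C = 1.0 default, exposed in config);
ε_t is the weighted training error clipped to [1e−10, 1−1e−10],
α_t = ½ ln((1−ε_t)/ε_t) for ε_t < 0.5 and 0 otherwise, and sample weights are
multiplied by exp(α_t·[misclassified]) and renormalized. Prediction is the
sign of the α-weighted vote, with exact ties going to the patient class.
Weighted refitting (rather than resampling) realizes the distribution update
deterministically. Evaluation uses stratified k-fold (default 10) folds drawn
from the run seed; scaling parameters, coupling weights, CCA spectra and the
ensemble are all fitted on each fold's training rows only, so held-out rows
cannot leak into the representation (a `transductive` switch restores
whole-dataset fitting for comparison, since the source protocol does not
specify fold handling).

### Extraction front end (voxel mode)

Component count: the classic eigenvalue-based MDL order estimator applied to
the subjects × subjects covariance spectrum with voxels as observations —
the log-ratio of geometric to arithmetic mean of the trailing eigenvalues
against a ½·k·(2M−k+1)·ln V penalty, minimized over k and clamped to
1 ≤ K < M. Unmixing: FastICA on the voxel dimension (spatial ICA; logcosh
negentropy, PCA whitening, tol 1e−6, max 1000 iterations, up to 5 re-seeded
restarts before a convergence error). Source maps are z-scored across voxels
and sign-fixed to nonnegative skewness, the scale being pushed into the
mixing columns. Group testing: two-sided two-sample t-tests per mixing
column at the Bonferroni-corrected threshold α/K. Masks: z ≥ 3 binarization;
"cluster size" is implemented as in-mask voxel count per atlas region
(label-based overlap, not 3-D connected components — the artifact's atlas is
a label volume), ranked descending with ties to the smaller region id.

## Tunable parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| E₁ | ROI power-expansion order | 3 (grid {2,3,4}) | 1 disables coupling; accepted 1–6 |
| E₂ | retained canonical correlations | 2 (grid {1,…,5}) | > n zero-pads |
| α (coupling) | revision threshold | 0.05 | two-sided |
| α (extraction) | group-test level | 0.05 | Bonferroni over K components |
| Z | binarization threshold | 3.0 | on z-scored source maps |
| top_k | ROIs kept per network | 3 | atlas-overlap ranking |
| C | SVM regularization | 1.0 | source silent on this |
| folds / rounds | CV folds / boosting passes | 10 / 1 | |

## Scaling choice

Features are min–max scaled to **[−1, 1]** (parameters fitted on training
rows; constant features map to the midpoint; held-out values are not
clipped). The range is symmetric about zero on purpose: a positive-shifted
feature is ~0.97 correlated with its own square, so with a [0, 1] range the
curvature directions of the power expansion are numerically buried and an
L2-regularized linear SVM cannot afford the large opposing weights needed to
recover them. Scaling a feature to a zero-centered range makes x and x²
nearly uncorrelated, turning each expansion order into a genuinely new
direction. Correlations — and hence the revision rule and all coupling
weights — are location/scale invariant, so this choice affects only the
coupled values, not which couplings survive. A `scale=False` switch
preserves raw behavior.

## What the synthetic generator emulates — and what it does not

Feature mode draws each network's ROI block from an equicorrelated Gaussian
(off-diagonal ρ), independent across networks; the network feature is exactly
the mean of its ROIs. Affected networks lower the patient group's mean by
d·sd (atrophy), optionally raise its within-network correlation
(`within_network_rho` as a `(rho_base, rho_affected)` pair) and scale its sd
(`patient_sd_ratio`) — correlated variability, the pattern of heterogeneous
atrophy. Voxel mode plants spatial components with exponential-magnitude
values on contiguous disjoint supports (so z-scored maps have a genuine tail
above Z = 3 and positive skewness), mixes them with Gaussian subject
loadings (mean 4, sd 1) and adds voxel noise; group differences enter the
loadings. `n_voxels_per_roi` defaults to 200, keeping voxels ≫ subjects —
the regime the MDL estimator assumes and the right order of magnitude for
atlas regions.

Not emulated: spatial smoothness and autocorrelation, scanner/site effects,
registration error, non-Gaussian gray-matter distributions, overlapping
network supports. Passing tests therefore show that the pipeline recovers
the structure it assumes, not that it is robust to realistic violations of
those assumptions.

### The planted-coupling comparison scenario

`synthetic.coupled_difference_config` defines the conditions under which the
representations are compared: 60 subjects per group, 4 networks × 3 ROIs, one
affected network with ρ 0.3 → 0.8, sd ×1.8 and mean shift d = 0.5. The
design follows from an analysis of what each representation can express to a
linear classifier:

- A *pure* correlation change (marginals untouched) is provably invisible to
  `OFM_ROI`, `CFM_ROI` and the U part of `CFM_network`: all are fixed linear
  maps of single-feature powers, and equicorrelation changes no single-ROI
  moment. The only ρ-sensitive statistic anywhere in the representation is
  E[v^e] (e ≥ 2) of the network means inside f, where the formula fixes the
  power-mixing coefficients at (1/e!)·ρ_e — empirically worth less than one
  accuracy point. This expressiveness boundary is a genuine property of the
  method and is documented rather than papered over.
- A *covariance* change that includes the diagonal (correlated variability)
  is visible to the power expansion: E[z²] shifts per ROI, which U exposes as
  near-free directions while the original features cannot.
- The L + 1 hard-vote ensemble discards base-learner margins, costing roughly
  ten accuracy points against a joint SVM when signal is spread over all
  networks; with signal concentrated in few networks the null blocks get
  α ≈ 0 (built-in network selection) and the design plays to its strength.

## Numerical choices and degenerate inputs

Ridge 1e−8 in CCA whitening; canonical correlations clipped to [0, 1];
ε clipped to [1e−10, 1−1e−10] in boosting; zero-variance expanded columns get
zero coupling weights (warning) while the definitional unit diagonal of
R_intra is kept; constant feature columns are flagged and map to the scaling
midpoint; empty binarization masks, rank-deficient covariance, single-class
labels and undefined t-statistics raise typed errors rather than propagating
NaNs. Grid ties go to the smaller E₁, then E₂. All randomness flows from a
single root seed through per-operation child streams, and every output is
byte-reproducible for a fixed config + seed.

## Problem sizes

The test suite and the acceptance script run the extraction recovery at
40 + 40 subjects × 2400 voxels over 20 seeds, the null-label check at
20 + 20 subjects over 10–20 seeds, and the representation comparison at
60 + 60 subjects over 10 seeds with the full E₁ × E₂ grid — sizes chosen so
each Monte-Carlo estimate is stable at a few percent while a full run stays
in the tens of seconds on one CPU.

## Known limitations

The ensemble's fixed block order and one-pass default follow the source
design; no per-round block selection or margin-weighted voting is attempted.
CCA is unregularized beyond the ridge (no sparse/kernel variants). The
extraction front end assumes a label atlas aligned to the voxel axis and
does not model template reuse across cohorts beyond exposing the fitted
masks. Reported sensitivities/specificities are per-fold means, which can be
noisy for small folds.
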