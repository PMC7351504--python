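# Methods

`covnet` re-creates, on synthetic data with planted ground truth, the
analysis chain used to study structural covariance network disruption and
its functional counterpart in Parkinson's disease: spatial group ICA of
morphometric maps, stability-selected components, per-subject network
integrity, goodness-of-fit matching of functional components to structural
templates, functional network connectivity (FNC), and covariate-adjusted
group statistics. This note documents the models, the defaults, and the
design decisions that were genuinely open.

## The synthetic cohort

Real deformation-based morphometry (DBM) maps and resting-state BOLD series
are not available, so the generator plants exactly the statistical
structure the analysis is designed to detect.

**Phantom atlas.** Six spatial sources on a 32×40×32 voxel grid at 3 mm
isotropic with an ellipsoidal brain mask (~11 k in-mask voxels). Each
source is a sum of two 3-D Gaussian blobs (σ ≈ 2.5 voxels); roles are
anterior cingulate, posterior cingulate, frontoparietal, two generic
networks, and one *artifact* source placed outside the brain mask
(emulating the non-brain components a real group ICA produces). Placement
is rejection-sampled until every source pair has absolute spatial
correlation < 0.2, non-artifact sources keep ≥ 95 % of their energy inside
the mask, and the artifact source keeps ≥ 80 % outside. Sources are scaled
to unit RMS amplitude over the grid; with that normalization the default
noise SD of 0.5 corresponds to a per-subject voxelwise SNR near 2.5, at
which single-subject maps look noisy but a 170-subject decomposition is
comfortably identifiable — the regime morphometric group studies operate
in.

**Structural maps.** Subject *s* gets `map_s = Σ_j A[s,j]·source_j +
σ·ε`, ε i.i.d. standard normal, σ = 0.5, then 6 mm FWHM Gaussian
smoothing. The loading matrix A is standard normal except for the
anterior/posterior cingulate pair, drawn via a 2×2 Cholesky factor with
correlation 0.6 in controls and 0.1 in patients (the planted "structural
covariance disruption"), and shifted by −0.6 SD in patients (the planted
mean integrity deficit). The shift size is a choice: the source study
reports only directions and p-values, and −0.6 SD is a moderate effect
that a 100-vs-70 comparison detects with high power without being trivial.

**Functional series.** Each subject-visit receives one band-limited
(≤ 0.1 Hz) unit-variance Gaussian time course per source, built in the
frequency domain; volumes are `Σ_j tc_j(t)·source_j + ε`. The
anterior–posterior pair is drawn with a planted correlation of 0.25 (HC),
0.55 (PD baseline) and 0.25 (PD follow-up) — the qualitative trajectory of
the study's longitudinal finding (connectivity elevated at baseline,
normalized at follow-up). On top of the group value, each subject's
planted correlation moves by −0.12 per SD of their cingulate integrity
score (clipped to |ρ| ≤ 0.9), which is what produces the negative
integrity–FNC partial correlation in patients; this subject-level coupling
is the package's own construction, since group directions alone cannot
yield a within-group correlation. The first 10 volumes carry a decaying
additive transient (a T1-saturation stand-in) so the
initial-volume-removal step is consequential and testable. The acquisition
length is configurable (default 230 volumes at TR = 2 s; only the number
of discarded volumes, 10, is fixed by convention).

**What the generator does not emulate:** anatomy, registration error,
physiological noise, motion, scanner drift beyond a linear trend, spatial
autocorrelation of noise, site effects. Passing tests therefore show that
the *pipeline machinery* recovers planted structure through the full
measurement chain — not that it would behave identically on real MRI data.

**Clinical tables.** Gaussian draws per variable around published-style
group summaries (age, education, UPDRS I–IV and total, H-Y, PDQ-39, MMSE),
clipped to plausible ranges, with exact group sizes. Floor-clipping biases
variables whose SD spans the floor (e.g. UPDRS IV); the tables exist to
exercise the summary-statistic tests, which operate on the published
summaries themselves, not on these draws.

## Decomposition

**PCA whitening.** The subjects × voxels matrix is centred (mean map
across subjects, then per-subject means so whitened rows are exactly
zero-mean) and reduced to k = 20 whitened rows via the n×n Gram
eigendecomposition.

**Infomax ICA.** Stochastic natural-gradient ascent with the logistic
nonlinearity: `W ← W + η(I + (1−2y)uᵀ/L)W` over randomized blocks of size
⌊√(m/3)⌋, η = 0.015/ln k, annealed ×0.9 whenever the update direction
turns by more than 60°, with a restart at halved rate on divergence. A
pass's summed squared weight change below 1e−6 stops the iteration (the
conventional stopping rule for this algorithm family); non-convergence at
512 passes is flagged, not raised. Source sign is fixed by positive map
skewness; components are ordered by explained variance.

**Stability (ICASSO-style).** Infomax is repeated 20 times from seeded
random initial matrices on the same whitened data (randomized initial
conditions only — no bootstrap, the minimal faithful reading of
"ran the algorithm 20 times"). All 20×k estimates are clustered by
absolute Pearson correlation with average linkage, cut at k clusters. The
quality index is Iq = mean intra-cluster similarity (over distinct member
pairs; 0 for singletons by convention) minus mean member-to-non-member
similarity; the cluster centrotype (maximal summed intra-cluster
similarity) becomes the component map. A cluster may contain several
estimates from one run; this is reported, not forbidden.

**Functional group ICA.** Standard two-stage temporal-concatenation
recipe: per-subject PCA to ⌈1.5 k⌉ whitened rows, concatenation, group PCA
to k, then the same ICASSO-stabilized spatial Infomax. The group stage
runs on a 30-subject random subset (memory-bounded; component maps
stabilize well below that), while dual regression estimates subject
time courses and maps for *every* subject-visit. How per-subject
time courses should be derived from group components was an open choice;
dual regression (two-stage least squares, both stages with intercepts) was
chosen because it is standard, linear, and exactly testable.

## Scoring and selection

* **Integrity** — each subject's map is regressed on all k component maps
  jointly plus intercept; the beta on network j is that subject's
  integrity score. Joint (not one-at-a-time) regression decorrelates
  overlapping networks; the same code path supplies the decomposition's
  loadings, so there is exactly one definition of integrity in the
  package.
* **Artifact flagging** — a component is excluded when > 50 % of its
  z > 3 voxels fall outside the brain mask (or when it has no z > 3
  voxels). On the 6-source phantom this removes the planted artifact
  component *and* the spatially diffuse noise components, leaving ~5–6
  retained networks; the retained set defines the FDR family.
* **Dice matching** — component sets are paired greedily by Dice of their
  z > 3 masks (k is small; the greedy pairing is documented as swappable
  for optimal assignment).
* **GOF** — mean of a statistic map inside a binary template minus the
  mean outside. Selection uses the mean per-subject GOF across subjects
  (each subject has one GOF per component); group one-sample t-maps are
  also produced. Ties break toward the lower component index.

## FNC and statistics

Component time courses are linearly detrended, despiked by Hampel
winsorization at 3.5 scaled-MAD (the despiking algorithm in the original
toolbox is unspecified; the Hampel rule is deterministic and testable),
and band-passed 0.013–0.24 Hz with a 5th-order Butterworth applied
forward–backward (zero phase; the original filter family is unspecified
and configurable here). FNC is the Pearson correlation of the two
conditioned time courses — one value per subject-visit. Group statistics
operate on Fisher-z values; raw r is reported alongside.

The phantom splits the cingulate system into anterior and posterior
sources, whereas the original network is a single component spanning both.
The component matched to the anterior source is designated *the* cingulate
network wherever one network must be named (the integrity–FNC partial
correlation, the FNC coupling); for the group-level disruption finding the
two cingulate components are read jointly — both must show the deficit's
direction, and the disruption is considered FDR-confirmed when at least
one survives correction.

Group comparisons use a single linear model (outcome ~ group + age + sex),
equivalent to residualize-then-test for the group term but numerically
cleaner; families are corrected with Benjamini–Hochberg FDR at 0.05.
Longitudinal contrasts use paired t-tests. Brain–behaviour association
uses partial correlation (residualize both variables on age and sex,
correlate residuals, t with n−2−c df). Demographic tables published as
mean ± SD are tested with pooled-variance summary t-tests and one-way
ANOVA reconstructed from summaries — pooled variance reproduces the
published table p-values to the printed precision, which Welch does not.

## Numerical choices and edge cases

* Smoothing uses zero-padding at the volume boundary; sums are conserved
  only for interior signal.
* Voxel linearization is C-order over in-mask voxels; mask → unmask is an
  exact inverse on the mask support, zeros elsewhere.
* Dice of two empty masks is 0 by convention; a constant time course
  despikes to the zero vector; a zero-variance voxel gets t = 0 (counted);
  zero-variance FNC inputs yield NaN with a flag rather than an exception;
  paired differences that are constant but nonzero are flagged undefined.
* All randomness flows from one seed through named child seeds per stage;
  rerunning a configuration reproduces every output byte-for-byte.

## Problem sizes

The default study is 100 patients + 70 controls (51 patients with a
follow-up visit), a 32×40×32 grid, k = 20 components, 20 stability runs,
230 volumes at TR = 2 s. A full end-to-end run takes a few minutes on one
CPU; unit tests run the same code on 16×20×16 grids with k = 6–8 and a
handful of subjects. These sizes are the package's chosen operating point:
large enough for every planted effect to be comfortably detectable, small
enough to iterate on.

## Known limitations

* The artifact rule is calibrated to the phantom's geometry (brain mask
  ≈ 27 % of the grid); on data where the analysis mask *is* the brain,
  diffuse noise components would not be auto-excluded this way.
* The published imaging effect sizes (specific IC p-values, Dice = 0.68,
  r = −0.238…−0.416) depend on the original patient data and are not
  reproduction targets; the package reproduces the *directions* of those
  findings on planted effects, and the exact table statistics that are
  derivable from published summaries.
* Infomax here is the classic logistic (super-Gaussian) variant; there is
  no extended-Infomax sub-Gaussian switching and no bootstrap ICASSO.
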