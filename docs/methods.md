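# Methods

This note documents the models, algorithms and numerical choices behind
connectokit, what the synthetic cohort generator does and does not emulate,
and the design decisions taken where the methodology was genuinely open.

## Pipeline overview

The analysis chain operates on masked voxel × time BOLD matrices and runs,
per the standard order: (1) drop initial volumes; (2) detrending + nuisance
regression; (3) 0.01–0.1 Hz band-pass; (4) motion scrubbing; then network
mapping, connectivity, graph, community and statistics stages. Image-domain
preprocessing (realignment, registration, smoothing) is out of scope: the
package assumes its input is already a masked voxel time-series matrix.

## Preprocessing

* **Framewise displacement** follows the Power convention: the sum of
  absolute backward differences of the three translations (mm) plus the
  three rotations (rad) scaled by a 50 mm head radius; fd[0] = 0. FD is
  translation-invariant by construction. A formula had to be fixed because
  only "mean FD in mm" is commonly reported; Power FD is the field default.
* **Nuisance regression** projects each voxel series onto the orthogonal
  complement of [intercept, linear trend, Friston-24 motion expansion,
  global/WM/CSF series]. Detrending is folded into the same regression
  (intercept + linear term). Collinear design columns are detected by
  rank-revealing QR and dropped with a warning rather than failing.
* **Band-pass** is a zero-phase (forward–backward) Butterworth of order 4.
  Only the band (0.01–0.1 Hz) is methodologically fixed; the filter family
  and order are our choice, validated by FFT checks (passband retention
  ≥ 95 %, ≥ 90 % attenuation at twice the upper edge).
* **Scrubbing** replaces frames with FD > 0.5 mm by cubic-spline
  interpolation over the clean frames, per voxel. Flagged frames outside the
  clean support take the nearest clean value, because splines extrapolate
  unstably. Scrubbing runs after filtering, following the listed step order;
  with FD defined by backward differences the first frame is never flagged.
* **Exclusion**: subjects with mean FD > 0.5 mm or any motion excursion
  beyond one voxel (3 mm default, rotations converted via the 50 mm radius)
  are removed with a per-subject reason report.

## Spatially regularized NMF network mapping

The subject matrix is made non-negative per voxel (subtract minimum, divide
by maximum, constants → zeros) and decomposed as X ≈ W H minimizing

    ‖X − WH‖²_F + β_eff·tr(H L Hᵀ) + α_eff·‖H − H₀‖²_F,

L the 6-neighbourhood voxel-grid graph Laplacian, H₀ the group atlas prior
(α_eff = 0 without a prior). The penalty weights are scale-adaptive:
β_eff = β·‖X‖²_F/V and α_eff = α·‖X‖²_F/V, so the regularization strength
tracks the data energy (and, deliberately, the number of concatenated
frames).

**Solver.** The default solver is HALS: per-component Gauss–Seidel sweeps
with closed-form non-negative updates; the Laplacian coupling across voxels
is handled by the standard D/A splitting (degree term in the denominator,
adjacency term evaluated at the current iterate). A Lee–Seung multiplicative
solver extended with the same two penalties is available (`solver="mu"`),
and doubles as a safeguard: if a HALS iteration ever increases the
objective — possible in principle through the splitting approximation — that
iteration is redone with the provably monotone multiplicative step, so the
recorded objective trace is non-increasing (asserted in tests at 1e−10
relative slack). HALS is the default because multiplicative updates from
random initializations consistently plateau in poor local optima on this
model class (mean atlas-row correlation with the generating atlas ~0.5–0.65,
confirmed independently with scikit-learn's MU solver), whereas HALS reaches
~0.95 on identical data. The method is specified only as alternating
optimization with random non-negative initialization, which both solvers
satisfy.

**Weights.** α = 0.1 balances prior adherence against subject fit and is
kept from the original design. β defaults to 1e−5: a sweep on synthetic
cohorts showed that at β = 1e−2 the spatial penalty is the same order as the
fit term and flattens the maps enough to halve atlas recovery (0.44 vs 0.93
mean row correlation at 1e−5), so the strong default was rejected. Both
knobs are exposed in `NmfConfig`.

**Group stage.** Up to 50 subjects' normalized matrices are concatenated
along time (sampled without replacement once if more are available) and
decomposed `repeats` times with fresh random initializations (config default
50, matching full-scale practice; the desk-scale default used throughout the
tests is 5). All repeat atlases' rows are pooled and spectrally clustered
(similarity = (corr + 1)/2) into K groups; cluster means, max-rescaled, form
the consensus atlas. An empty cluster triggers a reseeded retry (cap 5).
The repeats re-initialize the decomposition of one concatenated matrix
rather than re-sampling subjects: robustness-by-repetition refers to the
factorization, and at desk scale every subject is in the sample anyway.

**Personalization.** The subject matrix is decomposed with H initialized at
the consensus atlas and the prior penalty active, so subject network k stays
in registration with consensus network k — no post-hoc matching. After every
decomposition H rows are max-normalized and W rescaled inversely (WH
unchanged), fixing the scale indeterminacy.

**Outputs.** Voxels are assigned to their argmax network (ties to the lowest
index, logged). Reconstruction accuracy is the per-voxel Pearson r between
the normalized signal and W H, averaged over each network's voxels and over
subjects. Inter-subject variability is the across-subject median absolute
deviation of the loadings, summarized per voxel as the mean over networks.
Networks can be named against a reference parcellation by maximal Dice
overlap, with -1/-2 suffixes (by descending loading mass) for duplicates.

Note an identifiability subtlety used by the tests: because each voxel is
range-normalized before decomposition, the recoverable spatial map is the
generating map scaled by the inverse per-voxel signal range; comparisons
with ground truth use that scaled target.

## Connectivity layers

Edge time series are products of z-scored node series; z-scoring uses
population (1/T) variance so that the time mean of an edge series equals the
node-pair Pearson correlation exactly (asserted at 1e−10). The product form
without standardization would break this identity, so standardization is
treated as part of the definition. RSS tails use k = ⌈frac·T⌉ frames (for
T = 170, frac = 0.05 → 9 frames per tail), ties broken toward the earlier
frame for determinism; "top" means highest amplitude. Transition counts are
a 3 × 3 matrix over bottom/normal/top labels including self-transitions;
counts sum to T − 1.

## Graph attributes

Correlation matrices are binarized by per-entry significance (two-sided
t-transform with T − 2 df) at p < 0.05 — a single statistical threshold, not
a sparsity sweep. Negative significant correlations count by default
(|r| convention); a positive-only flag exists. Conventions for fragmented
graphs: Lp averages over connected pairs only; disconnected pairs contribute
0 to Eglob; nodal Eloc is the global efficiency of the neighbour subgraph;
assortativity is NaN when all end-node degrees are equal (the correlation is
undefined). Modularity is Newman Q of the greedy agglomerative partition
(deterministic; two equal disconnected cliques give Q = 0.5). Small-world
indices compare against degree-preserving double-edge-swap nulls (default
100; swaps saturate gracefully on rigid graphs); the criterion record uses
γ > 1, λ ∈ [0.8, 1.2], σ > 1. All metrics are verified against exhaustive
brute-force implementations on every non-isomorphic graph with ≤ 6 nodes.

## Edge communities

The module count comes from recursive spectral bipartitioning of the signed
modularity matrix B = B⁺ − B⁻ (separate null models for the positive and
negative parts of the eFC), with Newman's generalized matrix for
subdivisions and a vertex-moving fine-tuning pass after each eigenvector
split; recursion stops when the modularity gain is non-positive. A fully
constant matrix is rejected; an identity-like matrix (no off-diagonal
signal) yields a single module. The partition itself comes from k-means on
the eFC rows under correlation distance (1 − Pearson; centroids are mean
rows), with farthest-point reseeding of emptied clusters and 50 restarts by
default, best by total within-cluster distance. Community-level FC
correlates the mean member *edge* time series of each community (communities
are sets of edges); a node-basis alternative is exposed as a flag.
Community detection runs per subject, with a group-average eFC mode
available, since the level of analysis is not pinned down.

## Statistics

The screening scheme per feature: type-II partial F for the group factor in
y ~ group + covariate (covariate = subject mean FD), gate at α = 0.05;
gated features get all pairwise equal-variance two-sample t-tests (Welch is
an option); BH-FDR at q = 0.05 runs across the pooled post-hoc p-values of
all gated features (a per-feature FDR family is a flag — pooling matches
correcting the post-hoc stage as one family). A covariate collinear with
the group dummies triggers a warning and an ANOVA fallback. Type-I error of
the ANCOVA gate is verified at 5 % ± binomial error over 1000 null
replicates, and BH is verified against the explicit step-up rule on all
subsets of 8 p-values.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes —
it is the test bed, not a biophysical simulator.

* **Atlas**: K contiguous blocks (row-major on a near-cubic grid) of
  dominant loadings (0.7–1.0) with weak random cross-loadings (≤ 0.25);
  every voxel has a unique dominant network.
* **Latents**: per-subject network time series are Gaussian with an AR(1)
  coefficient of 0.3 (BOLD-like smoothness in the 0.01–0.1 Hz band) and a
  stationary covariance equal to the subject covariance: the group base
  matrix (unit diagonal, 0.1 off-diagonal) plus planted per-group deltas on
  named pairs, plus subject-level jitter (sd 0.05), eigenvalue-clipped back
  to SPD. A planted delta that the projection cannot essentially preserve
  (more than half lost) raises rather than silently shrinking.
* **Voxels**: signal = subject loadings ᵀ × latents + i.i.d. Gaussian noise
  at SNR 2 (signal RMS / noise sd — mid-range for band-passed BOLD), plus a
  weak global nuisance component (weight 0.3) that the nuisance regression
  stage can remove; subject loadings are the atlas plus clipped Gaussian
  jitter (sd 0.1).
* **Motion**: cumulative-sum Gaussian steps in 3 translations (mm) and
  3 rotations (rad), step sizes calibrated so the expected mean FD equals
  the per-group motion level (defaults mirror typical TD < ASD < ADHD
  ordering: 0.13/0.18/0.22/0.33 mm).
* **Clinical scores**: generated post hoc as target_r · z(true metric) +
  √(1 − r²) · noise, scaled to a score-like range — the simplest way to hit
  a target correlation exactly in expectation.
* **Planted edge communities** (`planted_edge_ets`): balanced modules of
  edges; an edge's series is √w · module latent + √(1−w) · private noise
  with w = 0.5. Module latents are orthogonalized in-sample: with finite
  T = 170, chance correlations between independent module latents (sd
  ≈ 0.08) are inherited coherently by entire cross-module blocks of the eFC
  matrix, which makes merged partitions the genuine signed-modularity
  optimum — under plain independent latents no algorithm could return the
  planted count. Orthogonalization makes the planted partition identifiable;
  it is the one place the generator is cleaner than any real data would be.

What the generator does **not** emulate: hemodynamic response shapes,
scanner drift and artifacts, physiological noise, spatial autocorrelation of
the noise, registration imperfections, or site effects. Passing tests
therefore demonstrate that the algorithms recover the structure they assume,
at realistic noise and motion levels — not that the pipeline is robust to
every artifact of real fMRI.

## Problem sizes and defaults

The reference ("desk-scale") cohort used by the test suite and the
acceptance script is V = 2000 voxels, K = 17 networks, T = 180 frames at
TR = 2 s, 20 subjects in four groups, NMF repeats = 5 — chosen so a full
network-mapping run completes in minutes on one CPU while keeping every
structural constant of the full-scale analysis (K, T, TR, thresholds).
Planted-effect recovery experiments use 2 × 30 subjects, K = 6, V = 120;
statistical calibration uses n = 60 with 1000 replicates. The config default
of 50 repeats reflects full-scale practice.

## Known limitations

* NMF recovery guarantees are empirical, not theoretical; badly separated
  or strongly overlapping networks can still defeat the consensus stage.
* The signed-modularity module count inherits modularity's resolution
  limits; very small or low-contrast modules merge.
* The ANCOVA assumes homoscedastic Gaussian residuals; only the t-test
  stage offers a Welch option.
* NIfTI I/O is a convenience for masked-grid exports, not a full
  neuroimaging I/O layer (no affine/orientation handling beyond identity).
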