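# Methods

## Pipeline model

The package treats network identification as consensus clustering of
per-subject connectivity features. Two feature matrices are supported for a
subject's BOLD matrix X (T time points × R ROIs):

* **Static FC** B ∈ [−1,1]^{R×R}: Pearson correlation of each ROI pair over
  the whole scan. Row B_i is ROI i's connectivity fingerprint and is the
  clustering observation.
* **SampEn of dynamic FC** E ∈ [0,∞)^{R×R}: each pair's sliding-window
  correlation series is reduced to a single complexity score, its sample
  entropy. Row E_i is the fingerprint of how *variable* ROI i's coupling is
  with every other ROI.

Subject partitions are combined through co-cluster adjacency matrices:
F with f_ij = 1 iff i and j share a cluster (diagonal 1); the subject mean
G holds co-cluster frequencies (entries are multiples of 1/n_subjects).
Re-clustering the rows of G gives the group partition. This consensus step
assumes subjects share one underlying partition and treats disagreement as
noise to be averaged out.

## Tapered sliding window

The window is a length-20 unit rectangle convolved with a Gaussian density
sampled at integer offsets over ±4 SD (SD = 3 samples, >99.99% of mass).
The realized window spans **21 samples**: with a 943-point scan and step 1
this yields 923 windows (943 − 21 + 1), the count the rest of the pipeline
assumes; the 21-sample effective length is exposed in configuration. The
full convolution of an even-length rectangle with an odd-support Gaussian
has even length, so no single centred 21-sample slice exists; the two
central alignments (mutual reverses) are averaged, keeping the taper exactly
symmetric, then renormalized to sum 1.

The taper enters as **observation weights** in a weighted Pearson
correlation (weighted means, variances, covariance), not as a signal
multiplier. This reading makes the taper a pure down-weighting of window
edges and keeps the unit diagonal exact. Windowed correlation matrices are
symmetrized to remove last-ulp floating asymmetry and clipped to [−1,1].
A window in which some ROI has zero weighted variance yields 0 correlations
for that ROI with a warning — one flat window must not abort a 923-window
stack — whereas a globally flat ROI is treated as a data defect and errors
in the static path.

## Sample entropy

SampEn(x; m, r) = −ln(U^{m+1}/U^m) with m = 2, Chebyshev distance between
embedding vectors, and tolerance r = ε·σ_x, ε = 0.2. Conventions, fixed
deliberately:

* σ_x is the **population** SD (divide by N), the common SampEn convention;
  a switch to the sample SD is exposed.
* Matching uses Θ(0) = 1: a distance exactly equal to r counts. A constant
  series therefore attains the lower bound SampEn = 0 exactly.
* U^m averages, over the N−m+1 m-vectors, the fraction of the *other*
  vectors within r (normalization 1/(N−m)); U^{m+1} analogously over the
  N−m (m+1)-vectors with 1/(N−m−1).
* U^{m+1} = 0 (no (m+1)-matches) returns +inf with a warning and is
  propagated, never clamped — silent clamping would corrupt clustering
  distances. Downstream clustering refuses non-finite features.

The implementation vectorizes the pairwise Chebyshev distance grid; its
arithmetic is validated against an independent O(N²) double-loop oracle for
exact equality in the tests. SampEn is exactly invariant to affine
rescaling of the series (r scales with σ). Monotonicity in ε (larger
tolerance ⇒ no larger entropy) is an *empirical* property of the dense-count
regime: it holds in every tested series of ≥300 points but can be inverted
by sparse match counts in very short series, so tests assert it at N = 300.

## K-means and consensus

Classical Lloyd iteration, written in-package: squared Euclidean distance,
initial centroids drawn uniformly as K distinct rows, hard assignment
(ties to the lowest cluster index), centroid update by cluster means,
stop when assignments no longer change (iteration cap 300 with a warning).
An emptied cluster is repaired by moving the row farthest from its current
centroid into it, skipping rows that are sole members of their cluster —
deterministic given the seed and preserving K non-empty clusters. Among
restarts (default 500, applied at both the subject and the group level) the
partition with the lowest total within-cluster squared distance wins.
scikit-learn's K-means is used only as an independent cross-check in the
test suite. Seeding is counter-based: subject s clusters with stream
[seed, s] and the group step with [seed, 2^20], so results do not depend on
subject processing order.

## Validity index and elbow

For each K the index is (total within-cluster squared distance) / (total
squared distance of rows to the centroids of all clusters they do not
belong to), from the best-of-restarts partition. On well-separated data the
index decays by orders of magnitude up to the true K and flattens after it.
Because a raw second difference of such a geometric decay always peaks at
the smallest K, the elbow detector measures discrete curvature on
**log(index)** (scale-invariant; indices below 1e−12 are clamped before the
log). On planted six-community data the maximal log-curvature over
K = 2..12 sits at K = 6.

Under the high-SNR synthetic conditions every subject recovers the planted
partition, so the group adjacency is exactly binary with only six distinct
rows and K > 6 is not a valid K-means input for it. The K-scan is therefore
run on the subject-averaged static-FC matrix, whose rows are continuous and
distinct at every K in 2..12; with noisy real data the group adjacency
itself would be scanned.

## Cluster–network agreement

Clusters are matched to reference networks by maximizing the total matched
ROI count over all bijections (linear assignment). On tables whose
per-cluster argmax networks are already distinct — including both packaged
reference tables — this coincides with the greedy per-cluster rule; on
adversarial tables with argmax collisions the assignment optimum is the
documented extension. Overlap (precision) and consistency (Jaccard) ratios
are kept as exact rationals; percentage rendering quantizes to 2 decimals,
rounding half away from zero. Consistency never exceeds overlap
(|C∩N|/|C∪N| ≤ |C∩N|/|C|).

## Synthetic cohort generator

Emulates the statistical shape of a preprocessed resting-state acquisition:
31 subjects × 160 ROIs × 943 time points at TR 0.475 s (947 acquired
volumes minus 4 discarded at preprocessing — the pipeline consumes
post-discard series), band-limited to 0.01–0.08 Hz, six communities of
sizes 34/21/32/33/22/18. Per subject, one latent signal per (community,
hidden state) and private per-ROI noise are drawn as white Gaussian noise
band-limited by FFT masking (bins outside the band zeroed — exactly
reproducible, no filter transients) and standardized; ROI i in community c
reads `within·latent(c, state(t), t) + noise·private(i, t)`. Hidden states
follow a Markov chain with uniform off-diagonal transitions and geometric
dwell times (mean `state_dwell_mean`), making windowed coupling genuinely
non-stationary when `n_states > 1`.

Defaults, chosen once: `within_strength = 0.8`, `noise_strength = 0.4`
(within-community static correlation ≈ 0.8, a strong but noisy planted
structure), `n_states = 1` (stationary coupling; the dynamic path must not
depend on engineered state switching), `state_dwell_mean = 50` TRs (~24 s,
the time scale usually reported for dynamic FC states). The generator does
**not** model hemodynamics, spatial structure, motion or physiological
artifacts, scanner drift, or inter-subject variability in community
membership; recovery results on it demonstrate correctness of the pipeline
machinery, not performance on real fMRI.

## Problem sizes

The validation runs use: the full 31 × 160 × 943 cohort for the static-FC
consensus path and the K-scan; a reduced cohort (8 subjects × 60 ROIs,
community sizes 13/8/12/12/8/7, full 943-point scans hence 923 windows) for
the SampEn path, whose 12,720-pair entropy matrices per full-size subject
are the single most expensive step — the reduction preserves every
qualitative property being checked. Under these conditions both paths
recover the planted partition exactly (adjusted Rand index 1.0) and the
distance between the group adjacency and the planted-partition adjacency is
0; agreement with real-cohort results additionally requires the original
fMRI data, which the packaged confusion tables summarize.

## Known limitations

* Real preprocessed fMRI is the intended input; no volume-level
  preprocessing (registration, nuisance regression, filtering) is included.
* The elbow detector assumes a monotonically decreasing validity curve;
  on data without cluster structure the log-curvature maximum is not
  meaningful.
* SampEn of near-constant dynamic-FC series (within-community pairs at very
  high SNR) can hit the +inf branch; the pipeline surfaces this rather than
  guessing a value.
* The consensus step assumes one shared partition across subjects.
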