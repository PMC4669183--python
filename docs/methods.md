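# Methods

`mr2plan` implements an MR-only treatment-planning workflow for the rat
brain on a kilovoltage small-animal irradiation platform: multi-sequence
MR volumes are bias-corrected, segmented into air / soft tissue / bone,
converted to a pseudo-CT by bulk tissue-property assignment, and used for
dose calculation whose DVH metrics are compared against CT-based planning.
This note records the models, the tunables that matter, and the design
choices made where the problem was genuinely open.

## Synthetic rat-head phantom

The package ships a generator rather than data. A phantom is built
inside-out on a 128³ grid with 0.275 × 0.5 × 0.275 mm voxels (matching a
typical 7 T rodent acquisition matrix): an ellipsoidal brain (soft tissue,
default semi-axes 13 × 22 × 12 mm), a skull shell of configurable
thickness (default 0.7 mm), a soft-tissue scalp layer outside the shell
(default 1.2 mm), and air beyond. The shell has a posterior aperture
(default 50° cone) where the spinal canal exits; this both mimics anatomy
and connects brain and scalp into one soft-tissue component, which the
T1-based head-masking recipe relies on (see below). Internal air pockets
(tympanic-bulla-like cavities) and thin coronal bone septa in the anterior
soft tissue emulate the intricate rostrum, the structure hardest to
segment from MR. Voxels are pure-class: no partial-volume mixing, no
k-space simulation, no cone-beam projection physics.

MR intensities are a class-mean lookup per sequence, multiplied by a
smooth positive bias field and passed through Rician noise (magnitude of
two noisy quadrature channels), so signal-free air shows the
characteristic σ√(π/2) noise floor. The default intensity tables are
synthetic configuration, not measured values; what they encode is the
contrast structure the workflow depends on: bone is near the noise floor
on conventional sequences (T1, T2, UTE2 at 2 ms echo time) and
hyperintense on short-echo sequences (UTE1 at 20 µs, ZTE), while soft
tissue is bright everywhere. Default noise is 5 % of each sequence's
soft-tissue mean; the default bias field spans 1 ± 0.3 with a 12 mm
correlation length, synthesized as Gaussian-filtered white noise (on a
coarse grid, spline-upsampled) and normalised to mean exactly 1. The bias
ground truth is deliberately *not* drawn from the estimator's own model
class. The reference CT is a Hounsfield lookup (air −1000, soft 40, bone
700) with Gaussian noise (default σ 30 HU).

Consequences for interpretation: passing segmentation tests on these
phantoms demonstrates that the pipeline's machinery is correct and that
the *qualitative* sequence-combination ranking (short-TE channels are
necessary for air/bone separation; single conventional sequences fail) is
reproduced. Absolute Dice values are far higher than on real animals,
where partial volume, anatomy-dependent contrast and registration error
dominate; the phantom's Dice numbers should never be quoted as expected
real-data performance.

## Bias-field correction (CLIC)

The estimator minimises the coherent-local-intensity-clustering energy

    E(u, c, b) = Σ_x Σ_i u_i(x)^q [ K * (I(x) − b(·) c_i)² ](x)

over fuzzy memberships `u`, class centroids `c`, and a voxel-wise bias
field `b`, where `K` is a truncated Gaussian window (3 σ support) and all
window sums are evaluated by separable Gaussian convolution restricted to
the head mask. Each block has a closed-form minimiser given the other
two, so the cyclic update decreases the energy monotonically — a property
the tests assert from the stored energy trace. Only the bias estimate is
kept; the fuzzy classification from this stage is discarded and the real
segmentation runs afterwards on the corrected images.

Tunables: 3 classes; fuzzifier q = 2; relative energy tolerance 1e-4 with
a 50-iteration cap (non-convergence is flagged, not raised); centroids
initialised at the 10th/50th/90th percentiles of masked intensity, making
the stage fully deterministic. The window scale defaults to 2 mm: the
local-constancy assumption wants the window small against the bias
correlation length (~12 mm here) but large against the voxel, and on
64³–128³ phantoms recovery correlation degrades monotonically as the
window widens (≈0.99 at 2 mm vs ≈0.95 at 4 mm vs ≈0.89 at 6 mm).
Correction is limited to the head mask because the multiplicative model is
meaningless in the Rician background; the returned field is normalised to
mean 1 over the mask, so correction preserves mean intensity.

## Segmentation: multi-channel fuzzy c-means

Any non-empty subset of the five sequences is stacked into per-voxel
feature vectors and clustered into c = 3 fuzzy classes by minimising
Q = Σ_i Σ_j u_ij^m ‖x_i − c_j‖² under Σ_j u_ij = 1, with the standard
alternating closed-form updates (m = 2, relative tolerance 1e-5, cap 200
iterations). Channels are z-scored over the clustering mask first —
without normalisation the Euclidean norm across sequences with different
intensity scales is meaningless — and put in a canonical order so permuted
subsets are bit-identical. Initialisation is k-means++ on a deterministic
4096-voxel subsample with a recorded seed. A spatial-smoothness hook
(neighbourhood membership averaging, weight β) exists but defaults to off;
enabling it voids the strict monotonicity guarantee.

Clustering runs on the whole volume by default: the large background air
population anchors the air cluster, which is far more robust than
clustering inside the head mask where air is only a few cavity voxels
(masked clustering remains available via the `cluster_mask` argument).

Clusters are named air / soft / bone from raw-intensity centroid
signatures: the cluster darkest on the conventional channels is air; of
the remaining two, the one with the higher short-TE-to-conventional
intensity ratio is bone when a short-TE channel is present (higher
short-TE mean when no conventional channel is in the subset), otherwise
the darker remaining cluster is bone. Ties within a relative 1e-6 fall
back to centroid norm, with a warning. Hard labels are the per-voxel
membership argmax, ties resolved toward air before soft before bone, and
everything outside the head mask is forced to air.

The head mask itself comes from the T1 image: Otsu threshold, largest
connected foreground component, morphological closing with a 2-voxel
ball. On a real head — and on the phantom, thanks to scalp plus posterior
aperture — the T1 foreground is scalp∪brain connected through the neck,
and the closing bridges the thin dark skull so the mask covers the whole
head.

With five sequences the subset sweep yields 2⁵ − 1 = 31 segmentations,
enumerated by size then lexicographically in canonical order.

## Similarity

Agreement with the reference segmentation is the 3-D Dice coefficient
2|R_t ∩ A_t| / (|R_t| + |A_t|) per class, computed independently for bone
and soft tissue; their mean is the ranking measure. Air Dice is reported
as a diagnostic only (the background would otherwise dominate). A class
absent from both volumes scores 1 with a warning — vacuous agreement,
kept finite so rankings stay total. Aggregation across phantom "animals"
is the arithmetic mean ± SD of per-animal values.

## Pseudo-CT and dose engine

Dose calculation needs attenuation, which MR intensities do not provide;
each tissue class is therefore assigned fixed bulk properties. The default
table, representative of a ~70 kVp beam (≈40 keV effective): air
ρ = 0.0012 g/cm³, soft tissue ρ = 1.0, cortical-bone surrogate ρ = 1.6,
with μ/ρ of 0.2485, 0.2683 and 0.6655 cm²/g and μ_en/ρ of 0.0671, 0.0647
and 0.3026 cm²/g respectively (standard tabulated values at 40 keV).
Because the identical table is applied to the CT-derived and MR-derived
segmentations, the plan comparison is insensitive to the absolute
numbers — it probes segmentation differences only.

The dose engine is a deliberately simple, fully documented primary-photon
model at a single effective energy:

    D(p) ∝ (SAD / r)² · exp(−∫ μ dl) · (μ_en/ρ)(p)

for voxels inside the diverging rectangular field cone (default 3 × 3 mm
at the isocenter, SAD 350 mm), with exact voxel-intersection radiological
paths (Siddon's method, vectorised over rays), sharp collimation, and no
scatter, spectrum or penumbra. Arcs are discretised into equal-weight
static beams (default step 5°; halving the step from 10° to 5° moves D50
by <0.5 % on a symmetric phantom). Geometry: at gantry 0/couch 0 the
source is on +z; the gantry rotates the source about y, then the couch
about z (right-handed, fixed axes).

Plans are scaled so the 2.5 mm spherical target receives the prescription
(default 15 Gy) as its *mean* dose; a D50-based prescription mode is
available. For CT-vs-MR comparison, the machine scale is fixed by the
CT-based calculation and reapplied to the MR-based one, so identical
segmentations give ratios of exactly 1, and segmentation errors move the
ratios — an overestimated anterior skull makes the single anterior beam's
MR calculation underestimate the target dose (ratio < 1), while
three-arc plans, which spread the entry directions, are markedly less
sensitive to the same error.

Since only the relative CT-vs-MR comparison is claimed, the engine's
simplifications (no scatter, no spectrum, no output calibration) apply
identically to both arms; absolute dose values are machine units scaled
to the prescription and carry no clinical meaning.

## DVH analysis and statistics

The cumulative DVH of the target reports, for each dose level, the VOI
fraction receiving at least that dose (≥-convention); bins are at most
0.05 Gy wide and additionally include every exact voxel dose, so the
curve is the exact step function of the data. D_x (x = 5, 50, 90) is the
largest bin whose fraction is still ≥ x/100 — exact on voxel data (a
two-voxel VOI at 10/20 Gy has D50 = 20 Gy) and within one bin width of
the continuous crossing otherwise, which keeps D5 ≥ D50 ≥ D90 by
construction. Group differences are tested with the two-sided
Mann-Whitney U test: the exact null distribution for combined n ≤ 20
without ties, otherwise the normal approximation with tie correction
(significance at p < 0.05).

## Experiment driver and reproducibility

`run_experiment` runs N synthetic animals (default 6) end to end and
emits the per-animal and aggregated Dice sweep, absolute and normalised
dose metrics for three beam arrangements — one static anterior beam, one
120° coplanar arc (couch 0°), three non-coplanar 120° arcs (couch 0°,
45°, 90°) — the Mann-Whitney table, and a provenance JSON capturing every
parameter. Per-animal seeds derive deterministically from the master seed
via `numpy` seed sequences; identical configurations produce
byte-identical CSVs. Default planning methods are the ZTE+UTE2,
T1+T2+UTE1 and UTE1+UTE2 combinations, named by their exact input
subsets.

Problem sizes used by the test suite and the acceptance script are the
package's own choices: full 128³ phantoms for segmentation recovery and
dose directionality (arcs at 10° there), 64³ heads with the full field of
view (spacing doubled, skull 1.2 mm so the shell still spans a voxel) for
bias-recovery studies and the multi-animal acceptance experiment (3
animals, arcs at 10°).

## Known limitations

- Pure-class voxels make segmentation on phantoms far easier than on real
  data; Dice values near 1 are expected and say nothing about in-vivo
  accuracy.
- The dose engine omits scatter, which at 70 kVp in a rat head is a
  genuine contribution; only relative CT-vs-MR conclusions are supported.
- Inputs are assumed co-registered; no registration is performed.
- Three tissue classes suit the head; thorax or abdomen would need more.
- The FCM "modification" hook is limited to optional neighbourhood
  membership smoothing; no atlas or learning-based priors.
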