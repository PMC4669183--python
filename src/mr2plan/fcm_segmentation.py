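"""Multi-channel fuzzy c-means tissue segmentation.

Any non-empty subset of the five co-registered, bias-corrected MR volumes
(T1, T2, UTE1, UTE2, ZTE) is stacked into per-voxel feature vectors and
clustered into three fuzzy classes by minimising

    Q = sum_i sum_j  u_ij^m  || x_i - c_j ||^2 ,   sum_j u_ij = 1,

with the standard alternating closed-form updates.  Clusters are then
named air / soft tissue / bone from their centroid signatures in raw
(un-normalised) intensity space, voxels are hard-classified by maximum
membership, and everything outside a T1-derived head mask is forced to
air.  With five sequences there are 2^5 - 1 = 31 distinct input subsets;
``sweep_combinations`` produces the automatic segmentation (ASMR image)
for all of them.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import ball
from sklearn.cluster import kmeans_plusplus

from .phantom import CONVENTIONAL, SEQUENCES, SHORT_TE
from .volume import AIR, BONE, SOFT, ImageVolume, LabelVolume

log = logging.getLogger(__name__)


class MaskingError(ValueError):
    """Head-mask construction failed (e.g. empty foreground)."""


class ClusteringError(ValueError):
    """The feature stack cannot support c distinct clusters."""


@dataclass(frozen=True)
class FcmParams:
    """Clustering tunables: number of classes ``c``, fuzzifier ``m``
    (standard value 2), relative-change stopping tolerance on Q, and an
    optional spatial smoothness weight ``beta`` (neighbourhood membership
    averaging; 0 disables it)."""

    c: int = 3
    m: float = 2.0
    tol: float = 1e-5
    max_iters: int = 200
    beta: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.c < 2:
            raise ValueError("need at least two clusters")
        if self.m <= 1:
            raise ValueError("fuzzifier m must exceed 1")
        if not 0 <= self.beta < 1:
            raise ValueError("beta must lie in [0, 1)")


@dataclass
class FeatureStack:
    """Per-voxel feature vectors for clustering.

    ``channels`` is the canonical-ordered subset of sequence names;
    ``data`` the (n_voxels, n_channels) z-scored features over ``mask``;
    ``raw`` the matching un-normalised intensities (used for cluster
    identification); ``mask`` marks the voxels entering clustering.
    """

    channels: tuple[str, ...]
    data: np.ndarray
    raw: np.ndarray
    mask: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]


@dataclass
class FcmResult:
    memberships: np.ndarray  # (n_voxels, c)
    centroids: np.ndarray    # (c, n_channels)
    objective_trace: list[float]
    n_iters: int
    fuzzifier_m: float
    converged: bool


@dataclass
class AsmrImage:
    """Automatic segmented MR image: the hard three-class labelling
    produced from one subset of sequences."""

    labels: LabelVolume
    combination: tuple[str, ...]
    provenance: dict


def canonical_subset(subset) -> tuple[str, ...]:
    """Order a subset of sequence names canonically (T1, T2, UTE1, UTE2, ZTE)."""
    subset = tuple(subset)
    unknown = [s for s in subset if s not in SEQUENCES]
    if unknown:
        raise ValueError(f"unknown sequence names: {unknown}")
    if len(set(subset)) != len(subset):
        raise ValueError(f"duplicate sequence names in subset {subset}")
    return tuple(sorted(subset, key=SEQUENCES.index))


def subset_name(subset) -> str:
    return "-".join(canonical_subset(subset))


# ---------------------------------------------------------------------------
# head mask
# ---------------------------------------------------------------------------

def make_air_mask(t1: ImageVolume) -> np.ndarray:
    """Head mask from the bias-corrected T1 image.

    Otsu threshold, largest connected component, morphological closing with
    a ball of radius 2 voxels.  The closing bridges the thin (dark) skull
    between scalp and brain so the mask covers the whole head; its
    complement is forced to air after classification.
    """
    data = np.asarray(t1.data, dtype=float)
    if np.ptp(data) == 0:
        raise MaskingError("T1 image is constant; cannot threshold")
    thr = threshold_otsu(data)
    fg = data > thr
    if not fg.any():
        raise MaskingError("empty foreground after Otsu thresholding")
    lab, n = ndimage.label(fg)
    if n == 0:
        raise MaskingError("no connected foreground component")
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    largest = int(np.argmax(sizes)) + 1
    comp = lab == largest
    closed = ndimage.binary_closing(comp, structure=ball(2))
    return closed


# ---------------------------------------------------------------------------
# features
# ---------------------------------------------------------------------------

def build_features(
    images: dict[str, ImageVolume],
    subset,
    mask: np.ndarray | None = None,
) -> FeatureStack:
    """Stack and z-score the selected channels over the clustering mask.

    Channels are put in canonical order, so permuted subsets give
    bit-identical stacks.  By default every voxel enters clustering (the
    head mask is applied later, at classification time).
    """
    subset = canonical_subset(subset)
    if not subset:
        raise ValueError("subset must be non-empty")
    missing = [s for s in subset if s not in images]
    if missing:
        raise ValueError(f"subset members missing from images: {missing}")
    ref = images[subset[0]]
    for s in subset[1:]:
        ref.check_same_grid(images[s])
    if mask is None:
        mask = np.ones(ref.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != ref.shape:
        raise ValueError("mask shape does not match images")

    raw = np.stack([np.asarray(images[s].data, dtype=float)[mask] for s in subset], axis=1)
    mu = raw.mean(axis=0)
    sd = raw.std(axis=0)
    if np.any(sd == 0):
        flat = [subset[i] for i in np.flatnonzero(sd == 0)]
        raise ClusteringError(f"channels with zero variance over mask: {flat}")
    data = (raw - mu) / sd
    return FeatureStack(
        channels=subset, data=data, raw=raw, mask=mask,
        spacing=ref.spacing, origin=ref.origin,
    )


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def _sq_distances(x: np.ndarray, centroids: np.ndarray, xx: np.ndarray | None = None) -> np.ndarray:
    # (n, c) squared Euclidean distances via ||x||^2 - 2 x.c + ||c||^2;
    # the ||x||^2 term can be precomputed and reused across iterations
    if xx is None:
        xx = np.einsum("nd,nd->n", x, x)
    d = x @ centroids.T
    d *= -2.0
    d += xx[:, None]
    d += np.einsum("cd,cd->c", centroids, centroids)[None, :]
    return np.maximum(d, 0.0)


def fcm_objective(x: np.ndarray, u: np.ndarray, centroids: np.ndarray, m: float) -> float:
    """The FCM objective Q at an arbitrary state (independent evaluation)."""
    return float((u**m * _sq_distances(x, centroids)).sum())


def fcm_cluster(stack: FeatureStack, params: FcmParams | None = None) -> FcmResult:
    """Fuzzy c-means on the feature stack.

    Alternates the closed-form membership and centroid updates until the
    relative change of Q drops below ``tol`` or ``max_iters`` is reached.
    Voxels hitting a centroid exactly receive membership 1 for that
    cluster.  Initialisation is k-means++ on a deterministic subsample.
    """
    if params is None:
        params = FcmParams()
    x = np.asarray(stack.data, dtype=float)
    n = x.shape[0]
    if n < params.c:
        raise ClusteringError(f"only {n} voxels in mask; need >= {params.c}")
    if np.ptp(x, axis=0).max() == 0:
        raise ClusteringError("all feature vectors identical; clustering is degenerate")

    rng = np.random.default_rng(params.seed)
    n_sub = min(n, 4096)
    idx = rng.choice(n, size=n_sub, replace=False)
    centroids, _ = kmeans_plusplus(x[idx], n_clusters=params.c, random_state=params.seed)
    centroids = centroids.astype(float)

    m = params.m
    expo = -1.0 / (m - 1.0)
    trace: list[float] = []
    converged = False
    u = np.full((n, params.c), 1.0 / params.c)
    xx = np.einsum("nd,nd->n", x, x)
    for it in range(params.max_iters):
        d = _sq_distances(x, centroids, xx)
        exact = d < 1e-24
        d_safe = np.maximum(d, 1e-24)
        w = d_safe**expo if expo != -1.0 else 1.0 / d_safe
        u = w / w.sum(axis=1, keepdims=True)
        hit_rows = exact.any(axis=1)
        if hit_rows.any():
            u[hit_rows] = 0.0
            u[hit_rows, np.argmax(exact[hit_rows], axis=1)] = 1.0
        if params.beta > 0:
            u = _smooth_memberships(u, stack, params.beta)

        um = np.square(u) if m == 2.0 else u**m
        centroids = (um.T @ x) / np.maximum(um.sum(axis=0)[:, None], 1e-24)

        q = float((um * _sq_distances(x, centroids, xx)).sum())
        trace.append(q)
        if len(trace) >= 2:
            prev = trace[-2]
            if abs(prev - q) <= params.tol * max(abs(prev), 1e-24):
                converged = True
                break

    if not converged:
        log.warning("FCM did not converge within %d iterations", params.max_iters)
    return FcmResult(
        memberships=u, centroids=centroids, objective_trace=trace,
        n_iters=len(trace), fuzzifier_m=m, converged=converged,
    )


def _smooth_memberships(u: np.ndarray, stack: FeatureStack, beta: float) -> np.ndarray:
    """Optional spatial regularisation: blend each voxel's memberships with
    the 6-neighbourhood average, then renormalise.  Breaks the strict
    monotonicity guarantee of plain FCM; off by default."""
    full = np.zeros(stack.mask.shape + (u.shape[1],))
    full[stack.mask] = u
    kernel = np.zeros((3, 3, 3))
    kernel[1, 1, 1] = 0.0
    kernel[0, 1, 1] = kernel[2, 1, 1] = kernel[1, 0, 1] = kernel[1, 2, 1] = 1 / 6
    kernel[1, 1, 0] = kernel[1, 1, 2] = 1 / 6
    for j in range(u.shape[1]):
        avg = ndimage.convolve(full[..., j], kernel, mode="nearest")
        full[..., j] = (1 - beta) * full[..., j] + beta * avg
    out = full[stack.mask]
    return out / np.maximum(out.sum(axis=1, keepdims=True), 1e-24)


# ---------------------------------------------------------------------------
# cluster identification and classification
# ---------------------------------------------------------------------------

def identify_clusters(result: FcmResult, stack: FeatureStack) -> dict[int, int]:
    """Name the c=3 clusters as air / soft / bone from raw-intensity
    centroid signatures.

    Air is the cluster with the lowest mean raw intensity over the
    conventional channels (T1/T2/UTE2; all channels if none present).  Of
    the remaining two: if a short-TE channel (UTE1/ZTE) is present, bone is
    the cluster with the higher short-TE-to-conventional intensity ratio
    (higher short-TE mean when no conventional channel exists); otherwise
    bone is the darker remaining cluster.  Ties within a relative 1e-6 are
    broken deterministically by centroid norm, with a warning.
    """
    if result.centroids.shape[0] != 3:
        raise ValueError("cluster identification requires exactly 3 clusters")
    channels = stack.channels
    conv_idx = [i for i, ch in enumerate(channels) if ch in CONVENTIONAL]
    short_idx = [i for i, ch in enumerate(channels) if ch in SHORT_TE]

    # membership-weighted mean raw intensity of each cluster in each channel
    w = result.memberships  # (n, c)
    wsum = np.maximum(w.sum(axis=0), 1e-24)
    raw_centroids = (w.T @ stack.raw) / wsum[:, None]  # (c, n_channels)

    ref_idx = conv_idx if conv_idx else list(range(len(channels)))
    conv_mean = raw_centroids[:, ref_idx].mean(axis=1)

    order = _argsort_with_tie_warning(conv_mean, result.centroids)
    air_cluster = order[0]
    rest = [j for j in range(3) if j != air_cluster]

    if short_idx:
        short_mean = raw_centroids[:, short_idx].mean(axis=1)
        if conv_idx:
            score = short_mean / np.maximum(conv_mean, 1e-24)
        else:
            score = short_mean
        pair = sorted(rest, key=lambda j: (score[j], np.linalg.norm(result.centroids[j])))
        if np.isclose(score[pair[0]], score[pair[1]], rtol=1e-6):
            warnings.warn("ambiguous bone/soft signature; tie broken by centroid norm")
        soft_cluster, bone_cluster = pair[0], pair[1]
    else:
        pair = sorted(rest, key=lambda j: (conv_mean[j], np.linalg.norm(result.centroids[j])))
        if np.isclose(conv_mean[pair[0]], conv_mean[pair[1]], rtol=1e-6):
            warnings.warn("ambiguous bone/soft signature; tie broken by centroid norm")
        bone_cluster, soft_cluster = pair[0], pair[1]

    return {air_cluster: AIR, soft_cluster: SOFT, bone_cluster: BONE}


def _argsort_with_tie_warning(values: np.ndarray, centroids: np.ndarray) -> list[int]:
    order = sorted(range(len(values)), key=lambda j: (values[j], np.linalg.norm(centroids[j])))
    if np.isclose(values[order[0]], values[order[1]], rtol=1e-6):
        warnings.warn("ambiguous air signature; tie broken by centroid norm")
    return order


def classify(
    result: FcmResult,
    mapping: dict[int, int],
    air_mask: np.ndarray,
    stack: FeatureStack,
    provenance: dict | None = None,
) -> AsmrImage:
    """Hard-classify by maximum membership and apply the head mask.

    Ties are broken toward the class earlier in (air, soft, bone); voxels
    outside ``air_mask`` are forced to air.
    """
    if sorted(mapping.values()) != [AIR, SOFT, BONE]:
        raise ValueError("mapping must be a bijection onto {air, soft, bone}")
    # reorder membership columns by mapped class so argmax's first-wins tie
    # rule lands on the earlier tissue class
    cluster_of_class = {tissue: cluster for cluster, tissue in mapping.items()}
    ordered = result.memberships[:, [cluster_of_class[t] for t in (AIR, SOFT, BONE)]]
    hard = np.argmax(ordered, axis=1)  # already tissue-coded

    labels = np.full(stack.mask.shape, AIR, dtype=np.int16)
    labels[stack.mask] = hard
    labels[~np.asarray(air_mask, dtype=bool)] = AIR
    vol = LabelVolume(labels, stack.spacing, stack.origin)
    return AsmrImage(
        labels=vol,
        combination=stack.channels,
        provenance=provenance or {},
    )


def segment_subset(
    images: dict[str, ImageVolume],
    subset,
    air_mask: np.ndarray,
    params: FcmParams | None = None,
    cluster_mask: np.ndarray | None = None,
) -> AsmrImage:
    """Segment one subset of sequences end to end.

    ``cluster_mask`` restricts which voxels enter clustering (default: the
    whole volume, so the large background air population anchors the air
    cluster); ``air_mask`` is always applied to the final labels.
    """
    if params is None:
        params = FcmParams()
    stack = build_features(images, subset, mask=cluster_mask)
    result = fcm_cluster(stack, params)
    mapping = identify_clusters(result, stack)
    prov = {
        "subset": list(stack.channels),
        "seed": params.seed,
        "m": params.m,
        "tol": params.tol,
        "beta": params.beta,
        "n_iters": result.n_iters,
        "converged": result.converged,
    }
    return classify(result, mapping, air_mask, stack, provenance=prov)


def all_subsets(sequences=SEQUENCES) -> list[tuple[str, ...]]:
    """All non-empty subsets, ordered by size then lexicographically in
    canonical sequence order."""
    seqs = canonical_subset(sequences)
    out: list[tuple[str, ...]] = []
    for size in range(1, len(seqs) + 1):
        for comb in itertools.combinations(seqs, size):
            out.append(comb)
    return out


def sweep_combinations(
    images: dict[str, ImageVolume],
    air_mask: np.ndarray,
    params: FcmParams | None = None,
    cluster_mask: np.ndarray | None = None,
) -> list[AsmrImage]:
    """Segment every non-empty subset of the available sequences
    (31 for the full five-sequence protocol)."""
    if params is None:
        params = FcmParams()
    available = canonical_subset([s for s in SEQUENCES if s in images])
    if not available:
        raise ValueError("no recognised sequences in images")
    if len(available) < len(SEQUENCES):
        log.info(
            "only %d sequences available; sweeping %d subsets",
            len(available), 2 ** len(available) - 1,
        )
    results = []
    for i, subset in enumerate(all_subsets(available)):
        sub_params = FcmParams(
            c=params.c, m=params.m, tol=params.tol, max_iters=params.max_iters,
            beta=params.beta, seed=params.seed + i,
        )
        results.append(segment_subset(images, subset, air_mask, sub_params, cluster_mask))
    return results
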