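import numpy as np
import pytest

from mr2plan.fcm_segmentation import (
    AsmrImage,
    ClusteringError,
    FcmParams,
    FcmResult,
    MaskingError,
    all_subsets,
    build_features,
    canonical_subset,
    classify,
    fcm_cluster,
    fcm_objective,
    identify_clusters,
    make_air_mask,
    segment_subset,
    subset_name,
    sweep_combinations,
)
from mr2plan.volume import AIR, BONE, SOFT, ImageVolume

from conftest import TINY_SPEC


# ---------------------------------------------------------------------------
# head mask
# ---------------------------------------------------------------------------

def test_air_mask_matches_truth_head_on_clean_t1(tiny_truth):
    mask = make_air_mask(tiny_truth.clean_images["T1"])
    head = tiny_truth.labels.data != AIR
    dice = 2 * (mask & head).sum() / (mask.sum() + head.sum())
    assert dice >= 0.99


def test_air_mask_constant_image_fails():
    img = ImageVolume(np.full((8, 8, 8), 3.0), spacing=(1, 1, 1))
    with pytest.raises(MaskingError):
        make_air_mask(img)


def test_air_mask_drops_isolated_speck(tiny_truth):
    t1 = tiny_truth.clean_images["T1"]
    data = t1.data.copy()
    data[1, 1, 1] = data.max() * 2  # bright artifact far from the head
    mask = make_air_mask(t1.like(data))
    assert not mask[1, 1, 1]


# ---------------------------------------------------------------------------
# features
# ---------------------------------------------------------------------------

def test_feature_stack_order_invariance(tiny_truth):
    imgs = tiny_truth.noisy_images
    a = build_features(imgs, ("ZTE", "UTE2"))
    b = build_features(imgs, ("UTE2", "ZTE"))
    assert a.channels == b.channels == ("UTE2", "ZTE")
    assert np.array_equal(a.data, b.data)


def test_feature_normalisation_moments(tiny_truth):
    stack = build_features(tiny_truth.noisy_images, ("T1", "UTE1", "ZTE"))
    assert np.allclose(stack.data.mean(axis=0), 0.0, atol=1e-6)
    assert np.allclose(stack.data.var(axis=0), 1.0, atol=1e-6)


def test_feature_errors(tiny_truth):
    with pytest.raises(ValueError):
        build_features(tiny_truth.noisy_images, ())
    with pytest.raises(ValueError):
        build_features({"T1": tiny_truth.noisy_images["T1"]}, ("T1", "ZTE"))
    with pytest.raises(ValueError):
        canonical_subset(("T1", "T1"))


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def _cloud_stack(means, n=200, spread=0.1, seed=0):
    rng = np.random.default_rng(seed)
    pts = np.concatenate([m + spread * rng.standard_normal((n, len(means[0]))) for m in means])
    mask = np.ones((pts.shape[0], 1, 1), dtype=bool)
    from mr2plan.fcm_segmentation import FeatureStack

    return FeatureStack(channels=("T1", "T2")[: len(means[0])], data=pts, raw=pts,
                        mask=mask, spacing=(1, 1, 1), origin=(0, 0, 0)), pts


def test_well_separated_clouds_recovered():
    means = [np.array([0.0, 0.0]), np.array([10.0, 0.0]), np.array([0.0, 10.0])]
    stack, pts = _cloud_stack(means, spread=0.1, seed=1)
    res = fcm_cluster(stack, FcmParams(seed=0))
    # match each cloud mean to nearest centroid
    hard = np.argmax(res.memberships, axis=1)
    for ci, m in enumerate(means):
        d = np.linalg.norm(res.centroids - m, axis=1)
        j = int(np.argmin(d))
        assert d[j] < 0.1  # within 1 % of the 10-unit separation
        assert np.all(hard[ci * 200 : (ci + 1) * 200] == j)


def test_objective_trace_monotone_and_final_value_consistent():
    means = [np.array([0.0, 0.0]), np.array([4.0, 0.0]), np.array([0.0, 4.0])]
    stack, pts = _cloud_stack(means, spread=0.5, seed=2)
    res = fcm_cluster(stack, FcmParams(seed=0))
    trace = np.array(res.objective_trace)
    assert np.all(np.diff(trace) <= 1e-9 * np.abs(trace[:-1]) + 1e-12)
    assert fcm_objective(stack.data, res.memberships, res.centroids, res.fuzzifier_m) == pytest.approx(
        trace[-1], rel=1e-9
    )
    assert np.allclose(res.memberships.sum(axis=1), 1.0)


def test_equidistant_point_gets_half_memberships():
    from mr2plan.fcm_segmentation import FeatureStack

    pts = np.array([[-1.0], [-1.0], [1.0], [1.0], [0.0]])
    mask = np.ones((5, 1, 1), dtype=bool)
    stack = FeatureStack(channels=("T1",), data=pts, raw=pts, mask=mask,
                         spacing=(1, 1, 1), origin=(0, 0, 0))
    res = fcm_cluster(stack, FcmParams(c=2, seed=0))
    assert np.allclose(res.memberships[-1], [0.5, 0.5], atol=1e-6)


def test_exact_centroid_hit_gets_unit_membership():
    from mr2plan.fcm_segmentation import FeatureStack

    # two tight clusters plus a point exactly on one converged centroid
    pts = np.concatenate([np.full((50, 1), -5.0), np.full((50, 1), 5.0)])
    mask = np.ones((100, 1, 1), dtype=bool)
    stack = FeatureStack(channels=("T1",), data=pts, raw=pts, mask=mask,
                         spacing=(1, 1, 1), origin=(0, 0, 0))
    res = fcm_cluster(stack, FcmParams(c=2, seed=0))
    hit = np.isclose(np.abs(res.centroids).ravel(), 5.0, atol=1e-9)
    assert hit.all()
    assert np.allclose(np.sort(res.memberships[0]), [0.0, 1.0])


def test_degenerate_stack_raises():
    from mr2plan.fcm_segmentation import FeatureStack

    pts = np.ones((20, 2))
    mask = np.ones((20, 1, 1), dtype=bool)
    stack = FeatureStack(channels=("T1", "T2"), data=pts, raw=pts, mask=mask,
                         spacing=(1, 1, 1), origin=(0, 0, 0))
    with pytest.raises(ClusteringError):
        fcm_cluster(stack, FcmParams(seed=0))


def test_oracle_equivalence_small_instance():
    """Final Q matches the best of 50 random-restart alternating optimisers."""
    rng = np.random.default_rng(3)
    means = [np.array([0.0, 0.0]), np.array([3.0, 1.0]), np.array([1.0, 4.0])]
    pts = np.concatenate([m + 0.4 * rng.standard_normal((66, 2)) for m in means])[:200]
    from mr2plan.fcm_segmentation import FeatureStack

    mask = np.ones((pts.shape[0], 1, 1), dtype=bool)
    stack = FeatureStack(channels=("T1", "T2"), data=pts, raw=pts, mask=mask,
                         spacing=(1, 1, 1), origin=(0, 0, 0))
    res = fcm_cluster(stack, FcmParams(seed=0, tol=1e-12, max_iters=500))

    def brute_force_fcm(x, c, m, restarts=50, iters=300):
        best = np.inf
        orng = np.random.default_rng(12345)
        for _ in range(restarts):
            cent = x[orng.choice(len(x), c, replace=False)].astype(float)
            for _ in range(iters):
                d = np.maximum(((x[:, None, :] - cent[None]) ** 2).sum(-1), 1e-24)
                w = d ** (-1.0 / (m - 1))
                u = w / w.sum(1, keepdims=True)
                um = u**m
                cent = (um.T @ x) / um.sum(0)[:, None]
            q = (um * ((x[:, None, :] - cent[None]) ** 2).sum(-1)).sum()
            best = min(best, q)
        return best

    q_oracle = brute_force_fcm(pts, 3, 2.0)
    assert res.objective_trace[-1] == pytest.approx(q_oracle, abs=1e-6)


# ---------------------------------------------------------------------------
# identification and classification
# ---------------------------------------------------------------------------

def _majority_mapping(asmr_free_result, stack, truth_labels):
    """Oracle: name each cluster by majority vote of the truth labels."""
    hard = np.argmax(asmr_free_result.memberships, axis=1)
    truth = truth_labels.data[stack.mask]
    mapping = {}
    for j in range(3):
        sel = truth[hard == j]
        mapping[j] = int(np.bincount(sel, minlength=3).argmax())
    return mapping


@pytest.mark.parametrize("subset", [("ZTE", "UTE2"), ("T1", "ZTE"), ("UTE1", "UTE2")])
def test_cluster_identification_matches_majority_vote(tiny_truth, subset):
    # oracle only valid where the classes are actually separable, i.e. the
    # subset contains a short-TE channel resolving bone from air
    stack = build_features(tiny_truth.noisy_images, subset)
    res = fcm_cluster(stack, FcmParams(seed=0))
    mapping = identify_clusters(res, stack)
    oracle = _majority_mapping(res, stack, tiny_truth.labels)
    assert mapping == oracle


def test_single_conventional_channel_rule(tiny_truth):
    # with only T1 the darkest cluster is air and the middle one is called
    # bone (bone carries almost no signal on conventional sequences)
    stack = build_features(tiny_truth.noisy_images, ("T1",))
    res = fcm_cluster(stack, FcmParams(seed=0))
    mapping = identify_clusters(res, stack)
    w = res.memberships
    raw_means = (w.T @ stack.raw).ravel() / w.sum(axis=0)
    order = np.argsort(raw_means)  # darkest, middle, brightest
    assert mapping[int(order[0])] == AIR
    assert mapping[int(order[1])] == BONE
    assert mapping[int(order[2])] == SOFT


def test_identification_invariant_to_cluster_permutation(tiny_truth):
    stack = build_features(tiny_truth.noisy_images, ("ZTE", "UTE2"))
    res = fcm_cluster(stack, FcmParams(seed=0))
    mapping = identify_clusters(res, stack)
    perm = [2, 0, 1]
    permuted = FcmResult(
        memberships=res.memberships[:, perm],
        centroids=res.centroids[perm],
        objective_trace=res.objective_trace,
        n_iters=res.n_iters,
        fuzzifier_m=res.fuzzifier_m,
        converged=res.converged,
    )
    mapping_p = identify_clusters(permuted, stack)
    # same tissue assigned to the same underlying cluster
    for new_idx, old_idx in enumerate(perm):
        assert mapping_p[new_idx] == mapping[old_idx]


def test_classify_argmax_tie_rule_and_mask():
    from mr2plan.fcm_segmentation import FeatureStack

    mask = np.ones((2, 2, 1), dtype=bool)
    memberships = np.array(
        [[0.2, 0.5, 0.3], [0.5, 0.5, 0.0], [0.0, 0.5, 0.5], [1.0, 0.0, 0.0]]
    )
    stack = FeatureStack(channels=("T1",), data=np.zeros((4, 1)), raw=np.zeros((4, 1)),
                         mask=mask, spacing=(1, 1, 1), origin=(0, 0, 0))
    res = FcmResult(memberships=memberships, centroids=np.zeros((3, 1)),
                    objective_trace=[0.0], n_iters=1, fuzzifier_m=2.0, converged=True)
    mapping = {0: AIR, 1: SOFT, 2: BONE}
    air_mask = np.ones((2, 2, 1), dtype=bool)
    out = classify(res, mapping, air_mask, stack)
    assert out.labels.data.ravel().tolist() == [SOFT, AIR, SOFT, AIR]
    # with the head mask off everywhere, everything is air
    out2 = classify(res, mapping, np.zeros_like(air_mask), stack)
    assert np.all(out2.labels.data == AIR)


def test_no_tissue_outside_air_mask(tiny_truth, tiny_mask):
    asmr = segment_subset(tiny_truth.noisy_images, ("ZTE", "UTE2"), tiny_mask, FcmParams(seed=0))
    assert np.all(asmr.labels.data[~tiny_mask] == AIR)


# ---------------------------------------------------------------------------
# sweep
# ---------------------------------------------------------------------------

def test_two_inputs_give_three_results(tiny_truth, tiny_mask):
    imgs = {k: tiny_truth.noisy_images[k] for k in ("T1", "ZTE")}
    res = sweep_combinations(imgs, tiny_mask, FcmParams(seed=0))
    assert [r.combination for r in res] == [("T1",), ("ZTE",), ("T1", "ZTE")]


def test_sweep_subset_matches_direct_call(tiny_truth, tiny_mask):
    params = FcmParams(seed=0)
    res = sweep_combinations(tiny_truth.noisy_images, tiny_mask, params)
    subsets = all_subsets()
    idx = subsets.index(("T1", "ZTE"))
    direct = segment_subset(
        tiny_truth.noisy_images, ("T1", "ZTE"), tiny_mask, FcmParams(seed=params.seed + idx)
    )
    assert np.array_equal(res[idx].labels.data, direct.labels.data)


def test_subset_enumeration_order():
    subsets = all_subsets()
    assert len(subsets) == 31
    sizes = [len(s) for s in subsets]
    assert sizes == sorted(sizes)
    assert subsets[0] == ("T1",)
    assert subsets[-1] == ("T1", "T2", "UTE1", "UTE2", "ZTE")
    assert subset_name(("ZTE", "UTE2")) == "UTE2-ZTE"
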