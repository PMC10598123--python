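"""UDC core: patch extraction, DCN training, assignment, signatures."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from nashmri.clustering import (
    ClusterModel,
    DCNConfig,
    UDCSignature,
    assign_cluster,
    concat_signatures,
    extract_patches,
    signature,
    train_dcn,
    _normalize,
    _valid_positions,
)
from tests.conftest import texture_family_patches


def test_extract_patches_count_validity_determinism(small_cohort):
    stream = np.random.default_rng(3)
    patches = extract_patches(small_cohort, "t1_pre", 100, stream=stream)
    assert len(patches) == 100
    masks = {r.subject_id: s.liver_mask for r, s in small_cohort}
    for p in patches:
        y, x = p.origin
        window = masks[p.subject_id][y : y + 16, x : x + 16]
        assert window.mean() >= 0.9  # mask-fraction rule
        assert p.pixels.shape == (16, 16)
    again = extract_patches(small_cohort, "t1_pre", 100, stream=np.random.default_rng(3))
    assert all(
        (a.subject_id, a.origin) == (b.subject_id, b.origin)
        and (a.pixels == b.pixels).all()
        for a, b in zip(patches, again)
    )


def test_extract_patches_errors(small_cohort):
    with pytest.raises(ValueError):
        extract_patches(small_cohort, "t1_pre", 10, patch_size=100)
    with pytest.raises(ValueError):
        extract_patches(small_cohort, "nonsense", 10)


def test_train_dcn_preconditions():
    x = np.random.default_rng(0).standard_normal((5, 16, 16))
    with pytest.raises(ValueError):
        train_dcn(x, k=10)  # fewer patches than clusters
    with pytest.raises(ValueError):
        ClusterModel(DCNConfig(k=0))
    with pytest.raises(ValueError):
        ClusterModel(DCNConfig(patch_size=12))


def test_assign_cluster_matches_bruteforce_scan(tiny_dcn):
    rng = np.random.default_rng(4)
    model = tiny_dcn
    patches = rng.standard_normal((30, 16, 16))
    latents = model.encode(patches)
    codes = model.cluster_codes(latents)
    for i in range(30):
        best, best_d = 0, np.inf
        for j, c in enumerate(model.centroids):
            d = float(((codes[i] - c) ** 2).sum())
            if d < best_d - 1e-15:
                best, best_d = j, d
        assert assign_cluster(model, patches[i]) == best


def test_assign_cluster_tie_breaks_to_lowest_index(tiny_dcn):
    model = tiny_dcn
    saved = model.centroids.copy()
    try:
        model.centroids = np.zeros_like(model.centroids)
        model.centroids[2] = 1.0
        model.centroids[5] = 1.0  # duplicate of 2: equidistant everywhere
        model.centroids[[0, 1, 3, 4, 6, 7, 8, 9]] = 1e6
        patch = np.random.default_rng(5).standard_normal((16, 16))
        assert assign_cluster(model, patch) == 2
    finally:
        model.centroids = saved


def test_assign_cluster_shape_mismatch(tiny_dcn):
    with pytest.raises(ValueError):
        assign_cluster(tiny_dcn, np.zeros((8, 8)))


def test_signature_is_normalized_histogram(tiny_dcn, small_cohort):
    _, study = small_cohort[0]
    sig = signature(tiny_dcn, study, "t1_hbp")
    assert len(sig.proportions) == tiny_dcn.k
    assert sig.proportions.sum() == pytest.approx(1.0, abs=1e-12)
    assert (sig.proportions >= 0).all()


def test_signature_stride1_matches_exhaustive_enumeration(tiny_dcn, small_cohort):
    # Independent oracle: enumerate every valid window position explicitly
    # and histogram brute-force nearest-centroid assignments.
    _, study = small_cohort[1]
    sig = signature(tiny_dcn, study, "t1_hbp", stride=1)
    norm = _normalize(study.t1_hbp, study.liver_mask)
    counts = np.zeros(tiny_dcn.k)
    h, w = study.liver_mask.shape
    for y in range(h - 15):
        for x in range(w - 15):
            if study.liver_mask[y : y + 16, x : x + 16].mean() >= 0.9:
                window = norm[y : y + 16, x : x + 16]
                code = tiny_dcn.cluster_codes(tiny_dcn.encode(window[None]))[0]
                d = ((code - tiny_dcn.centroids) ** 2).sum(axis=1)
                counts[int(np.argmin(d))] += 1
    np.testing.assert_allclose(sig.proportions, counts / counts.sum(), atol=1e-12)


def test_signature_one_hot_when_single_cluster_wins(tiny_dcn, small_cohort):
    _, study = small_cohort[2]
    saved = tiny_dcn.centroids.copy()
    try:
        tiny_dcn.centroids = saved + 1e6
        tiny_dcn.centroids[4] = 0.0  # closest to every standardized code
        sig = signature(tiny_dcn, study, "t1_pre")
        expected = np.zeros(tiny_dcn.k)
        expected[4] = 1.0
        np.testing.assert_array_equal(sig.proportions, expected)
    finally:
        tiny_dcn.centroids = saved


def test_signature_invariant_under_joint_relabeling(tiny_dcn, small_cohort):
    _, study = small_cohort[0]
    base = signature(tiny_dcn, study, "t1_hbp")
    perm = np.random.default_rng(6).permutation(tiny_dcn.k)
    saved = tiny_dcn.centroids.copy()
    try:
        tiny_dcn.centroids = saved[perm]
        permuted = signature(tiny_dcn, study, "t1_hbp")
        np.testing.assert_allclose(permuted.proportions, base.proportions[perm])
    finally:
        tiny_dcn.centroids = saved


def test_k1_gives_trivial_signature(small_cohort):
    stream = np.random.default_rng(0)
    patches = extract_patches(small_cohort, "t1_pre", 50, stream=stream)
    model = train_dcn(patches, k=1, config=DCNConfig(k=1, pretrain_epochs=1, joint_epochs=1))
    _, study = small_cohort[0]
    np.testing.assert_array_equal(signature(model, study, "t1_pre").proportions, [1.0])


def test_concat_signatures_blocks_and_errors():
    a = UDCSignature(np.full(10, 0.1), ("t1_pre",), (10,))
    b = UDCSignature(np.full(10, 0.1), ("t1_hbp",), (10,))
    cat = concat_signatures(a, b)
    assert len(cat.proportions) == 20
    np.testing.assert_array_equal(cat.proportions[:10], a.proportions)
    assert cat.block_sizes == (10, 10)
    with pytest.raises(ValueError):
        concat_signatures(a, a)


def test_udc_signature_validates_probability_blocks():
    with pytest.raises(ValueError):
        UDCSignature(np.array([0.5, 0.4]), ("x",), (2,))  # sums to 0.9
    with pytest.raises(ValueError):
        UDCSignature(np.array([0.5, 0.5, 1.0]), ("x",), (2,))  # uncovered tail


def test_dcn_recovers_distinct_texture_families():
    rng = np.random.default_rng(0)
    x, truth = texture_family_patches(rng, n_per=300)
    model = train_dcn(x, k=3, config=DCNConfig(k=3, seed=3))
    assignments = model.assign(model.encode(x))
    assert adjusted_rand_score(truth, assignments) > 0.8


def test_train_dcn_deterministic(small_cohort):
    stream = np.random.default_rng(9)
    patches = extract_patches(small_cohort, "t1_hbp", 120, stream=stream)
    cfg = DCNConfig(k=4, pretrain_epochs=2, joint_epochs=1, seed=5)
    a = train_dcn(patches, k=4, config=cfg)
    b = train_dcn(patches, k=4, config=cfg)
    np.testing.assert_array_equal(a.centroids, b.centroids)
    np.testing.assert_array_equal(a.conv1.W, b.conv1.W)


def test_model_save_load_roundtrip(tmp_path, tiny_dcn, small_cohort):
    path = tmp_path / "model.npz"
    tiny_dcn.save(path)
    back = ClusterModel.load(path)
    _, study = small_cohort[0]
    np.testing.assert_array_equal(
        signature(tiny_dcn, study, "t1_hbp").proportions,
        signature(back, study, "t1_hbp").proportions,
    )


def test_valid_positions_respect_mask_fraction(small_cohort):
    _, study = small_cohort[3]
    for y, x in _valid_positions(study.liver_mask, 16, 0.9):
        assert study.liver_mask[y : y + 16, x : x + 16].mean() >= 0.9
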