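"""Late-frame summation, quantization, 3D GLCM and Haralick features,
including a brute-force double-loop oracle."""

import itertools

import numpy as np
import pytest

import petquant as pq
from petquant.core import DynamicPETImage, FrameSchedule
from petquant.texture import (DISTANCE_1_OFFSETS_3D, GLCM,
                              HARALICK_FEATURE_NAMES, QuantizedVolume,
                              compute_glcm, haralick_features, quantize,
                              sum_frames)

# ---------------------------------------------------------------------------
# independent brute-force reference implementation
# ---------------------------------------------------------------------------

def brute_glcm(levels, mask, offsets, ng, symmetric=True):
    """Triple-loop co-occurrence counting; O(voxels x offsets)."""
    counts = np.zeros((ng, ng))
    nx, ny, nz = levels.shape
    for (dx, dy, dz) in offsets:
        for x in range(nx):
            for y in range(ny):
                for z in range(nz):
                    x2, y2, z2 = x + dx, y + dy, z + dz
                    if not (0 <= x2 < nx and 0 <= y2 < ny and 0 <= z2 < nz):
                        continue
                    if mask[x, y, z] and mask[x2, y2, z2]:
                        counts[levels[x, y, z], levels[x2, y2, z2]] += 1
    if symmetric:
        counts = counts + counts.T
    return counts / counts.sum()


def brute_haralick(p):
    """Direct double-loop evaluation of the 14 statistics (base-2 logs)."""
    ng = p.shape[0]
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = sum(i * px[i] for i in range(ng))
    mu_y = sum(j * py[j] for j in range(ng))
    sx = np.sqrt(sum((i - mu_x) ** 2 * px[i] for i in range(ng)))
    sy = np.sqrt(sum((j - mu_y) ** 2 * py[j] for j in range(ng)))

    def xlog2(v):
        return v * np.log2(v) if v > 0 else 0.0

    energy = sum(p[i, j] ** 2 for i in range(ng) for j in range(ng))
    contrast = sum((i - j) ** 2 * p[i, j] for i in range(ng) for j in range(ng))
    corr = (sum(i * j * p[i, j] for i in range(ng) for j in range(ng))
            - mu_x * mu_y) / (sx * sy) if sx > 0 and sy > 0 else np.nan
    variance = sum((i - mu_x) ** 2 * p[i, j]
                   for i in range(ng) for j in range(ng))
    homog = sum(p[i, j] / (1 + (i - j) ** 2)
                for i in range(ng) for j in range(ng))
    p_sum = np.zeros(2 * ng - 1)
    p_dif = np.zeros(ng)
    for i in range(ng):
        for j in range(ng):
            p_sum[i + j] += p[i, j]
            p_dif[abs(i - j)] += p[i, j]
    sum_avg = sum(k * p_sum[k] for k in range(2 * ng - 1))
    sum_var = sum((k - sum_avg) ** 2 * p_sum[k] for k in range(2 * ng - 1))
    sum_ent = -sum(xlog2(v) for v in p_sum)
    entropy = -sum(xlog2(p[i, j]) for i in range(ng) for j in range(ng))
    dif_mean = sum(k * p_dif[k] for k in range(ng))
    dif_var = sum((k - dif_mean) ** 2 * p_dif[k] for k in range(ng))
    dif_ent = -sum(xlog2(v) for v in p_dif)
    hx = -sum(xlog2(v) for v in px)
    hy = -sum(xlog2(v) for v in py)
    hxy1 = -sum(p[i, j] * np.log2(px[i] * py[j] + 1e-12)
                for i in range(ng) for j in range(ng) if p[i, j] > 0)
    hxy2 = -sum(xlog2(px[i] * py[j]) for i in range(ng) for j in range(ng))
    imc1 = (entropy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    imc2 = np.sqrt(max(1 - np.exp(-2 * (hxy2 - entropy)), 0.0))
    occ = (px > 0) & (py > 0)
    if occ.sum() >= 2 and sx > 0 and sy > 0:
        sub = p[np.ix_(occ, occ)]
        q = np.zeros((occ.sum(), occ.sum()))
        pxo, pyo = px[occ], py[occ]
        for i in range(occ.sum()):
            for j in range(occ.sum()):
                q[i, j] = sum(sub[i, k] * sub[j, k] / (pxo[i] * pyo[k])
                              for k in range(occ.sum()))
        eig = np.sort(np.real(np.linalg.eigvals(q)))[::-1]
        mcc = np.sqrt(min(max(eig[1], 0.0), 1.0))
    else:
        mcc = np.nan
    return dict(zip(HARALICK_FEATURE_NAMES,
                    (energy, contrast, corr, variance, homog, sum_avg,
                     sum_var, sum_ent, entropy, dif_var, dif_ent, imc1,
                     imc2, mcc)))


def random_quantized(rng, shape=(6, 6, 3), ng=4):
    levels = rng.integers(0, ng, size=shape)
    return QuantizedVolume(levels, ng, (0.0, float(ng - 1)))


# ---------------------------------------------------------------------------
# frame summation
# ---------------------------------------------------------------------------

class TestSumFrames:
    def test_late_window_selects_four_300s_frames(self, schedule):
        data = np.zeros((2, 2, 1, 22))
        data[..., :] = np.arange(22)
        img = DynamicPETImage(data, schedule)
        out = sum_frames(img, (40.0, 60.0))
        # frames starting at 40, 45, 50, 55 min are indices 18..21
        np.testing.assert_allclose(out.data, 18 + 19 + 20 + 21)

    def test_single_frame_window(self, schedule):
        data = np.random.default_rng(0).random((2, 2, 2, 22))
        img = DynamicPETImage(data, schedule)
        out = sum_frames(img, (0.0, 0.5))
        np.testing.assert_allclose(out.data, data[..., 0])

    def test_zero_image_sums_to_zero(self, schedule):
        img = DynamicPETImage(np.zeros((2, 2, 1, 22)), schedule)
        np.testing.assert_array_equal(sum_frames(img, (40.0, 60.0)).data, 0.0)

    @pytest.mark.parametrize("window", [(50.0, 70.0), (40.3, 59.6)])
    def test_bad_windows_rejected(self, schedule, window):
        img = DynamicPETImage(np.zeros((2, 2, 1, 22)), schedule)
        with pytest.raises(ValueError):
            sum_frames(img, window)


class TestQuantize:
    def test_three_values_two_levels(self):
        img = pq.SummedImage(np.array([[[0.0, 5.0, 10.0]]]), (40, 60))
        mask = np.ones((1, 1, 3), bool)
        q = quantize(img, mask, n_levels=2)
        np.testing.assert_array_equal(q.levels[0, 0], [0, 1, 1])

    def test_extremes_map_to_first_and_last_level(self):
        rng = np.random.default_rng(1)
        vals = rng.random((4, 4, 4)) * 100
        img = pq.SummedImage(vals, (40, 60))
        mask = np.ones((4, 4, 4), bool)
        q = quantize(img, mask, n_levels=16)
        assert q.levels[np.unravel_index(vals.argmin(), vals.shape)] == 0
        assert q.levels[np.unravel_index(vals.argmax(), vals.shape)] == 15

    def test_integer_ramp_is_identity_at_matching_levels(self):
        vals = np.arange(64, dtype=float).reshape(4, 4, 4)
        img = pq.SummedImage(vals, (40, 60))
        q = quantize(img, np.ones((4, 4, 4), bool), n_levels=64)
        np.testing.assert_array_equal(q.levels.ravel(), np.arange(64))

    def test_constant_image_rejected(self):
        img = pq.SummedImage(np.ones((2, 2, 2)), (40, 60))
        with pytest.raises(ValueError):
            quantize(img, np.ones((2, 2, 2), bool), n_levels=8)


class TestGLCM:
    def test_hand_enumerated_2x2_slice(self):
        levels = np.array([[0, 1], [0, 1]])[:, :, None]
        q = QuantizedVolume(levels, 2, (0, 1))
        mask = np.ones((2, 2, 1), bool)
        g = compute_glcm(q, mask, offsets=[(0, 1, 0)], symmetric=True)
        expected = np.array([[0.0, 0.5], [0.5, 0.0]])
        np.testing.assert_allclose(g.p, expected)

    def test_constant_volume_concentrates_one_cell(self):
        q = QuantizedVolume(np.zeros((3, 3, 2), int), 4, (0, 1))
        g = compute_glcm(q, np.ones((3, 3, 2), bool))
        assert g.p[0, 0] == 1.0
        assert g.p.sum() == pytest.approx(1.0)

    def test_symmetric_matrix_equals_transpose(self):
        rng = np.random.default_rng(3)
        q = random_quantized(rng)
        g = compute_glcm(q, np.ones(q.levels.shape, bool), symmetric=True)
        np.testing.assert_array_equal(g.p, g.p.T)

    def test_mask_aware_pairs_only(self):
        levels = np.array([[0, 1, 1]])[:, :, None]
        mask = np.array([[True, False, True]])[:, :, None]
        q = QuantizedVolume(levels, 2, (0, 1))
        with pytest.raises(ValueError):
            # middle voxel masked out: no adjacent in-mask pair remains
            compute_glcm(q, mask, offsets=[(0, 1, 0)])

    def test_matches_brute_force_counting(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            q = random_quantized(rng)
            mask = rng.random(q.levels.shape) > 0.2
            if not mask.any():
                continue
            g = compute_glcm(q, mask)
            ref = brute_glcm(q.levels, mask, DISTANCE_1_OFFSETS_3D, q.n_levels)
            np.testing.assert_allclose(g.p, ref, atol=1e-12)


class TestHaralick:
    def test_single_level_closed_forms(self):
        p = np.zeros((4, 4))
        p[2, 2] = 1.0
        f = haralick_features(GLCM(p, ((0, 0, 1),), True, 1))
        assert f["energy"] == 1.0
        assert f["contrast"] == 0.0
        assert f["entropy"] == 0.0
        assert f["homogeneity"] == 1.0
        assert np.isnan(f["correlation"])       # degenerate marginal

    def test_uniform_glcm_closed_forms(self):
        ng = 8
        p = np.full((ng, ng), 1.0 / ng ** 2)
        f = haralick_features(GLCM(p, ((0, 0, 1),), True, ng * ng))
        assert f["energy"] == pytest.approx(1.0 / ng ** 2)
        assert f["entropy"] == pytest.approx(2 * np.log2(ng))
        assert f["correlation"] == pytest.approx(0.0, abs=1e-12)

    def test_checkerboard_correlation_is_minus_one(self):
        x, y, z = np.meshgrid(np.arange(4), np.arange(4), np.arange(4),
                              indexing="ij")
        levels = (x + y + z) % 2
        q = QuantizedVolume(levels, 2, (0, 1))
        g = compute_glcm(q, np.ones((4, 4, 4), bool),
                         offsets=[(1, 0, 0), (0, 1, 0), (0, 0, 1)])
        f = haralick_features(g)
        assert f["correlation"] == pytest.approx(-1.0)

    def test_all_features_match_brute_force(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            q = random_quantized(rng)
            g = compute_glcm(q, np.ones(q.levels.shape, bool))
            ours = haralick_features(g)
            ref = brute_haralick(g.p)
            for name in HARALICK_FEATURE_NAMES:
                assert ours[name] == pytest.approx(ref[name], abs=1e-10), name

    def test_invariant_ranges(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            q = random_quantized(rng, ng=6)
            f = haralick_features(compute_glcm(q, np.ones(q.levels.shape, bool)))
            assert 0 < f["energy"] <= 1
            assert f["contrast"] >= 0
            assert -1 <= f["correlation"] <= 1
            assert 0 < f["homogeneity"] <= 1
            assert f["entropy"] >= 0 and f["sum_entropy"] >= 0
            assert 0 <= f["imc2"] <= 1
            assert 0 <= f["max_corr_coeff"] <= 1


class TestTexturePipeline:
    def test_deterministic_for_identical_subjects(self, small_config):
        a = pq.generate_subject(small_config, "HC", seed=4)
        b = pq.generate_subject(small_config, "HC", seed=4)
        fa = pq.texture_pipeline(a.dynamic_image, a.brain_mask)
        fb = pq.texture_pipeline(b.dynamic_image, b.brain_mask)
        assert fa == fb
        assert list(fa) == list(HARALICK_FEATURE_NAMES)
        assert len(fa) == 14

    def test_smoother_field_raises_glcm_correlation(self, small_config):
        """Longer texture correlation length -> higher GLCM correlation,
        averaged over seeds."""
        import copy
        rough_cfg = copy.deepcopy(small_config)
        rough_cfg.texture_correlation_length = {"HC": 0.5, "AD": 0.5}
        rough_cfg.texture_length_jitter_sd = 0.0
        smooth_cfg = copy.deepcopy(rough_cfg)
        smooth_cfg.texture_correlation_length = {"HC": 2.0, "AD": 2.0}
        vals = {"rough": [], "smooth": []}
        for seed in range(10):
            for key, cfg in (("rough", rough_cfg), ("smooth", smooth_cfg)):
                sub = pq.generate_subject(cfg, "HC", seed=seed)
                f = pq.texture_pipeline(sub.dynamic_image, sub.brain_mask)
                vals[key].append(f["correlation"])
        assert np.mean(vals["smooth"]) > np.mean(vals["rough"])

    def test_axis_permutation_invariance_with_full_offsets(self):
        rng = np.random.default_rng(17)
        vol = rng.random((6, 6, 6))
        mask = rng.random((6, 6, 6)) > 0.2
        img = pq.SummedImage(vol, (40, 60))
        q = quantize(img, mask, n_levels=4)
        base = haralick_features(compute_glcm(q, mask))
        for perm in itertools.permutations(range(3)):
            qp = QuantizedVolume(np.transpose(q.levels, perm), 4, q.bounds)
            fp = haralick_features(compute_glcm(qp, np.transpose(mask, perm)))
            for name in HARALICK_FEATURE_NAMES:
                assert fp[name] == pytest.approx(base[name], abs=1e-12), name

    def test_noise_raises_entropy_lowers_energy(self, small_config):
        """Additive voxel noise increases pooled-GLCM entropy and decreases
        energy on smooth phantoms (mean over seeds)."""
        import copy
        quiet = copy.deepcopy(small_config)
        quiet.noise_scale = 0.5
        loud = copy.deepcopy(small_config)
        loud.noise_scale = 8.0
        ent, eng = {"quiet": [], "loud": []}, {"quiet": [], "loud": []}
        for seed in range(8):
            for key, cfg in (("quiet", quiet), ("loud", loud)):
                sub = pq.generate_subject(cfg, "HC", seed=seed)
                f = pq.texture_pipeline(sub.dynamic_image, sub.brain_mask)
                ent[key].append(f["entropy"])
                eng[key].append(f["energy"])
        assert np.mean(ent["loud"]) > np.mean(ent["quiet"])
        assert np.mean(eng["loud"]) < np.mean(eng["quiet"])
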