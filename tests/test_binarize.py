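import numpy as np
import pytest
from skimage.morphology import disk

from octaprof.binarize import (NormalCCDatabase, binarize_cc, binarize_plexus,
                               cc_threshold_from_normals, hessian_vesselness,
                               huang_threshold, large_vessel_mask,
                               local_median_binarize, top_hat, _quantize_u8)
from octaprof.io import EnFaceImage
from octaprof.synth import _large_vessels


# ---------------------------------------------------------------------------
# independent oracles


def _brute_top_hat(img, radius):
    """Opening by explicit min/max over the disk neighborhood."""
    se = disk(radius)
    offs = [(dy - radius, dx - radius) for dy, dx in zip(*np.nonzero(se))]
    n, m = img.shape
    pad = radius
    padded = np.pad(img, pad, mode="reflect")

    def sweep(src, fn):
        out = np.empty_like(img)
        for y in range(n):
            for x in range(m):
                vals = [src[y + pad + dy, x + pad + dx] for dy, dx in offs]
                out[y, x] = fn(vals)
        return out

    eroded = sweep(padded, min)
    opened_p = np.pad(eroded, pad, mode="reflect")
    opened = sweep(opened_p, max)
    return img - opened


def _brute_huang(img):
    """Direct double-loop fuzzy-entropy minimization over all levels."""
    g = _quantize_u8(img).ravel()
    gmin, gmax = g.min(), g.max()
    c = gmax - gmin
    best_t, best_s = None, np.inf
    for t in range(gmin, gmax):
        lo = g[g <= t]
        hi = g[g > t]
        if lo.size == 0 or hi.size == 0:
            continue
        m0, m1 = lo.mean(), hi.mean()
        s = 0.0
        for v in g:
            m = m0 if v <= t else m1
            mu = 1.0 / (1.0 + abs(v - m) / c)
            if 0 < mu < 1:
                s += -mu * np.log(mu) - (1 - mu) * np.log(1 - mu)
        if s < best_s - 1e-12:
            best_s, best_t = s, t
    return best_t


def _brute_local_median(img, radius):
    se = disk(radius)
    offs = [(dy - radius, dx - radius) for dy, dx in zip(*np.nonzero(se))]
    g = _quantize_u8(img)
    pad = radius
    padded = np.pad(g, pad, mode="reflect")
    out = np.zeros(g.shape, dtype=bool)
    for y in range(g.shape[0]):
        for x in range(g.shape[1]):
            vals = sorted(padded[y + pad + dy, x + pad + dx] for dy, dx in offs)
            med = vals[len(vals) // 2]      # upper-middle rank, like the impl
            out[y, x] = g[y, x] > med
    return out


# ---------------------------------------------------------------------------
# top-hat


class TestTopHat:
    def test_constant_image_maps_to_zeros(self):
        assert np.allclose(top_hat(np.full((32, 32), 0.7), 5), 0.0)

    def test_single_bright_pixel_survives_unchanged(self):
        img = np.zeros((31, 31))
        img[15, 15] = 1.0
        out = top_hat(img, 5)
        assert out[15, 15] == pytest.approx(1.0)

    def test_matches_brute_force_opening_residual(self, rng):
        img = rng.random((16, 16))
        assert np.allclose(top_hat(img, 2), _brute_top_hat(img, 2), atol=1e-12)


# ---------------------------------------------------------------------------
# Hessian vesselness


class TestVesselness:
    def test_constant_image_maps_to_zeros(self):
        assert np.allclose(hessian_vesselness(np.full((64, 64), 0.5), 2.0), 0.0)

    def test_response_peaks_on_ridge_centerline(self):
        yy = np.arange(65)[:, None] * np.ones((1, 64))
        ridge = np.exp(-((yy - 32) ** 2) / (2 * 2.0**2))   # width ~ 2 sigma
        v = hessian_vesselness(ridge[:64], 2.0)
        interior = v[:, 8:-8]
        assert np.all(np.abs(np.argmax(interior, axis=0) - 32) <= 1)

    def test_isotropic_blob_scores_below_equal_contrast_ridge(self):
        yy, xx = np.mgrid[0:64, 0:64]
        blob = np.exp(-((yy - 32) ** 2 + (xx - 32) ** 2) / (2 * 2.0**2))
        ridge = np.exp(-((yy - 32) ** 2) / (2 * 2.0**2))
        both = np.zeros((64, 130))
        both[:, :64] = ridge
        both[:, 66:] = blob
        v = hessian_vesselness(both, 2.0)
        assert v[32, 32] > v[32, 98]    # ridge center beats blob center


# ---------------------------------------------------------------------------
# Huang threshold


class TestHuangThreshold:
    def test_matches_exhaustive_minimization_on_random_images(self, rng):
        for _ in range(20):
            img = rng.integers(0, 256, size=(12, 12)).astype(np.uint8)
            if img.min() == img.max():
                continue
            assert huang_threshold(img) == _brute_huang(img)

    def test_two_level_image_threshold_separates_the_levels(self):
        img = np.array([40] * 8 + [200] * 8, dtype=np.uint8).reshape(4, 4)
        t = huang_threshold(img)
        assert 40 <= t < 200
        assert t == _brute_huang(img)

    def test_worked_three_level_histogram(self):
        img = np.array([10] * 10 + [120] * 4 + [240] * 2,
                       dtype=np.uint8).reshape(4, 4)
        assert huang_threshold(img) == _brute_huang(img)

    def test_constant_offset_shifts_threshold_equally(self, rng):
        img = rng.integers(20, 120, size=(10, 10)).astype(np.int64)
        t0 = huang_threshold(img)
        t1 = huang_threshold(img + 30)
        assert t1 == t0 + 30

    def test_single_valued_image_raises(self):
        with pytest.raises(ValueError, match="single-valued"):
            huang_threshold(np.full((8, 8), 7, dtype=np.uint8))


# ---------------------------------------------------------------------------
# local median


class TestLocalMedian:
    def test_constant_image_is_all_background(self):
        assert not local_median_binarize(np.full((16, 16), 0.3), 3).any()

    def test_single_bright_pixel_is_foreground(self):
        img = np.zeros((16, 16))
        img[8, 8] = 1.0
        out = local_median_binarize(img, 3)
        assert out[8, 8]
        assert out.sum() == 1

    def test_matches_brute_force_on_toy_grid(self, rng):
        img = rng.random((9, 9))
        assert np.array_equal(local_median_binarize(img, 2),
                              _brute_local_median(img, 2))


# ---------------------------------------------------------------------------
# plexus chain, CC threshold, large-vessel mask


class TestBinarizePlexus:
    def test_flow_is_subset_of_each_branch(self, small_case, small_bparams):
        from octaprof.binarize import local_median_binarize, top_hat
        img = small_case.patient.dcc
        bm = binarize_plexus(img, small_bparams)
        th = top_hat(img.pixels, small_bparams.tophat_radius_px)
        vess = hessian_vesselness(th, small_bparams.vesselness_sigma_px)
        t = huang_threshold(vess)
        branch_h = _quantize_u8(vess) > t
        branch_m = local_median_binarize(th, small_bparams.median_radius_px)
        assert not (bm.flow & ~branch_h).any()
        assert not (bm.flow & ~branch_m).any()
        assert np.array_equal(bm.flow, branch_h & branch_m)

    def test_dcc_flow_overlaps_generator_labels(self, small_case, small_bparams):
        # regression floor on segmentation quality, not a physiological claim
        label = small_case.truth.vessel_labels["DCC"]
        bm = binarize_plexus(small_case.patient.dcc, small_bparams)
        dice = 2 * np.sum(bm.flow & label) / (bm.flow.sum() + label.sum())
        assert dice >= 0.7


class TestCCThreshold:
    def _db(self, arrays):
        imgs = [EnFaceImage(a, 23.4, (a.shape[0] / 2, a.shape[0] / 2), "CC")
                for a in arrays]
        return NormalCCDatabase(imgs)

    def test_constant_database_returns_the_constant(self):
        db = self._db([np.full((128, 128), 0.6), np.full((128, 128), 0.6)])
        assert cc_threshold_from_normals(db) == pytest.approx(0.6)

    def test_two_image_toy_database_arithmetic(self):
        a = np.full((128, 128), 0.4)
        b = np.full((128, 128), 0.8)
        db = self._db([a, b])
        # pooled mean 0.6, pooled SD 0.2
        assert cc_threshold_from_normals(db) == pytest.approx(0.4)

    def test_duplicating_an_image_leaves_threshold_unchanged(self, rng):
        base = np.clip(0.6 + 0.1 * rng.standard_normal((128, 128)), 0, 1)
        other = np.clip(0.55 + 0.1 * rng.standard_normal((128, 128)), 0, 1)
        t1 = cc_threshold_from_normals(self._db([base, base, other, other]))
        t2 = cc_threshold_from_normals(self._db([base, other, base, other]))
        assert t1 == pytest.approx(t2)

    def test_image_pooling_variant_differs_but_is_close(self, rng):
        imgs = [np.clip(0.6 + 0.08 * rng.standard_normal((64, 64)), 0, 1)
                for _ in range(4)]
        db = self._db(imgs)
        t_px = cc_threshold_from_normals(db, pooling="pixel")
        t_im = cc_threshold_from_normals(db, pooling="image")
        assert t_px == pytest.approx(t_im, abs=0.02)

    def test_raising_threshold_never_decreases_fd(self, small_case):
        img = small_case.patient.cc
        fds = []
        for thr in (0.3, 0.45, 0.6):
            bm = binarize_cc(img, thr)
            fds.append(1 - bm.flow.mean())
        assert fds == sorted(fds)

    def test_degenerate_thresholds(self, small_case):
        img = small_case.patient.cc
        assert (1 - binarize_cc(img, 0.0).flow.mean()) == 0.0
        assert (1 - binarize_cc(img, 1.01).flow.mean()) == 1.0


class TestLargeVesselMask:
    def test_uniform_dim_image_gives_empty_mask(self):
        img = EnFaceImage(np.full((128, 128), 0.2), 23.4, (64, 64), "SVC")
        assert not large_vessel_mask(img).any()

    def test_uniform_bright_image_gives_full_mask(self):
        img = EnFaceImage(np.full((128, 128), 0.9), 23.4, (64, 64), "SVC")
        assert large_vessel_mask(img).all()

    def test_mask_covers_generator_vessel_labels(self, small_case,
                                                 small_params, small_bparams):
        lv = _large_vessels(small_params)
        mask = large_vessel_mask(small_case.patient.svc, small_bparams)
        assert (mask & lv).sum() / lv.sum() >= 0.8


def test_masked_pixels_never_counted_in_metrics(small_case, small_bparams):
    """The exclusion mask removes pixels from both numerator and denominator."""
    from octaprof.profiles import area_metric, build_series
    img = small_case.patient.dcc
    n = img.n_px
    mask = np.zeros((n, n), dtype=bool)
    mask[:, : int(0.47 * n)] = True      # ~26% of each central sample area
    bm_masked = binarize_plexus(img, small_bparams, vessel_mask=mask)
    bm_plain = binarize_plexus(img, small_bparams)
    series = build_series(n, img.scale_um_per_px, "superior",
                          img.fovea_xy_px)
    area = series.areas[3]
    v_masked, _ = area_metric(bm_masked, area, "VD")
    flow = bm_plain.flow[area.slice()]
    keep = ~mask[area.slice()]
    assert v_masked == pytest.approx(flow[keep].sum() / keep.sum())
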