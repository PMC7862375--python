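import numpy as np
import pytest

from octaprof.binarize import BinarizedMap
from octaprof.io import EnFaceImage
from octaprof.nirfaf import APAEdge, detect_edge, has_apa
from octaprof.profiles import (ProfileSeries, align_to_edge, area_metric,
                               build_series, compute_profile, il_profile,
                               profiles_to_frame)

SCALE_1024 = 6000 / 1024  # um/px


class TestBuildSeries:
    def test_centered_fovea_gives_30_areas_per_direction(self):
        for d in ("superior", "inferior", "temporal"):
            s = build_series(1024, SCALE_1024, d, (511.5, 511.5))
            assert len(s) == 30

    def test_offset_fovea_shortens_the_series(self):
        # fovea 1 mm superior of center -> only 2 mm of superior field left
        fovea_y = 511.5 - 1.0 * 1000 / SCALE_1024
        s = build_series(1024, SCALE_1024, "superior", (511.5, fovea_y))
        assert len(s) == 20

    def test_temporal_series_follows_the_stated_side(self):
        left = build_series(1024, SCALE_1024, "temporal", (511.5, 511.5),
                            temporal_side="left")
        right = build_series(1024, SCALE_1024, "temporal", (511.5, 511.5),
                            temporal_side="right")
        assert left.areas[5].x0 < left.areas[0].x0
        assert right.areas[5].x0 > right.areas[0].x0

    def test_area_pixel_dimensions_at_native_grid(self):
        s = build_series(1024, SCALE_1024, "superior", (511.5, 511.5))
        a = s.areas[3]
        assert a.y1 - a.y0 == 17          # 0.1 mm along
        assert a.x1 - a.x0 == 137         # 0.8 mm across

    def test_areas_are_contiguous_and_non_overlapping(self):
        s = build_series(1024, SCALE_1024, "inferior", (511.5, 511.5))
        for prev, nxt in zip(s.areas, s.areas[1:]):
            assert nxt.y0 == prev.y1
            assert (prev.x0, prev.x1) == (nxt.x0, nxt.x1)


def _toy_map(flow, mask=None, valid=None):
    n = flow.shape[0]
    if mask is None:
        mask = np.zeros_like(flow)
    if valid is None:
        valid = np.ones_like(flow)
    return BinarizedMap(flow=flow.astype(bool), vessel_mask=mask.astype(bool),
                        valid=valid.astype(bool), modality="DCC")


class TestAreaMetric:
    def _area(self, x1=10, y1=8):
        from octaprof.profiles import SampleArea
        return SampleArea(0, 0, x1, 0, y1, 0.0)

    def test_all_flow_unmasked_area_is_one(self):
        bm = _toy_map(np.ones((8, 10)))
        v, reason = area_metric(bm, self._area(), "VD")
        assert v == 1.0 and reason == ""

    def test_hand_counted_masked_area(self):
        # 10x8 area, 32 flow pixels, 20 masked of which 12 are flow:
        # VD = (32 - 12) / (80 - 20) = 20/60
        flow = np.zeros((8, 10))
        flow.ravel()[:32] = 1
        mask = np.zeros((8, 10))
        mask.ravel()[20:40] = 1          # overlaps flow on pixels 20..31
        bm = _toy_map(flow, mask)
        v, _ = area_metric(bm, self._area(), "VD")
        assert v == pytest.approx(20 / 60)

    def test_fd_is_complement_of_flow_fraction(self):
        flow = np.zeros((8, 10))
        flow.ravel()[:60] = 1
        bm = _toy_map(flow)
        fd, _ = area_metric(bm, self._area(), "FD")
        assert fd == pytest.approx(1 - 60 / 80)

    @pytest.mark.parametrize("mask_fraction,excluded", [(0.41, True),
                                                        (0.39, False)])
    def test_forty_percent_mask_rule(self, mask_fraction, excluded):
        n_px = 100 * 10
        flow = np.ones((10, 100))
        mask = np.zeros((10, 100))
        mask.ravel()[: int(round(mask_fraction * n_px))] = 1
        from octaprof.profiles import SampleArea
        area = SampleArea(0, 0, 100, 0, 10, 0.0)
        v, reason = area_metric(_toy_map(flow, mask), area, "VD")
        assert bool(np.isnan(v)) == excluded
        if excluded:
            assert "40%" in reason

    def test_mostly_invalid_area_is_excluded(self):
        valid = np.zeros((8, 10))
        valid.ravel()[:30] = 1           # 37.5% valid < 50%
        v, reason = area_metric(_toy_map(np.ones((8, 10)), valid=valid),
                                self._area(), "VD")
        assert np.isnan(v)
        assert "field" in reason


class TestAlignment:
    def _profile(self, k=12, n=30):
        return ProfileSeries("superior", "VD", np.linspace(0, 1, n),
                             np.arange(n) * 0.1,
                             excluded_reasons=[""] * (n - 1) + ["masked"])

    def test_edge_area_becomes_offset_zero(self):
        p = align_to_edge(self._profile(), 12)
        assert p.offsets_mm[12] == pytest.approx(0.0)
        assert p.offsets_mm[0] == pytest.approx(-1.2)
        assert p.offsets_mm[-1] == pytest.approx(1.7)

    def test_alignment_preserves_values_and_exclusions(self):
        orig = self._profile()
        p = align_to_edge(orig, 7)
        assert np.array_equal(p.values, orig.values)
        assert p.excluded_reasons == orig.excluded_reasons
        assert p.aligned


class TestILProfile:
    def _nirfaf(self, px):
        n = px.shape[0]
        return EnFaceImage(px, 6000 / n, ((n - 1) / 2, (n - 1) / 2), "NIRFAF")

    def test_uniform_image_gives_flat_profile(self):
        img = self._nirfaf(np.full((512, 512), 0.6))
        s = build_series(512, 6000 / 512, "superior", img.fovea_xy_px)
        prof = il_profile(img, s)
        assert len(prof.values) == len(s)
        assert np.allclose(prof.values, 0.6)

    def test_two_level_image_gives_step_profile_at_known_edge(self):
        n = 512
        px = np.full((n, n), 0.2)
        px[:, :] = 0.2
        center = (n - 1) / 2
        yy = np.abs(np.arange(n) - center) * (6000 / n) / 1000
        px[yy < 1.0, :] = 0.8            # bright band within 1 mm vertically
        img = self._nirfaf(px)
        s = build_series(n, 6000 / n, "superior", img.fovea_xy_px)
        prof = il_profile(img, s)
        assert prof.values[0] == pytest.approx(0.8, abs=0.01)
        assert prof.values[-1] == pytest.approx(0.2, abs=0.01)
        drop = np.diff(prof.values).argmin()
        assert abs(drop * 0.1 - 1.0) <= 0.15

    def test_mask_exclusion_removes_shadow_dips(self):
        n = 512
        px = np.full((n, n), 0.8)
        px[200:215, :] = 0.3             # horizontal vessel shadow
        img = self._nirfaf(px)
        s = build_series(n, 6000 / n, "superior", img.fovea_xy_px)
        mask = np.zeros((n, n), dtype=bool)
        mask[198:217, :] = True
        masked = il_profile(img, s, mask)
        unmasked = il_profile(img, s)
        assert masked.values.min() == pytest.approx(0.8, abs=0.01)
        assert unmasked.values.min() < 0.7


class TestDetectEdge:
    def _profile(self, values):
        values = np.asarray(values, dtype=float)
        return ProfileSeries("superior", "IL", values,
                             np.arange(values.size) * 0.1)

    def test_ideal_step_detected_at_step_index(self):
        vals = [0.8] * 10 + [0.2] * 10
        e = detect_edge(self._profile(vals))
        assert e.detected
        assert abs(e.edge_index - 10) <= 1

    def test_uniform_low_profile_has_no_edge(self):
        e = detect_edge(self._profile([0.2] * 20))
        assert not e.detected
        assert "contrast floor" in e.reason

    def test_short_profile_raises(self):
        with pytest.raises(ValueError, match="too short"):
            detect_edge(self._profile([0.8, 0.5, 0.2]))

    def test_hyperautofluorescent_ring_does_not_displace_edge(self):
        # plateau, bright ring just inside the border, then the decline
        vals = [0.75] * 8 + [0.95, 0.95] + [0.2] * 10
        e = detect_edge(self._profile(vals))
        assert e.detected
        assert abs(e.edge_index - 10) <= 1


class TestHasAPA:
    def _edge(self, d, det=True):
        return APAEdge(d, det, 5 if det else None, 0.5 if det else None)

    def test_all_three_directions_detected(self):
        edges = {d: self._edge(d) for d in ("superior", "inferior", "temporal")}
        ok, reason = has_apa(edges)
        assert ok and reason == ""

    def test_one_missing_direction_fails_with_reason(self):
        edges = {"superior": self._edge("superior"),
                 "inferior": self._edge("inferior"),
                 "temporal": self._edge("temporal", det=False)}
        ok, reason = has_apa(edges)
        assert not ok
        assert "temporal" in reason

    def test_no_edges_at_all_fails(self):
        ok, _ = has_apa({d: self._edge(d, det=False)
                         for d in ("superior", "inferior", "temporal")})
        assert not ok


def test_profiles_frame_is_tidy(small_case):
    prof = ProfileSeries("superior", "VD", [0.5, np.nan], [0.0, 0.1],
                         excluded_reasons=["", "masked"], subject_id="P0",
                         modality="DCC")
    frame = profiles_to_frame([prof])
    assert list(frame["excluded"]) == [False, True]
    assert frame.loc[1, "reason"] == "masked"
    assert set(frame.columns) >= {"subject_id", "role", "direction", "metric",
                                  "offset_mm", "value", "excluded"}


def test_edge_recovery_on_synthetic_cases_within_one_step():
    """End-to-end IL -> edge on generated NIR-FAF, with and without ring."""
    from octaprof.synth import SyntheticCaseParams, generate_nirfaf
    for ring in (1.0, 1.5):
        for seed in range(3):
            p = SyntheticCaseParams(image_size_px=512, seed=seed,
                                    ring_gain=ring, large_vessel_count=0)
            nir, truth = generate_nirfaf(p)
            for d in ("superior", "inferior", "temporal"):
                s = build_series(512, p.scale_um_per_px, d, p.fovea,
                                 p.temporal_side)
                e = detect_edge(il_profile(nir, s))
                assert e.detected
                assert abs(e.edge_distance_mm
                           - truth.edge_distance_mm[d]) <= 0.1 + 1e-9
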