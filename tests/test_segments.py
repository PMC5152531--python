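"""Ventricular frame construction and the 14-segment parcellation."""

import numpy as np
import pytest

from rvquant.geometry import LandmarkSet
from rvquant.masks import VolumeMask, compute_edv, resample_mask
from rvquant.segments import (DEFAULT_LAYER_BOUNDS, DegenerateFrameError,
                              REGIONS_BY_LAYER, build_axis_frame,
                              cylindrical_coords, divide_segments,
                              region_labels, region_volume_table, voxel_region)
from rvquant.synthetic import PhantomParams, make_rv_phantom

from conftest import random_landmarks, random_transform


def canonical_landmarks(L=60.0, ra=20.0, rb=20.0) -> LandmarkSet:
    return LandmarkSet.from_mapping({
        "valve_center": [0.0, 0.0, L],
        "annulus_inferior": [0.0, rb, L],
        "annulus_anterior": [0.0, -rb, L],
        "annulus_left": [-ra, 0.0, L],
        "annulus_right": [ra, 0.0, L],
        "apex": [0.0, 0.0, 0.0],
    })


class TestAxisFrame:
    def test_canonical_axes(self):
        f = build_axis_frame(canonical_landmarks())
        np.testing.assert_allclose(f.long_axis, [0, 0, 1], atol=1e-12)
        np.testing.assert_allclose(f.inferior_axis, [0, 1, 0], atol=1e-12)
        np.testing.assert_allclose(f.left_axis, [-1, 0, 0], atol=1e-12)
        assert f.axis_length == pytest.approx(60.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_equivariance_under_rigid_transform(self, seed):
        rng = np.random.default_rng(seed)
        lm = random_landmarks(rng)
        t = random_transform(rng)
        f0 = build_axis_frame(lm)
        f1 = build_axis_frame(t.apply_landmarks(lm))
        for axis in ("long_axis", "inferior_axis", "left_axis"):
            np.testing.assert_allclose(getattr(f1, axis),
                                       t.rotation @ getattr(f0, axis), atol=1e-9)
        np.testing.assert_allclose(f1.apex_origin, t.apply_point(lm.apex).array,
                                   atol=1e-9)
        assert f1.axis_length == pytest.approx(f0.axis_length, abs=1e-9)

    def test_degenerate_chord_rejected(self):
        lm = LandmarkSet.from_mapping({
            "valve_center": [0, 0, 60], "apex": [0, 0, 0],
            "annulus_anterior": [5, 0, 58], "annulus_inferior": [5, 0, 70],
            "annulus_left": [-20, 0, 60], "annulus_right": [20, 0, 60],
        })
        with pytest.raises(DegenerateFrameError):
            build_axis_frame(lm)

    def test_chirality_flip(self):
        lm = canonical_landmarks()
        f = build_axis_frame(lm, flip_chirality=True)
        np.testing.assert_allclose(f.left_axis, [1, 0, 0], atol=1e-12)


@pytest.fixture(scope="module")
def frame():
    return build_axis_frame(canonical_landmarks())


class TestVoxelRegion:

    def test_apex_is_apical(self, frame):
        assert voxel_region([0.0, 0.0, 0.0], frame) == 14

    def test_medial_inferior(self, frame):
        # h = 0.4, displaced along +inferior (+y)
        assert voxel_region([0.0, 10.0, 24.0], frame) == 12

    @staticmethod
    def expected_label(h, theta):
        """Independent re-statement of the sector tables for the sweep oracle."""
        if h < 0.25:
            return 14
        if h < 0.5:
            if 315 <= theta or theta < 45:
                return 12
            if theta < 135:
                return 11
            if theta < 225:
                return 10
            return 13
        basal = {0: 6, 1: 5, 2: 4, 3: 9, 4: 8, 5: 7}[int(theta // 60)]
        if h < 0.75:
            return basal
        if theta < 180:
            return {0: 3, 1: 2, 2: 1}[int(theta // 60)]
        return basal  # septal fall-through at valvular height

    @pytest.mark.parametrize("h", [0.1, 0.4, 0.6, 0.9])
    def test_one_degree_sweep_matches_interval_oracle(self, frame, h):
        # half-degree offsets keep samples off the exact sector boundaries,
        # where trig round-trip noise would make the oracle comparison moot
        thetas = np.arange(0.5, 360.0, 1.0)
        pts = (frame.apex_origin
               + h * frame.axis_length * frame.long_axis
               + 10.0 * (np.cos(np.radians(thetas))[:, None] * frame.inferior_axis
                         + np.sin(np.radians(thetas))[:, None] * frame.left_axis))
        got = region_labels(pts, frame)
        want = [self.expected_label(h, t) for t in thetas]
        np.testing.assert_array_equal(got, want)
        # each label occupies one contiguous circular run of angles, with
        # changes only within 1 degree of the configured sector boundaries
        changes = int((np.diff(np.r_[got, got[0]]) != 0).sum())
        n_labels = len(set(got.tolist()))
        assert changes == (0 if n_labels == 1 else n_labels)
        boundary_set = {45, 135, 225, 315} if h < 0.5 else set(range(0, 360, 60))
        for i in np.nonzero(np.diff(got))[0]:
            assert any(abs(thetas[i + 1] - b) <= 1.0 for b in boundary_set)

    def test_layer_boundaries_are_half_open(self, frame):
        p = lambda h: frame.apex_origin + h * 60.0 * frame.long_axis + \
            5.0 * frame.inferior_axis
        assert voxel_region(p(0.25), frame) == 12   # lands in medial, not apical
        assert voxel_region(p(0.50), frame) == 6    # basal
        assert voxel_region(p(0.75), frame) == 3    # valvular

    def test_invalid_layer_bounds_rejected(self, frame):
        with pytest.raises(ValueError):
            voxel_region([0, 0, 0], frame, layer_bounds=(0.5, 0.25, 0.75))


class TestDivideSegments:
    def test_full_axis_phantom_has_14_labels(self, phantom50, frame50):
        mask, _ = phantom50
        sm = divide_segments(mask, frame50)
        present = np.nonzero(sm.region_voxel_counts()[1:])[0] + 1
        np.testing.assert_array_equal(present, np.arange(1, 15))

    def test_partition_conserves_voxel_count(self, phantom50, frame50):
        mask, _ = phantom50
        sm = divide_segments(mask, frame50)
        assert sm.region_voxel_counts()[1:].sum() == mask.data.sum()
        assert (sm.labels > 0).sum() == mask.data.sum()
        assert sm.region_volumes_ml().sum() == pytest.approx(compute_edv(mask),
                                                             abs=1e-9)

    def test_sector_counts_per_layer(self, phantom50, frame50):
        mask, _ = phantom50
        sm = divide_segments(mask, frame50)
        pts = mask.foreground_points()
        h, theta = cylindrical_coords(pts, frame50)
        lab = sm.labels[sm.labels > 0]
        b0, b1, b2 = DEFAULT_LAYER_BOUNDS
        assert set(lab[h < b0]) == {14}
        assert set(lab[(h >= b0) & (h < b1)]) == {10, 11, 12, 13}
        assert set(lab[(h >= b1) & (h < b2)]) == {4, 5, 6, 7, 8, 9}
        assert set(lab[(h >= b2) & (theta < 180)]) == {1, 2, 3}
        assert set(lab[(h >= b2) & (theta >= 180)]) <= {7, 8, 9}

    def test_layer_mean_height_ordering(self, phantom50, frame50):
        mask, _ = phantom50
        sm = divide_segments(mask, frame50)
        pts = mask.foreground_points()
        h, _ = cylindrical_coords(pts, frame50)
        lab = sm.labels[sm.labels > 0]
        means = [np.mean(h[np.isin(lab, REGIONS_BY_LAYER[layer])])
                 for layer in ("apical", "medial", "basal", "valvular")]
        assert means[0] < means[1] < means[2] < means[3]

    def test_region_volumes_match_monte_carlo_integration(self):
        """Voxel-counted region volumes vs dense MC integration of the
        analytic half-ellipsoid (taper = 2), independent of the grid."""
        params = PhantomParams(taper=2.0, target_volume_ml=50.0, spacing=1.0)
        mask, lm = make_rv_phantom(params)
        frame = build_axis_frame(lm)
        sm = divide_segments(mask, frame)
        vox = sm.region_volumes_ml()

        # recover the scaled radii from the landmarks (they lie on the surface)
        ra = lm.annulus_right.x
        rb = lm.annulus_inferior.y
        L = lm.valve_center.z
        rng = np.random.default_rng(12345)
        n = 1_200_000
        pts = rng.uniform([-ra, -rb, 0.0], [ra, rb, L], size=(n, 3))
        u = pts[:, 2] / L
        inside = ((pts[:, 0] / ra) ** 2 + (pts[:, 1] / rb) ** 2
                  <= 1.0 - (1.0 - u) ** 2)
        box_ml = (2 * ra) * (2 * rb) * L / 1000.0
        labels = region_labels(pts[inside], frame)
        mc = np.bincount(labels, minlength=15)[1:] / n * box_ml
        total = mc.sum()
        np.testing.assert_allclose(vox, mc, atol=0.02 * total)

    def test_empty_mask_warns(self, frame50):
        empty = VolumeMask(np.zeros((5, 5, 5), dtype=np.uint8))
        with pytest.warns(UserWarning, match="empty"):
            sm = divide_segments(empty, frame50)
        assert sm.labels.sum() == 0

    def test_rigid_equivariance_of_region_volumes(self, phantom50, frame50):
        mask, lm = phantom50
        rng = np.random.default_rng(9)
        t = random_transform(rng, max_translation=10.0)
        from rvquant.synthetic import _transformed_grid
        moved = resample_mask(mask, t, _transformed_grid(mask, t))
        frame_t = build_axis_frame(t.apply_landmarks(lm))
        v0 = divide_segments(mask, frame50).region_volumes_ml()
        v1 = divide_segments(moved, frame_t).region_volumes_ml()
        np.testing.assert_allclose(v1, v0, atol=0.02 * v0.sum())

    def test_volume_table_layout(self, phantom50, frame50):
        mask, _ = phantom50
        df = region_volume_table(divide_segments(mask, frame50))
        assert list(df.columns) == ["region", "name", "volume_ml"]
        assert len(df) == 14 and (df["volume_ml"] > 0).all()
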