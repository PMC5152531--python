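"""Mask I/O, consensus voting, resampling, volumetry, contour interpolation."""

import numpy as np
import pytest
import SimpleITK as sitk

from rvquant.geometry import RigidTransform
from rvquant.masks import (ContourStack, VolumeMask, compute_edv, consensus_mask,
                           contours_to_volume, read_contour_stack, read_mask,
                           resample_mask, write_mask)


def random_mask(rng, shape=(12, 10, 8), spacing=(1.0, 1.0, 1.0),
                origin=(0.0, 0.0, 0.0)):
    return VolumeMask((rng.random(shape) > 0.5).astype(np.uint8),
                      spacing=spacing, origin=origin)


class TestIO:
    @pytest.mark.parametrize("ext", [".nii.gz", ".nii", ".mha", ".mhd"])
    def test_roundtrip_preserves_everything(self, tmp_path, ext):
        rng = np.random.default_rng(0)
        m = random_mask(rng, spacing=(1.0, 1.0, 6.0), origin=(-4.5, 2.0, 10.0))
        path = tmp_path / f"m{ext}"
        write_mask(m, path)
        back = read_mask(path)
        np.testing.assert_array_equal(back.data, m.data)
        np.testing.assert_array_equal(back.spacing, m.spacing)
        np.testing.assert_array_equal(back.origin, m.origin)
        np.testing.assert_allclose(back.direction, m.direction, atol=1e-9)

    def test_anisotropic_slice_thickness_preserved(self, tmp_path):
        m = random_mask(np.random.default_rng(1), spacing=(1.25, 1.25, 8.0))
        path = tmp_path / "aniso.nii.gz"
        write_mask(m, path)
        assert tuple(read_mask(path).spacing) == (1.25, 1.25, 8.0)

    def test_empty_mask_reads_back_with_zero_volume(self, tmp_path):
        m = VolumeMask(np.zeros((5, 5, 5), dtype=np.uint8))
        write_mask(m, tmp_path / "empty.nii.gz")
        assert compute_edv(read_mask(tmp_path / "empty.nii.gz")) == 0.0

    def test_nonbinary_values_warn_and_binarize(self, tmp_path):
        arr = np.zeros((4, 4, 4), dtype=np.int16)
        arr[0, 0, 0] = 2
        arr[1, 1, 1] = 1
        img = sitk.GetImageFromArray(arr.transpose(2, 1, 0))
        path = tmp_path / "lab.nii.gz"
        sitk.WriteImage(img, str(path))
        with pytest.warns(UserWarning, match="non-binary"):
            m = read_mask(path)
        assert m.data.sum() == 2 and m.data.max() == 1

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_mask(tmp_path / "nope.nii.gz")


class TestVolumetry:
    def test_unit_voxels(self):
        m = VolumeMask(np.ones((10, 10, 10), dtype=np.uint8))
        assert compute_edv(m) == pytest.approx(1.0)

    def test_empty(self):
        assert compute_edv(VolumeMask(np.zeros((3, 3, 3), dtype=np.uint8))) == 0.0

    def test_digitized_sphere_matches_analytic_volume(self):
        # r = 20 mm at 0.5 mm spacing; 4/3 pi r^3 = 33.51 ml
        sp = 0.5
        xs = np.arange(-21.0, 21.0 + sp, sp)
        g = xs[:, None, None] ** 2 + xs[None, :, None] ** 2 + xs[None, None, :] ** 2
        m = VolumeMask((g <= 20.0 ** 2).astype(np.uint8), spacing=(sp, sp, sp),
                       origin=(xs[0],) * 3)
        analytic = 4.0 / 3.0 * np.pi * 20.0 ** 3 / 1000.0
        assert compute_edv(m) == pytest.approx(analytic, rel=0.01)

    def test_spacing_aware(self):
        """Same physical ball digitized at two spacings gives one volume."""
        vols = []
        for sp in (0.5, 1.0):
            xs = np.arange(-16.0, 16.0 + sp, sp)
            g = xs[:, None, None] ** 2 + xs[None, :, None] ** 2 + xs[None, None, :] ** 2
            vols.append(compute_edv(VolumeMask((g <= 15.0 ** 2).astype(np.uint8),
                                               spacing=(sp, sp, sp))))
        assert vols[0] == pytest.approx(vols[1], rel=0.02)


class TestConsensus:
    def test_two_of_three_kept_one_of_two_dropped(self):
        base = np.zeros((3, 3, 3), dtype=np.uint8)
        a, b, c = base.copy(), base.copy(), base.copy()
        a[1, 1, 1] = b[1, 1, 1] = 1          # 2 of 3 -> mean 2/3 > 0.5: kept
        a[0, 0, 0] = 1                        # 1 of 3: dropped
        masks3 = [VolumeMask(x) for x in (a, b, c)]
        out3 = consensus_mask(masks3)
        assert out3.data[1, 1, 1] == 1 and out3.data[0, 0, 0] == 0
        out2 = consensus_mask(masks3[:2])     # 1 of 2 -> mean 0.5: not > 0.5
        assert out2.data[0, 0, 0] == 0 and out2.data[1, 1, 1] == 1

    def test_idempotent_and_permutation_invariant(self):
        rng = np.random.default_rng(2)
        ms = [random_mask(rng) for _ in range(3)]
        np.testing.assert_array_equal(consensus_mask([ms[0]]).data, ms[0].data)
        np.testing.assert_array_equal(consensus_mask(ms).data,
                                      consensus_mask(ms[::-1]).data)

    def test_identical_masks_unchanged(self):
        m = random_mask(np.random.default_rng(3))
        np.testing.assert_array_equal(consensus_mask([m, m, m]).data, m.data)

    def test_grid_mismatch_rejected(self):
        rng = np.random.default_rng(4)
        a = random_mask(rng)
        b = random_mask(rng, spacing=(2.0, 1.0, 1.0))
        with pytest.raises(ValueError, match="grid"):
            consensus_mask([a, b])


class TestResample:
    def test_identity_same_grid_is_exact(self):
        m = random_mask(np.random.default_rng(5), shape=(15, 12, 9),
                        origin=(3.0, -2.0, 7.0))
        out = resample_mask(m, RigidTransform.identity(), m)
        np.testing.assert_array_equal(out.data, m.data)

    def test_one_voxel_translation_shifts_grid(self):
        m = random_mask(np.random.default_rng(6))
        t = RigidTransform(np.eye(3), [1.0, 0.0, 0.0])  # one voxel pitch in x
        out = resample_mask(m, t, m)
        expected = np.zeros_like(m.data)
        expected[1:] = m.data[:-1]
        np.testing.assert_array_equal(out.data, expected)

    def test_rotated_box_preserves_volume(self):
        box = np.zeros((70, 70, 70), dtype=np.uint8)
        box[25:45, 20:50, 15:55] = 1  # 20 x 30 x 40 mm at 1 mm spacing
        m = VolumeMask(box, origin=(-35.0, -35.0, -35.0))
        R = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        out = resample_mask(m, RigidTransform(R, np.zeros(3)), m)
        assert compute_edv(out) == pytest.approx(compute_edv(m), rel=0.05)


def circle(r, n=128):
    a = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([r * np.cos(a), r * np.sin(a)])


class TestContourInterpolation:
    def test_cylinder_volume(self):
        r, height = 15.0, 30.0
        stack = ContourStack(np.arange(0.0, height + 1, 5.0),
                             [circle(r)] * 7)
        m = contours_to_volume(stack, 0.5)
        assert compute_edv(m) == pytest.approx(np.pi * r ** 2 * height / 1000.0,
                                               rel=0.02)

    def test_frustum_volume(self):
        r0, r1, height = 20.0, 10.0, 30.0
        zs = np.arange(0.0, height + 1, 5.0)
        radii = r0 + (r1 - r0) * zs / height
        stack = ContourStack(zs, [circle(r) for r in radii])
        m = contours_to_volume(stack, 0.5)
        analytic = np.pi * height / 3.0 * (r0 ** 2 + r0 * r1 + r1 ** 2) / 1000.0
        assert compute_edv(m) == pytest.approx(analytic, rel=0.02)

    def test_duplicated_plane_gives_prism(self):
        square = np.array([[0.0, 0.0], [10.0, 0.0], [10.0, 10.0], [0.0, 10.0]])
        stack = ContourStack([0.0, 8.0], [square, square])
        m = contours_to_volume(stack, 1.0)
        assert compute_edv(m) == pytest.approx(10 * 10 * 8 / 1000.0, rel=0.05)
        # every slice is the same rasterization
        fg = m.data.sum(axis=(0, 1))
        assert len(set(fg[fg > 0])) == 1

    def test_requires_two_planes(self):
        with pytest.raises(ValueError, match="2 contour planes"):
            contours_to_volume(ContourStack([0.0], [circle(5)]), 1.0)

    def test_rejects_self_intersecting_polygon(self):
        bowtie = np.array([[0.0, 0.0], [10.0, 10.0], [10.0, 0.0], [0.0, 10.0]])
        with pytest.raises(ValueError, match="self-intersecting"):
            ContourStack([0.0, 5.0], [bowtie, bowtie])

    def test_text_format_roundtrip(self, tmp_path):
        path = tmp_path / "contours.txt"
        path.write_text("# demo stack\nplane 0.0\n0 0\n10 0\n10 10\n0 10\n"
                        "plane 6.0\n0 0\n10 0\n10 10\n0 10\n")
        stack = read_contour_stack(path)
        assert len(stack.plane_positions) == 2
        m = contours_to_volume(stack, 1.0)
        assert compute_edv(m) == pytest.approx(0.6, rel=0.1)
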