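"""Binary segmentation masks: I/O, geometry, interpolation, consensus, volumetry.

A :class:`VolumeMask` is a 3D binary grid plus the header geometry (spacing,
origin, direction) that places voxel (i, j, k) at the physical point
``origin + direction @ (spacing * (i, j, k))`` in the ITK-style LPS frame;
a voxel is "at" its center. SimpleITK backs file I/O (NIfTI, MetaImage) and
grid resampling; the consensus rule, volumetry, and the contour-stack
shape-based interpolation are implemented here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import SimpleITK as sitk
from scipy import ndimage
from shapely.geometry import Polygon as _ShapelyPolygon

from .geometry import RigidTransform

__all__ = [
    "VolumeMask",
    "ContourStack",
    "read_mask",
    "write_mask",
    "contours_to_volume",
    "resample_mask",
    "consensus_mask",
    "compute_edv",
    "signed_distance",
]


@dataclass
class VolumeMask:
    """3D binary mask with physical-frame metadata.

    ``data`` is indexed (i, j, k) in the same order as the ITK image axes
    (fastest-varying index first), values in {0, 1}.
    """

    data: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        self.data = np.ascontiguousarray(np.asarray(self.data), dtype=np.uint8)
        if self.data.ndim != 3:
            raise ValueError(f"mask grid must be 3D, got shape {self.data.shape}")
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.direction = np.asarray(self.direction, dtype=float).reshape(3, 3)
        if np.any(self.spacing <= 0):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if not np.allclose(self.direction.T @ self.direction, np.eye(3), atol=1e-6):
            raise ValueError("direction matrix must be orthonormal")
        if self.data.max(initial=0) > 1:
            raise ValueError("mask values must be in {0, 1}")

    # -- geometry ----------------------------------------------------------

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def indices_to_physical(self, idx: np.ndarray) -> np.ndarray:
        """Physical mm coordinates of (N, 3) voxel indices (centers)."""
        idx = np.asarray(idx, dtype=float)
        return (self.direction @ (self.spacing * idx).T).T + self.origin

    def physical_to_indices(self, pts: np.ndarray) -> np.ndarray:
        """Continuous index coordinates of (N, 3) physical points."""
        pts = np.asarray(pts, dtype=float)
        return ((self.direction.T @ (pts - self.origin).T).T) / self.spacing

    def foreground_indices(self) -> np.ndarray:
        return np.argwhere(self.data > 0)

    def foreground_points(self) -> np.ndarray:
        """(N, 3) physical centers of the foreground voxels."""
        return self.indices_to_physical(self.foreground_indices())

    def sample_at(self, pts: np.ndarray) -> np.ndarray:
        """Nearest-neighbor mask values at (N, 3) physical points (0 outside)."""
        idx = np.rint(self.physical_to_indices(pts)).astype(int)
        inside = np.all((idx >= 0) & (idx < np.array(self.data.shape)), axis=1)
        out = np.zeros(len(idx), dtype=np.uint8)
        ii = idx[inside]
        out[inside] = self.data[ii[:, 0], ii[:, 1], ii[:, 2]]
        return out

    def same_grid(self, other: "VolumeMask", atol: float = 1e-6) -> bool:
        return (self.data.shape == other.data.shape
                and np.allclose(self.spacing, other.spacing, atol=atol)
                and np.allclose(self.origin, other.origin, atol=atol)
                and np.allclose(self.direction, other.direction, atol=atol))

    def with_data(self, data: np.ndarray) -> "VolumeMask":
        """New mask on the same grid with different voxel values."""
        return replace(self, data=data)

    # -- SimpleITK bridge --------------------------------------------------

    def to_sitk(self) -> sitk.Image:
        img = sitk.GetImageFromArray(self.data.transpose(2, 1, 0))
        img.SetSpacing(tuple(self.spacing))
        img.SetOrigin(tuple(self.origin))
        img.SetDirection(tuple(self.direction.ravel()))
        return img

    @classmethod
    def from_sitk(cls, img: sitk.Image) -> "VolumeMask":
        arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
        if arr.dtype.kind == "f" or arr.max(initial=0) > 1 or arr.min(initial=0) < 0:
            if not np.isin(np.unique(arr), (0, 1)).all():
                warnings.warn("non-binary voxel values: thresholding at 0.5",
                              stacklevel=2)
            arr = (arr > 0.5)
        return cls(arr.astype(np.uint8),
                   spacing=np.array(img.GetSpacing()),
                   origin=np.array(img.GetOrigin()),
                   direction=np.array(img.GetDirection()).reshape(3, 3))


def read_mask(path) -> VolumeMask:
    """Read a binary mask from NIfTI (.nii/.nii.gz) or MetaImage (.mha/.mhd)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return VolumeMask.from_sitk(sitk.ReadImage(str(path)))


def write_mask(mask: VolumeMask, path) -> None:
    sitk.WriteImage(mask.to_sitk(), str(Path(path)))


def compute_edv(mask: VolumeMask) -> float:
    """Cavity volume in millilitres: foreground voxels x voxel volume / 1000."""
    return float(mask.data.sum(dtype=np.int64)) * mask.voxel_volume_mm3 / 1000.0


def consensus_mask(masks: Sequence[VolumeMask]) -> VolumeMask:
    """Voxelwise multi-expert consensus: keep voxels with mean strictly > 0.5.

    Implemented as exact integer voting (``2 * count > n``), so an even
    split (e.g. 1 of 2 experts) drops the voxel while 2 of 3 keeps it.
    """
    if len(masks) == 0:
        raise ValueError("consensus requires at least one mask")
    ref = masks[0]
    for m in masks[1:]:
        if not ref.same_grid(m):
            raise ValueError("consensus inputs must share one grid; resample first")
    count = np.zeros(ref.data.shape, dtype=np.int32)
    for m in masks:
        count += m.data
    return ref.with_data(2 * count > len(masks))


def resample_mask(mask: VolumeMask, transform: RigidTransform,
                  reference: VolumeMask) -> VolumeMask:
    """Resample a moving mask onto the reference grid under a rigid transform.

    ``transform`` maps moving physical space to reference physical space.
    Nearest-neighbor interpolation preserves binarity; voxels mapping
    outside the moving field of view become 0.
    """
    inv = transform.inverse()
    t = sitk.AffineTransform(3)
    t.SetMatrix(tuple(inv.rotation.ravel()))
    t.SetTranslation(tuple(inv.translation))
    out = sitk.Resample(mask.to_sitk(), reference.to_sitk(), t,
                        sitk.sitkNearestNeighbor, 0.0, sitk.sitkUInt8)
    return VolumeMask.from_sitk(out)


def signed_distance(mask: VolumeMask) -> np.ndarray:
    """Signed Euclidean distance to the mask boundary, mm; negative inside."""
    m = mask.data > 0
    if not m.any():
        return np.full(m.shape, np.inf)
    outside = ndimage.distance_transform_edt(~m, sampling=mask.spacing)
    inside = ndimage.distance_transform_edt(m, sampling=mask.spacing)
    return outside - inside


# --------------------------------------------------------------------------
# Contour stacks
# --------------------------------------------------------------------------

@dataclass
class ContourStack:
    """Closed endocardial contours on a stack of parallel short-axis planes.

    ``plane_positions`` are strictly increasing heights (mm) along the
    slicing axis; ``contours[i]`` is an (N_i, 2) array of in-plane vertices
    (mm) of a simple closed polygon (the closing edge is implicit).
    ``frame`` maps plane coordinates (u, v, height) to world coordinates.
    """

    plane_positions: Sequence[float]
    contours: Sequence[np.ndarray]
    frame: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        self.plane_positions = np.asarray(self.plane_positions, dtype=float)
        self.contours = [np.asarray(c, dtype=float).reshape(-1, 2) for c in self.contours]
        self.frame = np.asarray(self.frame, dtype=float).reshape(3, 3)
        if len(self.plane_positions) != len(self.contours):
            raise ValueError("one contour per plane position required")
        if np.any(np.diff(self.plane_positions) <= 0):
            raise ValueError("plane positions must be strictly increasing")
        for i, c in enumerate(self.contours):
            if len(c) < 3:
                raise ValueError(f"contour {i} has fewer than 3 vertices")
            poly = _ShapelyPolygon(c)
            if not poly.is_valid or not poly.is_simple:
                raise ValueError(f"contour {i} is self-intersecting or degenerate")


def read_contour_stack(path) -> ContourStack:
    """Read the per-slice polygon text format.

    Each slice starts with a line ``plane <height_mm>`` followed by one
    ``x y`` vertex (mm) per line; blank lines and ``#`` comments ignored.
    """
    positions: list[float] = []
    contours: list[list[list[float]]] = []
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.lower().startswith("plane"):
            positions.append(float(line.split()[1]))
            contours.append([])
        else:
            x, y = line.split()[:2]
            contours[-1].append([float(x), float(y)])
    return ContourStack(positions, [np.asarray(c) for c in contours])


def _rasterize_sdf(polygon: np.ndarray, xs: np.ndarray, ys: np.ndarray,
                   spacing_xy: tuple) -> np.ndarray:
    """Signed distance (mm) of a rasterized polygon on the pixel-center grid."""
    from matplotlib.path import Path as MplPath

    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    inside = MplPath(polygon).contains_points(pts).reshape(len(xs), len(ys))
    if inside.any():
        din = ndimage.distance_transform_edt(inside, sampling=spacing_xy)
    else:
        din = np.zeros(inside.shape)
    dout = ndimage.distance_transform_edt(~inside, sampling=spacing_xy)
    return dout - din


def contours_to_volume(stack: ContourStack, spacing) -> VolumeMask:
    """Interpolate a contour stack to a binary volume (shape-based).

    Between consecutive planes, the signed-distance maps of the two bounding
    contours are blended linearly at the voxel's fractional height and
    thresholded at zero; voxels on a contour plane reproduce that contour's
    rasterization. Slices outside the stack are background.
    """
    spacing = np.broadcast_to(np.asarray(spacing, dtype=float).ravel(), (3,)).copy()
    if np.any(spacing <= 0):
        raise ValueError("spacing must be positive")
    if len(stack.plane_positions) < 2:
        raise ValueError("need at least 2 contour planes to interpolate a volume")

    # Pixel centers are offset half a pixel from the padded bounding box, so
    # polygon edges at the bbox never coincide with sampling points.
    all_xy = np.vstack(stack.contours)
    margin = 2.0 * spacing[:2]
    x0, y0 = all_xy.min(axis=0) - margin
    x1, y1 = all_xy.max(axis=0) + margin
    nx = int(np.ceil((x1 - x0) / spacing[0]))
    ny = int(np.ceil((y1 - y0) / spacing[1]))
    xs = x0 + (np.arange(nx) + 0.5) * spacing[0]
    ys = y0 + (np.arange(ny) + 0.5) * spacing[1]

    z0 = stack.plane_positions[0]
    z1 = stack.plane_positions[-1]
    # Slice centers at z0 + (k + 1/2) * dz tile the slab without end bias.
    nz = max(1, int(round((z1 - z0) / spacing[2])))
    zs = z0 + (np.arange(nz) + 0.5) * spacing[2]

    sdfs = [_rasterize_sdf(c, xs, ys, (spacing[0], spacing[1]))
            for c in stack.contours]

    grid = np.zeros((nx, ny, nz), dtype=np.uint8)
    pos = stack.plane_positions
    for k, z in enumerate(zs):
        if z < pos[0] or z > pos[-1]:
            continue
        j = int(np.clip(np.searchsorted(pos, z, side="right") - 1, 0, len(pos) - 2))
        f = (z - pos[j]) / (pos[j + 1] - pos[j])
        blended = (1.0 - f) * sdfs[j] + f * sdfs[j + 1]
        grid[:, :, k] = blended < 0

    origin = stack.frame @ np.array([xs[0], ys[0], zs[0]])
    return VolumeMask(grid, spacing=spacing, origin=origin, direction=stack.frame)
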