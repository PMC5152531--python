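"""Synthetic paired CMR/echo phantoms of a globular systemic right ventricle.

No patient images accompany the study conditions this package emulates, so
every pipeline stage is exercised on generated data with known ground truth:

* a blunt-apex superellipsoid half-capsule phantom with the six anatomical
  landmarks placed analytically (volumes in the 18–58 ml range of a small
  single-ventricle cohort);
* an "echo observation" derived from the CMR phantom by modality-specific
  degradation — inward trabecular surface offset, apical volume deficit,
  medial wall deficit, an anterior shadow sector — followed by a known rigid
  misalignment of the image and its landmarks;
* simulated expert contouring variability (smooth zero-mean perturbation of
  the boundary's signed distance);
* a cohort writer that stores masks, landmarks, and a ground-truth manifest
  (true transforms and planned per-region deficits) for recovery tests.

Deficits are specified as fractions of the total CMR voxel count, so the
planned regional volume-difference fraction of a deficit d is exactly
−100·d percent.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from scipy.integrate import quad
from scipy.spatial.transform import Rotation

from .geometry import LandmarkSet, RigidTransform
from .masks import VolumeMask, compute_edv, resample_mask, signed_distance, write_mask
from .segments import (DEFAULT_LAYER_BOUNDS, build_axis_frame,
                       cylindrical_coords, region_labels)

__all__ = [
    "PhantomParams",
    "ShadowSpec",
    "DegradationParams",
    "make_rv_phantom",
    "simulate_echo_observation",
    "simulate_expert",
    "make_cohort",
    "random_rigid_transform",
    "read_manifest",
]


@dataclass(frozen=True)
class PhantomParams:
    """Geometry of the globular RV phantom.

    The cavity is a superellipsoid half-capsule: elliptical cross-sections
    whose radii follow ``s(u) = (1 - (1-u)^taper)^(1/taper)`` of the
    normalized height u (0 at the apex, 1 at the flat valve plane). The
    default taper of 5 gives a blunt, globular apex in which the apical
    quarter of the axis holds roughly a fifth of the cavity volume, as in a
    dilated systemic RV. Radii are rescaled so the analytic volume matches
    ``target_volume_ml``.
    """

    axis_length: float = 60.0
    equatorial_radii: tuple = (24.0, 20.0)
    taper: float = 5.0
    spacing: float = 1.0
    target_volume_ml: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.axis_length, *self.equatorial_radii, self.taper,
               self.spacing, self.target_volume_ml) <= 0:
            raise ValueError("all phantom parameters must be positive")


@dataclass(frozen=True)
class ShadowSpec:
    """Anterior acoustic-shadow sector: wall truncation over an angular span.

    ``center_theta_deg`` uses the ventricular angle convention (inferior 0°,
    left 90°, anterior 180°); the default centers the sector on the upper
    anterior free wall, where lung shadowing hits in practice.
    """

    center_theta_deg: float = 150.0
    width_deg: float = 60.0
    depth_mm: float = 6.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.width_deg <= 180.0):
            raise ValueError("shadow width must lie in [0, 180] degrees")
        if self.depth_mm < 0:
            raise ValueError("shadow depth must be non-negative")


@dataclass(frozen=True)
class DegradationParams:
    """Echo-specific degradation applied to a CMR phantom.

    Applied in a fixed order: trabecular inward offset, apical erosion,
    medial-band erosion, shadow sector, then the rigid misalignment of the
    degraded mask and its landmarks. Deficit fractions are relative to the
    total CMR voxel count.
    """

    apical_deficit_fraction: float = 0.0
    medial_deficit_fraction: float = 0.0
    trabecular_offset_mm: float = 0.0
    shadow: Optional[ShadowSpec] = None
    misalignment: RigidTransform = field(default_factory=RigidTransform.identity)
    expert_noise_sd_mm: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.apical_deficit_fraction < 0.5):
            raise ValueError("apical deficit fraction must lie in [0, 0.5)")
        if not (0.0 <= self.medial_deficit_fraction < 0.5):
            raise ValueError("medial deficit fraction must lie in [0, 0.5)")
        if self.trabecular_offset_mm < 0 or self.expert_noise_sd_mm < 0:
            raise ValueError("offsets and noise SDs must be non-negative")


def _profile(u: np.ndarray, taper: float) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return (1.0 - (1.0 - u) ** taper) ** (1.0 / taper)


def make_rv_phantom(params: PhantomParams) -> tuple[VolumeMask, LandmarkSet]:
    """Generate the phantom mask and its six landmarks.

    The apex sits at the world origin and the long axis runs along +z; the
    inferior annulus point lies at +y, the anterior at −y, and left/right at
    −x/+x (right-handed ventricular frame). Landmarks lie exactly on the
    analytic surface/axis. The voxelized volume lands within 5% of the
    target for any reasonable spacing.
    """
    L = params.axis_length
    ra, rb = params.equatorial_radii
    sp = float(params.spacing)

    # Scale the radii so the analytic volume hits the target exactly.
    shape_integral = quad(lambda u: _profile(u, params.taper) ** 2, 0.0, 1.0)[0]
    analytic_mm3 = np.pi * ra * rb * L * shape_integral
    scale = np.sqrt(params.target_volume_ml * 1000.0 / analytic_mm3)
    ra, rb = ra * scale, rb * scale

    if min(L, 2 * ra, 2 * rb) / sp < 10:
        raise ValueError(
            f"spacing {sp} mm too coarse: fewer than 10 voxels across the shape")

    margin = 3 * sp
    xs = np.arange(-ra - margin, ra + margin + sp, sp)
    ys = np.arange(-rb - margin, rb + margin + sp, sp)
    zs = np.arange(-margin, L + margin + sp, sp)
    u = zs / L
    s2 = _profile(u, params.taper) ** 2
    s2[(u < 0) | (u > 1)] = -1.0  # outside the axial extent
    rho2 = (xs[:, None] / ra) ** 2 + (ys[None, :] / rb) ** 2
    grid = rho2[:, :, None] <= s2[None, None, :]

    mask = VolumeMask(grid.astype(np.uint8), spacing=np.full(3, sp),
                      origin=np.array([xs[0], ys[0], zs[0]]))
    landmarks = LandmarkSet.from_mapping({
        "valve_center": [0.0, 0.0, L],
        "annulus_inferior": [0.0, rb, L],
        "annulus_anterior": [0.0, -rb, L],
        "annulus_left": [-ra, 0.0, L],
        "annulus_right": [ra, 0.0, L],
        "apex": [0.0, 0.0, 0.0],
    })
    return mask, landmarks


def _remove_lowest(order_values: np.ndarray, candidates: np.ndarray,
                   n_remove: int) -> np.ndarray:
    """Indices (into candidates) of the n_remove smallest order values."""
    if n_remove >= len(candidates):
        return np.arange(len(candidates))
    part = np.argpartition(order_values, n_remove)[:n_remove]
    return part


def _degrade(cmr_mask: VolumeMask, landmarks: LandmarkSet,
             deg: DegradationParams,
             layer_bounds=DEFAULT_LAYER_BOUNDS):
    """Degradation stages in CMR space; returns (mask, per-region removal counts)."""
    frame = build_axis_frame(landmarks)
    work = cmr_mask.data.copy().astype(bool)
    n_total = int(work.sum())

    # 1. Trabecular inward offset: erode the whole surface by a physical depth.
    if deg.trabecular_offset_mm > 0:
        dist_in = ndimage.distance_transform_edt(work, sampling=cmr_mask.spacing)
        work &= dist_in > deg.trabecular_offset_mm

    idx = np.argwhere(work)
    pts = cmr_mask.indices_to_physical(idx)
    h, theta = cylindrical_coords(pts, frame)

    # 2. Apical erosion: drop the lowest-height voxels until the requested
    #    fraction of the original CMR volume is gone.
    if deg.apical_deficit_fraction > 0:
        n_remove = int(round(deg.apical_deficit_fraction * n_total))
        sel = _remove_lowest(h, idx, n_remove)
        if h[sel].max(initial=0.0) >= layer_bounds[0]:
            warnings.warn("apical deficit exceeds the apical layer volume",
                          stacklevel=3)
        rm = idx[sel]
        work[rm[:, 0], rm[:, 1], rm[:, 2]] = False

    # 3. Medial-band erosion: peel the outermost shell of the medial layer
    #    (uniform in angle) until the requested fraction is gone.
    if deg.medial_deficit_fraction > 0:
        dist_in = ndimage.distance_transform_edt(work, sampling=cmr_mask.spacing)
        idx = np.argwhere(work)
        pts = cmr_mask.indices_to_physical(idx)
        h, theta = cylindrical_coords(pts, frame)
        band = (h >= layer_bounds[0]) & (h < layer_bounds[1])
        n_remove = int(round(deg.medial_deficit_fraction * n_total))
        if n_remove > band.sum():
            warnings.warn("medial deficit exceeds the medial layer volume",
                          stacklevel=3)
            n_remove = int(band.sum())
        cand = idx[band]
        depth = dist_in[cand[:, 0], cand[:, 1], cand[:, 2]]
        sel = _remove_lowest(depth, cand, n_remove)
        rm = cand[sel]
        work[rm[:, 0], rm[:, 1], rm[:, 2]] = False

    # 4. Shadow sector: truncate the wall within an angular span.
    if deg.shadow is not None and deg.shadow.depth_mm > 0 and deg.shadow.width_deg > 0:
        dist_in = ndimage.distance_transform_edt(work, sampling=cmr_mask.spacing)
        idx = np.argwhere(work)
        pts = cmr_mask.indices_to_physical(idx)
        _, theta = cylindrical_coords(pts, frame)
        dtheta = (theta - deg.shadow.center_theta_deg + 180.0) % 360.0 - 180.0
        in_sector = np.abs(dtheta) <= deg.shadow.width_deg / 2.0
        depth = dist_in[idx[:, 0], idx[:, 1], idx[:, 2]]
        rm = idx[in_sector & (depth <= deg.shadow.depth_mm)]
        work[rm[:, 0], rm[:, 1], rm[:, 2]] = False

    # Connectivity check: heavy degradation can split the cavity.
    _, n_comp = ndimage.label(work)
    if n_comp > 1:
        warnings.warn(f"degraded mask is disconnected ({n_comp} components)",
                      stacklevel=3)

    removed = cmr_mask.data.astype(bool) & ~work
    rm_idx = np.argwhere(removed)
    removal_counts = np.zeros(15, dtype=np.int64)
    if len(rm_idx):
        rm_labels = region_labels(cmr_mask.indices_to_physical(rm_idx), frame,
                                  layer_bounds)
        removal_counts = np.bincount(rm_labels, minlength=15)
    return cmr_mask.with_data(work), removal_counts, n_total


def _transformed_grid(mask: VolumeMask, transform: RigidTransform) -> VolumeMask:
    """Empty axis-aligned grid (same spacing) covering the transformed mask."""
    shape = np.array(mask.data.shape, dtype=float)
    corners = np.array([[i, j, k] for i in (0, shape[0] - 1)
                        for j in (0, shape[1] - 1) for k in (0, shape[2] - 1)])
    phys = transform.apply(mask.indices_to_physical(corners))
    lo = phys.min(axis=0) - 2 * mask.spacing
    hi = phys.max(axis=0) + 2 * mask.spacing
    n = np.ceil((hi - lo) / mask.spacing).astype(int) + 1
    return VolumeMask(np.zeros(tuple(n), dtype=np.uint8),
                      spacing=mask.spacing.copy(), origin=lo)


def simulate_echo_observation(cmr_mask: VolumeMask, landmarks: LandmarkSet,
                              deg: DegradationParams) -> tuple[VolumeMask, LandmarkSet]:
    """Degraded, misaligned echo counterpart of a CMR mask and its landmarks."""
    degraded, _, _ = _degrade(cmr_mask, landmarks, deg)
    if deg.misalignment.is_identity():
        return degraded, landmarks
    echo_grid = _transformed_grid(degraded, deg.misalignment)
    echo_mask = resample_mask(degraded, deg.misalignment, echo_grid)
    return echo_mask, deg.misalignment.apply_landmarks(landmarks)


def simulate_expert(mask: VolumeMask, noise_sd: float, seed: int,
                    correlation_mm: float = 4.0) -> VolumeMask:
    """Simulated expert contouring of a mask.

    A smooth zero-mean Gaussian random field (unit SD after smoothing over
    ``correlation_mm``) scaled by ``noise_sd`` (mm) is added to the mask's
    signed distance before re-thresholding, perturbing the boundary without
    a systematic volume bias.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if noise_sd == 0:
        return mask.with_data(mask.data.copy())
    rng = np.random.default_rng(seed)
    sdf = signed_distance(mask)
    white = rng.standard_normal(mask.data.shape)
    sigma_vox = correlation_mm / mask.spacing
    fieldv = ndimage.gaussian_filter(white, sigma=sigma_vox)
    fieldv /= fieldv.std()
    return mask.with_data(sdf + noise_sd * fieldv < 0)


def random_rigid_transform(rng: np.random.Generator,
                           max_angle_deg: float = 20.0,
                           max_translation_mm: float = 10.0) -> RigidTransform:
    """Random proper rigid transform (uniform axis, bounded angle/shift)."""
    axis = rng.standard_normal(3)
    axis /= np.linalg.norm(axis)
    angle = np.radians(rng.uniform(0.25 * max_angle_deg, max_angle_deg))
    R = Rotation.from_rotvec(angle * axis).as_matrix()
    t = rng.uniform(-max_translation_mm, max_translation_mm, size=3)
    return RigidTransform(R, t)


def make_cohort(out_dir, n_patients: int = 5, seed: int = 0,
                volume_range_ml: tuple = (18.0, 58.0),
                n_experts: int = 3,
                spacing: float = 1.0,
                apical_deficit_fraction: float = 0.142,
                medial_deficit_fraction: float = 0.05,
                trabecular_offset_mm: float = 0.0,
                shadow: Optional[ShadowSpec] = None,
                expert_noise_sd_mm: float = 0.5,
                max_angle_deg: float = 20.0,
                max_translation_mm: float = 10.0) -> dict:
    """Write a synthetic cohort to disk and return the ground-truth manifest.

    Defaults emulate the study conditions: 5 patients with CMR volumes drawn
    in 18–58 ml, 3 experts per image, a dominant apical echo deficit of
    14.2% of the CMR volume and a ~5% uniform medial deficit, and a random
    rigid echo-vs-CMR misalignment.

    Layout per patient directory ``patient_<k>``: ``cmr_mask.nii.gz`` (noise
    free ground truth), ``cmr_landmarks.json``, ``cmr_expert<e>_mask.nii.gz``
    and ``echo_expert<e>_mask.nii.gz`` (expert contours of both modalities),
    ``echo_landmarks.json``, and a cohort-level ``manifest.json``.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    if not (0 < volume_range_ml[0] < volume_range_ml[1]):
        raise ValueError(f"invalid volume range {volume_range_ml}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    root_ss = np.random.SeedSequence(seed)
    manifest: dict = {"seed": int(seed), "n_patients": int(n_patients),
                      "n_experts": int(n_experts), "spacing_mm": spacing,
                      "expert_noise_sd_mm": expert_noise_sd_mm, "patients": {}}

    for k, ss in enumerate(root_ss.spawn(n_patients), start=1):
        child = ss.spawn(3 + 2 * n_experts)
        rng = np.random.default_rng(child[0])
        target = float(rng.uniform(*volume_range_ml))
        # Keep the aspect ratio fixed and scale the axis with volume^(1/3).
        axis_len = 60.0 * (target / 50.0) ** (1.0 / 3.0)
        params = PhantomParams(axis_length=axis_len, spacing=spacing,
                               target_volume_ml=target,
                               seed=int(rng.integers(2 ** 31)))
        cmr_mask, cmr_lm = make_rv_phantom(params)

        misalignment = random_rigid_transform(np.random.default_rng(child[1]),
                                              max_angle_deg, max_translation_mm)
        deg = DegradationParams(
            apical_deficit_fraction=apical_deficit_fraction,
            medial_deficit_fraction=medial_deficit_fraction,
            trabecular_offset_mm=trabecular_offset_mm,
            shadow=shadow,
            misalignment=misalignment,
            expert_noise_sd_mm=expert_noise_sd_mm,
        )
        degraded, removal_counts, n_total = _degrade(cmr_mask, cmr_lm, deg)
        echo_grid = _transformed_grid(degraded, misalignment)
        echo_mask = resample_mask(degraded, misalignment, echo_grid)
        echo_lm = misalignment.apply_landmarks(cmr_lm)

        pdir = out_dir / f"patient_{k}"
        pdir.mkdir(exist_ok=True)
        write_mask(cmr_mask, pdir / "cmr_mask.nii.gz")
        from .geometry import write_landmarks  # local import avoids cycle at module load
        write_landmarks(cmr_lm, pdir / "cmr_landmarks.json")
        write_landmarks(echo_lm, pdir / "echo_landmarks.json")
        for e in range(1, n_experts + 1):
            cmr_e = simulate_expert(cmr_mask, expert_noise_sd_mm,
                                    int(child[1 + e].generate_state(1)[0] % 2 ** 31))
            echo_e = simulate_expert(echo_mask, expert_noise_sd_mm,
                                     int(child[1 + n_experts + e].generate_state(1)[0] % 2 ** 31))
            write_mask(cmr_e, pdir / f"cmr_expert{e}_mask.nii.gz")
            write_mask(echo_e, pdir / f"echo_expert{e}_mask.nii.gz")

        planned_pct = (-100.0 * removal_counts[1:] / n_total)
        manifest["patients"][f"patient_{k}"] = {
            "target_volume_ml": target,
            "cmr_volume_ml": compute_edv(cmr_mask),
            "phantom": {"axis_length": params.axis_length,
                        "taper": params.taper, "spacing": spacing},
            "degradation": {
                "apical_deficit_fraction": apical_deficit_fraction,
                "medial_deficit_fraction": medial_deficit_fraction,
                "trabecular_offset_mm": trabecular_offset_mm,
                "shadow": None if shadow is None else asdict(shadow),
            },
            "misalignment_matrix4": misalignment.matrix4().tolist(),
            "planned_region_delta_pct": planned_pct.tolist(),
            "planned_global_delta_ml": float(-removal_counts[1:].sum()
                                             * cmr_mask.voxel_volume_mm3 / 1000.0),
        }

    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


def read_manifest(dataset_dir) -> dict:
    return json.loads((Path(dataset_dir) / "manifest.json").read_text())
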