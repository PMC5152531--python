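"""Landmark model and rigid landmark-based registration.

Echo-to-CMR alignment is performed from six named anatomical landmarks
(valve center, four annulus compass points, apex) picked in each modality.
The rigid transform between the two point sets is the closed-form
least-squares solution of Arun et al. (centroid subtraction, SVD of the
cross-covariance matrix, determinant sign fix so the result is always a
proper rotation, translation from the centroids).

All coordinates are physical millimetres in the image world frame (ITK-style
LPS). Correspondence is strictly by landmark name; there is no permutation
search.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "LANDMARK_NAMES",
    "Point3",
    "LandmarkSet",
    "RigidTransform",
    "ResidualReport",
    "DegenerateFitError",
    "fit_rigid_transform",
    "apply_to_points",
    "landmark_residual",
    "invert",
    "compose",
    "read_landmarks",
    "write_landmarks",
    "read_fcsv",
]

#: Canonical landmark names, in protocol order 1-6.
LANDMARK_NAMES = (
    "valve_center",
    "annulus_inferior",
    "annulus_anterior",
    "annulus_left",
    "annulus_right",
    "apex",
)


class DegenerateFitError(ValueError):
    """Landmark configuration too degenerate for a stable rigid fit."""


@dataclass(frozen=True)
class Point3:
    """A point in physical space, millimetres."""

    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        if not all(math.isfinite(v) for v in (self.x, self.y, self.z)):
            raise ValueError(f"non-finite coordinates: {(self.x, self.y, self.z)}")

    @property
    def array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)

    @classmethod
    def from_array(cls, a: Sequence[float]) -> "Point3":
        a = np.asarray(a, dtype=float).reshape(3)
        return cls(float(a[0]), float(a[1]), float(a[2]))


@dataclass(frozen=True)
class LandmarkSet:
    """The six ventricular landmarks of the registration protocol.

    Numbering follows the selection protocol: (1) valve center,
    (2) inferior, (3) anterior, (4) left, (5) right annulus points,
    (6) ventricular apex.
    """

    valve_center: Point3
    annulus_inferior: Point3
    annulus_anterior: Point3
    annulus_left: Point3
    annulus_right: Point3
    apex: Point3

    def __post_init__(self) -> None:
        axis = self.valve_center.array - self.apex.array
        axis_len = np.linalg.norm(axis)
        if axis_len <= 1e-9:
            raise ValueError("apex coincides with valve_center: zero-length axis")
        # The annulus points must not all sit on the long axis.
        u = axis / axis_len
        perp = 0.0
        for p in (self.annulus_inferior, self.annulus_anterior,
                  self.annulus_left, self.annulus_right):
            d = p.array - self.apex.array
            perp = max(perp, np.linalg.norm(d - (d @ u) * u))
        if perp <= 1e-9:
            raise ValueError("annulus landmarks are collinear with the long axis")

    def to_array(self) -> np.ndarray:
        """(6, 3) array in canonical name order."""
        return np.stack([getattr(self, n).array for n in LANDMARK_NAMES])

    @classmethod
    def from_array(cls, a: np.ndarray) -> "LandmarkSet":
        a = np.asarray(a, dtype=float)
        if a.shape != (6, 3):
            raise ValueError(f"expected (6, 3) landmark array, got {a.shape}")
        return cls(**{n: Point3.from_array(row) for n, row in zip(LANDMARK_NAMES, a)})

    @classmethod
    def from_mapping(cls, m: Mapping[str, Sequence[float]]) -> "LandmarkSet":
        missing = [n for n in LANDMARK_NAMES if n not in m]
        if missing:
            raise ValueError(f"missing landmark(s): {missing}")
        return cls(**{n: Point3.from_array(np.asarray(m[n], dtype=float)) for n in LANDMARK_NAMES})

    def as_dict(self) -> dict:
        return {n: list(getattr(self, n).array) for n in LANDMARK_NAMES}


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid transform ``p -> rotation @ p + translation`` (mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValueError("rotation is not orthonormal within 1e-9")
        if abs(np.linalg.det(R) - 1.0) > 1e-9:
            raise ValueError("rotation is not proper (det != +1): reflections rejected")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to an (N, 3) array of physical points."""
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def apply_point(self, p: Point3) -> Point3:
        return Point3.from_array(self.rotation @ p.array + self.translation)

    def apply_landmarks(self, lm: LandmarkSet) -> LandmarkSet:
        return LandmarkSet.from_array(self.apply(lm.to_array()))

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    def matrix4(self) -> np.ndarray:
        """Homogeneous 4x4 matrix."""
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    @classmethod
    def from_matrix4(cls, m: np.ndarray) -> "RigidTransform":
        m = np.asarray(m, dtype=float).reshape(4, 4)
        return cls(m[:3, :3], m[:3, 3])

    def is_identity(self, atol: float = 1e-12) -> bool:
        return (np.allclose(self.rotation, np.eye(3), atol=atol)
                and np.allclose(self.translation, 0.0, atol=atol))


@dataclass(frozen=True)
class ResidualReport:
    """Post-alignment landmark distances, mm.

    Landmark registration of valve/annulus/apex points typically leaves a
    residual of a few millimetres even when the image alignment is good:
    the landmarks give groupwise rather than exact pairwise correspondence.
    """

    per_landmark_distance: dict
    rms: float
    max: float

    def __post_init__(self) -> None:
        if self.max + 1e-12 < self.rms or self.rms < 0:
            raise ValueError("residual invariant violated: need max >= rms >= 0")


def fit_rigid_transform(source: LandmarkSet, target: LandmarkSet) -> RigidTransform:
    """Least-squares proper rigid transform mapping source onto target.

    Closed form: subtract centroids, SVD the 3x3 cross-covariance
    ``H = sum (p_i - p̄)(q_i - q̄)^T``, take ``R = V D U^T`` with
    ``D = diag(1, 1, det(V U^T))`` so a reflection is never returned, and
    ``t = q̄ - R p̄``.

    Raises
    ------
    DegenerateFitError
        If the centered source points are (near-)collinear, i.e. the
        smallest singular value is below 1e-6 times the largest.
    """
    P = source.to_array()
    Q = target.to_array()
    p_bar = P.mean(axis=0)
    q_bar = Q.mean(axis=0)
    Pc = P - p_bar
    Qc = Q - q_bar

    sv = np.linalg.svd(Pc, compute_uv=False)
    if sv[-1] < 1e-6 * sv[0]:
        raise DegenerateFitError(
            "landmark configuration is unstable for a rigid fit "
            f"(singular-value ratio {sv[-1] / sv[0]:.2e})"
        )

    H = Pc.T @ Qc
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    # Re-orthonormalize against accumulated round-off so the invariant holds.
    Ru, _, Rvt = np.linalg.svd(R)
    R = Ru @ Rvt
    t = q_bar - R @ p_bar
    return RigidTransform(R, t)


def apply_to_points(transform: RigidTransform, points: Iterable[Point3]) -> list:
    """Apply a rigid transform to a sequence of points."""
    return [transform.apply_point(p) for p in points]


def landmark_residual(source: LandmarkSet, target: LandmarkSet,
                      transform: RigidTransform) -> ResidualReport:
    """Per-landmark, RMS and max distances after applying the transform."""
    moved = transform.apply(source.to_array())
    dists = np.linalg.norm(moved - target.to_array(), axis=1)
    return ResidualReport(
        per_landmark_distance={n: float(d) for n, d in zip(LANDMARK_NAMES, dists)},
        rms=float(np.sqrt(np.mean(dists ** 2))),
        max=float(dists.max()),
    )


def invert(transform: RigidTransform) -> RigidTransform:
    return transform.inverse()


def compose(a: RigidTransform, b: RigidTransform) -> RigidTransform:
    """``compose(a, b)`` applies b first, then a."""
    return RigidTransform(a.rotation @ b.rotation,
                          a.rotation @ b.translation + a.translation)


# --------------------------------------------------------------------------
# Landmark file I/O
# --------------------------------------------------------------------------

#: Accepted aliases for the canonical names (protocol numbers 1-6 included).
_NAME_ALIASES = {str(i + 1): n for i, n in enumerate(LANDMARK_NAMES)}
_NAME_ALIASES.update({n: n for n in LANDMARK_NAMES})


def _canonical_name(label: str) -> str | None:
    return _NAME_ALIASES.get(label.strip().lower().replace(" ", "_").replace("-", "_"))


def read_landmarks(path) -> LandmarkSet:
    """Read a landmark file (.json, .csv, or 3D Slicer .fcsv), mm."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".json":
        data = json.loads(path.read_text())
        mapped = {}
        for key, val in data.items():
            name = _canonical_name(str(key))
            if name is not None:
                if isinstance(val, Mapping):
                    val = [val["x"], val["y"], val["z"]]
                mapped[name] = val
        return LandmarkSet.from_mapping(mapped)
    if suffix == ".csv":
        mapped = {}
        with path.open(newline="") as fh:
            for row in csv.DictReader(fh):
                name = _canonical_name(row["name"])
                if name is not None:
                    mapped[name] = [float(row["x"]), float(row["y"]), float(row["z"])]
        return LandmarkSet.from_mapping(mapped)
    if suffix == ".fcsv":
        return read_fcsv(path)
    raise ValueError(f"unrecognized landmark file format: {path}")


def write_landmarks(landmarks: LandmarkSet, path) -> None:
    """Write landmarks as JSON (name -> [x, y, z] mm) or CSV."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(landmarks.as_dict(), indent=2) + "\n")
    elif path.suffix.lower() == ".csv":
        with path.open("w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["name", "x", "y", "z"])
            for n in LANDMARK_NAMES:
                p = getattr(landmarks, n)
                writer.writerow([n, repr(p.x), repr(p.y), repr(p.z)])
    else:
        raise ValueError(f"unsupported landmark output format: {path}")


def read_fcsv(path) -> LandmarkSet:
    """Read a 3D Slicer fiducial file, mapping labels to canonical names.

    Slicer stores fiducials in RAS by default; coordinates are converted to
    the LPS frame used throughout (x and y negated) unless the header
    declares ``CoordinateSystem = LPS`` (or ``0``).
    """
    path = Path(path)
    ras = True
    mapped = {}
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            lowered = line.lower().replace(" ", "")
            if "coordinatesystem=" in lowered:
                system = lowered.split("coordinatesystem=")[1]
                ras = system not in ("lps", "0")
            continue
        fields = line.split(",")
        if len(fields) < 12:
            continue
        x, y, z = (float(fields[1]), float(fields[2]), float(fields[3]))
        if ras:
            x, y = -x, -y
        name = _canonical_name(fields[11])
        if name is not None:
            mapped[name] = [x, y, z]
    return LandmarkSet.from_mapping(mapped)
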