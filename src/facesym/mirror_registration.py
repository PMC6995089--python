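"""Mirror the face and superimpose the reflection on the original.

The asymmetry analysis rests on mirror superimposition: reflect the
facial surface across an (arbitrary) plane, swap bilateral landmark
names so left maps to right, and rigidly register the five mirrored
midface landmarks — subnasale and both eye corners, inner and outer —
onto their original positions.  After that registration, any residual
distance between the surface and its mirror image measures left–right
asymmetry.

The reflection plane is immaterial: composing the explicit reflection
with the fitted proper rigid motion always yields the same mirrored
configuration, so all downstream metrics are invariant to the plane
choice (and to any rigid motion of the input).  The default plane passes
through subnasale with its normal along the outer-eye-corner axis,
which keeps intermediate meshes visually sensible.

The rigid fit is the classical closed-form least-squares solution over
proper rotations (Kabsch / Wahba), without scaling: the metrics are
absolute millimetre distances and isotropic scaling would deflate them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import DegenerateGeometryError, ValidationError
from .mesh_io import LandmarkSet, REGISTRATION_LANDMARKS, TriangleMesh

_ORTHONORMALITY_TOL = 1e-9


@dataclass
class RigidTransform:
    """Proper rigid motion x ↦ R x + t (rotation det = +1, translation mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        err = np.abs(self.rotation @ self.rotation.T - np.eye(3)).max()
        if err > 1e-6:
            raise ValidationError(f"rotation not orthonormal (error {err:.2e})")
        if np.linalg.det(self.rotation) < 0:
            raise ValidationError("rotation has negative determinant (reflection)")

    def apply(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        return points @ self.rotation.T + self.translation

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply ``other`` first."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )


@dataclass
class SuperimpositionResult:
    """Mirrored-and-registered surface plus the fit that produced it."""

    mesh: TriangleMesh
    landmarks: LandmarkSet  # mirrored, bilateral-swapped, registered
    transform: RigidTransform
    residual_mm: float  # RMS over the five landmark pairs
    plane_point: np.ndarray
    plane_normal: np.ndarray


def _unit_normal(plane_normal) -> np.ndarray:
    n = np.asarray(plane_normal, dtype=float).reshape(3)
    norm = np.linalg.norm(n)
    if norm == 0:
        raise ValidationError("mirror plane normal must be nonzero")
    return n / norm


def reflect_points(points, plane_point, plane_normal) -> np.ndarray:
    """Householder reflection of (…, 3) points across the plane."""
    n = _unit_normal(plane_normal)
    p = np.asarray(plane_point, dtype=float).reshape(3)
    points = np.asarray(points, dtype=float)
    dist = (points - p) @ n
    return points - 2.0 * dist[..., None] * n


def mirror_mesh(mesh: TriangleMesh, plane_point, plane_normal) -> TriangleMesh:
    """Reflect every vertex; reverse winding so normals stay outward."""
    vertices = reflect_points(mesh.vertices, plane_point, plane_normal)
    return TriangleMesh(vertices, mesh.faces[:, ::-1])


def mirror_landmarks(
    landmarks: LandmarkSet, plane_point, plane_normal
) -> LandmarkSet:
    """Reflect coordinates and swap bilateral names (left ↔ right).

    Midline landmarks (subnasale, pogonion) keep their names; after this
    swap, same-named landmarks on the original and the mirror correspond
    anatomically and can be registered directly.
    """
    swap: dict[str, str] = {}
    for left, right in landmarks.bilateral_pairs.items():
        swap[left] = right
        swap[right] = left
    points = {
        swap.get(name, name): reflect_points(p, plane_point, plane_normal)
        for name, p in landmarks.points.items()
    }
    return LandmarkSet(points, dict(landmarks.bilateral_pairs))


def rigid_register(source_points, target_points) -> RigidTransform:
    """Least-squares proper rigid motion taking source onto target.

    Closed form via the centred cross-covariance (Kabsch), determinant
    sign corrected so the result is always a rotation, never a
    reflection.  No scaling.
    """
    src = np.asarray(source_points, dtype=float).reshape(-1, 3)
    tgt = np.asarray(target_points, dtype=float).reshape(-1, 3)
    if src.shape != tgt.shape or len(src) < 3:
        raise ValidationError(
            "rigid_register needs >=3 correspondences with equal counts"
        )
    src_c = src - src.mean(axis=0)
    tgt_c = tgt - tgt.mean(axis=0)
    for pts in (src_c, tgt_c):
        s = np.linalg.svd(pts, compute_uv=False)
        if s[1] <= 1e-9 * max(s[0], 1.0):
            raise DegenerateGeometryError(
                "correspondences are collinear: rotation is underdetermined"
            )
    rot, _ = Rotation.align_vectors(tgt_c, src_c)
    R = rot.as_matrix()
    t = tgt.mean(axis=0) - R @ src.mean(axis=0)
    return RigidTransform(R, t)


def registration_residual(
    transform: RigidTransform, source_points, target_points
) -> float:
    """RMS distance between transformed source and target (mm)."""
    diff = transform.apply(source_points) - np.asarray(target_points, float)
    return float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))


def default_mirror_plane(landmarks: LandmarkSet) -> tuple[np.ndarray, np.ndarray]:
    """Plane through subnasale, normal along the outer-eye-corner axis."""
    point = landmarks["subnasale"]
    normal = landmarks["exocanthion_right"] - landmarks["exocanthion_left"]
    return point, _unit_normal(normal)


def superimpose_mirror(
    mesh: TriangleMesh,
    landmarks: LandmarkSet,
    plane_point=None,
    plane_normal=None,
) -> SuperimpositionResult:
    """Mirror the face and register the mirrored midface onto the original.

    The five registration landmarks are matched by name after the
    bilateral swap and fitted with equal weights; the fitted motion is
    then applied to the whole mirrored surface.
    """
    landmarks.validate()
    if plane_point is None or plane_normal is None:
        plane_point, plane_normal = default_mirror_plane(landmarks)
    mirrored_mesh = mirror_mesh(mesh, plane_point, plane_normal)
    mirrored_lm = mirror_landmarks(landmarks, plane_point, plane_normal)
    src = mirrored_lm.coords(REGISTRATION_LANDMARKS)
    tgt = landmarks.coords(REGISTRATION_LANDMARKS)
    transform = rigid_register(src, tgt)
    residual = registration_residual(transform, src, tgt)
    registered_mesh = TriangleMesh(
        transform.apply(mirrored_mesh.vertices), mirrored_mesh.faces
    )
    registered_lm = LandmarkSet(
        {n: transform.apply(p) for n, p in mirrored_lm.points.items()},
        dict(mirrored_lm.bilateral_pairs),
    )
    return SuperimpositionResult(
        mesh=registered_mesh,
        landmarks=registered_lm,
        transform=transform,
        residual_mm=residual,
        plane_point=np.asarray(plane_point, float).reshape(3),
        plane_normal=_unit_normal(plane_normal),
    )
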