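"""Per-patient asymmetry metrics over the lower-face region of interest.

After mirror superimposition the residual surface distance quantifies
left–right asymmetry.  Three numbers are recorded per patient:

* ``chin_asymmetry_mm`` — distance between the chin apex (pogonion) and
  its mirrored, midface-registered image.  A chin apex sitting δ mm off
  the symmetric position scores 2δ, because the mirror image sits at −δ.
* ``had_mean_mm`` / ``had_max_mm`` — mean and maximum of the directed
  per-vertex absolute closest-point distances (Hausdorff absolute
  distance, HAD) from the lower-face ROI of the original surface to the
  mirrored-registered surface.

Closest-point queries are exact: a k-d tree over triangle centroids
prunes candidates using the bound ``dist(q, T) ≥ |q − centroid(T)| −
radius(T)``, and the surviving triangles are resolved with the exact
point-to-triangle projection.  The result equals exhaustive search over
all triangles.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy.spatial import cKDTree
from trimesh.triangles import closest_point as _triangles_closest_point

from .errors import EmptyRoiError, ValidationError
from .mesh_io import LandmarkSet, TriangleMesh, crop_halfspace
from .mirror_registration import SuperimpositionResult, superimpose_mirror


@dataclass
class RoiSpec:
    """Lower-face ROI parameters.

    The boundary plane passes through subnasale with the cranio-caudal
    axis as normal; the chin region used for overlay visualization is a
    sphere of radius ``r_chin_mm`` around pogonion.
    """

    r_chin_mm: float = 15.0
    flip_boundary_normal: bool = False

    def validate(self) -> "RoiSpec":
        if self.r_chin_mm <= 0:
            raise ValidationError("r_chin_mm must be positive")
        return self


@dataclass
class DistanceField:
    """Directed per-vertex distances (mm) from ROI vertices to a surface."""

    vertex_indices: np.ndarray
    distances_mm: np.ndarray

    def validate(self) -> "DistanceField":
        d = np.asarray(self.distances_mm, float)
        if d.size == 0:
            raise ValidationError("empty distance field")
        if not np.isfinite(d).all() or (d < 0).any():
            raise ValidationError("distances must be finite and non-negative")
        if len(self.vertex_indices) != len(d):
            raise ValidationError("index / distance length mismatch")
        return self


@dataclass
class AsymmetryResult:
    """Digital asymmetry metrics for one patient (all mm)."""

    chin_asymmetry_mm: float
    had_mean_mm: float
    had_max_mm: float
    residual_mm: float
    roi_vertex_count: int

    def to_dict(self) -> dict:
        return asdict(self)

    def to_csv_row(self, patient_id: str) -> str:
        return (
            f"{patient_id},{self.chin_asymmetry_mm:.6g},"
            f"{self.had_mean_mm:.6g},{self.had_max_mm:.6g},"
            f"{self.residual_mm:.6g}"
        )


class SurfaceDistanceQuery:
    """Exact closest-point distances to a triangulated surface.

    Candidate triangles are pruned with a centroid k-d tree; the pruning
    bound guarantees equality with exhaustive search.
    """

    def __init__(self, mesh: TriangleMesh):
        mesh.validate()
        self.mesh = mesh
        self._triangles = mesh.triangles()
        centroids = self._triangles.mean(axis=1)
        self._radii = np.linalg.norm(
            self._triangles - centroids[:, None, :], axis=2
        ).max(axis=1)
        self._r_max = float(self._radii.max())
        self._centroid_tree = cKDTree(centroids)
        self._vertex_tree = cKDTree(mesh.vertices)

    def distances(self, points) -> np.ndarray:
        points = np.asarray(points, dtype=float).reshape(-1, 3)
        # distance to the nearest mesh vertex is a valid upper bound
        upper, _ = self._vertex_tree.query(points)
        out = np.empty(len(points))
        for i, (q, ub) in enumerate(zip(points, upper)):
            cand = self._centroid_tree.query_ball_point(q, ub + self._r_max)
            tris = self._triangles[cand]
            closest = _triangles_closest_point(
                tris, np.broadcast_to(q, (len(tris), 3))
            )
            out[i] = np.linalg.norm(closest - q, axis=1).min()
        return out


def closest_point_distance(point, mesh: TriangleMesh) -> float:
    """Exact distance (mm) from one point to the nearest surface point."""
    return float(SurfaceDistanceQuery(mesh).distances([point])[0])


def compute_distance_field(
    original_roi: TriangleMesh,
    mirrored_mesh: TriangleMesh,
    query: SurfaceDistanceQuery | None = None,
) -> DistanceField:
    """Directed distances from every ROI vertex to the mirrored surface."""
    if original_roi.n_vertices == 0 or original_roi.n_faces == 0:
        raise EmptyRoiError("region of interest is empty")
    if query is None:
        query = SurfaceDistanceQuery(mirrored_mesh)
    d = query.distances(original_roi.vertices)
    return DistanceField(
        vertex_indices=np.arange(original_roi.n_vertices),
        distances_mm=d,
    ).validate()


def had_summary(field: DistanceField) -> tuple[float, float]:
    """(mean, max) of the per-vertex absolute distances, in mm."""
    field.validate()
    d = np.asarray(field.distances_mm, float)
    return float(d.mean()), float(d.max())


def chin_asymmetry(
    landmarks: LandmarkSet, superimposition: SuperimpositionResult
) -> float:
    """Distance from the original pogonion to its registered mirror image."""
    if "pogonion" not in landmarks:
        raise ValidationError("missing required landmark(s): pogonion")
    if "pogonion" not in superimposition.landmarks:
        raise ValidationError("superimposition lacks a mirrored pogonion")
    return float(
        np.linalg.norm(
            landmarks["pogonion"] - superimposition.landmarks["pogonion"]
        )
    )


def craniocaudal_axis(landmarks: LandmarkSet) -> np.ndarray:
    """Unit caudal (downward) direction estimated from the landmarks.

    Component of (subnasale − inner-eye-corner midpoint) orthogonal to
    the inter-exocanthion axis; derivable from the required landmarks
    alone and invariant to the scan's coordinate frame.
    """
    landmarks.validate()
    mid_en = 0.5 * (
        landmarks["endocanthion_left"] + landmarks["endocanthion_right"]
    )
    down = landmarks["subnasale"] - mid_en
    lateral = landmarks["exocanthion_right"] - landmarks["exocanthion_left"]
    lateral = lateral / np.linalg.norm(lateral)
    down = down - (down @ lateral) * lateral
    norm = np.linalg.norm(down)
    if norm < 1e-12:
        raise ValidationError(
            "cannot estimate cranio-caudal axis: subnasale lies on the eye axis"
        )
    return down / norm


def lower_face_roi(
    mesh: TriangleMesh,
    landmarks: LandmarkSet,
    roi_spec: RoiSpec | None = None,
) -> TriangleMesh:
    """Crop the surface below the plane through subnasale."""
    spec = (roi_spec or RoiSpec()).validate()
    if "subnasale" not in landmarks:
        raise ValidationError("missing required landmark(s): subnasale")
    caudal = craniocaudal_axis(landmarks)
    if spec.flip_boundary_normal:
        caudal = -caudal
    # keep the caudal side: dot(v - subnasale, -caudal) <= 0
    return crop_halfspace(mesh, landmarks["subnasale"], -caudal)


def chin_region(
    mesh: TriangleMesh, landmarks: LandmarkSet, roi_spec: RoiSpec | None = None
) -> TriangleMesh:
    """Spherical chin patch around pogonion (visualization ROI)."""
    spec = (roi_spec or RoiSpec()).validate()
    if "pogonion" not in landmarks:
        raise ValidationError("missing required landmark(s): pogonion")
    dist = np.linalg.norm(mesh.vertices - landmarks["pogonion"], axis=1)
    keep = (dist[mesh.faces] <= spec.r_chin_mm).all(axis=1)
    if not keep.any():
        raise EmptyRoiError("chin region contains no faces")
    from .mesh_io import clean_mesh

    return clean_mesh(mesh.vertices, mesh.faces[keep])


def measure_patient(
    mesh: TriangleMesh,
    landmarks: LandmarkSet,
    roi_spec: RoiSpec | None = None,
    plane_point=None,
    plane_normal=None,
    return_field: bool = False,
):
    """Full digital pipeline: mirror → register → ROI → distances → summary.

    Deterministic for fixed inputs; returns an :class:`AsymmetryResult`,
    plus the ROI mesh and its :class:`DistanceField` when
    ``return_field`` is set (for overlay export).
    """
    mesh.validate()
    landmarks.validate()
    sup = superimpose_mirror(mesh, landmarks, plane_point, plane_normal)
    roi = lower_face_roi(mesh, landmarks, roi_spec)
    field = compute_distance_field(roi, sup.mesh)
    had_mean, had_max = had_summary(field)
    chin = chin_asymmetry(landmarks, sup)
    result = AsymmetryResult(
        chin_asymmetry_mm=chin,
        had_mean_mm=had_mean,
        had_max_mm=had_max,
        residual_mm=sup.residual_mm,
        roi_vertex_count=roi.n_vertices,
    )
    if return_field:
        return result, roi, field
    return result
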