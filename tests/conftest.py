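"""Shared fixtures and independent geometric oracles.

The closest-point oracle here is a deliberately naive, pure-numpy
implementation (exhaustive scan over all triangles, textbook
point-in-triangle projection) kept independent of the package's
accelerated query path.
"""

import numpy as np
import pytest

from facesym.mesh_io import TriangleMesh
from facesym.synthetic_data import FaceParams, generate_face


def point_triangle_distance(p, a, b, c):
    """Exact distance from point p to triangle abc (Ericson's method)."""
    ab, ac, ap = b - a, c - a, p - a
    d1, d2 = ab @ ap, ac @ ap
    if d1 <= 0 and d2 <= 0:
        return np.linalg.norm(p - a)
    bp = p - b
    d3, d4 = ab @ bp, ac @ bp
    if d3 >= 0 and d4 <= d3:
        return np.linalg.norm(p - b)
    vc = d1 * d4 - d3 * d2
    if vc <= 0 and d1 >= 0 and d3 <= 0:
        v = d1 / (d1 - d3)
        return np.linalg.norm(p - (a + v * ab))
    cp = p - c
    d5, d6 = ab @ cp, ac @ cp
    if d6 >= 0 and d5 <= d6:
        return np.linalg.norm(p - c)
    vb = d5 * d2 - d1 * d6
    if vb <= 0 and d2 >= 0 and d6 <= 0:
        w = d2 / (d2 - d6)
        return np.linalg.norm(p - (a + w * ac))
    va = d3 * d6 - d5 * d4
    if va <= 0 and (d4 - d3) >= 0 and (d5 - d6) >= 0:
        w = (d4 - d3) / ((d4 - d3) + (d5 - d6))
        return np.linalg.norm(p - (b + w * (c - b)))
    denom = va + vb + vc
    v, w = vb / denom, vc / denom
    return np.linalg.norm(p - (a + v * ab + w * ac))


def exhaustive_distance(point, mesh: TriangleMesh) -> float:
    """Brute-force closest-point distance over every triangle."""
    tris = mesh.triangles()
    return min(
        point_triangle_distance(np.asarray(point, float), *tri) for tri in tris
    )


def random_patch(rng, n_quads=10, span=20.0) -> TriangleMesh:
    """Bumpy open surface patch with ~2·n_quads² faces."""
    g = np.linspace(-span / 2, span / 2, n_quads + 1)
    xx, yy = np.meshgrid(g, g, indexing="ij")
    zz = rng.normal(scale=2.0, size=xx.shape)
    verts = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
    n = n_quads + 1
    idx = np.arange(n * n).reshape(n, n)
    faces = []
    for i in range(n_quads):
        for j in range(n_quads):
            faces.append([idx[i, j], idx[i + 1, j], idx[i + 1, j + 1]])
            faces.append([idx[i, j], idx[i + 1, j + 1], idx[i, j + 1]])
    return TriangleMesh(verts, faces).validate()


@pytest.fixture
def tetrahedron() -> TriangleMesh:
    verts = [(0, 0, 0), (1, 0, 0), (0, 1, 0), (0, 0, 1)]
    faces = [(0, 2, 1), (0, 1, 3), (0, 3, 2), (1, 2, 3)]
    return TriangleMesh(verts, faces).validate()


@pytest.fixture(scope="session")
def symmetric_face():
    """Perfectly mirror-symmetric synthetic face (δ = 0, σ = 0)."""
    mesh, landmarks, gt = generate_face(FaceParams())
    return mesh, landmarks, gt


@pytest.fixture(scope="session")
def offset_face():
    """Face with the chin apex displaced 2 mm laterally."""
    mesh, landmarks, gt = generate_face(FaceParams(chin_offset_mm=2.0))
    return mesh, landmarks, gt
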