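"""Mesh/landmark I/O: round-trips, dialect quirks, cropping, overlays."""

import numpy as np
import pytest

from facesym.errors import (
    EmptyRoiError,
    FormatError,
    MeshIOError,
    ValidationError,
)
from facesym.mesh_io import (
    LandmarkSet,
    ScalarOverlay,
    TriangleMesh,
    crop_halfspace,
    read_landmarks,
    read_mesh,
    read_scalar_overlay,
    write_landmarks,
    write_mesh,
    write_scalar_overlay,
)

UNIT_TET_OBJ = """\
v 0 0 0
v 1 0 0
v 0 1 0
v 0 0 1
f 1 3 2
f 1 2 4
f 1 4 3
f 2 3 4
"""


def test_obj_parse_unit_tetrahedron(tmp_path):
    path = tmp_path / "tet.obj"
    path.write_text(UNIT_TET_OBJ)
    mesh = read_mesh(path)
    assert mesh.n_vertices == 4
    assert mesh.n_faces == 4


@pytest.mark.parametrize("fmt", ["obj", "ply", "vtk"])
def test_roundtrip_preserves_geometry(fmt, tmp_path):
    rng = np.random.default_rng(42)
    verts = rng.uniform(-90, 90, size=(30, 3))
    faces = [[i, i + 1, i + 2] for i in range(28)]
    mesh = TriangleMesh(verts, faces).validate()
    path = tmp_path / f"mesh.{fmt}"
    write_mesh(mesh, path, fmt)
    back = read_mesh(path)
    assert np.abs(back.vertices - mesh.vertices).max() <= 1e-6
    assert (back.faces == mesh.faces).all()


def test_negative_obj_indices_match_positive(tmp_path):
    pos = tmp_path / "pos.obj"
    neg = tmp_path / "neg.obj"
    pos.write_text(UNIT_TET_OBJ)
    neg.write_text(
        "v 0 0 0\nv 1 0 0\nv 0 1 0\nv 0 0 1\n"
        "f -4 -2 -3\nf -4 -3 -1\nf -4 -1 -2\nf -3 -2 -1\n"
    )
    a, b = read_mesh(pos), read_mesh(neg)
    assert np.allclose(a.vertices, b.vertices)
    assert (a.faces == b.faces).all()


def test_obj_ignores_textures_normals_and_triangulates_quads(tmp_path):
    path = tmp_path / "quad.obj"
    path.write_text(
        "vn 0 0 1\nvt 0 0\n"
        "v 0 0 0\nv 1 0 0\nv 1 1 0\nv 0 1 0\n"
        "f 1/1/1 2/1/1 3/1/1 4/1/1\n"
    )
    mesh = read_mesh(path)
    assert mesh.n_vertices == 4
    assert mesh.n_faces == 2  # quad fan-triangulated


def test_vtk_writer_emits_legacy_polydata(tmp_path, tetrahedron):
    path = tmp_path / "tet.vtk"
    write_mesh(tetrahedron, path, "vtk")
    text = path.read_text()
    assert text.startswith("# vtk DataFile")
    assert "POLYGONS 4" in text


def test_write_empty_mesh_rejected(tmp_path):
    mesh = TriangleMesh(np.zeros((3, 3)), np.zeros((0, 3)))
    with pytest.raises(FormatError):
        write_mesh(mesh, tmp_path / "bad.obj", "obj")


def test_read_missing_file_names_path():
    with pytest.raises(MeshIOError, match="nowhere.obj"):
        read_mesh("nowhere.obj")


def test_degenerate_face_rejected():
    with pytest.raises(FormatError):
        TriangleMesh([[0, 0, 0], [1, 0, 0], [0, 1, 0]], [[0, 1, 1]]).validate()


# --- landmarks ---


LANDMARK_CSV = """\
name,x,y,z
subnasale,0,-10,50
endocanthion_left,-16,25,40
endocanthion_right,16,25,40
exocanthion_left,-45,25,30
exocanthion_right,45,25,30
pogonion,0,-55,45
"""


def test_read_landmarks_builds_bilateral_registry(tmp_path):
    path = tmp_path / "lm.csv"
    path.write_text(LANDMARK_CSV)
    lm = read_landmarks(path)
    assert lm.bilateral_pairs["endocanthion_left"] == "endocanthion_right"
    assert lm.bilateral_pairs["exocanthion_left"] == "exocanthion_right"
    assert "pogonion" not in lm.bilateral_pairs
    np.testing.assert_allclose(lm["subnasale"], [0, -10, 50])


def test_landmarks_roundtrip(tmp_path):
    path = tmp_path / "lm.csv"
    path.write_text(LANDMARK_CSV)
    lm = read_landmarks(path)
    out = tmp_path / "lm2.csv"
    write_landmarks(lm, out)
    lm2 = read_landmarks(out)
    for name in lm.names():
        np.testing.assert_allclose(lm2[name], lm[name])


def test_missing_required_landmark_named(tmp_path):
    path = tmp_path / "lm.csv"
    path.write_text(
        "\n".join(l for l in LANDMARK_CSV.splitlines() if "subnasale" not in l)
    )
    with pytest.raises(ValidationError, match="subnasale"):
        read_landmarks(path)


def test_duplicate_landmark_rejected(tmp_path):
    path = tmp_path / "lm.csv"
    path.write_text(LANDMARK_CSV + "pogonion,1,2,3\n")
    with pytest.raises(ValidationError, match="duplicate"):
        read_landmarks(path)


def test_collinear_registration_landmarks_rejected():
    pts = {
        "subnasale": (0, 0, 0),
        "endocanthion_left": (1, 0, 0),
        "endocanthion_right": (2, 0, 0),
        "exocanthion_left": (3, 0, 0),
        "exocanthion_right": (4, 0, 0),
    }
    with pytest.raises(ValidationError, match="collinear"):
        LandmarkSet(pts).validate()


# --- cropping ---


def unit_square():
    return TriangleMesh(
        [[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]],
        [[0, 1, 2], [0, 2, 3]],
    )


def test_crop_keeps_fully_inside_faces_only():
    # cut at x = 0.5: both triangles touch x = 1, the whole-face rule
    # keeps none; cut at x = 1.5 keeps both
    with pytest.raises(EmptyRoiError):
        crop_halfspace(unit_square(), [0.5, 0, 0], [1, 0, 0])
    mesh = TriangleMesh(
        [[0, 0, 0], [0.4, 0, 0], [0.4, 1, 0], [2, 0, 0], [2, 1, 0]],
        [[0, 1, 2], [1, 3, 4]],
    )
    cropped = crop_halfspace(mesh, [0.5, 0, 0], [1, 0, 0])
    assert cropped.n_faces == 1
    assert cropped.vertices[:, 0].max() <= 0.5


def test_crop_below_mesh_is_identity():
    sq = unit_square()
    out = crop_halfspace(sq, [0, 0, 10], [0, 0, 1])
    assert np.allclose(out.vertices, sq.vertices)
    assert (out.faces == sq.faces).all()


def test_crop_above_mesh_raises_empty_roi():
    with pytest.raises(EmptyRoiError):
        crop_halfspace(unit_square(), [0, 0, -10], [0, 0, 1])


def test_crop_idempotent_and_clean(symmetric_face):
    mesh, _, _ = symmetric_face
    once = crop_halfspace(mesh, [0, -10, 0], [0, 1, 0])
    twice = crop_halfspace(once, [0, -10, 0], [0, 1, 0])
    assert once.n_faces <= mesh.n_faces
    assert np.allclose(once.vertices, twice.vertices)
    assert (once.faces == twice.faces).all()
    # no unreferenced vertices
    assert set(np.unique(once.faces)) == set(range(once.n_vertices))


# --- scalar overlays ---


def test_overlay_roundtrip(tmp_path, tetrahedron):
    values = np.array([0.0, 1.0, 2.0, 0.5])
    overlay = ScalarOverlay(tetrahedron, values, name="had_mm")
    path = tmp_path / "overlay.vtk"
    write_scalar_overlay(overlay, path)
    text = path.read_text()
    assert "POINT_DATA 4" in text and "SCALARS had_mm" in text
    back = read_scalar_overlay(path)
    np.testing.assert_array_equal(back.values, values)


def test_overlay_length_mismatch_rejected(tetrahedron, tmp_path):
    with pytest.raises(ValidationError):
        write_scalar_overlay(
            ScalarOverlay(tetrahedron, [1.0, 2.0]), tmp_path / "o.vtk"
        )


def test_empty_overlay_rejected(tetrahedron, tmp_path):
    with pytest.raises(ValidationError):
        write_scalar_overlay(ScalarOverlay(tetrahedron, []), tmp_path / "o.vtk")
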