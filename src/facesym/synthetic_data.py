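"""Synthetic faces and synthetic patient cohorts with known ground truth.

No public per-patient dataset accompanies the analysis this package
implements, so everything is exercised on synthetic inputs with exact,
closed-form ground truth:

* :func:`generate_face` builds a parametric facial surface — a clipped
  half-ellipsoid dome with Gaussian nose and chin prominences and
  optional antegonial notches — that is *exactly* mirror-symmetric when
  the chin offset δ and the vertex noise σ are zero.  The chin apex
  (pogonion) sits δ mm off the midline, so the mirror-superimposition
  pipeline must score the chin asymmetry as 2δ.

* :func:`generate_cohort` draws patient records whose marginal
  frequencies match the published cohort: the left/right MRI level
  table is calibrated so 27/76 of patients carry asymmetrical osseous
  destruction, and the chin / Hausdorff metrics follow log-normal
  distributions matched to the published status-conditional medians and
  interquartile ranges (chin 2 mm vs 4 mm).  Values are positive and
  right-skewed, consistent with the reported non-normality.

* :func:`fixture_published_counts` reconstructs, deterministically, a 76-patient
  cohort reproducing every cell of the published binary contingency
  table and treatment cross-tabulation.  It is a synthetic
  reconstruction from printed counts, not patient data.

All randomness derives from one integer seed through per-patient
spawned streams, so individual records are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .errors import ValidationError
from .mesh_io import LandmarkSet, TriangleMesh
from .cohort_stats import MriStatus, PatientRecord, Treatment

_Z75 = float(norm.ppf(0.75))  # 0.6744897…


# ---------------------------------------------------------------------------
# parametric face


@dataclass
class FaceParams:
    """Parameters of the synthetic facial surface (all lengths mm)."""

    resolution: int = 61  # grid vertices per axis; forced odd internally
    chin_offset_mm: float = 0.0  # lateral displacement δ of the chin apex
    notch_depth_left_mm: float = 0.0  # antegonial notch depth per side
    notch_depth_right_mm: float = 0.0
    noise_mm: float = 0.0  # isotropic Gaussian vertex jitter σ
    seed: int = 0

    def validate(self) -> "FaceParams":
        if self.resolution < 20:
            raise ValidationError("resolution must be >= 20")
        if self.chin_offset_mm < 0 or self.noise_mm < 0:
            raise ValidationError("chin offset and noise must be >= 0")
        if self.notch_depth_left_mm < 0 or self.notch_depth_right_mm < 0:
            raise ValidationError("notch depths must be >= 0")
        return self


# face geometry constants (mm): dome semi-axes, feature centres and sizes
_DOME = dict(a=75.0, b=95.0, c=55.0)
_NOSE = dict(x=0.0, y=0.0, sigma=9.0, height=12.0)
_CHIN = dict(y=-55.0, sigma=12.0, height=10.0)
_GONION = dict(x=48.0, y=-45.0, sigma=8.0)
_EYES = dict(y=25.0, endo_x=16.0, exo_x=45.0)
_SUBNASALE_Y = -10.0
_X_EXTENT = 70.0
_Y_RANGE = (-80.0, 55.0)


def _face_height(x, y, params: FaceParams) -> np.ndarray:
    """Anterior (z) height of the face surface at lateral x, vertical y."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    r2 = (x / _DOME["a"]) ** 2 + (y / _DOME["b"]) ** 2
    z = _DOME["c"] * np.sqrt(np.clip(1.0 - r2, 0.0, None))
    z = z + _NOSE["height"] * np.exp(
        -((x - _NOSE["x"]) ** 2 + (y - _NOSE["y"]) ** 2) / (2 * _NOSE["sigma"] ** 2)
    )
    z = z + _CHIN["height"] * np.exp(
        -((x - params.chin_offset_mm) ** 2 + (y - _CHIN["y"]) ** 2)
        / (2 * _CHIN["sigma"] ** 2)
    )
    for side, depth in (
        (-1.0, params.notch_depth_left_mm),
        (+1.0, params.notch_depth_right_mm),
    ):
        if depth > 0:
            z = z - depth * np.exp(
                -((x - side * _GONION["x"]) ** 2 + (y - _GONION["y"]) ** 2)
                / (2 * _GONION["sigma"] ** 2)
            )
    return z


def _symmetric_grid_faces(n_x: int, n_y: int, x: np.ndarray) -> np.ndarray:
    """Quad-grid triangulation whose diagonal choice mirrors across x = 0.

    With an odd vertex count per axis no quad straddles the midline, and
    flipping the split diagonal between the two halves makes the
    triangulated surface an exactly reflection-symmetric point set.
    """
    idx = np.arange(n_x * n_y).reshape(n_x, n_y)
    faces = []
    for i in range(n_x - 1):
        x_c = 0.5 * (x[i] + x[i + 1])
        for j in range(n_y - 1):
            p00, p10 = idx[i, j], idx[i + 1, j]
            p01, p11 = idx[i, j + 1], idx[i + 1, j + 1]
            if x_c < 0:
                faces += [[p00, p10, p11], [p00, p11, p01]]
            else:
                faces += [[p10, p11, p01], [p10, p01, p00]]
    return np.asarray(faces, dtype=np.int64)


def generate_face(
    params: FaceParams | None = None,
) -> tuple[TriangleMesh, LandmarkSet, dict]:
    """Build the synthetic face, its landmarks, and the ground truth.

    Returns ``(mesh, landmarks, ground_truth)`` where the ground truth
    records the chin offset δ and the expected chin-asymmetry score 2δ.
    Deterministic per seed; bit-identical across calls.
    """
    params = (params or FaceParams()).validate()
    n = params.resolution | 1  # odd: keeps the midline on the grid
    x = np.linspace(-_X_EXTENT, _X_EXTENT, n)
    y = np.linspace(*_Y_RANGE, n)
    xx, yy = np.meshgrid(x, y, indexing="ij")
    zz = _face_height(xx, yy, params)
    vertices = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
    faces = _symmetric_grid_faces(n, n, x)
    if params.noise_mm > 0:
        rng = np.random.default_rng(np.random.SeedSequence(params.seed))
        vertices = vertices + rng.normal(
            scale=params.noise_mm, size=vertices.shape
        )
    mesh = TriangleMesh(vertices, faces).validate()

    delta = params.chin_offset_mm
    lm_pts = {
        "subnasale": (0.0, _SUBNASALE_Y),
        "endocanthion_left": (-_EYES["endo_x"], _EYES["y"]),
        "endocanthion_right": (+_EYES["endo_x"], _EYES["y"]),
        "exocanthion_left": (-_EYES["exo_x"], _EYES["y"]),
        "exocanthion_right": (+_EYES["exo_x"], _EYES["y"]),
        "pogonion": (delta, _CHIN["y"]),
        "gonion_left": (-_GONION["x"], _GONION["y"]),
        "gonion_right": (+_GONION["x"], _GONION["y"]),
    }
    symmetric = FaceParams(
        resolution=params.resolution,
        notch_depth_left_mm=params.notch_depth_left_mm,
        notch_depth_right_mm=params.notch_depth_right_mm,
    )
    points = {}
    for name, (px, py) in lm_pts.items():
        # midface landmark heights come from the symmetric surface so the
        # registration basis is exactly bilateral; the pogonion rides the
        # displaced chin bump
        src = params if name == "pogonion" else symmetric
        points[name] = np.array([px, py, float(_face_height(px, py, src))])
    landmarks = LandmarkSet(points).validate()
    ground_truth = {
        "chin_offset_mm": delta,
        "expected_chin_asymmetry_mm": 2.0 * delta,
        "notch_depth_left_mm": params.notch_depth_left_mm,
        "notch_depth_right_mm": params.notch_depth_right_mm,
        "noise_mm": params.noise_mm,
        "seed": params.seed,
    }
    return mesh, landmarks, ground_truth


# ---------------------------------------------------------------------------
# cohort generator


def _lognormal_params(median: float, iqr: float) -> tuple[float, float]:
    """(μ, σ) of the log-normal with the given median and IQR."""
    if median <= 0 or iqr <= 0:
        raise ValidationError("median and IQR must be positive")
    sigma = float(np.arcsinh(iqr / (2.0 * median)) / _Z75)
    return float(np.log(median)), sigma


#: Joint left×right MRI-level count table (rows: left NA/infl/destr,
#: cols: right), the unique-destruction-margin solution consistent with
#: the published marginals: 20 left / 23 right destroyed joints and 27
#: patients with exactly-one-side destruction (12 left-only, 15
#: right-only, 8 bilateral), 12 patients unaffected on both sides.
PUBLISHED_JOINT_LEVEL_COUNTS = np.array(
    [
        [12, 5, 2],
        [2, 22, 13],
        [1, 11, 8],
    ],
    dtype=float,
)

_LEVELS = (MriStatus.NOT_AFFECTED, MriStatus.INFLAMMATION, MriStatus.DESTRUCTION)


@dataclass
class CohortParams:
    """Cohort-generator parameters, calibrated to the published marginals.

    Chin and Hausdorff metrics are drawn from status-conditional
    log-normals matched to the published medians and IQRs (mm); the
    digital values are reported at 0.1 mm granularity.  Clinical chin
    flags threshold the true digital value at ``clinical_threshold_mm``
    with a symmetric misclassification rate; the gonion flag — which has
    no digital counterpart — is Bernoulli given destruction status with
    the published conditional rates.  Treatment is independent of
    asymmetry unless ``local_chin_log_odds_per_mm`` is nonzero.
    """

    n: int = 76
    joint_level_probs: np.ndarray = field(
        default_factory=lambda: PUBLISHED_JOINT_LEVEL_COUNTS / PUBLISHED_JOINT_LEVEL_COUNTS.sum()
    )
    chin_median_iqr_no: tuple[float, float] = (2.0, 3.0)
    chin_median_iqr_yes: tuple[float, float] = (4.0, 2.0)
    had_mean_median_iqr_no: tuple[float, float] = (1.5, 0.6)
    had_mean_median_iqr_yes: tuple[float, float] = (1.7, 0.9)
    had_max_median_iqr_no: tuple[float, float] = (14.3, 10.4)
    had_max_median_iqr_yes: tuple[float, float] = (13.7, 5.3)
    clinical_threshold_mm: float = 4.0
    chin_misclassification_rate: float = 0.1
    gonion_rate_destruction: float = 19.0 / 27.0
    gonion_rate_no_destruction: float = 26.0 / 49.0
    treatment_probs: tuple[float, float, float] = (16 / 76, 31 / 76, 29 / 76)
    local_chin_log_odds_per_mm: float = 0.0
    seed: int = 0

    def validate(self) -> "CohortParams":
        if self.n < 1:
            raise ValidationError("cohort size must be >= 1")
        p = np.asarray(self.joint_level_probs, dtype=float)
        if p.shape != (3, 3) or (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
            raise ValidationError("joint_level_probs must be a 3x3 simplex")
        t = np.asarray(self.treatment_probs, dtype=float)
        if (t < 0).any() or abs(t.sum() - 1.0) > 1e-9:
            raise ValidationError("treatment_probs must sum to 1")
        if not 0 <= self.chin_misclassification_rate <= 1:
            raise ValidationError("misclassification rate must be in [0, 1]")
        return self


def generate_cohort(params: CohortParams | None = None) -> list[PatientRecord]:
    """Draw a synthetic cohort; deterministic per seed, one stream per patient."""
    params = (params or CohortParams()).validate()
    streams = np.random.SeedSequence(params.seed).spawn(params.n)
    dists = {
        "chin_mm": (
            _lognormal_params(*params.chin_median_iqr_no),
            _lognormal_params(*params.chin_median_iqr_yes),
        ),
        "had_mean_mm": (
            _lognormal_params(*params.had_mean_median_iqr_no),
            _lognormal_params(*params.had_mean_median_iqr_yes),
        ),
        "had_max_mm": (
            _lognormal_params(*params.had_max_median_iqr_no),
            _lognormal_params(*params.had_max_median_iqr_yes),
        ),
    }
    joint_p = np.asarray(params.joint_level_probs, dtype=float).ravel()
    records = []
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        cell = rng.choice(9, p=joint_p)
        left, right = _LEVELS[cell // 3], _LEVELS[cell % 3]
        destr = (left == MriStatus.DESTRUCTION) != (right == MriStatus.DESTRUCTION)
        values = {}
        for key, (par_no, par_yes) in dists.items():
            mu, sigma = par_yes if destr else par_no
            values[key] = round(float(rng.lognormal(mu, sigma)), 1)
        flag = values["chin_mm"] >= params.clinical_threshold_mm
        if rng.random() < params.chin_misclassification_rate:
            flag = not flag
        gonion_rate = (
            params.gonion_rate_destruction
            if destr
            else params.gonion_rate_no_destruction
        )
        gonion = rng.random() < gonion_rate
        t_probs = np.asarray(params.treatment_probs, dtype=float).copy()
        if params.local_chin_log_odds_per_mm != 0.0:
            tilt = np.exp(
                params.local_chin_log_odds_per_mm * (values["chin_mm"] - 3.0)
            )
            t_probs[2] *= tilt
            t_probs /= t_probs.sum()
        treatment = (Treatment.NONE, Treatment.SYSTEMIC, Treatment.LOCAL)[
            rng.choice(3, p=t_probs)
        ]
        records.append(
            PatientRecord(
                patient_id=f"S{i + 1:04d}",
                mri_left=left,
                mri_right=right,
                clinical_chin_asym=bool(flag),
                clinical_gonion_asym=bool(gonion),
                treatment=treatment,
                **values,
            )
        )
    return records


# ---------------------------------------------------------------------------
# published-count contingency fixture


def fixture_published_counts() -> list[PatientRecord]:
    """Deterministic 76-patient cohort reproducing the published 2×2 cells.

    Reconstructed from printed counts: 27 patients with asymmetrical
    osseous destruction (19 gonion-positive, 13 clinical-chin-positive,
    17 digital-positive at the 4 mm threshold) against 49 without
    (26 / 11 / 16), for 33 digital positives overall; 29 patients carry
    local corticosteroid treatment, 16 of them digital-positive, and the
    16 untreated patients include 6 digital positives.  Continuous chin
    values are filled at 5.0 mm (digital-positive) and 2.0 mm
    (digital-negative); Hausdorff fills are the published overall
    medians.  Synthetic reconstruction — not patient data.
    """
    # (n, digital+, local, none) per destruction group; remaining
    # patients are systemic / digital-negative; within-group flag counts
    # are assigned from the front of each group.
    records: list[PatientRecord] = []

    def add_group(n, destr, n_digital, n_gonion, n_chin, treatments):
        start = len(records)
        for j in range(n):
            digital = j < n_digital
            records.append(
                PatientRecord(
                    patient_id=f"T{start + j + 1:03d}",
                    mri_left=MriStatus.DESTRUCTION if destr else MriStatus.NOT_AFFECTED,
                    mri_right=MriStatus.NOT_AFFECTED,
                    clinical_chin_asym=j < n_chin,
                    clinical_gonion_asym=j < n_gonion,
                    treatment=treatments[j],
                    chin_mm=5.0 if digital else 2.0,
                    had_mean_mm=1.6,
                    had_max_mm=14.1,
                )
            )

    L, S, N = Treatment.LOCAL, Treatment.SYSTEMIC, Treatment.NONE
    # destruction group, 27: digital+ 17 (10 local / 4 systemic / 3 none),
    # digital- 10 (5 local / 3 systemic / 2 none)
    destr_treat = [L] * 10 + [S] * 4 + [N] * 3 + [L] * 5 + [S] * 3 + [N] * 2
    add_group(27, True, 17, 19, 13, destr_treat)
    # no-destruction group, 49: digital+ 16 (6 local / 7 systemic / 3 none),
    # digital- 33 (8 local / 17 systemic / 8 none)
    no_treat = [L] * 6 + [S] * 7 + [N] * 3 + [L] * 8 + [S] * 17 + [N] * 8
    add_group(49, False, 16, 26, 11, no_treat)
    assert len(records) == 76
    return records
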