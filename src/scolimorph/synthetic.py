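"""Synthetic templates, scoliotic subjects and repeated-palpation panels.

Everything downstream (morphing, accuracy metrics, variability statistics) is
testable without any imaging data: this module fabricates

* a straight-spine *template bundle* with parametric vertebral meshes,
  analytically placed landmarks, muscle attachment chains and masses;
* *subjects* derived from the template by per-level anisotropic scaling and
  composed wedge rotations calibrated to hit a prescribed main-curve Cobb
  angle, lumbar lordosis and sacral slope, together with the full ground
  truth (frames, centres, rotations, meshes, achieved angles);
* repeated-palpation *panels* with per-operator bias, per-observation noise
  and sporadic outliers, for the reliability statistics.

Vertebral-body surrogate geometry: the anterior body is a zone of a sphere
whose radius is ``hypot(AP/2, IS/2)`` about the body centre, capped by flat
endplates (so endplate rims span exactly the nominal AP/RL dimensions), with
a posterior box standing in for the pedicles and processes.  With the default
AP == RL the anterior surface is exactly spherical, so the sphere-fit centre
estimator is unbiased on synthetic bodies — a deliberate idealisation of real
vertebrae.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq
from scipy.spatial.transform import Rotation

from .accuracy import CentreSet, cobb_from_frames, find_apex, lordosis_from_frame
from .errors import SpecError
from .geometry import BodyFrame, TriMesh
from .landmarks import (
    BONES,
    Landmark,
    LandmarkSet,
    MODEL_AXES_CODE,
    axes_code_rotation,
)
from .template import MusclePath, PELVIS, SACRUM, TemplateBody, TemplateBundle
from .variability import PalpationPanel

_LEVEL_INDEX = {b: i for i, b in enumerate(BONES)}
DEFAULT_LEVELS: tuple[str, ...] = ("T9", "T10", "T11", "T12", "L1", "L2", "L3", "L4", "L5")

_SACRUM_HEIGHT = 90.0  # mm, apex to superior plate
_PROMONTORY_LENGTH = 50.0  # mm, SP_POST -> SP_ANT
_TEMPLATE_SLOPE_DEG = 40.0


def _default_dims(level: str) -> tuple[float, float, float]:
    """Nominal (AP, IS, RL) body dimensions in mm, growing caudally."""
    i = _LEVEL_INDEX[level]  # 0 = T1 ... 16 = L5
    ap = 24.0 + 0.75 * i
    is_h = 16.0 + 0.75 * i
    return (ap, is_h, ap)


def _disc_height(level: str) -> float:
    return 4.0 + 0.25 * _LEVEL_INDEX[level]


def _vertebra_mass(level: str) -> float:
    return 1.0 + 0.1 * _LEVEL_INDEX[level]


@dataclass
class SpineSpec:
    """Study conditions for one synthetic spine.

    ``levels`` run cranial -> caudal.  ``dims`` are the *template* body
    dimensions; ``scales`` are the subject-over-template per-level (AP, IS,
    RL) factors.  A zero Cobb target with unit scales reproduces the template
    exactly.
    """

    levels: tuple[str, ...] = DEFAULT_LEVELS
    dims: dict[str, tuple[float, float, float]] | None = None
    scales: dict[str, tuple[float, float, float]] | None = None
    cobb_deg: float = 0.0
    lordosis_deg: float | None = None
    sacral_slope_deg: float = _TEMPLATE_SLOPE_DEG
    apex_level: str = "L2"
    curve_upper: str = "T12"
    curve_lower: str = "L4"
    axial_deg: dict[str, float] | None = None

    def __post_init__(self) -> None:
        unknown = [lvl for lvl in self.levels if lvl not in _LEVEL_INDEX]
        if unknown:
            raise SpecError(f"unknown levels {unknown}")
        if list(self.levels) != sorted(self.levels, key=_LEVEL_INDEX.get):
            raise SpecError("levels must be ordered cranial -> caudal")
        if self.dims is None:
            self.dims = {lvl: _default_dims(lvl) for lvl in self.levels}
        if self.scales is None:
            self.scales = {lvl: (1.0, 1.0, 1.0) for lvl in self.levels}
        if self.axial_deg is None:
            self.axial_deg = {lvl: 0.0 for lvl in self.levels}
        for lvl in self.levels:
            if any(d <= 0 for d in self.dims[lvl]):
                raise SpecError(f"non-positive dimension at {lvl}")
            if any(s <= 0 for s in self.scales[lvl]):
                raise SpecError(f"non-positive scale at {lvl}")
        if self.cobb_deg:
            for name in (self.curve_upper, self.curve_lower, self.apex_level):
                if name not in self.levels:
                    raise SpecError(f"curve level {name} not in spec levels")
            iu, il = self.levels.index(self.curve_upper), self.levels.index(self.curve_lower)
            ia = self.levels.index(self.apex_level)
            if not iu < ia < il:
                raise SpecError("apex must lie strictly between curve end levels")


def severe_scoliosis_spec(**overrides) -> SpineSpec:
    """A severe lumbar-scoliosis subject: Cobb 75 deg (T12-L4, apex L2),
    supine lumbar lordosis 34 deg, sacral slope 27.7 deg."""
    base = dict(
        cobb_deg=75.0,
        lordosis_deg=34.0,
        sacral_slope_deg=27.7,
        apex_level="L2",
        curve_upper="T12",
        curve_lower="L4",
    )
    base.update(overrides)
    return SpineSpec(**base)


@dataclass
class NoiseModel:
    """Palpation noise: per-axis SDs, per-operator bias, sporadic outliers.

    Defaults emulate the observed anisotropy of manual palpation (largest in
    the inferior-superior direction) and its overall ~1-2 mm scale; the total
    perturbation of any observation is capped at ``outlier_magnitude_mm``.
    """

    sd_mm: tuple[float, float, float] = (1.0, 1.2, 0.65)
    bias_sd_mm: tuple[float, float, float] = (0.45, 0.85, 0.25)
    outlier_probability: float = 0.02
    outlier_magnitude_mm: float = 10.3
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s < 0 for s in self.sd_mm) or any(s < 0 for s in self.bias_sd_mm):
            raise ValueError("noise SDs must be non-negative")
        if not 0.0 <= self.outlier_probability <= 1.0:
            raise ValueError("outlier probability must lie in [0, 1]")


# --------------------------------------------------------------------------
# mesh construction
# --------------------------------------------------------------------------

def _vertebra_mesh(
    ap: float, is_h: float, rl: float, n_theta: int = 32, n_bands: int = 9
) -> tuple[TriMesh, int]:
    """Barrel-plus-box vertebra mesh in body-local coordinates.

    Returns the mesh and the index of the first posterior-element (box)
    vertex, so the generator can label posterior vertices for tests.
    """
    rho = math.hypot(ap / 2.0, is_h / 2.0)
    ys = np.linspace(-is_h / 2.0, is_h / 2.0, n_bands)
    thetas = np.linspace(0.0, 2.0 * math.pi, n_theta, endpoint=False)
    rz_scale = rl / ap  # elliptic cross-section when RL != AP
    verts: list[np.ndarray] = []
    for y in ys:
        ry = math.sqrt(max(rho * rho - y * y, 1e-9))
        ring = np.column_stack(
            [ry * np.cos(thetas), np.full(n_theta, y), rz_scale * ry * np.sin(thetas)]
        )
        verts.append(ring)
    rings = np.vstack(verts)
    faces: list[tuple[int, int, int]] = []
    for b in range(n_bands - 1):
        for t in range(n_theta):
            t2 = (t + 1) % n_theta
            a0, a1 = b * n_theta + t, b * n_theta + t2
            b0, b1 = (b + 1) * n_theta + t, (b + 1) * n_theta + t2
            faces.append((a0, b1, a1))  # wound so normals point outward
            faces.append((a0, b0, b1))
    # endplate caps: centre vertex + fan
    v = [rings]
    base = len(rings)
    top_centre = np.array([0.0, is_h / 2.0, 0.0])
    bot_centre = np.array([0.0, -is_h / 2.0, 0.0])
    v.append(top_centre[None, :])
    v.append(bot_centre[None, :])
    top_ring0 = (n_bands - 1) * n_theta
    for t in range(n_theta):
        t2 = (t + 1) % n_theta
        faces.append((base, top_ring0 + t2, top_ring0 + t))  # top cap, +Y normal
        faces.append((base + 1, t, t2))  # bottom cap, -Y normal
    # posterior box
    depth = 0.6 * ap
    x0, x1 = -(ap / 2.0) - depth, -(ap / 2.0) * 0.8
    hb, wb = 0.35 * is_h, 0.4 * rl
    box = np.array(
        [
            [x0, -hb, -wb], [x1, -hb, -wb], [x1, hb, -wb], [x0, hb, -wb],
            [x0, -hb, wb], [x1, -hb, wb], [x1, hb, wb], [x0, hb, wb],
        ]
    )
    posterior_start = base + 2
    v.append(box)
    quads = [
        (0, 3, 2, 1), (4, 5, 6, 7), (0, 1, 5, 4),
        (3, 7, 6, 2), (1, 2, 6, 5), (0, 4, 7, 3),
    ]
    for a, b2, c, d in quads:
        faces.append((posterior_start + a, posterior_start + b2, posterior_start + c))
        faces.append((posterior_start + a, posterior_start + c, posterior_start + d))
    mesh = TriMesh(np.vstack(v), np.array(faces))
    return mesh, posterior_start


def _vertebra_landmarks(ap: float, is_h: float, rl: float) -> dict[str, np.ndarray]:
    """The 14 landmark positions on the local vertebra mesh surface."""
    depth = 0.6 * ap
    xc = (-(ap / 2.0) - depth + -(ap / 2.0) * 0.8) / 2.0
    hb, wb = 0.35 * is_h, 0.4 * rl
    y = is_h / 2.0
    return {
        "S1": np.array([ap / 2.0, y, 0.0]),
        "S2": np.array([-ap / 2.0, y, 0.0]),
        "S3": np.array([ap / 2.0, -y, 0.0]),
        "S4": np.array([-ap / 2.0, -y, 0.0]),
        "S5": np.array([0.0, y, rl / 2.0]),
        "S6": np.array([0.0, y, -rl / 2.0]),
        "S7": np.array([0.0, -y, rl / 2.0]),
        "S8": np.array([0.0, -y, -rl / 2.0]),
        "JM1": np.array([xc, 0.8 * hb, wb]),
        "JM2": np.array([xc, -0.8 * hb, wb]),
        "JM3": np.array([xc, 0.8 * hb, -wb]),
        "JM4": np.array([xc, -0.8 * hb, -wb]),
        "JM5": np.array([0.0, y, 0.0]),
        "JM6": np.array([0.0, -y, 0.0]),
    }


def _sacrum_mesh(slope_deg: float) -> tuple[TriMesh, dict[str, np.ndarray]]:
    """Wedge sacrum with its apex at the local origin and a tilted top plate."""
    sigma = math.radians(slope_deg)
    u = 0.5 * _PROMONTORY_LENGTH * np.array([math.cos(sigma), math.sin(sigma), 0.0])
    w = np.array([0.0, 0.0, 35.0])
    c_top = np.array([0.0, _SACRUM_HEIGHT, 0.0])
    top = [c_top + u + w, c_top + u - w, c_top - u - w, c_top - u + w]
    bot = [
        np.array([5.0, 0.0, 5.0]), np.array([5.0, 0.0, -5.0]),
        np.array([-5.0, 0.0, -5.0]), np.array([-5.0, 0.0, 5.0]),
    ]
    verts = np.array(top + bot)
    faces = [
        (0, 1, 2), (0, 2, 3),  # top
        (4, 6, 5), (4, 7, 6),  # bottom
        (0, 4, 5), (0, 5, 1),
        (1, 5, 6), (1, 6, 2),
        (2, 6, 7), (2, 7, 3),
        (3, 7, 4), (3, 4, 0),
    ]
    landmarks = {"SP_ANT": c_top + u, "SP_POST": c_top - u}
    return TriMesh(verts, np.array(faces)), landmarks


def _pelvis_mesh() -> TriMesh:
    hx, hy, hz = 60.0, 40.0, 80.0
    verts = np.array(
        [
            [-hx, -hy, -hz], [hx, -hy, -hz], [hx, hy, -hz], [-hx, hy, -hz],
            [-hx, -hy, hz], [hx, -hy, hz], [hx, hy, hz], [-hx, hy, hz],
        ]
    )
    quads = [
        (0, 3, 2, 1), (4, 5, 6, 7), (0, 1, 5, 4),
        (2, 3, 7, 6), (1, 2, 6, 5), (0, 4, 7, 3),
    ]
    faces = []
    for a, b, c, d in quads:
        faces.append((a, b, c))
        faces.append((a, c, d))
    return TriMesh(verts, np.array(faces))


# --------------------------------------------------------------------------
# template
# --------------------------------------------------------------------------

def generate_template(spec: SpineSpec | None = None) -> TemplateBundle:
    """Straight-spine template bundle for the given (or default) spec.

    Wedge rotations in the spec are ignored: the template is the zero-rotation,
    unit-scale configuration with the spec's dimensions and sacral slope.
    """
    spec = spec or SpineSpec()
    caudal_first = list(reversed(spec.levels))
    bodies: dict[str, TemplateBody] = {}

    sac_mesh, sac_lms = _sacrum_mesh(spec.sacral_slope_deg)
    bodies[SACRUM] = TemplateBody(
        name=SACRUM, mass=8.0, mesh=sac_mesh, landmarks=sac_lms,
        origin=np.zeros(3), posterior_start=None,
    )
    bodies[PELVIS] = TemplateBody(
        name=PELVIS, mass=12.0, mesh=_pelvis_mesh(), landmarks={},
        origin=np.array([0.0, -40.0, 0.0]), posterior_start=None,
    )

    y = _SACRUM_HEIGHT
    prev_half = 0.0
    for k, level in enumerate(caudal_first):
        ap, is_h, rl = spec.dims[level]
        y += prev_half + _disc_height(level) + is_h / 2.0
        mesh, posterior_start = _vertebra_mesh(ap, is_h, rl)
        bodies[level] = TemplateBody(
            name=level,
            mass=_vertebra_mass(level),
            mesh=mesh,
            landmarks=_vertebra_landmarks(ap, is_h, rl),
            origin=np.array([0.0, y, 0.0]),
            posterior_start=posterior_start,
        )
        prev_half = is_h / 2.0

    muscle_paths = []
    for side, tag in ((1.0, "r"), (-1.0, "l")):
        points: list[tuple[str, np.ndarray]] = [
            (SACRUM, np.array([-30.0, 70.0, side * 25.0]))
        ]
        for level in caudal_first:
            ap, is_h, rl = spec.dims[level]
            points.append(
                (level, np.array([-(ap / 2.0) - 0.6 * ap, 0.0, side * 0.45 * rl]))
            )
        muscle_paths.append(MusclePath(name=f"erector_spinae_{tag}", points=points))

    bundle = TemplateBundle(
        levels=list(spec.levels),
        bodies=bodies,
        muscle_paths=muscle_paths,
        sacral_slope_deg=spec.sacral_slope_deg,
        sacral_apex=np.zeros(3),
    )
    bundle.validate()
    return bundle


# --------------------------------------------------------------------------
# subject generation
# --------------------------------------------------------------------------

def _frontal_profile(spec: SpineSpec, phi_max_deg: float) -> dict[str, float]:
    """Per-level frontal tilt (deg): sine inside the main curve (end levels at
    +/- phi_max, zero at the apex) with linear decay to zero on the flanks."""
    levels = list(spec.levels)  # cranial -> caudal
    iu, ia, il = (
        levels.index(spec.curve_upper),
        levels.index(spec.apex_level),
        levels.index(spec.curve_lower),
    )
    half = max(ia - iu, il - ia)
    phi: dict[str, float] = {}
    for i, lvl in enumerate(levels):
        if iu <= i <= il:
            phi[lvl] = phi_max_deg * math.sin(0.5 * math.pi * (ia - i) / half)
        elif i < iu:  # cranial flank: decay from +phi_max at upper end to 0 at the top
            frac = (i + 1) / (iu + 1)
            phi[lvl] = phi_max_deg * frac
        else:  # caudal flank: decay to 0 toward the sacrum
            n_below = len(levels) - il
            frac = (len(levels) - i) / n_below
            phi[lvl] = -phi_max_deg * frac
    return phi


def _sagittal_profile(spec: SpineSpec) -> dict[str, float]:
    """Per-level sagittal pitch (deg) ramping to slope - lordosis at L1."""
    if spec.lordosis_deg is None:
        return {lvl: 0.0 for lvl in spec.levels}
    psi_l1 = spec.sacral_slope_deg - spec.lordosis_deg
    lumbar = [lvl for lvl in spec.levels if lvl.startswith("L")]
    psi: dict[str, float] = {}
    n = len(lumbar)
    for lvl in spec.levels:
        if lvl.startswith("L"):
            # caudal -> cranial ramp: L5 gets 1/n of the pitch, L1 the full pitch
            rank = n - lumbar.index(lvl)  # L1 -> n ... L5 -> 1
            psi[lvl] = psi_l1 * rank / n
        else:
            psi[lvl] = psi_l1
    return psi


def _rotation(psi_deg: float, phi_deg: float, axial_deg: float) -> np.ndarray:
    """Compose sagittal pitch (about RL/Z), frontal tilt (about AP/X) and
    axial rotation (about IS/Y): R = Rz(psi) Rx(phi) Ry(axial)."""
    return Rotation.from_euler("ZXY", [psi_deg, phi_deg, axial_deg], degrees=True).as_matrix()


def _achieved_cobb(spec: SpineSpec, psi: dict[str, float], phi_max: float) -> float:
    phi = _frontal_profile(spec, phi_max)
    frames = {}
    for lvl in (spec.curve_upper, spec.curve_lower):
        r = _rotation(psi[lvl], phi[lvl], spec.axial_deg[lvl])
        frames[lvl] = BodyFrame(np.zeros(3), r)
    return cobb_from_frames(frames[spec.curve_upper], frames[spec.curve_lower])


@dataclass
class SubjectTruth:
    """Ground truth accompanying a synthetic subject."""

    spec: SpineSpec
    template: TemplateBundle
    frames: dict[str, BodyFrame]
    centres: dict[str, np.ndarray]  # absolute, model frame
    rotations: dict[str, np.ndarray]
    scales: dict[str, tuple[float, float, float]]
    meshes: dict[str, TriMesh]  # posed subject meshes, model frame
    posterior_starts: dict[str, int]
    landmarks_model: LandmarkSet
    cobb_deg: float
    lordosis_deg: float | None
    apex_level: str
    sacral_slope_deg: float
    apex_ct: np.ndarray
    ct_axes_code: str

    def centre_set(self) -> CentreSet:
        return CentreSet(dict(self.centres))


def generate_subject(
    spec: SpineSpec,
    template: TemplateBundle | None = None,
    ct_axes_code: str = MODEL_AXES_CODE,
    ct_apex: np.ndarray | tuple = (0.0, 0.0, 0.0),
) -> tuple[LandmarkSet, SubjectTruth]:
    """Noiseless palpated landmarks plus full ground truth for one subject.

    The subject is the template scaled per level by ``spec.scales`` and bent
    by composed wedge rotations; the frontal profile amplitude is calibrated
    so the achieved Cobb angle between the curve end levels equals
    ``spec.cobb_deg``.  Landmarks are returned in the CT frame defined by
    ``ct_axes_code`` and the CT-frame sacral-apex position ``ct_apex``.
    """
    template = template or generate_template(
        replace(spec, cobb_deg=0.0, sacral_slope_deg=_TEMPLATE_SLOPE_DEG)
    )
    psi = _sagittal_profile(spec)

    if spec.cobb_deg:
        def gap(m: float) -> float:
            return _achieved_cobb(spec, psi, m) - spec.cobb_deg

        hi = 85.0
        if gap(hi) < 0:
            raise SpecError(
                f"Cobb target {spec.cobb_deg} deg unreachable for this level count"
            )
        phi_max = brentq(gap, 0.0, hi, xtol=1e-10)
    else:
        phi_max = 0.0
    phi = _frontal_profile(spec, phi_max) if phi_max else {l: 0.0 for l in spec.levels}

    rotations = {
        lvl: _rotation(psi[lvl], phi[lvl], spec.axial_deg[lvl]) for lvl in spec.levels
    }

    # sacrum: rotate about RL at the apex so its slope matches the spec
    d_sigma = spec.sacral_slope_deg - template.sacral_slope_deg
    r_sac = Rotation.from_euler("z", d_sigma, degrees=True).as_matrix()
    sac = template.bodies[SACRUM]
    sp = {c: r_sac @ p for c, p in sac.landmarks.items()}
    top_centre = 0.5 * (sp["SP_ANT"] + sp["SP_POST"])

    # stack bodies caudal -> cranial from the sacral plate
    caudal_first = list(reversed(spec.levels))
    positions: dict[str, np.ndarray] = {}
    y_hat = np.array([0.0, 1.0, 0.0])
    prev_pos, prev_half, prev_rot = top_centre, 0.0, r_sac
    for level in caudal_first:
        is_scaled = spec.dims[level][1] * spec.scales[level][1]
        step = prev_half + _disc_height(level) + is_scaled / 2.0
        u = prev_rot @ y_hat + rotations[level] @ y_hat
        u = u / np.linalg.norm(u)
        positions[level] = prev_pos + step * u
        prev_pos, prev_half, prev_rot = positions[level], is_scaled / 2.0, rotations[level]

    # landmarks, meshes, frames
    landmarks: list[Landmark] = []
    meshes: dict[str, TriMesh] = {}
    frames: dict[str, BodyFrame] = {}
    posterior_starts: dict[str, int] = {}
    for level in spec.levels:
        body = template.bodies[level]
        s = np.asarray(spec.scales[level], dtype=float)
        r, p = rotations[level], positions[level]
        for code, local in body.landmarks.items():
            landmarks.append(Landmark(level, code, r @ (s * local) + p))
        meshes[level] = TriMesh(body.mesh.vertices * s @ r.T + p, body.mesh.faces.copy())
        posterior_starts[level] = body.posterior_start
        frames[level] = BodyFrame(origin=p, axes=r)
    for code, pos in sp.items():
        landmarks.append(Landmark(SACRUM, code, pos))

    model_ls = LandmarkSet(landmarks, frame="MODEL")
    model_ls.axes_code = MODEL_AXES_CODE  # type: ignore[attr-defined]

    # achieved metrics (measured, not assumed)
    achieved_cobb = (
        cobb_from_frames(frames[spec.curve_upper], frames[spec.curve_lower])
        if spec.cobb_deg
        else 0.0
    )
    achieved_ll = (
        lordosis_from_frame(frames["L1"], spec.sacral_slope_deg)
        if "L1" in frames
        else None
    )
    centres = dict(positions)
    cs = CentreSet(dict(centres))
    apex = find_apex(cs, -np.asarray(centres["L5"]))  # sacral apex is the origin

    # express landmarks in the requested CT frame
    r_ct = axes_code_rotation(ct_axes_code)
    apex_ct = np.asarray(ct_apex, dtype=float)
    ct_landmarks = [
        Landmark(lm.bone, lm.name, r_ct.T @ lm.position + apex_ct) for lm in model_ls
    ]
    ct_ls = LandmarkSet(ct_landmarks, frame="CT")
    ct_ls.axes_code = ct_axes_code  # type: ignore[attr-defined]

    truth = SubjectTruth(
        spec=spec,
        template=template,
        frames=frames,
        centres=centres,
        rotations=rotations,
        scales=dict(spec.scales),
        meshes=meshes,
        posterior_starts=posterior_starts,
        landmarks_model=model_ls,
        cobb_deg=achieved_cobb,
        lordosis_deg=achieved_ll,
        apex_level=apex,
        sacral_slope_deg=spec.sacral_slope_deg,
        apex_ct=apex_ct,
        ct_axes_code=ct_axes_code,
    )
    return ct_ls, truth


# --------------------------------------------------------------------------
# palpation panels
# --------------------------------------------------------------------------

def generate_panel(
    subject: LandmarkSet,
    noise: NoiseModel | None = None,
    n_operators: int = 5,
    n_repeats: int = 3,
    seed: int | None = None,
) -> PalpationPanel:
    """Repeated palpations of ``subject`` with operator bias and noise.

    Each operator carries a fixed per-axis bias drawn from the bias SDs; each
    observation adds independent per-axis noise; with probability
    ``outlier_probability`` an isotropic outlier of up to the magnitude cap is
    added.  The total perturbation of any observation is clipped to the cap.
    Deterministic for a given seed (``seed`` overrides ``noise.seed``).
    """
    noise = noise or NoiseModel()
    rng = np.random.default_rng(noise.seed if seed is None else seed)
    sd = np.asarray(noise.sd_mm, dtype=float)
    bias_sd = np.asarray(noise.bias_sd_mm, dtype=float)
    cap = noise.outlier_magnitude_mm
    records = []
    lms = subject.landmarks()
    for op in range(1, n_operators + 1):
        bias = rng.normal(0.0, 1.0, 3) * bias_sd
        for rep in range(1, n_repeats + 1):
            for lm in lms:
                delta = bias + rng.normal(0.0, 1.0, 3) * sd
                if rng.random() < noise.outlier_probability:
                    # outliers share the per-axis anisotropy of the noise
                    # (mis-identified endplates displace mostly along IS)
                    direction = rng.normal(size=3) * sd
                    direction /= np.linalg.norm(direction)
                    delta = delta + direction * rng.uniform(0.5, 1.0) * cap
                norm = np.linalg.norm(delta)
                if norm > cap:
                    delta = delta * (cap / norm)
                x, y, z = lm.position + delta
                records.append((op, rep, lm.bone, lm.name, x, y, z))
    return PalpationPanel.from_records(records)
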