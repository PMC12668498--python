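"""Base-model construction and the six-step landmark-driven morphing workflow.

The spine model is a chain pelvis - sacrum - L5 - ... - T1 of rigid bodies.
Every intervertebral joint (IVJ) has 6 degrees of freedom and carries a
lumped-parameter linear spring-damper (bushing) whose default stiffness and
damping are literature values for the intervertebral disc; wrapping spheres
fitted to the anterior vertebral-body surfaces keep muscle paths out of the
bone when the scoliotic curvature is introduced.

The morphing workflow, given a virtually palpated landmark set:

1. align the landmarks to the model frame (sacral apex at the origin,
   +X anterior, +Y superior, +Z right);
2. scale each vertebra anisotropically (AP, IS, RL) by the ratio of
   subject-to-model landmark distances, and all body masses by the
   subject-to-template total-mass ratio;
3. rotate the sacrum (and the chain above it) so the sacral-promontory
   pitch matches the subject's sacral slope;
4. redefine each IVJ pose from the pedicle and endplate-centre landmarks;
5. realign each vertebra so its landmark-derived body frame matches the
   subject's;
6. re-seat the bushing frames on the new joint poses so the bushings are
   load-free in the constructed pose.

All geometry is millimetres internally; the osim writer converts to metres.
"""

from __future__ import annotations

import copy
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from xml.etree import ElementTree as ET

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import (
    IncompleteLandmarksError,
    MissingLandmarkError,
    TemplateError,
    ZeroDistanceError,
)
from .geometry import (
    BodyFrame,
    Sphere,
    TriMesh,
    fit_sphere,
    frame_from_landmarks,
    select_anterior_nodes,
)
from .landmarks import BONES, Landmark, LandmarkSet
from .template import MusclePath, PELVIS, SACRUM, TemplateBundle

_LEVEL_INDEX = {b: i for i, b in enumerate(BONES)}


@dataclass(frozen=True)
class BushingProperties:
    """Per-DoF linear bushing stiffness and damping at one IVJ.

    Components are ordered along the joint axes (AP/X, IS/Y, RL/Z):
    translational stiffness in N/m for anterior-posterior shear,
    inferior-superior and right-left translation; rotational stiffness in
    N*m/rad for lateral bending (about AP), axial rotation (about IS) and
    flexion-extension (about RL).  Defaults are the standard literature
    values for the intervertebral disc.
    """

    translational_stiffness: tuple[float, float, float] = (149_000.0, 1_890_000.0, 135_000.0)
    rotational_stiffness: tuple[float, float, float] = (68.8, 291.0, 51.0)
    translational_damping: tuple[float, float, float] = (1000.0, 1000.0, 1000.0)
    rotational_damping: tuple[float, float, float] = (2.3, 2.3, 2.3)

    def __post_init__(self) -> None:
        for name in (
            "translational_stiffness",
            "rotational_stiffness",
            "translational_damping",
            "rotational_damping",
        ):
            if any(v <= 0 for v in getattr(self, name)):
                raise ValueError(f"{name} components must be positive")


@dataclass
class LocalFrame:
    """A frame (origin mm + orthonormal axes) expressed in a body's frame."""

    origin: np.ndarray
    axes: np.ndarray


@dataclass
class JointPose:
    """A 6-DoF joint between two adjacent bodies, posed in the global frame."""

    parent: str
    child: str
    origin: np.ndarray  # global, mm
    axes: np.ndarray  # columns (AP, IS, RL)
    dof: int = 6

    @property
    def name(self) -> str:
        return f"{self.parent.lower()}_{self.child.lower()}"


@dataclass
class Bushing:
    """Spring-damper co-located with one IVJ; frames are body-local."""

    joint: str
    parent: str
    child: str
    props: BushingProperties
    frame_parent: LocalFrame
    frame_child: LocalFrame


@dataclass
class Body:
    """A rigid body: local mesh/markers/wrap sphere plus a global pose."""

    name: str
    mass: float
    mesh: TriMesh | None
    markers: dict[str, np.ndarray]
    wrap_sphere: Sphere | None = None
    pose_r: np.ndarray = field(default_factory=lambda: np.eye(3))
    pose_t: np.ndarray = field(default_factory=lambda: np.zeros(3))
    posterior_start: int | None = None

    def to_global(self, local: np.ndarray) -> np.ndarray:
        return self.pose_r @ np.asarray(local, dtype=float) + self.pose_t

    def to_local(self, point: np.ndarray) -> np.ndarray:
        return self.pose_r.T @ (np.asarray(point, dtype=float) - self.pose_t)


@dataclass
class ScaleFactors:
    """Per-vertebra (AP, IS, RL) scale factors plus the mass factor."""

    factors: dict[str, tuple[float, float, float]]
    mass_factor: float = 1.0

    def __post_init__(self) -> None:
        for lvl, f in self.factors.items():
            if any(not math.isfinite(v) or v <= 0 for v in f):
                raise ValueError(f"scale factors at {lvl} must be positive finite")
        if not self.mass_factor > 0:
            raise ValueError("mass factor must be positive")


class SpineModel:
    """Articulated spine: bodies, 6-DoF joints, bushings and muscle paths."""

    def __init__(
        self,
        bodies: dict[str, Body],
        joints: list[JointPose],
        bushings: dict[str, Bushing],
        muscle_paths: list[MusclePath],
        levels: list[str],
        template_mass: float,
    ) -> None:
        self.bodies = bodies
        self.joints = joints
        self.bushings = bushings
        self.muscle_paths = muscle_paths
        self.levels = levels  # vertebral levels, cranial -> caudal
        self.template_mass = template_mass

    # -- basic queries -------------------------------------------------------

    def copy(self) -> "SpineModel":
        return copy.deepcopy(self)

    @property
    def total_mass(self) -> float:
        return float(sum(b.mass for b in self.bodies.values()))

    def joint(self, name: str) -> JointPose:
        for j in self.joints:
            if j.name == name:
                return j
        raise KeyError(f"no joint named {name}")

    def ivj_names(self) -> list[str]:
        return [j.name for j in self.joints if j.parent != PELVIS]

    def marker_global(self, bone: str, code: str) -> np.ndarray:
        body = self.bodies[bone]
        if code not in body.markers:
            raise MissingLandmarkError(f"no marker {code} on {bone}")
        return body.to_global(body.markers[code])

    def landmark_set(self) -> LandmarkSet:
        """All model markers as a landmark set in the global (model) frame."""
        lms = []
        for body in self.bodies.values():
            for code, local in body.markers.items():
                lms.append(Landmark(body.name, code, body.to_global(local)))
        ls = LandmarkSet(lms, frame="MODEL")
        return ls

    def body_frame(self, level: str) -> BodyFrame:
        """Landmark-derived body frame of a vertebra, in the global frame."""
        body = self.bodies[level]
        try:
            g = {c: body.to_global(body.markers[c]) for c in
                 ("S1", "S2", "S3", "S4", "S5", "S6", "S7", "S8")}
        except KeyError as exc:
            raise KeyError(f"{level} missing scaling marker {exc}") from None
        sup_mean = np.mean([g["S1"], g["S2"], g["S5"], g["S6"]], axis=0)
        inf_mean = np.mean([g["S3"], g["S4"], g["S7"], g["S8"]], axis=0)
        return frame_from_landmarks(sup_mean, inf_mean, g["S1"], g["S2"], g["S3"], g["S4"])

    def meshes_global(self) -> dict[str, TriMesh]:
        """Posed vertebral meshes keyed by level (for accuracy assessment)."""
        out = {}
        for level in self.levels:
            body = self.bodies[level]
            if body.mesh is not None:
                out[level] = body.mesh.transformed(body.pose_r, body.pose_t)
        return out

    def body_frames(self) -> dict[str, BodyFrame]:
        return {lvl: self.body_frame(lvl) for lvl in self.levels}

    # -- serialisation -------------------------------------------------------

    def to_dict(self) -> dict:
        def arr(a):
            return np.asarray(a, dtype=float).tolist()

        return {
            "levels": list(self.levels),
            "template_mass": self.template_mass,
            "bodies": {
                name: {
                    "mass": b.mass,
                    "markers": {c: arr(p) for c, p in sorted(b.markers.items())},
                    "pose_r": arr(b.pose_r),
                    "pose_t": arr(b.pose_t),
                    "posterior_start": b.posterior_start,
                    "wrap_sphere": None
                    if b.wrap_sphere is None
                    else {
                        "centre": arr(b.wrap_sphere.centre),
                        "radius": b.wrap_sphere.radius,
                        "rms_residual": b.wrap_sphere.rms_residual,
                    },
                    "mesh": None
                    if b.mesh is None
                    else {"vertices": arr(b.mesh.vertices), "faces": b.mesh.faces.tolist()},
                }
                for name, b in sorted(self.bodies.items())
            },
            "joints": [
                {
                    "parent": j.parent,
                    "child": j.child,
                    "origin": arr(j.origin),
                    "axes": arr(j.axes),
                    "dof": j.dof,
                }
                for j in self.joints
            ],
            "bushings": {
                name: {
                    "joint": bu.joint,
                    "parent": bu.parent,
                    "child": bu.child,
                    "props": {
                        "translational_stiffness": list(bu.props.translational_stiffness),
                        "rotational_stiffness": list(bu.props.rotational_stiffness),
                        "translational_damping": list(bu.props.translational_damping),
                        "rotational_damping": list(bu.props.rotational_damping),
                    },
                    "frame_parent": {
                        "origin": arr(bu.frame_parent.origin),
                        "axes": arr(bu.frame_parent.axes),
                    },
                    "frame_child": {
                        "origin": arr(bu.frame_child.origin),
                        "axes": arr(bu.frame_child.axes),
                    },
                }
                for name, bu in sorted(self.bushings.items())
            },
            "muscle_paths": [
                {"name": mp.name, "points": [[b, arr(p)] for b, p in mp.points]}
                for mp in self.muscle_paths
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SpineModel":
        bodies = {}
        for name, info in d["bodies"].items():
            sphere = None
            if info["wrap_sphere"] is not None:
                sphere = Sphere(
                    centre=np.asarray(info["wrap_sphere"]["centre"]),
                    radius=info["wrap_sphere"]["radius"],
                    rms_residual=info["wrap_sphere"]["rms_residual"],
                )
            mesh = None
            if info["mesh"] is not None:
                mesh = TriMesh(
                    np.asarray(info["mesh"]["vertices"]), np.asarray(info["mesh"]["faces"])
                )
            bodies[name] = Body(
                name=name,
                mass=info["mass"],
                mesh=mesh,
                markers={c: np.asarray(p) for c, p in info["markers"].items()},
                wrap_sphere=sphere,
                pose_r=np.asarray(info["pose_r"]),
                pose_t=np.asarray(info["pose_t"]),
                posterior_start=info.get("posterior_start"),
            )
        joints = [
            JointPose(
                parent=j["parent"],
                child=j["child"],
                origin=np.asarray(j["origin"]),
                axes=np.asarray(j["axes"]),
                dof=j["dof"],
            )
            for j in d["joints"]
        ]
        bushings = {}
        for name, info in d["bushings"].items():
            props = BushingProperties(
                translational_stiffness=tuple(info["props"]["translational_stiffness"]),
                rotational_stiffness=tuple(info["props"]["rotational_stiffness"]),
                translational_damping=tuple(info["props"]["translational_damping"]),
                rotational_damping=tuple(info["props"]["rotational_damping"]),
            )
            bushings[name] = Bushing(
                joint=info["joint"],
                parent=info["parent"],
                child=info["child"],
                props=props,
                frame_parent=LocalFrame(
                    np.asarray(info["frame_parent"]["origin"]),
                    np.asarray(info["frame_parent"]["axes"]),
                ),
                frame_child=LocalFrame(
                    np.asarray(info["frame_child"]["origin"]),
                    np.asarray(info["frame_child"]["axes"]),
                ),
            )
        muscle_paths = [
            MusclePath(name=mp["name"], points=[(b, np.asarray(p)) for b, p in mp["points"]])
            for mp in d["muscle_paths"]
        ]
        return cls(
            bodies=bodies,
            joints=joints,
            bushings=bushings,
            muscle_paths=muscle_paths,
            levels=list(d["levels"]),
            template_mass=d["template_mass"],
        )

    def save_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), sort_keys=True))

    @classmethod
    def load_json(cls, path) -> "SpineModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


# --------------------------------------------------------------------------
# step 0: base model
# --------------------------------------------------------------------------

def build_base_model(
    template: TemplateBundle,
    props: BushingProperties | None = None,
    wrap_fraction: float = 0.35,
) -> SpineModel:
    """Assemble the base model from a template bundle.

    Creates the pelvis - sacrum - L5 - ... chain with a 6-DoF joint and a
    bushing (default literature disc properties) at every IVJ, and fits a
    wrapping sphere to the anterior surface of each vertebral-body mesh.
    """
    template.validate()
    props = props or BushingProperties()
    bodies: dict[str, Body] = {}
    for name, tb in template.bodies.items():
        sphere = None
        if name in template.levels:
            if tb.mesh is None:
                raise TemplateError(f"no mesh for vertebra {name}")
            idx = select_anterior_nodes(tb.mesh, BodyFrame.identity(), fraction=wrap_fraction)
            sphere = fit_sphere(tb.mesh.vertices[idx])
        bodies[name] = Body(
            name=name,
            mass=tb.mass,
            mesh=tb.mesh,
            markers={c: np.asarray(p, dtype=float) for c, p in tb.landmarks.items()},
            wrap_sphere=sphere,
            pose_r=np.eye(3),
            pose_t=np.asarray(tb.origin, dtype=float),
            posterior_start=tb.posterior_start,
        )

    caudal_first = list(reversed(template.levels))  # L5 ... T9 (or T1)
    chain = [PELVIS, SACRUM] + caudal_first
    joints: list[JointPose] = []
    bushings: dict[str, Bushing] = {}
    for parent, child in zip(chain[:-1], chain[1:]):
        if parent == PELVIS:
            origin = bodies[SACRUM].pose_t.copy()  # sacral apex
        elif parent == SACRUM:
            plate = 0.5 * (
                bodies[SACRUM].to_global(bodies[SACRUM].markers["SP_ANT"])
                + bodies[SACRUM].to_global(bodies[SACRUM].markers["SP_POST"])
            )
            origin = 0.5 * (plate + bodies[child].to_global(bodies[child].markers["JM6"]))
        else:
            origin = 0.5 * (
                bodies[parent].to_global(bodies[parent].markers["JM5"])
                + bodies[child].to_global(bodies[child].markers["JM6"])
            )
        joint = JointPose(parent=parent, child=child, origin=origin, axes=np.eye(3))
        joints.append(joint)
        if parent != PELVIS:
            bushings[joint.name] = _seat_bushing(bodies, joint, props)

    model = SpineModel(
        bodies=bodies,
        joints=joints,
        bushings=bushings,
        muscle_paths=copy.deepcopy(template.muscle_paths),
        levels=list(template.levels),
        template_mass=template.total_mass,
    )
    return model


def _seat_bushing(
    bodies: dict[str, Body], joint: JointPose, props: BushingProperties
) -> Bushing:
    """Create a bushing whose two frames coincide with the joint frame."""
    parent, child = bodies[joint.parent], bodies[joint.child]
    return Bushing(
        joint=joint.name,
        parent=joint.parent,
        child=joint.child,
        props=props,
        frame_parent=LocalFrame(
            origin=parent.to_local(joint.origin), axes=parent.pose_r.T @ joint.axes
        ),
        frame_child=LocalFrame(
            origin=child.to_local(joint.origin), axes=child.pose_r.T @ joint.axes
        ),
    )


# --------------------------------------------------------------------------
# step 2: scaling
# --------------------------------------------------------------------------

_AP_PAIRS = (("S1", "S3"), ("S2", "S4"))
_SUP = ("S1", "S2", "S5", "S6")
_INF = ("S3", "S4", "S7", "S8")
_RL_PAIRS = (("S5", "S7"), ("S6", "S8"))


def _span(ls: LandmarkSet, level: str, group_a, group_b) -> float:
    a = np.mean([ls.get(level, c) for c in group_a], axis=0)
    b = np.mean([ls.get(level, c) for c in group_b], axis=0)
    return float(np.linalg.norm(a - b))


def compute_scale_factors(
    model_lms: LandmarkSet, subject_lms: LandmarkSet, level: str
) -> tuple[float, float, float]:
    """(AP, IS, RL) subject-over-model scale factors for one vertebra.

    Each factor is the ratio of Euclidean distances between mean landmark
    positions: AP between the anterior-most and posterior-most endplate-point
    means, IS between the superior- and inferior-endplate means, RL between
    the right- and left-most endplate-point means.
    """
    for ls, tag in ((model_lms, "model"), (subject_lms, "subject")):
        if not ls.complete(level):
            raise IncompleteLandmarksError(f"{tag} landmarks incomplete at {level}")
    spans = []
    for group_a, group_b in (
        (("S1", "S3"), ("S2", "S4")),  # AP: anterior means vs posterior means
        (_SUP, _INF),  # IS: superior vs inferior endplate means
        (("S5", "S7"), ("S6", "S8")),  # RL: right vs left means
    ):
        num = _span(subject_lms, level, group_a, group_b)
        den = _span(model_lms, level, group_a, group_b)
        if den < 1e-9:
            raise ZeroDistanceError(f"zero model span at {level}")
        if num < 1e-9:
            raise ZeroDistanceError(f"zero subject span at {level}")
        spans.append(num / den)
    return tuple(spans)  # type: ignore[return-value]


def compute_all_scale_factors(
    model_lms: LandmarkSet,
    subject_lms: LandmarkSet,
    levels,
    subject_mass: float | None = None,
    template_mass: float | None = None,
) -> ScaleFactors:
    factors = {
        lvl: compute_scale_factors(model_lms, subject_lms, lvl) for lvl in levels
    }
    mass_factor = 1.0
    if subject_mass is not None and template_mass is not None:
        mass_factor = subject_mass / template_mass
    return ScaleFactors(factors=factors, mass_factor=mass_factor)


def apply_scaling(
    model: SpineModel,
    sf: ScaleFactors,
    subject_mass: float | None = None,
    template_mass: float | None = None,
) -> SpineModel:
    """Anisotropically scale vertebrae and scale all body masses.

    Vertebra meshes, markers, wrap spheres and the muscle points attached to
    them are scaled about the body origin along the body axes; the sacrum and
    pelvis geometry are untouched.  Every body mass is multiplied by
    ``subject_mass / template_mass`` (defaults: template total mass), so the
    scaled model's total mass equals the subject mass.
    """
    out = model.copy()
    template_mass = template_mass if template_mass is not None else model.total_mass
    mass_factor = (
        subject_mass / template_mass if subject_mass is not None else sf.mass_factor
    )
    for level, factors in sf.factors.items():
        if level not in out.bodies:
            raise KeyError(f"scale factor for unknown body {level}")
        s = np.asarray(factors, dtype=float)
        body = out.bodies[level]
        body.markers = {c: s * p for c, p in body.markers.items()}
        if body.mesh is not None:
            body.mesh = TriMesh(body.mesh.vertices * s, body.mesh.faces.copy())
            if body.wrap_sphere is not None:
                # an anisotropically scaled sphere is an ellipsoid: refit to
                # the scaled mesh instead of scaling the sphere analytically
                idx = select_anterior_nodes(body.mesh, BodyFrame.identity())
                body.wrap_sphere = fit_sphere(body.mesh.vertices[idx])
        for mp in out.muscle_paths:
            mp.points = [
                (b, s * p if b == level else p) for b, p in mp.points
            ]
    for body in out.bodies.values():
        body.mass *= mass_factor
    return out


# --------------------------------------------------------------------------
# step 3: sacrum alignment
# --------------------------------------------------------------------------

def _promontory_pitch_deg(sp_ant: np.ndarray, sp_post: np.ndarray) -> float:
    v = np.asarray(sp_ant, dtype=float) - np.asarray(sp_post, dtype=float)
    return math.degrees(math.atan2(v[1], v[0]))


def align_sacrum(model: SpineModel, sp_ant, sp_post) -> SpineModel:
    """Rotate the sacrum about the RL axis to match the subject sacral slope.

    The rotation (about the global Z axis, centred on the sacral apex) makes
    the model's promontory pitch equal the pitch of the subject's
    ``SP_ANT - SP_POST`` vector; everything above the sacrum in the chain
    follows the rotation.  The pelvis pose is untouched.  Applying the
    operation twice is a no-op.
    """
    if sp_ant is None or sp_post is None:
        raise MissingLandmarkError("sacral promontory landmarks required")
    out = model.copy()
    sac = out.bodies[SACRUM]
    model_pitch = _promontory_pitch_deg(
        sac.to_global(sac.markers["SP_ANT"]), sac.to_global(sac.markers["SP_POST"])
    )
    subject_pitch = _promontory_pitch_deg(sp_ant, sp_post)
    delta = subject_pitch - model_pitch
    r = Rotation.from_euler("z", delta, degrees=True).as_matrix()
    centre = sac.pose_t.copy()  # sacral apex
    moving = [SACRUM] + list(model.levels)
    for name in moving:
        body = out.bodies[name]
        body.pose_r = r @ body.pose_r
        body.pose_t = centre + r @ (body.pose_t - centre)
    for joint in out.joints:
        if joint.parent == PELVIS:
            continue
        joint.origin = centre + r @ (joint.origin - centre)
        joint.axes = r @ joint.axes
    return out


# --------------------------------------------------------------------------
# step 4: joint poses
# --------------------------------------------------------------------------

def _vertebra_rl(ls: LandmarkSet, level: str) -> np.ndarray:
    right = np.mean([ls.get(level, "JM1"), ls.get(level, "JM2")], axis=0)
    left = np.mean([ls.get(level, "JM3"), ls.get(level, "JM4")], axis=0)
    v = right - left
    n = np.linalg.norm(v)
    if n < 1e-9:
        raise MissingLandmarkError(f"degenerate pedicle landmarks at {level}")
    return v / n


def _endplate_ap(ls: LandmarkSet, level: str, plate: str) -> np.ndarray:
    ant, post = (("S1", "S2") if plate == "superior" else ("S3", "S4"))
    v = ls.get(level, ant) - ls.get(level, post)
    n = np.linalg.norm(v)
    if n < 1e-9:
        raise MissingLandmarkError(f"degenerate endplate midline at {level}")
    return v / n


def define_joint_pose(
    subject_lms: LandmarkSet, inf_level: str, sup_level: str
) -> JointPose:
    """IVJ pose between two adjacent vertebrae, from the subject landmarks.

    Origin: midpoint of the facing endplate centres (JM5 of the caudal
    vertebra, JM6 of the cranial one).  RL: unit pedicle right-minus-left
    vectors of the two vertebrae, averaged.  AP: the mean anterior midline
    direction of the two facing endplates, projected perpendicular to RL.
    IS completes the right-handed triad, pointing cephalad.
    """
    if inf_level == SACRUM:
        try:
            inf_centre = 0.5 * (
                subject_lms.get(SACRUM, "SP_ANT") + subject_lms.get(SACRUM, "SP_POST")
            )
            inf_ap = subject_lms.get(SACRUM, "SP_ANT") - subject_lms.get(SACRUM, "SP_POST")
        except KeyError:
            raise MissingLandmarkError("sacral promontory landmarks required") from None
        inf_ap = inf_ap / np.linalg.norm(inf_ap)
        rl_vectors = [_vertebra_rl(subject_lms, sup_level)]
    else:
        try:
            inf_centre = subject_lms.get(inf_level, "JM5")
        except KeyError:
            raise MissingLandmarkError(f"{inf_level} JM5 required") from None
        inf_ap = _endplate_ap(subject_lms, inf_level, "superior")
        rl_vectors = [
            _vertebra_rl(subject_lms, inf_level),
            _vertebra_rl(subject_lms, sup_level),
        ]
    try:
        sup_centre = subject_lms.get(sup_level, "JM6")
    except KeyError:
        raise MissingLandmarkError(f"{sup_level} JM6 required") from None
    sup_ap = _endplate_ap(subject_lms, sup_level, "inferior")

    origin = 0.5 * (inf_centre + sup_centre)
    rl = np.mean(rl_vectors, axis=0)
    rl = rl / np.linalg.norm(rl)
    ap0 = 0.5 * (inf_ap + sup_ap)
    ap = ap0 - (ap0 @ rl) * rl
    n = np.linalg.norm(ap)
    if n < 1e-9:
        raise MissingLandmarkError("anterior direction parallel to RL axis")
    ap = ap / n
    is_axis = np.cross(rl, ap)
    # cephalad: IS must point from the caudal toward the cranial endplate
    # centre (an intrinsic convention, so the pose is rotation-equivariant)
    if is_axis @ (sup_centre - inf_centre) < 0:
        is_axis, rl = -is_axis, -rl
    axes = np.column_stack([ap, is_axis, rl])
    return JointPose(parent=inf_level, child=sup_level, origin=origin, axes=axes)


def realign_joints(model: SpineModel, subject_lms: LandmarkSet) -> SpineModel:
    """Redefine every IVJ pose from the subject landmarks (workflow step 4)."""
    out = model.copy()
    for joint in out.joints:
        if joint.parent == PELVIS:
            continue
        new = define_joint_pose(subject_lms, joint.parent, joint.child)
        joint.origin = new.origin
        joint.axes = new.axes
    return out


# --------------------------------------------------------------------------
# step 5: vertebra realignment
# --------------------------------------------------------------------------

def subject_body_frame(subject_lms: LandmarkSet, level: str) -> BodyFrame:
    """Landmark-derived body frame of one vertebra, from palpated landmarks."""
    g = {c: subject_lms.get(level, c) for c in _SUP + _INF}
    sup_mean = np.mean([g[c] for c in _SUP], axis=0)
    inf_mean = np.mean([g[c] for c in _INF], axis=0)
    return frame_from_landmarks(sup_mean, inf_mean, g["S1"], g["S2"], g["S3"], g["S4"])


def realign_vertebrae(model: SpineModel, subject_lms: LandmarkSet) -> SpineModel:
    """Re-pose each vertebra so its landmark frame matches the subject's.

    For every vertebra with a complete palpation, the global pose is set so
    that the body frame computed from the model's own (scaled) markers
    coincides with the frame computed from the subject landmarks; afterwards
    the model's endplate-centre markers match the palpated ones up to the
    protocol's internal consistency.
    """
    out = model.copy()
    realigned = 0
    for level in out.levels:
        if not subject_lms.complete(level):
            continue
        target = subject_body_frame(subject_lms, level)
        body = out.bodies[level]
        local_ls = LandmarkSet(
            [Landmark(level, c, p) for c, p in body.markers.items()], frame="MODEL"
        )
        local = subject_body_frame(local_ls, level)
        body.pose_r = target.axes @ local.axes.T
        body.pose_t = target.origin - body.pose_r @ local.origin
        realigned += 1
    if realigned == 0:
        raise IncompleteLandmarksError("no vertebra has a complete landmark set")
    return out


def vertebra_orientation_in_joint(model: SpineModel, level: str) -> np.ndarray:
    """Rotation of a vertebra expressed in its parent joint frame."""
    for joint in model.joints:
        if joint.child == level:
            return joint.axes.T @ model.bodies[level].pose_r
    raise KeyError(f"no joint with child {level}")


# --------------------------------------------------------------------------
# step 6: bushing realignment, deflections and forces
# --------------------------------------------------------------------------

def realign_bushings(model: SpineModel) -> SpineModel:
    """Re-seat both frames of every bushing on its joint pose (step 6).

    After this, all six generalised bushing deflections are zero in the
    constructed pose, so the joint stiffness introduces no preload.
    """
    out = model.copy()
    for name, bushing in out.bushings.items():
        joint = out.joint(name)
        reseated = _seat_bushing(out.bodies, joint, bushing.props)
        bushing.frame_parent = reseated.frame_parent
        bushing.frame_child = reseated.frame_child
    return out


def bushing_deflection(model: SpineModel, joint_name: str) -> np.ndarray:
    """Six generalised deflections of one bushing at the current pose.

    Returns ``(dx, dy, dz, rx, ry, rz)``: translations of the child frame
    relative to the parent frame in parent-frame axes (mm) and the rotation
    vector (rad) of the relative orientation.
    """
    bushing = model.bushings[joint_name]
    parent = model.bodies[bushing.parent]
    child = model.bodies[bushing.child]
    o1 = parent.to_global(bushing.frame_parent.origin)
    a1 = parent.pose_r @ bushing.frame_parent.axes
    o2 = child.to_global(bushing.frame_child.origin)
    a2 = child.pose_r @ bushing.frame_child.axes
    d_trans = a1.T @ (o2 - o1)
    d_rot = Rotation.from_matrix(a1.T @ a2).as_rotvec()
    return np.concatenate([d_trans, d_rot])


def bushing_force(model: SpineModel, joint_name: str) -> tuple[np.ndarray, np.ndarray]:
    """Bushing force (N) and moment (N*m) on the child at the current pose.

    Linear spring law per DoF: translational deflections are converted from
    mm to m before multiplying by the stiffness.
    """
    bushing = model.bushings[joint_name]
    d = bushing_deflection(model, joint_name)
    k_t = np.asarray(bushing.props.translational_stiffness)
    k_r = np.asarray(bushing.props.rotational_stiffness)
    force = k_t * (d[:3] / 1000.0)
    moment = k_r * d[3:]
    return force, moment


# --------------------------------------------------------------------------
# muscle-path sanity
# --------------------------------------------------------------------------

def _segment_sphere_penetration(p0, p1, centre, radius) -> float:
    """How far (mm) the segment p0-p1 dips inside a sphere (0 if outside)."""
    d = p1 - p0
    dd = float(d @ d)
    t = 0.0 if dd == 0 else float(np.clip((centre - p0) @ d / dd, 0.0, 1.0))
    closest = p0 + t * d
    return max(0.0, radius - float(np.linalg.norm(closest - centre)))


def check_muscle_paths(model: SpineModel, tolerance: float = 0.5) -> list[dict]:
    """Straight-segment muscle paths versus wrapping spheres.

    Returns one record per (path segment, wrap sphere) pair whose straight
    line dips more than ``tolerance`` mm inside the sphere — the automated
    analogue of a visual no-muscle-in-bone check.
    """
    violations = []
    for mp in model.muscle_paths:
        pts = [model.bodies[b].to_global(p) for b, p in mp.points]
        for i, (p0, p1) in enumerate(zip(pts[:-1], pts[1:])):
            for level in model.levels:
                body = model.bodies[level]
                if body.wrap_sphere is None:
                    continue
                centre = body.to_global(body.wrap_sphere.centre)
                pen = _segment_sphere_penetration(p0, p1, centre, body.wrap_sphere.radius)
                if pen > tolerance:
                    violations.append(
                        {"muscle": mp.name, "segment": i, "level": level,
                         "penetration_mm": pen}
                    )
    return violations


# --------------------------------------------------------------------------
# full pipeline
# --------------------------------------------------------------------------

def build_subject_model(
    template: TemplateBundle,
    subject_lms_model_frame: LandmarkSet,
    subject_mass: float = 75.0,
    props: BushingProperties | None = None,
) -> SpineModel:
    """Run the full morphing workflow on model-frame subject landmarks.

    The landmark set must already be aligned to the model frame (use
    :func:`scolimorph.landmarks.align_to_model_frame` first); the sacral
    promontory landmarks must be present for the sacrum-alignment step.
    """
    base = build_base_model(template, props=props)
    model_lms = base.landmark_set()
    levels = [lvl for lvl in base.levels if subject_lms_model_frame.complete(lvl)]
    if not levels:
        raise IncompleteLandmarksError("subject landmarks complete at no level")
    sf = compute_all_scale_factors(
        model_lms,
        subject_lms_model_frame,
        levels,
        subject_mass=subject_mass,
        template_mass=base.total_mass,
    )
    model = apply_scaling(base, sf, subject_mass=subject_mass)
    model = align_sacrum(
        model,
        subject_lms_model_frame.get(SACRUM, "SP_ANT"),
        subject_lms_model_frame.get(SACRUM, "SP_POST"),
    )
    model = realign_joints(model, subject_lms_model_frame)
    model = realign_vertebrae(model, subject_lms_model_frame)
    model = realign_bushings(model)
    return model


# --------------------------------------------------------------------------
# osim writing
# --------------------------------------------------------------------------

_MM = 0.001


def _vec(v, scale=1.0) -> str:
    return " ".join(f"{float(x) * scale:.12g}" for x in v)


def _euler_xyz(r: np.ndarray) -> np.ndarray:
    """Body-fixed X-Y-Z Euler angles (rad) encoding a rotation matrix."""
    return Rotation.from_matrix(r).as_euler("XYZ")


def _offset_frame(parent_elem, name: str, socket: str, translation, rotation) -> None:
    f = ET.SubElement(parent_elem, "PhysicalOffsetFrame", name=name)
    ET.SubElement(f, "socket_parent").text = socket
    ET.SubElement(f, "translation").text = _vec(translation, _MM)
    ET.SubElement(f, "orientation").text = _vec(_euler_xyz(rotation))


def write_osim(model: SpineModel, path, model_name: str = "scoliotic_spine") -> None:
    """Write the model as OpenSim 4.x-dialect XML.

    Dialect notes: each joint is a ``CustomJoint`` with a 6-DoF spatial
    transform, rotations in Z-X-Y order followed by X/Y/Z translations, and
    both joint frames placed at the morphed joint pose so all coordinate
    defaults are zero; bushings are ``BushingForce`` elements on matching
    offset frames; wrap spheres are ``WrapSphere`` objects on their body;
    muscle paths are ``PathActuator`` geometry.  Units: metres, kilograms,
    radians (converted from the internal millimetres).  Element order is
    deterministic.
    """
    root = ET.Element("OpenSimDocument", Version="40000")
    mdl = ET.SubElement(root, "Model", name=model_name)
    ET.SubElement(mdl, "length_units").text = "meters"
    ET.SubElement(mdl, "force_units").text = "N"

    ground = ET.SubElement(mdl, "Ground", name="ground")
    ET.SubElement(ground, "FrameGeometry")

    body_set = ET.SubElement(mdl, "BodySet", name="bodyset")
    bs_objects = ET.SubElement(body_set, "objects")
    for name in sorted(model.bodies):
        body = model.bodies[name]
        b = ET.SubElement(bs_objects, "Body", name=name.lower())
        ET.SubElement(b, "mass").text = f"{body.mass:.12g}"
        ET.SubElement(b, "mass_center").text = "0 0 0"
        ET.SubElement(b, "inertia").text = "1 1 1 0 0 0"
        wrap_set = ET.SubElement(b, "WrapObjectSet")
        wrap_objects = ET.SubElement(wrap_set, "objects")
        if body.wrap_sphere is not None:
            w = ET.SubElement(wrap_objects, "WrapSphere", name=f"wrap_{name.lower()}")
            ET.SubElement(w, "translation").text = _vec(body.wrap_sphere.centre, _MM)
            ET.SubElement(w, "radius").text = f"{body.wrap_sphere.radius * _MM:.12g}"

    joint_set = ET.SubElement(mdl, "JointSet", name="jointset")
    js_objects = ET.SubElement(joint_set, "objects")
    for joint in model.joints:
        parent_body = model.bodies[joint.parent]
        child_body = model.bodies[joint.child]
        j = ET.SubElement(js_objects, "CustomJoint", name=joint.name)
        ET.SubElement(j, "socket_parent_frame").text = f"{joint.name}_parent_offset"
        ET.SubElement(j, "socket_child_frame").text = f"{joint.name}_child_offset"
        coords = ET.SubElement(j, "coordinates")
        for suffix in ("rz", "rx", "ry", "tx", "ty", "tz"):
            c = ET.SubElement(coords, "Coordinate", name=f"{joint.name}_{suffix}")
            ET.SubElement(c, "default_value").text = "0"
        frames = ET.SubElement(j, "frames")
        _offset_frame(
            frames,
            f"{joint.name}_parent_offset",
            f"/bodyset/{joint.parent.lower()}",
            parent_body.to_local(joint.origin),
            parent_body.pose_r.T @ joint.axes,
        )
        _offset_frame(
            frames,
            f"{joint.name}_child_offset",
            f"/bodyset/{joint.child.lower()}",
            child_body.to_local(joint.origin),
            child_body.pose_r.T @ joint.axes,
        )
        st = ET.SubElement(j, "SpatialTransform")
        axes_order = [
            ("rotation1", joint.axes[:, 2], "rz"),  # flexion-extension (Z)
            ("rotation2", joint.axes[:, 0], "rx"),  # lateral bending (X)
            ("rotation3", joint.axes[:, 1], "ry"),  # axial rotation (Y)
            ("translation1", joint.axes[:, 0], "tx"),
            ("translation2", joint.axes[:, 1], "ty"),
            ("translation3", joint.axes[:, 2], "tz"),
        ]
        for tag, axis, coord in axes_order:
            ta = ET.SubElement(st, "TransformAxis", name=tag)
            ET.SubElement(ta, "coordinates").text = f"{joint.name}_{coord}"
            ET.SubElement(ta, "axis").text = _vec(axis)

    force_set = ET.SubElement(mdl, "ForceSet", name="forceset")
    fs_objects = ET.SubElement(force_set, "objects")
    for name in sorted(model.bushings):
        bushing = model.bushings[name]
        f = ET.SubElement(fs_objects, "BushingForce", name=f"bushing_{name}")
        ET.SubElement(f, "socket_frame1").text = f"/jointset/{name}/{name}_parent_offset"
        ET.SubElement(f, "socket_frame2").text = f"/jointset/{name}/{name}_child_offset"
        ET.SubElement(f, "translational_stiffness").text = _vec(
            bushing.props.translational_stiffness
        )
        ET.SubElement(f, "rotational_stiffness").text = _vec(
            bushing.props.rotational_stiffness
        )
        ET.SubElement(f, "translational_damping").text = _vec(
            bushing.props.translational_damping
        )
        ET.SubElement(f, "rotational_damping").text = _vec(
            bushing.props.rotational_damping
        )
    for mp in model.muscle_paths:
        pa = ET.SubElement(fs_objects, "PathActuator", name=mp.name)
        gp = ET.SubElement(pa, "GeometryPath", name="path")
        pps = ET.SubElement(gp, "PathPointSet")
        pp_objects = ET.SubElement(pps, "objects")
        for i, (bone, local) in enumerate(mp.points, start=1):
            pp = ET.SubElement(pp_objects, "PathPoint", name=f"{mp.name}_p{i}")
            ET.SubElement(pp, "socket_parent_frame").text = f"/bodyset/{bone.lower()}"
            ET.SubElement(pp, "location").text = _vec(local, _MM)

    marker_set = ET.SubElement(mdl, "MarkerSet", name="markerset")
    ms_objects = ET.SubElement(marker_set, "objects")
    for name in sorted(model.bodies):
        body = model.bodies[name]
        for code in sorted(body.markers):
            m = ET.SubElement(ms_objects, "Marker", name=f"{name}_{code}")
            ET.SubElement(m, "socket_parent_frame").text = f"/bodyset/{name.lower()}"
            ET.SubElement(m, "location").text = _vec(body.markers[code], _MM)

    ET.indent(root)
    ET.ElementTree(root).write(path, encoding="unicode", xml_declaration=True)


_OSIM_REQUIRED = {
    "Body": ("mass",),
    "CustomJoint": ("coordinates", "frames", "SpatialTransform"),
    "BushingForce": (
        "translational_stiffness",
        "rotational_stiffness",
        "translational_damping",
        "rotational_damping",
    ),
    "WrapSphere": ("translation", "radius"),
    "PathPoint": ("socket_parent_frame", "location"),
    "Marker": ("socket_parent_frame", "location"),
}


def validate_osim(path) -> bool:
    """Structural validation of a written osim file against the dialect.

    Checks the document skeleton (Model with BodySet/JointSet/ForceSet) and
    that every element of a known type carries its required children; each
    CustomJoint must declare exactly six coordinates.  Raises ``ValueError``
    on the first violation, returns True otherwise.
    """
    root = ET.parse(path).getroot()
    if root.tag != "OpenSimDocument":
        raise ValueError("root element must be OpenSimDocument")
    mdl = root.find("Model")
    if mdl is None:
        raise ValueError("missing Model element")
    for section in ("BodySet", "JointSet", "ForceSet"):
        if mdl.find(section) is None:
            raise ValueError(f"missing {section}")
    for elem in mdl.iter():
        required = _OSIM_REQUIRED.get(elem.tag)
        if required:
            for child in required:
                if elem.find(child) is None:
                    raise ValueError(f"{elem.tag} {elem.get('name')} missing {child}")
        if elem.tag == "CustomJoint":
            n = len(elem.find("coordinates").findall("Coordinate"))
            if n != 6:
                raise ValueError(
                    f"CustomJoint {elem.get('name')} has {n} coordinates, expected 6"
                )
    return True
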