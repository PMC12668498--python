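"""Model-accuracy metrics: vertebral-centre errors, curvature polynomials,
Cobb angle, lumbar lordosis and apex detection.

Vertebral centres are estimated by fitting spheres to the anterior surface of
each vertebral-body mesh and are expressed relative to the centre of L5,
which serves as the common reference of model and ground truth.  Curvature is
summarised by 4th-order polynomials of the in-plane offset (AP for the
sagittal plane, RL for the frontal plane) as a function of the IS coordinate.

Angle conventions: the sagittal pitch of a direction ``v`` is
``atan2(v_y, v_x)`` (positive above the horizontal); lumbar lordosis is the
sacral slope minus the pitch of L1's anterior axis, positive for a lordotic
(extended) configuration.  The Cobb angle is the frontal-plane projected
angle between the right-left axes of the two end-vertebra frames and is
always reported >= 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (
    InsufficientLevelsError,
    LevelMismatchError,
    MissingFrameError,
    MissingL5Error,
)
from .geometry import BodyFrame, TriMesh, fit_sphere, select_anterior_nodes
from .landmarks import BONES

_LEVEL_ORDER = {b: i for i, b in enumerate(BONES)}


def _sorted_levels(levels) -> list[str]:
    return sorted(levels, key=lambda b: _LEVEL_ORDER[b])


@dataclass
class CentreSet:
    """Per-vertebra centres (mm) expressed relative to the centre of L5."""

    centres: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if "L5" not in self.centres:
            raise MissingL5Error("CentreSet requires an L5 entry")
        l5 = np.asarray(self.centres["L5"], dtype=float)
        self.centres = {
            lvl: np.asarray(c, dtype=float) - l5 for lvl, c in self.centres.items()
        }

    def levels(self) -> list[str]:
        return _sorted_levels(self.centres)

    def __getitem__(self, level: str) -> np.ndarray:
        return self.centres[level]

    def as_array(self) -> tuple[list[str], np.ndarray]:
        levels = self.levels()
        return levels, np.array([self.centres[lvl] for lvl in levels])


def extract_centres(
    meshes: dict[str, TriMesh],
    hints: dict[str, BodyFrame] | None = None,
    fraction: float = 0.35,
) -> CentreSet:
    """Sphere-fit centres of vertebral-body meshes, relative to L5.

    ``hints`` supplies per-level body frames used to pick the anterior
    surface; identity frames are assumed where absent.
    """
    if "L5" not in meshes:
        raise MissingL5Error("L5 mesh required as reference")
    hints = hints or {}
    centres: dict[str, np.ndarray] = {}
    for level, mesh in meshes.items():
        hint = hints.get(level, BodyFrame.identity())
        idx = select_anterior_nodes(mesh, hint, fraction=fraction)
        centres[level] = fit_sphere(mesh.vertices[idx]).centre
    return CentreSet(centres)


@dataclass
class CentreErrorReport:
    """Per-level absolute errors and pooled summaries, both in mm."""

    per_level: pd.DataFrame  # index level; columns ap, is, rl, euclidean
    summary: pd.DataFrame  # index median, iqr, rmse; same columns


def centre_errors(model_cs: CentreSet, truth_cs: CentreSet) -> CentreErrorReport:
    """Absolute per-axis and Euclidean centre errors, with pooled summaries."""
    if set(model_cs.centres) != set(truth_cs.centres):
        raise LevelMismatchError(
            f"level sets differ: {sorted(model_cs.centres)} vs {sorted(truth_cs.centres)}"
        )
    levels = model_cs.levels()
    delta = np.array([model_cs[lvl] - truth_cs[lvl] for lvl in levels])
    abs_err = np.abs(delta)
    eucl = np.linalg.norm(delta, axis=1)
    per_level = pd.DataFrame(
        np.column_stack([abs_err, eucl]),
        index=levels,
        columns=["ap", "is", "rl", "euclidean"],
    )
    summary = pd.DataFrame(
        {
            col: {
                "median": per_level[col].median(),
                "iqr": per_level[col].quantile(0.75) - per_level[col].quantile(0.25),
                "rmse": float(np.sqrt(np.mean(per_level[col] ** 2))),
            }
            for col in per_level.columns
        }
    ).loc[["median", "iqr", "rmse"]]
    return CentreErrorReport(per_level=per_level, summary=summary)


@dataclass
class CurvatureMetrics:
    """4th-order polynomial curvature fit in one anatomical plane."""

    plane: str  # 'sagittal' or 'frontal'
    coefficients: np.ndarray  # highest power first (numpy polyfit order)
    rmse: float
    r2: float
    adj_r2: float
    cobb_deg: float | None = None
    ll_deg: float | None = None
    apex_level: str | None = None


def fit_curvature(cs: CentreSet, plane: str, order: int = 4) -> CurvatureMetrics:
    """Least-squares polynomial of in-plane offset versus IS coordinate.

    Sagittal plane: AP offset vs IS; frontal plane: RL offset vs IS.
    Needs at least ``order + 2`` levels so that fit quality is measurable.
    """
    if plane not in ("sagittal", "frontal"):
        raise ValueError("plane must be 'sagittal' or 'frontal'")
    levels, arr = cs.as_array()
    if len(levels) < order + 2:
        raise InsufficientLevelsError(
            f"need >= {order + 2} levels for an order-{order} fit, got {len(levels)}"
        )
    y_is = arr[:, 1]
    offset = arr[:, 0] if plane == "sagittal" else arr[:, 2]
    coeffs = np.polyfit(y_is, offset, order)
    pred = np.polyval(coeffs, y_is)
    resid = offset - pred
    rmse = float(np.sqrt(np.mean(resid**2)))
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((offset - offset.mean()) ** 2))
    r2 = 1.0 if ss_tot < 1e-24 else 1.0 - ss_res / ss_tot
    n = len(levels)
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - order - 1)
    return CurvatureMetrics(
        plane=plane, coefficients=coeffs, rmse=rmse, r2=r2, adj_r2=adj_r2
    )


def _frame_of(model, level: str) -> BodyFrame:
    try:
        frame = model.body_frame(level)
    except KeyError as exc:
        raise MissingFrameError(str(exc)) from None
    if frame is None:
        raise MissingFrameError(f"no body frame for {level}")
    return frame


def cobb_from_frames(upper: BodyFrame, lower: BodyFrame) -> float:
    """Frontal-plane projected angle (deg, >= 0) between the RL axes."""
    angles = []
    for frame in (upper, lower):
        rl = frame.rl
        proj = np.array([rl[1], rl[2]])  # (IS, RL) components
        if np.linalg.norm(proj) < 1e-9:
            raise MissingFrameError("RL axis perpendicular to the frontal plane")
        angles.append(math.atan2(proj[0], proj[1]))
    diff = angles[0] - angles[1]
    diff = (diff + math.pi) % (2 * math.pi) - math.pi
    return abs(math.degrees(diff))


def cobb_angle(model, upper: str = "T12", lower: str = "L4") -> float:
    """Cobb angle of the main curve from the end-vertebra body frames."""
    return cobb_from_frames(_frame_of(model, upper), _frame_of(model, lower))


def sagittal_pitch_deg(direction: np.ndarray) -> float:
    """Pitch of a direction above the horizontal, in the sagittal plane."""
    return math.degrees(math.atan2(direction[1], direction[0]))


def lordosis_from_frame(l1_frame: BodyFrame, sacral_slope_deg: float) -> float:
    """Lumbar lordosis (deg): sacral slope minus the pitch of L1's AP axis."""
    return sacral_slope_deg - sagittal_pitch_deg(l1_frame.ap)


def lumbar_lordosis(model, sacral_slope_deg: float, level: str = "L1") -> float:
    """Lumbar lordosis from the sacral slope and the L1 body frame.

    Positive values are lordotic (extension); a kyphotic configuration of the
    lumbar segment yields a negative angle.
    """
    return lordosis_from_frame(_frame_of(model, level), sacral_slope_deg)


def find_apex(cs: CentreSet, reference: np.ndarray) -> str:
    """Level with the largest right-left displacement from the reference axis.

    ``reference`` must be expressed in the same (relative-to-L5) frame as the
    centre set; the displacement is measured from the vertical line through
    it, as the scoliotic apex is a frontal-plane concept.  Ties break toward
    the most caudal level.
    """
    ref_rl = float(np.asarray(reference, dtype=float)[2])
    best_level, best_disp = None, -np.inf
    for level in cs.levels():  # cranial -> caudal, so later levels win ties
        disp = abs(float(cs[level][2]) - ref_rl)
        if disp >= best_disp - 1e-12:
            best_level, best_disp = level, max(disp, best_disp)
    return best_level
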