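"""Geometric primitives: sphere fitting, anterior-node selection, body frames.

Conventions
-----------
All coordinates are millimetres.  The model frame is +X anterior, +Y superior
(inferior->superior), +Z toward the subject's right.  A :class:`BodyFrame`
stores its axes as the columns (AP, IS, RL) of an orthonormal right-handed
matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh as _trimesh
from scipy.optimize import least_squares

from .errors import (
    ConvergenceError,
    CoplanarPointsError,
    DegenerateFrameError,
    DegenerateSelectionError,
)

_ORTHO_TOL = 1e-9


@dataclass(frozen=True)
class Sphere:
    """A fitted sphere: centre (mm), radius (mm) and RMS fit residual (mm)."""

    centre: np.ndarray
    radius: float
    rms_residual: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "centre", np.asarray(self.centre, dtype=float))
        if not self.radius > 0:
            raise ValueError("sphere radius must be positive")
        if self.rms_residual < 0:
            raise ValueError("rms residual must be non-negative")


@dataclass(frozen=True)
class BodyFrame:
    """Origin (mm) plus orthonormal axes with columns (AP, IS, RL)."""

    origin: np.ndarray
    axes: np.ndarray

    def __post_init__(self) -> None:
        origin = np.asarray(self.origin, dtype=float)
        axes = np.asarray(self.axes, dtype=float)
        object.__setattr__(self, "origin", origin)
        object.__setattr__(self, "axes", axes)
        if axes.shape != (3, 3):
            raise ValueError("axes must be 3x3")
        if not np.allclose(axes.T @ axes, np.eye(3), atol=1e-8):
            raise ValueError("axes must be orthonormal")
        if np.linalg.det(axes) < 0:
            raise ValueError("axes must be right-handed")

    @property
    def ap(self) -> np.ndarray:
        return self.axes[:, 0]

    @property
    def is_(self) -> np.ndarray:
        return self.axes[:, 1]

    @property
    def rl(self) -> np.ndarray:
        return self.axes[:, 2]

    @staticmethod
    def identity(origin=(0.0, 0.0, 0.0)) -> "BodyFrame":
        return BodyFrame(np.asarray(origin, dtype=float), np.eye(3))


@dataclass
class TriMesh:
    """Triangle mesh (vertices in mm).  Thin wrapper over :mod:`trimesh`.

    Degenerate (zero-area) faces are dropped at construction.
    """

    vertices: np.ndarray
    faces: np.ndarray
    _cache: object = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if self.faces.size and self.faces.max() >= len(self.vertices):
            raise ValueError("face index out of range")
        if self.faces.size:
            v = self.vertices
            a = v[self.faces[:, 1]] - v[self.faces[:, 0]]
            b = v[self.faces[:, 2]] - v[self.faces[:, 0]]
            areas = 0.5 * np.linalg.norm(np.cross(a, b), axis=1)
            self.faces = self.faces[areas > 1e-12]
        self._cache = None

    def _tm(self) -> _trimesh.Trimesh:
        if self._cache is None:
            self._cache = _trimesh.Trimesh(
                vertices=self.vertices, faces=self.faces, process=False
            )
        return self._cache

    @property
    def vertex_normals(self) -> np.ndarray:
        return np.asarray(self._tm().vertex_normals)

    @staticmethod
    def from_stl(path) -> "TriMesh":
        """Load an STL file (binary or ASCII), welding coincident vertices."""
        tm = _trimesh.load_mesh(str(path), file_type="stl", process=True)
        tm.merge_vertices(merge_tex=True, merge_norm=True)
        return TriMesh(np.asarray(tm.vertices), np.asarray(tm.faces))

    def to_stl(self, path) -> None:
        self._tm().export(str(path), file_type="stl_ascii")

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "TriMesh":
        """Return a rigidly transformed copy: v -> R v + t."""
        r = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        return TriMesh(self.vertices @ r.T + t, self.faces.copy())


def surface_distance(mesh: TriMesh, points: np.ndarray) -> np.ndarray:
    """Distance of each point to the mesh surface (brute force over faces)."""
    import trimesh.triangles as _tt

    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    tris = mesh.vertices[mesh.faces]
    out = np.empty(len(pts))
    for i, p in enumerate(pts):
        closest = _tt.closest_point(tris, np.tile(p, (len(tris), 1)))
        out[i] = np.linalg.norm(closest - p, axis=1).min()
    return out


def select_anterior_nodes(
    mesh: TriMesh, frame_hint: BodyFrame, fraction: float = 0.35
) -> np.ndarray:
    """Indices of vertices on the anterior surface of a vertebral body.

    A vertex is selected when its anterior (AP) coordinate in ``frame_hint``
    exceeds the ``1 - fraction`` quantile over the whole mesh and its outward
    normal has a positive AP component.  This is a deterministic surrogate for
    the manual picking of anterior vertebral-body nodes prior to sphere
    fitting.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    if len(mesh.vertices) == 0:
        raise DegenerateSelectionError("empty mesh")
    ap_dir = frame_hint.ap
    ap_coord = (mesh.vertices - frame_hint.origin) @ ap_dir
    threshold = np.quantile(ap_coord, 1.0 - fraction)
    normals = mesh.vertex_normals
    sel = np.flatnonzero((ap_coord >= threshold) & (normals @ ap_dir > 0))
    if sel.size < 10:
        raise DegenerateSelectionError(
            f"anterior selection produced only {sel.size} vertices (need >= 10)"
        )
    return sel


def _kasa_fit(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Algebraic (Kåsa) sphere fit used to initialise the geometric fit."""
    a = np.column_stack([2.0 * points, np.ones(len(points))])
    b = (points**2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(a, b, rcond=None)
    centre = sol[:3]
    r2 = sol[3] + centre @ centre
    if r2 <= 0:
        raise CoplanarPointsError("algebraic fit produced non-positive radius")
    return centre, float(np.sqrt(r2))


def fit_sphere(points: np.ndarray, max_iter: int = 200) -> Sphere:
    """Geometric least-squares sphere fit.

    Minimises ``sum_i (||p_i - c|| - r)^2`` (true orthogonal distances), with
    the algebraic Kåsa solution as the initial guess, refined by
    Levenberg-Marquardt-style least squares (relative tolerance 1e-10).

    Raises
    ------
    CoplanarPointsError
        If fewer than four points are given or the points are (near-)coplanar.
    ConvergenceError
        If the refinement does not converge.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(pts) < 4:
        raise CoplanarPointsError("need at least 4 points to fit a sphere")
    centred = pts - pts.mean(axis=0)
    svals = np.linalg.svd(centred, compute_uv=False)
    if svals[2] < 1e-9 * max(svals[0], 1.0):
        raise CoplanarPointsError("points are coplanar to working precision")

    c0, r0 = _kasa_fit(pts)

    def residuals(params: np.ndarray) -> np.ndarray:
        c, r = params[:3], params[3]
        return np.linalg.norm(pts - c, axis=1) - r

    result = least_squares(
        residuals,
        np.append(c0, r0),
        method="lm",
        xtol=1e-12,
        ftol=1e-10,
        gtol=1e-12,
        max_nfev=max_iter * 5,
    )
    if not result.success:
        raise ConvergenceError(f"sphere fit did not converge: {result.message}")
    centre, radius = result.x[:3], float(result.x[3])
    if radius < 0:  # radius sign is a gauge freedom of the residual
        radius = -radius
    rms = float(np.sqrt(np.mean(result.fun**2)))
    return Sphere(centre=centre, radius=radius, rms_residual=rms)


def _normalise(v: np.ndarray, what: str) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise DegenerateFrameError(f"{what} direction has zero length")
    return v / n


def frame_from_landmarks(
    sup_mean, inf_mean, sup_ant, sup_post, inf_ant, inf_post
) -> BodyFrame:
    """Vertebral body frame from endplate landmarks.

    IS is the unit vector from the inferior-endplate mean to the
    superior-endplate mean; the provisional AP direction is the mean of the
    posterior->anterior midline vectors of the two endplates; RL completes the
    right-handed triad and AP is re-orthogonalised against IS (IS is kept
    exact, mirroring its priority in the frame definition).  The origin is the
    midpoint of the two endplate means.
    """
    sup_mean = np.asarray(sup_mean, dtype=float)
    inf_mean = np.asarray(inf_mean, dtype=float)
    is_axis = _normalise(sup_mean - inf_mean, "inferior-superior")
    ap0 = 0.5 * (
        np.asarray(sup_ant, dtype=float) - np.asarray(sup_post, dtype=float)
    ) + 0.5 * (np.asarray(inf_ant, dtype=float) - np.asarray(inf_post, dtype=float))
    ap0 = _normalise(ap0, "anterior-posterior")
    if abs(ap0 @ is_axis) > 1.0 - 1e-9:
        raise DegenerateFrameError("AP candidate parallel to IS axis")
    rl = _normalise(np.cross(ap0, is_axis), "right-left")
    ap = np.cross(is_axis, rl)  # unit by construction, exactly orthogonal
    axes = np.column_stack([ap, is_axis, rl])
    origin = 0.5 * (sup_mean + inf_mean)
    return BodyFrame(origin=origin, axes=axes)
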