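"""Virtually palpated anatomical landmark sets.

A palpation protocol assigns 14 landmarks to every vertebra: eight scaling
landmarks (S1-S8) on the endplate extremes and six joint landmarks (JM1-JM6)
on the pedicles and endplate centres, plus two sacral-promontory landmarks
(SP_ANT, SP_POST) on the sacrum.  The code-to-anatomy mapping used throughout
the package is:

========  ==================================================
code      anatomical location
========  ==================================================
S1 / S2   anterior- / posterior-most point, superior endplate
S3 / S4   anterior- / posterior-most point, inferior endplate
S5 / S6   right- / left-most point, superior endplate
S7 / S8   right- / left-most point, inferior endplate
JM1 / JM2 right pedicle top / base
JM3 / JM4 left pedicle top / base
JM5 / JM6 superior / inferior endplate centre
========  ==================================================

Users whose palpation protocol orders the codes differently can remap codes
before constructing a :class:`LandmarkSet`.

File format: whitespace- or comma-delimited rows ``bone code x y z`` (mm),
``#`` comments allowed, with an optional ``# axes: <code>`` header declaring
the source (CT) axis convention as three letters from {A,P,S,I,R,L} giving
the anatomical direction of the file's +X, +Y, +Z axes.  The model frame is
``ASR`` (+X anterior, +Y superior, +Z right).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .errors import (
    DuplicateError,
    MissingApexError,
    ParseError,
    VocabularyError,
)

VERTEBRA_LEVELS: tuple[str, ...] = tuple(
    [f"T{i}" for i in range(1, 13)] + [f"L{i}" for i in range(1, 6)]
)
#: All bone labels, ordered cranial -> caudal.
BONES: tuple[str, ...] = VERTEBRA_LEVELS + ("SACRUM", "PELVIS")

SCALING_CODES: tuple[str, ...] = tuple(f"S{i}" for i in range(1, 9))
JOINT_CODES: tuple[str, ...] = tuple(f"JM{i}" for i in range(1, 7))
SACRAL_CODES: tuple[str, ...] = ("SP_ANT", "SP_POST")
VERTEBRA_CODES: tuple[str, ...] = SCALING_CODES + JOINT_CODES
ALL_CODES: frozenset[str] = frozenset(VERTEBRA_CODES + SACRAL_CODES)

#: Landmarks required for a vertebra to count as complete.
REQUIRED_PER_VERTEBRA = 14

MODEL_AXES_CODE = "ASR"
_AXIS_DIRECTIONS: Mapping[str, np.ndarray] = {
    "A": np.array([1.0, 0.0, 0.0]),
    "P": np.array([-1.0, 0.0, 0.0]),
    "S": np.array([0.0, 1.0, 0.0]),
    "I": np.array([0.0, -1.0, 0.0]),
    "R": np.array([0.0, 0.0, 1.0]),
    "L": np.array([0.0, 0.0, -1.0]),
}


def axes_code_rotation(code: str) -> np.ndarray:
    """Rotation taking coordinates in axis convention ``code`` to model axes.

    ``code`` is three letters, e.g. ``"RAS"`` meaning the file's +X points to
    the subject's right, +Y anterior, +Z superior.  The three letters must
    name orthogonal directions.
    """
    code = code.strip().upper()
    if len(code) != 3 or any(c not in _AXIS_DIRECTIONS for c in code):
        raise VocabularyError(f"invalid axes code {code!r}")
    cols = [_AXIS_DIRECTIONS[c] for c in code]
    r = np.column_stack(cols)
    if abs(abs(np.linalg.det(r)) - 1.0) > 1e-12 or np.linalg.det(r) < 0:
        raise VocabularyError(
            f"axes code {code!r} is not a right-handed orthogonal triple"
        )
    return r


@dataclass(frozen=True)
class Landmark:
    """A named anatomical point on one bone, in millimetres."""

    bone: str
    name: str
    position: np.ndarray

    def __post_init__(self) -> None:
        if self.bone not in BONES:
            raise VocabularyError(f"unknown bone label {self.bone!r}")
        if self.name not in ALL_CODES:
            raise VocabularyError(f"unknown landmark code {self.name!r}")
        pos = np.asarray(self.position, dtype=float).reshape(3)
        if not np.all(np.isfinite(pos)):
            raise ValueError(f"non-finite position for {self.bone} {self.name}")
        object.__setattr__(self, "position", pos)


@dataclass(frozen=True)
class FrameTransform:
    """Rigid transform ``x -> R x + t`` (rotation orthonormal, det +1)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.allclose(r.T @ r, np.eye(3), atol=1e-9):
            raise ValueError("rotation must be orthonormal within 1e-9")
        if np.linalg.det(r) < 0:
            raise ValueError("rotation must be proper (det +1)")
        object.__setattr__(self, "rotation", r)
        object.__setattr__(self, "translation", t)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.rotation.T + self.translation

    def inverse(self) -> "FrameTransform":
        return FrameTransform(self.rotation.T, -self.rotation.T @ self.translation)


class LandmarkSet:
    """A collection of landmarks with at most one landmark per (bone, code)."""

    def __init__(self, landmarks: Iterable[Landmark], frame: str = "CT") -> None:
        if frame not in ("CT", "MODEL"):
            raise ValueError("frame must be 'CT' or 'MODEL'")
        self.frame = frame
        self._by_key: dict[tuple[str, str], Landmark] = {}
        for lm in landmarks:
            key = (lm.bone, lm.name)
            if key in self._by_key:
                raise DuplicateError(f"duplicate landmark {lm.bone} {lm.name}")
            self._by_key[key] = lm

    def __len__(self) -> int:
        return len(self._by_key)

    def __iter__(self):
        return iter(self.landmarks())

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in self._by_key

    def landmarks(self) -> list[Landmark]:
        """Landmarks in canonical order (bone cranial->caudal, then code)."""
        order = {b: i for i, b in enumerate(BONES)}
        code_order = {c: i for i, c in enumerate(VERTEBRA_CODES + SACRAL_CODES)}
        return sorted(
            self._by_key.values(),
            key=lambda lm: (order[lm.bone], code_order[lm.name]),
        )

    def get(self, bone: str, code: str) -> np.ndarray:
        try:
            return self._by_key[(bone, code)].position
        except KeyError:
            raise KeyError(f"landmark {bone} {code} not present") from None

    def bones(self) -> list[str]:
        present = {lm.bone for lm in self._by_key.values()}
        return [b for b in BONES if b in present]

    def codes(self, bone: str) -> list[str]:
        return [lm.name for lm in self.landmarks() if lm.bone == bone]

    def positions(self) -> np.ndarray:
        return np.array([lm.position for lm in self.landmarks()])

    def complete(self, bone: str) -> bool:
        return all((bone, c) in self._by_key for c in VERTEBRA_CODES)

    def subset(self, bones: Iterable[str]) -> "LandmarkSet":
        keep = set(bones)
        return LandmarkSet(
            [lm for lm in self._by_key.values() if lm.bone in keep], frame=self.frame
        )

    def transformed(self, t: FrameTransform, frame: str | None = None) -> "LandmarkSet":
        return LandmarkSet(
            [
                Landmark(lm.bone, lm.name, t.apply(lm.position))
                for lm in self._by_key.values()
            ],
            frame=frame or self.frame,
        )

    def to_file(self, path, axes: str = MODEL_AXES_CODE) -> None:
        """Serialise in canonical order (byte-stable for a given set)."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# axes: {axes}\n")
            for lm in self.landmarks():
                x, y, z = lm.position
                fh.write(f"{lm.bone} {lm.name} {x:.9g} {y:.9g} {z:.9g}\n")


@dataclass(frozen=True)
class CompletenessReport:
    """Per-level missing landmark codes and an overall verdict."""

    ok: bool
    missing: dict[str, list[str]]
    required_per_vertebra: int = REQUIRED_PER_VERTEBRA

    def __str__(self) -> str:
        if self.ok:
            return "complete: 14 landmarks (8 scaling + 6 joint) per vertebra"
        lines = [f"{lvl}: missing {', '.join(codes)}" for lvl, codes in self.missing.items()]
        return "incomplete:\n" + "\n".join(lines)


_ROW_RE = re.compile(r"[,\s]+")


def parse_landmark_file(path) -> LandmarkSet:
    """Parse a landmark text file into a :class:`LandmarkSet` (CT frame).

    Rows are ``bone code x y z``; an optional ``# axes: <code>`` header
    declares the CT axis convention (default: model axes).  The axes code is
    attached to the returned set as ``.axes_code``.
    """
    landmarks: list[Landmark] = []
    axes_code = MODEL_AXES_CODE
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                m = re.match(r"#\s*axes\s*:\s*(\S+)", line, flags=re.IGNORECASE)
                if m:
                    axes_code = m.group(1).upper()
                continue
            fields = _ROW_RE.split(line)
            if len(fields) != 5:
                raise ParseError(f"{path}:{lineno}: expected 5 fields, got {len(fields)}")
            bone, code = fields[0].upper(), fields[1].upper()
            try:
                xyz = [float(v) for v in fields[2:5]]
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad coordinate: {exc}") from None
            try:
                lm = Landmark(bone, code, np.array(xyz))
            except VocabularyError as exc:
                raise VocabularyError(f"{path}:{lineno}: {exc}") from None
            landmarks.append(lm)
    ls = LandmarkSet(landmarks, frame="CT")
    ls.axes_code = axes_code  # type: ignore[attr-defined]
    return ls


def validate_completeness(ls: LandmarkSet, levels: Iterable[str]) -> CompletenessReport:
    """Report, per requested level, which of the 14 required codes are missing."""
    missing: dict[str, list[str]] = {}
    for level in levels:
        if level not in BONES:
            raise VocabularyError(f"unknown bone label {level!r}")
        absent = [c for c in VERTEBRA_CODES if (level, c) not in ls]
        if absent:
            missing[level] = absent
    return CompletenessReport(ok=not missing, missing=missing)


def align_to_model_frame(
    ls: LandmarkSet,
    sacral_apex_ct: np.ndarray | None,
    axes_code: str | None = None,
) -> tuple[LandmarkSet, FrameTransform]:
    """Re-express a CT-frame landmark set in the model frame.

    The rotation maps the CT axis convention (``axes_code``, or the code
    attached by :func:`parse_landmark_file`, default model axes) onto the
    model convention (+X anterior, +Y superior, +Z right); the translation
    places the sacral apex at the origin.  The transform is rigid, so all
    inter-landmark distances are preserved.
    """
    if sacral_apex_ct is None:
        raise MissingApexError("sacral apex position is required for alignment")
    code = axes_code or getattr(ls, "axes_code", MODEL_AXES_CODE)
    rotation = axes_code_rotation(code)
    apex = np.asarray(sacral_apex_ct, dtype=float).reshape(3)
    transform = FrameTransform(rotation, -rotation @ apex)
    aligned = ls.transformed(transform, frame="MODEL")
    return aligned, transform
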