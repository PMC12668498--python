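"""Template bundle: the generic straight-spine assets consumed by the builder.

A bundle provides, per body, a surface mesh in body-local coordinates, the
template landmark (marker) positions in the same frame, a mass, and the
body-origin position in the template's global frame, plus muscle attachment
chains.  The packaged schematic template is produced parametrically by
:mod:`scolimorph.synthetic`; ``TemplateBundle.load`` accepts a directory of
real landmark/mesh files laid out the same way as ``TemplateBundle.save``
writes them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import TemplateError
from .geometry import TriMesh

SACRUM = "SACRUM"
PELVIS = "PELVIS"


@dataclass
class TemplateBody:
    """One body of the template, in body-local millimetre coordinates."""

    name: str
    mass: float
    mesh: TriMesh | None
    landmarks: dict[str, np.ndarray]
    origin: np.ndarray  # body origin in template global frame
    posterior_start: int | None = None  # first posterior-element vertex index


@dataclass
class MusclePath:
    """Ordered muscle attachment chain; each point is (body name, local xyz)."""

    name: str
    points: list[tuple[str, np.ndarray]] = field(default_factory=list)


@dataclass
class TemplateBundle:
    """Bodies (vertebrae + sacrum + pelvis), muscle chains and metadata."""

    levels: list[str]  # vertebral levels, cranial -> caudal
    bodies: dict[str, TemplateBody]
    muscle_paths: list[MusclePath]
    sacral_slope_deg: float
    sacral_apex: np.ndarray  # template global frame

    @property
    def total_mass(self) -> float:
        return float(sum(b.mass for b in self.bodies.values()))

    def validate(self) -> None:
        for name in self.levels + [SACRUM, PELVIS]:
            if name not in self.bodies:
                raise TemplateError(f"template missing body {name!r}")
        for level in self.levels:
            body = self.bodies[level]
            if body.mesh is None:
                raise TemplateError(f"template body {level} has no mesh")
            if not body.landmarks:
                raise TemplateError(f"template body {level} has no landmarks")
        sac = self.bodies[SACRUM]
        for code in ("SP_ANT", "SP_POST"):
            if code not in sac.landmarks:
                raise TemplateError(f"template sacrum missing landmark {code}")

    # -- persistence --------------------------------------------------------

    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        meta = {
            "levels": self.levels,
            "sacral_slope_deg": self.sacral_slope_deg,
            "sacral_apex": self.sacral_apex.tolist(),
            "bodies": {},
            "muscle_paths": [
                {
                    "name": mp.name,
                    "points": [[b, p.tolist()] for b, p in mp.points],
                }
                for mp in self.muscle_paths
            ],
        }
        for name, body in self.bodies.items():
            meta["bodies"][name] = {
                "mass": body.mass,
                "origin": body.origin.tolist(),
                "posterior_start": body.posterior_start,
                "landmarks": {c: p.tolist() for c, p in body.landmarks.items()},
                "mesh": f"{name}.stl" if body.mesh is not None else None,
            }
            if body.mesh is not None:
                body.mesh.to_stl(d / f"{name}.stl")
        (d / "template.json").write_text(json.dumps(meta, indent=1, sort_keys=True))

    @classmethod
    def load(cls, directory) -> "TemplateBundle":
        d = Path(directory)
        meta_path = d / "template.json"
        if not meta_path.exists():
            raise TemplateError(f"no template.json in {d}")
        meta = json.loads(meta_path.read_text())
        bodies: dict[str, TemplateBody] = {}
        for name, info in meta["bodies"].items():
            mesh = None
            if info.get("mesh"):
                mesh = TriMesh.from_stl(d / info["mesh"])
            bodies[name] = TemplateBody(
                name=name,
                mass=float(info["mass"]),
                mesh=mesh,
                landmarks={c: np.asarray(p, float) for c, p in info["landmarks"].items()},
                origin=np.asarray(info["origin"], float),
                posterior_start=info.get("posterior_start"),
            )
        bundle = cls(
            levels=list(meta["levels"]),
            bodies=bodies,
            muscle_paths=[
                MusclePath(
                    name=mp["name"],
                    points=[(b, np.asarray(p, float)) for b, p in mp["points"]],
                )
                for mp in meta["muscle_paths"]
            ],
            sacral_slope_deg=float(meta["sacral_slope_deg"]),
            sacral_apex=np.asarray(meta["sacral_apex"], float),
        )
        bundle.validate()
        return bundle
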