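"""Planar four-segment lower-limb model: geometry, inertia, markers, muscles.

The chain is pelvis -> thigh -> shank -> foot with three revolute joints
(hip, knee, ankle) plus two pelvis translation degrees of freedom.  The
pelvis lumps every body part proximal to the analyzed leg, so the segment
mass fractions of the whole chain sum to one.

Conventions (right-handed, sagittal plane):
  * +x is the approach direction, +y is up, rotations are CCW-positive.
  * Knee flexion is positive with 0 deg at full extension; hip flexion and
    ankle dorsiflexion rotate the distal segment forward (+x).
  * Segment-local frames have their origin at the proximal joint; at the
    reference pose (all angles zero) thigh and shank hang along -y and the
    foot points along +x.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .errors import ModelError
from .muscle_forces import MuscleSpec
from .pfj_model import PatellarMechanism
from .resources import default_path

SEGMENT_ORDER = ("pelvis", "thigh", "shank", "foot")
JOINTS = ("hip", "knee", "ankle")
#: q-vector layout used throughout: pelvis translation then joint angles (deg).
DOFS = ("pelvis_x", "pelvis_y", "hip", "knee", "ankle")


@dataclass(frozen=True)
class Segment:
    name: str
    length: float           # m
    mass: float             # kg
    com_offset: tuple[float, float]  # fractions of length, segment-local
    inertia: float          # kg m^2 about the segment COM

    @property
    def com_fraction(self) -> float:
        return float(np.hypot(*self.com_offset))


@dataclass
class PlanarModel:
    """Scaled planar model for one participant."""

    segments: dict[str, Segment]
    marker_map: dict[str, tuple[str, tuple[float, float]]]  # name -> (segment, offset fracs)
    marker_weights: dict[str, float]
    muscles: list[MuscleSpec]
    mechanism: PatellarMechanism
    body_mass: float
    height: float
    ankle_height: float
    gravity: float = 9.81
    source_version: int = 0
    _ref: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.validate()

    # -- validation -------------------------------------------------------

    def validate(self) -> None:
        for name in SEGMENT_ORDER:
            if name not in self.segments:
                raise ModelError(f"missing segment {name!r}")
            seg = self.segments[name]
            if seg.length <= 0 or seg.mass <= 0:
                raise ModelError(f"segment {name!r}: length and mass must be > 0")
            if not 0.0 <= seg.com_fraction <= 1.0:
                raise ModelError(f"segment {name!r}: COM fraction outside [0, 1]")
        per_segment: dict[str, int] = {}
        for marker, (seg, _) in self.marker_map.items():
            if seg not in self.segments:
                raise ModelError(f"marker {marker!r} attached to unknown segment {seg!r}")
            w = self.marker_weights.get(marker, 1.0)
            if w < 0:
                raise ModelError(f"marker {marker!r}: negative weight")
            if w > 0:
                per_segment[seg] = per_segment.get(seg, 0) + 1
        if any(n < 2 for n in per_segment.values()) or len(per_segment) < len(SEGMENT_ORDER):
            raise ModelError("each segment needs at least 2 positively weighted markers")

    # -- construction -----------------------------------------------------

    @classmethod
    def from_yaml(cls, path=None, *, body_mass: float | None = None,
                  height: float | None = None,
                  mechanism: PatellarMechanism | None = None) -> "PlanarModel":
        """Load a model definition and scale it to the given anthropometry.

        ``path=None`` loads the packaged default definition.
        """
        path = default_path("planar_model.yaml") if path is None else path
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        ref_mass = float(raw["reference"]["body_mass_kg"])
        ref_height = float(raw["reference"]["height_m"])
        body_mass = ref_mass if body_mass is None else float(body_mass)
        height = ref_height if height is None else float(height)
        if body_mass <= 0 or height <= 0:
            raise ModelError("body mass and height must be > 0")

        segments = {}
        for name, spec in raw["segments"].items():
            length = float(spec["length_frac_height"]) * height
            mass = float(spec["mass_frac"]) * body_mass
            rho = float(spec["gyration_frac"]) * length
            segments[name] = Segment(
                name=name, length=length, mass=mass,
                com_offset=tuple(float(v) for v in spec["com_offset"]),
                inertia=mass * rho * rho,
            )
        marker_map = {}
        weights = {}
        for name, spec in raw["markers"].items():
            marker_map[name] = (spec["segment"], tuple(float(v) for v in spec["offset"]))
            weights[name] = float(spec.get("weight", 1.0))
        muscles = [
            MuscleSpec(
                name=name,
                f_max=float(spec["f_max"]),
                arms={j: tuple(float(c) for c in coeffs) for j, coeffs in spec["arms"].items()},
                group=spec.get("group", ""),
                is_quadriceps=bool(spec.get("quadriceps", False)),
            )
            for name, spec in raw["muscles"].items()
        ]
        if mechanism is None:
            mechanism = PatellarMechanism.from_yaml()
        return cls(
            segments=segments,
            marker_map=marker_map,
            marker_weights=weights,
            muscles=muscles,
            mechanism=mechanism,
            body_mass=body_mass,
            height=height,
            ankle_height=float(raw["ankle_height_frac"]) * height,
            gravity=float(raw.get("gravity", 9.81)),
            source_version=int(raw.get("version", 0)),
            _ref={"body_mass_kg": ref_mass, "height_m": ref_height},
        )

    def scaled(self, body_mass: float, height: float) -> "PlanarModel":
        """Return a copy rescaled to new anthropometry.

        COM fractions and mass fractions are preserved: lengths scale with
        height, masses with body mass, inertias with mass * length^2.
        """
        if body_mass <= 0 or height <= 0:
            raise ModelError("body mass and height must be > 0")
        ls = height / self.height
        ms = body_mass / self.body_mass
        segments = {
            name: replace(
                seg,
                length=seg.length * ls,
                mass=seg.mass * ms,
                inertia=seg.inertia * ms * ls * ls,
            )
            for name, seg in self.segments.items()
        }
        out = replace(self, segments=segments, body_mass=body_mass, height=height,
                      ankle_height=self.ankle_height * ls)
        return out

    @property
    def body_weight(self) -> float:
        """Body weight in newtons (mass * g)."""
        return self.body_mass * self.gravity

    # -- forward kinematics ----------------------------------------------

    def pose(self, q: np.ndarray) -> dict:
        """Frame positions/orientations for pose vector(s) ``q``.

        ``q`` has columns (pelvis_x, pelvis_y, hip, knee, ankle), angles in
        degrees, and may be a single pose ``(5,)`` or a trajectory ``(n, 5)``.
        Returns joint positions, segment origins and rotation angles (rad).
        """
        q = np.atleast_2d(np.asarray(q, dtype=float))
        px, py = q[:, 0], q[:, 1]
        hip, knee, ankle = (np.radians(q[:, i]) for i in (2, 3, 4))
        phi = {
            "pelvis": np.zeros_like(px),
            "thigh": hip,
            "shank": hip - knee,
        }
        phi["foot"] = phi["shank"] + ankle
        lt = self.segments["thigh"].length
        lsh = self.segments["shank"].length
        p_hip = np.stack([px, py], axis=1)
        p_knee = p_hip + np.stack([lt * np.sin(phi["thigh"]), -lt * np.cos(phi["thigh"])], axis=1)
        p_ankle = p_knee + np.stack([lsh * np.sin(phi["shank"]), -lsh * np.cos(phi["shank"])], axis=1)
        origins = {"pelvis": p_hip, "thigh": p_hip, "shank": p_knee, "foot": p_ankle}
        return {
            "phi": phi,
            "origins": origins,
            "joints": {"hip": p_hip, "knee": p_knee, "ankle": p_ankle},
        }

    def _local_to_global(self, pose: dict, segment: str,
                         offset_frac: tuple[float, float]) -> np.ndarray:
        seg = self.segments[segment]
        ox, oy = offset_frac[0] * seg.length, offset_frac[1] * seg.length
        phi = pose["phi"][segment]
        c, s = np.cos(phi), np.sin(phi)
        rot = np.stack([c * ox - s * oy, s * ox + c * oy], axis=1)
        return pose["origins"][segment] + rot

    def marker_positions(self, q: np.ndarray,
                         names: list[str] | None = None) -> dict[str, np.ndarray]:
        """Global marker positions ``(n, 2)`` per marker for pose(s) ``q``."""
        pose = self.pose(q)
        names = list(self.marker_map) if names is None else names
        out = {}
        for name in names:
            if name not in self.marker_map:
                raise ModelError(f"unknown marker {name!r} in attachment map")
            seg, off = self.marker_map[name]
            out[name] = self._local_to_global(pose, seg, off)
        return out

    def segment_coms(self, q: np.ndarray) -> dict[str, np.ndarray]:
        """Global segment COM positions ``(n, 2)`` per segment."""
        pose = self.pose(q)
        return {
            name: self._local_to_global(pose, name, self.segments[name].com_offset)
            for name in SEGMENT_ORDER
        }

    def com(self, q: np.ndarray) -> np.ndarray:
        """Whole-chain mass-weighted COM trajectory ``(n, 2)``."""
        coms = self.segment_coms(q)
        total = sum(self.segments[s].mass for s in SEGMENT_ORDER)
        acc = np.zeros_like(coms["pelvis"])
        for name in SEGMENT_ORDER:
            acc += self.segments[name].mass * coms[name]
        return acc / total

    def standing_pelvis_height(self, hip_deg: float, knee_deg: float) -> float:
        """Pelvis height placing the ankle joint at its nominal height."""
        hip = math.radians(hip_deg)
        shank = hip - math.radians(knee_deg)
        return (self.ankle_height
                + self.segments["thigh"].length * math.cos(hip)
                + self.segments["shank"].length * math.cos(shank))
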