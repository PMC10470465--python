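"""Rigid and non-rigid vertex trajectories in the object's native dimension.

Rigid motion is a composition of plane rotations whose angles oscillate
sinusoidally, realising an object that "rocks" back and forth over a
fixed angular range during the 3-s presentation.  In 3D a rotation fixes
a line (the familiar axis); in 4D it fixes a 2D plane and rotates the
complementary coordinate pair — the hypercube stimuli rotate with the
y-z, x-z and x-y planes as invariant (axis) planes.

Non-rigid motion starts from the same rigid backbone and adds two
distance-violating terms: a per-vertex deformation along a fixed random
direction with sinusoidal time course, and a shear that displaces
vertices along one coordinate axis in proportion to a transverse
coordinate.  A small per-vertex jitter (used in the stimuli to enhance
stereoscopy) can be layered on either kind.

Coordinate convention (right-handed as implemented): x runs left to
right, y up to down, z "in to out" (towards the viewer), w is the fourth
dimension.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .geometry import WireframeObject, _from_dict, _to_dict

__all__ = [
    "AXIS_INDEX",
    "RotationPlane",
    "MotionSpec",
    "TrajectorySet",
    "rotation_operator",
    "rigid_pose",
    "nonrigid_pose",
    "generate_trajectory",
    "default_motion_spec",
]

AXIS_INDEX = {"x": 0, "y": 1, "z": 2, "w": 3}
_AXIS_NAME = {v: k for k, v in AXIS_INDEX.items()}

#: transverse coordinate used by the shear, cyclic x -> y -> z -> x
SHEAR_TRANSVERSE = {"x": "y", "y": "z", "z": "x"}


@dataclass(frozen=True)
class RotationPlane:
    """One oscillating plane rotation of the rigid backbone.

    ``invariant`` names the coordinates held fixed: a single axis for 3D
    (e.g. ``"x"``), a coordinate pair for 4D (e.g. ``("x", "y")``, which
    rotates the complementary z-w plane).
    """

    invariant: str | tuple[str, ...]
    amplitude_deg: float = 30.0
    frequency_hz: float = 0.25
    phase_rad: float = 0.0

    def angle_deg(self, t: float | np.ndarray, waveform: str = "sine") -> np.ndarray:
        """Instantaneous rotation angle at time ``t`` (seconds)."""
        arg = 2 * np.pi * self.frequency_hz * np.asarray(t, dtype=float) + self.phase_rad
        if waveform == "sine":
            osc = np.sin(arg)
        elif waveform == "triangle":
            osc = 2 / np.pi * np.arcsin(np.sin(arg))
        else:
            raise ValueError(f"unknown waveform {waveform!r}")
        return self.amplitude_deg * osc


@dataclass(frozen=True)
class MotionSpec:
    """Parameters of one stimulus animation.

    ``kind`` selects rigid or non-rigid motion; a rigid spec must carry
    no shear or deformation.  Amplitudes are in cm except the shear,
    which is a dimensionless gain on the transverse coordinate.
    """

    kind: Literal["rigid", "nonrigid"]
    rotation_planes: tuple[RotationPlane, ...]
    shear_axis: str | None = None
    shear_amplitude: float = 0.0
    shear_frequency_hz: float = 0.5
    deform_amplitude: float = 0.0
    deform_frequency_hz: float = 0.5
    jitter_amplitude: float = 0.0
    duration_s: float = 3.0
    frame_rate_hz: float = 90.0
    angle_waveform: Literal["sine", "triangle"] = "sine"
    #: space in which deformation and jitter act for 4D objects
    deform_space: Literal["xyz", "full"] = "xyz"

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.frame_rate_hz <= 0:
            raise ValueError("duration and frame rate must be positive")
        if self.kind == "rigid" and (
            self.shear_axis is not None
            or self.shear_amplitude != 0
            or self.deform_amplitude != 0
        ):
            raise ValueError("a rigid spec cannot carry shear or deformation")
        if self.kind == "nonrigid" and self.shear_axis is None:
            raise ValueError("a non-rigid spec requires a shear_axis")
        if self.shear_axis is not None and self.shear_axis not in ("x", "y", "z"):
            raise ValueError(f"shear_axis must be x, y or z, got {self.shear_axis!r}")

    @property
    def n_frames(self) -> int:
        return round(self.duration_s * self.frame_rate_hz)


@dataclass(frozen=True)
class TrajectorySet:
    """Vertex positions over one presentation: ``frames`` is (T, V, d) cm."""

    frames: np.ndarray
    frame_times: np.ndarray
    source_spec: MotionSpec
    source_object: WireframeObject

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=float)
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "frame_times", np.asarray(self.frame_times, dtype=float))
        V, d = self.source_object.vertices.shape
        if frames.ndim != 3 or frames.shape[1:] != (V, d):
            raise ValueError(
                f"frames must be (T, {V}, {d}), got {frames.shape}"
            )

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def dimension(self) -> int:
        return self.frames.shape[2]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table with frame, time_s, vertex and one column per coordinate."""
        T, V, d = self.frames.shape
        cols = [_AXIS_NAME[k] for k in range(d)]
        df = pd.DataFrame(
            self.frames.reshape(T * V, d),
            columns=cols,
        )
        df.insert(0, "vertex", np.tile(np.arange(V), T))
        df.insert(0, "time_s", np.repeat(self.frame_times, V))
        df.insert(0, "frame", np.repeat(np.arange(T), V))
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path: str | Path, compress: bool = False) -> None:
        payload = json.dumps(
            {
                "frames": self.frames.tolist(),
                "frame_times": self.frame_times.tolist(),
                "object": _to_dict(self.source_object),
                "spec": _spec_to_dict(self.source_spec),
            }
        )
        path = Path(path)
        if compress:
            with gzip.open(path, "wt") as fh:
                fh.write(payload)
        else:
            path.write_text(payload)

    @classmethod
    def from_json(cls, path: str | Path) -> "TrajectorySet":
        path = Path(path)
        opener = gzip.open if path.suffix == ".gz" else open
        with opener(path, "rt") as fh:
            d = json.load(fh)
        return cls(
            frames=np.array(d["frames"], dtype=float),
            frame_times=np.array(d["frame_times"], dtype=float),
            source_spec=_spec_from_dict(d["spec"]),
            source_object=_from_dict(d["object"]),
        )


def _invariant_indices(dimension: int, invariant: str | Sequence[str]) -> tuple[int, ...]:
    names = (invariant,) if isinstance(invariant, str) else tuple(invariant)
    try:
        idx = tuple(AXIS_INDEX[n] for n in names)
    except KeyError as err:
        raise ValueError(f"unknown coordinate name in {names!r}") from err
    if any(i >= dimension for i in idx):
        raise ValueError(f"coordinates {names!r} invalid for dimension {dimension}")
    if len(set(idx)) != len(idx):
        raise ValueError(f"repeated coordinate in {names!r}")
    if dimension - len(idx) != 2:
        raise ValueError(
            f"invariant set {names!r} must leave exactly two rotating "
            f"coordinates in dimension {dimension}"
        )
    return idx


def rotation_operator(
    dimension: int, invariant: str | Sequence[str], angle_deg: float
) -> np.ndarray:
    """Rotation matrix fixing ``invariant`` coordinates, rotating the rest.

    In 3D ``invariant`` is a single axis name and the result is the
    familiar rotation about that axis; in 4D it is a coordinate pair and
    the complementary pair rotates.  The result is orthonormal with
    determinant +1.
    """
    fixed = _invariant_indices(dimension, invariant)
    i, j = sorted(set(range(dimension)) - set(fixed))
    a = np.deg2rad(angle_deg)
    R = np.eye(dimension)
    R[i, i] = R[j, j] = np.cos(a)
    R[i, j] = -np.sin(a)
    R[j, i] = np.sin(a)
    return R


def _rigid_operator(dimension: int, spec: MotionSpec, t: float) -> np.ndarray:
    R = np.eye(dimension)
    for plane in spec.rotation_planes:
        angle = float(plane.angle_deg(t, spec.angle_waveform))
        R = rotation_operator(dimension, plane.invariant, angle) @ R
    return R


def rigid_pose(obj: WireframeObject, spec: MotionSpec, t: float) -> np.ndarray:
    """Vertex snapshot of the rigid backbone at time ``t`` (seconds).

    Each configured plane's angle follows an oscillation
    ``A * sin(2*pi*f*t + phase)`` and the plane rotations are composed in
    list order.  The result is an exact isometry of ``obj``.
    """
    return obj.vertices @ _rigid_operator(obj.dimension, spec, t).T


def _deform_directions(obj: WireframeObject, spec: MotionSpec, seed: int) -> np.ndarray:
    k = obj.dimension if spec.deform_space == "full" else min(3, obj.dimension)
    rng = np.random.default_rng(seed)
    dirs = rng.standard_normal((obj.n_vertices, k))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    out = np.zeros_like(obj.vertices)
    out[:, :k] = dirs
    return out


def nonrigid_pose(
    obj: WireframeObject, spec: MotionSpec, t: float, seed: int
) -> np.ndarray:
    """Non-rigid snapshot: rigid backbone + deformation + axial shear.

    Deformation moves each vertex along a fixed random unit direction
    (drawn once from ``seed``) by ``deform_amplitude * sin(2*pi*f_d*t)``.
    The shear increments the shear-axis coordinate by
    ``shear_amplitude * sin(2*pi*f_s*t)`` times the transverse coordinate
    (next axis in cyclic x->y->z order).  Both violate pairwise-distance
    conservation at generic times.
    """
    if spec.kind != "nonrigid":
        raise ValueError("nonrigid_pose requires a non-rigid spec")
    snap = rigid_pose(obj, spec, t)

    if spec.deform_amplitude != 0:
        dirs = _deform_directions(obj, spec, seed)
        snap = snap + dirs * (
            spec.deform_amplitude * np.sin(2 * np.pi * spec.deform_frequency_hz * t)
        )

    if spec.shear_amplitude != 0:
        a = AXIS_INDEX[spec.shear_axis]
        trans = AXIS_INDEX[SHEAR_TRANSVERSE[spec.shear_axis]]
        gain = spec.shear_amplitude * np.sin(2 * np.pi * spec.shear_frequency_hz * t)
        snap = snap.copy()
        snap[:, a] += gain * snap[:, trans]
    return snap


def generate_trajectory(
    obj: WireframeObject, spec: MotionSpec, seed: int
) -> TrajectorySet:
    """Full presentation: ``round(duration * frame_rate)`` uniform frames.

    Per-vertex jitter, when enabled, adds an independent displacement per
    frame drawn uniformly inside a ball of radius ``jitter_amplitude``
    (in the deformation space), seeded from ``seed``.
    """
    T = spec.n_frames
    times = np.arange(T) / spec.frame_rate_hz
    if spec.kind == "rigid":
        frames = np.stack([rigid_pose(obj, spec, t) for t in times])
    else:
        frames = np.stack([nonrigid_pose(obj, spec, t, seed) for t in times])

    if spec.jitter_amplitude > 0:
        k = obj.dimension if spec.deform_space == "full" else min(3, obj.dimension)
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0x6A17]))
        dirs = rng.standard_normal((T, obj.n_vertices, k))
        dirs /= np.linalg.norm(dirs, axis=2, keepdims=True)
        radii = spec.jitter_amplitude * rng.random((T, obj.n_vertices, 1)) ** (1 / k)
        frames[:, :, :k] += dirs * radii

    return TrajectorySet(
        frames=frames, frame_times=times, source_spec=spec, source_object=obj
    )


def default_motion_spec(
    dimension: int,
    kind: Literal["rigid", "nonrigid"],
    displacement_axis: str | None = None,
    *,
    jitter_amplitude: float = 0.5,
    amplitude_deg: float = 30.0,
    frequency_hz: float = 0.25,
    shear_amplitude: float = 0.2,
    deform_amplitude: float = 5.0,
    duration_s: float = 3.0,
    frame_rate_hz: float = 90.0,
) -> MotionSpec:
    """Stimulus spec with the pipeline's default animation parameters.

    3D objects rock about the x and y axes; 4D objects rotate with the
    y-z, x-z and x-y planes invariant simultaneously, with staggered
    phases.  ``displacement_axis`` sets the shear axis of non-rigid
    stimuli (the experiment's x / y / z displacement conditions).
    """
    if dimension == 3:
        planes = (
            RotationPlane("x", amplitude_deg, frequency_hz, 0.0),
            RotationPlane("y", amplitude_deg, frequency_hz, np.pi / 2),
        )
    elif dimension == 4:
        planes = tuple(
            RotationPlane(inv, amplitude_deg, frequency_hz, phase)
            for inv, phase in [
                (("y", "z"), 0.0),
                (("x", "z"), 2 * np.pi / 3),
                (("x", "y"), 4 * np.pi / 3),
            ]
        )
    else:
        raise ValueError(f"no default motion for dimension {dimension}")

    if kind == "rigid":
        return MotionSpec(
            kind="rigid",
            rotation_planes=planes,
            jitter_amplitude=jitter_amplitude,
            duration_s=duration_s,
            frame_rate_hz=frame_rate_hz,
        )
    if displacement_axis is None:
        raise ValueError("non-rigid motion requires a displacement_axis")
    return MotionSpec(
        kind="nonrigid",
        rotation_planes=planes,
        shear_axis=displacement_axis,
        shear_amplitude=shear_amplitude,
        deform_amplitude=deform_amplitude,
        jitter_amplitude=jitter_amplitude,
        duration_s=duration_s,
        frame_rate_hz=frame_rate_hz,
    )


# ---------------------------------------------------------------------------
# spec (de)serialisation for trajectory files


def _spec_to_dict(spec: MotionSpec) -> dict:
    d = {
        k: getattr(spec, k)
        for k in (
            "kind",
            "shear_axis",
            "shear_amplitude",
            "shear_frequency_hz",
            "deform_amplitude",
            "deform_frequency_hz",
            "jitter_amplitude",
            "duration_s",
            "frame_rate_hz",
            "angle_waveform",
            "deform_space",
        )
    }
    d["rotation_planes"] = [
        {
            "invariant": p.invariant if isinstance(p.invariant, str) else list(p.invariant),
            "amplitude_deg": p.amplitude_deg,
            "frequency_hz": p.frequency_hz,
            "phase_rad": p.phase_rad,
        }
        for p in spec.rotation_planes
    ]
    return d


def _spec_from_dict(d: dict) -> MotionSpec:
    planes = tuple(
        RotationPlane(
            invariant=p["invariant"] if isinstance(p["invariant"], str) else tuple(p["invariant"]),
            amplitude_deg=p["amplitude_deg"],
            frequency_hz=p["frequency_hz"],
            phase_rad=p["phase_rad"],
        )
        for p in d["rotation_planes"]
    )
    kwargs = {k: v for k, v in d.items() if k != "rotation_planes"}
    return MotionSpec(rotation_planes=planes, **kwargs)
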