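"""4D -> 3D projection and stereoscopic 3D -> 2D image formation.

The hypercube is shown as its 3D projection.  Two 4D projection modes
are supported: *orthographic* (drop w) and *perspective* (scale x, y, z
by ``w_eye / (w_eye - w)``, which gives the familiar nested-cube look of
a tesseract).  The 3D scene is then imaged by two pinhole cameras — one
per eye — displaced horizontally by the eye separation and using an
off-axis (asymmetric-frustum) projection so both eyes centre the
fixation point, the VR-standard arrangement.  Horizontal disparity is
then ``f * e * (1/Z - 1/D)``: zero at the fixation distance ``D``, and
its sign flips with depth relative to fixation.

A key property of the whole pipeline: rigid motion in 4D generally does
NOT project to rigid motion in 3D — lengths in the projection stretch
and shrink as the object rotates through w.  Judging the rigidity of the
original object therefore requires recovering structure beyond the
presented dimension.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np

from .motion import TrajectorySet

__all__ = [
    "CameraParams",
    "ProjectionSingularityError",
    "project_4d_to_3d",
    "project_trajectory_4d",
    "project_3d_to_stereo",
    "horizontal_disparity",
]


class ProjectionSingularityError(ValueError):
    """A vertex sits at or behind a centre of projection."""


@dataclass(frozen=True)
class CameraParams:
    """Viewing geometry of the (emulated) headset.

    Screen geometry follows the headset used in the study: per-eye
    resolution 1200 x 1080 at 90 Hz, 91.4 mm screen diagonal, 18 mm
    pupil-to-lens distance.  ``view_distance_cm`` is the fixed distance
    from the eyes to the object centre; ``w_eye_distance_cm`` is the 4D
    centre-of-projection distance used by the perspective 4D mode.
    """

    eye_separation_mm: float = 63.0
    view_distance_cm: float = 150.0
    screen_resolution: tuple[int, int] = (1200, 1080)
    refresh_rate_hz: float = 90.0
    pupil_to_lens_mm: float = 18.0
    screen_diagonal_mm: float = 91.4
    projection_4d: Literal["orthographic", "perspective"] = "perspective"
    w_eye_distance_cm: float = 250.0

    def __post_init__(self) -> None:
        for name in (
            "eye_separation_mm",
            "view_distance_cm",
            "pupil_to_lens_mm",
            "screen_diagonal_mm",
            "w_eye_distance_cm",
        ):
            if getattr(self, name) < 0 or (
                name != "eye_separation_mm" and getattr(self, name) == 0
            ):
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if any(r <= 0 for r in self.screen_resolution):
            raise ValueError("screen_resolution entries must be positive")

    @property
    def focal_px(self) -> float:
        """Focal length in pixels, from the lens distance and pixel pitch."""
        w, h = self.screen_resolution
        pitch_mm = self.screen_diagonal_mm / float(np.hypot(w, h))
        return self.pupil_to_lens_mm / pitch_mm


def project_4d_to_3d(
    snapshot: np.ndarray, params: CameraParams | None = None
) -> np.ndarray:
    """Project 4D vertex coordinates to 3D.

    ``snapshot`` is ``(..., 4)``; the result is ``(..., 3)``.
    Orthographic mode drops w; perspective mode scales (x, y, z) by
    ``w_eye / (w_eye - w)`` and requires every vertex to satisfy
    ``w < w_eye``.
    """
    params = params or CameraParams()
    snapshot = np.asarray(snapshot, dtype=float)
    if snapshot.shape[-1] != 4:
        raise ValueError(f"expected 4D coordinates, got shape {snapshot.shape}")
    xyz, w = snapshot[..., :3], snapshot[..., 3]
    if params.projection_4d == "orthographic":
        return xyz.copy()
    we = params.w_eye_distance_cm
    if np.any(w >= we):
        raise ProjectionSingularityError(
            f"vertex at w >= w_eye_distance ({we} cm); cannot project"
        )
    return xyz * (we / (we - w))[..., None]


def project_trajectory_4d(
    traj: TrajectorySet, params: CameraParams | None = None
) -> TrajectorySet:
    """Project every frame of a 4D trajectory; edges carry through."""
    if traj.dimension != 4:
        raise ValueError("project_trajectory_4d requires a 4D trajectory")
    frames3 = project_4d_to_3d(traj.frames, params)
    obj3 = replace(
        traj.source_object,
        dimension=3,
        vertices=project_4d_to_3d(traj.source_object.vertices, params),
    )
    return TrajectorySet(
        frames=frames3,
        frame_times=traj.frame_times,
        source_spec=traj.source_spec,
        source_object=obj3,
    )


def _eye_image(
    snapshot: np.ndarray, params: CameraParams, eye_x_cm: float
) -> np.ndarray:
    W, H = params.screen_resolution
    f = params.focal_px
    D = params.view_distance_cm
    X = snapshot[..., 0] - eye_x_cm
    Y = snapshot[..., 1]
    Z = D - snapshot[..., 2]  # distance along the viewing direction
    if np.any(Z <= 1e-9):
        raise ProjectionSingularityError("vertex at or behind the eye plane")
    # off-axis frustum: principal point shifted so the fixation point
    # (object centre, at distance D) maps to the screen centre
    cx = W / 2 + f * eye_x_cm / D
    u = f * X / Z + cx
    v = f * Y / Z + H / 2  # y runs downward, matching image coordinates
    return np.stack([u, v], axis=-1)


def project_3d_to_stereo(
    snapshot: np.ndarray, params: CameraParams | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Pinhole-project 3D vertices to left- and right-eye pixel coordinates.

    The eyes sit at ``x = -+ eye_separation/2`` at the viewing distance
    along z; each uses an off-axis frustum converged (without rotation)
    on the object centre.  Returns ``(left, right)`` arrays of shape
    ``(..., 2)`` in pixels.
    """
    params = params or CameraParams()
    snapshot = np.asarray(snapshot, dtype=float)
    if snapshot.shape[-1] != 3:
        raise ValueError(f"expected 3D coordinates, got shape {snapshot.shape}")
    half_e_cm = params.eye_separation_mm / 10.0 / 2.0
    left = _eye_image(snapshot, params, -half_e_cm)
    right = _eye_image(snapshot, params, +half_e_cm)
    return left, right


def horizontal_disparity(
    left: np.ndarray, right: np.ndarray
) -> np.ndarray:
    """Per-vertex horizontal disparity (left u minus right u), pixels.

    Positive for points nearer than fixation, negative beyond it, zero
    at the fixation distance.
    """
    return left[..., 0] - right[..., 0]
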