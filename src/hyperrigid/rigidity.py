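"""Ground-truth rigidity oracle for vertex trajectories.

A trajectory is rigid when every pairwise inter-vertex distance is
conserved across frames in the object's native dimension.  The oracle
measures the maximum relative deviation of any pairwise distance from
its first-frame value, and additionally reports a per-frame RMSD after
optimal proper-rotation-plus-translation alignment onto frame 0 (a
generalized orthogonal / Kabsch fit in the native dimension, reflections
excluded since physical motion cannot mirror an object).

This is the pipeline's verification surface: generated rigid stimuli
must classify rigid, sheared stimuli must not, and a rigid 4D trajectory
assessed AFTER projection to 3D must generally fail — the premise that
a dimension-reduced projection does not preserve rigidity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial.distance import pdist

from .motion import TrajectorySet

__all__ = ["RigidityReport", "assess_rigidity", "default_tolerance"]

#: floor used when the stimulus carries no jitter
_MIN_TOL = 1e-6


@dataclass(frozen=True)
class RigidityReport:
    """Outcome of a rigidity assessment."""

    is_rigid: bool
    max_distance_deviation: float
    per_frame_fit_residual: np.ndarray
    tolerance: float

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "is_rigid": bool(self.is_rigid),
                "max_distance_deviation": float(self.max_distance_deviation),
                "per_frame_fit_residual_cm": [float(r) for r in self.per_frame_fit_residual],
                "tolerance": float(self.tolerance),
            },
            indent=1,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload


def default_tolerance(traj: TrajectorySet) -> float:
    """Tolerance admitting the stimulus's own stereoscopy jitter.

    Jittered rigid stimuli are rigid by design.  A pairwise distance
    between two frames can shift by at most four per-vertex jitter radii
    (two vertices, and the reference frame is jittered too), so the
    tolerance is four times the jitter amplitude relative to the side
    length, with a floor of 1e-6 for jitter-free trajectories.
    """
    spec = traj.source_spec
    side = traj.source_object.side_length
    return max(_MIN_TOL, 4.0 * spec.jitter_amplitude / side)


def _kabsch_rmsd(frame: np.ndarray, ref: np.ndarray) -> float:
    """RMSD after optimal translation + proper rotation in any dimension."""
    a = frame - frame.mean(axis=0)
    b = ref - ref.mean(axis=0)
    U, _, Vt = np.linalg.svd(a.T @ b)
    # exclude reflections: force det(+1)
    sign = np.sign(np.linalg.det(U @ Vt))
    d = np.ones(U.shape[0])
    d[-1] = sign if sign != 0 else 1.0
    R = U @ np.diag(d) @ Vt
    return float(np.sqrt(np.mean(np.sum((a @ R - b) ** 2, axis=1))))


def assess_rigidity(traj: TrajectorySet, tol: float | None = None) -> RigidityReport:
    """Classify a trajectory as rigid and quantify its deviation.

    Parameters
    ----------
    traj
        At least 2 frames and 2 vertices.
    tol
        Maximum admissible relative pairwise-distance deviation; default
        from :func:`default_tolerance`.

    Returns
    -------
    RigidityReport
        ``is_rigid`` iff no pairwise distance in any frame deviates from
        its frame-0 value by more than ``tol`` (relative); the per-frame
        residual is the aligned RMSD against frame 0, cm.
    """
    frames = traj.frames
    if frames.shape[0] < 2 or frames.shape[1] < 2:
        raise ValueError("rigidity assessment needs >= 2 frames and >= 2 vertices")
    if tol is None:
        tol = default_tolerance(traj)

    d0 = pdist(frames[0])
    max_dev = 0.0
    for t in range(1, frames.shape[0]):
        dev = np.max(np.abs(pdist(frames[t]) - d0) / d0)
        max_dev = max(max_dev, float(dev))

    residuals = np.array([_kabsch_rmsd(frames[t], frames[0]) for t in range(frames.shape[0])])
    return RigidityReport(
        is_rigid=max_dev <= tol,
        max_distance_deviation=max_dev,
        per_frame_fit_residual=residuals,
        tolerance=float(tol),
    )
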