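"""Two-alternative forced-choice session design and trial running.

Each trial shows two stimuli in a top-bottom arrangement — one moving
rigidly, one non-rigidly — and the observer reports which one is rigid
within a 3-s window, then rates confidence 1 (guessing) to 5 (firm
belief).  A session crosses dimensionality (3D, 4D) with displacement
axis and irregularity level:

* Experiment 1 (fixed headset): axes x/y/z, 3 repetitions per cell,
  54 trials per session.
* Experiment 2 (active headset): the x axis is removed, 7 repetitions
  per cell, 84 trials per session.

3D and 4D trials form separate blocks (text-instruction break in the
original procedure, metadata here); within a block the cell sequence is
a counterbalanced seeded shuffle with equal repetition counts, and the
rigid stimulus's top/bottom position is balanced within each cell.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Literal, Protocol, Sequence

import numpy as np
import pandas as pd

from .geometry import make_hypercube, perturb_vertices
from .motion import TrajectorySet, default_motion_spec, generate_trajectory

__all__ = [
    "Condition",
    "Trial",
    "TrialResult",
    "HeadPoseTrace",
    "Session",
    "Observer",
    "Response",
    "ProtocolViolationError",
    "build_session",
    "make_trial_stimuli",
    "run_session",
    "results_to_frame",
    "traces_to_frame",
    "EXP1_AXES",
    "EXP2_AXES",
    "IRREGULARITY_LEVELS",
    "RESPONSE_WINDOW_MS",
    "HEAD_SAMPLE_RATE_HZ",
]

EXP1_AXES = ("x", "y", "z")
EXP2_AXES = ("y", "z")  # the x-axis displacement is removed in Experiment 2
IRREGULARITY_LEVELS = (0.12, 0.18, 0.24)
REPETITIONS = {1: 3, 2: 7}
RESPONSE_WINDOW_MS = 3000.0
HEAD_SAMPLE_RATE_HZ = 18.0
OBSERVATION_S = 3.0
INTER_BLOCK_INTERVAL_S = 5.0


class ProtocolViolationError(ValueError):
    """An observer returned a response outside the task protocol."""


@dataclass(frozen=True)
class Condition:
    """One cell of the factorial design."""

    dimension: int  # 3 or 4
    displacement_axis: str  # x, y or z
    irregularity: float  # fraction of side length


@dataclass(frozen=True)
class Trial:
    index: int
    condition: Condition
    rigid_position: Literal["top", "bottom"]
    seed: int
    block: int = 0


@dataclass(frozen=True)
class Response:
    choice: Literal["top", "bottom"]
    rt_ms: float
    confidence: int


@dataclass(frozen=True)
class TrialResult:
    trial: Trial
    choice: Literal["top", "bottom", "none"]
    correct: bool
    rt_ms: float | None
    confidence: int | None
    timed_out: bool


@dataclass(frozen=True)
class HeadPoseTrace:
    """Per-trial head-angle series: ``angles_deg`` is (samples, 3) for x, y, z."""

    trial_index: int
    times_s: np.ndarray
    angles_deg: np.ndarray

    @property
    def n_samples(self) -> int:
        return self.angles_deg.shape[0]


@dataclass(frozen=True)
class Session:
    experiment: Literal[1, 2]
    trials: tuple[Trial, ...]
    seed: int
    subject: str = "S1"
    session_index: int = 1
    training: bool = False
    block_order: tuple[int, ...] = (3, 4)
    inter_block_interval_s: float = INTER_BLOCK_INTERVAL_S

    @property
    def n_trials(self) -> int:
        return len(self.trials)


class Observer(Protocol):
    """Anything that can answer a trial (synthetic or replayed)."""

    def respond(self, trial: Trial) -> Response | None:
        """Return a response, or None on timeout."""
        ...


def build_session(
    experiment: Literal[1, 2],
    seed: int,
    *,
    subject: str = "S1",
    session_index: int = 1,
    training: bool = False,
) -> Session:
    """Assemble one session's counterbalanced, seeded trial sequence.

    The full factorial grid (dimension x axis x irregularity) is
    repeated 3 times (Experiment 1) or 7 times (Experiment 2), shuffled
    within the 3D and 4D blocks.  The rigid stimulus's position is
    balanced across the repetitions of each cell, the odd repetition
    assigned by a seeded coin flip.  Block order alternates with
    ``session_index`` (odd sessions run the 3D block first).
    """
    if experiment not in REPETITIONS:
        raise ValueError(f"experiment must be 1 or 2, got {experiment}")
    axes = EXP1_AXES if experiment == 1 else EXP2_AXES
    reps = REPETITIONS[experiment]
    rng = np.random.default_rng(np.random.SeedSequence([seed, experiment, session_index]))

    block_order = (3, 4) if session_index % 2 == 1 else (4, 3)
    trials: list[Trial] = []
    for block_pos, dim in enumerate(block_order):
        block_trials: list[tuple[Condition, str]] = []
        for axis, irr in product(axes, IRREGULARITY_LEVELS):
            cond = Condition(dimension=dim, displacement_axis=axis, irregularity=irr)
            positions = ["top", "bottom"] * (reps // 2)
            if reps % 2:
                positions.append("top" if rng.random() < 0.5 else "bottom")
            rng.shuffle(positions)
            block_trials += [(cond, pos) for pos in positions]
        order = rng.permutation(len(block_trials))
        for k in order:
            cond, pos = block_trials[k]
            trials.append(
                Trial(
                    index=len(trials),
                    condition=cond,
                    rigid_position=pos,  # type: ignore[arg-type]
                    seed=int(rng.integers(0, 2**31 - 1)),
                    block=block_pos,
                )
            )
    return Session(
        experiment=experiment,
        trials=tuple(trials),
        seed=seed,
        subject=subject,
        session_index=session_index,
        training=training,
        block_order=block_order,
    )


def make_trial_stimuli(
    trial: Trial,
    side_length: float = 100.0,
    *,
    jitter_amplitude: float = 0.5,
) -> tuple[TrajectorySet, TrajectorySet]:
    """Materialise the (top, bottom) stimulus pair for a trial.

    Both stimuli share the trial's condition (dimension, irregularity);
    exactly one — at ``trial.rigid_position`` — moves rigidly, the other
    carries the condition's axial shear plus deformation.  Everything is
    seeded from ``trial.seed``.
    """
    cond = trial.condition
    ss = np.random.SeedSequence([trial.seed, cond.dimension])
    seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(4)]

    def stimulus(kind: str, perturb_seed: int, motion_seed: int) -> TrajectorySet:
        obj = make_hypercube(cond.dimension, side_length)
        obj = perturb_vertices(obj, cond.irregularity, perturb_seed)
        spec = default_motion_spec(
            cond.dimension,
            kind,  # type: ignore[arg-type]
            cond.displacement_axis if kind == "nonrigid" else None,
            jitter_amplitude=jitter_amplitude,
        )
        return generate_trajectory(obj, spec, motion_seed)

    rigid = stimulus("rigid", seeds[0], seeds[1])
    nonrigid = stimulus("nonrigid", seeds[2], seeds[3])
    if trial.rigid_position == "top":
        return rigid, nonrigid
    return nonrigid, rigid


def _fixed_trace(trial_index: int) -> HeadPoseTrace:
    n = round(HEAD_SAMPLE_RATE_HZ * OBSERVATION_S)
    return HeadPoseTrace(
        trial_index=trial_index,
        times_s=np.arange(n) / HEAD_SAMPLE_RATE_HZ,
        angles_deg=np.zeros((n, 3)),
    )


def run_session(
    session: Session,
    observer: Observer,
    headset_mode: Literal["fixed", "active"] = "fixed",
) -> tuple[list[TrialResult], list[HeadPoseTrace]]:
    """Run every trial of a session against an observer.

    Responses beyond the 3000 ms window (or None) are marked timed out
    with no recorded choice/RT/confidence.  Each trial gets a head-pose
    trace: constant front-view angles in fixed mode, or the observer's
    own trace (``observer.head_trace(trial, mode)``) in active mode,
    sampled at 18 Hz over the 3-s observation (54 samples).
    """
    results: list[TrialResult] = []
    traces: list[HeadPoseTrace] = []
    for trial in session.trials:
        resp = observer.respond(trial)
        if resp is not None and (
            not isinstance(resp.confidence, (int, np.integer))
            or not 1 <= resp.confidence <= 5
        ):
            raise ProtocolViolationError(
                f"confidence must be an integer in [1, 5], got {resp.confidence!r}"
            )
        if resp is None or resp.rt_ms > RESPONSE_WINDOW_MS:
            results.append(
                TrialResult(trial, "none", False, None, None, timed_out=True)
            )
        else:
            results.append(
                TrialResult(
                    trial,
                    resp.choice,
                    correct=resp.choice == trial.rigid_position,
                    rt_ms=float(resp.rt_ms),
                    confidence=int(resp.confidence),
                    timed_out=False,
                )
            )
        if headset_mode == "active" and hasattr(observer, "head_trace"):
            traces.append(observer.head_trace(trial, headset_mode))
        else:
            traces.append(_fixed_trace(trial.index))
    return results, traces


def results_to_frame(
    session: Session, results: Sequence[TrialResult]
) -> pd.DataFrame:
    """One row per trial, the pipeline's CSV interchange schema."""
    rows = []
    for r in results:
        t = r.trial
        rows.append(
            {
                "subject": session.subject,
                "experiment": session.experiment,
                "session": session.session_index,
                "training": session.training,
                "block": t.block,
                "trial": t.index,
                "dimension": t.condition.dimension,
                "displacement_axis": t.condition.displacement_axis,
                "irregularity": t.condition.irregularity,
                "rigid_position": t.rigid_position,
                "choice": r.choice,
                "correct": r.correct,
                "rt_ms": r.rt_ms,
                "confidence": r.confidence,
                "timed_out": r.timed_out,
            }
        )
    return pd.DataFrame(rows)


def traces_to_frame(
    session: Session, traces: Sequence[HeadPoseTrace]
) -> pd.DataFrame:
    """Long-format head-pose table: one row per trial sample."""
    frames = []
    for tr in traces:
        df = pd.DataFrame(tr.angles_deg, columns=["angle_x", "angle_y", "angle_z"])
        df.insert(0, "sample_index", np.arange(tr.n_samples))
        df.insert(0, "trial", tr.trial_index)
        df.insert(0, "subject", session.subject)
        df.insert(1, "session", session.session_index)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
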