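"""Synthetic observer: configurable choice / RT / confidence generator.

The observer stands in for human subjects so the analysis stage can be
exercised and validated end to end.  Per condition cell (dimension x
displacement axis) it is parameterised by an accuracy probability, a
log-normal reaction-time mean/SD (ms) and a 1-5 confidence mean/SD.
Confidence is drawn from a latent normal negatively coupled to the RT
draw (fast answers tend to be confident ones) and discretised to the
1-5 key presses; the default coupling of -0.52 matches the pooled
confidence-RT correlation reported for the human data.

Two default profiles ship with the package:

* ``table1`` — fixed-headset performance (Experiment 1): near-ceiling
  on x-axis displacement, much poorer on y and z.
* ``table2`` — active-headset performance (Experiment 2, y/z only):
  uniformly high after the recovery brought by head movement.

Head-pose traces emulate the recorded behaviour: small within-trial
angle ranges and a preferred viewpoint around 45 degrees on the y axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .experiment import (
    HEAD_SAMPLE_RATE_HZ,
    OBSERVATION_S,
    RESPONSE_WINDOW_MS,
    HeadPoseTrace,
    Response,
    Trial,
)

__all__ = [
    "CellParams",
    "ObserverProfile",
    "SyntheticObserver",
    "load_profile",
    "simulate_trials",
]


@dataclass(frozen=True)
class CellParams:
    """Response statistics of one condition cell."""

    accuracy: float  # probability of a correct choice
    rt_mean_ms: float
    rt_sd_ms: float
    confidence_mean: float  # on the 1-5 scale
    confidence_sd: float

    def __post_init__(self) -> None:
        if not 0 <= self.accuracy <= 1:
            raise ValueError(f"accuracy must be in [0, 1], got {self.accuracy}")
        if self.rt_mean_ms <= 0 or self.rt_sd_ms < 0:
            raise ValueError("RT parameters must be positive")

    def lognormal_params(self) -> tuple[float, float]:
        """(mu, sigma) of the log-normal matching the configured mean/SD."""
        m, s = self.rt_mean_ms, self.rt_sd_ms
        sigma2 = math.log(1 + (s / m) ** 2)
        return math.log(m) - sigma2 / 2, math.sqrt(sigma2)


# Fixed-headset cell statistics (Experiment 1): accuracy %, RT ms mean (SD),
# confidence mean (SD), by (dimension, displacement axis).
_TABLE1 = {
    (3, "x"): CellParams(0.9884, 580.19, 317.86, 4.94, 0.32),
    (4, "x"): CellParams(0.9759, 529.45, 256.19, 4.67, 0.87),
    (3, "z"): CellParams(0.6705, 782.63, 343.97, 3.73, 1.35),
    (4, "z"): CellParams(0.5250, 1019.79, 429.32, 3.35, 1.31),
    (3, "y"): CellParams(0.6184, 847.70, 354.20, 4.03, 1.12),
    (4, "y"): CellParams(0.7176, 726.29, 389.60, 3.86, 1.18),
}

# Active-headset cell statistics (Experiment 2, x removed).
_TABLE2 = {
    (3, "z"): CellParams(0.9704, 543.97, 289.04, 4.83, 0.65),
    (4, "z"): CellParams(0.8921, 590.42, 294.07, 4.32, 1.12),
    (3, "y"): CellParams(0.9659, 534.33, 298.23, 4.84, 0.53),
    (4, "y"): CellParams(0.9227, 627.32, 318.93, 4.32, 1.20),
}

#: overall fraction of timed-out trials in the recorded sessions (63/1380)
DEFAULT_TIMEOUT_RATE = 63 / 1380


@dataclass(frozen=True)
class ObserverProfile:
    """Full parameterisation of a synthetic observer.

    ``cells`` maps (dimension, displacement_axis) to response
    statistics; irregularity has no configured effect, matching the null
    irregularity findings.  ``confidence_rt_coupling`` is the latent
    correlation (<= 0) between the RT z-score and the confidence latent.
    Head-pose parameters give the per-axis preferred viewpoint medians
    and the within-trial interquartile range, degrees.
    """

    cells: dict[tuple[int, str], CellParams]
    confidence_rt_coupling: float = -0.52
    timeout_rate: float = DEFAULT_TIMEOUT_RATE
    head_median_deg: tuple[float, float, float] = (10.0, 45.0, 5.0)
    head_iqr_deg: float = 2.0
    name: str = "custom"

    def __post_init__(self) -> None:
        if self.confidence_rt_coupling > 0:
            raise ValueError("confidence_rt_coupling must be <= 0")
        if not 0 <= self.timeout_rate <= 1:
            raise ValueError("timeout_rate must be a probability")

    @classmethod
    def table1(cls, **overrides) -> "ObserverProfile":
        """Fixed-headset defaults (Experiment 1)."""
        return cls(cells=dict(_TABLE1), name="table1", **overrides)

    @classmethod
    def table2(cls, **overrides) -> "ObserverProfile":
        """Active-headset defaults (Experiment 2)."""
        return cls(cells=dict(_TABLE2), name="table2", **overrides)

    def cell(self, dimension: int, axis: str) -> CellParams:
        try:
            return self.cells[(dimension, axis)]
        except KeyError:
            raise KeyError(
                f"profile {self.name!r} has no cell for dimension={dimension}, "
                f"axis={axis!r}"
            ) from None

    # -- YAML round trip ----------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "name": self.name,
            "confidence_rt_coupling": self.confidence_rt_coupling,
            "timeout_rate": self.timeout_rate,
            "head_median_deg": list(self.head_median_deg),
            "head_iqr_deg": self.head_iqr_deg,
            "cells": [
                {
                    "dimension": dim,
                    "displacement_axis": axis,
                    "accuracy": c.accuracy,
                    "rt_mean_ms": c.rt_mean_ms,
                    "rt_sd_ms": c.rt_sd_ms,
                    "confidence_mean": c.confidence_mean,
                    "confidence_sd": c.confidence_sd,
                }
                for (dim, axis), c in sorted(self.cells.items())
            ],
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ObserverProfile":
        d = yaml.safe_load(Path(path).read_text())
        cells = {
            (int(c["dimension"]), str(c["displacement_axis"])): CellParams(
                accuracy=float(c["accuracy"]),
                rt_mean_ms=float(c["rt_mean_ms"]),
                rt_sd_ms=float(c["rt_sd_ms"]),
                confidence_mean=float(c["confidence_mean"]),
                confidence_sd=float(c["confidence_sd"]),
            )
            for c in d["cells"]
        }
        return cls(
            cells=cells,
            confidence_rt_coupling=float(d.get("confidence_rt_coupling", -0.52)),
            timeout_rate=float(d.get("timeout_rate", DEFAULT_TIMEOUT_RATE)),
            head_median_deg=tuple(d.get("head_median_deg", (10.0, 45.0, 5.0))),
            head_iqr_deg=float(d.get("head_iqr_deg", 2.0)),
            name=str(d.get("name", "custom")),
        )


def load_profile(name_or_path: str) -> ObserverProfile:
    """Resolve a profile bundle name (``table1``/``table2``) or a YAML path."""
    if name_or_path == "table1":
        return ObserverProfile.table1()
    if name_or_path == "table2":
        return ObserverProfile.table2()
    return ObserverProfile.from_yaml(name_or_path)


class SyntheticObserver:
    """Seeded response generator implementing the observer interface."""

    def __init__(self, profile: ObserverProfile, seed: int):
        self.profile = profile
        self.rng = np.random.default_rng(np.random.SeedSequence([seed, 0x0B5E]))

    def respond(self, trial: Trial) -> Response | None:
        """Sample (choice, rt, confidence) for a trial, or None on timeout."""
        p = self.profile
        cell = p.cell(trial.condition.dimension, trial.condition.displacement_axis)
        rng = self.rng

        if rng.random() < p.timeout_rate:
            return None

        correct = rng.random() < cell.accuracy
        choice = (
            trial.rigid_position
            if correct
            else ("bottom" if trial.rigid_position == "top" else "top")
        )

        mu, sigma = cell.lognormal_params()
        z = rng.standard_normal()
        rt = math.exp(mu + sigma * z)
        for _ in range(100):  # truncate to the response window
            if rt <= RESPONSE_WINDOW_MS:
                break
            z = rng.standard_normal()
            rt = math.exp(mu + sigma * z)
        else:
            rt, z = RESPONSE_WINDOW_MS, (math.log(RESPONSE_WINDOW_MS) - mu) / sigma

        rho = p.confidence_rt_coupling
        latent = (
            cell.confidence_mean
            + cell.confidence_sd
            * (rho * z + math.sqrt(1 - rho**2) * rng.standard_normal())
        )
        confidence = int(np.clip(round(latent), 1, 5))
        return Response(choice=choice, rt_ms=rt, confidence=confidence)

    def head_trace(self, trial: Trial, mode: str = "active") -> HeadPoseTrace:
        """54-sample (18 Hz x 3 s) head-angle series for one trial.

        Fixed mode returns constant front-view angles.  Active mode
        draws, per axis, a per-trial baseline near the profile's
        preferred median plus one slow sinusoidal sweep whose amplitude
        is set so the within-trial interquartile range matches
        ``head_iqr_deg`` (IQR of a uniformly sampled sinusoid is
        ``sqrt(2)`` times its amplitude).
        """
        n = round(HEAD_SAMPLE_RATE_HZ * OBSERVATION_S)
        t = np.arange(n) / HEAD_SAMPLE_RATE_HZ
        if mode == "fixed":
            return HeadPoseTrace(trial.index, t, np.zeros((n, 3)))
        p = self.profile
        rng = self.rng
        amp = p.head_iqr_deg / math.sqrt(2)
        angles = np.empty((n, 3))
        for k in range(3):
            baseline = p.head_median_deg[k] + rng.normal(0.0, 1.0)
            phase = rng.uniform(0, 2 * np.pi)
            angles[:, k] = (
                baseline
                + amp * np.sin(2 * np.pi * t / OBSERVATION_S + phase)
                + rng.normal(0.0, 0.05, n)
            )
        return HeadPoseTrace(trial.index, t, angles)


def simulate_trials(
    profile: ObserverProfile,
    n_per_cell: int,
    seed: int,
    *,
    irregularities: tuple[float, ...] = (0.12, 0.18, 0.24),
    subject: str = "S1",
) -> "pd.DataFrame":
    """Bulk-sample a trial log with ``n_per_cell`` trials per profile cell.

    Convenience for parameter-recovery and calibration studies: returns a
    DataFrame in the experiment CSV schema, cycling irregularity levels
    and the rigid stimulus's position across trials.
    """
    import pandas as pd

    from .experiment import Condition

    observer = SyntheticObserver(profile, seed)
    rows = []
    for dim, axis in sorted(profile.cells):
        for i in range(n_per_cell):
            trial = Trial(
                index=i,
                condition=Condition(dim, axis, irregularities[i % len(irregularities)]),
                rigid_position="top" if i % 2 == 0 else "bottom",
                seed=i,
            )
            r = observer.respond(trial)
            rows.append(
                {
                    "subject": subject,
                    "dimension": dim,
                    "displacement_axis": axis,
                    "irregularity": trial.condition.irregularity,
                    "rigid_position": trial.rigid_position,
                    "choice": r.choice if r else "none",
                    "correct": (r.choice == trial.rigid_position) if r else False,
                    "rt_ms": r.rt_ms if r else None,
                    "confidence": r.confidence if r else None,
                    "timed_out": r is None,
                }
            )
    return pd.DataFrame(rows)
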