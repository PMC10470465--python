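"""Statistical pipeline for 2AFC rigidity-judgment trial logs.

Mirrors the study's analysis chain on any conforming trial log
(typically the synthetic observer's output):

1. filtering — drop timed-out trials globally, restrict the RT view to
   correct trials, drop training sessions, and flag subjects whose
   overall accuracy is indistinguishable from chance while their mean
   confidence signals guessing;
2. per-cell summary tables (accuracy % / RT ms / confidence, mean and
   SD) in the dimension x displacement-axis layout;
3. LMM-ANOVA — linear mixed model with a random intercept per subject
   and Wald F tests for the fixed factors and their interactions;
4. Pearson confidence-RT correlation;
5. head-movement statistics — per-trial median and interquartile
   (Q3 - Q1) range of the 18 Hz head-angle series, per axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm

__all__ = [
    "FilterResult",
    "LmmResult",
    "DegenerateDesignError",
    "filter_trials",
    "summarize",
    "lmm_anova",
    "confidence_rt_correlation",
    "head_movement_stats",
    "angles_from_pose",
    "lmm_null_rejection_rate",
]

#: columns every trial log must carry
_SCHEMA = (
    "subject",
    "dimension",
    "displacement_axis",
    "irregularity",
    "correct",
    "rt_ms",
    "confidence",
    "timed_out",
)


class DegenerateDesignError(ValueError):
    """The mixed model cannot be estimated on this design."""


@dataclass(frozen=True)
class FilterResult:
    """Filtered trial log plus bookkeeping.

    ``trials`` drops timed-out trials (and training sessions); the
    ``rt_view`` additionally keeps correct trials only, the convention
    for reaction-time analyses.  Row counts in ``report`` reconcile
    exactly with the input.
    """

    trials: pd.DataFrame
    rt_view: pd.DataFrame
    excluded_subjects: tuple[str, ...]
    report: dict


def _check_schema(df: pd.DataFrame) -> None:
    missing = [c for c in _SCHEMA if c not in df.columns]
    if missing:
        raise ValueError(f"trial log is missing columns: {missing}")


def filter_trials(
    df: pd.DataFrame,
    *,
    exclude_training: bool = True,
    exclude_subjects: bool = True,
    chance_alpha: float = 0.05,
    confidence_threshold: float = 2.0,
) -> FilterResult:
    """Apply the study's trial- and subject-level exclusions.

    Timed-out (overtime) trials are removed globally.  A subject is
    excluded when a two-sided binomial test cannot distinguish their
    overall accuracy from chance (p > ``chance_alpha`` against 0.5) AND
    their mean confidence is below ``confidence_threshold`` — the
    formalisation of dropping a participant who performed at 54.9% with
    mean confidence 1.71.  The RT view keeps correct trials only.
    """
    _check_schema(df)
    n_input = len(df)
    out = df.copy()

    n_training = 0
    if exclude_training and "training" in out.columns:
        n_training = int(out["training"].sum())
        out = out[~out["training"]]

    n_timeout = int(out["timed_out"].sum())
    out = out[~out["timed_out"]]

    excluded: list[str] = []
    if exclude_subjects:
        for subject, grp in out.groupby("subject"):
            k, n = int(grp["correct"].sum()), len(grp)
            if n == 0:
                continue
            at_chance = stats.binomtest(k, n, 0.5).pvalue > chance_alpha
            if at_chance and grp["confidence"].mean() < confidence_threshold:
                excluded.append(str(subject))
    n_subject_excluded = int(out["subject"].isin(excluded).sum())
    out = out[~out["subject"].isin(excluded)]

    rt_view = out[out["correct"]]
    report = {
        "n_input": n_input,
        "n_training_dropped": n_training,
        "n_timed_out_dropped": n_timeout,
        "n_subject_excluded_dropped": n_subject_excluded,
        "n_retained": len(out),
        "n_rt_view": len(rt_view),
        "excluded_subjects": list(excluded),
    }
    assert report["n_input"] == (
        report["n_training_dropped"]
        + report["n_timed_out_dropped"]
        + report["n_subject_excluded_dropped"]
        + report["n_retained"]
    )
    return FilterResult(
        trials=out.reset_index(drop=True),
        rt_view=rt_view.reset_index(drop=True),
        excluded_subjects=tuple(excluded),
        report=report,
    )


def summarize(
    filtered: pd.DataFrame,
    by: Sequence[str] = ("dimension", "displacement_axis"),
    rt_correct_only: bool = True,
) -> pd.DataFrame:
    """Cellwise mean (SD) of accuracy %, RT ms and confidence.

    Accuracy is summarised on the per-trial 0/100 indicator, so an SD
    accompanies the percentage (the "98.84 (10.78)" style).  RT cells
    use correct trials only by default.  Cells with no trials are
    reported as missing, not zero.
    """
    if filtered.empty:
        raise ValueError("cannot summarize an empty trial log")
    by = list(by)
    acc = filtered.assign(acc=filtered["correct"].astype(float) * 100.0)
    rows = []
    for key, grp in acc.groupby(by, observed=True):
        key = key if isinstance(key, tuple) else (key,)
        rt_src = grp[grp["correct"]] if rt_correct_only else grp
        row = dict(zip(by, key))
        row.update(
            n_trials=len(grp),
            accuracy_mean=grp["acc"].mean(),
            accuracy_sd=grp["acc"].std(ddof=1),
            rt_mean=rt_src["rt_ms"].mean() if len(rt_src) else np.nan,
            rt_sd=rt_src["rt_ms"].std(ddof=1) if len(rt_src) > 1 else np.nan,
            confidence_mean=grp["confidence"].mean(),
            confidence_sd=grp["confidence"].std(ddof=1),
        )
        rows.append(row)
    return pd.DataFrame(rows).set_index(by).sort_index()


# ---------------------------------------------------------------------------
# LMM-ANOVA


@dataclass(frozen=True)
class LmmResult:
    """F table of a mixed-model ANOVA plus estimation metadata."""

    table: pd.DataFrame  # index: effect; columns: F, df_num, df_den, p
    metadata: dict = field(default_factory=dict)

    def p(self, effect: str) -> float:
        return float(self.table.loc[effect, "p"])

    def f(self, effect: str) -> float:
        return float(self.table.loc[effect, "F"])


def _sum_coded(values: pd.Series) -> tuple[np.ndarray, list]:
    """Sum-to-zero (effects) coding: k levels -> k-1 columns."""
    levels = sorted(pd.unique(values))
    k = len(levels)
    if k < 2:
        raise DegenerateDesignError(
            f"factor {values.name!r} has fewer than 2 levels"
        )
    X = np.zeros((len(values), k - 1))
    arr = np.asarray(values)
    for j, lev in enumerate(levels[:-1]):
        X[arr == lev, j] = 1.0
    X[arr == levels[-1], :] = -1.0
    return X, levels


def _interaction_block(blocks: list[np.ndarray]) -> np.ndarray:
    out = blocks[0]
    for b in blocks[1:]:
        out = np.einsum("ni,nj->nij", out, b).reshape(len(out), -1)
    return out


def lmm_anova(
    df: pd.DataFrame,
    response: str,
    fixed: Sequence[str],
    random_group: str = "subject",
    *,
    include_interactions: bool = True,
    aggregate: bool = False,
    reml: bool = True,
) -> LmmResult:
    """ANOVA-style F tests from a linear mixed model.

    Fits ``response ~ fixed factors (+ interactions) + (1 | group)``
    with sum-to-zero factor coding and reports a Wald F test per term.
    The denominator degrees of freedom use the residual (containment)
    approximation ``n - rank(X) - (g - 1)``, recorded in the metadata.
    With ``aggregate=True`` the response is first averaged per group x
    cell (the aggregated-percentages mode for accuracy); the default
    fits trial-level observations.

    A constant response is reported as a degenerate fit with F = 0 for
    every term rather than an error.
    """
    fixed = list(fixed)
    if random_group not in df.columns:
        raise ValueError(f"random_group column {random_group!r} not in data")
    data = df.dropna(subset=[response, random_group, *fixed]).copy()
    if data[random_group].nunique() < 2:
        raise DegenerateDesignError("need >= 2 grouping levels (subjects)")

    if aggregate:
        data = (
            data.groupby([random_group, *fixed], observed=True)[response]
            .mean()
            .reset_index()
        )

    y = np.asarray(data[response], dtype=float)

    # design: intercept + sum-coded main effects + product interactions
    main_blocks = {f: _sum_coded(data[f])[0] for f in fixed}
    terms: dict[str, np.ndarray] = {f: main_blocks[f] for f in fixed}
    if include_interactions and len(fixed) > 1:
        for order in range(2, len(fixed) + 1):
            for combo in combinations(fixed, order):
                terms[":".join(combo)] = _interaction_block(
                    [main_blocks[f] for f in combo]
                )

    X = np.column_stack([np.ones(len(y))] + list(terms.values()))
    col_index = {}
    start = 1
    for name, block in terms.items():
        col_index[name] = list(range(start, start + block.shape[1]))
        start += block.shape[1]

    n, p_cols = X.shape
    g = data[random_group].nunique()
    df_den = n - np.linalg.matrix_rank(X) - (g - 1)
    if df_den <= 0:
        raise DegenerateDesignError("not enough observations for the design")

    meta = {
        "n_obs": n,
        "n_groups": g,
        "ddf_method": "residual (containment): n - rank(X) - (g - 1)",
        "coding": "sum-to-zero",
        "reml": reml,
        "aggregate": aggregate,
    }

    if np.std(y) == 0:
        table = pd.DataFrame(
            {
                "F": 0.0,
                "df_num": [len(cols) for cols in col_index.values()],
                "df_den": df_den,
                "p": 1.0,
            },
            index=list(col_index),
        )
        meta["degenerate"] = True
        return LmmResult(table=table, metadata=meta)

    # standardize the response for numerical conditioning: Wald F statistics
    # are invariant to affine rescaling of y
    y_std = (y - y.mean()) / y.std()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y_std, X, groups=np.asarray(data[random_group]))
        fit = None
        for method in ("lbfgs", "powell", "cg"):
            try:
                fit = model.fit(reml=reml, method=method)
                break
            except (np.linalg.LinAlgError, ValueError):
                continue
        if fit is None:
            raise DegenerateDesignError("mixed-model estimation failed")

    k_fe = len(fit.fe_params)
    beta = np.asarray(fit.fe_params)
    cov = np.asarray(fit.cov_params())[:k_fe, :k_fe]

    rows = []
    for name, cols in col_index.items():
        b = beta[cols]
        V = cov[np.ix_(cols, cols)]
        q = len(cols)
        F = float(b @ np.linalg.solve(V, b)) / q
        rows.append(
            {
                "effect": name,
                "F": F,
                "df_num": q,
                "df_den": df_den,
                "p": float(stats.f.sf(F, q, df_den)),
            }
        )
    table = pd.DataFrame(rows).set_index("effect")
    meta["degenerate"] = False
    meta["converged"] = bool(fit.converged)
    return LmmResult(table=table, metadata=meta)


def confidence_rt_correlation(df: pd.DataFrame) -> tuple[float, float]:
    """Pearson correlation between trial-level confidence and RT.

    Returns ``(r, p)``.  Raises on fewer than 3 pairs or zero variance
    in either variable.
    """
    pairs = df.dropna(subset=["confidence", "rt_ms"])
    if len(pairs) < 3:
        raise ValueError("need at least 3 paired observations")
    c = np.asarray(pairs["confidence"], dtype=float)
    r = np.asarray(pairs["rt_ms"], dtype=float)
    if np.std(c) == 0 or np.std(r) == 0:
        raise ValueError("correlation undefined: zero variance")
    res = stats.pearsonr(c, r)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# head movement


def angles_from_pose(
    positions: np.ndarray,
    view_dirs: np.ndarray,
    object_pos: np.ndarray,
) -> np.ndarray:
    """Per-axis angles between the viewing direction and the head-to-object vector.

    For each axis the two vectors are projected onto the plane
    perpendicular to that axis and the signed angle between the
    projections (about the axis) is returned, degrees; collinear vectors
    give 0 on every axis.  ``positions``/``view_dirs`` are (n, 3).
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    view_dirs = np.atleast_2d(np.asarray(view_dirs, dtype=float))
    to_obj = np.asarray(object_pos, dtype=float) - positions
    out = np.zeros((positions.shape[0], 3))
    for k in range(3):
        keep = [i for i in range(3) if i != k]
        a = view_dirs[:, keep]
        b = to_obj[:, keep]
        cross = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
        dot = np.einsum("ij,ij->i", a, b)
        ang = np.degrees(np.arctan2(cross, dot))
        # degenerate projections (vector parallel to the axis) -> 0
        ang[(np.linalg.norm(a, axis=1) < 1e-12) | (np.linalg.norm(b, axis=1) < 1e-12)] = 0.0
        out[:, k] = ang
    return out


def head_movement_stats(traces: pd.DataFrame) -> pd.DataFrame:
    """Per-trial median and percentile range of head angles, per axis.

    ``traces`` is the long-format head-pose table (columns ``trial``,
    ``angle_x``, ``angle_y``, ``angle_z``, optionally ``subject``).  The
    percentile range is Q3 - Q1 with linear quantile interpolation
    (numpy's default rule).
    """
    axis_cols = ["angle_x", "angle_y", "angle_z"]
    keys = [c for c in ("subject", "session", "trial") if c in traces.columns]
    if not keys:
        raise ValueError("traces need at least a 'trial' column")
    rows = []
    for key, grp in traces.groupby(keys, observed=True):
        if len(grp) < 2:
            raise ValueError("each trace needs >= 2 samples")
        key = key if isinstance(key, tuple) else (key,)
        row = dict(zip(keys, key))
        for col in axis_cols:
            v = np.asarray(grp[col], dtype=float)
            q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75])
            row[f"median_{col[-1]}"] = med
            row[f"range_{col[-1]}"] = q3 - q1
        rows.append(row)
    return pd.DataFrame(rows).set_index(keys)


# ---------------------------------------------------------------------------
# calibration


def lmm_null_rejection_rate(
    n_reps: int = 1000,
    *,
    n_subjects: int = 5,
    n_per_cell: int = 20,
    n_levels: int = 2,
    subject_sd: float = 0.5,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Empirical type-I error of the LMM F test under a null simulation.

    Generates datasets in which a balanced within-subject factor has no
    effect (response = subject offset + noise), fits the mixed model and
    returns the fraction of replicates with p < ``alpha`` for that
    factor.  A calibrated test should land near ``alpha``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x714A]))
    levels = [f"L{i}" for i in range(n_levels)]
    n_rows = n_subjects * n_levels * n_per_cell
    subjects = np.repeat([f"S{i}" for i in range(n_subjects)], n_levels * n_per_cell)
    factor = np.tile(np.repeat(levels, n_per_cell), n_subjects)
    rejections = 0
    for _ in range(n_reps):
        offsets = np.repeat(
            rng.normal(0, subject_sd, n_subjects), n_levels * n_per_cell
        )
        df = pd.DataFrame(
            {
                "subject": subjects,
                "factor": factor,
                "y": offsets + rng.standard_normal(n_rows),
            }
        )
        res = lmm_anova(df, "y", ["factor"], "subject")
        if res.p("factor") < alpha:
            rejections += 1
    return rejections / n_reps
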