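"""Movement kinematics: filtering, tangential velocity, velocity-threshold
segmentation, temporal parameters, time-normalised trajectories, and
repeated-measures ANOVAs across conditions.

Segmentation follows the relative-threshold rule: a movement begins at the
first sample whose tangential speed reaches 5 % of the trial's peak speed and
ends at the first sample after the peak where speed falls back below that
threshold.  Trials whose speed profile carries more than one prominent peak
(several maxima above half the global peak) reflect target-selection errors
and are flagged invalid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import signal, stats

from .core import CONDITIONS, RunConfig, TrialRecording

__all__ = [
    "Segmentation",
    "SegmentedMovement",
    "exponential_filter",
    "tangential_velocity",
    "segment_movement",
    "temporal_parameters",
    "resample_trajectory",
    "repeated_measures_anova",
    "pointwise_condition_anova",
    "temporal_anova",
    "TEMPORAL_PARAMETERS",
]

logger = logging.getLogger(__name__)

#: Temporal parameters reported per trial and compared across conditions.
TEMPORAL_PARAMETERS = (
    "cRT_ms",
    "dur_ms",
    "ttp_ms",
    "maxvel_mm_s",
    "meanvel_mm_s",
    "distance_mm",
)


def exponential_filter(
    series: np.ndarray, coefficient: float = 0.1, *, recursive: bool = True
) -> np.ndarray:
    """Smooth a series with the single-coefficient exponential filter.

    With ``recursive=True`` (default) each output blends the previous
    *filtered* value with the new sample,
    ``xx[i] = xx[i-1] + (x[i] - xx[i-1]) * c``, initialised ``xx[0] = x[0]``
    — the conventional first-order exponential smoother.  With
    ``recursive=False`` the literal two-tap blend of the raw previous sample,
    ``xx[i] = x[i-1] + (x[i] - x[i-1]) * c``, is applied instead.

    Applied independently along each column of a 2-D input (axis 0 = time).
    """
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("cannot filter an empty series")
    if not 0.0 < coefficient <= 1.0:
        raise ValueError(f"coefficient must lie in (0, 1], got {coefficient}")
    if not recursive:
        out = x.copy()
        out[1:] = x[:-1] + (x[1:] - x[:-1]) * coefficient
        return out
    b = np.array([coefficient])
    a = np.array([1.0, -(1.0 - coefficient)])
    # initial condition chosen so xx[0] == x[0]
    zi = (1.0 - coefficient) * x[:1]
    if x.ndim == 1:
        out, _ = signal.lfilter(b, a, x, zi=zi)
    else:
        out, _ = signal.lfilter(b, a, x, axis=0, zi=zi)
    return out


def tangential_velocity(trajectory: np.ndarray, sampling_rate_hz: float) -> np.ndarray:
    """Instantaneous tangential speed (mm/s) of a (filtered) trajectory.

    Central differences on interior samples, one-sided at the boundaries;
    output has the same length as the input.
    """
    pos = np.asarray(trajectory, dtype=float)
    if pos.shape[0] < 2:
        raise ValueError("velocity needs at least two samples")
    if sampling_rate_hz <= 0:
        raise ValueError("sampling_rate_hz must be positive")
    deriv = np.gradient(pos, axis=0) * sampling_rate_hz
    if pos.ndim == 1:
        return np.abs(deriv)
    return np.linalg.norm(deriv, axis=1)


class Segmentation(NamedTuple):
    onset_index: int
    offset_index: int
    peak_index: int
    peak_count: int
    valid: bool
    offset_clipped: bool  # velocity never fell back below threshold


def _count_peaks(velocity: np.ndarray, level: float, prominence: float) -> int:
    """Distinct velocity peaks above ``level``.

    A countable peak must rise at least ``prominence`` above the deepest
    surrounding valley, so measurement micro-jitter on a flat peak does not
    split one movement into several.  Boundary samples count when they are
    strict local maxima above the level.
    """
    v = velocity
    n = v.shape[0]
    peaks, _ = signal.find_peaks(v, height=level, prominence=prominence)
    count = int(peaks.size)
    if n >= 2 and v[0] > v[1] and v[0] > level:
        count += 1
    if n >= 2 and v[-1] > v[-2] and v[-1] > level:
        count += 1
    return count


def segment_movement(
    velocity: np.ndarray,
    threshold_frac: float = 0.05,
    peak_multiplicity_frac: float = 0.5,
) -> Segmentation:
    """Locate movement onset and offset by the relative velocity threshold.

    Onset is the first sample with ``v >= threshold_frac * max(v)`` (searched
    from the series start); offset is the first sample after the global peak
    with ``v`` strictly below the threshold, or the final sample (with a
    logged warning) if speed never falls back.  ``valid`` is ``False`` when
    more than one strict local maximum exceeds
    ``peak_multiplicity_frac * max(v)``.
    """
    v = np.asarray(velocity, dtype=float)
    if v.size < 2:
        raise ValueError("velocity series too short to segment")
    vmax = float(np.max(v))
    if vmax <= 0.0:
        raise ValueError("no movement: velocity has no positive maximum")
    threshold = threshold_frac * vmax
    onset = int(np.argmax(v >= threshold))
    peak = int(np.argmax(v))
    after = v[peak + 1 :] < threshold
    clipped = not bool(after.any())
    if clipped:
        offset = v.shape[0] - 1
        logger.warning(
            "velocity never fell below %.3g after the peak; offset clipped to "
            "the final sample",
            threshold,
        )
    else:
        offset = peak + 1 + int(np.argmax(after))
    peak_count = _count_peaks(v, peak_multiplicity_frac * vmax, threshold_frac * vmax)
    return Segmentation(
        onset_index=onset,
        offset_index=offset,
        peak_index=peak,
        peak_count=peak_count,
        valid=peak_count == 1,
        offset_clipped=clipped,
    )


@dataclass
class SegmentedMovement:
    """Temporal parameters of one segmented pointing movement.

    ``cRT_ms`` corrects the recorded reaction time by the gap between the
    button release and the detected movement onset; ``meanvel`` is the
    straight-line start-to-end distance divided by movement duration.
    """

    onset_index: int
    offset_index: int
    peak_index: int
    cRT_ms: float
    dur_ms: float
    ttp_ms: float
    maxvel_mm_s: float
    meanvel_mm_s: float
    distance_mm: float
    valid: bool
    peak_count: int
    invalid_reason: str | None = None


def temporal_parameters(
    trial: TrialRecording,
    positions: np.ndarray,
    velocity: np.ndarray,
    seg: Segmentation,
) -> SegmentedMovement:
    """Derive the per-trial temporal parameters from a segmentation.

    ``positions`` and ``velocity`` are the filtered fingertip trajectory and
    its tangential speed (same sampling grid as ``trial.t``).  A movement
    whose detected onset precedes the button release is flagged invalid.
    """
    t = trial.t
    onset, offset, peak = seg.onset_index, seg.offset_index, seg.peak_index
    release = trial.release_index()
    gap_s = float(t[onset] - t[release])
    dur_ms = float((t[offset] - t[onset]) * 1000.0)
    ttp_ms = float((t[peak] - t[onset]) * 1000.0)
    distance = float(np.linalg.norm(positions[offset] - positions[onset]))
    meanvel = distance / (dur_ms / 1000.0) if dur_ms > 0 else float("nan")
    reason = None
    valid = seg.valid
    if not seg.valid:
        reason = f"multiple velocity peaks (n={seg.peak_count})"
    if gap_s < 0:
        valid = False
        reason = "movement onset precedes button release"
        logger.warning(
            "trial %s/%s block %d: %s; excluded",
            trial.participant_id,
            trial.target_id,
            trial.block_index,
            reason,
        )
    return SegmentedMovement(
        onset_index=onset,
        offset_index=offset,
        peak_index=peak,
        cRT_ms=float(trial.rt_raw_ms + gap_s * 1000.0),
        dur_ms=dur_ms,
        ttp_ms=ttp_ms,
        maxvel_mm_s=float(velocity[peak]),
        meanvel_mm_s=meanvel,
        distance_mm=distance,
        valid=valid,
        peak_count=seg.peak_count,
        invalid_reason=reason,
    )


def resample_trajectory(
    positions: np.ndarray,
    t: np.ndarray,
    onset_index: int,
    offset_index: int,
    n_points: int = 20,
) -> np.ndarray:
    """Time-normalise the segmented trajectory to ``n_points`` samples.

    Points are taken at ``t_onset + k * dur / n_points`` for ``k = 1..n``,
    positions linearly interpolated between neighbouring raw samples; the
    final point therefore coincides with the movement offset.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    if offset_index - onset_index < 1:
        raise ValueError("segment must span at least two samples")
    pos = np.asarray(positions, dtype=float)
    t = np.asarray(t, dtype=float)
    t0, t1 = t[onset_index], t[offset_index]
    tk = t0 + np.arange(1, n_points + 1) * (t1 - t0) / n_points
    seg_t = t[onset_index : offset_index + 1]
    seg_p = pos[onset_index : offset_index + 1]
    if seg_p.ndim == 1:
        return np.interp(tk, seg_t, seg_p)
    return np.column_stack([np.interp(tk, seg_t, seg_p[:, j]) for j in range(seg_p.shape[1])])


def _rm_anova_arrays(y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One-way repeated-measures ANOVA on a ``(..., subjects, conditions)``
    stack of cell means; returns broadcast arrays of F and p.

    The condition effect is tested against the subject-by-condition
    interaction (the classical within-subject error term).  Degenerate
    inputs follow the convention F = 0, p = 1 when the condition sum of
    squares vanishes.
    """
    y = np.asarray(y, dtype=float)
    n_subj, n_cond = y.shape[-2], y.shape[-1]
    if n_subj < 2 or n_cond < 2:
        raise ValueError("repeated-measures ANOVA needs >= 2 subjects and >= 2 conditions")
    grand = y.mean(axis=(-2, -1), keepdims=True)
    cond_m = y.mean(axis=-2, keepdims=True)
    subj_m = y.mean(axis=-1, keepdims=True)
    ss_cond = (n_subj * (cond_m - grand) ** 2).sum(axis=(-2, -1))
    resid = y - cond_m - subj_m + grand
    ss_err = (resid**2).sum(axis=(-2, -1))
    df_cond = n_cond - 1
    df_err = (n_cond - 1) * (n_subj - 1)
    scale = (y**2).mean(axis=(-2, -1)) + 1.0
    tiny = 1e-12 * scale
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ss_cond / df_cond) / (ss_err / df_err)
    F = np.where(ss_cond <= tiny, 0.0, F)
    F = np.where((ss_err <= tiny) & (ss_cond > tiny), np.inf, F)
    p = stats.f.sf(F, df_cond, df_err)
    p = np.where(F == 0.0, 1.0, p)
    return np.atleast_1d(F), np.atleast_1d(p)


def repeated_measures_anova(
    cell_means: pd.DataFrame,
    subject: str = "participant",
    condition: str = "condition",
    value: str = "value",
) -> tuple[float, float]:
    """F and p for a one-way within-subject ANOVA on one value per
    subject-condition cell (long format)."""
    wide = cell_means.pivot_table(index=subject, columns=condition, values=value)
    if wide.isna().any().any():
        missing = wide[wide.isna().any(axis=1)].index.tolist()
        raise ValueError(f"subject(s) missing a condition: {missing}")
    F, p = _rm_anova_arrays(wide.to_numpy()[None, :, :])
    return float(F[0]), float(p[0])


def _cell_mean_stack(
    df: pd.DataFrame,
    group_col: str,
    conditions: Sequence,
) -> tuple[np.ndarray, list, list]:
    """Per-(group value, participant, condition) means as a dense stack."""
    participants = sorted(df["participant"].unique())
    groups = sorted(df[group_col].unique())
    agg = df.groupby([group_col, "participant", "condition"], observed=True)["value"].mean()
    stack = np.empty((len(groups), len(participants), len(conditions)))
    for gi, g in enumerate(groups):
        for pi, p in enumerate(participants):
            for ci, c in enumerate(conditions):
                key = (g, p, c)
                if key not in agg.index:
                    raise ValueError(
                        f"participant {p!r} has no data for condition "
                        f"{getattr(c, 'value', c)!r} (at {group_col}={g!r})"
                    )
                stack[gi, pi, ci] = agg.loc[key]
    return stack, groups, participants


def pointwise_condition_anova(
    resampled: pd.DataFrame,
    alpha: float = 0.05,
    conditions: Sequence = CONDITIONS,
) -> pd.DataFrame:
    """Condition effect at each time-normalised trajectory point.

    ``resampled`` is long-format with columns ``participant``, ``condition``,
    ``point`` (1-based resample index) and ``value`` (the coordinate on the
    axis under test).  Per-trial values are first averaged into one mean per
    participant and condition at each point, then submitted to the
    within-subject ANOVA.  Returns one row per point with F, p and a
    significance flag at ``alpha``.
    """
    stack, points, _ = _cell_mean_stack(resampled, "point", list(conditions))
    F, p = _rm_anova_arrays(stack)
    means = (
        resampled.groupby(["point", "condition"], observed=True)["value"].mean().unstack()
    )
    out = pd.DataFrame({"point": points, "F": F, "p": p})
    for cond in conditions:
        label = getattr(cond, "value", str(cond))
        out[f"mean_{label}"] = means[cond].to_numpy()
    out["significant"] = out["p"] < alpha
    return out


def temporal_anova(
    params: pd.DataFrame,
    parameters: Sequence[str] = TEMPORAL_PARAMETERS,
    alpha: float = 0.05,
    conditions: Sequence = CONDITIONS,
) -> pd.DataFrame:
    """Condition effect on each temporal parameter (one row per parameter).

    ``params`` holds one row per valid trial with columns ``participant``,
    ``condition`` and the parameter columns.  Per-condition mean and SD of
    the raw trials are reported alongside F and p from the within-subject
    ANOVA on participant means.
    """
    rows = []
    for name in parameters:
        long = params.rename(columns={name: "value"})[
            ["participant", "condition", "value"]
        ].assign(point=0)
        stack, _, _ = _cell_mean_stack(long, "point", list(conditions))
        F, p = _rm_anova_arrays(stack)
        row: dict[str, object] = {"parameter": name, "F": float(F[0]), "p": float(p[0])}
        for cond in conditions:
            sel = params.loc[params["condition"] == cond, name]
            label = getattr(cond, "value", str(cond))
            row[f"{label}_mean"] = float(sel.mean())
            row[f"{label}_sd"] = float(sel.std(ddof=1))
        row["significant"] = row["p"] < alpha
        rows.append(row)
    return pd.DataFrame(rows)


def process_trial(
    trial: TrialRecording, config: RunConfig
) -> tuple[SegmentedMovement, np.ndarray, np.ndarray]:
    """Filter, differentiate, and segment a single trial.

    Returns the :class:`SegmentedMovement`, the filtered fingertip
    trajectory, and the tangential speed series.
    """
    filtered = exponential_filter(trial.led1, config.filter_coefficient)
    velocity = tangential_velocity(filtered, trial.sampling_rate_hz)
    seg = segment_movement(
        velocity, config.velocity_threshold_frac, config.peak_multiplicity_frac
    )
    movement = temporal_parameters(trial, filtered, velocity, seg)
    return movement, filtered, velocity
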