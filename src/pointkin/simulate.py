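"""Synthetic pointing experiments with known ground truth.

The raw recordings of the original study are not public, so this module
generates complete stand-in datasets with the same structure: a balanced
10-participant design of 300 trials in 30 blocks (10 blocks per condition,
each of the 5 targets pointed at twice per block), 400 Hz marker streams
with quantisation-level jitter, a single-peaked minimum-jerk speed profile
toward each target, condition-dependent anisotropic 2-D endpoint scatter,
and a button channel released shortly before movement start.

Ground truth for every configured parameter is available for recovery
tests: endpoint-ellipse orientations per condition, threshold-to-threshold
movement duration per trial, and the trunk angle.

The generator's ``duration_ms`` denotes the span between the 5 %-of-peak
speed crossings — the quantity the segmentation stage measures — so the
underlying minimum-jerk movement lasts ``duration_ms / threshold_span(0.05)``
in total.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

from .core import (
    CONDITIONS,
    DEFAULT_TARGETS,
    Condition,
    CoordinateFrame,
    TrialRecording,
    ValidationError,
)
from . import io as pio

__all__ = [
    "EndpointModel",
    "GeneratorConfig",
    "TrialTruth",
    "threshold_span",
    "minimum_jerk_position",
    "sample_endpoints",
    "generate_design",
    "generate_trial",
    "generate_trials",
    "generate_experiment",
    "GROUND_TRUTH_NAME",
]

GROUND_TRUTH_NAME = "ground_truth.txt"


def threshold_span(threshold_frac: float) -> float:
    """Fraction of total minimum-jerk time between the two crossings of
    ``threshold_frac`` x peak speed.

    The minimum-jerk speed is proportional to ``tau^2 (1 - tau)^2``, so the
    crossings solve ``tau(1 - tau) = sqrt(f)/4`` and the span reduces to
    ``sqrt(1 - sqrt(f))``.
    """
    if not 0.0 < threshold_frac < 1.0:
        raise ValueError("threshold_frac must lie in (0, 1)")
    return math.sqrt(1.0 - math.sqrt(threshold_frac))


def minimum_jerk_position(tau: np.ndarray) -> np.ndarray:
    """Normalised minimum-jerk path fraction ``s(tau) = 10t^3 - 15t^4 + 6t^5``."""
    tau = np.asarray(tau, dtype=float)
    return tau**3 * (10.0 - 15.0 * tau + 6.0 * tau**2)


@dataclass(frozen=True)
class EndpointModel:
    """2-D Gaussian endpoint scatter for one condition.

    ``orientation_deg`` is the major-axis direction against the x-axis,
    ``axis_ratio`` the eigenvalue ratio ``lambda2/lambda1`` and ``scale_mm``
    the SD along the major axis.
    """

    orientation_deg: float
    axis_ratio: float = 0.25
    scale_mm: float = 10.0

    def __post_init__(self) -> None:
        if self.scale_mm < 0:
            raise ValidationError("scale_mm must be >= 0")
        if not 0.0 < self.axis_ratio <= 1.0:
            raise ValidationError("axis_ratio must lie in (0, 1]")

    def cholesky_like(self) -> np.ndarray:
        """Matrix L with covariance ``L L^T``."""
        theta = math.radians(self.orientation_deg)
        rot = np.array(
            [[math.cos(theta), -math.sin(theta)], [math.sin(theta), math.cos(theta)]]
        )
        return rot @ np.diag([self.scale_mm, self.scale_mm * math.sqrt(self.axis_ratio)])

    def covariance(self) -> np.ndarray:
        L = self.cholesky_like()
        return L @ L.T


def sample_endpoints(
    model: EndpointModel, n: int, rng: np.random.Generator | int
) -> np.ndarray:
    """Draw ``n`` endpoint deviations (mm) from the condition's 2-D Gaussian."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    z = rng.standard_normal(size=(n, 2))
    return z @ model.cholesky_like().T


#: Per-condition endpoint scatter used by default; orientations are the
#: per-condition average-ellipse angles reported for this paradigm.
def _arc_path(
    start: np.ndarray, end: np.ndarray, lift_mm: float, s: np.ndarray
) -> np.ndarray:
    """Positions along a circular arc from ``start`` to ``end`` lifted by
    ``lift_mm`` (sagitta) toward vertical, traversed at path fraction ``s``.

    The path is parametrised by arc length, so the tangential speed profile
    equals ``ds/dt`` times a constant — the speed profile shape (and its
    single peak) is preserved exactly regardless of the lift.
    """
    chord = end - start
    length = float(np.linalg.norm(chord))
    if lift_mm <= 0.0 or length <= 0.0:
        return start[None, :] + s[:, None] * chord[None, :]
    c_hat = chord / length
    lift_dir = np.array([0.0, 0.0, 1.0]) - np.dot([0.0, 0.0, 1.0], c_hat) * c_hat
    norm = float(np.linalg.norm(lift_dir))
    if norm < 1e-9:  # vertical chord: lift backward instead
        lift_dir = np.array([0.0, 1.0, 0.0]) - np.dot([0.0, 1.0, 0.0], c_hat) * c_hat
        norm = float(np.linalg.norm(lift_dir))
    n_hat = lift_dir / norm
    radius = (length**2 / 4.0 + lift_mm**2) / (2.0 * lift_mm)
    half_angle = math.asin(min(length / (2.0 * radius), 1.0))
    mid = (start + end) / 2.0
    center = mid - (radius - lift_mm) * n_hat
    theta = -half_angle + 2.0 * half_angle * s
    return (
        center[None, :]
        + radius * np.cos(theta)[:, None] * n_hat[None, :]
        + radius * np.sin(theta)[:, None] * c_hat[None, :]
    )


def _default_endpoint_models() -> dict[Condition, EndpointModel]:
    return {
        Condition.LEFT_CP: EndpointModel(orientation_deg=72.8),
        Condition.RIGHT_CP: EndpointModel(orientation_deg=112.7),
        Condition.NCP: EndpointModel(orientation_deg=100.4),
    }


def _default_target_positions() -> dict[str, tuple[float, float, float]]:
    # Cross arrangement on the table, 100 mm apart, central glass in the
    # middle; frame origin at the button-press fingertip (x right->left,
    # y front->back, z up), table surface below and in front of the hand.
    return {
        "glass": (0.0, -250.0, -150.0),
        "battery": (0.0, -150.0, -150.0),
        "saltcellar": (0.0, -350.0, -150.0),
        "lighter": (100.0, -250.0, -150.0),
        "eraser": (-100.0, -250.0, -150.0),
    }


@dataclass
class GeneratorConfig:
    """Design, trajectory, and noise parameters of a synthetic experiment.

    Defaults reproduce the study's structure: 10 participants, 3 conditions,
    5 targets, 20 repetitions per target and condition grouped into 10
    blocks per condition (each target twice per block) — 300 trials per
    participant.
    """

    n_participants: int = 10
    conditions: tuple[Condition, ...] = CONDITIONS
    targets: tuple[str, ...] = DEFAULT_TARGETS
    reps_per_target_per_condition: int = 20
    blocks_per_condition: int = 10
    endpoint_models: dict[Condition, EndpointModel] = field(
        default_factory=_default_endpoint_models
    )
    target_positions: dict[str, tuple[float, float, float]] = field(
        default_factory=_default_target_positions
    )
    start_position: tuple[float, float, float] = (0.0, 0.0, 0.0)
    duration_ms: float = 600.0
    duration_jitter_ms: float = 50.0
    arc_height_mm: float = 15.0
    pre_hold_ms: float = 150.0
    post_hold_ms: float = 100.0
    button_gap_range_ms: tuple[float, float] = (10.0, 40.0)
    rt_mean_ms: float = 700.0
    rt_sd_ms: float = 120.0
    # quantisation-level marker noise: 0.1 mm resolution / sqrt(12)
    marker_jitter_mm: float = 0.03
    shoulder_left: tuple[float, float, float] = (190.0, 150.0, 380.0)
    shoulder_right: tuple[float, float, float] = (-190.0, 150.0, 380.0)
    trunk_jitter_deg: float = 1.0
    #: optional per-condition (x shift at movement end, z bump at movement
    #: start) in mm; exercises the pointwise trajectory ANOVA
    bias_ramp_mm: Mapping[Condition, tuple[float, float]] | None = None
    sampling_rate_hz: float = 400.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValidationError("n_participants must be >= 1")
        if self.reps_per_target_per_condition % self.blocks_per_condition:
            raise ValidationError(
                "blocks_per_condition must divide reps_per_target_per_condition"
            )
        if self.duration_ms <= 0:
            raise ValidationError("duration_ms must be positive")
        missing = set(self.targets) - set(self.target_positions)
        if missing:
            raise ValidationError(f"targets without positions: {sorted(missing)}")
        missing_models = set(self.conditions) - set(self.endpoint_models)
        if missing_models:
            raise ValidationError(
                f"conditions without endpoint models: {sorted(missing_models)}"
            )

    @property
    def trials_per_participant(self) -> int:
        return (
            self.reps_per_target_per_condition
            * len(self.targets)
            * len(self.conditions)
        )

    @property
    def blocks_per_participant(self) -> int:
        return self.blocks_per_condition * len(self.conditions)

    @property
    def reps_per_block(self) -> int:
        return self.reps_per_target_per_condition // self.blocks_per_condition

    def participant_ids(self) -> list[str]:
        return [f"P{i + 1:02d}" for i in range(self.n_participants)]


@dataclass(frozen=True)
class TrialTruth:
    """Generator-side ground truth for one trial."""

    duration_ms: float  # threshold-to-threshold span
    ttp_ms: float  # onset-to-peak time (= duration/2, symmetric profile)
    endpoint_xy: tuple[float, float]
    trunk_angle_deg: float
    movement_start_s: float
    release_time_s: float


def _design_rng(config: GeneratorConfig) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), 1]))


def _trial_rng(config: GeneratorConfig, p_idx: int, trial_idx: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(config.seed), 2, int(p_idx), int(trial_idx)])
    )


def generate_design(config: GeneratorConfig) -> pd.DataFrame:
    """Balanced per-participant trial schedule.

    Block condition order is counterbalanced across participants by rotating
    the condition cycle; within each block the target sequence (each target
    ``reps/blocks`` times) is randomised from the design seed.

    Returns a DataFrame with columns ``participant, trial_index, block,
    condition, target``.
    """
    rng = _design_rng(config)
    n_cond = len(config.conditions)
    rows = []
    for p_idx, pid in enumerate(config.participant_ids()):
        rotation = p_idx % n_cond
        cycle = (
            list(config.conditions[rotation:]) + list(config.conditions[:rotation])
        )
        block_conditions = cycle * config.blocks_per_condition
        trial_idx = 0
        for block, cond in enumerate(block_conditions, start=1):
            targets = np.repeat(np.array(config.targets, dtype=object), config.reps_per_block)
            rng.shuffle(targets)
            for target in targets:
                rows.append(
                    {
                        "participant": pid,
                        "trial_index": trial_idx,
                        "block": block,
                        "condition": cond.value,
                        "target": str(target),
                    }
                )
                trial_idx += 1
    return pd.DataFrame(rows)


def generate_trial(
    config: GeneratorConfig,
    participant_idx: int,
    trial_index: int,
    block: int,
    condition: Condition,
    target: str,
) -> tuple[TrialRecording, TrialTruth]:
    """Synthesise one trial's marker streams plus its ground truth.

    The fingertip follows a straight line to the sampled endpoint with a
    minimum-jerk speed profile and a small vertical lift arc shaped by
    ``sin(pi * s)`` (zero path speed contribution at both ends, so the speed
    profile keeps a single peak).  The button channel switches off a sampled
    10-40 ms before movement start to exercise the reaction-time correction.
    """
    if config.duration_ms <= 0:
        raise ValidationError("duration_ms must be positive")
    rng = _trial_rng(config, participant_idx, trial_index)
    fs = config.sampling_rate_hz
    model = config.endpoint_models[condition]
    target_pos = np.asarray(config.target_positions[target], dtype=float)
    start = np.asarray(config.start_position, dtype=float)

    deviation = sample_endpoints(model, 1, rng)[0]
    bias_x = bias_z = 0.0
    if config.bias_ramp_mm and condition in config.bias_ramp_mm:
        bias_x, bias_z = config.bias_ramp_mm[condition]
    end = target_pos + np.array([deviation[0] + bias_x, deviation[1], 0.0])

    d5_ms = config.duration_ms
    if config.duration_jitter_ms > 0:
        d5_ms = max(config.duration_ms + rng.normal(0.0, config.duration_jitter_ms), 200.0)
    span = threshold_span(0.05)
    total_s = d5_ms / 1000.0 / span

    n_pre = int(round(config.pre_hold_ms / 1000.0 * fs))
    n_mov = int(round(total_s * fs))
    n_post = int(round(config.post_hold_ms / 1000.0 * fs))
    n = n_pre + n_mov + n_post + 1
    t = np.arange(n) / fs
    t_move = t[n_pre]

    tau = np.clip((t - t_move) / total_s, 0.0, 1.0)
    s = minimum_jerk_position(tau)
    pos = _arc_path(start, end, config.arc_height_mm, s)
    if bias_z:
        # start-loaded vertical bump, back to zero by mid-movement
        pos[:, 2] += bias_z * np.sin(np.pi * np.minimum(2.0 * s, 1.0))

    trunk_angle = rng.normal(0.0, config.trunk_jitter_deg) if config.trunk_jitter_deg > 0 else 0.0
    theta = math.radians(trunk_angle)
    rot = np.array([[math.cos(theta), -math.sin(theta)], [math.sin(theta), math.cos(theta)]])
    shoulders = np.array([config.shoulder_left, config.shoulder_right], dtype=float)
    mid = shoulders.mean(axis=0)
    for row in range(2):
        shoulders[row, :2] = mid[:2] + rot @ (shoulders[row, :2] - mid[:2])
    led3 = np.tile(shoulders[0], (n, 1))
    led4 = np.tile(shoulders[1], (n, 1))
    # the shoulder line through the rotated markers forms `trunk_angle` with x
    true_trunk = math.degrees(
        math.atan2(shoulders[0, 1] - shoulders[1, 1], shoulders[0, 0] - shoulders[1, 0])
    ) % 180.0

    if config.marker_jitter_mm > 0:
        pos = pos + rng.normal(0.0, config.marker_jitter_mm, size=pos.shape)
        led3 = led3 + rng.normal(0.0, config.marker_jitter_mm, size=led3.shape)
        led4 = led4 + rng.normal(0.0, config.marker_jitter_mm, size=led4.shape)

    gap_ms = rng.uniform(*config.button_gap_range_ms)
    release_time = t_move - gap_ms / 1000.0
    led2_on = t < release_time
    if not led2_on[0] or led2_on[-1]:
        raise ValidationError("pre/post hold too short for the button release")

    rt_raw = max(rng.normal(config.rt_mean_ms, config.rt_sd_ms), 150.0)

    trial = TrialRecording(
        participant_id=config.participant_ids()[participant_idx],
        condition=condition,
        target_id=target,
        block_index=block,
        rt_raw_ms=float(rt_raw),
        t=t,
        led1=pos,
        led2_on=led2_on,
        led3=led3,
        led4=led4,
        sampling_rate_hz=fs,
    )
    truth = TrialTruth(
        duration_ms=float(d5_ms),
        ttp_ms=float(d5_ms / 2.0),
        endpoint_xy=(float(end[0]), float(end[1])),
        trunk_angle_deg=float(true_trunk),
        movement_start_s=float(t_move),
        release_time_s=float(release_time),
    )
    return trial, truth


def generate_trials(
    config: GeneratorConfig, design: pd.DataFrame | None = None
) -> Iterator[tuple[TrialRecording, TrialTruth]]:
    """Yield every trial of the experiment (design order) with ground truth."""
    if design is None:
        design = generate_design(config)
    pid_to_idx = {pid: i for i, pid in enumerate(config.participant_ids())}
    for row in design.itertuples(index=False):
        yield generate_trial(
            config,
            participant_idx=pid_to_idx[row.participant],
            trial_index=int(row.trial_index),
            block=int(row.block),
            condition=Condition.parse(row.condition),
            target=str(row.target),
        )


def _ground_truth_lines(config: GeneratorConfig) -> list[str]:
    lines = [
        f"seed = {config.seed}",
        f"n_participants = {config.n_participants}",
        f"trials_per_participant = {config.trials_per_participant}",
        f"duration_ms = {config.duration_ms}",
        f"duration_jitter_ms = {config.duration_jitter_ms}",
        f"marker_jitter_mm = {config.marker_jitter_mm}",
        f"trunk_angle_deg = 0.0",
        f"trunk_jitter_deg = {config.trunk_jitter_deg}",
    ]
    for cond in config.conditions:
        model = config.endpoint_models[cond]
        lines += [
            f"{cond.value}.orientation_deg = {model.orientation_deg}",
            f"{cond.value}.axis_ratio = {model.axis_ratio}",
            f"{cond.value}.scale_mm = {model.scale_mm}",
        ]
    return lines


def generate_experiment(config: GeneratorConfig, path: str | Path) -> Path:
    """Write a full synthetic dataset (trials + manifest + ground-truth
    sidecar) in the package's on-disk format; deterministic per seed."""
    root = Path(path)
    trials = (trial for trial, _ in generate_trials(config))
    pio.write_trials(trials, root, frame=CoordinateFrame())
    (root / GROUND_TRUTH_NAME).write_text(
        "\n".join(_ground_truth_lines(config)) + "\n", encoding="utf-8"
    )
    return root
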