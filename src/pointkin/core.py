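"""Core domain types: conditions, trial recordings, coordinate frame, run configuration.

The experiment this package analyses records repeated right-hand pointing
gestures toward a small array of table-top objects under three instruction
conditions: pointing for a left addressee (``LEFT_CP``), for a right addressee
(``RIGHT_CP``), or for nobody (``NCP``).  An optical tracker samples active
LED markers at 400 Hz: LED1 on the index fingertip, LED2 switched by the
response button, LED3/LED4 on the shoulders.

Coordinates follow the body-centred frame fixed at the button-press fingertip
position: x runs horizontally from the participant's right to left (parallel
to the shoulder line), y horizontally front to back, z vertically bottom to
up.  All positions are millimetres, all times seconds; milliseconds appear
only in reported quantities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from enum import Enum

import numpy as np

__all__ = [
    "Condition",
    "CONDITIONS",
    "DEFAULT_TARGETS",
    "CENTRAL_TARGET",
    "ValidationError",
    "TrialRecording",
    "CoordinateFrame",
    "RunConfig",
]


class Condition(str, Enum):
    """Communicative context of a pointing gesture."""

    LEFT_CP = "left_cp"
    RIGHT_CP = "right_cp"
    NCP = "ncp"

    @classmethod
    def parse(cls, text: "str | Condition") -> "Condition":
        if isinstance(text, cls):
            return text
        key = str(text).strip().lower()
        for cond in cls:
            if key in (cond.value, cond.name.lower()):
                return cond
        raise ValidationError(f"unknown condition {text!r}")


CONDITIONS: tuple[Condition, ...] = (
    Condition.LEFT_CP,
    Condition.RIGHT_CP,
    Condition.NCP,
)

#: The five target objects; the round glass sits at the centre of the cross
#: arrangement and, being isotropic, is the principal target for the
#: endpoint-variability analysis.
DEFAULT_TARGETS: tuple[str, ...] = (
    "glass",
    "battery",
    "lighter",
    "saltcellar",
    "eraser",
)
CENTRAL_TARGET: str = "glass"


class ValidationError(ValueError):
    """A recording, file, or configuration violates its invariants."""


@dataclass
class TrialRecording:
    """Raw multi-marker time series plus metadata for one pointing trial.

    Parameters
    ----------
    t
        Sample times in seconds, strictly increasing and uniform at
        ``1 / sampling_rate_hz``.
    led1, led3, led4
        ``(n, 3)`` marker positions in mm (fingertip, left shoulder,
        right shoulder).
    led2_on
        Button-state channel; ``True`` while the answer button is held.
        Exactly one ``True -> False`` transition (the button release).
    rt_raw_ms
        Reaction time from stimulus onset to button release, as recorded by
        the stimulus computer (to be corrected downstream).
    """

    participant_id: str
    condition: Condition
    target_id: str
    block_index: int
    rt_raw_ms: float
    t: np.ndarray
    led1: np.ndarray
    led2_on: np.ndarray
    led3: np.ndarray
    led4: np.ndarray
    sampling_rate_hz: float = 400.0

    def __post_init__(self) -> None:
        self.condition = Condition.parse(self.condition)
        self.t = np.asarray(self.t, dtype=float)
        self.led1 = np.asarray(self.led1, dtype=float)
        self.led2_on = np.asarray(self.led2_on).astype(bool)
        self.led3 = np.asarray(self.led3, dtype=float)
        self.led4 = np.asarray(self.led4, dtype=float)

    @property
    def n_samples(self) -> int:
        return int(self.t.shape[0])

    def validate(self) -> None:
        """Raise :class:`ValidationError` on any invariant violation."""
        n = self.n_samples
        if n < 2:
            raise ValidationError("trial needs at least two samples")
        for name in ("led1", "led3", "led4"):
            arr = getattr(self, name)
            if arr.shape != (n, 3):
                raise ValidationError(
                    f"{name} has shape {arr.shape}, expected ({n}, 3)"
                )
            if not np.isfinite(arr).all():
                bad = int(np.argwhere(~np.isfinite(arr))[0, 0])
                raise ValidationError(f"{name} non-finite at sample {bad}")
        if self.led2_on.shape != (n,):
            raise ValidationError("led2_on length mismatch")
        if not np.isfinite(self.t).all():
            raise ValidationError("non-finite timestamp")
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            bad = int(np.argmax(dt <= 0))
            raise ValidationError(
                f"timestamps not strictly increasing at sample {bad + 1}"
            )
        if self.sampling_rate_hz <= 0:
            raise ValidationError("sampling_rate_hz must be positive")
        step = 1.0 / self.sampling_rate_hz
        if np.any(np.abs(dt - step) > 1e-9):
            bad = int(np.argmax(np.abs(dt - step) > 1e-9))
            raise ValidationError(
                f"non-uniform sampling at sample {bad + 1}: dt={dt[bad]:.9g}, "
                f"expected {step:.9g}"
            )
        state = self.led2_on.astype(int)
        falls = int(np.sum(np.diff(state) == -1))
        rises = int(np.sum(np.diff(state) == 1))
        if falls != 1 or rises != 0:
            raise ValidationError(
                "led2_on must switch True->False exactly once "
                f"(found {falls} releases, {rises} presses)"
            )
        if self.block_index < 1:
            raise ValidationError("block_index must be >= 1")

    def release_index(self) -> int:
        """First sample at which the answer button is no longer held."""
        state = self.led2_on.astype(int)
        return int(np.argmax(np.diff(state) == -1)) + 1


@dataclass(frozen=True)
class CoordinateFrame:
    """Right-handed body-centred frame used for all positions.

    The origin is the fingertip position while pressing the start button;
    x points right -> left along the shoulder line, y front -> back, z up.
    """

    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    x_axis: tuple[float, float, float] = (1.0, 0.0, 0.0)
    y_axis: tuple[float, float, float] = (0.0, 1.0, 0.0)
    z_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)

    def validate(self) -> None:
        axes = np.array([self.x_axis, self.y_axis, self.z_axis], dtype=float)
        if not np.allclose(axes @ axes.T, np.eye(3), atol=1e-9):
            raise ValidationError("frame axes must be orthonormal")
        if np.linalg.det(axes) < 0:
            raise ValidationError("frame must be right-handed (x, y, z order)")

    def describe(self) -> str:
        return (
            "origin=button-press fingertip; x=right->left (shoulder line); "
            "y=front->back; z=bottom->up; units mm"
        )


def _check_fraction(name: str, value: float) -> None:
    if not 0.0 < value <= 1.0:
        raise ValidationError(f"{name} must lie in (0, 1], got {value}")


@dataclass
class RunConfig:
    """Analysis constants, all tunable in one place.

    Attributes
    ----------
    filter_coefficient
        Blend weight of the exponential position filter (0.1: heavy
        smoothing appropriate for 400 Hz marker data).
    velocity_threshold_frac
        Movement onset/offset threshold as a fraction of peak tangential
        speed (0.05 = the 5 % rule).
    resample_points
        Number of time-normalised trajectory points (20).
    cooks_cutoff
        Cook's-distance cutoff for endpoint outlier exclusion (0.25).
    n_permutations
        Monte-Carlo resamples for the orientation tests (10,000).
    peak_multiplicity_frac
        A trial is invalid when its speed profile has more than one strict
        local maximum exceeding this fraction of the global peak.
    alpha
        Significance level used to flag ANOVA and permutation results.
    """

    filter_coefficient: float = 0.1
    velocity_threshold_frac: float = 0.05
    resample_points: int = 20
    cooks_cutoff: float = 0.25
    n_permutations: int = 10_000
    rng_seed: int = 0
    peak_multiplicity_frac: float = 0.5
    alpha: float = 0.05

    def __post_init__(self) -> None:
        _check_fraction("filter_coefficient", self.filter_coefficient)
        _check_fraction("velocity_threshold_frac", self.velocity_threshold_frac)
        _check_fraction("peak_multiplicity_frac", self.peak_multiplicity_frac)
        _check_fraction("alpha", self.alpha)
        if int(self.resample_points) < 2:
            raise ValidationError("resample_points must be >= 2")
        if int(self.n_permutations) < 1:
            raise ValidationError("n_permutations must be >= 1")
        if not math.isfinite(self.cooks_cutoff) and self.cooks_cutoff < 0:
            raise ValidationError("cooks_cutoff must be nonnegative")
        self.resample_points = int(self.resample_points)
        self.n_permutations = int(self.n_permutations)
        self.rng_seed = int(self.rng_seed)

    def to_mapping(self) -> dict[str, object]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_mapping(cls, mapping: dict[str, object]) -> "RunConfig":
        kwargs: dict[str, object] = {}
        known = {f.name: f.type for f in fields(cls)}
        for key, raw in mapping.items():
            if key not in known:
                raise ValidationError(f"unknown config key {key!r}")
            if key in ("resample_points", "n_permutations", "rng_seed"):
                kwargs[key] = int(float(raw))  # tolerate "10000.0"
            else:
                kwargs[key] = float(raw)
        return cls(**kwargs)
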