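"""On-disk formats: per-trial marker files, the trial manifest, run
configuration, and results tables.

The raw export format of the tracking hardware is not standardised, so the
package defines its own plain-text dialect: UTF-8 comma-separated values with
``.`` as decimal separator, one file per trial plus a ``manifest.csv`` of
trial metadata.  The coordinate frame is recorded as a comment line at the
top of the manifest.

Trial file columns (markers 1, 3, 4; ``led2`` is the button channel, 0/1)::

    t,x1,y1,z1,led2,x3,y3,z3,x4,y4,z4

Manifest columns::

    participant,condition,target,block,rt_raw_ms,trial_file
"""

from __future__ import annotations

import logging
from collections import Counter
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .core import Condition, CoordinateFrame, RunConfig, TrialRecording, ValidationError

__all__ = [
    "FormatError",
    "TRIAL_COLUMNS",
    "MANIFEST_COLUMNS",
    "read_trials",
    "write_trials",
    "read_config",
    "write_config",
    "read_results",
    "write_results",
]

logger = logging.getLogger(__name__)

def _FLOAT_FORMAT(value: float) -> str:
    """Shortest decimal representation that round-trips exactly."""
    return repr(float(value))

TRIAL_COLUMNS = ["t", "x1", "y1", "z1", "led2", "x3", "y3", "z3", "x4", "y4", "z4"]
MANIFEST_COLUMNS = ["participant", "condition", "target", "block", "rt_raw_ms", "trial_file"]
MANIFEST_NAME = "manifest.csv"


class FormatError(ValidationError):
    """A file does not conform to the documented dialect."""


def _read_trial_file(path: Path, sampling_rate_hz: float) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # malformed CSV
        raise FormatError(f"{path.name}: unreadable trial file ({exc})") from exc
    if list(df.columns) != TRIAL_COLUMNS:
        missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
        raise FormatError(
            f"{path.name}: malformed header {list(df.columns)}"
            + (f", missing column(s) {missing}" if missing else "")
        )
    numeric = [c for c in TRIAL_COLUMNS if c != "led2"]
    values = df[numeric].to_numpy()
    if not np.isfinite(values).all():
        row = int(np.argwhere(~np.isfinite(values))[0, 0])
        raise FormatError(f"{path.name}: non-finite value at line {row + 2}")
    t = df["t"].to_numpy(dtype=float)
    dt = np.diff(t)
    if np.any(dt <= 0):
        row = int(np.argmax(dt <= 0)) + 1
        raise FormatError(
            f"{path.name}: time not strictly increasing at line {row + 2}"
        )
    step = 1.0 / sampling_rate_hz
    if np.any(np.abs(dt - step) > 1e-9):
        row = int(np.argmax(np.abs(dt - step) > 1e-9)) + 1
        raise FormatError(f"{path.name}: non-uniform sampling at line {row + 2}")
    led2 = df["led2"].to_numpy()
    if not np.isin(led2, (0, 1)).all():
        row = int(np.argmax(~np.isin(led2, (0, 1))))
        raise FormatError(f"{path.name}: led2 not in {{0,1}} at line {row + 2}")
    state = led2.astype(int)
    if int(np.sum(np.diff(state) == -1)) != 1 or int(np.sum(np.diff(state) == 1)) != 0:
        raise FormatError(
            f"{path.name}: led2 must switch 1->0 exactly once over the trial"
        )
    return df


def read_trials(path: str | Path, sampling_rate_hz: float = 400.0) -> list[TrialRecording]:
    """Read a trial directory (manifest + per-trial files) into memory.

    Every trial is validated against the :class:`TrialRecording` invariants;
    the first violation raises :class:`FormatError` naming the offending file
    and line.  Trial counts per condition/target/block are logged.
    """
    root = Path(path)
    manifest_path = root / MANIFEST_NAME
    if not manifest_path.is_file():
        raise FormatError(f"no {MANIFEST_NAME} in {root}")
    manifest = pd.read_csv(manifest_path, comment="#", float_precision="round_trip")
    if list(manifest.columns) != MANIFEST_COLUMNS:
        raise FormatError(
            f"{MANIFEST_NAME}: malformed header {list(manifest.columns)}"
        )
    trials: list[TrialRecording] = []
    for row in manifest.itertuples(index=False):
        trial_path = root / str(row.trial_file)
        if not trial_path.is_file():
            raise FormatError(f"missing trial file {row.trial_file}")
        df = _read_trial_file(trial_path, sampling_rate_hz)
        trial = TrialRecording(
            participant_id=str(row.participant),
            condition=Condition.parse(row.condition),
            target_id=str(row.target),
            block_index=int(row.block),
            rt_raw_ms=float(row.rt_raw_ms),
            t=df["t"].to_numpy(dtype=float),
            led1=df[["x1", "y1", "z1"]].to_numpy(dtype=float),
            led2_on=df["led2"].to_numpy().astype(bool),
            led3=df[["x3", "y3", "z3"]].to_numpy(dtype=float),
            led4=df[["x4", "y4", "z4"]].to_numpy(dtype=float),
            sampling_rate_hz=sampling_rate_hz,
        )
        try:
            trial.validate()
        except ValidationError as exc:
            raise FormatError(f"{trial_path.name}: {exc}") from exc
        trials.append(trial)
    logger.info(
        "read %d trials: conditions %s, targets %s, blocks %s",
        len(trials),
        dict(Counter(t.condition.value for t in trials)),
        dict(Counter(t.target_id for t in trials)),
        dict(Counter(t.block_index for t in trials)),
    )
    return trials


def write_trials(
    trials: Iterable[TrialRecording],
    path: str | Path,
    frame: CoordinateFrame | None = None,
) -> list[Path]:
    """Write trials and their manifest under ``path`` (created if needed).

    Values round-trip exactly: floats are written with ``repr`` precision.
    """
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    frame = frame or CoordinateFrame()
    frame.validate()
    rows = []
    written: list[Path] = []
    for i, trial in enumerate(trials):
        trial.validate()
        name = f"trial_{i:05d}.csv"
        df = pd.DataFrame(
            {
                "t": trial.t,
                "x1": trial.led1[:, 0],
                "y1": trial.led1[:, 1],
                "z1": trial.led1[:, 2],
                "led2": trial.led2_on.astype(int),
                "x3": trial.led3[:, 0],
                "y3": trial.led3[:, 1],
                "z3": trial.led3[:, 2],
                "x4": trial.led4[:, 0],
                "y4": trial.led4[:, 1],
                "z4": trial.led4[:, 2],
            }
        )
        df.to_csv(root / name, index=False, float_format=_FLOAT_FORMAT)
        written.append(root / name)
        rows.append(
            {
                "participant": trial.participant_id,
                "condition": trial.condition.value,
                "target": trial.target_id,
                "block": trial.block_index,
                "rt_raw_ms": trial.rt_raw_ms,
                "trial_file": name,
            }
        )
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    with open(root / MANIFEST_NAME, "w", encoding="utf-8") as fh:
        fh.write(f"# coordinate_frame: {frame.describe()}\n")
        manifest.to_csv(fh, index=False, float_format=_FLOAT_FORMAT)
    return written


def write_config(config: RunConfig, path: str | Path) -> None:
    """Write a :class:`RunConfig` as a flat ``key = value`` text file."""
    lines = [f"{key} = {value}" for key, value in config.to_mapping().items()]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_config(path: str | Path) -> RunConfig:
    mapping: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        text = line.strip()
        if not text or text.startswith("#"):
            continue
        if "=" not in text:
            raise FormatError(f"{path}: malformed config line {lineno}: {line!r}")
        key, _, value = text.partition("=")
        mapping[key.strip()] = value.strip()
    return RunConfig.from_mapping(mapping)


def write_results(tables: Mapping[str, pd.DataFrame], path: str | Path) -> list[Path]:
    """Write a bundle of results tables as one CSV per table.

    Empty tables still produce a header-bearing file; re-reading reproduces
    every value to full precision.
    """
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    written = []
    for name, table in tables.items():
        out = root / f"{name}.csv"
        table.to_csv(out, index=False, float_format=_FLOAT_FORMAT)
        written.append(out)
    return written


def read_results(path: str | Path) -> dict[str, pd.DataFrame]:
    root = Path(path)
    return {
        p.stem: pd.read_csv(p, float_precision="round_trip")
        for p in sorted(root.glob("*.csv"))
        if p.name != MANIFEST_NAME
    }
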