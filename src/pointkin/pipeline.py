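"""End-to-end analysis: raw trials -> kinematics -> trajectory ANOVAs ->
endpoint ellipses -> pairwise Monte-Carlo orientation tests -> trunk check.

The pipeline is a pure function of (dataset, configuration, seed): identical
inputs produce identical tables.  Every analysis constant lives in
:class:`pointkin.core.RunConfig`; every excluded trial is traceable to a
rule in the run report.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import io as pio
from .core import CENTRAL_TARGET, CONDITIONS, Condition, RunConfig, TrialRecording
from .endpoints import (
    ToleranceEllipse,
    average_ellipse,
    cooks_outlier_filter,
    covariance_ellipse,
    normalize_matrix,
    trunk_orientation,
)
from .kinematics import (
    TEMPORAL_PARAMETERS,
    pointwise_condition_anova,
    process_trial,
    resample_trajectory,
    temporal_anova,
)
from .permutation import permutation_angle_test, permutation_orientation_test

__all__ = ["RunReport", "analyze_trials", "run_analysis"]

logger = logging.getLogger(__name__)


@dataclass
class RunReport:
    """Counts, seeds, and timings of one pipeline run."""

    config: dict = field(default_factory=dict)
    n_ingested: int = 0
    n_valid: int = 0
    n_invalid: int = 0
    n_central_endpoints: int = 0
    n_outliers_excluded: int = 0
    stage_seconds: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)
    tables: list = field(default_factory=list)
    exclusions: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, default=str)


def _pair_seed(base_seed: int, kind: str, index: int) -> list[int]:
    offset = {"endpoint": 10, "trunk": 20}[kind]
    return [int(base_seed), offset + index]


def _condition_pairs(conditions: Sequence[Condition]) -> list[tuple[Condition, Condition]]:
    return list(combinations(conditions, 2))


def analyze_trials(
    trials: Iterable[TrialRecording],
    config: RunConfig | None = None,
    central_target: str = CENTRAL_TARGET,
    include_peripheral: bool = False,
) -> tuple[dict[str, pd.DataFrame], RunReport]:
    """Run the complete analysis on in-memory trials.

    Returns the results bundle (tables keyed by name) and the run report.
    Tables: ``temporal_parameters`` (per-condition mean/SD + ANOVA per
    parameter), ``pointwise_anova_x`` / ``pointwise_anova_z`` (20 rows each),
    ``ellipses`` (one row per participant x condition), ``condition_ellipses``
    (average-ellipse orientations), ``permutation`` (three endpoint pairs
    plus three trunk pairs).
    """
    config = config or RunConfig()
    report = RunReport(config=config.to_mapping())
    t_start = time.perf_counter()

    param_rows: list[dict] = []
    resampled_rows: list[dict] = []
    endpoint_store: dict[tuple[str, Condition, str], list[np.ndarray]] = {}
    trunk_store: dict[tuple[str, Condition], list[float]] = {}

    for trial in trials:
        report.n_ingested += 1
        movement, filtered, _velocity = process_trial(trial, config)
        row = {
            "participant": trial.participant_id,
            "condition": trial.condition,
            "target": trial.target_id,
            "block": trial.block_index,
            "valid": movement.valid,
            "RT_ms": trial.rt_raw_ms,
        }
        for name in TEMPORAL_PARAMETERS:
            row[name] = getattr(movement, name)
        param_rows.append(row)
        if not movement.valid:
            report.n_invalid += 1
            report.exclusions.append(
                {
                    "participant": trial.participant_id,
                    "target": trial.target_id,
                    "block": trial.block_index,
                    "rule": movement.invalid_reason or "invalid segmentation",
                }
            )
            continue
        report.n_valid += 1
        points = resample_trajectory(
            filtered, trial.t, movement.onset_index, movement.offset_index,
            config.resample_points,
        )
        for k in range(config.resample_points):
            resampled_rows.append(
                {
                    "participant": trial.participant_id,
                    "condition": trial.condition,
                    "point": k + 1,
                    "x": points[k, 0],
                    "y": points[k, 1],
                    "z": points[k, 2],
                }
            )
        endpoint_store.setdefault(
            (trial.participant_id, trial.condition, trial.target_id), []
        ).append(filtered[movement.offset_index, :2])
        trunk_store.setdefault((trial.participant_id, trial.condition), []).append(
            trunk_orientation(
                trial.led3[movement.onset_index], trial.led4[movement.onset_index]
            )
        )
    report.stage_seconds["kinematics"] = round(time.perf_counter() - t_start, 3)

    params = pd.DataFrame(param_rows)
    valid_params = params[params["valid"]]
    t0 = time.perf_counter()
    tables: dict[str, pd.DataFrame] = {}
    tables["temporal_parameters"] = temporal_anova(valid_params, alpha=config.alpha)
    resampled = pd.DataFrame(resampled_rows)
    for axis in ("x", "z"):
        tables[f"pointwise_anova_{axis}"] = pointwise_condition_anova(
            resampled.rename(columns={axis: "value"})[
                ["participant", "condition", "point", "value"]
            ],
            alpha=config.alpha,
        )
    report.stage_seconds["anova"] = round(time.perf_counter() - t0, 3)

    # ---- endpoint ellipses (central target, Cook's filter, normalisation)
    t0 = time.perf_counter()
    targets_to_analyze = [central_target]
    if include_peripheral:
        seen = {key[2] for key in endpoint_store}
        targets_to_analyze += sorted(seen - {central_target})
    ellipse_rows = []
    kept_sets: dict[Condition, dict[str, np.ndarray]] = {c: {} for c in CONDITIONS}
    per_participant: dict[Condition, list[ToleranceEllipse]] = {c: [] for c in CONDITIONS}
    for target in targets_to_analyze:
        for (pid, cond, tgt), pts in sorted(
            endpoint_store.items(), key=lambda kv: (kv[0][0], kv[0][1].value, kv[0][2])
        ):
            if tgt != target:
                continue
            cloud = np.asarray(pts)
            kept, excluded = cooks_outlier_filter(cloud, config.cooks_cutoff)
            ellipse = covariance_ellipse(kept, n_excluded=len(excluded))
            normalized = normalize_matrix(ellipse)
            if target == central_target:
                report.n_central_endpoints += len(cloud)
                report.n_outliers_excluded += len(excluded)
                kept_sets[cond][pid] = kept
                per_participant[cond].append(normalized)
                for _ in range(len(excluded)):
                    report.exclusions.append(
                        {
                            "participant": pid,
                            "target": tgt,
                            "condition": cond.value,
                            "rule": f"Cook's distance > {config.cooks_cutoff}",
                        }
                    )
            ellipse_rows.append(
                {
                    "participant": pid,
                    "condition": cond.value,
                    "target": tgt,
                    "n_points": ellipse.n_points,
                    "n_excluded": ellipse.n_excluded,
                    "cov_xx": ellipse.cov[0, 0],
                    "cov_xy": ellipse.cov[0, 1],
                    "cov_yy": ellipse.cov[1, 1],
                    "lambda1": ellipse.eigenvalues[0],
                    "lambda2": ellipse.eigenvalues[1],
                    "orientation_deg": ellipse.orientation_deg,
                    "degenerate": ellipse.degenerate,
                }
            )
    tables["ellipses"] = pd.DataFrame(ellipse_rows)

    condition_rows = []
    averages: dict[Condition, ToleranceEllipse] = {}
    for cond in CONDITIONS:
        avg = average_ellipse(per_participant[cond])
        averages[cond] = avg
        condition_rows.append(
            {
                "condition": cond.value,
                "orientation_deg": avg.orientation_deg,
                "lambda1": avg.eigenvalues[0],
                "lambda2": avg.eigenvalues[1],
                "n_participants": len(per_participant[cond]),
                "degenerate": avg.degenerate,
            }
        )
    tables["condition_ellipses"] = pd.DataFrame(condition_rows)
    report.stage_seconds["ellipses"] = round(time.perf_counter() - t0, 3)

    # ---- Monte-Carlo orientation tests (endpoints, then trunk angles)
    t0 = time.perf_counter()
    perm_rows = []
    for i, (ca, cb) in enumerate(_condition_pairs(CONDITIONS)):
        seed = _pair_seed(config.rng_seed, "endpoint", i)
        result = permutation_orientation_test(
            kept_sets[ca],
            kept_sets[cb],
            n_sims=config.n_permutations,
            seed=seed,
            pair=(ca.value, cb.value),
        )
        report.seeds[f"endpoint:{ca.value}-{cb.value}"] = seed
        perm_rows.append(
            {
                "kind": "endpoint",
                "pair": f"{ca.value} vs {cb.value}",
                "observed_diff_deg": result.observed_diff_deg,
                "N": result.exceed_count,
                "n_sims": result.n_sims,
                "p_value": result.p_value,
                "significant": result.p_value < config.alpha,
                "seed": str(seed),
            }
        )
    trunk_sets = {
        cond: {
            pid: np.asarray(angles)
            for (pid, c), angles in trunk_store.items()
            if c == cond
        }
        for cond in CONDITIONS
    }
    for i, (ca, cb) in enumerate(_condition_pairs(CONDITIONS)):
        seed = _pair_seed(config.rng_seed, "trunk", i)
        result = permutation_angle_test(
            trunk_sets[ca],
            trunk_sets[cb],
            n_sims=config.n_permutations,
            seed=seed,
            pair=(ca.value, cb.value),
        )
        report.seeds[f"trunk:{ca.value}-{cb.value}"] = seed
        perm_rows.append(
            {
                "kind": "trunk",
                "pair": f"{ca.value} vs {cb.value}",
                "observed_diff_deg": result.observed_diff_deg,
                "N": result.exceed_count,
                "n_sims": result.n_sims,
                "p_value": result.p_value,
                "significant": result.p_value < config.alpha,
                "seed": str(seed),
            }
        )
    tables["permutation"] = pd.DataFrame(perm_rows)
    report.stage_seconds["permutation"] = round(time.perf_counter() - t0, 3)
    report.tables = sorted(tables)
    return tables, report


def run_analysis(
    data_path: str | Path,
    out_path: str | Path,
    config: RunConfig | None = None,
    include_peripheral: bool = False,
) -> RunReport:
    """Read a dataset directory, analyse it, and write tables + report."""
    config = config or RunConfig()
    trials = pio.read_trials(data_path)
    tables, report = analyze_trials(
        trials, config, include_peripheral=include_peripheral
    )
    out = Path(out_path)
    written = pio.write_results(tables, out)
    report.tables = [str(p) for p in written]
    (out / "report.json").write_text(report.to_json(), encoding="utf-8")
    logger.info(
        "analysis complete: %d trials (%d valid), %d endpoint outliers excluded",
        report.n_ingested,
        report.n_valid,
        report.n_outliers_excluded,
    )
    return report
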