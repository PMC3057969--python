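"""Monte-Carlo resampling tests for differences in average-ellipse
orientation (and trunk angle) between two conditions.

The observed statistic mirrors the averaging pipeline exactly: per subject,
the endpoint covariance of each condition is computed and normalized by its
largest eigenvalue; the normalized matrices are averaged across subjects per
condition; the statistic is the axial angle between the two average-ellipse
major axes.  Under the null hypothesis that both conditions' endpoints come
from the same population, each subject's two samples are interchangeable
with draws from their union: every simulation redraws, per subject and with
replacement, ``n`` and ``m`` points (the subject's original per-condition
counts) from the pooled set, rebuilds both average ellipses, and records the
simulated angle difference.  With ``N`` simulations at least as large as the
observed difference over ``n_sims`` runs, ``p = N / n_sims``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .endpoints import DEGENERACY_RATIO, axial_difference, covariance_ellipse, normalize_matrix, average_ellipse

__all__ = [
    "PermutationResult",
    "permutation_orientation_test",
    "permutation_angle_test",
]

logger = logging.getLogger(__name__)

_MAX_RETRIES = 100
_TINY = 1e-12


@dataclass(frozen=True)
class PermutationResult:
    """Outcome of one pairwise Monte-Carlo comparison."""

    condition_pair: tuple[str, str]
    observed_diff_deg: float
    n_sims: int
    exceed_count: int
    p_value: float
    seed: object
    degenerate_redraws: int = 0

    def __post_init__(self) -> None:
        assert 0.0 <= self.p_value <= 1.0


# ---------------------------------------------------------------- helpers

def _batch_cov(points: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Unbiased sample covariances of resampled clouds.

    ``points`` is ``(n_pool, 2)``; ``idx`` is ``(n_sims, k)`` integer draws.
    Returns ``(n_sims, 2, 2)``.
    """
    x = points[idx]  # (S, k, 2)
    d = x - x.mean(axis=1, keepdims=True)
    return np.einsum("ski,skj->sij", d, d) / (idx.shape[1] - 1)


def _batch_eigvals(covs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = covs[..., 0, 0]
    b = covs[..., 0, 1]
    c = covs[..., 1, 1]
    half_tr = 0.5 * (a + c)
    root = np.sqrt(np.maximum(0.25 * (a - c) ** 2 + b**2, 0.0))
    return half_tr + root, np.maximum(half_tr - root, 0.0)


def _batch_orientation_deg(covs: np.ndarray) -> np.ndarray:
    a = covs[..., 0, 0]
    b = covs[..., 0, 1]
    c = covs[..., 1, 1]
    return np.degrees(0.5 * np.arctan2(2.0 * b, a - c)) % 180.0


def _batch_axial_diff(a_deg: np.ndarray, b_deg: np.ndarray) -> np.ndarray:
    d = np.abs(a_deg % 180.0 - b_deg % 180.0)
    return np.minimum(d, 180.0 - d)


def _as_point_map(samples: Mapping) -> dict:
    out = {}
    for key, pts in samples.items():
        arr = np.asarray(pts, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError(f"subject {key!r}: endpoint sets must be (n, 2) arrays")
        if arr.shape[0] < 3:
            raise ValueError(f"subject {key!r}: needs >= 3 endpoints per condition")
        out[key] = arr
    return out


def _check_subjects(samples_a: Mapping, samples_b: Mapping) -> list:
    only_a = set(samples_a) - set(samples_b)
    only_b = set(samples_b) - set(samples_a)
    if only_a or only_b:
        raise ValueError(
            f"subjects present in only one condition: {sorted(only_a | only_b)!r}"
        )
    return sorted(samples_a)


def _observed_orientation_stat(samples_a, samples_b, subjects) -> float:
    mats_a = [normalize_matrix(covariance_ellipse(samples_a[s])) for s in subjects]
    mats_b = [normalize_matrix(covariance_ellipse(samples_b[s])) for s in subjects]
    avg_a = average_ellipse(mats_a)
    avg_b = average_ellipse(mats_b)
    for label, avg in (("a", avg_a), ("b", avg_b)):
        if avg.degenerate:
            raise ValueError(
                f"average ellipse of condition {label!r} is degenerate "
                f"(eigenvalue ratio {avg.eigenvalues[1] / avg.eigenvalues[0]:.4f}); "
                "orientation difference undefined"
            )
    return axial_difference(avg_a.orientation_deg, avg_b.orientation_deg)


def _subject_normalized_draws(
    pooled: np.ndarray, k_draw: int, n_sims: int, rng: np.random.Generator
) -> np.ndarray:
    """Normalized covariance matrices of ``n_sims`` with-replacement draws of
    ``k_draw`` points each; singular draws (all points identical) redrawn."""
    n_pool = pooled.shape[0]
    idx = rng.integers(0, n_pool, size=(n_sims, k_draw))
    covs = _batch_cov(pooled, idx)
    lam1, _ = _batch_eigvals(covs)
    scale = float(np.trace(np.cov(pooled.T))) + _TINY
    for _ in range(_MAX_RETRIES):
        bad = lam1 <= _TINY * scale
        if not bad.any():
            break
        redo = rng.integers(0, n_pool, size=(int(bad.sum()), k_draw))
        covs[bad] = _batch_cov(pooled, redo)
        lam1[bad], _ = _batch_eigvals(covs[bad])
    return covs / lam1[:, None, None]


def permutation_orientation_test(
    samples_a: Mapping,
    samples_b: Mapping,
    n_sims: int = 10_000,
    seed: int | Sequence[int] = 0,
    pair: tuple[str, str] = ("a", "b"),
) -> PermutationResult:
    """Monte-Carlo test of the average-ellipse orientation difference.

    Parameters
    ----------
    samples_a, samples_b
        Per-subject ``(n, 2)`` endpoint arrays for the two conditions;
        the same subjects must appear in both.
    n_sims
        Number of union resamples (``p`` resolves to multiples of
        ``1/n_sims``).
    seed
        Integer (or sequence) feeding a :class:`numpy.random.SeedSequence`;
        identical seed and inputs give a bit-identical exceedance count.
        Per-subject streams are spawned independently, so draws do not
        depend on subject iteration order.

    Simulated iterations whose average ellipse is near-isotropic (eigenvalue
    ratio above the degeneracy threshold) have no defined orientation and are
    redrawn, up to 100 rounds, with the count reported.
    """
    samples_a = _as_point_map(samples_a)
    samples_b = _as_point_map(samples_b)
    subjects = _check_subjects(samples_a, samples_b)
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    observed = _observed_orientation_stat(samples_a, samples_b, subjects)

    root = np.random.SeedSequence(seed)
    rngs = {s: np.random.default_rng(child) for s, child in zip(subjects, root.spawn(len(subjects)))}
    pooled = {s: np.vstack([samples_a[s], samples_b[s]]) for s in subjects}
    counts = {s: (samples_a[s].shape[0], samples_b[s].shape[0]) for s in subjects}

    def simulate(k: int) -> tuple[np.ndarray, np.ndarray]:
        sum_a = np.zeros((k, 2, 2))
        sum_b = np.zeros((k, 2, 2))
        for s in subjects:
            n_a, n_b = counts[s]
            sum_a += _subject_normalized_draws(pooled[s], n_a, k, rngs[s])
            sum_b += _subject_normalized_draws(pooled[s], n_b, k, rngs[s])
        avg_a = sum_a / len(subjects)
        avg_b = sum_b / len(subjects)
        diffs = _batch_axial_diff(
            _batch_orientation_deg(avg_a), _batch_orientation_deg(avg_b)
        )
        degenerate = np.zeros(k, dtype=bool)
        for avg in (avg_a, avg_b):
            lam1, lam2 = _batch_eigvals(avg)
            degenerate |= lam2 > DEGENERACY_RATIO * lam1
        return diffs, degenerate

    diffs, degenerate = simulate(n_sims)
    redraws = 0
    for _ in range(_MAX_RETRIES):
        if not degenerate.any():
            break
        redraws += int(degenerate.sum())
        new_diffs, new_degenerate = simulate(int(degenerate.sum()))
        where = np.flatnonzero(degenerate)
        diffs[where] = new_diffs
        degenerate[where] = new_degenerate
    if redraws:
        logger.info("redrew %d degenerate simulated iterations", redraws)

    # ties at floating-point resolution count as exceedances
    exceed = int(np.count_nonzero(diffs >= observed - 1e-9))
    return PermutationResult(
        condition_pair=pair,
        observed_diff_deg=float(observed),
        n_sims=int(n_sims),
        exceed_count=exceed,
        p_value=exceed / n_sims,
        seed=seed,
    )


# ------------------------------------------------------- axial-angle test

def _axial_mean_deg(z: np.ndarray, axis: int = -1) -> np.ndarray:
    """Axial mean of unit vectors on the doubled-angle circle."""
    m = z.mean(axis=axis)
    return (np.degrees(np.angle(m)) / 2.0) % 180.0


def _angles_to_z(deg: np.ndarray) -> np.ndarray:
    return np.exp(2j * np.radians(np.asarray(deg, dtype=float)))


def _group_mean_angle(per_subject_angles: Sequence[np.ndarray]) -> float:
    subject_means = [_axial_mean_deg(_angles_to_z(a)) for a in per_subject_angles]
    return float(_axial_mean_deg(_angles_to_z(np.asarray(subject_means)), axis=0))


def permutation_angle_test(
    samples_a: Mapping,
    samples_b: Mapping,
    n_sims: int = 10_000,
    seed: int | Sequence[int] = 0,
    pair: tuple[str, str] = ("a", "b"),
) -> PermutationResult:
    """Monte-Carlo test for a difference of mean axial angles (e.g. per-trial
    trunk orientations) between two conditions.

    Same union-resampling scheme as the ellipse test; the statistic is the
    axial difference between across-subject mean angles, where means are
    taken on the doubled-angle circle to respect the 180-degree wrap.
    """
    sa = {k: np.atleast_1d(np.asarray(v, dtype=float)) for k, v in samples_a.items()}
    sb = {k: np.atleast_1d(np.asarray(v, dtype=float)) for k, v in samples_b.items()}
    subjects = _check_subjects(sa, sb)
    for s in subjects:
        if sa[s].size < 1 or sb[s].size < 1:
            raise ValueError(f"subject {s!r}: needs >= 1 angle per condition")
    observed = axial_difference(
        _group_mean_angle([sa[s] for s in subjects]),
        _group_mean_angle([sb[s] for s in subjects]),
    )

    root = np.random.SeedSequence(seed)
    rngs = {s: np.random.default_rng(child) for s, child in zip(subjects, root.spawn(len(subjects)))}

    mean_a = np.zeros(n_sims, dtype=complex)
    mean_b = np.zeros(n_sims, dtype=complex)
    for s in subjects:
        pooled = _angles_to_z(np.concatenate([sa[s], sb[s]]))
        n_pool = pooled.shape[0]
        idx_a = rngs[s].integers(0, n_pool, size=(n_sims, sa[s].size))
        idx_b = rngs[s].integers(0, n_pool, size=(n_sims, sb[s].size))
        za = pooled[idx_a].mean(axis=1)
        zb = pooled[idx_b].mean(axis=1)
        mean_a += np.exp(1j * np.angle(za))
        mean_b += np.exp(1j * np.angle(zb))
    ang_a = (np.degrees(np.angle(mean_a)) / 2.0) % 180.0
    ang_b = (np.degrees(np.angle(mean_b)) / 2.0) % 180.0
    diffs = _batch_axial_diff(ang_a, ang_b)

    exceed = int(np.count_nonzero(diffs >= observed - 1e-9))
    return PermutationResult(
        condition_pair=pair,
        observed_diff_deg=float(observed),
        n_sims=int(n_sims),
        exceed_count=exceed,
        p_value=exceed / n_sims,
        seed=seed,
    )
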