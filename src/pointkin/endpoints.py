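"""Endpoint variability: Cook's-distance outlier exclusion, 2x2 covariance
(tolerance) ellipses, eigenvalue normalisation, across-participant averaging,
axial orientation arithmetic, and trunk orientation from the shoulder markers.

Repeated pointing at one target scatters the fingertip endpoints into an
anisotropic 2-D cloud on the horizontal plane.  The cloud's unbiased sample
covariance defines the tolerance ellipse; its major-axis direction — an
*axial* quantity, defined modulo 180 degrees — is measured against the
horizontal trace of the frontal plane (the x-axis) and is the statistic of
interest, because its tilt reflects the reference frame used to plan the
movement.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ToleranceEllipse",
    "DEGENERACY_RATIO",
    "cooks_outlier_filter",
    "covariance_ellipse",
    "ellipse_from_cov",
    "normalize_matrix",
    "average_ellipse",
    "axial_difference",
    "trunk_orientation",
    "ellipse_axis_lengths",
]

logger = logging.getLogger(__name__)

#: An ellipse with eigenvalue ratio above this is near-isotropic: its
#: orientation is numerically meaningless and is flagged.
DEGENERACY_RATIO = 0.999


@dataclass(frozen=True)
class ToleranceEllipse:
    """Eigenstructure of a 2x2 endpoint covariance matrix.

    ``eigenvalues`` are ordered ``lambda1 >= lambda2 >= 0``; the column
    ``eigenvectors[:, 0]`` spans the major axis.  ``orientation_deg`` is the
    axial angle of the major axis against the x-axis, in ``[0, 180)``.
    """

    cov: np.ndarray
    eigenvalues: tuple[float, float]
    eigenvectors: np.ndarray
    orientation_deg: float
    normalized: bool = False
    degenerate: bool = False
    n_points: int | None = None
    n_excluded: int = 0


def _axial_deg(vx: float, vy: float) -> float:
    return math.degrees(math.atan2(vy, vx)) % 180.0


def ellipse_from_cov(
    cov: np.ndarray,
    *,
    normalized: bool = False,
    n_points: int | None = None,
    n_excluded: int = 0,
) -> ToleranceEllipse:
    """Eigen-decompose a symmetric PSD 2x2 matrix into a tolerance ellipse."""
    cov = np.asarray(cov, dtype=float)
    if cov.shape != (2, 2):
        raise ValueError("covariance must be 2x2")
    if not np.allclose(cov, cov.T, atol=1e-9):
        raise ValueError("covariance must be symmetric")
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    lam1, lam2 = float(evals[0]), float(evals[1])
    degenerate = lam1 <= 0.0 or (lam2 / lam1) > DEGENERACY_RATIO
    orientation = _axial_deg(float(evecs[0, 0]), float(evecs[1, 0]))
    return ToleranceEllipse(
        cov=cov,
        eigenvalues=(lam1, lam2),
        eigenvectors=evecs,
        orientation_deg=orientation,
        normalized=normalized,
        degenerate=degenerate,
        n_points=n_points,
        n_excluded=n_excluded,
    )


def covariance_ellipse(points: np.ndarray, n_excluded: int = 0) -> ToleranceEllipse:
    """Tolerance ellipse of a 2-D endpoint cloud (unbiased covariance).

    Requires at least 3 points; a collinear cloud is allowed and yields
    ``lambda2 = 0``.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    if pts.shape[0] < 3:
        raise ValueError("need >= 3 points to estimate an ellipse")
    cov = np.cov(pts[:, 0], pts[:, 1], ddof=1)
    return ellipse_from_cov(cov, n_points=pts.shape[0], n_excluded=n_excluded)


def normalize_matrix(ellipse: ToleranceEllipse) -> ToleranceEllipse:
    """Divide the covariance by its largest eigenvalue (size normalisation).

    The output has ``lambda1 = 1`` and an unchanged orientation.
    """
    lam1 = ellipse.eigenvalues[0]
    if lam1 <= 0.0:
        raise ValueError("cannot normalize: largest eigenvalue is zero")
    out = ellipse_from_cov(
        ellipse.cov / lam1,
        normalized=True,
        n_points=ellipse.n_points,
        n_excluded=ellipse.n_excluded,
    )
    # orientation is scale-invariant; keep the original to the last bit
    return replace(out, orientation_deg=ellipse.orientation_deg)


def average_ellipse(ellipses: Sequence[ToleranceEllipse]) -> ToleranceEllipse:
    """Element-wise mean of normalized matrices, re-decomposed.

    All inputs must be normalized (mixing raises); degenerate inputs carry
    no meaningful orientation and are dropped with a logged warning.
    """
    if len(ellipses) == 0:
        raise ValueError("need at least one matrix to average")
    if any(not e.normalized for e in ellipses):
        raise ValueError("average_ellipse requires all inputs normalized")
    usable = [e for e in ellipses if not e.degenerate]
    n_dropped = len(ellipses) - len(usable)
    if n_dropped:
        logger.warning("dropping %d degenerate ellipse(s) from the average", n_dropped)
    if not usable:
        raise ValueError("all input ellipses are degenerate")
    mean_cov = np.mean([e.cov for e in usable], axis=0)
    return ellipse_from_cov(mean_cov, n_points=len(usable))


def axial_difference(a_deg: float, b_deg: float) -> float:
    """Unsigned angle in ``[0, 90]`` between two axial directions (degrees).

    Axial directions are lines, not vectors, so the difference wraps modulo
    180: ``min(|a - b|, 180 - |a - b|)``.
    """
    a = float(a_deg) % 180.0
    b = float(b_deg) % 180.0
    d = abs(a - b)
    return min(d, 180.0 - d)


def cooks_outlier_filter(
    points: np.ndarray, cutoff: float = 0.25
) -> tuple[np.ndarray, np.ndarray]:
    """Split endpoints into (kept, excluded) by per-coordinate Cook's distance.

    Influence is measured against the simplest location model: an
    intercept-only fit of each coordinate, for which every point has leverage
    ``h = 1/n`` and Cook's distance
    ``D_i = (e_i^2 / s^2) * h / (1 - h)^2`` with ``e_i`` the residual from
    the mean and ``s^2`` the unbiased residual variance.  A point is excluded
    when either coordinate's distance exceeds ``cutoff``; the filter is a
    single pass (no re-fitting after exclusion).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    n = pts.shape[0]
    if n < 4:
        raise ValueError("Cook's filter needs >= 4 points")
    h = 1.0 / n
    lever = h / (1.0 - h) ** 2
    D = np.zeros_like(pts)
    for j in range(2):
        e = pts[:, j] - pts[:, j].mean()
        s2 = float(np.sum(e**2)) / (n - 1)
        if s2 > 0.0:
            D[:, j] = (e**2 / s2) * lever
    excluded_mask = D.max(axis=1) > cutoff
    if excluded_mask.any():
        logger.info(
            "Cook's filter excluded %d/%d endpoints (%.1f%%)",
            int(excluded_mask.sum()),
            n,
            100.0 * excluded_mask.mean(),
        )
    return pts[~excluded_mask], pts[excluded_mask]


def trunk_orientation(led3: np.ndarray, led4: np.ndarray) -> float:
    """Axial angle (degrees, ``[0, 180)``) between the shoulder line and the
    x-axis, evaluated on the horizontal plane.

    ``led3`` and ``led4`` are the left and right shoulder marker positions at
    movement onset.
    """
    v = np.asarray(led3, dtype=float)[:2] - np.asarray(led4, dtype=float)[:2]
    norm = float(np.linalg.norm(v))
    if norm <= 0.0:
        raise ValueError("shoulder markers coincide; trunk orientation undefined")
    return _axial_deg(float(v[0]), float(v[1]))


def ellipse_axis_lengths(
    ellipse: ToleranceEllipse, coverage: float = 0.95
) -> tuple[float, float]:
    """Semi-axis lengths of the plotted tolerance region (reporting only).

    Axes are ``sqrt(lambda * chi2_2(coverage))``; orientation statistics
    never depend on this scaling.
    """
    q = float(stats.chi2.ppf(coverage, df=2))
    lam1, lam2 = ellipse.eigenvalues
    return math.sqrt(lam1 * q), math.sqrt(lam2 * q)
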