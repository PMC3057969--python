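"""Cook's-distance filtering, tolerance ellipses, axial arithmetic, and
trunk orientation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import pointkin as pk
from pointkin.endpoints import (
    average_ellipse,
    axial_difference,
    cooks_outlier_filter,
    covariance_ellipse,
    ellipse_from_cov,
    normalize_matrix,
    trunk_orientation,
)


def _cloud(rng, n=50, orientation=30.0, ratio=0.25, scale=10.0):
    return pk.sample_endpoints(
        pk.EndpointModel(orientation, axis_ratio=ratio, scale_mm=scale), n, rng
    )


# ------------------------------------------------------------- ellipses

def test_collinear_cloud_oriented_45_degrees():
    pts = np.column_stack([np.arange(10.0), np.arange(10.0)])
    ell = covariance_ellipse(pts)
    assert ell.orientation_deg == pytest.approx(45.0)
    assert ell.eigenvalues[1] == pytest.approx(0.0, abs=1e-12)


def test_isotropic_grid_flagged_degenerate():
    g = np.arange(-2.0, 3.0)
    pts = np.array([(x, y) for x in g for y in g])
    ell = covariance_ellipse(pts)
    assert ell.degenerate


def test_minimum_points_enforced():
    with pytest.raises(ValueError):
        covariance_ellipse(np.zeros((2, 2)))


def test_orientation_recovery_large_sample(rng):
    pts = _cloud(rng, n=5000, orientation=112.7)
    ell = covariance_ellipse(pts)
    assert axial_difference(ell.orientation_deg, 112.7) < 1.5


@given(st.integers(0, 2**31 - 1), st.floats(0.0, 180.0))
def test_rotation_equivariance(seed, theta):
    rng = np.random.default_rng(seed)
    pts = _cloud(rng, n=30)
    base = covariance_ellipse(pts).orientation_deg
    rad = np.radians(theta)
    rot = np.array([[np.cos(rad), -np.sin(rad)], [np.sin(rad), np.cos(rad)]])
    mean = pts.mean(axis=0)
    rotated = (pts - mean) @ rot.T + mean
    turned = covariance_ellipse(rotated).orientation_deg
    assert axial_difference(turned, (base + theta) % 180.0) < 1e-9


@given(
    st.integers(0, 2**31 - 1),
    st.floats(-1e3, 1e3),
    st.floats(-1e3, 1e3),
    st.floats(0.01, 100.0),
)
def test_orientation_invariant_to_translation_and_scaling(seed, dx, dy, factor):
    rng = np.random.default_rng(seed)
    pts = _cloud(rng, n=30)
    base = covariance_ellipse(pts).orientation_deg
    moved = covariance_ellipse(pts * factor + np.array([dx, dy])).orientation_deg
    assert axial_difference(base, moved) < 1e-8


def test_orientation_invariant_to_point_reflection(rng):
    pts = _cloud(rng, n=40)
    mean = pts.mean(axis=0)
    reflected = 2 * mean - pts
    assert axial_difference(
        covariance_ellipse(pts).orientation_deg,
        covariance_ellipse(reflected).orientation_deg,
    ) < 1e-9


def test_estimator_consistency_error_shrinks_with_n(rng):
    medians = []
    for n in (20, 200, 2000):
        errors = [
            axial_difference(
                covariance_ellipse(_cloud(rng, n=n, orientation=72.8)).orientation_deg,
                72.8,
            )
            for _ in range(200)
        ]
        medians.append(np.median(errors))
    assert medians[0] > medians[1] > medians[2]


# -------------------------------------------------------- normalisation

def test_normalize_divides_by_largest_eigenvalue():
    ell = ellipse_from_cov(np.diag([4.0, 1.0]))
    out = normalize_matrix(ell)
    np.testing.assert_allclose(out.cov, np.diag([1.0, 0.25]))
    assert out.eigenvalues[0] == pytest.approx(1.0)
    assert out.normalized
    assert out.orientation_deg == ell.orientation_deg


def test_normalize_identity_is_noop():
    out = normalize_matrix(ellipse_from_cov(np.eye(2)))
    np.testing.assert_allclose(out.cov, np.eye(2))


def test_normalize_rejects_zero_matrix():
    with pytest.raises(ValueError):
        normalize_matrix(ellipse_from_cov(np.zeros((2, 2))))


def test_average_of_identical_matrices_is_that_matrix(rng):
    ell = normalize_matrix(covariance_ellipse(_cloud(rng)))
    avg = average_ellipse([ell, ell, ell])
    np.testing.assert_allclose(avg.cov, ell.cov, atol=1e-12)


def test_average_of_symmetric_pair_is_90_degrees():
    def at(theta):
        return normalize_matrix(
            ellipse_from_cov(pk.EndpointModel(theta, axis_ratio=0.25).covariance())
        )

    avg = average_ellipse([at(80.0), at(100.0)])
    assert avg.orientation_deg == pytest.approx(90.0, abs=1e-9)


def test_average_rejects_unnormalized_input(rng):
    raw = covariance_ellipse(_cloud(rng))
    with pytest.raises(ValueError, match="normalized"):
        average_ellipse([normalize_matrix(raw), raw])


def test_average_recovers_common_axis_across_participants(rng):
    mats = [
        normalize_matrix(covariance_ellipse(_cloud(rng, n=200, orientation=72.8)))
        for _ in range(10)
    ]
    avg = average_ellipse(mats)
    assert axial_difference(avg.orientation_deg, 72.8) < 2.0


# ----------------------------------------------------- axial arithmetic

@pytest.mark.parametrize(
    "a, b, expected",
    [
        (72.8, 112.7, 39.9),
        (72.8, 100.4, 27.6),
        (112.7, 100.4, 12.3),
        (10.0, 170.0, 20.0),
        (33.3, 33.3, 0.0),
    ],
)
def test_axial_difference_examples(a, b, expected):
    assert axial_difference(a, b) == pytest.approx(expected, abs=1e-9)


@given(st.floats(-720, 720), st.floats(-720, 720))
def test_axial_difference_symmetric_and_bounded(a, b):
    d = axial_difference(a, b)
    assert d == pytest.approx(axial_difference(b, a))
    assert 0.0 <= d <= 90.0
    assert axial_difference(a + 180.0, b) == pytest.approx(d, abs=1e-6)


# ------------------------------------------------------- Cook's filter

def test_cooks_all_identical_points_kept():
    pts = np.ones((10, 2))
    kept, excluded = cooks_outlier_filter(pts, 0.25)
    assert len(kept) == 10 and len(excluded) == 0


def test_cooks_infinite_cutoff_keeps_everything(rng):
    pts = _cloud(rng, n=30)
    kept, excluded = cooks_outlier_filter(pts, np.inf)
    assert len(kept) == 30 and len(excluded) == 0


def test_cooks_far_point_excluded_matches_hand_formula(rng):
    cluster = rng.normal(size=(19, 2))
    outlier = np.array([[20.0, 0.0]])
    pts = np.vstack([cluster, outlier])
    kept, excluded = cooks_outlier_filter(pts, 0.25)
    assert any(np.allclose(row, outlier[0]) for row in excluded)
    assert len(kept) >= 17  # cluster essentially intact
    # hand evaluation of the intercept-only Cook's distance for x
    n = 20
    e = pts[:, 0] - pts[:, 0].mean()
    s2 = (e**2).sum() / (n - 1)
    d_far = (e[-1] ** 2 / s2) * (1 / n) / (1 - 1 / n) ** 2
    assert d_far > 0.25


def test_cooks_matches_statsmodels_intercept_only(rng):
    import statsmodels.api as sm

    pts = _cloud(rng, n=25)
    n = len(pts)
    for j in range(2):
        fit = sm.OLS(pts[:, j], np.ones((n, 1))).fit()
        expected = fit.get_influence().cooks_distance[0]
        e = pts[:, j] - pts[:, j].mean()
        s2 = (e**2).sum() / (n - 1)
        ours = (e**2 / s2) * (1 / n) / (1 - 1 / n) ** 2
        np.testing.assert_allclose(ours, expected, atol=1e-10)


def test_cooks_needs_four_points():
    with pytest.raises(ValueError):
        cooks_outlier_filter(np.zeros((3, 2)), 0.25)


# ----------------------------------------------------- trunk orientation

def test_trunk_aligned_with_x_axis_is_zero():
    assert trunk_orientation([-200.0, 0.0, 400.0], [200.0, 0.0, 400.0]) == 0.0


def test_trunk_rotated_ten_degrees():
    rad = np.radians(10.0)
    led3 = np.array([200 * np.cos(rad), 200 * np.sin(rad), 400.0])
    led4 = -led3 + np.array([0, 0, 800.0])
    assert trunk_orientation(led3, led4) == pytest.approx(10.0, abs=1e-9)


def test_trunk_coincident_markers_error():
    with pytest.raises(ValueError):
        trunk_orientation([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
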