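"""Point-pattern statistics vs closed-form and brute-force oracles."""

import numpy as np
import pytest

from calyxsim import (
    exclusion_zone_area,
    generate_active_zone,
    largest_empty_circle,
    nn_distances,
    null_envelope,
    ripley_deviation,
)
from calyxsim.azmap import ActiveZoneMap
from calyxsim.synthetic import _place_csr


def square_map(half, vesicles):
    boundary = np.array(
        [[-half, -half], [half, -half], [half, half], [-half, half]], float
    )
    return ActiveZoneMap("sq", boundary, np.asarray(vesicles, float).reshape(-1, 2))


class TestNearestNeighbour:
    @pytest.mark.parametrize(
        "pts,expected",
        [
            ([(0, 0), (0, 50)], [50, 50]),
            ([(0, 0), (50, 0), (120, 0)], [50, 50, 70]),
        ],
    )
    def test_small_configurations(self, pts, expected):
        np.testing.assert_allclose(nn_distances(pts), expected)

    def test_fewer_than_two_points_fails(self):
        with pytest.raises(ValueError):
            nn_distances([(0, 0)])

    def test_csr_mean_matches_closed_form(self):
        """For CSR at intensity lambda, E[NN distance] = 1/(2 sqrt(lambda))."""
        half = 500.0
        az = square_map(half, np.zeros((0, 2)))
        rng = np.random.default_rng(3)
        n = 1000  # lambda = 1e-3 /nm^2 in a 1 um^2 window; edge effects tiny
        means = [
            nn_distances(_place_csr(az.boundary, n, rng)).mean() for _ in range(30)
        ]
        lam = n / (2 * half) ** 2
        assert np.mean(means) == pytest.approx(1 / (2 * np.sqrt(lam)), rel=0.03)

    def test_hard_core_random_maps_near_reference_value(self):
        """Hard-core-random vesicles at ~120/um^2 give mean NN distance in the
        ~80 nm range reported for random re-placements (loose: boundary shape
        matters)."""
        vals = []
        for s in range(40):
            az = generate_active_zone(0.05, 6, seed=100 + s)
            vals.append(nn_distances(az.vesicle_centres).mean())
        assert abs(np.mean(vals) - 80.0) < 15.0


class TestLargestEmptyCircle:
    def test_single_central_vesicle_in_square(self):
        az = square_map(150.0, [(0.0, 0.0)])
        (cx, cy), r = largest_empty_circle(az)
        # optimum is a corner: sqrt(2)*150 - 22.5
        assert r == pytest.approx(np.sqrt(2) * 150 - 22.5, abs=1e-6)
        assert max(abs(cx), abs(cy)) == pytest.approx(150.0, abs=1e-6)

    def test_no_vesicles_is_an_error(self):
        az = square_map(150.0, np.zeros((0, 2)))
        with pytest.raises(ValueError, match="unbounded"):
            largest_empty_circle(az)

    def test_matches_one_nanometre_grid_oracle(self):
        az = generate_active_zone(0.05, 6, seed=11)
        _, r = largest_empty_circle(az)
        # brute-force oracle: 1 nm grid over the polygon
        import shapely

        minx, miny, maxx, maxy = az.polygon.bounds
        xs = np.arange(minx, maxx, 1.0)
        ys = np.arange(miny, maxy, 1.0)
        gx, gy = np.meshgrid(xs, ys)
        pts = np.column_stack([gx.ravel(), gy.ravel()])
        pts = pts[shapely.contains_xy(az.polygon, pts[:, 0], pts[:, 1])]
        d = np.sqrt(
            ((pts[:, None, :] - az.vesicle_centres[None, :, :]) ** 2).sum(-1)
        ).min(1)
        r_grid = max(d.max() - az.vesicle_radius, 0.0)
        assert abs(r - r_grid) <= 1.0
        assert r >= r_grid - 1e-9  # candidate set search can only do better


class TestExclusionZoneArea:
    def test_single_deep_vesicle_closed_form(self):
        az = square_map(500.0, [(0.0, 0.0)])
        assert exclusion_zone_area(az, 30.0) == pytest.approx(np.pi * 52.5**2, rel=1e-3)
        assert exclusion_zone_area(az, 0.0) == pytest.approx(np.pi * 22.5**2, rel=1e-3)

    def test_overlapping_discs_subadditive(self):
        az = square_map(500.0, [(0.0, 0.0), (50.0, 0.0)])
        area = exclusion_zone_area(az, 30.0)
        assert area < 2 * np.pi * 52.5**2

    def test_monotone_in_distance(self):
        az = generate_active_zone(0.05, 6, seed=4)
        areas = [exclusion_zone_area(az, d) for d in (0, 10, 20, 30, 50)]
        assert np.all(np.diff(areas) > 0)

    def test_matches_monte_carlo_integration(self):
        az = generate_active_zone(0.05, 6, seed=5)
        rng = np.random.default_rng(1)
        minx, miny, maxx, maxy = az.polygon.bounds
        n = 1_000_000
        xs = rng.uniform(minx, maxx, n)
        ys = rng.uniform(miny, maxy, n)
        import shapely

        inside_poly = shapely.contains_xy(az.polygon, xs, ys)
        d2 = ((xs[:, None] - az.vesicle_centres[:, 0]) ** 2
              + (ys[:, None] - az.vesicle_centres[:, 1]) ** 2).min(1)
        inside_zone = inside_poly & (d2 < 52.5**2)
        mc = inside_zone.mean() * (maxx - minx) * (maxy - miny)
        assert exclusion_zone_area(az, 30.0) == pytest.approx(mc, rel=0.01)


class TestRipley:
    def test_tight_cluster_detected_at_small_radii(self):
        az = square_map(300.0, np.zeros((0, 2)))
        rng = np.random.default_rng(0)
        pts = rng.normal(0, 8.0, (10, 2))
        res = ripley_deviation(pts, az, radii_nm=np.array([20.0, 40.0, 80.0]),
                               n_null=200, conf=0.95, seed=1)
        assert res.observed[0] > 1.0  # outside the envelope: clustered

    def test_envelope_calibration_under_csr(self):
        """CSR data fall outside a pointwise (1-conf) envelope at ~alpha of radii."""
        az = square_map(250.0, np.zeros((0, 2)))
        rng = np.random.default_rng(7)
        outside = 0
        total = 0
        for rep in range(40):
            pts = rng.uniform(-250, 250, (12, 2))
            res = ripley_deviation(pts, az, radii_nm=np.array([30.0, 60.0, 120.0]),
                                   n_null=199, conf=0.90, seed=rep)
            outside += int(np.sum(np.abs(res.observed) > 1))
            total += 3
        rate = outside / total
        assert 0.02 < rate < 0.25  # nominal 0.10

    def test_near_random_vesicle_maps_stay_inside_99_band(self):
        az = generate_active_zone(0.07, 8, seed=21)
        res = ripley_deviation(az.vesicle_centres, az, n_null=150, conf=0.99,
                               seed=3, hard_core=True)
        assert np.all(np.abs(res.observed) <= 1.0)

    def test_too_few_nulls_at_high_confidence_fails(self):
        az = square_map(200.0, np.zeros((0, 2)))
        with pytest.raises(ValueError, match="n_null"):
            ripley_deviation(np.random.default_rng(0).uniform(-100, 100, (8, 2)),
                             az, n_null=50, conf=0.99)


class TestNullEnvelope:
    def test_degenerate_single_rep(self, az5_like):
        res = null_envelope(az5_like, 6, "mean_nn_distance", n_reps=1, seed=0)
        assert res.envelope_lower == res.envelope_upper

    def test_exclusion_area_null_tracks_observed_for_random_data(self):
        """For hard-core-random maps the observed exclusion area sits on the
        identity line with the null mean (points follow slope 1)."""
        obs, null = [], []
        for s in range(8):
            az = generate_active_zone(0.06, 7, seed=400 + s)
            res = null_envelope(az, 7, "exclusion_zone_area_30nm", n_reps=60,
                                hard_core=True, seed=s)
            obs.append(res.observed)
            null.append(res.null_mean)
        obs, null = np.array(obs), np.array(null)
        rel = (obs - null) / null
        assert np.all(np.abs(rel) < 0.25)  # each point near the identity line
        assert abs(rel.mean()) < 0.10  # and no systematic offset

    def test_observed_rank_uniform_under_matching_null(self):
        """Exchangeability: for CSR data the observed statistic's rank among
        CSR nulls is uniform (here: not in the extreme tails too often)."""
        extreme = 0
        for s in range(20):
            az = generate_active_zone(0.05, 6, seed=600 + s, hard_core=False)
            res = null_envelope(az, 6, "mean_nn_distance", n_reps=99,
                                hard_core=False, conf=0.9, seed=s)
            r = (res.null_values < res.observed).mean()
            extreme += int(r < 0.05 or r > 0.95)
        assert extreme <= 6

    def test_unknown_statistic_rejected(self, az5_like):
        with pytest.raises(ValueError, match="unknown statistic"):
            null_envelope(az5_like, 6, "skewness", n_reps=10)
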