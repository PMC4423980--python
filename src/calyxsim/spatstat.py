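"""Point-pattern statistics of docked vesicles with Monte Carlo nulls.

Implements the four analyses applied to the docked-vesicle maps: nearest-
neighbour distances, the largest empty circle, the exclusion-zone area, and
Ripley's K with a Monte Carlo confidence envelope.  No analytic edge
correction is applied to K: the null re-placements share the exact window
geometry of the data, so edge bias cancels in the envelope comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy.spatial import Voronoi, cKDTree
from shapely.geometry import LineString, Point, Polygon
from shapely.ops import unary_union

from .azmap import ActiveZoneMap
from .synthetic import _place_csr, _place_hard_core


@dataclass
class SpatStatResult:
    statistic_name: str
    observed: np.ndarray | float
    null_mean: np.ndarray | float | None = None
    null_sd: np.ndarray | float | None = None
    envelope_lower: np.ndarray | float | None = None
    envelope_upper: np.ndarray | float | None = None
    confidence: float | None = None
    n_null: int = 0
    seed: int | None = None
    radii_nm: np.ndarray | None = None
    null_values: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n_null < 0:
            raise ValueError("n_null must be >= 0")
        lo, up = self.envelope_lower, self.envelope_upper
        if lo is not None and up is not None:
            if np.any(np.asarray(lo) > np.asarray(up) + 1e-12):
                raise ValueError("envelope lower bound exceeds upper bound")


def nn_distances(points: np.ndarray) -> np.ndarray:
    """Distance from each point to its nearest other point (order preserved)."""
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(points) < 2:
        raise ValueError("nearest-neighbour distances need at least 2 points")
    tree = cKDTree(points)
    d, _ = tree.query(points, k=2)
    return d[:, 1]


def largest_empty_circle(az: ActiveZoneMap) -> tuple[tuple[float, float], float]:
    """Largest circle centred in the AZ that overlaps no vesicle.

    Maximises min_v(||c - v|| - vesicle_radius) over centres c in the polygon,
    clamped at 0; the circle itself may extend beyond the polygon.  Candidate
    centres are Voronoi vertices of the vesicle centres, intersections of
    Voronoi edges with the polygon boundary, and polygon vertices — the
    complete candidate set for a max-min-distance problem in a polygon.
    """
    if az.n_vesicles == 0:
        raise ValueError("radius unbounded: active zone has no vesicles")
    poly = az.polygon
    centres = az.vesicle_centres
    cand: list[tuple[float, float]] = [tuple(p) for p in az.boundary]

    if len(centres) >= 2:
        # Voronoi of the centres; pad with far-away points so every ridge
        # between data points is represented with finite vertices.
        span = max(np.ptp(az.boundary[:, 0]), np.ptp(az.boundary[:, 1]), 1.0)
        pad = np.array(
            [[-4 * span, -4 * span], [4 * span, -4 * span],
             [-4 * span, 4 * span], [4 * span, 4 * span]]
        )
        vor = Voronoi(np.vstack([centres, pad]))
        ring = LineString(np.vstack([az.boundary, az.boundary[:1]]))
        for v in vor.vertices:
            if poly.covers(Point(*v)):
                cand.append(tuple(v))
        for (p1, p2) in vor.ridge_vertices:
            if p1 == -1 or p2 == -1:
                continue
            seg = LineString([vor.vertices[p1], vor.vertices[p2]])
            inter = seg.intersection(ring)
            if inter.is_empty:
                continue
            for g in getattr(inter, "geoms", [inter]):
                if g.geom_type == "Point":
                    cand.append((g.x, g.y))

    cand_arr = np.array(cand)
    tree = cKDTree(centres)
    d, _ = tree.query(cand_arr)
    radii = np.clip(d - az.vesicle_radius, 0.0, None)
    i = int(np.argmax(radii))
    return (float(cand_arr[i, 0]), float(cand_arr[i, 1])), float(radii[i])


def exclusion_zone_area(az: ActiveZoneMap, d_nm: float) -> float:
    """Area (nm^2) of the union of discs (vesicle_radius + d) clipped to the polygon.

    The vesicle footprint itself is counted as part of the zone.  Monotone
    non-decreasing in d.
    """
    if d_nm < 0:
        raise ValueError("d must be >= 0")
    if az.n_vesicles == 0:
        return 0.0
    discs = unary_union(
        [Point(x, y).buffer(az.vesicle_radius + d_nm, 128) for x, y in az.vesicle_centres]
    )
    return float(discs.intersection(az.polygon).area)


def _ripley_L(points: np.ndarray, area_nm2: float, radii: np.ndarray) -> np.ndarray:
    """L(r) = sqrt(K(r)/pi) without analytic edge correction."""
    n = len(points)
    diff = points[:, None, :] - points[None, :, :]
    d = np.sqrt((diff**2).sum(-1))
    iu = np.triu_indices(n, 1)
    pd = d[iu]
    counts = (pd[None, :] <= radii[:, None]).sum(1) * 2  # ordered pairs
    K = area_nm2 * counts / (n * (n - 1))
    return np.sqrt(K / np.pi)


def ripley_deviation(
    points: np.ndarray,
    az: ActiveZoneMap,
    radii_nm: np.ndarray | None = None,
    n_null: int = 500,
    conf: float = 0.99,
    seed: int = 0,
    hard_core: bool = False,
) -> SpatStatResult:
    """Clustering excess L(r) - r, normalised by the MC envelope half-width.

    The envelope comes from ``n_null`` random re-placements of the same point
    count in the same polygon.  Normalised values within +/-1 at all radii
    mean no significant clustering at the given confidence.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(points) < 2:
        raise ValueError("Ripley's K needs at least 2 points")
    if radii_nm is None:
        span = np.sqrt(az.area_nm2)
        radii_nm = np.linspace(10.0, 0.5 * span, 12)
    radii_nm = np.asarray(radii_nm, dtype=float)
    if np.any(radii_nm <= 0) or np.any(np.diff(radii_nm) <= 0):
        raise ValueError("radii must be positive and increasing")
    if conf >= 0.99 and n_null < 100:
        raise ValueError("envelope unreliable: need n_null >= 100 at 99% confidence")

    area = az.area_nm2
    obs = _ripley_L(points, area, radii_nm) - radii_nm
    rng = np.random.default_rng(seed)
    nulls = np.empty((n_null, len(radii_nm)))
    placer = _place_hard_core if hard_core else _place_csr
    for i in range(n_null):
        if hard_core:
            p = placer(az.boundary, len(points), 2 * az.vesicle_radius, rng)
        else:
            p = placer(az.boundary, len(points), rng)
        nulls[i] = _ripley_L(p, area, radii_nm) - radii_nm
    alpha = 1.0 - conf
    lower = np.quantile(nulls, alpha / 2, axis=0)
    upper = np.quantile(nulls, 1 - alpha / 2, axis=0)
    half = np.maximum((upper - lower) / 2, 1e-12)
    centre = (upper + lower) / 2
    return SpatStatResult(
        statistic_name="ripley_L_minus_r_normalised",
        observed=(obs - centre) / half,
        null_mean=nulls.mean(0),
        null_sd=nulls.std(0, ddof=1),
        envelope_lower=lower,
        envelope_upper=upper,
        confidence=conf,
        n_null=n_null,
        seed=seed,
        radii_nm=radii_nm,
    )


_STATISTICS = {
    "mean_nn_distance": lambda az, pts: float(np.mean(nn_distances(pts))),
    "largest_empty_circle_radius": lambda az, pts: largest_empty_circle(
        ActiveZoneMap("null", az.boundary, pts, az.vesicle_radius)
    )[1],
    "exclusion_zone_area_30nm": lambda az, pts: exclusion_zone_area(
        ActiveZoneMap("null", az.boundary, pts, az.vesicle_radius), 30.0
    ),
}


def null_envelope(
    az: ActiveZoneMap,
    n_points: int,
    statistic: str,
    n_reps: int = 1000,
    hard_core: bool = True,
    conf: float = 0.95,
    seed: int = 0,
) -> SpatStatResult:
    """Null distribution of a scalar statistic under random vesicle re-placement.

    ``statistic`` is one of ``mean_nn_distance``, ``largest_empty_circle_radius``,
    ``exclusion_zone_area_30nm``.  Null placements default to hard-core (45 nm,
    vesicles are impenetrable spheres); CSR is available with hard_core=False.
    """
    if statistic not in _STATISTICS:
        raise ValueError(f"unknown statistic {statistic!r}; choose from {sorted(_STATISTICS)}")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    fn = _STATISTICS[statistic]
    observed = fn(az, az.vesicle_centres) if az.n_vesicles else float("nan")
    rng = np.random.default_rng(seed)
    vals = np.empty(n_reps)
    for i in range(n_reps):
        if hard_core:
            pts = _place_hard_core(az.boundary, n_points, 2 * az.vesicle_radius, rng)
        else:
            pts = _place_csr(az.boundary, n_points, rng)
        vals[i] = fn(az, pts)
    alpha = 1 - conf
    return SpatStatResult(
        statistic_name=statistic,
        observed=observed,
        null_mean=float(vals.mean()),
        null_sd=float(vals.std(ddof=1)) if n_reps > 1 else 0.0,
        envelope_lower=float(np.quantile(vals, alpha / 2)),
        envelope_upper=float(np.quantile(vals, 1 - alpha / 2)),
        confidence=conf,
        n_null=n_reps,
        seed=seed,
        null_values=vals,
    )
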