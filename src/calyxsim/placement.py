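"""Ca2+-channel placement rules: random, exclusion zone, supercluster.

Channels are points on the z = 0 membrane plane.  Three rules are provided:

* ``random`` — uniform over the polygon minus the vesicle footprints (a
  channel cannot sit under a docked vesicle);
* ``exclusion_zone`` — uniform over the polygon minus discs of radius
  (vesicle radius + d_ex) around every vesicle centre, i.e. every channel
  keeps at least d_ex from every vesicle *edge*;
* ``supercluster`` — all channels on one tight hexagonal patch.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import shapely
from shapely.geometry import Point, Polygon
from shapely.ops import unary_union

from .azmap import ActiveZoneMap

MAX_REJECTION_ATTEMPTS = 100_000


class LayoutError(RuntimeError):
    """Raised when a channel layout cannot be constructed or is invalid."""


def channel_count(area_um2: float, density_per_um2: float = 280.0) -> int:
    """Number of channels at the given density, rounded, minimum 1.

    The reference density is 280 channels/um^2 (14 channels on the 0.05 um^2
    example active zone; 25 on the 0.089 um^2 one).
    """
    if area_um2 <= 0 or density_per_um2 <= 0:
        raise ValueError("area and density must be positive")
    return max(1, round(area_um2 * density_per_um2))


@dataclass
class ChannelLayout:
    """Channel x-y positions plus the placement rule that generated them."""

    positions: np.ndarray  # (n, 2) nm
    rule: str  # random | exclusion_zone | supercluster
    exclusion_distance_nm: float = 0.0
    cluster_pitch_nm: float | None = None
    cluster_centre_nm: tuple[float, float] | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 2)

    @property
    def n_channels(self) -> int:
        return len(self.positions)

    def to_dict(self) -> dict:
        return {
            "positions": np.round(self.positions, 6).tolist(),
            "rule": self.rule,
            "exclusion_distance_nm": self.exclusion_distance_nm,
            "cluster_pitch_nm": self.cluster_pitch_nm,
            "cluster_centre_nm": self.cluster_centre_nm,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ChannelLayout":
        return cls(
            positions=np.asarray(d["positions"], dtype=float),
            rule=d["rule"],
            exclusion_distance_nm=float(d.get("exclusion_distance_nm", 0.0)),
            cluster_pitch_nm=d.get("cluster_pitch_nm"),
            cluster_centre_nm=tuple(d["cluster_centre_nm"]) if d.get("cluster_centre_nm") else None,
            seed=d.get("seed"),
        )


def write_layout(layout: ChannelLayout, az: ActiveZoneMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump({"active_zone": az.to_dict(), "layout": layout.to_dict()}, fh, indent=1)


def read_layout(path: str | Path) -> tuple[ActiveZoneMap, ChannelLayout]:
    with open(path) as fh:
        d = json.load(fh)
    return ActiveZoneMap.from_dict(d["active_zone"]), ChannelLayout.from_dict(d["layout"])


# -- permitted regions ------------------------------------------------------


def permitted_region(az: ActiveZoneMap, clearance_nm: float):
    """Polygon minus the union of discs of radius ``clearance_nm`` around vesicles.

    ``clearance = vesicle_radius`` gives the free area for random placement;
    ``clearance = vesicle_radius + d_ex`` the exclusion-zone permitted region.
    """
    poly = az.polygon
    if az.n_vesicles == 0 or clearance_nm <= 0:
        return poly
    discs = unary_union([Point(x, y).buffer(clearance_nm, 64) for x, y in az.vesicle_centres])
    return poly.difference(discs)


def _sample_in_region(region, n: int, rng: np.random.Generator,
                      max_attempts: int = MAX_REJECTION_ATTEMPTS) -> np.ndarray:
    if region.is_empty or region.area <= 0:
        raise LayoutError("permitted region has zero area")
    minx, miny, maxx, maxy = region.bounds
    prepared = shapely.prepared.prep(region)
    out: list[tuple[float, float]] = []
    attempts = 0
    while len(out) < n:
        if attempts >= max_attempts:
            raise LayoutError(f"rejection budget exhausted ({len(out)}/{n} placed)")
        m = 256
        attempts += m
        xs = rng.uniform(minx, maxx, m)
        ys = rng.uniform(miny, maxy, m)
        for x, y in zip(xs, ys):
            if prepared.contains(Point(x, y)):
                out.append((x, y))
                if len(out) == n:
                    break
    return np.array(out)


# -- placement rules --------------------------------------------------------


def place_channels_random(az: ActiveZoneMap, n: int, seed: int = 0) -> ChannelLayout:
    """Uniform channel placement over the polygon minus vesicle footprints."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    region = permitted_region(az, az.vesicle_radius)
    pos = _sample_in_region(region, n, rng)
    return ChannelLayout(pos, "random", 0.0, seed=seed)


def place_channels_exclusion_zone(
    az: ActiveZoneMap, n: int, d_ex_nm: float = 30.0, seed: int = 0
) -> ChannelLayout:
    """Uniform placement at least ``d_ex_nm`` from every vesicle edge.

    ``d_ex = 0`` reduces to :func:`place_channels_random`.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if d_ex_nm < 0:
        raise ValueError("exclusion distance must be >= 0")
    rng = np.random.default_rng(seed)
    region = permitted_region(az, az.vesicle_radius + d_ex_nm)
    if region.is_empty or region.area <= 0:
        raise LayoutError(
            f"exclusion zone infeasible: no permitted area at d_ex = {d_ex_nm} nm"
        )
    pos = _sample_in_region(region, n, rng)
    return ChannelLayout(pos, "exclusion_zone", d_ex_nm, seed=seed)


def hex_positions(n: int, centre: tuple[float, float], pitch_nm: float) -> np.ndarray:
    """The n sites of a triangular lattice closest to ``centre`` (ties by angle)."""
    cx, cy = centre
    k = int(np.ceil(np.sqrt(n))) + 2
    pts = []
    for i in range(-k, k + 1):
        for j in range(-k, k + 1):
            x = pitch_nm * (i + 0.5 * j)
            y = pitch_nm * (np.sqrt(3) / 2) * j
            pts.append((x, y))
    pts = np.array(pts)
    r = np.hypot(pts[:, 0], pts[:, 1])
    ang = np.arctan2(pts[:, 1], pts[:, 0])
    order = np.lexsort((ang, np.round(r, 9)))
    sel = pts[order[:n]]
    return sel + np.array([cx, cy])


def build_supercluster(
    az: ActiveZoneMap,
    n: int,
    centre: tuple[float, float],
    pitch_nm: float = 14.0,
    min_vesicle_edge_distance_nm: float = 30.0,
) -> ChannelLayout:
    """All channels on one hexagonal patch of the given pitch around ``centre``.

    Fails if the patch leaves the polygon, touches a vesicle footprint, or sits
    closer than ``min_vesicle_edge_distance_nm`` to the nearest vesicle edge.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    pos = hex_positions(n, centre, pitch_nm)
    poly = az.polygon
    offenders = [tuple(p) for p in pos if not poly.covers(Point(*p))]
    if offenders:
        raise LayoutError(f"supercluster leaves the polygon at {offenders[:3]}")
    if az.n_vesicles:
        d = np.sqrt(
            ((pos[:, None, :] - az.vesicle_centres[None, :, :]) ** 2).sum(-1)
        )
        edge = d.min() - az.vesicle_radius
        if edge < min_vesicle_edge_distance_nm - 1e-9:
            i, j = np.unravel_index(np.argmin(d), d.shape)
            raise LayoutError(
                f"supercluster channel {tuple(np.round(pos[i], 1))} is {edge:.1f} nm from "
                f"vesicle {j} edge (< {min_vesicle_edge_distance_nm} nm)"
            )
    return ChannelLayout(
        pos, "supercluster",
        exclusion_distance_nm=min_vesicle_edge_distance_nm,
        cluster_pitch_nm=pitch_nm, cluster_centre_nm=tuple(centre),
    )


def patch_diameter(layout: ChannelLayout) -> float:
    """Largest pairwise channel distance within a layout (patch diameter)."""
    p = layout.positions
    d2 = ((p[:, None, :] - p[None, :, :]) ** 2).sum(-1)
    return float(np.sqrt(d2.max()))


# -- supercluster position candidates and tuning ----------------------------


def void_space_candidates(
    az: ActiveZoneMap,
    n_candidates: int = 5,
    bottom_half_only: bool = False,
    grid_step_nm: float = 8.0,
    margin_nm: float = 20.0,
) -> list[tuple[float, float]]:
    """Local maxima of the distance-to-nearest-vesicle-edge transform.

    Candidate supercluster centres are the void spaces between docked
    vesicles; optionally restricted to the bottom half of the map (y < 0).
    """
    poly = az.polygon
    minx, miny, maxx, maxy = poly.bounds
    xs = np.arange(minx, maxx, grid_step_nm)
    ys = np.arange(miny, maxy, grid_step_nm)
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    inside = shapely.contains_xy(poly.buffer(-margin_nm), pts[:, 0], pts[:, 1])
    if bottom_half_only:
        inside &= pts[:, 1] < 0
    pts = pts[inside]
    if len(pts) == 0:
        return []
    if az.n_vesicles:
        d = np.sqrt(
            ((pts[:, None, :] - az.vesicle_centres[None, :, :]) ** 2).sum(-1)
        ).min(1) - az.vesicle_radius
    else:
        d = np.full(len(pts), np.inf)
    # greedy selection of well-separated high-clearance points
    order = np.argsort(-d)
    chosen: list[np.ndarray] = []
    for idx in order:
        p = pts[idx]
        if all(np.hypot(*(p - q)) > 60.0 for q in chosen):
            chosen.append(p)
        if len(chosen) == n_candidates:
            break
    return [tuple(p) for p in chosen]


@dataclass
class TuningRecord:
    centre: tuple[float, float]
    mean_pves: float
    layout: ChannelLayout


def tune_supercluster_position(
    az: ActiveZoneMap,
    n: int,
    candidate_centres: list[tuple[float, float]],
    score_fn,
    target_mean_pves: float = 0.1,
    pitch_nm: float = 14.0,
    min_vesicle_edge_distance_nm: float = 30.0,
) -> tuple[ChannelLayout, list[TuningRecord]]:
    """Pick the candidate whose simulated mean p_ves is closest to target.

    ``score_fn(layout) -> mean p_ves`` encapsulates the simulation protocol
    (standard AP, chosen trial budget).  Infeasible candidates are skipped;
    all candidate scores are returned for the record.
    """
    records: list[TuningRecord] = []
    for centre in candidate_centres:
        try:
            layout = build_supercluster(
                az, n, centre, pitch_nm, min_vesicle_edge_distance_nm
            )
        except LayoutError:
            continue
        records.append(TuningRecord(centre, float(score_fn(layout)), layout))
    if not records:
        raise LayoutError("no feasible supercluster candidate position")
    best = min(records, key=lambda r: abs(r.mean_pves - target_mean_pves))
    return best.layout, records


# -- invariant checker (public surface) --------------------------------------


def validate_layout(layout: ChannelLayout, az: ActiveZoneMap) -> None:
    """Re-validate a layout against its declared rule; raise LayoutError."""
    poly = az.polygon
    pos = layout.positions
    for p in pos:
        if not poly.covers(Point(*p)):
            raise LayoutError(f"channel {tuple(np.round(p, 1))} outside the polygon")
    if az.n_vesicles:
        d = np.sqrt(((pos[:, None, :] - az.vesicle_centres[None, :, :]) ** 2).sum(-1))
        edge = d.min(1) - az.vesicle_radius
        if (edge < -1e-9).any():
            raise LayoutError("channel under a vesicle footprint")
        if layout.rule == "exclusion_zone" and (
            edge < layout.exclusion_distance_nm - 1e-6
        ).any():
            raise LayoutError("exclusion-zone rule violated")
        if layout.rule == "supercluster" and edge.min() < layout.exclusion_distance_nm - 1e-6:
            raise LayoutError("supercluster too close to a vesicle edge")
    if layout.rule == "supercluster" and layout.cluster_pitch_nm:
        if patch_diameter(layout) > 10 * layout.cluster_pitch_nm * max(
            1.0, np.sqrt(layout.n_channels)
        ):
            raise LayoutError("supercluster is not a compact patch")
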