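"""Planar active-zone maps: a polygon outline plus docked-vesicle centres.

The active zone (AZ) is the presynaptic membrane patch where vesicles dock and
fuse.  All geometry is two-dimensional (the AZ plane, z = 0), in nanometres,
with the origin at the polygon centroid.  Docked vesicles are represented by
their centre coordinates; in the reaction-diffusion model they become
reflective spheres of 45 nm diameter resting on the membrane.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from shapely.geometry import Point, Polygon

VESICLE_RADIUS_NM = 22.5  # 45 nm spheres


class InvalidActiveZoneError(ValueError):
    """Raised when an active-zone map violates its structural invariants."""


@dataclass
class ActiveZoneMap:
    """A flattened active zone: boundary polygon and docked-vesicle centres.

    Parameters
    ----------
    id : str
        Free-form label.
    boundary : (n, 2) float array
        Ordered vertices of a simple polygon, nm, origin at the centroid.
    vesicle_centres : (m, 2) float array
        Docked-vesicle centre coordinates, nm.  May be empty.
    vesicle_radius : float
        Vesicle radius in nm (default 22.5, i.e. 45 nm spheres).
    """

    id: str
    boundary: np.ndarray
    vesicle_centres: np.ndarray
    vesicle_radius: float = VESICLE_RADIUS_NM

    def __post_init__(self) -> None:
        self.boundary = np.asarray(self.boundary, dtype=float)
        self.vesicle_centres = np.asarray(self.vesicle_centres, dtype=float)
        if self.vesicle_centres.size == 0:
            self.vesicle_centres = self.vesicle_centres.reshape(0, 2)

    # -- derived geometry ---------------------------------------------------

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.boundary)

    @property
    def area_nm2(self) -> float:
        return self.polygon.area

    @property
    def area_um2(self) -> float:
        return self.area_nm2 * 1e-6

    @property
    def n_vesicles(self) -> int:
        return len(self.vesicle_centres)

    @property
    def vesicle_density_per_um2(self) -> float:
        return self.n_vesicles / self.area_um2

    # -- invariants ---------------------------------------------------------

    def validate(self) -> None:
        """Check all structural invariants; raise InvalidActiveZoneError."""
        poly = self.polygon
        if not poly.is_valid or poly.is_empty:
            raise InvalidActiveZoneError(f"{self.id}: boundary is not a simple polygon")
        if poly.area <= 0:
            raise InvalidActiveZoneError(f"{self.id}: polygon area must be positive")
        for i, (x, y) in enumerate(self.vesicle_centres):
            if not poly.covers(Point(x, y)):
                raise InvalidActiveZoneError(
                    f"{self.id}: vesicle {i} centre ({x:.1f}, {y:.1f}) lies outside the polygon"
                )
        if self.n_vesicles >= 2:
            d = _pairwise_min_distance(self.vesicle_centres)
            if d < 2 * self.vesicle_radius - 1e-9:
                raise InvalidActiveZoneError(
                    f"{self.id}: vesicles overlap (min centre distance {d:.2f} nm "
                    f"< {2 * self.vesicle_radius} nm)"
                )

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "boundary": np.round(self.boundary, 6).tolist(),
            "vesicles": np.round(self.vesicle_centres, 6).tolist(),
            "vesicle_radius": self.vesicle_radius,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ActiveZoneMap":
        az = cls(
            id=str(d["id"]),
            boundary=np.asarray(d["boundary"], dtype=float),
            vesicle_centres=np.asarray(d.get("vesicles", []), dtype=float),
            vesicle_radius=float(d.get("vesicle_radius", VESICLE_RADIUS_NM)),
        )
        az.validate()
        return az


def _pairwise_min_distance(points: np.ndarray) -> float:
    diff = points[:, None, :] - points[None, :, :]
    d2 = (diff**2).sum(-1)
    np.fill_diagonal(d2, np.inf)
    return float(np.sqrt(d2.min()))


# -- file IO ----------------------------------------------------------------


def write_az_map(az: ActiveZoneMap, path: str | Path) -> None:
    """Write a map as JSON, or as a vesicle CSV with a JSON sidecar polygon.

    JSON is the lossless format.  A ``.csv`` path writes the flat x,y vesicle
    table plus ``<stem>.boundary.json`` holding the polygon.
    """
    path = Path(path)
    if path.suffix == ".csv":
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["x_nm", "y_nm"])
            for x, y in az.vesicle_centres:
                w.writerow([f"{x:.6f}", f"{y:.6f}"])
        sidecar = path.with_suffix(".boundary.json")
        with open(sidecar, "w") as fh:
            json.dump(
                {
                    "id": az.id,
                    "boundary": np.round(az.boundary, 6).tolist(),
                    "vesicle_radius": az.vesicle_radius,
                },
                fh,
            )
    else:
        with open(path, "w") as fh:
            json.dump(az.to_dict(), fh, indent=1)


def read_az_map(path: str | Path) -> ActiveZoneMap:
    """Load a map written by :func:`write_az_map`; validates invariants."""
    path = Path(path)
    if path.suffix == ".csv":
        sidecar = path.with_suffix(".boundary.json")
        if not sidecar.exists():
            raise FileNotFoundError(
                f"{path}: vesicle CSV requires the sidecar polygon file {sidecar.name}"
            )
        with open(sidecar) as fh:
            meta = json.load(fh)
        centres = []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                centres.append((float(row["x_nm"]), float(row["y_nm"])))
        az = ActiveZoneMap(
            id=str(meta["id"]),
            boundary=np.asarray(meta["boundary"], dtype=float),
            vesicle_centres=np.asarray(centres, dtype=float).reshape(-1, 2),
            vesicle_radius=float(meta.get("vesicle_radius", VESICLE_RADIUS_NM)),
        )
    else:
        with open(path) as fh:
            return ActiveZoneMap.from_dict(json.load(fh))
    az.validate()
    return az


def write_population(
    maps: list[ActiveZoneMap], directory: str | Path, index_name: str = "index.csv"
) -> Path:
    """Write one JSON file per map plus an index CSV (id, area, vesicle count)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    index = directory / index_name
    with open(index, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "area_um2", "n_vesicles", "density_per_um2", "file"])
        for az in maps:
            fname = f"{az.id}.json"
            write_az_map(az, directory / fname)
            w.writerow(
                [
                    az.id,
                    f"{az.area_um2:.6f}",
                    az.n_vesicles,
                    f"{az.vesicle_density_per_um2:.2f}",
                    fname,
                ]
            )
    return index
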