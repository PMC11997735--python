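"""Named spherical polygons (MPA, EEZ, sample-grid extent) and overlap tests.

Zones are plain shapely polygons in WGS84 lon/lat.  The boundary counts as
inside everywhere in this package: a daily location sitting exactly on an
MPA edge is credited to the protected area (the conservative
protection-accounting choice).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import shapely
from shapely.geometry import box, mapping, shape
from shapely.geometry.base import BaseGeometry


@dataclass
class ZoneSet:
    """Mapping of zone name -> polygon, with GeoJSON round-tripping."""

    zones: dict[str, BaseGeometry] = field(default_factory=dict)

    def __post_init__(self):
        for name, geom in self.zones.items():
            if not geom.is_valid:
                raise ValueError(f"zone {name!r} is not a valid polygon")

    def __getitem__(self, name: str) -> BaseGeometry:
        return self.zones[name]

    def __contains__(self, name: str) -> bool:
        return name in self.zones

    def names(self) -> list[str]:
        return list(self.zones)

    def contains_points(self, name: str, lon, lat) -> np.ndarray:
        """Boolean mask of points inside the named zone (boundary inside)."""
        return points_in_zone(self.zones[name], lon, lat)

    def to_geojson(self, path: str | Path) -> None:
        features = [
            {"type": "Feature", "properties": {"name": name},
             "geometry": mapping(geom)}
            for name, geom in self.zones.items()
        ]
        obj = {"type": "FeatureCollection", "features": features}
        Path(path).write_text(json.dumps(obj))

    @classmethod
    def from_geojson(cls, path: str | Path) -> "ZoneSet":
        obj = json.loads(Path(path).read_text())
        zones = {f["properties"]["name"]: shape(f["geometry"])
                 for f in obj["features"]}
        return cls(zones)


def points_in_zone(zone: BaseGeometry, lon, lat) -> np.ndarray:
    """Vectorized point-in-polygon with boundary counted as inside."""
    lon = np.atleast_1d(np.asarray(lon, dtype=float))
    lat = np.atleast_1d(np.asarray(lat, dtype=float))
    pts = shapely.points(lon, lat)
    return shapely.covers(zone, pts)


def box_zone(lon0: float, lat0: float, half_deg: float) -> BaseGeometry:
    """Axis-aligned lon/lat box centred on (lon0, lat0)."""
    return box(lon0 - half_deg, lat0 - half_deg, lon0 + half_deg, lat0 + half_deg)
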