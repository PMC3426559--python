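"""Population geographic coordinates and map projection.

Coordinates are decimal degrees with southern latitudes and western
longitudes negative.  For worldwide analyses the Americas are first shifted
east by 360 degrees (so they sit past Eurasia instead of wrapping around the
Atlantic) and the map is then projected with the Gall-Peters equal-area
cylindrical projection, standard parallels at 45 degrees.  Regional analyses
use unprojected (longitude, latitude) treated as an isotropic plane.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genotype import GenotypeMatrix

__all__ = ["GeoTable", "load_geo_table", "expand_to_individuals",
           "shift_americas", "gall_peters_project"]


@dataclass
class GeoTable:
    """Population -> (latitude, longitude) with optional planar projection."""

    coords: dict[str, tuple[float, float]]  # population -> (lat, lon), degrees
    projected: dict[str, tuple[float, float]] | None = None  # population -> (x, y)
    projection_name: str = "unprojected"

    def __post_init__(self) -> None:
        for pop, (lat, lon) in self.coords.items():
            if not -90 <= lat <= 90:
                raise ValueError(f"latitude {lat} out of range for population {pop!r}")

    def planar(self, population: str) -> tuple[float, float]:
        """Planar coordinates of one population: projected (x, y) if a
        projection was applied, otherwise (longitude, latitude)."""
        if self.projected is not None:
            return self.projected[population]
        lat, lon = self.coords[population]
        return (lon, lat)

    def populations(self) -> list[str]:
        return list(self.coords)


def load_geo_table(path) -> GeoTable:
    """Read a coordinates TSV with columns population, latitude, longitude."""
    df = pd.read_csv(path, sep="\t")
    required = {"population", "latitude", "longitude"}
    if not required.issubset(df.columns):
        raise ValueError(f"coordinate table must have columns {sorted(required)}")
    if df["population"].duplicated().any():
        raise ValueError("duplicate population in coordinate table")
    coords = {
        str(r.population): (float(r.latitude), float(r.longitude))
        for r in df.itertuples()
    }
    return GeoTable(coords)


def expand_to_individuals(geo: GeoTable, G: GenotypeMatrix) -> np.ndarray:
    """Per-individual planar coordinates: all members of a population share
    that population's single location.  Rows align with ``G.individual_ids``."""
    missing = [p for p in set(G.populations) if p not in geo.coords]
    if missing:
        raise ValueError(f"populations without coordinates: {sorted(missing)}")
    return np.array([geo.planar(p) for p in G.populations], dtype=float)


def shift_americas(geo: GeoTable, threshold_lon: float = -40.0,
                   shift: float = 360.0) -> GeoTable:
    """Add ``shift`` degrees to longitudes strictly below ``threshold_lon``.

    Used before the worldwide projection so the Americas plot east of Asia.
    Idempotent: shifted longitudes exceed the threshold.
    """
    if geo.projection_name != "unprojected":
        raise ValueError("shift must be applied before projection")
    coords = {
        pop: (lat, lon + shift if lon < threshold_lon else lon)
        for pop, (lat, lon) in geo.coords.items()
    }
    return replace(geo, coords=coords)


def gall_peters_project(geo: GeoTable, standard_parallel: float = 45.0,
                        radius: float = 1.0) -> GeoTable:
    """Apply the Gall-Peters equal-area cylindrical projection.

    x = R * lon_rad * cos(phi0), y = R * sin(lat) / cos(phi0) with standard
    parallel phi0 (default 45 degrees).  Equal-area: the Jacobian is the
    constant R^2.  Distance along the standard parallel is preserved.
    """
    c = math.cos(math.radians(standard_parallel))
    projected = {
        pop: (radius * math.radians(lon) * c, radius * math.sin(math.radians(lat)) / c)
        for pop, (lat, lon) in geo.coords.items()
    }
    return replace(geo, projected=projected, projection_name="gall_peters")
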