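"""Occurrence ingestion, quality filtering, spatial thinning, study area.

Occurrence records carry a positional uncertainty in km; the accuracy
filter drops records at or above the configured bound (strictly-less-than
retention), mirroring the practice of keeping only georeferenced or highly
accurate data.  Spatial thinning enforces a minimum great-circle distance
between retained records by randomized greedy subsetting over many
iterations, keeping the largest subset found — the standard declustering
step against uneven sampling effort.  The study area is the union of
planar-degree disks buffered around the retained presences.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .grid import Grid

logger = logging.getLogger(__name__)

__all__ = [
    "OccurrenceSet",
    "StudyArea",
    "read_occurrences",
    "filter_accuracy",
    "thin_spatial",
    "build_study_area",
    "haversine_km",
]

REQUIRED_COLUMNS = ["species", "lon", "lat", "uncertainty_km", "source"]

EARTH_RADIUS_KM = 6371.0088


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km between points in decimal degrees."""
    lon1, lat1, lon2, lat2 = map(np.radians, (np.asarray(lon1), np.asarray(lat1),
                                              np.asarray(lon2), np.asarray(lat2)))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


@dataclass
class OccurrenceSet:
    """Ordered presence records for one species.

    Backed by a DataFrame with columns species, lon, lat, uncertainty_km,
    source (plus an optional ``flagged`` column added by the non-strict
    accuracy filter). ``n_dropped`` counts rows rejected during ingestion.
    """

    df: pd.DataFrame
    crs: str = "EPSG:4326"
    n_dropped: int = field(default=0, compare=False)

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"occurrence table missing columns {missing}")
        species = self.df["species"].unique()
        if len(species) > 1:
            raise ValueError(f"one species per set; found {list(species)}")
        bad = ((self.df["lon"].abs() > 180) | (self.df["lat"].abs() > 90)).sum()
        if bad:
            raise ValueError(f"{bad} records have out-of-range coordinates")

    @classmethod
    def from_arrays(cls, species: str, lon, lat, uncertainty_km=np.nan,
                    source: str = "unknown") -> "OccurrenceSet":
        lon = np.atleast_1d(np.asarray(lon, dtype=float))
        lat = np.atleast_1d(np.asarray(lat, dtype=float))
        n = len(lon)
        return cls(pd.DataFrame({
            "species": np.repeat(species, n),
            "lon": lon,
            "lat": lat,
            "uncertainty_km": np.broadcast_to(np.asarray(uncertainty_km, float), n).copy(),
            "source": np.repeat(source, n),
        }))

    def __len__(self) -> int:
        return len(self.df)

    @property
    def species(self) -> str:
        return "" if self.df.empty else str(self.df["species"].iloc[0])

    @property
    def lon(self) -> np.ndarray:
        return self.df["lon"].to_numpy()

    @property
    def lat(self) -> np.ndarray:
        return self.df["lat"].to_numpy()

    def cells(self, template: Grid) -> tuple[np.ndarray, np.ndarray]:
        """Unique (rows, cols) of the template cells containing the records."""
        r, c = template.cell_index(self.lon, self.lat)
        inside = (r >= 0) & (r < template.n_rows) & (c >= 0) & (c < template.n_cols)
        pairs = np.unique(np.column_stack([r[inside], c[inside]]), axis=0)
        return pairs[:, 0], pairs[:, 1]

    def subset(self, index) -> "OccurrenceSet":
        return OccurrenceSet(self.df.iloc[index].reset_index(drop=True), crs=self.crs)

    def to_csv(self, path: str | Path) -> None:
        self.df[REQUIRED_COLUMNS].to_csv(path, index=False)


@dataclass
class StudyArea:
    """Boolean mask grid delimiting the modeling extent."""

    mask: Grid  # values in {0,1}; nodata where the template itself is nodata
    buffer_deg: float

    @property
    def bool_mask(self) -> np.ndarray:
        return (self.mask.values > 0.5) & ~self.mask.nodata_mask

    @property
    def n_cells(self) -> int:
        return int(self.bool_mask.sum())

    def valid_cells(self) -> tuple[np.ndarray, np.ndarray]:
        return np.nonzero(self.bool_mask)


def read_occurrences(path: str | Path | io.IOBase) -> OccurrenceSet:
    """Read an occurrence CSV, rejecting rows without parseable coordinates.

    Rows whose lon/lat fail numeric parsing or fall outside valid ranges are
    dropped; the count is logged and exposed as ``OccurrenceSet.n_dropped``.
    """
    df = pd.read_csv(path, dtype={"species": str, "source": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"occurrence CSV missing required columns {missing}")
    n_raw = len(df)
    df["lon"] = pd.to_numeric(df["lon"], errors="coerce")
    df["lat"] = pd.to_numeric(df["lat"], errors="coerce")
    df["uncertainty_km"] = pd.to_numeric(df["uncertainty_km"], errors="coerce")
    ok = (df["lon"].notna() & df["lat"].notna()
          & (df["lon"].abs() <= 180) & (df["lat"].abs() <= 90))
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.warning("dropped %d of %d occurrence rows with unparseable or "
                       "out-of-range coordinates", n_dropped, n_raw)
    return OccurrenceSet(df[ok].reset_index(drop=True), n_dropped=n_dropped)


def filter_accuracy(occ: OccurrenceSet, max_uncertainty_km: float,
                    strict: bool = True) -> OccurrenceSet:
    """Retain records with uncertainty strictly below the bound.

    In strict mode (default) records with missing uncertainty are dropped;
    in non-strict mode they are retained and marked in a boolean ``flagged``
    column, with the flagged count logged.
    """
    if not max_uncertainty_km > 0:
        raise ValueError("max_uncertainty_km must be positive")
    unc = occ.df["uncertainty_km"]
    known_ok = unc.notna() & (unc < max_uncertainty_km)
    if strict:
        out = occ.df[known_ok].reset_index(drop=True)
        return OccurrenceSet(out, crs=occ.crs)
    keep = known_ok | unc.isna()
    out = occ.df[keep].reset_index(drop=True)
    out = out.assign(flagged=out["uncertainty_km"].isna())
    n_flagged = int(out["flagged"].sum())
    if n_flagged:
        logger.warning("retained %d records with missing uncertainty (flagged)",
                       n_flagged)
    return OccurrenceSet(out, crs=occ.crs)


def thin_spatial(occ: OccurrenceSet, min_dist_km: float = 10.0,
                 iterations: int = 1000, seed: int = 0) -> OccurrenceSet:
    """Randomized greedy spatial thinning to a minimum pairwise distance.

    Repeats ``iterations`` times: visit records in random order, greedily
    accepting each one at least ``min_dist_km`` (great-circle) from every
    record already accepted; the largest accepted subset across iterations
    is returned (first attained on ties).  The result is always a subset of
    the input with all pairwise distances >= ``min_dist_km``, and its size
    is monotone non-decreasing in ``iterations`` for a fixed seed.
    """
    if not min_dist_km > 0:
        raise ValueError("min_dist_km must be positive")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    n = len(occ)
    if n <= 1:
        return occ.subset(slice(None))

    # canonical (lon, lat)-sorted index space so the seeded result does not
    # depend on the order records arrived in
    canon = np.lexsort((occ.lat, occ.lon))
    lon, lat = occ.lon[canon], occ.lat[canon]
    d = haversine_km(lon[:, None], lat[:, None], lon[None, :], lat[None, :])
    conflict = d < min_dist_km
    np.fill_diagonal(conflict, False)
    if not conflict.any():
        return occ.subset(slice(None))

    rng = np.random.default_rng(seed)
    best: np.ndarray | None = None
    for _ in range(iterations):
        order = rng.permutation(n)
        accepted_mask = np.zeros(n, dtype=bool)
        accepted: list[int] = []
        for i in order:
            if not conflict[i][accepted_mask].any():
                accepted_mask[i] = True
                accepted.append(i)
        if best is None or len(accepted) > len(best):
            best = np.array(accepted)
        if len(best) == n:
            break
    return occ.subset(np.sort(canon[best]))


def build_study_area(occ: OccurrenceSet, buffer_deg: float, template: Grid) -> StudyArea:
    """Union of planar-degree disks of radius ``buffer_deg`` around presences.

    A template cell belongs to the study area when its center lies within
    ``buffer_deg`` decimal degrees (planar) of any presence point and the
    template itself has data there.  Contiguity of the resulting area is
    emergent, not enforced.
    """
    if len(occ) == 0:
        raise ValueError("cannot buffer an empty occurrence set")
    if not buffer_deg > 0:
        raise ValueError("buffer_deg must be positive")
    lon_mesh, lat_mesh = template.lon_lat_mesh()
    inside = np.zeros(template.shape, dtype=bool)
    b2 = buffer_deg**2
    for x, y in zip(occ.lon, occ.lat):
        inside |= (lon_mesh - x) ** 2 + (lat_mesh - y) ** 2 <= b2
    inside &= ~template.nodata_mask
    mask = Grid(inside.astype(float), template.nodata_mask.copy(),
                template.origin_lon, template.origin_lat,
                template.cell_size, template.crs)
    return StudyArea(mask=mask, buffer_deg=buffer_deg)
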