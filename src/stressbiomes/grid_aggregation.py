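"""Equal-area hexagon grids, occurrence cleaning, and assemblage aggregation.

Occurrence points are binned into congruent flat-top hexagons of a fixed
area (7500 km2 by default, in an equal-area planar projection).  Within
each hexagon and plant functional type, the set of distinct species
present defines an assemblage; assemblage values are unweighted means of
species values (presence-based, not abundance-weighted).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from shapely.geometry import Polygon

from stressbiomes.config import TRAITS

_SQRT3 = math.sqrt(3.0)


@dataclass
class HexGrid:
    """A lattice of congruent flat-top hexagons covering a rectangular extent.

    Cell ids are row-major over the lattice.  ``circumradius`` is in the
    planar units of the extent (meters); ``cell_area_km2`` is the exact
    polygon area of every cell.
    """

    centers: np.ndarray  # (n_cells, 2)
    hex_ids: np.ndarray  # (n_cells,) ints
    circumradius: float
    cell_area_km2: float
    extent: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        self._tree = cKDTree(self.centers)

    def __len__(self) -> int:
        return len(self.hex_ids)

    def polygon(self, i: int) -> Polygon:
        """Shapely polygon of cell index ``i`` (flat-top orientation)."""
        cx, cy = self.centers[i]
        R = self.circumradius
        angles = np.deg2rad(np.arange(0, 360, 60))
        return Polygon(np.column_stack([cx + R * np.cos(angles), cy + R * np.sin(angles)]))

    def polygons(self) -> list[Polygon]:
        return [self.polygon(i) for i in range(len(self))]

    def assign(self, points: np.ndarray) -> np.ndarray:
        """Map points to hex ids.

        The Voronoi diagram of the hexagon centers coincides with the
        hexagons themselves, so nearest-center lookup is an exact
        point-in-cell test.  Points equidistant from two centers (on a
        shared edge or vertex) go to the cell with the smaller id, which
        makes the assignment a deterministic partition.
        """
        points = np.asarray(points, dtype=float)
        dist, idx = self._tree.query(points, k=min(2, len(self)))
        if dist.ndim == 1:  # single-cell grid
            return self.hex_ids[np.atleast_1d(idx)]
        tie = np.isclose(dist[:, 0], dist[:, 1], rtol=0, atol=1e-6)
        chosen = idx[:, 0].copy()
        chosen[tie] = np.minimum(idx[tie, 0], idx[tie, 1])
        return self.hex_ids[chosen]


def circumradius_for_area(cell_area_km2: float) -> float:
    """Circumradius R (meters) of a hexagon with the given area.

    A regular hexagon of circumradius R has area (3*sqrt(3)/2) R^2.
    """
    area_m2 = cell_area_km2 * 1e6
    return math.sqrt(2.0 * area_m2 / (3.0 * _SQRT3))


def build_hex_grid(
    extent: tuple[float, float, float, float],
    cell_area_km2: float,
    single_cell: bool = False,
) -> HexGrid:
    """Build a flat-top hexagon lattice covering ``extent``.

    Every cell whose center lies within one lattice step of the extent is
    kept, so the rectangle is fully covered.  Raises if the extent cannot
    hold a single cell center.  With ``single_cell=True`` one hexagon is
    placed at the extent center instead of a lattice.
    """
    if cell_area_km2 <= 0:
        raise ValueError("cell_area_km2 must be positive")
    x0, y0, x1, y1 = extent
    if x1 <= x0 or y1 <= y0:
        raise ValueError("extent must be a non-degenerate rectangle")
    R = circumradius_for_area(cell_area_km2)
    if single_cell:
        center = np.array([[(x0 + x1) / 2.0, (y0 + y1) / 2.0]])
        return HexGrid(
            centers=center,
            hex_ids=np.arange(1),
            circumradius=R,
            cell_area_km2=cell_area_km2,
            extent=extent,
        )
    dx = 1.5 * R  # column spacing for flat-top hexes
    dy = _SQRT3 * R  # row spacing
    if (x1 - x0) < dx and (y1 - y0) < dy and (x1 - x0) * (y1 - y0) < cell_area_km2 * 1e6:
        raise ValueError("extent smaller than one hexagon cell")

    n_cols = int(math.ceil((x1 - x0) / dx)) + 1
    n_rows = int(math.ceil((y1 - y0) / dy)) + 1
    centers = []
    for row in range(n_rows):
        for col in range(n_cols):
            cx = x0 + col * dx
            cy = y0 + row * dy + (0.5 * dy if col % 2 == 1 else 0.0)
            centers.append((cx, cy))
    centers = np.array(centers)
    return HexGrid(
        centers=centers,
        hex_ids=np.arange(len(centers)),
        circumradius=R,
        cell_area_km2=cell_area_km2,
        extent=extent,
    )


# ---------------------------------------------------------------------------
# Occurrence cleaning
# ---------------------------------------------------------------------------

_REQUIRED_COLS = ("species_id", "x", "y")


def clean_occurrences(
    raw: pd.DataFrame, lonlat: bool = False
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop invalid occurrence rows; report counts removed per rule.

    Rules, applied in order: non-finite coordinates; coordinates outside
    the valid longitude/latitude ranges (only when ``lonlat=True``);
    points at exactly (0, 0); exact duplicates of (species_id, x, y).

    Returns the cleaned table and a dict of removal counts keyed by rule.
    """
    missing = [c for c in _REQUIRED_COLS if c not in raw.columns]
    if missing:
        raise ValueError(f"occurrence table missing columns: {missing}")
    df = raw.copy()
    report: dict[str, int] = {}

    finite = np.isfinite(df["x"].to_numpy(dtype=float)) & np.isfinite(
        df["y"].to_numpy(dtype=float)
    )
    report["non_finite"] = int((~finite).sum())
    df = df[finite]

    if lonlat:
        valid = df["x"].between(-180, 180) & df["y"].between(-90, 90)
    else:
        valid = pd.Series(True, index=df.index)
    report["coordinate_validity"] = int((~valid).sum())
    df = df[valid]

    at_origin = (df["x"] == 0) & (df["y"] == 0)
    report["zero_zero"] = int(at_origin.sum())
    df = df[~at_origin]

    dup = df.duplicated(subset=["species_id", "x", "y"], keep="first")
    report["duplicates"] = int(dup.sum())
    df = df[~dup]

    return df.reset_index(drop=True), report


DEFAULT_DEPTH_INTERVALS = ("0-5cm", "5-15cm", "15-30cm", "30-60cm")


def average_soil_depths(
    table: pd.DataFrame,
    variables: list[str],
    intervals: tuple[str, ...] = DEFAULT_DEPTH_INTERVALS,
) -> pd.DataFrame:
    """Average per-depth soil columns over the shallow depth intervals.

    Real-data soil products report each variable at several depth
    intervals (columns named ``{variable}_{interval}``); the analysis uses
    the mean of the first four intervals (0-60 cm).  Returns a copy of the
    table with one ``{variable}`` column added per input variable.  This
    helper is optional: pre-averaged columns can be supplied directly.
    """
    out = table.copy()
    for var in variables:
        cols = [f"{var}_{iv}" for iv in intervals]
        missing = [c for c in cols if c not in table.columns]
        if missing:
            raise ValueError(f"missing depth columns for {var!r}: {missing}")
        out[var] = table[cols].mean(axis=1)
    return out


# ---------------------------------------------------------------------------
# Assemblage aggregation
# ---------------------------------------------------------------------------


def aggregate_assemblages(
    occurrences: pd.DataFrame,
    species: pd.DataFrame,
    grid: HexGrid,
    landscape: pd.DataFrame | None = None,
    min_species: int = 3,
) -> pd.DataFrame:
    """Per-(hexagon, PFT) assemblage means of STS axes and log10 traits.

    The species set of an assemblage is the set of *distinct* species of
    one PFT occurring in one hexagon; duplicate occurrences do not change
    the mean (presence semantics).  Trait columns are averaged on the
    log10 scale.  Rows with fewer than ``min_species`` species are
    dropped.  Environmental columns are joined from ``landscape`` (keyed
    by hex_id) when given.
    """
    unknown = set(occurrences["species_id"]) - set(species["species_id"])
    if unknown:
        raise ValueError(
            f"occurrences reference unknown species: {sorted(unknown)[:10]}"
        )

    occ = occurrences.copy()
    occ["hex_id"] = grid.assign(occ[["x", "y"]].to_numpy())
    pairs = occ[["hex_id", "species_id"]].drop_duplicates()

    sp = species.set_index("species_id")
    value_cols = ["axis1", "axis2"] + [f"log10_{t}" for t in TRAITS]
    sp_vals = pd.DataFrame(
        {
            "pft": sp["pft"],
            "axis1": sp["axis1"],
            "axis2": sp["axis2"],
            **{f"log10_{t}": np.log10(sp[t]) for t in TRAITS},
        }
    )
    merged = pairs.join(sp_vals, on="species_id")

    grouped = merged.groupby(["hex_id", "pft"], observed=True)
    agg = grouped[value_cols].mean()
    agg["species_richness"] = grouped.size()
    agg = agg[agg["species_richness"] >= min_species].reset_index()

    centers = pd.DataFrame(
        {
            "hex_id": grid.hex_ids,
            "center_x": grid.centers[:, 0],
            "center_y": grid.centers[:, 1],
        }
    )
    agg = agg.merge(centers, on="hex_id", how="left")
    if landscape is not None:
        env_cols = [c for c in landscape.columns if c not in agg.columns or c == "hex_id"]
        agg = agg.merge(landscape[env_cols], on="hex_id", how="left")
    return agg.sort_values(["pft", "hex_id"]).reset_index(drop=True)
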