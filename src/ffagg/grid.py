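"""Nested analysis grid and rasterization of survey records.

Aerial strip surveys record point detections of forage-fish aggregations
(FFAs) and the area of sea surface actually photographed.  Analysis happens
on a regular planar lattice of fine cells (default 4 x 4 km) nested inside
coarse blocks (default 32 x 32 km); the coarse blocks carry the spatial
random effects, the fine cells carry the counts.  Coordinates are planar km;
projecting real survey data into a planar CRS is the caller's problem.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SEASONS = ("autumn", "spring", "winter", "summer")


@dataclass
class NestedGrid:
    """A fine lattice nested inside a coarse block lattice.

    Fine cells are half-open squares ``[x, x+size) x [y, y+size)`` indexed
    row-major from the lower-left corner of the extent.  Every fine cell
    belongs to exactly one coarse block of ``coarse_factor`` x
    ``coarse_factor`` fine cells; blocks are adjacent under rook (default)
    or queen contiguity.
    """

    extent: tuple[float, float, float, float]  # xmin, ymin, xmax, ymax
    fine_size: float
    coarse_factor: int
    nx: int
    ny: int
    fine_cell_ids: np.ndarray
    fine_cell_centers: np.ndarray  # (n_cells, 2) km
    fine_to_coarse: np.ndarray  # fine id -> coarse block id
    coarse_adjacency: dict[int, list[int]] = field(repr=False)

    @property
    def n_cells(self) -> int:
        return self.fine_cell_ids.size

    @property
    def n_blocks(self) -> int:
        return int(self.fine_to_coarse.max()) + 1

    @property
    def cell_area_km2(self) -> float:
        return self.fine_size**2

    def to_frame(self) -> pd.DataFrame:
        """Cell table (cell_id, x, y, block) for serialization."""
        return pd.DataFrame(
            {
                "cell_id": self.fine_cell_ids,
                "x": self.fine_cell_centers[:, 0],
                "y": self.fine_cell_centers[:, 1],
                "block": self.fine_to_coarse,
            }
        )

    def adjacency_edges(self) -> pd.DataFrame:
        """Unique undirected block adjacency edges as a two-column table."""
        rows = [
            (k, l)
            for k, nbrs in sorted(self.coarse_adjacency.items())
            for l in nbrs
            if k < l
        ]
        return pd.DataFrame(rows, columns=["block_a", "block_b"], dtype=int)


def _lattice_adjacency(bx: int, by: int, rule: str) -> dict[int, list[int]]:
    """Contiguity neighbor lists over a ``bx`` x ``by`` block lattice."""
    adj: dict[int, list[int]] = {k: [] for k in range(bx * by)}
    for j in range(by):
        for i in range(bx):
            k = j * bx + i
            steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
            if rule == "queen":
                steps += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
            for di, dj in steps:
                ii, jj = i + di, j + dj
                if 0 <= ii < bx and 0 <= jj < by:
                    adj[k].append(jj * bx + ii)
    return {k: sorted(v) for k, v in adj.items()}


def build_nested_grid(
    extent: tuple[float, float, float, float],
    fine_size: float = 4.0,
    coarse_factor: int = 8,
    adjacency_rule: str = "rook",
) -> NestedGrid:
    """Tile a planar extent with fine cells nested in coarse blocks.

    Parameters
    ----------
    extent : (xmin, ymin, xmax, ymax) in km.
    fine_size : fine cell edge length in km (default 4).
    coarse_factor : fine cells per coarse block edge (default 8, i.e.
        32 km blocks for 4 km cells).
    adjacency_rule : "rook" (4-neighbour, default) or "queen" (8-neighbour)
        contiguity for the coarse blocks.
    """
    xmin, ymin, xmax, ymax = map(float, extent)
    if xmax <= xmin or ymax <= ymin:
        raise ValueError(f"extent must have positive width and height, got {extent}")
    if fine_size <= 0:
        raise ValueError(f"fine_size must be positive, got {fine_size}")
    if int(coarse_factor) != coarse_factor or coarse_factor < 1:
        raise ValueError(f"coarse_factor must be an integer >= 1, got {coarse_factor}")
    if adjacency_rule not in ("rook", "queen"):
        raise ValueError(f"adjacency_rule must be 'rook' or 'queen', got {adjacency_rule!r}")
    coarse_factor = int(coarse_factor)

    nx = int(np.ceil((xmax - xmin) / fine_size - 1e-9))
    ny = int(np.ceil((ymax - ymin) / fine_size - 1e-9))
    ids = np.arange(nx * ny)
    cx = xmin + (ids % nx + 0.5) * fine_size
    cy = ymin + (ids // nx + 0.5) * fine_size

    bx = int(np.ceil(nx / coarse_factor))
    by = int(np.ceil(ny / coarse_factor))
    block_i = (ids % nx) // coarse_factor
    block_j = (ids // nx) // coarse_factor
    fine_to_coarse = block_j * bx + block_i

    return NestedGrid(
        extent=(xmin, ymin, xmax, ymax),
        fine_size=float(fine_size),
        coarse_factor=coarse_factor,
        nx=nx,
        ny=ny,
        fine_cell_ids=ids,
        fine_cell_centers=np.column_stack([cx, cy]),
        fine_to_coarse=fine_to_coarse,
        coarse_adjacency=_lattice_adjacency(bx, by, adjacency_rule),
    )


def assign_cells(
    points: np.ndarray, grid: NestedGrid
) -> tuple[np.ndarray, np.ndarray]:
    """Map planar points to the fine cells containing them.

    Cells are half-open, so a point on a cell's lower/left edge belongs to
    that cell and a point on the shared upper edge belongs to the cell above.

    Returns
    -------
    cell_ids : fine cell id per in-extent point.
    kept : boolean mask over the input rows; out-of-extent points are
        excluded from ``cell_ids``, reported in a warning.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    xmin, ymin, xmax, ymax = grid.extent
    ix = np.floor((pts[:, 0] - xmin) / grid.fine_size).astype(int)
    iy = np.floor((pts[:, 1] - ymin) / grid.fine_size).astype(int)
    kept = (ix >= 0) & (ix < grid.nx) & (iy >= 0) & (iy < grid.ny)
    if not kept.all():
        bad = np.flatnonzero(~kept)
        warnings.warn(
            f"{bad.size} point(s) outside the grid extent excluded "
            f"(row indices {bad[:20].tolist()}{'...' if bad.size > 20 else ''})",
            stacklevel=2,
        )
    return (iy[kept] * grid.nx + ix[kept]), kept


def aggregate_counts(
    ffa_points: pd.DataFrame,
    survey_footprints: pd.DataFrame,
    grid: NestedGrid,
    survey_seasons: dict | pd.Series | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rasterize FFA detections and survey effort to (cell x survey) tables.

    Parameters
    ----------
    ffa_points : one row per detected aggregation with columns
        ``x, y, survey_id, area_m2`` (planar km; surface area in m^2).
    survey_footprints : surveyed area per cell and survey with columns
        ``cell_id, survey_id, effort_km2``.
    survey_seasons : optional map survey_id -> season label; if given, a
        ``season`` column is attached to the count table.

    Returns
    -------
    counts : one row per surveyed (cell, survey) with positive effort:
        ``cell_id, survey_id, effort_km2, count`` (zeros retained — an
        empty surveyed cell is data).
    sizes : one row per FFA point: ``aggregation_id, cell_id, survey_id,
        area_m2, log_area``.

    Zero-effort footprint rows are dropped (and logged); an FFA detection
    falling in a (cell, survey) with no recorded positive effort is a
    consistency error.
    """
    fp = survey_footprints.copy()
    required = {"cell_id", "survey_id", "effort_km2"}
    if not required.issubset(fp.columns):
        raise ValueError(f"footprints need columns {sorted(required)}")
    if (fp["effort_km2"] < 0).any():
        raise ValueError("negative effort_km2 in footprints")
    n_zero = int((fp["effort_km2"] == 0).sum())
    if n_zero:
        logger.warning("dropping %d zero-effort footprint rows", n_zero)
        fp = fp[fp["effort_km2"] > 0]
    fp = fp.groupby(["cell_id", "survey_id"], as_index=False)["effort_km2"].sum()

    pts = ffa_points.copy()
    if len(pts):
        if (pts["area_m2"] <= 0).any():
            raise ValueError("area_m2 must be strictly positive")
        cell_ids, kept = assign_cells(pts[["x", "y"]].to_numpy(), grid)
        pts = pts.loc[kept].copy()
        pts["cell_id"] = cell_ids
    else:
        pts["cell_id"] = np.array([], dtype=int)

    effort_lookup = fp.set_index(["cell_id", "survey_id"])["effort_km2"]
    if len(pts):
        keys = pd.MultiIndex.from_frame(pts[["cell_id", "survey_id"]])
        missing = ~np.asarray(keys.isin(effort_lookup.index))
        if missing.any():
            bad = pts.loc[missing, ["cell_id", "survey_id"]]
            raise ValueError(
                "FFA detections in (cell, survey) combinations with no positive "
                f"recorded effort:\n{bad.drop_duplicates().to_string(index=False)}"
            )

    tallied = (
        pts.groupby(["cell_id", "survey_id"]).size().rename("count")
        if len(pts)
        else pd.Series(dtype=int, name="count")
    )
    counts = fp.merge(tallied, on=["cell_id", "survey_id"], how="left")
    counts["count"] = counts["count"].fillna(0).astype(int)
    if survey_seasons is not None:
        counts["season"] = counts["survey_id"].map(dict(survey_seasons))
        unknown = ~counts["season"].isin(SEASONS)
        if unknown.any():
            raise ValueError(
                f"unknown season label(s): {counts.loc[unknown, 'season'].unique()}"
            )

    sizes = pts.reset_index(drop=True)
    sizes.insert(0, "aggregation_id", np.arange(len(sizes)))
    sizes = sizes[["aggregation_id", "cell_id", "survey_id", "area_m2"]].copy()
    sizes["log_area"] = np.log(sizes["area_m2"].to_numpy(dtype=float)) if len(sizes) else []
    return counts, sizes
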