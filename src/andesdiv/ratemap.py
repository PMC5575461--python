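"""Speciation-rate mapping: tip rates -> occurrences -> thinned points -> IDW raster.

The method joins per-species speciation rates (e.g. tip rates exported
from an upstream rate-shift analysis) to georeferenced occurrence
records, thins the records to one per 0.5-degree grid cell to blunt
collection-density bias, and interpolates the thinned, rated points onto
a raster restricted to the clade's distribution polygon using inverse
distance weighting (IDW) with great-circle distances. Per-region
summaries with bootstrap intervals quantify contrasts such as
"Northern Andes versus everywhere else".
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import MultiPoint, Polygon, box as shapely_box
from sklearn.neighbors import BallTree

__all__ = [
    "RateRaster",
    "thin_occurrences",
    "attach_tip_rates",
    "idw_interpolate",
    "summarize_regions",
    "write_raster",
    "read_raster",
]

EARTH_RADIUS_KM = 6371.0088


@dataclass
class RateRaster:
    """Gridded rate surface in WGS84 decimal degrees.

    ``values[0, 0]`` is the north-west cell (ESRI ASCII row order);
    ``lon0``/``lat0`` give the lower-left corner of the grid. Missing
    (outside-mask) cells are NaN.
    """

    lon0: float
    lat0: float
    cell: float
    n_cols: int
    n_rows: int
    values: np.ndarray

    def lon_centers(self) -> np.ndarray:
        return self.lon0 + (np.arange(self.n_cols) + 0.5) * self.cell

    def lat_centers(self) -> np.ndarray:
        """North to south, matching row order of ``values``."""
        top = self.lat0 + self.n_rows * self.cell
        return top - (np.arange(self.n_rows) + 0.5) * self.cell


def _cell_index(coord: np.ndarray, cell: float) -> np.ndarray:
    # half-open [k*cell, (k+1)*cell) anchored at integer degrees
    return np.floor(np.asarray(coord) / cell).astype(np.int64)


def thin_occurrences(
    occ: pd.DataFrame, cell: float = 0.5, seed=None
) -> pd.DataFrame:
    """Keep exactly one record per occupied grid cell, chosen at random.

    Cells are half-open ``[k*cell, (k+1)*cell)`` in both lon and lat,
    anchored at integer degrees; the seed changes which record survives,
    never how many.
    """
    if occ.empty:
        raise ValueError("empty occurrence table")
    if cell <= 0:
        raise ValueError("cell size must be positive")
    rng = np.random.default_rng(seed)
    ix = _cell_index(occ["lon"].to_numpy(), cell)
    iy = _cell_index(occ["lat"].to_numpy(), cell)
    df = occ.reset_index(drop=True)
    keys = pd.DataFrame({"_cx": ix, "_cy": iy})
    picked = []
    for _, grp in df.groupby([keys["_cx"], keys["_cy"]], sort=True):
        picked.append(grp.index[rng.integers(len(grp))])
    return df.loc[sorted(picked)].reset_index(drop=True)


def attach_tip_rates(
    occ: pd.DataFrame,
    rates: Mapping[str, float],
    *,
    strict: bool = True,
) -> pd.DataFrame:
    """Join per-species speciation rates onto occurrence records.

    In strict mode any occurrence species missing from the rate table is
    an error; in lenient mode those records are dropped with a warning
    reporting the count.
    """
    rate_map = dict(rates)
    missing = sorted(set(occ["species"]) - set(rate_map))
    if missing:
        if strict:
            raise KeyError(f"species without tip rates: {missing}")
        n_before = len(occ)
        occ = occ[occ["species"].isin(rate_map)]
        warnings.warn(
            f"dropped {n_before - len(occ)} records of {len(missing)} "
            "species without tip rates"
        )
    out = occ.copy()
    out["rate"] = out["species"].map(rate_map)
    return out.reset_index(drop=True)


def idw_interpolate(
    points: pd.DataFrame,
    *,
    cell: float = 0.5,
    power: float = 2.0,
    k_neighbors: int = 12,
    mask: Optional[Polygon] = None,
    bounds: Optional[Tuple[float, float, float, float]] = None,
    exact_eps_km: float = 1e-6,
) -> RateRaster:
    """Inverse-distance-weighted rate surface over a masked grid.

    Each cell centre takes the distance^-power weighted mean of the rates
    of its ``k_neighbors`` nearest points, with great-circle (haversine)
    distances. A cell centre coinciding with a point (closer than
    ``exact_eps_km``) takes that point's rate exactly. Cells outside the
    mask polygon (default: convex hull of the points buffered by one
    cell) are NaN. Grid lines are anchored at integer degrees.
    """
    if points.empty:
        raise ValueError("empty point set")
    if power <= 0:
        raise ValueError("power must be positive")
    lon = points["lon"].to_numpy(float)
    lat = points["lat"].to_numpy(float)
    rate = points["rate"].to_numpy(float)
    if mask is None:
        mask = MultiPoint(list(zip(lon, lat))).convex_hull.buffer(cell)
    if bounds is None:
        bx0, by0, bx1, by1 = mask.bounds
    else:
        bx0, by0, bx1, by1 = bounds
    lon0 = math.floor(bx0 / cell) * cell
    lat0 = math.floor(by0 / cell) * cell
    n_cols = max(1, int(math.ceil((bx1 - lon0) / cell)))
    n_rows = max(1, int(math.ceil((by1 - lat0) / cell)))
    raster = RateRaster(lon0, lat0, cell, n_cols, n_rows,
                        np.full((n_rows, n_cols), np.nan))
    lonc = raster.lon_centers()
    latc = raster.lat_centers()
    gx, gy = np.meshgrid(lonc, latc)
    inside = shapely.contains_xy(mask, gx.ravel(), gy.ravel())
    if not inside.any():
        return raster
    tree = BallTree(np.radians(np.c_[lat, lon]), metric="haversine")
    k = min(k_neighbors, len(points))
    q = np.radians(np.c_[gy.ravel()[inside], gx.ravel()[inside]])
    dist, idx = tree.query(q, k=k)
    dist_km = dist * EARTH_RADIUS_KM
    vals = np.empty(q.shape[0])
    exact = dist_km[:, 0] < exact_eps_km
    vals[exact] = rate[idx[exact, 0]]
    rest = ~exact
    if rest.any():
        w = dist_km[rest] ** (-power)
        vals[rest] = np.sum(w * rate[idx[rest]], axis=1) / np.sum(w, axis=1)
    flat = raster.values.ravel()
    flat[np.nonzero(inside)[0]] = vals
    raster.values = flat.reshape(n_rows, n_cols)
    return raster


def summarize_regions(
    points: pd.DataFrame,
    regions: Mapping[str, Polygon],
    *,
    n_boot: int = 500,
    seed=None,
    ci: float = 0.95,
) -> pd.DataFrame:
    """Per-region mean/median rate with a bootstrap confidence interval.

    Points are assigned to the first region polygon containing them;
    the bootstrap resamples points (not grid cells). Regions containing
    no points produce a row of NaNs and a warning.
    """
    rng = np.random.default_rng(seed)
    rows = []
    alpha = (1.0 - ci) / 2.0
    lon = points["lon"].to_numpy(float)
    lat = points["lat"].to_numpy(float)
    rate = points["rate"].to_numpy(float)
    for name, poly in regions.items():
        sel = shapely.contains_xy(poly, lon, lat)
        r = rate[sel]
        if r.size == 0:
            warnings.warn(f"region {name!r} contains no points")
            rows.append({"region": name, "n": 0, "mean": np.nan,
                         "median": np.nan, "ci_lo": np.nan, "ci_hi": np.nan})
            continue
        boots = np.empty(n_boot)
        for b in range(n_boot):
            boots[b] = r[rng.integers(0, r.size, r.size)].mean()
        rows.append({
            "region": name,
            "n": int(r.size),
            "mean": float(r.mean()),
            "median": float(np.median(r)),
            "ci_lo": float(np.quantile(boots, alpha)) if r.size > 1 else float(r.mean()),
            "ci_hi": float(np.quantile(boots, 1 - alpha)) if r.size > 1 else float(r.mean()),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------- #
# raster I/O (plain-text formats)

def write_raster(raster: RateRaster, path: str, fmt: Optional[str] = None) -> None:
    """Write the raster as an ESRI ASCII grid (.asc) or long CSV.

    Missing cells are encoded as the nodata value (-9999 in .asc, empty
    in CSV). The format is inferred from the extension when ``fmt`` is
    None. Round-trips through :func:`read_raster` are bit-exact.
    """
    fmt = fmt or ("asc" if str(path).endswith(".asc") else "csv")
    if fmt == "asc":
        nodata = -9999.0
        vals = np.where(np.isnan(raster.values), nodata, raster.values)
        with open(path, "w") as fh:
            fh.write(f"ncols {raster.n_cols}\n")
            fh.write(f"nrows {raster.n_rows}\n")
            fh.write(f"xllcorner {float(raster.lon0)!r}\n")
            fh.write(f"yllcorner {float(raster.lat0)!r}\n")
            fh.write(f"cellsize {float(raster.cell)!r}\n")
            fh.write(f"nodata_value {float(nodata)!r}\n")
            for row in vals:
                fh.write(" ".join(repr(float(v)) for v in row) + "\n")
    elif fmt == "csv":
        lonc = raster.lon_centers()
        latc = raster.lat_centers()
        rows, cols = np.meshgrid(np.arange(raster.n_rows), np.arange(raster.n_cols),
                                 indexing="ij")
        df = pd.DataFrame({
            "row": rows.ravel(),
            "col": cols.ravel(),
            "lon": lonc[cols.ravel()],
            "lat": latc[rows.ravel()],
            "rate": raster.values.ravel(),
        })
        df.attrs = {}
        header = (f"# raster lon0={raster.lon0!r} lat0={raster.lat0!r} "
                  f"cell={raster.cell!r} ncols={raster.n_cols} nrows={raster.n_rows}\n")
        with open(path, "w") as fh:
            fh.write(header)
            df.to_csv(fh, index=False, float_format="%.17g")
    else:
        raise ValueError(f"unsupported raster format {fmt!r} (use 'asc' or 'csv')")


def read_raster(path: str, fmt: Optional[str] = None) -> RateRaster:
    """Read a raster written by :func:`write_raster`."""
    fmt = fmt or ("asc" if str(path).endswith(".asc") else "csv")
    if fmt == "asc":
        header: Dict[str, float] = {}
        with open(path) as fh:
            lines = fh.read().splitlines()
        for line in lines[:6]:
            key, val = line.split()
            header[key.lower()] = float(val)
        n_cols = int(header["ncols"])
        n_rows = int(header["nrows"])
        nodata = header["nodata_value"]
        vals = np.loadtxt(lines[6:]).reshape(n_rows, n_cols)
        vals[vals == nodata] = np.nan
        return RateRaster(header["xllcorner"], header["yllcorner"],
                          header["cellsize"], n_cols, n_rows, vals)
    with open(path) as fh:
        header_line = fh.readline()
        df = pd.read_csv(fh, float_precision="round_trip")
    meta = dict(tok.split("=") for tok in header_line.strip("#\n ").split()[1:])
    n_cols, n_rows = int(meta["ncols"]), int(meta["nrows"])
    vals = np.full((n_rows, n_cols), np.nan)
    vals[df["row"].to_numpy(), df["col"].to_numpy()] = df["rate"].to_numpy()
    return RateRaster(float(meta["lon0"]), float(meta["lat0"]),
                      float(meta["cell"]), n_cols, n_rows, vals)
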