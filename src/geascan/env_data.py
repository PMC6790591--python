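"""Environmental-table construction: raster point extraction, coordinate
projection, CSV merge and correlation pruning.

Rasters are regular lon/lat grids read from ESRI ASCII grid or GeoTIFF.
Missing environmental values are NaN throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class EnvError(ValueError):
    """Fatal environmental-data error."""


@dataclass
class RasterGrid:
    """Regular geographic grid.

    ``origin`` is the (min lon, max lat) corner of the *grid extent* (upper
    left corner of the upper-left cell); ``cell_size`` is (dx, dy) in degrees;
    ``values`` is row-major with row 0 the northernmost row.
    """

    name: str
    origin: tuple
    cell_size: tuple
    values: np.ndarray
    nodata: float | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.size == 0:
            raise EnvError("raster grid must be a nonempty 2-D array")
        if self.cell_size[0] <= 0 or self.cell_size[1] <= 0:
            raise EnvError("cell sizes must be positive")


@dataclass
class EnvTable:
    """Sample table: IDs, WGS84 coordinates, and named numeric variables.

    ``pop_vars`` flags which columns are population-structure covariates
    (exempt from correlation pruning).
    """

    samples: list
    coordinates: np.ndarray  # (n, 2) lon, lat
    data: pd.DataFrame  # columns = variables, index positional
    pop_vars: list = field(default_factory=list)

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if len(set(self.samples)) != len(self.samples):
            raise EnvError("duplicate sample IDs in EnvTable")
        if self.coordinates.shape != (len(self.samples), 2):
            raise EnvError("coordinates must be (n_samples, 2)")
        if self.data.shape[0] != len(self.samples):
            raise EnvError("data rows do not match samples")
        unknown = set(self.pop_vars) - set(self.data.columns)
        if unknown:
            raise EnvError(f"pop_vars not in table: {sorted(unknown)}")
        self.data = self.data.reset_index(drop=True)

    @property
    def env_vars(self) -> list:
        return [c for c in self.data.columns if c not in self.pop_vars]


# ---------------------------------------------------------------------------
# Coordinate projection (WGS84 geographic + UTM; pyproj-free)
# ---------------------------------------------------------------------------

_WGS84_A = 6378137.0
_WGS84_F = 1.0 / 298.257223563
_UTM_K0 = 0.9996
_UTM_FE = 500000.0
_UTM_FN_S = 10000000.0


def _tm_coefficients():
    # Krueger series (order 6) for the transverse Mercator projection
    f = _WGS84_F
    n = f / (2 - f)
    n2, n3, n4, n5, n6 = n**2, n**3, n**4, n**5, n**6
    A = _WGS84_A / (1 + n) * (1 + n2 / 4 + n4 / 64 + n6 / 256)
    beta = [
        n / 2 - 2 * n2 / 3 + 37 * n3 / 96 - n4 / 360 - 81 * n5 / 512 + 96199 * n6 / 604800,
        n2 / 48 + n3 / 15 - 437 * n4 / 1440 + 46 * n5 / 105 - 1118711 * n6 / 3870720,
        17 * n3 / 480 - 37 * n4 / 840 - 209 * n5 / 4480 + 5569 * n6 / 90720,
        4397 * n4 / 161280 - 11 * n5 / 504 - 830251 * n6 / 7257600,
        4583 * n5 / 161280 - 108847 * n6 / 3991680,
        20648693 * n6 / 638668800,
    ]
    delta = [
        2 * n - 2 * n2 / 3 - 2 * n3 + 116 * n4 / 45 + 26 * n5 / 45 - 2854 * n6 / 675,
        7 * n2 / 3 - 8 * n3 / 5 - 227 * n4 / 45 + 2704 * n5 / 315 + 2323 * n6 / 945,
        56 * n3 / 15 - 136 * n4 / 35 - 1262 * n5 / 105 + 73814 * n6 / 2835,
        4279 * n4 / 630 - 332 * n5 / 35 - 399572 * n6 / 14175,
        4174 * n5 / 315 - 144838 * n6 / 6237,
        601676 * n6 / 22275,
    ]
    return n, A, beta, delta


_TM_N, _TM_A, _TM_BETA, _TM_DELTA = _tm_coefficients()


def _utm_inverse(easting: float, northing: float, zone: int, south: bool):
    """UTM easting/northing -> (lon, lat) degrees on WGS84."""
    lon0 = math.radians(-183.0 + 6.0 * zone)
    x = easting - _UTM_FE
    y = northing - (_UTM_FN_S if south else 0.0)
    xi = y / (_UTM_K0 * _TM_A)
    eta = x / (_UTM_K0 * _TM_A)
    xi_p, eta_p = xi, eta
    for j, b in enumerate(_TM_BETA, start=1):
        xi_p -= b * math.sin(2 * j * xi) * math.cosh(2 * j * eta)
        eta_p -= b * math.cos(2 * j * xi) * math.sinh(2 * j * eta)
    chi = math.asin(math.sin(xi_p) / math.cosh(eta_p))
    lat = chi
    for j, d in enumerate(_TM_DELTA, start=1):
        lat += d * math.sin(2 * j * chi)
    lon = lon0 + math.atan2(math.sinh(eta_p), math.cos(xi_p))
    return math.degrees(lon), math.degrees(lat)


def _utm_forward(lon: float, lat: float, zone: int, south: bool):
    """(lon, lat) degrees -> UTM easting/northing (inverse of above)."""
    lon0 = math.radians(-183.0 + 6.0 * zone)
    phi = math.radians(lat)
    lam = math.radians(lon) - lon0
    n = _TM_N
    t = math.sinh(
        math.atanh(math.sin(phi))
        - 2 * math.sqrt(n) / (1 + n) * math.atanh(2 * math.sqrt(n) / (1 + n) * math.sin(phi))
    )
    xi_p = math.atan2(t, math.cos(lam))
    eta_p = math.atanh(math.sin(lam) / math.sqrt(1 + t * t))
    xi, eta = xi_p, eta_p
    n2, n3, n4, n5, n6 = n**2, n**3, n**4, n**5, n**6
    alpha = [
        n / 2 - 2 * n2 / 3 + 5 * n3 / 16 + 41 * n4 / 180 - 127 * n5 / 288 + 7891 * n6 / 37800,
        13 * n2 / 48 - 3 * n3 / 5 + 557 * n4 / 1440 + 281 * n5 / 630 - 1983433 * n6 / 1935360,
        61 * n3 / 240 - 103 * n4 / 140 + 15061 * n5 / 26880 + 167603 * n6 / 181440,
        49561 * n4 / 161280 - 179 * n5 / 168 + 6601661 * n6 / 7257600,
        34729 * n5 / 80640 - 3418889 * n6 / 1995840,
        212378941 * n6 / 319334400,
    ]
    for j, a in enumerate(alpha, start=1):
        xi += a * math.sin(2 * j * xi_p) * math.cosh(2 * j * eta_p)
        eta += a * math.cos(2 * j * xi_p) * math.sinh(2 * j * eta_p)
    easting = _UTM_FE + _UTM_K0 * _TM_A * eta
    northing = _UTM_K0 * _TM_A * xi + (_UTM_FN_S if south else 0.0)
    return easting, northing


def _parse_utm_epsg(epsg: int):
    if 32601 <= epsg <= 32660:
        return epsg - 32600, False
    if 32701 <= epsg <= 32760:
        return epsg - 32700, True
    return None


def project_coordinates(points, epsg_in: int):
    """Project (x, y) pairs from ``epsg_in`` to WGS84 (lon, lat) degrees.

    Supported systems: EPSG:4326 (identity) and the WGS84 UTM zones
    (EPSG:32601-32660 north, 32701-32760 south).  Other codes are fatal.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise EnvError("points must be an (n, 2) array of (x, y)")
    if epsg_in == 4326:
        return pts.copy()
    utm = _parse_utm_epsg(epsg_in)
    if utm is None:
        raise EnvError(
            f"unsupported EPSG code {epsg_in}: only 4326 and WGS84 UTM zones "
            "(326xx/327xx) are available offline"
        )
    zone, south = utm
    out = np.empty_like(pts)
    for i, (x, y) in enumerate(pts):
        out[i] = _utm_inverse(x, y, zone, south)
    return out


def inverse_project_coordinates(lonlat, epsg_out: int):
    """WGS84 (lon, lat) -> target system; inverse of :func:`project_coordinates`."""
    pts = np.asarray(lonlat, dtype=float)
    if epsg_out == 4326:
        return pts.copy()
    utm = _parse_utm_epsg(epsg_out)
    if utm is None:
        raise EnvError(f"unsupported EPSG code {epsg_out}")
    zone, south = utm
    out = np.empty_like(pts)
    for i, (lon, lat) in enumerate(pts):
        out[i] = _utm_forward(lon, lat, zone, south)
    return out


# ---------------------------------------------------------------------------
# Raster IO and extraction
# ---------------------------------------------------------------------------


def read_esri_ascii(path, name: str | None = None) -> RasterGrid:
    """Read an ESRI ASCII grid (.asc)."""
    header = {}
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "xllcenter",
            "yllcenter", "cellsize", "nodata_value",
        }:
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    try:
        ncols = int(header["ncols"])
        nrows = int(header["nrows"])
        cell = header["cellsize"]
    except KeyError as exc:
        raise EnvError(f"{path}: missing ESRI ASCII header field {exc}") from exc
    if "xllcorner" in header:
        xll, yll = header["xllcorner"], header["yllcorner"]
    else:
        xll = header["xllcenter"] - cell / 2
        yll = header["yllcenter"] - cell / 2
    values = np.loadtxt(lines[i:], dtype=float).reshape(nrows, ncols)
    nodata = header.get("nodata_value")
    import os

    return RasterGrid(
        name=name or os.path.splitext(os.path.basename(str(path)))[0],
        origin=(xll, yll + nrows * cell),
        cell_size=(cell, cell),
        values=values,
        nodata=nodata,
    )


def read_geotiff(path, name: str | None = None) -> RasterGrid:
    """Read a single-band GeoTIFF in geographic coordinates via tifffile.

    Georeferencing comes from the ModelPixelScale (33550) and ModelTiepoint
    (33922) tags; nodata from GDAL_NODATA (42113) when present.
    """
    import os

    import tifffile

    with tifffile.TiffFile(str(path)) as tif:
        page = tif.pages[0]
        values = page.asarray().astype(float)
        tags = page.tags
        try:
            scale = tags[33550].value  # (sx, sy, sz)
            tiepoint = tags[33922].value  # (i, j, k, x, y, z)
        except KeyError as exc:
            raise EnvError(f"{path}: missing GeoTIFF georeferencing tags") from exc
        nodata = None
        if 42113 in tags:
            try:
                nodata = float(str(tags[42113].value).strip("\x00 "))
            except ValueError:
                nodata = None
    if values.ndim == 3:
        values = values[..., 0]
    sx, sy = float(scale[0]), float(scale[1])
    px, py = float(tiepoint[0]), float(tiepoint[1])
    gx, gy = float(tiepoint[3]), float(tiepoint[4])
    origin = (gx - px * sx, gy + py * sy)
    return RasterGrid(
        name=name or os.path.splitext(os.path.basename(str(path)))[0],
        origin=origin,
        cell_size=(sx, sy),
        values=values,
        nodata=nodata,
    )


def read_raster(path, name: str | None = None) -> RasterGrid:
    p = str(path).lower()
    if p.endswith((".tif", ".tiff")):
        return read_geotiff(path, name)
    return read_esri_ascii(path, name)


def extract_at_points(r: RasterGrid, pts) -> np.ndarray:
    """Value of the grid cell containing each (lon, lat) point.

    Nearest-cell rule (no interpolation); out-of-extent points and nodata
    cells give NaN.
    """
    pts = np.asarray(pts, dtype=float)
    nrows, ncols = r.values.shape
    x0, y0 = r.origin
    dx, dy = r.cell_size
    col = np.floor((pts[:, 0] - x0) / dx).astype(int)
    row = np.floor((y0 - pts[:, 1]) / dy).astype(int)
    # points exactly on the max edge belong to the last cell
    col[(pts[:, 0] == x0 + ncols * dx)] = ncols - 1
    row[(pts[:, 1] == y0 - nrows * dy)] = nrows - 1
    out = np.full(len(pts), np.nan)
    ok = (col >= 0) & (col < ncols) & (row >= 0) & (row < nrows)
    out[ok] = r.values[row[ok], col[ok]]
    if r.nodata is not None:
        out[np.isclose(out, r.nodata, equal_nan=False)] = np.nan
    return out


# ---------------------------------------------------------------------------
# Table assembly and pruning
# ---------------------------------------------------------------------------


def build_env_table(samples, coordinates, rasters=(), extra: pd.DataFrame | None = None,
                    epsg: int = 4326) -> EnvTable:
    """Assemble an :class:`EnvTable` from rasters and/or a ready-made frame.

    Coordinates are projected to WGS84 first; raster values are extracted at
    the projected locations.  ``extra`` columns (indexed like ``samples``
    order) are appended as-is.
    """
    lonlat = project_coordinates(coordinates, epsg)
    data = {}
    for r in rasters:
        data[r.name] = extract_at_points(r, lonlat)
    df = pd.DataFrame(data, index=range(len(samples)))
    if extra is not None:
        for c in extra.columns:
            df[c] = np.asarray(extra[c], dtype=float)
    return EnvTable(samples=list(samples), coordinates=lonlat, data=df)


def prune_correlated(env: EnvTable, r2_threshold: float):
    """Greedy correlation pruning of environmental variables.

    Scanning columns in order, a variable is dropped when its squared Pearson
    correlation (pairwise-complete) with any already-retained environmental
    variable exceeds ``r2_threshold``.  Population-structure columns are
    never dropped and never cause drops.  Returns ``(pruned EnvTable,
    curve DataFrame)`` where the curve gives #retained per threshold on a
    0.05-step grid.
    """
    if not 0.0 < r2_threshold <= 1.0:
        raise EnvError(f"r2_threshold must be in (0, 1], got {r2_threshold}")
    env_cols = env.env_vars
    if len(env.data.columns) == 0:
        raise EnvError("EnvTable has no variables")

    def greedy(thr):
        kept = []
        for c in env_cols:
            col = env.data[c].to_numpy(dtype=float)
            if np.nanstd(col) == 0 or np.isnan(col).all():
                continue  # constant column: uninformative, always dropped
            ok = True
            for k in kept:
                if _r2_pairwise(col, env.data[k].to_numpy(dtype=float)) > thr:
                    ok = False
                    break
            if ok:
                kept.append(c)
        return kept

    kept = greedy(r2_threshold)
    grid = np.round(np.arange(0.05, 1.0001, 0.05), 2)
    curve = pd.DataFrame(
        {"r2_threshold": grid, "n_retained": [len(greedy(t)) for t in grid]}
    )
    cols = kept + list(env.pop_vars)
    pruned = EnvTable(
        samples=list(env.samples),
        coordinates=env.coordinates.copy(),
        data=env.data[cols].copy(),
        pop_vars=list(env.pop_vars),
    )
    return pruned, curve


def _r2_pairwise(x: np.ndarray, y: np.ndarray) -> float:
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < 2:
        return 0.0
    xo, yo = x[ok], y[ok]
    sx, sy = xo.std(), yo.std()
    if sx == 0 or sy == 0:
        return 0.0
    r = np.mean((xo - xo.mean()) * (yo - yo.mean())) / (sx * sy)
    return float(r * r)


# ---------------------------------------------------------------------------
# CSV round-trip
# ---------------------------------------------------------------------------


def write_env_csv(env: EnvTable, path) -> None:
    """Write ``ID, lon, lat, variables...`` as RFC-4180 CSV.  Population
    columns are marked by a ``#pop_vars`` comment line at the top."""
    with open(path, "w") as fh:
        if env.pop_vars:
            fh.write("#pop_vars=" + ",".join(env.pop_vars) + "\n")
        out = pd.DataFrame({"ID": env.samples})
        out["lon"] = env.coordinates[:, 0]
        out["lat"] = env.coordinates[:, 1]
        for c in env.data.columns:
            out[c] = env.data[c].to_numpy()
        out.to_csv(fh, index=False)


def read_env_csv(path) -> EnvTable:
    pop_vars: list = []
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#pop_vars="):
            pop_vars = [c for c in first.strip().split("=", 1)[1].split(",") if c]
            df = pd.read_csv(fh)
        else:
            fh.seek(0)
            df = pd.read_csv(fh)
    for col in ("ID", "lon", "lat"):
        if col not in df.columns:
            raise EnvError(f"{path}: missing required column {col!r}")
    if df["ID"].duplicated().any():
        dup = df.loc[df["ID"].duplicated(), "ID"].iloc[0]
        raise EnvError(f"{path}: duplicate sample ID {dup!r}")
    samples = df["ID"].astype(str).tolist()
    coords = df[["lon", "lat"]].to_numpy(dtype=float)
    data = df.drop(columns=["ID", "lon", "lat"]).astype(float)
    return EnvTable(samples=samples, coordinates=coords, data=data, pop_vars=pop_vars)


def reorder_to(env: EnvTable, sample_order) -> EnvTable:
    """Reorder rows to match a genotype file's sample order (fatal on
    mismatch, listing offending IDs)."""
    idx = {s: i for i, s in enumerate(env.samples)}
    missing = [s for s in sample_order if s not in idx]
    extra = [s for s in env.samples if s not in set(sample_order)]
    if missing or extra:
        raise EnvError(
            f"sample ID mismatch: missing from env table {missing[:5]}, "
            f"not in genotype file {extra[:5]}"
        )
    order = [idx[s] for s in sample_order]
    return EnvTable(
        samples=list(sample_order),
        coordinates=env.coordinates[order],
        data=env.data.iloc[order].reset_index(drop=True),
        pop_vars=list(env.pop_vars),
    )
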