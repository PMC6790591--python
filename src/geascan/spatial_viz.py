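"""Spatial diagnostics and plots: local Moran's I of genotype indicators,
Manhattan plots, occurrence maps and overlap-free point placement."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from geascan.genotype_io import MISSING  # noqa: E402

EARTH_RADIUS_KM = 6371.0


class VizError(ValueError):
    pass


@dataclass
class NeighborWeights:
    """Row-standardized spatial weights.

    ``neighbors[i]`` lists neighbor indices of sample i and ``weights[i]``
    their weights summing to 1 (empty rows are flagged in ``isolated``).
    """

    neighbors: list
    weights: list
    scheme: str
    parameter: float

    def __post_init__(self):
        for i, (nb, w) in enumerate(zip(self.neighbors, self.weights)):
            if i in nb:
                raise VizError(f"self-neighbor at sample {i}")
            if len(nb) and not math.isclose(sum(w), 1.0, abs_tol=1e-9):
                raise VizError(f"weights row {i} not standardized")

    @property
    def isolated(self):
        return [i for i, nb in enumerate(self.neighbors) if not nb]

    @property
    def n(self) -> int:
        return len(self.neighbors)


def great_circle_km(lonlat_a: np.ndarray, lonlat_b: np.ndarray) -> np.ndarray:
    """Haversine distance matrix in km between two (n,2)/(m,2) point sets."""
    a = np.radians(np.asarray(lonlat_a, float))
    b = np.radians(np.asarray(lonlat_b, float))
    dlat = a[:, None, 1] - b[None, :, 1]
    dlon = a[:, None, 0] - b[None, :, 0]
    h = (
        np.sin(dlat / 2) ** 2
        + np.cos(a[:, None, 1]) * np.cos(b[None, :, 1]) * np.sin(dlon / 2) ** 2
    )
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))


def build_weights(lonlat, scheme: str = "knn", k: int = 10,
                  radius_km: float | None = None) -> NeighborWeights:
    """k-nearest (great-circle) or distance-band neighbor weights,
    row-standardized."""
    lonlat = np.asarray(lonlat, float)
    n = len(lonlat)
    d = great_circle_km(lonlat, lonlat)
    np.fill_diagonal(d, np.inf)
    neighbors, weights = [], []
    if scheme == "knn":
        k_eff = min(k, n - 1)
        if k_eff < 1:
            raise VizError("need at least 2 samples for knn weights")
        for i in range(n):
            nb = np.argsort(d[i], kind="mergesort")[:k_eff]
            neighbors.append(nb.tolist())
            weights.append([1.0 / k_eff] * k_eff)
        param = float(k_eff)
    elif scheme == "distance_band":
        if radius_km is None:
            raise VizError("distance_band requires radius_km")
        for i in range(n):
            nb = np.where(d[i] <= radius_km)[0]
            neighbors.append(nb.tolist())
            weights.append([1.0 / len(nb)] * len(nb) if len(nb) else [])
        param = float(radius_km)
    else:
        raise VizError(f"unknown weight scheme {scheme!r}")
    return NeighborWeights(neighbors=neighbors, weights=weights,
                           scheme=scheme, parameter=param)


def _lag(z: np.ndarray, w: NeighborWeights) -> np.ndarray:
    out = np.zeros_like(z)
    for i, (nb, wt) in enumerate(zip(w.neighbors, w.weights)):
        if nb:
            out[i] = float(np.dot(z[nb], wt))
    return out


def local_moran(ind, w: NeighborWeights, permutations: int = 999,
                seed: int = 0):
    """Local Moran's I per sample with conditional-permutation pseudo-p.

    The indicator is z-scored (population sd) over non-missing samples;
    ``I_i = z_i * sum_j w_ij z_j``.  Pseudo-p is two-sided: the rank of
    ``|I_i|`` among ``|I|`` values recomputed with the other samples' values
    permuted among i's neighbors.  Missing-indicator samples get NaN.
    A constant indicator is fatal-flagged (all NaN, ok=False).
    """
    x = np.asarray(ind, dtype=float)
    x[np.asarray(ind) == MISSING] = np.nan
    valid = np.isfinite(x)
    n_valid = int(valid.sum())
    if n_valid < 2:
        raise VizError("need at least 2 non-missing samples")
    mu = x[valid].mean()
    sd = x[valid].std(ddof=0)
    n = len(x)
    I = np.full(n, np.nan)
    pseudo_p = np.full(n, np.nan)
    if sd == 0:
        return I, pseudo_p, False
    z = np.full(n, np.nan)
    z[valid] = (x[valid] - mu) / sd
    rng = np.random.default_rng(seed)
    zvalid = z[valid]
    valid_idx = np.where(valid)[0]
    pos_of = {g: i for i, g in enumerate(valid_idx)}
    for i in valid_idx:
        nb = [j for j in w.neighbors[i] if valid[j]]
        wt = [wt_ for j, wt_ in zip(w.neighbors[i], w.weights[i]) if valid[j]]
        if not nb:
            continue
        lag = float(np.dot(z[nb], wt))
        I[i] = z[i] * lag
        if permutations > 0:
            others = np.delete(zvalid, pos_of[i])
            k = len(nb)
            count = 0
            for _ in range(permutations):
                draw = others[rng.choice(len(others), size=k, replace=False)]
                i_perm = z[i] * float(np.dot(draw, wt))
                if abs(i_perm) >= abs(I[i]) - 1e-15:
                    count += 1
            pseudo_p[i] = (count + 1) / (permutations + 1)
    return I, pseudo_p, True


def global_moran(ind, w: NeighborWeights) -> float:
    """Global Moran's I (independent of :func:`local_moran`'s z route):
    ``(n / S0) * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2``."""
    x = np.asarray(ind, dtype=float)
    x[np.asarray(ind) == MISSING] = np.nan
    valid = np.isfinite(x)
    xv = x.copy()
    xbar = x[valid].mean()
    dev = np.where(valid, x - xbar, 0.0)
    num = 0.0
    s0 = 0.0
    for i in np.where(valid)[0]:
        for j, wt in zip(w.neighbors[i], w.weights[i]):
            if valid[j]:
                num += wt * dev[i] * dev[j]
                s0 += wt
    denom = float((dev[valid] ** 2).sum())
    n = int(valid.sum())
    return (n / s0) * num / denom


# ---------------------------------------------------------------------------
# Plots
# ---------------------------------------------------------------------------


def manhattan_plot(rt: pd.DataFrame, snp_meta: pd.DataFrame, env_var: str,
                   value: str = "q_G", threshold: float = 0.05,
                   out: str = "manhattan.png") -> dict:
    """Manhattan plot of ``-log10(value)`` vs cumulative genomic position.

    ``snp_meta`` must supply chrom/pos for every plotted SNP (missing
    coordinates are fatal, listing the SNPs).  Returns the plotted data
    layer (for tests): n_points, n_above threshold line, per-chromosome
    offsets.
    """
    sub = rt[rt["env"] == env_var].copy()
    if sub.empty:
        raise VizError(f"no rows for env variable {env_var!r}")
    sub["snp"] = sub["indicator"].str.rsplit("_", n=1).str[0]
    meta = snp_meta.set_index("name")[["chrom", "pos"]]
    missing = sorted(set(sub["snp"]) - set(meta.index))
    if missing:
        raise VizError(f"no genomic coordinates for SNPs: {missing[:10]}")
    sub = sub.join(meta, on="snp")
    sub = sub[np.isfinite(sub[value].to_numpy(dtype=float))]
    if sub.empty:
        raise VizError("nothing to plot: all values are NaN")

    chrom_order = list(dict.fromkeys(snp_meta["chrom"]))
    offsets = {}
    cum = 0
    for c in chrom_order:
        offsets[c] = cum
        cmax = snp_meta.loc[snp_meta["chrom"] == c, "pos"].max()
        cum += int(cmax) + 1
    xs = sub["pos"].to_numpy(float) + np.array([offsets[c] for c in sub["chrom"]])
    ys = -np.log10(np.clip(sub[value].to_numpy(float), 1e-300, None))

    fig, ax = plt.subplots(figsize=(9, 3.5))
    for idx, c in enumerate(chrom_order):
        m = (sub["chrom"] == c).to_numpy()
        if not m.any():
            continue
        ax.scatter(xs[m], ys[m], s=6,
                   color="#4477aa" if idx % 2 == 0 else "#99bbdd")
    line_y = -math.log10(threshold)
    ax.axhline(line_y, color="red", lw=1)
    ax.set_xlabel("cumulative genomic position (bp)")
    ax.set_ylabel(f"-log10({value})")
    ax.set_title(env_var)
    fig.tight_layout()
    fig.savefig(out, dpi=110)
    plt.close(fig)
    return {
        "n_points": int(len(xs)),
        "n_above": int((ys > line_y).sum()),
        "offsets": offsets,
    }


def scatter_points(pts, min_sep: float, max_iter: int = 1000) -> np.ndarray:
    """Displace overlapping points until all pairwise separations reach
    ``min_sep`` degrees (or ``max_iter`` rounds).

    Deterministic: conflicting points move radially outward from the local
    conflict centroid at golden-angle-spaced directions; points with no
    conflict never move.
    """
    pts = np.asarray(pts, dtype=float).copy()
    n = len(pts)
    if n < 2:
        return pts
    golden = math.pi * (3.0 - math.sqrt(5.0))
    for it in range(max_iter):
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        np.fill_diagonal(d, np.inf)
        conflict = d < min_sep
        if not conflict.any():
            break
        moved = conflict.any(axis=1)
        for rank, i in enumerate(np.where(moved)[0]):
            others = np.where(conflict[i])[0]
            center = pts[others].mean(axis=0)
            vec = pts[i] - center
            norm = np.hypot(*vec)
            ang = golden * (rank + 1 + it * n)
            if norm < 1e-12:
                vec = np.array([math.cos(ang), math.sin(ang)])
            else:
                vec = vec / norm
            pts[i] = pts[i] + vec * (0.6 * min_sep)
    return pts


def genotype_map(pts, indicator, out: str, raster=None, popvar=None,
                 min_sep: float = 0.0) -> dict:
    """Map genotype presence/absence over an optional environmental raster.

    Returns the data layer: counts of present/absent/missing points.
    """
    pts = np.asarray(pts, dtype=float)
    ind = np.asarray(indicator)
    if min_sep > 0:
        pts = scatter_points(pts, min_sep)
    fig, ax = plt.subplots(figsize=(6, 5))
    if raster is not None:
        nrows, ncols = raster.values.shape
        x0, y0 = raster.origin
        dx, dy = raster.cell_size
        vals = raster.values.astype(float)
        if raster.nodata is not None:
            vals = np.where(np.isclose(vals, raster.nodata), np.nan, vals)
        ax.imshow(vals, extent=(x0, x0 + ncols * dx, y0 - nrows * dy, y0),
                  origin="upper", cmap="viridis", alpha=0.6, aspect="auto")
    present = ind == 1
    absent = ind == 0
    missing = ~present & ~absent
    ax.scatter(pts[absent, 0], pts[absent, 1], marker="o", facecolors="none",
               edgecolors="grey", s=30, label="absent")
    ax.scatter(pts[present, 0], pts[present, 1], marker="^", color="black",
               s=40, label="present")
    if popvar is not None:
        sc = ax.scatter(pts[:, 0], pts[:, 1], c=np.asarray(popvar, float),
                        cmap="coolwarm", s=8)
        fig.colorbar(sc, ax=ax, label="population variable")
    ax.set_xlabel("longitude")
    ax.set_ylabel("latitude")
    ax.legend(loc="best", fontsize=7)
    fig.tight_layout()
    fig.savefig(out, dpi=110)
    plt.close(fig)
    return {
        "n_present": int(present.sum()),
        "n_absent": int(absent.sum()),
        "n_missing": int(missing.sum()),
    }
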