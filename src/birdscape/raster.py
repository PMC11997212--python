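"""Georeferenced raster grids and zonal extraction around points.

The container is deliberately small: a rectangular grid of float values with
an upper-left origin, a square pixel size in metres and NaN as the nodata
sentinel.  All operations assume a planar metric CRS; geographic coordinates
must be projected upstream.  Text I/O uses the ESRI ASCII grid format.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "RasterLayer",
    "read_ascii_grid",
    "ndvi_from_bands",
    "evi_from_bands",
    "veg_volume_layer",
    "aggregate",
    "buffer_mean",
    "buffer_volume_density",
    "site_buffer_table",
    "distance_to_centre",
    "BUFFER_RADII_M",
]

#: Buffer radii (m) used for site characterisation.
BUFFER_RADII_M = (25.0, 50.0, 100.0, 200.0, 400.0, 800.0)


class RasterInputError(ValueError):
    """Raised when raster operands are incompatible or a query is empty."""


@dataclass
class RasterLayer:
    """A rectangular grid of values anchored at its upper-left corner.

    Parameters
    ----------
    origin_xy
        ``(x, y)`` map coordinate of the upper-left corner of the grid
        (not of the first pixel centre).
    resolution_m
        Square pixel edge length in metres, > 0.
    values
        2-D float array; ``NaN`` encodes nodata.
    crs_label
        Free-text label of the (projected, metric) CRS.
    """

    origin_xy: tuple[float, float]
    resolution_m: float
    values: np.ndarray
    crs_label: str = "local-metric"
    nodata: float = field(default=np.nan, repr=False)

    def __post_init__(self) -> None:
        if self.resolution_m <= 0:
            raise RasterInputError("resolution_m must be positive")
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise RasterInputError("values must be a 2-D grid")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def pixel_centres(self) -> tuple[np.ndarray, np.ndarray]:
        """Map coordinates of every pixel centre as ``(X, Y)`` grids."""
        nrow, ncol = self.shape
        x0, y0 = self.origin_xy
        r = self.resolution_m
        xs = x0 + (np.arange(ncol) + 0.5) * r
        ys = y0 - (np.arange(nrow) + 0.5) * r
        return np.meshgrid(xs, ys)

    def valid_mask(self) -> np.ndarray:
        return ~np.isnan(self.values)

    def with_values(self, values: np.ndarray) -> "RasterLayer":
        return replace(self, values=np.asarray(values, dtype=np.float64))

    # ------------------------------------------------------------------ I/O

    def to_ascii_grid(self, path) -> None:
        """Write as an ESRI ASCII grid (nodata written as -9999)."""
        nrow, ncol = self.shape
        x0, y0 = self.origin_xy
        yll = y0 - nrow * self.resolution_m
        header = (
            f"ncols {ncol}\n"
            f"nrows {nrow}\n"
            f"xllcorner {x0!r}\n"
            f"yllcorner {yll!r}\n"
            f"cellsize {self.resolution_m!r}\n"
            f"NODATA_value -9999\n"
        )
        body = np.where(np.isnan(self.values), -9999.0, self.values)
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, body, fmt="%.6g")


def read_ascii_grid(path, crs_label: str = "local-metric") -> RasterLayer:
    """Read an ESRI ASCII grid written by :meth:`RasterLayer.to_ascii_grid`."""
    meta: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            meta[key.lower()] = float(val)
        values = np.loadtxt(fh)
    values = np.atleast_2d(values)
    nodata = meta.get("nodata_value", -9999.0)
    values = np.where(values == nodata, np.nan, values)
    res = meta["cellsize"]
    origin = (meta["xllcorner"], meta["yllcorner"] + meta["nrows"] * res)
    return RasterLayer(origin, res, values, crs_label=crs_label)


# ----------------------------------------------------------- index algebra


def _check_coregistered(*layers: RasterLayer) -> None:
    ref = layers[0]
    for lyr in layers[1:]:
        if lyr.shape != ref.shape or lyr.resolution_m != ref.resolution_m:
            raise RasterInputError(
                f"bands are not co-registered: {lyr.shape}@{lyr.resolution_m} "
                f"vs {ref.shape}@{ref.resolution_m}"
            )


def ndvi_from_bands(red: RasterLayer, nir: RasterLayer) -> RasterLayer:
    """NDVI = (NIR − Red) / (NIR + Red), bounded in [−1, 1].

    Pixels where the denominator is zero, or either band is nodata, are
    nodata in the result.
    """
    _check_coregistered(red, nir)
    r, n = red.values, nir.values
    denom = n + r
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom == 0, np.nan, (n - r) / denom)
    return red.with_values(np.clip(out, -1.0, 1.0))


def evi_from_bands(blue: RasterLayer, red: RasterLayer, nir: RasterLayer) -> RasterLayer:
    """Enhanced Vegetation Index, 2.5 (NIR − Red)/(NIR + 6 Red − 7.5 Blue + 1)."""
    _check_coregistered(blue, red, nir)
    b, r, n = blue.values, red.values, nir.values
    denom = n + 6.0 * r - 7.5 * b + 1.0
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom == 0, np.nan, 2.5 * (n - r) / denom)
    return red.with_values(out)


def veg_volume_layer(ndsm: RasterLayer, veg_mask: RasterLayer) -> RasterLayer:
    """Per-pixel canopy volume (m³): height × pixel area on vegetated pixels.

    Non-vegetated pixels are nodata.  Negative heights are physically
    impossible for a normalised surface model and are clipped to 0 with a
    warning.
    """
    _check_coregistered(ndsm, veg_mask)
    h = ndsm.values.copy()
    if np.nanmin(h, initial=0.0) < 0:
        warnings.warn("negative nDSM heights clipped to 0", stacklevel=2)
        h = np.clip(h, 0.0, None)
    area = ndsm.resolution_m**2
    mask = veg_mask.values > 0
    vol = np.where(mask, h * area, np.nan)
    return ndsm.with_values(vol)


def aggregate(raster: RasterLayer, target_resolution_m: float, stat: str = "mean") -> RasterLayer:
    """Block-aggregate to a coarser resolution, ignoring nodata.

    The target resolution must be an integer multiple of the source
    resolution and the grid must tile evenly.  Blocks that are entirely
    nodata stay nodata; for ``sum`` partially-valid blocks sum the valid
    pixels only.
    """
    ratio = target_resolution_m / raster.resolution_m
    k = int(round(ratio))
    if k < 1 or abs(ratio - k) > 1e-9:
        raise RasterInputError(
            f"target resolution {target_resolution_m} is not an integer "
            f"multiple of source resolution {raster.resolution_m}"
        )
    if k == 1:
        return raster.with_values(raster.values.copy())
    nrow, ncol = raster.shape
    if nrow % k or ncol % k:
        raise RasterInputError(f"grid {raster.shape} does not tile into {k}×{k} blocks")
    blocks = raster.values.reshape(nrow // k, k, ncol // k, k)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN blocks
        if stat == "mean":
            out = np.nanmean(blocks, axis=(1, 3))
        elif stat == "sum":
            out = np.nansum(blocks, axis=(1, 3))
            out[np.all(np.isnan(blocks), axis=(1, 3))] = np.nan
        else:
            raise ValueError(f"unknown stat {stat!r}")
    return RasterLayer(raster.origin_xy, target_resolution_m, out, raster.crs_label)


# ------------------------------------------------------- buffer extraction


def _buffer_window(raster: RasterLayer, point, radius_m: float):
    """Boolean in-buffer mask over a clipped window, plus the window values.

    A pixel belongs to the buffer iff its *centre* lies within ``radius_m``
    of the point (all-or-nothing edge pixels).
    """
    x, y = point
    x0, y0 = raster.origin_xy
    r = raster.resolution_m
    nrow, ncol = raster.shape
    # Window of candidate rows/cols, clipped to the grid.
    c_lo = max(int(np.floor((x - radius_m - x0) / r)), 0)
    c_hi = min(int(np.ceil((x + radius_m - x0) / r)), ncol)
    r_lo = max(int(np.floor((y0 - (y + radius_m)) / r)), 0)
    r_hi = min(int(np.ceil((y0 - (y - radius_m)) / r)), nrow)
    if c_lo >= c_hi or r_lo >= r_hi:
        raise RasterInputError(f"buffer at {point} r={radius_m} misses the raster")
    xs = x0 + (np.arange(c_lo, c_hi) + 0.5) * r
    ys = y0 - (np.arange(r_lo, r_hi) + 0.5) * r
    dx = xs[None, :] - x
    dy = ys[:, None] - y
    inside = dx**2 + dy**2 <= radius_m**2
    window = raster.values[r_lo:r_hi, c_lo:c_hi]
    # Coverage check: was any part of the circle clipped off the grid?
    clipped = (
        x - radius_m < x0
        or x + radius_m > x0 + ncol * r
        or y + radius_m > y0
        or y - radius_m < y0 - nrow * r
    )
    return inside, window, clipped


def buffer_mean(raster: RasterLayer, point, radius_m: float) -> float:
    """Mean of in-buffer pixel values, nodata excluded."""
    inside, window, clipped = _buffer_window(raster, point, radius_m)
    if clipped:
        warnings.warn(f"buffer at {point} r={radius_m} partially outside raster", stacklevel=2)
    sel = window[inside]
    sel = sel[~np.isnan(sel)]
    if sel.size == 0:
        raise RasterInputError(f"no valid pixel centres in buffer at {point} r={radius_m}")
    return float(sel.mean())


def buffer_volume_density(volume_layer: RasterLayer, point, radius_m: float) -> float:
    """Total in-buffer volume divided by in-buffer area, in m³/m².

    Nodata pixels contribute zero volume but still count toward the buffer
    area, so sparse vegetation is not inflated by the missing pixels.
    """
    inside, window, clipped = _buffer_window(volume_layer, point, radius_m)
    if clipped:
        warnings.warn(f"buffer at {point} r={radius_m} partially outside raster", stacklevel=2)
    n_pix = int(inside.sum())
    if n_pix == 0:
        raise RasterInputError(f"no pixel centres in buffer at {point} r={radius_m}")
    total = np.nansum(window[inside])
    area = n_pix * volume_layer.resolution_m**2
    return float(total / area)


def site_buffer_table(sites, ndvi: RasterLayer, volume_layer: RasterLayer, radii=BUFFER_RADII_M):
    """Per-site, per-radius vegetation summaries.

    Parameters
    ----------
    sites
        DataFrame with columns ``site_id``, ``x``, ``y``.
    radii
        Buffer radii in metres.

    Returns
    -------
    DataFrame with columns site_id, radius_m, mean_ndvi, veg_volume_density,
    log_veg_volume.  Zero densities are logged as ``ln(density + eps)`` with
    eps = 1e-3 × the smallest positive density observed, with a warning.
    """
    import pandas as pd

    rows = []
    for rec in sites.itertuples(index=False):
        point = (rec.x, rec.y)
        for radius in radii:
            try:
                mean_ndvi = buffer_mean(ndvi, point, radius)
                dens = buffer_volume_density(volume_layer, point, radius)
            except RasterInputError as err:
                raise RasterInputError(f"site {rec.site_id}: {err}") from err
            rows.append((rec.site_id, radius, mean_ndvi, dens))
    out = pd.DataFrame(rows, columns=["site_id", "radius_m", "mean_ndvi", "veg_volume_density"])
    dens = out["veg_volume_density"].to_numpy()
    pos = dens[dens > 0]
    if (dens <= 0).any():
        eps = (pos.min() if pos.size else 1.0) * 1e-3
        warnings.warn(
            f"{int((dens <= 0).sum())} zero vegetation-volume densities; "
            f"log computed as ln(density + {eps:.3g})",
            stacklevel=2,
        )
        out["log_veg_volume"] = np.log(dens + eps)
    else:
        out["log_veg_volume"] = np.log(dens)
    return out


def distance_to_centre(points, centre) -> np.ndarray:
    """Euclidean distance (m) from each point to the centre.

    ``points`` is an (n, 2) array of map coordinates in a metric CRS.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    cx, cy = centre
    return np.hypot(pts[:, 0] - cx, pts[:, 1] - cy)
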