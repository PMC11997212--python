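"""Stratified random site selection over NDVI bins and city-centre rings.

Candidate cells come from a 100 m mean-aggregated NDVI map with negative
values zeroed.  The city is divided into concentric distance rings and the
NDVI range into even bins; within each ring × bin stratum a fixed number of
cells is drawn uniformly at random, subject to two constraints: a cell must
be mostly inside the city boundary, and all selected cells must be at least
a minimum distance apart.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely import contains_xy
from shapely.geometry import shape as shapely_shape

from .raster import RasterLayer, aggregate

__all__ = ["SelectionConfig", "prepare_selection_raster", "bin_edges", "stratified_select"]

log = logging.getLogger(__name__)


class SelectionError(ValueError):
    pass


@dataclass
class SelectionConfig:
    """Stratification and spacing rules for site selection."""

    n_rings: int = 5
    ring_width_m: float = 3000.0
    n_bins: int = 5
    sites_per_bin_per_ring: int = 2
    min_separation_m: float = 300.0
    max_outside_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_rings, self.n_bins, self.sites_per_bin_per_ring) < 1:
            raise SelectionError("counts must be positive")
        if self.min_separation_m < 0:
            raise SelectionError("min separation must be nonnegative")


def prepare_selection_raster(ndvi: RasterLayer, target_resolution_m: float = 100.0) -> RasterLayer:
    """Mean-aggregate NDVI to the selection resolution, then zero negatives.

    Zeroing after aggregation collapses the non-vegetated (negative) part of
    the range so the bins resolve the vegetated gradient.
    """
    agg = aggregate(ndvi, target_resolution_m, stat="mean")
    vals = agg.values.copy()
    vals[vals < 0] = 0.0
    return agg.with_values(vals)


def bin_edges(values, n_bins: int) -> np.ndarray:
    """Equal-width bin edges spanning the value range.

    Interior-edge values belong to the upper bin; the last bin is closed on
    the right.  A degenerate (zero-range) input collapses to a single bin
    with a warning.
    """
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    lo, hi = values.min(), values.max()
    if lo == hi:
        import warnings

        warnings.warn("degenerate value range; using a single bin", stacklevel=2)
        return np.array([lo, lo + 1.0])
    return np.linspace(lo, hi, n_bins + 1)


def _bin_index(values, edges) -> np.ndarray:
    idx = np.searchsorted(edges, values, side="right") - 1
    return np.clip(idx, 0, len(edges) - 2)


def read_boundary_geojson(path):
    """Read the first polygon from a GeoJSON file."""
    import json

    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") == "FeatureCollection":
        geom = gj["features"][0]["geometry"]
    elif gj.get("type") == "Feature":
        geom = gj["geometry"]
    else:
        geom = gj
    return shapely_shape(geom)


def _fraction_inside(boundary, cx, cy, cell_m: float, subgrid: int = 10) -> np.ndarray:
    """Fraction of each cell inside the boundary, via a subgrid rasterisation."""
    offs = (np.arange(subgrid) + 0.5) / subgrid - 0.5
    ox, oy = np.meshgrid(offs * cell_m, offs * cell_m)
    fracs = np.empty(len(cx))
    for i, (x, y) in enumerate(zip(cx, cy)):
        fracs[i] = contains_xy(boundary, x + ox.ravel(), y + oy.ravel()).mean()
    return fracs


def stratified_select(
    ndvi100: RasterLayer,
    centre,
    boundary,
    cfg: SelectionConfig,
    max_retries: int = 200,
) -> pd.DataFrame:
    """Random stratified sampling of monitoring cells.

    Strata are (distance ring) × (NDVI bin).  Within each stratum, cells
    are drawn uniformly without replacement; a draw is rejected if its
    centre is closer than ``min_separation_m`` to any already-selected cell
    (checked against the full growing set, across strata).  Strata that run
    out of eligible cells simply yield fewer sites — nothing is fabricated.

    Returns a DataFrame site_id, x, y, ring, bin, ndvi.
    """
    X, Y = ndvi100.pixel_centres()
    vals = ndvi100.values
    valid = ~np.isnan(vals)
    cx, cy, v = X[valid], Y[valid], vals[valid]

    dist = np.hypot(cx - centre[0], cy - centre[1])
    ring = (dist // cfg.ring_width_m).astype(int)
    in_rings = ring < cfg.n_rings

    edges = bin_edges(v, cfg.n_bins)
    bins = _bin_index(v, edges)

    frac_in = _fraction_inside(boundary, cx, cy, ndvi100.resolution_m)
    eligible = in_rings & (1.0 - frac_in <= cfg.max_outside_fraction)
    if not eligible.any():
        raise SelectionError("no eligible cells inside the boundary and rings")
    if not contains_xy(boundary, *centre):
        raise SelectionError("centre must lie inside the boundary")

    rng = np.random.default_rng(cfg.seed)
    chosen_idx: list[int] = []
    chosen_xy: list[tuple[float, float]] = []
    records = []
    unfilled = []
    for r in range(cfg.n_rings):
        for b in range(cfg.n_bins):
            stratum = np.flatnonzero(eligible & (ring == r) & (bins == b))
            stratum = stratum[~np.isin(stratum, chosen_idx)]
            order = rng.permutation(stratum)
            taken = 0
            tries = 0
            for cand in order:
                if taken >= cfg.sites_per_bin_per_ring or tries >= max_retries:
                    break
                tries += 1
                px, py = cx[cand], cy[cand]
                if any(
                    np.hypot(px - qx, py - qy) < cfg.min_separation_m for qx, qy in chosen_xy
                ):
                    continue
                chosen_idx.append(int(cand))
                chosen_xy.append((px, py))
                records.append((px, py, r, b, v[cand]))
                taken += 1
            if taken < cfg.sites_per_bin_per_ring:
                unfilled.append((r, b, taken))
    if unfilled:
        log.info("under-filled strata (ring, bin, n): %s", unfilled)
    out = pd.DataFrame(records, columns=["x", "y", "ring", "bin", "ndvi"])
    out.insert(0, "site_id", [f"site{i:03d}" for i in range(len(out))])
    out.attrs["unfilled_strata"] = unfilled
    out.attrs["bin_edges"] = edges.tolist()
    return out


def check_selection(sites: pd.DataFrame, boundary, cfg: SelectionConfig, ndvi100: RasterLayer):
    """Independent post-hoc audit of the selection constraints.

    Returns a dict of booleans; used by tests, not by the selector itself.
    """
    xy = sites[["x", "y"]].to_numpy()
    ok_sep = True
    for i in range(len(xy)):
        for j in range(i + 1, len(xy)):
            if np.hypot(*(xy[i] - xy[j])) < cfg.min_separation_m:
                ok_sep = False
    frac = _fraction_inside(boundary, xy[:, 0], xy[:, 1], ndvi100.resolution_m)
    ok_boundary = bool((1.0 - frac <= cfg.max_outside_fraction).all())
    per_ring = sites.groupby("ring").size()
    ok_counts = bool((per_ring <= cfg.n_bins * cfg.sites_per_bin_per_ring).all())
    return {"separation": ok_sep, "boundary": ok_boundary, "ring_counts": ok_counts}
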