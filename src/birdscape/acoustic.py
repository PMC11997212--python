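"""Detection-table filtering and acoustic diversity metrics.

The pipeline order is fixed: confidence filter → singleton removal → rare
species review → vocal activity rate (VAR).  VAR for a species at a site is
the number of distinct 15-minute recording periods containing at least one
detection, divided by the days recorded; repeated vocalisations within a
period count once, which damps the influence of very vocal species.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

__all__ = [
    "filter_confidence",
    "remove_singletons",
    "rare_species_review",
    "var_per_species",
    "site_diversity",
    "read_detections_csv",
    "DETECTION_COLUMNS",
]

log = logging.getLogger(__name__)

DETECTION_COLUMNS = ["site_id", "start_s", "end_s", "species", "confidence"]

#: Column aliases seen in BirdNET-Analyzer output dialects.
_COLUMN_ALIASES = {
    "site_id": ["site_id", "site", "file", "filepath"],
    "start_s": ["start_s", "start (s)", "begin time (s)", "start"],
    "end_s": ["end_s", "end (s)", "end time (s)", "end"],
    "species": ["species", "scientific name", "common name", "species code"],
    "confidence": ["confidence", "conf"],
}


class DetectionInputError(ValueError):
    """Raised when a detection table violates its contract."""


def _validate(dets: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in DETECTION_COLUMNS if c not in dets.columns]
    if missing:
        raise DetectionInputError(f"detection table missing columns: {missing}")
    if len(dets):
        conf = dets["confidence"].to_numpy()
        if ((conf < 0) | (conf > 1)).any():
            raise DetectionInputError("confidence values outside [0, 1]")
        if (dets["end_s"].to_numpy() <= dets["start_s"].to_numpy()).any():
            raise DetectionInputError("detections with end_s <= start_s")
    return dets


def read_detections_csv(path) -> pd.DataFrame:
    """Read a detections CSV, tolerating BirdNET-Analyzer column dialects."""
    raw = pd.read_csv(path)
    lower = {c.lower().strip(): c for c in raw.columns}
    cols = {}
    for canon, aliases in _COLUMN_ALIASES.items():
        for alias in aliases:
            if alias in lower:
                cols[canon] = raw[lower[alias]]
                break
        else:
            raise DetectionInputError(f"no column for {canon!r} in {list(raw.columns)}")
    return _validate(pd.DataFrame(cols))


def filter_confidence(dets: pd.DataFrame, min_conf: float = 0.8) -> pd.DataFrame:
    """Keep detections with confidence ≥ ``min_conf`` (inclusive)."""
    _validate(dets)
    kept = dets[dets["confidence"] >= min_conf].reset_index(drop=True)
    log.info("confidence filter removed %d of %d rows", len(dets) - len(kept), len(dets))
    return kept


def remove_singletons(dets: pd.DataFrame) -> pd.DataFrame:
    """Drop species–site pairs represented by exactly one detection.

    Singletons are judged per site: a species detected once at site A and
    twice at site B loses only its site-A row.
    """
    _validate(dets)
    if not len(dets):
        return dets.reset_index(drop=True)
    counts = dets.groupby(["site_id", "species"])["species"].transform("size")
    kept = dets[counts > 1].reset_index(drop=True)
    log.info("singleton removal dropped %d rows", len(dets) - len(kept))
    return kept


def rare_species_review(
    dets: pd.DataFrame, max_total: int = 10, removals: list[str] | None = None
) -> tuple[list[str], pd.DataFrame]:
    """Flag rare species for manual review and delete confirmed errors.

    Species with ``max_total`` or fewer detections overall (across all
    sites) are flagged.  ``removals`` names the flagged species whose
    identifications were judged incorrect; their rows are deleted.  The
    review itself happens outside the software — this operation only
    enforces that removals come from the flagged set.
    """
    _validate(dets)
    totals = dets.groupby("species").size()
    flagged = sorted(totals[totals <= max_total].index.tolist())
    removals = list(removals or [])
    bad = [s for s in removals if s not in flagged]
    if bad:
        raise DetectionInputError(
            f"cannot remove species not flagged for review (> {max_total} detections): {bad}"
        )
    out = dets[~dets["species"].isin(removals)].reset_index(drop=True)
    return flagged, out


def var_per_species(
    dets: pd.DataFrame, effort: pd.DataFrame, period_s: float = 900.0
) -> pd.DataFrame:
    """Vocal activity rate per site × species.

    Recording time is partitioned into consecutive ``period_s`` bins from
    each site's recording start; a detection occupies the bin containing
    its start time.  VAR = distinct occupied bins / days recorded.

    Parameters
    ----------
    effort
        DataFrame with columns ``site_id`` and ``days_recorded`` (fractional
        days of actual recording).

    Returns
    -------
    DataFrame with columns site_id, species, n_periods, var.
    """
    _validate(dets)
    if (effort["days_recorded"] <= 0).any():
        raise DetectionInputError("days_recorded must be positive")
    days = effort.set_index("site_id")["days_recorded"]

    unknown = set(dets["site_id"]) - set(days.index)
    if unknown:
        raise DetectionInputError(f"detections at sites without effort records: {sorted(unknown)}")
    if len(dets):
        span = dets["site_id"].map(days).to_numpy() * 86400.0
        outside = dets["start_s"].to_numpy() >= span
        outside |= dets["start_s"].to_numpy() < 0
        if outside.any():
            rows = dets.index[outside].tolist()[:5]
            raise DetectionInputError(f"detections outside the recording span at rows {rows}")

    if not len(dets):
        return pd.DataFrame(columns=["site_id", "species", "n_periods", "var"])
    bins = (dets["start_s"] // period_s).astype(int)
    grouped = (
        dets.assign(_bin=bins)
        .groupby(["site_id", "species"])["_bin"]
        .nunique()
        .rename("n_periods")
        .reset_index()
    )
    grouped["var"] = grouped["n_periods"] / grouped["site_id"].map(days)
    return grouped


def site_diversity(var_table: pd.DataFrame, site_ids=None) -> pd.DataFrame:
    """Site-level richness, summed VAR, and VAR-weighted Shannon diversity.

    Shannon diversity uses each species' VAR share in place of abundance:
    H = −Σ p ln p with p = var_i / Σ var.  Sites with no species get
    richness 0, var_total 0 and Shannon 0 (flagged with a warning).
    """
    rows = []
    by_site = dict(tuple(var_table.groupby("site_id"))) if len(var_table) else {}
    all_sites = list(site_ids) if site_ids is not None else sorted(by_site)
    for site in all_sites:
        sub = by_site.get(site)
        if sub is None or not len(sub):
            log.warning("site %s has no species after filtering; Shannon reported as 0", site)
            rows.append((site, 0, 0.0, 0.0))
            continue
        v = sub["var"].to_numpy(dtype=float)
        v = v[v > 0]
        total = v.sum()
        p = v / total
        shannon = float(-(p * np.log(p)).sum()) if len(p) > 1 else 0.0
        rows.append((site, int(len(v)), float(total), shannon))
    return pd.DataFrame(rows, columns=["site_id", "richness", "var_total", "shannon"])
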