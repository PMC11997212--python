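"""Train/test splitting, city-wide prediction grids and model evaluation.

The fitted diversity models are projected onto a 100 m NDVI grid: each cell
gets the model's linear predictor evaluated at the cell's NDVI and distance
to the city centre, averaged over the recording-week levels (the temporal
block is a nuisance term, so predictions marginalise over it).  Held-out
predictions are scored by RMSE and MAE and by a standardized major axis
(model II) regression of predicted on observed values, which treats both
axes symmetrically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .models import ModelFit
from .raster import RasterLayer

__all__ = ["SplitSpec", "split_data", "predict_rows", "predict_grid", "evaluate", "sma_regression"]


class PredictionError(ValueError):
    pass


@dataclass
class SplitSpec:
    train_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise PredictionError("train_fraction must be in (0, 1)")


def split_data(sites: pd.DataFrame, spec: SplitSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Uniform random train/test partition (no stratification).

    The training set has ``ceil(train_fraction * n)`` rows, matching an
    80/20 split of 86 sites into 69/17.
    """
    n = len(sites)
    if n < 5:
        raise PredictionError("need at least 5 sites to split")
    n_train = int(np.ceil(spec.train_fraction * n))
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(n)
    train = sites.iloc[np.sort(perm[:n_train])].reset_index(drop=True)
    test = sites.iloc[np.sort(perm[n_train:])].reset_index(drop=True)
    return train, test


def _linear_predictor(fit: ModelFit, veg: np.ndarray, dist_km: np.ndarray) -> np.ndarray:
    """Week-averaged linear predictor at given vegetation and distance values."""
    p = fit.params
    veg_name = next(t for t in fit.term_columns if t not in ("week", "distance_km"))
    base = p["const"] + p["distance_km"] * dist_km + p[veg_name] * veg
    week_cols = fit.term_columns["week"]
    n_levels = len(week_cols) + 1  # reference level has no dummy
    week_mean = sum(p[c] for c in week_cols) / n_levels
    return base + week_mean


def predict_rows(fit: ModelFit, data: pd.DataFrame) -> np.ndarray:
    """Predict for tabular rows with their own week labels (no averaging).

    Week dummies are built against the training factor levels, so test rows
    may cover only a subset of the weeks seen in training.
    """
    unknown = set(data["week"]) - set(fit.week_levels)
    if unknown:
        raise PredictionError(f"unseen week levels: {sorted(unknown)}")
    veg = data[fit.spec.predictor].to_numpy(dtype=float)
    if fit.spec.log_predictor:
        veg = np.log(veg)
    X = pd.DataFrame({"const": 1.0}, index=data.index)
    for lev in fit.week_levels[1:]:
        X[f"week_{lev}"] = (data["week"] == lev).astype(float)
    X["distance_km"] = data["distance_km"].to_numpy(dtype=float)
    veg_name = next(t for t in fit.term_columns if t not in ("week", "distance_km"))
    X[veg_name] = veg
    X = X[fit.params.index]
    return X.to_numpy() @ fit.params.to_numpy()


def predict_grid(
    fit: ModelFit,
    ndvi100: RasterLayer,
    centre,
    log_predictor: bool | None = None,
) -> tuple[RasterLayer, RasterLayer]:
    """Predict a diversity metric over a 100 m NDVI grid.

    Each cell's prediction averages the fitted linear predictor over the
    recording-week levels.  Returns ``(prediction, extrapolation_flag)``
    where the flag raster marks cells whose NDVI lies outside the training
    range (predictions are still produced there).
    """
    ndvi = ndvi100.values
    X, Y = ndvi100.pixel_centres()
    dist_km = np.hypot(X - centre[0], Y - centre[1]) / 1000.0

    veg_name = next(t for t in fit.term_columns if t not in ("week", "distance_km"))
    use_log = fit.spec.log_predictor if log_predictor is None else log_predictor
    train_veg = fit._X[veg_name].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        veg = np.log(ndvi) if use_log else ndvi
        pred = _linear_predictor(fit, veg, dist_km)
    pred = np.where(np.isnan(ndvi) | np.isnan(veg), np.nan, pred)
    extrap = ((veg < train_veg.min()) | (veg > train_veg.max())).astype(float)
    extrap[np.isnan(pred)] = np.nan
    return ndvi100.with_values(pred), ndvi100.with_values(extrap)


def evaluate(pred, obs) -> tuple[float, float]:
    """Root-mean-square error and mean absolute error."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape or pred.size == 0:
        raise PredictionError("pred and obs must be equal-length and non-empty")
    err = pred - obs
    return float(np.sqrt(np.mean(err**2))), float(np.mean(np.abs(err)))


def sma_regression(x, y, alpha: float = 0.05) -> dict:
    """Standardized major axis (reduced major axis, model II) regression.

    slope = sign(r) · s_y / s_x, intercept = ȳ − slope·x̄.  The (1−alpha)
    slope CI is slope·(√(B+1) ± √B) with B = (1−r²)·F(1−alpha; 1, n−2)/(n−2).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3:
        raise PredictionError("need at least 3 points")
    if np.std(x) == 0 or np.std(y) == 0:
        raise PredictionError("zero variance in x or y")
    r = float(np.corrcoef(x, y)[0, 1])
    slope = float(np.sign(r) if r != 0 else 1.0) * float(np.std(y, ddof=1) / np.std(x, ddof=1))
    intercept = float(y.mean() - slope * x.mean())
    F = sstats.f.ppf(1 - alpha, 1, n - 2)
    B = (1 - r * r) * F / (n - 2)
    ci = (slope * (np.sqrt(B + 1) - np.sqrt(B)), slope * (np.sqrt(B + 1) + np.sqrt(B)))
    if slope < 0:
        ci = (ci[1], ci[0])
    return {
        "slope": slope,
        "intercept": intercept,
        "r": r,
        "ci_slope": (float(ci[0]), float(ci[1])),
        "n": n,
    }
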