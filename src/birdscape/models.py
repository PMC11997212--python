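"""Linear models linking bird diversity metrics to vegetation predictors.

Each diversity metric (richness, total VAR, Shannon) is modelled as

    metric ~ week + distance_km + vegetation_b

where ``vegetation_b`` is the mean NDVI or log vegetation-volume density in
a buffer of radius *b* around the site, week is a categorical temporal
block, and distance is the site's distance to the city centre in km.  The
buffer radius is chosen by comparing the vegetation term's partial R²
across radii; NDVI and vegetation volume are compared on full-model R².
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "ModelSpec",
    "ModelFit",
    "fit_ols",
    "partial_r2",
    "vif_step",
    "buffer_selection",
    "compare_predictors",
    "morans_i_test",
    "fit_metric_buffer_models",
]

RESPONSES = ("richness", "var_total", "shannon")
PREDICTORS = ("mean_ndvi", "log_veg_volume")


class ModelError(ValueError):
    pass


@dataclass
class ModelSpec:
    """Which response, vegetation predictor and buffer radius to fit.

    ``log_predictor`` applies a natural-log transform to the vegetation
    column before fitting (used for NDVI in the Shannon model; vegetation
    volume arrives already log-transformed as ``log_veg_volume``).
    """

    response: str
    predictor: str
    buffer_m: float
    log_predictor: bool = False

    def __post_init__(self) -> None:
        if self.response not in RESPONSES:
            raise ModelError(f"unknown response {self.response!r}")


@dataclass
class ModelFit:
    """An OLS fit with term-level bookkeeping.

    ``term_columns`` maps model terms ("week", "distance_km", the
    vegetation predictor) to their design-matrix column names, so partial
    R² can treat the multi-column week factor as one term.
    """

    spec: ModelSpec
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    df_resid: float
    r_squared: float
    adj_r_squared: float
    residuals: np.ndarray
    fitted: np.ndarray
    term_columns: dict[str, list[str]]
    week_levels: list = field(default_factory=list)
    _X: pd.DataFrame | None = field(default=None, repr=False)
    _y: np.ndarray | None = field(default=None, repr=False)

    def conf_int(self, name: str, alpha: float = 0.05):
        from scipy import stats

        t = stats.t.ppf(1 - alpha / 2, self.df_resid)
        return (self.params[name] - t * self.bse[name], self.params[name] + t * self.bse[name])


def build_design(data: pd.DataFrame, spec: ModelSpec):
    """Design matrix with intercept, dummy-coded week, distance and the
    vegetation predictor; returns (X, y, term_columns, week_levels)."""
    for col in ("week", "distance_km", spec.predictor, spec.response):
        if col not in data.columns:
            raise ModelError(f"missing column {col!r}")
    if data[[spec.predictor, spec.response, "distance_km"]].isna().any().any():
        raise ModelError("missing values in model columns")
    veg = data[spec.predictor].to_numpy(dtype=float)
    veg_name = spec.predictor
    if spec.log_predictor:
        if (veg <= 0).any():
            # Kindred rule to the vegetation-volume log: nonpositive values
            # are floored at a small epsilon tied to the smallest positive
            # value, leaving positive values untouched, with a warning.
            pos = veg[veg > 0]
            if pos.size == 0:
                raise ModelError(f"log transform of {spec.predictor}: no positive values")
            eps = pos.min() * 1e-3
            import warnings

            warnings.warn(
                f"{int((veg <= 0).sum())} nonpositive {spec.predictor} values "
                f"floored at {eps:.3g} before the log",
                stacklevel=3,
            )
            veg = np.log(np.clip(veg, eps, None))
        else:
            veg = np.log(veg)
        veg_name = f"log_{spec.predictor}"
    week_levels = sorted(pd.unique(data["week"]))
    X = pd.DataFrame({"const": 1.0}, index=data.index)
    week_cols = []
    for lev in week_levels[1:]:  # first level is the reference
        col = f"week_{lev}"
        X[col] = (data["week"] == lev).astype(float)
        week_cols.append(col)
    X["distance_km"] = data["distance_km"].to_numpy(dtype=float)
    X[veg_name] = veg
    terms = {"week": week_cols, "distance_km": ["distance_km"], veg_name: [veg_name]}
    y = data[spec.response].to_numpy(dtype=float)
    return X, y, terms, week_levels


def fit_ols(spec: ModelSpec, data: pd.DataFrame) -> ModelFit:
    """Ordinary least squares fit of the diversity model."""
    X, y, terms, week_levels = build_design(data, spec)
    if len(y) <= X.shape[1]:
        raise ModelError(f"n={len(y)} too small for {X.shape[1]} parameters")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise ModelError(f"rank-deficient design (rank {rank} < {X.shape[1]} columns)")
    res = sm.OLS(y, X).fit()
    return ModelFit(
        spec=spec,
        params=res.params,
        bse=res.bse,
        tvalues=res.tvalues,
        df_resid=res.df_resid,
        r_squared=float(res.rsquared),
        adj_r_squared=float(res.rsquared_adj),
        residuals=np.asarray(res.resid),
        fitted=np.asarray(res.fittedvalues),
        term_columns=terms,
        week_levels=week_levels,
        _X=X,
        _y=y,
    )


def partial_r2(fit: ModelFit, term: str) -> float:
    """Partial R² of one model term.

    Single-column terms use t²/(t² + df_resid).  Multi-column terms (the
    week factor) use the nested-model form
    (R²_full − R²_reduced) / (1 − R²_reduced).
    """
    if term not in fit.term_columns:
        raise ModelError(f"unknown term {term!r}; have {list(fit.term_columns)}")
    cols = fit.term_columns[term]
    if len(cols) == 1:
        t = float(fit.tvalues[cols[0]])
        return t * t / (t * t + fit.df_resid)
    reduced = fit._X.drop(columns=cols)
    r2_red = float(sm.OLS(fit._y, reduced).fit().rsquared)
    return (fit.r_squared - r2_red) / (1.0 - r2_red)


def vif_step(X: pd.DataFrame, threshold: float = 5.0):
    """Iteratively drop the worst-collinear column until all VIFs < threshold.

    VIF_j = 1/(1 − R²_j) from regressing column j on the remaining columns
    (with an intercept).  Constant columns have infinite VIF and are dropped
    first.  Returns (kept column names, {dropped name: VIF at drop time}).
    """
    if X.shape[1] < 2:
        raise ModelError("need at least 2 columns for collinearity screening")
    cols = list(X.columns)
    dropped: dict[str, float] = {}
    while len(cols) >= 2:
        vifs = {}
        for j, c in enumerate(cols):
            others = [c2 for c2 in cols if c2 != c]
            xj = X[c].to_numpy(dtype=float)
            if np.ptp(xj) == 0:
                vifs[c] = np.inf
                continue
            Z = sm.add_constant(X[others].to_numpy(dtype=float))
            r2 = sm.OLS(xj, Z).fit().rsquared
            vifs[c] = np.inf if r2 >= 1.0 else 1.0 / (1.0 - r2)
        worst = max(vifs, key=vifs.get)
        if vifs[worst] < threshold:
            break
        dropped[worst] = vifs[worst]
        cols.remove(worst)
    return cols, dropped


def fit_metric_buffer_models(
    metrics: pd.DataFrame,
    buffers: pd.DataFrame,
    radii=None,
    shannon_log_ndvi: bool = True,
) -> pd.DataFrame:
    """Fit every response × predictor × buffer model and tabulate results.

    ``metrics`` carries site_id, week, distance_km and the three diversity
    responses; ``buffers`` is the long site × radius vegetation table.
    NDVI enters the Shannon models log-transformed (configurable).

    Returns a DataFrame with one row per fit: metric, predictor, buffer_m,
    r_squared, partial_r2 (of the vegetation term), and the fit object.
    """
    if radii is None:
        radii = sorted(buffers["radius_m"].unique())
    rows = []
    for radius in radii:
        sub = buffers[buffers["radius_m"] == radius][
            ["site_id", "mean_ndvi", "log_veg_volume"]
        ]
        merged = metrics.merge(sub, on="site_id", how="inner")
        if len(merged) < len(metrics):
            raise ModelError(f"buffer table incomplete at radius {radius}")
        for response in RESPONSES:
            for predictor in PREDICTORS:
                logp = shannon_log_ndvi and response == "shannon" and predictor == "mean_ndvi"
                spec = ModelSpec(response, predictor, radius, log_predictor=logp)
                fit = fit_ols(spec, merged)
                veg_term = next(t for t in fit.term_columns if t not in ("week", "distance_km"))
                rows.append(
                    {
                        "metric": response,
                        "predictor": predictor,
                        "buffer_m": radius,
                        "r_squared": fit.r_squared,
                        "partial_r2": partial_r2(fit, veg_term),
                        "fit": fit,
                    }
                )
    return pd.DataFrame(rows)


def buffer_selection(table: pd.DataFrame) -> float:
    """Choose the buffer radius whose partial R² peaks most often.

    For every (metric, predictor) combination the argmax-partial-R² buffer
    is recorded; the modal argmax wins.  Ties are broken by the tied buffer
    with the highest mean partial R² across all combinations.
    """
    need = {"metric", "predictor", "buffer_m", "partial_r2"}
    if not need <= set(table.columns):
        raise ModelError(f"buffer table needs columns {sorted(need)}")
    combos = table.groupby(["metric", "predictor"])
    radii = set(table["buffer_m"].unique())
    missing = [
        key for key, sub in combos if set(sub["buffer_m"]) != radii
    ]
    if missing:
        raise ModelError(f"incomplete buffer coverage for combinations: {missing}")
    argmaxes = combos.apply(
        lambda sub: sub.loc[sub["partial_r2"].idxmax(), "buffer_m"], include_groups=False
    )
    counts = argmaxes.value_counts()
    top = counts[counts == counts.max()].index
    if len(top) == 1:
        return float(top[0])
    mean_pr2 = table[table["buffer_m"].isin(top)].groupby("buffer_m")["partial_r2"].mean()
    return float(mean_pr2.idxmax())


def compare_predictors(table: pd.DataFrame, buffer_m: float) -> dict:
    """Rank NDVI vs vegetation volume at the chosen buffer.

    Per metric the predictor with the larger full-model R² wins.  The
    summary reports the mean R² per predictor and the relative variance
    gain of the winner under both conventions, (a−b)/b and (a−b)/a, since
    "x% more variance" is ambiguous.
    """
    at = table[table["buffer_m"] == buffer_m]
    per_metric = {}
    for metric, sub in at.groupby("metric"):
        r2 = sub.set_index("predictor")["r_squared"]
        per_metric[metric] = {
            "winner": r2.idxmax(),
            "r_squared": r2.to_dict(),
        }
    means = at.groupby("predictor")["r_squared"].mean()
    a, b = means.max(), means.min()
    return {
        "buffer_m": buffer_m,
        "per_metric": per_metric,
        "mean_r_squared": means.to_dict(),
        "best_predictor": means.idxmax(),
        "relative_gain_over_loser": (a - b) / b if b > 0 else np.inf,
        "relative_gain_of_winner_share": (a - b) / a if a > 0 else np.nan,
    }


def morans_i_test(
    residuals, coords, n_perm: int = 999, seed: int | None = None
) -> tuple[float, float, float]:
    """Global Moran's I with inverse-distance weights and a permutation test.

    I = (n/W) Σᵢⱼ wᵢⱼ zᵢ zⱼ / Σ zᵢ² with wᵢⱼ = 1/dᵢⱼ (i ≠ j), z the centred
    residuals.  The two-sided p-value comes from ``n_perm`` random
    relabelings of residuals over locations using the (r+1)/(n_perm+1)
    estimator.  Returns (I, E[I] = −1/(n−1), p).
    """
    x = np.asarray(residuals, dtype=float)
    pts = np.asarray(coords, dtype=float)
    n = len(x)
    if n < 10:
        raise ModelError("need at least 10 observations for Moran's I")
    d = np.hypot(pts[:, None, 0] - pts[None, :, 0], pts[:, None, 1] - pts[None, :, 1])
    off = ~np.eye(n, dtype=bool)
    if (d[off] == 0).any():
        raise ModelError("duplicate coordinates give infinite weights; jitter the points")
    with np.errstate(divide="ignore"):
        w = np.where(off, 1.0 / d, 0.0)
    W = w.sum()

    def stat(z):
        z = z - z.mean(axis=-1, keepdims=True)
        num = np.einsum("ij,...i,...j->...", w, z, z)
        den = (z**2).sum(axis=-1)
        return (n / W) * num / den

    I = float(stat(x))
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(x) for _ in range(n_perm)])
    I_perm = stat(perms)
    expected = -1.0 / (n - 1)
    # Two-sided: how extreme is I relative to the permutation distribution.
    p_hi = (np.sum(I_perm >= I) + 1) / (n_perm + 1)
    p_lo = (np.sum(I_perm <= I) + 1) / (n_perm + 1)
    p = min(1.0, 2.0 * min(p_hi, p_lo))
    return I, expected, p
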