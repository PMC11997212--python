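"""Community composition: dissimilarities, NMDS and concordance tests.

The site × species vocal-activity matrix is ordinated by non-metric
multidimensional scaling on Bray–Curtis dissimilarities (after a log(1+x)
transform that damps highly vocal species).  A parallel presence–absence
ordination on Jaccard distances checks that composition patterns are not
artefacts of vocal activity; the two are compared by Procrustes
superimposition (PROTEST) and a Mantel test on the distance matrices.
Environmental vectors (NDVI, vegetation volume, distance, week) are fitted
post hoc onto the ordination with permutation significance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.spatial import procrustes as _scipy_procrustes
from sklearn.isotonic import IsotonicRegression

__all__ = [
    "OrdinationResult",
    "EnvFitResult",
    "bray_curtis",
    "to_presence_absence",
    "jaccard",
    "nmds",
    "rotate_to_variable",
    "envfit",
    "assign_habitat",
    "procrustes_protest",
    "mantel",
]


class OrdinationError(ValueError):
    pass


# ------------------------------------------------------------- distances


def _check_rows(X: np.ndarray, labels) -> None:
    zero = np.flatnonzero(X.sum(axis=1) == 0)
    if len(zero):
        names = [labels[i] for i in zero] if labels is not None else zero.tolist()
        raise OrdinationError(f"all-zero community rows make distances undefined: {names}")


def _as_matrix(X):
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.index)
    return np.asarray(X, dtype=float), None


def bray_curtis(X, log1p: bool = True) -> np.ndarray:
    """Bray–Curtis dissimilarity matrix, optionally after ln(1+x).

    d(i,j) = Σ|xᵢ−xⱼ| / Σ(xᵢ+xⱼ); a semimetric bounded in [0, 1].
    """
    M, labels = _as_matrix(X)
    if (M < 0).any():
        raise OrdinationError("community matrix must be nonnegative")
    _check_rows(M, labels)
    if log1p:
        M = np.log1p(M)
    return squareform(pdist(M, metric="braycurtis"))


def to_presence_absence(X):
    """Binarise a community matrix (presence = value > 0)."""
    if isinstance(X, pd.DataFrame):
        return (X > 0).astype(float)
    return (np.asarray(X) > 0).astype(float)


def jaccard(Xb) -> np.ndarray:
    """Jaccard distance on a binary matrix: (b+c)/(a+b+c)."""
    M, labels = _as_matrix(Xb)
    if not np.isin(M, (0.0, 1.0)).all():
        raise OrdinationError("Jaccard requires a binary matrix; use to_presence_absence")
    _check_rows(M, labels)
    return squareform(pdist(M.astype(bool), metric="jaccard"))


# ------------------------------------------------------------------ NMDS


@dataclass
class OrdinationResult:
    """Site scores with the Kruskal stress-1 of the best start.

    Scores are centred and rotated to their principal axes.  ``linear_r2``
    is the squared correlation between monotone-fitted and configuration
    distances (one common 'goodness' readout; the stress itself is the
    primary diagnostic).  ``species_scores`` are abundance-weighted
    averages of site scores, filled in when the ordination came from a
    community matrix.
    """

    scores: np.ndarray
    stress: float
    linear_r2: float
    n_starts: int
    converged: bool
    seed: int | None
    stress_trace: list = field(default_factory=list, repr=False)
    site_labels: list | None = None
    species_scores: pd.DataFrame | None = None

    def copy_with_scores(self, scores: np.ndarray) -> "OrdinationResult":
        return OrdinationResult(
            scores=scores,
            stress=self.stress,
            linear_r2=self.linear_r2,
            n_starts=self.n_starts,
            converged=self.converged,
            seed=self.seed,
            stress_trace=self.stress_trace,
            site_labels=self.site_labels,
            species_scores=self.species_scores,
        )


def _stress1(config_d: np.ndarray, disp: np.ndarray) -> float:
    denom = (config_d**2).sum()
    if denom == 0:
        return 0.0
    return float(np.sqrt(((config_d - disp) ** 2).sum() / denom))


def _nmds_single(D_cond, n, k, init, max_iter, tol):
    """One NMDS start: SMACOF-style alternation of isotonic regression and
    Guttman updates, accepting only stress-decreasing steps so the recorded
    stress trace is monotone."""
    # Regressing configuration distances on the dissimilarities themselves
    # gives primary (averaging) treatment of tied dissimilarities for free.
    iso = IsotonicRegression()
    iu = np.triu_indices(n, k=1)

    X = init.copy()
    trace = []

    def distances(Y):
        return np.sqrt(((Y[iu[0]] - Y[iu[1]]) ** 2).sum(axis=1))

    d = distances(X)
    disp = iso.fit_transform(D_cond, d)
    stress = _stress1(d, disp)
    trace.append(stress)
    for _ in range(max_iter):
        # Guttman transform with current disparities as targets.
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(d > 0, disp / d, 0.0)
        B = np.zeros((n, n))
        B[iu] = -ratio
        B += B.T
        np.fill_diagonal(B, -B.sum(axis=1))
        X_new = B @ X / n
        d_new = distances(X_new)
        disp_new = iso.fit_transform(D_cond, d_new)
        # Scale invariance: stress-1 is normalised, no rescale needed.
        stress_new = _stress1(d_new, disp_new)
        if stress_new > stress - 1e-12:
            break
        X, d, disp = X_new, d_new, disp_new
        improvement = stress - stress_new
        stress = stress_new
        trace.append(stress)
        if improvement < tol:
            break
    return X, stress, d, disp, trace


def _principal_axes(X: np.ndarray) -> np.ndarray:
    X = X - X.mean(axis=0)
    _, _, vt = np.linalg.svd(X, full_matrices=False)
    return X @ vt.T


def nmds(
    D,
    k: int = 2,
    n_starts: int = 20,
    max_iter: int = 300,
    tol: float = 1e-7,
    seed: int | None = None,
    site_labels=None,
) -> OrdinationResult:
    """Non-metric multidimensional scaling minimising Kruskal stress-1.

    Runs one classical-scaling (principal coordinates) start plus
    ``n_starts − 1`` random starts and keeps the lowest-stress solution.
    Convergence is declared when the two best starts agree under Procrustes
    superimposition (m² < 1e-4); otherwise the best solution is returned
    with ``converged=False``.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n) or not np.allclose(D, D.T):
        raise OrdinationError("D must be a square symmetric distance matrix")
    if k >= n - 1:
        raise OrdinationError(f"k={k} must be < n−1 = {n - 1}")
    D_cond = squareform(D, checks=False)
    rng = np.random.default_rng(seed)

    # Classical-scaling start from double-centred squared distances.
    J = np.eye(n) - np.ones((n, n)) / n
    B0 = -0.5 * J @ (D**2) @ J
    vals, vecs = np.linalg.eigh(B0)
    idx = np.argsort(vals)[::-1][:k]
    pcoa = vecs[:, idx] * np.sqrt(np.clip(vals[idx], 0, None))

    solutions = []
    scale = D_cond.mean() if D_cond.mean() > 0 else 1.0
    for s in range(n_starts):
        init = pcoa if s == 0 else rng.normal(0.0, scale, size=(n, k))
        X, stress, d, disp, trace = _nmds_single(D_cond, n, k, init, max_iter, tol)
        solutions.append((stress, X, d, disp, trace))
    solutions.sort(key=lambda t: t[0])
    stress, X, d, disp, trace = solutions[0]

    converged = False
    if len(solutions) > 1:
        try:
            _, _, m2 = _scipy_procrustes(solutions[0][1], solutions[1][1])
            converged = m2 < 1e-4
        except ValueError:
            converged = False

    var_disp = disp - disp.mean()
    var_d = d - d.mean()
    denom = np.sqrt((var_disp**2).sum() * (var_d**2).sum())
    linear_r2 = float(((var_disp * var_d).sum() / denom) ** 2) if denom > 0 else 1.0

    return OrdinationResult(
        scores=_principal_axes(X),
        stress=stress,
        linear_r2=linear_r2,
        n_starts=n_starts,
        converged=converged,
        seed=seed,
        stress_trace=trace,
        site_labels=list(site_labels) if site_labels is not None else None,
    )


def species_scores(ord_res: OrdinationResult, community: pd.DataFrame) -> pd.DataFrame:
    """Species scores as abundance-weighted averages of site scores."""
    W = community.to_numpy(dtype=float)
    totals = W.sum(axis=0)
    keep = totals > 0
    S = (W.T @ ord_res.scores)[keep] / totals[keep, None]
    return pd.DataFrame(
        S, index=np.asarray(community.columns)[keep], columns=["nmds1", "nmds2"][: S.shape[1]]
    )


def rotate_to_variable(ord_res: OrdinationResult, v) -> OrdinationResult:
    """Rigidly rotate a 2-D ordination so the fitted direction of ``v``
    points along the first axis (for display; distances are unchanged)."""
    if ord_res.scores.shape[1] != 2:
        raise OrdinationError("rotation requires a 2-D ordination")
    v = np.asarray(v, dtype=float)
    if np.ptp(v) == 0:
        raise OrdinationError("cannot rotate to a zero-variance variable")
    direction = _envfit_vector(ord_res.scores, v)[0]
    a, b = direction
    R = np.array([[a, -b], [b, a]])  # maps (a, b) -> (1, 0) via scores @ R
    out = ord_res.copy_with_scores(ord_res.scores @ R)
    if out.species_scores is not None:
        rotated = out.species_scores.to_numpy() @ R
        out.species_scores = pd.DataFrame(
            rotated, index=out.species_scores.index, columns=out.species_scores.columns
        )
    return out


# ---------------------------------------------------------------- envfit


@dataclass
class EnvFitResult:
    """Directions/centroids, r² and permutation p per environmental variable."""

    vectors: pd.DataFrame  # columns: dir1, dir2, r2, p
    factors: dict  # name -> {"centroids": DataFrame, "r2": float, "p": float}


def _envfit_vector(scores: np.ndarray, v: np.ndarray):
    """Least-squares fit of a centred variable on ordination scores.

    Returns (unit direction, r²): direction is the normalised regression
    coefficient vector, r² the squared correlation between the variable and
    its projection on the fitted axis.
    """
    vc = v - v.mean()
    Xc = scores - scores.mean(axis=0)
    coef, *_ = np.linalg.lstsq(Xc, vc, rcond=None)
    norm = np.linalg.norm(coef)
    if norm == 0:
        return np.array([1.0] + [0.0] * (scores.shape[1] - 1)), 0.0
    fitted = Xc @ coef
    ss_tot = (vc**2).sum()
    r2 = float((fitted * vc).sum() / ss_tot) if ss_tot > 0 else 0.0
    return coef / norm, r2


def _envfit_factor(scores: np.ndarray, f: np.ndarray):
    """Centroid fit of a factor: r² = 1 − SS_within/SS_total of the scores."""
    Xc = scores - scores.mean(axis=0)
    ss_tot = (Xc**2).sum()
    levels = pd.unique(f)
    cents = {}
    ss_within = 0.0
    for lev in levels:
        sub = Xc[f == lev]
        c = sub.mean(axis=0)
        cents[lev] = c
        ss_within += ((sub - c) ** 2).sum()
    r2 = 1.0 - ss_within / ss_tot if ss_tot > 0 else 0.0
    return cents, float(r2)


def envfit(ord_res: OrdinationResult, env: pd.DataFrame, n_perm: int = 999, seed=None) -> EnvFitResult:
    """Post-hoc fit of environmental variables onto ordination scores.

    Continuous columns get a unit direction vector and r²; categorical
    (object/categorical dtype) columns get level centroids and a
    dispersion-based r².  Significance comes from permuting the variable's
    rows ``n_perm`` times, p = (r+1)/(n_perm+1).
    """
    scores = ord_res.scores
    if len(env) != len(scores):
        raise OrdinationError("env rows must match ordination sites")
    rng = np.random.default_rng(seed)
    vec_rows = {}
    factors = {}
    for name in env.columns:
        col = env[name]
        if col.dtype.kind in "OUSb" or isinstance(col.dtype, pd.CategoricalDtype):
            f = col.to_numpy()
            cents, r2 = _envfit_factor(scores, f)
            perm_r2 = np.array(
                [_envfit_factor(scores, rng.permutation(f))[1] for _ in range(n_perm)]
            )
            p = (np.sum(perm_r2 >= r2) + 1) / (n_perm + 1)
            factors[name] = {
                "centroids": pd.DataFrame(cents).T,
                "r2": r2,
                "p": float(p),
            }
        else:
            v = col.to_numpy(dtype=float)
            if np.ptp(v) == 0:
                import warnings

                warnings.warn(f"constant environmental variable {name!r}", stacklevel=2)
                vec_rows[name] = {"dir1": 1.0, "dir2": 0.0, "r2": 0.0, "p": 1.0}
                continue
            direction, r2 = _envfit_vector(scores, v)
            perm_r2 = np.array(
                [_envfit_vector(scores, rng.permutation(v))[1] for _ in range(n_perm)]
            )
            p = (np.sum(perm_r2 >= r2) + 1) / (n_perm + 1)
            vec_rows[name] = {
                "dir1": float(direction[0]),
                "dir2": float(direction[1]) if len(direction) > 1 else 0.0,
                "r2": r2,
                "p": float(p),
            }
    vectors = pd.DataFrame(vec_rows).T if vec_rows else pd.DataFrame(
        columns=["dir1", "dir2", "r2", "p"]
    )
    return EnvFitResult(vectors=vectors, factors=factors)


# ------------------------------------------------------ habitat annotation

#: Habitat-preference reassignments applied to the trait table: cliff/rock
#: dwellers and (inland) coastal species behave as human-modified; water-
#: associated and open-land preferences are pooled.
HABITAT_REASSIGNMENTS = {
    "rock": "human-modified",
    "coastal": "human-modified",
    "riverine": "aquatic",
    "wetland": "aquatic",
    "grassland": "open",
    "shrubland": "open",
}

_KNOWN_HABITATS = {
    "forest",
    "woodland",
    "human-modified",
    "open",
    "aquatic",
    "desert",
    "marine",
} | set(HABITAT_REASSIGNMENTS)


def assign_habitat(traits: pd.DataFrame, species=None) -> dict[str, str]:
    """Map species to pooled habitat classes from an AVONET-style table.

    ``traits`` needs columns ``species`` and ``habitat``.  If ``species``
    is given, every one of them must be present in the trait table.
    """
    if species is not None:
        missing = sorted(set(species) - set(traits["species"]))
        if missing:
            raise OrdinationError(f"species missing from trait table: {missing}")
    out = {}
    for rec in traits.itertuples(index=False):
        h = str(rec.habitat).strip().lower().replace("_", "-")
        if h not in _KNOWN_HABITATS:
            raise OrdinationError(f"unknown habitat label {rec.habitat!r} for {rec.species}")
        out[rec.species] = HABITAT_REASSIGNMENTS.get(h, h)
    return out


# ------------------------------------------------- concordance statistics


def procrustes_protest(A, B, n_perm: int = 999, seed=None) -> tuple[float, float, float]:
    """Procrustes superimposition of B onto A with a PROTEST permutation test.

    Both configurations are centred and scaled to unit sum of squares; B is
    optimally rotated (reflections allowed) onto A.  Returns (m², t, p)
    with m² the residual sum of squares, t = √(1−m²) the Procrustes
    correlation, and p from ``n_perm`` random row permutations of B.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape[0] != B.shape[0]:
        raise OrdinationError("configurations must have equal row counts")
    try:
        _, _, m2 = _scipy_procrustes(A, B)
    except ValueError as err:
        raise OrdinationError(f"degenerate configuration: {err}") from err
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        _, _, m2_perm = _scipy_procrustes(A, B[rng.permutation(B.shape[0])])
        if m2_perm <= m2:
            count += 1
    p = (count + 1) / (n_perm + 1)
    t = float(np.sqrt(max(0.0, 1.0 - m2)))
    return float(m2), t, p


def mantel(D1, D2, n_perm: int = 999, seed=None) -> tuple[float, float]:
    """Mantel correlation between two distance matrices.

    r is the Pearson correlation of the lower-triangle entries; the
    one-sided p-value permutes rows and columns of D2 simultaneously.
    """
    D1 = np.asarray(D1, dtype=float)
    D2 = np.asarray(D2, dtype=float)
    if D1.shape != D2.shape or D1.ndim != 2 or D1.shape[0] != D1.shape[1]:
        raise OrdinationError("distance matrices must be square with equal shape")
    n = D1.shape[0]
    il = np.tril_indices(n, k=-1)
    a = D1[il]

    def corr(b):
        ac = a - a.mean()
        bc = b - b.mean()
        denom = np.sqrt((ac**2).sum() * (bc**2).sum())
        return (ac * bc).sum() / denom if denom > 0 else 0.0

    r = corr(D2[il])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if corr(D2[np.ix_(perm, perm)][il]) >= r:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return float(r), float(p)
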