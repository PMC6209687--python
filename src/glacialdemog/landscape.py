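"""Genetic-geographic/ecological association tests.

Distance matrices (great-circle geographic, z-scaled Euclidean
ecological), Mantel and partial Mantel tests with two-tailed permutation
p-values, and stepwise-AIC regressions of per-population diversity on
geographic and ecological predictors (Gaussian GLM and Huber robust
linear model).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.metrics.pairwise import haversine_distances

from .seqdata import PopulationTable

EARTH_RADIUS_KM = 6371.0


class DegenerateControlError(ValueError):
    pass


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray
    kind: str = ""

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(np.nan_to_num(v), np.nan_to_num(v.T)):
            raise ValueError("distance matrix must be symmetric")
        self.values = v

    @property
    def n(self) -> int:
        return len(self.labels)

    def upper(self) -> np.ndarray:
        iu = np.triu_indices(self.n, 1)
        return self.values[iu]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, kind: str = "") -> "DistanceMatrix":
        return cls(list(df.index), df.to_numpy(float), kind)


def geographic_distances(pops: PopulationTable) -> DistanceMatrix:
    """Great-circle distances in km (spherical Earth, R = 6371.0 km)."""
    coords = np.radians(
        pops.table[["latitude", "longitude"]].to_numpy(float)
    )
    km = haversine_distances(coords) * EARTH_RADIUS_KM
    np.fill_diagonal(km, 0.0)
    return DistanceMatrix(pops.population_ids, km, "geographic-km")


def ecological_distances(
    pops: PopulationTable, variables: list[str] | None = None
) -> DistanceMatrix:
    """Scaled-Euclidean ecological distance: each variable z-standardized
    across populations (sample SD), then Euclidean distance. Zero-
    variance variables are dropped with a warning."""
    E = pops.env_matrix(variables)
    if E.shape[1] < 1:
        raise ValueError("need at least one ecological variable")
    if E.isna().any().any():
        raise ValueError("missing ecological values")
    sd = E.std(ddof=1)
    dead = sd[sd == 0].index.tolist()
    if dead:
        warnings.warn(f"dropping zero-variance variables: {dead}")
        E = E.drop(columns=dead)
        sd = sd.drop(dead)
    Z = ((E - E.mean()) / sd).to_numpy(float)
    diff = Z[:, None, :] - Z[None, :, :]
    d = np.sqrt((diff**2).sum(axis=2))
    return DistanceMatrix(pops.population_ids, d, "ecological-scaled")


def _check_conformable(*mats: DistanceMatrix):
    labels = mats[0].labels
    for m in mats[1:]:
        if m.labels != labels:
            raise ValueError("distance matrices have mismatched labels")


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xs = x - x.mean()
    ys = y - y.mean()
    den = np.sqrt((xs**2).sum() * (ys**2).sum())
    return float((xs * ys).sum() / den) if den > 0 else float("nan")


@dataclass
class MantelResult:
    r: float
    p_two_tailed: float
    n_permutations: int
    partialed_on: str | None = None


def mantel(
    A: DistanceMatrix,
    B: DistanceMatrix,
    permutations: int = 999,
    rng: np.random.Generator | None = None,
) -> MantelResult:
    """Mantel correlation between two distance matrices.

    r is the Pearson correlation over strictly-upper-triangle entries;
    the permutation simultaneously permutes rows and columns of B, and
    the two-tailed p counts |r_perm| >= |r_obs| with the observed
    configuration included: p = (1 + x) / (permutations + 1).
    """
    _check_conformable(A, B)
    rng = rng or np.random.default_rng()
    n = A.n
    iu = np.triu_indices(n, 1)
    a = A.values[iu]
    r_obs = _pearson(a, B.values[iu])
    exceed = 0
    for _ in range(permutations):
        perm = rng.permutation(n)
        b = B.values[np.ix_(perm, perm)][iu]
        if abs(_pearson(a, b)) >= abs(r_obs) - 1e-12:
            exceed += 1
    return MantelResult(
        r=r_obs,
        p_two_tailed=(1.0 + exceed) / (permutations + 1.0),
        n_permutations=permutations,
    )


def _partial_r(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    r_ab = _pearson(a, b)
    r_ac = _pearson(a, c)
    r_bc = _pearson(b, c)
    den = (1.0 - r_ac**2) * (1.0 - r_bc**2)
    if den <= 0:
        return float("nan")
    return (r_ab - r_ac * r_bc) / np.sqrt(den)


def partial_mantel(
    A: DistanceMatrix,
    B: DistanceMatrix,
    C: DistanceMatrix,
    permutations: int = 999,
    rng: np.random.Generator | None = None,
) -> MantelResult:
    """Partial Mantel correlation of A and B controlling for C.

    r_AB.C = (r_AB - r_AC r_BC) / sqrt((1-r_AC^2)(1-r_BC^2)); the
    permutation permutes A's rows/columns and recomputes the partial
    statistic, two-tailed as in :func:`mantel`.
    """
    _check_conformable(A, B, C)
    rng = rng or np.random.default_rng()
    n = A.n
    iu = np.triu_indices(n, 1)
    a, b, c = A.values[iu], B.values[iu], C.values[iu]
    # constant control matrix: zero correlation by convention
    if np.allclose(b, b[0]) or np.allclose(c, c[0]):
        r_bc = 0.0
    else:
        r_bc = _pearson(b, c)
    if abs(r_bc) >= 1.0 - 1e-12:
        raise DegenerateControlError("B and C are perfectly correlated")
    r_ac0 = 0.0 if np.allclose(c, c[0]) else _pearson(a, c)
    if abs(r_ac0) >= 1.0 - 1e-12:
        raise DegenerateControlError("A and C are perfectly correlated")
    if np.allclose(c, c[0]):
        base = mantel(A, B, permutations, rng)
        return MantelResult(base.r, base.p_two_tailed, permutations, C.kind or "C")
    r_obs = _partial_r(a, b, c)
    exceed = 0
    for _ in range(permutations):
        perm = rng.permutation(n)
        ap = A.values[np.ix_(perm, perm)][iu]
        rp = _partial_r(ap, b, c)
        if np.isfinite(rp) and abs(rp) >= abs(r_obs) - 1e-12:
            exceed += 1
    return MantelResult(
        r=r_obs,
        p_two_tailed=(1.0 + exceed) / (permutations + 1.0),
        n_permutations=permutations,
        partialed_on=C.kind or "C",
    )


# ---------------------------------------------------------------------------
# Stepwise-AIC regression
# ---------------------------------------------------------------------------

@dataclass
class RegressionFit:
    response: str
    family: str  # "GLM-gaussian" | "RLM-huber"
    predictors: list[str]
    aic: float
    r_squared: float
    coefficients: pd.DataFrame  # coef, se, p per term
    univariate: dict[str, pd.DataFrame]


def _fit(y: np.ndarray, X: pd.DataFrame, family: str):
    """Fit one model; return (result, aic, r2)."""
    n = len(y)
    X1 = sm.add_constant(X, has_constant="add")
    if family == "GLM-gaussian":
        res = sm.OLS(y, X1).fit()
        rss = float(res.ssr)
        k = X1.shape[1]
        aic = n * np.log(max(rss, 1e-300) / n) + 2 * k
        r2 = float(res.rsquared)
        return res, aic, r2
    if family == "RLM-huber":
        res = sm.RLM(y, X1, M=sm.robust.norms.HuberT()).fit(scale_est="mad")
        w = res.weights
        rss = float(np.sum(w * res.resid**2))
        k = X1.shape[1]
        aic = n * np.log(max(rss, 1e-300) / n) + 2 * k
        sst = float(np.sum(w * (y - np.average(y, weights=w)) ** 2))
        r2 = 1.0 - rss / sst if sst > 0 else float("nan")
        return res, aic, r2
    raise ValueError(f"unknown family {family!r}")


def _drop_aliased(X: pd.DataFrame) -> pd.DataFrame:
    """Drop columns until the design is numerically full-rank."""
    X = X.copy()
    while X.shape[1] > 1:
        M = np.column_stack([np.ones(len(X)), X.to_numpy(float)])
        if np.linalg.cond(M) < 1e8:
            break
        # drop the column most explained by the others
        worst, worst_col = -1.0, X.columns[-1]
        for col in X.columns:
            others = X.drop(columns=col)
            beta, *_ = np.linalg.lstsq(
                np.column_stack([np.ones(len(X)), others]), X[col], rcond=None
            )
            resid = X[col] - np.column_stack([np.ones(len(X)), others]) @ beta
            r2 = 1 - resid.var() / max(X[col].var(), 1e-300)
            if r2 > worst:
                worst, worst_col = r2, col
        warnings.warn(f"dropping aliased predictor {worst_col!r}")
        X = X.drop(columns=worst_col)
    return X


def stepwise_regression(
    y: pd.Series,
    X: pd.DataFrame,
    family: str = "GLM-gaussian",
    direction: str = "both",
) -> RegressionFit:
    """Stepwise model selection by AIC with forward and backward moves.

    Starts from the full candidate model and greedily adds/drops single
    predictors until no move lowers the AIC
    (AIC = n ln(RSS/n) + 2k for the Gaussian GLM; the Huber RLM uses the
    analogous criterion on its converged weighted RSS).
    """
    y_arr = np.asarray(y, dtype=float)
    X = _drop_aliased(X.astype(float))
    if len(y_arr) <= X.shape[1] + 2:
        raise ValueError("need n > number of predictors + 2")
    current = list(X.columns)
    _, best_aic, _ = _fit(y_arr, X[current], family)
    improved = True
    while improved:
        improved = False
        moves: list[tuple[float, list[str]]] = []
        if direction in ("both", "backward"):
            for col in current:
                cand = [c for c in current if c != col]
                _, aic, _ = _fit(y_arr, X[cand], family)
                moves.append((aic, cand))
        if direction in ("both", "forward"):
            for col in X.columns:
                if col not in current:
                    cand = current + [col]
                    _, aic, _ = _fit(y_arr, X[cand], family)
                    moves.append((aic, cand))
        if moves:
            aic, cand = min(moves, key=lambda m: m[0])
            if aic < best_aic - 1e-9:
                best_aic, current, improved = aic, cand, True
    res, aic, r2 = _fit(y_arr, X[current], family)
    coefs = pd.DataFrame(
        dict(coef=res.params, se=res.bse, p=res.pvalues)
    )
    uni = {}
    for col in X.columns:
        r, a, rr = _fit(y_arr, X[[col]], family)
        uni[col] = pd.DataFrame(dict(coef=r.params, se=r.bse, p=r.pvalues))
    return RegressionFit(
        response=getattr(y, "name", "y") or "y",
        family=family,
        predictors=current,
        aic=aic,
        r_squared=r2,
        coefficients=coefs,
        univariate=uni,
    )
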