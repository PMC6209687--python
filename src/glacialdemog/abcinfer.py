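"""Approximate Bayesian computation over demographic scenarios.

DIY-ABC-style machinery: per-locus-group summary statistics, a mass-
simulation reference table, scenario choice by rejection (direct) and by
multinomial logistic regression on the accepted simulations, local-
linear parameter estimation, POD-based confidence in scenario choice
(type I / type II error), relative median absolute error (RMAE) of
parameter estimates, and a PCA-based posterior-predictive goodness-of-
fit check.

The five summary statistics per locus group (plastid, nuclear) are the
variance of pairwise differences (VPD), Tajima's D, the number of
private (singleton) segregating sites (PSS), and the mean (MNS) and
variance (VNS) of the count of the rarest nucleotide over segregating
sites; statistics are averaged across the loci of a group and
concatenated plastid-first into a fixed 10-vector. A locus with S = 0
contributes zeros (not NA) so every simulated row is usable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from . import coalsim
from .coalsim import (
    SCENARIOS,
    SCENARIO_IDS,
    DemographicParams,
    DemographicScenario,
    LocusSpec,
    SiteData,
    sample_prior,
    simulate_site_data,
    study_design,
)
from .diversity import encode, tajimas_d
from .seqdata import StudyDataset, drop_gap_columns

STAT_NAMES = ("VPD", "TajD", "PSS", "MNS", "VNS")
GROUP_ORDER = ("plastid", "nuclear")
STAT_COLUMNS = tuple(f"{g}_{s}" for g in GROUP_ORDER for s in STAT_NAMES)
LOG_SCALE_PARAMS = frozenset({"Ne", "Na", "Ndb", "Ta", "Tdb"})


class ToleranceError(ValueError):
    pass


class ConfigurationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Summary statistics
# ---------------------------------------------------------------------------

def _locus_stats(G: np.ndarray, n: int) -> np.ndarray:
    """(VPD, TajD, PSS, MNS, VNS) for one locus.

    G is an (S, n) matrix of state codes with -1 for missing; only
    segregating sites should be present. All five statistics are 0 when
    S = 0 (mass-simulation convention).
    """
    S = G.shape[0]
    if S == 0 or n < 2:
        return np.zeros(5)
    has_missing = bool((G < 0).any())
    # pairwise difference counts via one-hot "same state" inner products
    states = int(G.max()) + 1
    Y = np.zeros((n, S * states), dtype=np.float32)
    rows, cols = np.where(G.T >= 0)
    Y[rows, cols * states + G.T[rows, cols]] = 1.0
    same = Y @ Y.T
    if has_missing:
        B = (G.T >= 0).astype(np.float32)
        both = B @ B.T
        D = both - same
    else:
        D = float(S) - same
    # mean/variance over the n(n-1)/2 unordered pairs, off-diagonal sums
    m = n * (n - 1) // 2
    np.fill_diagonal(D, 0.0)
    tot = float(D.sum()) / 2.0
    tot2 = float((D * D).sum()) / 2.0
    k_hat = tot / m
    vpd = (tot2 - m * k_hat**2) / (m - 1) if m > 1 else 0.0
    tajd = tajimas_d(n, S, k_hat)
    if not np.isfinite(tajd):
        tajd = 0.0
    # rarest-nucleotide counts per segregating site, vectorized
    counts = Y.sum(axis=0).reshape(S, states)
    counts[counts == 0] = n + 1
    rarest = counts.min(axis=1)
    pss = float(np.sum(rarest == 1))
    mns = float(rarest.mean())
    vns = float(rarest.var(ddof=1)) if S > 1 else 0.0
    return np.array([vpd, tajd, pss, mns, vns])


def stats_from_site_data(
    site_data: list[SiteData], design: list[LocusSpec]
) -> np.ndarray:
    """10-vector of group-averaged summary statistics from simulator
    output (fast path, no sequence strings)."""
    per_group: dict[str, list[np.ndarray]] = {g: [] for g in GROUP_ORDER}
    for sd, spec in zip(site_data, design):
        per_group[spec.group].append(_locus_stats(sd.genotypes, sd.n))
    out = []
    for g in GROUP_ORDER:
        if not per_group[g]:
            raise ConfigurationError(f"design lacks locus group {g!r}")
        out.append(np.mean(per_group[g], axis=0))
    return np.concatenate(out)


def summary_stats(dataset: StudyDataset) -> np.ndarray:
    """10-vector of summary statistics for an observed dataset.

    Gap-containing columns are discarded (the ABC convention for indels)
    and 'N' is treated as missing, pairwise-complete.
    """
    per_group: dict[str, list[np.ndarray]] = {}
    for group, names in dataset.locus_groups.items():
        rows = []
        for name in names:
            aln = drop_gap_columns(dataset.locus(name))
            X = encode(aln, indels_informative=False)
            seg = []
            for j in range(X.shape[1]):
                col = X[:, j]
                obs = col[col >= 0]
                if obs.size and np.unique(obs).size > 1:
                    seg.append(j)
            G = X[:, seg].T if seg else np.empty((0, X.shape[0]), np.int8)
            rows.append(_locus_stats(G, aln.n))
        per_group[group] = rows
    out = []
    for g in GROUP_ORDER:
        if g not in per_group:
            raise ConfigurationError(f"dataset lacks locus group {g!r}")
        out.append(np.mean(per_group[g], axis=0))
    return np.concatenate(out)


# ---------------------------------------------------------------------------
# Reference table
# ---------------------------------------------------------------------------

@dataclass
class ReferenceTable:
    """Scenario labels, parameter draws and summary-stat rows from mass
    simulation, plus the per-column standardization constants."""

    scenario_ids: tuple[str, ...]
    scenario_index: np.ndarray  # (N,) int, indexes scenario_ids
    params: np.ndarray  # (N, 7) in DemographicParams.NAMES order
    stats: np.ndarray  # (N, 10) in STAT_COLUMNS order
    seed: int | None = None
    means: np.ndarray = field(default=None)
    sds: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.means is None:
            self.means = self.stats.mean(axis=0)
        if self.sds is None:
            sds = self.stats.std(axis=0, ddof=1)
            sds[sds == 0] = 1.0
            self.sds = sds

    @property
    def n_rows(self) -> int:
        return self.stats.shape[0]

    def standardized(self) -> np.ndarray:
        return (self.stats - self.means) / self.sds

    def standardize(self, obs: np.ndarray) -> np.ndarray:
        return (np.asarray(obs, dtype=float) - self.means) / self.sds

    def scenario_labels(self) -> np.ndarray:
        return np.asarray(self.scenario_ids)[self.scenario_index]

    def subset(self, scenario: str) -> "ReferenceTable":
        mask = self.scenario_labels() == scenario
        return ReferenceTable(
            scenario_ids=(scenario,),
            scenario_index=np.zeros(int(mask.sum()), dtype=int),
            params=self.params[mask],
            stats=self.stats[mask],
            seed=self.seed,
            means=self.means,
            sds=self.sds,
        )

    def head(self, n: int) -> "ReferenceTable":
        """First n rows, with standardization recomputed on the subset
        (behaves like an independently built smaller table)."""
        return ReferenceTable(
            scenario_ids=self.scenario_ids,
            scenario_index=self.scenario_index[:n],
            params=self.params[:n],
            stats=self.stats[:n],
            seed=self.seed,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.stats, columns=list(STAT_COLUMNS))
        for i, name in enumerate(DemographicParams.NAMES):
            df.insert(i, name, self.params[:, i])
        df.insert(0, "scenario", self.scenario_labels())
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, seed=None) -> "ReferenceTable":
        ids = tuple(dict.fromkeys(df["scenario"]))
        index = np.array([ids.index(s) for s in df["scenario"]])
        return cls(
            scenario_ids=ids,
            scenario_index=index,
            params=df[list(DemographicParams.NAMES)].to_numpy(float),
            stats=df[list(STAT_COLUMNS)].to_numpy(float),
            seed=seed,
        )


def build_reference_table(
    n_sims: int,
    scenarios: tuple[str, ...] = SCENARIO_IDS,
    design: list[LocusSpec] | None = None,
    seed: int | None = None,
) -> ReferenceTable:
    """Simulate the ABC reference table with equal allocation across
    scenarios (n_sims // n_scenarios rows each), reproducibly under
    ``seed``."""
    if n_sims < len(scenarios):
        raise ValueError("n_sims smaller than the number of scenarios")
    design = design or study_design()
    per = n_sims // len(scenarios)
    rows, labels, pdraws = [], [], []
    for s_idx, sid in enumerate(scenarios):
        scen = SCENARIOS[sid]
        rng = np.random.default_rng(
            None if seed is None else [int(seed), s_idx]
        )
        for _ in range(per):
            p = sample_prior(scen, rng)
            sds = simulate_site_data(scen, p, design, rng)
            rows.append(stats_from_site_data(sds, design))
            labels.append(s_idx)
            pdraws.append([getattr(p, k) for k in DemographicParams.NAMES])
    return ReferenceTable(
        scenario_ids=tuple(scenarios),
        scenario_index=np.array(labels, dtype=int),
        params=np.array(pdraws, dtype=float),
        stats=np.array(rows, dtype=float),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Scenario choice
# ---------------------------------------------------------------------------

@dataclass
class ScenarioChoice:
    method: str
    tolerance: float
    n_accepted: int
    posterior: pd.DataFrame  # scenario, pp, ci_low, ci_high

    @property
    def best(self) -> str:
        return str(self.posterior.loc[self.posterior["pp"].idxmax(), "scenario"])


def _accepted_indices(table: ReferenceTable, obs: np.ndarray, tolerance: float):
    if not (0 < tolerance <= 1):
        raise ToleranceError("tolerance must be in (0, 1]")
    z = table.standardized()
    zobs = table.standardize(obs)
    d2 = np.einsum("ij,ij->i", z - zobs, z - zobs)
    m = math.ceil(tolerance * table.n_rows)
    if m < 1:
        raise ToleranceError("empty acceptance set")
    idx = np.argpartition(d2, m - 1)[:m]
    return idx, np.sqrt(d2[idx]), z, zobs


def _multinomial_logit_pp(X: np.ndarray, y: np.ndarray, n_classes: int):
    """Fit a multinomial logit of class on covariates (no standardization)
    and return (probabilities at the origin, asymptotic covariance of the
    free intercepts). X excludes the intercept column."""
    from sklearn.linear_model import LogisticRegression

    # lbfgs fits the full multinomial likelihood; mild L2 keeps the fit
    # finite under perfect separation
    clf = LogisticRegression(C=1e4, max_iter=500, tol=1e-6)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf.fit(X, y)
    origin = np.zeros((1, X.shape[1]))
    probs0 = clf.predict_proba(origin)[0]
    # asymptotic covariance of the parameter vector from the observed
    # Fisher information, then delta method for softmax(intercepts)
    classes = clf.classes_
    K = len(classes)
    X1 = np.column_stack([np.ones(len(X)), X])
    P = clf.predict_proba(X)
    p_dim = X1.shape[1]
    n_par = (K - 1) * p_dim
    info = np.zeros((n_par, n_par))
    for a in range(K - 1):
        for b in range(K - 1):
            w = P[:, a + 1] * ((1.0 if a == b else 0.0) - P[:, b + 1])
            info[a * p_dim:(a + 1) * p_dim, b * p_dim:(b + 1) * p_dim] = (
                X1.T * w
            ) @ X1
    try:
        cov = np.linalg.pinv(info)
    except np.linalg.LinAlgError:
        cov = np.full((n_par, n_par), np.nan)
    # gradient of softmax at origin wrt free intercepts (class 0 baseline)
    grad = np.zeros((K, K - 1))
    for i in range(K):
        for a in range(K - 1):
            grad[i, a] = probs0[i] * ((1.0 if i == a + 1 else 0.0) - probs0[a + 1])
    icols = [a * p_dim for a in range(K - 1)]
    cov_int = cov[np.ix_(icols, icols)]
    var_pp = np.einsum("ia,ab,ib->i", grad, cov_int, grad)
    se = np.sqrt(np.clip(var_pp, 0, None))
    return classes, probs0, se


def choose_scenario(
    obs: np.ndarray,
    table: ReferenceTable,
    tolerance: float = 0.01,
    method: str = "direct",
) -> ScenarioChoice:
    """Scenario posterior probabilities from the accepted simulations.

    direct: scenario frequencies among the ``ceil(tolerance * N)``
    closest rows (Euclidean distance on standardized statistics), with
    normal-approximation binomial 95% CIs. logistic: multinomial
    logistic regression of scenario on (stats - obs) over the accepted
    rows, evaluated at the origin, 95% CIs from the asymptotic
    covariance.
    """
    idx, _, z, zobs = _accepted_indices(table, obs, tolerance)
    m = idx.size
    if m < len(table.scenario_ids):
        raise ToleranceError("acceptance set smaller than the scenario count")
    y = table.scenario_index[idx]
    K = len(table.scenario_ids)
    pp = np.zeros(K)
    se = np.zeros(K)
    present = np.unique(y)
    if method == "direct" or present.size == 1:
        counts = np.bincount(y, minlength=K)
        pp = counts / m
        se = np.sqrt(pp * (1 - pp) / m)
        if method != "direct" and present.size == 1:
            pass  # degenerate logistic reduces to the point mass
    elif method == "logistic":
        X = z[idx] - zobs
        classes, probs0, se_cls = _multinomial_logit_pp(X, y, K)
        for cls, p0, s0 in zip(classes, probs0, se_cls):
            pp[cls] = p0
            se[cls] = s0
        pp = pp / pp.sum()
    else:
        raise ValueError(f"unknown method {method!r}")
    lo = np.clip(pp - 1.96 * se, 0, 1)
    hi = np.clip(pp + 1.96 * se, 0, 1)
    return ScenarioChoice(
        method=method,
        tolerance=tolerance,
        n_accepted=m,
        posterior=pd.DataFrame(
            dict(scenario=list(table.scenario_ids), pp=pp, ci_low=lo, ci_high=hi)
        ),
    )


# ---------------------------------------------------------------------------
# Parameter estimation
# ---------------------------------------------------------------------------

@dataclass
class PosteriorSummary:
    scenario: str
    adjustment: str  # "local-linear" | "rejection-only"
    n_accepted: int
    draws: pd.DataFrame  # adjusted draws, original scale
    summary: pd.DataFrame  # per parameter: mean, median, mode, q2.5, q97.5

    def point(self, name: str, which: str = "median") -> float:
        return float(self.summary.loc[name, which])


def _kde_mode(x: np.ndarray) -> float:
    if np.allclose(x, x[0]):
        return float(x[0])
    kde = gaussian_kde(x, bw_method="silverman")
    grid = np.linspace(x.min(), x.max(), 512)
    return float(grid[np.argmax(kde(grid))])


def estimate_params(
    obs: np.ndarray,
    table: ReferenceTable,
    scenario: str,
    tolerance: float = 0.01,
    parameters: tuple[str, ...] | None = None,
) -> PosteriorSummary:
    """Rejection + local-linear regression adjustment within a scenario.

    Each parameter is regressed on the standardized statistics over the
    accepted rows with Epanechnikov weights in distance; sizes and times
    are adjusted on the log scale and back-transformed. The mode is a
    Gaussian-kernel (Silverman bandwidth) density peak of the adjusted
    draws.
    """
    sub = table.subset(scenario)
    if sub.n_rows < 100:
        raise ValueError(f"fewer than 100 reference rows for {scenario}")
    parameters = parameters or SCENARIOS[scenario].free_parameters
    idx, dist, z, zobs = _accepted_indices(sub, obs, tolerance)
    dmax = dist.max()
    w = 1.0 - (dist / dmax) ** 2 if dmax > 0 else np.ones_like(dist)
    w = np.clip(w, 1e-12, None)
    X = z[idx] - zobs
    X1 = np.column_stack([np.ones(idx.size), X])
    sw = np.sqrt(w)
    adjustment = "local-linear"
    adj = {}
    pidx = {k: i for i, k in enumerate(DemographicParams.NAMES)}
    for name in parameters:
        theta = sub.params[idx, pidx[name]].astype(float)
        on_log = name in LOG_SCALE_PARAMS
        t = np.log(theta) if on_log else theta
        try:
            beta, *_ = np.linalg.lstsq(X1 * sw[:, None], t * sw, rcond=None)
            fitted_slope = X @ beta[1:]
            cond_ok = np.isfinite(beta).all()
        except np.linalg.LinAlgError:
            cond_ok = False
        if not cond_ok:
            warnings.warn("singular local-linear design; rejection-only")
            adjustment = "rejection-only"
            t_adj = t
        else:
            t_adj = t - fitted_slope
        adj[name] = np.exp(t_adj) if on_log else t_adj
    draws = pd.DataFrame(adj)
    rows = {}
    for name in parameters:
        x = draws[name].to_numpy()
        rows[name] = dict(
            mean=float(x.mean()),
            median=float(np.median(x)),
            mode=_kde_mode(x),
            q2_5=float(np.quantile(x, 0.025)),
            q97_5=float(np.quantile(x, 0.975)),
        )
    return PosteriorSummary(
        scenario=scenario,
        adjustment=adjustment,
        n_accepted=idx.size,
        draws=draws,
        summary=pd.DataFrame(rows).T,
    )


# ---------------------------------------------------------------------------
# POD calibration
# ---------------------------------------------------------------------------

def _pod_stats(
    scenario: DemographicScenario,
    design: list[LocusSpec],
    rng: np.random.Generator,
) -> tuple[DemographicParams, np.ndarray]:
    p = sample_prior(scenario, rng)
    sds = simulate_site_data(scenario, p, design, rng)
    return p, stats_from_site_data(sds, design)


def confidence_in_choice(
    focal: str,
    table: ReferenceTable,
    n_pods: int = 100,
    tolerance: float = 0.01,
    method: str = "direct",
    design: list[LocusSpec] | None = None,
    rng: np.random.Generator | None = None,
) -> dict:
    """Type I / type II error of scenario choice for a focal scenario.

    ``n_pods`` pseudo-observed datasets are drawn from the prior of each
    scenario and pushed through :func:`choose_scenario`; type I is the
    fraction of focal-scenario PODs where the focal scenario does not
    win, type II the mean over competing scenarios of the fraction of
    their PODs where it does. ``method`` may be ``"direct"``,
    ``"logistic"`` or ``"both"`` (both evaluated on the same PODs);
    results are keyed ``type_I`` / ``type_II`` for a single method and
    ``type_I_direct`` etc. for both.
    """
    rng = rng or np.random.default_rng()
    design = design or study_design()
    methods = ("direct", "logistic") if method == "both" else (method,)
    win_frac = {m: {} for m in methods}
    for sid in table.scenario_ids:
        scen = SCENARIOS[sid]
        wins = {m: 0 for m in methods}
        for _ in range(n_pods):
            _, stats = _pod_stats(scen, design, rng)
            for m in methods:
                if choose_scenario(stats, table, tolerance, m).best == focal:
                    wins[m] += 1
        for m in methods:
            win_frac[m][sid] = wins[m] / n_pods
    others = [s for s in table.scenario_ids if s != focal]
    out = dict(focal=focal, method=method, n_pods=n_pods)
    for m in methods:
        suffix = f"_{m}" if method == "both" else ""
        out[f"type_I{suffix}"] = 1.0 - win_frac[m][focal]
        out[f"type_II{suffix}"] = float(
            np.mean([win_frac[m][s] for s in others])
        )
        out[f"focal_win_fraction{suffix}"] = win_frac[m]
    return out


def rmae(estimates: np.ndarray, truths: np.ndarray) -> float:
    """Relative median absolute error: median |estimate - truth| / truth."""
    estimates = np.asarray(estimates, dtype=float)
    truths = np.asarray(truths, dtype=float)
    if np.any(truths == 0):
        raise ValueError("truth of 0 is outside the prior support")
    return float(np.median(np.abs(estimates - truths) / np.abs(truths)))


def rmae_params(
    scenario: str,
    table: ReferenceTable,
    n_pods: int = 100,
    tolerance: float = 0.01,
    design: list[LocusSpec] | None = None,
    rng: np.random.Generator | None = None,
) -> pd.Series:
    """Per-parameter RMAE of the posterior-median estimator over PODs
    drawn from the scenario's prior."""
    rng = rng or np.random.default_rng()
    design = design or study_design()
    scen = SCENARIOS[scenario]
    names = scen.free_parameters
    ests = {k: [] for k in names}
    trus = {k: [] for k in names}
    for _ in range(n_pods):
        p, stats = _pod_stats(scen, design, rng)
        post = estimate_params(stats, table, scenario, tolerance, names)
        for k in names:
            ests[k].append(post.point(k))
            trus[k].append(getattr(p, k))
    return pd.Series({k: rmae(ests[k], trus[k]) for k in names}, name="RMAE")


# ---------------------------------------------------------------------------
# Goodness of fit
# ---------------------------------------------------------------------------

@dataclass
class GofResult:
    tail_p: pd.Series  # per summary statistic
    pod_stats: np.ndarray
    pca_pods: np.ndarray
    pca_obs: np.ndarray


def goodness_of_fit(
    obs: np.ndarray,
    posterior: PosteriorSummary,
    table: ReferenceTable,
    n_pods: int = 1000,
    design: list[LocusSpec] | None = None,
    rng: np.random.Generator | None = None,
) -> GofResult:
    """Posterior-predictive check: PODs simulated from posterior draws,
    per-statistic two-sided tail probabilities of the observation, and a
    PCA projection (fitted on standardized reference statistics) of PODs
    and observation for plotting."""
    from sklearn.decomposition import PCA

    rng = rng or np.random.default_rng()
    design = design or study_design()
    scen = SCENARIOS[posterior.scenario]
    draws = posterior.draws
    prior_mid = {
        "Ne": 5e4, "Na": 5e4, "Ndb": 5e4, "Ta": 2.5e4,
        "Tdb": float(np.mean(scen.tdb_window or coalsim.TDB_PREGLACIAL)),
        "mu_cp": 6e-8, "mu_nr": 2e-7,
    }
    rows = []
    pick = rng.integers(0, len(draws), size=n_pods)
    for i in pick:
        vals = dict(prior_mid)
        vals.update({k: float(draws.iloc[i][k]) for k in draws.columns})
        p = DemographicParams(**vals)
        sds = simulate_site_data(scen, p, design, rng)
        rows.append(stats_from_site_data(sds, design))
    pod = np.array(rows)
    obs = np.asarray(obs, dtype=float)
    lo = (1.0 + (pod <= obs).sum(axis=0)) / (n_pods + 1.0)
    hi = (1.0 + (pod >= obs).sum(axis=0)) / (n_pods + 1.0)
    tail = np.minimum(1.0, 2.0 * np.minimum(lo, hi))
    pca = PCA(n_components=2)
    pca.fit(table.standardized())
    return GofResult(
        tail_p=pd.Series(tail, index=list(STAT_COLUMNS)),
        pod_stats=pod,
        pca_pods=pca.transform((pod - table.means) / table.sds),
        pca_obs=pca.transform(table.standardize(obs)[None, :])[0],
    )
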