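"""Conditional-logistic path-selection model.

Each observed path and its matched random paths form one *stratum* (choice
set).  The probability that the observed path is the one actually taken is a
softmax over the stratum's rows,

    P(obs | stratum s) = exp(eta_obs) / sum_m exp(eta_m),   eta = x' beta,

so the log-likelihood is ``sum_s [eta_obs - log sum_m exp(eta_m)]``.  This
conditional-logistic likelihood is algebraically identical to a Poisson
regression with one free intercept per stratum (profile the intercepts out
and the stratum constants cancel), which is what permits random, per-animal
selection coefficients: ``fit_poisson_equivalent`` verifies the equivalence
through an independent GLM route, and ``fit_random_slopes`` exploits it with
a Laplace-approximated marginal likelihood.

Missing covariates (NA-gated disturbance terms) contribute exactly zero to
the linear predictor — after standardization that is mean imputation, and
setting a column to missing for a whole stratum is identical to deleting it
from that stratum's model.

Models are ranked by WAIC computed from stratum-level pointwise likelihoods
under draws from the (approximating) posterior of the coefficients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "ModelSpec",
    "StratumData",
    "FittedModel",
    "clogit_loglik",
    "fit_fixed",
    "fit_poisson_equivalent",
    "fit_random_slopes",
    "waic",
    "run_model_ladder",
    "default_ladder",
]

_BETA_BOUND = 30.0  # |beta| beyond this on z-scored covariates signals separation


# ---------------------------------------------------------------------------
# model specification


def _term_parents(term: str) -> list[str]:
    if ":" in term:
        return term.split(":")
    if term.endswith("^2"):
        return [term[:-2]]
    return [term]


@dataclass
class ModelSpec:
    """A covariate formula: linear names, ``name^2`` quadratics, ``a:b``
    interactions.  Quadratics/interactions require their parent linear
    terms.  ``random_slopes`` flags terms that get per-animal deviations."""

    terms: list[str]
    label: str = ""
    random_slopes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.label:
            self.label = " + ".join(self.terms) if self.terms else "Null"
        linear = {t for t in self.terms if ":" not in t and not t.endswith("^2")}
        for t in self.terms:
            for p in _term_parents(t):
                if p not in linear:
                    raise ValueError(f"term {t!r} requires linear term {p!r} in the spec")
        for t in self.random_slopes:
            if t not in self.terms:
                raise ValueError(f"random slope on unknown term {t!r}")

    @property
    def n_terms(self) -> int:
        return len(self.terms)


def _compute_term(df: pd.DataFrame, term: str) -> np.ndarray:
    """Term column from (standardized) linear covariate columns."""
    if ":" in term:
        a, b = term.split(":")
        return df[a].to_numpy(float) * df[b].to_numpy(float)
    if term.endswith("^2"):
        return df[term[:-2]].to_numpy(float) ** 2
    return df[term].to_numpy(float)


# ---------------------------------------------------------------------------
# fit-ready strata


@dataclass
class StratumData:
    """Dense fit-ready container: X[s, m, p] are term values (NaN missing),
    obs_idx[s] the observed row, row_valid for padding when strata differ in
    row count."""

    X: np.ndarray
    obs_idx: np.ndarray
    animal_codes: np.ndarray
    animal_labels: list[str]
    terms: list[str]
    stratum_ids: list[str]
    row_valid: np.ndarray = None  # type: ignore[assignment]
    n_strata_total: int | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        S, M, P = self.X.shape
        if self.row_valid is None:
            self.row_valid = np.ones((S, M), dtype=bool)
        self.obs_idx = np.asarray(self.obs_idx, dtype=int)
        self.animal_codes = np.asarray(self.animal_codes, dtype=int)
        if self.n_strata_total is None:
            self.n_strata_total = S

    @property
    def n_strata(self) -> int:
        return self.X.shape[0]

    @property
    def n_terms(self) -> int:
        return self.X.shape[2]

    @classmethod
    def from_design(cls, design: pd.DataFrame, spec: ModelSpec) -> "StratumData":
        """Build strata from a standardized design table (one row per path,
        columns stratum_id / animal_id / role / covariates).  Strata whose
        term values are missing in every cell drop out (they carry no
        information about any coefficient)."""
        cols = {t: _compute_term(design, t) for t in spec.terms}
        groups = design.groupby("stratum_id", sort=False).indices
        n_total = len(groups)
        M = max((len(ix) for ix in groups.values()), default=0)
        P = len(spec.terms)
        roles = design["role"].to_numpy()
        animals = design["animal_id"].astype(str).to_numpy()
        labels = sorted(set(animals))
        code_of = {a: i for i, a in enumerate(labels)}
        X_list, obs_list, an_list, sid_list, valid_list = [], [], [], [], []
        for sid, ix in groups.items():
            obs_rows = np.nonzero(roles[ix] == "observed")[0]
            if len(obs_rows) != 1:
                raise ValueError(f"stratum {sid!r} must have exactly one observed row, has {len(obs_rows)}")
            Xs = np.full((M, P), np.nan)
            for p, t in enumerate(spec.terms):
                Xs[: len(ix), p] = cols[t][ix]
            if P and np.all(np.isnan(Xs[: len(ix)])):
                continue
            valid = np.zeros(M, dtype=bool)
            valid[: len(ix)] = True
            X_list.append(Xs)
            obs_list.append(obs_rows[0])
            an_list.append(code_of[animals[ix[0]]])
            sid_list.append(str(sid))
            valid_list.append(valid)
        if not X_list:
            X = np.zeros((0, M, P))
            valid = np.zeros((0, M), dtype=bool)
        else:
            X = np.stack(X_list)
            valid = np.stack(valid_list)
        return cls(
            X=X,
            obs_idx=np.array(obs_list, dtype=int),
            animal_codes=np.array(an_list, dtype=int),
            animal_labels=labels,
            terms=list(spec.terms),
            stratum_ids=sid_list,
            row_valid=valid,
            n_strata_total=n_total,
        )

    def subset(self, strata_mask: np.ndarray) -> "StratumData":
        return StratumData(
            X=self.X[strata_mask],
            obs_idx=self.obs_idx[strata_mask],
            animal_codes=self.animal_codes[strata_mask],
            animal_labels=self.animal_labels,
            terms=self.terms,
            stratum_ids=[s for s, m in zip(self.stratum_ids, strata_mask) if m],
            row_valid=self.row_valid[strata_mask],
            n_strata_total=int(strata_mask.sum()),
        )


# ---------------------------------------------------------------------------
# likelihood


def _ll_parts(strata: StratumData, beta: np.ndarray, order: int = 0):
    """Log-likelihood and optional analytic gradient / Hessian."""
    X0 = np.nan_to_num(strata.X)
    S, M, P = X0.shape
    beta = np.asarray(beta, dtype=float)
    eta = X0 @ beta if P else np.zeros((S, M))
    eta = np.where(strata.row_valid, eta, -np.inf)
    mx = eta.max(axis=1, keepdims=True)
    w = np.exp(eta - mx)
    Z = w.sum(axis=1)
    eta_obs = eta[np.arange(S), strata.obs_idx]
    ll = float(np.sum(eta_obs - (mx[:, 0] + np.log(Z))))
    if order == 0:
        return ll, None, None
    p = w / Z[:, None]
    xbar = np.einsum("sm,smp->sp", p, X0)
    x_obs = X0[np.arange(S), strata.obs_idx]
    grad = (x_obs - xbar).sum(axis=0)
    if order == 1:
        return ll, grad, None
    Exx = np.einsum("sm,smp,smq->pq", p, X0, X0)
    H = -(Exx - xbar.T @ xbar)
    return ll, grad, H


def clogit_loglik(strata: StratumData, beta: np.ndarray) -> float:
    """Exact conditional-logistic log-likelihood (missing covariates
    contribute zero to the linear predictor)."""
    return _ll_parts(strata, beta, order=0)[0]


# ---------------------------------------------------------------------------
# fitted model container


@dataclass
class FittedModel:
    terms: list[str]
    beta: np.ndarray
    se: np.ndarray
    vcov: np.ndarray
    loglik: float
    converged: bool
    n_strata_used: int
    n_strata_total: int
    label: str = ""
    method: str = "fixed"
    random_terms: list[str] = field(default_factory=list)
    random_sd: np.ndarray | None = None
    animal_deviations: dict[str, np.ndarray] | None = None
    notes: list[str] = field(default_factory=list)
    waic_: float | None = None
    p_waic_: float | None = None

    def coef(self, term: str) -> float:
        return float(self.beta[self.terms.index(term)])

    def summary(self) -> pd.DataFrame:
        z = np.divide(self.beta, self.se, out=np.zeros_like(self.beta), where=self.se > 0)
        return pd.DataFrame(
            {
                "term": self.terms,
                "estimate": self.beta,
                "se": self.se,
                "z": z,
                "ci_lo": self.beta - 1.96 * self.se,
                "ci_hi": self.beta + 1.96 * self.se,
            }
        )


# ---------------------------------------------------------------------------
# fixed-effects fit (Newton with analytic gradient/Hessian)


def fit_fixed(
    strata: StratumData,
    spec: ModelSpec | None = None,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> FittedModel:
    """Maximum-likelihood fixed-effects fit, started at beta = 0; standard
    errors from the inverse observed information."""
    P = strata.n_terms
    label = spec.label if spec is not None else " + ".join(strata.terms) or "Null"
    if P == 0:
        ll = clogit_loglik(strata, np.zeros(0))
        return FittedModel(
            terms=[], beta=np.zeros(0), se=np.zeros(0), vcov=np.zeros((0, 0)),
            loglik=ll, converged=True, n_strata_used=strata.n_strata,
            n_strata_total=strata.n_strata_total or strata.n_strata, label=label,
        )
    beta = np.zeros(P)
    ll, g, H = _ll_parts(strata, beta, order=2)
    converged = False
    notes: list[str] = []
    for _ in range(max_iter):
        if np.linalg.norm(g, ord=np.inf) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(-H + 1e-10 * np.eye(P), g)
        except np.linalg.LinAlgError:
            step = g
        # damped update: halve until the likelihood does not decrease
        t = 1.0
        for _half in range(40):
            cand = beta + t * step
            ll_new = clogit_loglik(strata, cand)
            if ll_new >= ll - 1e-12:
                break
            t /= 2
        beta = beta + t * step
        ll, g, H = _ll_parts(strata, beta, order=2)
        if np.any(np.abs(beta) > _BETA_BOUND):
            warnings.warn(
                "possible separation: a coefficient exceeded "
                f"{_BETA_BOUND}; estimate bounded", stacklevel=2,
            )
            notes.append("separation_bounded")
            beta = np.clip(beta, -_BETA_BOUND, _BETA_BOUND)
            ll, g, H = _ll_parts(strata, beta, order=2)
            break
    info = -H
    try:
        vcov = np.linalg.inv(info + 1e-12 * np.eye(P))
    except np.linalg.LinAlgError:
        vcov = np.full((P, P), np.nan)
    se = np.sqrt(np.clip(np.diag(vcov), 0, None))
    return FittedModel(
        terms=list(strata.terms), beta=beta, se=se, vcov=vcov, loglik=ll,
        converged=converged, n_strata_used=strata.n_strata,
        n_strata_total=strata.n_strata_total or strata.n_strata,
        label=label, notes=notes,
    )


def fit_poisson_equivalent(strata: StratumData, spec: ModelSpec | None = None) -> FittedModel:
    """The same model through the Poisson route: observed rows are count 1,
    random rows count 0, one free intercept per stratum (statsmodels GLM).
    Slope estimates agree with :func:`fit_fixed` to optimizer tolerance."""
    import statsmodels.api as sm

    S, M, P = strata.X.shape
    X0 = np.nan_to_num(strata.X)
    rows_y, rows_x, rows_s = [], [], []
    for s in range(S):
        for m in range(M):
            if not strata.row_valid[s, m]:
                continue
            rows_y.append(1.0 if m == strata.obs_idx[s] else 0.0)
            rows_x.append(X0[s, m])
            rows_s.append(s)
    y = np.array(rows_y)
    Xc = np.array(rows_x) if P else np.zeros((len(y), 0))
    dummies = np.zeros((len(y), S))
    dummies[np.arange(len(y)), rows_s] = 1.0
    design = np.hstack([dummies, Xc])
    res = sm.GLM(y, design, family=sm.families.Poisson()).fit(maxiter=200, tol=1e-12)
    beta = np.asarray(res.params[S:])
    se = np.asarray(res.bse[S:])
    vcov = np.asarray(res.cov_params())[S:, S:]
    ll = clogit_loglik(strata, beta)
    return FittedModel(
        terms=list(strata.terms), beta=beta, se=se, vcov=vcov, loglik=ll,
        converged=bool(res.converged), n_strata_used=S,
        n_strata_total=strata.n_strata_total or S,
        label=(spec.label if spec else ""), method="poisson",
    )


# ---------------------------------------------------------------------------
# random slopes (Laplace-approximated marginal likelihood)


def _animal_groups(strata: StratumData) -> dict[int, np.ndarray]:
    groups: dict[int, list[int]] = {}
    for s, a in enumerate(strata.animal_codes):
        groups.setdefault(int(a), []).append(s)
    return {a: np.array(ix) for a, ix in groups.items()}


def _inner_mode(
    sub: StratumData, beta: np.ndarray, r_idx: np.ndarray, inv_var: np.ndarray,
    b0: np.ndarray, tol: float = 1e-9, max_iter: int = 50,
):
    """Mode of the per-animal deviation posterior and the Laplace pieces."""
    q = len(r_idx)
    b = b0.copy()
    for _ in range(max_iter):
        bb = beta.copy()
        bb[r_idx] += b
        ll, g, H = _ll_parts(sub, bb, order=2)
        g_pen = g[r_idx] - inv_var * b
        if np.linalg.norm(g_pen, ord=np.inf) < tol:
            break
        H_pen = H[np.ix_(r_idx, r_idx)] - np.diag(inv_var)
        try:
            step = np.linalg.solve(-H_pen, g_pen)
        except np.linalg.LinAlgError:
            step = g_pen
        f_cur = ll - 0.5 * np.sum(inv_var * b * b)
        t = 1.0
        for _half in range(30):
            cand = b + t * step
            bb2 = beta.copy()
            bb2[r_idx] += cand
            f_new = clogit_loglik(sub, bb2) - 0.5 * np.sum(inv_var * cand * cand)
            if f_new >= f_cur - 1e-12:
                break
            t /= 2
        b = b + t * step
    bb = beta.copy()
    bb[r_idx] += b
    ll, g, H = _ll_parts(sub, bb, order=2)
    A = -H[np.ix_(r_idx, r_idx)] + np.diag(inv_var)
    sign, logdetA = np.linalg.slogdet(A)
    if sign <= 0:
        logdetA = q * 20.0  # pathological curvature; heavy penalty
    return b, ll, logdetA


def fit_random_slopes(
    strata: StratumData,
    random_terms: list[str],
    spec: ModelSpec | None = None,
    prior_fixed_sd: float = 10.0,
    prior_sd_scale: float = 1.0,
    sd_start: float = 0.3,
    seed: int = 0,
) -> FittedModel:
    """Hierarchical fit: per-animal normal deviations on the flagged slopes.

    Maximizes the Laplace-approximated marginal likelihood over the fixed
    effects and the between-animal sds, with weakly-informative penalties
    (normal sd ``prior_fixed_sd`` on fixed effects, half-normal
    ``prior_sd_scale`` on the sds). If a variance component collapses to the
    boundary the fit is noted as effectively fixed-effects.
    """
    P = strata.n_terms
    r_idx = np.array([strata.terms.index(t) for t in random_terms], dtype=int)
    q = len(r_idx)
    if q == 0:
        return fit_fixed(strata, spec)
    groups = _animal_groups(strata)
    subs = {a: strata.subset(np.isin(np.arange(strata.n_strata), ix)) for a, ix in groups.items()}
    modes: dict[int, np.ndarray] = {a: np.zeros(q) for a in groups}
    log_sd_lo, log_sd_hi = np.log(1e-3), np.log(5.0)

    def neg_marginal(theta: np.ndarray) -> float:
        beta = theta[:P]
        sd = np.exp(np.clip(theta[P:], log_sd_lo, log_sd_hi))
        inv_var = 1.0 / sd**2
        total = 0.0
        for a, sub in subs.items():
            b, ll, logdetA = _inner_mode(sub, beta, r_idx, inv_var, modes[a])
            modes[a] = b
            total += ll - 0.5 * np.sum(inv_var * b * b) - np.sum(np.log(sd)) - 0.5 * logdetA
        total += -0.5 * np.sum((beta / prior_fixed_sd) ** 2)
        total += -0.5 * np.sum((sd / prior_sd_scale) ** 2)
        return -total

    start_beta = fit_fixed(strata).beta
    theta0 = np.concatenate([start_beta, np.full(q, np.log(sd_start))])
    bounds = [(None, None)] * P + [(log_sd_lo, log_sd_hi)] * q
    res = optimize.minimize(
        neg_marginal, theta0, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 300, "ftol": 1e-11, "gtol": 1e-7},
    )
    beta_hat = res.x[:P]
    sd_hat = np.exp(res.x[P:])
    notes = []
    if np.any(res.x[P:] <= log_sd_lo + 1e-9):
        notes.append("variance_component_collapsed_to_zero; effectively fixed-effects for that term")
    # fixed-effect covariance from the curvature of the marginal in beta
    eps = 1e-4
    Hb = np.zeros((P, P))
    f0 = neg_marginal(res.x)
    base = res.x.copy()
    for i in range(P):
        for j in range(i, P):
            tpp = base.copy(); tpp[i] += eps; tpp[j] += eps
            tpm = base.copy(); tpm[i] += eps; tpm[j] -= eps
            tmp = base.copy(); tmp[i] -= eps; tmp[j] += eps
            tmm = base.copy(); tmm[i] -= eps; tmm[j] -= eps
            Hb[i, j] = Hb[j, i] = (
                neg_marginal(tpp) - neg_marginal(tpm) - neg_marginal(tmp) + neg_marginal(tmm)
            ) / (4 * eps * eps)
    try:
        vcov = np.linalg.inv(Hb + 1e-10 * np.eye(P))
        se = np.sqrt(np.clip(np.diag(vcov), 0, None))
    except np.linalg.LinAlgError:
        vcov = np.full((P, P), np.nan)
        se = np.full(P, np.nan)
    dev = {
        strata.animal_labels[a]: modes[a].copy() for a in groups
    }
    ll = -f0  # penalized marginal at the optimum
    return FittedModel(
        terms=list(strata.terms), beta=beta_hat, se=se, vcov=vcov, loglik=ll,
        converged=bool(res.success), n_strata_used=strata.n_strata,
        n_strata_total=strata.n_strata_total or strata.n_strata,
        label=(spec.label if spec else ""), method="random_slopes",
        random_terms=list(random_terms), random_sd=sd_hat,
        animal_deviations=dev, notes=notes,
    )


# ---------------------------------------------------------------------------
# WAIC


def waic(
    fitted: FittedModel,
    strata: StratumData,
    n_draws: int = 2000,
    seed: int = 0,
    chunk: int = 250,
) -> tuple[float, float]:
    """WAIC = -2 (lppd - p_waic) with stratum-level pointwise likelihoods;
    posterior draws come from the normal approximation N(beta_hat, vcov)."""
    rng = np.random.default_rng(seed)
    P = len(fitted.beta)
    S = strata.n_strata
    if P == 0 or not np.all(np.isfinite(fitted.vcov)) or np.allclose(fitted.vcov, 0):
        ll = clogit_loglik(strata, fitted.beta)
        return float(-2 * ll), 0.0
    jitter = 1e-12 * np.eye(P)
    L = np.linalg.cholesky(fitted.vcov + jitter)
    X0 = np.nan_to_num(strata.X)
    Xf = X0.reshape(S * X0.shape[1], P)
    valid = strata.row_valid.reshape(-1)
    obs = strata.obs_idx
    logp = np.empty((S, n_draws))
    done = 0
    while done < n_draws:
        d = min(chunk, n_draws - done)
        draws = fitted.beta[None, :] + rng.standard_normal((d, P)) @ L.T
        eta = (Xf @ draws.T).reshape(S, X0.shape[1], d)
        eta = np.where(valid.reshape(S, -1, 1), eta, -np.inf)
        mx = eta.max(axis=1, keepdims=True)
        lse = mx[:, 0, :] + np.log(np.exp(eta - mx).sum(axis=1))
        logp[:, done : done + d] = eta[np.arange(S), obs, :] - lse
        done += d
    mx = logp.max(axis=1, keepdims=True)
    lppd = float(np.sum(mx[:, 0] + np.log(np.mean(np.exp(logp - mx), axis=1))))
    p_w = float(np.sum(np.var(logp, axis=1, ddof=1)))
    return float(-2 * (lppd - p_w)), p_w


# ---------------------------------------------------------------------------
# model ladder


def default_ladder() -> list[ModelSpec]:
    """The packaged comparison ladder: null, single disturbances, the
    disturbance backbone, natural terms with and without quadratics, and the
    two interaction variants, up to the full model."""
    full = ["slope", "slope^2", "wash", "wash^2", "veg", "veg^2", "habitat",
            "road", "fence", "floodcontrol", "rail"]
    dist = ["habitat", "road", "fence", "floodcontrol", "rail"]
    specs = [
        ModelSpec(full),
        ModelSpec(full + ["road:wash"]),
        ModelSpec(["slope", "slope^2", "wash", "wash^2", "veg"] + dist[:1] + dist[1:]),
        ModelSpec(["wash", "wash^2"] + dist),
        ModelSpec(["wash"] + dist),
        ModelSpec(full + ["slope:wash"]),
        ModelSpec(["slope", "slope^2"] + dist),
        ModelSpec(["road", "slope", "fence", "floodcontrol", "rail", "habitat"],
                  label="road + slope + fence + floodcontrol + rail + habitat"),
        ModelSpec(["veg", "veg^2"] + dist),
        ModelSpec(["road", "veg", "fence", "floodcontrol", "rail", "habitat"],
                  label="road + veg + fence + floodcontrol + rail + habitat"),
        ModelSpec(dist),
        ModelSpec(["habitat", "road", "fence", "floodcontrol"]),
        ModelSpec(["habitat", "road"]),
        ModelSpec(["habitat", "floodcontrol", "rail"]),
        ModelSpec(["habitat", "floodcontrol"]),
        ModelSpec(["habitat", "fence"]),
        ModelSpec(["habitat"]),
        ModelSpec(["habitat", "rail"]),
        ModelSpec([], label="Null"),
    ]
    return specs


def run_model_ladder(
    design: pd.DataFrame,
    specs: list[ModelSpec] | None = None,
    n_draws: int = 2000,
    seed: int = 0,
    method: str = "fixed",
) -> pd.DataFrame:
    """Fit every spec on the same design table and rank by WAIC (ascending;
    ties keep the input spec order).  ``method`` chooses the fixed-effects
    or random-slopes route for each fit."""
    specs = specs if specs is not None else default_ladder()
    recs = []
    for i, spec in enumerate(specs):
        strata = StratumData.from_design(design, spec)
        if method == "random_slopes" and spec.random_slopes:
            fitted = fit_random_slopes(strata, spec.random_slopes, spec, seed=seed)
        else:
            fitted = fit_fixed(strata, spec)
        w, p_w = waic(fitted, strata, n_draws=n_draws, seed=seed + i)
        recs.append(
            {
                "label": spec.label, "waic": w, "p_waic": p_w,
                "loglik": fitted.loglik, "n_terms": spec.n_terms,
                "n_strata_used": fitted.n_strata_used, "order": i,
            }
        )
    tab = pd.DataFrame(recs)
    tab = tab.sort_values(["waic", "order"], kind="stable").reset_index(drop=True)
    tab["delta_waic"] = tab["waic"] - tab["waic"].iloc[0]
    return tab.drop(columns="order")
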