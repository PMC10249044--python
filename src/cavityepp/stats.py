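"""Statistical battery: chi-square, Mann-Whitney, binomial GLM/GLMM, VIF, SMI.

Three analysis levels mirror the study design:

* plot level — Yates-corrected 2x2 chi-square tests on the proportion of
  EPP-positive broods and of extra-pair offspring between cavity types, and
  Mann-Whitney U tests on the spatiotemporal metrics;
* nest level — binomial-logit models of (a) EPP occurrence (0/1) and
  (b) the proportion of extra-pair young per nest, with mother identity as
  a random intercept and cavity type, laying date, clutch size and one
  z-scaled spatiotemporal covariate as predictors;
* individual level — a mixed logit of a nestling's extra-pair status (and
  of fledging success) with a nest random intercept.

Per-term p-values come from drop-one likelihood-ratio chi-square tests
("Pr(>Chisq)" convention); Wald standard errors are also reported.  The
mixed models maximise the exact marginal likelihood by adaptive
Gauss-Hermite quadrature over the single random intercept; when the
optimiser fails to converge the model silently *never* degrades — it
returns the fixed-effects GLM fit carrying an explicit
``random term dropped`` flag, the same fallback the field uses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial.hermite_e import hermegauss
from scipy import optimize, special, stats as sps

import statsmodels.api as sm

__all__ = [
    "TestResult",
    "ModelFit",
    "chi_square_2x2",
    "mann_whitney_u",
    "zscale",
    "glm_binomial",
    "glmm_binomial",
    "compute_vif",
    "scaled_mass_index",
    "run_model_battery",
]


@dataclass
class TestResult:
    """A single hypothesis-test outcome."""

    name: str
    statistic: float
    df: float | None
    p_value: float
    n: tuple[int, ...]
    notes: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


@dataclass
class ModelFit:
    """Fitted binomial GLM/GLMM with drop-one LRT p-values."""

    terms: list[str]
    estimates: np.ndarray
    se: np.ndarray
    p_lrt: dict[str, float]
    p_wald: dict[str, float]
    converged: bool
    loglik: float
    n: int
    random_intercept_var: float | None = None
    random_term_dropped: bool = False
    vif: dict[str, float] = field(default_factory=dict)
    dropped_columns: list[str] = field(default_factory=list)
    dispersion_ratio: float | None = None
    warnings: list[str] = field(default_factory=list)

    def coef(self, term: str) -> float:
        return float(self.estimates[self.terms.index(term)])

    def se_of(self, term: str) -> float:
        return float(self.se[self.terms.index(term)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.terms,
                "estimate": self.estimates,
                "se": self.se,
                "p_lrt": [self.p_lrt.get(t, np.nan) for t in self.terms],
                "p_wald": [self.p_wald.get(t, np.nan) for t in self.terms],
            }
        )


# ---------------------------------------------------------------------------
# plot-level tests
# ---------------------------------------------------------------------------

def chi_square_2x2(
    a: int, b: int, c: int, d: int, continuity: bool = True
) -> TestResult:
    """Pearson chi-square on the 2x2 table [[a, b], [c, d]], df = 1.

    Yates continuity correction is applied by default (the convention that
    reproduces the published test statistics from their printed counts).
    """
    table = np.array([[a, b], [c, d]], dtype=float)
    if (table < 0).any() or not np.allclose(table, np.round(table)):
        raise ValueError("counts must be non-negative integers")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("2x2 table has a zero margin")
    res = sps.chi2_contingency(table, correction=continuity)
    return TestResult(
        name="chi_square_2x2",
        statistic=float(res.statistic),
        df=1.0,
        p_value=float(res.pvalue),
        n=(int(table.sum()),),
        notes="Yates continuity correction" if continuity else "uncorrected",
    )


def mann_whitney_u(
    x,
    y,
    continuity: bool = True,
    exact_max_n: int = 8,
    alternative: str = "two-sided",
) -> TestResult:
    """Mann-Whitney U test; W = R1 - n1(n1+1)/2 (first-sample convention).

    Exact enumeration is used when both samples have at most ``exact_max_n``
    observations and no ties are present; otherwise the tie-corrected
    normal approximation (with optional continuity correction) applies.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        warnings.warn("all values identical; U test degenerate, p = 1")
        return TestResult(
            "mann_whitney_u",
            statistic=len(x) * len(y) / 2.0,
            df=None,
            p_value=1.0,
            n=(len(x), len(y)),
            notes="degenerate: all values tied",
        )
    has_ties = len(np.unique(pooled)) < len(pooled)
    use_exact = (len(x) <= exact_max_n and len(y) <= exact_max_n
                 and not has_ties)
    res = sps.mannwhitneyu(
        x,
        y,
        alternative=alternative,
        method="exact" if use_exact else "asymptotic",
        use_continuity=continuity,
    )
    return TestResult(
        name="mann_whitney_u",
        statistic=float(res.statistic),
        df=None,
        p_value=float(res.pvalue),
        n=(len(x), len(y)),
        notes=("exact enumeration" if use_exact
               else f"normal approx, tie correction, continuity={continuity}"),
    )


def zscale(values) -> np.ndarray:
    """(x - mean) / sample SD (ddof=1)."""
    v = np.asarray(values, dtype=float)
    if len(np.unique(v[~np.isnan(v)])) < 2:
        raise ValueError("zscale: zero variance in covariate")
    return (v - np.nanmean(v)) / np.nanstd(v, ddof=1)


# ---------------------------------------------------------------------------
# binomial GLM
# ---------------------------------------------------------------------------

def _prepare_design(X: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Add intercept, drop constant/aliased columns (reported)."""
    X = X.copy().astype(float)
    dropped = []
    for colname in list(X.columns):
        if X[colname].nunique(dropna=True) < 2:
            dropped.append(colname)
            X = X.drop(columns=colname)
    Xc = sm.add_constant(X, has_constant="add")
    # drop columns that are linearly dependent on the preceding ones
    q = np.linalg.matrix_rank(Xc.to_numpy())
    while q < Xc.shape[1]:
        for colname in list(Xc.columns[1:])[::-1]:
            trial = Xc.drop(columns=colname)
            if np.linalg.matrix_rank(trial.to_numpy()) == q:
                dropped.append(colname)
                Xc = trial
                break
        q = np.linalg.matrix_rank(Xc.to_numpy())
    return Xc, dropped


def _binom_response(y, trials) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float)
    if trials is None:
        trials = np.ones_like(y)
    trials = np.asarray(trials, dtype=float)
    if np.any(y < 0) or np.any(y > trials):
        raise ValueError("successes must lie in [0, trials]")
    return y, trials


def glm_binomial(
    y, X: pd.DataFrame, trials=None, compute_lrt: bool = True
) -> ModelFit:
    """Binomial-logit GLM by IRLS with drop-one LRT per term.

    ``y`` is 0/1 (Bernoulli) or a success count with ``trials`` giving the
    number of sampled nestlings per nest (proportion models).  Separation
    (diverging coefficients) is flagged in ``warnings`` but estimates are
    still reported.
    """
    y, n_trials = _binom_response(y, trials)
    Xc, dropped = _prepare_design(X)
    endog = np.column_stack([y, n_trials - y])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.GLM(endog, Xc, family=sm.families.Binomial()).fit()
    warns = []
    if np.any(np.abs(fit.params) > 15) or np.any(fit.bse > 50):
        warns.append("possible separation: diverging coefficients")
    p_lrt: dict[str, float] = {}
    p_wald = {
        t: float(2 * sps.norm.sf(abs(fit.params[t] / fit.bse[t])))
        for t in Xc.columns
    }
    if compute_lrt:
        for term in Xc.columns:
            if term == "const":
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sub = sm.GLM(
                    endog, Xc.drop(columns=term), family=sm.families.Binomial()
                ).fit()
            lr = 2.0 * (fit.llf - sub.llf)
            p_lrt[term] = float(sps.chi2.sf(max(lr, 0.0), df=1))
    mu = fit.fittedvalues
    pearson = np.sum(
        (y - n_trials * mu) ** 2 / np.maximum(n_trials * mu * (1 - mu), 1e-12)
    )
    df_resid = max(len(y) - Xc.shape[1], 1)
    vif = compute_vif(Xc.drop(columns="const")) if Xc.shape[1] > 2 else {}
    return ModelFit(
        terms=list(Xc.columns),
        estimates=fit.params.to_numpy(),
        se=fit.bse.to_numpy(),
        p_lrt=p_lrt,
        p_wald=p_wald,
        converged=bool(fit.converged),
        loglik=float(fit.llf),
        n=len(y),
        vif=vif,
        dropped_columns=dropped,
        dispersion_ratio=float(pearson / df_resid),
        warnings=warns,
    )


# ---------------------------------------------------------------------------
# binomial GLMM: single random intercept, adaptive Gauss-Hermite
# ---------------------------------------------------------------------------

def _group_loglik_agh(
    beta: np.ndarray,
    log_sigma: float,
    Xg: np.ndarray,
    yg: np.ndarray,
    ng: np.ndarray,
    nodes: np.ndarray,
    weights: np.ndarray,
) -> float:
    """log marginal likelihood of one group by adaptive Gauss-Hermite.

    The integrand h(u) = N(u; 0, sigma^2) * prod_j Binom(y_j | n_j, expit(eta_j + u))
    is integrated after centering/scaling the probabilists' Hermite nodes at
    the mode and curvature of log h.
    """
    sigma = np.exp(log_sigma)
    eta0 = Xg @ beta

    def neg_log_h(u: float) -> float:
        eta = eta0 + u
        ll = np.sum(yg * eta - ng * np.logaddexp(0.0, eta))
        return -(ll - 0.5 * u * u / (sigma * sigma))

    # Newton iterations for the mode
    u = 0.0
    for _ in range(50):
        p = special.expit(eta0 + u)
        g = np.sum(yg - ng * p) - u / (sigma * sigma)
        h = -np.sum(ng * p * (1 - p)) - 1.0 / (sigma * sigma)
        step = -g / h
        u_new = u + step
        if not np.isfinite(u_new):
            break
        u = u_new
        if abs(step) < 1e-10:
            break
    p = special.expit(eta0 + u)
    curv = np.sum(ng * p * (1 - p)) + 1.0 / (sigma * sigma)
    tau = 1.0 / np.sqrt(curv)
    # probabilists' nodes: int f(u) du ~= tau * sum w_k e^{z_k^2/2} f(u + tau z_k)
    z = u + tau * nodes
    etaz = eta0[:, None] + z[None, :]
    ll_obs = np.sum(
        yg[:, None] * etaz - ng[:, None] * np.logaddexp(0.0, etaz), axis=0
    )
    log_prior = -0.5 * z * z / (sigma * sigma) - 0.5 * np.log(
        2 * np.pi * sigma * sigma
    )
    log_terms = (
        np.log(weights) + 0.5 * nodes**2 + ll_obs + log_prior + np.log(tau)
    )
    return float(special.logsumexp(log_terms))


def _glmm_loglik(
    params: np.ndarray, X: np.ndarray, y: np.ndarray, n: np.ndarray,
    group_idx: list[np.ndarray], nodes: np.ndarray, weights: np.ndarray,
) -> float:
    beta, log_sigma = params[:-1], params[-1]
    return sum(
        _group_loglik_agh(beta, log_sigma, X[g], y[g], n[g], nodes, weights)
        for g in group_idx
    )


def _group_loglik_grad_agh(
    beta: np.ndarray,
    log_sigma: float,
    Xg: np.ndarray,
    yg: np.ndarray,
    ng: np.ndarray,
    nodes: np.ndarray,
    weights: np.ndarray,
) -> tuple[float, np.ndarray]:
    """(log marginal likelihood, gradient wrt (beta, log_sigma)) per group.

    The gradient is the posterior expectation of the complete-data score,
    evaluated with the same adaptive quadrature as the likelihood.
    """
    sigma = np.exp(log_sigma)
    eta0 = Xg @ beta
    u = 0.0
    for _ in range(50):
        p = special.expit(eta0 + u)
        g = np.sum(yg - ng * p) - u / (sigma * sigma)
        h = -np.sum(ng * p * (1 - p)) - 1.0 / (sigma * sigma)
        step = -g / h
        if not np.isfinite(step):
            break
        u += step
        if abs(step) < 1e-10:
            break
    p = special.expit(eta0 + u)
    curv = np.sum(ng * p * (1 - p)) + 1.0 / (sigma * sigma)
    tau = 1.0 / np.sqrt(curv)
    z = u + tau * nodes
    etaz = eta0[:, None] + z[None, :]
    pz = special.expit(etaz)
    ll_obs = np.sum(yg[:, None] * etaz - ng[:, None] * np.logaddexp(0.0, etaz),
                    axis=0)
    log_prior = -0.5 * z * z / (sigma * sigma) - 0.5 * np.log(
        2 * np.pi * sigma * sigma
    )
    log_terms = np.log(weights) + 0.5 * nodes**2 + ll_obs + log_prior + np.log(tau)
    ll = float(special.logsumexp(log_terms))
    w_post = np.exp(log_terms - ll)
    resid = yg[:, None] - ng[:, None] * pz        # (n_obs, n_nodes)
    g_beta = Xg.T @ (resid @ w_post)
    g_logsig = float(np.sum(w_post * (z * z / (sigma * sigma) - 1.0)))
    return ll, np.append(g_beta, g_logsig)


def _glmm_loglik_grad(
    params: np.ndarray, X: np.ndarray, y: np.ndarray, n: np.ndarray,
    group_idx: list[np.ndarray], nodes: np.ndarray, weights: np.ndarray,
) -> tuple[float, np.ndarray]:
    beta, log_sigma = params[:-1], params[-1]
    total_ll = 0.0
    total_grad = np.zeros_like(params)
    for g in group_idx:
        ll, grad = _group_loglik_grad_agh(
            beta, log_sigma, X[g], y[g], n[g], nodes, weights
        )
        total_ll += ll
        total_grad += grad
    return total_ll, total_grad


def glmm_binomial(
    y,
    X: pd.DataFrame,
    groups,
    trials=None,
    n_quad: int = 15,
    compute_lrt: bool = True,
) -> ModelFit:
    """Binomial-logit mixed model with one random intercept.

    Maximises the marginal likelihood integrated over the group intercepts
    by adaptive Gauss-Hermite quadrature (``n_quad`` nodes; 1 node is the
    Laplace approximation).  On optimisation failure the fixed-effects GLM
    is returned with ``random_term_dropped=True`` — never silently.
    """
    y, n_trials = _binom_response(y, trials)
    groups = pd.Series(list(groups))
    if groups.nunique() < 2:
        raise ValueError("need at least 2 groups for a random intercept")
    Xc, dropped = _prepare_design(X)
    Xm = Xc.to_numpy()
    codes = groups.astype("category").cat.codes.to_numpy()
    group_idx = [np.where(codes == g)[0] for g in range(codes.max() + 1)]
    nodes, weights = hermegauss(n_quad)

    # start from the GLM solution
    glm_fit = glm_binomial(y, X, trials=trials, compute_lrt=False)
    beta0 = np.zeros(Xm.shape[1])
    for i, t in enumerate(Xc.columns):
        if t in glm_fit.terms:
            beta0[i] = glm_fit.coef(t)
    x0 = np.append(beta0, np.log(0.5))

    def nll(params):
        try:
            return -_glmm_loglik(
                params, Xm, y, n_trials, group_idx, nodes, weights
            )
        except (FloatingPointError, OverflowError):
            return 1e12

    def nll_grad(params):
        try:
            ll, grad = _glmm_loglik_grad(
                params, Xm, y, n_trials, group_idx, nodes, weights
            )
            return -ll, -grad
        except (FloatingPointError, OverflowError):
            return 1e12, np.zeros_like(params)

    with np.errstate(all="ignore"):
        res = optimize.minimize(nll_grad, x0, jac=True, method="L-BFGS-B",
                                options={"maxiter": 500, "gtol": 1e-7})
        if not res.success:
            res2 = optimize.minimize(nll, res.x, method="Nelder-Mead",
                                     options={"maxiter": 2000, "fatol": 1e-9})
            if res2.fun <= res.fun:
                res = res2
    if not np.isfinite(res.fun):
        fallback = glm_binomial(y, X, trials=trials, compute_lrt=compute_lrt)
        fallback.random_term_dropped = True
        fallback.warnings.append("GLMM did not converge; random term dropped")
        return fallback

    params_hat = res.x
    ll = -float(res.fun)
    sigma2 = float(np.exp(2 * params_hat[-1]))

    # Wald SEs from a central-difference Hessian of the fixed effects
    k = Xm.shape[1]
    eps = 1e-4
    hess = np.zeros((k, k))
    for i in range(k):
        for j in range(i, k):
            pp = params_hat.copy(); pp[i] += eps; pp[j] += eps
            pm = params_hat.copy(); pm[i] += eps; pm[j] -= eps
            mp = params_hat.copy(); mp[i] -= eps; mp[j] += eps
            mm = params_hat.copy(); mm[i] -= eps; mm[j] -= eps
            hess[i, j] = hess[j, i] = (
                nll(pp) - nll(pm) - nll(mp) + nll(mm)
            ) / (4 * eps * eps)
    try:
        cov = np.linalg.inv(hess)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
        se_ok = np.all(np.isfinite(se)) and np.all(se > 0)
    except np.linalg.LinAlgError:
        se = np.full(k, np.nan)
        se_ok = False
    converged = bool(res.success or se_ok)
    if not converged:
        fallback = glm_binomial(y, X, trials=trials, compute_lrt=compute_lrt)
        fallback.random_term_dropped = True
        fallback.warnings.append("GLMM did not converge; random term dropped")
        return fallback

    p_wald = {
        t: float(2 * sps.norm.sf(abs(params_hat[i] / se[i]))) if se[i] > 0 else np.nan
        for i, t in enumerate(Xc.columns)
    }
    p_lrt: dict[str, float] = {}
    if compute_lrt:
        for term in Xc.columns:
            if term == "const":
                continue
            keep = [c for c in Xc.columns if c != term]
            Xs = Xc[keep].to_numpy()
            bs0 = np.append(
                params_hat[[Xc.columns.get_loc(c) for c in keep]],
                params_hat[-1],
            )

            def nll_sub_grad(params, Xs=Xs):
                try:
                    ll_s, grad = _glmm_loglik_grad(
                        params, Xs, y, n_trials, group_idx, nodes, weights
                    )
                    return -ll_s, -grad
                except (FloatingPointError, OverflowError):
                    return 1e12, np.zeros_like(params)

            with np.errstate(all="ignore"):
                sub = optimize.minimize(nll_sub_grad, bs0, jac=True,
                                        method="L-BFGS-B",
                                        options={"maxiter": 500, "gtol": 1e-7})
                ll_sub = -float(sub.fun)
            lr = 2.0 * (ll - ll_sub)
            p_lrt[term] = float(sps.chi2.sf(max(lr, 0.0), df=1))

    vif = compute_vif(Xc.drop(columns="const")) if Xc.shape[1] > 2 else {}
    return ModelFit(
        terms=list(Xc.columns),
        estimates=params_hat[:-1],
        se=se,
        p_lrt=p_lrt,
        p_wald=p_wald,
        converged=True,
        loglik=ll,
        n=len(y),
        random_intercept_var=sigma2,
        vif=vif,
        dropped_columns=dropped,
    )


# ---------------------------------------------------------------------------
# diagnostics and covariates
# ---------------------------------------------------------------------------

def compute_vif(X: pd.DataFrame) -> dict[str, float]:
    """Variance inflation factor 1/(1-R^2) per predictor.

    Perfect collinearity yields ``inf`` for the offending columns.
    """
    X = X.astype(float)
    if X.shape[1] < 2:
        raise ValueError("VIF needs at least 2 predictors")
    out = {}
    for colname in X.columns:
        others = sm.add_constant(X.drop(columns=colname), has_constant="add")
        fit = sm.OLS(X[colname], others).fit()
        r2 = min(fit.rsquared, 1.0)
        out[colname] = float("inf") if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def scaled_mass_index(
    mass, tarsus, reference_length: float | None = None
) -> np.ndarray:
    """Scaled mass index: mass standardised to a reference tarsus length.

    SMI_i = mass_i * (L0 / tarsus_i) ** b_SMA, where b_SMA is the
    standardised-major-axis slope of ln(mass) on ln(tarsus) (OLS slope
    divided by Pearson r) and L0 defaults to the sample mean tarsus.
    """
    mass = np.asarray(mass, dtype=float)
    tarsus = np.asarray(tarsus, dtype=float)
    if np.any(mass <= 0) or np.any(tarsus <= 0):
        raise ValueError("mass and tarsus must be positive")
    if reference_length is None:
        reference_length = float(np.mean(tarsus))
    lm, lt = np.log(mass), np.log(tarsus)
    if np.std(lt) == 0 or np.std(lm) == 0:
        # identical individuals keep their mass; anything else has an
        # undefined allometric slope
        if np.std(lt) == 0 and np.std(lm) == 0 and np.allclose(
            tarsus, reference_length
        ):
            return mass.copy()
        raise ValueError("SMA slope undefined: zero variance in mass or tarsus")
    r = np.corrcoef(lm, lt)[0, 1]
    if abs(r) < 1e-8:
        raise ValueError("SMA slope undefined: |r| ~ 0 between ln mass and ln tarsus")
    b_ols = np.cov(lm, lt, ddof=1)[0, 1] / np.var(lt, ddof=1)
    b_sma = b_ols / r
    return mass * (reference_length / tarsus) ** b_sma


# ---------------------------------------------------------------------------
# the full model battery
# ---------------------------------------------------------------------------

def run_model_battery(
    calls,
    metrics: pd.DataFrame,
    records: pd.DataFrame,
    offspring: pd.DataFrame | None = None,
    min_sampled_fraction: float = 0.5,
    interaction_drop_p: float = 0.05,
) -> dict:
    """Fit the nest- and individual-level model battery on one species.

    Filters applied before fitting: first clutches only; proportion models
    exclude nests whose social father was unsampled and nests with less
    than ``min_sampled_fraction`` of the clutch sampled; spatiotemporal
    covariates are z-scaled within the modelling dataset.

    Returns a dict with keys ``occurrence`` (models a/b/c), ``proportion``
    (models a/b/c), ``individual`` and ``fledging`` (each a
    :class:`ModelFit` or None), plus a ``filter_ledger``.
    """
    rec = records.copy()
    ledger = {"n_nests_in": len(rec)}
    if "first_clutch" in rec.columns:
        rec = rec[rec["first_clutch"].astype(bool)]
    ledger["n_first_clutch"] = len(rec)

    nest_epp = calls.nest_epp.set_index("nest_id")
    metrics = metrics.set_index("nest_id")
    rec = rec.set_index("nest_id")

    spat_cols = [("nnd", "a"), ("density_r1", "b"), ("sync_density_r1", "c")]
    df = rec.join(metrics[[c for c, _ in spat_cols]], how="inner").join(
        nest_epp[["epp", "n_epo", "n_called", "source"]], how="left"
    )
    df["cavity"] = (df["cavity_type"] == "nestbox").astype(float)

    occ = df[df["epp"].notna()].copy()
    if len(occ) == 0:
        raise ValueError("occurrence models: no nests with EPP information")
    if occ["epp"].astype(bool).nunique() < 2:
        raise ValueError("occurrence models: zero-variance EPP response")
    ledger["n_occurrence"] = len(occ)

    occurrence = {}
    for colname, tag in spat_cols:
        X = pd.DataFrame(
            {
                colname: zscale(occ[colname]),
                "cavity": occ["cavity"],
                "laying_date": zscale(occ["laying_date"]),
                "clutch_size": occ["clutch_size"].astype(float),
            },
            index=occ.index,
        )
        occurrence[tag] = glmm_binomial(
            occ["epp"].astype(float).to_numpy(), X, occ["mother_id"]
        )

    prop = df[(df["source"] == "father_calls") & df["n_called"].notna()].copy()
    if "father_sampled" in prop.columns:
        prop = prop[prop["father_sampled"].astype(bool)]
    prop = prop[
        prop["n_called"] >= min_sampled_fraction * prop["clutch_size"]
    ]
    ledger["n_proportion"] = len(prop)
    proportion = {}
    if len(prop) >= 10 and prop["n_epo"].astype(float).sum() > 0:
        for colname, tag in spat_cols:
            X = pd.DataFrame(
                {
                    colname: zscale(prop[colname]),
                    "cavity": prop["cavity"],
                    "laying_date": zscale(prop["laying_date"]),
                    "clutch_size": prop["clutch_size"].astype(float),
                },
                index=prop.index,
            )
            proportion[tag] = glmm_binomial(
                prop["n_epo"].astype(float).to_numpy(),
                X,
                prop["mother_id"],
                trials=prop["n_called"].astype(float).to_numpy(),
            )
    else:
        ledger["proportion_skipped"] = "too few informative nests"

    individual = None
    fledging = None
    if offspring is not None:
        status = calls.offspring_status.set_index("offspring")["status"]
        ind = offspring.copy()
        if "id" in ind.columns:
            ind = ind.set_index("id")
        ind = ind.join(status.rename("status"), how="inner")
        ind = ind[ind["status"].isin(["wpo", "epo"])]
        ind = ind.join(
            rec[["laying_date", "clutch_size"]], on="nest_id", how="left"
        )
        ind["cavity"] = (ind["cavity_type"] == "nestbox").astype(float)
        ind["is_male"] = (ind["sex"] == "M").astype(float)
        ind["body_index"] = scaled_mass_index(ind["mass"], ind["tarsus"])
        ledger["n_individual"] = len(ind)
        if len(ind) >= 30 and ind["status"].nunique() == 2:
            y = (ind["status"] == "epo").astype(float).to_numpy()
            base = pd.DataFrame(
                {
                    "cavity": ind["cavity"],
                    "year": ind["year"].astype(float),
                    "sex": ind["is_male"],
                    "laying_date": zscale(ind["laying_date"]),
                    "clutch_size": ind["clutch_size"].astype(float),
                    "body_index": zscale(ind["body_index"]),
                },
                index=ind.index,
            )
            Xint = base.assign(cavity_x_sex=base["cavity"] * base["sex"])
            fit = glmm_binomial(y, Xint, ind["nest_id"])
            if (
                "cavity_x_sex" in fit.p_lrt
                and fit.p_lrt["cavity_x_sex"] > interaction_drop_p
            ):
                fit = glmm_binomial(y, base, ind["nest_id"])
                fit.warnings.append("cavity x sex interaction dropped (p > 0.05)")
            individual = fit
            if ind["fledged"].astype(bool).nunique() == 2:
                Xf = base.assign(ep_status=y)
                fledging = glmm_binomial(
                    ind["fledged"].astype(float).to_numpy(), Xf, ind["nest_id"]
                )
            else:
                ledger["fledging_skipped"] = "zero-variance fledging response"
        else:
            ledger["individual_skipped"] = "too few offspring with calls"

    return {
        "occurrence": occurrence,
        "proportion": proportion,
        "individual": individual,
        "fledging": fledging,
        "filter_ledger": ledger,
    }
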