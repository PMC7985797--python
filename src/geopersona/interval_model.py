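"""Random-effects interval regression by Gauss–Hermite quadrature.

Model: for county i in year t, a latent Gaussian outcome

    y*_it = x_it' beta + u_i + e_it,   u_i ~ N(0, sigma_u^2),  e_it ~ N(0, sigma_e^2)

is observed either exactly or only as an interval [lower, upper] (suppressed
small counts are released as [0, threshold-1]; bounds may be infinite).  An
exact record contributes a normal density, a censored record a CDF
difference, and the county random effect is integrated out of each county's
product of contributions with Gauss–Hermite quadrature after the change of
variables u = sqrt(2) * sigma_u * x.  Variances are optimized on the log
scale, so they are non-negative by construction.

Standard errors come from the inverse numerical Hessian by default, or from a
county-cluster bootstrap (whole counties resampled with replacement).  A
within-transformation fixed-effects estimator on the exactly observed
subsample is provided as a robustness check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy.optimize import minimize
from scipy.special import logsumexp, ndtr
from scipy.stats import norm
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted
from statsmodels.tools.numdiff import approx_hess

from geopersona.errors import DataError, DesignError

_LOG_SQRT_PI = 0.5 * np.log(np.pi)


def gh_nodes(K: int) -> tuple[np.ndarray, np.ndarray]:
    """Gauss–Hermite abscissae and weights for integrals against exp(-x^2)."""
    if K < 1:
        raise ValueError("need at least one quadrature node")
    return hermgauss(K)


def _interval_logprob(zl: np.ndarray, zu: np.ndarray) -> np.ndarray:
    """log(Phi(zu) - Phi(zl)), stable in both tails.

    Mirrors the upper tail onto the lower one (Phi(zu)-Phi(zl) =
    Phi(-zl)-Phi(-zu)) so the difference is always between small CDF values.
    """
    flip = zu > -zl  # i.e. zl + zu > 0, written to avoid inf - inf
    a = np.where(flip, -zu, zl)
    b = np.where(flip, -zl, zu)
    p = ndtr(b) - ndtr(a)
    return np.log(np.clip(p, 1e-300, None))


def _log_contrib(
    mu: np.ndarray,
    lower: np.ndarray,
    upper: np.ndarray,
    exact: np.ndarray,
    sigma_e: float,
) -> np.ndarray:
    """Per-record log contribution given the conditional mean mu.

    ``mu`` is (n,) or (n, K); the bound/flag arrays are (n,) and broadcast
    across quadrature nodes.
    """
    if mu.ndim == 2:
        lower, upper, exact = lower[:, None], upper[:, None], exact[:, None]
    with np.errstate(invalid="ignore"):
        zl = np.where(np.isneginf(lower), -np.inf, (lower - mu) / sigma_e)
        zu = np.where(np.isposinf(upper), np.inf, (upper - mu) / sigma_e)
        logpdf = norm.logpdf(np.where(exact, lower, 0.0), loc=mu, scale=sigma_e)
    return np.where(
        np.broadcast_to(exact, mu.shape),
        logpdf,
        _interval_logprob(zl, zu),
    )


def county_loglik(
    X: np.ndarray,
    lower: np.ndarray,
    upper: np.ndarray,
    observed_exact: np.ndarray,
    beta: np.ndarray,
    sigma_u: float,
    sigma_e: float,
    K: int = 20,
) -> float:
    """Log-likelihood of one county block, random effect integrated out by GH.

    With ``sigma_u == 0`` the integral short-circuits to the product of
    marginal contributions.  A zero-width interval is treated as exact.
    """
    lower = np.asarray(lower, float)
    upper = np.asarray(upper, float)
    if np.any(upper < lower):
        raise DataError("upper < lower in outcome intervals")
    exact = np.asarray(observed_exact, bool) | (lower == upper)
    mu = np.asarray(X, float) @ np.asarray(beta, float)
    if sigma_u == 0:
        return float(_log_contrib(mu, lower, upper, exact, sigma_e).sum())
    nodes, weights = gh_nodes(K)
    u = np.sqrt(2.0) * sigma_u * nodes  # (K,)
    logg = _log_contrib(mu[:, None] + u[None, :], lower, upper, exact, sigma_e)
    s = logg.sum(axis=0)  # (K,)
    return float(logsumexp(s + np.log(weights)) - _LOG_SQRT_PI)


def _total_negloglik(
    theta: np.ndarray,
    X: np.ndarray,
    lower: np.ndarray,
    upper: np.ndarray,
    exact: np.ndarray,
    block_starts: np.ndarray,
    K: int,
    random_effects: bool,
) -> float:
    p = X.shape[1]
    beta = theta[:p]
    sigma_e = np.exp(theta[p + 1]) if random_effects else np.exp(theta[p])
    mu = X @ beta
    if not random_effects:
        return -float(_log_contrib(mu, lower, upper, exact, sigma_e).sum())
    sigma_u = np.exp(theta[p])
    nodes, weights = gh_nodes(K)
    u = np.sqrt(2.0) * sigma_u * nodes
    logg = _log_contrib(mu[:, None] + u[None, :], lower, upper, exact, sigma_e)
    s = np.add.reduceat(logg, block_starts, axis=0)  # (n_counties, K)
    ll = logsumexp(s + np.log(weights)[None, :], axis=1) - _LOG_SQRT_PI
    return -float(ll.sum())


@dataclass
class IntervalREFit:
    """Fit summary for the panel interval model."""

    params: pd.Series  # coefficients, named
    sigma_u: float
    sigma_e: float
    loglik: float
    aic: float
    bic: float
    se: pd.Series
    se_method: str
    converged: bool
    n_obs: int
    n_counties: int
    quadrature_nodes: int

    def summary_dict(self) -> dict:
        return {
            "loglik": self.loglik,
            "aic": self.aic,
            "bic": self.bic,
            "sigma_u": self.sigma_u,
            "sigma_e": self.sigma_e,
            "n_obs": self.n_obs,
            "n_counties": self.n_counties,
            "converged": self.converged,
            "se_method": self.se_method,
        }


class IntervalRandomEffectsRegressor(BaseEstimator, RegressorMixin):
    """Scikit-learn estimator for Gaussian interval regression with random effects.

    Parameters
    ----------
    K : number of Gauss–Hermite quadrature nodes (default 20; doubling it
        should leave the log-likelihood essentially unchanged on a healthy
        fit — see ``loglik_at``).
    tol : gradient-based convergence tolerance, scaled by max(1, |loglik|).
    random_effects : set False to fix sigma_u at 0 (pooled interval model).
    fit_intercept : prepend an intercept column.
    max_iter : optimizer iteration cap.

    ``fit(X, y, groups=...)`` takes ``y`` of shape (n, 2) as [lower, upper]
    bounds (equal where observed exactly; +/-inf allowed) or shape (n,) for
    fully exact outcomes; ``groups`` are county labels.

    Fitted attributes: ``coef_``, ``intercept_``, ``sigma_u_``, ``sigma_e_``,
    ``loglik_``, ``aic_``, ``bic_``, ``se_``, ``converged_``, ``n_obs_``,
    ``n_counties_``.
    """

    def __init__(
        self,
        K: int = 20,
        tol: float = 1e-6,
        random_effects: bool = True,
        fit_intercept: bool = True,
        max_iter: int = 500,
    ):
        self.K = K
        self.tol = tol
        self.random_effects = random_effects
        self.fit_intercept = fit_intercept
        self.max_iter = max_iter

    # ------------------------------------------------------------------
    def _prepare(self, X, y, groups):
        X = np.asarray(X, float)
        if X.ndim != 2:
            raise DesignError("X must be 2-D")
        y = np.asarray(y, float)
        if y.ndim == 1:
            y = np.column_stack([y, y])
        lower, upper = y[:, 0], y[:, 1]
        if np.any(upper < lower):
            raise DataError("upper < lower in outcome intervals")
        exact = lower == upper
        if groups is None:
            groups = np.arange(len(lower))
        groups = np.asarray(groups)
        if self.fit_intercept:
            X = np.column_stack([np.ones(len(X)), X])
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            raise DesignError(
                f"design matrix is rank deficient (rank {rank} < {X.shape[1]})"
            )
        order = np.argsort(groups, kind="stable")
        X, lower, upper, exact, groups = (
            X[order], lower[order], upper[order], exact[order], groups[order],
        )
        starts = np.flatnonzero(
            np.r_[True, groups[1:] != groups[:-1]]
        )
        return X, lower, upper, exact, groups, starts, order

    def _start_values(self, X, lower, upper, exact, groups):
        mid = np.where(
            np.isposinf(upper), lower + 1.0,
            np.where(np.isneginf(lower), upper - 1.0, 0.5 * (lower + upper)),
        )
        beta0, *_ = np.linalg.lstsq(X, mid, rcond=None)
        resid = mid - X @ beta0
        s_tot = max(resid.std(), 0.1)
        gmeans = pd.Series(resid).groupby(pd.Series(groups)).mean()
        nbar = len(resid) / len(gmeans)
        s_b2 = max(gmeans.to_numpy().std() ** 2 - s_tot**2 / nbar, 0.01)
        sigma_u0 = np.sqrt(s_b2)
        sigma_e0 = np.sqrt(max(s_tot**2 - s_b2, 0.04))
        return beta0, sigma_u0, sigma_e0

    def fit(self, X, y, groups=None):
        Xs, lower, upper, exact, groups_s, starts, _ = self._prepare(X, y, groups)
        p = Xs.shape[1]
        # standardize columns for the optimizer: regressors on wildly
        # different scales (percentiles, word counts, component scores) make
        # the likelihood badly conditioned otherwise; coefficients and the
        # covariance are mapped back afterwards
        means = Xs.mean(axis=0)
        sds = Xs.std(axis=0)
        if self.fit_intercept:
            means[0], sds[0] = 0.0, 1.0
        else:
            means[:] = 0.0
        sds[sds == 0] = 1.0
        Xz = (Xs - means) / sds
        beta0, su0, se0 = self._start_values(Xz, lower, upper, exact, groups_s)
        if self.random_effects:
            theta0 = np.r_[beta0, np.log(su0), np.log(se0)]
        else:
            theta0 = np.r_[beta0, np.log(se0)]
        args = (Xz, lower, upper, exact, starts, self.K, self.random_effects)
        res = minimize(
            _total_negloglik,
            theta0,
            args=args,
            method="L-BFGS-B",
            options={"maxiter": self.max_iter, "ftol": 1e-12, "gtol": 1e-8},
        )
        # restart with a fresh Hessian approximation if the score is still
        # large relative to the likelihood; L-BFGS often stalls on ftol first
        for _ in range(2):
            if np.linalg.norm(res.jac, np.inf) < self.tol * max(1.0, abs(res.fun)):
                break
            res = minimize(
                _total_negloglik,
                res.x,
                args=args,
                method="L-BFGS-B",
                options={"maxiter": self.max_iter, "ftol": 1e-14, "gtol": 1e-9},
            )
        theta = res.x
        ll = -res.fun
        # gradient criterion scaled by the likelihood magnitude: the absolute
        # score of a well-converged fit grows with n, a fixed 1e-6 would not
        self.converged_ = bool(
            res.success
            and np.linalg.norm(res.jac, np.inf) < self.tol * max(1.0, abs(ll))
        )

        self._theta_ = theta
        self._args_ = args
        k = len(theta)
        # map standardized-space estimates back to the original columns:
        # beta_orig = A beta_std with A the (intercept-absorbing) rescaling
        A = np.eye(k)
        start = 1 if self.fit_intercept else 0
        for j in range(start, p):
            A[j, j] = 1.0 / sds[j]
            if self.fit_intercept:
                A[0, j] = -means[j] / sds[j]
        coef = (A[:p, :p] @ theta[:p])
        if self.fit_intercept:
            self.intercept_, self.coef_ = float(coef[0]), coef[1:]
        else:
            self.intercept_, self.coef_ = 0.0, coef
        if self.random_effects:
            self.sigma_u_ = float(np.exp(theta[p]))
            self.sigma_e_ = float(np.exp(theta[p + 1]))
        else:
            self.sigma_u_ = 0.0
            self.sigma_e_ = float(np.exp(theta[p]))
        self.loglik_ = float(ll)
        self.n_obs_ = len(lower)
        self.n_counties_ = len(starts)
        self.aic_ = float(-2 * ll + 2 * k)
        self.bic_ = float(-2 * ll + k * np.log(self.n_obs_))
        self.se_ = self._hessian_se(theta, args, p, A)
        self.se_method_ = "hessian"
        self.n_features_in_ = np.asarray(X).shape[1]
        return self

    def _hessian_se(self, theta, args, p, A) -> np.ndarray:
        """Coefficient SEs from the inverse numerical Hessian (NaN on failure).

        The Hessian is computed in the well-conditioned standardized space
        and the covariance mapped back through the rescaling matrix A.
        """
        try:
            H = approx_hess(theta, _total_negloglik, args=args)
            cov = A @ np.linalg.inv(H) @ A.T
            var = np.diag(cov)[:p].copy()
            var[var < 0] = np.nan
            return np.sqrt(var)
        except np.linalg.LinAlgError:
            return np.full(p, np.nan)

    def predict(self, X):
        check_is_fitted(self, "coef_")
        return self.intercept_ + np.asarray(X, float) @ self.coef_

    def loglik_at(self, K: int) -> float:
        """Re-evaluate the maximized log-likelihood with K quadrature nodes."""
        check_is_fitted(self, "_theta_")
        Xs, lower, upper, exact, starts, _, re_flag = self._args_
        return -_total_negloglik(
            self._theta_, Xs, lower, upper, exact, starts, K, re_flag
        )


# ---------------------------------------------------------------------------
# functional wrappers over the estimator


def fit_interval_re(
    panel: pd.DataFrame,
    regressors: list[str],
    K: int = 20,
    tol: float = 1e-6,
    random_effects: bool = True,
    year_dummies: bool = True,
    suppressed_bounds: str = "latent",
) -> IntervalREFit:
    """Fit the panel interval model from a tidy panel DataFrame.

    ``panel`` needs columns ``fips, year, lower, upper`` plus the named
    regressors.  Year dummies use the earliest year as reference.

    ``suppressed_bounds`` controls how censored rows (``observed_exact``
    False) map onto latent-scale bounds.  Reported counts are floored at
    zero, so a suppressed count in [0, 9] constrains the latent outcome only
    from above (y* < upper + 0.5); the default ``"latent"`` uses
    (-inf, upper + 0.5) accordingly.  ``"literal"`` evaluates the released
    interval [lower, upper] as given, the convention mortality tables print.
    """
    X, names = design_matrix(panel, regressors, year_dummies=year_dummies)
    y = panel[["lower", "upper"]].to_numpy(float)
    if suppressed_bounds not in ("latent", "literal"):
        raise ValueError("suppressed_bounds must be 'latent' or 'literal'")
    if suppressed_bounds == "latent" and "observed_exact" in panel.columns:
        censored = ~panel["observed_exact"].to_numpy(bool)
        y = y.copy()
        y[censored, 0] = -np.inf
        y[censored, 1] = y[censored, 1] + 0.5
    est = IntervalRandomEffectsRegressor(
        K=K, tol=tol, random_effects=random_effects, fit_intercept=True
    ).fit(X, y, groups=panel["fips"].to_numpy())
    full_names = ["intercept", *names]
    params = pd.Series(np.r_[est.intercept_, est.coef_], index=full_names)
    return IntervalREFit(
        params=params,
        sigma_u=est.sigma_u_,
        sigma_e=est.sigma_e_,
        loglik=est.loglik_,
        aic=est.aic_,
        bic=est.bic_,
        se=pd.Series(est.se_, index=full_names),
        se_method="hessian",
        converged=est.converged_,
        n_obs=est.n_obs_,
        n_counties=est.n_counties_,
        quadrature_nodes=K,
    )


def design_matrix(
    panel: pd.DataFrame, regressors: list[str], year_dummies: bool = True
) -> tuple[np.ndarray, list[str]]:
    """Stack regressor columns and reference-coded year indicators."""
    cols = [panel[c].to_numpy(float) for c in regressors]
    names = list(regressors)
    if year_dummies:
        years = sorted(panel["year"].unique())
        for yr in years[1:]:
            cols.append((panel["year"] == yr).to_numpy(float))
            names.append(f"year_{yr}")
    return np.column_stack(cols), names


def cluster_bootstrap(
    panel: pd.DataFrame,
    regressors: list[str],
    B: int = 200,
    seed: int = 0,
    K: int = 20,
    **fit_kwargs,
) -> pd.Series:
    """County-cluster bootstrap SEs: resample whole counties with replacement.

    Non-convergent replicates are dropped (with a warning if more than 10%
    are lost).  Deterministic under ``seed``.
    """
    import warnings

    if B < 2:
        raise ValueError("need at least 2 bootstrap replicates")
    rng = np.random.default_rng(seed)
    counties = panel["fips"].unique()
    blocks = {f: panel[panel["fips"] == f] for f in counties}
    estimates, dropped = [], 0
    for b in range(B):
        draw = rng.choice(counties, size=len(counties), replace=True)
        parts = []
        for j, f in enumerate(draw):
            blk = blocks[f].copy()
            blk["fips"] = f"{f}#{j}"  # resampled copies are distinct clusters
            parts.append(blk)
        boot = pd.concat(parts, ignore_index=True)
        fit = fit_interval_re(boot, regressors, K=K, **fit_kwargs)
        if fit.converged:
            estimates.append(fit.params)
        else:
            dropped += 1
    if dropped > 0.1 * B:
        warnings.warn(f"{dropped}/{B} bootstrap refits failed to converge")
    est = pd.DataFrame(estimates)
    return est.std(ddof=1)


def fit_fe_within(
    panel: pd.DataFrame, regressors: list[str], year_dummies: bool = True
) -> tuple[pd.Series, list[str]]:
    """Fixed-effects (within) OLS on the exactly observed subsample.

    County-demeans outcome and regressors over counties with >= 2 exact
    records; time-invariant columns (zero within-variance) are dropped and
    reported.  Returns ``(coefficients, dropped_columns)``.
    """
    sub = panel[panel["observed_exact"].astype(bool)].copy()
    counts = sub.groupby("fips")["year"].transform("count")
    sub = sub[counts >= 2]
    if sub.empty:
        raise DesignError("no county has >= 2 exactly observed records")
    X, names = design_matrix(sub, regressors, year_dummies=year_dummies)
    y = sub["lower"].to_numpy(float)
    codes = sub["fips"].astype("category").cat.codes.to_numpy()
    ng = codes.max() + 1
    cnt = np.bincount(codes, minlength=ng).astype(float)

    def demean(v):
        return v - (np.bincount(codes, weights=v, minlength=ng) / cnt)[codes]

    yd = demean(y)
    Xd = np.column_stack([demean(X[:, j]) for j in range(X.shape[1])])
    within_sd = Xd.std(axis=0)
    keep = within_sd > 1e-10
    dropped = [n for n, k in zip(names, keep) if not k]
    coefs, *_ = np.linalg.lstsq(Xd[:, keep], yd, rcond=None)
    return pd.Series(coefs, index=[n for n, k in zip(names, keep) if k]), dropped
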