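"""Two-stage control-function endogeneity correction with IV diagnostics.

County trait percentiles may be endogenous in the mortality equation (omitted
factors such as cultural norms plausibly move both).  The correction used
here instruments each trait with linguistic-style features: screen candidate
instruments (correlated with the trait, nearly uncorrelated with the outcome,
significant in the first stage), regress each trait on its instruments plus
all second-stage observables (pooled OLS, county-cluster-robust SEs), and add
the first-stage residuals to the interval model — the control-function
analogue of 2SLS that survives the nonlinear (censored) second stage.  On
linear, fully observed data the control-function point estimates coincide
with textbook 2SLS, which this module also implements as an independent
oracle.

Diagnostics mirror the weak-identification battery: Anderson
canonical-correlation underidentification LM test, Cragg–Donald
minimum-eigenvalue statistic against Stock–Yogo critical values, Sargan
overidentification test, and a Davidson–MacKinnon artificial-regression test
of endogeneity.  Classical IV tests assume an observed outcome, so all
diagnostics are computed with midpoint coding for any interval rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator

from geopersona.errors import DataError, DegenerateError, DesignError, ScreeningFailureError
from geopersona.interval_model import (
    IntervalREFit,
    design_matrix,
    fit_interval_re,
)
from geopersona.lexicon import TRAITS

#: Stock–Yogo critical values, single endogenous regressor, by instrument
#: count: 5% maximal 2SLS relative bias (defined for >= 3 instruments) and
#: 10% maximal 2SLS size (from the published Stock–Yogo tables).
STOCK_YOGO_BIAS_5PCT = {3: 13.91, 4: 16.85, 5: 18.37, 6: 19.28, 7: 19.86,
                        8: 20.25, 9: 20.53, 10: 20.74}
STOCK_YOGO_SIZE_10PCT = {1: 16.38, 2: 19.93, 3: 22.30, 4: 24.58, 5: 26.87,
                         6: 29.18, 7: 31.50, 8: 33.84, 9: 36.19, 10: 38.54}


def stock_yogo_critical(n_instruments: int) -> float | None:
    """5% relative-bias critical value, falling back to the 10% size table."""
    return STOCK_YOGO_BIAS_5PCT.get(
        n_instruments, STOCK_YOGO_SIZE_10PCT.get(n_instruments)
    )


def _annihilate(A: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Residuals of each column of A after OLS on C (with intercept)."""
    C1 = np.column_stack([np.ones(len(C)), C]) if C.size else np.ones((len(A), 1))
    coef, *_ = np.linalg.lstsq(C1, A, rcond=None)
    return A - C1 @ coef


@dataclass
class InstrumentSet:
    """Retained instruments per trait plus the full screening report."""

    instruments: dict[str, list[str]]
    report: pd.DataFrame  # trait, candidate, r_trait, r_outcome, first_stage_p, retained


def select_instruments(
    candidates: pd.DataFrame,
    traits: pd.DataFrame,
    outcome: np.ndarray,
    r_trait_min: float = 0.3,
    r_outcome_max: float = 0.1,
    alpha: float = 0.05,
) -> InstrumentSet:
    """Three-screen instrument selection, reported for every candidate.

    A candidate is retained for a trait when |corr(Z, trait)| >= r_trait_min,
    |corr(Z, outcome)| <= r_outcome_max, and its first-stage coefficient
    (trait on the candidate alone, with intercept) has p < alpha.
    """
    outcome = np.asarray(outcome, float)
    rows, retained = [], {t: [] for t in traits.columns}
    for trait in traits.columns:
        x = traits[trait].to_numpy(float)
        for cand in candidates.columns:
            z = candidates[cand].to_numpy(float)
            r_t = float(np.corrcoef(z, x)[0, 1])
            r_y = float(np.corrcoef(z, outcome)[0, 1])
            ols = sm.OLS(x, sm.add_constant(z)).fit()
            p = float(ols.pvalues[1])
            ok = abs(r_t) >= r_trait_min and abs(r_y) <= r_outcome_max and p < alpha
            rows.append(
                {"trait": trait, "candidate": cand, "r_trait": r_t,
                 "r_outcome": r_y, "first_stage_p": p, "retained": ok}
            )
            if ok:
                retained[trait].append(cand)
    failed = [t for t, z in retained.items() if not z]
    if failed:
        raise ScreeningFailureError(
            f"no instrument survived screening for trait(s): {failed}"
        )
    return InstrumentSet(instruments=retained, report=pd.DataFrame(rows))


@dataclass
class FirstStageFit:
    """Pooled OLS of one trait on [instruments, controls, year dummies]."""

    trait: str
    params: pd.Series
    se: pd.Series  # county-cluster robust
    residuals: np.ndarray
    r2: float
    partial_f: float
    instrument_names: list[str] = field(default_factory=list)


def first_stage(
    trait: str,
    panel: pd.DataFrame,
    instrument_cols: list[str],
    control_cols: list[str],
    year_dummies: bool = True,
) -> FirstStageFit:
    """Eq-2-style first stage with cluster-robust SEs and instrument partial F."""
    Xfull, names = design_matrix(
        panel, instrument_cols + control_cols, year_dummies=year_dummies
    )
    y = panel[trait].to_numpy(float)
    X1 = sm.add_constant(Xfull)
    if np.linalg.matrix_rank(X1) < X1.shape[1]:
        raise DesignError("first-stage design is rank deficient")
    res = sm.OLS(y, X1).fit(
        cov_type="cluster", cov_kwds={"groups": panel["fips"].to_numpy()}
    )
    # homoskedastic partial F of the instrument block (restricted vs full RSS)
    Xr, _ = design_matrix(panel, control_cols, year_dummies=year_dummies)
    res_r = sm.OLS(y, sm.add_constant(Xr)).fit()
    kz = len(instrument_cols)
    df_resid = len(y) - X1.shape[1]
    f = ((res_r.ssr - res.ssr) / kz) / (res.ssr / df_resid)
    idx = ["const", *names]
    return FirstStageFit(
        trait=trait,
        params=pd.Series(res.params, index=idx),
        se=pd.Series(res.bse, index=idx),
        residuals=np.asarray(res.resid),
        r2=float(res.rsquared),
        partial_f=float(f),
        instrument_names=list(instrument_cols),
    )


# ---------------------------------------------------------------------------
# diagnostics


def anderson_underid(
    endog: np.ndarray, Z: np.ndarray, C: np.ndarray
) -> tuple[float, float]:
    """Anderson canonical-correlation LM test of underidentification.

    stat = n * (smallest squared canonical correlation between the endogenous
    block and the instrument block, both partialled of controls), chi-square
    with df = k_Z - m + 1.
    """
    X = np.atleast_2d(np.asarray(endog, float).T).T
    Z = np.atleast_2d(np.asarray(Z, float).T).T
    n, m = X.shape
    kz = Z.shape[1]
    if kz < m:
        raise DesignError("need at least as many instruments as endogenous regressors")
    Xp = _annihilate(X, np.asarray(C, float))
    Zp = _annihilate(Z, np.asarray(C, float))
    Sxx = Xp.T @ Xp
    Szz = Zp.T @ Zp
    Sxz = Xp.T @ Zp
    try:
        M = np.linalg.solve(Sxx, Sxz) @ np.linalg.solve(Szz, Sxz.T)
    except np.linalg.LinAlgError as exc:
        raise DegenerateError("singular block in canonical correlation") from exc
    can2 = np.sort(np.real(np.linalg.eigvals(M)))
    r2min = float(np.clip(can2[0], 0.0, 1.0))
    stat = n * r2min
    df = kz - m + 1
    return float(stat), float(stats.chi2.sf(stat, df))


def cragg_donald(endog: np.ndarray, Z: np.ndarray, C: np.ndarray) -> float:
    """Cragg–Donald minimum-eigenvalue weak-instrument statistic.

    With one endogenous regressor this equals the first-stage partial F of
    the instrument block.
    """
    X = np.atleast_2d(np.asarray(endog, float).T).T
    Z = np.atleast_2d(np.asarray(Z, float).T).T
    n = X.shape[0]
    C = np.asarray(C, float)
    kc = C.shape[1] + 1 if C.size else 1
    kz = Z.shape[1]
    Xp = _annihilate(X, C)
    Zp = _annihilate(Z, C)
    coef, *_ = np.linalg.lstsq(Zp, Xp, rcond=None)
    Xhat = Zp @ coef
    S_hat = Xp.T @ Xhat                      # X'P_Z X
    S_res = Xp.T @ Xp - S_hat                # X'M_Z X
    dof = n - kc - kz
    try:
        eigs = np.real(np.linalg.eigvals(np.linalg.solve(S_res, S_hat)))
    except np.linalg.LinAlgError as exc:
        raise DegenerateError("singular concentration matrix") from exc
    return float(np.min(eigs) * dof / kz)


def sargan(
    resid_2sls: np.ndarray, Z: np.ndarray, C: np.ndarray, n_endog: int = 1
) -> tuple[float, int, float]:
    """Sargan overidentification test: n * R^2 of 2SLS residuals on [Z, C]."""
    Z = np.atleast_2d(np.asarray(Z, float).T).T
    df = Z.shape[1] - n_endog
    if df < 1:
        raise DesignError("Sargan test requires an overidentified model (df >= 1)")
    e = np.asarray(resid_2sls, float)
    W = sm.add_constant(np.column_stack([Z, np.asarray(C, float)]) if np.asarray(C).size else Z)
    r2 = sm.OLS(e, W).fit().rsquared
    stat = len(e) * float(r2)
    return stat, df, float(stats.chi2.sf(stat, df))


def davidson_mackinnon(
    outcome: np.ndarray,
    endog: np.ndarray,
    C: np.ndarray,
    first_stage_resids: np.ndarray,
) -> tuple[float, float]:
    """Artificial-regression endogeneity test (joint F on first-stage residuals).

    Regress the (midpoint-coded) outcome on [endogenous regressors, controls,
    first-stage residuals]; under exogeneity the residual coefficients are
    jointly zero.
    """
    X = np.atleast_2d(np.asarray(endog, float).T).T
    R = np.atleast_2d(np.asarray(first_stage_resids, float).T).T
    if np.allclose(R, 0.0):
        raise DegenerateError(
            "first-stage residuals are identically zero; endogeneity test degenerate"
        )
    C = np.asarray(C, float)
    blocks = [X] + ([C] if C.size else []) + [R]
    W = sm.add_constant(np.column_stack(blocks))
    res = sm.OLS(np.asarray(outcome, float), W).fit()
    kr = R.shape[1]
    contrast = np.zeros((kr, W.shape[1]))
    for j in range(kr):
        contrast[j, W.shape[1] - kr + j] = 1.0
    ftest = res.f_test(contrast)
    return float(ftest.fvalue), float(ftest.pvalue)


def two_sls(
    outcome: np.ndarray, endog: np.ndarray, Z: np.ndarray, C: np.ndarray
) -> np.ndarray:
    """Textbook 2SLS; the independent oracle for the control function.

    Structural regressors [1, X, C], instruments [1, Z, C].  Returns the
    coefficient vector in that order.  Also exposed so Sargan can consume its
    residuals.
    """
    X = np.atleast_2d(np.asarray(endog, float).T).T
    Z = np.atleast_2d(np.asarray(Z, float).T).T
    C = np.asarray(C, float)
    n = X.shape[0]
    W = np.column_stack([np.ones(n), X] + ([C] if C.size else []))
    Ins = np.column_stack([np.ones(n), Z] + ([C] if C.size else []))
    if Ins.shape[1] < W.shape[1]:
        raise DesignError("order condition failed: fewer instruments than regressors")
    coef_fs, *_ = np.linalg.lstsq(Ins, W, rcond=None)
    What = Ins @ coef_fs
    beta, *_ = np.linalg.lstsq(What.T @ W, What.T @ np.asarray(outcome, float), rcond=None)
    return beta


def linear_control_function(
    outcome: np.ndarray, endog: np.ndarray, Z: np.ndarray, C: np.ndarray
) -> np.ndarray:
    """Control function in the linear special case: OLS on [1, X, C, R].

    R are the first-stage residuals of X on [1, Z, C].  Algebraically, the
    coefficients on [1, X, C] coincide with 2SLS — the identity that anchors
    the interval-model control function.  Returns those coefficients in the
    same order as :func:`two_sls`.
    """
    X = np.atleast_2d(np.asarray(endog, float).T).T
    Z = np.atleast_2d(np.asarray(Z, float).T).T
    C = np.asarray(C, float)
    n = X.shape[0]
    Ins = np.column_stack([np.ones(n), Z] + ([C] if C.size else []))
    coef_fs, *_ = np.linalg.lstsq(Ins, X, rcond=None)
    R = X - Ins @ coef_fs
    W = np.column_stack([np.ones(n), X] + ([C] if C.size else []) + [R])
    beta, *_ = np.linalg.lstsq(W, np.asarray(outcome, float), rcond=None)
    return beta[: W.shape[1] - R.shape[1]]


@dataclass
class IVDiagnostics:
    trait: str
    anderson_stat: float
    anderson_p: float
    cragg_donald: float
    stock_yogo_crit: float | None
    sargan_stat: float
    sargan_df: int
    sargan_p: float
    dm_stat: float
    dm_p: float


def diagnose_trait(
    panel: pd.DataFrame,
    trait: str,
    instrument_cols: list[str],
    control_cols: list[str],
    year_dummies: bool = True,
) -> IVDiagnostics:
    """Table-4-style diagnostic row: one trait instrumented separately.

    Outcome intervals are midpoint-coded, since the classical tests assume an
    observed outcome.
    """
    y = midpoint_outcome(panel)
    x = panel[trait].to_numpy(float)
    Z, _ = design_matrix(panel, instrument_cols, year_dummies=False)
    C, _ = design_matrix(panel, control_cols, year_dummies=year_dummies)
    a_stat, a_p = anderson_underid(x, Z, C)
    cd = cragg_donald(x, Z, C)
    beta = two_sls(y, x, Z, C)
    W = np.column_stack([np.ones(len(y)), x, C])
    resid = y - W @ beta
    s_stat, s_df, s_p = sargan(resid, Z, C, n_endog=1)
    fs = first_stage(trait, panel, instrument_cols, control_cols, year_dummies)
    dm_stat, dm_p = davidson_mackinnon(y, x, C, fs.residuals)
    return IVDiagnostics(
        trait=trait,
        anderson_stat=a_stat,
        anderson_p=a_p,
        cragg_donald=cd,
        stock_yogo_crit=stock_yogo_critical(len(instrument_cols)),
        sargan_stat=s_stat,
        sargan_df=s_df,
        sargan_p=s_p,
        dm_stat=dm_stat,
        dm_p=dm_p,
    )


def midpoint_outcome(panel: pd.DataFrame) -> np.ndarray:
    """Interval midpoints (exact value where observed exactly)."""
    lower = panel["lower"].to_numpy(float)
    upper = panel["upper"].to_numpy(float)
    if np.any(upper < lower):
        raise DataError("upper < lower in outcome intervals")
    return np.where(np.isposinf(upper), lower, 0.5 * (lower + upper))


def cf_second_stage(
    panel: pd.DataFrame,
    residuals: pd.DataFrame,
    trait_cols: list[str],
    control_cols: list[str],
    K: int = 20,
    **fit_kwargs,
) -> IntervalREFit:
    """Interval RE fit on the design augmented with first-stage residuals.

    ``residuals`` has columns ``fips, year, resid_<trait>...``; rows of the
    panel lacking any residual are listwise-dropped (mirroring the reduced n
    of a residual-augmented model).
    """
    merged = panel.merge(residuals, on=["fips", "year"], how="left")
    resid_cols = [c for c in residuals.columns if c.startswith("resid_")]
    n_before = len(merged)
    merged = merged.dropna(subset=resid_cols)
    if merged.empty:
        raise DataError("no panel rows have complete first-stage residuals")
    fit = fit_interval_re(
        merged, trait_cols + control_cols + resid_cols, K=K, **fit_kwargs
    )
    fit.n_dropped = n_before - len(merged)  # type: ignore[attr-defined]
    return fit


class ControlFunctionRegressor(BaseEstimator):
    """Two-stage control-function estimator for the interval panel model.

    ``fit(panel)`` expects a tidy DataFrame with ``fips, year, lower, upper,
    observed_exact``, trait percentile columns, control columns and
    instrument columns.  Stage one regresses each trait on its instruments
    plus all controls; stage two refits the interval random-effects model
    with the residuals included.

    Parameters
    ----------
    trait_cols, control_cols : regressor names (traits default to the Big
        Five).
    instruments : mapping trait -> list of instrument column names.
    K : Gauss–Hermite nodes for the second stage.

    Fitted attributes: ``first_stages_`` (per trait), ``fit_`` (the augmented
    :class:`IntervalREFit`), ``diagnostics_`` (per-trait
    :class:`IVDiagnostics`).
    """

    def __init__(self, instruments=None, trait_cols=None, control_cols=None, K=20):
        self.instruments = instruments
        self.trait_cols = trait_cols
        self.control_cols = control_cols
        self.K = K

    def fit(self, panel: pd.DataFrame, y=None):
        traits = self.trait_cols or [t for t in TRAITS if t in panel.columns]
        controls = self.control_cols or []
        if self.instruments is None:
            raise DesignError("instruments mapping is required")
        self.first_stages_ = {}
        resid = panel[["fips", "year"]].copy()
        for trait in traits:
            fs = first_stage(trait, panel, list(self.instruments[trait]), controls)
            self.first_stages_[trait] = fs
            resid[f"resid_{trait}"] = fs.residuals
        self.residuals_ = resid
        self.fit_ = cf_second_stage(panel, resid, traits, controls, K=self.K)
        self.diagnostics_ = [
            diagnose_trait(panel, t, list(self.instruments[t]), controls)
            for t in traits
        ]
        return self

    def diagnostics_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(d) for d in self.diagnostics_])
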