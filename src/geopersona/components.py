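"""Alpha/beta superordinate personality components from facet matrices.

The Big Five literature groups facets into two higher-order dimensions —
*alpha* (stability: neuroticism, conscientiousness, agreeableness) and *beta*
(plasticity: extraversion, openness).  As county-level controls, facet scores
per dimension are screened (inter-item correlations), checked for sampling
adequacy (Kaiser–Meyer–Olkin) and internal consistency (Cronbach's alpha),
then reduced by PCA on the correlation matrix, retaining components with
eigenvalue strictly greater than 1 (Kaiser rule).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from geopersona.errors import DegenerateError, DesignError


def _as_matrix(M) -> np.ndarray:
    X = np.asarray(M, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise DesignError("facet matrix must be 2-D with >= 2 columns")
    if np.isnan(X).any():
        raise DesignError("facet matrix contains missing cells; apply listwise deletion first")
    return X


def listwise_delete(df: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Drop rows with any missing facet cell; returns (clean, n_dropped)."""
    clean = df.dropna(axis=0, how="any")
    return clean, len(df) - len(clean)


def _corr(X: np.ndarray) -> np.ndarray:
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise DegenerateError("constant facet column; correlation undefined")
    return np.corrcoef(X, rowvar=False)


def interitem_screen(M, threshold: float = 0.3) -> tuple[float, list[tuple[int, int, float]]]:
    """Share of pairwise |r| at or above ``threshold``, plus the below-threshold pairs.

    Returns ``(fraction, flags)`` where ``flags`` lists ``(i, j, r)`` for
    every pair whose |r| falls below the threshold.
    """
    R = _corr(_as_matrix(M))
    k = R.shape[0]
    iu = np.triu_indices(k, 1)
    absr = np.abs(R[iu])
    fraction = float(np.mean(absr >= threshold)) if absr.size else 1.0
    flags = [
        (int(i), int(j), float(R[i, j]))
        for i, j in zip(*iu)
        if abs(R[i, j]) < threshold
    ]
    return fraction, flags


def kmo(M) -> float:
    """Kaiser–Meyer–Olkin measure of sampling adequacy.

    KMO = sum r_ij^2 / (sum r_ij^2 + sum p_ij^2) over i != j, with p the
    anti-image partial correlations p_ij = -S_ij / sqrt(S_ii S_jj) from the
    inverse correlation matrix S = R^{-1}.
    """
    R = _corr(_as_matrix(M))
    try:
        S = np.linalg.inv(R)
    except np.linalg.LinAlgError as exc:
        raise DegenerateError("singular correlation matrix") from exc
    d = np.sqrt(np.outer(np.diag(S), np.diag(S)))
    P = -S / d
    off = ~np.eye(R.shape[0], dtype=bool)
    r2 = np.sum(R[off] ** 2)
    p2 = np.sum(P[off] ** 2)
    return float(r2 / (r2 + p2))


def cronbach(M) -> float:
    """Cronbach's alpha: k/(k-1) * (1 - sum item variances / variance of sums)."""
    X = _as_matrix(M)
    k = X.shape[1]
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise DegenerateError("zero total-score variance")
    return float(k / (k - 1) * (1.0 - X.var(axis=0, ddof=1).sum() / total_var))


@dataclass
class ComponentModel:
    """Correlation-matrix PCA with Kaiser (eigenvalue > 1) retention."""

    eigenvalues: np.ndarray
    loadings: np.ndarray  # eigenvectors, columns, all k of them
    retained: int
    variance_explained: float
    kmo: float
    cronbach_alpha: float
    means: np.ndarray = field(repr=False, default=None)
    sds: np.ndarray = field(repr=False, default=None)


def pca_retain(M) -> ComponentModel:
    """Eigendecompose the correlation matrix and retain eigenvalues > 1.

    Sign convention: within each component, the largest-|loading| entry is
    made positive.  ``variance_explained`` is the retained eigenvalue sum
    over the column count.
    """
    X = _as_matrix(M)
    R = _corr(X)
    evals, evecs = np.linalg.eigh(R)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    for j in range(evecs.shape[1]):
        i = np.argmax(np.abs(evecs[:, j]))
        if evecs[i, j] < 0:
            evecs[:, j] = -evecs[:, j]
    retained = int(np.sum(evals > 1.0))
    return ComponentModel(
        eigenvalues=evals,
        loadings=evecs,
        retained=retained,
        variance_explained=float(evals[:retained].sum() / X.shape[1]),
        kmo=kmo(X),
        cronbach_alpha=cronbach(X),
        means=X.mean(axis=0),
        sds=X.std(axis=0, ddof=1),
    )


def component_scores(model: ComponentModel, M) -> np.ndarray:
    """Project standardized data onto the retained eigenvectors.

    On the fitting sample, scores are zero-mean and each column's variance
    equals its eigenvalue (PCA identity).
    """
    X = np.asarray(M, dtype=float)
    if X.shape[1] != model.loadings.shape[0]:
        raise DesignError(
            f"column mismatch: model fitted on {model.loadings.shape[0]} facets, "
            f"got {X.shape[1]}"
        )
    Z = (X - model.means) / model.sds
    return Z @ model.loadings[:, : model.retained]


class SuperordinateComponents(BaseEstimator, TransformerMixin):
    """Kaiser-retained correlation PCA with psychometric diagnostics.

    Fitted attributes: ``eigenvalues_``, ``loadings_``, ``n_retained_``,
    ``variance_explained_``, ``kmo_``, ``cronbach_alpha_``.

    Parameters
    ----------
    screen_threshold : inter-item |r| threshold reported by the screening
        diagnostic (default 0.3, the conventional cutoff).
    """

    def __init__(self, screen_threshold: float = 0.3):
        self.screen_threshold = screen_threshold

    def fit(self, X, y=None):
        X = _as_matrix(X)
        self.screen_fraction_, self.screen_flags_ = interitem_screen(
            X, self.screen_threshold
        )
        model = pca_retain(X)
        self.model_ = model
        self.eigenvalues_ = model.eigenvalues
        self.loadings_ = model.loadings[:, : model.retained]
        self.n_retained_ = model.retained
        self.variance_explained_ = model.variance_explained
        self.kmo_ = model.kmo
        self.cronbach_alpha_ = model.cronbach_alpha
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        return component_scores(self.model_, np.asarray(X, dtype=float))

    def diagnostics(self) -> dict:
        check_is_fitted(self, "model_")
        return {
            "kmo": self.kmo_,
            "cronbach_alpha": self.cronbach_alpha_,
            "eigenvalues": list(map(float, self.eigenvalues_)),
            "n_retained": self.n_retained_,
            "variance_explained": self.variance_explained_,
            "screen_fraction_above_threshold": self.screen_fraction_,
        }
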