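"""Stage-2 analysis: PLSR of stage-1 residuals on viewing-geometry covariates.

After the mixed-model correction the remaining per-record residuals still
carry viewing-geometry structure (vignetting, FCC viewing-angle effects,
sun-direction gradients, path-length attenuation).  These are modelled with
partial least squares regression (PLS1, NIPALS) on the linearized geometric
covariates.  Covariate importance is summarised per flight as relative
coefficient magnitudes

    beta_rel_i = |beta_i| / sum_i |beta_i|

and across flights as the per-covariate median beta_med_i of the relative
magnitudes; a supervised backward elimination repeatedly drops the covariate
with the lowest median until a target survivor count (default 9) remains.

Coefficients are reported on unit-variance scaled covariates, so magnitudes
are comparable across covariates with different units.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import KFold

from .viewgeom import LINEARIZED_COVARIATE_NAMES

logger = logging.getLogger(__name__)

__all__ = [
    "GeometryPLSR",
    "PLSRResults",
    "EliminationTrace",
    "fit_plsr",
    "relative_magnitudes",
    "median_importance",
    "backward_eliminate",
    "residual_variance_report",
]

MAX_AUTO_COMPONENTS = 5


class GeometryPLSR:
    """PLS1 model of residuals against geometric covariates.

    Parameters
    ----------
    residuals : array-like
        Stage-1 residuals, one per record.
    covariates : DataFrame
        One column per linearized covariate, aligned with ``residuals``.
    n_components : int or "auto"
        "auto" picks the component count (1..5) minimising 10-fold
        cross-validated prediction error.
    """

    def __init__(self, residuals, covariates: pd.DataFrame, n_components="auto", cv_folds=10,
                 random_state: int = 0):
        y = np.asarray(residuals, dtype=float)
        X = covariates.astype(float)
        if len(y) != len(X):
            raise ValueError("residuals and covariates must align")
        keep = []
        for c in X.columns:
            if X[c].std(ddof=0) <= 1e-12:
                logger.warning("dropping constant covariate %r", c)
            else:
                keep.append(c)
        if not keep:
            raise ValueError("no non-constant covariates")
        self.X = X[keep]
        self.y = y
        self.n_components = n_components
        self.cv_folds = cv_folds
        self.random_state = random_state

    def _cv_r2(self, k: int) -> float:
        """10-fold cross-validated explained variance for k components."""
        X, y = self.X.to_numpy(), self.y
        kf = KFold(n_splits=min(self.cv_folds, len(y)), shuffle=True,
                   random_state=self.random_state)
        press, tss = 0.0, 0.0
        for tr, te in kf.split(X):
            m = PLSRegression(n_components=k, scale=True)
            m.fit(X[tr], y[tr])
            pred = m.predict(X[te]).ravel()
            press += float(((y[te] - pred) ** 2).sum())
            tss += float(((y[te] - y[tr].mean()) ** 2).sum())
        return 1.0 - press / tss if tss > 0 else 0.0

    def fit(self) -> "PLSRResults":
        rank = int(np.linalg.matrix_rank(self.X - self.X.mean()))
        if self.n_components == "auto":
            kmax = max(1, min(MAX_AUTO_COMPONENTS, rank))
            scores = {k: self._cv_r2(k) for k in range(1, kmax + 1)}
            k = max(scores, key=scores.get)  # min CV error == max CV R^2
            cv_r2 = scores[k]
        else:
            k = int(self.n_components)
            if k > rank:
                logger.warning("n_components %d > rank %d; clipped", k, rank)
                k = max(1, rank)
            cv_r2 = self._cv_r2(k)
        if len(self.y) < 10 * k:
            raise ValueError(f"need >= {10 * k} records for {k} components")

        m = PLSRegression(n_components=k, scale=True)
        m.fit(self.X.to_numpy(), self.y)
        pred = m.predict(self.X.to_numpy()).ravel()
        ss_res = float(((self.y - pred) ** 2).sum())
        ss_tot = float(((self.y - self.y.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0

        # coefficients on unit-variance covariates
        coef_raw = np.ravel(m.coef_)
        stds = self.X.std(ddof=1).to_numpy()
        coef_scaled = coef_raw * stds

        return PLSRResults(
            covariate_names=list(self.X.columns),
            coefficients=pd.Series(coef_scaled, index=self.X.columns, name="beta"),
            raw_coefficients=pd.Series(coef_raw, index=self.X.columns),
            intercept=float(np.ravel(m.intercept_)[0]) if hasattr(m, "intercept_") else float(self.y.mean()),
            n_components=k,
            x_mean=self.X.mean(),
            x_std=pd.Series(stds, index=self.X.columns),
            scores=m.x_scores_,
            loadings=m.x_loadings_,
            explained_variance=max(r2, 0.0),
            cv_explained_variance=cv_r2,
            fitted=pred,
            residuals=self.y - pred,
            _sk_model=m,
        )


@dataclass
class PLSRResults:
    """Fitted PLS1 model: coefficients, scores/loadings, explained variance."""

    covariate_names: list
    coefficients: pd.Series  # on unit-variance covariates
    raw_coefficients: pd.Series  # on original covariate units
    intercept: float
    n_components: int
    x_mean: pd.Series
    x_std: pd.Series
    scores: np.ndarray
    loadings: np.ndarray
    explained_variance: float  # in-sample, in [0, 1]
    cv_explained_variance: float  # cross-validated; may be negative for noise
    fitted: np.ndarray
    residuals: np.ndarray
    _sk_model: object = None

    def predict(self, covariates: pd.DataFrame) -> np.ndarray:
        X = covariates[self.covariate_names].to_numpy(dtype=float)
        return self._sk_model.predict(X).ravel()

    def relative_magnitudes(self) -> pd.Series:
        return relative_magnitudes(self)

    def summary(self) -> str:
        lines = [
            "Geometry PLSR on stage-1 residuals",
            f"  records: {len(self.fitted)}  covariates: {len(self.covariate_names)}"
            f"  components: {self.n_components}",
            f"  explained variance (in-sample): {self.explained_variance:.3f}",
            f"  explained variance (10-fold CV): {self.cv_explained_variance:.3f}",
            "  relative coefficient magnitudes:",
        ]
        rel = self.relative_magnitudes().sort_values(ascending=False)
        for name, v in rel.items():
            lines.append(f"    {name:<24s} {v:6.3f}")
        return "\n".join(lines)


@dataclass
class EliminationTrace:
    """Backward-elimination record: removal order and surviving covariates."""

    removed: list  # [(covariate, beta_med at removal), ...]
    survivors: list


def fit_plsr(residuals, covariates: pd.DataFrame, n_components="auto", **kw) -> PLSRResults:
    """Fit the stage-2 PLSR (see :class:`GeometryPLSR`)."""
    return GeometryPLSR(residuals, covariates, n_components=n_components, **kw).fit()


def relative_magnitudes(model: PLSRResults) -> pd.Series:
    """Relative coefficient magnitudes |beta_i| / sum|beta_i| (sums to 1)."""
    b = model.coefficients.abs()
    total = float(b.sum())
    if total <= 0:
        raise ValueError("all PLSR coefficients are zero")
    return b / total


def median_importance(models) -> pd.Series:
    """Per-covariate median over flights of the relative magnitudes."""
    models = list(models)
    if not models:
        raise ValueError("no models")
    names = models[0].covariate_names
    for m in models[1:]:
        if m.covariate_names != names:
            raise ValueError("all models must share one covariate set")
    rel = pd.DataFrame([relative_magnitudes(m) for m in models])
    return rel.median(axis=0)


def _canonical_order(names):
    order = {n: i for i, n in enumerate(LINEARIZED_COVARIATE_NAMES)}
    return sorted(names, key=lambda n: order.get(n, len(order)))


def backward_eliminate(
    flights,
    stop: int = 9,
    n_components="auto",
) -> EliminationTrace:
    """Supervised backward feature elimination across flights.

    ``flights`` is a list of (residuals, covariates DataFrame) pairs, one per
    flight.  At each step all flights are refitted on the current covariate
    set, the per-covariate median relative magnitude is computed, and the
    single covariate with the lowest median is removed (ties resolve to
    canonical covariate-table order) until ``stop`` covariates survive.
    """
    flights = list(flights)
    current = _canonical_order(flights[0][1].columns)
    if len(current) < 2:
        raise ValueError("need >= 2 covariates to eliminate")
    if stop > len(current):
        raise ValueError(f"stop={stop} exceeds the {len(current)} initial covariates")

    removed = []
    while len(current) > stop:
        models = [
            fit_plsr(res, cov[current], n_components=n_components)
            for res, cov in flights
        ]
        med = median_importance(models).reindex(current)
        worst = med.idxmin()  # idxmin takes the first occurrence = canonical order
        removed.append((worst, float(med[worst])))
        current = [c for c in current if c != worst]
    return EliminationTrace(removed=removed, survivors=current)


def residual_variance_report(raw_variances: dict, models: dict) -> pd.DataFrame:
    """Variance bookkeeping per flight, as fractions of the initial variance.

    ``raw_variances`` maps flight_id to the variance of the uncorrected
    records; ``models`` maps flight_id to the fitted :class:`PLSRResults` on
    that flight's stage-1 residuals.  Reports the residual-variance fraction
    after stage 1, after PLSR, and the PLSR-explained fraction of the
    stage-1 residuals.
    """
    rows = []
    for fid, raw_var in raw_variances.items():
        if raw_var <= 0:
            raise ValueError(f"zero raw variance for flight {fid}")
        m = models[fid]
        e = m.fitted + m.residuals  # the stage-1 residuals that were modelled
        var_e = float(np.var(e, ddof=1))
        var_post = float(np.var(m.residuals, ddof=1))
        rows.append(
            {
                "flight_id": fid,
                "frac_after_stage1": var_e / raw_var,
                "frac_after_plsr": var_post / raw_var,
                "plsr_explained_of_residuals": 1.0 - var_post / var_e if var_e > 0 else 0.0,
            }
        )
    return pd.DataFrame(rows)
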