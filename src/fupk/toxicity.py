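"""Logistic regression of severe-adverse-event probability on muscle indices.

Severe is CTCAE grade >= 2.  For a subject with skeletal muscle index x the
model is P(severe) = 1/(1 + e^(−z)) with z = β0 + β1·x (univariable by
default; multivariable z = β0 + Σ βk·xk supported).  The odds ratio per
1 cm²/m² SMI increase is exp(β1); an OR below 1 is also reported as the
percent reduction 100·(1 − OR) in the odds of a severe event.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from scipy import stats
from sklearn.base import BaseEstimator

from .dataset import AE_TYPES, AnalysisDataset, dichotomize_grades

__all__ = ["LogisticFit", "SmiToxicityModel", "fit_logistic", "probability",
           "odds", "odds_ratio", "probability_band", "run_all_ae"]


@dataclass
class LogisticFit:
    """Maximum-likelihood logistic fit.

    ``beta`` is (β0, β1, ..., βk) — intercept first; ``cov`` the Wald
    covariance of the coefficients (inverse observed information).
    """

    beta: np.ndarray
    cov: np.ndarray | None
    n: int
    loglik: float
    converged: bool
    separation: bool = False

    @property
    def beta0(self) -> float:
        return float(self.beta[0])

    def slope(self, k: int = 1) -> float:
        return float(self.beta[k])

    def se(self, k: int) -> float:
        if self.cov is None:
            raise ValueError("covariance unavailable")
        return float(np.sqrt(self.cov[k, k]))


def _design(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    return sm.add_constant(x, has_constant="add")


def fit_logistic(x: np.ndarray, y: np.ndarray) -> LogisticFit:
    """Fit P(y=1) = expit(β0 + βᵀx) by maximum likelihood (Newton/IRLS).

    ``x`` is (n,) or (n, k).  Complete separation is flagged (estimates from
    the last stable iterate); constant ``y`` raises.
    """
    y = np.asarray(y, dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("y must be binary 0/1")
    X = _design(x)
    if len(y) <= X.shape[1]:
        raise ValueError("need more observations than coefficients")
    if y.min() == y.max():
        raise ValueError("y is constant (no events or all events)")
    separation = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=100)
        except (np.linalg.LinAlgError, sm.tools.sm_exceptions
                .PerfectSeparationError):
            res = sm.Logit(y, X).fit(disp=0, method="bfgs", maxiter=200)
            separation = True
        for w in caught:
            if "separat" in str(w.message).lower() or \
                    "convergence" in str(w.message).lower():
                separation = separation or "separat" in str(w.message).lower()
    converged = bool(res.mle_retvals.get("converged", True))
    if separation:
        warnings.warn("possible complete separation; estimates are the last "
                      "stable iterate", stacklevel=2)
    try:
        cov = np.asarray(res.cov_params())
    except Exception:
        cov = None
    return LogisticFit(beta=np.asarray(res.params, dtype=float), cov=cov,
                       n=len(y), loglik=float(res.llf), converged=converged,
                       separation=separation)


def probability(fit: LogisticFit, x: np.ndarray) -> np.ndarray | float:
    """P(severe AE) = 1/(1 + e^(−z)) at covariate values ``x``."""
    z = _design(np.atleast_1d(np.asarray(x, dtype=float))) @ fit.beta
    p = expit(z)
    return float(p[0]) if p.size == 1 else p


def odds(p: float) -> float:
    """Odds = p/(1−p); infinity (with a warning) at p = 1."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if p == 1.0:
        warnings.warn("odds are infinite at p = 1", stacklevel=2)
        return float("inf")
    return p / (1.0 - p)


def odds_ratio(fit: LogisticFit, k: int = 1, delta: float = 1.0,
               level: float = 0.95) -> dict[str, float]:
    """Odds ratio per ``delta``-unit increase of covariate ``k``.

    Returns OR = exp(βk·δ) with its Wald CI and, when OR < 1, the percent
    reduction 100·(1 − OR) in the odds of a severe event.
    """
    b = fit.slope(k)
    zc = stats.norm.ppf(0.5 + level / 2.0)
    out = {"odds_ratio": float(np.exp(b * delta))}
    if fit.cov is not None:
        se = fit.se(k)
        out["ci_lower"] = float(np.exp((b - zc * se) * delta))
        out["ci_upper"] = float(np.exp((b + zc * se) * delta))
    if out["odds_ratio"] < 1.0:
        out["percent_reduction"] = 100.0 * (1.0 - out["odds_ratio"])
    return out


def probability_band(fit: LogisticFit, x_grid: np.ndarray,
                     level: float = 0.95) -> pd.DataFrame:
    """Pointwise delta-method confidence band for P(severe AE).

    var(z) = xᵀΣx on the linear predictor; the symmetric z-interval is
    mapped through the inverse logit, so the band stays inside (0, 1).
    """
    if fit.cov is None:
        raise ValueError("fit has no covariance matrix")
    X = _design(np.asarray(x_grid, dtype=float))
    z = X @ fit.beta
    sd = np.sqrt(np.einsum("ij,jk,ik->i", X, fit.cov, X))
    zc = stats.norm.ppf(0.5 + level / 2.0)
    return pd.DataFrame({
        "x": np.atleast_1d(np.asarray(x_grid, dtype=float)).reshape(len(z), -1)[:, 0],
        "p": expit(z),
        "lower": expit(z - zc * sd),
        "upper": expit(z + zc * sd),
    })


class SmiToxicityModel(BaseEstimator):
    """Severe-AE probability vs. muscle index (scikit-learn style).

    A thin estimator around the univariable/multivariable logistic model.
    After ``fit(X, y)``: ``fit_`` (the :class:`LogisticFit`), ``coef_``,
    ``intercept_``.
    """

    def fit(self, X: np.ndarray, y: np.ndarray) -> "SmiToxicityModel":
        self.fit_ = fit_logistic(X, y)
        self.intercept_ = self.fit_.beta0
        self.coef_ = self.fit_.beta[1:].copy()
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        p = np.atleast_1d(probability(self.fit_, X))
        return np.column_stack([1.0 - p, p])

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def odds_ratio(self, k: int = 1, delta: float = 1.0) -> dict[str, float]:
        return odds_ratio(self.fit_, k=k, delta=delta)


def run_all_ae(dataset: AnalysisDataset,
               smi_measures: dict[str, str] | None = None,
               ae_types: tuple[str, ...] = AE_TYPES) -> pd.DataFrame:
    """Univariable logistic fit for every requested (AE, SMI measure) pair.

    Returns one row per pair with the odds ratio per 1 cm²/m², its 95% CI
    and Wald p-value.  No multiplicity adjustment is applied (recorded in
    the ``multiplicity_adjustment`` column).  Degenerate outcomes (no or
    only events for an AE) flag that row and leave the others unaffected.
    """
    if smi_measures is None:
        smi_measures = {"smi_psoas": "smi_psoas", "smi_back": "smi_back",
                        "smi_total_hu": "smi_total_hu",
                        "smi_total_seg": "smi_total_seg"}
    ids = [s.subject_id for s in dataset.subjects]
    rows = []
    for ae in ae_types:
        outcomes = dichotomize_grades(dataset.adverse_events, ae,
                                      subject_ids=ids)
        y = outcomes["outcome"].to_numpy(dtype=float)
        for label, field in smi_measures.items():
            x = np.array([dataset.subjects[i].covariate(field)
                          for i in range(len(ids))], dtype=float)
            row = {"ae_type": ae, "smi_measure": label,
                   "n": len(ids), "n_events": int(y.sum()),
                   "multiplicity_adjustment": "none"}
            if y.min() == y.max():
                row.update({"flag": "degenerate_outcome"})
            else:
                try:
                    lf = fit_logistic(x, y)
                    orr = odds_ratio(lf)
                    se = lf.se(1)
                    wald_p = 2.0 * stats.norm.sf(abs(lf.slope() / se)) \
                        if se > 0 else float("nan")
                    row.update({
                        "odds_ratio": orr["odds_ratio"],
                        "ci_lower": orr.get("ci_lower", float("nan")),
                        "ci_upper": orr.get("ci_upper", float("nan")),
                        "p_value": wald_p,
                        "flag": "separation" if lf.separation else "",
                    })
                except ValueError as exc:
                    row.update({"flag": f"failed: {exc}"})
            rows.append(row)
    return pd.DataFrame(rows)
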