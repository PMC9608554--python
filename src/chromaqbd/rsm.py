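"""Response-surface model fitting in coded factor units.

Two polynomial models are supported, both fitted by ordinary least squares:

    linear:     y = b0 + sum_j b_j x_j
    quadratic:  y = b0 + sum_j b_j x_j + sum_{j<l} b_jl x_j x_l + sum_j b_jj x_j^2

Fitting always happens in coded units, so coefficient magnitudes are
directly comparable across factors (minutes per coded unit for retention
responses). Model adequacy is summarised by R^2, adjusted R^2 and the
PRESS-based predicted R^2; per-coefficient t tests use the residual
variance with n - p degrees of freedom.

The OLS solve itself is delegated to :mod:`statsmodels`; this module owns
the term layout, the PRESS/leave-one-out arithmetic and the prediction
variance decomposition used downstream by the Monte Carlo design-space
sampler.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .designs import DesignTable

__all__ = [
    "ModelFit",
    "term_labels",
    "build_model_matrix",
    "fit_ols",
    "goodness_of_fit",
    "coefficient_inference",
    "sequential_order_report",
]

_ORDERS = ("linear", "quadratic")


def term_labels(symbols: list[str], order: str) -> list[str]:
    """Ordered term labels: 1, mains, pairwise interactions, squares."""
    if order not in _ORDERS:
        raise ValueError(f"order must be one of {_ORDERS}, got {order!r}")
    labels = ["1"] + list(symbols)
    if order == "quadratic":
        labels += [
            symbols[i] + symbols[j]
            for i in range(len(symbols))
            for j in range(i + 1, len(symbols))
        ]
        labels += [s + "^2" for s in symbols]
    return labels


def build_model_matrix(coded, symbols: list[str], order: str) -> pd.DataFrame:
    """Expand coded runs into the named model matrix for the given order."""
    x = np.atleast_2d(np.asarray(coded, dtype=float))
    if not np.all(np.isfinite(x)):
        raise ValueError("coded runs must be finite")
    if x.shape[1] != len(symbols):
        raise ValueError(f"{x.shape[1]} coded columns for {len(symbols)} symbols")
    cols: dict[str, np.ndarray] = {"1": np.ones(len(x))}
    for j, s in enumerate(symbols):
        cols[s] = x[:, j]
    if order == "quadratic":
        for i in range(len(symbols)):
            for j in range(i + 1, len(symbols)):
                cols[symbols[i] + symbols[j]] = x[:, i] * x[:, j]
        for j, s in enumerate(symbols):
            cols[s + "^2"] = x[:, j] ** 2
    labels = term_labels(symbols, order)
    return pd.DataFrame({t: cols[t] for t in labels})


@dataclass
class ModelFit:
    """A fitted polynomial response surface and its uncertainty.

    ``beta`` is ordered as :func:`term_labels`; ``cov_beta`` is the usual
    OLS coefficient covariance sigma2 * (X'X)^-1; ``dof`` = n - p.
    """

    response_name: str
    order: str
    symbols: list[str]
    terms: list[str]
    beta: np.ndarray
    cov_beta: np.ndarray
    sigma2: float
    dof: int
    r2: float
    adj_r2: float
    pred_r2: float
    press: float
    model_matrix: np.ndarray
    y: np.ndarray

    @property
    def n(self) -> int:
        return self.model_matrix.shape[0]

    @property
    def p(self) -> int:
        return self.model_matrix.shape[1]

    @property
    def xtx_inv(self) -> np.ndarray:
        return np.linalg.inv(self.model_matrix.T @ self.model_matrix)

    def design_row(self, coded_point) -> np.ndarray:
        row = build_model_matrix(
            np.atleast_2d(coded_point), self.symbols, self.order
        ).to_numpy()
        return row[0] if np.ndim(coded_point) == 1 else row

    def predict_mean(self, coded_point):
        """Predict at one coded point.

        Returns ``(mean, var_mean, var_new)`` where ``var_mean`` is the
        variance of the estimated mean response x' cov_beta x and
        ``var_new`` adds the residual variance of a new observation.
        """
        x = np.asarray(coded_point, dtype=float)
        if x.shape[-1] != len(self.symbols):
            raise ValueError(
                f"point has {x.shape[-1]} coordinates for {len(self.symbols)} factors"
            )
        row = self.design_row(x)
        mean = row @ self.beta
        if row.ndim == 1:
            var_mean = float(row @ self.cov_beta @ row)
        else:
            var_mean = np.einsum("ij,jk,ik->i", row, self.cov_beta, row)
        return mean, var_mean, var_mean + self.sigma2

    def predict(self, coded_points) -> np.ndarray:
        rows = self.design_row(np.atleast_2d(coded_points))
        return rows @ self.beta

    def to_dict(self) -> dict:
        return {
            "response_name": self.response_name,
            "order": self.order,
            "symbols": self.symbols,
            "terms": self.terms,
            "beta": self.beta.tolist(),
            "cov_beta": self.cov_beta.tolist(),
            "sigma2": self.sigma2,
            "dof": self.dof,
            "r2": self.r2,
            "adj_r2": self.adj_r2,
            "pred_r2": self.pred_r2,
            "press": self.press,
            "model_matrix": self.model_matrix.tolist(),
            "y": self.y.tolist(),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelFit":
        d = dict(d)
        for k in ("beta", "cov_beta", "model_matrix", "y"):
            d[k] = np.asarray(d[k], dtype=float)
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "ModelFit":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def fit_ols(design: DesignTable, response: str, order: str = "quadratic") -> ModelFit:
    """Fit a linear or full quadratic surface to one response by OLS."""
    if response not in design.data.columns:
        raise KeyError(f"response {response!r} not in design table")
    X = build_model_matrix(design.coded.to_numpy(), design.symbols, order)
    y = design.data[response].to_numpy(dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more runs ({n}) than terms ({p})")
    if np.linalg.matrix_rank(X.to_numpy()) < p:
        raise ValueError("model matrix is rank deficient on this design")
    with np.errstate(divide="ignore", invalid="ignore"):  # constant y has SST=0
        res = sm.OLS(y, X.to_numpy()).fit()
        hat = res.get_influence().hat_matrix_diag
    resid = res.resid
    press = float(np.sum((resid / (1.0 - hat)) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    pred_r2 = 1.0 - press / sst if sst > 0 else np.nan
    r2 = float(res.rsquared) if sst > 0 else np.nan
    adj_r2 = float(res.rsquared_adj) if sst > 0 else np.nan
    return ModelFit(
        response_name=response,
        order=order,
        symbols=design.symbols,
        terms=list(X.columns),
        beta=np.asarray(res.params),
        cov_beta=np.asarray(res.cov_params()),
        sigma2=float(res.mse_resid),
        dof=int(res.df_resid),
        r2=r2,
        adj_r2=adj_r2,
        pred_r2=pred_r2,
        press=press,
        model_matrix=X.to_numpy(),
        y=y,
    )


@dataclass(frozen=True)
class FitStatistics:
    r2: float
    adj_r2: float
    pred_r2: float
    press: float
    f_stat: float
    f_pvalue: float
    degenerate: bool = False


def goodness_of_fit(fit: ModelFit) -> FitStatistics:
    """R^2 triple, PRESS, and the overall regression F test."""
    y = fit.y
    n, p = fit.n, fit.p
    resid = y - fit.model_matrix @ fit.beta
    rss = float(resid @ resid)
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        return FitStatistics(np.nan, np.nan, np.nan, fit.press, np.nan, np.nan, True)
    ssr = sst - rss
    f = (ssr / (p - 1)) / (rss / (n - p)) if rss > 0 else np.inf
    pval = float(stats.f.sf(f, p - 1, n - p)) if np.isfinite(f) else 0.0
    return FitStatistics(fit.r2, fit.adj_r2, fit.pred_r2, fit.press, f, pval)


_STARS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def coefficient_inference(fit: ModelFit) -> pd.DataFrame:
    """Per-term standard error, t statistic, two-sided p and star level."""
    se = np.sqrt(np.diag(fit.cov_beta))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = fit.beta / se
    p = 2.0 * stats.t.sf(np.abs(t), fit.dof)
    p = np.where(np.isnan(t), np.nan, p)
    stars = [
        next((s for thr, s in _STARS if pj < thr), "") if np.isfinite(pj) else ""
        for pj in p
    ]
    return pd.DataFrame(
        {"coef": fit.beta, "se": se, "t": t, "p": p, "stars": stars}, index=fit.terms
    )


def sequential_order_report(design: DesignTable, response: str) -> pd.DataFrame:
    """Advisory extra-sum-of-squares F test of quadratic over linear terms.

    Reported for model-order selection; never applied automatically.
    """
    lin = fit_ols(design, response, "linear")
    quad = fit_ols(design, response, "quadratic")
    rss_l = float(np.sum((lin.y - lin.model_matrix @ lin.beta) ** 2))
    rss_q = float(np.sum((quad.y - quad.model_matrix @ quad.beta) ** 2))
    df_extra = quad.p - lin.p
    f = ((rss_l - rss_q) / df_extra) / (rss_q / quad.dof)
    pval = float(stats.f.sf(f, df_extra, quad.dof))
    return pd.DataFrame(
        {
            "order": ["linear", "quadratic"],
            "rss": [rss_l, rss_q],
            "adj_r2": [lin.adj_r2, quad.adj_r2],
            "pred_r2": [lin.pred_r2, quad.pred_r2],
            "extra_F": [np.nan, f],
            "extra_p": [np.nan, pval],
        }
    )
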