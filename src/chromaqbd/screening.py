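"""Main-effect estimation and significance screening for two-level designs.

An unreplicated two-level fraction gives one orthogonal contrast per alias
set; for a regular 2^(k-p) fraction with 2^(k-p) factorial runs there are
2^(k-p) - 1 such contrasts. Each contrast's *effect* is the change in mean
response from the low to the high level:

    effect(c) = mean(y | c = +1) - mean(y | c = -1)

Centre points carry no contrast information and are excluded; they feed an
informational curvature check instead.

With no replicate degrees of freedom, significance is judged by Lenth's
pseudo standard error (PSE): a robust scale estimate built from the
(mostly null) contrast effects. The default critical value is the
simulation-calibrated individual-error-rate quantile of |effect|/PSE,
which is well known to hold its nominal level where Lenth's original
t(1-alpha/2, m/3) approximation is conservative; the t approximation
remains available via ``critical="t"``.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from .designs import DesignTable

__all__ = [
    "EffectTable",
    "contrast_columns",
    "estimate_effects",
    "half_normal_coordinates",
    "lenth_pse",
    "lenth_critical",
    "lenth_significance",
    "curvature_check",
]


def contrast_columns(design: DesignTable, include_interactions: bool = True) -> pd.DataFrame:
    """All alias-distinct +/-1 contrast columns over the factorial rows.

    Each column is labelled by the shortest word in its alias set (ties
    broken alphabetically), so main effects keep their single-letter
    labels. With ``include_interactions=False`` only the k main-effect
    columns are returned.
    """
    coded = np.rint(design.coded.to_numpy()[design.factorial_mask])
    symbols = design.symbols
    if not np.all(np.isin(coded, (-1.0, 1.0))):
        raise ValueError("factorial rows must be +/-1 in every factor column")
    cols: dict[tuple, tuple[str, np.ndarray]] = {}
    max_order = len(symbols) if include_interactions else 1
    for r in range(1, max_order + 1):
        for sub in itertools.combinations(range(len(symbols)), r):
            v = coded[:, sub].prod(axis=1)
            if np.all(v == v[0]):  # defining-relation word, no contrast
                continue
            key = tuple((v if v[0] > 0 else -v).astype(int))
            label = "".join(symbols[i] for i in sub)
            if key not in cols or (len(label), label) < (len(cols[key][0]), cols[key][0]):
                cols[key] = (label, v)
    out = pd.DataFrame({lbl: v for lbl, v in cols.values()})
    return out[sorted(out.columns, key=lambda s: (len(s), s))]


def _column_effects(contrasts: pd.DataFrame, y: np.ndarray) -> pd.Series:
    effects = {}
    for lbl in contrasts.columns:
        v = contrasts[lbl].to_numpy()
        hi, lo = y[v > 0], y[v < 0]
        if len(hi) != len(lo):
            raise ValueError(f"contrast {lbl} is unbalanced ({len(hi)} vs {len(lo)})")
        effects[lbl] = hi.mean() - lo.mean()
    return pd.Series(effects)


def lenth_pse(effects) -> float:
    """Lenth's pseudo standard error of a set of effects."""
    e = np.abs(np.asarray(effects, dtype=float))
    if len(e) < 3:
        raise ValueError("need at least 3 effects for Lenth's PSE")
    s0 = 1.5 * np.median(e)
    trimmed = e[e < 2.5 * s0]
    if len(trimmed) == 0 or np.all(e == 0):
        return 0.0
    return 1.5 * float(np.median(trimmed))


@lru_cache(maxsize=32)
def _simulated_critical(m: int, alpha: float, n_rep: int = 50000) -> float:
    """Null quantile of |effect|/PSE for m iid normal effects.

    Calibrated by Monte Carlo with a fixed internal seed, so the critical
    value is a deterministic constant of (m, alpha). Reproduces published
    individual-error-rate tables (e.g. 2.16 for m=15, alpha=0.05).
    """
    rng = np.random.default_rng(902210405)
    e = np.abs(rng.standard_normal((n_rep, m)))
    s0 = 1.5 * np.median(e, axis=1, keepdims=True)
    trimmed = np.where(e < 2.5 * s0, e, np.nan)
    pse = 1.5 * np.nanmedian(trimmed, axis=1, keepdims=True)
    ratios = (e / pse).ravel()
    return float(np.quantile(ratios, 1.0 - alpha))


def lenth_critical(m: int, alpha: float = 0.05, method: str = "simulation") -> float:
    """Critical multiple of PSE for declaring an effect significant."""
    if method == "simulation":
        return _simulated_critical(m, alpha)
    if method == "t":
        return float(stats.t.ppf(1.0 - alpha / 2.0, m / 3.0))
    raise ValueError(f"unknown critical-value method {method!r}")


def lenth_significance(
    effects, alpha: float = 0.05, critical: str = "simulation"
) -> tuple[float, float, list[str]]:
    """Flag significant effects by Lenth's method.

    Returns ``(pse, margin, significant_labels)`` where ``margin`` is the
    critical value times the PSE and an effect is significant when its
    magnitude exceeds the margin.
    """
    e = pd.Series(effects, dtype=float)
    pse = lenth_pse(e.to_numpy())
    if pse == 0.0:
        warnings.warn("all effects are zero; PSE = 0, nothing flagged")
        return 0.0, 0.0, []
    margin = lenth_critical(len(e), alpha, critical) * pse
    sig = [str(lbl) for lbl, val in e.items() if abs(val) > margin]
    return pse, margin, sig


def half_normal_coordinates(effects) -> pd.DataFrame:
    """Half-normal plot coordinates for a set of effects.

    The i-th smallest |effect| (i = 1..m) is paired with the half-normal
    quantile Phi^-1(0.5 + 0.5 (i - 0.5)/m); significant effects fall off
    the straight line through the bulk.
    """
    e = pd.Series(effects, dtype=float)
    if len(e) < 1:
        raise ValueError("need at least one effect")
    order = e.abs().sort_values(kind="stable")
    m = len(order)
    q = stats.norm.ppf(0.5 + 0.5 * (np.arange(1, m + 1) - 0.5) / m)
    return pd.DataFrame(
        {"label": order.index, "abs_effect": order.to_numpy(), "quantile": q}
    )


@dataclass
class EffectTable:
    """Estimated contrast effects for one response with Lenth screening."""

    response_name: str
    effects: pd.Series  # change in response from -1 to +1, per contrast
    pse: float
    margin: float
    significant: list[str]
    alpha: float

    @property
    def half_effects(self) -> pd.Series:
        """Effects on the regression-coefficient scale (effect / 2)."""
        return self.effects / 2.0

    @property
    def abs_rank(self) -> list[str]:
        """Contrast labels ordered by decreasing |effect|."""
        return list(self.effects.abs().sort_values(ascending=False, kind="stable").index)

    def half_normal(self) -> pd.DataFrame:
        return half_normal_coordinates(self.effects)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "effect": self.effects,
                "half_effect": self.half_effects,
                "significant": [lbl in self.significant for lbl in self.effects.index],
            }
        )
        return df.loc[self.abs_rank]


def estimate_effects(
    design: DesignTable,
    response: str,
    include_interactions: bool = True,
    alpha: float = 0.05,
    critical: str = "simulation",
) -> EffectTable:
    """Estimate all contrast effects of a response and screen them.

    Centre points are excluded from the contrasts. By default the full set
    of alias-distinct contrasts is used, which is what half-normal and
    Pareto screening of an unreplicated fraction requires: the many null
    interaction contrasts are what make the PSE informative.
    """
    if response not in design.data.columns:
        raise KeyError(f"response {response!r} not in design table")
    contrasts = contrast_columns(design, include_interactions)
    y = design.data[response].to_numpy(dtype=float)[design.factorial_mask]
    effects = _column_effects(contrasts, y)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pse, margin, sig = lenth_significance(effects, alpha, critical)
    return EffectTable(response, effects, pse, margin, sig, alpha)


def curvature_check(design: DesignTable, response: str) -> dict:
    """Informational centre-vs-factorial curvature summary.

    Compares the mean response at the centre points with the factorial
    mean; the t statistic uses the pooled centre-point standard deviation.
    """
    y = design.data[response].to_numpy(dtype=float)
    yc = y[design.center_mask]
    yf = y[design.factorial_mask]
    out = {
        "n_center": int(len(yc)),
        "center_mean": float(yc.mean()) if len(yc) else np.nan,
        "factorial_mean": float(yf.mean()),
        "difference": float(yc.mean() - yf.mean()) if len(yc) else np.nan,
    }
    if len(yc) >= 2:
        sd = yc.std(ddof=1)
        se = sd * np.sqrt(1.0 / len(yc) + 1.0 / len(yf))
        t = out["difference"] / se if se > 0 else np.nan
        out["center_sd"] = float(sd)
        out["t"] = float(t)
        out["p"] = float(2.0 * stats.t.sf(abs(t), len(yc) - 1)) if np.isfinite(t) else np.nan
    return out
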