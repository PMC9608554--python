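"""ICH-style method-validation statistics.

Covers the quantities a validation protocol for an impurity method
reports: calibration regression (slope, intercept, Pearson r), detection
and quantification limits (LOD = 3.3 sigma/S, LOQ = 10 sigma/S), percent
recovery, and percent relative standard deviation, together with the
tiered acceptance rules that depend on an impurity's specification limit
(SL, as a percentage of the active ingredient):

    role / SL tier                   recovery (%)   max %RSD   min r
    active ingredient                98.0 - 102.0      2.0     0.99
    impurity, SL >= 1.0%             90.0 - 110.0      5.0     0.98
    impurity, 0.5% <= SL < 1.0%      80.0 - 120.0     10.0     0.98
    impurity, 0.1% <= SL < 0.5%      70.0 - 130.0     15.0     0.98

sigma in the LOD/LOQ formulas is taken as the standard error of the fitted
intercept of the calibration line; a user-supplied sigma (e.g. from
replicate intercepts) may be passed instead.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats

__all__ = [
    "CalibrationSeries",
    "CalibrationFit",
    "Tier",
    "ValidationReport",
    "fit_calibration",
    "lod_loq",
    "recovery",
    "rsd",
    "acceptance_tier",
    "validate_analyte",
]


@dataclass(frozen=True)
class CalibrationSeries:
    """Signal-vs-concentration calibration data for one analyte."""

    analyte: str
    concentrations: tuple[float, ...]  # ug/mL
    signals: tuple[float, ...]  # area units
    role: str = "impurity"  # "API" or "impurity"
    specification_limit_pct: float | None = None

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations, dtype=float)
        s = np.asarray(self.signals, dtype=float)
        if len(c) != len(s) or len(c) < 3:
            raise ValueError("need equal-length concentration/signal vectors, >= 3 points")
        if np.any(c < 0):
            raise ValueError("concentrations must be non-negative")
        if np.allclose(c, c[0]):
            raise ValueError("concentrations are all equal; regression is degenerate")
        if self.role not in ("API", "impurity"):
            raise ValueError(f"role must be 'API' or 'impurity', got {self.role!r}")


@dataclass(frozen=True)
class CalibrationFit:
    slope: float
    intercept: float
    r: float
    se_slope: float
    se_intercept: float
    n: int


def fit_calibration(series: CalibrationSeries) -> CalibrationFit:
    """Least-squares line of signal on concentration with Pearson r."""
    c = np.asarray(series.concentrations, dtype=float)
    s = np.asarray(series.signals, dtype=float)
    res = stats.linregress(c, s)
    return CalibrationFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        se_slope=float(res.stderr),
        se_intercept=float(res.intercept_stderr),
        n=len(c),
    )


def lod_loq(sigma_intercept: float, slope: float) -> tuple[float, float]:
    """Detection and quantification limits, 3.3 sigma/S and 10 sigma/S."""
    if slope == 0:
        raise ZeroDivisionError("calibration slope is zero; LOD/LOQ undefined")
    if sigma_intercept < 0:
        raise ValueError("sigma must be non-negative")
    lod = 3.3 * sigma_intercept / abs(slope)
    loq = 10.0 * sigma_intercept / abs(slope)
    return lod, loq


def recovery(measured: float, nominal: float) -> float:
    """Percent recovery of a spiked amount."""
    if nominal <= 0:
        raise ValueError("nominal concentration must be positive")
    return 100.0 * measured / nominal


def rsd(values) -> float:
    """Percent relative standard deviation (sample SD / mean * 100)."""
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise ValueError("need at least 2 replicates for %RSD")
    mean = v.mean()
    if mean == 0:
        raise ZeroDivisionError("mean of replicates is zero; %RSD undefined")
    return 100.0 * v.std(ddof=1) / abs(mean)


@dataclass(frozen=True)
class Tier:
    recovery_low: float
    recovery_high: float
    rsd_max: float
    r_min: float


def acceptance_tier(role: str, specification_limit_pct: float | None = None) -> Tier:
    """Acceptance limits for recovery, %RSD and r by role and SL tier.

    Tier boundaries are inclusive on the left: SL = 1.0% falls in the
    >= 1.0% tier and SL = 0.5% in the [0.5%, 1.0%) tier. Impurities below
    SL = 0.1% have no defined tier.
    """
    if role == "API":
        return Tier(98.0, 102.0, 2.0, 0.99)
    if role != "impurity":
        raise ValueError(f"role must be 'API' or 'impurity', got {role!r}")
    if specification_limit_pct is None:
        raise ValueError("impurity tier lookup requires a specification limit")
    sl = float(specification_limit_pct)
    if sl >= 1.0:
        return Tier(90.0, 110.0, 5.0, 0.98)
    if sl >= 0.5:
        return Tier(80.0, 120.0, 10.0, 0.98)
    if sl >= 0.1:
        return Tier(70.0, 130.0, 15.0, 0.98)
    raise ValueError(f"no acceptance tier defined for specification limit {sl}% (< 0.1%)")


@dataclass
class ValidationReport:
    """Validation summary for one analyte with pass/fail flags."""

    analyte: str
    role: str
    specification_limit_pct: float | None
    slope: float
    intercept: float
    r: float
    lod: float
    loq: float
    tier: Tier
    recoveries: dict[str, float] = field(default_factory=dict)  # level -> mean %recovery
    rsds: dict[str, float] = field(default_factory=dict)  # level -> %RSD
    pass_flags: dict[str, bool] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["tier"] = asdict(self.tier)
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    def format_table(self) -> str:
        lines = [
            f"Analyte: {self.analyte} ({self.role}"
            + (f", SL {self.specification_limit_pct}%" if self.specification_limit_pct else "")
            + ")",
            f"  calibration: slope {self.slope:.4g}, intercept {self.intercept:.4g}, "
            f"r {self.r:.4f} (min {self.tier.r_min}) -> "
            + ("pass" if self.pass_flags.get("linearity") else "FAIL"),
            f"  LOD {self.lod:.4g} ug/mL, LOQ {self.loq:.4g} ug/mL",
        ]
        for level in self.recoveries:
            rec = self.recoveries[level]
            tag = "pass" if self.pass_flags.get(f"recovery:{level}") else "FAIL"
            line = f"  recovery @{level}: {rec:.1f}% ({self.tier.recovery_low}-{self.tier.recovery_high}%) -> {tag}"
            if level in self.rsds:
                tag2 = "pass" if self.pass_flags.get(f"rsd:{level}") else "FAIL"
                line += f"; %RSD {self.rsds[level]:.2f} (max {self.tier.rsd_max}) -> {tag2}"
            lines.append(line)
        return "\n".join(lines)


def validate_analyte(
    series: CalibrationSeries,
    recovery_replicates: dict[str, tuple[tuple[float, float], ...]] | None = None,
    sigma_intercept: float | None = None,
) -> ValidationReport:
    """Run the full validation computation for one analyte.

    ``recovery_replicates`` maps a level label to replicate
    (measured, nominal) pairs in ug/mL; mean recovery and %RSD of the
    replicate recoveries are evaluated against the analyte's tier.
    ``sigma_intercept`` overrides the regression-derived intercept SE in
    the LOD/LOQ formulas.
    """
    fit = fit_calibration(series)
    sigma = fit.se_intercept if sigma_intercept is None else float(sigma_intercept)
    lod, loq = lod_loq(sigma, fit.slope)
    tier = acceptance_tier(series.role, series.specification_limit_pct)
    report = ValidationReport(
        analyte=series.analyte,
        role=series.role,
        specification_limit_pct=series.specification_limit_pct,
        slope=fit.slope,
        intercept=fit.intercept,
        r=fit.r,
        lod=lod,
        loq=loq,
        tier=tier,
    )
    report.pass_flags["linearity"] = fit.r > tier.r_min
    for level, pairs in (recovery_replicates or {}).items():
        recs = [recovery(m, nom) for m, nom in pairs]
        mean_rec = float(np.mean(recs))
        report.recoveries[level] = mean_rec
        report.pass_flags[f"recovery:{level}"] = (
            tier.recovery_low <= mean_rec <= tier.recovery_high
        )
        if len(recs) >= 2:
            level_rsd = rsd(recs)
            report.rsds[level] = level_rsd
            report.pass_flags[f"rsd:{level}"] = level_rsd <= tier.rsd_max
    return report
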