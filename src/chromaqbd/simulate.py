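"""Synthetic studies with known ground truth.

Every pipeline stage can be exercised without laboratory data: screening
studies are drawn from a known main-effects model, optimization studies
from a known quadratic surface evaluated on a Box-Behnken design, and
calibration series from a known line -- all with i.i.d. Gaussian noise and
deterministic under a seed.

The default true surfaces mirror the magnitudes of a real gradient
retention study: an intercept near 9.35 min, a dominant negative organic-
ratio main effect near -1.67 min per coded unit, a salt-concentration
effect near +0.59, and small curvature; the default noise SD (0.09 min,
about 1% of the centre response) is of the order of retention-time
repeatability on a well-behaved system.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .designs import DesignTable, make_box_behnken, make_fractional_factorial
from .factors import FactorSpec
from .rsm import build_model_matrix, term_labels
from .validation import CalibrationSeries

__all__ = [
    "TrueSurface",
    "default_bbd_specs",
    "default_true_surfaces",
    "simulate_bbd_study",
    "simulate_screening_study",
    "simulate_calibration",
]


def default_bbd_specs() -> list[FactorSpec]:
    """The three optimization factors with their study ranges and grids."""
    return [
        FactorSpec("ACN at gradient start", "A", 37.0, 41.0, "%", 21),
        FactorSpec("chaotropic salt concentration", "B", 30.0, 60.0, "mM", 21),
        FactorSpec("gradient start time", "C", 7.0, 11.0, "min", 11),
    ]


@dataclass(frozen=True)
class TrueSurface:
    """A known polynomial surface used as simulation ground truth."""

    beta: tuple[float, ...]  # ordered as rsm.term_labels(symbols, order)
    noise_sd: float
    factor_specs: tuple[FactorSpec, ...]
    order: str = "quadratic"

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        expected = len(term_labels([s.symbol for s in self.factor_specs], self.order))
        if len(self.beta) != expected:
            raise ValueError(f"beta has {len(self.beta)} terms, expected {expected}")

    @property
    def symbols(self) -> list[str]:
        return [s.symbol for s in self.factor_specs]

    def evaluate(self, coded) -> np.ndarray:
        X = build_model_matrix(np.atleast_2d(coded), self.symbols, self.order)
        return X.to_numpy() @ np.asarray(self.beta)


def default_true_surfaces(noise_sd: float = 0.09) -> dict[str, TrueSurface]:
    """Known-truth surfaces for the four retention responses.

    Coefficients follow the fitted models of the real optimization study
    (quadratic for the first three responses, linear for the last), so the
    implied separation criteria are small but positive over most of the
    region, as in the real system.
    """
    specs = tuple(default_bbd_specs())
    quad = {
        "t_e_bup": (9.35, -1.67, 0.59, 0.063, -0.14, -0.061, 0.012, 0.22, -0.16, 0.00075),
        "t_b_imp2": (9.4, -1.72, 0.59, 0.065, -0.14, -0.076, 0.00325, 0.21, -0.14, -0.00425),
        "t_e_imp2": (9.65, -1.80, 0.59, 0.099, -0.15, -0.12, 0.027, 0.19, -0.063, -0.081),
    }
    out = {
        nm: TrueSurface(beta, noise_sd, specs, "quadratic") for nm, beta in quad.items()
    }
    out["t_b_imp3"] = TrueSurface((9.90, -1.89, 0.61, 0.14), noise_sd, specs, "linear")
    return out


def simulate_bbd_study(
    true_surfaces: dict[str, TrueSurface],
    n_center: int = 4,
    seed: int = 0,
) -> DesignTable:
    """Simulate a Box-Behnken study from known surfaces plus Gaussian noise."""
    surfaces = dict(true_surfaces)
    specs = None
    for s in surfaces.values():
        if specs is None:
            specs = list(s.factor_specs)
        elif list(s.factor_specs) != specs:
            raise ValueError("all true surfaces must share the same factor specs")
    design = make_box_behnken(specs, n_center=n_center)
    coded = design.coded.to_numpy()
    rng = np.random.default_rng(seed)
    responses = {}
    for nm, surf in surfaces.items():
        mu = surf.evaluate(coded)
        responses[nm] = mu + rng.normal(0.0, surf.noise_sd, size=len(mu))
    return design.with_responses(pd.DataFrame(responses))


def simulate_screening_study(
    main_effects: dict[str, float],
    noise_sd: float = 0.1,
    seed: int = 0,
    grand_mean: float = 10.0,
    n_generators: int = 2,
    n_center: int = 3,
    factor_specs: list[FactorSpec] | None = None,
) -> DesignTable:
    """Simulate a two-level screening study with known main effects.

    The response is grand_mean + sum(effect/2 * x) + noise, so a factor's
    *effect* (change from -1 to +1) equals the stated value exactly in the
    noiseless limit.
    """
    symbols = list(main_effects)
    design = make_fractional_factorial(
        len(symbols),
        n_generators,
        n_center=n_center,
        factor_specs=factor_specs
        or [FactorSpec(name=s, symbol=s, low=-1.0, high=1.0) for s in symbols],
    )
    coded = design.coded.to_numpy()
    half = np.array([main_effects[s] / 2.0 for s in design.symbols])
    mu = grand_mean + coded @ half
    rng = np.random.default_rng(seed)
    y = mu + rng.normal(0.0, noise_sd, size=len(mu))
    return design.with_responses(pd.DataFrame({"y": y}))


def simulate_calibration(
    slope: float,
    intercept: float,
    noise_sd: float,
    levels,
    replicates: int = 1,
    seed: int = 0,
    analyte: str = "synthetic",
    role: str = "impurity",
    specification_limit_pct: float | None = 0.2,
) -> CalibrationSeries:
    """Simulate a calibration series from a known line plus Gaussian noise."""
    levels = np.asarray(levels, dtype=float)
    if len(levels) < 3:
        raise ValueError("need at least 3 concentration levels")
    conc = np.repeat(levels, replicates)
    rng = np.random.default_rng(seed)
    signals = slope * conc + intercept + rng.normal(0.0, noise_sd, size=len(conc))
    return CalibrationSeries(
        analyte=analyte,
        concentrations=tuple(conc),
        signals=tuple(signals),
        role=role,
        specification_limit_pct=specification_limit_pct,
    )
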