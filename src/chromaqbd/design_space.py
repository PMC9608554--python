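"""Probabilistic design-space mapping by Monte Carlo uncertainty propagation.

The method's performance is summarised by *separation criteria*: each one
is the retention time of the beginning of a later peak minus the retention
time of the end of an earlier peak, and the method is acceptable when every
criterion is non-negative (baseline separation). The *design space* (DS)
is the sub-region of the gridded knowledge space where all criteria are met
with predictive probability pi at or above a threshold (default 85%).

Uncertainty model
-----------------
For a fitted surface with coefficients b, covariance sigma2 (X'X)^-1 and
nu = n - p residual degrees of freedom, the posterior under the standard
noninformative prior is

    sigma*^2 ~ nu sigma2_hat / chi2(nu),     b* | sigma* ~ N(b_hat, sigma*^2 (X'X)^-1)

and each Monte Carlo iteration predicts the criterion at a point x as
x'b* (plus N(0, sigma*^2) observation noise when enabled). pi is the
fraction of iterations in which every criterion meets its threshold.

Criterion models
----------------
Two routes to a criterion's sampling distribution are provided:

* ``"indirect"`` (default): the criterion is computed per run from the
  measured response columns and fitted as its own surface. Because the
  paired retention times come from the same chromatogram, their errors
  are almost perfectly correlated and the per-run difference is far less
  noisy than the individual responses; modelling the difference directly
  retains that cancellation.
* ``"difference"``: the criterion is the difference of two independently
  sampled response models. This ignores the residual correlation between
  the paired responses and therefore overstates the criterion's variance;
  it is kept for sensitivity analysis, optionally with jointly drawn
  observation noise from the empirical residual covariance
  (``joint_across_responses``).

Reproducibility: each grid point uses its own RNG stream derived from
(master seed, point index), so pi values do not depend on evaluation order
or chunking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .designs import DesignTable
from .factors import FactorSpec, code_factors
from .rsm import ModelFit, fit_ols

__all__ = [
    "CMADefinition",
    "MCConfig",
    "DesignSpaceResult",
    "GradientProgram",
    "make_grid",
    "evaluate_cma",
    "fit_cma_surfaces",
    "mc_predictive_probability",
    "compute_design_space",
    "slice_2d",
    "working_point_to_gradient_program",
]


@dataclass(frozen=True)
class CMADefinition:
    """A separation criterion: minuend response minus subtrahend response.

    The criterion is satisfied when ``minuend - subtrahend >= threshold``
    (threshold in minutes, default 0 = touching peaks).
    """

    name: str
    minuend_response: str
    subtrahend_response: str
    threshold: float = 0.0

    def compute(self, responses: pd.DataFrame | dict) -> pd.Series | float:
        return evaluate_cma(responses, self)

    @classmethod
    def parse(cls, text: str) -> "CMADefinition":
        """Parse ``name:minuend-subtrahend>=threshold`` (threshold optional)."""
        name, _, rest = text.partition(":")
        if not rest:
            raise ValueError(f"cannot parse CMA {text!r}")
        thr = 0.0
        if ">=" in rest:
            rest, _, t = rest.partition(">=")
            thr = float(t)
        minu, _, sub = rest.partition("-")
        if not sub:
            raise ValueError(f"cannot parse CMA {text!r}: need minuend-subtrahend")
        return cls(name.strip(), minu.strip(), sub.strip(), thr)


def evaluate_cma(responses, cma: CMADefinition):
    """Criterion value(s) from named response values (table, dict or Series)."""
    try:
        minu = responses[cma.minuend_response]
        sub = responses[cma.subtrahend_response]
    except KeyError as err:
        raise KeyError(f"CMA {cma.name}: missing response {err}") from err
    return minu - sub


@dataclass(frozen=True)
class MCConfig:
    """Monte Carlo settings for predictive-probability computation."""

    iterations: int = 5000
    seed: int = 0
    include_observation_noise: bool = True
    sample_sigma: bool = True
    joint_across_responses: bool = False
    cma_mode: str = "indirect"  # or "difference"

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.cma_mode not in ("indirect", "difference"):
            raise ValueError(f"unknown cma_mode {self.cma_mode!r}")
        if self.iterations < 100:
            warnings.warn(
                f"iterations={self.iterations} gives a large Monte Carlo error on pi"
            )


def make_grid(specs: list[FactorSpec]) -> pd.DataFrame:
    """Full Cartesian grid of the knowledge space in natural units.

    Each factor contributes ``grid_levels`` evenly spaced levels including
    both endpoints; columns are named by factor symbol.
    """
    axes = [s.grid() for s in specs]
    mesh = np.meshgrid(*axes, indexing="ij")
    return pd.DataFrame(
        {s.symbol: m.ravel() for s, m in zip(specs, mesh)}
    )


def fit_cma_surfaces(
    design: DesignTable, cmas: list[CMADefinition], order: str = "quadratic"
) -> dict[str, ModelFit]:
    """Fit each separation criterion as its own response surface.

    The criterion is evaluated per run from the measured response columns
    and the resulting column fitted by OLS, preserving the within-run
    error cancellation between the paired retention times.
    """
    fits = {}
    for cma in cmas:
        col = evaluate_cma(design.data, cma)
        augmented = design.with_responses(
            pd.concat([design.responses, col.rename(cma.name)], axis=1)
        )
        fits[cma.name] = fit_ols(augmented, cma.name, order)
    return fits


class _ModelAtGrid:
    """Precomputed per-point prediction mean and leverage for one model.

    The coefficient draw enters the criterion only through x'b*, whose
    conditional distribution given sigma* is
    N(x'b_hat, sigma*^2 x'(X'X)^-1 x), so sampling the scalar directly is
    exact and avoids materialising coefficient vectors.
    """

    def __init__(self, fit: ModelFit, coded_points: np.ndarray):
        rows = fit.design_row(np.atleast_2d(coded_points))
        xtx_inv = fit.xtx_inv
        self.mean = rows @ fit.beta
        self.unit_var = np.einsum("ij,jk,ik->i", rows, xtx_inv, rows)
        self.sigma2 = fit.sigma2
        self.dof = fit.dof

    def draw(self, i: int, n: int, rng: np.random.Generator, config: MCConfig) -> np.ndarray:
        if config.sample_sigma and self.dof > 0 and self.sigma2 > 0:
            s2 = self.dof * self.sigma2 / rng.chisquare(self.dof, n)
        else:
            s2 = np.full(n, self.sigma2)
        draws = self.mean[i] + np.sqrt(s2 * self.unit_var[i]) * rng.standard_normal(n)
        if config.include_observation_noise:
            draws = draws + np.sqrt(s2) * rng.standard_normal(n)
        return draws


def _empirical_residual_cov(fits: dict[str, ModelFit]) -> tuple[list[str], np.ndarray]:
    names = list(fits)
    resid = np.column_stack(
        [fits[nm].y - fits[nm].model_matrix @ fits[nm].beta for nm in names]
    )
    return names, np.cov(resid, rowvar=False)


class _GridSampler:
    """Shared precomputation for pi evaluation over a set of coded points."""

    def __init__(
        self,
        fits: dict[str, ModelFit],
        cmas: list[CMADefinition],
        coded_points: np.ndarray,
        config: MCConfig,
    ):
        self.config = config
        self.direct = [c for c in cmas if c.name in fits]
        self.viadiff = [c for c in cmas if c.name not in fits]
        needed = sorted(
            {c.minuend_response for c in self.viadiff}
            | {c.subtrahend_response for c in self.viadiff}
        )
        missing = [nm for nm in needed if nm not in fits]
        if missing:
            raise KeyError(f"no fitted model for response(s) {missing}")
        names = [c.name for c in self.direct] + needed
        pts = np.atleast_2d(np.asarray(coded_points, dtype=float))
        self.models = {nm: _ModelAtGrid(fits[nm], pts) for nm in names}
        self.joint_eps_cov = None
        if self.viadiff and config.joint_across_responses and config.include_observation_noise:
            _, self.joint_eps_cov = _empirical_residual_cov(
                {nm: fits[nm] for nm in needed}
            )
            self.joint_names = needed

    def satisfied(self, i: int, rng: np.random.Generator) -> np.ndarray:
        """Boolean (iterations,) array: all criteria satisfied per iteration."""
        n = self.config.iterations
        cfg = self.config
        ok = np.ones(n, dtype=bool)
        for cma in self.direct:
            s = self.models[cma.name].draw(i, n, rng, cfg)
            ok &= s >= cma.threshold
        if self.viadiff:
            if self.joint_eps_cov is not None:
                cfg_resp = replace(cfg, include_observation_noise=False)
                draws = {
                    nm: self.models[nm].draw(i, n, rng, cfg_resp)
                    for nm in self.joint_names
                }
                eps = rng.multivariate_normal(
                    np.zeros(len(self.joint_names)), self.joint_eps_cov, size=n
                )
                for j, nm in enumerate(self.joint_names):
                    draws[nm] = draws[nm] + eps[:, j]
            else:
                draws = {
                    nm: m.draw(i, n, rng, cfg)
                    for nm, m in self.models.items()
                    if nm not in {c.name for c in self.direct}
                }
            for cma in self.viadiff:
                s = draws[cma.minuend_response] - draws[cma.subtrahend_response]
                ok &= s >= cma.threshold
        return ok


def _point_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(index,)))


def mc_predictive_probability(
    fits: dict[str, ModelFit],
    cmas: list[CMADefinition],
    point_coded,
    config: MCConfig = MCConfig(),
    point_index: int = 0,
) -> float:
    """Monte Carlo probability that every criterion is met at one point.

    ``fits`` maps names to fitted surfaces. A criterion whose *own name*
    appears in ``fits`` is sampled from that directly fitted surface
    (indirect CMA modelling); otherwise it is formed per iteration as the
    difference of the two named response models, each sampled
    independently.
    """
    sampler = _GridSampler(fits, cmas, np.asarray(point_coded, dtype=float), config)
    rng = _point_rng(config.seed, point_index)
    return float(sampler.satisfied(0, rng).mean())


@dataclass
class DesignSpaceResult:
    """Per-grid-point predictive probability and the thresholded DS mask."""

    specs: list[FactorSpec]
    grid: pd.DataFrame  # natural units, one column per factor symbol
    pi: np.ndarray
    threshold_pi: float
    working_point: np.ndarray | None = None  # natural units

    @property
    def mask(self) -> np.ndarray:
        return self.pi >= self.threshold_pi  # ties at the threshold are inside

    @property
    def coded(self) -> pd.DataFrame:
        x = code_factors(self.grid.to_numpy(), self.specs, warn_outside=False)
        return pd.DataFrame(x, columns=self.grid.columns)

    @property
    def working_point_in_ds(self) -> bool | None:
        if self.working_point is None:
            return None
        d = np.abs(self.grid.to_numpy() - np.asarray(self.working_point)).sum(axis=1)
        return bool(self.mask[int(np.argmin(d))])

    def to_frame(self) -> pd.DataFrame:
        df = self.grid.copy()
        df["pi"] = self.pi
        df["in_ds"] = self.mask
        return df

    def summary(self) -> dict:
        n_in = int(self.mask.sum())
        out = {
            "n_grid": int(len(self.grid)),
            "n_in_ds": n_in,
            "fraction_in_ds": n_in / len(self.grid),
            "threshold_pi": self.threshold_pi,
        }
        if n_in:
            inside = self.grid[self.mask]
            out["bounding_box"] = {
                c: [float(inside[c].min()), float(inside[c].max())] for c in inside
            }
        if self.working_point is not None:
            out["working_point"] = [float(v) for v in self.working_point]
            out["working_point_in_ds"] = self.working_point_in_ds
        return out


def compute_design_space(
    fits: dict[str, ModelFit],
    cmas: list[CMADefinition],
    specs: list[FactorSpec],
    threshold_pi: float = 0.85,
    config: MCConfig = MCConfig(),
    grid: pd.DataFrame | None = None,
    working_point=None,
) -> DesignSpaceResult:
    """Map pi over the gridded knowledge space and threshold it.

    An empty design space is a valid outcome, reported in the summary
    rather than raised. Each grid point gets an independent RNG stream
    keyed by (config.seed, point index).
    """
    if grid is None:
        grid = make_grid(specs)
    if len(grid) == 0:
        raise ValueError("grid is empty")
    coded = code_factors(grid.to_numpy(), specs, warn_outside=False)
    sampler = _GridSampler(fits, cmas, coded, config)
    pi = np.empty(len(grid))
    for i in range(len(grid)):
        rng = _point_rng(config.seed, i)
        pi[i] = sampler.satisfied(i, rng).mean()
    wp = None if working_point is None else np.asarray(working_point, dtype=float)
    return DesignSpaceResult(list(specs), grid.reset_index(drop=True), pi, threshold_pi, wp)


def slice_2d(
    result: DesignSpaceResult, fixed_factor: str, fixed_value: float
) -> DesignSpaceResult:
    """Restrict a DS result to the sub-grid at one level of one factor.

    If ``fixed_value`` is not a grid level the nearest level is used with
    a warning.
    """
    col = result.grid[fixed_factor]
    levels = np.unique(col.to_numpy())
    if not np.any(np.isclose(levels, fixed_value)):
        nearest = float(levels[np.argmin(np.abs(levels - fixed_value))])
        warnings.warn(
            f"{fixed_value} is not a grid level of {fixed_factor}; using {nearest}"
        )
        fixed_value = nearest
    keep = np.isclose(col.to_numpy(), fixed_value)
    sub_specs = [s for s in result.specs if s.symbol != fixed_factor]
    sub_grid = result.grid.loc[keep, [s.symbol for s in sub_specs]].reset_index(drop=True)
    return DesignSpaceResult(
        sub_specs, sub_grid, result.pi[keep], result.threshold_pi, None
    )


@dataclass(frozen=True)
class GradientProgram:
    """Piecewise-linear %organic timetable of a gradient elution method."""

    timetable: tuple[tuple[float, float], ...]  # (time min, %organic)

    def __post_init__(self) -> None:
        times = [t for t, _ in self.timetable]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("breakpoint times must be strictly increasing")
        if any(not (0.0 <= pct <= 100.0) for _, pct in self.timetable):
            raise ValueError("%organic must lie in [0, 100]")

    @property
    def total_time(self) -> float:
        return self.timetable[-1][0]

    def percent_at(self, t: float) -> float:
        times = np.array([b[0] for b in self.timetable])
        pcts = np.array([b[1] for b in self.timetable])
        return float(np.interp(t, times, pcts))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.timetable, columns=["time_min", "percent_organic"])


def working_point_to_gradient_program(
    point_natural,
    gradient_end_time: float = 17.0,
    final_pct: float = 70.0,
    return_time: float = 4.0,
    reequil: float = 2.0,
) -> GradientProgram:
    """Translate a working point into a runnable gradient timetable.

    The point is (start %organic, salt concentration, gradient start time);
    the program holds the start composition during the isocratic step, ramps
    linearly to ``final_pct`` by ``gradient_end_time``, steps back to the
    start composition within ``return_time`` minutes and re-equilibrates for
    ``reequil`` more minutes.
    """
    start_pct, _, grad_start = (float(v) for v in point_natural)
    if grad_start >= gradient_end_time:
        raise ValueError(
            f"gradient start time ({grad_start}) must precede end time ({gradient_end_time})"
        )
    return GradientProgram(
        (
            (0.0, start_pct),
            (grad_start, start_pct),
            (gradient_end_time, final_pct),
            (gradient_end_time + return_time, start_pct),
            (gradient_end_time + return_time + reequil, start_pct),
        )
    )
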