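"""CSV/JSON/YAML readers and writers, study configuration, and the pipeline.

Design tables travel as plain CSV (comma-separated, UTF-8, dot decimal)
with one column per factor in natural units plus optional response
columns; factor metadata lives in a JSON or YAML sidecar. A study
configuration bundles every setting the optimization pipeline needs so a
run is reproducible from the config plus a seed alone.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .design_space import (
    CMADefinition,
    MCConfig,
    compute_design_space,
    fit_cma_surfaces,
    working_point_to_gradient_program,
)
from .designs import DesignTable
from .factors import FactorSpec
from .rsm import ModelFit, coefficient_inference, fit_ols

__all__ = [
    "read_factor_specs",
    "write_factor_specs",
    "read_design_csv",
    "write_design_csv",
    "load_fixture",
    "StudyConfig",
    "default_study_config",
    "load_config",
    "run_pipeline",
]


def _load_mapping(path: Path) -> dict:
    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        return yaml.safe_load(text)
    return json.loads(text)


def read_factor_specs(path) -> list[FactorSpec]:
    """Read factor metadata from a JSON or YAML sidecar file."""
    doc = _load_mapping(Path(path))
    return [FactorSpec.from_dict(d) for d in doc["factors"]]


def write_factor_specs(specs: list[FactorSpec], path, responses: list[str] | None = None) -> None:
    doc = {"factors": [s.to_dict() for s in specs]}
    if responses:
        doc["responses"] = responses
    text = (
        yaml.safe_dump(doc, sort_keys=False)
        if str(path).endswith((".yaml", ".yml"))
        else json.dumps(doc, indent=1)
    )
    Path(path).write_text(text)


def read_design_csv(path, specs: list[FactorSpec]) -> DesignTable:
    """Read a run table; factor columns are matched by symbol.

    A ``run`` column, if present, becomes the run index. Any other column
    is treated as a response. Missing factor columns and non-numeric cells
    are reported with row and column.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as err:
        raise ValueError(f"{path}: empty or unparsable design CSV") from err
    if "run" in df.columns:
        df = df.set_index("run")
    symbols = [s.symbol for s in specs]
    missing = [s for s in symbols if s not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing factor column(s) {missing}")
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            row = df.index[bad][0]
            raise ValueError(f"{path}: non-numeric value in column {col!r}, run {row}")
        df[col] = pd.to_numeric(df[col])
    if df.isna().any().any():
        col = df.columns[df.isna().any()][0]
        row = df.index[df[col].isna()][0]
        raise ValueError(f"{path}: missing value in column {col!r}, run {row}")
    ordered = df[symbols + [c for c in df.columns if c not in symbols]]
    return DesignTable(list(specs), ordered)


def write_design_csv(design: DesignTable, path) -> None:
    design.data.to_csv(path, index_label="run")


def load_fixture(name: str) -> DesignTable:
    """Load a packaged study: ``table1_screening`` or ``table2_bbd``."""
    pkg = resources.files("chromaqbd.data")
    specs = read_factor_specs(pkg / f"{name}.json")
    return read_design_csv(pkg / f"{name}.csv", specs)


@dataclass
class StudyConfig:
    """Everything the optimization pipeline needs besides the run table."""

    factors: list[FactorSpec]
    response_orders: dict[str, str]  # response -> "linear" | "quadratic"
    cmas: list[CMADefinition]
    cma_order: str = "quadratic"
    threshold_pi: float = 0.85
    mc: MCConfig = field(default_factory=MCConfig)
    gradient_end_time: float = 17.0
    final_pct: float = 70.0
    return_time: float = 4.0
    reequil: float = 2.0
    working_point: list[float] | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold_pi <= 1.0):
            raise ValueError("threshold_pi must lie in (0, 1]")
        declared = set(self.response_orders)
        for cma in self.cmas:
            for nm in (cma.minuend_response, cma.subtrahend_response):
                if nm not in declared:
                    raise ValueError(f"CMA {cma.name} references undeclared response {nm!r}")

    def to_dict(self) -> dict:
        return {
            "factors": [s.to_dict() for s in self.factors],
            "response_orders": dict(self.response_orders),
            "cmas": [
                {
                    "name": c.name,
                    "minuend_response": c.minuend_response,
                    "subtrahend_response": c.subtrahend_response,
                    "threshold": c.threshold,
                }
                for c in self.cmas
            ],
            "cma_order": self.cma_order,
            "threshold_pi": self.threshold_pi,
            "mc": {
                "iterations": self.mc.iterations,
                "seed": self.mc.seed,
                "include_observation_noise": self.mc.include_observation_noise,
                "sample_sigma": self.mc.sample_sigma,
                "joint_across_responses": self.mc.joint_across_responses,
                "cma_mode": self.mc.cma_mode,
            },
            "gradient_end_time": self.gradient_end_time,
            "final_pct": self.final_pct,
            "return_time": self.return_time,
            "reequil": self.reequil,
            "working_point": self.working_point,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        return cls(
            factors=[FactorSpec.from_dict(f) for f in d["factors"]],
            response_orders=dict(d["response_orders"]),
            cmas=[CMADefinition(**c) for c in d["cmas"]],
            cma_order=d.get("cma_order", "quadratic"),
            threshold_pi=d.get("threshold_pi", 0.85),
            mc=MCConfig(**d.get("mc", {})),
            gradient_end_time=d.get("gradient_end_time", 17.0),
            final_pct=d.get("final_pct", 70.0),
            return_time=d.get("return_time", 4.0),
            reequil=d.get("reequil", 2.0),
            working_point=d.get("working_point"),
        )


def default_study_config(seed: int = 0, iterations: int = 5000) -> StudyConfig:
    """The packaged optimization study's settings.

    Quadratic surfaces for the three early responses and a linear one for
    the last; two separation criteria at threshold 0; a 21 x 21 x 11 grid;
    pi threshold 85%; gradient ramp ending at 17 min and reaching 70%
    organic; working point 37.5% / 45 mM / 10.0 min.
    """
    pkg = resources.files("chromaqbd.data")
    specs = read_factor_specs(pkg / "table2_bbd.json")
    return StudyConfig(
        factors=specs,
        response_orders={
            "t_e_bup": "quadratic",
            "t_b_imp2": "quadratic",
            "t_e_imp2": "quadratic",
            "t_b_imp3": "linear",
        },
        cmas=[
            CMADefinition("s1", "t_b_imp2", "t_e_bup", 0.0),
            CMADefinition("s2", "t_b_imp3", "t_e_imp2", 0.0),
        ],
        mc=MCConfig(iterations=iterations, seed=seed),
        working_point=[37.5, 45.0, 10.0],
    )


def _provenance(config: StudyConfig) -> dict:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return {
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": config.mc.seed,
        "python": sys.version.split()[0],
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }


def load_config(path) -> StudyConfig:
    return StudyConfig.from_dict(_load_mapping(Path(path)))


def run_pipeline(config: StudyConfig, design: DesignTable | str | Path, outdir) -> dict:
    """Fit models, map the design space, and emit all artifacts.

    Writes ``fits.json`` (all fitted surfaces), ``coefficients.csv``,
    ``design_space.csv`` (one row per grid point with pi and the DS flag),
    ``gradient_program.csv`` if a working point is configured, and
    ``report.json`` with the DS summary and a provenance block. Returns
    the report dict. Deterministic under a fixed config and seed.
    """
    if not isinstance(design, DesignTable):
        design = read_design_csv(design, config.factors)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    fits: dict[str, ModelFit] = {}
    for resp, order in config.response_orders.items():
        try:
            fits[resp] = fit_ols(design, resp, order)
        except Exception as err:
            raise RuntimeError(f"[fit] response {resp!r}: {err}") from err
    try:
        if config.mc.cma_mode == "indirect":
            fits.update(fit_cma_surfaces(design, config.cmas, config.cma_order))
    except Exception as err:
        raise RuntimeError(f"[fit] criterion surfaces: {err}") from err

    with open(outdir / "fits.json", "w") as fh:
        json.dump({nm: f.to_dict() for nm, f in fits.items()}, fh, indent=1)
    coef = pd.concat(
        {nm: coefficient_inference(f) for nm, f in fits.items()}, names=["response", "term"]
    )
    coef.to_csv(outdir / "coefficients.csv")

    try:
        mc_fits = (
            fits
            if config.mc.cma_mode == "indirect"
            else {nm: f for nm, f in fits.items() if nm in config.response_orders}
        )
        result = compute_design_space(
            mc_fits,
            config.cmas,
            config.factors,
            threshold_pi=config.threshold_pi,
            config=config.mc,
            working_point=config.working_point,
        )
    except Exception as err:
        raise RuntimeError(f"[design-space] {err}") from err
    ds_frame = result.to_frame()
    ds_frame.to_csv(outdir / "design_space.csv", index=False, float_format="%.10g")

    report = {"design_space": result.summary(), "provenance": _provenance(config)}
    report["fit_statistics"] = {
        nm: {"order": f.order, "r2": f.r2, "adj_r2": f.adj_r2, "pred_r2": f.pred_r2}
        for nm, f in fits.items()
    }
    if config.working_point is not None:
        try:
            program = working_point_to_gradient_program(
                config.working_point,
                config.gradient_end_time,
                config.final_pct,
                config.return_time,
                config.reequil,
            )
        except Exception as err:
            raise RuntimeError(f"[gradient] {err}") from err
        program.to_frame().to_csv(outdir / "gradient_program.csv", index=False)
        report["gradient_program"] = list(map(list, program.timetable))
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1)
    return report
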