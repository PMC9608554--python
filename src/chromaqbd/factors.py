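"""Controllable method parameters and the coded-unit convention.

A factor (critical method parameter) is a controllable setting of the
chromatographic method -- e.g. the acetonitrile ratio at the start of the
gradient, the chaotropic-salt concentration, or the gradient start time.
Response-surface models are always fitted in *coded* units, where the low
and high level of each factor map to -1 and +1 and the centre of the range
to 0:

    x = 2 * (v - (low + high)/2) / (high - low)

Values outside the stated range are permitted (they code to |x| > 1) but
trigger a warning, because design-space evaluation may probe points near or
on the border of the knowledge space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["FactorSpec", "code_factors", "decode_factors"]


@dataclass(frozen=True)
class FactorSpec:
    """One controllable method parameter with its natural-unit range.

    Parameters
    ----------
    name : str
        Descriptive name, e.g. ``"ACN at gradient start"``.
    symbol : str
        Single-letter symbol (A-F) used in model term labels.
    low, high : float
        Natural-unit levels that code to -1 and +1.
    units : str
        Natural units, e.g. ``"%"``, ``"mM"``, ``"min"``.
    grid_levels : int
        Number of evenly spaced levels used when gridding the knowledge
        space for design-space mapping (>= 2).
    """

    name: str
    symbol: str
    low: float
    high: float
    units: str = ""
    grid_levels: int = 2

    def __post_init__(self) -> None:
        if not (self.low < self.high):
            raise ValueError(
                f"factor {self.symbol!r}: low ({self.low}) must be < high ({self.high})"
            )
        if self.grid_levels < 2:
            raise ValueError(f"factor {self.symbol!r}: grid_levels must be >= 2")
        if len(self.symbol) != 1 or not self.symbol.isalpha():
            raise ValueError(f"factor symbol must be a single letter, got {self.symbol!r}")

    @property
    def mid(self) -> float:
        return 0.5 * (self.low + self.high)

    @property
    def half_range(self) -> float:
        return 0.5 * (self.high - self.low)

    def code(self, values):
        """Natural units -> coded units for this factor."""
        return (np.asarray(values, dtype=float) - self.mid) / self.half_range

    def decode(self, coded):
        """Coded units -> natural units for this factor."""
        return np.asarray(coded, dtype=float) * self.half_range + self.mid

    def grid(self) -> np.ndarray:
        """Evenly spaced natural-unit levels, endpoints included."""
        return np.linspace(self.low, self.high, self.grid_levels)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "symbol": self.symbol,
            "low": self.low,
            "high": self.high,
            "units": self.units,
            "grid_levels": self.grid_levels,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FactorSpec":
        return cls(**d)


def _check_specs(specs: list[FactorSpec]) -> None:
    symbols = [s.symbol for s in specs]
    if len(set(symbols)) != len(symbols):
        raise ValueError(f"duplicate factor symbols: {symbols}")


def code_factors(values, specs: list[FactorSpec], warn_outside: bool = True) -> np.ndarray:
    """Convert natural-unit factor settings to coded units.

    ``values`` may be a vector (one point) or a matrix (one row per run);
    the last axis must match ``specs``. Settings outside [low, high] code
    to |x| > 1 and emit a warning rather than an error.
    """
    _check_specs(specs)
    v = np.atleast_2d(np.asarray(values, dtype=float))
    if v.shape[-1] != len(specs):
        raise ValueError(f"got {v.shape[-1]} values for {len(specs)} factor specs")
    coded = np.column_stack([s.code(v[:, j]) for j, s in enumerate(specs)])
    if warn_outside and np.any(np.abs(coded) > 1 + 1e-9):
        warnings.warn("some factor settings lie outside [low, high]; coded |x| > 1")
    out = coded if np.ndim(values) > 1 else coded[0]
    return out


def decode_factors(coded, specs: list[FactorSpec]) -> np.ndarray:
    """Exact inverse of :func:`code_factors`."""
    _check_specs(specs)
    x = np.atleast_2d(np.asarray(coded, dtype=float))
    if x.shape[-1] != len(specs):
        raise ValueError(f"got {x.shape[-1]} coded values for {len(specs)} factor specs")
    nat = np.column_stack([s.decode(x[:, j]) for j, s in enumerate(specs)])
    return nat if np.ndim(coded) > 1 else nat[0]
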