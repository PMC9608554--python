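"""Two-level fractional factorial and Box-Behnken design generation.

The screening stage uses a regular two-level fraction 2^(k-p): all +/-1
combinations of k-p basic factors, with the remaining p columns generated
as products of basic columns (alias words such as E=ABC). The defining
relation is the set of words that multiply to the identity column; the
design resolution is the length of its shortest word.

The optimization stage uses a Box-Behnken design (BBD): for three factors,
the twelve edge midpoints of the cube -- every (+/-1, +/-1, 0) pattern over
a factor pair -- plus replicated centre points.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .factors import FactorSpec, code_factors, decode_factors

__all__ = ["DesignTable", "make_fractional_factorial", "make_box_behnken"]

_ALPHABET = "ABCDEFGHJKLMNPQRSTUVWXYZ"  # I reserved for the identity word


@dataclass
class DesignTable:
    """A run matrix in natural units with optional response columns.

    ``data`` holds one column per factor (natural units, named by factor
    symbol) followed by any response columns; the coded matrix is derived
    on demand from the factor specs. Centre-point rows are rows whose coded
    entries are all (numerically) zero.
    """

    factors: list[FactorSpec]
    data: pd.DataFrame
    defining_relation: list[str] | None = None
    resolution: int | None = None

    def __post_init__(self) -> None:
        missing = [s.symbol for s in self.factors if s.symbol not in self.data.columns]
        if missing:
            raise ValueError(f"design data lacks factor columns {missing}")

    @property
    def symbols(self) -> list[str]:
        return [s.symbol for s in self.factors]

    @property
    def n_runs(self) -> int:
        return len(self.data)

    @property
    def run_ids(self) -> list:
        return list(self.data.index)

    @property
    def runs(self) -> pd.DataFrame:
        """Natural-unit factor settings, one row per run."""
        return self.data[self.symbols]

    @property
    def coded(self) -> pd.DataFrame:
        """Coded factor settings in [-1, +1] (0 at centre)."""
        x = code_factors(self.runs.to_numpy(), self.factors, warn_outside=False)
        # design levels are exact by construction; snap near-integer codes
        x = np.where(np.isclose(x, np.rint(x), atol=1e-9), np.rint(x), x)
        return pd.DataFrame(x, columns=self.symbols, index=self.data.index)

    @property
    def response_names(self) -> list[str]:
        return [c for c in self.data.columns if c not in self.symbols]

    @property
    def responses(self) -> pd.DataFrame:
        return self.data[self.response_names]

    @property
    def center_mask(self) -> np.ndarray:
        return np.all(np.isclose(self.coded.to_numpy(), 0.0), axis=1)

    @property
    def factorial_mask(self) -> np.ndarray:
        return ~self.center_mask

    def with_responses(self, responses: pd.DataFrame | dict) -> "DesignTable":
        """Return a copy with response columns attached."""
        resp = pd.DataFrame(responses)
        if len(resp) != self.n_runs:
            raise ValueError("response rows do not match design runs")
        resp.index = self.data.index
        data = pd.concat([self.runs, resp], axis=1)
        return DesignTable(self.factors, data, self.defining_relation, self.resolution)

    def spec_for(self, symbol: str) -> FactorSpec:
        for s in self.factors:
            if s.symbol == symbol:
                return s
        raise KeyError(symbol)


def _word_product(*words: str) -> str:
    """Multiply alias words: letters appearing an even number of times cancel."""
    counts: dict[str, int] = {}
    for w in words:
        for ch in w:
            counts[ch] = counts.get(ch, 0) + 1
    return "".join(sorted(ch for ch, c in counts.items() if c % 2 == 1))


def _default_generators(n_factors: int, n_generators: int) -> dict[str, str]:
    """Default alias words for the generated factors.

    Generated factor j is the product of all basic factors except one; the
    omitted basic factor alternates between the two ends of the basic list
    (last, first, second-to-last, second, ...), so for 2^(6-2) the defaults
    are E=ABC, F=BCD (resolution IV).
    """
    k, p = n_factors, n_generators
    basics = list(_ALPHABET[: k - p])
    gens: dict[str, str] = {}
    for j in range(p):
        omit = basics[-(1 + j // 2)] if j % 2 == 0 else basics[j // 2]
        word = "".join(b for b in basics if b != omit)
        gens[_ALPHABET[k - p + j]] = word
    return gens


def make_fractional_factorial(
    n_factors: int,
    n_generators: int,
    n_center: int = 0,
    generators: dict[str, str] | None = None,
    factor_specs: list[FactorSpec] | None = None,
    shuffle_seed: int | None = None,
) -> DesignTable:
    """Generate a regular 2^(k-p) fraction with appended centre points.

    Parameters
    ----------
    n_factors, n_generators : int
        k and p of the 2^(k-p) fraction; ``n_generators = 0`` gives the
        full factorial.
    n_center : int
        Number of all-zero centre rows appended after the factorial rows.
    generators : dict, optional
        Alias words, e.g. ``{"E": "ABC", "F": "BCD"}`` (the default for
        2^(6-2)). Words may reference basic factors only.
    factor_specs : list of FactorSpec, optional
        Natural-unit ranges; defaults to dimensionless [-1, +1] factors.
    shuffle_seed : int, optional
        If given, the run order is randomized with this seed; by default
        runs are in standard order with centre points last.
    """
    k, p = n_factors, n_generators
    if k < 2:
        raise ValueError("need at least 2 factors")
    if not (0 <= p < k):
        raise ValueError("need 0 <= n_generators < n_factors")
    symbols = list(_ALPHABET[:k]) if factor_specs is None else [s.symbol for s in factor_specs]
    basics = symbols[: k - p]
    if generators is None:
        gens = _default_generators(k, p)
        # re-key onto the actual symbols if custom specs are used
        gens = {
            symbols[k - p + j]: "".join(
                basics[_ALPHABET.index(ch)] for ch in word
            )
            for j, (word) in enumerate(gens.values())
        }
    else:
        gens = dict(generators)
        if sorted(gens) != sorted(symbols[k - p :]):
            raise ValueError(
                f"generators must define exactly the generated factors {symbols[k - p:]}"
            )
        for g, word in gens.items():
            bad = [ch for ch in word if ch not in basics]
            if bad:
                raise ValueError(f"generator {g}={word} references non-basic factors {bad}")

    base = np.array(list(itertools.product([-1.0, 1.0], repeat=k - p)))
    cols = {s: base[:, j] for j, s in enumerate(basics)}
    seen = {tuple(v) for v in base.T}
    for g in symbols[k - p :]:
        col = np.prod([cols[ch] for ch in gens[g]], axis=0)
        if tuple(col) in seen or tuple(-col) in seen:
            raise ValueError(f"generator {g}={gens[g]} duplicates an existing column")
        seen.add(tuple(col))
        cols[g] = col

    coded = np.column_stack([cols[s] for s in symbols])
    if n_center:
        coded = np.vstack([coded, np.zeros((n_center, k))])
    if shuffle_seed is not None:
        rng = np.random.default_rng(shuffle_seed)
        coded = coded[rng.permutation(len(coded))]

    # defining relation: products of every non-empty subset of generator words
    words = []
    gen_words = [g + gens[g] for g in symbols[k - p :]]
    for r in range(1, p + 1):
        for sub in itertools.combinations(gen_words, r):
            words.append(_word_product(*sub))
    resolution = min((len(w) for w in words), default=None)

    specs = factor_specs or [
        FactorSpec(name=s, symbol=s, low=-1.0, high=1.0) for s in symbols
    ]
    nat = decode_factors(coded, specs)
    data = pd.DataFrame(nat, columns=symbols, index=range(1, len(nat) + 1))
    return DesignTable(specs, data, defining_relation=sorted(words), resolution=resolution)


def make_box_behnken(factor_specs: list[FactorSpec], n_center: int = 4) -> DesignTable:
    """Generate a three-factor Box-Behnken design.

    The twelve edge midpoints (every (+/-1, +/-1) combination over each
    factor pair, third factor at 0) plus ``n_center`` centre rows.
    """
    if len(factor_specs) != 3:
        raise ValueError(f"Box-Behnken generation requires exactly 3 factors, got {len(factor_specs)}")
    symbols = [s.symbol for s in factor_specs]
    rows = []
    for i, j in itertools.combinations(range(3), 2):
        for a, b in itertools.product([-1.0, 1.0], repeat=2):
            row = [0.0, 0.0, 0.0]
            row[i], row[j] = a, b
            rows.append(row)
    coded = np.array(rows + [[0.0, 0.0, 0.0]] * n_center)
    nat = decode_factors(coded, factor_specs)
    data = pd.DataFrame(nat, columns=symbols, index=range(1, len(nat) + 1))
    return DesignTable(factor_specs, data)
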