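"""Experimental designs and deviation (sum) coding matrices.

A designed experiment is described by a :class:`DesignTable` — one row per
observation, one categorical factor per column — and a :class:`ModelTerms`
declaration of which main effects and two-way interactions enter the model.
:func:`build_coding` turns the pair into the regressor matrix ``C`` used by
the ASCA+ least-squares factorization: for a factor with ``L`` levels the
block has ``L − 1`` columns, an observation at level ``l < L`` carries a one
in column ``l`` and zeros elsewhere, and an observation at the last level
carries −1 in every column of the block.  Interaction blocks are the
element-wise products of the parent factors' coding columns, giving
``(L_Z − 1)·(L_Y − 1)`` columns.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DesignTable",
    "ModelTerms",
    "CodingMatrix",
    "parse_design",
    "build_coding",
    "full_factorial",
]


@dataclass
class DesignTable:
    """Categorical factor levels for each observation of an experiment.

    Parameters
    ----------
    factors : list of str
        Factor names, in column order.
    levels : dict
        Maps each factor name to its ordered list of level labels.  The
        *last* level in this order receives the −1 deviation coding.
    codes : dict
        Maps each factor name to an integer array of per-observation level
        indices (0-based positions into ``levels``).
    """

    factors: list[str]
    levels: dict[str, list]
    codes: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if not self.factors:
            raise ValueError("design must declare at least one factor")
        n = {f: len(np.asarray(self.codes[f])) for f in self.factors}
        if len(set(n.values())) != 1:
            raise ValueError("factor assignment lengths disagree: %r" % n)
        if self.n_obs < 2:
            raise ValueError("a design needs at least two observations")
        for f in self.factors:
            codes = np.asarray(self.codes[f], dtype=np.intp)
            self.codes[f] = codes
            L = len(self.levels[f])
            if codes.min(initial=0) < 0 or (L and codes.max(initial=-1) >= L):
                raise ValueError(f"factor {f!r}: assignment outside declared levels")
            used = np.bincount(codes, minlength=L) > 0
            if not used.all():
                missing = [self.levels[f][i] for i in np.nonzero(~used)[0]]
                raise ValueError(
                    f"factor {f!r}: declared level(s) {missing} never observed"
                )

    @property
    def n_obs(self) -> int:
        return len(self.codes[self.factors[0]])

    def n_levels(self, factor: str) -> int:
        return len(self.levels[factor])

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, levels: Mapping[str, Sequence] | None = None
    ) -> "DesignTable":
        """Build a design from a DataFrame of factor columns.

        Levels are enumerated in first-appearance order unless an explicit
        order is supplied through ``levels``.  Missing cells are rejected
        with the offending row index.
        """
        if frame.shape[0] == 0 or frame.shape[1] == 0:
            raise ValueError("empty design table")
        bad = frame.isna().any(axis=1)
        if bad.any():
            row = int(np.nonzero(bad.to_numpy())[0][0])
            raise ValueError(f"design row {row} has a missing level")
        levels = dict(levels or {})
        lv: dict[str, list] = {}
        codes: dict[str, np.ndarray] = {}
        for col in frame.columns:
            values = frame[col].to_numpy()
            if col in levels:
                order = list(levels[col])
                extra = set(values) - set(order)
                if extra:
                    raise ValueError(
                        f"factor {col!r}: values {sorted(map(str, extra))} not in "
                        f"the supplied level order"
                    )
            else:
                order = list(pd.unique(values))
            index = {v: i for i, v in enumerate(order)}
            lv[col] = order
            codes[col] = np.array([index[v] for v in values], dtype=np.intp)
        return cls(list(map(str, frame.columns)), {str(k): v for k, v in lv.items()},
                   {str(k): v for k, v in codes.items()})

    def to_frame(self) -> pd.DataFrame:
        data = {
            f: [self.levels[f][i] for i in self.codes[f]] for f in self.factors
        }
        return pd.DataFrame(data)

    def cell_ids(self, factors: Sequence[str] | None = None) -> np.ndarray:
        """Integer id of the level combination (cell) of each observation."""
        factors = list(factors) if factors is not None else self.factors
        out = np.zeros(self.n_obs, dtype=np.intp)
        for f in factors:
            out = out * self.n_levels(f) + self.codes[f]
        return out


def parse_design(
    source,
    levels: Mapping[str, Sequence] | None = None,
    sep: str | None = None,
) -> DesignTable:
    """Read a design from delimited text (CSV/TSV) or an in-memory table.

    Parameters
    ----------
    source : path-like, str or pandas.DataFrame
        File with a header row and one column per factor, or a DataFrame.
    levels : mapping, optional
        Explicit level order per factor (``{"temp": [10, 20, 30]}``); the
        last level gets the −1 coding.
    sep : str, optional
        Field separator; sniffed from the file when omitted.
    """
    if isinstance(source, pd.DataFrame):
        frame = source
    else:
        path = Path(source)
        if not path.exists():
            raise FileNotFoundError(f"design file not found: {path}")
        frame = pd.read_csv(path, sep=sep or sniff_delimiter(path),
                            skipinitialspace=True)
    return DesignTable.from_frame(frame, levels=levels)


def sniff_delimiter(path) -> str:
    """Infer the field separator from the header line (tab, ';' or ',')."""
    with open(path) as fh:
        header = fh.readline()
    for candidate in ("\t", ";", ","):
        if candidate in header:
            return candidate
    return ","


def full_factorial(
    levels: Sequence[int],
    replicates: int = 1,
    names: Sequence[str] | None = None,
) -> DesignTable:
    """Balanced full-factorial design.

    ``levels`` is the number of levels per factor (each ≥ 2); every level
    combination appears exactly ``replicates`` times.  Level labels are the
    integers ``1..L``; rows are ordered with the first factor varying
    fastest and replicates of a cell adjacent.
    """
    levels = [int(L) for L in levels]
    if any(L < 2 for L in levels):
        raise ValueError("every factor needs at least two levels")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    names = list(names) if names is not None else [f"f{i + 1}" for i in range(len(levels))]
    if len(names) != len(levels):
        raise ValueError("names and levels length mismatch")
    rows = []
    # slowest factor last, replicates innermost; matches the usual listing
    # where the first factor cycles fastest within the second
    for combo in itertools.product(*[range(L) for L in reversed(levels)]):
        for _ in range(replicates):
            rows.append(tuple(reversed(combo)))
    arr = np.array(rows, dtype=np.intp)
    codes = {names[j]: arr[:, j] for j in range(len(levels))}
    lv = {names[j]: list(range(1, levels[j] + 1)) for j in range(len(levels))}
    return DesignTable(names, lv, codes)


@dataclass(frozen=True)
class ModelTerms:
    """Main effects and two-way interactions to include in the model."""

    main: tuple[str, ...]
    interactions: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if not self.main:
            raise ValueError("at least one main effect is required")
        if len(set(self.main)) != len(self.main):
            raise ValueError("duplicate main terms")
        seen = set()
        for pair in self.interactions:
            if len(pair) != 2:
                raise ValueError(
                    "only two-way interactions are supported; got %r" % (pair,)
                )
            for f in pair:
                if f not in self.main:
                    raise ValueError(
                        f"interaction member {f!r} is not a declared main term"
                    )
            key = tuple(sorted(pair))
            if key in seen:
                raise ValueError(f"duplicate interaction {pair!r}")
            seen.add(key)

    @classmethod
    def from_string(cls, spec: str) -> "ModelTerms":
        """Parse ``"A + B + A:B"`` style term specifications."""
        spec = spec.strip().lstrip("~").strip()
        main: list[str] = []
        inter: list[tuple[str, str]] = []
        for token in (t.strip() for t in spec.split("+")):
            if not token:
                continue
            if ":" in token:
                parts = tuple(p.strip() for p in token.split(":"))
                inter.append(parts)  # arity validated in __post_init__
            else:
                main.append(token)
        return cls(tuple(main), tuple(inter))

    @property
    def names(self) -> tuple[str, ...]:
        return self.main + tuple(f"{a}:{b}" for a, b in self.interactions)


@dataclass
class CodingMatrix:
    """Deviation-coded regressor matrix with per-term column blocks.

    ``blocks`` maps every term (including ``"intercept"``) to a contiguous
    column slice of ``values``; ``df`` holds the per-term column counts.
    """

    values: np.ndarray
    blocks: dict[str, slice]
    df: dict[str, int]
    terms: ModelTerms
    design: DesignTable = field(repr=False, default=None)

    @property
    def n_obs(self) -> int:
        return self.values.shape[0]

    @property
    def n_params(self) -> int:
        return self.values.shape[1]

    def term_columns(self, term: str) -> np.ndarray:
        return self.values[:, self.blocks[term]]

    def drop_term(self, term: str) -> "CodingMatrix":
        """Coding matrix with one term's block removed (for Type-III SSQ)."""
        if term not in self.blocks or term == "intercept":
            raise KeyError(f"cannot drop term {term!r}")
        keep = [t for t in self.blocks if t != term]
        cols = np.concatenate([np.arange(self.values.shape[1])[self.blocks[t]] for t in keep])
        blocks: dict[str, slice] = {}
        start = 0
        for t in keep:
            width = self.df[t]
            blocks[t] = slice(start, start + width)
            start += width
        return CodingMatrix(
            self.values[:, cols], blocks, {t: self.df[t] for t in keep},
            self.terms, self.design,
        )


def _factor_block(design: DesignTable, factor: str) -> np.ndarray:
    L = design.n_levels(factor)
    if L < 2:
        raise ValueError(
            f"factor {factor!r} has a single level (zero degrees of freedom)"
        )
    codes = design.codes[factor]
    block = np.zeros((design.n_obs, L - 1))
    last = codes == L - 1
    block[last, :] = -1.0
    rows = np.nonzero(~last)[0]
    block[rows, codes[rows]] = 1.0
    return block


def build_coding(design: DesignTable, terms: ModelTerms) -> CodingMatrix:
    """Assemble the deviation-coded matrix ``C = [1, C_A, C_B, C_AB, …]``."""
    for f in terms.main:
        if f not in design.factors:
            raise KeyError(f"term {f!r} is not a factor of the design")
    columns = [np.ones((design.n_obs, 1))]
    blocks = {"intercept": slice(0, 1)}
    df = {"intercept": 1}
    start = 1
    factor_blocks: dict[str, np.ndarray] = {}
    for f in terms.main:
        blk = _factor_block(design, f)
        factor_blocks[f] = blk
        columns.append(blk)
        blocks[f] = slice(start, start + blk.shape[1])
        df[f] = blk.shape[1]
        start += blk.shape[1]
    for a, b in terms.interactions:
        prods = [
            factor_blocks[a][:, i] * factor_blocks[b][:, j]
            for i in range(factor_blocks[a].shape[1])
            for j in range(factor_blocks[b].shape[1])
        ]
        blk = np.column_stack(prods)
        name = f"{a}:{b}"
        columns.append(blk)
        blocks[name] = slice(start, start + blk.shape[1])
        df[name] = blk.shape[1]
        start += blk.shape[1]
    values = np.hstack(columns)
    return CodingMatrix(values, blocks, df, terms, design)
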