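"""ASCA-genes baseline: variable relevance via leverage and SPE.

For a model term with at least two degrees of freedom, a PCA of the effect
matrix ``Z`` with ``r`` components yields two per-variable indices borrowed
from multivariate statistical process control:

* leverage — the variable's squared loading mass ``Σ_a P(v,a)²`` on the
  retained components;
* SPE — the squared residual of the variable's effect column after the
  rank-``r`` reconstruction, ``‖Z(·,v) − Ẑ(·,v)‖²``.

Relevant variables are expected to combine high leverage with low SPE;
high SPE with high leverage marks a poorly modelled but possibly
interesting variable, high SPE alone an odd one, and low/low a
non-relevant one.  Control limits are empirical ``1 − α`` quantiles of the
leverage and SPE values pooled over all permutations and variables of the
permutation null (variables are *not* re-sorted within permutations — the
methodological contrast with the step-up selection test).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design import CodingMatrix
from .permutation import PermutationPlan, PermutedStats, permuted_column_ssq

__all__ = ["LeverageSpeResult", "leverage_spe", "asca_genes_test"]

FLAGS = ("relevant", "poorly_modelled", "odd", "not_relevant")


def leverage_spe(Z: np.ndarray, n_components: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-variable leverage and SPE of an effect matrix.

    Requires ``2 <= n_components <= rank(Z)``; one-df terms cannot support
    the two indices (use the variable-selection test instead).
    """
    Z = np.asarray(Z, dtype=float)
    if n_components < 2:
        raise ValueError(
            "leverage/SPE need a term with at least two degrees of freedom "
            "(>= 2 components); for one-df terms use the VASCA test instead"
        )
    s = np.linalg.svd(Z, compute_uv=False)
    rank = int(np.sum(s > 1e-10 * s[0])) if s.size and s[0] > 0 else 0
    if n_components > rank:
        raise ValueError(f"n_components={n_components} exceeds rank(Z)={rank}")
    U, s, Vh = np.linalg.svd(Z, full_matrices=False)
    V2 = Vh[:n_components] ** 2
    lev = V2.sum(axis=0)
    col_ssq = np.sum(Z**2, axis=0)
    hat = (s[:n_components, None] ** 2 * V2).sum(axis=0)
    return lev, np.maximum(col_ssq - hat, 0.0)


@dataclass
class LeverageSpeResult:
    """Leverage/SPE indices, permutation control limits and 2×2 flags."""

    term: str
    n_components: int
    alpha: float
    leverage: np.ndarray
    spe: np.ndarray
    leverage_limit: float
    spe_limit: float

    @property
    def flags(self) -> np.ndarray:
        high_lev = self.leverage >= self.leverage_limit
        high_spe = self.spe >= self.spe_limit
        out = np.full(self.leverage.size, "not_relevant", dtype=object)
        out[high_lev & ~high_spe] = "relevant"
        out[high_lev & high_spe] = "poorly_modelled"
        out[~high_lev & high_spe] = "odd"
        return out

    @property
    def positive(self) -> np.ndarray:
        """Variables exceeding either control limit (any flag but not_relevant)."""
        return (self.leverage >= self.leverage_limit) | (self.spe >= self.spe_limit)

    def to_frame(self, var_names=None):
        import pandas as pd

        names = var_names if var_names is not None else np.arange(self.leverage.size)
        return pd.DataFrame(
            {
                "variable": names,
                "leverage": self.leverage,
                "spe": self.spe,
                "flag": self.flags,
            }
        )


def asca_genes_test(
    X: np.ndarray,
    coding: CodingMatrix,
    term: str,
    plan: PermutationPlan | None = None,
    n_components: int | None = None,
    alpha: float = 0.01,
    stats: PermutedStats | None = None,
) -> LeverageSpeResult:
    """Leverage/SPE relevance screening with permutation control limits.

    ``n_components`` defaults to the term's degrees of freedom capped at 2
    (the usual visual practice).  Limits are the pooled empirical
    ``1 − α`` quantiles of the permuted leverage and SPE values; limits are
    monotone non-increasing in ``alpha`` by construction.
    """
    df = coding.df[term]
    if df < 2:
        raise ValueError(
            f"term {term!r} has {df} df; ASCA-genes needs at least two "
            "(factors with >= 3 levels) — use the VASCA test instead"
        )
    if n_components is None:
        n_components = min(df, 2)
    if stats is None or stats.leverage is None or stats.n_components != n_components:
        if plan is None:
            raise ValueError("either a plan or precomputed stats is required")
        stats = permuted_column_ssq(X, coding, term, plan, n_components=n_components)
    lev_limit = float(np.quantile(stats.leverage, 1.0 - alpha))
    spe_limit = float(np.quantile(stats.spe, 1.0 - alpha))
    return LeverageSpeResult(
        term=term,
        n_components=n_components,
        alpha=alpha,
        leverage=stats.observed_leverage,
        spe=stats.observed_spe,
        leverage_limit=lev_limit,
        spe_limit=spe_limit,
    )
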