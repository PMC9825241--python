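"""Variable-wise and sub-matrix test statistics for (V)ASCA.

Three sums-of-squares based statistics are supported for an effect matrix
``Z`` of a model term:

``ssq``
    Per variable, the squared norm of its effect column ``‖Z(·,v)‖²``; for a
    sub-matrix, the Frobenius sum of squares.  Requires autoscaled data for
    a meaningful comparison across variables.
``f_ratio``
    Ratio of mean sums of squares between the term and a denominator term
    (the residuals by default): ``(SSQ_Z/df_Z)/(SSQ_D/df_D)``.  Scale-free
    by construction.
``pc2_ssq``
    Sum of the two largest squared singular values of the (sub-)matrix —
    the variance captured by the first two principal components.  Not
    column-additive, hence available for whole-matrix tests only, not for
    the variable-selection curve.

The :class:`StatCurve` orders variables by decreasing per-variable
statistic and accumulates the sub-matrix statistic over the nested
prefixes, which is the object the VASCA step-up test evaluates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .decomposition import Decomposition

__all__ = [
    "StatisticSpec",
    "StatCurve",
    "variable_statistics",
    "subset_statistic",
    "stat_curve",
]

KINDS = ("ssq", "f_ratio", "pc2_ssq")


@dataclass(frozen=True)
class StatisticSpec:
    """Choice of test statistic and, for the F-ratio, its denominator."""

    kind: str = "f_ratio"
    denominator: str = "residual"

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown statistic {self.kind!r}; choose from {KINDS}")


def _column_ssq(decomp: Decomposition, term: str) -> np.ndarray:
    if term == "residual":
        return np.sum(decomp.residuals**2, axis=0)
    return np.sum(decomp.effects[term] ** 2, axis=0)


def _check_term(decomp: Decomposition, term: str) -> None:
    if term not in decomp.effects:
        raise KeyError(f"term {term!r} was not fitted; have {decomp.terms}")


def variable_statistics(
    decomp: Decomposition, term: str, spec: StatisticSpec | str = "f_ratio"
) -> np.ndarray:
    """Per-variable statistic ``S^v`` for one model term.

    A variable with zero denominator sum of squares (perfect fit) gets an
    infinite F-ratio with a warning; it still participates in the ordering.
    """
    if isinstance(spec, str):
        spec = StatisticSpec(spec)
    _check_term(decomp, term)
    ssq_z = _column_ssq(decomp, term)
    if spec.kind == "ssq":
        return ssq_z
    if spec.kind != "f_ratio":
        raise ValueError("per-variable statistics support 'ssq' and 'f_ratio' only")
    df_z = decomp.df[term]
    df_d = decomp.df[spec.denominator]
    if df_d <= 0:
        raise ValueError(f"denominator term {spec.denominator!r} has no df")
    ssq_d = _column_ssq(decomp, spec.denominator)
    if np.any(ssq_d == 0.0):
        warnings.warn(
            "zero denominator sum of squares; F-ratio set to +inf for "
            f"variable(s) {np.nonzero(ssq_d == 0.0)[0].tolist()}",
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssq_z / df_z) / (ssq_d / df_d)
    return np.where(ssq_z == 0.0, 0.0, f)  # 0/0 counts as no effect


def subset_statistic(
    decomp: Decomposition,
    term: str,
    subset: np.ndarray,
    spec: StatisticSpec | str = "f_ratio",
) -> float:
    """Whole-(sub)matrix statistic over a non-empty set of variables."""
    if isinstance(spec, str):
        spec = StatisticSpec(spec)
    _check_term(decomp, term)
    subset = np.asarray(subset, dtype=np.intp)
    if subset.size == 0:
        raise ValueError("subset must be non-empty")
    if spec.kind == "pc2_ssq":
        s = np.linalg.svd(decomp.effects[term][:, subset], compute_uv=False)
        return float(np.sum(s[:2] ** 2))
    ssq_z = _column_ssq(decomp, term)[subset].sum()
    if spec.kind == "ssq":
        return float(ssq_z)
    df_z = decomp.df[term]
    df_d = decomp.df[spec.denominator]
    ssq_d = _column_ssq(decomp, spec.denominator)[subset].sum()
    with np.errstate(divide="ignore"):
        return float((ssq_z / df_z) / (ssq_d / df_d))


@dataclass
class StatCurve:
    """Variables ordered by decreasing statistic with cumulative statistics.

    ``cumulative[m-1]`` is the sub-matrix statistic of the first ``m``
    ordered variables; the last entry equals the whole-matrix statistic.
    """

    order: np.ndarray
    per_variable: np.ndarray  # sorted decreasing along `order`
    cumulative: np.ndarray

    @property
    def n_vars(self) -> int:
        return self.order.size


def descending_order(stats: np.ndarray) -> np.ndarray:
    """Argsort by decreasing value; ties broken by ascending column index."""
    return np.argsort(-stats, axis=-1, kind="stable")


def cumulative_curve(
    ssq_num: np.ndarray,
    ssq_den: np.ndarray | None,
    df_num: int,
    df_den: int | None,
    kind: str,
) -> np.ndarray:
    """Cumulative sub-matrix statistic along the last axis (already ordered).

    Running column sums give the ssq and F-ratio curves in O(M); the final
    point is recomputed as the direct whole-matrix reduction so that it is
    bit-identical to the plain ASCA statistic.
    """
    num = np.cumsum(ssq_num, axis=-1)
    num[..., -1] = ssq_num.sum(axis=-1)
    if kind == "ssq":
        return num
    den = np.cumsum(ssq_den, axis=-1)
    den[..., -1] = ssq_den.sum(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        curve = (num / df_num) / (den / df_den)
    return curve


def stat_curve(
    decomp: Decomposition, term: str, spec: StatisticSpec | str = "f_ratio"
) -> StatCurve:
    """Ordered per-variable statistics and their cumulative curve."""
    if isinstance(spec, str):
        spec = StatisticSpec(spec)
    if spec.kind == "pc2_ssq":
        raise ValueError(
            "pc2_ssq is not column-additive; use it for whole-matrix tests only"
        )
    per_var = variable_statistics(decomp, term, spec)
    order = descending_order(per_var)
    ssq_z = _column_ssq(decomp, term)[order]
    if spec.kind == "ssq":
        cum = cumulative_curve(ssq_z, None, decomp.df[term], None, "ssq")
    else:
        ssq_d = _column_ssq(decomp, spec.denominator)[order]
        cum = cumulative_curve(
            ssq_z, ssq_d, decomp.df[term], decomp.df[spec.denominator], "f_ratio"
        )
    return StatCurve(order, per_var[order], cum)


def curve_frame(curve: StatCurve, var_names=None):
    """Long-format table (rank, variable, statistic, cumulative) for export."""
    import pandas as pd

    names = (
        np.asarray(var_names)[curve.order]
        if var_names is not None
        else curve.order
    )
    return pd.DataFrame(
        {
            "rank": np.arange(1, curve.n_vars + 1),
            "variable": names,
            "statistic": curve.per_variable,
            "cumulative": curve.cumulative,
        }
    )
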