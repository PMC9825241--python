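"""Permutation inference: ASCA test, VASCA step-up selection, FDR baseline.

All methods share one null model: the rows of the (preprocessed) data
matrix are shuffled by ``K`` independent uniform permutations, the
least-squares decomposition is refitted on each shuffle, and per-variable
effect and residual sums of squares are recorded.  P-values use the
add-one-corrected exceedance count ``p = (#{S*_k ≥ S} + 1)/(K + 1)``, so no
p-value is ever below ``1/(K+1)`` or exactly zero.

The VASCA test re-sorts the variables *inside every permutation* by their
permuted statistic before accumulating the sub-matrix statistic: the null
curve at ``m`` variables is built from each permutation's own best ``m``
variables, which is what keeps the step-up selection calibrated.  The
p-curve at ``m = M`` is by construction the ordinary ASCA p-value.

A single :class:`PermutationPlan` (count + seed) drives every method, so
ASCA, VASCA, the univariate-FDR baseline and ASCA-genes reuse the identical
permutation sequence when given the same plan.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .design import CodingMatrix
from .statistics import StatisticSpec, cumulative_curve, descending_order

__all__ = [
    "PermutationPlan",
    "PermutedStats",
    "AscaTestResult",
    "VascaResult",
    "FdrResult",
    "permuted_column_ssq",
    "permuted_variable_stats",
    "asca_test",
    "vasca_test",
    "univariate_pvalues",
    "fdr_test",
    "bh_adjust",
]


@dataclass
class PermutationPlan:
    """Number of permutations and the seed that generates them.

    The permutation sequence depends only on ``(n_perms, seed, n_obs)``,
    never on the method consuming it — that is the shared-draw contract.
    An explicit ``permutations`` array (K × N of row indices) may be
    supplied for testing, e.g. to force the identity permutation.
    """

    n_perms: int = 1000
    seed: int = 0
    permutations: np.ndarray | None = None
    _cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.n_perms < 1:
            raise ValueError("n_perms must be >= 1")

    def draw(self, n_obs: int) -> np.ndarray:
        if self.permutations is not None:
            perms = np.asarray(self.permutations, dtype=np.intp)
            if perms.shape != (self.n_perms, n_obs):
                raise ValueError(
                    f"explicit permutations must have shape {(self.n_perms, n_obs)}"
                )
            return perms
        if n_obs not in self._cache:
            rng = np.random.default_rng(self.seed)
            out = np.empty((self.n_perms, n_obs), dtype=np.intp)
            for k in range(self.n_perms):
                out[k] = rng.permutation(n_obs)
            self._cache[n_obs] = out
        return self._cache[n_obs]


@dataclass
class PermutedStats:
    """Observed and permuted per-variable sums of squares for one term.

    The K×M tables are the common currency of all methods; leverage/SPE
    and the top singular values of the permuted effect matrices are filled
    only when requested (ASCA-genes, pc2 statistic).
    """

    term: str
    df_effect: int
    df_resid: int
    effect_ssq: np.ndarray  # (K, M)
    resid_ssq: np.ndarray  # (K, M)
    observed_effect_ssq: np.ndarray  # (M,)
    observed_resid_ssq: np.ndarray  # (M,)
    svals: np.ndarray | None = None  # (K, df_effect)
    observed_svals: np.ndarray | None = None
    leverage: np.ndarray | None = None  # (K, M)
    spe: np.ndarray | None = None
    observed_leverage: np.ndarray | None = None
    observed_spe: np.ndarray | None = None
    n_components: int | None = None

    @property
    def n_perms(self) -> int:
        return self.effect_ssq.shape[0]

    @property
    def n_vars(self) -> int:
        return self.effect_ssq.shape[1]

    def variable_stats(self, kind: str, observed: bool = False):
        """Per-variable statistics (K×M, or M-vector for the observed fit)."""
        eff = self.observed_effect_ssq if observed else self.effect_ssq
        res = self.observed_resid_ssq if observed else self.resid_ssq
        if kind == "ssq":
            return eff
        if kind != "f_ratio":
            raise ValueError("per-variable statistics need 'ssq' or 'f_ratio'")
        with np.errstate(divide="ignore", invalid="ignore"):
            f = (eff / self.df_effect) / (res / self.df_resid)
        return np.where(eff == 0.0, 0.0, f)


def _batch_column_ssq(theta, G, block, G_t, x2):
    """Fitted/effect/residual column SSQs from batched coefficients."""
    fitted = np.einsum("...pm,...pm->...m", np.matmul(G, theta), theta)
    theta_t = theta[..., block, :]
    eff = np.einsum("...pm,...pm->...m", np.matmul(G_t, theta_t), theta_t)
    resid = np.maximum(x2 - fitted, 0.0)
    return eff, resid, theta_t


def _leverage_spe(theta_t, R_t, eff, n_components):
    """Per-variable leverage and SPE of ``Z = C_t Θ_t`` via the small Gram
    factor ``W = R_t Θ_t`` (``W^T W = Z^T Z``), batched over permutations."""
    W = np.matmul(R_t, theta_t)
    s, Vh = np.linalg.svd(W, full_matrices=False)[1:]
    r = n_components
    V2 = Vh[..., :r, :] ** 2
    lev = V2.sum(axis=-2)
    hat = (s[..., :r, None] ** 2 * V2).sum(axis=-2)
    spe = np.maximum(eff - hat, 0.0)
    return lev, spe, s


def permuted_column_ssq(
    X: np.ndarray,
    coding: CodingMatrix,
    term: str,
    plan: PermutationPlan,
    n_components: int | None = None,
    want_svals: bool = False,
    chunk_size: int = 256,
) -> PermutedStats:
    """Refit the decomposition under every permutation of the rows of X.

    Returns per-variable effect and residual sums of squares for the
    observed data and for each of the ``K`` permutations, processed in
    chunks of permutations with batched linear algebra.  Setting
    ``n_components`` additionally records per-variable leverage and SPE of
    the permuted effect matrices (the ASCA-genes null); ``want_svals``
    records the singular values of the permuted effect matrices (the pc2
    statistic's null).
    """
    X = np.asarray(X, dtype=float)
    C = coding.values
    if term not in coding.blocks or term == "intercept":
        raise KeyError(f"term {term!r} not in the coding matrix")
    n, p = C.shape
    block = np.arange(p)[coding.blocks[term]]
    pinvC = np.linalg.pinv(C)
    G = C.T @ C
    C_t = C[:, block]
    G_t = C_t.T @ C_t
    R_t = np.linalg.cholesky(G_t).T  # R_t^T R_t = G_t
    x2 = np.sum(X**2, axis=0)
    want_genes = n_components is not None
    if want_genes and n_components > len(block):
        raise ValueError(
            f"n_components={n_components} exceeds the term's {len(block)} df"
        )

    def stats_for(stack):
        theta = np.matmul(pinvC, stack)
        eff, resid, theta_t = _batch_column_ssq(theta, G, block, G_t, x2)
        lev = spe = s = None
        if want_genes or want_svals:
            lev, spe, s = _leverage_spe(
                theta_t, R_t, eff, n_components if want_genes else len(block)
            )
        return eff, resid, lev, spe, s

    obs_eff, obs_resid, obs_lev, obs_spe, obs_s = stats_for(X[None])
    perms = plan.draw(n)
    K = plan.n_perms
    M = X.shape[1]
    eff_out = np.empty((K, M))
    resid_out = np.empty((K, M))
    lev_out = np.empty((K, M)) if want_genes else None
    spe_out = np.empty((K, M)) if want_genes else None
    s_out = np.empty((K, len(block))) if (want_genes or want_svals) else None
    for start in range(0, K, chunk_size):
        sl = slice(start, min(start + chunk_size, K))
        eff, resid, lev, spe, s = stats_for(X[perms[sl]])
        eff_out[sl] = eff
        resid_out[sl] = resid
        if lev_out is not None:
            lev_out[sl], spe_out[sl] = lev, spe
        if s_out is not None:
            s_out[sl] = s
    return PermutedStats(
        term=term,
        df_effect=coding.df[term],
        df_resid=n - p,
        effect_ssq=eff_out,
        resid_ssq=resid_out,
        observed_effect_ssq=obs_eff[0],
        observed_resid_ssq=obs_resid[0],
        svals=s_out,
        observed_svals=obs_s[0] if obs_s is not None else None,
        leverage=lev_out,
        spe=spe_out,
        observed_leverage=obs_lev[0] if obs_lev is not None else None,
        observed_spe=obs_spe[0] if obs_spe is not None else None,
        n_components=n_components,
    )


def permuted_variable_stats(
    X: np.ndarray,
    coding: CodingMatrix,
    term: str,
    spec: StatisticSpec | str,
    plan: PermutationPlan,
) -> np.ndarray:
    """K × M matrix of permuted per-variable statistics ``(S^v)*_k``."""
    if isinstance(spec, str):
        spec = StatisticSpec(spec)
    stats = permuted_column_ssq(X, coding, term, plan)
    return stats.variable_stats(spec.kind)


def permutation_pvalue(observed: float, null_draws: np.ndarray) -> float:
    """Add-one-corrected exceedance p-value; ties count as exceedances."""
    null_draws = np.asarray(null_draws)
    return float((np.sum(null_draws >= observed) + 1) / (null_draws.size + 1))


@dataclass
class AscaTestResult:
    """Whole-matrix ASCA permutation test for one term."""

    term: str
    kind: str
    statistic: float
    null_draws: np.ndarray
    p_value: float

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"AscaTestResult(term={self.term!r}, kind={self.kind!r}, "
            f"S={self.statistic:.4g}, p={self.p_value:.4g}, "
            f"K={self.null_draws.size})"
        )


def _whole_matrix_stat(stats: PermutedStats, kind: str, observed: bool):
    if kind == "pc2_ssq":
        s = stats.observed_svals if observed else stats.svals
        if s is None:
            raise ValueError("pc2_ssq requires want_svals=True permuted stats")
        return np.sum(s[..., :2] ** 2, axis=-1)
    eff = stats.observed_effect_ssq if observed else stats.effect_ssq
    num = eff.sum(axis=-1) / stats.df_effect
    if kind == "ssq":
        return eff.sum(axis=-1)
    res = stats.observed_resid_ssq if observed else stats.resid_ssq
    den = res.sum(axis=-1) / stats.df_resid
    return num / den


def asca_test(
    X: np.ndarray,
    coding: CodingMatrix,
    term: str,
    spec: StatisticSpec | str = "f_ratio",
    plan: PermutationPlan | None = None,
    stats: PermutedStats | None = None,
) -> AscaTestResult:
    """Classical ASCA permutation test over all variables at once."""
    if isinstance(spec, str):
        spec = StatisticSpec(spec)
    if stats is None:
        if plan is None:
            raise ValueError("either a plan or precomputed stats is required")
        stats = permuted_column_ssq(
            X, coding, term, plan, want_svals=spec.kind == "pc2_ssq"
        )
    S = float(_whole_matrix_stat(stats, spec.kind, observed=True))
    null = np.asarray(_whole_matrix_stat(stats, spec.kind, observed=False))
    return AscaTestResult(term, spec.kind, S, null, permutation_pvalue(S, null))


@dataclass
class VascaResult:
    """Step-up variable selection with in-permutation reordering.

    ``p_curve[m-1]`` is the p-value of the sub-matrix of the ``m`` leading
    variables; selection takes the *largest* ``m`` with ``p_m < alpha``
    even when intermediate p-values are not significant (the full curve is
    kept so that non-monotonicity stays visible).
    """

    term: str
    kind: str
    alpha: float
    order: np.ndarray
    per_variable: np.ndarray
    cumulative: np.ndarray
    p_curve: np.ndarray
    null_curves: np.ndarray | None = None

    @property
    def selected_m(self) -> int:
        hits = np.nonzero(self.p_curve < self.alpha)[0]
        return int(hits[-1] + 1) if hits.size else 0

    @property
    def selected_variables(self) -> np.ndarray:
        return self.order[: self.selected_m]

    @property
    def p_value(self) -> float:
        """Whole-matrix (ASCA) p-value — the curve's last point."""
        return float(self.p_curve[-1])

    def to_frame(self, var_names=None):
        import pandas as pd

        names = (
            np.asarray(var_names)[self.order] if var_names is not None else self.order
        )
        return pd.DataFrame(
            {
                "m": np.arange(1, self.order.size + 1),
                "variable": names,
                "statistic": self.per_variable,
                "cumulative": self.cumulative,
                "p_value": self.p_curve,
                "selected": np.arange(self.order.size) < self.selected_m,
            }
        )


def vasca_test(
    X: np.ndarray,
    coding: CodingMatrix,
    term: str,
    spec: StatisticSpec | str = "f_ratio",
    plan: PermutationPlan | None = None,
    alpha: float = 0.05,
    stats: PermutedStats | None = None,
    keep_null: bool = False,
) -> VascaResult:
    """VASCA permutation test with embedded variable selection.

    With the raw ``ssq`` statistic the data must be autoscaled beforehand;
    the F-ratio is normalized by construction.  Inside each permutation the
    variables are re-sorted by their permuted statistic before the
    cumulative curve is formed, so the null at ``m`` variables reflects the
    best ``m`` variables of that permutation.
    """
    if isinstance(spec, str):
        spec = StatisticSpec(spec)
    if spec.kind not in ("ssq", "f_ratio"):
        raise ValueError("VASCA curves support 'ssq' and 'f_ratio' statistics")
    if stats is None:
        if plan is None:
            raise ValueError("either a plan or precomputed stats is required")
        stats = permuted_column_ssq(X, coding, term, plan)

    obs_stat = stats.variable_stats(spec.kind, observed=True)
    order = descending_order(obs_stat)
    obs_curve = _ordered_curve(
        stats.observed_effect_ssq, stats.observed_resid_ssq, order, stats, spec.kind
    )
    null_stat = stats.variable_stats(spec.kind)
    null_order = descending_order(null_stat)
    null_curves = _ordered_curve(
        stats.effect_ssq, stats.resid_ssq, null_order, stats, spec.kind
    )
    exceed = np.sum(null_curves >= obs_curve[None, :], axis=0)
    p_curve = (exceed + 1) / (stats.n_perms + 1)
    return VascaResult(
        term=term,
        kind=spec.kind,
        alpha=alpha,
        order=order,
        per_variable=obs_stat[order],
        cumulative=obs_curve,
        p_curve=p_curve,
        null_curves=null_curves if keep_null else None,
    )


def _ordered_curve(eff, resid, order, stats: PermutedStats, kind: str):
    eff_sorted = np.take_along_axis(eff, order, axis=-1)
    if kind == "ssq":
        return cumulative_curve(eff_sorted, None, stats.df_effect, None, "ssq")
    resid_sorted = np.take_along_axis(resid, order, axis=-1)
    return cumulative_curve(
        eff_sorted, resid_sorted, stats.df_effect, stats.df_resid, "f_ratio"
    )


def univariate_pvalues(
    perm_stats: np.ndarray, observed: np.ndarray, pooled: bool = True
) -> np.ndarray:
    """Per-variable permutation p-values for the univariate (FDR) baseline.

    With ``pooled=True`` (default) the empirical null distribution pools
    the permuted statistics of *all* variables, giving p-values with
    resolution ``1/(K·M + 1)``.  Pooling is what makes a BH correction at
    small levels attainable with moderate ``K`` and is valid because the
    statistics are exchangeable across variables under the null — exactly
    (autoscaled ssq: every column has the same total sum of squares) or by
    normalization (the F-ratio).  ``pooled=False`` uses each variable's
    own ``K`` draws, with resolution ``1/(K + 1)``.
    """
    perm_stats = np.asarray(perm_stats)
    observed = np.asarray(observed)
    if pooled:
        flat = np.sort(perm_stats, axis=None)
        exceed = flat.size - np.searchsorted(flat, observed, side="left")
        return (exceed + 1) / (flat.size + 1)
    K = perm_stats.shape[0]
    exceed = np.sum(perm_stats >= observed[None, :], axis=0)
    return (exceed + 1) / (K + 1)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment, clamped at 1.

    Sort ascending, multiply ``p_(i)`` by ``M/i``, enforce monotonicity
    from the largest rank down, and map back to the original order.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p must be a non-empty 1-D vector")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    M = p.size
    order = np.argsort(p, kind="stable")
    # grouping (M / i) first keeps the rank-M factor exactly 1.0, so the
    # adjusted value can never round below the raw one
    q = p[order] * (M / np.arange(1, M + 1))
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty_like(q)
    out[order] = q
    return out


@dataclass
class FdrResult:
    """Univariate permutation p-values with BH correction (FDR baseline)."""

    term: str
    kind: str
    alpha: float
    p_raw: np.ndarray
    p_adjusted: np.ndarray

    @property
    def significant(self) -> np.ndarray:
        return np.nonzero(self.p_adjusted < self.alpha)[0]

    def to_frame(self, var_names=None):
        import pandas as pd

        names = var_names if var_names is not None else np.arange(self.p_raw.size)
        return pd.DataFrame(
            {
                "variable": names,
                "p_value": self.p_raw,
                "p_adjusted": self.p_adjusted,
                "significant": self.p_adjusted < self.alpha,
            }
        )


def fdr_test(
    X: np.ndarray,
    coding: CodingMatrix,
    term: str,
    spec: StatisticSpec | str = "f_ratio",
    plan: PermutationPlan | None = None,
    alpha: float = 0.05,
    stats: PermutedStats | None = None,
    pooled: bool = True,
) -> FdrResult:
    """BH-FDR baseline on per-variable permutation p-values."""
    if isinstance(spec, str):
        spec = StatisticSpec(spec)
    if spec.kind not in ("ssq", "f_ratio"):
        raise ValueError("the FDR baseline supports 'ssq' and 'f_ratio' statistics")
    if stats is None:
        if plan is None:
            raise ValueError("either a plan or precomputed stats is required")
        stats = permuted_column_ssq(X, coding, term, plan)
    observed = stats.variable_stats(spec.kind, observed=True)
    null = stats.variable_stats(spec.kind)
    p_raw = univariate_pvalues(null, observed, pooled=pooled)
    return FdrResult(term, spec.kind, alpha, p_raw, bh_adjust(p_raw))
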