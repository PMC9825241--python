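"""Post hoc component analysis of significant effect matrices.

PCA is fitted to the effect matrix ``Z`` of a significant term (restricted
to the selected variables); at most ``df`` components are meaningful
because ``rank(Z) ≤ df``.  Observations are displayed by projecting
``Z + E`` — effect plus residual — onto the effect loadings, so the score
plot shows the effect structure with the unexplained variation around it.
A stratified bootstrap over the design cells yields percentile intervals
for each loading; variables whose interval covers zero on every component
can be pruned as not contributing to the effect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .design import CodingMatrix

__all__ = ["ComponentModel", "LoadingBootstrap", "fit_components", "bootstrap_loadings"]


@dataclass
class ComponentModel:
    """PCA of an effect matrix with projected effect-plus-residual scores."""

    term: str
    variables: np.ndarray  # column indices the model was fitted on
    loadings: np.ndarray  # (M_sel, r), orthonormal columns
    singular_values: np.ndarray  # (r,)
    scores: np.ndarray  # (N, r) = Z P
    projected_scores: np.ndarray | None  # (N, r) = (Z+E) P

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    @property
    def explained_ssq(self) -> np.ndarray:
        """Sum of squares captured per component (squared singular values)."""
        return self.singular_values**2

    def to_frame(self, var_names=None):
        import pandas as pd

        names = (
            np.asarray(var_names)[self.variables]
            if var_names is not None
            else self.variables
        )
        return pd.DataFrame(
            self.loadings,
            index=names,
            columns=[f"PC{a + 1}" for a in range(self.n_components)],
        )


def fit_components(
    Z: np.ndarray,
    n_components: int,
    residuals: np.ndarray | None = None,
    term: str = "",
    variables: np.ndarray | None = None,
) -> ComponentModel:
    """PCA of an effect (sub-)matrix via SVD.

    ``n_components`` is truncated to ``rank(Z)`` with a warning when it
    exceeds it.  When ``residuals`` is given, the same variables' residual
    columns are added to ``Z`` before projection onto the loadings.
    """
    Z = np.asarray(Z, dtype=float)
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    U, s, Vh = np.linalg.svd(Z, full_matrices=False)
    rank = int(np.sum(s > 1e-10 * s[0])) if s.size and s[0] > 0 else 0
    if n_components > rank:
        warnings.warn(
            f"n_components={n_components} exceeds rank(Z)={rank}; truncating",
            stacklevel=2,
        )
        n_components = max(rank, 1)
    P = Vh[:n_components].T
    scores = Z @ P
    projected = None
    if residuals is not None:
        projected = (Z + np.asarray(residuals, dtype=float)) @ P
    variables = (
        np.asarray(variables, dtype=np.intp)
        if variables is not None
        else np.arange(Z.shape[1])
    )
    return ComponentModel(term, variables, P, s[:n_components], scores, projected)


@dataclass
class LoadingBootstrap:
    """Percentile bootstrap intervals for PCA loadings of an effect matrix."""

    term: str
    variables: np.ndarray
    point: np.ndarray  # (M_sel, r) point-estimate loadings
    lower: np.ndarray  # (M_sel, r)
    upper: np.ndarray  # (M_sel, r)
    alpha: float
    n_boot: int

    @property
    def significant_by_component(self) -> np.ndarray:
        """(M_sel, r) flags — interval excludes zero."""
        return (self.lower > 0) | (self.upper < 0)

    @property
    def significant(self) -> np.ndarray:
        """Variable-level flags: significant on at least one component."""
        return self.significant_by_component.any(axis=1)

    def to_frame(self, var_names=None):
        import pandas as pd

        names = (
            np.asarray(var_names)[self.variables]
            if var_names is not None
            else self.variables
        )
        rows = []
        for a in range(self.point.shape[1]):
            for i in range(self.point.shape[0]):
                rows.append(
                    {
                        "component": a + 1,
                        "variable": names[i],
                        "loading": self.point[i, a],
                        "lower": self.lower[i, a],
                        "upper": self.upper[i, a],
                        "significant": self.significant_by_component[i, a],
                    }
                )
        return pd.DataFrame(rows)


def _align(Vb: np.ndarray, P0: np.ndarray) -> np.ndarray:
    """Match and sign-flip bootstrap components to the point estimate.

    Components are paired by maximal absolute congruence (Hungarian
    assignment on |V_b P0|) and each matched component's sign is chosen to
    make the congruence positive.  Without this step the pooled percentile
    interval would mix arbitrary SVD sign and order conventions.
    """
    G = Vb @ P0  # (r_b, r)
    rows, cols = linear_sum_assignment(-np.abs(G))
    r = P0.shape[1]
    out = np.zeros((r, Vb.shape[1]))
    for rb, c in zip(rows, cols):
        out[c] = Vb[rb] * np.sign(G[rb, c] if G[rb, c] != 0 else 1.0)
    return out


def bootstrap_loadings(
    X: np.ndarray,
    coding: CodingMatrix,
    term: str,
    variables: np.ndarray,
    n_components: int,
    n_boot: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    strata: np.ndarray | None = None,
) -> LoadingBootstrap:
    """Stratified observation bootstrap of the effect-matrix loadings.

    Observations are resampled with replacement *within* each design cell
    (the combination of all model factors by default), which preserves the
    coding matrix exactly — every resample refits the same balanced (or
    unbalanced) design, so no stratum can be emptied.  Per resample the
    GLM is refitted on the selected variables, the effect matrix's leading
    ``n_components`` right singular vectors are extracted, aligned to the
    point estimate, and pooled into percentile intervals at level
    ``1 − alpha``.
    """
    X = np.asarray(X, dtype=float)
    variables = np.asarray(variables, dtype=np.intp)
    if variables.size == 0:
        raise ValueError("variables must be non-empty")
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100 for stable percentile intervals")
    C = coding.values
    n = C.shape[0]
    block = np.arange(C.shape[1])[coding.blocks[term]]
    n_components = min(n_components, len(block), variables.size)
    if strata is None:
        strata = (
            coding.design.cell_ids(list(coding.terms.main))
            if coding.design is not None
            else np.zeros(n, dtype=np.intp)
        )
    strata = np.asarray(strata)

    Xsel = X[:, variables]
    pinvC = np.linalg.pinv(C)
    C_t = C[:, block]
    R_t = np.linalg.cholesky(C_t.T @ C_t).T

    # point estimate
    theta0 = pinvC @ Xsel
    _, s0, Vh0 = np.linalg.svd(R_t @ theta0[block], full_matrices=False)
    P0 = Vh0[:n_components].T

    rng = np.random.default_rng(seed)
    idx = np.empty((n_boot, n), dtype=np.intp)
    for cell in np.unique(strata):
        members = np.nonzero(strata == cell)[0]
        draw = rng.integers(0, members.size, size=(n_boot, members.size))
        idx[:, members] = members[draw]
    # within-cell resampling keeps every coding row multiset identical, so
    # the fit operator pinvC applies unchanged to the resampled rows of X
    Xb = Xsel[idx]  # (B, N, M_sel)
    theta = np.matmul(pinvC, Xb)
    W = np.matmul(R_t, theta[:, block, :])
    _, sb, Vhb = np.linalg.svd(W, full_matrices=False)
    samples = np.empty((n_boot, variables.size, n_components))
    for b in range(n_boot):
        samples[b] = _align(Vhb[b], P0).T
    lo = np.quantile(samples, alpha / 2, axis=0)
    hi = np.quantile(samples, 1 - alpha / 2, axis=0)
    return LoadingBootstrap(
        term=term,
        variables=variables,
        point=P0,
        lower=lo,
        upper=hi,
        alpha=alpha,
        n_boot=n_boot,
    )
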