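"""ASCA+ least-squares factorization of a designed multivariate dataset.

The (optionally preprocessed) data matrix ``X`` (observations × variables)
is regressed onto the deviation-coded design matrix ``C``::

    X = C Θ + E = 1 θ_m + C_A Θ_A + C_B Θ_B + C_AB Θ_AB + E

The least-squares solution partitions the variation of ``X`` into a grand
mean, one effect matrix ``Z = C_Z Θ_Z`` per model term and a residual
matrix ``E``.  On balanced designs the term blocks are mutually orthogonal
and the sums of squares are additive (Pythagoras); with mild unbalancedness
the least-squares estimates remain well defined and Type-III sums of
squares (:func:`type3_ssq`) quantify each term's unique contribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .design import CodingMatrix

__all__ = ["PreprocessSpec", "Decomposition", "preprocess", "fit_glm", "type3_ssq"]

#: singular values below RANK_TOL × largest are treated as zero
RANK_TOL = 1e-10


@dataclass
class PreprocessSpec:
    """Fitted column-wise preprocessing transform (invertible)."""

    mode: str
    mean_: np.ndarray
    scale_: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean_) / self.scale_

    def inverse_transform(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) * self.scale_ + self.mean_


def preprocess(
    X: np.ndarray, mode: str = "center", on_constant: str = "error"
) -> tuple[np.ndarray, PreprocessSpec]:
    """Column-wise preprocessing: ``none``, ``center`` or ``autoscale``.

    Autoscaling (mean 0, unit variance) is required when the raw
    sum-of-squares statistic is used for testing, so that all variables have
    comparable expected statistics under the null.  Zero-variance columns
    make autoscaling ill-defined; they raise by default or are flagged with
    a warning when ``on_constant="warn"`` (their scale is left at 1).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a 2-D observations x variables matrix")
    if X.shape[0] < 2:
        raise ValueError("need at least two observations")
    n, m = X.shape
    if mode == "none":
        spec = PreprocessSpec("none", np.zeros(m), np.ones(m))
        return X.copy(), spec
    mean = X.mean(axis=0)
    if mode == "center":
        return X - mean, PreprocessSpec("center", mean, np.ones(m))
    if mode == "autoscale":
        sd = X.std(axis=0, ddof=1)
        constant = np.nonzero(sd == 0.0)[0]
        if constant.size:
            if on_constant == "error":
                raise ValueError(
                    "autoscaling undefined for zero-variance column(s) "
                    f"{constant.tolist()}"
                )
            warnings.warn(
                f"zero-variance column(s) {constant.tolist()} left unscaled",
                stacklevel=2,
            )
            sd = sd.copy()
            sd[constant] = 1.0
        return (X - mean) / sd, PreprocessSpec("autoscale", mean, sd)
    raise ValueError(f"unknown preprocessing mode {mode!r}")


@dataclass
class Decomposition:
    """Least-squares partition of ``X`` into mean, effects and residuals."""

    mean: np.ndarray
    coefficients: np.ndarray
    effects: dict[str, np.ndarray]
    residuals: np.ndarray
    df: dict[str, int]
    coding: CodingMatrix = field(repr=False)

    @property
    def n_obs(self) -> int:
        return self.residuals.shape[0]

    @property
    def n_vars(self) -> int:
        return self.residuals.shape[1]

    @property
    def terms(self) -> tuple[str, ...]:
        return tuple(self.effects)

    def reconstruct(self) -> np.ndarray:
        """``1·m + Σ_terms Z + E`` — equals the fitted (preprocessed) X."""
        X = np.tile(self.mean, (self.n_obs, 1)) + self.residuals
        for Z in self.effects.values():
            X = X + Z
        return X

    @property
    def ssq(self) -> dict[str, float]:
        """Frobenius sum of squares per effect matrix plus the residual."""
        out = {t: float(np.sum(Z**2)) for t, Z in self.effects.items()}
        out["residual"] = float(np.sum(self.residuals**2))
        return out

    def export(self, directory, var_names=None) -> None:
        """Write mean, per-term effect matrices and residuals as CSV."""
        import pandas as pd
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        cols = var_names if var_names is not None else range(self.n_vars)

        def dump(name, values):
            pd.DataFrame(values, columns=list(cols)).to_csv(
                directory / f"{name}.csv", index=False
            )

        dump("mean", self.mean[None, :])
        for term, Z in self.effects.items():
            dump(f"effect_{term.replace(':', '_x_')}", Z)
        dump("residuals", self.residuals)


def _aliased_terms(coding: CodingMatrix, rank: int) -> list[str]:
    # a term is aliased if removing its block does not reduce the rank
    aliased = []
    for term in coding.blocks:
        if term == "intercept":
            continue
        keep = [t for t in coding.blocks if t != term]
        cols = np.hstack([coding.values[:, coding.blocks[t]] for t in keep])
        if np.linalg.matrix_rank(cols, tol=None) == rank:
            aliased.append(term)
    return aliased


def fit_glm(X: np.ndarray, coding: CodingMatrix) -> Decomposition:
    """Fit the ASCA+ decomposition by (QR-based) least squares.

    Raises on a rank-deficient coding matrix, naming the aliased terms.
    """
    X = np.asarray(X, dtype=float)
    C = coding.values
    if X.ndim != 2 or X.shape[0] != C.shape[0]:
        raise ValueError(
            f"X has {np.asarray(X).shape[0]} rows but the design has {C.shape[0]}"
        )
    s = np.linalg.svd(C, compute_uv=False)
    rank = int(np.sum(s > RANK_TOL * s[0]))
    if rank < C.shape[1]:
        aliased = _aliased_terms(coding, rank)
        raise np.linalg.LinAlgError(
            f"coding matrix is rank deficient; aliased term(s): {aliased}"
        )
    theta, *_ = np.linalg.lstsq(C, X, rcond=None)
    effects = {
        term: C[:, sl] @ theta[sl]
        for term, sl in coding.blocks.items()
        if term != "intercept"
    }
    residuals = X - C @ theta
    df = {t: coding.df[t] for t in effects}
    df["residual"] = C.shape[0] - rank
    mean = theta[coding.blocks["intercept"]][0]
    return Decomposition(mean, theta, effects, residuals, df, coding)


def type3_ssq(X: np.ndarray, coding: CodingMatrix, term: str) -> np.ndarray:
    """Per-variable Type-III sum of squares for one term.

    Difference between the residual sums of squares of the reduced model
    (term's block dropped, intercept always kept) and the full model.  On
    balanced designs this equals the Type-I sum of squares of the term's
    effect-matrix columns.
    """
    if term not in coding.blocks or term == "intercept":
        raise KeyError(f"term {term!r} not in the model")
    X = np.asarray(X, dtype=float)
    full = fit_glm(X, coding)
    reduced_coding = coding.drop_term(term)
    theta, *_ = np.linalg.lstsq(reduced_coding.values, X, rcond=None)
    resid_reduced = X - reduced_coding.values @ theta
    diff = np.sum(resid_reduced**2, axis=0) - np.sum(full.residuals**2, axis=0)
    return np.maximum(diff, 0.0)
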