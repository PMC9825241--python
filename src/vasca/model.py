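"""Model/results interface tying the analysis pipeline together.

:class:`ASCA` is constructed from a measurement matrix, a design table and
a term specification; ``fit()`` performs the ASCA+ least-squares
factorization and returns :class:`ASCAResults`, from which the inference
and visualization steps hang: whole-matrix permutation tests, the VASCA
step-up selection, the univariate BH-FDR baseline, ASCA-genes leverage/SPE
screening, post hoc component models and bootstrap loading intervals.

Permutation draws are cached per (term, plan) on the results object, so
the different methods answer from the identical permutation sequence —
essential for the comparisons to be fair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import asca_genes as _genes
from . import components as _components
from .decomposition import Decomposition, fit_glm, preprocess
from .design import CodingMatrix, DesignTable, ModelTerms, build_coding, parse_design
from .permutation import (
    AscaTestResult,
    FdrResult,
    PermutationPlan,
    PermutedStats,
    VascaResult,
    asca_test,
    fdr_test,
    permuted_column_ssq,
    vasca_test,
)
from .statistics import StatisticSpec

__all__ = ["ASCA", "ASCAResults"]


class ASCA:
    """ANOVA simultaneous component analysis of a designed experiment.

    Parameters
    ----------
    data : array-like or DataFrame, observations × variables
        The measurement matrix.  Non-numeric cells are rejected.
    design : DesignTable, DataFrame or path
        Categorical factor levels per observation.
    terms : ModelTerms or str, optional
        Model terms, e.g. ``"temp + pH + temp:pH"``.  Defaults to the main
        effects of every design factor.
    statistic : {"f_ratio", "ssq", "pc2_ssq"}
        Default test statistic for the permutation tests.
    scaling : {"center", "autoscale", "none"}, optional
        Column preprocessing.  Defaults to centering; the raw ``ssq``
        statistic *requires* autoscaling so that variables share the same
        expected statistic under the null, and an informative error is
        raised otherwise.
    """

    def __init__(self, data, design, terms=None, statistic="f_ratio", scaling=None):
        if isinstance(data, pd.DataFrame):
            self.var_names = np.asarray(data.columns.astype(str))
            X = data.to_numpy()
        else:
            X = np.asarray(data)
            self.var_names = np.asarray([f"x{i + 1}" for i in range(X.shape[1])])
        if X.ndim != 2:
            raise ValueError("data must be a 2-D observations x variables matrix")
        try:
            X = X.astype(float)
        except (TypeError, ValueError) as err:
            raise ValueError(f"non-numeric data cells: {err}") from None
        if not isinstance(design, DesignTable):
            design = parse_design(design)
        if X.shape[0] != design.n_obs:
            raise ValueError(
                f"data has {X.shape[0]} rows but the design has {design.n_obs}"
            )
        if terms is None:
            terms = ModelTerms(tuple(design.factors))
        elif isinstance(terms, str):
            terms = ModelTerms.from_string(terms)
        StatisticSpec(statistic)  # validate
        if scaling is None:
            scaling = "autoscale" if statistic == "ssq" else "center"
        if statistic == "ssq" and scaling != "autoscale":
            raise ValueError(
                "the raw sum-of-squares statistic requires autoscaled data "
                "(scaling='autoscale'); otherwise high-variance variables "
                "dominate the null — or use statistic='f_ratio'"
            )
        self.raw_data = X
        self.design = design
        self.terms = terms
        self.statistic = statistic
        self.scaling = scaling
        self.coding: CodingMatrix = build_coding(design, terms)

    @classmethod
    def from_formula(cls, formula: str, data, design, **kwargs) -> "ASCA":
        """``ASCA.from_formula("~ temp + pH + temp:pH", data, design)``."""
        return cls(data, design, terms=formula, **kwargs)

    def fit(self) -> "ASCAResults":
        X, spec = preprocess(self.raw_data, self.scaling)
        decomposition = fit_glm(X, self.coding)
        return ASCAResults(self, X, decomposition, spec)


@dataclass
class ASCAResults:
    """Fitted factorization plus cached permutation machinery."""

    model: ASCA
    data: np.ndarray  # preprocessed
    decomposition: Decomposition
    preprocess_spec: object
    _cache: dict = field(default_factory=dict, repr=False)

    @property
    def terms(self) -> tuple[str, ...]:
        return self.decomposition.terms

    @property
    def var_names(self) -> np.ndarray:
        return self.model.var_names

    def _term(self, term: str | None) -> str:
        if term is None:
            if len(self.terms) == 1:
                return self.terms[0]
            raise ValueError(f"specify one of the model terms {self.terms}")
        if term not in self.terms:
            raise KeyError(f"unknown term {term!r}; model has {self.terms}")
        return term

    def _stats(
        self, term: str, plan: PermutationPlan, n_components=None, want_svals=False
    ) -> PermutedStats:
        """Permuted per-variable SSQs, shared across methods for one plan."""
        key = (
            term,
            plan.n_perms,
            plan.seed,
            None if plan.permutations is None else id(plan.permutations),
        )
        cached = self._cache.get(key)
        needs_genes = n_components is not None and (
            cached is None
            or cached.leverage is None
            or cached.n_components != n_components
        )
        needs_svals = want_svals and (cached is None or cached.svals is None)
        if cached is None or needs_genes or needs_svals:
            cached = permuted_column_ssq(
                self.data,
                self.model.coding,
                term,
                plan,
                n_components=n_components,
                want_svals=want_svals,
            )
            self._cache[key] = cached
        return cached

    # ---------------------------------------------------------- inference
    def permutation_test(
        self, term=None, n_perms=1000, seed=0, statistic=None, plan=None
    ) -> AscaTestResult:
        """Whole-matrix ASCA permutation test for one term."""
        term = self._term(term)
        statistic = statistic or self.model.statistic
        plan = plan or PermutationPlan(n_perms, seed)
        stats = self._stats(term, plan, want_svals=statistic == "pc2_ssq")
        result = asca_test(self.data, self.model.coding, term, statistic, stats=stats)
        self._cache.setdefault("pvalues", {})[term] = result.p_value
        return result

    def vasca(
        self, term=None, n_perms=1000, seed=0, alpha=0.05, statistic=None, plan=None
    ) -> VascaResult:
        """VASCA step-up selection for one term."""
        term = self._term(term)
        statistic = statistic or self.model.statistic
        plan = plan or PermutationPlan(n_perms, seed)
        stats = self._stats(term, plan)
        return vasca_test(
            self.data, self.model.coding, term, statistic, alpha=alpha, stats=stats
        )

    def univariate_fdr(
        self, term=None, n_perms=1000, seed=0, alpha=0.05, statistic=None, plan=None
    ) -> FdrResult:
        """Per-variable permutation p-values with BH correction."""
        term = self._term(term)
        statistic = statistic or self.model.statistic
        plan = plan or PermutationPlan(n_perms, seed)
        stats = self._stats(term, plan)
        return fdr_test(
            self.data, self.model.coding, term, statistic, alpha=alpha, stats=stats
        )

    def asca_genes(
        self, term=None, n_perms=1000, seed=0, alpha=0.01, n_components=None, plan=None
    ) -> _genes.LeverageSpeResult:
        """Leverage/SPE relevance screening (baseline)."""
        term = self._term(term)
        df = self.decomposition.df[term]
        if n_components is None:
            n_components = min(df, 2)
        plan = plan or PermutationPlan(n_perms, seed)
        stats = self._stats(term, plan, n_components=n_components)
        return _genes.asca_genes_test(
            self.data,
            self.model.coding,
            term,
            n_components=n_components,
            alpha=alpha,
            stats=stats,
        )

    # ------------------------------------------------------ visualization
    def components(
        self, term=None, variables=None, n_components=None
    ) -> _components.ComponentModel:
        """PCA of a term's effect matrix with projected Z+E scores."""
        term = self._term(term)
        variables = (
            np.asarray(variables, dtype=np.intp)
            if variables is not None
            else np.arange(self.decomposition.n_vars)
        )
        if n_components is None:
            n_components = min(self.decomposition.df[term], variables.size)
        Z = self.decomposition.effects[term][:, variables]
        E = self.decomposition.residuals[:, variables]
        return _components.fit_components(
            Z, n_components, residuals=E, term=term, variables=variables
        )

    def apca_components(self, term=None, variables=None, n_components=None):
        """APCA-style variant: PCA on Z+E rather than on Z (optional view)."""
        term = self._term(term)
        variables = (
            np.asarray(variables, dtype=np.intp)
            if variables is not None
            else np.arange(self.decomposition.n_vars)
        )
        if n_components is None:
            n_components = min(self.decomposition.df[term], variables.size)
        ZE = (
            self.decomposition.effects[term][:, variables]
            + self.decomposition.residuals[:, variables]
        )
        return _components.fit_components(
            ZE, n_components, residuals=None, term=term, variables=variables
        )

    def bootstrap_loadings(
        self,
        term=None,
        variables=None,
        n_components=None,
        n_boot=1000,
        seed=0,
        alpha=0.05,
    ) -> _components.LoadingBootstrap:
        """Bootstrap percentile intervals for the effect loadings."""
        term = self._term(term)
        if variables is None:
            raise ValueError(
                "pass the variables to bootstrap (e.g. a VASCA selection)"
            )
        if n_components is None:
            n_components = min(self.decomposition.df[term], 2)
        return _components.bootstrap_loadings(
            self.data,
            self.model.coding,
            term,
            np.asarray(variables, dtype=np.intp),
            n_components=n_components,
            n_boot=n_boot,
            seed=seed,
            alpha=alpha,
        )

    # ------------------------------------------------------------ summary
    def summary(self) -> "Summary":
        ssq = self.decomposition.ssq
        total = sum(ssq.values())
        pvals = self._cache.get("pvalues", {})
        rows = []
        for term in self.terms:
            rows.append(
                {
                    "term": term,
                    "df": self.decomposition.df[term],
                    "SSQ": ssq[term],
                    "%SSQ": 100 * ssq[term] / total if total else np.nan,
                    "p_perm": pvals.get(term, np.nan),
                }
            )
        rows.append(
            {
                "term": "residual",
                "df": self.decomposition.df["residual"],
                "SSQ": ssq["residual"],
                "%SSQ": 100 * ssq["residual"] / total if total else np.nan,
                "p_perm": np.nan,
            }
        )
        frame = pd.DataFrame(rows).set_index("term")
        header = (
            f"ASCA+ decomposition  (N={self.decomposition.n_obs}, "
            f"M={self.decomposition.n_vars}, scaling={self.model.scaling}, "
            f"statistic={self.model.statistic})"
        )
        return Summary(header, frame)

    def plot_pcurve(self, results, ax=None, **kwargs):
        from .viz import plot_pcurve
        from .workflow import export_pcurve

        return plot_pcurve(export_pcurve(**results), ax=ax, **kwargs)


class Summary:
    """Plain-text summary table (printable)."""

    def __init__(self, header: str, frame: pd.DataFrame):
        self.header = header
        self.frame = frame

    def as_text(self) -> str:
        body = self.frame.to_string(
            float_format=lambda v: f"{v:.4g}", na_rep="-"
        )
        rule = "=" * max(len(self.header), len(body.splitlines()[0]))
        return f"{self.header}\n{rule}\n{body}\n{rule}"

    def __str__(self) -> str:
        return self.as_text()

    def __repr__(self) -> str:
        return self.as_text()
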