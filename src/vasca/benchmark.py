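"""Multi-method Monte-Carlo benchmarks over the simulation scenarios.

Each replicate draws one dataset from a scenario and evaluates the
requested methods — ASCA, VASCA, the BH-FDR baseline, ASCA-genes and
VASCA followed by bootstrap loading pruning — on the *same* permutation
draws, then aggregates false-positive rates and power (fraction of
replicates recovering at least 1/2/3 of the truly informative variables)
with binomial standard errors.

False-positive conventions follow the method's granularity: per-dataset
for the whole-matrix tests (ASCA rejection; VASCA selecting any variable
on a null dataset) and per-variable for the selection methods (fraction of
non-informative variables flagged, pooled over replicates).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .asca_genes import asca_genes_test
from .components import bootstrap_loadings
from .decomposition import preprocess
from .design import build_coding
from .permutation import (
    PermutationPlan,
    asca_test,
    fdr_test,
    permuted_column_ssq,
    vasca_test,
)
from .simulate import Scenario, generate_scenario, scenario_seed_sequence

__all__ = ["BenchmarkReport", "run_benchmark", "METHODS"]

METHODS = ("asca", "vasca", "fdr", "asca_genes", "vasca_bootstrap")


@dataclass
class BenchmarkReport:
    """Aggregated rates per term and method, plus mean p-value curves."""

    scenario: str
    methods: tuple[str, ...]
    terms: tuple[str, ...]
    reps: int
    n_perms: int
    alpha: float
    seed: int
    statistic: str
    results: dict = field(default_factory=dict)
    pcurves: dict = field(default_factory=dict)
    notes: list = field(default_factory=list)

    def summary(self):
        import pandas as pd

        rows = []
        for term, per_method in self.results.items():
            for method, metrics in per_method.items():
                rows.append({"term": term, "method": method, **metrics})
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        def clean(x):
            if isinstance(x, dict):
                return {k: clean(v) for k, v in x.items()}
            if isinstance(x, (list, tuple)):
                return [clean(v) for v in x]
            if isinstance(x, np.ndarray):
                return x.tolist()
            if isinstance(x, (np.floating, np.integer)):
                return x.item()
            return x

        return clean(
            {
                "scenario": self.scenario,
                "methods": list(self.methods),
                "terms": list(self.terms),
                "reps": self.reps,
                "n_perms": self.n_perms,
                "alpha": self.alpha,
                "seed": self.seed,
                "statistic": self.statistic,
                "results": self.results,
                "pcurves": self.pcurves,
                "notes": self.notes,
            }
        )

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def _binomial_se(p: float, n: int) -> float:
    return float(np.sqrt(max(p * (1 - p), 0.0) / n)) if n else float("nan")


class _SetAccumulator:
    """Counts for a method that flags sets of variables."""

    def __init__(self) -> None:
        self.reps = 0
        self.any_flagged = 0
        self.false_flags = 0
        self.hits = []  # informative variables recovered per replicate

    def add(self, flagged: np.ndarray, truth: np.ndarray) -> None:
        self.reps += 1
        truth_set = set(truth.tolist())
        flagged = np.asarray(flagged)
        self.any_flagged += int(flagged.size > 0)
        self.false_flags += int(sum(1 for v in flagged.tolist() if v not in truth_set))
        self.hits.append(sum(1 for v in flagged.tolist() if v in truth_set))

    def metrics(self, n_noise: int, n_truth: int) -> dict:
        out = {"reps": self.reps}
        rate = self.any_flagged / self.reps
        out["reject_rate"] = rate
        out["se_reject_rate"] = _binomial_se(rate, self.reps)
        trials = self.reps * n_noise
        fpr = self.false_flags / trials if trials else float("nan")
        out["fpr_variable"] = fpr
        out["se_fpr_variable"] = _binomial_se(fpr, trials)
        if n_truth:
            hits = np.asarray(self.hits)
            for j in range(1, n_truth + 1):
                p = float(np.mean(hits >= j))
                out[f"power_{j}"] = p
                out[f"se_power_{j}"] = _binomial_se(p, self.reps)
        return out


def run_benchmark(
    scenario: Scenario | str,
    methods=("asca", "vasca", "fdr"),
    reps: int = 100,
    n_perms: int = 1000,
    alpha: float = 0.01,
    seed: int = 0,
    statistic: str = "f_ratio",
    bootstrap_reps: int | None = None,
    n_boot: int = 1000,
    keep_pcurves: bool = True,
    only_terms: tuple[str, ...] | None = None,
) -> BenchmarkReport:
    """Run a scenario ``reps`` times and aggregate per-method rates.

    ``bootstrap_reps`` limits the (expensive) bootstrap pruning to the
    first so-many replicates; the other methods still use all ``reps``.
    ``only_terms`` restricts evaluation to a subset of the scenario's
    factors (the full model is still fitted).  All randomness derives from
    ``seed`` via per-replicate seed sequences, and within a replicate every
    method shares one permutation plan.
    """
    if isinstance(scenario, str):
        scenario = Scenario(scenario)
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValueError(f"unknown method(s) {sorted(unknown)}; choose from {METHODS}")
    if "vasca_bootstrap" in methods and bootstrap_reps is None:
        bootstrap_reps = reps
    # autoscaling is part of the study conditions: the whole-matrix and
    # cumulative statistics are scale-dependent, and the benchmark datasets
    # mix variables of very different variance (e.g. the biased variables)
    mode = "autoscale"

    acc: dict[str, dict] = {}
    asca_p: dict[str, list] = {}
    pcurve_sum: dict[str, dict[str, np.ndarray]] = {}
    pcurve_sumsq: dict[str, dict[str, np.ndarray]] = {}
    notes: list[str] = []
    terms_seen: tuple[str, ...] = ()
    n_truth = 0
    n_noise = 0

    for rep in range(reps):
        ss = scenario_seed_sequence(seed, scenario.id, rep)
        data_ss, perm_ss, boot_ss = ss.spawn(3)
        rng = np.random.default_rng(data_ss)
        X, design, truth, terms = generate_scenario(scenario, rng=rng)
        perm_seed = int(np.random.default_rng(perm_ss).integers(2**31))
        boot_seed = int(np.random.default_rng(boot_ss).integers(2**31))
        Xp, _ = preprocess(X, mode)
        coding = build_coding(design, terms)
        plan = PermutationPlan(n_perms, perm_seed)
        eval_terms = (
            tuple(t for t in terms.main if t in only_terms)
            if only_terms is not None
            else terms.main
        )
        terms_seen = eval_terms
        n_truth = truth.size
        n_noise = X.shape[1] - truth.size

        for term in eval_terms:
            per_term = acc.setdefault(term, {})
            want_genes = "asca_genes" in methods
            if want_genes and coding.df[term] < 2:
                if rep == 0:
                    notes.append(
                        f"asca_genes skipped for term {term!r}: "
                        f"{coding.df[term]} df < 2"
                    )
                want_genes = False
            stats = permuted_column_ssq(
                Xp,
                coding,
                term,
                plan,
                n_components=min(coding.df[term], 2) if want_genes else None,
            )
            vres = None
            if "asca" in methods:
                a = asca_test(Xp, coding, term, statistic, stats=stats)
                asca_p.setdefault(term, []).append(a.p_value)
                per_term.setdefault("asca", _SetAccumulator()).add(
                    np.arange(X.shape[1]) if a.p_value < alpha else np.array([]),
                    truth if truth.size else np.array([]),
                )
            if "vasca" in methods or "vasca_bootstrap" in methods:
                vres = vasca_test(Xp, coding, term, statistic, alpha=alpha, stats=stats)
                if "vasca" in methods:
                    per_term.setdefault("vasca", _SetAccumulator()).add(
                        vres.selected_variables, truth
                    )
                    if keep_pcurves:
                        s = pcurve_sum.setdefault(term, {}).setdefault(
                            "vasca", np.zeros(X.shape[1])
                        )
                        s += vres.p_curve
                        s2 = pcurve_sumsq.setdefault(term, {}).setdefault(
                            "vasca", np.zeros(X.shape[1])
                        )
                        s2 += vres.p_curve**2
            if "fdr" in methods:
                f = fdr_test(Xp, coding, term, statistic, alpha=alpha, stats=stats)
                per_term.setdefault("fdr", _SetAccumulator()).add(f.significant, truth)
                if keep_pcurves:
                    curve = np.sort(np.minimum(f.p_adjusted, 1.0))
                    s = pcurve_sum.setdefault(term, {}).setdefault(
                        "fdr", np.zeros(X.shape[1])
                    )
                    s += curve
                    s2 = pcurve_sumsq.setdefault(term, {}).setdefault(
                        "fdr", np.zeros(X.shape[1])
                    )
                    s2 += curve**2
            if want_genes:
                g = asca_genes_test(Xp, coding, term, alpha=alpha, stats=stats)
                per_term.setdefault("asca_genes", _SetAccumulator()).add(
                    np.nonzero(g.positive)[0], truth
                )
            if "vasca_bootstrap" in methods and rep < bootstrap_reps:
                assert vres is not None
                if vres.selected_m:
                    boot = bootstrap_loadings(
                        Xp,
                        coding,
                        term,
                        vres.selected_variables,
                        n_components=min(coding.df[term], 2),
                        n_boot=n_boot,
                        seed=boot_seed,
                        alpha=alpha,
                    )
                    retained = vres.selected_variables[boot.significant]
                else:
                    retained = np.array([], dtype=np.intp)
                per_term.setdefault("vasca_bootstrap", _SetAccumulator()).add(
                    retained, truth
                )

    results = {
        term: {
            method: a.metrics(n_noise, n_truth) for method, a in per_method.items()
        }
        for term, per_method in acc.items()
    }
    pcurves: dict = {}
    for term in terms_seen:
        pcurves[term] = {}
        if term in asca_p:
            p = np.asarray(asca_p[term])
            pcurves[term]["asca"] = {"mean": float(p.mean()), "sd": float(p.std())}
            results[term]["asca"]["mean_p"] = float(p.mean())
        for method, s in pcurve_sum.get(term, {}).items():
            n = results[term][method]["reps"]
            mean = s / n
            var = np.maximum(pcurve_sumsq[term][method] / n - mean**2, 0.0)
            pcurves[term][method] = {"mean": mean, "sd": np.sqrt(var)}
    return BenchmarkReport(
        scenario=scenario.id,
        methods=tuple(methods),
        terms=terms_seen,
        reps=reps,
        n_perms=n_perms,
        alpha=alpha,
        seed=seed,
        statistic=statistic,
        results=results,
        pcurves=pcurves,
        notes=notes,
    )
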