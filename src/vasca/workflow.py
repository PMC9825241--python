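"""End-to-end analysis runs: configuration, execution, serialization.

``run_analysis`` drives the factorize → test → visualize pipeline from a
:class:`RunConfig` and writes a reproducible output bundle: per-term VASCA
curves, optional FDR and ASCA-genes tables, component scores/loadings with
bootstrap intervals for significant terms, and a JSON summary embedding
the full configuration (re-running from the embedded config reproduces
identical numbers).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import ASCA
from .permutation import PermutationPlan

__all__ = ["RunConfig", "run_analysis", "export_pcurve"]


@dataclass
class RunConfig:
    """Serializable description of one analysis run."""

    data: str
    design: str
    out: str = "vasca_out"
    terms: str | None = None
    statistic: str = "f_ratio"
    scaling: str | None = None
    n_perms: int = 1000
    alpha: float = 0.05
    seed: int = 0
    n_boot: int = 1000
    levels: dict = field(default_factory=dict)
    methods: tuple[str, ...] = ("asca", "vasca")

    def __post_init__(self) -> None:
        if self.statistic == "ssq" and self.scaling not in (None, "autoscale"):
            raise ValueError(
                "statistic 'ssq' requires scaling 'autoscale' (or leave the "
                "scaling unset to get it by default)"
            )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "methods" in raw:
            raw["methods"] = tuple(raw["methods"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["methods"] = list(self.methods)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def export_pcurve(vasca=None, fdr=None, asca=None) -> pd.DataFrame:
    """Long-format table of ordered p-values for the significance plot.

    VASCA rows give the p-value of the best-``m``-variable sub-model at
    each rank ``m``; FDR rows are the BH-adjusted p-values sorted
    ascending (most significant first) and clamped at 1; the single ASCA
    p-value is repeated at rank ``M``.  Reference significance lines (0.05
    and 0.01) travel in ``frame.attrs``.
    """
    if vasca is None and fdr is None and asca is None:
        raise ValueError("nothing to export")
    pieces = []
    if vasca is not None:
        pieces.append(
            pd.DataFrame(
                {
                    "method": "vasca",
                    "m": np.arange(1, vasca.p_curve.size + 1),
                    "p_value": vasca.p_curve,
                }
            )
        )
    if fdr is not None:
        adj = np.sort(np.minimum(fdr.p_adjusted, 1.0))
        pieces.append(
            pd.DataFrame(
                {"method": "fdr", "m": np.arange(1, adj.size + 1), "p_value": adj}
            )
        )
    if asca is not None:
        m = vasca.p_curve.size if vasca is not None else (
            fdr.p_adjusted.size if fdr is not None else 1
        )
        pieces.append(
            pd.DataFrame({"method": "asca", "m": [m], "p_value": [asca.p_value]})
        )
    frame = (
        pd.concat(pieces, ignore_index=True)
        .sort_values(["method", "m"], kind="stable")
        .reset_index(drop=True)
    )
    frame.attrs["alpha_lines"] = [0.05, 0.01]
    return frame


def run_analysis(config: RunConfig) -> dict:
    """Execute the configured pipeline and write the output bundle.

    Returns a dict with the per-term result objects (also serialized under
    ``config.out``).
    """
    out = Path(config.out)
    out.mkdir(parents=True, exist_ok=True)
    data_path = Path(config.data)
    if not data_path.exists():
        raise FileNotFoundError(f"data file not found: {data_path}")
    from .design import parse_design, sniff_delimiter

    data = pd.read_csv(data_path, sep=sniff_delimiter(data_path))

    design = parse_design(config.design, levels=config.levels or None)
    model = ASCA(
        data,
        design,
        terms=config.terms,
        statistic=config.statistic,
        scaling=config.scaling,
    )
    results = model.fit()
    plan = PermutationPlan(config.n_perms, config.seed)
    bundle: dict = {"results": results, "terms": {}}
    summary: dict = {
        "config": {**asdict(config), "methods": list(config.methods)},
        "terms": {},
    }
    for term in results.terms:
        report: dict = {}
        a = results.permutation_test(term, plan=plan)
        v = results.vasca(term, alpha=config.alpha, plan=plan)
        report["asca"] = a
        report["vasca"] = v
        v.to_frame(results.var_names).to_csv(
            out / f"vasca_{_safe(term)}.csv", index=False
        )
        fdr = None
        if "fdr" in config.methods:
            fdr = results.univariate_fdr(term, alpha=config.alpha, plan=plan)
            report["fdr"] = fdr
            fdr.to_frame(results.var_names).to_csv(
                out / f"fdr_{_safe(term)}.csv", index=False
            )
        if "asca_genes" in config.methods and results.decomposition.df[term] >= 2:
            g = results.asca_genes(term, alpha=config.alpha, plan=plan)
            report["asca_genes"] = g
            g.to_frame(results.var_names).to_csv(
                out / f"asca_genes_{_safe(term)}.csv", index=False
            )
            summary["terms"].setdefault(term, {})["asca_genes_limits"] = {
                "leverage": g.leverage_limit,
                "spe": g.spe_limit,
            }
        export_pcurve(vasca=v, fdr=fdr, asca=a).to_csv(
            out / f"pcurve_{_safe(term)}.csv", index=False
        )
        term_summary = summary["terms"].setdefault(term, {})
        term_summary.update(
            {
                "asca_p": a.p_value,
                "vasca_selected_m": v.selected_m,
                "vasca_selected": results.var_names[v.selected_variables].tolist(),
            }
        )
        if v.selected_m:
            cm = results.components(term, variables=v.selected_variables)
            boot = results.bootstrap_loadings(
                term,
                variables=v.selected_variables,
                n_boot=config.n_boot,
                seed=config.seed,
                alpha=config.alpha,
            )
            report["components"] = cm
            report["bootstrap"] = boot
            boot.to_frame(results.var_names).to_csv(
                out / f"loadings_{_safe(term)}.csv", index=False
            )
            scores = pd.DataFrame(
                cm.projected_scores,
                columns=[f"PC{a_ + 1}" for a_ in range(cm.n_components)],
            )
            scores.to_csv(out / f"scores_{_safe(term)}.csv", index=False)
            term_summary["bootstrap_significant"] = results.var_names[
                v.selected_variables[boot.significant]
            ].tolist()
        bundle["terms"][term] = report
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    RunConfig(**{**asdict(config)}).to_yaml(out / "config.yaml")
    return bundle


def _safe(term: str) -> str:
    return term.replace(":", "_x_")
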