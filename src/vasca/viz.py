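"""Plot helpers: ordered p-value curves and component score/loading plots."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_pcurve", "plot_scores", "plot_loadings"]


def _get_ax(ax):
    if ax is not None:
        return ax
    import matplotlib.pyplot as plt

    _, ax = plt.subplots()
    return ax


def plot_pcurve(frame, ax=None, logy: bool = True):
    """Ordered p-values per method (the FDR/ASCA/VASCA comparison plot).

    ``frame`` is the long table from :func:`vasca.workflow.export_pcurve`;
    reference significance lines come from ``frame.attrs``.
    """
    ax = _get_ax(ax)
    styles = {"vasca": "-", "fdr": "--"}
    for method, sub in frame.groupby("method"):
        if method == "asca":
            ax.scatter(sub["m"], sub["p_value"], marker="s", label="asca")
        else:
            ax.plot(sub["m"], sub["p_value"], styles.get(method, "-"), label=method)
    for level in frame.attrs.get("alpha_lines", [0.05, 0.01]):
        ax.axhline(level, color="grey", lw=0.8, ls=":")
    if logy:
        ax.set_yscale("log")
    ax.set_xlabel("number of variables m")
    ax.set_ylabel("p-value")
    ax.legend()
    return ax


def plot_scores(component_model, design=None, factor=None, ax=None, components=(0, 1)):
    """Scatter of projected Z+E scores, colour-coded by factor level."""
    ax = _get_ax(ax)
    T = (
        component_model.projected_scores
        if component_model.projected_scores is not None
        else component_model.scores
    )
    a, b = components
    if T.shape[1] == 1:
        y = np.zeros(T.shape[0])
        b = None
    else:
        y = T[:, b]
    if design is not None and factor is not None:
        codes = design.codes[factor]
        for code in np.unique(codes):
            mask = codes == code
            ax.scatter(T[mask, a], y[mask], label=str(design.levels[factor][code]))
        ax.legend(title=factor)
    else:
        ax.scatter(T[:, a], y)
    ax.set_xlabel(f"PC{a + 1} scores")
    ax.set_ylabel(f"PC{b + 1} scores" if b is not None else "")
    return ax


def plot_loadings(bootstrap, var_names=None, component: int = 0, ax=None):
    """Loading point estimates with bootstrap percentile intervals."""
    ax = _get_ax(ax)
    point = bootstrap.point[:, component]
    lo = bootstrap.lower[:, component]
    hi = bootstrap.upper[:, component]
    x = np.arange(point.size)
    ax.errorbar(
        x,
        point,
        yerr=[point - lo, hi - point],
        fmt="o",
        capsize=3,
    )
    ax.axhline(0.0, color="grey", lw=0.8)
    names = (
        np.asarray(var_names)[bootstrap.variables]
        if var_names is not None
        else bootstrap.variables
    )
    ax.set_xticks(x, [str(n) for n in names], rotation=90)
    ax.set_ylabel(f"PC{component + 1} loading")
    return ax
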