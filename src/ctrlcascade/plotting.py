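"""Optional matplotlib renderings of trigger traces and sweep curves.

matplotlib is imported lazily so the rest of the package has no hard
dependency on it (install the ``plots`` extra).
"""

from __future__ import annotations

from .experiments import SweepResult, TriggerResult

__all__ = ["plot_trigger_trace", "plot_sweep"]


def _require_pyplot():
    try:
        import matplotlib.pyplot as plt
    except ImportError as exc:  # pragma: no cover
        raise ImportError("plotting requires matplotlib (pip extra 'plots')") from exc
    return plt


def plot_trigger_trace(result: TriggerResult, ax=None):
    """Averaged driver count and SCC edge count vs cascade stage."""
    plt = _require_pyplot()
    if ax is None:
        _, ax = plt.subplots()
    t = result.trace
    ax.errorbar(
        t["stage"], t["n_drivers_mean"], yerr=t["n_drivers_se"], label="driver nodes"
    )
    ax2 = ax.twinx()
    ax2.errorbar(
        t["stage"],
        t["scc_edges_mean"],
        yerr=t["scc_edges_se"],
        color="tab:red",
        label="SCC edges",
    )
    ax.set_xlabel("cascade stage")
    ax.set_ylabel("driver nodes $N_D$")
    ax2.set_ylabel("edges in SCC")
    ax.figure.legend(loc="upper center", ncol=2)
    return ax


def plot_sweep(result: SweepResult, quantity: str = "n_drivers_final", ax=None):
    """One curve per attack strategy of ``quantity`` vs removal fraction f."""
    plt = _require_pyplot()
    if ax is None:
        _, ax = plt.subplots()
    col = f"{quantity}_mean"
    se = f"{quantity}_se"
    for strategy, part in result.summary.groupby("strategy"):
        part = part.sort_values("f")
        ax.errorbar(part["f"], part[col], yerr=part[se], marker="o", label=strategy)
    ax.set_xlabel("removal fraction $f$")
    ax.set_ylabel(quantity.replace("_", " "))
    ax.legend()
    return ax
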