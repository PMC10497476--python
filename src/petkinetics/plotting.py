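"""Plot helpers for agreement and protocol-comparison figures."""

from __future__ import annotations

import numpy as np

from .evaluation import BlandAltman, ComparisonReport


def bland_altman_plot(ba: BlandAltman, ax=None, title: str | None = None):
    """Scatter of pairwise differences with bias and limits of agreement."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(ba.means, ba.diffs, s=12, alpha=0.7)
    for y, style in ((ba.bias, "-"), (ba.loa_low, "--"), (ba.loa_high, "--")):
        ax.axhline(y, color="k", linestyle=style, linewidth=1)
    ylab = "difference (%)" if ba.mode == "relative" else "difference"
    ax.set_xlabel("pairwise mean")
    ax.set_ylabel(ylab)
    if title:
        ax.set_title(title)
    return ax


def protocol_difference_bars(
    report: ComparisonReport, parameter: str = "ki", ax=None
):
    """Mean +/- SD relative difference per protocol vs the reference."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    mean = getattr(report, f"{parameter}_rel_diff_mean")
    sd = getattr(report, f"{parameter}_rel_diff_sd")
    protocols = [p for p in mean.columns if p != report.reference]
    m = mean[protocols].to_numpy().mean(axis=0)
    s = np.sqrt((sd[protocols].to_numpy() ** 2).mean(axis=0))
    ax.bar(protocols, m, yerr=s, capsize=4)
    ax.axhline(0, color="k", linewidth=1)
    ax.set_ylabel(f"{parameter} relative difference vs {report.reference} (%)")
    return ax
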