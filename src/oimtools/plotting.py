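"""Minimal figures: exposure eCDFs and UTP interval plots."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # headless by default; callers may switch backends
import matplotlib.pyplot as plt

from .exposure import ExposureEstimate


def plot_ecdfs(estimates: "dict[str, ExposureEstimate]", ax=None):
    """Overlay deterministic exposure eCDFs for several estimates."""
    if ax is None:
        _, ax = plt.subplots()
    for label, est in estimates.items():
        if est.ecdf_x is None:
            continue
        ax.step(est.ecdf_x, est.ecdf_p, where="post", label=label)
    ax.set_xlabel("exposure (ug/kg bw/day)")
    ax.set_ylabel("cumulative probability")
    ax.legend(fontsize=8)
    return ax


def plot_utp(estimates: "dict[str, ExposureEstimate]", tdi: "float | None" = None, ax=None):
    """UTP point estimates with their 95% CIs, one column per method."""
    if ax is None:
        _, ax = plt.subplots()
    for i, (label, est) in enumerate(estimates.items()):
        ax.plot([i], [est.de[0.95]], "ko")
        if est.ci is not None:
            lo, hi = est.ci[0.95]
            ax.vlines(i, lo, hi, colors="k")
    ax.set_xticks(range(len(estimates)), list(estimates), rotation=30, ha="right")
    if tdi is not None:
        ax.axhline(tdi, color="red", linestyle="--", label=f"TDI = {tdi}")
        ax.legend(fontsize=8)
    ax.set_ylabel("95th-percentile exposure (ug/kg bw/day)")
    return ax
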