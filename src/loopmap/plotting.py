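"""Minimal figures for the analysis outputs (matplotlib, Agg-safe)."""

from __future__ import annotations

from .density import DensityProfile
from .enrichment import DistanceWindowScan, QQResult

__all__ = ["plot_mirror_density", "plot_qq", "plot_scan"]


def _axes(ax):
    if ax is not None:
        return ax
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    _, ax = plt.subplots()
    return ax


def plot_mirror_density(profile: DensityProfile, ax=None):
    """Variant-side vs mirror-side interaction counts by distance bin."""
    ax = _axes(ax)
    df = profile.to_frame()
    x = (df["bin_start"] + profile.bin_size / 2) / 1e3
    ax.plot(x, df["variant_side_count"], label="variant side", color="tab:green")
    ax.plot(x, df["mirror_side_count"], label="mirror side", color="tab:blue")
    ax.set_xlabel("distance (kb)")
    ax.set_ylabel("interaction count")
    ax.legend()
    return ax


def plot_qq(qq: QQResult, ax=None):
    """Quantile-quantile plot of -log10 p-values, real vs control."""
    ax = _axes(ax)
    ax.plot(qq.control, qq.real, ".", ms=3)
    lim = max(qq.control.max(), qq.real.max())
    ax.plot([0, lim], [0, lim], "k--", lw=1)
    ax.set_xlabel("control -log10 p")
    ax.set_ylabel("real -log10 p")
    return ax


def plot_scan(scan: DistanceWindowScan, ax=None):
    """Fold enrichment over the distance-window scan, with the horizon."""
    ax = _axes(ax)
    df = scan.to_frame()
    for kind, style in (("cumulative", "-o"), ("annulus", "--s")):
        sub = df[df["kind"] == kind]
        ax.plot(sub["window"] / 1e3, sub["fold"], style, ms=3, label=kind)
    if scan.horizon is not None:
        ax.axvline(scan.horizon / 1e3, color="r", lw=1, label="horizon")
    ax.axhline(1.0, color="k", lw=0.5)
    ax.set_xlabel("distance window (kb)")
    ax.set_ylabel("fold enrichment")
    ax.legend()
    return ax
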