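"""Optional plotting layer over the pipeline tables (requires matplotlib)."""

from __future__ import annotations

import pandas as pd

__all__ = ["plot_metagene_profile", "plot_bin_curve"]


def _pyplot():
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError as exc:  # pragma: no cover
        raise ImportError("plotting requires the 'plot' extra (matplotlib)") from exc
    return plt


def plot_metagene_profile(profile: pd.DataFrame, path) -> None:
    """Windowed methylation around TSS/TTS, one line per expression bin."""
    plt = _pyplot()
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5), sharey=True)
    for ax, anchor in zip(axes, ("TSS", "TTS")):
        sub = profile[profile["anchor"] == anchor]
        for b, grp in sub.groupby("bin"):
            ax.plot(grp["offset"], grp["mean_percent"], label=f"bin {b}", lw=1)
        ax.axvline(0, color="grey", lw=0.5)
        ax.set_xlabel(f"bp from {anchor}")
        ax.set_title(anchor)
    axes[0].set_ylabel("% methylation")
    axes[0].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_bin_curve(bins: pd.DataFrame, path, xlabel="mean log2 expression",
                   ylabel="mean % methylation") -> None:
    """Scatter of bin means (the binned-regression view)."""
    plt = _pyplot()
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    ax.plot(bins["mean_x"], bins["mean_y"], "o", ms=3)
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
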