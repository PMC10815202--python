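"""Optional track plots (requires matplotlib, installed via the ``plot``
extra)."""

from __future__ import annotations

from .pipeline import ScanResult

METHOD_LABELS = {
    "delta": "Δ(SNP-index)",
    "ed": "ED$^p$",
    "g": "G",
    "fisher": "mean −log10 p",
}


def plot_tracks(result: ScanResult, path: str | None = None):
    """One panel per statistic: smoothed window values along the genome with
    the significance threshold and called consensus regions."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import numpy as np

    fig, axes = plt.subplots(4, 1, figsize=(10, 9), sharex=True)
    for ax, (method, track) in zip(axes, result.tracks.items()):
        win = track.windows
        offset = 0
        ticks, labels = [], []
        for chrom, block in win.groupby("chrom", sort=False):
            x = (block["start"] + block["end"]) / 2 + offset
            ax.plot(x, block["value"], lw=0.8)
            ticks.append(offset + block["end"].max() / 2)
            labels.append(chrom)
            offset += block["end"].max()
        thr = result.thresholds[method]
        if np.ndim(thr) == 0 and method != "fisher":
            ax.axhline(float(thr), color="red", lw=0.8, ls="--")
        ax.set_ylabel(METHOD_LABELS.get(method, method))
        ax.set_xticks(ticks, labels)
    axes[-1].set_xlabel("genomic position")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
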