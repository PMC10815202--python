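"""End-to-end BSA-seq scan: statistics → smoothing → thresholds → intervals.

:func:`scan` wires the full per-dataset analysis together and is what the
command-line interface, the example scripts and the simulation-recovery
harness run.  Each statistic carries its own significance rule:

========  ==============================================================
method    99%-level rule
========  ==============================================================
delta     |window mean Δ| above the simulated null envelope at the
          window's mean read depth (:func:`bsaqtl.windows.takagi_ci`)
ed        window mean ED^power above the genome-wide empirical quantile
g         window mean G above the genome-wide empirical quantile
fisher    minimum member q-value below ``q_threshold`` (BH-adjusted)
========  ==============================================================
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import intervals as iv
from . import stats as st
from . import windows as wd

__all__ = ["ScanConfig", "ScanResult", "scan"]

METHODS = ("delta", "ed", "g", "fisher")


@dataclass
class ScanConfig:
    """Tunable parameters of the windowed scan."""

    window_size_bp: int = 1_000_000
    step_bp: int = 10_000
    level: float = 0.99
    q_threshold: float = 0.01
    ed_power: float = 2.0
    min_snps_per_window: int = 10
    pool_size: int = 30
    ci_reps: int = 10_000
    ci_depths: tuple[int, ...] = (5, 10, 20, 30, 50, 75, 100, 150, 200)
    min_support: int = 4
    seed: int = 0
    #: "simulation" (null Monte Carlo, default) or "empirical" (genome-wide
    #: quantile of window values) for the ED and G thresholds
    ed_g_threshold_kind: str = "simulation"
    #: precomputed {depth: half width} Δ envelope; reused across replicates
    delta_envelope: dict[int, float] | None = None
    #: precomputed scalar ED/G thresholds; reused across replicates
    ed_threshold: float | None = None
    g_threshold: float | None = None


@dataclass
class ScanResult:
    """Everything the scan produced, from per-variant rows to named regions."""

    stats: pd.DataFrame
    tracks: dict[str, wd.StatTrack]
    thresholds: dict[str, float | np.ndarray]
    intervals: dict[str, list[iv.QtlInterval]]
    consensus: list[iv.ConsensusRegion]

    def tracks_frame(self) -> pd.DataFrame:
        """Long-format per-window table across methods (for TSV export)."""
        frames = []
        for method, track in self.tracks.items():
            f = track.windows.copy()
            f.insert(0, "method", method)
            frames.append(f)
        return pd.concat(frames, ignore_index=True)


def scan(
    table: pd.DataFrame,
    chrom_lengths: dict[str, int] | None = None,
    config: ScanConfig | None = None,
) -> ScanResult:
    """Run the four-statistic windowed QTL scan on an allele-count table.

    ``table`` is a filtered allele-count table (see :mod:`bsaqtl.io`);
    ``chrom_lengths`` defaults to the last variant position per chromosome.
    Returns per-variant statistics, the four smoothed tracks, per-method
    thresholds and intervals, and the named multi-method consensus regions.
    """
    if config is None:
        config = ScanConfig()
    if chrom_lengths is None:
        chrom_lengths = {
            str(c): int(g["pos"].max()) for c, g in table.groupby("chrom", sort=False)
        }
    stats = st.compute_statistics(table, ed_power=config.ed_power)
    grid = wd.make_grid(chrom_lengths, config.window_size_bp, config.step_bp)
    depth = np.minimum(
        (table["ref_h"] + table["alt_h"]).to_numpy(),
        (table["ref_l"] + table["alt_l"]).to_numpy(),
    )

    tracks = {
        "delta": wd.smooth(
            stats, grid, "delta_snp_index", method="delta",
            min_snps_per_window=config.min_snps_per_window, depth=depth,
        ),
        "ed": wd.smooth(
            stats, grid, "ed_pow", method="ed",
            min_snps_per_window=config.min_snps_per_window,
        ),
        "g": wd.smooth(
            stats, grid, "g_stat", method="g",
            min_snps_per_window=config.min_snps_per_window,
        ),
        "fisher": wd.smooth(
            stats, grid, "fisher_p", method="fisher",
            min_snps_per_window=config.min_snps_per_window,
            q_column="fisher_q",
        ),
    }
    # Fisher windows display mean -log10(p); significance uses min member q.
    with np.errstate(divide="ignore", invalid="ignore"):
        fw = tracks["fisher"].windows
        logp = wd.smooth(
            stats.assign(neglog10p=-np.log10(stats["fisher_p"])),
            grid, "neglog10p", method="fisher",
            min_snps_per_window=config.min_snps_per_window,
        )
        fw["value"] = logp.windows["value"]

    envelope = config.delta_envelope
    if envelope is None:
        envelope = wd.takagi_ci(
            config.pool_size, config.ci_depths,
            level=config.level, reps=config.ci_reps, seed=config.seed,
        )
    ed_thr, g_thr = config.ed_threshold, config.g_threshold
    if ed_thr is None or g_thr is None:
        if config.ed_g_threshold_kind == "empirical":
            ed_thr = wd.empirical_threshold(tracks["ed"], config.level)
            g_thr = wd.empirical_threshold(tracks["g"], config.level)
        elif config.ed_g_threshold_kind == "simulation":
            depth_h = float((table["ref_h"] + table["alt_h"]).mean())
            depth_l = float((table["ref_l"] + table["alt_l"]).mean())
            n_typ = int(
                np.median(tracks["ed"].unmasked()["n_variants"].to_numpy())
            )
            common = dict(
                pool_size=config.pool_size, mean_depth_h=depth_h,
                mean_depth_l=depth_l, n_variants=max(n_typ, 1),
                level=config.level, reps=config.ci_reps,
                ed_power=config.ed_power,
            )
            if ed_thr is None:
                ed_thr = wd.null_window_threshold("ed", seed=config.seed + 1, **common)
            if g_thr is None:
                g_thr = wd.null_window_threshold("g", seed=config.seed + 2, **common)
        else:
            raise ValueError(
                f"unknown ed_g_threshold_kind {config.ed_g_threshold_kind!r}"
            )
    thresholds: dict[str, float | np.ndarray] = {
        "delta": wd.envelope_for_track(tracks["delta"], envelope),
        "ed": float(ed_thr),
        "g": float(g_thr),
        "fisher": config.q_threshold,
    }
    called = {
        "delta": iv.call_intervals(tracks["delta"], thresholds["delta"], "abs_greater"),
        "ed": iv.call_intervals(tracks["ed"], thresholds["ed"], "greater"),
        "g": iv.call_intervals(tracks["g"], thresholds["g"], "greater"),
        "fisher": iv.call_intervals(tracks["fisher"], thresholds["fisher"], "min_q_less"),
    }
    consensus = iv.name_regions(
        iv.intersect_methods(called, min_support=config.min_support)
    )
    return ScanResult(
        stats=stats, tracks=tracks, thresholds=thresholds,
        intervals=called, consensus=consensus,
    )
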