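"""Replicate studies validating the scan against simulated ground truth.

Two standard studies at the emulated experiment's conditions (860 F2 plants,
30 + 30 extreme pools, ~20x pool depth, 2,000 markers on 2 x 50 Mb):

* a **null study** (no QTL) checking that Δ(SNP-index) is centred on zero
  and that the four-method consensus stays silent, and
* a **recovery study** (planted additive QTL) measuring how often the
  consensus region covers the true locus and how far the Δ(SNP-index) peak
  lands from it.

Thresholds (the Δ depth envelope and the ED/G null quantiles) are computed
once per study and shared across replicates — they depend only on the
design, not on any one replicate's reads.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .intervals import evaluate_recovery
from .pipeline import ScanConfig, scan
from .simulate import SimConfig, run_simulation

__all__ = ["ReplicateStudy", "run_replicates"]


@dataclass
class ReplicateStudy:
    """Aggregated outcomes of a replicate study."""

    n_replicates: int
    mean_delta_genomewide: float
    se_delta_genomewide: float
    n_with_consensus: int
    coverage_rate: float
    mean_consensus_width_bp: float
    peak_distances_bp: list[float]

    @property
    def no_consensus_rate(self) -> float:
        return 1.0 - self.n_with_consensus / self.n_replicates

    def peak_within(self, radius_bp: float) -> float:
        """Fraction of replicates whose Δ peak lies within ``radius_bp`` of
        the true QTL (replicates without a finite peak count as misses)."""
        d = np.asarray(self.peak_distances_bp, dtype=float)
        return float(np.mean(np.where(np.isfinite(d), d <= radius_bp, False)))


def run_replicates(
    n_replicates: int,
    additive_effect: float,
    seed: int,
    sim_kwargs: dict | None = None,
    scan_config: ScanConfig | None = None,
) -> ReplicateStudy:
    """Run ``n_replicates`` independent simulate-and-scan experiments.

    ``additive_effect`` is the planted QTL effect in branches per allele
    (0 gives the null study).  ``sim_kwargs`` override :class:`SimConfig`
    fields; each replicate gets its own sub-seed drawn from ``seed``.
    """
    master = np.random.default_rng(seed)
    sub_seeds = master.integers(0, 2**31 - 1, size=n_replicates)
    base = dict(sim_kwargs or {})
    base["additive_effect"] = additive_effect

    if scan_config is None:
        scan_config = ScanConfig(seed=int(master.integers(0, 2**31 - 1)))
    # Precompute design-level thresholds once, if not supplied.
    probe = SimConfig(seed=0, **base)
    if scan_config.delta_envelope is None:
        from .windows import takagi_ci

        d = int(round(probe.pool_depth))
        depths = sorted({max(d // 2, 1), d, 2 * d, 4 * d})
        scan_config.delta_envelope = takagi_ci(
            probe.pool_size, depths, level=scan_config.level,
            reps=scan_config.ci_reps, seed=scan_config.seed,
        )
    if scan_config.ed_threshold is None or scan_config.g_threshold is None:
        from .windows import null_window_threshold

        n_per_window = max(
            int(scan_config.window_size_bp // probe.marker_spacing_bp), 1
        )
        common = dict(
            pool_size=probe.pool_size, mean_depth_h=probe.pool_depth,
            mean_depth_l=probe.pool_depth, n_variants=n_per_window,
            level=scan_config.level, reps=scan_config.ci_reps,
            ed_power=scan_config.ed_power,
        )
        scan_config.ed_threshold = null_window_threshold(
            "ed", seed=scan_config.seed + 1, **common
        )
        scan_config.g_threshold = null_window_threshold(
            "g", seed=scan_config.seed + 2, **common
        )

    delta_means = []
    regions_per_rep = []
    truths = []
    widths = []
    peak_dist = []
    for s in sub_seeds:
        cfg = SimConfig(seed=int(s), **base)
        table, truth = run_simulation(cfg)
        result = scan(table, chrom_lengths=cfg.chrom_lengths(), config=scan_config)
        delta_means.append(float(np.nanmean(result.stats["delta_snp_index"])))
        regions_per_rep.append(result.consensus)
        truths.append(truth.qtl_position)
        widths.extend(r.width for r in result.consensus)

        dwin = result.tracks["delta"].windows
        vals = np.abs(dwin["value"].to_numpy(dtype=float))
        if np.isfinite(vals).any():
            i = int(np.nanargmax(vals))
            same_chrom = dwin["chrom"].iloc[i] == truth.qtl_position[0]
            mid = (dwin["start"].iloc[i] + dwin["end"].iloc[i]) / 2
            peak_dist.append(
                abs(mid - truth.qtl_position[1]) if same_chrom else np.inf
            )
        else:
            peak_dist.append(np.inf)

    recovery = evaluate_recovery(regions_per_rep, truths)
    delta_means = np.asarray(delta_means)
    return ReplicateStudy(
        n_replicates=n_replicates,
        mean_delta_genomewide=float(delta_means.mean()),
        se_delta_genomewide=float(
            delta_means.std(ddof=1) / np.sqrt(n_replicates)
        ),
        n_with_consensus=sum(bool(r) for r in regions_per_rep),
        coverage_rate=recovery.coverage_rate,
        mean_consensus_width_bp=recovery.mean_width_bp,
        peak_distances_bp=peak_dist,
    )
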