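"""Forward simulation of an F2 pooled-sequencing (BSA-seq) experiment.

The generator emulates a biparental cross between a high- and a low-branching
cultivar: an F2 population segregating 1:2:1 at every marker, a quantitative
phenotype (branch count) controlled by one or more planted QTLs plus Gaussian
noise, truncation selection of the two phenotypic extremes into DNA pools, and
binomial read sampling of pooled allele frequencies at sequencing depth.

Recombination follows Haldane's map function (no interference): for two
markers ``d`` Morgans apart the recombinant fraction is ``(1 - exp(-2 d))/2``.
Parents are fully homozygous and fully informative — the high-branching parent
carries the ``alt`` allele at every marker, so a genotype value in {0, 1, 2}
counts copies of the high-parent allele.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam

from .io import TABLE_COLUMNS

__all__ = [
    "QtlEffect",
    "SimConfig",
    "SimTruth",
    "haldane_r",
    "simulate_gametes",
    "simulate_f2",
    "select_pools",
    "pool_reads",
    "write_sim_outputs",
    "run_simulation",
]


def haldane_r(distance_cm: np.ndarray | float) -> np.ndarray | float:
    """Recombinant fraction for a map distance in centimorgans (Haldane)."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(distance_cm) / 100.0))


@dataclass(frozen=True)
class QtlEffect:
    """A planted QTL: location plus additive/dominance effects in branches.

    ``a`` is the half-difference between the two homozygote means; ``d`` the
    deviation of the heterozygote from the midpoint.
    """

    chrom: str
    pos: int
    a: float = 0.0
    d: float = 0.0


@dataclass(frozen=True)
class SimConfig:
    """Design of the simulated pooled-sequencing experiment.

    Defaults mirror the motivating study: 860 F2 plants scored for branch
    number, 30 + 30 extreme-tail pools, pools at ~20x and parents at ~30x,
    and a strong branching QTL near 12.3 Mb of a chromosome-2-like scaffold.
    The genome defaults to a desk-scale 2 x 50 Mb layout with a marker every
    50 kb (2,000 variants); everything is configurable up to genome scale.
    """

    n_f2: int = 860
    pool_size: int = 30
    n_chrom: int = 2
    chrom_length_bp: int = 50_000_000
    marker_spacing_bp: int = 50_000
    cm_per_mb: float = 2.5
    qtl_position: tuple[str, int] = ("Gm02", 12_300_000)
    additive_effect: float = 1.5
    dominance_effect: float = 0.0
    extra_qtls: tuple[QtlEffect, ...] = ()
    baseline_mu: float = 3.4
    residual_sd: float = 1.5
    pool_depth: float = 20.0
    parent_depth: float = 30.0
    depth_model: str = "poisson"  # or "fixed"
    parent_contamination: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_f2 < 2:
            raise ValueError("n_f2 must be at least 2")
        if not 1 <= self.pool_size <= self.n_f2 // 2:
            raise ValueError("pool_size must satisfy 1 <= pool_size <= n_f2/2")
        if self.n_chrom < 1 or self.chrom_length_bp < 1:
            raise ValueError("genome dimensions must be positive")
        if self.marker_spacing_bp < 1:
            raise ValueError("marker_spacing_bp must be >= 1")
        if self.cm_per_mb <= 0:
            raise ValueError("cm_per_mb must be positive")
        if self.depth_model not in ("poisson", "fixed"):
            raise ValueError("depth_model must be 'poisson' or 'fixed'")
        if self.pool_depth <= 0 or self.parent_depth <= 0:
            raise ValueError("sequencing depths must be positive")
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be non-negative")
        for q in self.qtls():
            if not np.isfinite([q.a, q.d]).all():
                raise ValueError("QTL effects must be finite")
            if q.chrom not in self.chrom_names():
                raise ValueError(f"QTL chromosome {q.chrom!r} not in genome")
            if not 1 <= q.pos <= self.chrom_length_bp:
                raise ValueError(f"QTL position {q.pos} outside chromosome")

    def chrom_names(self) -> list[str]:
        return [f"Gm{i + 1:02d}" for i in range(self.n_chrom)]

    def chrom_lengths(self) -> dict[str, int]:
        return {c: self.chrom_length_bp for c in self.chrom_names()}

    def qtls(self) -> list[QtlEffect]:
        """All planted QTLs (primary + extras); an additive-only genetic model."""
        primary = QtlEffect(
            self.qtl_position[0],
            int(self.qtl_position[1]),
            self.additive_effect,
            self.dominance_effect,
        )
        return [primary, *self.extra_qtls]

    def marker_map(self) -> pd.DataFrame:
        """Marker coordinates: one row per variant, sorted by (chrom, pos)."""
        pos = np.arange(
            self.marker_spacing_bp, self.chrom_length_bp + 1, self.marker_spacing_bp
        )
        frames = [
            pd.DataFrame({"chrom": name, "pos": pos}) for name in self.chrom_names()
        ]
        return pd.concat(frames, ignore_index=True)


@dataclass
class SimTruth:
    """Ground truth of one simulated experiment, for recovery testing."""

    qtl_position: tuple[str, int]
    qtl_marker_index: int
    phenotypes: np.ndarray
    marker_chrom: np.ndarray
    marker_pos: np.ndarray
    high_pool_ids: np.ndarray | None = None
    low_pool_ids: np.ndarray | None = None
    true_high_alt_freq: np.ndarray | None = None
    true_low_alt_freq: np.ndarray | None = None

    def to_json(self) -> str:
        def conv(x):
            if isinstance(x, np.ndarray):
                return x.tolist()
            return x

        payload = {k: conv(v) for k, v in dataclasses.asdict(self).items()}
        payload["qtl_position"] = list(self.qtl_position)
        return json.dumps(payload, indent=1)


def simulate_gametes(
    rng: np.random.Generator, n: int, r_adjacent: np.ndarray
) -> np.ndarray:
    """Simulate ``n`` gametes over one chromosome as a Markov chain of alleles.

    ``r_adjacent`` holds the recombinant fraction between each pair of
    adjacent markers (length m-1).  Returns an (n, m) 0/1 array; allele 1 is
    the high-parent allele.  The first marker is a fair coin; each interval
    switches parental phase with its Haldane probability.
    """
    m = len(r_adjacent) + 1
    first = rng.random((n, 1)) < 0.5
    switches = rng.random((n, m - 1)) < r_adjacent[None, :]
    crossovers = np.cumsum(switches, axis=1) % 2
    out = np.empty((n, m), dtype=np.int8)
    out[:, 0] = first[:, 0]
    out[:, 1:] = first ^ crossovers
    return out


def simulate_f2(config: SimConfig, rng: np.random.Generator | None = None):
    """Simulate F2 genotypes and phenotypes.

    Returns ``(genotypes, truth)`` where ``genotypes`` is an
    ``(n_f2, n_markers)`` int8 array of high-parent allele counts {0,1,2}
    and ``truth`` a partially filled :class:`SimTruth` (pool fields are set
    by :func:`select_pools` / :func:`pool_reads`).

    Phenotype model: ``mu + sum_q [a_q (g_q - 1) + d_q 1{g_q = 1}] + N(0, sd)``
    truncated below at zero and rounded to the nearest integer (branch counts
    are non-negative integers).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    markers = config.marker_map()
    d_cm = config.cm_per_mb * config.marker_spacing_bp / 1e6
    r = np.full(max(len(markers) // config.n_chrom - 1, 0), haldane_r(d_cm))

    blocks = []
    for _ in config.chrom_names():
        g1 = simulate_gametes(rng, config.n_f2, r)
        g2 = simulate_gametes(rng, config.n_f2, r)
        blocks.append(g1 + g2)
    genotypes = np.concatenate(blocks, axis=1).astype(np.int8)

    raw = np.full(config.n_f2, config.baseline_mu, dtype=float)
    qtl_idx = None
    for q in config.qtls():
        idx = _nearest_marker(markers, q.chrom, q.pos)
        if qtl_idx is None:
            qtl_idx = idx
        g = genotypes[:, idx]
        raw += q.a * (g - 1) + q.d * (g == 1)
    if config.residual_sd > 0:
        raw += rng.normal(0.0, config.residual_sd, size=config.n_f2)
    phenotypes = np.rint(np.clip(raw, 0.0, None)).astype(int)

    truth = SimTruth(
        qtl_position=(config.qtl_position[0], int(config.qtl_position[1])),
        qtl_marker_index=int(qtl_idx),
        phenotypes=phenotypes,
        marker_chrom=markers["chrom"].to_numpy(),
        marker_pos=markers["pos"].to_numpy(),
    )
    return genotypes, truth


def _nearest_marker(markers: pd.DataFrame, chrom: str, pos: int) -> int:
    on_chrom = np.flatnonzero(markers["chrom"].to_numpy() == chrom)
    if on_chrom.size == 0:
        raise ValueError(f"no markers on chromosome {chrom!r}")
    p = markers["pos"].to_numpy()[on_chrom]
    return int(on_chrom[np.argmin(np.abs(p - pos))])


def select_pools(
    phenotypes: Sequence[float] | np.ndarray, pool_size: int
) -> tuple[np.ndarray, np.ndarray]:
    """Pick the extreme-phenotype tails as the two sequencing pools.

    The high pool holds the ``pool_size`` largest phenotypes, the low pool the
    smallest.  Selection uses one stable ascending sort on phenotype, so ties
    resolve by individual index: the low pool prefers the *smallest* indices
    among tied values and the high pool the *largest*.  The two pools are
    always disjoint when ``pool_size <= n/2``.
    """
    ph = np.asarray(phenotypes)
    n = len(ph)
    if pool_size < 1:
        raise ValueError("pool_size must be >= 1")
    if pool_size > n // 2:
        raise ValueError("pool_size > n/2: pools would overlap")
    order = np.argsort(ph, kind="stable")
    low = order[:pool_size].copy()
    high = order[n - pool_size:].copy()
    return high, low


def _draw_depths(rng, model: str, mean_depth: float, size: int) -> np.ndarray:
    if model == "fixed":
        return np.full(size, int(round(mean_depth)), dtype=np.int64)
    return rng.poisson(mean_depth, size=size)


def pool_reads(
    genotypes: np.ndarray,
    truth: SimTruth,
    high_ids: np.ndarray,
    low_ids: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Sample pooled sequencing reads; returns an allele-count table.

    Per variant the true pool alt fraction is ``sum(g)/(2 pool_size)`` over
    the pool's members; read depth is drawn from the configured depth model
    and the alt depth is Binomial(depth, fraction).  Parents are emitted as
    opposite homozygotes (high parent = alt) with their own depths; the
    ``parent_contamination`` fraction, if nonzero, leaks wrong-allele reads
    into the parents.
    """
    if len(high_ids) == 0 or len(low_ids) == 0:
        raise ValueError("pools must be non-empty")
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    k = len(high_ids)
    n_var = genotypes.shape[1]
    p_h = genotypes[high_ids].sum(axis=0) / (2.0 * k)
    p_l = genotypes[low_ids].sum(axis=0) / (2.0 * len(low_ids))
    truth.high_pool_ids = np.asarray(high_ids)
    truth.low_pool_ids = np.asarray(low_ids)
    truth.true_high_alt_freq = p_h
    truth.true_low_alt_freq = p_l

    d_h = _draw_depths(rng, config.depth_model, config.pool_depth, n_var)
    d_l = _draw_depths(rng, config.depth_model, config.pool_depth, n_var)
    alt_h = rng.binomial(d_h, p_h)
    alt_l = rng.binomial(d_l, p_l)

    d_ph = _draw_depths(rng, config.depth_model, config.parent_depth, n_var)
    d_pl = _draw_depths(rng, config.depth_model, config.parent_depth, n_var)
    c = config.parent_contamination
    ph_alt = rng.binomial(d_ph, 1.0 - c)
    pl_alt = rng.binomial(d_pl, c)

    # Alternating ref/alt bases; allele identity is irrelevant to the statistics.
    bases = np.array(["A", "C", "G", "T"])
    idx = np.arange(n_var)
    table = pd.DataFrame(
        {
            "chrom": truth.marker_chrom,
            "pos": truth.marker_pos,
            "ref": bases[idx % 4],
            "alt": bases[(idx + 2) % 4],
            "ref_h": d_h - alt_h,
            "alt_h": alt_h,
            "ref_l": d_l - alt_l,
            "alt_l": alt_l,
            "parent_h_gt": 2,
            "parent_l_gt": 0,
            "ph_ref": d_ph - ph_alt,
            "ph_alt": ph_alt,
            "pl_ref": d_pl - pl_alt,
            "pl_alt": pl_alt,
            "qual": 60.0,
            "variant_type": "SNP",
        }
    )
    return table[TABLE_COLUMNS]


def run_simulation(config: SimConfig) -> tuple[pd.DataFrame, SimTruth]:
    """Simulate genotypes, select pools and sample reads in one call."""
    rng = np.random.default_rng(config.seed)
    genotypes, truth = simulate_f2(config, rng)
    high, low = select_pools(truth.phenotypes, config.pool_size)
    table = pool_reads(genotypes, truth, high, low, config, rng)
    return table, truth


def write_sim_outputs(
    table: pd.DataFrame,
    truth: SimTruth,
    out_dir: str | Path,
    chrom_lengths: dict[str, int] | None = None,
) -> dict[str, Path]:
    """Write ``pools.vcf`` (VCF 4.2 with per-sample AD), ``phenotypes.csv``
    and ``truth.json`` into ``out_dir``; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "pools.vcf",
        "phenotypes": out / "phenotypes.csv",
        "truth": out / "truth.json",
    }
    if chrom_lengths is None:
        chrom_lengths = {
            str(c): int(g["pos"].max())
            for c, g in table.groupby("chrom", sort=False)
        }
        for c in np.unique(truth.marker_chrom):
            chrom_lengths.setdefault(str(c), int(truth.marker_pos.max()))

    header = pysam.VariantHeader()
    for chrom, length in chrom_lengths.items():
        header.contigs.add(chrom, length=length)
    header.add_meta(
        "FORMAT",
        items=[("ID", "GT"), ("Number", 1), ("Type", "String"),
               ("Description", "Genotype")],
    )
    header.add_meta(
        "FORMAT",
        items=[("ID", "AD"), ("Number", "R"), ("Type", "Integer"),
               ("Description", "Allelic depths (ref,alt)")],
    )
    samples = ["parent_high", "parent_low", "high_pool", "low_pool"]
    for s in samples:
        header.add_sample(s)

    gt_codes = {0: (0, 0), 1: (0, 1), 2: (1, 1)}
    with pysam.VariantFile(str(paths["vcf"]), "w", header=header) as vf:
        for row in table.itertuples(index=False):
            rec = vf.new_record(
                contig=row.chrom,
                start=int(row.pos) - 1,
                stop=int(row.pos) - 1 + len(row.ref),
                alleles=(row.ref, row.alt),
                qual=float(row.qual),
            )
            rec.samples["parent_high"]["GT"] = gt_codes.get(row.parent_h_gt, (None, None))
            rec.samples["parent_low"]["GT"] = gt_codes.get(row.parent_l_gt, (None, None))
            rec.samples["parent_high"]["AD"] = (int(row.ph_ref), int(row.ph_alt))
            rec.samples["parent_low"]["AD"] = (int(row.pl_ref), int(row.pl_alt))
            for pool in ("high_pool", "low_pool"):
                rec.samples[pool]["GT"] = (None, None)
            rec.samples["high_pool"]["AD"] = (int(row.ref_h), int(row.alt_h))
            rec.samples["low_pool"]["AD"] = (int(row.ref_l), int(row.alt_l))
            vf.write(rec)

    pd.DataFrame(
        {"individual": np.arange(len(truth.phenotypes)),
         "branch_number": truth.phenotypes}
    ).to_csv(paths["phenotypes"], index=False)
    paths["truth"].write_text(truth.to_json())
    return paths
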