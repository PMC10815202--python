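"""GWAS hit clustering, LD-window construction and BSA co-localization.

This module consumes an association-results table (one row per significant
SNP x model x year), clusters nearby hits into loci, puts an LD-decay-sized
window around each locus, intersects those windows with BSA consensus
regions, and counts candidate genes in the co-located intervals.  It also
provides the descriptive phenotype summary used for trait tables
(mean, SD, CV%, min, max, skewness, excess kurtosis).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .intervals import ConsensusRegion, chrom_sort_key

__all__ = [
    "GwasHit",
    "GwasLocus",
    "GeneRecord",
    "PhenotypeSummary",
    "load_hits",
    "unique_snps",
    "cluster_hits",
    "locus_window",
    "colocalize",
    "read_gene_models",
    "genes_in_interval",
    "summarize_phenotype",
    "cv_percent",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GwasHit:
    """One significant association: SNP, position, p-value and provenance."""

    snp_id: str
    chrom: str
    pos: int
    p_value: float
    r2_pve: float | None = None
    model: str | None = None
    year: str | None = None
    alleles: str | None = None

    def __post_init__(self) -> None:
        if not 0 < self.p_value <= 1:
            raise ValueError("p_value must be in (0, 1]")
        if self.pos < 1:
            raise ValueError("pos must be >= 1")


@dataclass
class GwasLocus:
    """A cluster of nearby significant SNPs with its peak and LD window."""

    name: str
    chrom: str
    members: tuple[GwasHit, ...]
    peak: GwasHit
    window: tuple[int, int] | None = None


@dataclass(frozen=True)
class GeneRecord:
    """A gene model: 1-based inclusive coordinates plus optional annotation."""

    gene_id: str
    chrom: str
    start: int
    end: int
    symbol: str | None = None
    annotation: str | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("gene start > end")


def load_hits(path: str | Path, alpha: float = 1e-5) -> list[GwasHit]:
    """Load an association table (TSV/CSV) and keep rows with p <= alpha.

    Requires columns ``snp_id, chrom, pos, p_value``; ``r2, model, year,
    alleles`` are optional.  Duplicate (snp_id, model, year) rows are
    rejected.  When a SNP id carries an ``S<chrom>_`` prefix that disagrees
    with the chromosome column, the column wins and a warning is logged.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype={"chrom": str})
    required = ["snp_id", "chrom", "pos", "p_value"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"association table missing columns: {missing}")
    if len(df) == 0:
        return []
    key_cols = [c for c in ("snp_id", "model", "year") if c in df.columns]
    if df.duplicated(subset=key_cols).any():
        dup = df[df.duplicated(subset=key_cols)].iloc[0]
        raise ValueError(f"duplicate association row: {tuple(dup[key_cols])}")
    df = df[df["p_value"] <= alpha]
    hits = []
    for row in df.itertuples(index=False):
        m = re.match(r"S(\d+)_", str(row.snp_id))
        if m and int(m.group(1)) != _chrom_number(str(row.chrom)):
            logger.warning(
                "SNP id %s prefix disagrees with chromosome column %s; "
                "trusting the column", row.snp_id, row.chrom,
            )
        hits.append(
            GwasHit(
                snp_id=str(row.snp_id),
                chrom=str(row.chrom),
                pos=int(row.pos),
                p_value=float(row.p_value),
                r2_pve=float(row.r2) if "r2" in df.columns and pd.notna(row.r2) else None,
                model=str(row.model) if "model" in df.columns else None,
                year=str(row.year) if "year" in df.columns else None,
                alleles=str(row.alleles)
                if "alleles" in df.columns and pd.notna(row.alleles)
                else None,
            )
        )
    return hits


def _chrom_number(chrom: str) -> int | None:
    m = re.search(r"(\d+)", chrom)
    return int(m.group(1)) if m else None


def unique_snps(hits: list[GwasHit]) -> list[GwasHit]:
    """One hit per SNP id, keeping the smallest p-value (tie: first seen)."""
    best: dict[str, GwasHit] = {}
    for h in hits:
        cur = best.get(h.snp_id)
        if cur is None or h.p_value < cur.p_value:
            best[h.snp_id] = h
    return list(best.values())


def cluster_hits(
    hits: list[GwasHit], max_gap_bp: int = 100_000, prefix: str = "qGBN"
) -> list[GwasLocus]:
    """Single-linkage clustering of SNPs within each chromosome.

    Two hits join the same locus when their positions differ by at most
    ``max_gap_bp`` (default 100 kb, a typical genome-wide LD-decay
    distance), transitively.  The locus peak is the member with the
    smallest p-value (tie: smaller position).  Loci are named
    ``<prefix>1..N`` ordered by (chromosome, start).
    """
    ids = [h.snp_id for h in hits]
    if len(set(ids)) != len(ids):
        raise ValueError("cluster_hits requires hits deduplicated by snp_id")
    loci: list[GwasLocus] = []
    by_chrom: dict[str, list[GwasHit]] = {}
    for h in hits:
        by_chrom.setdefault(h.chrom, []).append(h)
    for chrom in sorted(by_chrom, key=chrom_sort_key):
        members = sorted(by_chrom[chrom], key=lambda h: h.pos)
        cluster: list[GwasHit] = []
        for h in members:
            if cluster and h.pos - cluster[-1].pos > max_gap_bp:
                loci.append(_finish_locus(chrom, cluster))
                cluster = []
            cluster.append(h)
        if cluster:
            loci.append(_finish_locus(chrom, cluster))
    for i, locus in enumerate(loci, start=1):
        locus.name = f"{prefix}{i}"
    return loci


def _finish_locus(chrom: str, members: list[GwasHit]) -> GwasLocus:
    peak = min(members, key=lambda h: (h.p_value, h.pos))
    return GwasLocus(name="", chrom=chrom, members=tuple(members), peak=peak)


def locus_window(
    locus: GwasLocus,
    total_width_bp: int = 260_000,
    chrom_length: int | None = None,
) -> tuple[int, int]:
    """LD-based window of fixed total width centred on the locus midpoint.

    The midpoint is ``(min member pos + max member pos) / 2``; the window is
    ``total_width_bp`` wide, 1-based inclusive, clipped at position 1 and at
    ``chrom_length`` when given.  The width must cover the member span.
    """
    pos = [h.pos for h in locus.members]
    span = max(pos) - min(pos)
    if total_width_bp < span:
        raise ValueError("window narrower than the locus member span")
    start = (min(pos) + max(pos) - total_width_bp) // 2 + 1
    end = start + total_width_bp - 1
    start = max(1, start)
    if chrom_length is not None:
        end = min(end, chrom_length)
    locus.window = (int(start), int(end))
    return locus.window


def colocalize(
    loci: list[GwasLocus], regions: list[ConsensusRegion]
) -> list[dict]:
    """Intersect GWAS locus windows with BSA consensus regions.

    Every (locus, region) pair on the same chromosome with a non-empty
    overlap yields one record holding both parents and the intersection
    interval.  Loci must have their windows set (:func:`locus_window`).
    """
    out = []
    for locus in loci:
        if locus.window is None:
            raise ValueError(f"locus {locus.name} has no window; call locus_window")
        ws, we = locus.window
        for region in regions:
            if locus.chrom != region.chrom:
                continue
            s, e = max(ws, region.start), min(we, region.end)
            if s <= e:
                out.append(
                    {
                        "locus": locus,
                        "region": region,
                        "chrom": locus.chrom,
                        "start": int(s),
                        "end": int(e),
                    }
                )
    return out


def read_gene_models(path: str | Path) -> list[GeneRecord]:
    """Gene models from GFF3 (feature type ``gene``), 4+-column BED, or a
    TSV with explicit ``gene_id, chrom, start, end`` columns.

    BED input (0-based half-open) is converted to 1-based inclusive.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".gff", ".gff3"):
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None,
            names=["chrom", "source", "feature", "start", "end",
                   "score", "strand", "frame", "attributes"],
        )
        df = df[df["feature"] == "gene"]
        genes = []
        for row in df.itertuples(index=False):
            m = re.search(r"ID=([^;]+)", str(row.attributes))
            name = re.search(r"Name=([^;]+)", str(row.attributes))
            genes.append(
                GeneRecord(
                    gene_id=m.group(1) if m else f"{row.chrom}:{row.start}",
                    chrom=str(row.chrom),
                    start=int(row.start),
                    end=int(row.end),
                    symbol=name.group(1) if name else None,
                )
            )
        return sorted(genes, key=lambda g: (chrom_sort_key(g.chrom), g.start))
    if suffix == ".bed":
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
        genes = [
            GeneRecord(
                gene_id=str(row[3]) if len(row) > 3 else f"{row[0]}:{row[1]}",
                chrom=str(row[0]),
                start=int(row[1]) + 1,
                end=int(row[2]),
            )
            for row in df.itertuples(index=False)
        ]
        return sorted(genes, key=lambda g: (chrom_sort_key(g.chrom), g.start))
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = ["gene_id", "chrom", "start", "end"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"gene table missing columns: {missing}")
    return sorted(
        (
            GeneRecord(
                gene_id=str(r.gene_id), chrom=str(r.chrom),
                start=int(r.start), end=int(r.end),
                symbol=str(r.symbol) if "symbol" in df.columns and pd.notna(r.symbol) else None,
                annotation=str(r.annotation)
                if "annotation" in df.columns and pd.notna(r.annotation)
                else None,
            )
            for r in df.itertuples(index=False)
        ),
        key=lambda g: (chrom_sort_key(g.chrom), g.start),
    )


def genes_in_interval(
    genes: list[GeneRecord], chrom: str, start: int, end: int
) -> tuple[int, list[GeneRecord]]:
    """Genes overlapping ``[start, end]`` on ``chrom`` by >= 1 bp, sorted by
    start; returns ``(count, gene list)``."""
    hits = sorted(
        (g for g in genes
         if g.chrom == chrom and g.start <= end and start <= g.end),
        key=lambda g: g.start,
    )
    return len(hits), hits


@dataclass(frozen=True)
class PhenotypeSummary:
    """Descriptive statistics of a phenotype vector (trait-table style)."""

    n: int
    mean: float
    sd: float
    cv_percent: float
    min: float
    max: float
    skew: float
    kurt: float


def cv_percent(mean: float, sd: float) -> float:
    """Coefficient of variation in percent, ``100 * sd / mean``."""
    if mean <= 0:
        raise ValueError("CV is defined only for a positive mean")
    return 100.0 * sd / mean


def summarize_phenotype(values, bias_corrected: bool = True) -> PhenotypeSummary:
    """Mean, sample SD, CV%, range, skewness and excess kurtosis.

    Skewness and kurtosis default to the small-sample bias-corrected
    (spreadsheet-convention) estimators conventional in agronomic trait
    tables; ``bias_corrected=False`` gives the plain moment estimators.
    A constant vector has SD 0 and CV 0, with skew/kurt flagged as NaN.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("need a 1-D vector with n >= 2")
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    if sd == 0:
        skew = kurt = float("nan")
        cv = 0.0
    else:
        skew = float(sps.skew(x, bias=not bias_corrected))
        kurt = float(sps.kurtosis(x, bias=not bias_corrected))
        cv = cv_percent(mean, sd) if mean > 0 else float("nan")
    return PhenotypeSummary(
        n=len(x), mean=mean, sd=sd, cv_percent=cv,
        min=float(np.min(x)), max=float(np.max(x)), skew=skew, kurt=kurt,
    )
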