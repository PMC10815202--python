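"""Reading pooled-sequencing VCFs into allele-count tables, plus filtering.

The central container is a plain :class:`pandas.DataFrame` with one row per
biallelic variant and the columns in :data:`TABLE_COLUMNS` — read depths for
the high- and low-phenotype pools, the two parents' allele depths and
genotypes (encoded as high-parent-allele dosage 0/1/2, -1 for missing), the
VCF QUAL and a SNP/InDel flag.  Coordinates are 1-based inclusive throughout.

Counts are *polarized*: wherever the high-phenotype parent is homozygous for
the reference allele, ref and alt are swapped so that "alt fraction" always
means "fraction of the high-parent allele".  A positive Δ(SNP-index) then
reads as enrichment of the high-parent allele in the high pool.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

__all__ = [
    "TABLE_COLUMNS",
    "FilterPolicy",
    "read_pools_vcf",
    "apply_filters",
    "validate_table",
]

TABLE_COLUMNS = [
    "chrom", "pos", "ref", "alt",
    "ref_h", "alt_h", "ref_l", "alt_l",
    "parent_h_gt", "parent_l_gt",
    "ph_ref", "ph_alt", "pl_ref", "pl_alt",
    "qual", "variant_type",
]

#: roles a sample_map must cover
ROLES = ("parent_high", "parent_low", "high_pool", "low_pool")


def validate_table(table: pd.DataFrame) -> None:
    """Raise ``ValueError`` if the allele-count table violates its contract."""
    missing = [c for c in TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"allele-count table missing columns: {missing}")
    if len(table) == 0:
        return
    if (table["pos"] < 1).any():
        raise ValueError("positions must be 1-based (>= 1)")
    counts = table[["ref_h", "alt_h", "ref_l", "alt_l"]]
    if (counts.to_numpy() < 0).any():
        raise ValueError("read counts must be non-negative")
    key = table[["chrom", "pos", "ref", "alt"]]
    if key.duplicated().any():
        raise ValueError("duplicate (chrom, pos, ref, alt) rows")
    by = table.sort_values(["chrom", "pos"], kind="stable").index
    if not (by.to_numpy() == table.index.to_numpy()).all():
        raise ValueError("rows must be sorted by (chrom, pos)")


@dataclass(frozen=True)
class FilterPolicy:
    """Variant-quality and informativeness filters for BSA-seq tables.

    Defaults follow common BSA-seq practice: biallelic sites only, parents
    required to be opposite homozygotes (otherwise the marker carries no
    linkage information for the cross), 4-200 reads per pool, QUAL >= 30,
    and InDels retained.
    """

    require_biallelic: bool = True
    require_parents_opposite_homozygous: bool = True
    min_depth_per_pool: int = 4
    max_depth_per_pool: int = 200
    min_quality: float = 30.0
    keep_indels: bool = True

    def __post_init__(self) -> None:
        if self.min_depth_per_pool > self.max_depth_per_pool:
            raise ValueError("min_depth_per_pool > max_depth_per_pool")


def _gt_dosage(gt: tuple | None) -> int:
    """High-parent allele dosage from a pysam GT tuple; -1 when missing."""
    if gt is None or any(a is None for a in gt):
        return -1
    return int(sum(gt))


def read_pools_vcf(
    path: str | Path,
    sample_map: dict[str, str],
    multiallelic: str = "drop",
) -> pd.DataFrame:
    """Read a two-pool + two-parent VCF into an allele-count table.

    Parameters
    ----------
    path
        VCF 4.x file, plain or bgzipped; every sample must carry AD.
    sample_map
        Maps the roles ``parent_high``, ``parent_low``, ``high_pool``,
        ``low_pool`` to sample names in the VCF.
    multiallelic
        ``"drop"`` discards records with more than one ALT allele;
        ``"split"`` emits one row per ALT, sharing the REF depth.

    Counts are polarized to the high-parent allele (see module docstring).
    """
    if multiallelic not in ("drop", "split"):
        raise ValueError("multiallelic must be 'drop' or 'split'")
    missing = [r for r in ROLES if r not in sample_map]
    if missing:
        raise ValueError(f"sample_map missing roles: {missing}")

    rows = []
    with pysam.VariantFile(str(path)) as vf:
        vcf_samples = list(vf.header.samples)
        for role in ROLES:
            if sample_map[role] not in vcf_samples:
                raise ValueError(
                    f"sample {sample_map[role]!r} (role {role}) not in VCF"
                )
        for rec in vf:
            alts = rec.alts or ()
            if len(alts) == 0:
                continue
            if len(alts) > 1 and multiallelic == "drop":
                continue
            ads = {}
            for role in ROLES:
                ad = rec.samples[sample_map[role]].get("AD")
                if ad is None or all(v is None for v in ad):
                    raise ValueError(
                        f"record {rec.chrom}:{rec.pos} lacks AD for "
                        f"sample {sample_map[role]!r}"
                    )
                ads[role] = [0 if v is None else int(v) for v in ad]
            gt_h = _gt_dosage(rec.samples[sample_map["parent_high"]].get("GT"))
            gt_l = _gt_dosage(rec.samples[sample_map["parent_low"]].get("GT"))
            for ai, alt in enumerate(alts, start=1):
                is_snp = len(rec.ref) == 1 and len(alt) == 1
                rows.append(
                    (
                        rec.chrom, rec.pos, rec.ref, alt,
                        ads["high_pool"][0], ads["high_pool"][ai],
                        ads["low_pool"][0], ads["low_pool"][ai],
                        gt_h if len(alts) == 1 else -1,
                        gt_l if len(alts) == 1 else -1,
                        ads["parent_high"][0], ads["parent_high"][ai],
                        ads["parent_low"][0], ads["parent_low"][ai],
                        float(rec.qual) if rec.qual is not None else np.nan,
                        "SNP" if is_snp else "InDel",
                    )
                )
    table = pd.DataFrame(rows, columns=TABLE_COLUMNS)
    if len(table) == 0:
        return table
    table = table.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    return _polarize(table)


def _polarize(table: pd.DataFrame) -> pd.DataFrame:
    """Swap ref/alt wherever the high parent is homozygous reference."""
    flip = table["parent_h_gt"] == 0
    if not flip.any():
        return table
    t = table.copy()
    swaps = [("ref", "alt"), ("ref_h", "alt_h"), ("ref_l", "alt_l"),
             ("ph_ref", "ph_alt"), ("pl_ref", "pl_alt")]
    for a, b in swaps:
        t.loc[flip, [a, b]] = t.loc[flip, [b, a]].to_numpy()
    for col in ("parent_h_gt", "parent_l_gt"):
        vals = t.loc[flip, col]
        t.loc[flip, col] = np.where(vals < 0, vals, 2 - vals)
    return t


#: order in which filter rules claim a removed row
FILTER_RULES = [
    "min_quality",
    "biallelic",
    "indel",
    "parents_not_opposite_homozygous",
    "depth_below_min",
    "depth_above_max",
]


def apply_filters(
    table: pd.DataFrame, policy: FilterPolicy | None = None
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply a :class:`FilterPolicy`; returns the surviving rows and per-rule
    removal counts.

    A row failing several rules is charged to the first failing rule in
    :data:`FILTER_RULES` order, so the counts sum to ``rows_in - rows_out``.
    Row order is preserved and filtering is idempotent.
    """
    if policy is None:
        policy = FilterPolicy()
    counts = {r: 0 for r in FILTER_RULES}
    if len(table) == 0:
        return table.copy(), counts

    fails = {}
    qual = table["qual"].to_numpy(dtype=float)
    fails["min_quality"] = ~(qual >= policy.min_quality)  # NaN QUAL fails
    if policy.require_biallelic:
        fails["biallelic"] = (
            table["alt"].astype(str).str.contains(",").to_numpy()
        )
    else:
        fails["biallelic"] = np.zeros(len(table), dtype=bool)
    if policy.keep_indels:
        fails["indel"] = np.zeros(len(table), dtype=bool)
    else:
        fails["indel"] = (table["variant_type"] == "InDel").to_numpy()
    if policy.require_parents_opposite_homozygous:
        gh = table["parent_h_gt"].to_numpy()
        gl = table["parent_l_gt"].to_numpy()
        fails["parents_not_opposite_homozygous"] = ~((gh == 2) & (gl == 0))
    else:
        fails["parents_not_opposite_homozygous"] = np.zeros(len(table), dtype=bool)
    depth_h = (table["ref_h"] + table["alt_h"]).to_numpy()
    depth_l = (table["ref_l"] + table["alt_l"]).to_numpy()
    fails["depth_below_min"] = (depth_h < policy.min_depth_per_pool) | (
        depth_l < policy.min_depth_per_pool
    )
    fails["depth_above_max"] = (depth_h > policy.max_depth_per_pool) | (
        depth_l > policy.max_depth_per_pool
    )

    removed = np.zeros(len(table), dtype=bool)
    for rule in FILTER_RULES:
        newly = fails[rule] & ~removed
        counts[rule] = int(newly.sum())
        removed |= fails[rule]
    return table.loc[~removed].copy(), counts
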