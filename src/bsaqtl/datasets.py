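"""Bundled case-study tables for the soybean branch-number locus.

Small published result tables from a soybean branch-number mapping study —
a 301-accession GWAS panel scored in 2022/2023 and an F2 cross between a
high-branching and a low-branching cultivar — used as worked examples: the
significant GWAS associations, the per-method BSA-seq QTL intervals, the
candidate genes of the chromosome-2 co-located region, and the phenotype
summary rows.  These are inputs for the interval arithmetic and clustering
routines; no sequencing data is included.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "load_gwas_hits_path",
    "load_bsa_intervals",
    "load_candidate_genes_path",
    "load_phenotype_summary",
]


def _data_path(name: str):
    return resources.files("bsaqtl.data") / name


def load_gwas_hits_path() -> str:
    """Path to the GWAS association TSV (columns snp_id, chrom, pos,
    p_value, r2, alleles, year, model) for :func:`bsaqtl.gwas.load_hits`."""
    return str(_data_path("gwas_hits_branch_number.tsv"))


def load_bsa_intervals() -> pd.DataFrame:
    """Per-method BSA-seq QTL intervals (qtl, chrom, start, end, peak,
    method) as published for the branch-number scan."""
    return pd.read_csv(_data_path("bsa_intervals_branch_number.tsv"), sep="\t")


def load_candidate_genes_path() -> str:
    """Path to the chromosome-2 candidate-gene TSV for
    :func:`bsaqtl.gwas.read_gene_models`."""
    return str(_data_path("candidate_genes_chr02.tsv"))


def load_phenotype_summary() -> pd.DataFrame:
    """Published descriptive statistics of branch number in the association
    panel (mean, sd, cv_percent, min, max, kurt, skew per year)."""
    return pd.read_csv(
        _data_path("phenotype_summary_branch_number.tsv"), sep="\t"
    )
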