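"""Cluster published GWAS hits, build LD windows, and co-localize with BSA.

Uses the bundled branch-number case-study tables: the 22 significant
association rows collapse to 18 unique SNPs and 16 loci (100 kb single-link
clustering); the chromosome-2 locus gets a 260 kb midpoint-centred LD
window, which is intersected with the published four-method BSA consensus
interval, and the candidate genes inside the overlap are counted.
"""

from bsaqtl import datasets
from bsaqtl.gwas import (
    cluster_hits, colocalize, genes_in_interval, load_hits, locus_window,
    read_gene_models, unique_snps,
)
from bsaqtl.intervals import QtlInterval, intersect_methods

hits = load_hits(datasets.load_gwas_hits_path(), alpha=1e-5)
snps = unique_snps(hits)
loci = cluster_hits(snps, max_gap_bp=100_000)
print(f"{len(hits)} association rows -> {len(snps)} unique SNPs -> "
      f"{len(loci)} loci")

(chr2,) = [l for l in loci if l.chrom == "2"]
start, end = locus_window(chr2, total_width_bp=260_000)
print(f"chromosome-2 locus {chr2.name}: peak {chr2.peak.snp_id} "
      f"(p={chr2.peak.p_value:.2e}), LD window {start:,}-{end:,}")

block = datasets.load_bsa_intervals().query("qtl == 'qBBN1'")
per_method = {
    r.method: [QtlInterval(chrom=r.chrom, start=int(r.start), end=int(r.end),
                           peak_value=float(r.peak), peak_pos=int(r.start),
                           method=r.method)]
    for r in block.itertuples(index=False)
}
(region,) = intersect_methods(per_method, min_support=4)
print(f"BSA consensus (all 4 methods): {region.chrom}:{region.start:,}-"
      f"{region.end:,}")

chr2.chrom = "Gm02"  # harmonize the numeric GWAS label with the BSA naming
pairs = colocalize([chr2], [region])
for p in pairs:
    print(f"co-located interval: {p['chrom']}:{p['start']:,}-{p['end']:,}")

genes = read_gene_models(datasets.load_candidate_genes_path())
n, lst = genes_in_interval(genes, "Gm02", 12_160_000, 12_420_000)
print(f"{n} candidate genes in the co-located 12.16-12.42 Mb region; "
      f"annotated: "
      + ", ".join(g.symbol for g in lst if g.symbol))
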