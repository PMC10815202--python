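"""GWAS hit loading, locus clustering, LD windows, co-localization, gene
overlap and phenotype summaries — worked against the bundled case-study
tables for the soybean branch-number locus."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from bsaqtl import datasets
from bsaqtl.gwas import (
    GwasHit,
    cluster_hits,
    colocalize,
    cv_percent,
    genes_in_interval,
    load_hits,
    locus_window,
    read_gene_models,
    summarize_phenotype,
    unique_snps,
)
from bsaqtl.intervals import ConsensusRegion


@pytest.fixture(scope="module")
def case_hits():
    return load_hits(datasets.load_gwas_hits_path(), alpha=1e-5)


class TestLoadHits:
    def test_empty_file(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text("snp_id\tchrom\tpos\tp_value\n")
        assert load_hits(p) == []

    def test_alpha_filter_drops_weak_hits(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text(
            "snp_id\tchrom\tpos\tp_value\n"
            "S01_1\t1\t100\t2e-5\nS01_2\t1\t200\t9e-6\n"
        )
        hits = load_hits(p, alpha=1e-5)
        assert [h.snp_id for h in hits] == ["S01_2"]

    def test_duplicate_rows_rejected(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text(
            "snp_id\tchrom\tpos\tp_value\tmodel\tyear\n"
            "S01_1\t1\t100\t1e-6\tMLM\t2022\n"
            "S01_1\t1\t100\t1e-7\tMLM\t2022\n"
        )
        with pytest.raises(ValueError, match="duplicate"):
            load_hits(p)

    def test_case_study_has_18_unique_significant_snps(self, case_hits):
        assert len(case_hits) == 22
        assert len(unique_snps(case_hits)) == 18


class TestClusterHits:
    def test_case_study_clusters_into_16_loci(self, case_hits):
        loci = cluster_hits(unique_snps(case_hits), max_gap_bp=100_000)
        assert len(loci) == 16

    def test_single_hit_single_locus(self):
        h = GwasHit("S01_1", "1", 500, 1e-6)
        loci = cluster_hits([h])
        assert len(loci) == 1 and loci[0].peak is h

    def test_matches_transitive_closure_oracle(self, rng):
        pos = np.sort(rng.integers(1, 3_000_000, size=100))
        hits = [GwasHit(f"S_{i}", "1", int(p), 1e-6) for i, p in enumerate(pos)]
        gap = 50_000
        loci = cluster_hits(hits, max_gap_bp=gap)
        # oracle: union-find over the pairwise <=gap relation
        parent = list(range(len(pos)))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(len(pos)):
            for j in range(i + 1, len(pos)):
                if abs(int(pos[j]) - int(pos[i])) <= gap:
                    parent[find(i)] = find(j)
        n_components = len({find(i) for i in range(len(pos))})
        assert len(loci) == n_components

    def test_gap_zero_and_gap_infinite_extremes(self):
        hits = [GwasHit(f"S_{i}", "1", p, 1e-6)
                for i, p in enumerate([100, 100_000, 200_000])]
        assert len(cluster_hits(hits, max_gap_bp=0)) == 3
        assert len(cluster_hits(hits, max_gap_bp=10**9)) == 1

    def test_duplicated_snp_ids_rejected(self):
        hits = [GwasHit("S_1", "1", 100, 1e-6), GwasHit("S_1", "1", 200, 1e-6)]
        with pytest.raises(ValueError):
            cluster_hits(hits)


class TestLocusWindow:
    def test_chromosome2_window_reproduces_published_region(self, case_hits):
        loci = cluster_hits(unique_snps(case_hits), max_gap_bp=100_000)
        chr2 = [l for l in loci if l.chrom == "2"]
        assert len(chr2) == 1
        start, end = locus_window(chr2[0], total_width_bp=260_000)
        assert (start, end) == (12_164_411, 12_424_410)
        # 10 kb rounding lands on the published 12.16-12.42 Mb bounds
        assert round(start, -4) / 1e6 == 12.16
        assert round(end, -4) / 1e6 == 12.42

    def test_singleton_centered(self):
        locus = cluster_hits([GwasHit("S", "1", 1_000_000, 1e-6)])[0]
        start, end = locus_window(locus, total_width_bp=200_000)
        assert (start, end) == (900_001, 1_100_000)

    def test_clipping_at_chromosome_start_and_end(self):
        locus = cluster_hits([GwasHit("S", "1", 1000, 1e-6)])[0]
        start, end = locus_window(locus, total_width_bp=200_000)
        assert start == 1
        locus2 = cluster_hits([GwasHit("S", "1", 999_000, 1e-6)])[0]
        _, end2 = locus_window(locus2, total_width_bp=200_000,
                               chrom_length=1_000_000)
        assert end2 == 1_000_000

    def test_window_narrower_than_span_rejected(self):
        hits = [GwasHit("Sa", "1", 100, 1e-6), GwasHit("Sb", "1", 900_000, 1e-6)]
        locus = cluster_hits(hits, max_gap_bp=10**9)[0]
        with pytest.raises(ValueError):
            locus_window(locus, total_width_bp=100_000)


class TestColocalize:
    def region(self, chrom, start, end):
        return ConsensusRegion(chrom, start, end, frozenset({"ed"}))

    def loci_with_window(self, chrom, window):
        locus = cluster_hits([GwasHit("S", chrom, sum(window) // 2, 1e-6)])[0]
        locus.window = window
        return [locus]

    def test_published_overlap(self):
        loci = self.loci_with_window("Gm02", (12_164_411, 12_424_410))
        regions = [self.region("Gm02", 12_280_001, 13_360_000)]
        out = colocalize(loci, regions)
        assert len(out) == 1
        assert (out[0]["start"], out[0]["end"]) == (12_280_001, 12_424_410)

    def test_disjoint_gives_nothing(self):
        loci = self.loci_with_window("Gm02", (1, 100))
        assert colocalize(loci, [self.region("Gm02", 200, 300)]) == []

    def test_nested_gives_inner(self):
        loci = self.loci_with_window("Gm02", (100, 1000))
        out = colocalize(loci, [self.region("Gm02", 400, 500)])
        assert (out[0]["start"], out[0]["end"]) == (400, 500)

    def test_symmetry(self):
        a = self.loci_with_window("Gm02", (100, 500))
        r = [self.region("Gm02", 300, 900)]
        out = colocalize(a, r)
        assert out[0]["start"] == max(100, 300)
        assert out[0]["end"] == min(500, 900)


class TestGenesInInterval:
    def test_published_interval_holds_15_genes(self):
        genes = read_gene_models(datasets.load_candidate_genes_path())
        n, lst = genes_in_interval(genes, "Gm02", 12_160_000, 12_420_000)
        assert n == 15
        assert lst[0].gene_id == "Glyma.02G125100"
        assert lst[-1].gene_id == "Glyma.02G126500"

    def test_empty_gene_set(self):
        assert genes_in_interval([], "Gm02", 1, 10**9) == (0, [])

    def test_against_bruteforce_overlap_oracle(self, rng):
        genes = read_gene_models(datasets.load_candidate_genes_path())
        for _ in range(50):
            s = int(rng.integers(12_200_000, 12_420_000))
            e = s + int(rng.integers(1, 150_000))
            n, lst = genes_in_interval(genes, "Gm02", s, e)
            expected = [g for g in genes
                        if max(g.start, s) <= min(g.end, e)]
            assert [g.gene_id for g in lst] == [g.gene_id for g in expected]

    def test_monotone_in_interval_width(self):
        genes = read_gene_models(datasets.load_candidate_genes_path())
        counts = [genes_in_interval(genes, "Gm02", 12_300_000 - w,
                                    12_300_000 + w)[0]
                  for w in (1_000, 20_000, 150_000)]
        assert counts == sorted(counts)

    def test_gff3_and_bed_inputs(self, tmp_path):
        gff = tmp_path / "genes.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "Gm02\tsrc\tgene\t100\t200\t.\t+\t.\tID=gene1;Name=ABC\n"
            "Gm02\tsrc\tmRNA\t100\t200\t.\t+\t.\tID=t1;Parent=gene1\n"
        )
        genes = read_gene_models(gff)
        assert len(genes) == 1
        assert genes[0].gene_id == "gene1" and genes[0].symbol == "ABC"
        bed = tmp_path / "genes.bed"
        bed.write_text("Gm02\t99\t200\tgene1\n")
        bgenes = read_gene_models(bed)
        assert (bgenes[0].start, bgenes[0].end) == (100, 200)


class TestSummarizePhenotype:
    def test_cv_from_published_2022_row(self):
        row = datasets.load_phenotype_summary().set_index("year").loc[2022]
        assert round(cv_percent(row["mean"], row["sd"]), 2) == row["cv_percent"]
        assert row["cv_percent"] == 40.25

    def test_constant_vector_flags_undefined_moments(self):
        s = summarize_phenotype([4.0, 4.0, 4.0])
        assert s.sd == 0 and s.cv_percent == 0
        assert np.isnan(s.skew) and np.isnan(s.kurt)

    def test_moments_match_definition_oracle(self):
        x = np.arange(11.0)  # uniform fixture {0..10}
        s = summarize_phenotype(x)
        n = len(x)
        m = x.mean()
        sd = np.sqrt(((x - m) ** 2).sum() / (n - 1))
        assert s.mean == pytest.approx(m)
        assert s.sd == pytest.approx(sd)
        assert s.cv_percent == pytest.approx(100 * sd / m)
        # spreadsheet-convention corrected skew / excess kurtosis
        z = (x - m) / sd
        skew = n / ((n - 1) * (n - 2)) * (z ** 3).sum()
        kurt = (
            n * (n + 1) / ((n - 1) * (n - 2) * (n - 3)) * (z ** 4).sum()
            - 3 * (n - 1) ** 2 / ((n - 2) * (n - 3))
        )
        assert s.skew == pytest.approx(skew)
        assert s.kurt == pytest.approx(kurt)
        assert s.skew == pytest.approx(sps.skew(x, bias=False))
        assert s.kurt == pytest.approx(sps.kurtosis(x, bias=False))

    def test_short_vector_rejected(self):
        with pytest.raises(ValueError):
            summarize_phenotype([1.0])
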