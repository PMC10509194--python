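"""Format I/O, variant filters, GFA bubble extraction, region annotation."""

import numpy as np
import pandas as pd
import pytest

from svorigin import variant_io as vio
from svorigin.synthetic import CohortConfig, cohort_to_matrices, simulate_cohort


class TestPopulationMap:
    def test_basic_read(self, tmp_path):
        p = tmp_path / "pop.tsv"
        p.write_text("s1\twild_yak\n")
        assert vio.read_population_map(p) == {"s1": "wild_yak"}

    def test_duplicate_sample_raises(self, tmp_path):
        p = tmp_path / "pop.tsv"
        p.write_text("s1\twild_yak\ns1\tcattle\n")
        with pytest.raises(vio.DataError, match="s1"):
            vio.read_population_map(p)

    def test_whitespace_normalized_then_matched(self, tmp_path):
        p = tmp_path / "pop.tsv"
        p.write_text("s1\tcattle \n")
        assert vio.read_population_map(p) == {"s1": "cattle"}

    def test_unknown_label_lists_vocabulary(self, tmp_path):
        p = tmp_path / "pop.tsv"
        p.write_text("s1\tzebu\n")
        with pytest.raises(vio.DataError, match="wild_yak"):
            vio.read_population_map(p)


class TestPhasedVCF:
    def test_phase_and_missing_parsing(self, tmp_path):
        p = tmp_path / "t.vcf"
        p.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n'
            "##contig=<ID=c>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ta\tb\tc\n"
            "c\t10\tv1\tA\tT,G\t.\tPASS\t.\tGT\t0|1\t./.\t1/2\n"
        )
        m = vio.read_phased_vcf(p)
        assert tuple(m.genotypes[0, 0]) == (0, 1) and m.phased[0, 0]
        assert tuple(m.genotypes[0, 1]) == (-1, -1)
        assert tuple(m.genotypes[0, 2]) == (1, 2) and not m.phased[0, 2]

    def test_require_phase_names_offender(self, tmp_path):
        p = tmp_path / "t.vcf"
        p.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n'
            "##contig=<ID=c>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ta\n"
            "c\t10\tv1\tA\tT\t.\tPASS\t.\tGT\t1/0\n"
        )
        with pytest.raises(vio.DataError, match="c:10"):
            vio.read_phased_vcf(p, require_phase=True)

    def test_short_sv_records_dropped_at_load(self, tmp_path):
        p = tmp_path / "t.vcf"
        p.write_text(
            "##fileformat=VCFv4.2\n"
            '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="t">\n'
            '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="l">\n'
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n'
            "##contig=<ID=c>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ta\n"
            "c\t10\tsmall\tN\t<DEL>\t.\tPASS\tSVTYPE=DEL;SVLEN=49\tGT\t0/1\n"
            "c\t20\tbig\tN\t<DEL>\t.\tPASS\tSVTYPE=DEL;SVLEN=50\tGT\t0/1\n"
        )
        m = vio.read_phased_vcf(p)
        assert list(m.variants["id"]) == ["big"]

    def test_round_trip_preserves_genotypes_phase_positions(self, tmp_path):
        cfg = CohortConfig(
            n_wild_yak=2, n_domestic_yak=2, n_cattle=2, n_outgroup=1,
            n_snps_per_window=30, n_sv_loci=2, seed=21,
        )
        snp, sv = cohort_to_matrices(simulate_cohort(cfg))
        for name, matrix in (("snp", snp), ("sv", sv)):
            path = tmp_path / f"{name}.vcf"
            vio.write_vcf(matrix, path)
            back = vio.read_phased_vcf(path)
            assert back.samples == matrix.samples
            assert (back.genotypes == matrix.genotypes).all()
            nonmissing = (matrix.genotypes >= 0).all(axis=2)
            assert (back.phased[nonmissing] == matrix.phased[nonmissing]).all()
            assert list(back.variants["pos"]) == list(matrix.variants["pos"])


class TestFilterVariants:
    def test_planted_outcomes_and_tallies(self, planted_filter_vcf):
        m = vio.read_phased_vcf(planted_filter_vcf)
        out, report = vio.filter_variants(m)
        assert list(out.variants["id"]) == ["v1", "v2", "v5"]
        assert report["n_dropped_call_rate"] == 1
        assert report["n_dropped_maf"] == 2
        assert report["n_retained"] == 3

    def test_idempotence(self, planted_filter_vcf):
        m = vio.read_phased_vcf(planted_filter_vcf)
        once, _ = vio.filter_variants(m)
        twice, report = vio.filter_variants(once)
        assert report["n_dropped_call_rate"] == 0
        assert report["n_dropped_maf"] == 0
        assert (twice.genotypes == once.genotypes).all()

    def test_depth_soft_filter_masks_genotypes(self, planted_filter_vcf):
        m = vio.read_phased_vcf(planted_filter_vcf)
        depths = np.full((m.n_variants, 10), 20.0)
        depths[0, 0] = 5.0    # < 20/3
        depths[0, 1] = 100.0  # > 3 * 20
        _, report = vio.filter_variants(
            m, genotype_depths=depths, mean_depths=np.full(10, 20.0)
        )
        assert report["n_genotypes_depth_masked"] == 2

    def test_empty_matrix_raises(self):
        m = vio.GenotypeMatrix(
            samples=["a"],
            variants=pd.DataFrame(
                columns=["chrom", "pos", "id", "ref", "alts", "svtype", "svlen"]
            ),
            genotypes=np.zeros((0, 1, 2), dtype=np.int8),
            phased=np.zeros((0, 1), dtype=bool),
        )
        with pytest.raises(vio.DataError):
            vio.filter_variants(m)


def _gfa(lines):
    return "\n".join(lines) + "\n"


class TestExtractBubbles:
    def test_linear_identical_paths_no_bubbles(self, tmp_path):
        p = tmp_path / "g.gfa"
        p.write_text(_gfa([
            "S\tu\tAAAAA", "S\tv\tCCCC",
            "P\tref\tu+,v+\t*", "P\talt\tu+,v+\t*",
        ]))
        assert vio.extract_bubbles(p, "ref") == []

    def test_diamond_insertion_bubble(self, tmp_path):
        p = tmp_path / "g.gfa"
        p.write_text(_gfa([
            "S\tu\t" + "A" * 5,
            "S\ta\t" + "C" * 10,
            "S\tb\t" + "G" * 100,
            "S\tv\t" + "T" * 4,
            "P\tref\tu+,a+,v+\t*",
            "P\talt\tu+,b+,v+\t*",
        ]))
        bubbles = vio.extract_bubbles(p, "ref")
        assert len(bubbles) == 1
        b = bubbles[0]
        assert (b.source, b.sink) == ("u", "v")
        assert b.pos == 5  # last base of u, 1-based
        assert b.allele_class == "biallelic"
        assert b.svlen == 90 and b.is_sv

    def test_three_paths_multiallelic(self, tmp_path):
        p = tmp_path / "g.gfa"
        p.write_text(_gfa([
            "S\tp\t" + "A" * 7,
            "S\tu\t" + "A" * 5,
            "S\ta\t" + "C" * 10,
            "S\tb\t" + "G" * 100,
            "S\tc\t" + "T" * 200,
            "S\tv\t" + "T" * 4,
            "P\tref\tp+,u+,a+,v+\t*",
            "P\talt1\tp+,u+,b+,v+\t*",
            "P\talt2\tp+,u+,c+,v+\t*",
        ]))
        bubbles = vio.extract_bubbles(p, "ref")
        assert len(bubbles) == 1
        assert bubbles[0].allele_class == "multiallelic"
        assert bubbles[0].pos == 12  # after p (7 bp) + u (5 bp)

    def test_deletion_and_sub_50bp_suppression(self, tmp_path):
        p = tmp_path / "g.gfa"
        p.write_text(_gfa([
            "S\tu\t" + "A" * 5,
            "S\ta\t" + "C" * 60,
            "S\tv\t" + "T" * 4,
            "S\tw\t" + "G" * 3,
            "S\tx\t" + "A" * 7,
            "P\tref\tu+,a+,v+,w+,x+\t*",
            "P\talt\tu+,v+,w+,x+\t*",   # 60 bp deletion
        ]))
        bubbles = vio.extract_bubbles(p, "ref")
        assert len(bubbles) == 1 and bubbles[0].svlen == 60 and bubbles[0].is_sv
        # shrink the deleted segment below 50 bp: bubble remains, SV suppressed
        p.write_text(p.read_text().replace("C" * 60, "C" * 30))
        bubbles = vio.extract_bubbles(p, "ref")
        assert len(bubbles) == 1 and not bubbles[0].is_sv

    def test_line_order_invariance(self, tmp_path):
        lines = [
            "S\tu\t" + "A" * 5,
            "S\ta\t" + "C" * 10,
            "S\tb\t" + "G" * 100,
            "S\tv\t" + "T" * 4,
            "P\tref\tu+,a+,v+\t*",
            "P\talt\tu+,b+,v+\t*",
        ]
        p1, p2 = tmp_path / "a.gfa", tmp_path / "b.gfa"
        p1.write_text(_gfa(lines))
        p2.write_text(_gfa([lines[4], lines[3], lines[5], lines[0], lines[2], lines[1]]))
        b1 = vio.extract_bubbles(p1, "ref")
        b2 = vio.extract_bubbles(p2, "ref")
        assert [(b.pos, b.svlen, b.alleles) for b in b1] == [
            (b.pos, b.svlen, b.alleles) for b in b2
        ]

    def test_missing_reference_and_reverse_orientation(self, tmp_path):
        p = tmp_path / "g.gfa"
        p.write_text(_gfa(["S\tu\tAAA", "P\tref\tu-\t*"]))
        with pytest.raises(vio.DataError, match="reverse"):
            vio.extract_bubbles(p, "ref")
        with pytest.raises(vio.DataError, match="absent"):
            vio.extract_bubbles(p, "nope")


class TestAnnotateSVRegions:
    @pytest.fixture
    def gff(self, tmp_path):
        p = tmp_path / "genes.gff3"
        p.write_text(
            "##gff-version 3\n"
            "chr1\t.\tgene\t10001\t20000\t.\t+\t.\tID=g1\n"
            "chr1\t.\texon\t10001\t10500\t.\t+\t.\tParent=g1\n"
            "chr1\t.\texon\t19500\t20000\t.\t+\t.\tParent=g1\n"
            "chr1\t.\tCDS\t10101\t10400\t.\t+\t0\tParent=g1\n"
        )
        return p

    def test_classes_and_precedence(self, gff):
        svs = pd.DataFrame(
            {
                "chrom": ["chr1"] * 4,
                "pos": [10200, 7000, 15000, 40000],
                "svtype": ["DEL", "INS", "DEL", "DEL"],
                "svlen": [50, 120, 80, 500],
            }
        )
        labels = vio.annotate_sv_regions(svs, gff)
        assert list(labels) == ["coding", "regulatory", "regulatory", "intergenic"]

    def test_malformed_gff_names_line(self, tmp_path):
        p = tmp_path / "bad.gff3"
        p.write_text("chr1\tgene\t1\n")
        with pytest.raises(vio.DataError, match=":1"):
            vio.annotate_sv_regions(
                pd.DataFrame({"chrom": [], "pos": [], "svtype": [], "svlen": []}), p
            )
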