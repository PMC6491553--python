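import pandas as pd
import pytest

from berrymir.annotation_stats import (AnnotationParseError, IdCapacityError,
                                       assign_ids, compare, expressed_count,
                                       parse_gff3, percent, ratio, summarize,
                                       support_metrics, transcript_registry)

TOY_GFF3 = """##gff-version 3
chr1\ttest\tgene\t100\t1000\t.\t+\t.\tID=g1
chr1\ttest\tmRNA\t100\t1000\t.\t+\t.\tID=g1.t1;Parent=g1
chr1\ttest\texon\t100\t400\t.\t+\t.\tParent=g1.t1
chr1\ttest\texon\t600\t1000\t.\t+\t.\tParent=g1.t1
chr1\ttest\tCDS\t200\t400\t.\t+\t0\tParent=g1.t1
chr1\ttest\tCDS\t600\t900\t.\t+\t0\tParent=g1.t1
chr1\ttest\tfive_prime_UTR\t100\t199\t.\t+\t.\tParent=g1.t1
chr1\ttest\tthree_prime_UTR\t901\t1000\t.\t+\t.\tParent=g1.t1
chr1\ttest\tmRNA\t100\t400\t.\t+\t.\tID=g1.t2;Parent=g1
chr1\ttest\texon\t100\t400\t.\t+\t.\tParent=g1.t2
chr1\ttest\tCDS\t200\t400\t.\t+\t0\tParent=g1.t2
chr2\ttest\tgene\t500\t800\t.\t-\t.\tID=g2
chr2\ttest\tmRNA\t500\t800\t.\t-\t.\tID=g2.t1;Parent=g2
chr2\ttest\texon\t500\t800\t.\t-\t.\tParent=g2.t1
chr2\ttest\tCDS\t500\t800\t.\t-\t0\tParent=g2.t1
"""


@pytest.fixture(scope="module")
def toy_models():
    return parse_gff3(TOY_GFF3)


class TestParseAndSummarize:
    def test_gene_and_transcript_counts(self, toy_models):
        s = summarize(toy_models)
        assert s.n_genes == 2
        assert s.n_transcripts == 3
        assert s.mean_isoforms_per_gene == 1.5

    def test_utr_counts_per_gene(self, toy_models):
        s = summarize(toy_models)
        assert s.n_with_5utr == 1
        assert s.n_with_3utr == 1
        assert s.n_with_both_utr == 1

    def test_single_exon_transcript_contributes_no_introns(self, toy_models):
        s = summarize(toy_models)
        # only g1.t1 has an intron: 401..599 -> 199 nt
        assert s.mean_intron_length == 199.0

    def test_locus_length_is_gene_span(self, toy_models):
        s = summarize(toy_models)
        assert s.mean_locus_length == pytest.approx((901 + 301) / 2)

    def test_malformed_hierarchy_raises(self):
        bad = "##gff-version 3\nchr1\tt\tgene\t1\t100\t.\t+\t.\tID=g\n" \
              "chr1\tt\tmRNA\t1\t100\t.\t+\t.\tID=m;Parent=g\n"
        with pytest.raises(AnnotationParseError):
            summarize(parse_gff3(bad))

    def test_registry_cds_span(self, toy_models):
        reg = transcript_registry(toy_models)
        # g1.t1: exons 301 + 401 nt; CDS from genomic 200 -> tx pos 101
        assert reg["g1.t1"].length == 301 + 401
        assert reg["g1.t1"].cds_start == 101
        assert reg["g1.t1"].cds_end == 301 + 301  # genomic 900


class TestPercent:
    @pytest.mark.parametrize("num,den,expected", [
        (34007 - 28588, 28588, 18.96),
        (24978, 28588, 87.37),
        (24978, 34007, 73.45),
        (4832, 9029, 53.52),
        (5793, 9029, 64.16),
        (7361, 9029, 81.53),
        (27554, 34007, 81.02),
        (0, 100, 0.00),
    ])
    def test_published_ratios(self, num, den, expected):
        assert percent(num, den) == expected

    def test_half_up_rounding(self):
        assert percent(1, 8, 1) == 12.5
        assert percent(125, 1000) == 12.5
        assert percent(1125, 10000, 1) == 11.3  # 11.25 rounds up, not to even

    def test_zero_denominator(self):
        with pytest.raises(ZeroDivisionError):
            percent(1, 0)

    def test_ratio_mean_isoforms(self):
        assert ratio(64598, 34007) == 1.90


class TestCompare:
    def test_identical_annotations_fully_shared(self, toy_models):
        res = compare(toy_models, toy_models)
        assert len(res.shared) == 2
        assert res.only_a == [] and res.only_b == []
        assert set(res.class_codes.values()) == {"identical"}

    def test_added_intergenic_gene_only_in_b(self, toy_models):
        extra = TOY_GFF3 + (
            "chr3\ttest\tgene\t10\t200\t.\t+\t.\tID=g3\n"
            "chr3\ttest\tmRNA\t10\t200\t.\t+\t.\tID=g3.t1;Parent=g3\n"
            "chr3\ttest\texon\t10\t200\t.\t+\t.\tParent=g3.t1\n")
        res = compare(toy_models, parse_gff3(extra))
        assert res.only_b == ["g3"]
        assert res.class_codes["g3"] == "novel"

    def test_shifted_exon_ends_same_introns_shared(self, toy_models):
        shifted = TOY_GFF3.replace("exon\t100\t400", "exon\t150\t400") \
                          .replace("mRNA\t100\t1000", "mRNA\t150\t1000") \
                          .replace("gene\t100\t1000", "gene\t150\t1000")
        res = compare(toy_models, parse_gff3(shifted))
        assert ("g1", "g1") in res.shared
        assert res.class_codes["g1"] == "intron-chain-match"

    def test_shared_membership_symmetric(self, toy_models):
        extra = parse_gff3(TOY_GFF3.replace("exon\t100\t400", "exon\t150\t400"))
        ab = {tuple(sorted(p)) for p in compare(toy_models, extra).shared}
        ba = {tuple(sorted(p)) for p in compare(extra, toy_models).shared}
        assert ab == ba


class TestAssignIds:
    EXISTING = ["FvH4_1g10010", "FvH4_1g10020", "FvH4_2g05550",
                "FvH4_2g05560", "FvH4_3g00110", "FvH4_3g00120"]

    def test_new_gene_gets_midpoint_id(self):
        out = assign_ids(self.EXISTING,
                         [("add", "FvH4_1g10010", "FvH4_1g10020")])
        assert out[0] == "FvH4_1g10015"

    def test_split_keeps_id_on_longest_fragment(self):
        out = assign_ids(self.EXISTING, [("split", "FvH4_2g05550", 2, 0)])
        assert out[0] == ["FvH4_2g05550", "FvH4_2g05555"]

    def test_merge_retains_lowest_id(self):
        out = assign_ids(self.EXISTING,
                         [("merge", ["FvH4_3g00120", "FvH4_3g00110"])])
        assert out[0] == "FvH4_3g00110"

    def test_removed_ids_never_reused(self):
        # a second insertion in the same gap must avoid the first id
        out = assign_ids(self.EXISTING, [
            ("add", "FvH4_1g10010", "FvH4_1g10020"),
            ("add", "FvH4_1g10010", "FvH4_1g10020")])
        assert out[0] == "FvH4_1g10015"
        assert out[1] != out[0]
        assert out[1].startswith("FvH4_1g1001")

    def test_ids_are_injective(self):
        events = [("add", "FvH4_1g10010", "FvH4_1g10020") for _ in range(9)]
        out = assign_ids(self.EXISTING, events)
        ids = [out[i] for i in range(9)]
        assert len(set(ids)) == 9
        assert not set(ids) & set(self.EXISTING)

    def test_capacity_error_after_nine_insertions(self):
        events = [("add", "FvH4_1g10010", "FvH4_1g10020")
                  for _ in range(10)]
        with pytest.raises(IdCapacityError):
            assign_ids(self.EXISTING, events)


class TestExpressedCount:
    def test_strict_threshold(self):
        tpm = pd.DataFrame({"t1": [0.5, 1.0, 7.0], "t2": [0.2, 0.9, 0.1]},
                           index=["g1", "g2", "g3"])
        n, gene_max = expressed_count(tpm)
        assert n == 1  # only g3; g2 max == 1.0 is not counted
        assert gene_max["g3"] == 7.0

    def test_three_gene_example(self):
        tpm = pd.DataFrame({"t1": [0.5, 1.2, 7.0]}, index=list("abc"))
        assert expressed_count(tpm)[0] == 2

    def test_negative_tpm_rejected(self):
        tpm = pd.DataFrame({"t1": [-0.1]}, index=["g1"])
        with pytest.raises(ValueError):
            expressed_count(tpm)


class TestSupportMetrics:
    def test_exact_agreement_gives_aed_zero(self):
        m = [(100, 199), (300, 399)]
        sm = support_metrics(m, m)
        assert sm.aed == 0.0
        assert sm.qi_exon_fraction == 1.0

    def test_disjoint_gives_aed_one(self):
        sm = support_metrics([(100, 199)], [(500, 599)])
        assert sm.aed == 1.0
        assert sm.qi_exon_fraction == 0.0

    def test_half_overlap(self):
        # model 100 nt, evidence 100 nt, overlap 50 nt -> SN = SP = 0.5
        sm = support_metrics([(1, 100)], [(51, 150)])
        assert sm.aed == pytest.approx(0.5)

    def test_empty_model_rejected(self):
        with pytest.raises(ValueError):
            support_metrics([], [(1, 10)])
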