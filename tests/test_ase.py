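import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest

from hybridreg.ase import (assign_allele_reads, call_fixed_snps, classify_all,
                           classify_regulatory, depth_adjust, filter_min_reads,
                           fisher_ase_test)


def _parent_counts(rows):
    return pd.DataFrame(rows, columns=["gene_id", "position", "parent",
                                       "base", "count"])


class TestFixedSnps:
    def test_clean_fixed_site_accepted(self):
        snps = call_fixed_snps(_parent_counts([
            ("g1", 100, "P1", "A", 10), ("g1", 100, "P2", "G", 8)]))
        assert len(snps) == 1
        assert (snps[0].allele_p1, snps[0].allele_p2) == ("A", "G")

    def test_polymorphic_parent_rejected(self):
        snps = call_fixed_snps(_parent_counts([
            ("g1", 100, "P1", "A", 10),
            ("g1", 100, "P2", "A", 7), ("g1", 100, "P2", "G", 5)]))
        assert snps == []

    def test_low_support_rejected(self):
        snps = call_fixed_snps(_parent_counts([
            ("g1", 100, "P1", "A", 2), ("g1", 100, "P2", "G", 9)]))
        assert snps == []
        # boundary: exactly the minimum support qualifies
        snps = call_fixed_snps(_parent_counts([
            ("g1", 100, "P1", "A", 3), ("g1", 100, "P2", "G", 3)]))
        assert len(snps) == 1

    def test_same_allele_in_both_parents_rejected(self):
        snps = call_fixed_snps(_parent_counts([
            ("g1", 100, "P1", "A", 10), ("g1", 100, "P2", "A", 10)]))
        assert snps == []

    def test_malformed_table_rejected(self):
        with pytest.raises(ValueError):
            call_fixed_snps(pd.DataFrame({"gene_id": [], "base": []}))


VCF_TEXT = """\
##fileformat=VCFv4.2
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene id">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">
##contig=<ID=chr1,length=100000>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tbog\tpse
chr1\t101\t.\tA\tG\t50\tPASS\tGENE=g1\tGT:DP\t0/0:12\t1/1:9
chr1\t202\t.\tC\tT\t50\tPASS\tGENE=g1\tGT:DP\t0/1:12\t1/1:9
chr1\t303\t.\tG\tA\t50\tq10\tGENE=g1\tGT:DP\t0/0:12\t1/1:9
chr1\t404\t.\tT\tC\t50\tPASS\tGENE=g2\tGT:DP\t0/0:2\t1/1:9
chr1\t505\t.\tT\tC\t50\tPASS\tGENE=g2\tGT:DP\t0/0:8\t0/0:9
chr1\t606\t.\tT\tCA\t50\tPASS\tGENE=g2\tGT:DP\t0/0:8\t1/1:9
"""


class TestVcfImport:
    def test_only_clean_fixed_biallelic_pass_sites_kept(self, tmp_path):
        from hybridreg.ase import read_fixed_snps_vcf
        path = tmp_path / "parents.vcf"
        path.write_text(VCF_TEXT)
        snps = read_fixed_snps_vcf(path, "bog", "pse")
        # heterozygous, filtered, low-depth, same-allele and indel
        # records are all rejected
        assert len(snps) == 1
        snp = snps[0]
        assert (snp.gene_id, snp.position) == ("g1", 100)
        assert (snp.allele_p1, snp.allele_p2) == ("A", "G")


class TestAssignAlleleReads:
    def _snps(self):
        return call_fixed_snps(_parent_counts([
            ("g1", 10, "P1", "A", 9), ("g1", 10, "P2", "G", 9),
            ("g1", 50, "P1", "A", 9), ("g1", 50, "P2", "G", 9)]))

    def test_reads_summed_across_snps(self):
        hyb = pd.DataFrame([
            ("g1", 10, "h1", "A", 30), ("g1", 10, "h1", "G", 10),
            ("g1", 50, "h1", "A", 25), ("g1", 50, "h1", "G", 15)],
            columns=["gene_id", "position", "sample", "base", "count"])
        out = assign_allele_reads(hyb, self._snps())
        row = out[(out.gene_id == "g1") & (out["sample"] == "h1")].iloc[0]
        assert (row.reads_p1, row.reads_p2) == (55, 25)

    def test_third_base_ignored(self):
        hyb = pd.DataFrame([
            ("g1", 10, "h1", "A", 30), ("g1", 10, "h1", "C", 99)],
            columns=["gene_id", "position", "sample", "base", "count"])
        out = assign_allele_reads(hyb, self._snps())
        row = out.iloc[0]
        assert (row.reads_p1, row.reads_p2) == (30, 0)

    def test_gene_without_snps_absent(self):
        hyb = pd.DataFrame([("g2", 7, "h1", "A", 30)],
                           columns=["gene_id", "position", "sample", "base",
                                    "count"])
        out = assign_allele_reads(hyb, self._snps())
        assert "g2" not in set(out.gene_id)


DESIGN = pd.DataFrame({
    "sample": ["P1_1", "P2_1", "HybSterile_1"],
    "group": ["P1", "P2", "HybSterile"],
    "replicate": [1, 1, 1]}).set_index("sample")


def _table(p1, p2, h1, h2, gene="g1"):
    return pd.DataFrame({
        "gene_id": [gene] * 3,
        "sample": ["P1_1", "P2_1", "HybSterile_1"],
        "reads_p1": [p1, 0, h1],
        "reads_p2": [0, p2, h2]})


class TestReadFloorAndDepth:
    @pytest.mark.parametrize("p1,p2,kept", [(12, 9, True), (10, 9, False),
                                            (10, 10, True)])
    def test_combined_parental_floor_boundary(self, p1, p2, kept):
        table = _table(p1, p2, 30, 30)
        out = filter_min_reads(table, DESIGN, min_total=20)
        assert ("g1" in set(out.gene_id)) is kept

    def test_equal_depths_leave_counts_unchanged(self):
        table = _table(50, 40, 30, 20)
        lib = pd.Series({"P1_1": 1e6, "P2_1": 1e6, "HybSterile_1": 1e6})
        out = depth_adjust(table, lib)
        pd.testing.assert_frame_equal(out, table)

    def test_half_depth_sample_doubled(self):
        table = _table(10, 10, 10, 10)
        lib = pd.Series({"P1_1": 5e5, "P2_1": 1e6, "HybSterile_1": 1.5e6})
        out = depth_adjust(table, lib)
        assert out.loc[out["sample"] == "P1_1", "reads_p1"].iloc[0] == 20
        assert out.loc[out["sample"] == "P2_1", "reads_p2"].iloc[0] == 10

    def test_zero_library_size_rejected(self):
        with pytest.raises(ValueError):
            depth_adjust(_table(1, 1, 1, 1),
                         pd.Series({"P1_1": 0, "P2_1": 1, "HybSterile_1": 1}))


def _fisher_oracle(a, b, c, d):
    """Exact two-sided p by brute-force hypergeometric tail summation."""
    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2

    def pmf(k):
        return (comb(row1, k) * comb(row2, col1 - k)) / comb(n, col1)

    p_obs = pmf(a)
    lo = max(0, col1 - row2)
    hi = min(col1, row1)
    return sum(pmf(k) for k in range(lo, hi + 1)
               if pmf(k) <= p_obs * (1 + 1e-9))


class TestFisher:
    def test_identical_ratios_give_unity(self):
        assert fisher_ase_test(10, 10, 10, 10) == pytest.approx(1.0)
        assert fisher_ase_test(5, 5, 50, 50) == pytest.approx(1.0)

    def test_extreme_imbalance_tiny_p(self):
        p = fisher_ase_test(100, 10, 10, 100)
        assert p < 1e-20
        assert p == pytest.approx(_fisher_oracle(100, 10, 10, 100), rel=1e-6)

    @pytest.mark.parametrize("table", [
        (3, 7, 8, 2), (5, 0, 1, 9), (12, 4, 3, 11), (2, 2, 9, 1)])
    def test_matches_bruteforce_hypergeometric_oracle(self, table):
        assert fisher_ase_test(*table) == \
            pytest.approx(_fisher_oracle(*table), rel=1e-9)

    def test_invariant_under_row_and_column_swap(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            a, b, c, d = rng.integers(0, 40, size=4)
            assert fisher_ase_test(a, b, c, d) == \
                pytest.approx(fisher_ase_test(d, c, b, a))

    def test_non_integer_rejected(self):
        with pytest.raises(ValueError):
            fisher_ase_test(1.5, 2, 3, 4)


class TestClassification:
    def test_decision_matrix(self):
        assert classify_regulatory(True, True) == "cis_trans_divergent"
        assert classify_regulatory(True, False) == "cis_only"
        assert classify_regulatory(False, True) == "compensatory"
        assert classify_regulatory(False, False) == "non_compensatory"

    def test_below_read_floor_is_uninformative(self):
        calls = classify_all(_table(5, 5, 100, 100), DESIGN, ["g1"],
                             "HybSterile", set())
        assert calls[0].category == "uninformative"
        assert calls[0].fisher_p is None

    def test_no_hybrid_reads_is_uninformative(self):
        calls = classify_all(_table(50, 50, 0, 0), DESIGN, ["g1"],
                             "HybSterile", set())
        assert calls[0].category == "uninformative"

    def test_zero_cell_replaced_by_one_for_testability(self):
        calls = classify_all(_table(50, 50, 40, 0), DESIGN, ["g1"],
                             "HybSterile", set())
        assert calls[0].hybrid_p2 == 1
        assert calls[0].fisher_p is not None

    def test_balanced_gene_is_non_compensatory(self):
        calls = classify_all(_table(50, 50, 48, 52), DESIGN, ["g1"],
                             "HybSterile", set())
        assert calls[0].category == "non_compensatory"

    def test_hidden_imbalance_without_parental_de_is_compensatory(self):
        calls = classify_all(_table(200, 200, 300, 100), DESIGN, ["g1"],
                             "HybSterile", set())
        assert calls[0].category == "compensatory"
        calls = classify_all(_table(200, 200, 300, 100), DESIGN, ["g1"],
                             "HybSterile", {"g1"})
        assert calls[0].category == "cis_trans_divergent"

    def test_every_gene_receives_exactly_one_call(self):
        table = pd.concat([_table(50, 50, 30, 30, "g1"),
                           _table(5, 5, 3, 3, "g2")], ignore_index=True)
        calls = classify_all(table, DESIGN, ["g1", "g2", "g3"],
                             "HybSterile", set())
        assert [c.gene_id for c in calls] == ["g1", "g2", "g3"]
        assert calls[2].category == "uninformative"  # never observed
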