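"""Context classification, coverage filtering, summaries and profiles."""

import math

import numpy as np
import pandas as pd
import pytest

from tuberkit.core import FeatureRecord, GenomeSequence, reverse_complement
from tuberkit.methylome import (call_methylation, classify_context,
                                filter_by_coverage, metagene_profile,
                                rank_te_by_expression, summarize_methylation,
                                summary_table)


class TestClassifyContext:
    def test_cg_plus_strand(self):
        assert classify_context(GenomeSequence("c1", "TTCGAA"), 3, "+") == \
            "CG"

    def test_chg_and_chh_plus_strand(self):
        assert classify_context(GenomeSequence("c1", "TTCAGA"), 3, "+") == \
            "CHG"
        assert classify_context(GenomeSequence("c1", "TTCAAA"), 3, "+") == \
            "CHH"

    def test_minus_strand_reads_reverse_complement(self):
        # G at position 4 of TTCGAA: minus-strand cytosine; upstream C at 3
        # reads as G downstream on the minus strand -> CG
        assert classify_context(GenomeSequence("c1", "TTCGAA"), 4, "-") == \
            "CG"

    def test_contig_edge_and_n_are_unknown(self):
        assert classify_context(GenomeSequence("c1", "AAAC"), 4, "+") == \
            "unknown"
        assert classify_context(GenomeSequence("c1", "CNA"), 1, "+") == \
            "unknown"

    def test_wrong_base_rejected(self):
        with pytest.raises(ValueError):
            classify_context(GenomeSequence("c1", "AAAA"), 2, "+")

    def test_agrees_with_trinucleotide_oracle_both_strands(self, rng):
        """Brute-force oracle: extract the trinucleotide, reverse-complement
        for minus strand, classify from the literal string."""
        seq = "".join(rng.choice(list("ACGTN"), size=10_000,
                                 p=[0.24, 0.25, 0.25, 0.24, 0.02]))
        g = GenomeSequence("c1", seq)

        def oracle(i, strand):  # i is 0-based
            if strand == "+":
                tri = seq[i:i + 3]
            else:
                tri = reverse_complement(seq[max(i - 2, 0):i + 1])
            if len(tri) < 2:
                return "unknown"
            if tri[1] == "G":
                return "CG"
            if tri[1] in "ACT":
                if len(tri) < 3:
                    return "unknown"
                if tri[2] == "G":
                    return "CHG"
                if tri[2] in "ACT":
                    return "CHH"
            return "unknown"

        for i, base in enumerate(seq):
            if base == "C":
                assert classify_context(g, i + 1, "+") == oracle(i, "+"), i
            elif base == "G":
                assert classify_context(g, i + 1, "-") == oracle(i, "-"), i


class TestCallMethylation:
    @pytest.mark.parametrize("mc,t,expected", [
        (6, 2, 0.75), (0, 5, 0.0), (4, 0, 1.0)])
    def test_level_is_c_over_total(self, mc, t, expected):
        assert call_methylation(mc, t) == expected

    def test_no_coverage_is_undefined(self):
        assert math.isnan(call_methylation(0, 0))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            call_methylation(-1, 2)


def _pileup(rows):
    return pd.DataFrame(rows, columns=[
        "contig_id", "position", "strand", "context", "mc_count", "t_count"])


class TestCoverageFilter:
    def test_boundary_at_least_four_reads_inclusive(self):
        df = _pileup([("c1", 1, "+", "CG", 2, 2),    # cov 4: retained
                      ("c1", 2, "+", "CG", 2, 1)])   # cov 3: removed
        retained, _ = filter_by_coverage(df, min_cov=4)
        assert list(retained.position) == [1]

    def test_retention_report_counts_and_fractions(self, rng):
        rows = []
        for i in range(100):
            cov = 6 if i < 40 else 2
            rows.append(("c1", i + 1, "+", "CG", cov // 2, cov - cov // 2))
        retained, report = filter_by_coverage(_pileup(rows), min_cov=4)
        cg = report[report.context == "CG"].iloc[0]
        assert (cg.n_total, cg.n_retained) == (100, 40)
        assert cg.percent_retained == pytest.approx(40.0)
        # retained + removed = total classifiable
        assert cg.n_total - cg.n_retained == 60

    def test_min_cov_one_keeps_all_covered(self):
        df = _pileup([("c1", 1, "+", "CG", 0, 1)])
        retained, _ = filter_by_coverage(df, min_cov=1)
        assert len(retained) == 1


class TestSummaries:
    def test_mean_of_sites_inside_te(self):
        df = _pileup([("c1", 11, "+", "CG", 1, 1),   # 0.5
                      ("c1", 12, "+", "CG", 2, 0),   # 1.0
                      ("c1", 13, "+", "CG", 0, 2),   # 0.0
                      ("c1", 99, "+", "CG", 9, 0)])  # outside the TE
        te = [FeatureRecord("t1", "c1", 10, 20, feature_class="TE")]
        s = summarize_methylation(df, te, "TE", "CG")
        assert s.n_sites_retained == 3
        assert s.mean_level == pytest.approx(0.5)

    def test_zero_qualifying_sites_is_undefined_not_error(self):
        df = _pileup([("c1", 1, "+", "CHH", 1, 1)])
        s = summarize_methylation(df, [], "TE", "CG")
        assert s.n_sites_retained == 0 and s.mean_level is None

    def test_overlapping_features_count_sites_once(self):
        df = _pileup([("c1", 15, "+", "CG", 2, 0)])
        tes = [FeatureRecord("a", "c1", 10, 20, feature_class="TE"),
               FeatureRecord("b", "c1", 12, 30, feature_class="TE")]
        s = summarize_methylation(df, tes, "TE", "CG")
        assert s.n_sites_retained == 1

    def test_levels_bounded_by_unit_interval(self, rng):
        rows = [("c1", i + 1, "+", "CG", int(rng.integers(0, 5)),
                 int(rng.integers(1, 5))) for i in range(200)]
        table = summary_table(_pileup(rows), [])
        means = table["mean_level"].dropna()
        assert ((means >= 0) & (means <= 1)).all()


class TestMetagene:
    def test_uniform_level_gives_flat_profile(self):
        rows = [("c1", p, "+", "CG", 1, 1) for p in range(1, 3_001)]
        genes = [FeatureRecord("g1", "c1", 1_000, 2_000, strand="+")]
        prof = metagene_profile(_pileup(rows), genes, n_bins_body=10,
                                flank_bp=500, n_bins_flank=5)
        filled = prof.table.dropna(subset=["mean_level"])
        assert (filled.mean_level == 0.5).all()
        assert filled.n_sites.min() > 0

    def test_strand_flip_gives_identical_profiles(self):
        """A minus-strand gene with the mirror-image site pattern produces
        the same 5'->3' profile as its plus-strand counterpart."""
        # plus gene [100, 200) on c1: high methylation near its 5' end
        rows_plus, rows_minus = [], []
        for off in range(0, 100, 5):
            level_mc = 4 if off < 50 else 0
            rows_plus.append(("c1", 101 + off, "+", "CG", level_mc, 4))
            # mirror position inside minus gene [300, 400) on c2
            rows_minus.append(("c2", 400 - off, "+", "CG", level_mc, 4))
        gp = [FeatureRecord("gp", "c1", 100, 200, strand="+")]
        gm = [FeatureRecord("gm", "c2", 300, 400, strand="-")]
        prof_p = metagene_profile(_pileup(rows_plus), gp, 10, 50, 5)
        prof_m = metagene_profile(_pileup(rows_minus), gm, 10, 50, 5)
        body_p = prof_p.table[prof_p.table.region == "body"]
        body_m = prof_m.table[prof_m.table.region == "body"]
        pd.testing.assert_frame_equal(body_p.reset_index(drop=True),
                                      body_m.reset_index(drop=True))

    def test_empty_bins_undefined_with_zero_sites(self):
        rows = [("c1", 150, "+", "CG", 1, 1)]
        genes = [FeatureRecord("g1", "c1", 100, 300, strand="+")]
        prof = metagene_profile(_pileup(rows), genes, n_bins_body=4,
                                flank_bp=100, n_bins_flank=2)
        empty = prof.table[prof.table.n_sites == 0]
        assert empty["mean_level"].isna().all()
        assert len(empty) > 0

    def test_short_gene_skipped_with_warning(self, caplog):
        genes = [FeatureRecord("tiny", "c1", 10, 15, strand="+")]
        with caplog.at_level("WARNING"):
            prof = metagene_profile(_pileup([]), genes, n_bins_body=20)
        assert "tiny" in caplog.text
        assert (prof.table.n_sites == 0).all()


class TestTeRanking:
    def test_partition_and_ascending_order(self):
        table = rank_te_by_expression(
            {"a": 0.8, "b": 0.6, "c": 0.7}, {"a": 0.0, "b": 5.0, "c": 1.0})
        silenced = table[table.partition == "silenced"]
        expressed = table[table.partition == "expressed"]
        assert list(silenced.feature_id) == ["a"]
        assert list(expressed.feature_id) == ["c", "b"]

    def test_all_silenced_leaves_expressed_empty(self):
        table = rank_te_by_expression({"a": 0.5, "b": 0.6},
                                      {"a": 0.0, "b": 0.0})
        assert (table.partition == "silenced").all()

    def test_missing_value_excluded_and_logged(self, caplog):
        with caplog.at_level("WARNING"):
            table = rank_te_by_expression({"a": 0.5}, {"a": 1.0, "b": 2.0})
        assert list(table.feature_id) == ["a"]
        assert "b" in caplog.text

    def test_planted_anticorrelation_detected(self, rng):
        """With methylation planted to fall as expression rises, the rank
        correlation between expression order and methylation is negative."""
        from scipy.stats import spearmanr
        n = 50
        expr = np.sort(rng.uniform(0.1, 50, size=n))
        meth = np.clip(0.9 - 0.015 * np.arange(n)
                       + rng.normal(0, 0.03, size=n), 0, 1)
        ids = [f"te{i:03d}" for i in range(n)]
        table = rank_te_by_expression(dict(zip(ids, meth)),
                                      dict(zip(ids, expr)))
        expressed = table[table.partition == "expressed"]
        rho = spearmanr(expressed["rank"], expressed.mean_level).statistic
        assert rho < -0.5
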