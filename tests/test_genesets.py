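"""Ranked targets, proximity pairs, strata, GMT and interaction readers."""

import numpy as np
import pandas as pd
import pytest

from covarnet import genesets


class TestMirnaRanking:
    def table(self, rows):
        return pd.DataFrame(
            rows, columns=["family", "gene", "n_8mer", "n_m8_7mer", "context_score"]
        )

    def test_lexicographic_rank_rule(self):
        t = self.table(
            [
                ("m1", "gB", 1, 3, -0.9),
                ("m1", "gA", 2, 0, -0.5),
                ("m1", "gC", 1, 3, -0.2),
            ]
        )
        ranked = genesets.rank_mirna_targets(t)
        # 8mer first (desc), then m8-7mer (desc), then context (asc: more
        # negative = stronger)
        assert ranked["m1"].targets == ["gA", "gB", "gC"]

    def test_expression_threshold_at_least_4000(self):
        t = self.table([("lo", "g1", 1, 0, -0.1), ("hi", "g2", 1, 0, -0.1)])
        ranked = genesets.rank_mirna_targets(
            t, expressed_mirnas={"lo": 3999.0, "hi": 4000.0}
        )
        assert set(ranked) == {"hi"}

    def test_duplicates_keep_best_rank(self):
        t = self.table([("m1", "gA", 2, 0, -0.5), ("m1", "gA", 0, 0, -0.1),
                        ("m1", "gB", 1, 0, -0.1)])
        assert genesets.rank_mirna_targets(t)["m1"].targets == ["gA", "gB"]

    def test_missing_columns_reported(self):
        with pytest.raises(ValueError, match="n_8mer"):
            genesets.rank_mirna_targets(pd.DataFrame({"family": [], "gene": []}))


class TestTfTargets:
    def test_tie_broken_by_gene_id(self):
        t = pd.DataFrame({"gene": ["z", "m", "a", "q"], "score": [9, 7, 7, 3]})
        rt = genesets.load_tf_targets(t, top_n=2)
        assert rt.targets == ["z", "a"]

    def test_top_n_beyond_length_warns_and_returns_all(self):
        t = pd.DataFrame({"gene": ["a", "b"], "score": [2, 1]})
        with pytest.warns(UserWarning):
            rt = genesets.load_tf_targets(t, top_n=10)
        assert rt.targets == ["a", "b"]


@pytest.fixture()
def annotation():
    return pd.DataFrame(
        {
            "chrom": ["chr1", "chr1", "chr1", "chr2"],
            "start": [100_000, 150_000, 4_000_000, 50_000],
            "end": [120_000, 170_000, 4_020_000, 60_000],
            "strand": ["+", "+", "+", "-"],
        },
        index=["gA", "gB", "gC", "gD"],
    )


class TestHicPairs:
    def contacts(self, rows):
        return pd.DataFrame(
            rows,
            columns=["chromA", "startA", "endA", "chromB", "startB", "endB", "support"],
        )

    def test_twenty_kb_boundary_inclusive(self, annotation):
        # gene gA body [98000,120000); bin [140000,180000) -> gap exactly 20 kb
        c = self.contacts([("chr1", 140_000, 180_000, "chr1", 140_000, 180_000, 2.0)])
        pairs = genesets.hic_gene_pairs(c, annotation, mode="intra")
        got = set(map(tuple, pairs[["gene_a", "gene_b"]].to_numpy()))
        assert ("gA", "gB") in got

    def test_support_must_exceed_one_read(self, annotation):
        c = self.contacts([("chr1", 100_000, 140_000, "chr1", 140_000, 180_000, 1.0)])
        assert genesets.hic_gene_pairs(c, annotation, mode="intra").empty

    def test_minus_strand_upstream_extension_rightward(self):
        ann = pd.DataFrame(
            {"chrom": ["chrX", "chrX"], "start": [50_000, 83_000],
             "end": [60_000, 90_000], "strand": ["-", "+"]},
            index=["gM", "gP"],
        )
        # minus-strand body [50000,62000): reaches a bin at 82000 (gap 20 kb)
        c = self.contacts([("chrX", 82_000, 84_000, "chrX", 82_000, 84_000, 2.0)])
        pairs = genesets.hic_gene_pairs(c, ann, mode="intra")
        got = set(map(tuple, pairs[["gene_a", "gene_b"]].to_numpy()))
        assert ("gM", "gP") in got

    def test_support_summed_and_order_invariant(self, annotation):
        rows = [
            ("chr1", 90_000, 130_000, "chr1", 140_000, 180_000, 2.0),
            ("chr1", 80_000, 120_000, "chr1", 150_000, 170_000, 3.0),
        ]
        p1 = genesets.hic_gene_pairs(self.contacts(rows), annotation, mode="intra")
        p2 = genesets.hic_gene_pairs(self.contacts(rows[::-1]), annotation, mode="intra")
        pd.testing.assert_frame_equal(p1, p2)
        row = p1[(p1["gene_a"] == "gA") & (p1["gene_b"] == "gB")]
        assert row["contact_support"].iloc[0] == pytest.approx(5.0)

    def test_chromosome_mismatch_rejected(self, annotation):
        c = self.contacts([("1", 0, 40_000, "1", 40_000, 80_000, 2.0)])
        with pytest.raises(ValueError, match="chromosome"):
            genesets.hic_gene_pairs(c, annotation, mode="intra")

    def test_inter_mode_keeps_cross_chromosome_only(self, annotation):
        c = self.contacts([
            ("chr1", 100_000, 600_000, "chr2", 0, 500_000, 1.0),
            ("chr1", 100_000, 140_000, "chr1", 140_000, 180_000, 5.0),
        ])
        pairs = genesets.hic_gene_pairs(c, annotation, mode="inter")
        assert set(pairs["gene_a"]) | set(pairs["gene_b"]) <= {"gA", "gB", "gD"}
        assert not pairs.empty
        assert not pairs["same_chromosome"].any()


class TestStrata:
    def pairs(self, rows):
        return pd.DataFrame(rows, columns=["gene_a", "gene_b", "contact_support"])

    def test_mutually_exclusive_distance_strata(self, annotation):
        out = genesets.stratify_pairs(
            self.pairs([("gA", "gC", 2.0)]), annotation
        )
        # distance ~3.9 MB, contact-supported, no TADs -> "<5MB" only
        assert list(out["stratum"]) == ["<5MB"]

    def test_tad_wins_over_distance(self, annotation):
        tads = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [5_000_000]})
        out = genesets.stratify_pairs(self.pairs([("gA", "gC", 2.0)]), annotation, tads)
        assert list(out["stratum"]) == ["TAD"]

    def test_unsupported_same_chromosome(self, annotation):
        out = genesets.stratify_pairs(self.pairs([("gA", "gC", 0.0)]), annotation)
        assert list(out["stratum"]) == ["same_chr_no_contact"]

    def test_interchromosomal(self, annotation):
        out = genesets.stratify_pairs(self.pairs([("gA", "gD", 2.0)]), annotation)
        assert list(out["stratum"]) == ["interchromosomal"]

    def test_partition_property(self, annotation):
        rows = [("gA", "gB", 2.0), ("gA", "gC", 2.0), ("gB", "gC", 0.0),
                ("gA", "gD", 1.0)]
        out = genesets.stratify_pairs(self.pairs(rows), annotation)
        assert len(out) == len(rows)
        assert out["stratum"].isin(genesets.STRATA).all()


class TestGMT:
    def test_roundtrip_and_size_filter(self, tmp_path):
        sets = {
            "tiny": [f"g{i}" for i in range(9)],
            "ok_low": [f"g{i}" for i in range(10)],
            "ok_high": [f"g{i}" for i in range(100)],
            "big": [f"g{i}" for i in range(101)],
        }
        path = tmp_path / "sets.gmt"
        genesets.write_gmt(sets, path)
        loaded = genesets.read_gmt(str(path))
        assert loaded == sets
        kept = genesets.load_functional_sets(loaded)
        assert set(kept) == {"ok_low", "ok_high"}

    def test_malformed_line_skipped(self, tmp_path):
        path = tmp_path / "bad.gmt"
        path.write_text("good\tna\tg1\tg2\nbroken_line\n")
        with pytest.warns(UserWarning, match="line 2"):
            sets = genesets.read_gmt(str(path))
        assert set(sets) == {"good"}

    def test_universe_intersection_after_size_filter(self):
        sets = {"s": [f"g{i}" for i in range(50)]}
        kept = genesets.load_functional_sets(sets, universe={"g0", "g1"})
        assert kept["s"] == ["g0", "g1"]
        # intersect-first mode drops the set (2 genes < 10)
        assert genesets.load_functional_sets(
            sets, universe={"g0", "g1"}, filter_on_annotated_size=False
        ) == {}


class TestInteractions:
    def test_string_experimental_filter_and_bins(self):
        t = pd.DataFrame({
            "gene_a": ["a", "b", "c"],
            "gene_b": ["x", "y", "z"],
            "experimental": [0, 250, 700],
        })
        out = genesets.stratify_interactions(t, mode="string_score")
        all_pairs = set().union(*out.values())
        assert ("a", "x") not in all_pairs  # no experimental evidence
        assert {("b", "y"), ("c", "z")} <= all_pairs

    def test_reactome_pair_in_both_sets(self):
        t = pd.DataFrame({
            "gene_a": ["a", "b"],
            "gene_b": ["x", "y"],
            "experimental": [1, 1],
            "kind": ["complex|reaction", "reaction"],
        })
        out = genesets.stratify_interactions(t, mode="reactome")
        assert ("a", "x") in out["complex"] and ("a", "x") in out["reaction"]
        assert ("b", "y") in out["reaction"] and ("b", "y") not in out["complex"]

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            genesets.stratify_interactions(pd.DataFrame(), mode="nope")

    def test_pi_split_partitions_input(self):
        pairs = {("a", "b"), ("c", "d"), ("e", "f")}
        inter = {("b", "a"), ("x", "y")}
        out = genesets.split_by_interaction(pairs, inter)
        assert out["+PI"] == {("a", "b")}
        assert out["+PI"] | out["-PI"] == pairs
        assert not out["+PI"] & out["-PI"]
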