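"""Anchor dedupe and collinear-block chaining, with a brute-force oracle."""

import numpy as np
import pytest

from helpers_oracle import exhaustive_blocks
from polyrearrange import collinearity as coll
from polyrearrange.errors import ValidationError
from polyrearrange.formats_io import AnchorPair, GeneRecord


def make_genes(prefix, chrom, n, label="g"):
    return {
        f"{prefix}{i}": GeneRecord(
            f"{prefix}{i}", chrom, 1000 * i + 100, 1000 * i + 600, "+", label,
            rank=i,
        )
        for i in range(n)
    }


def make_anchor_set(pairs_with_scores):
    return [AnchorPair(q, s, float(sc), 1e-40) for q, s, sc in pairs_with_scores]


class TestDedupe:
    def test_top_n_hits_per_query(self):
        # subjects on distinct chromosomes so no tandem collapse interferes
        gq = make_genes("q", "c1", 1)
        gs = {
            f"s{i}": GeneRecord(f"s{i}", f"c{i + 2}", 100, 600, "+", "g", rank=0)
            for i in range(7)
        }
        anchors = make_anchor_set([("q0", f"s{i}", 100 + i) for i in range(7)])
        kept = coll.dedupe_anchors(anchors, gq, gs, top_n=5)
        assert len(kept) == 5
        assert {a.gene_s for a in kept} == {"s2", "s3", "s4", "s5", "s6"}

    def test_tandem_array_collapses_to_best(self):
        # query genes at consecutive ranks 4,5 both hitting s0
        gq = make_genes("q", "c1", 6)
        gs = make_genes("s", "c2", 1)
        anchors = make_anchor_set([("q4", "s0", 200), ("q5", "s0", 300)])
        kept = coll.dedupe_anchors(anchors, gq, gs, top_n=5)
        assert [(a.gene_q, a.score) for a in kept] == [("q5", 300.0)]

    def test_non_consecutive_hits_not_collapsed(self):
        gq = make_genes("q", "c1", 10)
        gs = make_genes("s", "c2", 1)
        anchors = make_anchor_set([("q1", "s0", 200), ("q5", "s0", 300)])
        kept = coll.dedupe_anchors(anchors, gq, gs, top_n=5)
        assert len(kept) == 2

    def test_empty_input(self):
        assert coll.dedupe_anchors([], {}, {}, top_n=5) == []


class TestChaining:
    def test_perfect_run_gives_one_forward_block(self):
        gq = make_genes("q", "c1", 10)
        gs = make_genes("s", "c2", 10)
        anchors = make_anchor_set([(f"q{i}", f"s{i}", 1000) for i in range(10)])
        blocks = coll.chain_collinear_blocks(anchors, gq, gs, match_size=8)
        assert len(blocks) == 1
        assert blocks[0].orientation == "forward"
        assert blocks[0].n_anchors == 10

    def test_run_below_match_size_discarded(self):
        gq = make_genes("q", "c1", 7)
        gs = make_genes("s", "c2", 7)
        anchors = make_anchor_set([(f"q{i}", f"s{i}", 1000) for i in range(7)])
        assert coll.chain_collinear_blocks(anchors, gq, gs, match_size=8) == []

    def test_inverted_run_detected(self):
        gq = make_genes("q", "c1", 10)
        gs = make_genes("s", "c2", 10)
        anchors = make_anchor_set([(f"q{i}", f"s{9 - i}", 1000) for i in range(10)])
        (block,) = coll.chain_collinear_blocks(anchors, gq, gs, match_size=8)
        assert block.orientation == "inverted"

    def test_gap_rule_splits_chains(self):
        gq = make_genes("q", "c1", 40)
        gs = make_genes("s", "c2", 40)
        # two runs separated by a rank gap larger than max_gap_genes
        anchors = make_anchor_set(
            [(f"q{i}", f"s{i}", 1000) for i in range(10)]
            + [(f"q{i}", f"s{i}", 1000) for i in range(30, 40)]
        )
        blocks = coll.chain_collinear_blocks(
            anchors, gq, gs, match_size=8, max_gap_genes=10
        )
        assert len(blocks) == 2

    def test_match_size_below_two_rejected(self):
        with pytest.raises(ValidationError):
            coll.chain_collinear_blocks([], {}, {}, match_size=1)

    def test_span_bounds_member_genes(self):
        gq = make_genes("q", "c1", 10)
        gs = make_genes("s", "c2", 10)
        anchors = make_anchor_set([(f"q{i}", f"s{i}", 1000) for i in range(10)])
        (block,) = coll.chain_collinear_blocks(anchors, gq, gs, match_size=8)
        assert block.span_q == (100, 9600)
        assert block.span_s == (100, 9600)


def random_instance(rng, n_anchors=12, grid=15, planted_run=8, max_score=50):
    """Random anchor instance: a planted collinear run plus scattered noise,
    integer scores (exact tie-breaking)."""
    cells = set()
    start = rng.integers(0, grid - planted_run, size=2)
    flip = rng.random() < 0.5
    for k in range(planted_run):
        q = int(start[0]) + k
        s = int(start[1]) + (planted_run - 1 - k if flip else k)
        cells.add((q, s))
    while len(cells) < n_anchors:
        cells.add((int(rng.integers(grid)), int(rng.integers(grid))))
    return [
        (q, s, int(rng.integers(1, max_score))) for q, s in sorted(cells)
    ]


def dp_block_signatures(rows, match_size, max_gap):
    gq = make_genes("q", "c1", max(r[0] for r in rows) + 1)
    gs = make_genes("s", "c2", max(r[1] for r in rows) + 1)
    anchors = [AnchorPair(f"q{q}", f"s{s}", float(sc), 1e-40) for q, s, sc in rows]
    blocks = coll.chain_collinear_blocks(
        anchors, gq, gs, match_size=match_size, max_gap_genes=max_gap
    )
    return [
        (
            b.orientation,
            frozenset(
                (gq[a.gene_q].rank, gs[a.gene_s].rank) for a in b.anchors
            ),
        )
        for b in blocks
    ]


class TestOracleEquivalence:
    def test_dp_matches_exhaustive_enumeration(self):
        """200 random instances: the DP block set equals the exhaustive
        enumeration of maximal monotone chains under the same gap rule."""
        rng = np.random.default_rng(20240917)
        for _ in range(200):
            rows = random_instance(rng)
            got = dp_block_signatures(rows, match_size=4, max_gap=4)
            want = exhaustive_blocks(rows, match_size=4, max_gap=4)
            assert sorted(got) == sorted(want), rows

    def test_raising_match_size_never_adds_blocks(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            rows = random_instance(rng)
            counts = [
                len(dp_block_signatures(rows, match_size=m, max_gap=4))
                for m in (3, 4, 6, 8)
            ]
            assert counts == sorted(counts, reverse=True)

    def test_no_anchor_in_two_blocks(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            rows = random_instance(rng, n_anchors=14)
            sigs = dp_block_signatures(rows, match_size=3, max_gap=4)
            seen = set()
            for _, anchors in sigs:
                assert not (anchors & seen)
                seen |= anchors


class TestSummary:
    def test_percentage_from_counts(self):
        # the within-tetraploid collinear fraction arithmetic
        df = coll.collinearity_summary(
            None,
            totals={"subgenomes": 53042},
            collinear_counts={"subgenomes": 29742},
        )
        assert df.loc[0, "pct_collinear"] == pytest.approx(56.07, abs=0.005)

    def test_zero_total_gives_na(self):
        df = coll.collinearity_summary(None, {"x": 0}, collinear_counts={"x": 0})
        assert np.isnan(df.loc[0, "pct_collinear"])

    def test_all_genes_collinear_is_100(self):
        df = coll.collinearity_summary(None, {"x": 10}, collinear_counts={"x": 10})
        assert df.loc[0, "pct_collinear"] == 100.0

    def test_no_blocks_is_zero(self):
        df = coll.collinearity_summary([], {"x": 10}, comparison_of_block=lambda b: "x")
        assert df.loc[0, "pct_collinear"] == 0.0
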