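"""Repeat accounting, enrichment classification, and density tracks."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from polyrearrange import repeat_dynamics as repd
from polyrearrange.errors import ValidationError
from polyrearrange.formats_io import RepeatCopy


def copy(family="famX", superfamily="Gypsy", chrom="Cq1A", start=0, end=100,
         complete=True, genome="tetraploid", sub="A"):
    return RepeatCopy(family, superfamily, chrom, start, end, complete, genome, sub)


class TestSummarize:
    def test_overlapping_copies_merge_for_bp_but_count_raw(self):
        copies = [copy(start=0, end=100), copy(start=50, end=150)]
        (sub_a, whole) = repd.summarize_repeats(copies)
        assert sub_a.partition == "subgenome_A"
        assert sub_a.total_bp == 150
        assert sub_a.n_copies == 2

    def test_sum_raw_policy_keeps_double_counting(self):
        copies = [copy(start=0, end=100), copy(start=50, end=150)]
        (sub_a, _) = repd.summarize_repeats(copies, merge_policy="sum-raw")
        assert sub_a.total_bp == 200

    def test_empty_annotation(self):
        assert repd.summarize_repeats([]) == []

    def test_unknown_chromosome_rejected(self):
        with pytest.raises(ValidationError):
            repd.summarize_repeats([copy()], known_chroms={"Cq9A"})

    def test_partition_sums_to_whole(self, genome):
        stats = repd.summarize_repeats(genome.repeats)
        frame = repd.stats_frame(stats)
        for family in frame.family.unique():
            fam = frame[frame.family == family]
            whole = fam[fam.partition == "whole"]
            subs = fam[fam.partition.str.startswith("subgenome_")]
            if whole.empty:
                continue
            assert whole.n_copies.iloc[0] == subs.n_copies.sum()
            assert whole.total_bp.iloc[0] == subs.total_bp.sum()


class TestTeSpaceAttribution:
    def test_subgenome_difference_and_explained_fraction(self):
        te_diff, pct, contrib = repd.te_space_attribution(
            bp_A=323_470_441,
            bp_B=459_398_589,
            size_diff_bp=139_262_428,
            superfamily_deltas={"LTR": 112_037_747},
        )
        assert te_diff == 135_928_148
        assert pct == pytest.approx(97.61, abs=0.005)
        assert contrib.loc[0, "pct_of_te_diff"] == pytest.approx(82.42, abs=0.005)

    def test_equal_subgenomes(self):
        te_diff, pct, _ = repd.te_space_attribution(100, 100, 50)
        assert te_diff == 0 and pct == 0.0

    def test_zero_size_difference_is_na(self):
        _, pct, _ = repd.te_space_attribution(100, 200, 0)
        assert np.isnan(pct)


class TestEnrichment:
    def _stats(self, counts):
        """counts: {family: (superfamily, copies_A, copies_B)}"""
        out = []
        for fam, (sf, a, b) in counts.items():
            for part, n in (("subgenome_A", a), ("subgenome_B", b), ("whole", a + b)):
                out.append(repd.FamilyStats(fam, sf, part, n, max(n, 1) * 1000, n))
        return out

    def test_boundary_twofold_is_enriched(self):
        calls = repd.ltr_family_enrichment(
            self._stats({"f": ("Gypsy", 100, 200)}), avg_copy_threshold=0
        )
        assert calls[0].enrichment == "B_enriched"
        assert calls[0].log2fc == pytest.approx(1.0)

    def test_zero_side_is_specific(self):
        calls = repd.ltr_family_enrichment(
            self._stats({"f": ("Copia", 0, 50)}), avg_copy_threshold=0
        )
        assert calls[0].enrichment == "B_specific"

    def test_small_difference_not_enriched(self):
        calls = repd.ltr_family_enrichment(
            self._stats({"f": ("Gypsy", 150, 160)}), avg_copy_threshold=0
        )
        assert calls[0].enrichment == "not_enriched"

    def test_highly_repeated_above_mean_ltr_copy_number(self):
        stats = self._stats(
            {"big": ("Gypsy", 500, 600), "small": ("Copia", 10, 20)}
        )
        calls = {c.family: c for c in repd.ltr_family_enrichment(stats)}
        # default threshold = mean whole-genome copies = (1100 + 30) / 2
        assert calls["big"].highly_repeated
        assert not calls["small"].highly_repeated

    def test_non_ltr_superfamilies_ignored(self):
        calls = repd.ltr_family_enrichment(
            self._stats({"s": ("SINE", 100, 400)}), avg_copy_threshold=0
        )
        assert calls == []

    @settings(max_examples=60, deadline=None)
    @given(
        a=st.integers(min_value=0, max_value=2000),
        b=st.integers(min_value=0, max_value=2000),
    )
    def test_swapping_subgenomes_mirrors_classification(self, a, b):
        if a == 0 and b == 0:
            return
        fwd = repd.ltr_family_enrichment(
            self._stats({"f": ("Gypsy", a, b)}), avg_copy_threshold=0
        )
        rev = repd.ltr_family_enrichment(
            self._stats({"f": ("Gypsy", b, a)}), avg_copy_threshold=0
        )
        mirror = {
            "A_enriched": "B_enriched", "B_enriched": "A_enriched",
            "A_specific": "B_specific", "B_specific": "A_specific",
            "not_enriched": "not_enriched",
        }
        assert rev[0].enrichment == mirror[fwd[0].enrichment]
        if a > 0 and b > 0:
            assert rev[0].log2fc == pytest.approx(-fwd[0].log2fc)

    def test_planted_bias_recovered_across_seeds(self):
        from polyrearrange import synthetic_data as synth

        for seed in range(5):
            g = synth.simulate_genomes(
                synth.SimConfig(seed=seed, planted_events=[])
            )
            stats = repd.summarize_repeats(g.repeats)
            calls = {c.family: c for c in repd.ltr_family_enrichment(stats)}
            for fam, want in g.truth.family_truth.items():
                if fam in calls:
                    assert calls[fam].enrichment == want, (seed, fam)


class TestWindowDensity:
    def test_counts_by_start_window(self):
        copies = [copy(start=s, end=s + 10) for s in (0, 10, 999_999)]
        df = repd.window_density(copies, {"Cq1A": 2_500_000})
        assert df.loc[0, "count"] == 3  # all three start in [0, 1 Mb)
        assert df["count"].sum() == 3
        assert len(df) == 3  # last partial window kept

    def test_straddling_feature_assigned_to_start_window(self):
        copies = [copy(start=999_990, end=1_000_050)]
        df = repd.window_density(copies, {"Cq1A": 2_000_000})
        assert df.loc[0, "count"] == 1 and df.loc[1, "count"] == 0

    def test_empty_chromosome_all_zero(self):
        df = repd.window_density([], {"Cq1A": 3_200_000})
        assert len(df) == 4 and (df["count"] == 0).all()


class TestDynamicsVsDiploid:
    def test_reduction_counted(self, genome):
        stats = repd.summarize_repeats(genome.repeats)
        df, summary = repd.dynamics_vs_diploid(
            stats, stats, "subgenome_B", "diploidB"
        )
        gypsy = df[df.superfamily == "Gypsy"].iloc[0]
        # planted: B has 480 Gypsy copies vs 590 in the diploid relative
        assert gypsy.delta_copies == 480 - 590
        assert gypsy.label == "contraction"
        assert 0 <= summary["fraction_reduction"] <= 1

    def test_equal_inputs_zero_deltas(self):
        stats = [repd.FamilyStats("f", "Gypsy", "subgenome_B", 10, 1000, 10),
                 repd.FamilyStats("f", "Gypsy", "diploidB", 10, 1000, 10)]
        df, summary = repd.dynamics_vs_diploid(
            stats, stats, "subgenome_B", "diploidB"
        )
        assert (df.delta_copies == 0).all()
        assert np.isnan(summary["fraction_reduction"])

    def test_unshared_superfamily_flagged(self):
        sub = [repd.FamilyStats("f", "Gypsy", "subgenome_B", 10, 1000, 10)]
        dip = [repd.FamilyStats("g", "Copia", "diploidB", 5, 500, 5)]
        df, _ = repd.dynamics_vs_diploid(sub, dip, "subgenome_B", "diploidB")
        assert set(df[~df.shared].superfamily) == {"Gypsy", "Copia"}
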