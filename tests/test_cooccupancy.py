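import numpy as np
import pandas as pd
import pytest

from cooccmap import (
    GenomeAnnotation,
    Interval,
    cooccupancy_fraction,
    gene_binding_sets,
    overlap_length,
    peak_level_overlap,
    venn_counts,
)

from conftest import make_gene, random_intervals


class TestVennCounts:
    def test_enumerable_example(self):
        universe = {f"g{i}" for i in range(1, 11)}
        counts = venn_counts(
            {"g1", "g2", "g3", "g4"}, {"g1", "g2", "g3"}, {"g1", "g2"}, universe
        )
        assert counts["abc"] == 2
        assert counts["ab"] == 1
        assert counts["a_only"] == 1
        assert counts["outside"] == 6
        assert sum(counts.values()) == 10

    def test_disjoint_sets(self):
        counts = venn_counts({"a"}, {"b"}, {"c"}, {"a", "b", "c", "d"})
        assert counts["ab"] == counts["ac"] == counts["bc"] == counts["abc"] == 0
        assert counts["outside"] == 1

    def test_identical_sets(self):
        s = {"a", "b"}
        counts = venn_counts(s, s, s, s | {"c"})
        assert counts["abc"] == 2
        assert sum(v for k, v in counts.items() if k not in ("abc", "outside")) == 0

    def test_element_outside_universe_raises(self):
        with pytest.raises(ValueError, match="outside the universe"):
            venn_counts({"x"}, set(), set(), {"a"})

    def test_matches_brute_force_on_random_sets(self, rng):
        universe = [f"g{i}" for i in range(5000)]
        a = set(rng.choice(universe, 1500, replace=False))
        b = set(rng.choice(universe, 1200, replace=False))
        c = set(rng.choice(universe, 800, replace=False))
        counts = venn_counts(a, b, c, universe)
        brute = {"abc": 0, "ab": 0, "ac": 0, "bc": 0,
                 "a_only": 0, "b_only": 0, "c_only": 0, "outside": 0}
        for g in universe:
            key = ("a" if g in a else "") + ("b" if g in b else "") + ("c" if g in c else "")
            brute[{"abc": "abc", "ab": "ab", "ac": "ac", "bc": "bc",
                   "a": "a_only", "b": "b_only", "c": "c_only", "": "outside"}[key]] += 1
        assert counts == brute


class TestCooccupancyFraction:
    def frame(self, n_den=294, n_num=283, n_extra=500):
        rows = []
        for i in range(n_den):
            rows.append(
                {"foxp3_bound": i < n_num, "cxxc1_bound": True, "bd_reduced": True}
            )
        for i in range(n_extra):
            rows.append(
                {"foxp3_bound": i % 2 == 0, "cxxc1_bound": i % 3 == 0, "bd_reduced": False}
            )
        frame = pd.DataFrame(rows)
        frame["k4me3_enriched"] = False
        frame.index = pd.Index([f"g{i}" for i in range(len(frame))], name="gene_id")
        return frame

    def test_printed_ratio(self):
        num, den, frac, pct = cooccupancy_fraction(
            self.frame(), ["foxp3_bound"], ["cxxc1_bound", "bd_reduced"]
        )
        assert (num, den) == (283, 294)
        assert frac == pytest.approx(283 / 294)
        assert pct == "96%"

    def test_full_overlap_is_one(self):
        num, den, frac, pct = cooccupancy_fraction(
            self.frame(10, 10, 0), ["foxp3_bound"], ["cxxc1_bound", "bd_reduced"]
        )
        assert (num, den, frac, pct) == (10, 10, 1.0, "100%")

    def test_empty_denominator_raises(self):
        with pytest.raises(ValueError, match="denominator"):
            cooccupancy_fraction(
                self.frame(0, 0, 10), ["foxp3_bound"], ["cxxc1_bound", "bd_reduced"]
            )

    def test_numerator_forced_subset_of_denominator(self):
        # numerator conjunction is applied on top of the denominator mask
        frame = self.frame(50, 20, 100)
        num, den, frac, _ = cooccupancy_fraction(
            frame, ["foxp3_bound"], ["bd_reduced"]
        )
        assert num <= den == 50

    def test_invariant_to_row_order(self):
        frame = self.frame()
        shuffled = frame.sample(frac=1.0, random_state=0)
        assert cooccupancy_fraction(
            frame, ["foxp3_bound"], ["cxxc1_bound", "bd_reduced"]
        ) == cooccupancy_fraction(
            shuffled, ["foxp3_bound"], ["cxxc1_bound", "bd_reduced"]
        )


class TestGeneBindingSets:
    def test_promoter_peak_sets_single_flag(self, small_annotation):
        # gA promoter window [8000, 12000)
        sets = gene_binding_sets(
            [Interval("chr1", 8_500, 8_700)], [], [], small_annotation
        )
        assert bool(sets.loc["gA", "foxp3_bound"])
        assert not sets.loc["gA", ["cxxc1_bound", "k4me3_enriched", "bd_reduced"]].any()
        assert not sets.loc["gB"].any()

    def test_gene_body_peak_tf_vs_k4_modes(self, small_annotation):
        body_peak = [Interval("chr1", 13_000, 13_500)]  # gA intron
        sets = gene_binding_sets(body_peak, [], body_peak, small_annotation)
        assert bool(sets.loc["gA", "foxp3_bound"])  # gene_or_promoter
        assert not sets.loc["gA", "k4me3_enriched"]  # promoter_only

    def test_no_peaks_all_false(self, small_annotation):
        sets = gene_binding_sets([], [], [], small_annotation)
        assert not sets.to_numpy().any()

    def test_matches_brute_force(self, rng):
        genes = [
            make_gene(f"g{i}", "chr1", "+", 40_000 * i + 10_000, 40_000 * i + 20_000)
            for i in range(10)
        ]
        ann = GenomeAnnotation(genes=genes)
        foxp3 = random_intervals(rng, 40, n_chroms=1, span=420_000, max_len=2_000)
        k4 = random_intervals(rng, 40, n_chroms=1, span=420_000, max_len=2_000)
        sets = gene_binding_sets(foxp3, [], k4, ann)
        for g in genes:
            win = g.promoter_window(2000)
            expect_f = any(
                overlap_length(p, win) >= 1 or overlap_length(p, g.span) >= 1
                for p in foxp3
            )
            expect_k = any(overlap_length(p, win) >= 1 for p in k4)
            assert bool(sets.loc[g.gene_id, "foxp3_bound"]) == expect_f
            assert bool(sets.loc[g.gene_id, "k4me3_enriched"]) == expect_k


class TestPeakLevelOverlap:
    def test_all_contained(self):
        a = [Interval("chr1", 10, 20), Interval("chr1", 110, 120)]
        b = [Interval("chr1", 0, 200)]
        assert peak_level_overlap(a, b) == 1.0

    def test_disjoint_chromosomes(self):
        assert peak_level_overlap(
            [Interval("chr1", 0, 10)], [Interval("chr2", 0, 10)]
        ) == 0.0

    def test_empty_a_raises(self):
        with pytest.raises(ValueError):
            peak_level_overlap([], [Interval("chr1", 0, 10)])

    def test_asymmetry(self):
        a = [Interval("chr1", 0, 10), Interval("chr1", 100, 110)]
        b = [Interval("chr1", 0, 10)]
        assert peak_level_overlap(a, b) == 0.5
        assert peak_level_overlap(b, a) == 1.0

    def test_each_peak_counted_once(self):
        a = [Interval("chr1", 0, 100)]
        b = [Interval("chr1", 10, 20), Interval("chr1", 30, 40)]
        assert peak_level_overlap(a, b) == 1.0

    def test_matches_brute_force(self, rng):
        a = random_intervals(rng, 300)
        b = random_intervals(rng, 300)
        expected = sum(
            any(overlap_length(x, y) >= 1 for y in b) for x in a
        ) / len(a)
        assert peak_level_overlap(a, b) == pytest.approx(expected)
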