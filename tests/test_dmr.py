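"""Fisher's exact test, DMR calling, merging, annotation and DMG rules."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from dmrkit import (
    annotate_dmrs,
    call_dmr_bins,
    compare_bins,
    fisher_exact,
    identify_dmgs,
    intersect_gene_sets,
    merge_dmrs,
)
from dmrkit.errors import ValidationError

from conftest import make_annotation, make_track


def enumeration_p(a, b, c, d):
    """Exact-rational two-sided p by brute-force hypergeometric enumeration."""
    n1, n2, K = a + b, c + d, a + c
    if n1 == 0 or n2 == 0 or K == 0 or K == n1 + n2:
        return Fraction(1)
    w_obs = comb(n1, a) * comb(n2, c)
    num = 0
    total = 0
    for k in range(max(0, K - n2), min(K, n1) + 1):
        w = comb(n1, k) * comb(n2, K - k)
        total += w
        if w * 10**7 <= w_obs * (10**7 + 1):
            num += w
    return Fraction(num, total)


class TestFisherExact:
    def test_balanced_table_p_one(self):
        assert fisher_exact([[5, 5], [5, 5]]) == 1.0

    def test_maximally_skewed_table(self):
        # margins (10,10;10,10): only k=0 and k=10 are as extreme, each 1/184756
        assert fisher_exact([[10, 0], [0, 10]]) == pytest.approx(
            2 / 184756, rel=1e-9
        )

    def test_symmetric_moderate_table(self):
        # doubled lower tail of the (10,10;10,10) hypergeometric at k=3
        assert fisher_exact([[3, 7], [7, 3]]) == pytest.approx(
            33052 / 184756, rel=1e-9
        )

    def test_zero_margin_is_uninformative(self):
        assert fisher_exact([[1, 0], [0, 0]]) == 1.0
        assert fisher_exact([[0, 0], [3, 4]]) == 1.0
        assert fisher_exact([[0, 3], [0, 4]]) == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            fisher_exact([[-1, 2], [3, 4]])

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.tuples(*[st.integers(0, 60)] * 4))
    def test_matches_exact_enumeration(self, table):
        a, b, c, d = table
        p = fisher_exact([[a, b], [c, d]])
        assert 0.0 < p <= 1.0
        assert p == pytest.approx(float(enumeration_p(a, b, c, d)), abs=1e-10)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.tuples(*[st.integers(0, 200)] * 4))
    def test_matches_scipy_on_larger_tables(self, table):
        a, b, c, d = table
        p = fisher_exact([[a, b], [c, d]])
        p_scipy = scipy.stats.fisher_exact([[a, b], [c, d]])[1]
        assert p == pytest.approx(p_scipy, abs=1e-9)


def _comparison_frame(rows):
    cols = ["chrom", "start", "end", "context", "level_a", "level_b", "delta",
            "n_meth_a", "n_unmeth_a", "n_meth_b", "n_unmeth_b", "p_value"]
    return pd.DataFrame(rows, columns=cols)


class TestCallDmrBins:
    def _row(self, context, delta, p):
        return ("chr1", 0, 100, context, 0.3, 0.3 + delta, delta, 10, 10, 10, 10, p)

    def test_chg_bin_above_threshold_called_hyper(self):
        out = call_dmr_bins(_comparison_frame([self._row("CHG", 0.35, 0.001)]))
        assert len(out) == 1
        assert out.loc[0, "direction"] == "hyper"

    def test_fails_alpha(self):
        out = call_dmr_bins(_comparison_frame([self._row("CHG", 0.35, 0.02)]))
        assert out.empty

    def test_cg_threshold_is_stricter(self):
        out = call_dmr_bins(_comparison_frame([self._row("CG", 0.45, 1e-6)]))
        assert out.empty

    def test_hypo_direction(self):
        out = call_dmr_bins(_comparison_frame([self._row("CHH", -0.2, 1e-4)]))
        assert out.loc[0, "direction"] == "hypo"

    def test_raising_thresholds_never_adds_calls(self):
        rng = np.random.default_rng(5)
        rows = [
            self._row("CHG", float(rng.uniform(-0.8, 0.8)), float(rng.uniform(0, 0.05)))
            for _ in range(300)
        ]
        comp = _comparison_frame(rows)
        base = len(call_dmr_bins(comp))
        assert len(call_dmr_bins(comp, {"CHG": 0.5})) <= base
        assert len(call_dmr_bins(comp, alpha=0.001)) <= base


def _dmr_frame(rows):
    cols = ["chrom", "start", "end", "context", "direction", "min_p", "mean_delta", "n_bins"]
    return pd.DataFrame(rows, columns=cols)


class TestMergeDmrs:
    def test_gap_within_200_merges(self):
        dmrs = _dmr_frame(
            [
                ("chr1", 1000, 1100, "CHG", "hyper", 1e-4, 0.4, 1),
                ("chr1", 1250, 1350, "CHG", "hyper", 1e-3, 0.5, 1),
            ]
        )
        out = merge_dmrs(dmrs, 200)
        assert len(out) == 1
        assert (out.loc[0, "start"], out.loc[0, "end"]) == (1000, 1350)
        assert out.loc[0, "min_p"] == 1e-4
        assert out.loc[0, "n_bins"] == 2
        assert out.loc[0, "mean_delta"] == pytest.approx(0.45)

    def test_gap_exactly_200_merges(self):
        dmrs = _dmr_frame(
            [
                ("chr1", 1000, 1100, "CHG", "hyper", 1e-4, 0.4, 1),
                ("chr1", 1300, 1400, "CHG", "hyper", 1e-3, 0.4, 1),
            ]
        )
        assert len(merge_dmrs(dmrs, 200)) == 1

    def test_gap_beyond_200_stays_split(self):
        dmrs = _dmr_frame(
            [
                ("chr1", 1000, 1100, "CHG", "hyper", 1e-4, 0.4, 1),
                ("chr1", 1350, 1450, "CHG", "hyper", 1e-3, 0.4, 1),
            ]
        )
        assert len(merge_dmrs(dmrs, 200)) == 2

    def test_opposite_directions_never_merge(self):
        dmrs = _dmr_frame(
            [
                ("chr1", 1000, 1100, "CHG", "hyper", 1e-4, 0.4, 1),
                ("chr1", 1150, 1250, "CHG", "hypo", 1e-3, -0.4, 1),
            ]
        )
        assert len(merge_dmrs(dmrs, 200)) == 2

    def test_contexts_kept_separate(self):
        dmrs = _dmr_frame(
            [
                ("chr1", 1000, 1100, "CHG", "hyper", 1e-4, 0.4, 1),
                ("chr1", 1100, 1200, "CHH", "hyper", 1e-3, 0.2, 1),
            ]
        )
        assert len(merge_dmrs(dmrs, 200)) == 2

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.integers(0, 100_000))
    def test_merged_output_disjoint_sorted_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 60))
        starts = np.sort(rng.choice(np.arange(0, 500) * 100, size=n, replace=False))
        direction = rng.choice(["hyper", "hypo"], size=n)
        sign = np.where(direction == "hyper", 1.0, -1.0)
        dmrs = _dmr_frame(
            [
                ("chr1", int(s), int(s) + 100, "CHG", d, 1e-3, 0.4 * sg, 1)
                for s, d, sg in zip(starts, direction, sign)
            ]
        )
        merged = merge_dmrs(dmrs, 200)
        again = merge_dmrs(merged, 200)
        pd.testing.assert_frame_equal(
            merged.sort_values(["chrom", "start", "direction"], ignore_index=True),
            again.sort_values(["chrom", "start", "direction"], ignore_index=True),
        )
        for direction in ("hyper", "hypo"):
            grp = merged[merged["direction"] == direction]
            assert grp["start"].is_monotonic_increasing
            assert (grp["start"].to_numpy()[1:] - grp["end"].to_numpy()[:-1] > 200).all()
        assert int(merged["n_bins"].sum()) == n


class TestAnnotateDmrs:
    def _dmr(self, start=1000, end=1100):
        return _dmr_frame([("chr1", start, end, "CHG", "hyper", 1e-4, 0.4, 1)])

    def test_long_te_wins(self):
        ann = make_annotation([("chr1", 900, 1500, "TE", "te1")])  # 600 bp
        out = annotate_dmrs(self._dmr(), ann)
        assert out.loc[0, "feature_class"] == "TE"

    def test_short_te_falls_through_to_intergenic(self):
        ann = make_annotation([("chr1", 900, 1300, "TE", "te1")])  # 400 bp
        out = annotate_dmrs(self._dmr(), ann)
        assert out.loc[0, "feature_class"] == "intergenic"

    def test_teg_outranks_gene(self):
        ann = make_annotation(
            [("chr1", 900, 2000, "gene", "g1"), ("chr1", 950, 1600, "TEG", "teg1")]
        )
        out = annotate_dmrs(self._dmr(), ann)
        assert out.loc[0, "feature_class"] == "TEG"

    def test_te_boundary_is_strict(self):
        ann = make_annotation([("chr1", 1000, 1500, "TE", "te1")])  # exactly 500 bp
        out = annotate_dmrs(self._dmr(), ann)
        assert out.loc[0, "feature_class"] == "intergenic"

    def test_no_overlap_is_intergenic(self):
        ann = make_annotation([("chr1", 5000, 9000, "gene", "g1")])
        out = annotate_dmrs(self._dmr(), ann)
        assert out.loc[0, "feature_class"] == "intergenic"


class TestIdentifyDmgs:
    @pytest.mark.parametrize(
        "gene_start,gene_end,expected",
        [
            (1015, 2000, True),   # 85/100 overlap
            (1020, 2000, False),  # exactly 80%: strict rule
            (1025, 2000, False),  # 75/100
        ],
    )
    def test_strict_eighty_percent_rule(self, gene_start, gene_end, expected):
        dmrs = _dmr_frame([("chr1", 1000, 1100, "CHG", "hypo", 1e-4, -0.4, 1)])
        ann = make_annotation([("chr1", gene_start, gene_end, "gene", "g1")])
        dmgs = identify_dmgs(dmrs, ann)
        assert (len(dmgs) == 1) is expected

    def test_split_across_two_genes_nominates_none(self):
        dmrs = _dmr_frame([("chr1", 1000, 1100, "CHG", "hypo", 1e-4, -0.4, 1)])
        ann = make_annotation(
            [("chr1", 500, 1050, "gene", "g1"), ("chr1", 1050, 1600, "gene", "g2")]
        )
        assert identify_dmgs(dmrs, ann).empty

    def test_one_dmr_nominates_single_best_gene(self):
        dmrs = _dmr_frame([("chr1", 1000, 1100, "CHG", "hypo", 1e-4, -0.4, 1)])
        ann = make_annotation(
            [("chr1", 500, 1090, "gene", "g1"), ("chr1", 1005, 1600, "gene", "g2")]
        )
        dmgs = identify_dmgs(dmrs, ann)
        assert dmgs["gene_id"].tolist() == ["g2"]  # 95 bp beats 90 bp


class TestIntersectGeneSets:
    def test_partial_overlap(self):
        out = intersect_gene_sets({"g1", "g2", "g3"}, {"g2", "g3", "g4"})
        assert out["n_shared"] == 2
        assert out["shared"] == ["g2", "g3"]

    def test_disjoint(self):
        assert intersect_gene_sets({"a"}, {"b"})["n_shared"] == 0

    def test_identical(self):
        out = intersect_gene_sets({"a", "b"}, {"b", "a"})
        assert out["n_shared"] == out["n_a"] == 2


class TestCompareBins:
    def test_identical_tracks_give_zero_delta_p_one(self):
        rows = [("chr1", 10 * i + 5, "+", "CHG", 3, 3) for i in range(8)]
        t = make_track(rows)
        comp = compare_bins(t, t, "CHG")
        assert (comp["delta"] == 0).all()
        assert (comp["p_value"] == 1.0).all()

    def test_swapping_samples_negates_deltas(self):
        rng = np.random.default_rng(9)
        rows_a, rows_b = [], []
        for i in range(60):
            pos = 10 * i + 5
            cov_a, cov_b = rng.poisson(20, 2) + 5
            rows_a.append(("chr1", pos, "+", "CHG", int(rng.binomial(cov_a, 0.3)), 0))
            rows_a[-1] = rows_a[-1][:4] + (rows_a[-1][4], cov_a - rows_a[-1][4])
            mb = int(rng.binomial(cov_b, 0.7))
            rows_b.append(("chr1", pos, "+", "CHG", mb, cov_b - mb))
        ta, tb = make_track(rows_a), make_track(rows_b)
        ab = compare_bins(ta, tb, "CHG")
        ba = compare_bins(tb, ta, "CHG")
        assert np.allclose(ab["delta"].to_numpy(), -ba["delta"].to_numpy())
        assert np.allclose(ab["p_value"].to_numpy(), ba["p_value"].to_numpy())
        hyper_ab = call_dmr_bins(ab)
        hyper_ba = call_dmr_bins(ba)
        assert (hyper_ab["direction"] == "hyper").sum() == (
            hyper_ba["direction"] == "hypo"
        ).sum()
        assert (hyper_ab["direction"] == "hypo").sum() == (
            hyper_ba["direction"] == "hyper"
        ).sum()

    def test_bins_eligible_in_one_sample_dropped(self):
        rows_a = [("chr1", 10 * i + 5, "+", "CHG", 3, 3) for i in range(8)]
        rows_b = rows_a[:3]  # only 3 cytosines: ineligible at min_cytosines=5
        comp = compare_bins(make_track(rows_a), make_track(rows_b), "CHG")
        assert comp.empty
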