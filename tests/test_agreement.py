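"""Agreement statistics: paired-t, ICC(A,1) vs oracles, Bland-Altman, strata."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hragree.agreement import (
    agreement_suite,
    bland_altman,
    decile_summary,
    icc_a1,
    icc_consistency,
    icc_from_table,
    icc_strength,
    mean_difference,
    participant_stratifier,
    stratified_agreement,
    zone_stratifier,
)
from hragree.errors import DegenerateDataError, InsufficientDataError
from hragree.hr_zones import Zone
from hragree.stream_io import Participant

from conftest import make_pairs
from oracles import icc_a1_bruteforce, mean_and_sd


class TestMeanDifference:
    def test_hand_computed_fixture(self):
        diffs = [-4, -6, -5, -7, -3]
        ref = [100] * 5
        pairs = make_pairs([r + d for r, d in zip(ref, diffs)], ref)
        res = mean_difference(pairs)
        mean, sd = mean_and_sd(diffs)
        assert res.mean_diff_bpm == pytest.approx(mean)  # -5.0
        assert res.se_bpm == pytest.approx(sd / math.sqrt(5))
        assert res.ci95[0] < res.mean_diff_bpm < res.ci95[1]
        assert res.p_value < 0.01

    def test_constant_differences_flagged_degenerate(self):
        pairs = make_pairs([95, 95, 95, 95], [100, 100, 100, 100])
        res = mean_difference(pairs)
        assert res.mean_diff_bpm == -5.0
        assert res.se_bpm == 0.0
        assert math.isnan(res.t_statistic) and math.isnan(res.p_value)
        assert res.degenerate

    def test_identical_values_also_degenerate(self):
        res = mean_difference(make_pairs([90, 91], [90, 91]))
        assert res.mean_diff_bpm == 0.0
        assert res.degenerate

    def test_too_few_pairs(self):
        with pytest.raises(InsufficientDataError):
            mean_difference(make_pairs([90], [88]))


class TestICC:
    #: fixed 6-epoch x 2-device table of small integers; expected value frozen
    #: from the brute-force sums-of-squares oracle (icc_a1_bruteforce) below.
    FIXED_TABLE = [[70, 72], [80, 79], [90, 94], [100, 97], [110, 113], [120, 118]]

    def test_fixed_table_matches_bruteforce_oracle(self):
        expected = icc_a1_bruteforce(self.FIXED_TABLE)
        res = icc_from_table(np.array(self.FIXED_TABLE, dtype=float))
        assert res.icc == pytest.approx(expected, abs=1e-10)
        assert res.ci95[0] <= res.icc <= res.ci95[1]

    def test_perfect_agreement_gives_one(self):
        pairs = make_pairs([70, 90, 110, 130], [70, 90, 110, 130])
        res = icc_a1(pairs)
        assert res.icc == pytest.approx(1.0)
        assert res.strength_label == "strong"

    def test_constant_offset_penalized_and_below_consistency_form(self):
        ref = [60, 80, 100, 120, 140, 160, 180]
        pairs = make_pairs([r - 10 for r in ref], ref)
        res = icc_a1(pairs)
        assert res.icc < 1.0
        assert res.icc < icc_consistency(pairs)

    @given(
        st.lists(
            st.tuples(st.integers(40, 200), st.integers(-30, 30)),
            min_size=3,
            max_size=20,
        )
    )
    def test_matches_bruteforce_on_random_tables(self, rows):
        table = [[float(r), float(r + d)] for r, d in rows]
        if np.ptp(np.asarray(table)) == 0:
            return
        expected = icc_a1_bruteforce(table)
        got = icc_from_table(np.array(table)).icc
        assert got == pytest.approx(expected, abs=1e-10)

    @given(
        st.lists(st.integers(50, 190), min_size=5, max_size=30),
        st.integers(1, 40),
    )
    def test_adding_offset_never_increases_icc(self, ref, offset):
        if len(set(ref)) < 2:
            return
        base = icc_a1(make_pairs(ref, ref)).icc
        shifted = icc_a1(make_pairs([r - offset for r in ref], ref)).icc
        assert shifted <= base + 1e-12

    def test_matches_pingouin_reference_implementation(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(42)
        ref = rng.uniform(60, 180, size=40)
        test = ref - 8 + rng.normal(0, 5, size=40)
        res = icc_from_table(np.column_stack([test, ref]))

        long = pd.DataFrame(
            {
                "targets": np.repeat(np.arange(40), 2),
                "raters": ["test", "ref"] * 40,
                "ratings": np.column_stack([test, ref]).ravel(),
            }
        )
        out = pg.intraclass_corr(long, targets="targets", raters="raters", ratings="ratings")
        row = out.set_index("Type").loc["ICC(A,1)"]  # single-measure absolute agreement
        assert res.icc == pytest.approx(row["ICC"], abs=1e-9)
        # pingouin reports its CI rounded to 2 decimals
        assert res.ci95[0] == pytest.approx(row["CI95"][0], abs=6e-3)
        assert res.ci95[1] == pytest.approx(row["CI95"][1], abs=6e-3)

    def test_zero_variance_is_degenerate(self):
        with pytest.raises(DegenerateDataError):
            icc_a1(make_pairs([80, 80, 80], [80, 80, 80]))

    def test_too_few_epochs(self):
        with pytest.raises(InsufficientDataError):
            icc_a1(make_pairs([80, 90], [80, 90]))


class TestICCStrength:
    @pytest.mark.parametrize(
        "value, label",
        [
            (0.83, "strong"),
            (0.71, "strong"),
            (0.7, "moderate"),  # boundary: closed interval is moderate
            (0.5, "moderate"),
            (0.49, "weak"),
            (-0.2, "weak"),
        ],
    )
    def test_labels(self, value, label):
        assert icc_strength(value) == label


class TestBlandAltman:
    def test_constant_differences_collapse_limits(self):
        res = bland_altman(make_pairs([95, 95, 95], [100, 100, 100]))
        assert res.bias_bpm == -5.0
        assert res.loa_lower_bpm == res.loa_upper_bpm == -5.0

    def test_limits_are_1_96_sd(self):
        # differences {-2, 0, 2, ...} chosen symmetric with known sd
        ref = [100] * 6
        diffs = [-2, -2, 0, 0, 2, 2]
        res = bland_altman(make_pairs([r + d for r, d in zip(ref, diffs)], ref))
        _, sd = mean_and_sd(diffs)
        assert res.bias_bpm == 0.0
        assert res.loa_upper_bpm == pytest.approx(1.96 * sd)
        assert res.loa_lower_bpm == pytest.approx(-1.96 * sd)

    def test_ten_pair_fixture_matches_hand_computation(self):
        ref = [72, 85, 93, 101, 110, 118, 126, 133, 141, 150]
        test = [70, 80, 90, 95, 104, 110, 118, 124, 130, 138]
        res = bland_altman(make_pairs(test, ref))
        diffs = [t - r for t, r in zip(test, ref)]
        mean, sd = mean_and_sd(diffs)
        assert res.bias_bpm == pytest.approx(mean)
        assert res.sd_diff_bpm == pytest.approx(sd)
        assert res.loa_lower_bpm == pytest.approx(mean - 1.96 * sd)
        assert res.pair_means_bpm[0] == pytest.approx((70 + 72) / 2)


class TestStratified:
    def test_single_stratum_equals_unstratified(self):
        pairs = make_pairs([80, 90, 100, 110], [85, 92, 101, 115])
        whole = agreement_suite(pairs)
        strata = stratified_agreement(pairs, lambda p: "all")
        assert strata["all"] == whole

    def test_small_stratum_reported_not_dropped(self):
        p1 = Participant("P01", 25.0)
        p2 = Participant("P02", 30.0)
        pairs = make_pairs([80, 90, 100], [82, 91, 99], participant=p1) + make_pairs(
            [70], [75], participant=p2
        )
        strata = stratified_agreement(pairs, participant_stratifier)
        assert strata["P02"].n == 1
        assert strata["P02"].mean_difference is None
        assert strata["P02"].notes  # reason recorded

    def test_strata_partition_pairs(self):
        pairs = make_pairs([80, 95, 100, 120], [85, 96, 99, 125])
        strata = stratified_agreement(pairs, zone_stratifier())
        assert sum(r.n for r in strata.values()) == len(pairs)

    def test_zone_stratum_uses_reference_value(self):
        # age 25 -> cutoff 97.5; reference decides the stratum, not test
        pairs = make_pairs([80], [100]) + make_pairs([100], [80])
        strata = stratified_agreement(pairs, zone_stratifier())
        assert strata[Zone.MVPA].n == 1
        assert strata[Zone.LOW].n == 1


class TestDeciles:
    def test_rank_partition_of_twenty(self):
        ref = list(range(30, 50))
        pairs = make_pairs([r - 2 for r in ref], ref)
        dec = decile_summary(pairs)
        assert dec.decile_sizes == (2,) * 10
        assert dec.reference[0][0] == 30.0 and dec.reference[0][4] == 31.0
        assert dec.reference[9][0] == 48.0 and dec.reference[9][4] == 49.0

    def test_identical_values_collapse_summaries(self):
        pairs = make_pairs([90] * 12, [95] * 12)
        dec = decile_summary(pairs)
        for five in dec.reference:
            assert five == (95.0,) * 5

    def test_sizes_differ_by_at_most_one(self):
        ref = list(range(60, 60 + 23))
        dec = decile_summary(make_pairs(ref, ref))
        assert max(dec.decile_sizes) - min(dec.decile_sizes) <= 1
        assert sum(dec.decile_sizes) == 23

    def test_too_few_pairs(self):
        with pytest.raises(InsufficientDataError):
            decile_summary(make_pairs([80] * 9, [80] * 9))
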