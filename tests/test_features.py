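import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from melaccent import features as ft
from melaccent.score_io import Melody, Note, TimeSignature
from melaccent.synthetic import MelodyGenConfig, generate_melody
from conftest import melody_from_shorthand
from oracle_features import naive_feature_matrix


class TestRegistry:
    def test_exactly_43_features_and_group_sizes(self):
        assert len(ft.REGISTRY) == 43
        sizes = {g: 0 for g in ft.GROUPS}
        for s in ft.REGISTRY:
            sizes[s.group] += 1
        assert sizes == {
            "pitch_contour": 22, "tempo": 2, "timing": 11,
            "simple_phrasing": 4, "meter": 4,
        }

    def test_variant_groups(self):
        ids = {vg: set(fids) for vg, fids in ft.VARIANT_GROUPS.items()}
        assert sorted(map(sorted, ids.values())) == sorted(
            [[3, 4], [5, 6], [7, 8], [9, 10], [13, 14], [15, 16], [25, 26, 27], [32, 33]]
        )

    def test_registry_json_dump(self):
        import json

        entries = json.loads(ft.registry_json())
        assert len(entries) == 43
        assert entries[0]["name"] == "f0_pos_dist_mean"


class TestRunningPitchMean:
    def test_constant_pitch_gives_zero_distances(self):
        m = melody_from_shorthand([60] * 12)
        X = ft.extract_pitch_contour(m)
        assert (X["f0_pos_dist_mean"] == 0).all()
        assert (X["f0_neg_dist_mean"] == 0).all()

    def test_first_note_uses_own_pitch(self):
        m = melody_from_shorthand([72, 60])
        assert ft.running_pitch_mean(m, 0) == 72.0

    def test_window_of_recent_measures(self):
        # 12 preceding quarter C4s fill >= 2 measures; target E4 -> distance 4
        m = melody_from_shorthand([60] * 12 + [64])
        assert ft.running_pitch_mean(m, 12) == pytest.approx(60.0)
        X = ft.extract_pitch_contour(m)
        assert X["f0_pos_dist_mean"].iloc[12] == pytest.approx(4.0)

    def test_short_past_extends_to_ten_notes(self):
        # 11 sixteenths: the 2-measure window holds all, but with quarter
        # notes at a slow harmonic rhythm only the last 8 fit -> extend to 10
        pitches = [60, 62, 64, 65, 67, 69, 71, 72, 74, 76, 60]
        m = melody_from_shorthand(pitches, durations=[2] * 11)  # half notes, 2 bars = 4 notes
        got = ft.running_pitch_mean(m, 10)
        assert got == pytest.approx(np.mean(pitches[0:10]))


class TestPitchContour:
    def test_hand_traced_arpeggio_peak_and_leap(self):
        m = melody_from_shorthand([60, 64, 67, 64, 60])
        X = ft.extract_pitch_contour(m)
        assert X["f0_last_arp_up_p"].iloc[2] == 1
        assert X["f0_pos_peak_log"].iloc[2] == pytest.approx(2.0)  # log2(3+1)
        assert X["f0_aft_pos_leap_log"].iloc[1] == pytest.approx(math.log2(3))

    def test_chromatic_scale_has_no_leap_peak_arpeggio(self):
        m = melody_from_shorthand(list(range(60, 72)))
        X = ft.extract_pitch_contour(m)
        for col in X.columns:
            if col not in ("f0_pos_dist_mean", "f0_neg_dist_mean"):
                assert (X[col] == 0).all(), col

    def test_middle_interval_must_dominate_flanks(self):
        # up-down-up with middle |dST|=4 not larger than first |dST|=5
        m = melody_from_shorthand([60, 65, 61, 65])
        X = ft.extract_pitch_contour(m)
        assert (X["f0_aft_leap2_log"] == 0).all()
        assert (X["f0_bef_leap2_log"] == 0).all()

    def test_dominating_middle_leap_marks_both_notes(self):
        # down-up-down with dominating middle leap of 7 semitones
        m = melody_from_shorthand([64, 62, 69, 67])
        X = ft.extract_pitch_contour(m)
        w = math.log2(7 - 1)
        assert X["f0_bef_leap2_log"].iloc[1] == pytest.approx(w)
        assert X["f0_aft_leap2_log"].iloc[2] == pytest.approx(w)

    def test_peak_ties_do_not_count(self):
        m = melody_from_shorthand([60, 64, 64, 60])
        X = ft.extract_pitch_contour(m)
        assert (X["f0_pos_peak_p"] == 0).all()

    def test_pos_and_neg_peak_mutually_exclusive(self):
        m = generate_melody(MelodyGenConfig(notes_range=(40, 60)), 5)
        X = ft.extract_pitch_contour(m)
        assert ((X["f0_pos_peak_p"] + X["f0_neg_peak_p"]) <= 1).all()

    def test_transposition_invariance(self):
        m = generate_melody(MelodyGenConfig(notes_range=(40, 60)), 11)
        X1 = ft.extract_pitch_contour(m)
        X2 = ft.extract_pitch_contour(m.transposed(12))
        pd.testing.assert_frame_equal(X1, X2)

    def test_leap_log_weights_at_least_one(self):
        m = generate_melody(MelodyGenConfig(notes_range=(60, 80)), 3)
        X = ft.extract_pitch_contour(m)
        for col in ("f0_bef_pos_leap_log", "f0_bef_neg_leap_log",
                    "f0_aft_pos_leap_log", "f0_aft_neg_leap_log",
                    "f0_aft_leap2_log", "f0_bef_leap2_log"):
            nz = X[col][X[col] > 0]
            assert (nz >= 1.0 - 1e-12).all()


class TestTempo:
    @pytest.mark.parametrize("ioi,expected", [(40, 1.0), (100, 0.5), (500, 0.0),
                                              (50, 1.0), (150, 0.0)])
    def test_very_short_note_weight(self, ioi, expected):
        assert ft.very_short_note_weight(ioi) == pytest.approx(expected)

    def test_dr_ndr_equals_ioi(self, quarters_44):
        X = ft.extract_tempo(quarters_44)
        assert X["dr_ndr"].to_numpy() == pytest.approx(
            [n.ioi_ms for n in quarters_44.notes])

    def test_tempo_scaling_doubles_dr_ndr_keeps_binary_timing(self):
        from melaccent.score_io import compute_timing

        m = generate_melody(MelodyGenConfig(notes_range=(30, 40)), 21)
        slow = compute_timing(m, m.tempo_qpm / 2)
        assert ft.extract_tempo(slow)["dr_ndr"].to_numpy() == pytest.approx(
            2 * ft.extract_tempo(m)["dr_ndr"].to_numpy())
        binary = [c for c in ft.extract_timing(m).columns if c.endswith("_p")]
        pd.testing.assert_frame_equal(
            ft.extract_timing(m)[binary], ft.extract_timing(slow)[binary])


class TestTiming:
    def test_hand_traced_pattern(self):
        # IOIs [250,250,500,250,1000] at 120 qpm: durations in quarters
        m = melody_from_shorthand(
            [60] * 5, durations=[Fraction(1, 2), Fraction(1, 2), 1, Fraction(1, 2), 2],
            tempo=120)
        X = ft.extract_timing(m)
        assert list(np.flatnonzero(X["dr_short_before_p"])) == [2, 4]
        assert list(np.flatnonzero(X["dr_short2_before_p"])) == [2]
        assert list(np.flatnonzero(X["dr_short_after_p"])) == [2]
        assert list(np.flatnonzero(X["dr_short_between_long_p"])) == [3]
        assert list(np.flatnonzero(X["dr_long_after_p"])) == [1, 3]

    def test_isochronous_melody_all_zero(self):
        m = melody_from_shorthand([60, 64, 60, 67, 62, 65])
        X = ft.extract_timing(m)
        assert (X.to_numpy() == 0).all()

    def test_first_short_after_long(self):
        m = melody_from_shorthand(
            [60] * 4, durations=[2, Fraction(1, 2), Fraction(1, 2), 2], tempo=120)
        X = ft.extract_timing(m)
        assert list(np.flatnonzero(X["dr_first_short_p"])) == [1]

    def test_longest_five_weight(self):
        m = melody_from_shorthand([60] * 5, durations=[1, 1, 2, 1, 1], tempo=120)
        X = ft.extract_timing(m)
        assert X["dr_longest_five_p"].iloc[2] == 1
        assert X["dr_longest_five_w"].iloc[2] == pytest.approx(0.5)


class TestPhrasing:
    def test_melody_edges_marked(self, quarters_44):
        X = ft.extract_phrasing(quarters_44)
        assert X["ph_rest_before_or_first"].iloc[0] == 1
        assert X["ph_rest_after_or_last"].iloc[-1] == 1

    def test_rest_marks_neighbors(self):
        m = melody_from_shorthand([60, 62, 64, 65], rests_after=[1])
        X = ft.extract_phrasing(m)
        assert X["ph_rest_after_or_last"].iloc[1] == 1
        assert X["ph_rest_before_or_first"].iloc[2] == 1

    def test_boundaries_from_rest_and_last(self):
        m = melody_from_shorthand([60, 62, 64, 65], rests_after=[1])
        assert ft.punctuation_boundaries(m) == {1, 3}

    def test_stepwise_isochronous_has_only_final_boundary(self):
        m = melody_from_shorthand([60, 62, 64, 65, 67])
        assert ft.punctuation_boundaries(m) == {4}

    def test_long_note_with_leap_is_boundary(self):
        m = melody_from_shorthand(
            [60, 60, 60, 65, 65],
            durations=[Fraction(1, 2), Fraction(1, 2), 2, Fraction(1, 2), Fraction(1, 2)],
            tempo=120)
        assert 2 in ft.punctuation_boundaries(m)

    def test_units_mark_first_and_last(self):
        m = melody_from_shorthand([60, 62, 64, 65], rests_after=[1])
        X = ft.extract_phrasing(m)
        assert list(np.flatnonzero(X["ph_punct_first"])) == [0, 2]
        assert list(np.flatnonzero(X["ph_punct_last"])) == [1, 3]


class TestMeter:
    def test_level_table_44(self):
        periods = ft.metrical_levels(TimeSignature(4, 4))
        assert periods == (Fraction(1, 2), Fraction(1), Fraction(2), Fraction(4))

    def test_level_table_24_has_two_bar_level(self):
        periods = ft.metrical_levels(TimeSignature(2, 4))
        assert periods[2] == 2 and periods[3] == 4  # bar and 2 bars

    def test_unsupported_meter_lists_supported(self):
        with pytest.raises(ft.UnsupportedMeterError, match="5/4"):
            ft.metrical_levels(TimeSignature(5, 4))

    def test_extension_table(self):
        extra = {(5, 4): (Fraction(1, 2), Fraction(1), Fraction(5, 2), Fraction(5))}
        assert ft.metrical_levels(TimeSignature(5, 4), extra)[3] == 5

    def test_44_quarters_exclusive_pattern(self):
        m = melody_from_shorthand([60] * 8)
        X = ft.extract_meter(m)
        assert list(X["beat3"]) == [1, 0, 0, 0, 1, 0, 0, 0]
        assert list(X["beat2"]) == [0, 0, 1, 0, 0, 0, 1, 0]
        assert list(X["beat1"]) == [0, 1, 0, 1, 0, 1, 0, 1]
        assert (X["beat0"] == 0).all()

    def test_offbeat_sixteenth_is_off_grid(self):
        m = melody_from_shorthand(
            [60, 60, 60], durations=[Fraction(1, 4), Fraction(3, 4), 1])
        X = ft.extract_meter(m)
        assert X.iloc[1].sum() == 0  # onset at 0.25 quarter-beats

    def test_34_downbeats_alternate_two_bar_level(self):
        m = melody_from_shorthand([60] * 9, durations=[1] * 9, ts=(3, 4))
        X = ft.extract_meter(m)
        # downbeats at notes 0, 3, 6 -> measures 0, 1, 2
        assert X["beat3"].iloc[0] == 1 and X["beat2"].iloc[0] == 0
        assert X["beat3"].iloc[3] == 0 and X["beat2"].iloc[3] == 1
        assert X["beat3"].iloc[6] == 1

    def test_meter_columns_sum_at_most_one(self):
        m = generate_melody(MelodyGenConfig(notes_range=(40, 60)), 13)
        X = ft.extract_meter(m)
        assert (X.sum(axis=1) <= 1).all()


class TestExtractAll:
    def test_43_columns_in_registry_order(self, quarters_44):
        X = ft.extract_all([quarters_44])
        assert list(X.columns) == list(ft.FEATURE_NAMES)
        assert X.shape == (8, 43)

    def test_single_note_melody(self):
        m = melody_from_shorthand([60], tempo=120)
        X = ft.extract_all([m])
        assert len(X) == 1
        assert X["dr_ndr"].iloc[0] == pytest.approx(500)
        context_cols = [c for c in X.columns
                        if c not in ("dr_ndr", "f0_pos_dist_mean", "f0_neg_dist_mean",
                                     "ph_rest_before_or_first", "ph_rest_after_or_last",
                                     "ph_punct_first", "ph_punct_last",
                                     "beat0", "beat1", "beat2", "beat3",
                                     "dr_very_short_note")]
        assert (X[context_cols].to_numpy() == 0).all()

    def test_batch_rows_equal_single_melody_rows(self):
        m1 = generate_melody(MelodyGenConfig(notes_range=(20, 30)), 31, mel_id="a")
        m2 = generate_melody(MelodyGenConfig(notes_range=(20, 30)), 32, mel_id="b")
        batch = ft.extract_all([m1, m2])
        solo = ft.extract_all([m1])
        pd.testing.assert_frame_equal(batch.loc["a"], solo.loc["a"])

    def test_binary_columns_contain_only_01(self):
        m = generate_melody(MelodyGenConfig(notes_range=(50, 70)), 41)
        X = ft.extract_all([m])
        for col in ft.binary_feature_names():
            assert set(np.unique(X[col])) <= {0.0, 1.0}

    def test_gradual_columns_nonnegative(self):
        m = generate_melody(MelodyGenConfig(notes_range=(50, 70)), 43)
        X = ft.extract_all([m])
        assert (X.to_numpy() >= 0).all()

    def test_csv_round_trip(self, tmp_path, quarters_44):
        X = ft.extract_all([quarters_44])
        p = tmp_path / "f.csv"
        ft.write_feature_csv(X, p)
        again = ft.read_feature_csv(p)
        assert again.to_numpy() == pytest.approx(X.to_numpy())


class TestOracleEquivalence:
    def test_features_match_naive_reimplementation(self):
        """Every feature column equals a full-context per-note rescan on a
        batch of random melodies (exact for binary, 1e-9 for gradual)."""
        binary = set(ft.binary_feature_names())
        rng = np.random.default_rng(2024)
        config = MelodyGenConfig(notes_range=(15, 60), rest_prob=0.12)
        for _ in range(30):
            m = generate_melody(config, int(rng.integers(1 << 30)))
            X = ft.extract_melody(m)
            oracle = naive_feature_matrix(m)
            for col in ft.FEATURE_NAMES:
                got = X[col].to_numpy()
                want = np.array(oracle[col])
                if col in binary:
                    assert (got == want).all(), col
                else:
                    assert got == pytest.approx(want, abs=1e-9), col


@pytest.fixture(scope="module")
def corpus_features():
    config = MelodyGenConfig(n_melodies=8, notes_range=(40, 60))
    mels = [generate_melody(config, s, mel_id=f"m{s}") for s in range(8)]
    return ft.extract_all(mels)


class TestSelectVariants:
    def test_retains_exactly_34(self, corpus_features):
        rng = np.random.default_rng(0)
        y = rng.normal(size=len(corpus_features))
        X34, report = ft.select_variants(corpus_features, y)
        assert X34.shape[1] == 34
        assert len(report.retained_names) == 34
        assert len(corpus_features.columns) - X34.shape[1] == 9

    def test_log_variants_win_when_ratings_follow_log_weights(self, corpus_features):
        rng = np.random.default_rng(1)
        y = (corpus_features["f0_aft_pos_leap_log"]
             + corpus_features["f0_aft_neg_leap_log"]
             + 0.01 * rng.normal(size=len(corpus_features)))
        _, report = ft.select_variants(corpus_features, y)
        assert report.groups["aft_pos_leap"]["retained"] == "f0_aft_pos_leap_log"
        assert report.groups["aft_neg_leap"]["retained"] == "f0_aft_neg_leap_log"

    def test_tie_goes_to_lower_feature_id(self, corpus_features):
        # a constant rating vector makes every correlation 0 -> all ties
        y = np.ones(len(corpus_features))
        with pytest.warns(UserWarning):
            _, report = ft.select_variants(corpus_features, y)
        assert report.groups["bef_pos_leap"]["retained"] == "f0_bef_pos_leap_p"
        assert report.groups["short_before"]["retained"] == "dr_short_before_p"

    def test_misaligned_lengths_rejected(self, corpus_features):
        with pytest.raises(ValueError, match="length"):
            ft.select_variants(corpus_features, np.zeros(3))
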