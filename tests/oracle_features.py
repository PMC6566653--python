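"""Independent naive re-implementation of the 43 per-note features.

Deliberately unoptimized and structured differently from the package: one
function per note that re-scans the melody's full context each time, using
only the raw note lists.  Serves as the oracle for feature-equivalence tests.
"""

from __future__ import annotations

import math
from fractions import Fraction

from melaccent.features import METRICAL_LEVEL_TABLE


def naive_features_for_note(melody, i: int) -> dict[str, float]:
    notes = melody.notes
    n = len(notes)
    p = [nt.pitch_midi for nt in notes]
    ioi = [nt.ioi_ms for nt in notes]
    dur = [nt.duration_beats for nt in notes]
    out = {name: 0.0 for name in _ALL_NAMES}

    # 1/2 running-mean distances
    if i == 0:
        mean = float(p[0])
    else:
        bar = melody.signature_at_measure(notes[i].measure_index).bar_quarters
        lo = notes[i].onset_beats - 2 * bar
        window = [p[j] for j in range(i) if notes[j].onset_beats >= lo]
        if len(window) < 10:
            window = [p[j] for j in range(max(0, i - 10), i)]
        mean = sum(window) / len(window)
    out["f0_pos_dist_mean"] = max(0.0, p[i] - mean)
    out["f0_neg_dist_mean"] = max(0.0, mean - p[i])

    # leaps
    if i + 1 < n:
        d = p[i + 1] - p[i]
        if d > 2:
            out["f0_bef_pos_leap_p"] = 1.0
            out["f0_bef_pos_leap_log"] = math.log2(abs(d) - 1)
        if d < -2:
            out["f0_bef_neg_leap_p"] = 1.0
            out["f0_bef_neg_leap_log"] = math.log2(abs(d) - 1)
    if i >= 1:
        d = p[i] - p[i - 1]
        if d > 2:
            out["f0_aft_pos_leap_p"] = 1.0
            out["f0_aft_pos_leap_log"] = math.log2(abs(d) - 1)
        if d < -2:
            out["f0_aft_neg_leap_p"] = 1.0
            out["f0_aft_neg_leap_log"] = math.log2(abs(d) - 1)

    # features 11/12: note i as second (11) or first (12) note of the middle
    # interval of a zig-zag 4-note context with a dominating middle leap
    for role, name in ((2, "f0_aft_leap2_log"), (1, "f0_bef_leap2_log")):
        j = i - role  # context start
        if 0 <= j and j + 3 < n:
            d1, d2, d3 = p[j + 1] - p[j], p[j + 2] - p[j + 1], p[j + 3] - p[j + 2]
            leap = abs(d2) > 2
            dominant = abs(d2) > abs(d1) and abs(d2) > abs(d3)
            zig = (d1 > 0 > d2 and d3 > 0) or (d1 < 0 < d2 and d3 < 0)
            if leap and dominant and zig:
                out[name] = math.log2(abs(d2) - 1)

    # peaks / troughs
    if 1 <= i < n - 1:
        if p[i - 1] < p[i] > p[i + 1]:
            out["f0_pos_peak_p"] = 1.0
            out["f0_pos_peak_log"] = math.log2(abs(p[i] - p[i - 1]) + 1)
        if p[i - 1] > p[i] < p[i + 1]:
            out["f0_neg_peak_p"] = 1.0
            out["f0_neg_peak_log"] = math.log2(abs(p[i] - p[i - 1]) + 1)
    if 2 <= i < n - 1 and p[i] > max(p[i - 2], p[i - 1], p[i + 1]):
        out["f0_pos_peak2_p"] = 1.0
    if 3 <= i < n - 1 and p[i] > max(p[i - 3], p[i - 2], p[i - 1], p[i + 1]):
        out["f0_pos_peak3_p"] = 1.0

    # arpeggio edges
    def is_up(d):
        return d > 2

    def is_down(d):
        return d < -2

    if 1 <= i and i + 2 < n:
        d1, d2, d3 = p[i] - p[i - 1], p[i + 1] - p[i], p[i + 2] - p[i + 1]
        if not is_up(d1) and is_up(d2) and is_up(d3):
            out["f0_first_arp_up_p"] = 1.0
        if not is_down(d1) and is_down(d2) and is_down(d3):
            out["f0_first_arp_down_p"] = 1.0
    if 2 <= i and i + 1 < n:
        d1, d2, d3 = p[i - 1] - p[i - 2], p[i] - p[i - 1], p[i + 1] - p[i]
        if is_up(d1) and is_up(d2) and not is_up(d3):
            out["f0_last_arp_up_p"] = 1.0
        if is_down(d1) and is_down(d2) and not is_down(d3):
            out["f0_last_arp_down_p"] = 1.0

    # tempo
    out["dr_ndr"] = ioi[i]
    if 0 < ioi[i] < 50:
        out["dr_very_short_note"] = 1.0
    elif 50 <= ioi[i] <= 150:
        out["dr_very_short_note"] = (150 - ioi[i]) / 100
    # timing
    if i >= 1 and ioi[i - 1] < ioi[i]:
        out["dr_short_before_p"] = 1.0
        out["dr_short_before_rel"] = 1 - ioi[i - 1] / ioi[i]
        out["dr_short_before_log"] = abs(math.log(ioi[i - 1] / ioi[i]))
    if i >= 2 and dur[i - 1] == dur[i - 2] and max(ioi[i - 1], ioi[i - 2]) < ioi[i]:
        out["dr_short2_before_p"] = 1.0
    if (i >= 3 and dur[i - 1] == dur[i - 2] == dur[i - 3]
            and max(ioi[i - 1], ioi[i - 2], ioi[i - 3]) < ioi[i]):
        out["dr_short3_before_p"] = 1.0
    if i + 1 < n and ioi[i + 1] < ioi[i]:
        out["dr_short_after_p"] = 1.0
    if 1 <= i < n - 1 and ioi[i] < ioi[i - 1] and ioi[i + 1] < ioi[i - 1]:
        out["dr_first_short_p"] = 1.0
    if 2 <= i < n - 2 and ioi[i] > max(ioi[i - 2], ioi[i - 1], ioi[i + 1], ioi[i + 2]):
        out["dr_longest_five_p"] = 1.0
        w = 1 - (ioi[i - 2] + ioi[i - 1] + ioi[i + 1] + ioi[i + 2]) / (4 * ioi[i])
        out["dr_longest_five_w"] = max(0.0, w)
    if 1 <= i < n - 1 and ioi[i - 1] > ioi[i] < ioi[i + 1]:
        out["dr_short_between_long_p"] = 1.0
    if i + 1 < n and ioi[i + 1] > ioi[i]:
        out["dr_long_after_p"] = 1.0

    # phrasing
    if i == 0 or notes[i].preceded_by_rest:
        out["ph_rest_before_or_first"] = 1.0
    if i == n - 1 or notes[i].followed_by_rest:
        out["ph_rest_after_or_last"] = 1.0
    bounds = _naive_boundaries(melody)
    if i in bounds:
        out["ph_punct_last"] = 1.0
    if i == 0 or (i - 1) in bounds:
        out["ph_punct_first"] = 1.0

    # meter
    nt = notes[i]
    sig = melody.signature_at_measure(nt.measure_index)
    periods = METRICAL_LEVEL_TABLE[(sig.numerator, sig.denominator)]
    bar = sig.bar_quarters
    offq = nt.beat_in_measure * Fraction(4, sig.denominator)
    for lvl, name in ((3, "beat3"), (2, "beat2"), (1, "beat1"), (0, "beat0")):
        period = periods[lvl]
        if period > bar:
            hit = offq == 0 and (nt.measure_index * bar) % period == 0
        else:
            hit = offq % period == 0
        if hit:
            out[name] = 1.0
            break
    return out


def _naive_boundaries(melody) -> set[int]:
    notes = melody.notes
    n = len(notes)
    b = {n - 1}
    for i in range(n - 1):
        if notes[i].followed_by_rest:
            b.add(i)
        elif 0 < i < n - 1:
            long_enough = (notes[i].ioi_ms >= 2 * notes[i - 1].ioi_ms
                           and notes[i].ioi_ms >= 2 * notes[i + 1].ioi_ms)
            leap_after = abs(notes[i + 1].pitch_midi - notes[i].pitch_midi) > 2
            if long_enough and leap_after:
                b.add(i)
    return b


_ALL_NAMES = (
    "f0_pos_dist_mean", "f0_neg_dist_mean",
    "f0_bef_pos_leap_p", "f0_bef_pos_leap_log",
    "f0_bef_neg_leap_p", "f0_bef_neg_leap_log",
    "f0_aft_pos_leap_p", "f0_aft_pos_leap_log",
    "f0_aft_neg_leap_p", "f0_aft_neg_leap_log",
    "f0_aft_leap2_log", "f0_bef_leap2_log",
    "f0_pos_peak_p", "f0_pos_peak_log",
    "f0_neg_peak_p", "f0_neg_peak_log",
    "f0_pos_peak2_p", "f0_pos_peak3_p",
    "f0_first_arp_up_p", "f0_last_arp_up_p",
    "f0_first_arp_down_p", "f0_last_arp_down_p",
    "dr_ndr", "dr_very_short_note",
    "dr_short_before_p", "dr_short_before_rel", "dr_short_before_log",
    "dr_short2_before_p", "dr_short3_before_p",
    "dr_short_after_p", "dr_first_short_p",
    "dr_longest_five_p", "dr_longest_five_w",
    "dr_short_between_long_p", "dr_long_after_p",
    "ph_rest_before_or_first", "ph_rest_after_or_last",
    "ph_punct_first", "ph_punct_last",
    "beat0", "beat1", "beat2", "beat3",
)


def naive_feature_matrix(melody) -> dict[str, list[float]]:
    rows = [naive_features_for_note(melody, i) for i in range(len(melody.notes))]
    return {name: [r[name] for r in rows] for name in _ALL_NAMES}
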