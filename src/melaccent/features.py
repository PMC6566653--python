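"""Per-note accent features from the symbolic score.

43 features in five groups describe, for every sounded note, score properties
that make listeners hear the note as accented: position in the pitch contour
(distance from the running mean pitch, leaps, peaks, arpeggio edges), tempo
(the note's IOI and very-short-note weighting), local timing patterns (long
notes after runs of short ones, longest-of-five, and the inhibiting
short-before-long), simple phrasing (rests and boundaries of small melodic
units), and the metrical grid (four beat levels from sub-beat to two bars).

Several features exist in a binary and a gradual version; ``select_variants``
keeps, per variant group, the version that correlates best with the mean
ratings, reducing the 43 columns to 34.

Conventions shared by all features:

* a *leap* is an interval of more than 2 semitones;
* contexts never straddle melody boundaries — a truncated context yields 0;
* comparisons ("longest", "peak", "shorter") are strict, and "equally short"
  means identical notated duration;
* gradual weights are stored as magnitudes (>= 0); regression coefficients
  absorb direction;
* adjacency means adjacent *sounded* notes — rests do not break pitch or
  timing contexts (rest effects are carried by the phrasing features).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, asdict
from fractions import Fraction
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .score_io import Melody, TimeSignature

__all__ = [
    "FeatureSpec",
    "REGISTRY",
    "FEATURE_NAMES",
    "GROUPS",
    "VARIANT_GROUPS",
    "feature_groups",
    "binary_feature_names",
    "running_pitch_mean",
    "extract_pitch_contour",
    "extract_tempo",
    "extract_timing",
    "extract_phrasing",
    "extract_meter",
    "extract_melody",
    "extract_all",
    "punctuation_boundaries",
    "metrical_levels",
    "select_variants",
    "SelectionReport",
    "registry_json",
    "write_feature_csv",
    "read_feature_csv",
]

LEAP_SEMITONES = 2  # |interval| > 2 is a leap


@dataclass(frozen=True)
class FeatureSpec:
    feature_id: int
    name: str
    group: str  # pitch_contour | tempo | timing | simple_phrasing | meter
    output_kind: str  # binary | gradual
    variant_group: str | None
    formula_doc: str


def _spec(fid, name, group, kind, variant, doc) -> FeatureSpec:
    return FeatureSpec(fid, name, group, kind, variant, doc)


REGISTRY: tuple[FeatureSpec, ...] = (
    # -- pitch contour (22) --
    _spec(1, "f0_pos_dist_mean", "pitch_contour", "gradual", None,
          "max(0, pitch - running mean pitch) in semitones"),
    _spec(2, "f0_neg_dist_mean", "pitch_contour", "gradual", None,
          "max(0, running mean pitch - pitch) in semitones"),
    _spec(3, "f0_bef_pos_leap_p", "pitch_contour", "binary", "bef_pos_leap",
          "first note of an upward leap"),
    _spec(4, "f0_bef_pos_leap_log", "pitch_contour", "gradual", "bef_pos_leap",
          "first note of an upward leap, weight log2(|dST| - 1)"),
    _spec(5, "f0_bef_neg_leap_p", "pitch_contour", "binary", "bef_neg_leap",
          "first note of a downward leap"),
    _spec(6, "f0_bef_neg_leap_log", "pitch_contour", "gradual", "bef_neg_leap",
          "first note of a downward leap, weight log2(|dST| - 1)"),
    _spec(7, "f0_aft_pos_leap_p", "pitch_contour", "binary", "aft_pos_leap",
          "second note of an upward leap"),
    _spec(8, "f0_aft_pos_leap_log", "pitch_contour", "gradual", "aft_pos_leap",
          "second note of an upward leap, weight log2(|dST| - 1)"),
    _spec(9, "f0_aft_neg_leap_p", "pitch_contour", "binary", "aft_neg_leap",
          "second note of a downward leap"),
    _spec(10, "f0_aft_neg_leap_log", "pitch_contour", "gradual", "aft_neg_leap",
          "second note of a downward leap, weight log2(|dST| - 1)"),
    _spec(11, "f0_aft_leap2_log", "pitch_contour", "gradual", None,
          "4-note context, middle interval a leap strictly larger than its "
          "flanks, pattern up-down-up or down-up-down; log2(|dST| - 1) on the "
          "middle interval's second note"),
    _spec(12, "f0_bef_leap2_log", "pitch_contour", "gradual", None,
          "as feature 11 but weighted on the middle interval's first note"),
    _spec(13, "f0_pos_peak_p", "pitch_contour", "binary", "pos_peak",
          "strict local pitch maximum in a 3-note context"),
    _spec(14, "f0_pos_peak_log", "pitch_contour", "gradual", "pos_peak",
          "local maximum, weight log2(|dST| + 1) on the first interval"),
    _spec(15, "f0_neg_peak_p", "pitch_contour", "binary", "neg_peak",
          "strict local pitch minimum in a 3-note context"),
    _spec(16, "f0_neg_peak_log", "pitch_contour", "gradual", "neg_peak",
          "local minimum, weight log2(|dST| + 1) on the first interval"),
    _spec(17, "f0_pos_peak2_p", "pitch_contour", "binary", None,
          "strictly above two notes before and one after"),
    _spec(18, "f0_pos_peak3_p", "pitch_contour", "binary", None,
          "strictly above three notes before and one after"),
    _spec(19, "f0_first_arp_up_p", "pitch_contour", "binary", None,
          "first note of an upward arpeggio: previous interval not an up-leap, "
          "two following intervals both up-leaps"),
    _spec(20, "f0_last_arp_up_p", "pitch_contour", "binary", None,
          "last note of an upward arpeggio: two preceding up-leaps, next "
          "interval not an up-leap"),
    _spec(21, "f0_first_arp_down_p", "pitch_contour", "binary", None,
          "first note of a downward arpeggio"),
    _spec(22, "f0_last_arp_down_p", "pitch_contour", "binary", None,
          "last note of a downward arpeggio"),
    # -- tempo (2) --
    _spec(23, "dr_ndr", "tempo", "gradual", None, "the note's IOI in ms"),
    _spec(24, "dr_very_short_note", "tempo", "gradual", None,
          "1 for IOI < 50 ms, linear 1->0 for 50..150 ms, 0 above"),
    # -- timing (11) --
    _spec(25, "dr_short_before_p", "timing", "binary", "short_before",
          "long note with a shorter note immediately before"),
    _spec(26, "dr_short_before_rel", "timing", "gradual", "short_before",
          "as 25, weight 1 - IOI_short/IOI_long"),
    _spec(27, "dr_short_before_log", "timing", "gradual", "short_before",
          "as 25, weight |ln(IOI_short/IOI_long)|"),
    _spec(28, "dr_short2_before_p", "timing", "binary", None,
          "long note after two equally short notes"),
    _spec(29, "dr_short3_before_p", "timing", "binary", None,
          "long note after three equally short notes"),
    _spec(30, "dr_short_after_p", "timing", "binary", None,
          "long note with a shorter note immediately after"),
    _spec(31, "dr_first_short_p", "timing", "binary", None,
          "first of at least two short notes following a longer note"),
    _spec(32, "dr_longest_five_p", "timing", "binary", "longest_five",
          "strictly longest note centered in a 5-note context"),
    _spec(33, "dr_longest_five_w", "timing", "gradual", "longest_five",
          "as 32, weight 1 - mean(neighbor IOIs)/IOI_target, clipped at 0"),
    _spec(34, "dr_short_between_long_p", "timing", "binary", None,
          "note strictly shorter than both neighbors"),
    _spec(35, "dr_long_after_p", "timing", "binary", None,
          "note whose successor is strictly longer (inhibit feature)"),
    # -- simple phrasing (4) --
    _spec(36, "ph_rest_before_or_first", "simple_phrasing", "binary", None,
          "note after a rest, or the first note"),
    _spec(37, "ph_rest_after_or_last", "simple_phrasing", "binary", None,
          "note before a rest, or the last note"),
    _spec(38, "ph_punct_first", "simple_phrasing", "binary", None,
          "first note of a small melodic unit (punctuation)"),
    _spec(39, "ph_punct_last", "simple_phrasing", "binary", None,
          "last note of a small melodic unit (punctuation)"),
    # -- meter (4) --
    _spec(40, "beat0", "meter", "binary", None, "onset on the sub-beat grid only"),
    _spec(41, "beat1", "meter", "binary", None, "onset on the tactus grid"),
    _spec(42, "beat2", "meter", "binary", None, "onset on the half-bar or bar grid"),
    _spec(43, "beat3", "meter", "binary", None, "onset on the bar or 2-bar grid"),
)

FEATURE_NAMES: tuple[str, ...] = tuple(s.name for s in REGISTRY)
GROUPS: tuple[str, ...] = ("pitch_contour", "tempo", "timing", "simple_phrasing", "meter")

VARIANT_GROUPS: dict[str, tuple[int, ...]] = {}
for s in REGISTRY:
    if s.variant_group:
        VARIANT_GROUPS.setdefault(s.variant_group, ())
        VARIANT_GROUPS[s.variant_group] += (s.feature_id,)


def feature_groups(names: Sequence[str] | None = None) -> dict[str, list[str]]:
    """Map group name -> feature column names (optionally restricted)."""
    keep = set(names) if names is not None else None
    out: dict[str, list[str]] = {g: [] for g in GROUPS}
    for s in REGISTRY:
        if keep is None or s.name in keep:
            out[s.group].append(s.name)
    return out


def binary_feature_names() -> list[str]:
    return [s.name for s in REGISTRY if s.output_kind == "binary"]


def registry_json() -> str:
    return json.dumps([asdict(s) for s in REGISTRY], indent=1)


# -- pitch contour ----------------------------------------------------------

def running_pitch_mean(melody: Melody, index: int) -> float:
    """Mean pitch of the recent past: preceding notes within the previous two
    notated measures, extended backwards to at least 10 preceding notes.

    The first note has no past and returns its own pitch (so the distance
    features are 0 there).
    """
    notes = melody.notes
    if not 0 <= index < len(notes):
        raise IndexError(index)
    if index == 0:
        return float(notes[0].pitch_midi)
    target = notes[index]
    window = 2 * melody.signature_at_measure(target.measure_index).bar_quarters
    lo = target.onset_beats - window
    picked = [n.pitch_midi for n in notes[:index] if n.onset_beats >= lo]
    if len(picked) < 10:
        picked = [n.pitch_midi for n in notes[max(0, index - 10):index]]
    return float(np.mean(picked))


def _leap_log(dst: int) -> float:
    return math.log2(abs(dst) - 1)


def extract_pitch_contour(melody: Melody) -> pd.DataFrame:
    notes = melody.notes
    n = len(notes)
    p = [nt.pitch_midi for nt in notes]
    d = [p[i + 1] - p[i] for i in range(n - 1)]  # intervals
    cols = {s.name: np.zeros(n) for s in REGISTRY if s.group == "pitch_contour"}

    for i in range(n):
        rm = running_pitch_mean(melody, i)
        cols["f0_pos_dist_mean"][i] = max(0.0, p[i] - rm)
        cols["f0_neg_dist_mean"][i] = max(0.0, rm - p[i])

    def up_leap(x: int) -> bool:
        return x > LEAP_SEMITONES

    def down_leap(x: int) -> bool:
        return x < -LEAP_SEMITONES

    for i, dst in enumerate(d):
        if up_leap(dst):
            cols["f0_bef_pos_leap_p"][i] = 1
            cols["f0_bef_pos_leap_log"][i] = _leap_log(dst)
            cols["f0_aft_pos_leap_p"][i + 1] = 1
            cols["f0_aft_pos_leap_log"][i + 1] = _leap_log(dst)
        elif down_leap(dst):
            cols["f0_bef_neg_leap_p"][i] = 1
            cols["f0_bef_neg_leap_log"][i] = _leap_log(dst)
            cols["f0_aft_neg_leap_p"][i + 1] = 1
            cols["f0_aft_neg_leap_log"][i + 1] = _leap_log(dst)

    # features 11/12: 4-note context, middle interval a leap strictly larger
    # than both flanks, zig-zag direction pattern
    for j in range(n - 3):
        d1, d2, d3 = d[j], d[j + 1], d[j + 2]
        if abs(d2) <= LEAP_SEMITONES:
            continue
        if not (abs(d2) > abs(d1) and abs(d2) > abs(d3)):
            continue
        zigzag = (d1 > 0 and d2 < 0 and d3 > 0) or (d1 < 0 and d2 > 0 and d3 < 0)
        if not zigzag:
            continue
        w = _leap_log(d2)
        cols["f0_aft_leap2_log"][j + 2] = w
        cols["f0_bef_leap2_log"][j + 1] = w

    for i in range(1, n - 1):
        if p[i] > p[i - 1] and p[i] > p[i + 1]:
            cols["f0_pos_peak_p"][i] = 1
            cols["f0_pos_peak_log"][i] = math.log2(abs(d[i - 1]) + 1)
        if p[i] < p[i - 1] and p[i] < p[i + 1]:
            cols["f0_neg_peak_p"][i] = 1
            cols["f0_neg_peak_log"][i] = math.log2(abs(d[i - 1]) + 1)

    for i in range(2, n - 1):
        if p[i] > p[i - 1] and p[i] > p[i - 2] and p[i] > p[i + 1]:
            cols["f0_pos_peak2_p"][i] = 1
    for i in range(3, n - 1):
        if all(p[i] > p[i - k] for k in (1, 2, 3)) and p[i] > p[i + 1]:
            cols["f0_pos_peak3_p"][i] = 1

    # arpeggio edges, 4-note context
    for j in range(n - 3):
        d1, d2, d3 = d[j], d[j + 1], d[j + 2]
        if not up_leap(d1) and up_leap(d2) and up_leap(d3):
            cols["f0_first_arp_up_p"][j + 1] = 1
        if up_leap(d1) and up_leap(d2) and not up_leap(d3):
            cols["f0_last_arp_up_p"][j + 2] = 1
        if not down_leap(d1) and down_leap(d2) and down_leap(d3):
            cols["f0_first_arp_down_p"][j + 1] = 1
        if down_leap(d1) and down_leap(d2) and not down_leap(d3):
            cols["f0_last_arp_down_p"][j + 2] = 1

    return pd.DataFrame(cols)


# -- tempo ------------------------------------------------------------------

def very_short_note_weight(ioi_ms: float) -> float:
    """1 below 50 ms, linear down to 0 at 150 ms, 0 beyond."""
    if ioi_ms <= 0:
        return 0.0
    if ioi_ms < 50:
        return 1.0
    if ioi_ms <= 150:
        return (150.0 - ioi_ms) / 100.0
    return 0.0


def extract_tempo(melody: Melody) -> pd.DataFrame:
    ioi = np.array([nt.ioi_ms for nt in melody.notes])
    return pd.DataFrame({
        "dr_ndr": ioi,
        "dr_very_short_note": np.array([very_short_note_weight(x) for x in ioi]),
    })


# -- timing -----------------------------------------------------------------

def extract_timing(melody: Melody) -> pd.DataFrame:
    notes = melody.notes
    n = len(notes)
    ioi = [nt.ioi_ms for nt in notes]
    dur = [nt.duration_beats for nt in notes]
    cols = {s.name: np.zeros(n) for s in REGISTRY if s.group == "timing"}

    for i in range(n):
        if i >= 1 and ioi[i - 1] < ioi[i]:
            cols["dr_short_before_p"][i] = 1
            cols["dr_short_before_rel"][i] = 1 - ioi[i - 1] / ioi[i]
            cols["dr_short_before_log"][i] = abs(math.log(ioi[i - 1] / ioi[i]))
        if (i >= 2 and dur[i - 1] == dur[i - 2]
                and ioi[i - 1] < ioi[i] and ioi[i - 2] < ioi[i]):
            cols["dr_short2_before_p"][i] = 1
        if (i >= 3 and dur[i - 1] == dur[i - 2] == dur[i - 3]
                and all(ioi[i - k] < ioi[i] for k in (1, 2, 3))):
            cols["dr_short3_before_p"][i] = 1
        if i + 1 < n and ioi[i + 1] < ioi[i]:
            cols["dr_short_after_p"][i] = 1
        if (0 < i < n - 1 and ioi[i] < ioi[i - 1] and ioi[i + 1] < ioi[i - 1]):
            cols["dr_first_short_p"][i] = 1
        if 2 <= i < n - 2 and all(ioi[i] > ioi[i + k] for k in (-2, -1, 1, 2)):
            cols["dr_longest_five_p"][i] = 1
            w = 1 - (ioi[i - 2] + ioi[i - 1] + ioi[i + 1] + ioi[i + 2]) / (4 * ioi[i])
            cols["dr_longest_five_w"][i] = max(0.0, w)
        if 0 < i < n - 1 and ioi[i] < ioi[i - 1] and ioi[i] < ioi[i + 1]:
            cols["dr_short_between_long_p"][i] = 1
        if i + 1 < n and ioi[i + 1] > ioi[i]:
            cols["dr_long_after_p"][i] = 1

    return pd.DataFrame(cols)


# -- simple phrasing --------------------------------------------------------

def punctuation_boundaries(melody: Melody) -> set[int]:
    """Boundaries of small melodic units, as after-note indices.

    Simplified detector: a boundary falls after a note followed by a rest,
    after the last note, and after a note at least twice as long (by IOI) as
    both neighbors when the following interval is a leap.  A fuller
    punctuation model can be substituted via ``extract_phrasing``'s
    ``boundary_fn`` hook.
    """
    notes = melody.notes
    n = len(notes)
    ioi = [nt.ioi_ms for nt in notes]
    p = [nt.pitch_midi for nt in notes]
    bounds = {n - 1}
    for i in range(n - 1):
        if notes[i].followed_by_rest:
            bounds.add(i)
        elif (0 < i < n - 1 and ioi[i] >= 2 * ioi[i - 1] and ioi[i] >= 2 * ioi[i + 1]
                and abs(p[i + 1] - p[i]) > LEAP_SEMITONES):
            bounds.add(i)
    return bounds


def extract_phrasing(
    melody: Melody,
    boundary_fn: Callable[[Melody], set[int]] = punctuation_boundaries,
) -> pd.DataFrame:
    notes = melody.notes
    n = len(notes)
    cols = {s.name: np.zeros(n) for s in REGISTRY if s.group == "simple_phrasing"}
    for i, nt in enumerate(notes):
        if i == 0 or nt.preceded_by_rest:
            cols["ph_rest_before_or_first"][i] = 1
        if i == n - 1 or nt.followed_by_rest:
            cols["ph_rest_after_or_last"][i] = 1
    bounds = boundary_fn(melody)
    cols["ph_punct_first"][0] = 1
    for b in bounds:
        cols["ph_punct_last"][b] = 1
        if b + 1 < n:
            cols["ph_punct_first"][b + 1] = 1
    return pd.DataFrame(cols)


# -- meter ------------------------------------------------------------------

# (numerator, denominator) -> grid periods in quarter-note units for
# (sub-beat, tactus, half-bar-or-bar, bar-or-2-bars).  Extensible via the
# ``extra_levels`` argument of metrical_levels / extract_meter.
METRICAL_LEVEL_TABLE: dict[tuple[int, int], tuple[Fraction, ...]] = {
    (2, 4): (Fraction(1, 2), Fraction(1), Fraction(2), Fraction(4)),
    (3, 4): (Fraction(1, 2), Fraction(1), Fraction(3), Fraction(6)),
    (4, 4): (Fraction(1, 2), Fraction(1), Fraction(2), Fraction(4)),
    (2, 2): (Fraction(1), Fraction(2), Fraction(4), Fraction(8)),
    (3, 2): (Fraction(1), Fraction(2), Fraction(6), Fraction(12)),
    (6, 8): (Fraction(1, 2), Fraction(3, 2), Fraction(3), Fraction(6)),
    (9, 8): (Fraction(1, 2), Fraction(3, 2), Fraction(9, 2), Fraction(9)),
    (12, 8): (Fraction(1, 2), Fraction(3, 2), Fraction(3), Fraction(6)),
    (6, 4): (Fraction(1), Fraction(3), Fraction(6), Fraction(12)),
    (3, 8): (Fraction(1, 4), Fraction(3, 4), Fraction(3, 2), Fraction(3)),
}


class UnsupportedMeterError(ValueError):
    pass


def metrical_levels(
    ts: TimeSignature,
    extra_levels: dict[tuple[int, int], tuple[Fraction, ...]] | None = None,
) -> tuple[Fraction, ...]:
    """Grid periods (quarter units, anchored at measure starts) for the four
    metrical levels beat0..beat3 of a supported meter."""
    table = dict(METRICAL_LEVEL_TABLE)
    if extra_levels:
        table.update(extra_levels)
    key = (ts.numerator, ts.denominator)
    if key not in table:
        supported = sorted(table)
        raise UnsupportedMeterError(
            f"meter {ts.numerator}/{ts.denominator} not in the metrical-level "
            f"table; supported: {supported}"
        )
    return table[key]


def extract_meter(
    melody: Melody,
    extra_levels: dict[tuple[int, int], tuple[Fraction, ...]] | None = None,
) -> pd.DataFrame:
    """Mark each note's highest applicable metrical level (exclusive labeling).

    Within-bar levels test the note's offset from its measure start against
    the level period; levels longer than a bar additionally require an
    even measure index (the 2-bar grid is anchored at measure 0).  Off-grid
    onsets get 0 in all four columns.
    """
    notes = melody.notes
    n = len(notes)
    cols = {name: np.zeros(n) for name in ("beat0", "beat1", "beat2", "beat3")}
    level_names = ("beat0", "beat1", "beat2", "beat3")
    for i, nt in enumerate(notes):
        sig = melody.signature_at_measure(nt.measure_index)
        periods = metrical_levels(sig, extra_levels)
        bar = sig.bar_quarters
        offq = nt.beat_in_measure * Fraction(4, sig.denominator)
        for lvl in (3, 2, 1, 0):
            period = periods[lvl]
            if period > bar:
                on = offq == 0 and nt.measure_index % (period / bar) == 0
            else:
                on = offq % period == 0
            if on:
                cols[level_names[lvl]][i] = 1
                break
    return pd.DataFrame(cols)


# -- assembly ---------------------------------------------------------------

def extract_melody(melody: Melody) -> pd.DataFrame:
    """All 43 feature columns for one melody, rows indexed by note index."""
    df = pd.concat(
        [
            extract_pitch_contour(melody),
            extract_tempo(melody),
            extract_timing(melody),
            extract_phrasing(melody),
            extract_meter(melody),
        ],
        axis=1,
    )
    df = df[list(FEATURE_NAMES)]
    df.index = pd.MultiIndex.from_product(
        [[melody.id], range(len(melody.notes))], names=["melody_id", "note_index"]
    )
    return df


def extract_all(melodies: Iterable[Melody]) -> pd.DataFrame:
    """Feature matrix for a corpus: rows keyed (melody_id, note_index),
    columns the 43 registry features in feature-id order."""
    frames = [extract_melody(m) for m in melodies]
    if not frames:
        raise ValueError("no melodies given")
    return pd.concat(frames, axis=0)


# -- variant selection ------------------------------------------------------

@dataclass
class SelectionReport:
    """Per variant group: the candidates, their correlations with the mean
    ratings, and the retained feature."""

    groups: dict[str, dict]  # variant_group -> {candidates, correlations, retained}
    retained_names: list[str]

    def to_json(self) -> str:
        return json.dumps(
            {"groups": self.groups, "retained_names": self.retained_names}, indent=1
        )


def _safe_corr(x: np.ndarray, y: np.ndarray, name: str) -> float:
    if np.std(x) == 0 or np.std(y) == 0:
        warnings.warn(f"zero variance in correlation for {name}; treated as 0")
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def select_variants(
    features: pd.DataFrame, mean_ratings: pd.Series | np.ndarray
) -> tuple[pd.DataFrame, SelectionReport]:
    """Keep one version per multi-version feature: the candidate with the
    largest |correlation| with the mean ratings (point-biserial for binary
    columns — numerically Pearson on 0/1 coding — Pearson for gradual).
    Singletons are always kept; exact ties go to the lower feature id.
    """
    y = np.asarray(mean_ratings, dtype=float)
    if len(y) != len(features):
        raise ValueError(
            f"ratings length {len(y)} does not match feature rows {len(features)}"
        )
    by_id = {s.feature_id: s for s in REGISTRY}
    drop: set[str] = set()
    report: dict[str, dict] = {}
    for vg, fids in VARIANT_GROUPS.items():
        corrs = {}
        for fid in fids:
            name = by_id[fid].name
            corrs[name] = _safe_corr(features[name].to_numpy(dtype=float), y, name)
        best_fid = max(fids, key=lambda f: (abs(corrs[by_id[f].name]), -f))
        retained = by_id[best_fid].name
        report[vg] = {
            "candidates": [by_id[f].name for f in fids],
            "correlations": corrs,
            "retained": retained,
        }
        drop.update(by_id[f].name for f in fids if f != best_fid)
    kept = [name for name in FEATURE_NAMES if name not in drop]
    return features[kept], SelectionReport(groups=report, retained_names=kept)


# -- CSV --------------------------------------------------------------------

def write_feature_csv(features: pd.DataFrame, path) -> None:
    features.reset_index().to_csv(path, index=False)


def read_feature_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    return df.set_index(["melody_id", "note_index"])
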