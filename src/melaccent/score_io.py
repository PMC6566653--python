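"""Monophonic melody representation and I/O.

A :class:`Melody` is an ordered sequence of sounded note events with notated
meter and a nominal ("deadpan") tempo.  Beat positions and durations are exact
:class:`fractions.Fraction` values in quarter-note units, so metrical-grid
tests are free of float drift; millisecond timing (onsets and inter-onset
intervals) is derived from the nominal tempo.

The inter-onset interval (IOI) of a note is the time from its onset to the
next note's onset, so a notated rest between two notes lengthens the first
note's IOI.  The final note's IOI is its nominal duration.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Sequence

from lxml import etree

__all__ = [
    "TimeSignature",
    "Note",
    "Melody",
    "MelodyError",
    "load_melody_json",
    "write_melody_json",
    "load_musicxml",
    "compute_timing",
    "note_table",
]

STYLES = ("baroque", "romantic", "posttonal", "none")
GENRES = ("vocal", "instrumental", "none")

DEFAULT_TEMPO_QPM = 100.0


class MelodyError(ValueError):
    """Invalid melody content (schema, monophony, or timing violations)."""


@dataclass(frozen=True)
class TimeSignature:
    """Notated meter active from ``start_measure`` onwards."""

    numerator: int
    denominator: int
    start_measure: int = 0

    def __post_init__(self) -> None:
        if self.numerator < 1:
            raise MelodyError(f"time signature numerator must be >= 1, got {self.numerator}")
        if self.denominator not in (1, 2, 4, 8, 16, 32):
            raise MelodyError(
                f"time signature denominator must be a power of two <= 32, got {self.denominator}"
            )
        if self.start_measure < 0:
            raise MelodyError("start_measure must be >= 0")

    @property
    def bar_quarters(self) -> Fraction:
        """Length of one measure in quarter-note units."""
        return Fraction(self.numerator * 4, self.denominator)


@dataclass
class Note:
    """A sounded note event; derived timing fields are filled by the melody."""

    pitch_midi: int
    onset_beats: Fraction
    duration_beats: Fraction
    index: int = -1
    onset_ms: float = math.nan
    ioi_ms: float = math.nan
    measure_index: int = -1
    beat_in_measure: Fraction = Fraction(0)
    preceded_by_rest: bool = False
    followed_by_rest: bool = False

    def __post_init__(self) -> None:
        self.onset_beats = Fraction(self.onset_beats)
        self.duration_beats = Fraction(self.duration_beats)
        if self.duration_beats <= 0:
            raise MelodyError(f"note duration must be > 0, got {self.duration_beats}")
        if not isinstance(self.pitch_midi, int):
            raise MelodyError("pitch_midi must be an integer (semitones, 60 = middle C)")


@dataclass
class Melody:
    """An ordered monophonic melody with meter, tempo, and derived timing."""

    id: str
    notes: list[Note]
    tempo_qpm: float = DEFAULT_TEMPO_QPM
    time_signatures: list[TimeSignature] = field(
        default_factory=lambda: [TimeSignature(4, 4, 0)]
    )
    style: str = "none"
    genre: str = "none"
    anacrusis_beats: Fraction = Fraction(0)

    def __post_init__(self) -> None:
        self.anacrusis_beats = Fraction(self.anacrusis_beats)
        if self.style not in STYLES:
            raise MelodyError(f"style must be one of {STYLES}, got {self.style!r}")
        if self.genre not in GENRES:
            raise MelodyError(f"genre must be one of {GENRES}, got {self.genre!r}")
        if not self.notes:
            raise MelodyError(f"melody {self.id!r} has no notes")
        self._validate_signatures()
        self._validate_monophony()
        compute_timing(self, self.tempo_qpm, inplace=True)

    # -- validation ---------------------------------------------------------

    def _validate_signatures(self) -> None:
        sigs = self.time_signatures
        if not sigs:
            raise MelodyError("at least one time signature is required")
        if sigs[0].start_measure != 0:
            raise MelodyError("first time signature must start at measure 0")
        starts = [s.start_measure for s in sigs]
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise MelodyError("time signature start_measure values must strictly increase")
        if self.anacrusis_beats < 0 or self.anacrusis_beats >= sigs[0].bar_quarters:
            if self.anacrusis_beats != 0:
                raise MelodyError("anacrusis must be shorter than the first full measure")

    def _validate_monophony(self) -> None:
        prev_end = None
        prev_onset = None
        for n in self.notes:
            if prev_onset is not None and n.onset_beats <= prev_onset:
                raise MelodyError("note onsets must strictly increase")
            if prev_end is not None and n.onset_beats < prev_end:
                raise MelodyError(
                    f"overlapping notes at onset {n.onset_beats} (previous note ends {prev_end})"
                )
            prev_onset = n.onset_beats
            prev_end = n.onset_beats + n.duration_beats

    # -- meter --------------------------------------------------------------

    def signature_at_measure(self, measure_index: int) -> TimeSignature:
        active = self.time_signatures[0]
        for ts in self.time_signatures:
            if ts.start_measure <= measure_index:
                active = ts
            else:
                break
        return active

    def measure_starts(self, upto_beats: Fraction) -> list[Fraction]:
        """Onsets (quarter units) of measures 0.. covering ``upto_beats``.

        Measure 0 is the anacrusis (possibly partial); measure 1 starts where
        the first full downbeat falls.
        """
        starts = [Fraction(0)]
        pos = Fraction(0)
        m = 0
        while pos <= upto_beats:
            bar = self.signature_at_measure(m).bar_quarters
            if m == 0 and self.anacrusis_beats > 0:
                bar = self.anacrusis_beats
            pos += bar
            m += 1
            starts.append(pos)
        return starts

    def total_beats(self) -> Fraction:
        last = self.notes[-1]
        return last.onset_beats + last.duration_beats

    def transposed(self, semitones: int) -> "Melody":
        notes = [replace(n, pitch_midi=n.pitch_midi + semitones) for n in self.notes]
        return Melody(
            id=self.id,
            notes=notes,
            tempo_qpm=self.tempo_qpm,
            time_signatures=list(self.time_signatures),
            style=self.style,
            genre=self.genre,
            anacrusis_beats=self.anacrusis_beats,
        )


def compute_timing(melody: Melody, tempo_qpm: float, inplace: bool = False) -> Melody:
    """Fill derived timing fields at the nominal tempo.

    onset_ms = onset_beats * 60000 / tempo_qpm; ioi_ms is onset-to-onset
    (last note: nominal duration).  Also assigns measure indices, within-bar
    positions in denominator units, and rest flags.  Idempotent.
    """
    if tempo_qpm <= 0:
        raise MelodyError(f"tempo must be > 0 qpm, got {tempo_qpm}")
    if not inplace:
        melody = Melody(
            id=melody.id,
            notes=[replace(n) for n in melody.notes],
            tempo_qpm=tempo_qpm,
            time_signatures=list(melody.time_signatures),
            style=melody.style,
            genre=melody.genre,
            anacrusis_beats=melody.anacrusis_beats,
        )
        melody.tempo_qpm = tempo_qpm
        return melody

    melody.tempo_qpm = float(tempo_qpm)
    ms_per_quarter = 60000.0 / tempo_qpm
    notes = melody.notes
    starts = melody.measure_starts(melody.total_beats())
    first_sig = melody.time_signatures[0]

    for i, n in enumerate(notes):
        n.index = i
        n.onset_ms = float(n.onset_beats) * ms_per_quarter
        if i + 1 < len(notes):
            n.ioi_ms = float(notes[i + 1].onset_beats - n.onset_beats) * ms_per_quarter
            gap = notes[i + 1].onset_beats - (n.onset_beats + n.duration_beats)
            n.followed_by_rest = gap > 0
            notes[i + 1].preceded_by_rest = gap > 0
        else:
            n.ioi_ms = float(n.duration_beats) * ms_per_quarter
            n.followed_by_rest = False
        # measure assignment: last measure whose start <= onset
        m = 0
        for j in range(len(starts) - 1):
            if starts[j] <= n.onset_beats < starts[j + 1]:
                m = j
                break
        else:
            m = len(starts) - 1
        n.measure_index = m
        sig = melody.signature_at_measure(m)
        off_quarters = n.onset_beats - starts[m]
        if m == 0 and melody.anacrusis_beats > 0:
            # offset so the first full downbeat lands at notated position 0
            off_quarters += first_sig.bar_quarters - melody.anacrusis_beats
        n.beat_in_measure = off_quarters * Fraction(sig.denominator, 4)
    notes[0].preceded_by_rest = notes[0].onset_beats > 0
    return melody


# -- melody-JSON ------------------------------------------------------------
#
# Canonical fixture schema.  Beat values are exact rationals serialized as
# strings ("3/2"); derived fields (onset_ms, ioi_ms, measure_index, rest
# flags) are recomputed on load and never stored.
#
# {
#   "id": "demo", "style": "none", "genre": "none", "tempo_qpm": 120.0,
#   "anacrusis_beats": "0",
#   "time_signatures": [{"numerator": 4, "denominator": 4, "start_measure": 0}],
#   "notes": [{"pitch_midi": 60, "onset_beats": "0", "duration_beats": "1"}]
# }


def _frac(value: object, where: str) -> Fraction:
    try:
        return Fraction(str(value))
    except (ValueError, ZeroDivisionError) as exc:
        raise MelodyError(f"field {where!r}: not a rational number: {value!r}") from exc


def melody_from_dict(data: dict) -> Melody:
    for key in ("id", "tempo_qpm", "notes"):
        if key not in data:
            raise MelodyError(f"melody JSON missing required field {key!r}")
    sigs = [
        TimeSignature(int(s["numerator"]), int(s["denominator"]), int(s.get("start_measure", 0)))
        for s in data.get("time_signatures", [{"numerator": 4, "denominator": 4}])
    ]
    notes = []
    for i, nd in enumerate(data["notes"]):
        for key in ("pitch_midi", "onset_beats", "duration_beats"):
            if key not in nd:
                raise MelodyError(f"note {i}: missing field {key!r}")
        notes.append(
            Note(
                pitch_midi=int(nd["pitch_midi"]),
                onset_beats=_frac(nd["onset_beats"], f"notes[{i}].onset_beats"),
                duration_beats=_frac(nd["duration_beats"], f"notes[{i}].duration_beats"),
            )
        )
    return Melody(
        id=str(data["id"]),
        notes=notes,
        tempo_qpm=float(data["tempo_qpm"]),
        time_signatures=sigs,
        style=str(data.get("style", "none")),
        genre=str(data.get("genre", "none")),
        anacrusis_beats=_frac(data.get("anacrusis_beats", 0), "anacrusis_beats"),
    )


def melody_to_dict(melody: Melody) -> dict:
    return {
        "id": melody.id,
        "style": melody.style,
        "genre": melody.genre,
        "tempo_qpm": melody.tempo_qpm,
        "anacrusis_beats": str(melody.anacrusis_beats),
        "time_signatures": [
            {"numerator": s.numerator, "denominator": s.denominator, "start_measure": s.start_measure}
            for s in melody.time_signatures
        ],
        "notes": [
            {
                "pitch_midi": n.pitch_midi,
                "onset_beats": str(n.onset_beats),
                "duration_beats": str(n.duration_beats),
            }
            for n in melody.notes
        ],
    }


def load_melody_json(path: str | Path) -> Melody:
    """Load one melody from the canonical melody-JSON fixture format."""
    with open(path) as fh:
        try:
            data = json.load(fh)
        except json.JSONDecodeError as exc:
            raise MelodyError(f"{path}: malformed JSON: {exc}") from exc
    return melody_from_dict(data)


def write_melody_json(melody: Melody, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(melody_to_dict(melody), fh, indent=1)
        fh.write("\n")


# -- MusicXML ---------------------------------------------------------------

_STEP_TO_SEMITONE = {"C": 0, "D": 2, "E": 4, "F": 5, "G": 7, "A": 9, "B": 11}


def load_musicxml(path: str | Path, default_tempo_qpm: float = DEFAULT_TEMPO_QPM) -> Melody:
    """Read a single-part monophonic partwise MusicXML file.

    Ties are merged into single notes and dotted values come through the
    duration encoding.  Chords raise :class:`MelodyError`; tempo is taken from
    the first ``<sound tempo=...>`` direction, else ``default_tempo_qpm``
    (with a warning).
    """
    tree = etree.parse(str(path))
    root = tree.getroot()
    if root.tag != "score-partwise":
        raise MelodyError(f"{path}: only partwise MusicXML is supported (got <{root.tag}>)")
    parts = root.findall("part")
    if len(parts) != 1:
        raise MelodyError(f"{path}: expected exactly one part, found {len(parts)}")

    divisions: int | None = None
    tempo: float | None = None
    sigs: list[TimeSignature] = []
    notes: list[Note] = []
    pos = Fraction(0)  # quarter-note units
    pending_tie: Note | None = None

    for m_idx, measure in enumerate(parts[0].findall("measure")):
        attrs = measure.find("attributes")
        if attrs is not None:
            dv = attrs.findtext("divisions")
            if dv is not None:
                divisions = int(dv)
            t = attrs.find("time")
            if t is not None:
                sigs.append(
                    TimeSignature(int(t.findtext("beats")), int(t.findtext("beat-type")), m_idx)
                )
        for sound in measure.iter("sound"):
            if tempo is None and sound.get("tempo") is not None:
                tempo = float(sound.get("tempo"))
        for el in measure.findall("note"):
            if el.find("chord") is not None:
                raise MelodyError(f"{path}: chords are not supported (monophonic subset)")
            if divisions is None:
                raise MelodyError(f"{path}: <divisions> missing before first note")
            dur = Fraction(int(el.findtext("duration")), divisions)
            if el.find("rest") is not None:
                pos += dur
                pending_tie = None
                continue
            pitch_el = el.find("pitch")
            if pitch_el is None:
                raise MelodyError(f"{path}: note without <pitch> or <rest>")
            step = pitch_el.findtext("step")
            alter = int(pitch_el.findtext("alter") or 0)
            octave = int(pitch_el.findtext("octave"))
            midi = 12 * (octave + 1) + _STEP_TO_SEMITONE[step] + alter
            tie_types = {t.get("type") for t in el.findall("tie")}
            if pending_tie is not None and "stop" in tie_types:
                if pending_tie.pitch_midi != midi:
                    raise MelodyError(f"{path}: tie between different pitches")
                pending_tie.duration_beats += dur
                pos += dur
                pending_tie = pending_tie if "start" in tie_types else None
                continue
            note = Note(pitch_midi=midi, onset_beats=pos, duration_beats=dur)
            notes.append(note)
            pos += dur
            pending_tie = note if "start" in tie_types else None

    if not sigs:
        sigs = [TimeSignature(4, 4, 0)]
    if tempo is None:
        warnings.warn(f"{path}: no tempo marking; using default {default_tempo_qpm} qpm")
        tempo = default_tempo_qpm
    mel_id = root.findtext("work/work-title") or Path(path).stem
    return Melody(id=mel_id, notes=notes, tempo_qpm=tempo, time_signatures=sigs)


# -- tabular export ---------------------------------------------------------

NOTE_TABLE_COLUMNS = [
    "index",
    "pitch_midi",
    "onset_beats",
    "duration_beats",
    "onset_ms",
    "ioi_ms",
    "measure_index",
    "beat_in_measure",
    "preceded_by_rest",
    "followed_by_rest",
]


def note_table(melody: Melody):
    """One row per note with all Note fields, CSV-serializable."""
    import pandas as pd

    rows = [
        {
            "index": n.index,
            "pitch_midi": n.pitch_midi,
            "onset_beats": str(n.onset_beats),
            "duration_beats": str(n.duration_beats),
            "onset_ms": n.onset_ms,
            "ioi_ms": n.ioi_ms,
            "measure_index": n.measure_index,
            "beat_in_measure": str(n.beat_in_measure),
            "preceded_by_rest": int(n.preceded_by_rest),
            "followed_by_rest": int(n.followed_by_rest),
        }
        for n in melody.notes
    ]
    return pd.DataFrame(rows, columns=NOTE_TABLE_COLUMNS)


def load_melodies(paths: Iterable[str | Path]) -> list[Melody]:
    return [load_melody_json(p) for p in paths]
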