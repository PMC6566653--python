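from fractions import Fraction

import pytest

from melaccent.score_io import Melody, Note, TimeSignature


def melody_from_shorthand(
    pitches,
    durations=None,
    tempo=120.0,
    ts=(4, 4),
    rests_after=(),
    mel_id="m",
):
    """Build a melody from pitch list and quarter-unit durations; a rest of
    one beat is inserted after each index in ``rests_after``."""
    if durations is None:
        durations = [1] * len(pitches)
    durations = [Fraction(d) for d in durations]
    notes = []
    pos = Fraction(0)
    for i, (p, d) in enumerate(zip(pitches, durations)):
        notes.append(Note(pitch_midi=int(p), onset_beats=pos, duration_beats=d))
        pos += d
        if i in set(rests_after):
            pos += 1
    return Melody(
        id=mel_id, notes=notes, tempo_qpm=tempo,
        time_signatures=[TimeSignature(ts[0], ts[1], 0)],
    )


@pytest.fixture
def quarters_44():
    """Two 4/4 measures of quarter notes at 100 qpm, stepwise contour."""
    return melody_from_shorthand([60, 62, 64, 65, 67, 65, 64, 62], tempo=100)
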