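"""Silent-pause detection and positional typology.

Silences are detected on frame-level RMS intensity with a relative
threshold (frames more than ``threshold_db`` below the file's maximum
level are silent), merged, and kept when at least ``min_dur_ms`` long —
150 ms by default, the average closure duration of a stop consonant, so
that stop closures are not mistaken for pauses.

Each pause is then classified by where it falls in the interaction:

* ``T`` — turn-taking silence before a tracked speaker's turn (an index
  of reaction time; pauses before the interviewer's turns are excluded);
* ``UT`` — between two utterances (terminated sequences) of one turn;
* ``IU`` — between two information units inside one utterance;
* ``excluded`` — anything else.

Durations are grouped into the four conventional bins 150-250, 251-500,
501-1000 and >=1001 ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .audio import AudioSignal, frame_rms_db
from .chat_corpus import AlignmentTier, Transcript, attach_alignment
from .info_structure import round_pct

__all__ = [
    "SilentInterval",
    "PauseProfile",
    "detect_silences",
    "segment_sounding_silent",
    "bin_duration",
    "classify_pause_position",
    "pause_profile",
    "BINS",
]

BINS = ("b150_250", "b251_500", "b501_1000", "b1001_plus")
POSITIONS = ("T", "UT", "IU")

#: below this absolute level (dB re 2e-5) a file counts as digital silence
_ABS_SILENCE_FLOOR_DB = 10.0


@dataclass
class SilentInterval:
    start_s: float
    end_s: float
    position: Optional[str] = None  # T | UT | IU | excluded

    @property
    def duration_ms(self) -> int:
        return int(np.floor((self.end_s - self.start_s) * 1000.0 + 1e-9))

    @property
    def bin(self) -> str:
        return bin_duration(self.duration_ms)

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start_s + self.end_s)


def bin_duration(duration_ms: int) -> str:
    """Map an integer millisecond duration to its bin."""
    d = int(duration_ms)
    if d < 150:
        raise ValueError(f"duration {d} ms below the 150 ms pause threshold")
    if d <= 250:
        return "b150_250"
    if d <= 500:
        return "b251_500"
    if d <= 1000:
        return "b501_1000"
    return "b1001_plus"


def segment_sounding_silent(audio: AudioSignal, threshold_db: float = 25.0,
                            frame_ms: float = 30.0, hop_ms: float = 10.0,
                            ) -> list[tuple[float, float, bool]]:
    """Tile the file into alternating (start, end, is_silent) stretches.

    No minimum-duration filtering: the tiles partition [0, duration]
    exactly.
    """
    if audio.samples.size == 0:
        raise ValueError("zero-length audio")
    times, levels = frame_rms_db(audio, frame_ms=frame_ms, hop_ms=hop_ms)
    frame = max(1, int(round(frame_ms * audio.rate / 1000.0)))
    hop = max(1, int(round(hop_ms * audio.rate / 1000.0)))
    n = audio.samples.size
    starts = np.arange(levels.size) * hop

    max_level = np.max(levels)
    if not np.isfinite(max_level) or max_level < _ABS_SILENCE_FLOOR_DB:
        return [(0.0, audio.duration, True)]
    silent = levels < (max_level - threshold_db)

    tiles: list[tuple[float, float, bool]] = []
    i = 0
    cursor = 0.0
    while i < silent.size:
        j = i
        while j + 1 < silent.size and silent[j + 1] == silent[i]:
            j += 1
        if silent[i]:
            s = starts[i] / audio.rate if i > 0 else 0.0
            e = (starts[j] + frame) / audio.rate if j < silent.size - 1 \
                else audio.duration
        else:
            s = cursor
            e = (starts[j + 1]) / audio.rate if j < silent.size - 1 \
                else audio.duration
        s = max(s, cursor)
        e = min(max(e, s), audio.duration)
        if e > s:
            tiles.append((s, e, bool(silent[i])))
            cursor = e
        i = j + 1
    if cursor < audio.duration and tiles:
        s, e, flag = tiles[-1]
        tiles[-1] = (s, audio.duration, flag)
    return tiles


def detect_silences(audio: AudioSignal, min_dur_ms: float = 150.0,
                    threshold_db: float = 25.0, frame_ms: float = 30.0,
                    hop_ms: float = 10.0) -> list[SilentInterval]:
    """Detect silent intervals at least ``min_dur_ms`` long.

    All-silent input yields a single interval spanning the whole file.
    """
    tiles = segment_sounding_silent(audio, threshold_db=threshold_db,
                                    frame_ms=frame_ms, hop_ms=hop_ms)
    out = []
    for (s, e, is_silent) in tiles:
        if is_silent and (e - s) * 1000.0 >= min_dur_ms - 1e-9:
            out.append(SilentInterval(s, e))
    return out


def _tracked(t: Transcript, code: str) -> bool:
    return t.speakers.get(code) != "interviewer"


def classify_pause_position(s: SilentInterval, align: Optional[AlignmentTier],
                            t: Transcript) -> str:
    """Assign a silence to T / UT / IU / excluded by its midpoint's gap."""
    if align is not None and any(
            turn.time_span is None for turn in t.turns):
        attach_alignment(t, align)
    m = s.midpoint
    turns = t.turns
    for prev, nxt in zip(turns, turns[1:]):
        if prev.time_span and nxt.time_span and \
                prev.time_span[1] - 1e-9 <= m <= nxt.time_span[0] + 1e-9:
            if _tracked(t, nxt.speaker) and nxt.speaker != prev.speaker:
                return "T"
            return "excluded"
    for turn in turns:
        if not (turn.time_span and
                turn.time_span[0] <= m <= turn.time_span[1]):
            continue
        if not _tracked(t, turn.speaker):
            return "excluded"
        seqs = turn.sequences
        for prev, nxt in zip(seqs, seqs[1:]):
            if prev.time_span and nxt.time_span and \
                    prev.time_span[1] - 1e-9 <= m <= nxt.time_span[0] + 1e-9:
                return "UT"
        for ts in seqs:
            if not (ts.time_span and
                    ts.time_span[0] <= m <= ts.time_span[1]):
                continue
            units = ts.units
            for prev, nxt in zip(units, units[1:]):
                if prev.time_span and nxt.time_span and \
                        prev.time_span[1] - 1e-9 <= m <= nxt.time_span[0] + 1e-9:
                    return "IU"
        return "excluded"
    return "excluded"


@dataclass
class PauseProfile:
    """Per-position pause counts by duration bin, plus missed opportunities.

    ``counts[position]`` maps each bin, and the key ``no_pause``, to the
    number of opportunities of that position falling in it; percentages
    are taken over opportunities.
    """

    speaker: str
    counts: dict[str, dict[str, int]] = field(default_factory=dict)

    def n_opportunities(self, position: str) -> int:
        return sum(self.counts.get(position, {}).values())

    def percentages(self, position: str) -> Optional[dict[str, float]]:
        row = self.counts.get(position)
        total = sum(row.values()) if row else 0
        if total == 0:
            return None
        return {key: round_pct(100.0 * v / total) for key, v in row.items()}


def _opportunities(t: Transcript, speaker: str) -> dict[str, list[tuple[float, float]]]:
    gaps: dict[str, list[tuple[float, float]]] = {p: [] for p in POSITIONS}
    turns = t.turns
    for prev, turn in zip(turns, turns[1:]):
        if turn.speaker == speaker and prev.speaker != speaker \
                and prev.time_span and turn.time_span:
            gaps["T"].append((prev.time_span[1], turn.time_span[0]))
    for turn in turns:
        if turn.speaker != speaker:
            continue
        for a, b in zip(turn.sequences, turn.sequences[1:]):
            if a.time_span and b.time_span:
                gaps["UT"].append((a.time_span[1], b.time_span[0]))
        for ts in turn.sequences:
            for a, b in zip(ts.units, ts.units[1:]):
                if a.time_span and b.time_span:
                    gaps["IU"].append((a.time_span[1], b.time_span[0]))
    return gaps


def pause_profile(t: Transcript, align: Optional[AlignmentTier],
                  audio: Optional[AudioSignal], speaker: str,
                  silences: Optional[Sequence[SilentInterval]] = None,
                  min_dur_ms: float = 150.0, threshold_db: float = 25.0,
                  ) -> PauseProfile:
    """Count pauses per position and duration bin for one speaker.

    Opportunities: each tracked turn start preceded by another speaker's
    turn (T), each adjacent same-turn TS pair (UT), each adjacent
    within-TS unit pair (IU).  An opportunity with no qualifying silence
    counts as ``no_pause``.  A pre-computed (e.g. hand-checked) silence
    list may be passed instead of raw audio.
    """
    if align is not None:
        attach_alignment(t, align)
    if silences is None:
        if audio is None:
            raise ValueError("need either audio or a silence list")
        silences = detect_silences(audio, min_dur_ms=min_dur_ms,
                                   threshold_db=threshold_db)
    profile = PauseProfile(speaker=speaker, counts={
        p: {**{b: 0 for b in BINS}, "no_pause": 0} for p in POSITIONS})
    gaps = _opportunities(t, speaker)
    for position in POSITIONS:
        for (g0, g1) in gaps[position]:
            inside = [s for s in silences
                      if g0 - 1e-9 <= s.midpoint <= g1 + 1e-9]
            if inside:
                longest = max(inside, key=lambda s: s.duration_ms)
                profile.counts[position][longest.bin] += 1
            else:
                profile.counts[position]["no_pause"] += 1
    return profile
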