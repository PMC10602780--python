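"""Synthetic interview corpora with known ground truth.

Generates (a) CHAT-LABLITA transcripts whose terminated-sequence
classes, Topic/Appendix presence and retracing events follow prescribed
probabilities, and (b) time-aligned audio rendered as harmonic complexes
(5 partials, configurable spectral rolloff) with prescribed f0 contours,
intensity levels and silent gaps — so every pipeline stage can be tested
against exact generator truth without any corpus download.

The default ``SynthSpec`` encodes the pathological-interview regime the
pipeline is built to profile (simple-heavy TS classes, frequent long
turn-taking silences, elevated retracing, low-effort Comment nuclei);
``preset("control-like")`` encodes the matching non-pathological regime.
All randomness flows from one seeded generator per corpus: the same spec
and seed reproduce the same transcript, audio and alignment bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .audio import AudioSignal, DB_REFERENCE
from .chat_corpus import AlignmentTier, Transcript, parse_transcript

__all__ = [
    "RoleAcoustics",
    "SynthSpec",
    "UnitTruth",
    "TSTruth",
    "PauseTruth",
    "SpanTruth",
    "GroundTruth",
    "SynthCorpus",
    "preset",
    "gen_transcript",
    "gen_audio",
    "generate",
    "gen_patient_vs_control",
]

_LEXICON = (
    "bano dela miro tasso lino pove cada rena fusto gira nave sole "
    "toro lima pera vasto neto rullo sima bocca dirle fama lepre vota"
).split()


@dataclass
class RoleAcoustics:
    """How a unit role is rendered: pitch target, movement, spectrum."""
    base_mult: float          # baseline f0 = speaker base * base_mult
    excursion: float          # nucleus peak f0 = baseline * excursion
    rolloff_db_per_oct: float  # partial amplitude slope (more negative
    #                            = duller spectrum = lower emphasis)
    amp_mod_depth_db: float   # slow intensity modulation depth


@dataclass
class SynthSpec:
    seed: int = 0
    speaker: str = "PAT"
    group: str = "patient"
    interviewer: str = "DOC"
    n_turns: int = 20                  # tracked-speaker turns
    mean_ts_per_turn: float = 2.0
    # TS structure
    p_ts_class: tuple[float, float, float] = (0.454, 0.409, 0.137)
    p_top: float = 0.32                # per complex TS / stanza
    p_apc: float = 0.14
    mean_ts_words: float = 6.5
    p_scansion: float = 0.10           # extra untagged '/' inside a unit
    # retracing
    retracing_episode_rate: float = 0.09   # events per information unit
    chain_fraction: float = 0.27
    position_weights: tuple[float, float, float] = (0.126, 0.549, 0.324)
    kind_weights: tuple[float, float, float] = (0.6, 0.25, 0.15)
    # pauses: per position, probability and planted duration range (ms)
    pause_p: dict = field(default_factory=lambda: {
        "T": 0.74, "UT": 0.42, "IU": 0.31})
    pause_dur_ms: dict = field(default_factory=lambda: {
        "T": (300.0, 3000.0), "UT": (200.0, 2000.0), "IU": (180.0, 1200.0)})
    p_gap_before_interviewer: float = 0.3  # exercised as 'excluded' pauses
    # audio
    base_f0_hz: float = 110.0
    interviewer_f0_hz: float = 185.0
    com: RoleAcoustics = field(default_factory=lambda: RoleAcoustics(
        base_mult=1.0, excursion=1.15, rolloff_db_per_oct=-9.0,
        amp_mod_depth_db=1.0))
    top: RoleAcoustics = field(default_factory=lambda: RoleAcoustics(
        base_mult=1.15, excursion=1.35, rolloff_db_per_oct=-5.0,
        amp_mod_depth_db=2.0))
    other: RoleAcoustics = field(default_factory=lambda: RoleAcoustics(
        base_mult=0.95, excursion=1.05, rolloff_db_per_oct=-7.0,
        amp_mod_depth_db=1.0))
    amplitude_db: float = 70.0
    syllable_ms: float = 180.0
    sample_rate: int = 16000

    def validate(self) -> None:
        p = self.p_ts_class
        if any(x < 0 for x in p) or abs(sum(p) - 1.0) > 1e-6:
            raise ValueError("p_ts_class must be a probability vector")
        if self.sample_rate < 8000:
            raise ValueError("sample rate below 8 kHz")
        if self.n_turns > 0 and sum(self.p_ts_class) == 0:
            raise ValueError("degenerate spec: no TS class possible")


def preset(name: str, seed: int = 0) -> SynthSpec:
    """Named parameter regimes: ``cipps-like`` (default spec) or
    ``control-like``."""
    if name == "cipps-like":
        return SynthSpec(seed=seed)
    if name == "control-like":
        return SynthSpec(
            seed=seed, speaker="CTL", group="control",
            p_ts_class=(0.314, 0.464, 0.222),
            p_top=0.475, p_apc=0.086, mean_ts_words=8.8,
            retracing_episode_rate=0.053, chain_fraction=0.18,
            position_weights=(0.131, 0.461, 0.408),
            pause_p={"T": 0.28, "UT": 0.30, "IU": 0.21},
            pause_dur_ms={"T": (180.0, 700.0), "UT": (180.0, 600.0),
                          "IU": (160.0, 500.0)},
            base_f0_hz=120.0,
            com=RoleAcoustics(1.0, 1.30, -6.0, 2.5),
            top=RoleAcoustics(1.0, 1.15, -7.0, 1.5),
        )
    raise ValueError(f"unknown preset {name!r}")


# ---------------------------------------------------------------------------
# ground-truth records

@dataclass
class UnitTruth:
    tag: str
    words: list[str]                  # non-retracted surfaces, in order
    retrace_groups: list[dict] = field(default_factory=list)
    # each: {"index": word index where the group starts, "tokens": [...],
    #        "kind": ..., "chain_id": int | None}


@dataclass
class TSTruth:
    speaker: str
    ts_class: str
    has_top: bool
    has_apc: bool
    units: list[UnitTruth]
    episode_positions: list[str] = field(default_factory=list)  # per event
    n_single: int = 0
    n_chain: int = 0

    @property
    def n_words(self) -> int:
        return sum(len(u.words) for u in self.units)


@dataclass
class PauseTruth:
    position: str          # T | UT | IU | before_interviewer
    duration_ms: float
    start_s: float = 0.0
    end_s: float = 0.0


@dataclass
class SpanTruth:
    speaker: str
    unit_role: str         # COM | TOP
    start_s: float
    end_s: float
    n_syllables: int
    f0_mean_hz: float      # mean of the planted contour over the span
    f0_sd_hz: float
    syllables: list[tuple[float, float]] = field(default_factory=list)


@dataclass
class GroundTruth:
    sequences: list[TSTruth] = field(default_factory=list)
    turn_sizes: list[int] = field(default_factory=list)  # TSs per tracked turn
    pauses: list[PauseTruth] = field(default_factory=list)
    spans: list[SpanTruth] = field(default_factory=list)

    def class_counts(self) -> dict[str, int]:
        out = {"simple": 0, "complex": 0, "stanza": 0}
        for ts in self.sequences:
            out[ts.ts_class] += 1
        return out


@dataclass
class SynthCorpus:
    spec: SynthSpec
    text: str
    truth: GroundTruth
    audio: Optional[AudioSignal] = None
    alignment: Optional[AlignmentTier] = None

    @property
    def transcript(self) -> Transcript:
        return parse_transcript(self.text)


# ---------------------------------------------------------------------------
# transcript generation

def _draw_words(rng: np.random.Generator, n: int) -> list[str]:
    return [str(rng.choice(_LEXICON)) for _ in range(n)]


def _different_word(rng: np.random.Generator, avoid: str) -> str:
    while True:
        w = str(rng.choice(_LEXICON))
        if w[0] != avoid[0]:
            return w


def _plant_event(rng: np.random.Generator, unit: UnitTruth, position: str,
                 is_chain: bool, kind_weights) -> tuple[str, str]:
    """Insert a retracing event into the unit's word list; returns
    (actual position, kind)."""
    if position == "inside_ts" and len(unit.words) < 2:
        position = "start_of_ts"  # caller guarantees unit choice; safety net
    index = 0 if position in ("start_of_ts", "start_of_iu_inside_ts") \
        else int(rng.integers(1, len(unit.words)))
    repair = unit.words[index]
    kind = ("repetition_total", "repetition_partial", "modification")[
        int(rng.choice(3, p=kind_weights))]
    if kind == "repetition_total":
        group_tokens = [repair]
    elif kind == "repetition_partial":
        group_tokens = ["&" + repair[0]]
    else:
        group_tokens = [_different_word(rng, repair)]
    n_groups = int(rng.integers(2, 4)) if is_chain else 1
    chain_id = int(rng.integers(1 << 30)) if is_chain else None
    for g in range(n_groups):
        unit.retrace_groups.append({
            "index": index, "tokens": list(group_tokens),
            "kind": kind, "chain_id": chain_id})
    return position, kind


def _gen_ts(rng: np.random.Generator, spec: SynthSpec, speaker: str) -> TSTruth:
    classes = ("simple", "complex", "stanza")
    ts_class = classes[int(rng.choice(3, p=spec.p_ts_class))]
    has_top = has_apc = False
    tags: list[str]
    if ts_class == "simple":
        tags = ["COM"]
    elif ts_class == "complex":
        has_top = bool(rng.random() < spec.p_top)
        has_apc = bool(rng.random() < spec.p_apc)
        tags = (["TOP"] if has_top else []) + ["COM"] + \
            (["APC"] if has_apc else [])
        if len(tags) == 1:
            tags = ["PAR", "COM"]  # parenthetical support unit
    else:
        n_cob = int(rng.integers(2, 5))
        has_top = bool(rng.random() < spec.p_top)
        has_apc = bool(rng.random() < spec.p_apc)
        tags = (["TOP"] if has_top else []) + ["COB"] * n_cob + \
            (["APC"] if has_apc else [])
    n_units = len(tags)
    n_words = max(n_units, int(rng.poisson(spec.mean_ts_words)))
    per_unit = np.ones(n_units, dtype=int)
    extra = n_words - n_units
    if extra > 0:
        per_unit += rng.multinomial(extra, np.ones(n_units) / n_units)
    units = [UnitTruth(tag=tag, words=_draw_words(rng, int(k)))
             for tag, k in zip(tags, per_unit)]
    ts = TSTruth(speaker=speaker, ts_class=ts_class,
                 has_top=has_top, has_apc=has_apc, units=units)

    # retracing: at most one event per unit
    n_events = int(rng.binomial(n_units, spec.retracing_episode_rate))
    free = list(range(n_units))
    for _ in range(n_events):
        if not free:
            break
        position = ("start_of_ts", "start_of_iu_inside_ts", "inside_ts")[
            int(rng.choice(3, p=np.asarray(spec.position_weights)
                           / sum(spec.position_weights)))]
        eligible = []
        if position == "start_of_ts":
            eligible = [u for u in free if u == 0]
        elif position == "start_of_iu_inside_ts":
            eligible = [u for u in free if u > 0]
        else:
            eligible = [u for u in free if len(units[u].words) >= 2]
        if not eligible:
            # fall back to any feasible placement
            fallback = [u for u in free
                        if u > 0 or len(units[u].words) >= 2 or u == 0]
            if not fallback:
                break
            u = int(rng.choice(fallback))
            position = ("start_of_ts" if u == 0 else "start_of_iu_inside_ts")
        else:
            u = int(rng.choice(eligible))
        free.remove(u)
        is_chain = bool(rng.random() < spec.chain_fraction)
        actual, _kind = _plant_event(rng, units[u], position, is_chain,
                                     np.asarray(spec.kind_weights))
        ts.episode_positions.append(actual)
        if is_chain:
            ts.n_chain += 1
        else:
            ts.n_single += 1
    return ts


def _render_ts_line(rng: np.random.Generator, spec: SynthSpec,
                    ts: TSTruth) -> str:
    parts = []
    for unit in ts.units:
        pieces = []
        groups_at = {}
        for g in unit.retrace_groups:
            groups_at.setdefault(g["index"], []).append(g)
        for i, word in enumerate(unit.words):
            for g in groups_at.get(i, []):
                toks = g["tokens"]
                pieces.append("*" + " ".join(toks) + " [/]")
            pieces.append(word)
        body = " ".join(pieces)
        if len(unit.words) >= 3 and rng.random() < spec.p_scansion \
                and not unit.retrace_groups:
            words = body.split(" ")
            cut = int(rng.integers(1, len(words)))
            body = " ".join(words[:cut]) + " / " + " ".join(words[cut:])
        boundary = "//" if unit is ts.units[-1] else "/"
        parts.append(f"{body} {boundary}^{unit.tag}^")
    return f"*{ts.speaker}:\t" + " ".join(parts)


_INTERVIEWER_LINES = [
    "e poi //^COM^",
    "mi dica //^COM^",
    "come mai //^COM^",
    "davvero //^COM^",
    "e questo quando //^COM^",
]


def gen_transcript(spec: SynthSpec) -> tuple[str, GroundTruth]:
    """Generate CHAT-LABLITA text plus its ground truth.

    The corpus alternates short interviewer turns with tracked-speaker
    turns; every generated line parses back to exactly the structures
    recorded in the ground truth.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    truth = GroundTruth()
    lines = [f"@Participants:\t{spec.speaker} {spec.group}, "
             f"{spec.interviewer} interviewer"]
    for _ in range(spec.n_turns):
        lines.append(f"*{spec.interviewer}:\t"
                     + _INTERVIEWER_LINES[int(rng.integers(
                         len(_INTERVIEWER_LINES)))])
        n_ts = 1 + int(rng.poisson(max(spec.mean_ts_per_turn - 1.0, 0.0)))
        truth.turn_sizes.append(n_ts)
        for _ in range(n_ts):
            ts = _gen_ts(rng, spec, spec.speaker)
            truth.sequences.append(ts)
            lines.append(_render_ts_line(rng, spec, ts))
    return "\n".join(lines) + "\n", truth


# ---------------------------------------------------------------------------
# audio generation

def _role_acoustics(spec: SynthSpec, tag: str) -> RoleAcoustics:
    if tag in ("COM", "COB"):
        return spec.com
    if tag == "TOP":
        return spec.top
    return spec.other


def _render_unit(spec: SynthSpec, rng: np.random.Generator, tag: str,
                 n_syll: int, base_f0: float, t0: float,
                 ) -> tuple[np.ndarray, np.ndarray, list[tuple[float, float]],
                            Optional[tuple[int, int]]]:
    """Render one unit; returns (samples, f0_per_sample, syllables,
    nucleus syllable index range or None)."""
    sr = spec.sample_rate
    role = _role_acoustics(spec, tag)
    syl_n = int(round(spec.syllable_ms * sr / 1000.0))
    n = syl_n * n_syll
    tt = np.arange(n) / sr
    baseline = base_f0 * role.base_mult

    f0 = np.full(n, baseline)
    nucleus = None
    if tag in ("COM", "COB", "TOP"):
        k0 = 1 if n_syll >= 4 else 0
        k1 = n_syll - 2 if n_syll >= 4 else n_syll - 1
        nucleus = (k0, k1)
        a, b = k0 * syl_n, (k1 + 1) * syl_n
        m = b - a
        peak = baseline * role.excursion
        half = m // 2
        ramp = np.concatenate([
            np.linspace(baseline, peak, half, endpoint=False),
            np.linspace(peak, baseline, m - half)])
        f0[a:b] = ramp

    phase = 2 * np.pi * np.cumsum(f0) / sr
    samples = np.zeros(n)
    for k in range(1, 6):
        amp = 10 ** (role.rolloff_db_per_oct * np.log2(k) / 20.0)
        samples += amp * np.sin(k * phase)
    target_rms = DB_REFERENCE * 10 ** (spec.amplitude_db / 20.0)
    samples *= target_rms / max(np.sqrt(np.mean(samples ** 2)), 1e-12)
    # slow intensity modulation (gives the contour its planted variation)
    mod_hz = 3.0
    gain_db = role.amp_mod_depth_db * np.sin(2 * np.pi * mod_hz * tt
                                             + float(rng.uniform(0, 2 * np.pi)))
    samples *= 10 ** (gain_db / 20.0)
    edge = max(1, int(0.005 * sr))
    env = np.ones(n)
    env[:edge] = np.linspace(0, 1, edge)
    env[-edge:] = np.linspace(1, 0, edge)
    samples *= env
    syllables = [(t0 + k * syl_n / sr, t0 + (k + 1) * syl_n / sr)
                 for k in range(n_syll)]
    return samples, f0, syllables, nucleus


def gen_audio(spec: SynthSpec, truth: GroundTruth,
              ) -> tuple[AudioSignal, AlignmentTier]:
    """Render aligned audio for a generated transcript.

    Each information unit becomes a harmonic complex (one syllable per
    token, retracted tokens included); planted silences are inserted at
    T/UT/IU opportunities with the spec's probabilities and duration
    ranges and recorded, with their final times, in ``truth.pauses``.
    Prominence ground truth (COM/TOP nucleus spans with exact f0
    statistics) is recorded in ``truth.spans``.
    """
    spec.validate()
    rng = np.random.default_rng((spec.seed * 2654435761 + 1) % (1 << 31))
    sr = spec.sample_rate
    pieces: list[np.ndarray] = []
    cursor = 0.0
    align = AlignmentTier()
    truth.pauses = []
    truth.spans = []

    def emit_silence(ms: float):
        nonlocal cursor
        n = int(round(ms * sr / 1000.0))
        pieces.append(np.zeros(n))
        cursor += n / sr

    def draw_dur(position: str) -> float:
        lo, hi = spec.pause_dur_ms[position]
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    turns = []
    pos = 0
    for n in truth.turn_sizes:
        turns.append(truth.sequences[pos:pos + n])
        pos += n

    for ti, ts_group in enumerate(turns):
        # interviewer turn
        gap_before_int = (draw_dur("T") / 4.0
                          if rng.random() < spec.p_gap_before_interviewer
                          else 60.0)
        if gap_before_int >= 150.0 and ti > 0:
            truth.pauses.append(PauseTruth("before_interviewer",
                                           gap_before_int, cursor,
                                           cursor + gap_before_int / 1000.0))
        if ti > 0:
            emit_silence(gap_before_int)
        turn_start = cursor
        n_syll_int = 2 + int(rng.integers(0, 3))
        samples, _f0, _syl, _nuc = _render_unit(
            spec, rng, "OTHER", n_syll_int, spec.interviewer_f0_hz, cursor)
        unit_span = (cursor, cursor + samples.size / sr, "COM")
        pieces.append(samples)
        cursor = unit_span[1]
        align.turns.append((turn_start, cursor, spec.interviewer))
        align.terminated_sequences.append((turn_start, cursor, "TS"))
        align.information_units.append(unit_span)

        # tracked-speaker turn
        if rng.random() < spec.pause_p["T"]:
            dur = draw_dur("T")
            truth.pauses.append(PauseTruth("T", dur, cursor,
                                           cursor + dur / 1000.0))
            emit_silence(dur)
        turn_start = cursor
        for si, ts in enumerate(ts_group):
            if si > 0 and rng.random() < spec.pause_p["UT"]:
                dur = draw_dur("UT")
                truth.pauses.append(PauseTruth("UT", dur, cursor,
                                               cursor + dur / 1000.0))
                emit_silence(dur)
            ts_start = cursor
            for ui, unit in enumerate(ts.units):
                if ui > 0 and rng.random() < spec.pause_p["IU"]:
                    dur = draw_dur("IU")
                    truth.pauses.append(PauseTruth("IU", dur, cursor,
                                                   cursor + dur / 1000.0))
                    emit_silence(dur)
                n_syll = len(unit.words) + sum(
                    len(g["tokens"]) for g in unit.retrace_groups)
                samples, f0, syllables, nucleus = _render_unit(
                    spec, rng, unit.tag, n_syll, spec.base_f0_hz, cursor)
                start = cursor
                pieces.append(samples)
                cursor += samples.size / sr
                align.information_units.append((start, cursor, unit.tag))
                if nucleus is not None and unit.tag in ("COM", "TOP"):
                    k0, k1 = nucleus
                    syl_n = int(round(spec.syllable_ms * sr / 1000.0))
                    a, b = k0 * syl_n, (k1 + 1) * syl_n
                    truth.spans.append(SpanTruth(
                        speaker=ts.speaker, unit_role=unit.tag,
                        start_s=syllables[k0][0], end_s=syllables[k1][1],
                        n_syllables=k1 - k0 + 1,
                        f0_mean_hz=float(np.mean(f0[a:b])),
                        f0_sd_hz=float(np.std(f0[a:b])),
                        syllables=syllables))
            align.terminated_sequences.append((ts_start, cursor, ts.ts_class))
        align.turns.append((turn_start, cursor, ts.speaker))

    samples = np.concatenate(pieces) if pieces else np.zeros(1)
    return AudioSignal(samples, sr), align


def generate(spec: SynthSpec) -> SynthCorpus:
    """Full corpus: transcript + ground truth + aligned audio."""
    text, truth = gen_transcript(spec)
    audio, align = gen_audio(spec, truth)
    return SynthCorpus(spec=spec, text=text, truth=truth,
                       audio=audio, alignment=align)


def gen_patient_vs_control(spec_pair: Optional[tuple[SynthSpec, SynthSpec]] = None,
                           seed: int = 0) -> tuple[SynthCorpus, SynthCorpus]:
    """Paired corpora in the pathological and control regimes."""
    if spec_pair is None:
        spec_pair = (preset("cipps-like", seed=seed),
                     preset("control-like", seed=seed + 1))
    return generate(spec_pair[0]), generate(spec_pair[1])
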