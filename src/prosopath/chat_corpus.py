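"""Reading, validating and writing CHAT-LABLITA-style transcripts.

The transcript dialect handled here is the one used for L-AcT (Language
into Act Theory) annotation of spontaneous speech:

* one utterance line per terminated sequence (TS), prefixed ``*SPK:``;
* ``//`` marks a terminal prosodic boundary (end of TS), ``/`` a
  non-terminal one (end of a prosodic/information unit or of a scansion
  chunk inside a unit);
* ``^TAG^`` immediately after a boundary labels the information unit the
  boundary closes (COM, COB, TOP, APC, or any other L-AcT label);
* ``*word ... [/]`` brackets retracted material (false starts, repeats,
  repairs); a leading ``&`` marks a word fragment;
* any other bracketed code is preserved verbatim but not interpreted.

The parsed hierarchy is Transcript -> Turn -> TerminatedSequence ->
InformationUnit -> Token.  A companion tab-separated alignment file
carries the time intervals of turns, TSs and units so that the audio
analyses (pauses, prominence) can be anchored to the annotation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

__all__ = [
    "Token",
    "InformationUnit",
    "TerminatedSequence",
    "Turn",
    "Transcript",
    "AlignmentTier",
    "AnnotationError",
    "AlignmentError",
    "parse_transcript",
    "serialize_transcript",
    "read_alignment",
    "attach_alignment",
    "alignment_to_textgrid",
    "textgrid_to_alignment",
]

ILLOCUTION_TAGS = frozenset({"COM", "COB"})
CORE_TAGS = frozenset({"COM", "COB", "TOP", "APC"})

#: speaker codes treated as the interviewer when no role is declared
DEFAULT_INTERVIEWER_CODES = frozenset({"DOC", "INT", "INV"})


class AnnotationError(ValueError):
    """A transcript line violates the annotation conventions."""

    def __init__(self, message: str, line_no: Optional[int] = None):
        self.line_no = line_no
        if line_no is not None:
            message = f"line {line_no}: {message}"
        super().__init__(message)


class AlignmentError(ValueError):
    """An interval-annotation file is inconsistent (overlap, nesting, counts)."""


@dataclass
class Token:
    surface: str
    is_retracted: bool = False
    is_fragment: bool = False
    index_in_unit: int = -1
    retrace_group: Optional[int] = None
    codes: tuple[str, ...] = ()

    def signature(self):
        return (self.surface, self.is_retracted, self.is_fragment,
                self.retrace_group, self.codes)


@dataclass
class InformationUnit:
    tag: Optional[str]
    tokens: list[Token]
    trailing_boundary: str  # "terminal" | "non_terminal"
    time_span: Optional[tuple[float, float]] = None
    internal_boundaries: tuple[int, ...] = ()  # '/' after tokens[i]
    tag_inferred: bool = False

    @property
    def scansion_prefixes(self) -> int:
        """Untagged '/'-delimited chunks merged into this unit."""
        return len(self.internal_boundaries)

    @property
    def has_retracing(self) -> bool:
        return any(tok.is_retracted for tok in self.tokens)

    def signature(self):
        return (
            self.tag, self.trailing_boundary, self.internal_boundaries,
            self.tag_inferred, tuple(t.signature() for t in self.tokens),
        )


@dataclass
class TerminatedSequence:
    units: list[InformationUnit]
    speaker: str = "SPK"
    time_span: Optional[tuple[float, float]] = None
    line_no: Optional[int] = None

    @property
    def tokens(self) -> list[Token]:
        return [tok for u in self.units for tok in u.tokens]

    @property
    def ts_class(self) -> str:
        from .info_structure import classify_ts  # cycle-free at call time
        return classify_ts(self)

    def signature(self):
        return (self.speaker, tuple(u.signature() for u in self.units))


@dataclass
class Turn:
    speaker: str
    sequences: list[TerminatedSequence]
    time_span: Optional[tuple[float, float]] = None

    def signature(self):
        return (self.speaker, tuple(ts.signature() for ts in self.sequences))


@dataclass
class Transcript:
    turns: list[Turn]
    speakers: dict[str, str] = field(default_factory=dict)  # code -> group
    metadata: dict[str, str] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def sequences(self, speaker: Optional[str] = None,
                  groups: Optional[Iterable[str]] = None,
                  ) -> Iterator[TerminatedSequence]:
        groups = set(groups) if groups is not None else None
        for turn in self.turns:
            if speaker is not None and turn.speaker != speaker:
                continue
            if groups is not None and self.speakers.get(turn.speaker) not in groups:
                continue
            yield from turn.sequences

    def tracked_speakers(self) -> list[str]:
        """Speakers analyzed by the pipeline (patients/controls, not the interviewer)."""
        seen: list[str] = []
        for turn in self.turns:
            code = turn.speaker
            if self.speakers.get(code) != "interviewer" and code not in seen:
                seen.append(code)
        return seen

    def signature(self):
        return tuple(t.signature() for t in self.turns)


# ---------------------------------------------------------------------------
# parsing

_LEXER = re.compile(
    r"(?P<ret_end>\[/\])"
    r"|(?P<code>\[[^\]\s]+\])"
    r"|(?P<tag>\^[^\^\s]+\^)"
    r"|(?P<term>//)"
    r"|(?P<nonterm>/)"
    r"|(?P<word>[^\s/\[\]\^]+)"
)

_SPEAKER_LINE = re.compile(r"^\*(?P<code>[A-Za-z0-9]+):\s*(?P<body>.*)$")

_GROUP_NAMES = frozenset({"patient", "control", "interviewer"})


@dataclass
class _Chunk:
    tokens: list[Token] = field(default_factory=list)
    boundary: Optional[str] = None  # terminal | non_terminal
    tag: Optional[str] = None


def _lex_body(body: str, line_no: int) -> list[_Chunk]:
    """Split one utterance-line body into boundary-delimited chunks."""
    chunks: list[_Chunk] = []
    current = _Chunk()
    retract_open = False
    group_counter = 0

    def close_chunk(boundary: str) -> None:
        nonlocal current
        if not current.tokens:
            return  # stray boundary with no text: ignore silently
        current.boundary = boundary
        chunks.append(current)
        current = _Chunk()

    for m in _LEXER.finditer(body):
        kind = m.lastgroup
        text = m.group()
        if kind == "word":
            surface = text
            if surface.startswith("*"):
                if retract_open:
                    raise AnnotationError(
                        "nested '*' inside an open retracing group", line_no)
                retract_open = True
                group_counter += 1
                surface = surface[1:]
                if not surface:
                    continue  # detached '*': applies to next word
            if not surface:
                raise AnnotationError("empty token", line_no)
            current.tokens.append(Token(
                surface=surface,
                is_retracted=retract_open,
                is_fragment=surface.startswith("&"),
                retrace_group=group_counter if retract_open else None,
            ))
        elif kind == "ret_end":
            if not retract_open:
                raise AnnotationError("'[/]' without a matching '*'", line_no)
            retract_open = False
        elif kind == "code":
            target = current.tokens or (chunks[-1].tokens if chunks else None)
            if not target:
                raise AnnotationError(
                    f"bracketed code {text!r} with no preceding token", line_no)
            target[-1].codes = target[-1].codes + (text,)
        elif kind in ("term", "nonterm"):
            if retract_open:
                raise AnnotationError(
                    "unmatched '*' without '[/]' before a prosodic boundary",
                    line_no)
            close_chunk("terminal" if kind == "term" else "non_terminal")
        elif kind == "tag":
            label = text[1:-1]
            if not chunks or chunks[-1].tag is not None:
                raise AnnotationError(
                    f"tag ^{label}^ with no preceding text", line_no)
            chunks[-1].tag = label

    if retract_open:
        raise AnnotationError("unmatched '*' without '[/]'", line_no)
    if current.tokens:
        # text after the last boundary: handled by the caller as a
        # missing-terminal warning
        current.boundary = None
        chunks.append(current)
    return chunks


def _assemble_units(chunks: list[_Chunk]) -> list[InformationUnit]:
    """Merge scansion chunks and build InformationUnits for one TS.

    When the line carries explicit tags, untagged chunks are scansion and
    attach forward to the next tagged unit.  A fully untagged line is
    segmented one unit per chunk, and the terminal unit is inferred COM
    (a TS must bear an illocution).
    """
    units: list[InformationUnit] = []
    if any(c.tag for c in chunks):
        pending: list[_Chunk] = []
        for chunk in chunks:
            if chunk.tag is not None:
                units.append(_merge_chunks(pending + [chunk], chunk.tag))
                pending = []
            else:
                pending.append(chunk)
        if pending:
            units.append(_merge_chunks(pending, None))
    else:
        units = [_merge_chunks([c], None) for c in chunks]

    if not any(u.tag in ILLOCUTION_TAGS for u in units):
        last = units[-1]
        if last.tag is None:
            last.tag = "COM"
            last.tag_inferred = True
    for unit in units:
        for i, tok in enumerate(unit.tokens):
            tok.index_in_unit = i
    return units


def _merge_chunks(chunks: list[_Chunk], tag: Optional[str]) -> InformationUnit:
    tokens: list[Token] = []
    internal: list[int] = []
    for chunk in chunks[:-1]:
        tokens.extend(chunk.tokens)
        internal.append(len(tokens) - 1)
    tokens.extend(chunks[-1].tokens)
    return InformationUnit(
        tag=tag,
        tokens=tokens,
        trailing_boundary=chunks[-1].boundary or "terminal",
        internal_boundaries=tuple(internal),
    )


def _parse_participants(value: str, speakers: dict[str, str]) -> None:
    for part in value.split(","):
        fields = part.split()
        if len(fields) >= 2 and fields[-1].lower() in _GROUP_NAMES:
            speakers[fields[0]] = fields[-1].lower()


def parse_transcript(text: str, default_group: str = "patient") -> Transcript:
    """Parse CHAT-LABLITA text into the Transcript hierarchy.

    Lines starting with ``@`` are metadata; ``@Participants:`` (or
    ``@Group:``) lines of the form ``CODE ... role`` declare speaker
    groups (patient / control / interviewer).  Undeclared speakers whose
    code is DOC/INT/INV are taken to be the interviewer; any other
    undeclared speaker gets ``default_group``.  Bare lines without a
    ``*SPK:`` prefix are accepted and assigned to speaker ``SPK``.

    Consecutive same-speaker lines merge into a single Turn.
    """
    turns: list[Turn] = []
    speakers: dict[str, str] = {}
    metadata: dict[str, str] = {}
    warnings: list[str] = []

    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("@"):
            key, _, value = line[1:].partition(":")
            value = value.strip()
            metadata[key] = value
            if key.lower() in ("participants", "group"):
                _parse_participants(value, speakers)
            continue
        m = _SPEAKER_LINE.match(line)
        if m:
            code, body = m.group("code"), m.group("body")
        else:
            code, body = "SPK", line
        chunks = _lex_body(body, line_no)
        if not chunks:
            continue
        if chunks[-1].boundary != "terminal":
            warnings.append(
                f"line {line_no}: missing terminal boundary '//'; "
                "line treated as one terminated sequence")
            chunks[-1].boundary = "terminal"

        # one TS per terminal boundary (robustness: a line may hold several)
        ts_chunks: list[_Chunk] = []
        sequences: list[TerminatedSequence] = []
        for chunk in chunks:
            ts_chunks.append(chunk)
            if chunk.boundary == "terminal":
                units = _assemble_units(ts_chunks)
                sequences.append(TerminatedSequence(
                    units=units, speaker=code, line_no=line_no))
                ts_chunks = []

        if turns and turns[-1].speaker == code:
            turns[-1].sequences.extend(sequences)
        else:
            turns.append(Turn(speaker=code, sequences=sequences))

    for turn in turns:
        if turn.speaker not in speakers:
            speakers[turn.speaker] = (
                "interviewer" if turn.speaker in DEFAULT_INTERVIEWER_CODES
                else default_group)
    return Transcript(turns=turns, speakers=speakers,
                      metadata=metadata, warnings=warnings)


# ---------------------------------------------------------------------------
# serialization

def _serialize_unit(unit: InformationUnit) -> str:
    parts: list[str] = []
    open_group: Optional[int] = None
    internal = set(unit.internal_boundaries)
    for i, tok in enumerate(unit.tokens):
        if open_group is not None and tok.retrace_group != open_group:
            parts.append("[/]")
            open_group = None
        piece = tok.surface
        if tok.retrace_group is not None and tok.retrace_group != open_group:
            piece = "*" + piece
            open_group = tok.retrace_group
        parts.append(piece)
        parts.extend(tok.codes)
        if open_group is not None and (
                i + 1 == len(unit.tokens)
                or unit.tokens[i + 1].retrace_group != open_group):
            parts.append("[/]")
            open_group = None
        if i in internal:
            parts.append("/")
    boundary = "//" if unit.trailing_boundary == "terminal" else "/"
    tail = boundary
    if unit.tag is not None and not unit.tag_inferred:
        tail += f"^{unit.tag}^"
    parts.append(tail)
    return " ".join(parts)


def serialize_transcript(t: Transcript) -> str:
    """Write a Transcript back to CHAT-LABLITA text (round-trip safe).

    ``parse_transcript(serialize_transcript(t))`` is structurally equal
    to ``t`` (same hierarchy, tags, boundaries and retracing marks; time
    spans are not serialized).
    """
    lines: list[str] = []
    for key, value in t.metadata.items():
        lines.append(f"@{key}:\t{value}" if value else f"@{key}:")
    declared = {code: group for code, group in t.speakers.items()}
    if declared and "Participants" not in t.metadata:
        spec = ", ".join(f"{code} {group}" for code, group in declared.items())
        lines.append(f"@Participants:\t{spec}")
    for turn in t.turns:
        for ts in turn.sequences:
            body = " ".join(_serialize_unit(u) for u in ts.units)
            lines.append(f"*{ts.speaker}:\t{body}")
    return "\n".join(lines) + ("\n" if lines else "")


# ---------------------------------------------------------------------------
# alignment

_TIER_ALIASES = {
    "turn": "turns", "turns": "turns",
    "ts": "terminated_sequences", "terminated_sequence": "terminated_sequences",
    "terminated_sequences": "terminated_sequences",
    "iu": "information_units", "unit": "information_units",
    "units": "information_units", "information_unit": "information_units",
    "information_units": "information_units",
}

Interval = tuple[float, float, str]


@dataclass
class AlignmentTier:
    """Time intervals for the three annotation tiers, in document order.

    Within a tier the intervals are sorted and non-overlapping; unit
    intervals nest inside TS intervals and TS intervals inside turn
    intervals.
    """

    turns: list[Interval] = field(default_factory=list)
    terminated_sequences: list[Interval] = field(default_factory=list)
    information_units: list[Interval] = field(default_factory=list)

    def tier(self, name: str) -> list[Interval]:
        return getattr(self, _TIER_ALIASES[name.lower()])


def _check_sorted(name: str, intervals: Sequence[Interval]) -> None:
    for (s, e, _lab) in intervals:
        if not e > s:
            raise AlignmentError(f"{name}: empty or inverted interval [{s}, {e})")
    for (s1, e1, _l1), (s2, e2, _l2) in zip(intervals, intervals[1:]):
        if s2 < e1 - 1e-9:
            raise AlignmentError(
                f"{name}: intervals [{s1}, {e1}) and [{s2}, {e2}) overlap")


def _check_nesting(inner_name: str, inner: Sequence[Interval],
                   outer_name: str, outer: Sequence[Interval]) -> None:
    for (s, e, lab) in inner:
        if not any(os - 1e-9 <= s and e <= oe + 1e-9 for os, oe, _ in outer):
            raise AlignmentError(
                f"{inner_name} interval [{s}, {e}) ({lab!r}) does not nest "
                f"inside any {outer_name} interval")


def validate_alignment(a: AlignmentTier) -> None:
    _check_sorted("turns", a.turns)
    _check_sorted("terminated_sequences", a.terminated_sequences)
    _check_sorted("information_units", a.information_units)
    _check_nesting("TS", a.terminated_sequences, "turn", a.turns)
    _check_nesting("unit", a.information_units, "TS", a.terminated_sequences)


def read_alignment(text: str) -> AlignmentTier:
    """Parse a TSV alignment file: ``tier<TAB>start_s<TAB>end_s<TAB>label``."""
    tier_map: dict[str, list[Interval]] = {
        "turns": [], "terminated_sequences": [], "information_units": []}
    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise AlignmentError(f"line {line_no}: expected tier\\tstart\\tend[\\tlabel]")
        tier_name = _TIER_ALIASES.get(fields[0].strip().lower())
        if tier_name is None:
            raise AlignmentError(f"line {line_no}: unknown tier {fields[0]!r}")
        label = fields[3] if len(fields) > 3 else ""
        tier_map[tier_name].append((float(fields[1]), float(fields[2]), label))
    align = AlignmentTier(
        turns=sorted(tier_map["turns"]),
        terminated_sequences=sorted(tier_map["terminated_sequences"]),
        information_units=sorted(tier_map["information_units"]),
    )
    validate_alignment(align)
    return align


def write_alignment(a: AlignmentTier) -> str:
    lines = []
    for name, attr in (("turn", a.turns), ("TS", a.terminated_sequences),
                       ("IU", a.information_units)):
        for (s, e, lab) in attr:
            lines.append(f"{name}\t{s:.4f}\t{e:.4f}\t{lab}")
    return "\n".join(lines) + ("\n" if lines else "")


def attach_alignment(t: Transcript, a: AlignmentTier) -> Transcript:
    """Populate time_span fields from an AlignmentTier (in document order)."""
    turns = list(t.turns)
    sequences = [ts for turn in turns for ts in turn.sequences]
    units = [u for ts in sequences for u in ts.units]
    for name, objs, intervals in (
            ("turns", turns, a.turns),
            ("terminated_sequences", sequences, a.terminated_sequences),
            ("information_units", units, a.information_units)):
        if len(objs) != len(intervals):
            raise AlignmentError(
                f"tier {name!r}: transcript has {len(objs)} elements but "
                f"alignment has {len(intervals)} intervals "
                f"(first divergence at position {min(len(objs), len(intervals))})")
        for obj, (s, e, _lab) in zip(objs, intervals):
            obj.time_span = (s, e)
    return t


# ---------------------------------------------------------------------------
# Praat TextGrid conversion (interval tiers "turn", "TS", "IU")

def alignment_to_textgrid(a: AlignmentTier) -> str:
    """Render the alignment as a Praat long-format TextGrid."""
    tiers = [("turn", a.turns), ("TS", a.terminated_sequences),
             ("IU", a.information_units)]
    xmax = max((e for _, ivs in tiers for (_s, e, _l) in ivs), default=0.0)
    out = [
        'File type = "ooTextFile"', 'Object class = "TextGrid"', "",
        "xmin = 0", f"xmax = {xmax:.6f}", "tiers? <exists>",
        f"size = {len(tiers)}", "item []:",
    ]
    for ti, (name, ivs) in enumerate(tiers, start=1):
        out += [f"    item [{ti}]:", '        class = "IntervalTier"',
                f'        name = "{name}"', "        xmin = 0",
                f"        xmax = {xmax:.6f}",
                f"        intervals: size = {len(ivs)}"]
        for ii, (s, e, lab) in enumerate(ivs, start=1):
            out += [f"        intervals [{ii}]:",
                    f"            xmin = {s:.6f}",
                    f"            xmax = {e:.6f}",
                    f'            text = "{lab}"']
    return "\n".join(out) + "\n"


_TG_TIER = re.compile(r'name\s*=\s*"([^"]*)"')
_TG_INTERVAL = re.compile(
    r"xmin\s*=\s*([\d.eE+-]+)\s*\n\s*xmax\s*=\s*([\d.eE+-]+)"
    r'\s*\n\s*text\s*=\s*"([^"]*)"')


def textgrid_to_alignment(text: str) -> AlignmentTier:
    """Read interval tiers named turn/TS/IU from a long-format TextGrid."""
    align = AlignmentTier()
    # split on tier headers; the chunk following each name holds its intervals
    pieces = re.split(r'class\s*=\s*"IntervalTier"', text)[1:]
    for piece in pieces:
        name_m = _TG_TIER.search(piece)
        if not name_m or name_m.group(1).lower() not in _TIER_ALIASES:
            continue
        tier = align.tier(name_m.group(1))
        for (s, e, lab) in _TG_INTERVAL.findall(piece):
            start, end = float(s), float(e)
            if lab == "" and not tier:
                continue  # leading padding interval
            if lab == "":
                continue  # gaps between annotated spans
            tier.append((start, end, lab))
    validate_alignment(align)
    return align
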