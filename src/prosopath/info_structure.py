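"""Information-structure metrics over parsed transcripts.

Implements the structural layer of the profiling pipeline: classification
of terminated sequences (simple utterance / complex utterance / stanza),
per-speaker tables of TS classes and of Topic/Appendix presence, mean
length of utterance (MLU), and the Kruskal-Wallis nonparametric group
comparison used on per-TS length distributions.

Classification follows L-AcT: a *simple* utterance is a single
prosodic/information unit, necessarily a Comment (COM); a *complex*
utterance has more than one unit, one of which is the COM; a *stanza* is
a TS whose illocution is spread over Bound Comments (COB).  Scansion
chunks absorbed into a tagged unit do not count as extra units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .chat_corpus import Transcript, TerminatedSequence, ILLOCUTION_TAGS

__all__ = [
    "TSClassCounts",
    "UnitPresenceCounts",
    "MLUResult",
    "WordCountPolicy",
    "classify_ts",
    "ts_class_table",
    "unit_presence_table",
    "mlu",
    "kruskal_wallis",
    "round_pct",
]


class ClassificationError(ValueError):
    """A TS carries no illocution-bearing unit (invalid annotation)."""


def round_pct(value: float, decimals: int = 1) -> float:
    """Round half-up to the given number of decimals (table convention)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def classify_ts(ts: TerminatedSequence) -> str:
    """Classify one terminated sequence as simple / complex / stanza.

    Stanza takes precedence: any COB unit makes the TS a stanza even if
    it also hosts a Topic or Appendix.
    """
    tags = [u.tag for u in ts.units]
    if not any(t in ILLOCUTION_TAGS for t in tags):
        raise ClassificationError(
            f"TS (line {ts.line_no}) has neither COM nor COB unit")
    if "COB" in tags:
        return "stanza"
    if len(ts.units) == 1:
        return "simple"
    return "complex"


@dataclass
class TSClassCounts:
    speaker: str
    n_ts: int
    n_simple: int
    n_complex: int
    n_stanza: int

    @property
    def pct_simple(self) -> float:
        return round_pct(100.0 * self.n_simple / self.n_ts)

    @property
    def pct_complex(self) -> float:
        return round_pct(100.0 * self.n_complex / self.n_ts)

    @property
    def pct_stanza(self) -> float:
        return round_pct(100.0 * self.n_stanza / self.n_ts)


@dataclass
class UnitPresenceCounts:
    speaker: str
    n_ts: int
    n_with_top: int
    n_with_apc: int

    @property
    def pct_top(self) -> float:
        return round_pct(100.0 * self.n_with_top / self.n_ts)

    @property
    def pct_apc(self) -> float:
        return round_pct(100.0 * self.n_with_apc / self.n_ts)


@dataclass
class WordCountPolicy:
    """What counts as a word toward a TS's semantic content.

    The default mirrors the study's notion of words contributing to the
    semantic content: retracted material is replaced by its repair and
    word fragments never surface as words, so both are excluded.
    """

    count_retracted: bool = False
    count_fragments: bool = False

    def count(self, ts: TerminatedSequence) -> int:
        n = 0
        for tok in ts.tokens:
            if tok.is_retracted and not self.count_retracted:
                continue
            if tok.is_fragment and not self.count_fragments:
                continue
            n += 1
        return n


@dataclass
class MLUResult:
    speaker: str
    n_ts: int
    n_words: int
    per_ts_lengths: list[int] = field(default_factory=list)

    @property
    def mlu(self) -> float:
        return self.n_words / self.n_ts


def _select_speakers(t: Transcript,
                     speakers: Optional[Sequence[str]]) -> list[str]:
    if speakers is None:
        selected = t.tracked_speakers()
    else:
        selected = list(speakers)
    if not selected:
        raise ValueError("empty speaker selection")
    return selected


def ts_class_table(t: Transcript,
                   speakers: Optional[Sequence[str]] = None,
                   ) -> list[TSClassCounts]:
    """Per-speaker TS-class counts plus a pooled row (speaker ``ALL``).

    The pooled row sums raw counts and recomputes percentages from the
    sums (not an average of per-speaker percentages).
    """
    rows = []
    for code in _select_speakers(t, speakers):
        counts = {"simple": 0, "complex": 0, "stanza": 0}
        n_ts = 0
        for ts in t.sequences(speaker=code):
            counts[classify_ts(ts)] += 1
            n_ts += 1
        if n_ts == 0:
            raise ValueError(f"speaker {code!r} has no terminated sequences")
        rows.append(TSClassCounts(code, n_ts, counts["simple"],
                                  counts["complex"], counts["stanza"]))
    rows.append(TSClassCounts(
        "ALL",
        sum(r.n_ts for r in rows),
        sum(r.n_simple for r in rows),
        sum(r.n_complex for r in rows),
        sum(r.n_stanza for r in rows),
    ))
    return rows


def unit_presence_table(t: Transcript,
                        speakers: Optional[Sequence[str]] = None,
                        ) -> list[UnitPresenceCounts]:
    """Per-speaker counts of TSs containing >=1 TOP / >=1 APC, plus pooled.

    Presence, not multiplicity: a TS with two Topics counts once.
    """
    rows = []
    for code in _select_speakers(t, speakers):
        n_ts = n_top = n_apc = 0
        for ts in t.sequences(speaker=code):
            n_ts += 1
            tags = {u.tag for u in ts.units}
            n_top += "TOP" in tags
            n_apc += "APC" in tags
        if n_ts == 0:
            raise ValueError(f"speaker {code!r} has no terminated sequences")
        rows.append(UnitPresenceCounts(code, n_ts, n_top, n_apc))
    rows.append(UnitPresenceCounts(
        "ALL",
        sum(r.n_ts for r in rows),
        sum(r.n_with_top for r in rows),
        sum(r.n_with_apc for r in rows),
    ))
    return rows


def mlu(t: Transcript,
        speakers: Optional[Sequence[str]] = None,
        policy: Optional[WordCountPolicy] = None) -> list[MLUResult]:
    """Mean length of utterance (words per TS) per speaker."""
    policy = policy or WordCountPolicy()
    results = []
    for code in _select_speakers(t, speakers):
        lengths = [policy.count(ts) for ts in t.sequences(speaker=code)]
        if not lengths:
            raise ValueError(f"speaker {code!r} has no terminated sequences")
        results.append(MLUResult(code, len(lengths), sum(lengths), lengths))
    return results


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> dict[str, float]:
    """Kruskal-Wallis H test on >=2 groups of real values.

    H is computed on mid-ranks with the standard tie correction, and the
    p-value comes from the chi-square approximation with k-1 degrees of
    freedom.  When every value in every group is identical the statistic
    is defined as H = 0 with p = 1.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("each group needs at least one value")
    if sum(a.size for a in arrays) < 3:
        raise ValueError("need at least three values in total")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return {"H": 0.0, "p": 1.0}
    h, p = stats.kruskal(*arrays)
    return {"H": float(h), "p": float(p)}
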