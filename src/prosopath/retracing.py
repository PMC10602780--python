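"""Retracing (repair/restart) mining from parsed transcripts.

A retracing episode is one ``* ... [/]`` group: the speaker abandons the
bracketed tokens and restarts.  Adjacent groups with no intervening
non-retracted token form a *chain* (a succession of restarts on the same
stretch).  Episodes are classified

* by position in the terminated sequence: at the very start of the TS
  (``start_of_ts``), at the start of a non-first information unit
  (``start_of_iu_inside_ts``), or elsewhere (``inside_ts``);
* by kind, comparing the retracted tokens to the repair that follows:
  identical material is a total repetition, shared prefixes/fragments a
  partial repetition, anything else a modification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .chat_corpus import Transcript, TerminatedSequence, Token
from .info_structure import classify_ts, round_pct

__all__ = [
    "RetracingEpisode",
    "RetracingChain",
    "RetracingRates",
    "find_episodes",
    "retracing_events",
    "retracted_token_rate",
    "episode_rates_by_ts_type",
    "position_distribution",
]

POSITIONS = ("start_of_ts", "start_of_iu_inside_ts", "inside_ts")
KINDS = ("repetition_total", "repetition_partial", "modification")


@dataclass
class RetracingEpisode:
    ts_index: int
    unit_index: int
    token_index: int  # index_in_unit of the first retracted token
    n_retracted_tokens: int
    position: str
    kind: str
    retracted: tuple[str, ...] = ()
    repair: tuple[str, ...] = ()


@dataclass
class RetracingChain:
    episodes: list[RetracingEpisode]

    @property
    def position(self) -> str:
        return self.episodes[0].position

    @property
    def kind(self) -> str:
        return self.episodes[0].kind


@dataclass
class RetracingRates:
    """Per-speaker single-episode and chain rates by TS type.

    Rates are percentages of retracing events over the *clean* units
    (units containing no retracing) of TSs of each type; ``None`` where
    a type has no clean units.
    """

    speaker: str
    retracted_token_pct: float
    single_rate: dict[str, Optional[float]] = field(default_factory=dict)
    chain_rate: dict[str, Optional[float]] = field(default_factory=dict)
    n_singles: dict[str, int] = field(default_factory=dict)
    n_chains: dict[str, int] = field(default_factory=dict)
    n_clean_units: dict[str, int] = field(default_factory=dict)


def _core(surface: str) -> str:
    """Comparable word form: fragment marker stripped."""
    return surface.lstrip("&")


def _token_match(a: str, b: str) -> str:
    """full | partial | none comparison of two word surfaces."""
    ca, cb = _core(a), _core(b)
    if a == b or ca == cb:
        return "full" if a == b else "partial"
    if ca and cb and (ca.startswith(cb) or cb.startswith(ca)):
        return "partial"
    return "none"


def _classify_kind(retracted: Sequence[str], repair: Sequence[str]) -> str:
    if not repair:
        return "modification"  # abandoned restart, nothing to compare
    matches = [_token_match(r, p) for r, p in zip(retracted, repair)]
    if len(matches) == len(retracted) and all(m == "full" for m in matches):
        return "repetition_total"
    if any(m in ("full", "partial") for m in matches):
        return "repetition_partial"
    return "modification"


def find_episodes(ts: TerminatedSequence, ts_index: int = 0,
                  ) -> tuple[list[RetracingEpisode], list[RetracingChain]]:
    """Extract retracing episodes from one TS and group adjacent ones.

    Returns ``(episodes, chains)``; every episode appears once in
    ``episodes``, and chains reference (do not copy) their episodes.
    The repair used for kind classification is the first run of
    non-retracted tokens after the *whole* adjacent group sequence, so
    each link of a chain is judged against the eventual repair.
    """
    stream: list[tuple[int, Token]] = [
        (ui, tok) for ui, unit in enumerate(ts.units) for tok in unit.tokens]

    # group boundaries by retrace_group id
    groups: list[dict] = []
    for pos, (ui, tok) in enumerate(stream):
        if tok.retrace_group is None:
            continue
        if groups and groups[-1]["gid"] == tok.retrace_group:
            groups[-1]["end"] = pos
        else:
            groups.append({"gid": tok.retrace_group, "start": pos, "end": pos,
                           "unit": ui})

    episodes: list[RetracingEpisode] = []
    chains: list[RetracingChain] = []
    i = 0
    while i < len(groups):
        # collect maximal run of adjacent groups sharing a unit
        run = [groups[i]]
        j = i + 1
        while (j < len(groups)
               and groups[j]["start"] == run[-1]["end"] + 1
               and groups[j]["unit"] == run[0]["unit"]):
            run.append(groups[j])
            j += 1
        # repair = non-retracted tokens following the run
        repair_tokens: list[str] = []
        k = run[-1]["end"] + 1
        while k < len(stream) and not stream[k][1].is_retracted:
            repair_tokens.append(stream[k][1].surface)
            k += 1
        run_episodes = []
        for g in run:
            retracted = tuple(stream[p][1].surface
                              for p in range(g["start"], g["end"] + 1))
            ui, first_tok = stream[g["start"]]
            if ui == 0 and first_tok.index_in_unit == 0:
                position = "start_of_ts"
            elif first_tok.index_in_unit == 0:
                position = "start_of_iu_inside_ts"
            else:
                position = "inside_ts"
            run_episodes.append(RetracingEpisode(
                ts_index=ts_index,
                unit_index=ui,
                token_index=first_tok.index_in_unit,
                n_retracted_tokens=len(retracted),
                position=position,
                kind=_classify_kind(retracted,
                                    repair_tokens[:len(retracted)]),
                retracted=retracted,
                repair=tuple(repair_tokens[:len(retracted)]),
            ))
        episodes.extend(run_episodes)
        if len(run_episodes) >= 2:
            chains.append(RetracingChain(run_episodes))
        i = j
    return episodes, chains


def retracing_events(t: Transcript, speaker: Optional[str] = None,
                     ) -> tuple[list[RetracingEpisode], list[RetracingChain],
                                list[RetracingEpisode]]:
    """All episodes, chains and single (non-chained) episodes for a speaker."""
    episodes: list[RetracingEpisode] = []
    chains: list[RetracingChain] = []
    for idx, ts in enumerate(t.sequences(speaker=speaker)):
        eps, chs = find_episodes(ts, ts_index=idx)
        episodes.extend(eps)
        chains.extend(chs)
    chained = {id(e) for c in chains for e in c.episodes}
    singles = [e for e in episodes if id(e) not in chained]
    return episodes, chains, singles


def retracted_token_rate(t: Transcript, speaker: Optional[str] = None) -> float:
    """Percentage of retracted tokens over all tokens (fragments included)."""
    total = retracted = 0
    for ts in t.sequences(speaker=speaker):
        for tok in ts.tokens:
            total += 1
            retracted += tok.is_retracted
    if total == 0:
        raise ValueError("no tokens in selection")
    return 100.0 * retracted / total


TS_TYPES = ("all", "simple", "complex", "stanza")


def _rates_for(t: Transcript, code: Optional[str], label: str) -> RetracingRates:
    n_singles = {k: 0 for k in TS_TYPES}
    n_chains = {k: 0 for k in TS_TYPES}
    n_clean = {k: 0 for k in TS_TYPES}
    for idx, ts in enumerate(t.sequences(speaker=code)):
        ts_type = classify_ts(ts)
        eps, chs = find_episodes(ts, ts_index=idx)
        chained = {id(e) for c in chs for e in c.episodes}
        singles = [e for e in eps if id(e) not in chained]
        for key in ("all", ts_type):
            n_singles[key] += len(singles)
            n_chains[key] += len(chs)
            n_clean[key] += sum(1 for u in ts.units if not u.has_retracing)
    single_rate = {}
    chain_rate = {}
    for key in TS_TYPES:
        if n_clean[key] == 0:
            single_rate[key] = chain_rate[key] = None
        else:
            single_rate[key] = round_pct(100.0 * n_singles[key] / n_clean[key], 2)
            chain_rate[key] = round_pct(100.0 * n_chains[key] / n_clean[key], 2)
    return RetracingRates(
        speaker=label,
        retracted_token_pct=retracted_token_rate(t, code),
        single_rate=single_rate, chain_rate=chain_rate,
        n_singles=n_singles, n_chains=n_chains, n_clean_units=n_clean)


def episode_rates_by_ts_type(t: Transcript,
                             speakers: Optional[Sequence[str]] = None,
                             ) -> list[RetracingRates]:
    """Single-episode and chain rates by TS type, per speaker + pooled.

    The rate divides retracing events in TSs of a type by the number of
    information units of that type containing no retracing.
    """
    codes = list(speakers) if speakers is not None else t.tracked_speakers()
    if not codes:
        raise ValueError("empty speaker selection")
    rows = [_rates_for(t, code, code) for code in codes]
    if len(codes) > 1:
        merged = _pooled_rates(rows)
        total = retr = 0
        for code in codes:
            for ts in t.sequences(speaker=code):
                for tok in ts.tokens:
                    total += 1
                    retr += tok.is_retracted
        merged.retracted_token_pct = 100.0 * retr / total if total else 0.0
        rows.append(merged)
    return rows


def _pooled_rates(rows: list[RetracingRates]) -> RetracingRates:
    n_singles = {k: sum(r.n_singles[k] for r in rows) for k in TS_TYPES}
    n_chains = {k: sum(r.n_chains[k] for r in rows) for k in TS_TYPES}
    n_clean = {k: sum(r.n_clean_units[k] for r in rows) for k in TS_TYPES}
    single_rate = {}
    chain_rate = {}
    for key in TS_TYPES:
        if n_clean[key] == 0:
            single_rate[key] = chain_rate[key] = None
        else:
            single_rate[key] = round_pct(100.0 * n_singles[key] / n_clean[key], 2)
            chain_rate[key] = round_pct(100.0 * n_chains[key] / n_clean[key], 2)
    return RetracingRates(
        speaker="ALL", retracted_token_pct=float("nan"),
        single_rate=single_rate, chain_rate=chain_rate,
        n_singles=n_singles, n_chains=n_chains, n_clean_units=n_clean)


def position_distribution(t: Transcript,
                          speakers: Optional[Sequence[str]] = None,
                          ) -> dict[str, float]:
    """Percentage of retracing events per position (chains count once).

    Returns an empty dict when the selection contains no events.
    """
    codes = list(speakers) if speakers is not None else t.tracked_speakers()
    counts = {p: 0 for p in POSITIONS}
    for code in codes:
        _eps, chains, singles = retracing_events(t, speaker=code)
        for ev in singles:
            counts[ev.position] += 1
        for ch in chains:
            counts[ch.position] += 1
    total = sum(counts.values())
    if total == 0:
        return {}
    return {p: round_pct(100.0 * c / total) for p, c in counts.items()}
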