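"""Parser, serializer and alignment-file behaviour."""

import pytest

from prosopath import chat_corpus, synth
from prosopath.chat_corpus import (
    AlignmentError, AnnotationError, attach_alignment, parse_transcript,
    read_alignment, serialize_transcript, alignment_to_textgrid,
    textgrid_to_alignment,
)

from conftest import (EX_COMPLEX, EX_RETRACE_IU, EX_RETRACE_START,
                      EX_SIMPLE, EX_TWO_UNITS, parse_one)


class TestParsing:
    def test_simple_utterance_single_com(self):
        ts = parse_one(EX_SIMPLE)
        assert len(ts.units) == 1
        assert ts.units[0].tag == "COM"
        assert [t.surface for t in ts.units[0].tokens] == \
            ["faccio", "un", "po'", "di", "tutto"]

    def test_untagged_chunks_become_units_with_terminal_com(self):
        ts = parse_one(EX_TWO_UNITS)
        assert len(ts.units) == 2
        assert ts.units[0].tag is None
        assert ts.units[1].tag == "COM"
        assert [t.surface for t in ts.units[1].tokens] == ["niente"]

    def test_scansion_attaches_forward_to_tagged_unit(self):
        ts = parse_one(EX_COMPLEX)
        tags = [u.tag for u in ts.units]
        assert tags == ["TOP", "COM", "APC"]
        top, com, apc = ts.units
        # "allora /" is absorbed by the TOP, "ho iniziato a venti /" by the COM
        assert top.scansion_prefixes == 1
        assert [t.surface for t in top.tokens] == ["allora", "i'", "camionista"]
        assert com.scansion_prefixes == 1
        assert len(com.tokens) == 6
        assert apc.trailing_boundary == "terminal"
        assert top.trailing_boundary == "non_terminal"

    def test_retracing_flags(self):
        ts = parse_one(EX_RETRACE_START)
        tokens = ts.units[0].tokens
        assert tokens[0].surface == "pe'" and tokens[0].is_retracted
        assert sum(not t.is_retracted for t in tokens) == 6

    def test_fragment_tokens(self):
        ts = parse_one(EX_RETRACE_IU)
        frags = [t for u in ts.units for t in u.tokens if t.is_fragment]
        assert len(frags) == 2
        assert all(t.is_retracted for t in frags)
        assert all(t.surface == "&d" for t in frags)

    def test_terminal_boundary_is_last_and_unique(self):
        for line in (EX_SIMPLE, EX_TWO_UNITS, EX_COMPLEX):
            ts = parse_one(line)
            terminals = [u.trailing_boundary == "terminal" for u in ts.units]
            assert terminals[-1] and sum(terminals) == 1

    def test_same_speaker_lines_merge_into_one_turn(self):
        text = "*PAT:\tuno //\n*PAT:\tdue //\n*DOC:\tsi //\n*PAT:\ttre //\n"
        t = parse_transcript(text)
        assert [turn.speaker for turn in t.turns] == ["PAT", "DOC", "PAT"]
        assert len(t.turns[0].sequences) == 2

    def test_speaker_groups_and_tracking(self):
        text = "*PAT:\tuno //\n*DOC:\tsi //\n"
        t = parse_transcript(text)
        assert t.speakers == {"PAT": "patient", "DOC": "interviewer"}
        assert t.tracked_speakers() == ["PAT"]

    def test_unknown_tag_preserved(self):
        ts = parse_one("mah /^INP^ non saprei //^COM^")
        assert ts.units[0].tag == "INP"

    def test_unknown_bracketed_code_preserved(self):
        ts = parse_one("parola [!] strana //")
        assert ts.units[0].tokens[0].codes == ("[!]",)


class TestParseErrors:
    @pytest.mark.parametrize("line,fragment", [
        ("*pe' pe' dargli //", "unmatched '*'"),
        ("pe' [/] dargli //", "without a matching '*'"),
        ("^TOP^ parola //", "no preceding text"),
    ])
    def test_annotation_errors(self, line, fragment):
        with pytest.raises(AnnotationError, match=fragment):
            parse_transcript(line)

    def test_missing_terminal_boundary_is_recoverable(self):
        t = parse_transcript("una frase senza chiusura /")
        assert len(t.warnings) == 1
        assert "terminal" in t.warnings[0]
        assert len(t.turns[0].sequences) == 1


class TestRoundTrip:
    def test_complex_example_round_trips(self):
        t = parse_transcript(EX_COMPLEX)
        again = parse_transcript(serialize_transcript(t))
        assert again.signature() == t.signature()

    def test_empty_transcript(self):
        t = parse_transcript("")
        assert serialize_transcript(t) == ""

    @pytest.mark.parametrize("seed", range(100))
    def test_seeded_synthetic_round_trip(self, seed):
        spec = synth.SynthSpec(seed=seed, n_turns=2)
        text, _truth = synth.gen_transcript(spec)
        t = parse_transcript(text)
        again = parse_transcript(serialize_transcript(t))
        assert again.signature() == t.signature()

    def test_token_conservation(self, cipps_corpus):
        t = cipps_corpus.transcript
        for ts in t.sequences():
            n_re = sum(tok.is_retracted for tok in ts.tokens)
            n_ok = sum(not tok.is_retracted for tok in ts.tokens)
            assert n_re + n_ok == len(ts.tokens)


class TestAlignment:
    def test_read_valid(self):
        text = ("turn\t0\t2\tPAT\n"
                "TS\t0\t2\tTS\n"
                "IU\t0\t1\tTOP\nIU\t1\t2\tCOM\n")
        a = read_alignment(text)
        assert len(a.information_units) == 2

    def test_nesting_violation(self):
        text = ("turn\t0\t2\tPAT\n"
                "TS\t0\t1\tTS\nTS\t1\t2\tTS\n"
                "IU\t0.5\t1.5\tCOM\n")
        with pytest.raises(AlignmentError, match="nest"):
            read_alignment(text)

    def test_overlap_within_tier(self):
        text = "turn\t0\t2\tA\nturn\t1.5\t3\tB\n"
        with pytest.raises(AlignmentError, match="overlap"):
            read_alignment(text)

    def test_attach_populates_spans(self):
        t = parse_transcript("*PAT:\tuno /^TOP^ due /^COM^ tre //^APC^")
        a = read_alignment("turn\t0\t3\tPAT\nTS\t0\t3\tTS\n"
                           "IU\t0\t1\tTOP\nIU\t1\t2\tCOM\nIU\t2\t3\tAPC\n")
        attach_alignment(t, a)
        spans = [u.time_span for u in t.turns[0].sequences[0].units]
        assert spans == [(0, 1), (1, 2), (2, 3)]
        assert t.turns[0].time_span == (0, 3)

    def test_attach_count_mismatch_names_tier(self):
        t = parse_transcript("*PAT:\tuno / due //")
        a = read_alignment("turn\t0\t3\tPAT\nTS\t0\t3\tTS\n"
                           "IU\t0\t1\ta\nIU\t1\t2\tb\nIU\t2\t3\tc\n")
        with pytest.raises(AlignmentError, match="information_units"):
            attach_alignment(t, a)

    def test_synthetic_alignment_nests(self, cipps_corpus, aligned_cipps):
        chat_corpus.validate_alignment(cipps_corpus.alignment)
        for turn in aligned_cipps.turns:
            for ts in turn.sequences:
                assert turn.time_span[0] <= ts.time_span[0]
                assert ts.time_span[1] <= turn.time_span[1]
                for u in ts.units:
                    assert ts.time_span[0] <= u.time_span[0] <= u.time_span[1] \
                        <= ts.time_span[1]

    def test_textgrid_round_trip(self, cipps_corpus):
        a = cipps_corpus.alignment
        back = textgrid_to_alignment(alignment_to_textgrid(a))
        for tier in ("turns", "terminated_sequences", "information_units"):
            got = getattr(back, tier)
            want = getattr(a, tier)
            assert len(got) == len(want)
            for (s1, e1, l1), (s2, e2, l2) in zip(got, want):
                assert abs(s1 - s2) < 1e-5 and abs(e1 - e2) < 1e-5
                assert l1 == l2
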