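import numpy as np
import pytest

from prosopath import chat_corpus, synth
from prosopath.audio import AudioSignal

# printed annotation examples used across test modules
EX_SIMPLE = "faccio un po' di tutto //"
EX_TWO_UNITS = "e poi / niente //"
EX_COMPLEX = ("allora / i' camionista /^TOP^ ho iniziato a venti / "
              "tre anni /^COM^ a farlo //^APC^")
EX_STANZA = ("l' ho fatto per diversi anni /^COB^ poi mi sono messo in "
             "proprio /^COB^ s' è creato una piccola azienda /^COB^ "
             "da una piccola azienda viene poi /^COB^ quell' altra /^COB^ "
             "e via //^COB^")
EX_RETRACE_START = "*pe' [/] pe' dargli un colore più uniforme //"
EX_RETRACE_IU = ("i' ramo / *&d [/] *&d [/] d' un noce / "
                 "gl' è più chiaro d' i' fusto //")
EX_RETRACE_PARTIAL = ("a casa mia *s' era [/] gl' eran poveri / "
                      "e quindi 'un c' era / tanto da mangiare //")
EX_RETRACE_MOD = "ha fatto *le [/] il tecnico industriale //"


def parse_one(line: str):
    """Parse a single utterance line and return its only TS."""
    t = chat_corpus.parse_transcript(line)
    (turn,) = t.turns
    (ts,) = turn.sequences
    return ts


@pytest.fixture(scope="session")
def cipps_corpus():
    """Small pathological-regime corpus with audio (seeded)."""
    spec = synth.preset("cipps-like", seed=3)
    return synth.generate(spec)


@pytest.fixture(scope="session")
def control_corpus():
    spec = synth.preset("control-like", seed=4)
    return synth.generate(spec)


@pytest.fixture(scope="session")
def aligned_cipps(cipps_corpus):
    """Parsed transcript of the synthetic corpus with spans attached."""
    t = cipps_corpus.transcript
    chat_corpus.attach_alignment(t, cipps_corpus.alignment)
    return t


def harmonic_tone(f0: float, duration_s: float, sr: int = 16000,
                  n_partials: int = 3, amp: float = 0.2) -> AudioSignal:
    tt = np.arange(int(duration_s * sr)) / sr
    x = sum(amp / k * np.sin(2 * np.pi * k * f0 * tt)
            for k in range(1, n_partials + 1))
    return AudioSignal(x, sr)
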