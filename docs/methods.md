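# Methods

This note documents the models, conventions and numerical choices
behind each pipeline stage, what the synthetic generator does and does
not emulate, and the known limitations.

## Transcript model (chat_corpus)

The parser targets the CHAT-LABLITA dialect used for L-AcT annotation:
`//` terminal and `/` non-terminal prosodic boundaries, suffixed
`^TAG^` information-unit labels, `* … [/]` retracing brackets, `&`
word-fragment prefixes. The parsed hierarchy is Transcript → Turn →
TerminatedSequence (TS) → InformationUnit → Token; consecutive
same-speaker lines merge into one Turn.

Two segmentation conventions deserve explicit statement:

* **Scansion.** When a line carries at least one explicit tag, untagged
  `/`-chunks are scansion and attach *forward* to the next tagged unit
  (tags are suffixed, so a tag closes everything since the previous
  tagged unit). The absorbed chunk count is kept as
  `scansion_prefixes`; a scanned Comment is still one unit and does not
  make its TS complex.
* **Untagged lines.** A line with no tags at all is segmented one unit
  per `/`-chunk, and the terminal unit is inferred to be the COM — a TS
  must bear an illocution, and in an utterance the Comment is the unit
  carrying the terminal contour. The inferred tag is marked as such and
  is not re-serialized, so round-trips are exact.

Unknown `^TAG^` labels are preserved verbatim (the full L-AcT tagset is
open-ended here); unknown bracketed codes attach to the preceding token
untouched. Words are split on whitespace only: elided forms (`i'`,
`pe'`, `s'`) are single tokens. Lines lacking a final `//` produce a
recoverable warning and are treated as one TS.

Time alignment arrives in a TSV of `(tier, start, end, label)` rows for
three interval tiers (turn / TS / IU), validated for ordering and
nesting, with a Praat-TextGrid converter for interoperability.
Interviewer turns are parsed but excluded from every per-speaker
metric; speaker roles come from `@Participants:` headers, with DOC/INT/
INV defaulting to the interviewer role.

## Information structure (info_structure)

Classification is purely tag-driven: any COB ⇒ stanza (stanza takes
precedence over complexity, so a stanza with a Topic is still a
stanza); otherwise one unit ⇒ simple, several ⇒ complex. A TS with
neither COM nor COB is an annotation error.

MLU counts "semantic" words per TS: the default `WordCountPolicy`
excludes retracted tokens (their repair replaces them) and word
fragments, and counts everything else, fillers included. The policy is
configurable because reasonable annotation traditions differ on this
point. Percentages in all tables are rounded half-up to one decimal;
pooled rows sum raw counts and recompute percentages rather than
averaging per-speaker percentages.

The Kruskal–Wallis test delegates to `scipy.stats.kruskal` (mid-ranks,
tie correction, χ² approximation with k−1 df); the degenerate
all-values-identical case is defined as H = 0, p = 1 before scipy is
consulted. p-values are reported unadjusted.

## Silent pauses (pauses)

Detection mirrors a Praat sounding/silent segmentation: frame RMS
levels (30 ms frames, 10 ms hop) in dB; frames more than 25 dB below
the file's maximum level are silent; adjacent silent frames merge and
intervals shorter than 150 ms are dropped. The 150 ms floor is the
average stop-closure duration, so plosive closures are not counted as
pauses. Durations are floored to integer milliseconds to match the
integer bin edges (150–250, 251–500, 501–1000, ≥1001 ms); no upper cap
is applied. Both the threshold and the frame/hop sizes are parameters;
a hand-checked interval list can be supplied in place of detection.

Position classification assigns each silence by its midpoint to the
annotated gap it falls into: between two turns of different speakers ⇒
`T`, but only when the *following* turn belongs to a tracked speaker
(pauses before the turn index reaction time; silences before the
interviewer's turns are excluded); between two TSs of one turn ⇒ `UT`;
between two units of one TS ⇒ `IU`; anything else ⇒ excluded. Pause
profiles count *opportunities* (tracked turn starts, adjacent TS pairs,
adjacent unit pairs); an opportunity without a qualifying silence is a
"no pause" outcome, and percentages are over opportunities, so the
"no-pause" share is directly comparable across speakers.

## Retracing (retracing)

One `* … [/]` group is one episode; adjacent groups in the same unit
with no intervening non-retracted token form a chain. Position:
`start_of_ts` requires token index 0 of the first unit;
`start_of_iu_inside_ts` token index 0 of a later unit; everything else
is `inside_ts`. Kind compares the retracted tokens with the same number
of repair tokens — the first non-retracted run after the *whole* chain,
so every link of a chain is judged against the eventual repair:
identical surfaces ⇒ total repetition; any full or prefix/fragment
match (`&d` vs `d'`) ⇒ partial repetition; otherwise modification. An
abandoned restart with no repair is counted as modification.

Rates divide events by the *clean* information units (units containing
no retracing) of each TS type; a chain counts once as a chain and never
additionally as singles, both in rates and in the position
distribution. Types with no clean units report an absent (None) rate
rather than zero.

## Prominence acoustics (prominence)

f0 is tracked by normalized, bias-corrected autocorrelation on 40 ms
frames (10 ms hop) with a 0.55 voicing threshold, an energy gate, and
octave-error protection (the smallest lag within 90% of the best peak
wins); parabolic interpolation refines the lag, keeping errors on clean
voiced material well under 1 Hz in the 50–300 Hz default range.

Semitone statistics use per-frame conversion st = 12·log₂(f/f_ref)
with f_ref = 1 Hz by default, then mean/sd over frames — *not* the
conversion of the Hz mean, which differs whenever the contour moves.
Standard deviations are population (n) deviations: a span's frames are
the whole population of that span.

Spectral emphasis is full-band SPL minus low-band SPL on the span's
power spectrum, with the cutoff at 1.43× the span's median f0
(Traunmüller–Eriksson style) so only the fundamental sits in the low
band; a fixed 400 Hz cutoff serves as policy for unvoiced material. It
is non-negative by construction and invariant to overall gain. cvint is
the conventional coefficient of variation of the dB intensity contour,
100·σ/μ (the reciprocal is available as an option), zero for constant
contours and invariant to linear rescaling.

Nucleus selection on an f0 contour smooths with a 3-point median plus a
~20 ms moving average (guarding rise/fall landmarks against octave
spikes), takes the global maximum of the voiced run as the peak, and
places the rise start / fall end where the contour leaves its flanking
low plateau (2% of the movement's range, absorbing smoothing leakage).
The span snaps to the syllables containing the movement and can be
padded by at most two syllables per side — the conventional limit that
preserves word unity without engulfing the unit; larger requests are
clamped. Monotone or flat contours fall back, flagged, to the longest
voiced run.

Group summaries average per (speaker, role) and pool per role over
*prominences* (not speakers), carrying n per cell; prominence-weighted
pooling was chosen because corpus-level rows describe the corpus of
prominences, not an average speaker.

## Synthetic generator (synth)

`SynthSpec` fixes, per corpus: TS-class probabilities (default 0.454 /
0.409 / 0.137), conditional Topic/Appendix probabilities for non-simple
TSs (0.32 / 0.14), mean words per TS (6.5), retracing event rate per
unit (0.09) with chain fraction 0.27 and position weights (0.126,
0.549, 0.324), per-position pause probabilities (T 0.74, UT 0.42, IU
0.31) with log-uniform duration ranges, and rendering parameters (male
base f0 110 Hz, interviewer 185 Hz, 70 dB level, 180 ms syllables,
16 kHz). These defaults encode the pathological-interview regime the
pipeline profiles; `preset("control-like")` encodes the matching
non-pathological regime (fewer simple TSs and pauses, more Topics,
longer utterances, brighter Comment nuclei, COM-over-TOP orderings).
Every draw comes from one seeded NumPy generator per corpus; a fixed
(spec, seed) reproduces transcript, audio and alignment exactly.

Audio is rendered as harmonic complexes (5 partials with a configurable
dB/octave rolloff) — sufficient ground truth for f0, band-energy and
intensity measures, deliberately *not* naturalistic speech: no
formants, no coarticulation, no channel noise, no overlap or crosstalk.
Each token is one syllable; COM/COB/TOP units carry a planted
rise–peak–fall nucleus whose exact per-sample f0 statistics are
recorded; a slow (3 Hz) dB-domain amplitude modulation plants the
intensity variation. Silences are inserted at T/UT/IU opportunities
with the spec's probabilities; sub-threshold 60 ms padding precedes
interviewer turns (sometimes widened to exercise the "excluded" pause
class). Consequently, passing tests demonstrate correct *recovery of
planted structure* under clean conditions; they do not demonstrate
robustness to reverberation, spontaneous-speech voicing irregularities,
or segmentation disagreement between annotators — on real recordings
the detection thresholds and the manual-override interval input exist
precisely because automatic output needs human checking.

When an event's drawn retracing position is infeasible for the TS shape
(e.g. a unit-internal position in a one-word unit), the generator
re-places it deterministically and records the *actual* position, so
ground-truth comparisons stay exact even though realized position
frequencies can drift slightly from the configured weights in
simple-heavy corpora.

## Problem sizes and tolerances

Structural recovery tests run at ~2,000 TSs (1,000 turns, text only);
audio-bearing tests use 20–50 turn interviews (1.5–7 minutes of 16 kHz
audio), sizes at which every binomial 4σ band is a few percentage
points and each test completes in seconds. Silence-edge recovery is
asserted to one hop (10 ms) per edge; f0 recovery to 2 Hz; spectral
emphasis to 0.3 dB of closed forms; cvint closed forms exactly.

## Known limitations

* No automatic prosodic segmentation of raw audio into TSs/units and no
  automatic prominence detection: both are perceptual acts in the
  underlying methodology; the package consumes those annotations.
* The CHAT dialect coverage is the L-AcT subset described above, not
  full CHAT/CLAN (`%mor` tiers, overlap marks, etc.).
* The f0 tracker is tuned for the 50–300 Hz range of adult male
  interview speech; soprano ranges need the ceiling raised.
* No diarization: turn attribution comes entirely from the transcript
  and alignment.
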