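# artlang

Generation and diagnosis of artificial pseudoword languages for
frequency-tagging statistical-learning (SL) experiments.

`artlang` builds pseudoword lexicons under linguistic, phonotactic, and
phonological-rhythmicity controls, renders them as syllable streams with
exactly controlled transitional-probability (TP) structure, and provides
diagnostics for the result: information metrics, a Phonological Rhythmicity
Index (PRI), and amplitude-modulation spectra of rendered audio.

## What it does

1. **Phonology** — loads phoneme inventories annotated with binary
   distinctive features (a 39-phoneme German-flavoured inventory is
   bundled), parses IPA transcripts (`|` syllable / `_` phoneme
   separators), and builds syllable registers from a fixed pattern
   (default `cV`: consonant + long vowel).
2. **Corpus controls** — filters syllable and word registers toward uniform
   frequency-of-use using a z-scored log-frequency uniformity test, plus
   phoneme bigram/trigram and positional filters. A synthetic Zipf corpus
   generator stands in for real corpora (which are not redistributed).
3. **Lexicons** — samples pseudowords under obligatory-contour-principle
   (OCP) constraints on consonant place, manner, and vowel identity, then
   assembles lexicons by lazy best-first search so that word combinations
   with the least pairwise feature overlap come first.
4. **Streams** — builds balanced directed multigraphs in three TP modes
   (`word_structured`, `position_random`, `position_fixed`) and walks
   Eulerian circuits with a greedy minimum-count rule, yielding streams
   whose empirical TPs are as uniform as a finite sequence allows.
5. **Diagnostics & audio** — empirical TP matrices, online
   surprisal/entropy/KL traces, structure-aware surprisal, per-feature PRI
   with two-period kernels, isochronous audio rendering (300 ms syllables,
   common RMS), pitch-contour application, and envelope modulation spectra.

## CLI

```sh
artlang fixtures --out fixtures --seed 1        # synthetic corpus + phoneme table
artlang make-lexicons --seed 1 --output-dir out
artlang make-streams  --seed 1 --output-dir out # lexicons + streams + PRI reports
artlang render-audio  --seed 1 --output-dir out # plus WAV rendering
artlang evaluate out/stream_lex0_word_structured_0.csv
```

All commands accept `--config path.yaml`; the config surface mirrors the
published parameter sheet (stage defaults such as `n_repetitions: 15`,
`n_words_per_lexicon: 4`, `max_overlap: 1`, `tp_modes: random,
word_structured, position_controlled`), plus a global `seed` and
`output_dir`. Unknown keys are rejected.

Note: with full OCP constraints on, 4 trisyllabic words cannot be pairwise
overlap-free (each word has exactly one labial consonant in one of 3
positions — pigeonhole), so the pipeline relaxes `max_overlap` stepwise
with a logged warning when the configured bound is infeasible.

## Library example

```python
import artlang as al

table = al.default_feature_table()
syllables = al.build_syllable_register(table, "cV")
words = al.generate_word_register(syllables, table, n_words=400, seed=1)
lexicon = al.assemble_lexicons(words, n_lexicons=1, max_overlap=2, seed=1)[0]

stream = al.generate_stream(lexicon, "word_structured", n_repetitions=15, seed=1)
report = al.stream_pri_report(stream)
print(report.max_pri, report.max_feature)

wave = al.render_stream_audio(stream, al.AudioSpec())
spectrum = al.amplitude_modulation_spectrum(wave, 44_100)
print(spectrum.peak_frequency(2, 5))  # 3.33 Hz syllable rate
```
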