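"""Corpus-based register filters and a synthetic Zipf corpus generator.

Real syllable/n-gram corpora are user-supplied CSV tables; the synthetic
generator stands in for them in tests and demos.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .phonology import FeatureTable, Syllable, build_syllable_register

TokenKind = str  # "syllable" | "ngram" | "positional"


class CorpusError(ValueError):
    pass


@dataclass(frozen=True)
class FrequencyTable:
    """Token -> count (or probability) mapping of a single kind.

    Positional tokens are ``(phoneme, position)`` tuples; syllable and n-gram
    tokens are plain strings.
    """

    counts: Mapping[object, float]
    kind: TokenKind = "syllable"

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.counts.values()):
            raise CorpusError("all counts must be positive")

    def __len__(self) -> int:
        return len(self.counts)

    def __contains__(self, token) -> bool:
        return token in self.counts

    @classmethod
    def from_csv(cls, path: str | Path, kind: TokenKind = "syllable") -> "FrequencyTable":
        df = pd.read_csv(path, dtype={0: str})
        if kind == "positional":
            counts = {
                (str(r.phoneme), int(r.position)): float(r.freq)
                for r in df.itertuples()
            }
        else:
            tok_col, freq_col = df.columns[0], df.columns[-1]
            counts = dict(zip(df[tok_col].astype(str), df[freq_col].astype(float)))
        return cls(counts=counts, kind=kind)

    def to_csv(self, path: str | Path) -> None:
        if self.kind == "positional":
            rows = [
                {"phoneme": p, "position": pos, "freq": f}
                for (p, pos), f in self.counts.items()
            ]
        else:
            name = "ngram" if self.kind == "ngram" else "token"
            rows = [{name: t, "freq": f} for t, f in self.counts.items()]
        pd.DataFrame(rows).to_csv(path, index=False)


@dataclass(frozen=True)
class UniformityResult:
    """Per-token uniformity test results and the surviving token set."""

    log_freq: Mapping[object, float]
    z_score: Mapping[object, float]
    p_value: Mapping[object, float]
    alpha: float
    kept: frozenset


def uniformity_filter(freqs: FrequencyTable, alpha: float) -> UniformityResult:
    """Remove tokens whose log frequency deviates from uniformity.

    Counts are log-transformed and z-scored; each token gets a two-sided
    standard-normal tail probability, and tokens with ``p <= alpha`` are
    removed.  Constant counts have zero variance; z is defined as 0 there
    (p = 1, everything kept).  ``alpha = 0`` keeps all tokens.
    """
    if len(freqs) < 3:
        raise CorpusError("need at least 3 tokens for the uniformity test")
    if not 0.0 <= alpha <= 1.0:
        raise CorpusError(f"alpha must be in [0, 1], got {alpha}")
    tokens = list(freqs.counts)
    logf = np.log(np.array([freqs.counts[t] for t in tokens], dtype=float))
    sd = logf.std(ddof=0)
    z = np.zeros_like(logf) if sd == 0 else (logf - logf.mean()) / sd
    p = 2.0 * stats.norm.sf(np.abs(z))
    kept = frozenset(t for t, pv in zip(tokens, p) if pv > alpha)
    return UniformityResult(
        log_freq=dict(zip(tokens, logf)),
        z_score=dict(zip(tokens, z)),
        p_value=dict(zip(tokens, p)),
        alpha=alpha,
        kept=kept,
    )


def filter_syllable_register(
    register: Sequence[Syllable], freqs: FrequencyTable, alpha: float
) -> list[Syllable]:
    """Keep register syllables present in the corpus and surviving the
    uniformity filter at ``alpha``."""
    kept = uniformity_filter(freqs, alpha).kept
    out = [s for s in register if "".join(s.phonemes) in kept]
    if not out:
        raise CorpusError(
            "syllable filter removed the whole register; relax alpha or supply "
            "a richer corpus"
        )
    return out


def _word_phonemes(word: Sequence[Syllable]) -> list[str]:
    return [p for s in word for p in s.phonemes]


def word_ngrams(word: Sequence[Syllable], n: int) -> list[str]:
    """Length-``n`` windows (stride 1) over the word's flattened phoneme string."""
    ph = _word_phonemes(word)
    return ["".join(ph[i:i + n]) for i in range(len(ph) - n + 1)]


def _rejected_tokens(table: FrequencyTable, alpha: float | None) -> frozenset:
    if alpha is None:
        return frozenset()
    res = uniformity_filter(table, alpha)
    return frozenset(table.counts) - res.kept


def ngram_filter(
    words: Sequence[Sequence[Syllable]],
    ngrams: FrequencyTable,
    n: int,
    alpha: float | None = None,
) -> list[Sequence[Syllable]]:
    """Drop words containing a phoneme n-gram absent from the corpus, and —
    if ``alpha`` is set — words containing an n-gram rejected by the
    uniformity filter at that threshold."""
    rejected = _rejected_tokens(ngrams, alpha)
    out = []
    for w in words:
        grams = word_ngrams(w, n)
        if all(g in ngrams for g in grams) and not any(g in rejected for g in grams):
            out.append(w)
    if not out:
        raise CorpusError(
            f"{n}-gram filter removed the whole register; relax thresholds or "
            "disable the control"
        )
    return out


def positional_filter(
    words: Sequence[Sequence[Syllable]],
    positional: FrequencyTable,
    position: int | None = None,
    alpha: float | None = None,
) -> list[Sequence[Syllable]]:
    """Drop words whose phoneme never (or too rarely) occupies its word
    position.  Positions index syllables (0-based); ``None`` checks all."""
    rejected = _rejected_tokens(positional, alpha)
    out = []
    for w in words:
        ok = True
        for pos, syl in enumerate(w):
            if position is not None and pos != position:
                continue
            for p in syl.phonemes:
                tok = (p, pos)
                if tok not in positional or tok in rejected:
                    ok = False
        if ok:
            out.append(w)
    if not out:
        raise CorpusError(
            "positional filter removed the whole register; relax thresholds or "
            "disable the control"
        )
    return out


@dataclass(frozen=True)
class CorpusTables:
    """Bundle of synthetic corpus statistics over one syllable inventory."""

    syllables: FrequencyTable
    bigrams: FrequencyTable
    trigrams: FrequencyTable
    positional: FrequencyTable

    def write(self, directory: str | Path) -> dict[str, Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name in ("syllables", "bigrams", "trigrams", "positional"):
            paths[name] = directory / f"{name}.csv"
            getattr(self, name).to_csv(paths[name])
        return paths


def generate_synthetic_corpus(
    n_tokens: int,
    zipf_s: float,
    seed: int,
    register: Sequence[Syllable] | None = None,
    table: FeatureTable | None = None,
    pattern: str = "cV",
    n_syllables_per_word: int = 3,
) -> CorpusTables:
    """Draw a Zipf-distributed pseudo-corpus over a syllable register.

    Rank ``r`` (seeded random rank assignment) receives expected count
    proportional to ``r**-zipf_s``.  ``n_tokens`` pseudo-utterances of
    ``n_syllables_per_word`` syllables are sampled, from which syllable,
    phoneme bigram/trigram, and positional tables are accumulated.
    Deterministic for a fixed seed.
    """
    if n_tokens < 1:
        raise CorpusError("n_tokens must be >= 1")
    if register is None:
        if table is None:
            from .phonology import default_feature_table

            table = default_feature_table()
        register = build_syllable_register(table, pattern)
    rng = np.random.default_rng(seed)
    n = len(register)
    ranks = rng.permutation(n) + 1
    weights = ranks.astype(float) ** -zipf_s
    probs = weights / weights.sum()

    syll_counts: dict[str, float] = {}
    bigram_counts: dict[str, float] = {}
    trigram_counts: dict[str, float] = {}
    pos_counts: dict[tuple[str, int], float] = {}
    draws = rng.choice(n, size=(n_tokens, n_syllables_per_word), p=probs)
    for row in draws:
        word = [register[i] for i in row]
        for s in word:
            key = "".join(s.phonemes)
            syll_counts[key] = syll_counts.get(key, 0) + 1
        for g in word_ngrams(word, 2):
            bigram_counts[g] = bigram_counts.get(g, 0) + 1
        for g in word_ngrams(word, 3):
            trigram_counts[g] = trigram_counts.get(g, 0) + 1
        for pos, s in enumerate(word):
            for p in s.phonemes:
                pos_counts[(p, pos)] = pos_counts.get((p, pos), 0) + 1
    return CorpusTables(
        syllables=FrequencyTable(syll_counts, kind="syllable"),
        bigrams=FrequencyTable(bigram_counts, kind="ngram"),
        trigrams=FrequencyTable(trigram_counts, kind="ngram"),
        positional=FrequencyTable(pos_counts, kind="positional"),
    )
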