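"""Pseudoword generation under OCP constraints and lexicon assembly with
minimal pairwise phonological feature overlap.

A word's feature matrix stacks, per syllable, the designated feature subset
of each phoneme slot (consonant features from ``c`` slots, vowel features
from vowel slots).  Two words *overlap* on a feature when their per-syllable
binary sequences for that feature are identical and non-constant: such a
sequence repeats at the word period in a stream and confounds the
transition-probability rhythm.
"""

from __future__ import annotations

import heapq
import itertools
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

from .phonology import (
    FeatureTable,
    SYLLABLE_SEP,
    Syllable,
    parse_ipa,
    phono_class_of,
    slot_feature_names,
)


class LexiconError(ValueError):
    pass


@dataclass(frozen=True)
class Word:
    """An ordered sequence of syllables with a features-by-syllable matrix."""

    syllables: tuple[Syllable, ...]
    feature_matrix: np.ndarray  # (n_features, S) binary
    feature_names: tuple[str, ...]

    @property
    def n_syllables(self) -> int:
        return len(self.syllables)

    @property
    def id(self) -> str:
        return SYLLABLE_SEP.join(s.id for s in self.syllables)

    def __str__(self) -> str:
        return self.id

    def __hash__(self) -> int:
        return hash(self.syllables)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Word):
            return NotImplemented
        return self.syllables == other.syllables


def make_word(syllables: Sequence[Syllable]) -> Word:
    pattern = syllables[0].pattern
    if any(s.pattern != pattern for s in syllables):
        raise LexiconError("all syllables of a word must share the pattern")
    # each slot's feature block is nonzero only in its own column, so .any(axis=1)
    # recovers the stacked per-slot feature vector of the syllable
    mat = np.stack([s.feature_matrix.any(axis=1) for s in syllables], axis=1)
    names = slot_feature_names(pattern)
    return Word(syllables=tuple(syllables), feature_matrix=mat.astype(bool), feature_names=names)


def words_from_ipa(text: str, table: FeatureTable) -> list[Word]:
    return [make_word(w) for w in parse_ipa(text, table)]


def generate_word_register(
    syllables: Sequence[Syllable],
    table: FeatureTable,
    n_syllables_per_word: int = 3,
    n_words: int = 10_000,
    max_word_tries: int = 100_000,
    ocp_place: bool = True,
    ocp_manner: bool = True,
    ocp_vowel: bool = True,
    n_look_back: int = 2,
    seed: int = 0,
) -> list[Word]:
    """Sample pseudowords whose adjacent syllables avoid repeated
    phono-articulatory classes.

    A candidate syllable is rejected when, within the previous
    ``n_look_back`` syllables of the word under construction, any enabled
    class (consonant place, consonant manner, vowel identity) repeats.
    Sampling stops after ``n_words`` distinct words or ``max_word_tries``
    attempts, whichever comes first.
    """
    if not syllables:
        raise LexiconError("empty syllable register")
    if n_look_back < 1:
        raise LexiconError("n_look_back must be >= 1")
    rng = np.random.default_rng(seed)

    classes = {}
    for s in syllables:
        places, manners, vowels = set(), set(), set()
        for p in s.phonemes:
            pc = phono_class_of(p, table)
            if pc.vowel_id is not None:
                vowels.add(pc.vowel_id)
            else:
                places.add(pc.place)
                manners.add(pc.manner)
        classes[s] = (frozenset(places), frozenset(manners), frozenset(vowels))

    def conflicts(candidate: Syllable, prefix: list[Syllable]) -> bool:
        cp, cm, cv = classes[candidate]
        for prev in prefix[-n_look_back:]:
            pp, pm, pv = classes[prev]
            if ocp_place and cp & pp:
                return True
            if ocp_manner and cm & pm:
                return True
            if ocp_vowel and cv & pv:
                return True
        return False

    register: list[Word] = []
    seen: set[tuple[Syllable, ...]] = set()
    tries = 0
    any_completed = False
    pool = list(syllables)
    while len(register) < n_words and tries < max_word_tries:
        tries += 1
        prefix: list[Syllable] = []
        ok = True
        for _ in range(n_syllables_per_word):
            order = rng.permutation(len(pool))
            chosen = None
            for i in order:
                if not conflicts(pool[i], prefix):
                    chosen = pool[i]
                    break
            if chosen is None:
                ok = False
                break
            prefix.append(chosen)
        if not ok:
            continue
        any_completed = True
        key = tuple(prefix)
        if key in seen:
            continue
        seen.add(key)
        register.append(make_word(prefix))
    if not register and not any_completed:
        raise LexiconError(
            "no word could be completed under the OCP constraints; disable "
            "controls or reduce n_look_back (register too small)"
        )
    return register


def pair_overlap(a: Word, b: Word, lag: int | None = None) -> tuple[np.ndarray, int]:
    """Per-feature overlap flags between two words and their sum.

    A feature is flagged when the two per-syllable binary sequences are
    identical and non-constant (neither all-absent nor all-present): only
    such sequences impose a rhythm at the word rate.  ``lag`` other than the
    word length (the default) cyclically shifts ``b``'s sequences by
    ``lag - S`` before comparison (experimental).
    """
    if a.n_syllables != b.n_syllables:
        raise LexiconError("words must have the same number of syllables")
    fa = a.feature_matrix
    fb = b.feature_matrix
    S = a.n_syllables
    if lag is not None and lag != S:
        fb = np.roll(fb, lag - S, axis=1)
    same = (fa == fb).all(axis=1)
    non_constant = fa.any(axis=1) & ~fa.all(axis=1)
    flags = same & non_constant
    return flags, int(flags.sum())


def overlap_matrix(words: Sequence[Word], lag: int | None = None) -> np.ndarray:
    """Symmetric matrix of pairwise overlap counts, zero diagonal."""
    n = len(words)
    mat = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            _, tot = pair_overlap(words[i], words[j], lag=lag)
            mat[i, j] = mat[j, i] = tot
    return mat


@dataclass(frozen=True)
class Lexicon:
    """A small ordered set of pseudowords with its pairwise overlap matrix."""

    words: tuple[Word, ...]
    overlap: np.ndarray

    @property
    def total_overlap(self) -> int:
        return int(self.overlap[np.triu_indices(len(self.words), 1)].sum())

    @property
    def n_words(self) -> int:
        return len(self.words)

    @property
    def n_syllables_per_word(self) -> int:
        return self.words[0].n_syllables

    @property
    def syllables(self) -> list[Syllable]:
        return [s for w in self.words for s in w.syllables]

    def to_dict(self) -> dict:
        return {
            "words": [w.id for w in self.words],
            "overlap": self.overlap.tolist(),
            "total_overlap": self.total_overlap,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, ensure_ascii=False))


def iter_lexicons(
    register: Sequence[Word],
    n_words_per_lexicon: int = 4,
    max_word_matrix: int = 200,
    max_overlap: int | None = 1,
    unique_words: bool = False,
    binary_feature_control: bool = True,
    lag: int | None = None,
    seed: int = 0,
) -> Iterator[Lexicon]:
    """Yield lexicons lazily in non-decreasing total-overlap order.

    A seeded subsample of ``max_word_matrix`` register words is drawn and its
    overlap matrix computed once; lexicons (word combinations) are then
    produced by uniform-cost best-first search over the combination lattice,
    so the first yield attains the global minimum total overlap.  With
    ``binary_feature_control``, combinations containing a pair with overlap
    ``>= max_overlap`` are pruned.  With ``unique_words``, later lexicons
    share no word with earlier ones.  Ties are broken by a seeded random key.
    """
    words = list(dict.fromkeys(register))  # dedupe, keep order
    if len(words) < n_words_per_lexicon:
        raise LexiconError(
            f"register has {len(words)} words, need {n_words_per_lexicon}"
        )
    rng = np.random.default_rng(seed)
    if len(words) > max_word_matrix:
        idx = rng.choice(len(words), size=max_word_matrix, replace=False)
        words = [words[i] for i in sorted(idx)]
    mat = overlap_matrix(words, lag=lag)
    n = len(words)
    k = n_words_per_lexicon
    limit = max_overlap if (binary_feature_control and max_overlap is not None) else None

    if limit is not None:
        best_pair = mat[np.triu_indices(n, 1)].min() if n > 1 else 0
        admissible = mat < limit
        np.fill_diagonal(admissible, False)
        if not any(
            admissible[i, j]
            for i in range(n) for j in range(i + 1, n)
        ) and k > 1:
            raise LexiconError(
                f"no admissible lexicon under max_overlap={limit}; minimal "
                f"achievable pairwise overlap is {best_pair}"
            )

    used: set[Word] = set()
    syl_sets = [set(w.syllables) for w in words]
    # heap entries: (partial total overlap, tiebreak, member indices, next index)
    heap: list[tuple[int, float, tuple[int, ...], int]] = [
        (0, float(rng.random()), (), 0)
    ]
    yielded_any = False
    while heap:
        total, _, members, start = heapq.heappop(heap)
        if len(members) == k:
            if unique_words and any(words[i] in used for i in members):
                continue
            chosen = [words[i] for i in members]
            if unique_words:
                used.update(chosen)
            sub = mat[np.ix_(members, members)]
            yielded_any = True
            yield Lexicon(words=tuple(chosen), overlap=sub)
            continue
        for j in range(start, n):
            if unique_words and words[j] in used:
                continue
            # words sharing a syllable would break stream token accounting
            # (per-syllable repetition counts, no-immediate-repeat)
            if any(syl_sets[j] & syl_sets[i] for i in members):
                continue
            add = sum(mat[i, j] for i in members)
            if limit is not None and any(mat[i, j] >= limit for i in members):
                continue
            heapq.heappush(
                heap, (total + add, float(rng.random()), members + (j,), j + 1)
            )
    if not yielded_any:
        best_pair = mat[np.triu_indices(n, 1)].min() if n > 1 else 0
        raise LexiconError(
            f"no {k}-word combination with all pairwise overlaps < {limit} in "
            f"the subsample (minimal pairwise overlap achieved: {best_pair}); "
            "raise max_overlap or disable binary_feature_control"
        )


def assemble_lexicons(
    register: Sequence[Word],
    n_lexicons: int = 2,
    n_words_per_lexicon: int = 4,
    max_word_matrix: int = 200,
    max_overlap: int | None = 1,
    unique_words: bool = False,
    binary_feature_control: bool = True,
    lag: int | None = None,
    seed: int = 0,
) -> list[Lexicon]:
    """First ``n_lexicons`` lexicons from :func:`iter_lexicons`."""
    it = iter_lexicons(
        register,
        n_words_per_lexicon=n_words_per_lexicon,
        max_word_matrix=max_word_matrix,
        max_overlap=max_overlap,
        unique_words=unique_words,
        binary_feature_control=binary_feature_control,
        lag=lag,
        seed=seed,
    )
    out = list(itertools.islice(it, n_lexicons))
    if not out:
        raise LexiconError("no lexicon could be assembled")
    return out


def random_lexicons(
    register: Sequence[Word],
    n_lexicons: int,
    n_words_per_lexicon: int = 4,
    seed: int = 0,
) -> list[Lexicon]:
    """Uncontrolled baseline: uniformly sampled word combinations."""
    words = list(dict.fromkeys(register))
    if len(words) < n_words_per_lexicon:
        raise LexiconError("register too small")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_lexicons):
        for _try in range(1000):
            idx = rng.choice(len(words), size=n_words_per_lexicon, replace=False)
            chosen = [words[i] for i in idx]
            syls = [s for w in chosen for s in w.syllables]
            if len(set(syls)) == len(syls):  # streams need distinct syllables
                break
        else:
            raise LexiconError("could not draw words with distinct syllables")
        out.append(Lexicon(words=tuple(chosen), overlap=overlap_matrix(chosen)))
    return out


def write_register(words: Sequence[Word], path: str | Path) -> None:
    Path(path).write_text("\n".join(w.id for w in words) + "\n", encoding="utf-8")


def read_register(path: str | Path, table: FeatureTable) -> list[Word]:
    return words_from_ipa(Path(path).read_text(encoding="utf-8"), table)
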