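"""Phoneme inventories, distinctive features, syllables, and IPA parsing.

Phonemes are annotated with binary distinctive-feature vectors loaded from a
CSV inventory.  Syllables are built from a fixed pattern over consonant and
vowel slots; words are ``|``-separated strings of ``_``-separated phonemes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: The canonical distinctive features every inventory is expected to accept.
CANONICAL_FEATURES = (
    "syl", "son", "cons", "cont", "delrel", "lat", "nas", "strid",
    "voi", "sg", "cg", "ant", "cor", "distr", "lab", "hi", "lo",
    "back", "rnd", "tense", "long",
)

#: Default feature subsets carried as annotations (consonant slots / vowel slots).
DEFAULT_CONSONANT_FEATURES = ("son", "cont", "lat", "nas", "voi", "cor", "lab", "hi", "back")
DEFAULT_VOWEL_FEATURES = ("lab", "hi", "lo", "back", "tense", "long")

SYLLABLE_SEP = "|"
PHONEME_SEP = "_"

#: Length marker that does not count against the single-character restriction.
_LENGTH_MARK = "ː"


class PhonologyError(ValueError):
    """Raised on malformed inventories, patterns, or transcripts."""


@dataclass(frozen=True)
class FeatureTable:
    """Mapping from phoneme symbols to binary feature vectors.

    ``entries[p]`` is a boolean vector ordered like ``feature_names``
    (``True`` = feature present).
    """

    entries: Mapping[str, np.ndarray]
    feature_names: tuple[str, ...]

    def __post_init__(self) -> None:
        n = len(self.feature_names)
        for sym, vec in self.entries.items():
            if vec.shape != (n,):
                raise PhonologyError(
                    f"feature vector of {sym!r} has length {vec.shape}, expected {n}"
                )

    def __contains__(self, phoneme: str) -> bool:
        return phoneme in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def phonemes(self) -> list[str]:
        return list(self.entries)

    def vector(self, phoneme: str) -> np.ndarray:
        try:
            return self.entries[phoneme]
        except KeyError:
            raise PhonologyError(f"unknown phoneme {phoneme!r}") from None

    def has(self, phoneme: str, feature: str) -> bool:
        try:
            idx = self.feature_names.index(feature)
        except ValueError:
            raise PhonologyError(f"unknown feature {feature!r}") from None
        return bool(self.vector(phoneme)[idx])

    def is_vowel(self, phoneme: str) -> bool:
        # vowel status keyed on syllabicity
        return self.has(phoneme, "syl")

    def subset(self, feature_subset: Sequence[str]) -> "FeatureTable":
        unknown = [f for f in feature_subset if f not in self.feature_names]
        if unknown:
            raise PhonologyError(f"unknown feature name(s) in subset: {unknown}")
        idx = [self.feature_names.index(f) for f in feature_subset]
        return FeatureTable(
            entries={p: v[idx] for p, v in self.entries.items()},
            feature_names=tuple(feature_subset),
        )

    def restrict_phonemes(self, keep: Iterable[str]) -> "FeatureTable":
        keep = set(keep)
        return FeatureTable(
            entries={p: v for p, v in self.entries.items() if p in keep},
            feature_names=self.feature_names,
        )


def _is_simple_symbol(symbol: str) -> bool:
    """Single IPA character; a trailing length mark is tolerated."""
    core = symbol.rstrip(_LENGTH_MARK)
    return len(core) == 1


def load_feature_table(
    path: str | Path,
    feature_subset: Sequence[str] | None = None,
    *,
    single_char_only: bool = True,
) -> FeatureTable:
    """Load a phoneme inventory from CSV (``phoneme,<f1>,<f2>,...``).

    Cell values ``+``/``1`` mean *present*; anything else (``-``, ``0``)
    means *absent*.  By default multi-character (coarticulated) symbols are
    dropped; a trailing length mark (``ː``) does not count.

    Parameters
    ----------
    path
        CSV file with a ``phoneme`` column and one column per feature.
    feature_subset
        Restrict the table to these features (order preserved).
    single_char_only
        Drop phonemes whose symbol is not a single IPA character.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "phoneme" not in df.columns:
        raise PhonologyError(f"{path}: missing 'phoneme' column")
    symbols = df["phoneme"].tolist()
    dupes = {s for s in symbols if symbols.count(s) > 1}
    if dupes:
        raise PhonologyError(f"duplicate phoneme symbol(s): {sorted(dupes)}")
    features = tuple(c for c in df.columns if c != "phoneme")
    present = df[list(features)].isin(["+", "1"]).to_numpy(dtype=bool)
    entries: dict[str, np.ndarray] = {}
    for i, sym in enumerate(symbols):
        if single_char_only and not _is_simple_symbol(sym):
            continue
        entries[sym] = present[i]
    table = FeatureTable(entries=entries, feature_names=features)
    if feature_subset is not None:
        table = table.subset(feature_subset)
    return table


def default_feature_table(**kwargs) -> FeatureTable:
    """The bundled toy inventory (German-flavoured CV phonemes)."""
    with resources.as_file(
        resources.files("artlang.data").joinpath("phonemes.csv")
    ) as p:
        return load_feature_table(p, **kwargs)


@dataclass(frozen=True)
class Syllable:
    """A fixed-pattern sequence of phonemes with per-slot feature columns."""

    phonemes: tuple[str, ...]
    pattern: str
    feature_matrix: np.ndarray  # (n_selected_features, len(pattern)) binary

    def __post_init__(self) -> None:
        if len(self.phonemes) != len(self.pattern):
            raise PhonologyError(
                f"{self.id}: {len(self.phonemes)} phonemes for pattern {self.pattern!r}"
            )
        if self.feature_matrix.shape[1] != len(self.pattern):
            raise PhonologyError(f"{self.id}: feature matrix column mismatch")

    @property
    def id(self) -> str:
        return PHONEME_SEP.join(self.phonemes)

    def __str__(self) -> str:
        return self.id

    def __hash__(self) -> int:
        return hash((self.phonemes, self.pattern))

    def __eq__(self, other) -> bool:
        if not isinstance(other, Syllable):
            return NotImplemented
        return self.phonemes == other.phonemes and self.pattern == other.pattern


@dataclass(frozen=True)
class PhonoClass:
    """Phono-articulatory class of a phoneme (place x manner, or vowel identity)."""

    place: str | None  # labial | apical | other (consonants)
    manner: str | None  # sonorant | plosive | fricative (consonants)
    vowel_id: str | None  # the symbol itself for vowels


def phono_class_of(phoneme: str, table: FeatureTable) -> PhonoClass:
    """Collapse distinctive features into place/manner classes.

    Place: labial if [lab]; else apical if [cor]; else other.
    Manner: sonorant if [son]; else fricative if [cont]; else plosive.
    Vowels map to their own identity instead.
    """
    if table.is_vowel(phoneme):
        return PhonoClass(place=None, manner=None, vowel_id=phoneme)
    if table.has(phoneme, "lab"):
        place = "labial"
    elif table.has(phoneme, "cor"):
        place = "apical"
    else:
        place = "other"
    if table.has(phoneme, "son"):
        manner = "sonorant"
    elif table.has(phoneme, "cont"):
        manner = "fricative"
    else:
        manner = "plosive"
    return PhonoClass(place=place, manner=manner, vowel_id=None)


def _slot_features(slot: str) -> tuple[str, ...]:
    return DEFAULT_VOWEL_FEATURES if slot in "vV" else DEFAULT_CONSONANT_FEATURES


def slot_feature_names(pattern: str) -> tuple[str, ...]:
    """Row labels of a syllable/word feature matrix for ``pattern``.

    Each slot contributes its designated subset (consonant features for ``c``
    slots, vowel features for ``v``/``V`` slots), prefixed by slot index.
    """
    names: list[str] = []
    for i, slot in enumerate(pattern):
        names.extend(f"{slot}{i}:{f}" for f in _slot_features(slot))
    return tuple(names)


def _slot_values(phoneme: str, slot: str, table: FeatureTable) -> np.ndarray:
    """Designated feature values of a phoneme; features missing from the
    table count as absent."""
    vec = table.vector(phoneme)
    return np.array(
        [
            vec[table.feature_names.index(f)] if f in table.feature_names else False
            for f in _slot_features(slot)
        ],
        dtype=bool,
    )


def syllable_feature_vector(phonemes: Sequence[str], pattern: str, table: FeatureTable) -> np.ndarray:
    """Stacked per-slot feature values: one binary vector per syllable."""
    return np.concatenate(
        [_slot_values(p, slot, table) for slot, p in zip(pattern, phonemes)]
    )


def _eligible(table: FeatureTable, slot: str) -> list[str]:
    if slot == "c":
        return [p for p in table.phonemes if not table.is_vowel(p)]
    if slot == "v":
        return [
            p for p in table.phonemes
            if table.is_vowel(p) and not table.has(p, "long")
        ]
    if slot == "V":
        return [
            p for p in table.phonemes
            if table.is_vowel(p) and table.has(p, "long")
        ]
    raise PhonologyError(f"unknown slot symbol {slot!r} (use 'c', 'v' or 'V')")


def make_syllable(phonemes: Sequence[str], pattern: str, table: FeatureTable) -> Syllable:
    n_feat = sum(len(_slot_features(s)) for s in pattern)
    mat = np.zeros((n_feat, len(pattern)), dtype=bool)
    row = 0
    for col, (slot, p) in enumerate(zip(pattern, phonemes)):
        vals = _slot_values(p, slot, table)
        mat[row:row + len(vals), col] = vals
        row += len(vals)
    return Syllable(phonemes=tuple(phonemes), pattern=pattern, feature_matrix=mat)


def build_syllable_register(table: FeatureTable, pattern: str) -> list[Syllable]:
    """Cartesian product of eligible phonemes per slot, lexicographic order.

    Pattern grammar: ``c`` consonant, ``v`` short vowel, ``V`` long vowel.
    """
    if not pattern:
        raise PhonologyError("empty syllable pattern")
    pools = []
    for slot in pattern:
        pool = sorted(_eligible(table, slot))
        if not pool:
            raise PhonologyError(f"no eligible phonemes for slot {slot!r} in pattern {pattern!r}")
        pools.append(pool)
    return [make_syllable(combo, pattern, table) for combo in itertools.product(*pools)]


def parse_ipa(text: str, table: FeatureTable, pattern: str | None = None) -> list[list[Syllable]]:
    """Parse a transcript into words of syllables.

    One word per line; syllables separated by ``|``, phonemes by ``_``.
    All words must share the same syllable count and phoneme pattern.
    """
    words: list[list[Syllable]] = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        syllables: list[Syllable] = []
        for syl_str in line.split(SYLLABLE_SEP):
            phonemes = syl_str.split(PHONEME_SEP)
            for p in phonemes:
                if p not in table:
                    raise PhonologyError(
                        f"unknown phoneme {p!r} in word {line!r}"
                    )
            pat = pattern
            if pat is None:
                pat = "".join(
                    ("V" if table.has(p, "long") else "v") if table.is_vowel(p) else "c"
                    for p in phonemes
                )
            syllables.append(make_syllable(phonemes, pat, table))
        words.append(syllables)
    if words:
        n0 = len(words[0])
        pat0 = tuple(s.pattern for s in words[0])
        for w in words[1:]:
            if len(w) != n0 or tuple(s.pattern for s in w) != pat0:
                raise PhonologyError(
                    "ragged register: all words must share syllable count and pattern "
                    f"(expected {n0} syllables of pattern {pat0})"
                )
    return words


def render_ipa(word: Sequence[Syllable]) -> str:
    """Inverse of :func:`parse_ipa` for a single word."""
    return SYLLABLE_SEP.join(s.id for s in word)
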