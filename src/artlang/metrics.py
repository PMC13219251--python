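"""Stream diagnostics: empirical TP matrices, online information traces,
structure-aware surprisal, and the Phonological Rhythmicity Index (PRI).

The PRI slides two-period binary kernels over each phonological feature's
presence/absence sequence along the stream and reports the fraction of
windows exactly matching any kernel: 1 means the feature is perfectly
periodic at the word rate, 0 means no such pattern anywhere.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .streams import Stream


class MetricsError(ValueError):
    pass


def empirical_tp(stream: Stream) -> tuple[list[str], np.ndarray]:
    """Final-position row-normalized transition counts.

    Rows with no outgoing observations stay all-zero.
    """
    if len(stream) < 2:
        raise MetricsError("stream too short")
    alphabet, counts = stream.transition_counts()
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        tp = np.where(totals > 0, counts / np.maximum(totals, 1), 0.0)
    return alphabet, tp


def boundary_tps(stream: Stream) -> np.ndarray:
    """Empirical TPs realized at word-boundary transitions.

    For annotated streams (word_structured / position_fixed), boundaries are
    positions where the next token starts a new word; for unannotated
    streams every transition counts.
    """
    alphabet, tp = empirical_tp(stream)
    index = {t: i for i, t in enumerate(alphabet)}
    vals = []
    for t in range(len(stream) - 1):
        pos = stream.word_position[t + 1]
        if pos is None or pos == 0:
            vals.append(tp[index[stream.tokens[t]], index[stream.tokens[t + 1]]])
    return np.asarray(vals)


@dataclass
class InfoTrace:
    """Per-position surprisal and per-source entropy/divergence traces (bits)."""

    surprisal: np.ndarray  # S(t), t = 1..T-1
    entropy: np.ndarray  # H(t) averaged over observed sources
    divergence: np.ndarray  # D(t) = log2(N-1) - H(t)
    n_tokens: int  # alphabet size N


def info_traces(stream: Stream) -> InfoTrace:
    """Online surprisal, mean conditional entropy, and KL distance to the
    uniform transition distribution.

    Surprisal at position ``t`` uses counts observed strictly before ``t``
    with add-one smoothing over the ``N - 1`` admissible successors (raw
    counts give infinite surprisal on first encounters).  Entropy and
    divergence use raw normalized counts with the ``0 log 0 = 0``
    convention; ``D(t) = log2(N-1) - H(t) >= 0`` vanishes exactly at
    perfectly uniform counts.
    """
    if len(stream) < 2:
        raise MetricsError("stream too short")
    alphabet = sorted(set(stream.tokens))
    N = len(alphabet)
    index = {t: i for i, t in enumerate(alphabet)}
    counts = np.zeros((N, N), dtype=float)
    surprisal, entropy, divergence = [], [], []
    log_uniform = np.log2(N - 1) if N > 1 else 0.0
    toks = [index[t] for t in stream.tokens]
    for t in range(len(toks) - 1):
        i, j = toks[t], toks[t + 1]
        # surprisal of the observed transition under add-one smoothing
        smoothed = counts[i, j] + 1.0
        total = counts[i].sum() + (N - 1)
        surprisal.append(-np.log2(smoothed / total))
        counts[i, j] += 1.0
        # entropy averaged over sources with observations, raw counts
        row_totals = counts.sum(axis=1)
        hs = []
        for s in range(N):
            if row_totals[s] == 0:
                continue
            p = counts[s] / row_totals[s]
            nz = p[p > 0]
            hs.append(float(-(nz * np.log2(nz)).sum()))
        H = float(np.mean(hs))
        entropy.append(H)
        divergence.append(log_uniform - H)
    return InfoTrace(
        surprisal=np.asarray(surprisal),
        entropy=np.asarray(entropy),
        divergence=np.asarray(divergence),
        n_tokens=N,
    )


def structure_aware_surprisal(stream: Stream, n_words: int | None = None) -> np.ndarray:
    """Surprisal under a model that already knows the word structure:
    0 within words, ``log2(W - 1)`` at word boundaries.

    Values are reported for positions ``1..T-1`` (the incoming transition).
    """
    if any(p is None for p in stream.word_position):
        raise MetricsError("stream has no word annotations")
    W = n_words if n_words is not None else stream.lexicon.n_words
    out = np.zeros(len(stream) - 1)
    for t in range(1, len(stream)):
        if stream.word_position[t] == 0:
            out[t - 1] = np.log2(W - 1) if W > 1 else 0.0
    return out


@dataclass(frozen=True)
class KernelSet:
    """Two-period binary TP-decay templates at every cyclic lag."""

    kernels: tuple[tuple[int, ...], ...]

    @property
    def length(self) -> int:
        return len(self.kernels[0])

    def __iter__(self):
        return iter(self.kernels)

    def __len__(self) -> int:
        return len(self.kernels)


def make_kernels(S: int | None = None, pattern: Sequence[int] | None = None) -> KernelSet:
    """Kernels for word period ``S`` (one-hot decay), or two concatenated
    copies of an explicit binary ``pattern`` at all its cyclic lags."""
    if pattern is not None:
        base = np.asarray(pattern, dtype=int)
        if base.sum() == 0:
            raise MetricsError("all-zero kernel template")
        kernels = []
        for lag in range(len(base)):
            rolled = np.roll(base, lag)
            kernels.append(tuple(np.concatenate([rolled, rolled]).tolist()))
        return KernelSet(kernels=tuple(dict.fromkeys(kernels)))
    if S is None or S < 2:
        raise MetricsError("S must be >= 2 (or give an explicit pattern)")
    kernels = []
    for lag in range(S):
        base = np.zeros(S, dtype=int)
        base[lag] = 1
        kernels.append(tuple(np.concatenate([base, base]).tolist()))
    return KernelSet(kernels=tuple(kernels))


def compute_pri(
    feature_vector: Sequence[int], kernels: KernelSet
) -> tuple[int, int, float]:
    """Slide a kernel-length window over the vector (stride 1); a window
    scores one match when it equals any kernel exactly.

    Returns ``(matches, windows, matches / windows)``.
    """
    vec = np.asarray(feature_vector, dtype=int)
    k = kernels.length
    if len(vec) < k:
        raise MetricsError(f"vector of length {len(vec)} shorter than kernel ({k})")
    kernel_set = {tuple(kv) for kv in kernels}
    windows = len(vec) - k + 1
    matches = sum(
        1 for i in range(windows) if tuple(vec[i:i + k].tolist()) in kernel_set
    )
    return matches, windows, matches / windows


@dataclass
class PRIReport:
    """Per-feature PRI values and their maximum for one stream."""

    per_feature: Mapping[str, float]
    matches: Mapping[str, int]
    windows: int
    max_pri: float
    max_feature: str

    def to_dict(self) -> dict:
        return {
            "per_feature": dict(self.per_feature),
            "matches": dict(self.matches),
            "windows": self.windows,
            "max_pri": self.max_pri,
            "max_feature": self.max_feature,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, ensure_ascii=False))


def stream_feature_matrix(stream: Stream) -> tuple[tuple[str, ...], np.ndarray]:
    """Binary features-by-positions matrix of the stream's syllables."""
    lookup = {}
    names = None
    for word in stream.lexicon.words:
        for syl in word.syllables:
            vec = syl.feature_matrix.any(axis=1)
            lookup[syl.id] = vec
        if names is None:
            names = word.feature_names
    cols = []
    for tok in stream.tokens:
        if tok not in lookup:
            raise MetricsError(f"stream syllable {tok!r} has no feature annotation")
        cols.append(lookup[tok])
    return names, np.stack(cols, axis=1).astype(int)


def stream_pri_report(stream: Stream, kernels: KernelSet | None = None) -> PRIReport:
    """PRI of every phonological feature along the stream, and the maximum."""
    if kernels is None:
        kernels = make_kernels(stream.lexicon.n_syllables_per_word)
    names, mat = stream_feature_matrix(stream)
    per_feature: dict[str, float] = {}
    match_counts: dict[str, int] = {}
    windows = mat.shape[1] - kernels.length + 1
    for name, row in zip(names, mat):
        m, w, pri = compute_pri(row, kernels)
        per_feature[name] = pri
        match_counts[name] = m
    max_feature = max(per_feature, key=per_feature.get)
    return PRIReport(
        per_feature=per_feature,
        matches=match_counts,
        windows=windows,
        max_pri=per_feature[max_feature],
        max_feature=max_feature,
    )


def overlap_pri_correlation(
    lexicons: Sequence,
    n_streams_per_lexicon: int = 2,
    mode: str = "word_structured",
    n_repetitions: int = 15,
    seed: int = 0,
) -> float:
    """Pearson correlation between lexicon total feature overlap and the
    mean maximum PRI of its streams.  Returns ``nan`` when either variable
    has zero variance (undefined)."""
    from .streams import generate_stream

    import hashlib

    if len(lexicons) < 3:
        raise MetricsError("need at least 3 lexicons")
    overlaps, mean_pris = [], []
    for lex in lexicons:
        # per-lexicon seed from content, not list position: permuting the
        # lexicon order leaves the statistic unchanged
        key = "|".join(w.id for w in lex.words)
        base = int.from_bytes(
            hashlib.sha256(f"{seed}:{key}".encode()).digest()[:4], "big"
        )
        pris = []
        for s_i in range(n_streams_per_lexicon):
            stream = generate_stream(lex, mode, n_repetitions, seed=base + s_i)
            pris.append(stream_pri_report(stream).max_pri)
        overlaps.append(lex.total_overlap)
        mean_pris.append(float(np.mean(pris)))
    ov = np.asarray(overlaps, dtype=float)
    pr = np.asarray(mean_pris)
    if ov.std() == 0 or pr.std() == 0:
        return float("nan")
    return float(np.corrcoef(ov, pr)[0, 1])
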