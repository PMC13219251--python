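"""Transition-probability-controlled token streams via Eulerian circuits.

Three stream modes over a lexicon of ``W`` words of ``S`` syllables:

``word_structured``
    Complete digraph on the ``W`` words (no self-loops); the circuit is
    walked at the word level and expanded into syllables, so within-word
    transitions have probability 1 and boundary transitions ~``1/(W-1)``.
``position_random``
    Complete digraph on all ``N = W*S`` syllables; every syllable can follow
    every other with probability ~``1/(N-1)``.
``position_fixed``
    Syllables keep their within-word ordinal position: ``S`` position groups
    of ``W`` syllables with edges only from group ``p`` to ``p+1 (mod S)``;
    each transition has ``W`` equally likely targets (~``1/W``).

Edges are laid down with near-equal multiplicity (differing by at most one),
surplus edges distributed by seeded cyclic offsets so in-degree equals
out-degree everywhere; the circuit is walked with Hierholzer's algorithm
using a greedy minimum-used-count edge choice with seeded tie-breaks.
"""

from __future__ import annotations

import json
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Hashable, Sequence

import numpy as np
import pandas as pd

from .lexicon import Lexicon

MODES = ("word_structured", "position_random", "position_fixed")

#: Aliases accepted on input (CLI/config naming).
MODE_ALIASES = {
    "word_structured": "word_structured",
    "structured": "word_structured",
    "random": "position_random",
    "position_random": "position_random",
    "position_controlled": "position_fixed",
    "position_fixed": "position_fixed",
}


class StreamError(ValueError):
    pass


def normalize_mode(mode: str) -> str:
    try:
        return MODE_ALIASES[mode]
    except KeyError:
        raise StreamError(f"unknown stream mode {mode!r}; expected one of {MODES}") from None


@dataclass
class TransitionGraph:
    """Directed multigraph with per-ordered-pair edge multiplicities."""

    vertices: tuple[Hashable, ...]
    multiplicity: dict[tuple[Hashable, Hashable], int]

    @property
    def n_edges(self) -> int:
        return sum(self.multiplicity.values())

    def out_degree(self, v: Hashable) -> int:
        return sum(m for (i, _), m in self.multiplicity.items() if i == v)

    def in_degree(self, v: Hashable) -> int:
        return sum(m for (_, j), m in self.multiplicity.items() if j == v)

    def validate(self) -> None:
        for (i, j) in self.multiplicity:
            if i == j:
                raise StreamError(f"self-loop on {i!r}")
        outs = defaultdict(int)
        ins = defaultdict(int)
        for (i, j), m in self.multiplicity.items():
            outs[i] += m
            ins[j] += m
        for v in self.vertices:
            if outs[v] != ins[v]:
                raise StreamError(f"unbalanced vertex {v!r}: out {outs[v]} != in {ins[v]}")
        if not self._connected():
            raise StreamError("graph is not connected on vertices with edges")

    def _connected(self) -> bool:
        adj = defaultdict(set)
        touched = set()
        for (i, j), m in self.multiplicity.items():
            if m > 0:
                adj[i].add(j)
                adj[j].add(i)  # weak connectivity; balanced => strongly connected
                touched.update((i, j))
        if not touched:
            return False
        seen = set()
        stack = [next(iter(touched))]
        while stack:
            v = stack.pop()
            if v in seen:
                continue
            seen.add(v)
            stack.extend(adj[v] - seen)
        return seen >= touched


def _cyclic_surplus(
    n: int, r: int, rng: np.random.Generator, allow_zero_offset: bool
) -> list[tuple[int, int]]:
    """r extra edges out of (and into) each of n vertices via distinct cyclic
    offsets, preserving degree balance; returns (source, target) index pairs."""
    if r == 0:
        return []
    lo = 0 if allow_zero_offset else 1
    offsets = rng.choice(np.arange(lo, n), size=r, replace=False)
    return [(i, (i + int(d)) % n) for d in offsets for i in range(n)]


def build_transition_graph(
    lexicon: Lexicon, mode: str, n_repetitions: int, seed: int = 0
) -> TransitionGraph:
    """Lay down a balanced multigraph whose Eulerian circuit realizes the
    target uniform transition counts for ``mode``.

    Per-ordered-pair multiplicities differ by at most one; the surplus from
    non-integral targets is assigned by seeded cyclic offsets over a random
    vertex relabeling, keeping in-degree equal to out-degree everywhere.
    Sparse surplus layouts (base multiplicity 0) can come out disconnected;
    construction retries with derived seeds until the graph validates.
    """
    mode = normalize_mode(mode)
    if n_repetitions < 1:
        raise StreamError("n_repetitions must be >= 1")
    last_err: StreamError | None = None
    for attempt in range(50):
        graph = _construct_graph(lexicon, mode, n_repetitions, seed + 100_003 * attempt)
        try:
            graph.validate()
            return graph
        except StreamError as err:  # pragma: no cover - rare sparse layouts
            last_err = err
    raise last_err  # pragma: no cover


def _construct_graph(
    lexicon: Lexicon, mode: str, n_repetitions: int, seed: int
) -> TransitionGraph:
    rng = np.random.default_rng(seed)
    W = lexicon.n_words
    S = lexicon.n_syllables_per_word

    if mode == "word_structured":
        labels = list(range(W))  # word indices
        if W < 2:
            raise StreamError("word_structured needs at least 2 words")
        n = W
        q, r = divmod(n_repetitions, n - 1)
        perm = rng.permutation(n)
        mult: dict[tuple[Hashable, Hashable], int] = {}
        for i in range(n):
            for j in range(n):
                if i != j:
                    mult[(labels[i], labels[j])] = q
        for a, b in _cyclic_surplus(n, r, rng, allow_zero_offset=False):
            key = (labels[int(perm[a])], labels[int(perm[b])])
            mult[key] = mult.get(key, 0) + 1
        mult = {k: m for k, m in mult.items() if m > 0}
        return TransitionGraph(vertices=tuple(labels), multiplicity=mult)
    if mode == "position_random":
        syls = [s.id for s in lexicon.syllables]
        if len(set(syls)) != len(syls):
            raise StreamError(
                "lexicon words share syllables; syllable-mode streams need "
                "distinct syllables across words"
            )
        n = len(syls)
        if n < 2:
            raise StreamError("position_random needs at least 2 syllables")
        q, r = divmod(n_repetitions, n - 1)
        perm = rng.permutation(n)
        mult = {}
        for i in range(n):
            for j in range(n):
                if i != j:
                    mult[(syls[i], syls[j])] = q
        for a, b in _cyclic_surplus(n, r, rng, allow_zero_offset=False):
            key = (syls[int(perm[a])], syls[int(perm[b])])
            mult[key] = mult.get(key, 0) + 1
        mult = {k: m for k, m in mult.items() if m > 0}
        return TransitionGraph(vertices=tuple(syls), multiplicity=mult)
    if mode == "position_fixed":
        if S < 2:
            raise StreamError("position_fixed needs words of at least 2 syllables")
        groups = [[w.syllables[p].id for w in lexicon.words] for p in range(S)]
        flat = [s for g in groups for s in g]
        if len(set(flat)) != len(flat):
            raise StreamError(
                "lexicon words share syllables; syllable-mode streams need "
                "distinct syllables across words"
            )
        q, r = divmod(n_repetitions, W)
        mult = {}
        for p in range(S):
            nxt = (p + 1) % S
            for a in groups[p]:
                for b in groups[nxt]:
                    mult[(a, b)] = q
            perm = rng.permutation(W)
            for a, b in _cyclic_surplus(W, r, rng, allow_zero_offset=True):
                key = (groups[p][int(perm[a])], groups[nxt][int(perm[b])])
                mult[key] = mult.get(key, 0) + 1
        mult = {k: m for k, m in mult.items() if m > 0}
        return TransitionGraph(vertices=tuple(flat), multiplicity=mult)
    raise StreamError(f"unknown stream mode {mode!r}")  # pragma: no cover


def euler_circuit(graph: TransitionGraph, seed: int = 0) -> list[Hashable]:
    """Walk an Eulerian circuit with Hierholzer splicing and a greedy
    minimum-used-count edge rule (seeded uniform tie-breaks).

    Returns the vertex sequence with the closing return-to-start dropped:
    ``T`` tokens realizing ``T - 1`` of the ``T`` edges.
    """
    graph.validate()
    rng = np.random.default_rng(seed)
    remaining: dict[Hashable, dict[Hashable, int]] = defaultdict(dict)
    used: dict[tuple[Hashable, Hashable], int] = defaultdict(int)
    for (i, j), m in graph.multiplicity.items():
        if m > 0:
            remaining[i][j] = m
    T = graph.n_edges

    def pick(v: Hashable) -> Hashable:
        succ = remaining[v]
        lo = min(used[(v, j)] for j in succ)
        cands = [j for j in succ if used[(v, j)] == lo]
        return cands[int(rng.integers(len(cands)))] if len(cands) > 1 else cands[0]

    with_edges = [v for v in graph.vertices if remaining.get(v)]
    start = with_edges[int(rng.integers(len(with_edges)))]
    # iterative Hierholzer: walk until stuck, splice detours at vertices
    # with unused edges (the stack realizes the splicing)
    stack = [start]
    trail: list[Hashable] = []
    while stack:
        v = stack[-1]
        if remaining.get(v):
            j = pick(v)
            remaining[v][j] -= 1
            if remaining[v][j] == 0:
                del remaining[v][j]
            used[(v, j)] += 1
            stack.append(j)
        else:
            trail.append(stack.pop())
    trail.reverse()
    if len(trail) != T + 1:
        raise StreamError("graph admits no Eulerian circuit (disconnected edges)")
    return trail[:-1]


@dataclass
class Stream:
    """A token sequence with word/position annotations and provenance."""

    tokens: list[str]
    mode: str
    lexicon: Lexicon
    n_repetitions: int
    seed: int
    word_index: list[int | None] = field(default_factory=list)
    word_position: list[int | None] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def n_tokens(self) -> int:
        return len(self.tokens)

    def transition_counts(self) -> tuple[list[str], np.ndarray]:
        """Token alphabet (sorted) and realized ordered-pair counts."""
        alphabet = sorted(set(self.tokens))
        index = {t: i for i, t in enumerate(alphabet)}
        counts = np.zeros((len(alphabet), len(alphabet)), dtype=int)
        for a, b in zip(self.tokens, self.tokens[1:]):
            counts[index[a], index[b]] += 1
        return alphabet, counts

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": np.arange(len(self.tokens)),
                "syllable": self.tokens,
                "word_index": self.word_index,
                "word_position": self.word_position,
            }
        )

    def write(self, path: str | Path) -> None:
        """CSV of tokens plus a JSON sidecar with provenance and TP matrix."""
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        from .metrics import empirical_tp

        alphabet, tp = empirical_tp(self)
        sidecar = {
            "mode": self.mode,
            "seed": self.seed,
            "n_repetitions": self.n_repetitions,
            "lexicon": self.lexicon.to_dict(),
            "alphabet": alphabet,
            "tp_matrix": np.round(tp, 6).tolist(),
        }
        path.with_suffix(".json").write_text(
            json.dumps(sidecar, indent=2, ensure_ascii=False)
        )


def _expand_words(
    word_tokens: Sequence[int], lexicon: Lexicon
) -> tuple[list[str], list[int | None], list[int | None]]:
    tokens, widx, wpos = [], [], []
    for w in word_tokens:
        for p, syl in enumerate(lexicon.words[w].syllables):
            tokens.append(syl.id)
            widx.append(w)
            wpos.append(p)
    return tokens, widx, wpos


def generate_stream(
    lexicon: Lexicon, mode: str, n_repetitions: int = 15, seed: int = 0
) -> Stream:
    """Eulerian-circuit stream of ``n_repetitions * S * W`` syllables."""
    mode = normalize_mode(mode)
    graph = build_transition_graph(lexicon, mode, n_repetitions, seed=seed)
    walk = euler_circuit(graph, seed=seed)
    if mode == "word_structured":
        tokens, widx, wpos = _expand_words(walk, lexicon)
    else:
        tokens = [str(t) for t in walk]
        if mode == "position_fixed":
            lookup = {
                w.syllables[p].id: (i, p)
                for i, w in enumerate(lexicon.words)
                for p in range(lexicon.n_syllables_per_word)
            }
            widx = [lookup[t][0] for t in tokens]
            wpos = [lookup[t][1] for t in tokens]
        else:
            widx = [None] * len(tokens)
            wpos = [None] * len(tokens)
    return Stream(
        tokens=tokens,
        mode=mode,
        lexicon=lexicon,
        n_repetitions=n_repetitions,
        seed=seed,
        word_index=widx,
        word_position=wpos,
    )


def naive_shuffle_stream(
    lexicon: Lexicon,
    mode: str,
    n_repetitions: int = 15,
    seed: int = 0,
    max_retries: int = 100,
) -> Stream:
    """Baseline: shuffle the same token multiset, repairing immediate
    repetitions by local swaps; no transition-count control."""
    mode = normalize_mode(mode)
    rng = np.random.default_rng(seed)
    W = lexicon.n_words
    if mode == "word_structured":
        multiset = list(range(W)) * n_repetitions
    else:
        multiset = [s.id for s in lexicon.syllables] * n_repetitions

    def repair(seq: list) -> list | None:
        seq = list(seq)
        for _ in range(10 * len(seq)):
            bad = [t for t in range(1, len(seq)) if seq[t] == seq[t - 1]]
            if not bad:
                return seq
            t = bad[0]
            swaps = [
                u for u in range(len(seq))
                if seq[u] != seq[t]
                and (u == 0 or seq[u - 1] != seq[t])
                and (u == len(seq) - 1 or seq[u + 1] != seq[t])
                and (t == 0 or u != t - 1)
            ]
            if not swaps:
                return None
            u = swaps[int(rng.integers(len(swaps)))]
            seq[t], seq[u] = seq[u], seq[t]
        return None

    fixed = None
    for _ in range(max_retries):
        cand = list(rng.permutation(multiset))
        fixed = repair(cand)
        if fixed is not None:
            break
    if fixed is None:
        raise StreamError("could not remove immediate repetitions (degenerate multiset)")

    if mode == "word_structured":
        tokens, widx, wpos = _expand_words([int(x) for x in fixed], lexicon)
    else:
        tokens = [str(x) for x in fixed]
        widx = [None] * len(tokens)
        wpos = [None] * len(tokens)
    return Stream(
        tokens=tokens,
        mode=mode,
        lexicon=lexicon,
        n_repetitions=n_repetitions,
        seed=seed,
        word_index=widx,
        word_position=wpos,
    )


def reject_by_rhythmicity(
    lexicon: Lexicon,
    modes: Sequence[str],
    n_streams_per_lexicon: int = 2,
    n_repetitions: int = 15,
    max_rhythmicity: float | None = None,
    max_tries_randomize: int = 10,
    require_all_tp_modes: bool = True,
    seed: int = 0,
) -> dict[str, list[Stream]]:
    """Generate streams per mode, regenerating those whose maximum PRI
    exceeds ``max_rhythmicity`` with fresh seeds.

    Returns a mode -> streams mapping; with ``require_all_tp_modes`` the
    result is empty when any requested mode fails (all-or-none per lexicon).
    ``max_rhythmicity = None`` accepts everything.
    """
    from .metrics import stream_pri_report

    out: dict[str, list[Stream]] = {}
    failed = False
    for m, mode in enumerate(normalize_mode(x) for x in modes):
        accepted: list[Stream] = []
        for s_i in range(n_streams_per_lexicon):
            base = seed + 10_007 * m + 101 * s_i
            stream = None
            for attempt in range(max(1, max_tries_randomize)):
                cand = generate_stream(lexicon, mode, n_repetitions, seed=base + attempt)
                if max_rhythmicity is None:
                    stream = cand
                    break
                report = stream_pri_report(cand)
                if report.max_pri <= max_rhythmicity:
                    stream = cand
                    break
            if stream is None:
                failed = True
                break
            accepted.append(stream)
        if failed:
            break
        out[mode] = accepted
    if failed and require_all_tp_modes:
        return {}
    return out
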