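"""Configuration surface and the linear generation pipeline.

``Config`` mirrors the published parameter sheet exactly (names and
defaults), plus a global ``seed`` and ``output_dir``: every stochastic stage
derives a child seed from the global one, so a config fully determines the
artifact bundle.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

log = logging.getLogger("artlang")


class ConfigError(ValueError):
    pass


@dataclass
class Config:
    # --- syllable stage ---
    lang: str = "deu"
    phoneme_pattern: str = "cV"
    syllable_control: bool = True
    syllable_alpha: float = 0.05
    syllable_corpus: str | None = None
    # --- word stage ---
    n_syllables_per_word: int = 3
    n_words: int = 10_000
    max_word_tries: int = 100_000
    phonotactic_control: bool = True
    n_look_back: int = 2
    bigram_control: bool = True
    bigram_alpha: float | None = None
    trigram_control: bool = True
    trigram_alpha: float | None = None
    positional_control: bool = True
    positional_position: int | None = None
    position_alpha: float | None = None
    # --- lexicon stage ---
    n_lexicons: int = 2
    n_words_per_lexicon: int = 4
    binary_feature_control: bool = True
    max_overlap: int = 1
    lag: int | None = None
    max_word_matrix: int = 200
    unique_words: bool = False
    # --- stream stage ---
    n_repetitions: int = 15
    n_streams_per_lexicon: int = 2
    tp_modes: tuple[str, ...] = ("random", "word_structured", "position_controlled")
    max_rhythmicity: float | None = None
    max_tries_randomize: int = 10
    require_all_tp_modes: bool = True
    # --- bookkeeping (not part of the published sheet) ---
    seed: int = 0
    output_dir: str = "artlang_output"

    def __post_init__(self) -> None:
        if isinstance(self.tp_modes, (list, str)):
            modes = (
                tuple(m.strip() for m in self.tp_modes.split(","))
                if isinstance(self.tp_modes, str)
                else tuple(self.tp_modes)
            )
            object.__setattr__(self, "tp_modes", modes)

    @classmethod
    def field_names(cls) -> set[str]:
        return {f.name for f in dataclasses.fields(cls)}

    @classmethod
    def from_dict(cls, data: dict) -> "Config":
        unknown = set(data) - cls.field_names()
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Config":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: expected a flat key/value mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["tp_modes"] = list(self.tp_modes)
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    def child_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the global seed."""
        import hashlib

        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big")


@dataclass
class PipelineResult:
    """Artifacts of one pipeline run."""

    config: Config
    syllable_register: list
    word_register: list
    lexicons: list
    streams: dict  # lexicon index -> mode -> list[Stream]
    output_dir: Path


def _load_corpus(config: Config):
    """Corpus tables: user-supplied CSVs, or a seeded synthetic stand-in."""
    from .corpus import CorpusTables, FrequencyTable, generate_synthetic_corpus

    if config.syllable_corpus is None:
        log.info("no corpus given; generating a synthetic Zipf corpus")
        return generate_synthetic_corpus(
            n_tokens=20_000,
            zipf_s=1.0,
            seed=config.child_seed("corpus"),
            pattern=config.phoneme_pattern,
            n_syllables_per_word=config.n_syllables_per_word,
        )
    path = Path(config.syllable_corpus)
    directory = path if path.is_dir() else path.parent
    syllables = FrequencyTable.from_csv(
        path if path.is_file() else directory / "syllables.csv", kind="syllable"
    )

    def opt(name: str, kind: str):
        p = directory / f"{name}.csv"
        return FrequencyTable.from_csv(p, kind=kind) if p.exists() else None

    return CorpusTables(
        syllables=syllables,
        bigrams=opt("bigrams", "ngram"),
        trigrams=opt("trigrams", "ngram"),
        positional=opt("positional", "positional"),
    )


def run_pipeline(config: Config, render_audio: bool = False) -> PipelineResult:
    """Execute the five generation steps with seeded determinism.

    Writes lexicon JSON, stream CSVs (plus TP sidecars), PRI reports, and —
    optionally — rendered WAVs under ``config.output_dir``.  Register sizes
    before/after every filter are logged.
    """
    from . import audio as audio_mod
    from . import corpus as corpus_mod
    from . import lexicon as lexicon_mod
    from . import metrics as metrics_mod
    from . import phonology, streams as streams_mod

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    current = {"stage": "setup"}

    def stage(name: str):
        current["stage"] = name
        log.info("stage: %s", name)

    try:
        stage("phonology")
        table = phonology.default_feature_table()
        register = phonology.build_syllable_register(table, config.phoneme_pattern)
        log.info("syllable register: %d syllables", len(register))

        stage("corpus")
        corpora = _load_corpus(config)
        if config.syllable_control:
            before = len(register)
            register = corpus_mod.filter_syllable_register(
                register, corpora.syllables, config.syllable_alpha
            )
            log.info("syllable uniformity filter: %d -> %d", before, len(register))

        stage("words")
        words = lexicon_mod.generate_word_register(
            register,
            table,
            n_syllables_per_word=config.n_syllables_per_word,
            n_words=config.n_words,
            max_word_tries=config.max_word_tries,
            ocp_place=config.phonotactic_control,
            ocp_manner=config.phonotactic_control,
            ocp_vowel=config.phonotactic_control,
            n_look_back=config.n_look_back,
            seed=config.child_seed("words"),
        )
        log.info("word register: %d words", len(words))
        filters = (
            ("bigram", config.bigram_control, corpora.bigrams,
             lambda w: corpus_mod.ngram_filter(w, corpora.bigrams, 2, config.bigram_alpha)),
            ("trigram", config.trigram_control, corpora.trigrams,
             lambda w: corpus_mod.ngram_filter(w, corpora.trigrams, 3, config.trigram_alpha)),
            ("positional", config.positional_control, corpora.positional,
             lambda w: corpus_mod.positional_filter(
                 w, corpora.positional, config.positional_position, config.position_alpha)),
        )
        for name, enabled, tbl, fn in filters:
            if not enabled:
                continue
            if tbl is None:
                log.warning("%s control enabled but no table available; skipped", name)
                continue
            before = len(words)
            words = [lexicon_mod.make_word(w) if not isinstance(w, lexicon_mod.Word) else w
                     for w in fn([w.syllables for w in words])]
            log.info("%s filter: %d -> %d words", name, before, len(words))

        stage("lexicons")
        # With OCP-place on, every word's labial-feature row is one-hot over
        # S positions, so >S words cannot be pairwise overlap-free
        # (pigeonhole).  When the requested max_overlap admits no lexicon we
        # relax it stepwise rather than abort, logging each relaxation.
        lexicons = None
        effective = config.max_overlap
        n_features = words[0].feature_matrix.shape[0] if words else 1
        while lexicons is None:
            try:
                lexicons = lexicon_mod.assemble_lexicons(
                    words,
                    n_lexicons=config.n_lexicons,
                    n_words_per_lexicon=config.n_words_per_lexicon,
                    max_word_matrix=config.max_word_matrix,
                    max_overlap=effective,
                    unique_words=config.unique_words,
                    binary_feature_control=config.binary_feature_control,
                    lag=config.lag,
                    seed=config.child_seed("lexicons"),
                )
            except lexicon_mod.LexiconError as err:
                if not config.binary_feature_control or effective > n_features:
                    raise
                effective += 1
                log.warning(
                    "lexicon assembly infeasible (%s); relaxing max_overlap to %d",
                    err, effective,
                )
        log.info("assembled %d lexicons", len(lexicons))
        for i, lex in enumerate(lexicons):
            lex.to_json(out / f"lexicon_{i}.json")

        stage("streams")
        all_streams: dict[int, dict[str, list]] = {}
        for i, lex in enumerate(lexicons) if config.tp_modes else []:
            per_mode = streams_mod.reject_by_rhythmicity(
                lex,
                modes=config.tp_modes,
                n_streams_per_lexicon=config.n_streams_per_lexicon,
                n_repetitions=config.n_repetitions,
                max_rhythmicity=config.max_rhythmicity,
                max_tries_randomize=config.max_tries_randomize,
                require_all_tp_modes=config.require_all_tp_modes,
                seed=config.child_seed(f"streams:{i}"),
            )
            if not per_mode:
                log.warning("lexicon %d failed rhythmicity screening; dropped", i)
                continue
            all_streams[i] = per_mode
            for mode, ss in per_mode.items():
                for k, stream in enumerate(ss):
                    stream.write(out / f"stream_lex{i}_{mode}_{k}.csv")
                    report = metrics_mod.stream_pri_report(stream)
                    report.to_json(out / f"pri_lex{i}_{mode}_{k}.json")

        if render_audio:
            stage("audio")
            spec = audio_mod.AudioSpec()
            for i, per_mode in all_streams.items():
                for mode, ss in per_mode.items():
                    for k, stream in enumerate(ss):
                        wave = audio_mod.render_stream_audio(stream, spec)
                        audio_mod.write_wav(
                            out / f"stream_lex{i}_{mode}_{k}.wav", wave, spec
                        )
    except ConfigError:
        raise
    except Exception as err:
        raise ConfigError(
            f"pipeline failed at stage {current['stage']!r}: {err}"
        ) from err

    config.to_yaml(out / "config.yaml")
    return PipelineResult(
        config=config,
        syllable_register=register,
        word_register=words,
        lexicons=lexicons,
        streams=all_streams,
        output_dir=out,
    )
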