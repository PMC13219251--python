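import numpy as np
import pytest

from artlang.corpus import generate_synthetic_corpus
from artlang.lexicon import assemble_lexicons, generate_word_register, make_word
from artlang.phonology import build_syllable_register, default_feature_table


@pytest.fixture(scope="session")
def table():
    return default_feature_table()


@pytest.fixture(scope="session")
def cv_register(table):
    return build_syllable_register(table, "cV")


@pytest.fixture(scope="session")
def word_register(table, cv_register):
    return generate_word_register(
        cv_register, table, n_words=400, max_word_tries=20_000, seed=11
    )


@pytest.fixture(scope="session")
def lexicon(table, word_register):
    # max_overlap=2: with OCP-place on, 4 trisyllabic words cannot all be
    # pairwise overlap-free (the labial one-hot pigeonhole), so 1 is infeasible
    return assemble_lexicons(
        word_register, n_lexicons=1, max_word_matrix=80, max_overlap=2, seed=5
    )[0]


@pytest.fixture(scope="session")
def synthetic_corpus(cv_register, table):
    return generate_synthetic_corpus(
        n_tokens=5000, zipf_s=1.0, seed=3, register=cv_register, table=table
    )


def words_from_strings(strings, table):
    """Build Word objects from '|'/'_' IPA strings (test helper)."""
    from artlang.lexicon import words_from_ipa

    return words_from_ipa("\n".join(strings), table)
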