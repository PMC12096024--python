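"""Tokenization and readability formula tests."""
import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eduscore.text_metrics import (
    Document,
    TokenStats,
    coleman_liau_index,
    compute_token_stats,
    count_syllables,
    flesch_kincaid_grade,
    gunning_fog_index,
    smog_index,
    split_sentences,
    words_per_minute,
)
from eduscore.synthetic import TextTarget, generate_text


# dictionary-syllabified words frozen as the oracle for the counter
DICTIONARY_WORDS = [
    ("a", 1), ("knee", 1), ("pain", 1), ("strength", 1), ("ice", 1),
    ("doctor", 2), ("patient", 2), ("muscle", 2), ("gentle", 2),
    ("balance", 2), ("being", 2), ("diet", 2), ("apple", 2),
    ("exercise", 3), ("arthritis", 3), ("therapy", 3), ("medicine", 3),
    ("injection", 3), ("hospital", 3), ("idea", 3), ("area", 3),
    ("medication", 4), ("activity", 4), ("education", 4), ("ibuprofen", 4),
    ("participation", 5), ("university", 5),
    ("osteoarthritis", 6), ("rehabilitation", 6), ("acetaminophen", 6),
    ("physiotherapy", 6),
]


@pytest.mark.parametrize("word,expected", DICTIONARY_WORDS)
def test_count_syllables_dictionary(word, expected):
    assert count_syllables(word) == expected


def test_count_syllables_case_and_compounds():
    assert count_syllables("Knee") == count_syllables("knee")
    # hyphenated parts are summed
    assert count_syllables("self-management") == (
        count_syllables("self") + count_syllables("management")
    )


@pytest.mark.parametrize("bad", ["", "123", "…", "--"])
def test_count_syllables_rejects_nonalphabetic(bad):
    with pytest.raises(ValueError):
        count_syllables(bad)


@given(st.text(alphabet="abcdefghijklmnopqrstuvwxyz", min_size=1, max_size=20))
@settings(max_examples=200, deadline=None)
def test_count_syllables_bounds(word):
    n = count_syllables(word)
    assert 1 <= n <= len(word)


def test_token_stats_worked_example():
    s = compute_token_stats("The knee hurts. Rest it.")
    assert (s.n_sentences, s.n_words, s.n_syllables) == (2, 5, 5)
    assert (s.n_polysyllables, s.n_complex, s.n_letters) == (0, 0, 18)


def test_token_stats_single_word():
    s = compute_token_stats("Rest.")
    assert (s.n_sentences, s.n_words, s.n_syllables, s.n_polysyllables) == (1, 1, 1, 0)


def test_sentence_guards():
    # abbreviation, decimal number, and lowercase-after-period guards
    assert len(split_sentences("Dr. Smith saw the patient. It helped.")) == 2
    assert len(split_sentences("Take 2.5 mg daily. Rest often.")) == 2
    assert len(split_sentences("See e.g. the knee. It hurts!")) == 2
    assert len(split_sentences("An ellipsis... continues here. Done.")) == 2


def test_proper_noun_and_hyphen_exclusions_from_complex():
    # "Ibuprofen" capitalized mid-sentence is a proper-noun proxy; the
    # hyphenated compound is excluded; both still count as polysyllables
    s = compute_token_stats("She takes Ibuprofen and self-medication now.")
    assert s.n_polysyllables == 2
    assert s.n_complex == 0
    # sentence-initial capitalized polysyllables are NOT excluded
    s2 = compute_token_stats("Medication helps the knee.")
    assert s2.n_complex == 1


def test_empty_text_rejected():
    for bad in ("", "   \n\t"):
        with pytest.raises(ValueError):
            compute_token_stats(bad)


def test_flesch_kincaid_values():
    assert flesch_kincaid_grade(TokenStats(10, 100, 150, 0, 0, 400)) == pytest.approx(6.01)
    # one monosyllabic word per sentence: minimal-complexity limit
    assert flesch_kincaid_grade(TokenStats(5, 5, 5, 0, 0, 20)) == pytest.approx(-3.40)
    with pytest.raises(ValueError):
        flesch_kincaid_grade(TokenStats(0, 100, 150, 0, 0, 400))
    with pytest.raises(ValueError):
        flesch_kincaid_grade(TokenStats(10, 0, 0, 0, 0, 0))


def test_gunning_fog_values():
    assert gunning_fog_index(TokenStats(5, 100, 150, 10, 10, 400)) == pytest.approx(12.0)
    assert gunning_fog_index(TokenStats(10, 100, 100, 0, 0, 400)) == pytest.approx(4.0)
    # one extra complex word at W=100 raises the index by exactly 0.4
    lo = gunning_fog_index(TokenStats(5, 100, 150, 10, 10, 400))
    hi = gunning_fog_index(TokenStats(5, 100, 150, 11, 11, 400))
    assert hi - lo == pytest.approx(0.4)


def test_coleman_liau_values():
    # L/W = 5, S/W = 0.05
    assert coleman_liau_index(TokenStats(5, 100, 150, 0, 0, 500)) == pytest.approx(12.12)
    # L/W = 3, S/W = 0.2: very short words and sentences
    assert coleman_liau_index(TokenStats(20, 100, 100, 0, 0, 300)) == pytest.approx(-4.08)
    with pytest.raises(ValueError):
        coleman_liau_index(TokenStats(5, 0, 0, 0, 0, 0))


def test_smog_values():
    assert smog_index(TokenStats(30, 900, 900, 0, 0, 100)) == pytest.approx(3.1291)
    assert smog_index(TokenStats(30, 900, 1000, 30, 30, 100)) == pytest.approx(8.84, abs=5e-3)
    assert smog_index(TokenStats(10, 300, 400, 30, 30, 100)) == pytest.approx(13.02, abs=5e-3)
    with pytest.raises(ValueError):
        smog_index(TokenStats(0, 10, 10, 0, 0, 10))


def test_words_per_minute():
    assert words_per_minute(TokenStats(10, 600, 700, 0, 0, 100), 2.0) == 300.0
    assert words_per_minute(TokenStats(1, 0, 0, 0, 0, 0), 5.0) == 0.0
    assert words_per_minute(TokenStats(10, 1060, 1200, 0, 0, 100), 2.0) == 530.0
    with pytest.raises(ValueError):
        words_per_minute(TokenStats(10, 600, 700, 0, 0, 100), 0.0)


def test_document_validation():
    with pytest.raises(ValueError):
        Document(doc_id="d", text="  ", authoring_minutes=1.0)
    with pytest.raises(ValueError):
        Document(doc_id="d", text="Rest the knee.", authoring_minutes=0.0)


@pytest.mark.parametrize("seed", range(5))
def test_indices_invariant_to_whitespace_and_sentence_order(seed, rng):
    text, _ = generate_text(TextTarget(8, 9, 1.6), seed=seed)
    base = compute_token_stats(text)
    # whitespace normalization
    ragged = text.replace(" ", "  \n", 3).replace(". ", ".\n\n", 2)
    assert compute_token_stats(ragged) == base
    # sentence order permutation
    sentences = [s + "." for s in text.split(". ")]
    sentences[-1] = sentences[-1].rstrip(".") + "." if not sentences[-1].endswith("..") else sentences[-1]
    perm = rng.permutation(len(sentences))
    shuffled = " ".join(sentences[i].strip() for i in perm).replace("..", ".")
    assert compute_token_stats(shuffled) == base


def test_monotonicity_in_word_complexity():
    # swapping a monosyllable for a 4-syllable word of equal letters
    # raises FK and SMOG, does not lower Fog, leaves Coleman-Liau fixed
    base = TokenStats(10, 100, 130, 12, 12, 480)
    harder = TokenStats(10, 100, 133, 13, 13, 480)
    assert flesch_kincaid_grade(harder) > flesch_kincaid_grade(base)
    assert smog_index(harder) > smog_index(base)
    assert gunning_fog_index(harder) >= gunning_fog_index(base)
    assert coleman_liau_index(harder) == coleman_liau_index(base)


@pytest.mark.parametrize("seed", range(10))
def test_syllables_at_least_words(seed):
    text, ledger = generate_text(TextTarget(6, 8, 1.0 + (seed % 5) * 0.3), seed=seed)
    stats = compute_token_stats(text)
    assert stats.n_syllables >= stats.n_words
    assert stats.n_letters >= stats.n_words
    assert stats == ledger
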