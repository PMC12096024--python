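"""Tokenization, readability grade indices, and authoring efficiency.

Four grade-level readability formulas are computed from one shared set of
token statistics per document:

* Flesch-Kincaid grade:  ``0.39*(W/S) + 11.8*(Syll/W) - 15.59``
* Gunning Fog index:     ``0.4*((W/S) + 100*(C/W))``
* Coleman-Liau index:    ``0.0588*L100 - 0.296*S100 - 15.8``
* SMOG index:            ``1.0430*sqrt(30*P/S) + 3.1291``

where W = words, S = sentences, Syll = syllables, P = polysyllables
(>= 3 syllables), C = Fog "complex" words (polysyllables surviving the
exclusion rules), L = alphabetic letters inside word tokens, and
L100/S100 are letters/sentences per 100 words.

Authoring efficiency is words per minute: W divided by authoring time.

Tokenization is deliberately simple, deterministic, and auditable; it is a
dialect, not a reimplementation of any commercial readability product.
"""
from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass
from enum import Enum
from importlib import resources
from typing import Iterable, Optional

__all__ = [
    "Arm",
    "Document",
    "TokenStats",
    "count_syllables",
    "compute_token_stats",
    "flesch_kincaid_grade",
    "gunning_fog_index",
    "coleman_liau_index",
    "smog_index",
    "words_per_minute",
    "readability_indices",
    "analyze_document",
]

logger = logging.getLogger(__name__)

#: Word token: maximal run of alphanumerics, allowing internal hyphens and
#: apostrophes ("self-management", "patient's").  Numerals are words too.
_WORD_RE = re.compile(r"[A-Za-z0-9]+(?:['’-][A-Za-z0-9]+)*")
_ALPHA_RE = re.compile(r"[A-Za-z]")
_ALPHA_RUN_RE = re.compile(r"[a-z]+")
_VOWEL_GROUP_RE = re.compile(r"[aeiouy]+")

#: A period after one of these (case-insensitive) does not end a sentence.
ABBREVIATIONS = frozenset(
    {"dr", "mr", "mrs", "ms", "prof", "st", "no", "fig", "vs", "etc",
     "e.g", "i.e", "cf", "al", "approx"}
)

_SMOG_MIN_SENTENCES = 30  # formula's design sample size; below it we warn


class Arm(str, Enum):
    """Provenance of a document: AI-generated or clinician-written."""

    AI = "AI"
    CLINICIAN = "CLINICIAN"


@dataclass(frozen=True)
class Document:
    """One piece of education content with its authoring time.

    ``arm`` is ``None`` once the document has been blinded.
    """

    doc_id: str
    text: str
    authoring_minutes: float
    arm: Optional[Arm] = None
    profile_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.text or not self.text.strip():
            raise ValueError(f"document {self.doc_id!r}: text is empty")
        if not self.authoring_minutes > 0:
            raise ValueError(
                f"document {self.doc_id!r}: authoring_minutes must be > 0, "
                f"got {self.authoring_minutes!r}"
            )


@dataclass(frozen=True)
class TokenStats:
    """Counted text features feeding every readability formula."""

    n_sentences: int
    n_words: int
    n_syllables: int
    n_complex: int
    n_polysyllables: int
    n_letters: int

    def __post_init__(self) -> None:
        for name in ("n_sentences", "n_words", "n_syllables", "n_complex",
                     "n_polysyllables", "n_letters"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_complex > self.n_polysyllables:
            raise ValueError("complex words are polysyllables minus exclusions")
        if self.n_words > 0 and self.n_syllables < self.n_words:
            raise ValueError("every word carries at least one syllable")


def _load_exception_table() -> dict:
    table = {}
    ref = resources.files("eduscore.data").joinpath("syllable_exceptions.txt")
    for line in ref.read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        word, _, count = line.partition(" ")
        table[word.lower()] = int(count)
    return table


_EXCEPTIONS: Optional[dict] = None


def _exceptions() -> dict:
    global _EXCEPTIONS
    if _EXCEPTIONS is None:
        _EXCEPTIONS = _load_exception_table()
    return _EXCEPTIONS


def _heuristic_syllables(part: str) -> int:
    """Vowel-group heuristic for a lowercase alphabetic run."""
    n = len(_VOWEL_GROUP_RE.findall(part))
    if n > 1 and part.endswith("e") and not part.endswith("ee"):
        # silent trailing "e", except a "-le" syllable after a consonant
        if not (part.endswith("le") and len(part) >= 3 and part[-3] not in "aeiouy"):
            n -= 1
    return max(1, n)


def count_syllables(word: str, exceptions: Optional[dict] = None) -> int:
    """Count syllables in one token.

    Heuristic: vowel groups (a, e, i, o, u, y), minus a silent trailing "e"
    (kept when the word ends consonant + "le"), overridden by a small
    editable exception table for words the heuristic gets wrong.
    Hyphen/apostrophe-separated parts are counted separately and summed.
    Always returns at least 1.
    """
    if exceptions is None:
        exceptions = _exceptions()
    lowered = word.lower()
    if not _ALPHA_RE.search(lowered):
        raise ValueError(f"token {word!r} has no alphabetic character")
    key = re.sub(r"[^a-z]", "", lowered)
    if key in exceptions:
        return exceptions[key]
    total = sum(_heuristic_syllables(p) for p in _ALPHA_RUN_RE.findall(lowered))
    return max(1, total)


def _is_sentence_break(text: str, i: int) -> bool:
    """Whether the terminal punctuation at position ``i`` ends a sentence."""
    ch = text[i]
    if ch in "!?":
        return True
    # decimal number guard: digit "." digit
    if 0 < i < len(text) - 1 and text[i - 1].isdigit() and text[i + 1].isdigit():
        return False
    # abbreviation guard: token (letters, possibly with internal periods)
    # immediately before the period
    j = i - 1
    while j >= 0 and (text[j].isalpha() or text[j] == "."):
        j -= 1
    token = text[j + 1 : i].lower().rstrip(".")
    if token in ABBREVIATIONS:
        return False
    # a period followed by a lowercase letter does not end a sentence
    # (skipping further dots, so an ellipsis inherits the same rule)
    k = i + 1
    while k < len(text) and (text[k].isspace() or text[k] == "."):
        k += 1
    if k < len(text) and text[k].isalpha() and text[k].islower():
        return False
    return True


def split_sentences(text: str) -> list[str]:
    """Split text into sentences on terminal ``.!?`` with guards for
    abbreviations, decimal numbers, and periods followed by lowercase."""
    sentences: list[str] = []
    start = 0
    for i, ch in enumerate(text):
        if ch in ".!?" and _is_sentence_break(text, i):
            chunk = text[start : i + 1]
            if _WORD_RE.search(chunk):
                sentences.append(chunk)
            start = i + 1
    tail = text[start:]
    if _WORD_RE.search(tail):
        sentences.append(tail)
    return sentences


def _token_syllables(token: str) -> int:
    if not _ALPHA_RE.search(token):
        return 1  # purely numeric token
    return count_syllables(token)


def compute_token_stats(text: str) -> TokenStats:
    """Tokenize ``text`` and count the features used by the four indices.

    Sentences: terminal punctuation with abbreviation/decimal/lowercase
    guards.  Words: maximal alphanumeric runs with internal hyphens or
    apostrophes; numeric tokens contribute one syllable.  Complex words:
    polysyllables excluding capitalized non-sentence-initial tokens
    (proper-noun proxy) and hyphenated compounds.
    """
    if not text or not text.strip():
        raise ValueError("text is empty or whitespace-only")
    sentences = split_sentences(text)
    n_sentences = len(sentences)
    n_words = n_syllables = n_poly = n_complex = n_letters = 0
    for sentence in sentences:
        for rank, match in enumerate(_WORD_RE.finditer(sentence)):
            token = match.group()
            n_words += 1
            n_letters += sum(1 for c in token if c.isalpha())
            syl = _token_syllables(token)
            n_syllables += syl
            if syl >= 3:
                n_poly += 1
                first_alpha = next((c for c in token if c.isalpha()), "")
                capitalized = first_alpha.isupper()
                hyphenated = "-" in token
                if not (capitalized and rank > 0) and not hyphenated:
                    n_complex += 1
    return TokenStats(
        n_sentences=n_sentences,
        n_words=n_words,
        n_syllables=n_syllables,
        n_complex=n_complex,
        n_polysyllables=n_poly,
        n_letters=n_letters,
    )


def _require(condition: bool, message: str) -> None:
    if not condition:
        raise ValueError(message)


def flesch_kincaid_grade(stats: TokenStats) -> float:
    """US grade level from mean sentence length and syllables per word."""
    _require(stats.n_words > 0, "Flesch-Kincaid requires at least one word")
    _require(stats.n_sentences > 0, "Flesch-Kincaid requires at least one sentence")
    return (
        0.39 * stats.n_words / stats.n_sentences
        + 11.8 * stats.n_syllables / stats.n_words
        - 15.59
    )


def gunning_fog_index(stats: TokenStats) -> float:
    """Years of schooling from sentence length and complex-word share."""
    _require(stats.n_words > 0, "Gunning Fog requires at least one word")
    _require(stats.n_sentences > 0, "Gunning Fog requires at least one sentence")
    return 0.4 * (
        stats.n_words / stats.n_sentences
        + 100.0 * stats.n_complex / stats.n_words
    )


def coleman_liau_index(stats: TokenStats) -> float:
    """Grade level from letters and sentences per 100 words (no syllables)."""
    _require(stats.n_words > 0, "Coleman-Liau requires at least one word")
    letters_per_100 = 100.0 * stats.n_letters / stats.n_words
    sentences_per_100 = 100.0 * stats.n_sentences / stats.n_words
    return 0.0588 * letters_per_100 - 0.296 * sentences_per_100 - 15.8


def smog_index(stats: TokenStats) -> float:
    """Grade level from the polysyllable count, general scaling form.

    Applied regardless of sentence count; a warning is logged below 30
    sentences, the design sample size of the formula.
    """
    _require(stats.n_sentences > 0, "SMOG requires at least one sentence")
    if stats.n_sentences < _SMOG_MIN_SENTENCES:
        logger.warning(
            "SMOG computed on %d sentences (< %d, the formula's design "
            "sample); interpret with care",
            stats.n_sentences, _SMOG_MIN_SENTENCES,
        )
    return 1.0430 * math.sqrt(
        stats.n_polysyllables * 30.0 / stats.n_sentences
    ) + 3.1291


def words_per_minute(stats: TokenStats, authoring_minutes: float) -> float:
    """Authoring efficiency: word count over authoring time in minutes."""
    _require(authoring_minutes > 0, "authoring_minutes must be > 0")
    return stats.n_words / authoring_minutes


def readability_indices(stats: TokenStats) -> dict:
    """All four grade indices as a dict keyed by metric name."""
    return {
        "flesch_kincaid": flesch_kincaid_grade(stats),
        "gunning_fog": gunning_fog_index(stats),
        "coleman_liau": coleman_liau_index(stats),
        "smog": smog_index(stats),
    }


def analyze_document(doc: Document) -> dict:
    """Token stats, readability indices, and WPM for one document."""
    stats = compute_token_stats(doc.text)
    out = {
        "doc_id": doc.doc_id,
        "W": stats.n_words,
        "S": stats.n_sentences,
        "Syll": stats.n_syllables,
        "C": stats.n_complex,
        "P": stats.n_polysyllables,
        "L": stats.n_letters,
    }
    out.update(
        {k: v for k, v in readability_indices(stats).items()}
    )
    out["wpm"] = words_per_minute(stats, doc.authoring_minutes)
    return out
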