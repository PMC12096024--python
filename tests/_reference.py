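"""Independent reference readability implementation, used only as a
cross-check oracle in tests.

Deliberately its own tokenization dialect: naive sentence splitting on
terminal punctuation without abbreviation guards, no syllable-exception
table, no proper-noun exclusion for complex words.  Agreement with the
package is expected within a fraction of a grade, not exactly.
"""
import math
import re


def syllables(word: str) -> int:
    word = word.lower()
    n = len(re.findall(r"[aeiouy]+", word))
    if n > 1 and word.endswith("e") and not word.endswith(("le", "ee")):
        n -= 1
    return max(1, n)


def reference_indices(text: str) -> dict:
    sentences = [s for s in re.split(r"[.!?]+", text) if re.search(r"[A-Za-z0-9]", s)]
    words = re.findall(r"[A-Za-z0-9'’-]+", text)
    s_count, w_count = len(sentences), len(words)
    syll = sum(syllables(w) for w in words)
    poly = sum(1 for w in words if syllables(w) >= 3)
    letters = sum(1 for w in words for ch in w if ch.isalpha())
    return {
        "flesch_kincaid": 0.39 * w_count / s_count + 11.8 * syll / w_count - 15.59,
        "gunning_fog": 0.4 * (w_count / s_count + 100.0 * poly / w_count),
        "coleman_liau": (
            0.0588 * 100.0 * letters / w_count
            - 0.296 * 100.0 * s_count / w_count
            - 15.8
        ),
        "smog": 1.0430 * math.sqrt(30.0 * poly / s_count) + 3.1291,
    }
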