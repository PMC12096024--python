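"""Synthetic study cohorts: documents with exactly ledgered token
statistics, a guideline table, planted treatment mentions, and noisy
simulated raters.

The generator emulates the shape of the source study: 50 patient
profiles, each with one AI-arm and one clinician-arm document (100
documents), arm-level differences in authoring speed, readability,
guideline concordance and rubric scores, and two raters whose scores
occasionally diverge past the adjudication threshold.  Every document is
synthesized from a curated knee-osteoarthritis word bank whose syllable
and letter counts are recorded while the text is built, so the
generator's ledger equals the tokenizer's output exactly (a tested
round-trip).  All randomness flows from one seed through named
substreams (table, text, mentions, raters, timing).
"""
from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator

from .concordance import (
    Category,
    Mention,
    Polarity,
    SOCIETIES,
    consolidate_table,
    document_accuracy_score,
    max_positive_score,
    normalize_accuracy,
)
from .rubrics import (
    ADJUDICATION_THRESHOLD,
    INSTRUMENTS,
    Instrument,
    ScoreSheet,
    final_score,
    needs_adjudication,
)
from .text_metrics import (
    Arm,
    Document,
    TokenStats,
    count_syllables,
    readability_indices,
)

__all__ = [
    "CohortConfig",
    "WordBank",
    "TextTarget",
    "Cohort",
    "generate_text",
    "generate_guideline_table",
    "simulate_raters",
    "sample_cohort_plan",
    "generate_cohort",
    "metrics_from_plan",
    "simulate_paired_metrics",
    "RUBRIC_METRICS",
    "ALL_METRICS",
]

RUBRIC_METRICS = {
    Instrument.PERSONALIZATION: "personalization",
    Instrument.COMPREHENSIVENESS: "comprehensiveness",
    Instrument.SAFETY: "safety",
}

ALL_METRICS = (
    "wpm",
    "flesch_kincaid",
    "gunning_fog",
    "coleman_liau",
    "smog",
    "accuracy",
    "personalization",
    "comprehensiveness",
    "safety",
)

_MAX_SYLLABLE_CLASS = 5


class CohortConfig(BaseModel):
    """Parameters of a synthetic study cohort.

    Defaults mirror the study conditions: 50 profiles, authoring-speed
    medians near 530 (AI) and 37.3 (clinician) words per minute, lower
    grade-level readability in the AI arm, accuracy means 5.31 vs 4.76 on
    a 6-point scale, and the published rubric arm means.  Rater noise and
    the disagreement rate have no counterpart in the study report and are
    documented placeholders.
    """

    schema_version: int = 1
    n_profiles: int = Field(default=50, ge=2)
    seed: int = 0
    n_treatments: int = Field(default=12, ge=1)

    # document shape
    words_median: float = Field(default=450.0, gt=0)
    words_sigma: float = Field(default=0.2, ge=0)
    wps_ai: float = Field(default=16.0, gt=0)      # words per sentence
    wps_clin: float = Field(default=18.0, gt=0)
    wps_sd: float = Field(default=1.5, ge=0)
    spw_ai: float = Field(default=1.77, ge=1.0)    # syllables per word
    spw_clin: float = Field(default=1.80, ge=1.0)
    spw_sd: float = Field(default=0.04, ge=0)

    # authoring speed (words per minute), lognormal medians/log-sigmas
    wpm_median_ai: float = Field(default=530.03, gt=0)
    wpm_median_clin: float = Field(default=37.29, gt=0)
    wpm_sigma_ai: float = Field(default=0.188, ge=0)
    wpm_sigma_clin: float = Field(default=0.079, ge=0)

    # guideline-concordance accuracy on the normalized scale
    accuracy_scale_max: float = Field(default=6.0, gt=0)
    accuracy_mean_ai: float = 5.31
    accuracy_mean_clin: float = 4.76
    accuracy_sd: float = Field(default=0.75, ge=0)

    # rubric instrument arm means (out of 100) and document-level spread
    personalization_ai: float = 54.32
    personalization_clin: float = 33.20
    comprehensiveness_ai: float = 51.74
    comprehensiveness_clin: float = 35.26
    safety_ai: float = 61.0
    safety_clin: float = 51.0
    rubric_doc_sd: float = Field(default=6.0, ge=0)

    # simulated raters
    rater_noise_sd: float = Field(default=2.0, ge=0)
    p_disagreement: float = Field(default=0.1, ge=0.0, le=1.0)
    adjudication_threshold: float = Field(default=ADJUDICATION_THRESHOLD, gt=0)

    def zero_delta(self) -> "CohortConfig":
        """Copy with every arm effect removed (AI parameters set to the
        clinician-arm values); downstream paired tests then run under the
        null."""
        return self.model_copy(
            update={
                "wps_ai": self.wps_clin,
                "spw_ai": self.spw_clin,
                "wpm_median_ai": self.wpm_median_clin,
                "wpm_sigma_ai": self.wpm_sigma_clin,
                "accuracy_mean_ai": self.accuracy_mean_clin,
                "personalization_ai": self.personalization_clin,
                "comprehensiveness_ai": self.comprehensiveness_clin,
                "safety_ai": self.safety_clin,
            }
        )

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=True)


class WordBank:
    """Words with known syllable and letter counts, grouped by syllables.

    The packaged default bank is knee-osteoarthritis vocabulary whose
    syllable counts come from the package's own counter, which is what
    makes the generator's ledger exact.
    """

    def __init__(self, entries: Iterable[tuple[str, int, int, bool]]):
        self.entries = [tuple(e) for e in entries]
        by: dict[int, list[str]] = {}
        for word, syllables, letters, _ in self.entries:
            if syllables < 1 or letters < 1:
                raise ValueError(f"bad bank entry {word!r}")
            by.setdefault(int(syllables), []).append(word)
        for c in range(1, _MAX_SYLLABLE_CLASS + 1):
            if c not in by:
                raise ValueError(f"word bank needs a word with {c} syllables")
        self._words = {c: tuple(ws) for c, ws in by.items()}
        self._letters = {
            c: np.array([sum(ch.isalpha() for ch in w) for w in ws], dtype=np.int64)
            for c, ws in self._words.items()
        }

    @classmethod
    def default(cls) -> "WordBank":
        ref = resources.files("eduscore.data").joinpath("wordbank.csv")
        df = pd.read_csv(io.StringIO(ref.read_text(encoding="utf-8")))
        return cls(
            (r.word, int(r.syllables), int(r.letters), int(r.syllables) >= 3)
            for r in df.itertuples()
        )

    def classes(self) -> tuple[int, ...]:
        return tuple(sorted(self._words))

    def words(self, syllables: int) -> tuple[str, ...]:
        return self._words[syllables]

    def letters(self, syllables: int) -> np.ndarray:
        return self._letters[syllables]

    def treatment_names(self) -> tuple[str, ...]:
        return tuple(w for w, _, _, _ in self.entries if w in _TREATMENT_SET)


_DEFAULT_BANK: Optional[WordBank] = None


def default_bank() -> WordBank:
    global _DEFAULT_BANK
    if _DEFAULT_BANK is None:
        _DEFAULT_BANK = WordBank.default()
    return _DEFAULT_BANK


def _load_treatment_names() -> tuple[str, ...]:
    ref = resources.files("eduscore.data").joinpath("wordbank.csv")
    df = pd.read_csv(io.StringIO(ref.read_text(encoding="utf-8")))
    return tuple(df.loc[df.category == "treatment", "word"])


_TREATMENT_NAMES = _load_treatment_names()
_TREATMENT_SET = set(_TREATMENT_NAMES)

#: Sentence templates used to plant treatment mentions in document text.
_ADVISED_TEMPLATES = (
    ("we", "recommend"),
    ("consider",),
    ("doctors", "advise"),
    ("try", "gentle"),
)
_DISCOURAGED_TEMPLATES = (
    ("avoid",),
    ("do", "not", "use"),
)


@dataclass(frozen=True)
class TextTarget:
    """Desired token-statistics profile for one generated text."""

    n_sentences: int
    words_per_sentence: int
    syllables_per_word: float

    def __post_init__(self) -> None:
        if self.n_sentences < 1 or self.words_per_sentence < 1:
            raise ValueError("need at least one sentence and one word per sentence")
        if self.syllables_per_word < 1.0:
            raise ValueError("syllables_per_word must be >= 1")


def _word_stats(word: str) -> tuple[int, int]:
    """(syllables, letters) for an arbitrary token (cached)."""
    if word not in _WORD_STATS_CACHE:
        _WORD_STATS_CACHE[word] = (
            count_syllables(word),
            sum(ch.isalpha() for ch in word),
        )
    return _WORD_STATS_CACHE[word]


_WORD_STATS_CACHE: dict[str, tuple[int, int]] = {}


def _render_sentence(words: Sequence[str]) -> str:
    first = words[0]
    return " ".join([first[0].upper() + first[1:], *words[1:]]) + "."


def _ledger_from_words(sentences: Sequence[Sequence[str]]) -> TokenStats:
    n_words = n_syll = n_poly = n_letters = 0
    for sent in sentences:
        for w in sent:
            syl, letters = _word_stats(w)
            n_words += 1
            n_syll += syl
            n_letters += letters
            if syl >= 3:
                n_poly += 1
    return TokenStats(
        n_sentences=len(sentences),
        n_words=n_words,
        n_syllables=n_syll,
        n_complex=n_poly,  # no capitalized mid-sentence or hyphenated words
        n_polysyllables=n_poly,
        n_letters=n_letters,
    )


def generate_text(
    target: TextTarget,
    bank: Optional[WordBank] = None,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[str, TokenStats]:
    """Emit text hitting ``target`` exactly, with its bookkeeping ledger.

    The total syllable count is ``round(syllables_per_word * W)``.  The
    word multiset is a deterministic function of the target (extra
    syllables spread round-robin, bank words cycled within each syllable
    class); the seed only shuffles word order, so the ledger is
    identical across seeds.  Raises if the syllable mix is unsatisfiable
    from the bank (more than 5 syllables per word on average).
    """
    if bank is None:
        bank = default_bank()
    if rng is None:
        rng = np.random.default_rng(seed)
    S, wps = target.n_sentences, target.words_per_sentence
    W = S * wps
    total = int(round(target.syllables_per_word * W))
    extras = total - W
    if extras < 0 or extras > (_MAX_SYLLABLE_CLASS - 1) * W:
        raise ValueError(
            f"syllable mix unsatisfiable: {total} syllables over {W} words"
        )
    counts = np.ones(W, dtype=np.int64)
    for i in range(extras):  # round-robin keeps every word within the cap
        counts[i % W] += 1
    per_class = {c: int((counts == c).sum()) for c in range(1, _MAX_SYLLABLE_CLASS + 1)}
    words = [
        bank.words(c)[j % len(bank.words(c))]
        for c in sorted(per_class)
        for j in range(per_class[c])
    ]
    order = rng.permutation(W)
    words = [words[int(j)] for j in order]
    sentences = [words[i * wps : (i + 1) * wps] for i in range(S)]
    text = " ".join(_render_sentence(s) for s in sentences)
    return text, _ledger_from_words(sentences)


def generate_guideline_table(
    n_treatments: int,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Seeded synthetic guideline table with consolidated fields.

    The first eight treatments rotate through consensus sizes 5..1 so the
    table spans every weight class whenever n >= 8; the first treatment
    is always a unanimous strong recommendation so a positive ceiling for
    normalization exists.  This is a demonstration table, not a statement
    of any society's actual guidance.
    """
    if n_treatments < 1:
        raise ValueError("n_treatments must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    rotation = (5, 4, 3, 2, 1, 4, 3, 2)
    categories = [Category.SR, Category.CR, Category.INC, Category.CRA, Category.SRA]
    probs = np.array([0.30, 0.30, 0.15, 0.15, 0.10])
    rows = []
    for i in range(n_treatments):
        name = (
            _TREATMENT_NAMES[i]
            if i < len(_TREATMENT_NAMES)
            else f"therapy{i + 1}"
        )
        consensus_n = rotation[i] if i < len(rotation) else int(rng.integers(1, 6))
        cat = Category.SR if i == 0 else categories[rng.choice(len(categories), p=probs)]
        stances = {s: Category.NOT_ADDRESSED for s in SOCIETIES}
        order = rng.permutation(len(SOCIETIES))
        for j in order[:consensus_n]:
            stances[SOCIETIES[j]] = cat
        if 2 <= consensus_n <= 4 and rng.random() < 0.5:
            other = categories[int(rng.integers(len(categories)))]
            if other != cat:
                stances[SOCIETIES[order[consensus_n]]] = other
        rows.append(
            {"treatment_id": f"T{i + 1:02d}", "name": name, **{
                s: stances[s].value for s in SOCIETIES
            }}
        )
    return consolidate_table(pd.DataFrame(rows))


def simulate_raters(
    true_sheet: ScoreSheet,
    noise_sd: float,
    p_disagreement: float,
    rng: np.random.Generator,
    threshold: float = ADJUDICATION_THRESHOLD,
) -> tuple[ScoreSheet, ScoreSheet, Optional[ScoreSheet]]:
    """Two noisy raters (and a third when adjudication is needed).

    Rater points are the truth plus rounded Gaussian noise, clipped to
    each dimension's range.  With probability ``p_disagreement`` one
    randomly chosen dimension is rewritten so the two raters differ by
    strictly more than ``threshold``.  The third sheet is drawn near the
    truth and returned only when some dimension is flagged.
    """
    definition = INSTRUMENTS[Instrument(true_sheet.instrument)]
    dims = [d for d, _ in definition.dimensions]
    maxima = definition.maxima
    truth = np.array([true_sheet.points[d] for d in dims], dtype=float)
    caps = np.array([maxima[d] for d in dims], dtype=float)

    def noisy() -> dict[str, int]:
        vals = np.clip(np.rint(truth + rng.normal(0.0, noise_sd, truth.size)),
                       0.0, caps)
        return {d: int(v) for d, v in zip(dims, vals)}

    p1, p2 = noisy(), noisy()
    disagree = rng.random() < p_disagreement
    dim = dims[int(rng.integers(len(dims)))]
    if disagree:
        step = int(threshold) + 1
        lo = int(min(max(round(true_sheet.points[dim]) - step // 2, 0),
                     maxima[dim] - step))
        p1[dim], p2[dim] = lo, lo + step
    p3 = noisy()
    r1 = ScoreSheet(true_sheet.doc_id, Instrument(true_sheet.instrument), "R1", p1)
    r2 = ScoreSheet(true_sheet.doc_id, Instrument(true_sheet.instrument), "R2", p2)
    r3 = ScoreSheet(true_sheet.doc_id, Instrument(true_sheet.instrument), "R3", p3)
    if needs_adjudication(r1, r2, threshold):
        return r1, r2, r3
    return r1, r2, None


@dataclass
class DocPlan:
    """Everything sampled for one document; text rendering is a
    deterministic function of this plan."""

    doc_id: str
    profile_id: str
    arm: Arm
    sentence_lengths: np.ndarray
    word_syllables: np.ndarray
    word_index: np.ndarray
    mentions: list[Mention]
    minutes: float
    sheets: dict[Instrument, tuple[ScoreSheet, ScoreSheet, Optional[ScoreSheet]]]

    def mention_sentences(self) -> list[list[str]]:
        return _mention_sentences(self.mentions)


@dataclass
class CohortPlan:
    config: CohortConfig
    table: pd.DataFrame
    docs: list[DocPlan]


_MENTION_NAME_BY_ID: dict[str, str] = {}


def _mention_sentences(mentions: Sequence[Mention]) -> list[list[str]]:
    out = []
    for k, m in enumerate(mentions):
        if m.polarity is Polarity.DISCOURAGED:
            template = _DISCOURAGED_TEMPLATES[k % len(_DISCOURAGED_TEMPLATES)]
        else:
            template = _ADVISED_TEMPLATES[k % len(_ADVISED_TEMPLATES)]
        out.append([*template, _MENTION_NAME_BY_ID[m.treatment_id]])
    return out


def _select_mentions(
    order: Sequence[str], weighted: dict[str, float], target: float
) -> set[str]:
    """Subset of treatments whose weighted-score sum approximates
    ``target``: one greedy pass, then toggle-improvement passes until a
    local optimum (keeps the quantization error within half the smallest
    improving step)."""
    chosen: set[str] = set()
    total = 0.0
    for tid in order:
        ws = weighted[tid]
        if abs(total + ws - target) < abs(total - target):
            chosen.add(tid)
            total += ws
    improved = True
    while improved:
        improved = False
        for tid in order:
            ws = weighted[tid]
            delta = -ws if tid in chosen else ws
            if abs(total + delta - target) < abs(total - target) - 1e-12:
                chosen.symmetric_difference_update({tid})
                total += delta
                improved = True
    return chosen


def _arm_value(config: CohortConfig, stem: str, arm: Arm) -> float:
    suffix = "ai" if arm is Arm.AI else "clin"
    return getattr(config, f"{stem}_{suffix}")


def sample_cohort_plan(config: CohortConfig, bank: Optional[WordBank] = None) -> CohortPlan:
    """Draw every random quantity of a cohort from the named substreams."""
    if bank is None:
        bank = default_bank()
    ss = np.random.SeedSequence(config.seed)
    streams = dict(
        zip(("table", "text", "mentions", "raters", "timing"),
            (np.random.default_rng(s) for s in ss.spawn(5)))
    )
    table = generate_guideline_table(config.n_treatments, rng=streams["table"])
    _MENTION_NAME_BY_ID.update(zip(table["treatment_id"], table["name"]))
    weighted = dict(zip(table["treatment_id"], table["weighted_score"]))
    tids = list(table["treatment_id"])
    ceiling = max_positive_score(table)

    docs: list[DocPlan] = []
    for p in range(config.n_profiles):
        profile_id = f"P{p + 1:03d}"
        for arm in (Arm.AI, Arm.CLINICIAN):
            rng_text = streams["text"]
            w_body = max(
                50, int(round(rng_text.lognormal(math.log(config.words_median),
                                                 config.words_sigma)))
            )
            wps = min(max(rng_text.normal(_arm_value(config, "wps", arm),
                                          config.wps_sd), 6.0), 40.0)
            n_sent = max(2, int(round(w_body / wps)))
            base, rem = divmod(w_body, n_sent)
            sentence_lengths = np.full(n_sent, base, dtype=np.int64)
            sentence_lengths[:rem] += 1
            spw = min(max(rng_text.normal(_arm_value(config, "spw", arm),
                                          config.spw_sd), 1.02), 3.5)
            extra = np.minimum(
                rng_text.poisson(spw - 1.0, w_body), _MAX_SYLLABLE_CLASS - 1
            )
            syllables = (1 + extra).astype(np.int64)
            word_index = np.zeros(w_body, dtype=np.int64)
            for c in range(1, _MAX_SYLLABLE_CLASS + 1):
                mask = syllables == c
                if mask.any():
                    word_index[mask] = rng_text.integers(
                        len(bank.words(c)), size=int(mask.sum())
                    )

            rng_m = streams["mentions"]
            target_norm = min(
                max(rng_m.normal(_arm_value(config, "accuracy_mean", arm),
                                 config.accuracy_sd), 0.0),
                config.accuracy_scale_max,
            )
            raw_target = target_norm * ceiling / config.accuracy_scale_max
            order = [tids[int(j)] for j in rng_m.permutation(len(tids))]
            chosen = _select_mentions(order, weighted, raw_target)
            mentions = [
                Mention(tid, Polarity.DISCOURAGED if weighted[tid] < 0
                        else Polarity.ADVISED)
                for tid in order if tid in chosen
            ]

            rng_r = streams["raters"]
            sheets = {}
            doc_id = f"{profile_id}-{arm.value}"
            for inst, stem in RUBRIC_METRICS.items():
                truth_total = float(
                    np.clip(rng_r.normal(_arm_value(config, stem, arm),
                                         config.rubric_doc_sd), 0.0, 100.0)
                )
                definition = INSTRUMENTS[inst]
                truth = ScoreSheet(
                    doc_id, inst, "truth",
                    {d: truth_total * mx / 100.0 for d, mx in definition.dimensions},
                )
                sheets[inst] = simulate_raters(
                    truth, config.rater_noise_sd, config.p_disagreement,
                    rng_r, config.adjudication_threshold,
                )

            w_total = w_body + sum(len(s) for s in _mention_sentences(mentions))
            rng_t = streams["timing"]
            wpm = rng_t.lognormal(
                math.log(_arm_value(config, "wpm_median", arm)),
                _arm_value(config, "wpm_sigma", arm),
            )
            minutes = w_total / wpm
            docs.append(
                DocPlan(doc_id, profile_id, arm, sentence_lengths, syllables,
                        word_index, mentions, minutes, sheets)
            )
    return CohortPlan(config=config, table=table, docs=docs)


def _plan_sentences(plan: DocPlan, bank: WordBank) -> list[list[str]]:
    words = [
        bank.words(int(c))[int(i)]
        for c, i in zip(plan.word_syllables, plan.word_index)
    ]
    sentences, pos = [], 0
    for length in plan.sentence_lengths:
        sentences.append(words[pos : pos + int(length)])
        pos += int(length)
    sentences.extend(plan.mention_sentences())
    return sentences


def _plan_ledger(plan: DocPlan, bank: WordBank) -> TokenStats:
    """Token stats of the rendered document, from bookkeeping alone."""
    n_body = int(plan.word_syllables.size)
    n_syll = int(plan.word_syllables.sum())
    n_poly = int((plan.word_syllables >= 3).sum())
    letters = 0
    for c in range(1, _MAX_SYLLABLE_CLASS + 1):
        mask = plan.word_syllables == c
        if mask.any():
            letters += int(bank.letters(c)[plan.word_index[mask]].sum())
    n_sent = len(plan.sentence_lengths)
    n_words, n_letters = n_body, letters
    for sent in plan.mention_sentences():
        n_sent += 1
        for w in sent:
            syl, let = _word_stats(w)
            n_words += 1
            n_syll += syl
            n_letters += let
            if syl >= 3:
                n_poly += 1
    return TokenStats(
        n_sentences=n_sent,
        n_words=n_words,
        n_syllables=n_syll,
        n_complex=n_poly,
        n_polysyllables=n_poly,
        n_letters=n_letters,
    )


def render_document(plan: DocPlan, bank: Optional[WordBank] = None) -> Document:
    if bank is None:
        bank = default_bank()
    text = " ".join(_render_sentence(s) for s in _plan_sentences(plan, bank))
    return Document(
        doc_id=plan.doc_id,
        text=text,
        authoring_minutes=plan.minutes,
        arm=plan.arm,
        profile_id=plan.profile_id,
    )


@dataclass
class Cohort:
    """A fully materialized synthetic study dataset."""

    config: CohortConfig
    plan: CohortPlan
    documents: list[Document]
    guidelines: pd.DataFrame
    mentions: pd.DataFrame
    ratings: pd.DataFrame

    def write(self, outdir) -> dict[str, Path]:
        """Write docs.jsonl, guidelines.csv, mentions.csv, ratings.csv,
        cohort.yaml; returns the paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "docs": outdir / "docs.jsonl",
            "guidelines": outdir / "guidelines.csv",
            "mentions": outdir / "mentions.csv",
            "ratings": outdir / "ratings.csv",
            "config": outdir / "cohort.yaml",
        }
        with open(paths["docs"], "w", encoding="utf-8") as fh:
            for doc in self.documents:
                fh.write(json.dumps({
                    "doc_id": doc.doc_id,
                    "profile_id": doc.profile_id,
                    "arm": doc.arm.value,
                    "authoring_minutes": doc.authoring_minutes,
                    "text": doc.text,
                }) + "\n")
        self.guidelines.to_csv(paths["guidelines"], index=False)
        self.mentions.to_csv(paths["mentions"], index=False)
        self.ratings.to_csv(paths["ratings"], index=False)
        self.config.to_yaml(paths["config"])
        return paths

    def metrics_table(self) -> pd.DataFrame:
        return metrics_from_plan(self.plan)


def generate_cohort(config: CohortConfig, bank: Optional[WordBank] = None) -> Cohort:
    """Materialize a complete synthetic cohort (documents rendered)."""
    if bank is None:
        bank = default_bank()
    plan = sample_cohort_plan(config, bank)
    documents = [render_document(d, bank) for d in plan.docs]
    mention_rows = [
        {"doc_id": d.doc_id, "treatment_id": m.treatment_id,
         "polarity": m.polarity.value}
        for d in plan.docs for m in d.mentions
    ]
    rating_rows = []
    for d in plan.docs:
        for inst, (r1, r2, r3) in d.sheets.items():
            for sheet in (r1, r2, r3):
                if sheet is None:
                    continue
                for dim, pts in sheet.points.items():
                    rating_rows.append({
                        "doc_id": d.doc_id,
                        "instrument": inst.value,
                        "rater_id": sheet.rater_id,
                        "dimension": dim,
                        "points": int(pts),
                    })
    return Cohort(
        config=config,
        plan=plan,
        documents=documents,
        guidelines=plan.table,
        mentions=pd.DataFrame(mention_rows,
                              columns=["doc_id", "treatment_id", "polarity"]),
        ratings=pd.DataFrame(rating_rows,
                             columns=["doc_id", "instrument", "rater_id",
                                      "dimension", "points"]),
    )


def metrics_from_plan(
    plan: CohortPlan,
    metrics: Sequence[str] = ALL_METRICS,
    bank: Optional[WordBank] = None,
) -> pd.DataFrame:
    """Tidy per-document metric table straight from a cohort plan.

    Identical to running the file-based pipeline on the rendered cohort
    (the ledger equals the tokenizer output; accuracy and adjudication
    use the same functions), but skips string rendering, so large
    replicate simulations stay cheap.
    """
    if bank is None:
        bank = default_bank()
    want = set(metrics)
    need_text = want & {"wpm", "flesch_kincaid", "gunning_fog", "coleman_liau", "smog"}
    rows = []
    for d in plan.docs:
        record = {"profile_id": d.profile_id, "arm": d.arm.value}
        values = {}
        if need_text:
            stats = _plan_ledger(d, bank)
            values.update(readability_indices(stats))
            values["wpm"] = stats.n_words / d.minutes
        if "accuracy" in want:
            raw = document_accuracy_score(d.mentions, plan.table)
            values["accuracy"] = normalize_accuracy(
                raw, plan.table, plan.config.accuracy_scale_max
            )
        for inst, metric in RUBRIC_METRICS.items():
            if metric in want:
                r1, r2, r3 = d.sheets[inst]
                adjudicated = final_score(
                    r1, r2, r3, threshold=plan.config.adjudication_threshold
                )
                values[metric] = sum(adjudicated.points.values())
        for metric in metrics:
            rows.append({**record, "metric": metric, "value": values[metric]})
    return pd.DataFrame(rows, columns=["profile_id", "arm", "metric", "value"])


def simulate_paired_metrics(
    config: CohortConfig,
    metrics: Sequence[str] = ALL_METRICS,
    bank: Optional[WordBank] = None,
) -> pd.DataFrame:
    """Sample one cohort and return its tidy metric table without
    rendering any text."""
    return metrics_from_plan(sample_cohort_plan(config, bank), metrics, bank)
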