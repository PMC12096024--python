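"""End-to-end evaluation run: blinding, per-document metrics,
adjudication, unblinded paired comparison, and a study-style report.

All inputs are validated up front and the run aborts before any
statistics if a problem is found (partial reports are never written).
Re-running with identical inputs and seeds reproduces the report
byte-identically; a provenance block records seeds, the configuration
hash, and input checksums.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import concordance, rubrics, stats, text_metrics
from .concordance import Mention, Polarity, PolarityMode
from .rubrics import INSTRUMENTS, Instrument, ScoreSheet
from .stats import PairedSample, TestPolicy, TestResult, format_p
from .text_metrics import Arm, Document

__all__ = [
    "BlindingKey",
    "RunConfig",
    "RunReport",
    "ValidationFailure",
    "blind_and_randomize",
    "unblind",
    "read_documents_jsonl",
    "paired_samples_from_table",
    "run_evaluation",
    "run_evaluation_from_paths",
]

logger = logging.getLogger(__name__)

READABILITY_METRICS = ("flesch_kincaid", "gunning_fog", "coleman_liau", "smog")


class ValidationFailure(ValueError):
    """Raised with an itemized list of input problems."""

    def __init__(self, problems: Sequence[str]):
        self.problems = list(problems)
        super().__init__(
            "input validation failed:\n" + "\n".join(f"  - {p}" for p in self.problems)
        )


@dataclass(frozen=True)
class BlindingKey:
    """Sealed mapping from anonymized codes back to provenance."""

    mapping: Mapping[str, tuple[str, Arm]]
    seed: int

    def arm_of(self, code: str) -> Arm:
        return self.mapping[code][1]

    def doc_id_of(self, code: str) -> str:
        return self.mapping[code][0]


def blind_and_randomize(
    documents: Sequence[Document], seed: int
) -> tuple[list[Document], BlindingKey]:
    """Strip arm labels, shuffle by seed, and assign opaque codes.

    The returned key inverts the blinding exactly; the same seed yields
    the same permutation and codes.
    """
    if not documents:
        raise ValueError("no documents to blind")
    ids = [d.doc_id for d in documents]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate doc_ids: {dupes}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(documents))
    blinded, mapping = [], {}
    for rank, j in enumerate(order):
        doc = documents[int(j)]
        code = f"DOC-{rank + 1:04d}"
        mapping[code] = (doc.doc_id, doc.arm)
        blinded.append(
            Document(
                doc_id=code,
                text=doc.text,
                authoring_minutes=doc.authoring_minutes,
                arm=None,
                profile_id=None,
            )
        )
    return blinded, BlindingKey(mapping=mapping, seed=seed)


def unblind(blinded: Sequence[Document], key: BlindingKey) -> list[Document]:
    """Restore original doc_ids and arm labels from the key."""
    out = []
    for doc in blinded:
        doc_id, arm = key.mapping[doc.doc_id]
        out.append(
            Document(
                doc_id=doc_id,
                text=doc.text,
                authoring_minutes=doc.authoring_minutes,
                arm=arm,
            )
        )
    return out


def read_documents_jsonl(path) -> list[Document]:
    """Documents from JSON-lines (doc_id, profile_id, arm, text,
    authoring_minutes)."""
    docs, problems = [], []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
                docs.append(
                    Document(
                        doc_id=str(obj["doc_id"]),
                        text=obj["text"],
                        authoring_minutes=float(obj["authoring_minutes"]),
                        arm=Arm(obj["arm"]) if obj.get("arm") else None,
                        profile_id=obj.get("profile_id"),
                    )
                )
            except (KeyError, ValueError, TypeError) as exc:
                problems.append(f"{path}: line {lineno}: {exc}")
    if problems:
        raise ValidationFailure(problems)
    return docs


def read_documents_dir(directory, metadata_csv) -> list[Document]:
    """Documents from a directory of .txt files plus a sidecar metadata
    CSV (doc_id, profile_id, arm, authoring_minutes)."""
    directory = Path(directory)
    meta = pd.read_csv(metadata_csv, dtype={"doc_id": str})
    docs, problems = [], []
    for row in meta.itertuples():
        path = directory / f"{row.doc_id}.txt"
        if not path.exists():
            problems.append(f"{metadata_csv}: doc {row.doc_id}: missing {path}")
            continue
        docs.append(
            Document(
                doc_id=row.doc_id,
                text=path.read_text(encoding="utf-8"),
                authoring_minutes=float(row.authoring_minutes),
                arm=Arm(row.arm) if isinstance(row.arm, str) else None,
                profile_id=getattr(row, "profile_id", None),
            )
        )
    if problems:
        raise ValidationFailure(problems)
    return docs


class RunConfig:
    """Knobs of an evaluation run (defaults mirror the study design)."""

    def __init__(
        self,
        adjudication_threshold: float = rubrics.ADJUDICATION_THRESHOLD,
        policy: TestPolicy = TestPolicy.AUTO,
        alpha: float = stats.DEFAULT_ALPHA,
        accuracy_scale_max: float = 6.0,
        polarity_mode: PolarityMode = PolarityMode.LITERAL,
        normalize_accuracy: bool = True,
    ):
        self.adjudication_threshold = adjudication_threshold
        self.policy = TestPolicy(policy)
        self.alpha = alpha
        self.accuracy_scale_max = accuracy_scale_max
        self.polarity_mode = PolarityMode(polarity_mode)
        self.normalize_accuracy = normalize_accuracy

    def as_dict(self) -> dict:
        return {
            "adjudication_threshold": self.adjudication_threshold,
            "policy": self.policy.value,
            "alpha": self.alpha,
            "accuracy_scale_max": self.accuracy_scale_max,
            "polarity_mode": self.polarity_mode.value,
            "normalize_accuracy": self.normalize_accuracy,
        }


def _validate_inputs(
    documents: Sequence[Document],
    guidelines: pd.DataFrame,
    mentions: pd.DataFrame,
    ratings: pd.DataFrame,
) -> None:
    problems: list[str] = []
    doc_ids = {d.doc_id for d in documents}
    if len(doc_ids) != len(documents):
        problems.append("documents: duplicate doc_ids")
    profiles: dict[str, set] = {}
    for d in documents:
        if d.arm is None or d.profile_id is None:
            problems.append(f"documents: {d.doc_id}: arm or profile_id missing")
            continue
        profiles.setdefault(d.profile_id, set()).add(d.arm)
    for pid, arms in profiles.items():
        if arms != {Arm.AI, Arm.CLINICIAN}:
            problems.append(f"documents: profile {pid}: needs exactly one document per arm")

    known_treatments = set(guidelines["treatment_id"].astype(str))
    for row in mentions.itertuples():
        if str(row.doc_id) not in doc_ids:
            problems.append(f"mentions: row {row.Index}: unknown doc_id {row.doc_id!r}")
        if str(row.treatment_id) not in known_treatments:
            problems.append(
                f"mentions: row {row.Index}: unknown treatment_id {row.treatment_id!r}"
            )
        try:
            Polarity(row.polarity)
        except ValueError:
            problems.append(f"mentions: row {row.Index}: bad polarity {row.polarity!r}")

    required = {"doc_id", "instrument", "rater_id", "dimension", "points"}
    missing_cols = required - set(ratings.columns)
    if missing_cols:
        problems.append(f"ratings: missing columns {sorted(missing_cols)}")
    else:
        for row in ratings.itertuples():
            if str(row.doc_id) not in doc_ids:
                problems.append(f"ratings: row {row.Index}: unknown doc_id {row.doc_id!r}")
            try:
                inst = Instrument(row.instrument)
            except ValueError:
                problems.append(
                    f"ratings: row {row.Index}: unknown instrument {row.instrument!r}"
                )
                continue
            maxima = INSTRUMENTS[inst].maxima
            if row.dimension not in maxima:
                problems.append(
                    f"ratings: row {row.Index}: unknown dimension {row.dimension!r}"
                )
            elif not float(row.points).is_integer() or not 0 <= row.points <= maxima[row.dimension]:
                problems.append(
                    f"ratings: row {row.Index}: points {row.points!r} invalid for "
                    f"{row.dimension} (max {maxima[row.dimension]})"
                )
        # every document must have complete sheets from raters R1 and R2
        have = {
            (str(r.doc_id), r.instrument, r.rater_id)
            for r in ratings.itertuples()
        }
        for d in documents:
            for inst in Instrument:
                for rater in ("R1", "R2"):
                    if (d.doc_id, inst.value, rater) not in have:
                        problems.append(
                            f"ratings: document {d.doc_id}: missing {inst.value} "
                            f"sheet from rater {rater}"
                        )
    if problems:
        raise ValidationFailure(problems)


def _sheets_from_ratings(ratings: pd.DataFrame) -> dict:
    sheets: dict[tuple[str, Instrument, str], dict] = {}
    for row in ratings.itertuples():
        key = (str(row.doc_id), Instrument(row.instrument), str(row.rater_id))
        sheets.setdefault(key, {})[row.dimension] = int(row.points)
    return {
        key: ScoreSheet(doc_id=key[0], instrument=key[1], rater_id=key[2], points=pts)
        for key, pts in sheets.items()
    }


def adjudicate_ratings(
    ratings: pd.DataFrame, threshold: float = rubrics.ADJUDICATION_THRESHOLD
) -> pd.DataFrame:
    """Adjudicated per-dimension scores for every (doc, instrument).

    Returns long-format rows (doc_id, instrument, dimension, final_points,
    adjudication_flag).
    """
    sheets = _sheets_from_ratings(ratings)
    keys = sorted({(d, i) for d, i, _ in sheets}, key=lambda k: (k[0], k[1].value))
    rows = []
    for doc_id, inst in keys:
        r1 = sheets.get((doc_id, inst, "R1"))
        r2 = sheets.get((doc_id, inst, "R2"))
        if r1 is None or r2 is None:
            raise ValidationFailure(
                [f"ratings: document {doc_id}: needs sheets from raters R1 and R2 "
                 f"for {inst.value}"]
            )
        r3 = sheets.get((doc_id, inst, "R3"))
        flagged = set(rubrics.needs_adjudication(r1, r2, threshold))
        final = rubrics.final_score(r1, r2, r3, threshold=threshold)
        for dim, _ in INSTRUMENTS[inst].dimensions:
            rows.append({
                "doc_id": doc_id,
                "instrument": inst.value,
                "dimension": dim,
                "final_points": final.points[dim],
                "adjudication_flag": dim in flagged,
            })
    return pd.DataFrame(rows)


def compute_document_metrics(
    documents: Sequence[Document],
    guidelines: pd.DataFrame,
    mentions: pd.DataFrame,
    ratings: pd.DataFrame,
    config: Optional[RunConfig] = None,
) -> pd.DataFrame:
    """Tidy (profile_id, arm, metric, value) table for all nine metrics."""
    config = config or RunConfig()
    table = concordance.consolidate_table(guidelines)
    mention_lists: dict[str, list[Mention]] = {}
    for row in mentions.itertuples():
        mention_lists.setdefault(str(row.doc_id), []).append(
            Mention(str(row.treatment_id), Polarity(row.polarity))
        )
    adjudicated = adjudicate_ratings(ratings, config.adjudication_threshold)
    rubric_totals = adjudicated.groupby(["doc_id", "instrument"])["final_points"].sum()

    rows = []
    for doc in documents:
        base = {"profile_id": doc.profile_id, "arm": doc.arm.value}
        analysis = text_metrics.analyze_document(doc)
        for metric in ("wpm", *READABILITY_METRICS):
            rows.append({**base, "metric": metric, "value": analysis[metric]})
        raw = concordance.document_accuracy_score(
            mention_lists.get(doc.doc_id, []), table, config.polarity_mode
        )
        accuracy = (
            concordance.normalize_accuracy(raw, table, config.accuracy_scale_max)
            if config.normalize_accuracy
            else raw
        )
        rows.append({**base, "metric": "accuracy", "value": accuracy})
        for inst, metric in (
            (Instrument.PERSONALIZATION, "personalization"),
            (Instrument.COMPREHENSIVENESS, "comprehensiveness"),
            (Instrument.SAFETY, "safety"),
        ):
            rows.append({
                **base,
                "metric": metric,
                "value": float(rubric_totals[(doc.doc_id, inst.value)]),
            })
    return pd.DataFrame(rows, columns=["profile_id", "arm", "metric", "value"])


def paired_samples_from_table(metric_table: pd.DataFrame) -> list[PairedSample]:
    """Pivot a tidy metric table into per-metric paired samples."""
    samples = []
    for metric, group in metric_table.groupby("metric", sort=False):
        wide = group.pivot(index="profile_id", columns="arm", values="value")
        if wide.isna().any().any():
            missing = wide[wide.isna().any(axis=1)].index.tolist()
            raise ValidationFailure(
                [f"metric {metric}: profiles missing one arm: {missing}"]
            )
        wide = wide.sort_index()
        samples.append(
            PairedSample(
                metric=metric,
                profile_ids=tuple(wide.index),
                x_ai=tuple(wide[Arm.AI.value]),
                x_clin=tuple(wide[Arm.CLINICIAN.value]),
            )
        )
    return samples


@dataclass
class RunReport:
    """Per-metric comparison rows plus a provenance block."""

    results: list[TestResult]
    metric_table: pd.DataFrame
    provenance: dict
    alpha: float

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            rows.append({
                "metric": r.metric,
                "test": r.test.value,
                "statistic": round(r.statistic, 4),
                "p": format_p(r.p_value),
                "significant": r.significant(self.alpha),
                "style": r.style,
                "ai_mean": round(r.summary_ai.mean, 2),
                "ai_sd": round(r.summary_ai.sd, 2),
                "ai_median": round(r.summary_ai.median, 2),
                "ai_q1": round(r.summary_ai.q1, 2),
                "ai_q3": round(r.summary_ai.q3, 2),
                "clin_mean": round(r.summary_clin.mean, 2),
                "clin_sd": round(r.summary_clin.sd, 2),
                "clin_median": round(r.summary_clin.median, 2),
                "clin_q1": round(r.summary_clin.q1, 2),
                "clin_q3": round(r.summary_clin.q3, 2),
                "n_pairs": r.n,
            })
        return pd.DataFrame(rows)

    def to_text(self) -> str:
        lines = [
            "Paired arm comparison (AI vs clinician)",
            f"alpha = {self.alpha}; t rows report mean (SD), Wilcoxon rows "
            "report median [Q1-Q3]",
            "",
        ]
        header = f"{'metric':<18}{'AI':>24}{'clinician':>24}{'test':>10}{'p':>8}"
        lines.append(header)
        lines.append("-" * len(header))
        for r in self.results:
            if r.style == "mean_sd":
                ai = f"{r.summary_ai.mean:.2f} ({r.summary_ai.sd:.2f})"
                cl = f"{r.summary_clin.mean:.2f} ({r.summary_clin.sd:.2f})"
            else:
                ai = f"{r.summary_ai.median:.2f} [{r.summary_ai.q1:.2f}-{r.summary_ai.q3:.2f}]"
                cl = f"{r.summary_clin.median:.2f} [{r.summary_clin.q1:.2f}-{r.summary_clin.q3:.2f}]"
            star = "*" if r.significant(self.alpha) else ""
            lines.append(
                f"{r.metric:<18}{ai:>24}{cl:>24}"
                f"{('t' if r.test.value == 'PAIRED_T' else 'W'):>10}"
                f"{format_p(r.p_value) + star:>8}"
            )
        lines.append("")
        lines.append("provenance: " + json.dumps(self.provenance, sort_keys=True))
        return "\n".join(lines) + "\n"

    def write(self, outdir) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "report_csv": outdir / "report.csv",
            "report_txt": outdir / "report.txt",
            "metrics_csv": outdir / "metrics.csv",
            "provenance": outdir / "provenance.json",
        }
        self.to_frame().to_csv(paths["report_csv"], index=False)
        paths["report_txt"].write_text(self.to_text(), encoding="utf-8")
        self.metric_table.to_csv(paths["metrics_csv"], index=False)
        paths["provenance"].write_text(
            json.dumps(self.provenance, indent=2, sort_keys=True) + "\n",
            encoding="utf-8",
        )
        return paths


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_evaluation(
    documents: Sequence[Document],
    guidelines: pd.DataFrame,
    mentions: pd.DataFrame,
    ratings: pd.DataFrame,
    config: Optional[RunConfig] = None,
    provenance: Optional[dict] = None,
) -> RunReport:
    """Validate inputs, compute all metrics, and compare the arms.

    Stages: fail-fast validation; WPM and the four readability indices
    per document; guideline-concordance accuracy from mentions;
    adjudicated rubric totals; pairing by profile; test selection and
    paired comparison per metric.
    """
    config = config or RunConfig()
    _validate_inputs(documents, guidelines, mentions, ratings)
    logger.info("validated %d documents, %d mention rows, %d rating rows",
                len(documents), len(mentions), len(ratings))
    metric_table = compute_document_metrics(
        documents, guidelines, mentions, ratings, config
    )
    samples = paired_samples_from_table(metric_table)
    logger.info("comparing %d metrics over %d pairs", len(samples),
                samples[0].n if samples else 0)
    results = [stats.compare_paired(s, config.policy, config.alpha) for s in samples]
    prov = {
        "config": config.as_dict(),
        "config_sha256": hashlib.sha256(
            json.dumps(config.as_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "n_documents": len(documents),
        "n_profiles": len({d.profile_id for d in documents}),
    }
    prov.update(provenance or {})
    return RunReport(results=results, metric_table=metric_table,
                     provenance=prov, alpha=config.alpha)


def run_evaluation_from_paths(
    docs_path, guidelines_path, mentions_path, ratings_path,
    config: Optional[RunConfig] = None,
) -> RunReport:
    """File-based entry point; records input checksums in provenance."""
    documents = read_documents_jsonl(docs_path)
    # "NA" is the NOT_ADDRESSED stance, not a missing value
    guidelines = pd.read_csv(
        guidelines_path, dtype={"treatment_id": str}, keep_default_na=False
    )
    mentions = pd.read_csv(
        mentions_path, dtype={"doc_id": str, "treatment_id": str}
    )
    ratings = pd.read_csv(ratings_path, dtype={"doc_id": str})
    checksums = {
        str(p): _sha256(p)
        for p in (docs_path, guidelines_path, mentions_path, ratings_path)
    }
    return run_evaluation(
        documents, guidelines, mentions, ratings, config,
        provenance={"input_sha256": checksums},
    )
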