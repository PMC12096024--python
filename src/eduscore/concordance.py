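"""Weighted guideline-consensus ("accuracy") scoring.

Each treatment carries a stance from up to five guideline bodies (ACR,
OARSI, ESCEO, AAOS, NICE).  The consolidated endorsement category maps to
an integer score s in {+2, +1, 0, -1, -2}; the number of agreeing
societies maps to a consensus weight w in {1, 0.75, 0.5, 0.25}; a
document's raw accuracy is the sum of s*w over the distinct treatments it
mentions.  An optional normalization expresses the raw sum against the
table's maximum achievable positive sum on a fixed scale (the study
reports accuracy out of 6 points).
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "Category",
    "Polarity",
    "PolarityMode",
    "SOCIETIES",
    "Mention",
    "Treatment",
    "category_score",
    "consensus_weight",
    "consolidate_stances",
    "treatment_weighted_score",
    "document_accuracy_score",
    "max_positive_score",
    "normalize_accuracy",
    "load_guidelines",
    "consolidate_table",
]

SOCIETIES = ("ACR", "OARSI", "ESCEO", "AAOS", "NICE")


class Category(str, Enum):
    """Endorsement category of a guideline body for one treatment."""

    SR = "SR"      # strongly recommended
    CR = "CR"      # conditionally recommended
    INC = "INC"    # inconclusive
    CRA = "CRA"    # conditionally recommended against
    SRA = "SRA"    # strongly recommended against
    NOT_ADDRESSED = "NA"


class Polarity(str, Enum):
    ADVISED = "ADVISED"
    DISCOURAGED = "DISCOURAGED"


class PolarityMode(str, Enum):
    """LITERAL sums s*w regardless of how a treatment is mentioned (the
    study's rule); POLARITY_AWARE flips the sign of discouraged mentions
    and is an extension, off by default."""

    LITERAL = "LITERAL"
    POLARITY_AWARE = "POLARITY_AWARE"


_CATEGORY_SCORES = {
    Category.SR: 2,
    Category.CR: 1,
    Category.INC: 0,
    Category.CRA: -1,
    Category.SRA: -2,
}

_CONSENSUS_WEIGHTS = {1: 0.25, 2: 0.5, 3: 0.75, 4: 1.0, 5: 1.0}


def category_score(category: Category) -> int:
    """Integer recommendation score: SR +2, CR +1, INC 0, CRA -1, SRA -2."""
    category = Category(category)
    if category is Category.NOT_ADDRESSED:
        raise ValueError("NOT_ADDRESSED has no recommendation score")
    return _CATEGORY_SCORES[category]


def consensus_weight(consensus_n: int) -> float:
    """Weight from the number of agreeing societies: >=4 -> 1.0, 3 -> 0.75,
    2 -> 0.5, 1 -> 0.25."""
    if not isinstance(consensus_n, int) or not 1 <= consensus_n <= 5:
        raise ValueError(f"consensus_n must be an integer in 1..5, got {consensus_n!r}")
    return _CONSENSUS_WEIGHTS[consensus_n]


def consolidate_stances(
    stances: Iterable[Category],
) -> tuple[Category, int]:
    """Modal non-NOT_ADDRESSED category and the size of the modal bloc.

    A tie between modal blocs consolidates to INC (societies disagree)
    with the tied bloc size as consensus_n.
    """
    cats = [Category(c) for c in stances]
    if len(cats) > len(SOCIETIES):
        raise ValueError(f"at most {len(SOCIETIES)} stances allowed")
    counts = Counter(c for c in cats if c is not Category.NOT_ADDRESSED)
    if not counts:
        raise ValueError("all stances NOT_ADDRESSED: no consolidated category")
    top = counts.most_common()
    best_n = top[0][1]
    modal = [c for c, n in top if n == best_n]
    if len(modal) > 1:
        return Category.INC, best_n
    return modal[0], best_n


@dataclass(frozen=True)
class Treatment:
    """A therapy with its per-society stances and derived consensus fields."""

    treatment_id: str
    name: str
    stances: Mapping[str, Category]
    category: Category = field(init=False)
    consensus_n: int = field(init=False)

    def __post_init__(self) -> None:
        unknown = set(self.stances) - set(SOCIETIES)
        if unknown:
            raise ValueError(f"unknown societies: {sorted(unknown)}")
        cat, n = consolidate_stances(self.stances.values())
        object.__setattr__(self, "category", cat)
        object.__setattr__(self, "consensus_n", n)

    @property
    def score(self) -> int:
        return category_score(self.category)

    @property
    def weight(self) -> float:
        return consensus_weight(self.consensus_n)

    @property
    def weighted_score(self) -> float:
        return treatment_weighted_score(self)


@dataclass(frozen=True)
class Mention:
    treatment_id: str
    polarity: Polarity = Polarity.ADVISED


def treatment_weighted_score(treatment: Treatment) -> float:
    """s * w, bounded in [-2, 2]."""
    return treatment.score * treatment.weight


def consolidate_table(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a guideline table and (re)compute its derived columns.

    Expects columns ``treatment_id``, ``name``, and one per society with
    values SR/CR/INC/CRA/SRA/NA.  If precomputed ``category`` or
    ``consensus_n`` columns are present they are validated against the
    recomputation and an error is raised on disagreement.
    """
    required = {"treatment_id", "name", *SOCIETIES}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"guideline table missing columns: {sorted(missing)}")
    if table["treatment_id"].duplicated().any():
        dupes = table.loc[table["treatment_id"].duplicated(), "treatment_id"]
        raise ValueError(f"duplicate treatment_ids: {sorted(set(dupes))}")
    out = table.copy()
    cats, ns = [], []
    for _, row in out.iterrows():
        cat, n = consolidate_stances(Category(row[s]) for s in SOCIETIES)
        cats.append(cat)
        ns.append(n)
    for col, fresh in (("category", [c.value for c in cats]), ("consensus_n", ns)):
        if col in out.columns:
            stale = [str(v) for v in out[col]]
            if stale != [str(v) for v in fresh]:
                raise ValueError(f"precomputed column {col!r} disagrees with recomputation")
    out["category"] = [c.value for c in cats]
    out["consensus_n"] = ns
    out["score"] = [category_score(c) for c in cats]
    out["weight"] = [consensus_weight(n) for n in ns]
    out["weighted_score"] = out["score"] * out["weight"]
    return out


def load_guidelines(path) -> pd.DataFrame:
    """Read a guidelines CSV and return the consolidated table.

    Default NA parsing is disabled: the literal string "NA" is the
    NOT_ADDRESSED stance, not a missing value.
    """
    return consolidate_table(
        pd.read_csv(path, dtype={"treatment_id": str}, keep_default_na=False)
    )


def _weighted_lookup(table: pd.DataFrame) -> Mapping[str, float]:
    if "weighted_score" not in table.columns:
        table = consolidate_table(table)
    return dict(zip(table["treatment_id"], table["weighted_score"]))


def document_accuracy_score(
    mentions: Sequence[Mention],
    table: pd.DataFrame,
    polarity_mode: PolarityMode = PolarityMode.LITERAL,
) -> float:
    """Sum of weighted scores over the distinct treatments mentioned.

    Duplicate mentions of a treatment count once.  In POLARITY_AWARE mode
    a DISCOURAGED mention contributes -(s*w) instead of s*w.
    """
    polarity_mode = PolarityMode(polarity_mode)
    lookup = _weighted_lookup(table)
    seen: dict[str, Mention] = {}
    for m in mentions:
        if not isinstance(m, Mention):
            m = Mention(*m) if isinstance(m, tuple) else Mention(m)
        seen.setdefault(m.treatment_id, m)
    unknown = [tid for tid in seen if tid not in lookup]
    if unknown:
        raise KeyError(f"treatments not in guideline table: {sorted(unknown)}")
    total = 0.0
    for tid, m in seen.items():
        ws = lookup[tid]
        if (
            polarity_mode is PolarityMode.POLARITY_AWARE
            and m.polarity is Polarity.DISCOURAGED
        ):
            ws = -ws
        total += ws
    return total


def max_positive_score(table: pd.DataFrame) -> float:
    """Maximum achievable raw sum: all positively weighted treatments."""
    if "weighted_score" not in table.columns:
        table = consolidate_table(table)
    positive = table.loc[table["weighted_score"] > 0, "weighted_score"]
    return float(positive.sum())


def normalize_accuracy(raw: float, table: pd.DataFrame, scale_max: float = 6.0) -> float:
    """Express a raw accuracy sum on a fixed scale.

    The raw sum is divided by the table's maximum achievable positive sum,
    multiplied by ``scale_max``, and clipped to [0, scale_max].
    """
    if not scale_max > 0:
        raise ValueError("scale_max must be > 0")
    ceiling = max_positive_score(table)
    if ceiling <= 0:
        raise ValueError("guideline table has no positively weighted treatment")
    return min(scale_max, max(0.0, raw / ceiling * scale_max))
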