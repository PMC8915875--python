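"""Multi-rater consolidation, agreement and variability classification.

When several assessors evaluate the same study, their ratings form a
rater x criterion matrix.  Agreement per criterion is summarised
semi-quantitatively by two signals: the number of distinct rating
categories observed, and the share of raters choosing each category.
Simple threshold rules then classify each criterion's inter-rater
variability:

* ``consensus`` — every retained rater chose the same category;
* ``low``      — the modal share is at least 80% but below 100%;
* ``high``     — the modal share falls below 60%, or at least three
  categories were used and the modal share is below 80%;
* ``moderate`` — the remaining band (the two published rules do not
  partition the space).

Criteria classified ``high`` in at least one study are prioritized for
refinement of their wording or guidance.  Removed criteria (``NA``
cells) are excluded from every denominator.  All thresholds are
configurable through :class:`DecisionRuleConfig` and are echoed into
output metadata for auditability.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .catalog import (
    NA_TOKEN,
    RELIABILITY_ORDER,
    RELEVANCE_ORDER,
)
from .scoring import StudyEvaluation

__all__ = [
    "RatingMatrix",
    "AgreementSummary",
    "DecisionRuleConfig",
    "DEFAULT_RULES",
    "VariabilityClassification",
    "IncompatibleEvaluationsError",
    "DuplicateRaterError",
    "consolidate",
    "agreement",
    "classify_variability",
    "classify_matrix",
    "prioritize",
    "percent_summary",
]


class IncompatibleEvaluationsError(ValueError):
    """Evaluations reference different catalogs or studies."""


class DuplicateRaterError(ValueError):
    """Two evaluations carry the same rater id."""


def _valid_tokens(section: str) -> tuple[str, ...]:
    if section == "REL":
        return RELEVANCE_ORDER
    return RELIABILITY_ORDER + (NA_TOKEN,)


@dataclass
class RatingMatrix:
    """Rater x criterion token matrix for one study and section.

    ``table`` is a pandas DataFrame indexed by rater id with one column
    per criterion/item id; cells hold rating tokens, with ``NA`` marking
    a criterion the rater removed.  ``NA`` never appears in relevance
    matrices (items cannot be removed).
    """

    study_label: str
    section: str
    table: pd.DataFrame

    def __post_init__(self) -> None:
        valid = set(_valid_tokens(self.section))
        bad = sorted(
            {str(v) for v in self.table.values.ravel() if str(v) not in valid}
        )
        if bad:
            raise ValueError(
                f"invalid token(s) {bad} for section {self.section}; "
                f"expected {sorted(valid)}"
            )

    @property
    def raters(self) -> tuple[str, ...]:
        return tuple(self.table.index)

    @property
    def criteria(self) -> tuple[str, ...]:
        return tuple(self.table.columns)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w", encoding="utf-8", newline="") as fh:
            fh.write(f"# study_label={self.study_label}\n")
            fh.write(f"# section={self.section}\n")
            self.table.to_csv(fh, index_label="rater")
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "RatingMatrix":
        path = Path(path)
        meta: dict[str, str] = {}
        with open(path, encoding="utf-8") as fh:
            pos = fh.tell()
            while True:
                line = fh.readline()
                if line.startswith("#"):
                    key, _, value = line[1:].strip().partition("=")
                    meta[key.strip()] = value.strip()
                    pos = fh.tell()
                else:
                    fh.seek(pos)
                    break
            table = pd.read_csv(fh, index_col=0, dtype=str)
        table.index = table.index.astype(str)
        return cls(
            study_label=meta.get("study_label", ""),
            section=meta.get("section", "RQ"),
            table=table,
        )


@dataclass
class AgreementSummary:
    """Per-criterion rating proportions over retained (non-NA) raters.

    ``proportions`` covers only observed categories and sums to 1;
    ``k_observed`` counts distinct categories; ``p_max`` is the modal
    share and ``modal_category`` the category achieving it (ties broken
    by the fixed category order).  ``n_retained == 0`` marks a criterion
    removed by every rater: no proportions, nothing to classify.
    """

    criterion_id: str
    n_retained: int
    proportions: dict[str, float]
    k_observed: int
    p_max: float | None
    modal_category: str | None


@dataclass(frozen=True)
class DecisionRuleConfig:
    """Thresholds of the variability decision rules.

    ``consensus_threshold`` is fixed at 1.0 (consensus means no
    variability at all); ``low_lower`` opens the low-variability band;
    ``high_pmax`` and (``high_k``, ``high_k_pmax``) are the two
    high-variability triggers; criteria retaining fewer than
    ``min_raters`` ratings are not classified.
    """

    consensus_threshold: float = 1.0
    low_lower: float = 0.8
    high_pmax: float = 0.6
    high_k: int = 3
    high_k_pmax: float = 0.8
    min_raters: int = 2

    def __post_init__(self) -> None:
        if self.consensus_threshold != 1.0:
            raise ValueError("consensus requires full agreement (threshold 1.0)")
        if not (0.0 < self.high_pmax <= self.high_k_pmax <= self.low_lower < 1.0):
            raise ValueError(
                "thresholds must satisfy 0 < high_pmax <= high_k_pmax "
                "<= low_lower < 1"
            )
        if self.min_raters < 1 or self.high_k < 2:
            raise ValueError("min_raters >= 1 and high_k >= 2 required")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DecisionRuleConfig":
        data = yaml.safe_load(Path(path).read_text("utf-8")) or {}
        return cls(**data)


DEFAULT_RULES = DecisionRuleConfig()


@dataclass
class VariabilityClassification:
    """Variability class of one criterion plus the rule branch that fired."""

    criterion_id: str
    variability: str  # consensus | low | moderate | high | unclassifiable
    triggering_rule: str


def consolidate(
    evaluations: Sequence[StudyEvaluation], section: str
) -> RatingMatrix:
    """Stack evaluations of one study into a rater x criterion matrix.

    Rater ids come from each evaluation's ``evaluator`` field (positional
    ``rater01`` style ids are assigned where absent).  Removed criteria
    map to ``NA`` cells.
    """
    if not evaluations:
        raise ValueError("no evaluations to consolidate")
    first = evaluations[0]
    rows: dict[str, list[str]] = {}
    for idx, ev in enumerate(evaluations):
        if ev.catalog_ref != first.catalog_ref:
            raise IncompatibleEvaluationsError(
                f"mixed catalogs: {ev.catalog_ref} vs {first.catalog_ref}"
            )
        if ev.study_label != first.study_label:
            raise IncompatibleEvaluationsError(
                f"mixed studies: {ev.study_label!r} vs {first.study_label!r}"
            )
        rater = ev.evaluator or f"rater{idx + 1:02d}"
        if rater in rows:
            raise DuplicateRaterError(f"duplicate rater id {rater!r}")
        if section == "REL":
            cells = [
                ev.relevance[i].rating or "ND" for i in ev.catalog.relevance_ids()
            ]
        else:
            cells = []
            for c in ev.catalog.criteria_for(section):
                a = ev.assessments[c.id]
                cells.append(NA_TOKEN if a.removed else (a.rating or "ND"))
        rows[rater] = cells
    if section == "REL":
        columns = list(first.catalog.relevance_ids())
    else:
        columns = [c.id for c in first.catalog.criteria_for(section)]
    table = pd.DataFrame.from_dict(rows, orient="index", columns=columns)
    return RatingMatrix(
        study_label=first.study_label, section=section, table=table
    )


def agreement(matrix: RatingMatrix, criterion_id: str) -> AgreementSummary:
    """Category proportions for one criterion over non-NA raters.

    "Not determined" is an ordinary category; removed (NA) cells leave
    both numerator and denominator.
    """
    if criterion_id not in matrix.table.columns:
        raise KeyError(f"criterion {criterion_id!r} not in matrix")
    col = matrix.table[criterion_id]
    retained = col[col != NA_TOKEN]
    n = int(len(retained))
    if n == 0:
        return AgreementSummary(criterion_id, 0, {}, 0, None, None)
    counts = retained.value_counts()
    order = RELEVANCE_ORDER if matrix.section == "REL" else RELIABILITY_ORDER
    proportions = {cat: counts[cat] / n for cat in order if cat in counts.index}
    p_max = max(proportions.values())
    modal = next(cat for cat in order if proportions.get(cat, 0.0) == p_max)
    return AgreementSummary(
        criterion_id=criterion_id,
        n_retained=n,
        proportions=proportions,
        k_observed=int(counts.size),
        p_max=float(p_max),
        modal_category=modal,
    )


def classify_variability(
    summary: AgreementSummary, rules: DecisionRuleConfig = DEFAULT_RULES
) -> VariabilityClassification:
    """Apply the decision rules to one criterion's agreement summary."""
    cid = summary.criterion_id
    if summary.n_retained < rules.min_raters:
        return VariabilityClassification(
            cid, "unclassifiable", f"n_retained < {rules.min_raters}"
        )
    p = summary.p_max
    k = summary.k_observed
    if p >= rules.consensus_threshold:
        return VariabilityClassification(cid, "consensus", "p_max = 1")
    if p >= rules.low_lower:
        return VariabilityClassification(
            cid, "low", f"{rules.low_lower} <= p_max < 1"
        )
    if p < rules.high_pmax:
        return VariabilityClassification(
            cid, "high", f"p_max < {rules.high_pmax}"
        )
    if k >= rules.high_k and p < rules.high_k_pmax:
        return VariabilityClassification(
            cid, "high", f"k >= {rules.high_k} and p_max < {rules.high_k_pmax}"
        )
    return VariabilityClassification(cid, "moderate", "no rule fired")


def classify_matrix(
    matrix: RatingMatrix, rules: DecisionRuleConfig = DEFAULT_RULES
) -> list[VariabilityClassification]:
    """Agreement + classification for every criterion column of a matrix."""
    return [
        classify_variability(agreement(matrix, cid), rules)
        for cid in matrix.criteria
    ]


def prioritize(
    classifications: Mapping[str, Iterable[VariabilityClassification]]
) -> pd.DataFrame:
    """Cross-study prioritization table.

    Input maps study label -> that study's classifications.  A criterion
    is flagged ``prioritized`` when it was classified ``high`` in at
    least one study; criteria at consensus or low variability everywhere
    are not prioritized.
    """
    if not classifications:
        raise ValueError("at least one study required")
    studies = list(classifications)
    per_study: dict[str, dict[str, str]] = {
        s: {c.criterion_id: c.variability for c in cls}
        for s, cls in classifications.items()
    }
    criteria: list[str] = []
    for s in studies:
        for cid in per_study[s]:
            if cid not in criteria:
                criteria.append(cid)
    data = {
        s: [per_study[s].get(cid, "") for cid in criteria] for s in studies
    }
    frame = pd.DataFrame(data, index=pd.Index(criteria, name="criterion_id"))
    frame["prioritized"] = (frame[studies] == "high").any(axis=1)
    return frame


def percent_summary(numerator: int, denominator: int) -> int:
    """Integer percentage, rounded half away from zero.

    Reproduces survey-style "(n = 26, 87%)" summaries exactly.
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if not (0 <= numerator <= denominator):
        raise ValueError("numerator must lie in [0, denominator]")
    return int(math.floor(Fraction(100 * numerator, denominator) + Fraction(1, 2)))
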