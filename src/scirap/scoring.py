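"""Single-study evaluation state, the weighted SciRAP score and colour profile.

The score for a section (RQ or MQ) is

    score = (F + 0.5 * PF) / T * 100

where ``F`` and ``PF`` are the weighted sums over criteria judged
fulfilled and partially fulfilled, and ``T`` is the total weight of all
retained (non-removed) criteria.  "Not fulfilled" and "not determined"
both contribute zero to the numerator and full weight to ``T``, so they
affect the score identically.  With all weights at the default 1.0 the
formula reduces to plain counts.  Weights live in [1.0, 1.5] and mark
criteria the assessor deems critical for the evaluation at hand.

Relevance items carry no weight, cannot be removed and produce no
numeric score — only the pie-chart colour profile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

from .catalog import (
    Catalog,
    CatalogLookupError,
    RELIABILITY_CATEGORIES,
    RELIABILITY_ORDER,
    RELEVANCE_CATEGORIES,
    RELEVANCE_ORDER,
)

__all__ = [
    "WEIGHT_MIN",
    "WEIGHT_MAX",
    "CriterionAssessment",
    "RelevanceAssessment",
    "StudyEvaluation",
    "ScoreResult",
    "ColourProfile",
    "EvaluationError",
    "RemovedCriterionError",
    "NotPermittedError",
    "WeightError",
    "IncompleteEvaluationError",
    "DegenerateInputError",
    "MissingJustificationWarning",
    "compute_score",
    "compute_colour_profile",
]

WEIGHT_MIN = 1.0
WEIGHT_MAX = 1.5


class EvaluationError(Exception):
    """Base class for evaluation-state problems."""


class RemovedCriterionError(EvaluationError):
    """Operation on a criterion that has been removed from the evaluation."""


class NotPermittedError(EvaluationError):
    """Weighting/removal attempted on a relevance item (items allow neither)."""


class WeightError(EvaluationError, ValueError):
    """Weight outside the permitted [1.0, 1.5] range."""


class IncompleteEvaluationError(EvaluationError):
    """Retained criteria are still unrated; carries their ids."""

    def __init__(self, missing: list[str]):
        self.missing = list(missing)
        super().__init__(f"unrated retained criteria: {', '.join(self.missing)}")


class DegenerateInputError(EvaluationError):
    """No retained criteria left to score or profile."""


class MissingJustificationWarning(UserWarning):
    """A criterion was removed without a stated justification."""


@dataclass
class CriterionAssessment:
    """One criterion's rating, weight, removal state and comment.

    A removed criterion holds no rating (the evaluator avoids judging it —
    distinct from rating it "not determined", which is a judgment that the
    report gives too little information to decide).
    """

    criterion_id: str
    rating: str | None = None
    weight: float = 1.0
    removed: bool = False
    removal_justification: str | None = None
    comment: str | None = None


@dataclass
class RelevanceAssessment:
    item_id: str
    rating: str | None = None
    comment: str | None = None


@dataclass
class ScoreResult:
    """Weighted score components for one section.

    ``F``/``PF`` are weighted sums over fulfilled / partially fulfilled
    criteria; ``T`` is the total retained weight; ``score`` is in [0, 100].
    """

    section: str
    F: float
    PF: float
    T: float
    score: float


@dataclass
class ColourProfile:
    """Per-domain weighted category fractions for the colour readout.

    ``bars`` maps each domain that retains at least one criterion to its
    category -> weighted-fraction mapping; ``overall`` pools the whole
    section.  Domains whose criteria were all removed are listed in
    ``omitted_domains`` rather than shown as empty bars.
    """

    section: str
    bars: dict[str, dict[str, float]]
    overall: dict[str, float]
    omitted_domains: tuple[str, ...] = ()


class StudyEvaluation:
    """Full assessment of one study against one catalog.

    Holds exactly one :class:`CriterionAssessment` per catalog criterion and
    one :class:`RelevanceAssessment` per relevance item — no extras, no gaps.
    Mutators return ``self`` for chaining.
    """

    def __init__(
        self,
        catalog: Catalog,
        study_label: str = "",
        evaluator: str | None = None,
        timestamp: str | None = None,
    ):
        self.catalog = catalog
        self.study_label = study_label
        self.evaluator = evaluator
        self.timestamp = timestamp
        self.assessments: dict[str, CriterionAssessment] = {
            c.id: CriterionAssessment(c.id) for c in catalog.criteria
        }
        self.relevance: dict[str, RelevanceAssessment] = {
            i.id: RelevanceAssessment(i.id) for i in catalog.relevance_items
        }

    @property
    def catalog_ref(self) -> str:
        return self.catalog.ref

    # -- lookups -----------------------------------------------------------

    def _assessment(self, criterion_id: str) -> CriterionAssessment:
        try:
            return self.assessments[criterion_id]
        except KeyError:
            raise CatalogLookupError(
                f"{criterion_id!r} is not a reliability criterion of "
                f"{self.catalog.ref}"
            )

    # -- mutators ----------------------------------------------------------

    def set_rating(self, criterion_id: str, rating: str) -> "StudyEvaluation":
        """Rate a reliability criterion F/PF/NF/ND; replaces any prior rating."""
        a = self._assessment(criterion_id)
        if a.removed:
            raise RemovedCriterionError(
                f"{criterion_id} is removed; restore it before rating"
            )
        if rating not in RELIABILITY_CATEGORIES:
            raise ValueError(
                f"invalid reliability rating {rating!r}; "
                f"expected one of {', '.join(RELIABILITY_ORDER)}"
            )
        a.rating = rating
        return self

    def set_relevance_rating(self, item_id: str, rating: str) -> "StudyEvaluation":
        """Rate a relevance item DR/IR/NR/ND."""
        try:
            r = self.relevance[item_id]
        except KeyError:
            raise CatalogLookupError(
                f"{item_id!r} is not a relevance item of {self.catalog.ref}"
            )
        if rating not in RELEVANCE_CATEGORIES:
            raise ValueError(
                f"invalid relevance rating {rating!r}; "
                f"expected one of {', '.join(RELEVANCE_ORDER)}"
            )
        r.rating = rating
        return self

    def remove_criterion(
        self, criterion_id: str, justification: str | None = None
    ) -> "StudyEvaluation":
        """Exclude a criterion as not applicable; clears its rating.

        Relevance items cannot be removed.  A missing justification is
        permitted but warned about — undocumented removals were a noted
        transparency gap in practice.
        """
        if criterion_id in self.relevance:
            raise NotPermittedError("relevance items cannot be removed")
        a = self._assessment(criterion_id)
        a.removed = True
        a.rating = None
        a.removal_justification = justification
        if justification is None:
            warnings.warn(
                f"criterion {criterion_id} removed without justification",
                MissingJustificationWarning,
                stacklevel=2,
            )
        return self

    def restore_criterion(self, criterion_id: str) -> "StudyEvaluation":
        """Undo a removal; the criterion returns unrated."""
        a = self._assessment(criterion_id)
        a.removed = False
        a.removal_justification = None
        return self

    def set_weight(self, criterion_id: str, weight: float) -> "StudyEvaluation":
        """Weight a criterion in [1.0, 1.5]; relevance items take no weight."""
        if criterion_id in self.relevance:
            raise NotPermittedError("relevance items cannot be weighed up")
        a = self._assessment(criterion_id)
        if a.removed:
            raise RemovedCriterionError(f"{criterion_id} is removed")
        if not (WEIGHT_MIN <= weight <= WEIGHT_MAX):
            raise WeightError(
                f"weight {weight} outside [{WEIGHT_MIN}, {WEIGHT_MAX}]"
            )
        a.weight = float(weight)
        return self

    def set_comment(self, any_id: str, comment: str | None) -> "StudyEvaluation":
        if any_id in self.relevance:
            self.relevance[any_id].comment = comment
        else:
            self._assessment(any_id).comment = comment
        return self

    # -- views -------------------------------------------------------------

    def retained(self, section: str, include_open_questions: bool = True):
        """(Criterion, CriterionAssessment) pairs entering score/profile."""
        out = []
        for c in self.catalog.criteria_for(section):
            if not include_open_questions and c.is_open_question:
                continue
            a = self.assessments[c.id]
            if not a.removed:
                out.append((c, a))
        return out


def _check_rated(pairs) -> None:
    missing = [c.id for c, a in pairs if a.rating is None]
    if missing:
        raise IncompleteEvaluationError(missing)


def compute_score(
    evaluation: StudyEvaluation,
    section: str,
    include_open_questions: bool = True,
) -> ScoreResult:
    """Weighted score for RQ or MQ over retained, rated criteria.

    ``include_open_questions=False`` drops the free-form "other aspects"
    entries from both numerator and denominator.

    Raises
    ------
    IncompleteEvaluationError
        A retained criterion is unrated (unrated is never treated as ND).
    DegenerateInputError
        Every criterion of the section was removed (T would be 0).
    """
    if section not in ("RQ", "MQ"):
        raise ValueError(f"score is defined for RQ and MQ only, not {section!r}")
    pairs = evaluation.retained(section, include_open_questions)
    if not pairs:
        raise DegenerateInputError(f"all {section} criteria are removed")
    _check_rated(pairs)
    f_sum = sum(a.weight for _, a in pairs if a.rating == "F")
    pf_sum = sum(a.weight for _, a in pairs if a.rating == "PF")
    t_sum = sum(a.weight for _, a in pairs)
    return ScoreResult(
        section=section,
        F=f_sum,
        PF=pf_sum,
        T=t_sum,
        score=(f_sum + 0.5 * pf_sum) / t_sum * 100.0,
    )


def _fractions(weighted: Mapping[str, float], order) -> dict[str, float]:
    # callers guarantee at least one positive mass
    total = sum(weighted.values())
    return {cat: weighted[cat] / total for cat in order if weighted.get(cat, 0.0) > 0.0}


def compute_colour_profile(
    evaluation: StudyEvaluation,
    section: str,
    include_open_questions: bool = True,
) -> ColourProfile:
    """Per-domain weighted category fractions (the bar/pie chart data).

    For RQ/MQ each domain bar shows the weighted share of its retained
    criteria in each category; a criterion with increased weight occupies
    proportionally more of the bar.  Removed criteria are excluded, and a
    domain with nothing retained is omitted (listed in
    ``omitted_domains``).  The relevance profile treats the four items
    with equal weight (items carry no weights).
    """
    if section == "REL":
        order = RELEVANCE_ORDER
        items = list(evaluation.catalog.relevance_items)
        missing = [i.id for i in items if evaluation.relevance[i.id].rating is None]
        if missing:
            raise IncompleteEvaluationError(missing)
        overall: dict[str, float] = {}
        # each relevance domain holds exactly one item in v2.0, but support many
        dom_counts: dict[str, dict[str, float]] = {}
        for item in items:
            rating = evaluation.relevance[item.id].rating
            dom_counts.setdefault(item.domain, {})
            dom_counts[item.domain][rating] = (
                dom_counts[item.domain].get(rating, 0.0) + 1.0
            )
            overall[rating] = overall.get(rating, 0.0) + 1.0
        bars = {d: _fractions(c, order) for d, c in dom_counts.items()}
        return ColourProfile(
            section="REL", bars=bars, overall=_fractions(overall, order)
        )

    if section not in ("RQ", "MQ"):
        raise ValueError(f"unknown section {section!r}")
    order = RELIABILITY_ORDER
    pairs = evaluation.retained(section, include_open_questions)
    if not pairs:
        raise DegenerateInputError(f"all {section} criteria are removed")
    _check_rated(pairs)
    dom_weighted: dict[str, dict[str, float]] = {}
    overall_weighted: dict[str, float] = {}
    for c, a in pairs:
        dom_weighted.setdefault(c.domain, {})
        dom_weighted[c.domain][a.rating] = (
            dom_weighted[c.domain].get(a.rating, 0.0) + a.weight
        )
        overall_weighted[a.rating] = overall_weighted.get(a.rating, 0.0) + a.weight
    bars = {d: _fractions(w, order) for d, w in dom_weighted.items()}
    present_domains = set(bars)
    omitted = tuple(
        d
        for d in evaluation.catalog.domains.get(section, ())
        if d not in present_domains
        and any(
            c.domain == d for c in evaluation.catalog.criteria_for(section)
        )
    )
    return ColourProfile(
        section=section,
        bars=bars,
        overall=_fractions(overall_weighted, order),
        omitted_domains=omitted,
    )
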