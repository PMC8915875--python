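"""Weighted score arithmetic, colour profiles and evaluation-state rules.

The reference oracle here is deliberately naive: a direct weighted-sum
over (rating, weight, removed) triples, written independently of the
evaluation machinery it checks.
"""

import math

import pytest
from hypothesis import given, settings, strategies as st

from scirap.catalog import CatalogLookupError
from scirap.scoring import (
    DegenerateInputError,
    IncompleteEvaluationError,
    MissingJustificationWarning,
    NotPermittedError,
    RemovedCriterionError,
    StudyEvaluation,
    WeightError,
    compute_colour_profile,
    compute_score,
)

from conftest import make_tiny_catalog, rate_all


def oracle_score(triples):
    """Brute-force (rating, weight, removed) -> score, straight arithmetic."""
    kept = [(r, w) for r, w, removed in triples if not removed]
    t = sum(w for _, w in kept)
    f = sum(w for r, w in kept if r == "F")
    pf = sum(w for r, w in kept if r == "PF")
    return (f + 0.5 * pf) / t * 100.0


# -- evaluation state ------------------------------------------------------


def test_set_rating_and_replacement(catalog):
    ev = StudyEvaluation(catalog)
    ev.set_rating("RQ01", "F")
    assert ev.assessments["RQ01"].rating == "F"
    ev.set_rating("RQ01", "PF")
    assert ev.assessments["RQ01"].rating == "PF"


def test_rating_a_removed_criterion_is_state_error(catalog):
    ev = StudyEvaluation(catalog)
    ev.remove_criterion("RQ09", "study used primary cells")
    with pytest.raises(RemovedCriterionError):
        ev.set_rating("RQ09", "PF")


def test_relevance_items_use_their_own_setter(catalog):
    ev = StudyEvaluation(catalog)
    with pytest.raises(CatalogLookupError):
        ev.set_rating("REL1", "F")
    with pytest.raises(ValueError):
        ev.set_relevance_rating("REL1", "F")  # F is not a relevance token
    ev.set_relevance_rating("REL1", "DR")
    assert ev.relevance["REL1"].rating == "DR"


def test_removal_clears_rating_and_warns_without_justification(catalog):
    ev = StudyEvaluation(catalog)
    ev.set_rating("MQ13", "F")
    with pytest.warns(MissingJustificationWarning):
        ev.remove_criterion("MQ13")
    a = ev.assessments["MQ13"]
    assert a.removed and a.rating is None


def test_relevance_items_cannot_be_removed_or_weighted(catalog):
    ev = StudyEvaluation(catalog)
    with pytest.raises(NotPermittedError):
        ev.remove_criterion("REL2", "any")
    with pytest.raises(NotPermittedError):
        ev.set_weight("REL1", 1.5)


@pytest.mark.parametrize("weight", [0.5, 0.99, 1.51, 2.0, -1.0])
def test_out_of_range_weight_rejected(catalog, weight):
    ev = StudyEvaluation(catalog)
    with pytest.raises(WeightError):
        ev.set_weight("MQ05", weight)


def test_weight_endpoints_accepted(catalog):
    ev = StudyEvaluation(catalog)
    ev.set_weight("MQ05", 1.5).set_weight("MQ06", 1.0)
    assert ev.assessments["MQ05"].weight == 1.5


# -- score arithmetic ------------------------------------------------------


def test_all_fulfilled_scores_100_and_all_not_fulfilled_scores_0(catalog):
    ev = rate_all(StudyEvaluation(catalog), "F")
    assert compute_score(ev, "RQ").score == 100.0
    assert compute_score(ev, "MQ").score == 100.0
    ev = rate_all(StudyEvaluation(catalog), "NF")
    assert compute_score(ev, "RQ").score == 0.0


def test_one_f_one_pf_scores_75():
    cat = make_tiny_catalog(n_per_domain=2)  # 2 RQ criteria
    ev = StudyEvaluation(cat)
    ev.set_rating("RQ01", "F").set_rating("RQ02", "PF")
    result = compute_score(ev, "RQ")
    assert result.score == pytest.approx(75.0)
    assert (result.F, result.PF, result.T) == (1.0, 1.0, 2.0)


def test_weighted_two_criterion_example_matches_oracle():
    # weight 1.5 rated F + weight 1.0 rated NF -> 1.5/2.5*100 = 60
    cat = make_tiny_catalog(n_per_domain=2)
    ev = StudyEvaluation(cat)
    ev.set_weight("RQ01", 1.5).set_rating("RQ01", "F").set_rating("RQ02", "NF")
    expected = oracle_score([("F", 1.5, False), ("NF", 1.0, False)])
    assert expected == pytest.approx(60.0)
    assert compute_score(ev, "RQ").score == pytest.approx(expected)


def test_nd_and_nf_have_identical_score_impact(catalog):
    rq_ids = [c.id for c in catalog.criteria_for("RQ")]
    scores = {}
    for filler in ("ND", "NF"):
        ev = StudyEvaluation(catalog)
        for cid in rq_ids[:10]:
            ev.set_rating(cid, "F")
        for cid in rq_ids[10:]:
            ev.set_rating(cid, filler)
        scores[filler] = compute_score(ev, "RQ").score
    assert scores["ND"] == scores["NF"] == pytest.approx(1000.0 / 24.0)


def test_unrated_retained_criterion_is_error_listing_ids(catalog):
    ev = rate_all(StudyEvaluation(catalog), "F")
    ev.assessments["RQ05"].rating = None
    with pytest.raises(IncompleteEvaluationError) as exc:
        compute_score(ev, "RQ")
    assert exc.value.missing == ["RQ05"]


def test_all_criteria_removed_is_degenerate(tiny_catalog):
    ev = StudyEvaluation(tiny_catalog)
    for c in tiny_catalog.criteria_for("RQ"):
        ev.remove_criterion(c.id, "n/a")
    with pytest.raises(DegenerateInputError):
        compute_score(ev, "RQ")


def test_open_question_criteria_can_be_excluded(catalog):
    ev = rate_all(StudyEvaluation(catalog), "F")
    ev.set_rating("RQ24", "NF")
    with_oq = compute_score(ev, "RQ")
    without_oq = compute_score(ev, "RQ", include_open_questions=False)
    assert with_oq.score == pytest.approx(2300.0 / 24.0)
    assert without_oq.score == 100.0
    assert without_oq.T == 23.0


def test_removed_criteria_leave_score_at_limits(catalog):
    ev = rate_all(StudyEvaluation(catalog), "F")
    ev.remove_criterion("RQ09", "not a cell line study")
    assert compute_score(ev, "RQ").score == 100.0
    ev = rate_all(StudyEvaluation(catalog), "NF")
    ev.remove_criterion("RQ09", "not a cell line study")
    assert compute_score(ev, "RQ").score == 0.0


# -- property-based checks against the oracle ------------------------------

ratings = st.sampled_from(["F", "PF", "NF", "ND"])
weights = st.floats(min_value=1.0, max_value=1.5, allow_nan=False)


@st.composite
def rq_assignments(draw, n=24):
    triples = draw(
        st.lists(
            st.tuples(ratings, weights, st.booleans()),
            min_size=n, max_size=n,
        )
    )
    if all(removed for _, _, removed in triples):
        rating, weight, _ = triples[0]
        triples[0] = (rating, weight, False)
    return triples


def _build(catalog, triples):
    ev = StudyEvaluation(catalog)
    for c, (rating, weight, removed) in zip(catalog.criteria_for("RQ"), triples):
        if removed:
            ev.remove_criterion(c.id, "n/a")
        else:
            ev.set_weight(c.id, weight)
            ev.set_rating(c.id, rating)
    return ev


@settings(max_examples=60, deadline=None, derandomize=True)
@given(rq_assignments())
def test_score_matches_bruteforce_oracle_and_is_bounded(catalog, triples):
    ev = _build(catalog, triples)
    score = compute_score(ev, "RQ").score
    assert score == pytest.approx(oracle_score(triples), abs=1e-9)
    assert 0.0 <= score <= 100.0


@settings(max_examples=60, deadline=None, derandomize=True)
@given(rq_assignments(), st.data())
def test_swapping_nd_and_nf_never_changes_the_score(catalog, triples, data):
    score_before = compute_score(_build(catalog, triples), "RQ").score
    swapped = []
    for rating, weight, removed in triples:
        if rating in ("ND", "NF") and data.draw(st.booleans()):
            rating = "NF" if rating == "ND" else "ND"
        swapped.append((rating, weight, removed))
    score_after = compute_score(_build(catalog, swapped), "RQ").score
    assert score_after == pytest.approx(score_before, abs=1e-9)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(rq_assignments(), st.data())
def test_upgrading_one_criterion_raises_score_by_half_weight_share(catalog, triples, data):
    upgradable = [
        i for i, (r, _, removed) in enumerate(triples)
        if not removed and r in ("NF", "PF")
    ]
    if not upgradable:
        return
    i = data.draw(st.sampled_from(upgradable))
    rating, weight, removed = triples[i]
    upgraded = list(triples)
    upgraded[i] = ("PF" if rating == "NF" else "F", weight, removed)
    before = compute_score(_build(catalog, triples), "RQ")
    after = compute_score(_build(catalog, upgraded), "RQ")
    assert after.score - before.score == pytest.approx(
        50.0 * weight / before.T, abs=1e-9
    )


@settings(max_examples=40, deadline=None, derandomize=True)
@given(rq_assignments())
def test_profile_overall_fractions_reproduce_the_score(catalog, triples):
    ev = _build(catalog, triples)
    profile = compute_colour_profile(ev, "RQ")
    score = compute_score(ev, "RQ").score
    from_profile = (
        profile.overall.get("F", 0.0) + 0.5 * profile.overall.get("PF", 0.0)
    ) * 100.0
    assert from_profile == pytest.approx(score, abs=1e-9)
    for domain, fractions in profile.bars.items():
        assert sum(fractions.values()) == pytest.approx(1.0, abs=1e-9)


# -- colour profiles -------------------------------------------------------


def test_funding_domain_bar_half_f_half_nf(catalog):
    ev = rate_all(StudyEvaluation(catalog), "F")
    ev.set_rating("RQ23", "NF")
    profile = compute_colour_profile(ev, "RQ")
    assert profile.bars["funding and competing interests"] == pytest.approx(
        {"F": 0.5, "NF": 0.5}
    )


def test_weighted_bar_fractions():
    # weight 1.5 F + weight 1.0 PF -> {F: 0.6, PF: 0.4}
    cat = make_tiny_catalog(n_per_domain=2)
    ev = StudyEvaluation(cat)
    ev.set_weight("RQ01", 1.5).set_rating("RQ01", "F").set_rating("RQ02", "PF")
    profile = compute_colour_profile(ev, "RQ")
    assert profile.bars["alpha"] == pytest.approx({"F": 0.6, "PF": 0.4})


def test_relevance_pie_equal_quarters(catalog):
    ev = StudyEvaluation(catalog)
    for iid, rating in zip(
        ("REL1", "REL2", "REL3", "REL4"), ("DR", "DR", "IR", "NR")
    ):
        ev.set_relevance_rating(iid, rating)
    profile = compute_colour_profile(ev, "REL")
    assert profile.overall == pytest.approx({"DR": 0.5, "IR": 0.25, "NR": 0.25})


def test_fully_removed_domain_is_omitted_with_notice(catalog):
    ev = rate_all(StudyEvaluation(catalog), "F")
    ev.remove_criterion("RQ22", "n/a").remove_criterion("RQ23", "n/a")
    profile = compute_colour_profile(ev, "RQ")
    assert "funding and competing interests" not in profile.bars
    assert profile.omitted_domains == ("funding and competing interests",)
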