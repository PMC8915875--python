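import pytest

from scirap.catalog import Catalog, Criterion, RelevanceItem, load_catalog


@pytest.fixture(scope="session")
def catalog():
    """The bundled v2.0 instrument."""
    return load_catalog("scirap-invitro-2.0")


def make_tiny_catalog(rq_domains=("alpha",), mq_domains=("alpha",), n_per_domain=2):
    """A minimal structurally-valid catalog for arithmetic-level tests."""
    criteria = []
    k = 0
    for dom in rq_domains:
        for _ in range(n_per_domain):
            k += 1
            criteria.append(Criterion(f"RQ{k:02d}", "RQ", dom, f"criterion {k}"))
    k = 0
    for dom in mq_domains:
        for _ in range(n_per_domain):
            k += 1
            criteria.append(Criterion(f"MQ{k:02d}", "MQ", dom, f"criterion {k}"))
    return Catalog(
        name="tiny",
        version="0",
        domains={
            "RQ": tuple(rq_domains) + ("funding and competing interests",),
            "MQ": tuple(mq_domains),
            "REL": ("test compound",),
        },
        criteria=tuple(criteria),
        relevance_items=(RelevanceItem("REL1", "test compound", "identity"),),
    )


@pytest.fixture
def tiny_catalog():
    return make_tiny_catalog()


def rate_all(evaluation, reliability="F", relevance="DR"):
    """Give every criterion/item of an evaluation one uniform rating."""
    for cid, a in evaluation.assessments.items():
        if not a.removed:
            evaluation.set_rating(cid, reliability)
    for iid in evaluation.relevance:
        evaluation.set_relevance_rating(iid, relevance)
    return evaluation
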