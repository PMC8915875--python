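"""Seeded generators for synthetic evaluations and rater panels.

Real expert panels are not redistributable, so testing the agreement and
prioritization machinery needs synthetic rater x criterion matrices with
a controlled agreement structure.  Cells are drawn independently per
rater and criterion: first a removal coin (reliability sections only),
then a category from the criterion's probability vector.  Independence
across raters and criteria is an explicit simplification — real panels
show rater leniency and criterion difficulty structure; a per-rater
leniency shift is available as an optional hook, off by default.

All generators take a mandatory integer seed and are deterministic for a
given seed (NumPy PCG64, no locale or time dependence).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import (
    Catalog,
    NA_TOKEN,
    RELIABILITY_ORDER,
    RELEVANCE_ORDER,
)
from .multirater import RatingMatrix
from .scoring import StudyEvaluation

__all__ = ["PanelSpec", "PRESETS", "generate_panel", "generate_evaluation"]

_PROB_TOL = 1e-9


@dataclass
class PanelSpec:
    """Sampling plan for one synthetic rater panel.

    ``category_probabilities`` is either a single category -> probability
    map applied to every criterion, or a per-criterion-id map of such
    maps.  Probabilities must sum to 1 per criterion.
    ``removal_probability`` applies to reliability criteria only
    (relevance items cannot be removed).
    """

    n_raters: int
    category_probabilities: Mapping[str, float] | Mapping[str, Mapping[str, float]]
    seed: int
    removal_probability: float = 0.0
    #: optional per-rater leniency in [-1, 1]; positive mixes the rater's
    #: distribution toward the most favourable category, negative toward
    #: the least favourable.  Length must equal ``n_raters``.
    leniency: Sequence[float] | None = field(default=None)

    def __post_init__(self) -> None:
        if self.n_raters < 1:
            raise ValueError("n_raters must be >= 1")
        if not (0.0 <= self.removal_probability < 1.0):
            raise ValueError("removal_probability must lie in [0, 1)")
        if self.leniency is not None and len(self.leniency) != self.n_raters:
            raise ValueError("leniency must give one value per rater")


def _resolve_probs(
    spec: PanelSpec, criterion_ids: Sequence[str], order: tuple[str, ...]
) -> dict[str, np.ndarray]:
    probs = spec.category_probabilities
    per_criterion = probs and all(
        isinstance(v, Mapping) for v in probs.values()
    )
    out: dict[str, np.ndarray] = {}
    for cid in criterion_ids:
        p = probs.get(cid) if per_criterion else probs
        if p is None:
            raise ValueError(f"no category probabilities for {cid}")
        unknown = set(p) - set(order)
        if unknown:
            raise ValueError(f"unknown categories {sorted(unknown)} for {cid}")
        vec = np.array([float(p.get(cat, 0.0)) for cat in order])
        if abs(vec.sum() - 1.0) > _PROB_TOL or (vec < 0).any():
            raise ValueError(
                f"probabilities for {cid} must be non-negative and sum to 1"
            )
        out[cid] = vec
    return out


def _shift(vec: np.ndarray, leniency: float) -> np.ndarray:
    """Mix a category distribution toward the best (or worst) category."""
    point = np.zeros_like(vec)
    point[0 if leniency > 0 else len(vec) - 2] = 1.0  # worst graded category (NF/NR)
    lam = min(abs(leniency), 1.0)
    return (1 - lam) * vec + lam * point


def generate_panel(
    catalog: Catalog, section: str, spec: PanelSpec
) -> RatingMatrix:
    """Draw a reproducible rater x criterion matrix for one section.

    Each cell is independent: removed (``NA``) with
    ``removal_probability`` (RQ/MQ only), otherwise a category drawn from
    the criterion's probability vector.  Identical seeds give identical
    matrices.
    """
    if section == "REL":
        order = RELEVANCE_ORDER
        ids = list(catalog.relevance_ids())
        if spec.removal_probability > 0:
            raise ValueError("relevance items cannot be removed")
    elif section in ("RQ", "MQ"):
        order = RELIABILITY_ORDER
        ids = [c.id for c in catalog.criteria_for(section)]
    else:
        raise ValueError(f"unknown section {section!r}")
    prob_vectors = _resolve_probs(spec, ids, order)
    rng = np.random.default_rng(spec.seed)
    cats = np.array(order)
    cells = np.empty((spec.n_raters, len(ids)), dtype=object)
    for j, cid in enumerate(ids):
        base = prob_vectors[cid]
        if spec.leniency is None:
            draws = cats[rng.choice(len(cats), size=spec.n_raters, p=base)]
        else:
            draws = np.empty(spec.n_raters, dtype=object)
            for i in range(spec.n_raters):
                vec = base
                if spec.leniency[i] != 0.0:
                    vec = _shift(base, float(spec.leniency[i]))
                draws[i] = cats[rng.choice(len(cats), p=vec)]
        if spec.removal_probability > 0.0:
            removed = rng.random(spec.n_raters) < spec.removal_probability
            draws = np.where(removed, NA_TOKEN, draws)
        cells[:, j] = draws
    raters = [f"r{i + 1:03d}" for i in range(spec.n_raters)]
    table = pd.DataFrame(cells, index=raters, columns=ids)
    return RatingMatrix(study_label="synthetic", section=section, table=table)


#: Named rating-tendency presets for whole-study evaluations.  The
#: reliability vectors put most mass on "fulfilled" for a well-reported
#: study and on "not fulfilled"/"not determined" for a poorly reported
#: one; "mixed" sits in between.
PRESETS: dict[str, dict[str, dict[str, float]]] = {
    "well_reported": {
        "reliability": {"F": 0.70, "PF": 0.20, "NF": 0.05, "ND": 0.05},
        "relevance": {"DR": 0.70, "IR": 0.20, "NR": 0.05, "ND": 0.05},
    },
    "poorly_reported": {
        "reliability": {"F": 0.10, "PF": 0.15, "NF": 0.35, "ND": 0.40},
        "relevance": {"DR": 0.15, "IR": 0.25, "NR": 0.25, "ND": 0.35},
    },
    "mixed": {
        "reliability": {"F": 0.35, "PF": 0.30, "NF": 0.20, "ND": 0.15},
        "relevance": {"DR": 0.40, "IR": 0.30, "NR": 0.15, "ND": 0.15},
    },
}


def generate_evaluation(
    catalog: Catalog, profile: str, seed: int, study_label: str | None = None
) -> StudyEvaluation:
    """Draw one complete evaluation from a named rating-tendency preset.

    Every criterion and relevance item receives a rating (no removals,
    default weights), so the result is always scoreable.
    """
    try:
        preset = PRESETS[profile]
    except KeyError:
        raise LookupError(
            f"unknown preset {profile!r}; expected one of {', '.join(PRESETS)}"
        )
    rng = np.random.default_rng(seed)
    ev = StudyEvaluation(
        catalog,
        study_label=study_label or f"synthetic-{profile}",
        evaluator=f"synthetic-{profile}-seed{seed}",
    )
    rel_vec = np.array([preset["reliability"][c] for c in RELIABILITY_ORDER])
    for c in catalog.criteria:
        ev.set_rating(c.id, RELIABILITY_ORDER[rng.choice(4, p=rel_vec)])
    relv_vec = np.array([preset["relevance"][c] for c in RELEVANCE_ORDER])
    for item in catalog.relevance_items:
        ev.set_relevance_rating(item.id, RELEVANCE_ORDER[rng.choice(4, p=relv_vec)])
    return ev
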