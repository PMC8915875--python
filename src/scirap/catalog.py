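"""The SciRAP in vitro instrument as structured, versioned data.

The instrument separates *reliability* of an in vitro toxicity study —
split into reporting quality (RQ) and methodological quality (MQ) — from
its *relevance* to a specific hazard or risk assessment question.
Reliability is judged against *criteria* on a four-category scale
(fulfilled / partially fulfilled / not fulfilled / not determined);
relevance is judged against *items* (directly / indirectly / not
relevant / not determined).

This module houses the version 2.0 catalog (24 RQ criteria, 16 MQ
criteria, 4 relevance items) as bundled data, and validates any
user-supplied catalog against the same structural rules.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Iterable, Mapping

import yaml

__all__ = [
    "RELIABILITY_CATEGORIES",
    "RELEVANCE_CATEGORIES",
    "RELIABILITY_ORDER",
    "RELEVANCE_ORDER",
    "NA_TOKEN",
    "SECTIONS",
    "Criterion",
    "RelevanceItem",
    "Catalog",
    "Violation",
    "CatalogError",
    "CatalogLookupError",
    "CatalogValidationError",
    "BUNDLED_CATALOGS",
    "load_catalog",
    "validate_catalog",
    "save_catalog",
]

#: Reliability rating tokens -> human-readable labels (bijective).
RELIABILITY_CATEGORIES: Mapping[str, str] = {
    "F": "fulfilled",
    "PF": "partially fulfilled",
    "NF": "not fulfilled",
    "ND": "not determined",
}

#: Relevance rating tokens -> labels (bijective).
RELEVANCE_CATEGORIES: Mapping[str, str] = {
    "DR": "directly relevant",
    "IR": "indirectly relevant",
    "NR": "not relevant",
    "ND": "not determined",
}

#: Fixed display / tie-break order of the categories.
RELIABILITY_ORDER: tuple[str, ...] = ("F", "PF", "NF", "ND")
RELEVANCE_ORDER: tuple[str, ...] = ("DR", "IR", "NR", "ND")

#: Marker for a criterion removed from an evaluation ("not applicable").
NA_TOKEN = "NA"

SECTIONS: tuple[str, ...] = ("RQ", "MQ", "REL")

#: RQ carries a funding/competing-interests domain; MQ must not.
_FUNDING_DOMAIN = "funding and competing interests"


class CatalogError(Exception):
    """Base class for catalog problems."""


class CatalogLookupError(CatalogError, KeyError):
    """Unknown bundled catalog name or unknown criterion/item id."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep message readable
        return Exception.__str__(self)


class CatalogValidationError(CatalogError, ValueError):
    """A catalog file or object violates the schema or its invariants."""

    def __init__(self, violations: Iterable["Violation"]):
        self.violations = tuple(violations)
        super().__init__(
            "invalid catalog: " + "; ".join(str(v) for v in self.violations)
        )


@dataclass(frozen=True)
class Violation:
    """One broken catalog rule, naming the offending subject."""

    subject: str  # criterion/item id or field name
    rule: str

    def __str__(self) -> str:
        return f"{self.subject}: {self.rule}"


@dataclass(frozen=True)
class Criterion:
    """One reliability criterion (an RQ or MQ checklist entry).

    ``conditional_note`` records applicability caveats stated alongside the
    criterion (e.g. cell-line-only criteria that should be removed for
    primary-cell studies); ``is_open_question`` flags the free-form "other
    aspects" entries whose fulfilled/not-fulfilled semantics are debatable.
    """

    id: str
    section: str  # "RQ" | "MQ"
    domain: str
    text: str
    conditional_note: str | None = None
    is_open_question: bool = False
    guidance: str | None = None


@dataclass(frozen=True)
class RelevanceItem:
    """One relevance item: an aspect to judge against the assessment context."""

    id: str
    domain: str
    text: str


@dataclass(frozen=True)
class Catalog:
    """A versioned instrument: ordered criteria, relevance items and domains."""

    name: str
    version: str
    domains: Mapping[str, tuple[str, ...]]  # section -> ordered domain labels
    criteria: tuple[Criterion, ...]
    relevance_items: tuple[RelevanceItem, ...]
    _by_id: Mapping[str, Criterion] = field(
        init=False, repr=False, compare=False, default_factory=dict
    )

    def __post_init__(self) -> None:
        object.__setattr__(self, "_by_id", {c.id: c for c in self.criteria})

    @property
    def ref(self) -> str:
        """Stable name+version reference, e.g. ``scirap-invitro-2.0``."""
        return f"{self.name}-{self.version}"

    def criteria_for(self, section: str) -> tuple[Criterion, ...]:
        return tuple(c for c in self.criteria if c.section == section)

    def get_criterion(self, criterion_id: str) -> Criterion:
        try:
            return self._by_id[criterion_id]
        except KeyError:
            raise CatalogLookupError(f"unknown criterion id {criterion_id!r}")

    def get_relevance_item(self, item_id: str) -> RelevanceItem:
        for item in self.relevance_items:
            if item.id == item_id:
                return item
        raise CatalogLookupError(f"unknown relevance item id {item_id!r}")

    def relevance_ids(self) -> tuple[str, ...]:
        return tuple(i.id for i in self.relevance_items)

    def to_dict(self) -> dict[str, Any]:
        """Schema-shaped plain dict; ``load_catalog`` round-trips it."""
        crits = []
        for c in self.criteria:
            d: dict[str, Any] = {
                "id": c.id, "section": c.section, "domain": c.domain, "text": c.text,
            }
            if c.conditional_note is not None:
                d["conditional_note"] = c.conditional_note
            if c.is_open_question:
                d["is_open_question"] = True
            if c.guidance is not None:
                d["guidance"] = c.guidance
            crits.append(d)
        return {
            "name": self.name,
            "version": self.version,
            "domains": {k: list(v) for k, v in self.domains.items()},
            "criteria": crits,
            "relevance_items": [
                {"id": i.id, "domain": i.domain, "text": i.text}
                for i in self.relevance_items
            ],
        }


#: Names resolvable without any file on disk.
BUNDLED_CATALOGS: tuple[str, ...] = ("scirap-invitro-2.0",)


def _catalog_from_dict(data: Mapping[str, Any]) -> Catalog:
    violations: list[Violation] = []
    for key in ("name", "version", "domains", "criteria", "relevance_items"):
        if key not in data:
            violations.append(Violation(key, "required top-level field missing"))
    if violations:
        raise CatalogValidationError(violations)
    try:
        criteria = tuple(Criterion(**c) for c in data["criteria"])
        items = tuple(RelevanceItem(**i) for i in data["relevance_items"])
    except TypeError as exc:
        raise CatalogValidationError(
            [Violation("criteria/relevance_items", f"malformed entry: {exc}")]
        )
    return Catalog(
        name=str(data["name"]),
        version=str(data["version"]),
        domains={k: tuple(v) for k, v in data["domains"].items()},
        criteria=criteria,
        relevance_items=items,
    )


def validate_catalog(catalog: Catalog) -> list[Violation]:
    """Check all catalog invariants; violations are data, not exceptions.

    Structural rules apply to every catalog (unique ids, declared domains,
    the funding domain belonging to RQ only).  The 24/16/4 composition is
    additionally enforced for any catalog claiming the bundled v2.0
    identity, so a mislabeled file cannot impersonate the instrument.
    """
    out: list[Violation] = []

    seen: set[str] = set()
    for c in catalog.criteria:
        if c.id in seen:
            out.append(Violation(c.id, "duplicate criterion id"))
        seen.add(c.id)
        if c.section not in ("RQ", "MQ"):
            out.append(Violation(c.id, f"unknown section {c.section!r}"))
        elif c.domain not in catalog.domains.get(c.section, ()):
            out.append(
                Violation(c.id, f"domain {c.domain!r} not declared for {c.section}")
            )
    for i in catalog.relevance_items:
        if i.id in seen:
            out.append(Violation(i.id, "duplicate id"))
        seen.add(i.id)
        if i.domain not in catalog.domains.get("REL", ()):
            out.append(Violation(i.id, f"domain {i.domain!r} not declared for REL"))

    if _FUNDING_DOMAIN in catalog.domains.get("MQ", ()):
        out.append(Violation("domains.MQ", f"{_FUNDING_DOMAIN!r} is RQ-only"))
    if _FUNDING_DOMAIN not in catalog.domains.get("RQ", ()):
        out.append(Violation("domains.RQ", f"{_FUNDING_DOMAIN!r} domain missing"))

    if catalog.ref in BUNDLED_CATALOGS:
        n_rq = len(catalog.criteria_for("RQ"))
        n_mq = len(catalog.criteria_for("MQ"))
        n_rel = len(catalog.relevance_items)
        if n_rq != 24:
            out.append(Violation("criteria.RQ", f"v2.0 requires 24 RQ criteria, got {n_rq}"))
        if n_mq != 16:
            out.append(Violation("criteria.MQ", f"v2.0 requires 16 MQ criteria, got {n_mq}"))
        if n_rel != 4:
            out.append(Violation("relevance_items", f"v2.0 requires 4 items, got {n_rel}"))
    return out


def load_catalog(source: str | Path) -> Catalog:
    """Load and validate a catalog from a bundled name or a JSON/YAML file.

    The name ``"scirap-invitro-2.0"`` always resolves to the bundled
    version 2.0 instrument without touching the filesystem.

    Raises
    ------
    CatalogLookupError
        Unknown bundled name and no such file.
    CatalogValidationError
        The file parses but violates the catalog schema or invariants.
    """
    if isinstance(source, str) and source in BUNDLED_CATALOGS:
        text = (
            resources.files("scirap.data").joinpath(f"{source}.json").read_text("utf-8")
        )
        data = json.loads(text)
    else:
        path = Path(source)
        if not path.exists():
            raise CatalogLookupError(
                f"{source!r} is neither a bundled catalog name "
                f"({', '.join(BUNDLED_CATALOGS)}) nor an existing file"
            )
        raw = path.read_text("utf-8")
        if path.suffix.lower() in (".yaml", ".yml"):
            data = yaml.safe_load(raw)
        else:
            data = json.loads(raw)
    catalog = _catalog_from_dict(data)
    violations = validate_catalog(catalog)
    if violations:
        raise CatalogValidationError(violations)
    return catalog


def save_catalog(catalog: Catalog, path: str | Path) -> Path:
    """Serialize a catalog to JSON (or YAML by suffix); load round-trips."""
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(catalog.to_dict(), sort_keys=False), "utf-8")
    else:
        path.write_text(
            json.dumps(catalog.to_dict(), indent=2, ensure_ascii=False), "utf-8"
        )
    return path
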