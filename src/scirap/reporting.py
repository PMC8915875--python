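"""Evaluation report import/export and colour-profile rendering.

A report is a pure function of a study evaluation and its catalog: a
header, the per-criterion table, the RQ and MQ scores and the three
colour profiles.  JSON is the canonical machine format; a flat CSV
dialect and an Excel workbook (with embedded charts) are provided as
conveniences.  Re-importing an exported report reconstructs the
evaluation exactly, and any scores embedded in a file are recomputed on
import — a mismatch raises a tamper warning rather than being trusted.
"""

from __future__ import annotations

import csv
import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Any

from .catalog import (
    Catalog,
    RELIABILITY_CATEGORIES,
    RELIABILITY_ORDER,
    RELEVANCE_CATEGORIES,
    RELEVANCE_ORDER,
    load_catalog,
)
from .scoring import (
    ColourProfile,
    DegenerateInputError,
    IncompleteEvaluationError,
    ScoreResult,
    StudyEvaluation,
    compute_colour_profile,
    compute_score,
)

__all__ = [
    "COLOURS",
    "EvaluationReport",
    "FormatError",
    "TamperWarning",
    "build_report",
    "export_report",
    "import_report",
    "render_profile",
]

#: Category -> display colour (green / yellow / red / grey).
COLOURS = {
    "F": "#2ca02c",
    "PF": "#ffd92f",
    "NF": "#d62728",
    "ND": "#bfbfbf",
    "DR": "#2ca02c",
    "IR": "#ffd92f",
    "NR": "#d62728",
}

_CSV_COLUMNS = ("id", "section", "rating", "weight", "removed", "justification", "comment")


class FormatError(ValueError):
    """File is not in a recognised report format or uses bad tokens."""


class TamperWarning(UserWarning):
    """Embedded scores disagree with recomputation from the ratings."""


@dataclass
class EvaluationReport:
    """In-memory report: header, per-criterion rows, scores, profiles."""

    header: dict[str, Any]
    per_criterion: list[dict[str, Any]]
    scores: dict[str, ScoreResult | None]
    profiles: dict[str, ColourProfile | None]


def _tool_version() -> str:
    from . import __version__

    return __version__


def build_report(
    evaluation: StudyEvaluation, catalog: Catalog, partial: bool = False
) -> EvaluationReport:
    """Assemble the report; ``partial=True`` omits unscoreable sections."""
    rows: list[dict[str, Any]] = []
    for c in catalog.criteria:
        a = evaluation.assessments[c.id]
        rows.append(
            {
                "id": c.id,
                "section": c.section,
                "domain": c.domain,
                "text": c.text,
                "rating": a.rating,
                "weight": a.weight,
                "removed": a.removed,
                "justification": a.removal_justification,
                "comment": a.comment,
            }
        )
    for item in catalog.relevance_items:
        r = evaluation.relevance[item.id]
        rows.append(
            {
                "id": item.id,
                "section": "REL",
                "domain": item.domain,
                "text": item.text,
                "rating": r.rating,
                "weight": None,
                "removed": None,
                "justification": None,
                "comment": r.comment,
            }
        )
    scores: dict[str, ScoreResult | None] = {}
    profiles: dict[str, ColourProfile | None] = {}
    for section in ("RQ", "MQ"):
        try:
            scores[section] = compute_score(evaluation, section)
            profiles[section] = compute_colour_profile(evaluation, section)
        except (IncompleteEvaluationError, DegenerateInputError):
            if not partial:
                raise
            scores[section] = None
            profiles[section] = None
    try:
        profiles["REL"] = compute_colour_profile(evaluation, "REL")
    except IncompleteEvaluationError:
        if not partial:
            raise
        profiles["REL"] = None
    header = {
        "study_label": evaluation.study_label,
        "catalog_ref": evaluation.catalog_ref,
        "evaluator": evaluation.evaluator,
        "timestamp": evaluation.timestamp,
        "tool_version": _tool_version(),
    }
    return EvaluationReport(header, rows, scores, profiles)


def _score_to_dict(s: ScoreResult | None):
    if s is None:
        return None
    return {"section": s.section, "F": s.F, "PF": s.PF, "T": s.T, "score": s.score}


def _profile_to_dict(p: ColourProfile | None):
    if p is None:
        return None
    return {
        "section": p.section,
        "bars": p.bars,
        "overall": p.overall,
        "omitted_domains": list(p.omitted_domains),
    }


def _detect_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("json", "csv", "xlsx"):
        return suffix
    raise FormatError(f"cannot infer report format from {path.name!r}")


def export_report(
    evaluation: StudyEvaluation,
    catalog: Catalog,
    path: str | Path,
    format: str | None = None,
    partial: bool = False,
) -> Path:
    """Write the report as JSON, CSV or XLSX (inferred from the suffix)."""
    path = Path(path)
    fmt = _detect_format(path, format)
    report = build_report(evaluation, catalog, partial=partial)
    if fmt == "json":
        _write_json(report, evaluation, path)
    elif fmt == "csv":
        _write_csv(report, path)
    elif fmt == "xlsx":
        _write_xlsx(report, path)
    else:
        raise FormatError(f"unknown format {fmt!r}")
    return path


def _write_json(report: EvaluationReport, evaluation: StudyEvaluation, path: Path):
    assessments = []
    for c in evaluation.catalog.criteria:
        a = evaluation.assessments[c.id]
        entry: dict[str, Any] = {"id": c.id}
        if a.removed:
            entry["removed"] = True
            if a.removal_justification:
                entry["justification"] = a.removal_justification
        else:
            entry["rating"] = a.rating
        entry["weight"] = a.weight
        if a.comment:
            entry["comment"] = a.comment
        assessments.append(entry)
    relevance = []
    for item in evaluation.catalog.relevance_items:
        r = evaluation.relevance[item.id]
        entry = {"id": item.id, "rating": r.rating}
        if r.comment:
            entry["comment"] = r.comment
        relevance.append(entry)
    doc = {
        **report.header,
        "assessments": assessments,
        "relevance": relevance,
        "scores": {k: _score_to_dict(v) for k, v in report.scores.items()},
        "profiles": {k: _profile_to_dict(v) for k, v in report.profiles.items()},
    }
    path.write_text(json.dumps(doc, indent=2, ensure_ascii=False), "utf-8")


def _write_csv(report: EvaluationReport, path: Path):
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for key in ("study_label", "catalog_ref", "evaluator", "timestamp", "tool_version"):
            value = report.header.get(key)
            if value is not None:
                fh.write(f"# {key}={value}\n")
        for section in ("RQ", "MQ"):
            s = report.scores.get(section)
            if s is not None:
                fh.write(f"# score_{section}={s.score!r}\n")
        writer = csv.writer(fh)
        writer.writerow(_CSV_COLUMNS)
        for row in report.per_criterion:
            if row["section"] == "REL":
                writer.writerow(
                    [row["id"], "REL", row["rating"] or "", "", "", "", row["comment"] or ""]
                )
            else:
                writer.writerow(
                    [
                        row["id"],
                        row["section"],
                        row["rating"] or "",
                        repr(float(row["weight"])),
                        "true" if row["removed"] else "false",
                        row["justification"] or "",
                        row["comment"] or "",
                    ]
                )


def _write_xlsx(report: EvaluationReport, path: Path):
    from openpyxl import Workbook
    from openpyxl.chart import BarChart, PieChart, Reference

    wb = Workbook()
    meta = wb.active
    meta.title = "Summary"
    for key in ("study_label", "catalog_ref", "evaluator", "timestamp", "tool_version"):
        meta.append([key, report.header.get(key)])
    for section in ("RQ", "MQ"):
        s = report.scores.get(section)
        meta.append([f"score_{section}", None if s is None else s.score])

    ev = wb.create_sheet("Evaluation")
    ev.append(list(_CSV_COLUMNS) + ["domain", "text"])
    for row in report.per_criterion:
        is_rel = row["section"] == "REL"
        ev.append(
            [
                row["id"],
                row["section"],
                row["rating"] or "",
                "" if is_rel else repr(float(row["weight"])),
                "" if is_rel else ("true" if row["removed"] else "false"),
                "" if is_rel else (row["justification"] or ""),
                row["comment"] or "",
                row["domain"],
                row["text"],
            ]
        )

    charts = wb.create_sheet("Profile")
    row_cursor = 1
    for section in ("RQ", "MQ"):
        profile = report.profiles.get(section)
        if profile is None:
            continue
        header_row = row_cursor
        charts.cell(header_row, 1, f"{section} domain")
        for j, cat in enumerate(RELIABILITY_ORDER, start=2):
            charts.cell(header_row, j, cat)
        for i, (domain, fractions) in enumerate(profile.bars.items(), start=1):
            charts.cell(header_row + i, 1, domain)
            for j, cat in enumerate(RELIABILITY_ORDER, start=2):
                charts.cell(header_row + i, j, fractions.get(cat, 0.0))
        chart = BarChart()
        chart.type = "bar"
        chart.grouping = "percentStacked"
        chart.overlap = 100
        chart.title = f"{section} colour profile"
        data = Reference(
            charts,
            min_col=2,
            max_col=1 + len(RELIABILITY_ORDER),
            min_row=header_row,
            max_row=header_row + len(profile.bars),
        )
        cats = Reference(
            charts,
            min_col=1,
            min_row=header_row + 1,
            max_row=header_row + len(profile.bars),
        )
        chart.add_data(data, titles_from_data=True)
        chart.set_categories(cats)
        charts.add_chart(chart, f"H{header_row}")
        row_cursor += len(profile.bars) + 2

    rel = report.profiles.get("REL")
    if rel is not None:
        header_row = row_cursor
        charts.cell(header_row, 1, "relevance category")
        charts.cell(header_row, 2, "fraction")
        for i, (cat, frac) in enumerate(rel.overall.items(), start=1):
            charts.cell(header_row + i, 1, cat)
            charts.cell(header_row + i, 2, frac)
        pie = PieChart()
        pie.title = "Relevance"
        data = Reference(
            charts, min_col=2, min_row=header_row, max_row=header_row + len(rel.overall)
        )
        labels = Reference(
            charts, min_col=1, min_row=header_row + 1, max_row=header_row + len(rel.overall)
        )
        pie.add_data(data, titles_from_data=True)
        pie.set_categories(labels)
        charts.add_chart(pie, f"H{header_row}")

    wb.save(path)


def _apply_row(
    evaluation: StudyEvaluation,
    row: dict[str, str],
    where: str,
) -> None:
    cid = row["id"]
    section = row["section"]
    rating = (row.get("rating") or "").strip()
    if section == "REL":
        if rating:
            if rating not in RELEVANCE_CATEGORIES:
                raise FormatError(
                    f"{where}: invalid relevance rating token {rating!r} "
                    f"(expected {'/'.join(RELEVANCE_ORDER)})"
                )
            evaluation.set_relevance_rating(cid, rating)
        if row.get("comment"):
            evaluation.set_comment(cid, row["comment"])
        return
    removed = (row.get("removed") or "").strip().lower() in ("true", "1", "yes")
    weight = (row.get("weight") or "").strip()
    if weight:
        evaluation.set_weight(cid, float(weight))
    if removed:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # justification warning fired at authoring time
            evaluation.remove_criterion(cid, row.get("justification") or None)
    elif rating:
        if rating not in RELIABILITY_CATEGORIES:
            raise FormatError(
                f"{where}: invalid reliability rating token {rating!r} "
                f"(expected {'/'.join(RELIABILITY_ORDER)})"
            )
        evaluation.set_rating(cid, rating)
    if row.get("comment"):
        evaluation.set_comment(cid, row["comment"])


def _check_embedded_scores(
    evaluation: StudyEvaluation, embedded: dict[str, float | None], source: str
) -> None:
    for section, claimed in embedded.items():
        if claimed is None:
            continue
        try:
            actual = compute_score(evaluation, section).score
        except (IncompleteEvaluationError, DegenerateInputError):
            continue
        if not math.isclose(actual, float(claimed), abs_tol=1e-6):
            warnings.warn(
                f"{source}: embedded {section} score {claimed} does not match "
                f"recomputed {actual}",
                TamperWarning,
                stacklevel=3,
            )


def import_report(
    path: str | Path,
    catalog: Catalog | None = None,
    format: str | None = None,
) -> tuple[StudyEvaluation, str]:
    """Reconstruct a StudyEvaluation from an exported report.

    Returns the evaluation and the catalog reference it was built
    against.  When ``catalog`` is not supplied, the reference is
    resolved against the bundled catalogs.  Embedded scores are
    recomputed and a :class:`TamperWarning` is issued on mismatch.
    """
    path = Path(path)
    fmt = _detect_format(path, format)
    if fmt == "json":
        return _read_json(path, catalog)
    if fmt == "csv":
        return _read_csv(path, catalog)
    if fmt == "xlsx":
        return _read_xlsx(path, catalog)
    raise FormatError(f"unknown format {fmt!r}")


def _resolve_catalog(catalog_ref: str, catalog: Catalog | None) -> Catalog:
    if catalog is not None:
        if catalog.ref != catalog_ref:
            raise FormatError(
                f"report references catalog {catalog_ref!r} but "
                f"{catalog.ref!r} was supplied"
            )
        return catalog
    return load_catalog(catalog_ref)


def _read_json(path: Path, catalog: Catalog | None):
    try:
        doc = json.loads(path.read_text("utf-8"))
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path.name}: not valid JSON ({exc})")
    catalog_ref = doc.get("catalog_ref", "")
    cat = _resolve_catalog(catalog_ref, catalog)
    ev = StudyEvaluation(
        cat,
        study_label=doc.get("study_label", ""),
        evaluator=doc.get("evaluator"),
        timestamp=doc.get("timestamp"),
    )
    for entry in doc.get("assessments", []):
        row = {
            "id": entry["id"],
            "section": cat.get_criterion(entry["id"]).section,
            "rating": entry.get("rating") or "",
            "weight": str(entry.get("weight", "")),
            "removed": "true" if entry.get("removed") else "false",
            "justification": entry.get("justification") or "",
            "comment": entry.get("comment") or "",
        }
        _apply_row(ev, row, f"{path.name}:{entry['id']}")
    for entry in doc.get("relevance", []):
        _apply_row(
            ev,
            {
                "id": entry["id"],
                "section": "REL",
                "rating": entry.get("rating") or "",
                "comment": entry.get("comment") or "",
            },
            f"{path.name}:{entry['id']}",
        )
    embedded = {
        s: (d or {}).get("score")
        for s, d in (doc.get("scores") or {}).items()
        if d is not None
    }
    _check_embedded_scores(ev, embedded, path.name)
    return ev, catalog_ref


def _read_csv(path: Path, catalog: Catalog | None):
    meta: dict[str, str] = {}
    body: list[str] = []
    for line in path.read_text("utf-8").splitlines():
        if line.startswith("#"):
            key, _, value = line[1:].strip().partition("=")
            meta[key.strip()] = value.strip()
        elif line.strip():
            body.append(line)
    if not body:
        raise FormatError(f"{path.name}: no CSV table found")
    reader = csv.DictReader(body)
    missing_cols = set(("id", "section", "rating")) - set(reader.fieldnames or ())
    if missing_cols:
        raise FormatError(
            f"{path.name}: missing required column(s) {sorted(missing_cols)}"
        )
    catalog_ref = meta.get("catalog_ref", "")
    cat = _resolve_catalog(catalog_ref, catalog)
    ev = StudyEvaluation(
        cat,
        study_label=meta.get("study_label", ""),
        evaluator=meta.get("evaluator") or None,
        timestamp=meta.get("timestamp") or None,
    )
    for lineno, row in enumerate(reader, start=2):
        _apply_row(ev, row, f"{path.name} row {lineno}")
    embedded = {
        s: float(meta[f"score_{s}"]) for s in ("RQ", "MQ") if f"score_{s}" in meta
    }
    _check_embedded_scores(ev, embedded, path.name)
    return ev, catalog_ref


def _read_xlsx(path: Path, catalog: Catalog | None):
    from openpyxl import load_workbook

    wb = load_workbook(path, read_only=True, data_only=True)
    if "Summary" not in wb.sheetnames or "Evaluation" not in wb.sheetnames:
        raise FormatError(f"{path.name}: missing Summary/Evaluation sheets")
    meta: dict[str, Any] = {}
    for key, value in wb["Summary"].iter_rows(values_only=True):
        meta[key] = value
    catalog_ref = str(meta.get("catalog_ref", ""))
    cat = _resolve_catalog(catalog_ref, catalog)
    ev = StudyEvaluation(
        cat,
        study_label=str(meta.get("study_label") or ""),
        evaluator=meta.get("evaluator"),
        timestamp=meta.get("timestamp"),
    )
    rows = wb["Evaluation"].iter_rows(values_only=True)
    header = next(rows)
    for i, values in enumerate(rows, start=2):
        row = {
            str(k): ("" if v is None else str(v))
            for k, v in zip(header, values)
        }
        _apply_row(ev, row, f"{path.name} row {i}")
    wb.close()
    embedded = {
        s: meta.get(f"score_{s}")
        for s in ("RQ", "MQ")
        if meta.get(f"score_{s}") is not None
    }
    _check_embedded_scores(ev, embedded, path.name)
    return ev, catalog_ref


def render_profile(
    profile: ColourProfile, out: str | Path, kind: str | None = None
) -> Path:
    """Render a colour profile to a vector image.

    ``kind="bars"`` draws one horizontally stacked bar per domain (the
    reliability readout); ``kind="pie"`` draws the category pie (the
    relevance readout).  Defaults to pie for relevance profiles and bars
    otherwise.  Fulfilled/directly-relevant is green, partial yellow,
    not-fulfilled red, not-determined grey; a criterion with increased
    weight occupies proportionally more area.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not profile.bars and not profile.overall:
        raise DegenerateInputError("empty profile: nothing to render")
    if kind is None:
        kind = "pie" if profile.section == "REL" else "bars"
    order = RELEVANCE_ORDER if profile.section == "REL" else RELIABILITY_ORDER
    out = Path(out)

    if kind == "pie":
        cats = [c for c in order if profile.overall.get(c, 0.0) > 0]
        fracs = [profile.overall[c] for c in cats]
        fig, ax = plt.subplots(figsize=(4, 4))
        ax.pie(
            fracs,
            labels=cats,
            colors=[COLOURS.get(c, "#999999") for c in cats],
            startangle=90,
            counterclock=False,
            autopct=lambda pct: f"{pct:.0f}%",
        )
        ax.set_title(f"{profile.section} profile")
    elif kind == "bars":
        domains = list(profile.bars)
        fig, ax = plt.subplots(figsize=(7, 0.6 * max(len(domains), 2) + 1.2))
        for i, domain in enumerate(domains):
            left = 0.0
            for cat in order:
                frac = profile.bars[domain].get(cat, 0.0)
                if frac > 0:
                    ax.barh(
                        i, frac * 100, left=left,
                        color=COLOURS.get(cat, "#999999"), edgecolor="white",
                    )
                    left += frac * 100
        ax.set_yticks(range(len(domains)), domains)
        ax.invert_yaxis()
        ax.set_xlim(0, 100)
        ax.set_xlabel("% of retained weighted criteria")
        ax.set_title(f"{profile.section} colour profile")
        handles = [
            plt.Rectangle((0, 0), 1, 1, color=COLOURS[c])
            for c in order
            if c in COLOURS
        ]
        ax.legend(handles, [c for c in order if c in COLOURS],
                  loc="lower right", fontsize=8)
        fig.tight_layout()
    else:
        raise ValueError(f"unknown kind {kind!r}; expected 'bars' or 'pie'")
    fig.savefig(out)
    plt.close(fig)
    return out
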