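"""Colour-coded rating matrices and per-study evaluation reports.

The colour convention follows the tool's published charts: fulfilled /
directly-relevant cells are green, partially-fulfilled / indirectly-relevant
cells yellow, not-fulfilled cells red and not-determined cells grey.
"Not relevant" is mapped to red by symmetry with the quality scale (the
published case study happened to contain none). Criteria removed for
inapplicability render as a distinct hatched "removed" cell — removal is an
applicability fact, not a judgement, so it must not look like ND.
"""

from __future__ import annotations

import html as _html
from dataclasses import dataclass, field

from .bank import CriteriaBank, Part
from .evaluation import (
    EvaluationSet,
    StudyEvaluation,
    export_matrix,
    validate_evaluation,
)
from .scoring import (
    DEFAULT_WEIGHTS,
    IncompleteEvaluationError,
    ScoreWeights,
    quality_score,
)

__all__ = [
    "ColorMatrix",
    "QUALITY_COLORS",
    "RELEVANCE_COLORS",
    "REMOVED_TOKEN",
    "build_color_matrix",
    "render_color_matrix",
    "study_report",
    "render_study_report_html",
]

#: rating token -> colour token; overridable via the ``colors`` argument.
QUALITY_COLORS = {"F": "#4caf50", "PF": "#ffeb3b", "NF": "#f44336", "ND": "#bdbdbd"}
RELEVANCE_COLORS = {"DR": "#4caf50", "IR": "#ffeb3b", "NR": "#f44336", "ND": "#bdbdbd"}
REMOVED_TOKEN = "REMOVED"
REMOVED_COLOR = "#ffffff"  # rendered hatched in HTML/SVG

_LEGEND_LABELS = {
    "F": "fulfilled", "PF": "partially fulfilled", "NF": "not fulfilled",
    "DR": "directly relevant", "IR": "indirectly relevant", "NR": "not relevant",
    "ND": "not determined", REMOVED_TOKEN: "criterion removed (not applicable)",
}


@dataclass(frozen=True)
class ColorMatrix:
    """A criteria-by-studies grid of (rating token, colour token) cells.

    ``rows`` are (section label, criterion id) pairs in bank order;
    ``cells[i][j]`` corresponds to ``rows[i]`` and ``columns[j]``. The
    legend contains exactly the tokens that occur in the grid.
    """

    part: Part
    rows: tuple          # ((section, id), ...)
    columns: tuple       # study ids
    cells: tuple         # ((token, color), ...) per row
    legend: dict = field(default_factory=dict)


def build_color_matrix(
    evalset: EvaluationSet,
    part: Part | str,
    bank: CriteriaBank | None = None,
    colors: dict | None = None,
) -> ColorMatrix:
    """Assemble the colour matrix for one part of an evaluation set."""
    part = Part(part)
    base = dict(RELEVANCE_COLORS if part is Part.REL else QUALITY_COLORS)
    if colors:
        base.update(colors)

    sections: dict[int, str] = {}
    if bank is None:
        from .evaluation import _bank_for
        try:
            bank = _bank_for(evalset.bank_version)
        except Exception:
            bank = None
    if bank is not None:
        sections = {c.id: c.section for c in bank.part(part)}

    ids = sorted({cid for ev in evalset for (p, cid) in (*ev.judged(part), *[k for k in ev.removed if k[0] is part])}
                 if evalset.evaluations else set())
    rows, cells, used = [], [], set()
    for cid in ids:
        rows.append((sections.get(cid, ""), cid))
        row = []
        for ev in evalset:
            if (part, cid) in ev.removed:
                token, color = REMOVED_TOKEN, REMOVED_COLOR
            else:
                r = ev.rating(part, cid)
                token = "" if r is None else r.value
                color = base.get(token, "#ffffff")
            used.add(token)
            row.append((token, color))
        cells.append(tuple(row))
    legend = {t: (REMOVED_COLOR if t == REMOVED_TOKEN else base[t])
              for t in sorted(used) if t in base or t == REMOVED_TOKEN}
    return ColorMatrix(part=part, rows=tuple(rows), columns=tuple(evalset.study_ids()),
                       cells=tuple(cells), legend=legend)


def render_color_matrix(
    evalset: EvaluationSet,
    part: Part | str,
    format: str = "csv",
    bank: CriteriaBank | None = None,
    colors: dict | None = None,
) -> str:
    """Render one part as ``csv`` (rating tokens), ``html`` or ``svg``.

    The CSV variant is byte-deterministic for identical inputs and carries
    tokens rather than colours; HTML and SVG carry both, plus a legend of
    every colour used.
    """
    part = Part(part)
    if format == "csv":
        return export_matrix(evalset, part)
    matrix = build_color_matrix(evalset, part, bank=bank, colors=colors)
    if format == "html":
        return _matrix_html(matrix)
    if format == "svg":
        return _matrix_svg(matrix)
    raise ValueError(f"unknown format {format!r}; expected csv, html or svg")


def _legend_html(legend: dict) -> str:
    items = "".join(
        f'<span class="legend-item"><span class="swatch" style="background:{color}"></span>'
        f"{token} = {_html.escape(_LEGEND_LABELS.get(token, token))}</span> "
        for token, color in legend.items()
    )
    return f'<div class="legend">{items}</div>'


def _matrix_html(m: ColorMatrix) -> str:
    head = "".join(f"<th>{_html.escape(c)}</th>" for c in m.columns)
    body = []
    last_section = object()
    for (section, cid), row in zip(m.rows, m.cells):
        if section and section != last_section:
            body.append(f'<tr class="section"><th colspan="{len(m.columns) + 1}">'
                        f"{_html.escape(section)}</th></tr>")
            last_section = section
        cells = "".join(
            f'<td class="removed">removed</td>' if token == REMOVED_TOKEN
            else f'<td style="background:{color}">{token}</td>'
            for token, color in row
        )
        body.append(f"<tr><th>{m.part.value}{cid}</th>{cells}</tr>")
    style = ("table{border-collapse:collapse}td,th{border:1px solid #999;padding:2px 6px;"
             "font:12px sans-serif}td.removed{background:repeating-linear-gradient(45deg,"
             "#fff,#fff 4px,#ddd 4px,#ddd 8px)}.swatch{display:inline-block;width:1em;"
             "height:1em;border:1px solid #999;margin-right:0.3em}.legend-item{margin-right:1em}")
    return ("<!DOCTYPE html><html><head><meta charset='utf-8'>"
            f"<style>{style}</style></head><body>"
            f"<table><tr><th>{m.part.value}</th>{head}</tr>{''.join(body)}</table>"
            f"{_legend_html(m.legend)}</body></html>")


def _matrix_svg(m: ColorMatrix, cell_w: int = 44, cell_h: int = 18, label_w: int = 60) -> str:
    width = label_w + cell_w * len(m.columns)
    height = cell_h * (len(m.rows) + 1) + 20 * (len(m.legend) + 1)
    parts = [f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" height="{height}" '
             f'font-family="sans-serif" font-size="10">',
             '<defs><pattern id="hatch" width="6" height="6" patternUnits="userSpaceOnUse">'
             '<path d="M0,6 L6,0" stroke="#bbb" stroke-width="1"/></pattern></defs>']
    for j, col in enumerate(m.columns):
        parts.append(f'<text x="{label_w + j * cell_w + 2}" y="12">{_html.escape(col)}</text>')
    for i, ((_, cid), row) in enumerate(zip(m.rows, m.cells)):
        y = cell_h * (i + 1)
        parts.append(f'<text x="2" y="{y + 13}">{m.part.value}{cid}</text>')
        for j, (token, color) in enumerate(row):
            x = label_w + j * cell_w
            fill = "url(#hatch)" if token == REMOVED_TOKEN else color
            parts.append(f'<rect x="{x}" y="{y}" width="{cell_w}" height="{cell_h}" '
                         f'fill="{fill}" stroke="#999"/>')
            parts.append(f'<text x="{x + 4}" y="{y + 13}">{token if token != REMOVED_TOKEN else "rm"}</text>')
    y0 = cell_h * (len(m.rows) + 1) + 14
    for n, (token, color) in enumerate(m.legend.items()):
        y = y0 + 20 * n
        fill = "url(#hatch)" if token == REMOVED_TOKEN else color
        parts.append(f'<rect x="2" y="{y - 10}" width="12" height="12" fill="{fill}" stroke="#999"/>')
        parts.append(f'<text x="18" y="{y}">{token} = {_html.escape(_LEGEND_LABELS.get(token, token))}</text>')
    parts.append("</svg>")
    return "".join(parts)


def study_report(
    ev: StudyEvaluation,
    bank: CriteriaBank,
    weights: ScoreWeights = DEFAULT_WEIGHTS,
) -> dict:
    """Structured per-study report.

    Contains the bank version, problem formulation, RQ and MQ score results
    with section breakdowns, the relevance profile, every judgement with its
    comment/rationale, and the removed-criteria list with reasons. Raises
    :class:`IncompleteEvaluationError` on an incomplete evaluation.
    """
    violations = validate_evaluation(ev, bank)
    if violations:
        raise IncompleteEvaluationError(
            f"{ev.study_id}: evaluation is not complete/consistent: "
            + "; ".join(str(v) for v in violations[:5])
            + ("..." if len(violations) > 5 else ""))

    report: dict = {
        "study_id": ev.study_id,
        "evaluator_id": ev.evaluator_id,
        "bank_version": ev.bank_version,
        "tool_name": bank.tool_name,
        "problem_formulation": ev.problem_formulation,
        "scores": {},
        "relevance": {},
        "judgements": [],
        "removed": [{"criterion": f"{p.value}{cid}", "reason": reason}
                    for (p, cid), reason in sorted(ev.removed.items(), key=lambda kv: (kv[0][0].value, kv[0][1]))],
    }
    for part in (Part.RQ, Part.MQ):
        res = quality_score(ev, part, weights, bank=bank)
        report["scores"][part.value] = {
            "score": res.rounded(1),
            "counts": res.counts,
            "denominator": res.denominator,
            "per_section": {k: (None if v is None else round(v, 1)) for k, v in res.per_section.items()},
        }
    rel = {cid: j.rating.value for (p, cid), j in sorted(ev.judged(Part.REL).items(), key=lambda kv: kv[0][1])}
    report["relevance"] = {f"REL{cid}": token for cid, token in rel.items()}
    for (p, cid), j in sorted(ev.judgements.items(), key=lambda kv: (kv[0][0].value, kv[0][1])):
        entry = {"criterion": f"{p.value}{cid}", "rating": None if j.rating is None else j.rating.value}
        if bank.has(p, cid):
            entry["text"] = bank.get(p, cid).text
        if j.comment:
            entry["comment"] = j.comment
        if j.rationale:
            entry["rationale"] = j.rationale
        report["judgements"].append(entry)
    return report


def render_study_report_html(report: dict) -> str:
    """Minimal HTML rendering of a :func:`study_report` dictionary."""
    rows = []
    for j in report["judgements"]:
        token = j["rating"] or ""
        color = (RELEVANCE_COLORS if j["criterion"].startswith("REL") else QUALITY_COLORS).get(token, "#fff")
        extra = "".join(f"<div class='note'>{_html.escape(k)}: {_html.escape(j[k])}</div>"
                        for k in ("comment", "rationale") if j.get(k))
        text = _html.escape(j.get("text", ""))
        rows.append(f"<tr><th>{j['criterion']}</th>"
                    f"<td style='background:{color}'>{token}</td><td>{text}{extra}</td></tr>")
    scores = "".join(
        f"<li>{part}: {s['score']} (denominator {s['denominator']})</li>"
        for part, s in report["scores"].items())
    removed = "".join(f"<li>{r['criterion']}: {_html.escape(r['reason'])}</li>" for r in report["removed"])
    return ("<!DOCTYPE html><html><head><meta charset='utf-8'><style>"
            "table{border-collapse:collapse}td,th{border:1px solid #999;padding:2px 6px;"
            "font:12px sans-serif}.note{color:#555;font-style:italic}</style></head><body>"
            f"<h1>{_html.escape(report['tool_name'])} report — {_html.escape(report['study_id'])}</h1>"
            f"<p>Bank version {report['bank_version']}; problem formulation: "
            f"{_html.escape(report['problem_formulation'])}</p>"
            f"<ul>{scores}</ul>"
            + (f"<h2>Removed criteria</h2><ul>{removed}</ul>" if removed else "")
            + f"<table>{''.join(rows)}</table></body></html>")
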