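"""Result rendering: compounds table, pathway-expanded table, HTML page.

Three artifacts per run, mirroring the classic web-tool output: a *compounds*
TSV listing one row per match without pathway information, a *pathways* TSV
repeating each match once per pathway it belongs to (sortable by pathway),
and a self-contained HTML page with the same rows plus hyperlinks into the
source pathway databases. The full search parameters and input provenance
are echoed identically at the top of all three artifacts so a result file
always documents how it was produced.

Queries with zero hits are emitted as explicit "no match" rows rather than
silently dropped: input and output row accounting always reconciles.
Payload columns carried through from the query file (retention times,
intensities, statistics) are appended verbatim to each row.
"""

from __future__ import annotations

import html as _html
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

from .matching import MatchResult, SearchParams
from .query_io import Query, QueryBatch

__all__ = [
    "ReportBundle",
    "params_echo_lines",
    "render_compounds_table",
    "render_pathways_table",
    "render_html",
    "build_report",
]

COMPOUND_COLUMNS = (
    "query", "query_type", "db_name", "compound_id", "compound_name",
    "formula", "theoretical_mass", "ion", "deviation_da", "deviation_ppm",
    "cas_id",
)
PATHWAY_COLUMNS = COMPOUND_COLUMNS + ("pathway_id", "pathway_name")

NO_MATCH = "no match"


def params_echo_lines(
    params: SearchParams, provenance: Optional[Mapping[str, str]] = None
) -> List[str]:
    """The canonical parameter echo, identical across all three outputs."""
    lines = [
        f"tolerance: {params.tolerance_value:g} {params.tolerance_unit}",
        f"mode: {params.mode}",
        f"max charge: {params.max_charge}",
        f"adducts: {', '.join(a.label for a in params.adducts) or 'none'}",
        f"deducts: {', '.join(d.label for d in params.deducts) or 'none'}",
        f"max adduct count: {params.max_adduct_count}",
        f"mass kind: {params.mass_kind}",
        f"neutral (z=0) hypotheses: {'on' if params.include_neutral else 'off'}",
    ]
    for key, value in (provenance or {}).items():
        lines.append(f"{key}: {value}")
    return lines


@dataclass(frozen=True)
class Precision:
    """Decimal places for the rendered numeric columns."""

    mass_dp: int = 4
    da_dp: int = 4
    ppm_dp: int = 2


def _group_by_query(
    batch: QueryBatch, results: Sequence[MatchResult]
) -> List[Tuple[Query, List[MatchResult]]]:
    by_query: Dict[int, List[MatchResult]] = {id(q): [] for q in batch.queries}
    for r in results:
        by_query.setdefault(id(r.query), []).append(r)
    return [(q, by_query[id(q)]) for q in batch.queries]


def _match_cells(r: MatchResult, prec: Precision) -> List[str]:
    rec = r.compound
    theoretical = rec.monoisotopic_mass
    if r.hypothesis is None and theoretical is None:
        theoretical = rec.average_mw
    return [
        r.query.raw,
        r.query.qtype,
        r.db_name,
        rec.compound_id,
        rec.name,
        str(rec.formula) if rec.formula is not None else "",
        f"{theoretical:.{prec.mass_dp}f}" if theoretical is not None else "",
        r.hypothesis.label if r.hypothesis is not None else "",
        f"{r.deviation_da:.{prec.da_dp}f}" if r.deviation_da is not None else "",
        f"{r.deviation_ppm:.{prec.ppm_dp}f}" if r.deviation_ppm is not None else "",
        rec.cas_id or "",
    ]


def _no_match_cells(q: Query) -> List[str]:
    return [q.raw, q.qtype, "", "", NO_MATCH, "", "", "", "", "", ""]


def _table_rows(
    batch: QueryBatch,
    results: Sequence[MatchResult],
    prec: Precision,
    expand_pathways: bool,
) -> List[List[str]]:
    rows: List[List[str]] = []
    for query, hits in _group_by_query(batch, results):
        if not hits:
            cells = _no_match_cells(query)
            if expand_pathways:
                cells += ["", ""]
            rows.append(cells + list(query.payload))
            continue
        for r in hits:
            base = _match_cells(r, prec)
            if not expand_pathways:
                rows.append(base + list(query.payload))
            elif r.pathways:
                for pid, pname in r.pathways:
                    rows.append(base + [pid, pname] + list(query.payload))
            else:
                rows.append(base + ["", ""] + list(query.payload))
    return rows


def _render_tsv(
    header: Sequence[str],
    rows: Sequence[Sequence[str]],
    echo: Sequence[str],
) -> str:
    lines = [f"# {line}" for line in echo]
    lines.append("\t".join(header))
    lines += ["\t".join(row) for row in rows]
    return "\n".join(lines) + "\n"


def render_compounds_table(
    batch: QueryBatch,
    results: Sequence[MatchResult],
    params: SearchParams,
    provenance: Optional[Mapping[str, str]] = None,
    precision: Precision = Precision(),
) -> str:
    """The compounds file: one row per match, no pathway columns."""
    rows = _table_rows(batch, results, precision, expand_pathways=False)
    return _render_tsv(COMPOUND_COLUMNS, rows, params_echo_lines(params, provenance))


def render_pathways_table(
    batch: QueryBatch,
    results: Sequence[MatchResult],
    params: SearchParams,
    provenance: Optional[Mapping[str, str]] = None,
    precision: Precision = Precision(),
) -> str:
    """The pathways file: each match repeated once per pathway (at least
    once, with blank pathway fields for pathway-less compounds)."""
    rows = _table_rows(batch, results, precision, expand_pathways=True)
    return _render_tsv(PATHWAY_COLUMNS, rows, params_echo_lines(params, provenance))


def _linkify(template: str, entity_id: str, text: str) -> str:
    escaped = _html.escape(text)
    if not template or not entity_id:
        return escaped
    href = template.replace("{id}", entity_id)
    return f'<a href="{_html.escape(href, quote=True)}">{escaped}</a>'


def render_html(
    batch: QueryBatch,
    results: Sequence[MatchResult],
    params: SearchParams,
    link_templates: Optional[Mapping[str, str]] = None,
    provenance: Optional[Mapping[str, str]] = None,
    precision: Precision = Precision(),
    tsv_names: Tuple[str, str] = ("compounds.tsv", "pathways.tsv"),
) -> str:
    """Self-contained HTML page: parameter echo, links to the two TSV files,
    and the match table with per-pathway/compound hyperlinks built from each
    database's link template (plain text when no template is known)."""
    link_templates = dict(link_templates or {})
    echo = params_echo_lines(params, provenance)

    head = [
        "<!DOCTYPE html>",
        "<html><head><meta charset='utf-8'>",
        "<title>metabosearch results</title>",
        "<style>body{font-family:sans-serif}table{border-collapse:collapse}"
        "td,th{border:1px solid #999;padding:2px 6px;font-size:90%}"
        "pre{background:#eee;padding:6px}</style>",
        "</head><body>",
        "<h1>Metabolite search results</h1>",
        "<h2>Search parameters</h2>",
        "<pre>" + "\n".join(_html.escape(l) for l in echo) + "</pre>",
        "<p>Download: "
        f"<a href='{tsv_names[0]}'>compounds file</a> | "
        f"<a href='{tsv_names[1]}'>pathways file</a></p>",
    ]

    grouped = _group_by_query(batch, results)
    n_hits = sum(len(hits) for _, hits in grouped)
    if n_hits == 0:
        head.append("<p><em>No matches found for any query.</em></p>")

    header_cells = COMPOUND_COLUMNS + ("pathways",)
    body = ["<h2>Matches</h2>", "<table>",
            "<tr>" + "".join(f"<th>{_html.escape(c)}</th>" for c in header_cells) + "</tr>"]
    for query, hits in grouped:
        if not hits:
            cells = [_html.escape(c) for c in _no_match_cells(query)] + [""]
            body.append("<tr>" + "".join(f"<td>{c}</td>" for c in cells) + "</tr>")
            continue
        for r in hits:
            template = link_templates.get(r.db_name, "")
            cells = [_html.escape(c) for c in _match_cells(r, precision)]
            cells[4] = _linkify(template, r.compound.compound_id, r.compound.name)
            pw = ", ".join(
                _linkify(template, pid, pname or pid) for pid, pname in r.pathways
            )
            body.append(
                "<tr>" + "".join(f"<td>{c}</td>" for c in cells + [pw]) + "</tr>"
            )
    body += ["</table>", "</body></html>"]
    return "\n".join(head + body) + "\n"


@dataclass
class ReportBundle:
    """The three rendered artifacts of one search run."""

    compounds_tsv: str
    pathways_tsv: str
    html: str

    def write(self, out_dir: Union[str, Path]) -> Dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "compounds": out / "compounds.tsv",
            "pathways": out / "pathways.tsv",
            "html": out / "report.html",
        }
        paths["compounds"].write_text(self.compounds_tsv, encoding="utf-8")
        paths["pathways"].write_text(self.pathways_tsv, encoding="utf-8")
        paths["html"].write_text(self.html, encoding="utf-8")
        return paths


def build_report(
    batch: QueryBatch,
    results: Sequence[MatchResult],
    params: SearchParams,
    link_templates: Optional[Mapping[str, str]] = None,
    provenance: Optional[Mapping[str, str]] = None,
    precision: Precision = Precision(),
) -> ReportBundle:
    """Render all three artifacts with one shared parameter echo."""
    return ReportBundle(
        compounds_tsv=render_compounds_table(batch, results, params, provenance, precision),
        pathways_tsv=render_pathways_table(batch, results, params, provenance, precision),
        html=render_html(batch, results, params, link_templates, provenance, precision),
    )
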