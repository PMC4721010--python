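"""Static HTML report of a full enrichment run.

The bundle contains an index page, a gene report with per-gene measures of
differential expression, one flat ranking page per executed method, detail
pages for significant gene sets (set-based view: volcano plot with the set
highlighted plus a member-gene table; network-based view: an induced-edge
table with consistency values), and a combined page showing the combined
ranking alongside the individual per-method ranks.  Every table is also
written as TSV next to its page.  Output is deterministic for identical
inputs: no timestamps, fixed SVG hash salt.
"""

from __future__ import annotations

import html
import logging
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .combine import CombinedRanking
from .datamodel import GeneSetCollection, RegulatoryNetwork
from .diffexp import DEResult
from .nbea import edge_table
from .sbea import EnrichmentRanking

logger = logging.getLogger(__name__)

_CSS = """\
body { font-family: sans-serif; margin: 2em; color: #222; }
h1, h2 { color: #1a3c5e; }
table { border-collapse: collapse; margin: 1em 0; }
th, td { border: 1px solid #bbb; padding: 0.3em 0.7em; text-align: left; }
th { background: #e8eef4; cursor: pointer; }
tr:nth-child(even) { background: #f6f8fa; }
a { color: #1a5e8e; }
.sig { background: #fff3cd; }
"""

_SORT_JS = """\
function sortTable(tbl, col) {
  var rows = Array.from(tbl.tBodies[0].rows);
  var dir = tbl.dataset.dir === 'asc' ? -1 : 1;
  tbl.dataset.dir = dir === 1 ? 'asc' : 'desc';
  rows.sort(function (a, b) {
    var x = a.cells[col].textContent, y = b.cells[col].textContent;
    var nx = parseFloat(x), ny = parseFloat(y);
    if (!isNaN(nx) && !isNaN(ny)) return dir * (nx - ny);
    return dir * x.localeCompare(y);
  });
  rows.forEach(function (r) { tbl.tBodies[0].appendChild(r); });
}
"""


@dataclass
class ReportBundle:
    outdir: Path
    index: Path
    files: list[Path] = field(default_factory=list)


def _page(title: str, body: str, css_rel: str = "style.css") -> str:
    return (
        "<!DOCTYPE html>\n<html>\n<head>\n<meta charset='utf-8'>\n"
        f"<title>{html.escape(title)}</title>\n"
        f"<link rel='stylesheet' href='{css_rel}'>\n"
        f"<script>{_SORT_JS}</script>\n"
        "</head>\n<body>\n"
        f"<h1>{html.escape(title)}</h1>\n{body}\n</body>\n</html>\n"
    )


def _table(df: pd.DataFrame, table_id: str = "t") -> str:
    head = "".join(
        f"<th onclick=\"sortTable(document.getElementById('{table_id}'),{j})\">"
        f"{html.escape(str(c))}</th>"
        for j, c in enumerate(df.columns)
    )
    rows = []
    for _, row in df.iterrows():
        cells = "".join(
            f"<td>{html.escape(_fmt(v))}</td>" for v in row.tolist()
        )
        rows.append(f"<tr>{cells}</tr>")
    return (
        f"<table id='{table_id}'><thead><tr>{head}</tr></thead>"
        f"<tbody>{''.join(rows)}</tbody></table>"
    )


def _fmt(v) -> str:
    if isinstance(v, float):
        return f"{v:.4g}"
    return str(v)


def _volcano(de: DEResult, highlight: set[str] | None, path: Path) -> None:
    with plt.rc_context({"svg.hashsalt": "enrichrank"}):
        fig, ax = plt.subplots(figsize=(5, 4))
        logp = -np.log10(np.maximum(de.pval, np.finfo(float).tiny))
        ax.scatter(de.log2fc, logp, s=6, c="#888", linewidths=0)
        if highlight:
            idx = [i for i, g in enumerate(de.gene_ids) if g in highlight]
            ax.scatter(de.log2fc[idx], logp[idx], s=10, c="#c0392b", linewidths=0)
        ax.set_xlabel("log2 fold change")
        ax.set_ylabel("-log10 p-value")
        fig.tight_layout()
        fig.savefig(path, format="svg", metadata={"Date": None})
        plt.close(fig)


def render_report(
    de: DEResult,
    rankings: list[EnrichmentRanking],
    outdir: str | Path,
    combined: CombinedRanking | None = None,
    gsc: GeneSetCollection | None = None,
    grn: RegulatoryNetwork | None = None,
    alpha: float = 0.05,
) -> ReportBundle:
    """Write the full HTML bundle; returns the generated file inventory."""
    if not rankings:
        raise ValueError("need at least one ranking to report")
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "sets").mkdir(exist_ok=True)
    except OSError as err:
        raise OSError(f"cannot create report directory {outdir}: {err}") from err

    files: list[Path] = []

    def emit(rel: str, content: str) -> Path:
        p = outdir / rel
        p.write_text(content, encoding="utf-8")
        files.append(p)
        return p

    emit("style.css", _CSS)

    # gene report: one row per gene in the DE result
    gene_df = de.to_frame()
    gene_df.to_csv(outdir / "genes.tsv", sep="\t", index=False, float_format="%.6g")
    files.append(outdir / "genes.tsv")
    emit(
        "genes.html",
        _page(
            "Gene report",
            f"<p>{len(gene_df)} genes; raw TSV: <a href='genes.tsv'>genes.tsv</a></p>"
            + _table(gene_df),
        ),
    )
    _volcano(de, None, outdir / "volcano.svg")
    files.append(outdir / "volcano.svg")

    index_items = [
        "<li><a href='genes.html'>Gene report</a></li>",
        "<li><a href='volcano.svg'>Volcano plot (all genes)</a></li>",
    ]

    for r in rankings:
        rel_tsv = f"ranking_{r.method_name}.tsv"
        rel_html = f"ranking_{r.method_name}.html"
        r.write_tsv(outdir / rel_tsv)
        files.append(outdir / rel_tsv)
        df = r.to_frame()
        sig_ids = [s for s, q in zip(r.set_ids, r.adj_pvals) if q < alpha]
        is_nbea = "n_edges" in r.info
        links = []
        for sid in sig_ids:
            page = _set_page(
                r, sid, de, gsc, grn, is_nbea, outdir, alpha
            )
            if page is not None:
                files.extend(page)
                rel = page[0].relative_to(outdir).as_posix()
                links.append(f"<li><a href='{rel}'>{html.escape(sid)}</a></li>")
        body = (
            f"<p>Method: {html.escape(r.method_name)}; {len(r)} sets; "
            f"raw TSV: <a href='{rel_tsv}'>{rel_tsv}</a></p>"
            + _table(df, table_id=f"rk_{r.method_name}")
            + (
                "<h2>Significant sets (adj. p &lt; %.3g)</h2><ul>%s</ul>"
                % (alpha, "".join(links))
                if links
                else "<p>No significant sets at adj. p &lt; %.3g.</p>" % alpha
            )
        )
        emit(rel_html, _page(f"Ranking: {r.method_name}", body))
        index_items.append(
            f"<li><a href='{rel_html}'>Ranking: {html.escape(r.method_name)}</a></li>"
        )

    if combined is not None:
        combined.write_tsv(outdir / "combined.tsv")
        files.append(outdir / "combined.tsv")
        body = (
            f"<p>Rank type: {combined.rank_type}; combination: {combined.combine_fn}; "
            f"support: {combined.support}; raw TSV: <a href='combined.tsv'>combined.tsv</a>"
            "</p><p>Click a column header to sort.</p>" + _table(combined.to_frame(), "cmb")
        )
        emit("combined.html", _page("Combined ranking", body))
        index_items.append("<li><a href='combined.html'>Combined ranking</a></li>")

    emit(
        "index.html",
        _page("Enrichment analysis report", "<ul>" + "".join(index_items) + "</ul>"),
    )
    return ReportBundle(outdir=outdir, index=outdir / "index.html", files=files)


def _set_page(
    r: EnrichmentRanking,
    sid: str,
    de: DEResult,
    gsc: GeneSetCollection | None,
    grn: RegulatoryNetwork | None,
    is_nbea: bool,
    outdir: Path,
    alpha: float,
) -> list[Path] | None:
    members: set[str] = set()
    if gsc is not None and sid in gsc.sets:
        members = set(gsc[sid]) & set(de.gene_ids)
    if is_nbea and grn is None:
        logger.info("network missing: network-based detail page for %s omitted", sid)
        return None

    rel_base = f"sets/{r.method_name}_{sid}"
    produced: list[Path] = []
    parts: list[str] = []
    if is_nbea:
        et = edge_table(de, grn)
        if members:
            et = et[
                et["regulator"].isin(members) | et["target"].isin(members)
            ].reset_index(drop=True)
        tsv = outdir / f"{rel_base}_edges.tsv"
        et.to_csv(tsv, sep="\t", index=False, float_format="%.6g")
        base = rel_base.split("/")[-1]
        parts.append(
            f"<h2>Induced regulatory edges</h2>"
            f"<p>TSV: <a href='{base}_edges.tsv'>{base}_edges.tsv</a></p>"
            + _table(et, "edges")
        )
        extra = [tsv]
    else:
        svg = outdir / f"{rel_base}_volcano.svg"
        _volcano(de, members, svg)
        base = rel_base.split("/")[-1]
        gidx = de.gene_index()
        mem_df = de.to_frame().iloc[[gidx[g] for g in sorted(members)]]
        tsv = outdir / f"{rel_base}_genes.tsv"
        mem_df.to_csv(tsv, sep="\t", index=False, float_format="%.6g")
        parts.append(
            f"<h2>Volcano plot (set highlighted)</h2>"
            f"<img src='{base}_volcano.svg' alt='volcano'>"
            f"<h2>Member genes</h2>"
            f"<p>TSV: <a href='{base}_genes.tsv'>{base}_genes.tsv</a></p>"
            + _table(mem_df, "mem")
        )
        extra = [svg, tsv]

    page = outdir / f"{rel_base}.html"
    page.write_text(
        _page(f"{r.method_name}: {sid}", "".join(parts), css_rel="../style.css"),
        encoding="utf-8",
    )
    return [page, *extra]
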