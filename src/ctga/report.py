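"""Deterministic rendering of pipeline summaries.

A :class:`ReportBundle` is an ordered list of named tables.  It renders
either to one self-contained static HTML page — inline CSS/JS, a
client-side search box per table and a CSV export button, no network
fetches — or to one plain CSV/TSV file per section.  With timestamps
disabled (the default) the output is byte-deterministic for identical
inputs, so reports diff cleanly across runs.
"""

from __future__ import annotations

import csv
import html
import io
import re
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

__all__ = ["ReportBundle", "render_report"]

_PAGE_TEMPLATE = """<!DOCTYPE html>
<html lang="en">
<head>
<meta charset="utf-8">
<title>{title}</title>
<style>
body {{ font-family: sans-serif; margin: 2em; }}
table {{ border-collapse: collapse; margin: 1em 0; }}
th, td {{ border: 1px solid #999; padding: 0.3em 0.6em; font-size: 0.9em; }}
th {{ background: #eee; }}
input.filter {{ margin: 0.5em 0; padding: 0.3em; width: 24em; }}
button.export {{ margin-left: 1em; }}
.meta {{ color: #555; font-size: 0.85em; }}
</style>
</head>
<body>
<h1>{title}</h1>
<div class="meta">{metadata}</div>
{sections}
<script>
function filterTable(input, tableId) {{
  var needle = input.value.toLowerCase();
  var rows = document.getElementById(tableId).tBodies[0].rows;
  for (var i = 0; i < rows.length; i++) {{
    rows[i].style.display =
      rows[i].textContent.toLowerCase().indexOf(needle) >= 0 ? "" : "none";
  }}
}}
function exportCsv(tableId, name) {{
  var table = document.getElementById(tableId);
  var lines = [];
  for (var r = 0; r < table.rows.length; r++) {{
    var cells = table.rows[r].cells, fields = [];
    for (var c = 0; c < cells.length; c++) {{
      fields.push('"' + cells[c].textContent.replace(/"/g, '""') + '"');
    }}
    lines.push(fields.join(","));
  }}
  var blob = new Blob([lines.join("\\n")], {{type: "text/csv"}});
  var a = document.createElement("a");
  a.href = URL.createObjectURL(blob);
  a.download = name + ".csv";
  a.click();
}}
</script>
</body>
</html>
"""

_SECTION_TEMPLATE = """<h2>{title}</h2>
<input class="filter" type="search" placeholder="search / filter rows"
 oninput="filterTable(this, '{table_id}')">
<button class="export" onclick="exportCsv('{table_id}', '{slug}')">Export CSV</button>
{table}
"""


def _slugify(title: str) -> str:
    return re.sub(r"[^a-z0-9]+", "_", title.lower()).strip("_")


@dataclass
class ReportBundle:
    """Ordered named tables plus run metadata."""

    title: str
    sections: list[tuple[str, pd.DataFrame]] = field(default_factory=list)
    metadata: Mapping[str, str] = field(default_factory=dict)
    include_timestamp: bool = False

    def add(self, title: str, table: pd.DataFrame) -> "ReportBundle":
        self.sections.append((title, table))
        return self


def render_report(
    bundle: ReportBundle, fmt: str, out: str | Path
) -> list[Path]:
    """Render a bundle to ``html`` (one page) or ``csv``/``tsv`` (one file
    per section under the ``out`` directory).  Returns the paths written."""
    if fmt == "html":
        out = Path(out)
        out.write_text(_render_html(bundle))
        return [out]
    if fmt in ("csv", "tsv"):
        sep = "," if fmt == "csv" else "\t"
        outdir = Path(out)
        outdir.mkdir(parents=True, exist_ok=True)
        written = []
        for title, table in bundle.sections:
            path = outdir / f"{_slugify(title)}.{fmt}"
            table.to_csv(
                path, sep=sep, index=False, quoting=csv.QUOTE_MINIMAL, encoding="utf-8"
            )
            written.append(path)
        return written
    raise ValueError(f"unknown report format {fmt!r}")


def _render_html(bundle: ReportBundle) -> str:
    meta_items = dict(bundle.metadata)
    if bundle.include_timestamp:
        meta_items["generated"] = datetime.now(timezone.utc).isoformat()
    metadata = " | ".join(
        f"{html.escape(k)}: {html.escape(str(v))}" for k, v in meta_items.items()
    )
    sections = []
    for i, (title, table) in enumerate(bundle.sections):
        table_id = f"tbl{i}"
        table_html = table.to_html(index=False, border=0, table_id=table_id)
        sections.append(
            _SECTION_TEMPLATE.format(
                title=html.escape(title),
                table_id=table_id,
                slug=_slugify(title),
                table=table_html,
            )
        )
    return _PAGE_TEMPLATE.format(
        title=html.escape(bundle.title),
        metadata=metadata,
        sections="\n".join(sections),
    )
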