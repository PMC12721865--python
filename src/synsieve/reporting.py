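"""Diagnostic outputs: interactive graph HTML and edge-weight histogram.

The HTML file is fully self-contained (embedded JSON data block + a small
vanilla-JS SVG renderer): nodes are neighbourhood labels with a tooltip
showing organism and kept/removed status, edges are the supra-threshold
pairs pruning acted on, labelled with their similarity to two decimals.
The histogram shows *all* non-zero pairwise scores (pre-threshold), since
its purpose is threshold tuning: it answers how the graph topology would
change if the similarity filter moved.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._log import log

__all__ = ["GraphView", "write_graph_html", "write_edge_histogram", "HISTOGRAM_BINS"]

HISTOGRAM_BINS = 20


@dataclass
class GraphView:
    """Pre-pruning neighbourhood graph plus kept/removed annotation."""

    nodes: list[tuple[str, bool, str]]  # (label, kept?, organism)
    edges: list[tuple[str, str, float]]  # (label_i, label_j, weight)
    threshold: float = 0.7


_HTML_TEMPLATE = """<!DOCTYPE html>
<html lang="en">
<head>
<meta charset="utf-8">
<title>neighbourhood similarity graph</title>
<style>
  body {{ font-family: sans-serif; margin: 1em; }}
  .kept circle {{ fill: #2b8a3e; }}
  .removed circle {{ fill: #c92a2a; }}
  circle {{ stroke: #333; stroke-width: 1px; }}
  line {{ stroke: #888; stroke-width: 2px; }}
  text.node-label {{ font-size: 11px; }}
  text.edge-label {{ font-size: 10px; fill: #555; }}
  .legend {{ margin-bottom: 0.5em; color: #333; }}
</style>
</head>
<body>
<div class="legend">Similarity threshold: <b>{threshold:.2f}</b> —
edges join pairs whose similarity exceeds it
(<span style="color:#2b8a3e">kept</span> /
<span style="color:#c92a2a">removed</span>)</div>
<svg id="graph" width="900" height="700"></svg>
<script id="graph-data" type="application/json">
{data}
</script>
<script>
(function () {{
  var data = JSON.parse(document.getElementById("graph-data").textContent);
  var svg = document.getElementById("graph");
  var W = 900, H = 700, R = Math.min(W, H) / 2 - 80;
  var pos = {{}};
  data.nodes.forEach(function (node, i) {{
    var a = 2 * Math.PI * i / data.nodes.length;
    pos[node.label] = [W / 2 + R * Math.cos(a), H / 2 + R * Math.sin(a)];
  }});
  var NS = "http://www.w3.org/2000/svg";
  function el(tag, attrs, parent) {{
    var e = document.createElementNS(NS, tag);
    for (var k in attrs) e.setAttribute(k, attrs[k]);
    (parent || svg).appendChild(e);
    return e;
  }}
  data.edges.forEach(function (edge) {{
    var p = pos[edge.source], q = pos[edge.target];
    el("line", {{x1: p[0], y1: p[1], x2: q[0], y2: q[1]}});
    var t = el("text", {{x: (p[0] + q[0]) / 2, y: (p[1] + q[1]) / 2,
                         "class": "edge-label"}});
    t.textContent = edge.weight.toFixed(2);
  }});
  data.nodes.forEach(function (node) {{
    var p = pos[node.label];
    var group = el("g", {{"class": node.kept ? "kept" : "removed"}});
    el("circle", {{cx: p[0], cy: p[1], r: 10}}, group);
    var title = document.createElementNS(NS, "title");
    title.textContent = node.label + "\\norganism: " + (node.organism || "?") +
      "\\nstatus: " + (node.kept ? "kept" : "removed");
    group.appendChild(title);
    var t = el("text", {{x: p[0] + 12, y: p[1] + 4, "class": "node-label"}}, group);
    t.textContent = node.label;
  }});
}})();
</script>
</body>
</html>
"""


def write_graph_html(view: GraphView, path: str | Path) -> Path:
    """Write the self-contained interactive graph view.

    The embedded ``#graph-data`` JSON block round-trips the node/edge data
    exactly, so downstream tooling (and the tests) can re-read it.
    """
    path = Path(path)
    data = {
        "threshold": view.threshold,
        "nodes": [
            {"label": label, "kept": kept, "organism": organism}
            for label, kept, organism in view.nodes
        ],
        "edges": [
            {"source": a, "target": b, "weight": w} for a, b, w in view.edges
        ],
    }
    try:
        path.write_text(
            _HTML_TEMPLATE.format(
                threshold=view.threshold, data=json.dumps(data, indent=1)
            ),
            encoding="utf-8",
        )
    except OSError as exc:
        raise IOError(f"cannot write graph HTML to {path}: {exc}") from exc
    return path


def read_graph_html_data(path: str | Path) -> dict:
    """Parse the JSON data block back out of a written graph HTML file."""
    text = Path(path).read_text(encoding="utf-8")
    marker = '<script id="graph-data" type="application/json">'
    start = text.index(marker) + len(marker)
    end = text.index("</script>", start)
    return json.loads(text[start:end])


def write_edge_histogram(
    weights: list[float],
    path: str | Path,
    threshold: float = 0.7,
) -> Path:
    """Histogram of all non-zero pairwise similarity scores.

    20 fixed-width bins over (0, 1], a vertical line at the active
    threshold; bin counts are also written as ``edge_histogram.csv`` next
    to the image.  An empty weight list yields an empty-axes image plus a
    logged notice rather than an error.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    path = Path(path)
    edges = np.linspace(0.0, 1.0, HISTOGRAM_BINS + 1)
    counts, _ = np.histogram(np.asarray(weights, dtype=float), bins=edges)

    fig, ax = plt.subplots(figsize=(7, 4.5))
    if weights:
        ax.bar(
            edges[:-1],
            counts,
            width=np.diff(edges),
            align="edge",
            color="#4c6ef5",
            edgecolor="white",
        )
    else:
        log(logging.INFO, "reporting", "no non-zero edge weights; histogram is empty")
    ax.axvline(threshold, color="#c92a2a", linestyle="--", label=f"threshold {threshold:.2f}")
    ax.set_xlim(0, 1)
    ax.set_xlabel("pairwise similarity")
    ax.set_ylabel("neighbourhood pairs")
    ax.legend(loc="upper left")
    fig.tight_layout()
    try:
        fig.savefig(path, dpi=120)
    except OSError as exc:
        raise IOError(f"cannot write histogram to {path}: {exc}") from exc
    finally:
        plt.close(fig)

    with open(path.with_name("edge_histogram.csv"), "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["bin_left", "bin_right", "count"])
        for left, right, count in zip(edges[:-1], edges[1:], counts):
            writer.writerow([f"{left:.2f}", f"{right:.2f}", int(count)])
    return path
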