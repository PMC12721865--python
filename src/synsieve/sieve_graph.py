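"""Sieve: score neighbourhood pairs, build the similarity graph, prune it.

The similarity between two neighbourhoods is the proportion of genes in
the smaller neighbourhood (fewer genes) that have a reciprocal best hit in
the larger one — a gene-content score in [0, 1] that stays meaningful for
short, fragmented contigs where nucleotide-level metrics break down.

Neighbourhood similarity is non-transitive: A can resemble B and B
resemble C while A and C differ.  Redundancy removal therefore operates on
a graph (nodes = neighbourhoods, edges = pairs whose similarity strictly
exceeds the user threshold) rather than on clusters.  Pruning deletes
nodes greedily until no edge remains: at each step the node with maximal
degree is removed, ties broken by larger incident-weight sum, then by
lexicographically largest label.  This guarantees the postcondition that
no surviving pair exceeds the threshold, while the max-degree heuristic
(a standard minimum-vertex-cover strategy) keeps retained diversity high.
"""

from __future__ import annotations

import csv
import itertools
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

from ._log import log
from .neighbourhood_io import (
    GENBANK_SUFFIXES,
    Neighbourhood,
    read_neighbourhood,
)
from .rbh_align import (
    DEFAULT_MAX_EVALUE,
    DEFAULT_MIN_IDENTITY,
    AlignmentEngine,
    BuiltinEngine,
    RBHPair,
    all_vs_all,
    reciprocal_best_hits,
)

__all__ = [
    "SimilarityGraph",
    "SieveReport",
    "similarity",
    "build_graph",
    "prune",
    "sieve",
    "DEFAULT_SIMILARITY_THRESHOLD",
]

DEFAULT_SIMILARITY_THRESHOLD = 0.7


@dataclass
class SimilarityGraph:
    """Threshold graph over neighbourhood labels.

    ``graph`` holds an edge (i, j) with attribute ``weight`` iff
    score(i, j) > ``threshold`` (strict: the pair *exceeds* the threshold).
    """

    graph: nx.Graph
    threshold: float


@dataclass
class SieveReport:
    kept: list[str] = field(default_factory=list)
    removed: list[tuple[str, str, int]] = field(default_factory=list)  # label, trigger, degree
    edge_weights: dict[tuple[str, str], float] = field(default_factory=dict)
    skipped: list[tuple[str, str]] = field(default_factory=list)  # unreadable inputs


def similarity(a: Neighbourhood, b: Neighbourhood, rbh: set[RBHPair]) -> float:
    """|RBH| / min(gene count of a, gene count of b), in [0, 1]."""
    if not a.genes or not b.genes:
        raise ValueError("similarity needs neighbourhoods with >= 1 gene")
    smallest = min(len(a.genes), len(b.genes))
    if len(rbh) > smallest:
        raise RuntimeError(
            f"RBH count {len(rbh)} exceeds smaller gene count {smallest} for "
            f"({a.label}, {b.label}): matching violated upstream"
        )
    return len(rbh) / smallest


def build_graph(
    labels: list[str],
    pair_scores: dict[tuple[str, str], float],
    threshold: float,
) -> SimilarityGraph:
    """All labels become nodes; pairs scoring strictly above ``threshold``
    become weighted edges."""
    if not (0 < threshold <= 1):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    g = nx.Graph()
    g.add_nodes_from(labels)
    for (i, j), score in pair_scores.items():
        if i == j:
            raise ValueError(f"self-score for {i!r}")
        if score > threshold:
            g.add_edge(i, j, weight=score)
    return SimilarityGraph(graph=g, threshold=threshold)


def prune(sim_graph: SimilarityGraph) -> SieveReport:
    """Greedy max-degree node deletion until the graph is edgeless.

    Selection key per round: (degree, incident-weight sum, label), taking
    the maximum — i.e. remaining ties fall to the lexicographically largest
    label, so the outcome is independent of input enumeration order.
    The recorded trigger neighbour is the removed node's heaviest remaining
    neighbour (ties to the smallest label).
    """
    g = sim_graph.graph.copy()
    report = SieveReport()
    while g.number_of_edges() > 0:
        victim = max(
            (node for node in g.nodes if g.degree(node) > 0),
            key=lambda n: (
                g.degree(n),
                sum(d["weight"] for _, _, d in g.edges(n, data=True)),
                n,
            ),
        )
        degree = g.degree(victim)
        trigger = min(
            g.neighbors(victim),
            key=lambda n: (-g.edges[victim, n]["weight"], n),
        )
        report.removed.append((victim, trigger, degree))
        g.remove_node(victim)
    report.kept = sorted(g.nodes)
    return report


def _read_folder(in_dir: Path) -> tuple[list[Neighbourhood], list[tuple[str, str]]]:
    neighbourhoods: list[Neighbourhood] = []
    skipped: list[tuple[str, str]] = []
    paths = sorted(
        p for p in in_dir.iterdir() if p.suffix.lower() in GENBANK_SUFFIXES
    )
    for path in paths:
        try:
            neighbourhoods.append(read_neighbourhood(path))
        except Exception as exc:
            skipped.append((path.name, str(exc)))
            log(logging.WARNING, "sieve", f"skipping unreadable {path.name}: {exc}")
    return neighbourhoods, skipped


def sieve(
    in_dir: str | Path,
    threshold: float = DEFAULT_SIMILARITY_THRESHOLD,
    max_evalue: float = DEFAULT_MAX_EVALUE,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    out_dir: str | Path = "sieve_out",
    engine: AlignmentEngine | None = None,
    write_reports: bool = True,
) -> SieveReport:
    """Run the full sieve stage on a folder of GenBank neighbourhood files.

    Surviving neighbourhoods are *copied byte-identically* to
    ``<out_dir>/kept/`` — sieve filters, it never mutates.  Alongside go
    ``sieve_report.csv``, ``edge_weights.csv`` and the diagnostic graph
    HTML / histogram from the reporting module.
    """
    in_dir, out_dir = Path(in_dir), Path(out_dir)
    neighbourhoods, skipped = _read_folder(in_dir)
    if len(neighbourhoods) < 2:
        raise ValueError(
            f"{in_dir}: need at least 2 readable neighbourhood files, "
            f"found {len(neighbourhoods)}"
        )
    by_label = {n.label: n for n in neighbourhoods}
    if len(by_label) != len(neighbourhoods):
        raise ValueError(f"{in_dir}: duplicate neighbourhood labels")

    out_dir.mkdir(parents=True, exist_ok=True)
    hits = all_vs_all(
        neighbourhoods,
        engine or BuiltinEngine(),
        max_evalue=max_evalue,
        min_identity=min_identity,
        workdir=out_dir / "alignment" if write_reports else None,
    )

    pair_scores: dict[tuple[str, str], float] = {}
    for la, lb in itertools.combinations(sorted(by_label), 2):
        rbh = reciprocal_best_hits(hits, (la, lb))
        score = similarity(by_label[la], by_label[lb], rbh)
        if score > 0:
            pair_scores[(la, lb)] = score

    sim_graph = build_graph(sorted(by_label), pair_scores, threshold)
    report = prune(sim_graph)
    report.edge_weights = dict(pair_scores)
    report.skipped = skipped

    # safety: no kept pair may exceed the threshold
    kept_set = set(report.kept)
    for (la, lb), score in pair_scores.items():
        if la in kept_set and lb in kept_set:
            assert score <= threshold, (
                f"pruning failed: kept pair ({la}, {lb}) scores {score} "
                f"> threshold {threshold}"
            )

    kept_dir = out_dir / "kept"
    kept_dir.mkdir(parents=True, exist_ok=True)
    source_paths = {
        p.stem: p for p in in_dir.iterdir() if p.suffix.lower() in GENBANK_SUFFIXES
    }
    for label in report.kept:
        shutil.copyfile(source_paths[label], kept_dir / source_paths[label].name)

    if write_reports:
        _write_reports(report, sim_graph, by_label, out_dir)
    return report


def _write_reports(
    report: SieveReport,
    sim_graph: SimilarityGraph,
    by_label: dict[str, Neighbourhood],
    out_dir: Path,
) -> None:
    from .reporting import GraphView, write_edge_histogram, write_graph_html

    with open(out_dir / "sieve_report.csv", "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["label", "outcome", "trigger_neighbour", "degree_at_removal"])
        for label in report.kept:
            writer.writerow([label, "kept", "", ""])
        for label, trigger, degree in report.removed:
            writer.writerow([label, "removed", trigger, degree])
        for name, reason in report.skipped:
            writer.writerow([name, "skipped", "", ""])

    with open(out_dir / "edge_weights.csv", "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["label_i", "label_j", "score"])
        for (la, lb), score in sorted(report.edge_weights.items()):
            writer.writerow([la, lb, f"{score:.6g}"])

    kept_set = set(report.kept)
    view = GraphView(
        nodes=[
            (label, label in kept_set, by_label[label].organism)
            for label in sorted(by_label)
        ],
        edges=[
            (la, lb, d["weight"])
            for la, lb, d in sim_graph.graph.edges(data=True)
        ],
        threshold=sim_graph.threshold,
    )
    write_graph_html(view, out_dir / "neighbourhood_graph.html")
    write_edge_histogram(
        list(report.edge_weights.values()),
        out_dir / "edge_histogram.png",
        threshold=sim_graph.threshold,
    )
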