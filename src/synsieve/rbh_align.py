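"""All-vs-all protein comparison and reciprocal-best-hit reduction.

Every gene is a protein; genes are compared all-vs-all across
neighbourhoods through a pluggable *alignment engine*:

* ``builtin`` — a deterministic Smith–Waterman aligner (BLOSUM62, BLAST-style
  gap costs open 11 / extend 1, bitscores via the Karlin–Altschul gapped
  constants for that scheme).  No external binary needed.
* ``blast`` — NCBI BLAST+ ``blastp`` via subprocess.
* ``diamond`` — DIAMOND ``blastp`` (``--very-sensitive``) via subprocess.

External engines receive one FASTA of all proteins (headers are qualified
``label::gene_id`` ids) and must produce tabular output with fields
qseqid, sseqid, pident, evalue, bitscore; both files are retained for
audit when a work directory is supplied.

A reciprocal best hit (RBH) between neighbourhoods A and B is a gene pair
(a, b) where b is a's best-scoring match in B and a is b's best-scoring
match in A.  Ties break by bitscore, then percent identity, then
lexicographically smallest subject id, making the matching deterministic.
"""

from __future__ import annotations

import math
import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Protocol, Sequence

from Bio.Align import PairwiseAligner, substitution_matrices

from .neighbourhood_io import Neighbourhood

__all__ = [
    "AlignmentHit",
    "RBHPair",
    "EngineError",
    "AlignmentEngine",
    "BuiltinEngine",
    "BlastEngine",
    "DiamondEngine",
    "make_engine",
    "qualified_id",
    "split_qualified_id",
    "all_vs_all",
    "best_hits",
    "reciprocal_best_hits",
    "DEFAULT_MAX_EVALUE",
    "DEFAULT_MIN_IDENTITY",
]

DEFAULT_MAX_EVALUE = 1e-5
DEFAULT_MIN_IDENTITY = 50.0

# Karlin-Altschul gapped constants for BLOSUM62 with gap open 11 / extend 1.
_KA_LAMBDA = 0.267
_KA_K = 0.041

_ID_SEP = "::"


class EngineError(RuntimeError):
    """An alignment-engine invocation failed; carries the engine diagnostic."""


@dataclass(frozen=True)
class AlignmentHit:
    """A directed, scored protein-vs-protein comparison."""

    query_id: str
    subject_id: str
    bitscore: float
    percent_identity: float
    evalue: float


@dataclass(frozen=True, order=True)
class RBHPair:
    """A mutual-best-hit gene pair; ``gene_a`` belongs to the neighbourhood
    whose label sorts lexicographically before ``gene_b``'s."""

    gene_a: str
    gene_b: str


def qualified_id(label: str, gene_id: str) -> str:
    return f"{label}{_ID_SEP}{gene_id}"


def split_qualified_id(qid: str) -> tuple[str, str]:
    label, _, gene = qid.partition(_ID_SEP)
    return label, gene


class AlignmentEngine(Protocol):
    """Contract: given qualified-id -> protein sequence, return every
    pairwise hit (self-hits allowed; filtered downstream)."""

    def run(
        self, proteins: dict[str, str], workdir: Path | None = None
    ) -> list[AlignmentHit]: ...


def _write_fasta(proteins: dict[str, str], path: Path) -> None:
    with open(path, "w", encoding="ascii") as handle:
        for qid in sorted(proteins):
            handle.write(f">{qid}\n{proteins[qid]}\n")


def _parse_tabular(path: Path) -> list[AlignmentHit]:
    hits = []
    for line in path.read_text().splitlines():
        if not line.strip():
            continue
        q, s, pident, evalue, bits = line.split("\t")[:5]
        hits.append(
            AlignmentHit(
                query_id=q,
                subject_id=s,
                bitscore=float(bits),
                percent_identity=float(pident),
                evalue=float(evalue),
            )
        )
    return hits


class BuiltinEngine:
    """Deterministic Smith-Waterman all-vs-all aligner.

    E-values follow E = K * m * n * exp(-lambda * S) with n the concatenated
    subject-set size (total residues over all proteins), mirroring a
    database search against the whole protein set.
    """

    def __init__(self) -> None:
        self._aligner = PairwiseAligner(
            mode="local",
            substitution_matrix=substitution_matrices.load("BLOSUM62"),
            # BLAST "open 11 / extend 1": a length-k gap costs 11 + k
            open_gap_score=-12,
            extend_gap_score=-1,
        )

    def _align(self, a: str, b: str) -> tuple[float, float]:
        """Return (raw score, percent identity over alignment columns)."""
        result = self._aligner.align(a, b)
        if result.score <= 0:
            return 0.0, 0.0
        best = result[0]
        counts = best.counts()
        pident = 100.0 * counts.identities / best.length if best.length else 0.0
        return float(result.score), pident

    def run(
        self, proteins: dict[str, str], workdir: Path | None = None
    ) -> list[AlignmentHit]:
        database_size = sum(len(s) for s in proteins.values())
        qids = sorted(proteins)
        hits: list[AlignmentHit] = []
        for i, qa in enumerate(qids):
            for qb in qids[i:]:
                raw, pident = self._align(proteins[qa], proteins[qb])
                if raw <= 0:
                    continue
                bits = (_KA_LAMBDA * raw - math.log(_KA_K)) / math.log(2)
                for query, subject in ((qa, qb), (qb, qa)) if qa != qb else ((qa, qb),):
                    evalue = len(proteins[query]) * database_size * 2.0**-bits
                    hits.append(
                        AlignmentHit(
                            query_id=query,
                            subject_id=subject,
                            bitscore=round(bits, 1),
                            percent_identity=round(pident, 3),
                            evalue=evalue,
                        )
                    )
        if workdir is not None:
            workdir.mkdir(parents=True, exist_ok=True)
            _write_fasta(proteins, workdir / "proteins.faa")
            with open(workdir / "hits.tsv", "w", encoding="ascii") as handle:
                for h in hits:
                    handle.write(
                        f"{h.query_id}\t{h.subject_id}\t{h.percent_identity}"
                        f"\t{h.evalue:.3g}\t{h.bitscore}\n"
                    )
        return hits


class _SubprocessEngine:
    """Shared FASTA-in / tabular-out plumbing for external aligners."""

    def _commands(self, fasta: Path, out: Path, tmp: Path) -> list[list[str]]:
        raise NotImplementedError

    def run(
        self, proteins: dict[str, str], workdir: Path | None = None
    ) -> list[AlignmentHit]:
        ctx = tempfile.TemporaryDirectory() if workdir is None else None
        base = Path(ctx.name) if ctx else workdir
        base.mkdir(parents=True, exist_ok=True)
        try:
            fasta = base / "proteins.faa"
            out = base / "hits.tsv"
            _write_fasta(proteins, fasta)
            for cmd in self._commands(fasta, out, base):
                proc = subprocess.run(cmd, capture_output=True, text=True)
                if proc.returncode != 0:
                    raise EngineError(
                        f"{cmd[0]} failed (exit {proc.returncode}): {proc.stderr.strip()}"
                    )
            return _parse_tabular(out)
        finally:
            if ctx:
                ctx.cleanup()


class BlastEngine(_SubprocessEngine):
    """NCBI BLAST+ blastp, one best HSP per protein pair."""

    def __init__(self, threads: int = 1):
        self.threads = threads
        if shutil.which("blastp") is None or shutil.which("makeblastdb") is None:
            raise EngineError("BLAST+ (blastp/makeblastdb) not found on PATH")

    def _commands(self, fasta: Path, out: Path, tmp: Path) -> list[list[str]]:
        db = tmp / "db"
        return [
            ["makeblastdb", "-in", str(fasta), "-dbtype", "prot", "-out", str(db)],
            [
                "blastp",
                "-query", str(fasta),
                "-db", str(db),
                "-outfmt", "6 qseqid sseqid pident evalue bitscore",
                "-max_hsps", "1",
                "-evalue", "10",
                "-num_threads", str(self.threads),
                "-out", str(out),
            ],
        ]


class DiamondEngine(_SubprocessEngine):
    """DIAMOND blastp in very-sensitive mode, one best HSP per pair."""

    def __init__(self, threads: int = 1):
        self.threads = threads
        if shutil.which("diamond") is None:
            raise EngineError("diamond not found on PATH")

    def _commands(self, fasta: Path, out: Path, tmp: Path) -> list[list[str]]:
        db = tmp / "db"
        return [
            ["diamond", "makedb", "--in", str(fasta), "-d", str(db), "--quiet"],
            [
                "diamond", "blastp",
                "-q", str(fasta),
                "-d", str(db),
                "--very-sensitive",
                "--max-hsps", "1",
                "-k", "0",
                "-e", "10",
                "-p", str(self.threads),
                "-f", "6", "qseqid", "sseqid", "pident", "evalue", "bitscore",
                "-o", str(out),
                "--quiet",
            ],
        ]


def make_engine(name: str) -> AlignmentEngine:
    """Resolve an engine by name: ``builtin``, ``blast`` or ``diamond``."""
    if name == "builtin":
        return BuiltinEngine()
    if name == "blast":
        return BlastEngine()
    if name == "diamond":
        return DiamondEngine()
    raise ValueError(f"unknown alignment engine {name!r}")


def all_vs_all(
    neighbourhoods: Sequence[Neighbourhood],
    engine: AlignmentEngine,
    max_evalue: float = DEFAULT_MAX_EVALUE,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    workdir: Path | None = None,
) -> list[AlignmentHit]:
    """Compare every protein against every protein in *other* neighbourhoods.

    Hits are filtered to evalue <= ``max_evalue`` and percent identity >=
    ``min_identity``; within-neighbourhood comparisons are excluded; output
    order is deterministic (sorted by query then subject id).
    """
    if len(neighbourhoods) < 2:
        raise ValueError("all_vs_all needs at least 2 neighbourhoods")
    proteins: dict[str, str] = {}
    label_of: dict[str, str] = {}
    for n in neighbourhoods:
        if not n.genes:
            raise ValueError(f"neighbourhood {n.label!r} has no genes")
        for g in n.genes:
            qid = qualified_id(n.label, g.gene_id)
            proteins[qid] = g.translation
            label_of[qid] = n.label
    raw = engine.run(proteins, workdir=workdir)
    kept = [
        h
        for h in raw
        if label_of.get(h.query_id) is not None
        and label_of.get(h.subject_id) is not None
        and label_of[h.query_id] != label_of[h.subject_id]
        and h.evalue <= max_evalue
        and h.percent_identity >= min_identity
    ]
    return sorted(kept, key=lambda h: (h.query_id, h.subject_id))


def best_hits(
    hits: Iterable[AlignmentHit], direction: tuple[str, str]
) -> dict[str, str]:
    """Per gene of neighbourhood A, its best-scoring subject in B.

    Ties break by higher bitscore, then higher identity, then
    lexicographically smallest subject id.  Genes with no passing hit are
    absent from the map.
    """
    label_a, label_b = direction
    best: dict[str, AlignmentHit] = {}
    for h in hits:
        if split_qualified_id(h.query_id)[0] != label_a:
            continue
        if split_qualified_id(h.subject_id)[0] != label_b:
            continue
        cur = best.get(h.query_id)
        if cur is None or _better(h, cur):
            best[h.query_id] = h
    return {q: h.subject_id for q, h in best.items()}


def _better(candidate: AlignmentHit, incumbent: AlignmentHit) -> bool:
    # bitscore, then identity, then lexicographically smallest subject id
    a = (candidate.bitscore, candidate.percent_identity)
    b = (incumbent.bitscore, incumbent.percent_identity)
    if a != b:
        return a > b
    return candidate.subject_id < incumbent.subject_id


def reciprocal_best_hits(
    hits: Iterable[AlignmentHit], pair: tuple[str, str]
) -> set[RBHPair]:
    """RBH set for an unordered neighbourhood pair.

    ``RBHPair(a, b)`` exists iff a's best hit in B is b and b's best hit in
    A is a; by construction no gene appears in more than one pair (it is a
    partial matching).
    """
    label_a, label_b = sorted(pair)
    hits = list(hits)
    a_to_b = best_hits(hits, (label_a, label_b))
    b_to_a = best_hits(hits, (label_b, label_a))
    return {
        RBHPair(gene_a=a, gene_b=b)
        for a, b in a_to_b.items()
        if b_to_a.get(b) == a
    }
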