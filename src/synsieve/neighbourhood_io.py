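"""GenBank neighbourhood I/O and filesystem-safe naming.

A *neighbourhood* is a contiguous genomic interval carrying an ordered set
of protein-coding genes.  All internal coordinates are 0-based half-open;
the 1-based inclusive GenBank convention is converted only at the I/O
boundary (which Biopython's feature locations already do for us).  Only CDS
features participate: the downstream similarity metric compares proteins,
so RNA genes and other feature types are ignored.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from ._log import log

__all__ = [
    "ProteinGene",
    "Neighbourhood",
    "NeighbourhoodFormatError",
    "EmptyNeighbourhoodError",
    "InvalidNameError",
    "read_neighbourhood",
    "write_neighbourhood",
    "sanitize_label",
    "GENBANK_SUFFIXES",
]

GENBANK_SUFFIXES = (".gbk", ".gb", ".gbff")


class NeighbourhoodFormatError(ValueError):
    """The file could not be parsed as a single-record GenBank flat file."""


class EmptyNeighbourhoodError(ValueError):
    """The record carries no usable CDS feature, so it cannot be scored."""


class InvalidNameError(ValueError):
    """A raw name sanitized to the empty string."""


@dataclass(frozen=True)
class ProteinGene:
    """One protein-coding gene within a neighbourhood.

    ``locus_start``/``locus_end`` are 0-based half-open offsets on the
    neighbourhood sequence; ``strand`` is +1 or -1; ``translation`` is the
    amino-acid sequence without a trailing stop symbol.
    """

    gene_id: str
    locus_start: int
    locus_end: int
    strand: int
    translation: str

    def __post_init__(self) -> None:
        if not self.locus_start < self.locus_end:
            raise ValueError(
                f"gene {self.gene_id!r}: locus_start must be < locus_end "
                f"({self.locus_start}, {self.locus_end})"
            )
        if self.strand not in (1, -1):
            raise ValueError(f"gene {self.gene_id!r}: strand must be +1 or -1")
        if len(self.translation) < 1:
            raise ValueError(f"gene {self.gene_id!r}: empty translation")


@dataclass
class Neighbourhood:
    """An annotated genomic interval with its ordered protein genes.

    ``contig_offset`` is the 0-based start of this interval on the source
    record; ``label`` is the file stem used for naming and as the graph node
    identifier.
    """

    source_accession: str
    organism: str
    contig_offset: int
    sequence: str
    genes: list[ProteinGene] = field(default_factory=list)
    label: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise ValueError(f"duplicate gene_id {g.gene_id!r} in {self.label!r}")
            seen.add(g.gene_id)
            if not (0 <= g.locus_start and g.locus_end <= len(self.sequence)):
                raise ValueError(
                    f"gene {g.gene_id!r} interval ({g.locus_start}, {g.locus_end}) "
                    f"outside sequence of length {len(self.sequence)}"
                )
        self.genes = sorted(
            self.genes, key=lambda g: (g.locus_start, g.locus_end, g.gene_id)
        )


def _gene_id_for(feature: SeqFeature, ordinal: int) -> str:
    for key in ("protein_id", "locus_tag"):
        values = feature.qualifiers.get(key)
        if values and values[0].strip():
            return values[0].strip()
    return f"cds_{ordinal}"


def _translation_for(
    feature: SeqFeature, record: SeqRecord, gene_id: str, path: Path
) -> str | None:
    values = feature.qualifiers.get("translation")
    if values and values[0].strip():
        return values[0].strip().upper().rstrip("*")
    span = feature.extract(record.seq)
    if len(span) % 3 != 0:
        log(
            logging.WARNING,
            "read_neighbourhood",
            f"{path.name}: CDS {gene_id} has no translation and span length "
            f"{len(span)} is not a multiple of 3; skipped",
        )
        return None
    aa = str(Seq(span).translate(table=11)).rstrip("*")
    return aa.upper() if aa else None


def read_neighbourhood(path: str | Path) -> Neighbourhood:
    """Parse a single-record GenBank file into a :class:`Neighbourhood`.

    One :class:`ProteinGene` is produced per CDS feature.  A CDS without a
    ``/translation`` qualifier is translated from its nucleotide span with
    translation table 11 when the span length is a multiple of 3, otherwise
    it is skipped with a warning.  Compound (joined) locations keep their
    outermost span as coordinates but are translated from the joined exons.
    """
    path = Path(path)
    try:
        record = SeqIO.read(str(path), "genbank")
    except Exception as exc:  # biopython raises bare ValueError on bad files
        raise NeighbourhoodFormatError(f"cannot parse GenBank file {path}: {exc}") from exc

    genes: list[ProteinGene] = []
    used_ids: set[str] = set()
    for ordinal, feature in enumerate(
        (f for f in record.features if f.type == "CDS"), start=1
    ):
        gene_id = _gene_id_for(feature, ordinal)
        if gene_id in used_ids:
            gene_id = f"{gene_id}_{ordinal}"
        translation = _translation_for(feature, record, gene_id, path)
        if translation is None:
            continue
        strand = feature.location.strand
        genes.append(
            ProteinGene(
                gene_id=gene_id,
                locus_start=int(feature.location.start),
                locus_end=int(feature.location.end),
                strand=1 if strand in (1, None) else -1,
                translation=translation,
            )
        )
        used_ids.add(gene_id)

    if not genes:
        raise EmptyNeighbourhoodError(
            f"{path}: no CDS features with usable translations; "
            "the neighbourhood cannot be scored"
        )

    organism = record.annotations.get("organism", "") or ""
    return Neighbourhood(
        source_accession=record.id,
        organism=organism,
        contig_offset=0,
        sequence=str(record.seq),
        genes=genes,
        label=path.stem,
    )


def neighbourhood_to_record(n: Neighbourhood) -> SeqRecord:
    """Render a neighbourhood as a Biopython SeqRecord (single GenBank record)."""
    name = re.sub(r"[^A-Za-z0-9_]", "_", (n.label or n.source_accession))[:16] or "REGION"
    record = SeqRecord(
        Seq(n.sequence),
        id=n.source_accession or n.label or "unknown",
        name=name,
        description=f"genomic neighbourhood {n.label}".strip(),
    )
    record.annotations["molecule_type"] = "DNA"
    record.annotations["organism"] = n.organism
    record.annotations["source"] = n.organism
    record.annotations["date"] = "01-JAN-1980"  # fixed: output must be deterministic
    for g in n.genes:
        record.features.append(
            SeqFeature(
                SimpleLocation(g.locus_start, g.locus_end, strand=g.strand),
                type="CDS",
                qualifiers={"protein_id": [g.gene_id], "translation": [g.translation]},
            )
        )
    return record


def write_neighbourhood(n: Neighbourhood, directory: str | Path) -> Path:
    """Write ``n`` as ``<directory>/<label>.gbk``; suffix ``_1``, ``_2``, … on
    label collision.  The written file round-trips through
    :func:`read_neighbourhood` with identical gene tables."""
    directory = Path(directory)
    if not directory.is_dir():
        raise IOError(f"not a writable directory: {directory}")
    label = n.label or sanitize_label(n.source_accession)
    target = directory / f"{label}.gbk"
    suffix = 0
    while target.exists():
        suffix += 1
        target = directory / f"{label}_{suffix}.gbk"
    if suffix:
        log(
            logging.INFO,
            "write_neighbourhood",
            f"label collision for {label!r}; writing {target.name}",
        )
    record = neighbourhood_to_record(n)
    try:
        with open(target, "w", encoding="ascii") as handle:
            SeqIO.write(record, handle, "genbank")
    except OSError as exc:
        raise IOError(f"cannot write to directory {directory}: {exc}") from exc
    return target


_UNSAFE = re.compile(r"[^A-Za-z0-9._-]")


def sanitize_label(raw: str) -> str:
    """Make a filesystem-safe label: unsafe characters become ``_``, runs of
    ``_`` collapse, leading/trailing ``_`` are stripped.  Idempotent."""
    if not raw:
        raise InvalidNameError("empty name")
    out = _UNSAFE.sub("_", raw)
    out = re.sub(r"_+", "_", out).strip("_")
    if not out:
        raise InvalidNameError(f"name {raw!r} sanitizes to an empty string")
    return out
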