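"""Collect: turn a cblaster binary hit table into centred, fixed-length
genomic neighbourhood files.

Each row of the hit table names a scaffold and the interval its clustered
homolog hits span.  A neighbourhood of user-defined length is centred on
that interval, quality-filtered (hits dispersed beyond the requested length
are rejected; spans overhanging the contig end are rejected in strict mode,
otherwise clamped provided the hit interval stays covered), sliced out of
the fetched source record, and written as a named GenBank file.

The record fetcher is an injected contract so the pipeline is testable
without network access: :class:`EntrezFetcher` talks to NCBI, while
:class:`FixtureFetcher` resolves accessions from a local folder of GenBank
files.
"""

from __future__ import annotations

import csv
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Protocol

from Bio import SeqIO
from Bio.SeqRecord import SeqRecord

from ._log import log
from .neighbourhood_io import sanitize_label

__all__ = [
    "HitRecord",
    "Span",
    "CollectReport",
    "MalformedTableError",
    "FetchError",
    "RecordFetcher",
    "EntrezFetcher",
    "FixtureFetcher",
    "parse_binary",
    "compute_span",
    "fetch_record",
    "collect",
]


class MalformedTableError(ValueError):
    """The hit table does not have the expected positional columns."""


class FetchError(Exception):
    """A typed record-fetch failure; never fatal to a batch.

    ``kind`` is one of ``not-found``, ``network-failure``, ``malformed-record``.
    """

    def __init__(self, kind: str, message: str):
        super().__init__(message)
        self.kind = kind


@dataclass(frozen=True)
class HitRecord:
    """One hit-table row; the interval is 0-based half-open internally
    (converted from the table's 1-based inclusive printing)."""

    organism: str
    scaffold_accession: str
    hit_start: int
    hit_end: int
    score: float
    query_counts: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if not self.scaffold_accession:
            raise ValueError("empty scaffold accession")
        if not self.hit_start < self.hit_end:
            raise ValueError(
                f"{self.scaffold_accession}: hit_start must be < hit_end "
                f"({self.hit_start}, {self.hit_end})"
            )


@dataclass(frozen=True)
class Span:
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid span ({self.start}, {self.end})")


@dataclass(frozen=True)
class Rejection:
    """Typed span rejection: ``reason`` is ``dispersed`` or ``small``."""

    reason: str


@dataclass
class CollectReport:
    written: list[tuple[str, Path]] = field(default_factory=list)
    rejected_dispersed: list[str] = field(default_factory=list)
    rejected_small: list[str] = field(default_factory=list)
    fetch_failures: list[tuple[str, str]] = field(default_factory=list)

    @property
    def total(self) -> int:
        return (
            len(self.written)
            + len(self.rejected_dispersed)
            + len(self.rejected_small)
            + len(self.fetch_failures)
        )


def parse_binary(path: str | Path) -> list[HitRecord]:
    """Parse a cblaster "binary" hit table (CSV or TSV, header row).

    Columns are mapped by position — organism, scaffold, start, end, score,
    then one count per query — because header wording varies between
    cblaster versions.  The delimiter is tab if the header contains any tab,
    else comma.  Printed intervals are 1-based inclusive and converted to
    0-based half-open.
    """
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as handle:
        header = handle.readline()
        if not header.strip():
            raise MalformedTableError(f"{path}: empty table")
        delimiter = "\t" if "\t" in header else ","
        reader = csv.reader(handle, delimiter=delimiter)
        hits: list[HitRecord] = []
        for row_number, row in enumerate(reader, start=2):
            if not any(cell.strip() for cell in row):
                continue
            if len(row) < 5:
                raise MalformedTableError(
                    f"{path}: row {row_number} has {len(row)} columns; "
                    "expected at least 5 (organism, scaffold, start, end, score)"
                )
            organism, scaffold = row[0].strip(), row[1].strip()
            try:
                start_1based = int(float(row[2]))
                end_1based = int(float(row[3]))
                score = float(row[4])
            except ValueError as exc:
                raise MalformedTableError(
                    f"{path}: row {row_number}: non-numeric start/end/score"
                ) from exc
            counts = tuple(int(float(c)) for c in row[5:] if c.strip() != "")
            hits.append(
                HitRecord(
                    organism=organism,
                    scaffold_accession=scaffold,
                    hit_start=start_1based - 1,
                    hit_end=end_1based,
                    score=score,
                    query_counts=counts,
                )
            )
    return hits


def compute_span(
    hit: HitRecord,
    neighbourhood_len: int,
    contig_len: int,
    strict: bool = False,
) -> Span | Rejection:
    """Centre a fixed-length span on the hit interval, or reject it.

    Rejections: ``dispersed`` when the hit interval itself is longer than
    the requested span (the homolog hits are not clustered tightly enough);
    ``small`` when the centred span overhangs the contig and either strict
    mode is on or clamping would clip the hit interval (fragmented contig).
    Even lengths use floor() for both midpoint and half-length.
    """
    if neighbourhood_len < 1:
        raise ValueError("neighbourhood_len must be >= 1")
    if hit.hit_end - hit.hit_start > neighbourhood_len:
        return Rejection("dispersed")
    mid = (hit.hit_start + hit.hit_end) // 2
    raw_start = mid - neighbourhood_len // 2
    raw_end = raw_start + neighbourhood_len
    if raw_start >= 0 and raw_end <= contig_len:
        return Span(raw_start, raw_end)
    if strict:
        return Rejection("small")
    clamped_start = max(0, raw_start)
    clamped_end = min(contig_len, raw_end)
    if clamped_start <= hit.hit_start and clamped_end >= hit.hit_end:
        return Span(clamped_start, clamped_end)
    return Rejection("small")


class RecordFetcher(Protocol):
    """Contract: resolve an accession to a full GenBank record, or raise
    :class:`FetchError`."""

    def __call__(self, accession: str) -> SeqRecord: ...


def _check_locus_length(record: SeqRecord, declared: int | None, accession: str) -> None:
    if declared is not None and declared != len(record.seq):
        raise FetchError(
            "malformed-record",
            f"{accession}: LOCUS declares {declared} bp but sequence has "
            f"{len(record.seq)} bp",
        )


def _declared_length(genbank_text: str) -> int | None:
    first = genbank_text.lstrip().splitlines()[0] if genbank_text.strip() else ""
    if first.startswith("LOCUS"):
        parts = first.split()
        for i, token in enumerate(parts):
            if token == "bp" and i > 0 and parts[i - 1].isdigit():
                return int(parts[i - 1])
    return None


class FixtureFetcher:
    """Resolve accessions from a local directory of ``<accession>.gbk`` files."""

    def __init__(self, directory: str | Path):
        self.directory = Path(directory)

    def __call__(self, accession: str) -> SeqRecord:
        for suffix in (".gbk", ".gb", ".gbff"):
            candidate = self.directory / f"{accession}{suffix}"
            if candidate.exists():
                text = candidate.read_text(encoding="utf-8")
                try:
                    record = SeqIO.read(str(candidate), "genbank")
                except Exception as exc:
                    raise FetchError(
                        "malformed-record", f"{accession}: {exc}"
                    ) from exc
                _check_locus_length(record, _declared_length(text), accession)
                return record
        raise FetchError("not-found", f"{accession}: no fixture file in {self.directory}")


class EntrezFetcher:
    """Fetch full GenBank records from NCBI Entrez (efetch, rettype
    ``gbwithparts``), with up to 3 retries and exponential backoff."""

    def __init__(self, email: str, api_key: str | None = None, retries: int = 3):
        if not email:
            raise ValueError("NCBI requires a contact e-mail address")
        self.email = email
        self.api_key = api_key
        self.retries = retries

    def __call__(self, accession: str) -> SeqRecord:
        from Bio import Entrez

        Entrez.email = self.email
        if self.api_key:
            Entrez.api_key = self.api_key
        last_error: Exception | None = None
        for attempt in range(self.retries):
            try:
                with Entrez.efetch(
                    db="nuccore",
                    id=accession,
                    rettype="gbwithparts",
                    retmode="text",
                ) as handle:
                    text = handle.read()
                if "LOCUS" not in text:
                    raise FetchError("not-found", f"{accession}: no record returned")
                import io

                record = SeqIO.read(io.StringIO(text), "genbank")
                _check_locus_length(record, _declared_length(text), accession)
                return record
            except FetchError:
                raise
            except Exception as exc:  # network hiccups: retry with backoff
                last_error = exc
                time.sleep(2**attempt)
        raise FetchError("network-failure", f"{accession}: {last_error}")


def fetch_record(accession: str, fetcher: RecordFetcher) -> SeqRecord:
    """Resolve ``accession`` through the fetcher contract (passthrough)."""
    return fetcher(accession)


def _slice_record(
    record: SeqRecord, span: Span, accession: str
) -> tuple[SeqRecord, list[str]]:
    """Slice the record to the span; CDS fully inside are kept with shifted
    coordinates, straddlers are dropped and reported."""
    dropped = [
        (feat.qualifiers.get("protein_id", feat.qualifiers.get("locus_tag", ["?"]))[0])
        for feat in record.features
        if feat.type == "CDS"
        and not (span.start <= int(feat.location.start) and int(feat.location.end) <= span.end)
        and not (int(feat.location.end) <= span.start or int(feat.location.start) >= span.end)
    ]
    sliced = record[span.start : span.end]
    sliced.annotations["molecule_type"] = record.annotations.get("molecule_type", "DNA")
    sliced.annotations["organism"] = record.annotations.get("organism", "")
    sliced.annotations["source"] = record.annotations.get("source", "")
    sliced.annotations["date"] = "01-JAN-1980"
    sliced.id = accession
    sliced.description = (
        f"{span.end - span.start} bp neighbourhood at {span.start}..{span.end} of {accession}"
    )
    return sliced, dropped


def _unique_path(directory: Path, stem: str) -> Path:
    target = directory / f"{stem}.gbk"
    i = 0
    while target.exists():
        i += 1
        target = directory / f"{stem}_{i}.gbk"
    return target


def collect(
    binary_path: str | Path,
    neighbourhood_len: int,
    naming_mode: str,
    strict: bool,
    fetcher: RecordFetcher,
    out_dir: str | Path,
) -> CollectReport:
    """Run the full collect stage: parse, filter, fetch, slice, write.

    Writes one ``.gbk`` per surviving hit into ``<out_dir>/neighbourhood/``
    and a ``collect_report.csv`` partitioning every parsed row into
    written / rejected_dispersed / rejected_small / fetch_failure.
    """
    if naming_mode not in ("accession", "organism"):
        raise ValueError(f"naming_mode must be 'accession' or 'organism', got {naming_mode!r}")
    out_dir = Path(out_dir)
    nbh_dir = out_dir / "neighbourhood"
    try:
        nbh_dir.mkdir(parents=True, exist_ok=True)
        probe = nbh_dir / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise IOError(f"output directory not writable: {out_dir}: {exc}") from exc

    hits = parse_binary(binary_path)
    report = CollectReport()
    rows: list[dict[str, str]] = []

    for row_index, hit in enumerate(hits, start=1):
        accession = hit.scaffold_accession
        row = {
            "row_index": str(row_index),
            "accession": accession,
            "organism": hit.organism,
            "outcome": "",
            "detail": "",
        }
        # the dispersed filter needs no record; skip the fetch entirely
        if hit.hit_end - hit.hit_start > neighbourhood_len:
            report.rejected_dispersed.append(accession)
            row.update(outcome="rejected_dispersed")
            rows.append(row)
            log(logging.INFO, "collect", f"{accession}: rejected (dispersed)")
            continue
        try:
            record = fetch_record(accession, fetcher)
        except FetchError as exc:
            report.fetch_failures.append((accession, exc.kind))
            row.update(outcome="fetch_failure", detail=exc.kind)
            rows.append(row)
            log(logging.WARNING, "collect", f"{accession}: fetch failed ({exc.kind}): {exc}")
            continue
        result = compute_span(hit, neighbourhood_len, len(record.seq), strict=strict)
        if isinstance(result, Rejection):
            if result.reason == "dispersed":
                report.rejected_dispersed.append(accession)
            else:
                report.rejected_small.append(accession)
            row.update(outcome=f"rejected_{result.reason}")
            rows.append(row)
            log(logging.INFO, "collect", f"{accession}: rejected ({result.reason})")
            continue
        sliced, dropped = _slice_record(record, result, accession)
        for gene in dropped:
            log(
                logging.INFO,
                "collect",
                f"{accession}: gene {gene} straddles span boundary; dropped",
            )
        raw_name = accession if naming_mode == "accession" else (hit.organism or accession)
        target = _unique_path(nbh_dir, sanitize_label(raw_name))
        with open(target, "w", encoding="ascii") as handle:
            SeqIO.write(sliced, handle, "genbank")
        report.written.append((accession, target))
        row.update(outcome="written", detail=target.name)
        rows.append(row)

    with open(out_dir / "collect_report.csv", "w", newline="", encoding="utf-8") as handle:
        writer = csv.DictWriter(
            handle, fieldnames=["row_index", "accession", "organism", "outcome", "detail"]
        )
        writer.writeheader()
        writer.writerows(rows)

    assert report.total == len(hits), "collect report must partition all parsed rows"
    return report
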