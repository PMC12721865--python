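"""Synthetic neighbourhood sets with controlled homology structure.

Neighbourhoods are built from *protein families*: random ancestral
proteins that each planned neighbourhood carries as an independently
mutated copy.  Because best hits are unambiguous at low divergence, the
expected reciprocal-best-hit count for a pair of neighbourhoods is simply
the number of families they share, and the expected similarity score is
shared / min(gene count) — both recorded in a manifest so every pipeline
stage can be checked against known ground truth without any downloads.

Nucleotide sequences are back-translated codon-wise with a fixed codon per
residue (the lexicographically first table-11 codon), genes laid
head-to-tail with 50 nt "A" spacers, so regenerating a folder under the
same seed is byte-identical.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Data import CodonTable

from .neighbourhood_io import Neighbourhood, ProteinGene, write_neighbourhood

__all__ = [
    "FamilySpec",
    "generate_family",
    "mutate",
    "build_neighbourhood_set",
    "default_family_spec",
    "build_collect_fixture",
    "AMINO_ACIDS",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

SPACER_LEN = 50
MIN_FAMILY_LENGTH = 30  # shorter proteins give unstable local alignments

# residue -> lexicographically first table-11 codon
_TABLE11 = CodonTable.unambiguous_dna_by_id[11].forward_table
_CODON_FOR: dict[str, str] = {}
for codon in sorted(_TABLE11):
    _CODON_FOR.setdefault(_TABLE11[codon], codon)
_STOP_CODON = "TAA"


@dataclass
class FamilySpec:
    """Plan for a synthetic neighbourhood set.

    ``neighbourhood_plan`` maps each neighbourhood label to its ordered
    gene list; a gene is a family index or a (family index, strand) pair.
    Each neighbourhood carries an independently mutated copy of every
    family it lists, mutated at ``substitution_rate`` per residue.
    """

    n_families: int
    family_length: int
    neighbourhood_plan: dict[str, list[int | tuple[int, int]]]
    substitution_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.substitution_rate < 1):
            raise ValueError("substitution_rate must be in [0, 1)")
        for label, plan in self.neighbourhood_plan.items():
            for entry in plan:
                fam = entry[0] if isinstance(entry, tuple) else entry
                if not (0 <= fam < self.n_families):
                    raise ValueError(
                        f"{label}: family index {fam} out of range "
                        f"[0, {self.n_families})"
                    )


def generate_family(length: int, rng: np.random.Generator) -> str:
    """Uniform-random protein over the 20 standard residues."""
    if length < MIN_FAMILY_LENGTH:
        raise ValueError(
            f"family length must be >= {MIN_FAMILY_LENGTH}, got {length}"
        )
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Replace each residue independently with probability ``rate`` by a
    uniformly chosen *different* residue; expected identity 100*(1-rate)%."""
    if not (0 <= rate < 1):
        raise ValueError("rate must be in [0, 1)")
    out = list(seq)
    flips = rng.random(len(seq)) < rate
    for i in np.flatnonzero(flips):
        alternatives = AMINO_ACIDS.replace(out[i], "")
        out[i] = alternatives[rng.integers(len(alternatives))]
    return "".join(out)


def back_translate(protein: str) -> str:
    """Deterministic codon-wise back-translation plus a TAA stop."""
    return "".join(_CODON_FOR[aa] for aa in protein) + _STOP_CODON


def _expected_pairs(
    spec: FamilySpec,
) -> list[dict]:
    labels = list(spec.neighbourhood_plan)
    pairs = []
    for i, la in enumerate(labels):
        for lb in labels[i + 1 :]:
            a, b = sorted((la, lb))
            fams_a = {e[0] if isinstance(e, tuple) else e for e in spec.neighbourhood_plan[a]}
            fams_b = {e[0] if isinstance(e, tuple) else e for e in spec.neighbourhood_plan[b]}
            shared = len(fams_a & fams_b)
            smallest = min(
                len(spec.neighbourhood_plan[a]), len(spec.neighbourhood_plan[b])
            )
            pairs.append(
                {
                    "pair": [a, b],
                    "expected_rbh": shared,
                    "expected_score": shared / smallest if smallest else 0.0,
                }
            )
    return pairs


def build_neighbourhood_set(spec: FamilySpec, out_dir: str | Path) -> dict:
    """Write one GenBank file per planned neighbourhood plus ``manifest.json``.

    Returns the manifest: labels, plans, and for every pair the expected
    RBH count and similarity score under the generator's construction.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    families = [generate_family(spec.family_length, rng) for _ in range(spec.n_families)]

    files: dict[str, str] = {}
    for label, plan in spec.neighbourhood_plan.items():
        genes: list[ProteinGene] = []
        chunks: list[str] = []
        cursor = 0
        for position, entry in enumerate(plan):
            fam, strand = entry if isinstance(entry, tuple) else (entry, 1)
            protein = mutate(families[fam], spec.substitution_rate, rng)
            nt = back_translate(protein)
            if strand == -1:
                from Bio.Seq import Seq

                nt = str(Seq(nt).reverse_complement())
            chunks.append("A" * SPACER_LEN)
            cursor += SPACER_LEN
            genes.append(
                ProteinGene(
                    gene_id=f"g{position}_fam{fam}",
                    locus_start=cursor,
                    locus_end=cursor + len(nt),
                    strand=strand,
                    translation=protein,
                )
            )
            chunks.append(nt)
            cursor += len(nt)
        chunks.append("A" * SPACER_LEN)
        cursor += SPACER_LEN
        if not genes:
            continue
        neighbourhood = Neighbourhood(
            source_accession=label,
            organism=f"Synthetica specimen {label}",
            contig_offset=0,
            sequence="".join(chunks),
            genes=genes,
            label=label,
        )
        path = write_neighbourhood(neighbourhood, out_dir)
        files[label] = path.name

    manifest = {
        "seed": spec.seed,
        "substitution_rate": spec.substitution_rate,
        "family_length": spec.family_length,
        "labels": list(files),
        "plans": {
            label: [list(e) if isinstance(e, tuple) else [e, 1] for e in plan]
            for label, plan in spec.neighbourhood_plan.items()
        },
        "files": files,
        "pairs": _expected_pairs(spec),
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2), encoding="utf-8"
    )
    return manifest


def default_family_spec(seed: int = 0, substitution_rate: float = 0.02) -> FamilySpec:
    """The canonical test set: three near-identical 5-gene neighbourhoods
    plus one unrelated 3-gene neighbourhood."""
    shared = [0, 1, 2, 3, 4]
    return FamilySpec(
        n_families=8,
        family_length=100,
        neighbourhood_plan={
            "copy_a": list(shared),
            "copy_b": list(shared),
            "copy_c": list(shared),
            "outsider": [5, 6, 7],
        },
        substitution_rate=substitution_rate,
        seed=seed,
    )


def build_collect_fixture(out_dir: str | Path, seed: int = 0) -> dict:
    """Build a toy collect-stage fixture: a folder of synthetic source
    records plus a cblaster-style binary table referencing them.

    The table has five rows engineered to exercise every outcome with a
    neighbourhood length of 1000 in strict mode: two good hits, one hit
    dispersed beyond the span, one hit overhanging the contig start, and
    one accession with no record.  Returns the paths and expected outcome
    per row.
    """
    out_dir = Path(out_dir)
    records_dir = out_dir / "records"
    records_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    from Bio.Seq import Seq
    from Bio.SeqFeature import SeqFeature, SimpleLocation
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    def make_record(accession: str, organism: str, gene_spans: list[tuple[int, int, int]]):
        seq = list("".join(rng.choice(list("ACGT"), size=5000)))
        features = []
        for start, end, strand in gene_spans:
            n_codons = (end - start) // 3 - 1
            protein = generate_family(max(n_codons, MIN_FAMILY_LENGTH), rng)[:n_codons]
            nt = back_translate(protein)
            if strand == -1:
                nt = str(Seq(nt).reverse_complement())
            seq[start:end] = list(nt)
            features.append(
                SeqFeature(
                    SimpleLocation(start, end, strand=strand),
                    type="CDS",
                    qualifiers={
                        "protein_id": [f"{accession}_p{start}"],
                        "translation": [protein],
                    },
                )
            )
        record = SeqRecord(
            Seq("".join(seq)),
            id=accession,
            name=accession.replace(".", "_")[:16],
            description=f"synthetic source record {accession}",
        )
        record.annotations["molecule_type"] = "DNA"
        record.annotations["organism"] = organism
        record.annotations["source"] = organism
        record.annotations["date"] = "01-JAN-1980"
        record.features = features
        with open(records_dir / f"{accession}.gbk", "w", encoding="ascii") as fh:
            SeqIO.write(record, fh, "genbank")

    # good hit: span (600,1600); gene at (590,650) straddles the boundary
    make_record(
        "SYN_OK1.1",
        "Synthetica prima",
        [(590, 650, 1), (700, 1000, 1), (1050, 1200, -1), (1250, 1550, 1)],
    )
    make_record("SYN_OK2.1", "Synthetica secunda", [(2200, 2500, 1), (2600, 2900, 1)])
    make_record("SYN_DISP.1", "Synthetica dispersa", [(100, 400, 1), (1300, 1600, 1)])
    make_record("SYN_EDGE.1", "Synthetica marginalis", [(30, 180, 1)])

    rows = [
        # organism, scaffold, 1-based start, 1-based end, score
        ("Synthetica prima", "SYN_OK1.1", 1001, 1200, 85.0, "written"),
        ("Synthetica secunda", "SYN_OK2.1", 2301, 2800, 60.5, "written"),
        ("Synthetica dispersa", "SYN_DISP.1", 101, 1600, 40.0, "rejected_dispersed"),
        ("Synthetica marginalis", "SYN_EDGE.1", 1, 200, 30.0, "rejected_small"),
        ("Synthetica absens", "SYN_GONE.1", 501, 700, 20.0, "fetch_failure"),
    ]
    binary_path = out_dir / "binary.csv"
    with open(binary_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["Organism", "Scaffold", "Start", "End", "Score", "query1"])
        for organism, scaffold, start, end, score, _ in rows:
            writer.writerow([organism, scaffold, start, end, score, 1])

    return {
        "records_dir": str(records_dir),
        "binary_path": str(binary_path),
        "neighbourhood_len": 1000,
        "expected_outcomes": {r[1]: r[5] for r in rows},
    }
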