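"""Sequence containers and file I/O.

Reads and datasets are plain in-memory containers; FASTA/FASTQ parsing is
delegated to Biopython's SeqIO.  Reference proteins carry gene-family, EC and
lineage metadata in a pipe-delimited FASTA header
(``accession|family|EC|phylum|class|genus``) so panels round-trip through
plain text.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Read",
    "Dataset",
    "ProteinRef",
    "read_sequences",
    "write_fasta",
    "write_fastq",
    "read_protein_fasta",
    "write_protein_fasta",
]

_DNA_ALPHABET = set("ACGTN")

#: Taxon groups that are not (phylum, class, genus) lineages but appear as
#: assignment categories in their own right.
SPECIAL_GROUPS = ("uncultured/unclassified", "Eukaryotes", "synthetic construct")


@dataclass
class Read:
    """One sequencing read: identifier plus an upper-case DNA sequence."""

    read_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.read_id:
            raise ValueError("read_id must be non-empty")
        if not self.sequence.isupper() and self.sequence:
            self.sequence = self.sequence.upper()
        bad = set(self.sequence) - _DNA_ALPHABET
        if bad:
            raise ValueError(
                f"read {self.read_id!r}: invalid characters {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class Dataset:
    """An ordered collection of reads from one sample."""

    sample_id: str
    reads: list[Read] = field(default_factory=list)

    @property
    def n_reads(self) -> int:
        return len(self.reads)

    @property
    def total_bp(self) -> int:
        return sum(r.length for r in self.reads)

    @property
    def mean_length(self) -> int:
        """Mean read length, rounded to integer bp for reporting."""
        if not self.reads:
            return 0
        return round(self.total_bp / self.n_reads)

    def read_ids(self) -> list[str]:
        return [r.read_id for r in self.reads]

    def __iter__(self):
        return iter(self.reads)

    def __len__(self) -> int:
        return len(self.reads)


def read_sequences(path: str | Path, format: str | None = None) -> Dataset:
    """Load a FASTA or FASTQ file into a :class:`Dataset`.

    ``format`` is inferred from the suffix when omitted.  Record order is
    preserved; sequences are upper-cased; ``N`` bases are allowed.  An empty
    file yields an empty dataset with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "fastq" if path.suffix.lower() in {".fastq", ".fq"} else "fasta"
    if format not in {"fasta", "fastq"}:
        raise ValueError(f"unsupported format {format!r}")
    reads: list[Read] = []
    try:
        for rec in SeqIO.parse(str(path), format):
            reads.append(Read(rec.id, str(rec.seq)))
    except ValueError as exc:
        raise ValueError(
            f"malformed {format} record in {path} near record {len(reads) + 1}: {exc}"
        ) from exc
    if not reads:
        warnings.warn(f"{path}: no records found; returning empty dataset")
    return Dataset(sample_id=path.stem, reads=reads)


def write_fasta(dataset: Dataset, path: str | Path) -> None:
    records = (
        SeqRecord(Seq(r.sequence), id=r.read_id, description="") for r in dataset
    )
    SeqIO.write(records, str(path), "fasta")


def write_fastq(dataset: Dataset, path: str | Path, quality: int = 30) -> None:
    def _records():
        for r in dataset:
            rec = SeqRecord(Seq(r.sequence), id=r.read_id, description="")
            rec.letter_annotations["phred_quality"] = [quality] * r.length
            yield rec

    SeqIO.write(_records(), str(path), "fastq")


@dataclass
class ProteinRef:
    """A reference or confirmation protein with family, EC and lineage metadata.

    ``family`` is ``None`` for decoys.  ``proteo_class`` is only meaningful
    when ``phylum == "Proteobacteria"``.  ``phylum`` may also be one of the
    special assignment categories ("uncultured/unclassified", "Eukaryotes",
    "synthetic construct").
    """

    accession: str
    sequence: str
    family: str | None = None
    ec_numbers: tuple[str, ...] = ()
    phylum: str = "uncultured/unclassified"
    proteo_class: str = ""
    genus: str = ""
    description: str = ""

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("accession must be non-empty")
        self.sequence = self.sequence.upper()
        if isinstance(self.ec_numbers, list):
            self.ec_numbers = tuple(self.ec_numbers)
        if self.proteo_class and self.phylum != "Proteobacteria":
            raise ValueError(
                f"{self.accession}: class {self.proteo_class!r} given but "
                f"phylum is {self.phylum!r} (class only under Proteobacteria)"
            )

    @property
    def group(self) -> str:
        """Phylum-level group, reported at class rank for Proteobacteria."""
        if self.phylum == "Proteobacteria" and self.proteo_class:
            return self.proteo_class
        return self.phylum

    @property
    def lineage(self) -> tuple[str, str, str]:
        return (self.phylum, self.proteo_class, self.genus)

    def header(self) -> str:
        fam = self.family or ""
        ec = ";".join(self.ec_numbers)
        return "|".join(
            [self.accession, fam, ec, self.phylum, self.proteo_class, self.genus]
        )


def _check_unique_accessions(proteins: Sequence[ProteinRef]) -> None:
    seen: set[str] = set()
    for p in proteins:
        if p.accession in seen:
            raise ValueError(f"duplicate accession {p.accession!r} in database")
        seen.add(p.accession)


def write_protein_fasta(proteins: Iterable[ProteinRef], path: str | Path) -> None:
    proteins = list(proteins)
    _check_unique_accessions(proteins)
    with open(path, "w") as fh:
        for p in proteins:
            fh.write(f">{p.header()}\n")
            seq = p.sequence
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def read_protein_fasta(path: str | Path) -> list[ProteinRef]:
    proteins: list[ProteinRef] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        # parse the full description: lineage fields may contain spaces
        parts = rec.description.split("|")
        if len(parts) != 6:
            raise ValueError(
                f"{path}: header {rec.description!r} does not match "
                "accession|family|EC|phylum|class|genus"
            )
        acc, fam, ec, phylum, cls, genus = parts
        proteins.append(
            ProteinRef(
                accession=acc,
                sequence=str(rec.seq),
                family=fam or None,
                ec_numbers=tuple(e for e in ec.split(";") if e),
                phylum=phylum,
                proteo_class=cls,
                genus=genus,
            )
        )
    _check_unique_accessions(proteins)
    return proteins
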