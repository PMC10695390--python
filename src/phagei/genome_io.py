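"""Annotated-genome input/output and strand-aware sequence extraction.

Internally all coordinates are 0-based, half-open ``[start, end)`` on the
forward (reference) strand.  GenBank files and the TSV gene tables written
by this package use the 1-based, inclusive convention that biologists
expect; the conversion happens exactly once, at the I/O boundary.

Circular genomes are accepted for storage, but features that wrap the
origin are rejected: both phage reference genomes used for benchmarking
are annotated without origin-spanning CDSs, and silently unwrapping
coordinates is a classic source of off-by-one bugs.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GeneFeature",
    "Genome",
    "GenomeValidationError",
    "reverse_complement",
    "coding_sequence",
    "read_genome",
    "read_genbank",
    "read_fasta_with_table",
    "write_genbank",
    "write_fasta",
    "write_gene_table",
    "read_gene_table",
]

VALID_BASES = frozenset("ACGTN")

GENE_TABLE_COLUMNS = ("locus_tag", "gene", "start", "end", "strand")


class GenomeValidationError(ValueError):
    """Raised when a genome or feature violates the coordinate contract."""


@dataclass(frozen=True)
class GeneFeature:
    """A simple-span coding sequence.

    ``start``/``end`` are 0-based half-open genomic coordinates; ``strand``
    is ``"+"`` or ``"-"``.  The coding-strand sequence always has length
    ``end - start``.
    """

    locus_tag: str
    start: int
    end: int
    strand: str
    gene_name: str | None = None
    product: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise GenomeValidationError(
                f"{self.locus_tag}: strand must be '+' or '-', got {self.strand!r}"
            )
        if not (0 <= self.start < self.end):
            raise GenomeValidationError(
                f"{self.locus_tag}: require 0 <= start < end, got [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Genome:
    """A nucleotide sequence plus an ordered list of gene features."""

    accession: str
    sequence: str
    features: list[GeneFeature] = field(default_factory=list)
    topology: str = "linear"
    description: str = ""

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise GenomeValidationError(
                f"{self.accession}: sequence contains non-ACGTN characters {sorted(bad)}; "
                "ambiguity codes other than N are not supported"
            )
        if self.topology not in ("linear", "circular"):
            raise GenomeValidationError(f"unknown topology {self.topology!r}")
        seen: set[str] = set()
        for f in self.features:
            if f.locus_tag in seen:
                raise GenomeValidationError(f"duplicate locus_tag {f.locus_tag!r}")
            seen.add(f.locus_tag)
            if f.end > len(self.sequence):
                raise GenomeValidationError(
                    f"{f.locus_tag}: feature [{f.start}, {f.end}) exceeds genome "
                    f"length {len(self.sequence)}"
                )
        self.features = sorted(self.features, key=lambda f: (f.start, f.end))

    def __len__(self) -> int:
        return len(self.sequence)

    def feature(self, locus_tag: str) -> GeneFeature:
        for f in self.features:
            if f.locus_tag == locus_tag:
                return f
        raise KeyError(locus_tag)


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string (case-insensitive)."""
    return seq.upper().translate(_COMPLEMENT)[::-1]


def coding_sequence(genome: Genome, feature: GeneFeature) -> str:
    """Coding-strand sequence of *feature*: the forward slice for ``+``
    genes, its reverse complement for ``-`` genes."""
    if feature.end > len(genome):
        raise GenomeValidationError(
            f"{feature.locus_tag}: feature exceeds genome bounds"
        )
    sub = genome.sequence[feature.start : feature.end]
    return sub if feature.strand == "+" else reverse_complement(sub)


# ---------------------------------------------------------------------------
# GenBank / FASTA+table readers
# ---------------------------------------------------------------------------


def _feature_from_seqfeature(feat: SeqFeature, idx: int, genome_len: int) -> GeneFeature:
    loc = feat.location
    if loc is None:
        raise GenomeValidationError(f"CDS #{idx}: feature has no location")
    if len(getattr(loc, "parts", [loc])) > 1:
        raise GenomeValidationError(
            f"CDS #{idx}: compound (joined) locations are not supported"
        )
    start, end = int(loc.start), int(loc.end)
    if not (0 <= start < end <= genome_len):
        raise GenomeValidationError(
            f"CDS #{idx}: location [{start}, {end}) outside genome of length {genome_len}"
        )
    quals = feat.qualifiers
    locus = quals.get("locus_tag", [None])[0] or quals.get("gene", [None])[0]
    if locus is None:
        locus = f"CDS_{idx:04d}"
    return GeneFeature(
        locus_tag=locus,
        start=start,
        end=end,
        strand="+" if loc.strand != -1 else "-",
        gene_name=quals.get("gene", [None])[0],
        product=quals.get("product", [None])[0],
    )


def read_genbank(path: str | Path) -> Genome:
    """Read a GenBank flat file into a :class:`Genome`.

    Coordinates are converted from GenBank's 1-based inclusive convention
    to the internal 0-based half-open one (Biopython already stores
    locations that way).  Only simple-span CDS features are kept.
    """
    try:
        record: SeqRecord = SeqIO.read(str(path), "genbank")
    except ValueError as exc:
        raise GenomeValidationError(f"cannot parse GenBank file {path}: {exc}") from exc
    topology = record.annotations.get("topology", "linear")
    features = [
        _feature_from_seqfeature(f, i, len(record.seq))
        for i, f in enumerate(record.features)
        if f.type == "CDS"
    ]
    return Genome(
        accession=record.id,
        sequence=str(record.seq),
        features=features,
        topology=topology if topology in ("linear", "circular") else "linear",
        description=record.description,
    )


def read_gene_table(path: str | Path) -> list[GeneFeature]:
    """Read a TSV gene table (locus_tag, gene, start, end, strand).

    File coordinates are 1-based inclusive; they are converted to the
    internal 0-based half-open convention here.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"locus_tag": str, "gene": str})
    missing = set(GENE_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise GenomeValidationError(
            f"gene table {path} missing columns {sorted(missing)}"
        )
    feats = []
    for row in df.itertuples(index=False):
        gene = getattr(row, "gene", None)
        if gene is not None and (gene != gene or gene == ""):  # NaN/empty
            gene = None
        feats.append(
            GeneFeature(
                locus_tag=str(row.locus_tag),
                start=int(row.start) - 1,
                end=int(row.end),
                strand=str(row.strand),
                gene_name=gene,
            )
        )
    return feats


def read_fasta_with_table(fasta_path: str | Path, table_path: str | Path) -> Genome:
    """Read a genome from a FASTA sequence plus a TSV gene table."""
    try:
        record = SeqIO.read(str(fasta_path), "fasta")
    except ValueError as exc:
        raise GenomeValidationError(f"cannot parse FASTA {fasta_path}: {exc}") from exc
    return Genome(
        accession=record.id,
        sequence=str(record.seq),
        features=read_gene_table(table_path),
        description=record.description,
    )


def read_genome(path: str | Path, format: str = "genbank", table: str | Path | None = None) -> Genome:
    """Dispatching reader: ``format`` is ``genbank`` or ``fasta+table``."""
    if format == "genbank":
        return read_genbank(path)
    if format == "fasta+table":
        if table is None:
            raise ValueError("fasta+table format requires a gene table path")
        return read_fasta_with_table(path, table)
    raise ValueError(f"unknown genome format {format!r}")


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def _to_seqrecord(genome: Genome) -> SeqRecord:
    record = SeqRecord(
        Seq(genome.sequence),
        id=genome.accession,
        name=genome.accession.split(".")[0][:16],
        description=genome.description,
        annotations={
            "molecule_type": "DNA",
            "topology": genome.topology,
        },
    )
    for f in genome.features:
        quals = {"locus_tag": [f.locus_tag]}
        if f.gene_name:
            quals["gene"] = [f.gene_name]
        if f.product:
            quals["product"] = [f.product]
        record.features.append(
            SeqFeature(
                FeatureLocation(f.start, f.end, strand=1 if f.strand == "+" else -1),
                type="CDS",
                qualifiers=quals,
            )
        )
    return record


def write_genbank(genome: Genome, path: str | Path) -> None:
    SeqIO.write(_to_seqrecord(genome), str(path), "genbank")


def write_fasta(genome: Genome, path: str | Path) -> None:
    SeqIO.write(_to_seqrecord(genome), str(path), "fasta")


def write_gene_table(features: Iterable[GeneFeature], path: str | Path) -> None:
    """Write features as a TSV gene table using 1-based inclusive coordinates."""
    import pandas as pd

    rows = [
        {
            "locus_tag": f.locus_tag,
            "gene": f.gene_name or "",
            "start": f.start + 1,
            "end": f.end,
            "strand": f.strand,
        }
        for f in features
    ]
    pd.DataFrame(rows, columns=list(GENE_TABLE_COLUMNS)).to_csv(path, sep="\t", index=False)
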