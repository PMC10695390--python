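"""DNA-barcode construct design, counterselection guides, and Barseq counting.

To barcode a phage, a recombination template is built from two homology
arms (default 100 bp each) copied exactly from the genome on either side
of an insertion point inside a nonessential locus.  Between the arms
sits a random 20-nt barcode flanked by two fixed primer-binding regions,
so that barcoded genomes can be quantified later by amplicon sequencing
(Barseq).  After recombination, wild-type phage is removed by plating on
a host expressing nuclease-active Cas12a with a guide whose protospacer
spans the insertion junction: the site is intact in wild type but
interrupted by the insert in the recombinant.

Barcode counting anchors on the primer-binding flanks (allowing a
configurable number of mismatches), extracts the 20-mer between them and
tallies it; no error correction is applied to the barcode itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .genome_io import GeneFeature, Genome, reverse_complement
from .guide_design import DesignConfig, GuideCandidate, match_iupac

__all__ = [
    "BarcodeConstruct",
    "BarcodeCountTable",
    "random_barcode",
    "random_barcode_set",
    "design_construct",
    "recombinant_sequence",
    "design_counterselection_guide",
    "count_barcodes",
]

# Placeholder primer-binding flanks; the real Barseq primers are an
# experimental choice, so flanks are always configurable.
DEFAULT_LEFT_FLANK = "GATGTCCACGAGGTCTCT"
DEFAULT_RIGHT_FLANK = "CGTACGCTGCAGGTCGAC"

BARCODE_LENGTH = 20
ARM_LENGTH = 100


@dataclass(frozen=True)
class BarcodeConstruct:
    """Homology arms + primer flanks + random barcode for recombination."""

    locus_tag: str
    insertion_point: int  # genomic coordinate the insert lands at
    upstream_arm: str
    downstream_arm: str
    barcode: str
    left_flank: str = DEFAULT_LEFT_FLANK
    right_flank: str = DEFAULT_RIGHT_FLANK

    @property
    def insert(self) -> str:
        return self.left_flank + self.barcode + self.right_flank

    @property
    def full_sequence(self) -> str:
        return self.upstream_arm + self.insert + self.downstream_arm


def _gc_fraction(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq)


def _max_homopolymer(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def random_barcode(
    rng: np.random.Generator,
    length: int = BARCODE_LENGTH,
    gc_range: tuple[float, float] = (0.25, 0.75),
    max_homopolymer: int = 4,
) -> str:
    """Draw one random barcode passing composition filters.

    Filters (balanced GC, no homopolymer of 5+) keep barcodes well-behaved
    in PCR and sequencing; both are configurable.
    """
    bases = np.array(list("ACGT"))
    for _ in range(10_000):
        bc = "".join(rng.choice(bases, size=length))
        if gc_range[0] <= _gc_fraction(bc) <= gc_range[1] and _max_homopolymer(bc) <= max_homopolymer:
            return bc
    raise RuntimeError("could not draw a barcode satisfying the filters")


def random_barcode_set(
    n: int,
    seed: int,
    length: int = BARCODE_LENGTH,
    min_pairwise_distance: int = 3,
) -> list[str]:
    """Draw *n* barcodes with a minimum pairwise Hamming distance."""
    rng = np.random.default_rng(seed)
    out: list[str] = []
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 100_000:
            raise RuntimeError("barcode set constraints too tight")
        bc = random_barcode(rng, length)
        if all(_hamming(bc, other) >= min_pairwise_distance for other in out):
            out.append(bc)
    return out


def design_construct(
    genome: Genome,
    locus: GeneFeature | tuple[int, int] | int,
    seed: int,
    arm_length: int = ARM_LENGTH,
    barcode_length: int = BARCODE_LENGTH,
    left_flank: str = DEFAULT_LEFT_FLANK,
    right_flank: str = DEFAULT_RIGHT_FLANK,
    essential_call: str | None = None,
) -> BarcodeConstruct:
    """Design a barcode-insertion construct at *locus*.

    *locus* may be a gene feature (insertion at its midpoint), a (start,
    end) span, or an explicit genomic insertion coordinate.  Arms are
    copied verbatim from the genome around the insertion point; the
    barcode is drawn from seeded randomness, so the same seed always
    yields the same construct.
    """
    if isinstance(locus, GeneFeature):
        midpoint = (locus.start + locus.end) // 2
        tag = locus.locus_tag
    elif isinstance(locus, tuple):
        midpoint = (locus[0] + locus[1]) // 2
        tag = f"span_{locus[0]}_{locus[1]}"
    else:
        midpoint = int(locus)
        tag = f"pos_{midpoint}"
    if essential_call == "E":
        import warnings

        warnings.warn(
            f"{tag}: inserting a barcode at a locus called essential", stacklevel=2
        )
    if midpoint - arm_length < 0 or midpoint + arm_length > len(genome):
        raise ValueError(
            f"{tag}: insertion point {midpoint} lacks {arm_length} nt of genomic "
            "context on each side"
        )
    rng = np.random.default_rng(seed)
    return BarcodeConstruct(
        locus_tag=tag,
        insertion_point=midpoint,
        upstream_arm=genome.sequence[midpoint - arm_length : midpoint],
        downstream_arm=genome.sequence[midpoint : midpoint + arm_length],
        barcode=random_barcode(rng, barcode_length),
        left_flank=left_flank,
        right_flank=right_flank,
    )


def recombinant_sequence(genome: Genome, construct: BarcodeConstruct) -> str:
    """Genome sequence after in-silico recombination of the construct."""
    m = construct.insertion_point
    return genome.sequence[:m] + construct.insert + genome.sequence[m:]


def design_counterselection_guide(
    genome: Genome,
    construct: BarcodeConstruct,
    config: DesignConfig = DesignConfig(),
    search_radius: int = 200,
) -> GuideCandidate:
    """A nuclease guide that cuts wild type but not the recombinant.

    Both strands around the insertion point are scanned for a PAM whose
    downstream protospacer spans the junction, so the recombinant's
    insert interrupts the target site.  Unlike knockdown design, strand
    does not matter for cutting.
    """
    m = construct.insertion_point
    pam_len = len(config.pam_motif)
    sp_len = config.spacer_length
    lo = max(0, m - search_radius)
    hi = min(len(genome), m + search_radius)
    region = genome.sequence[lo:hi]
    recombinant = recombinant_sequence(genome, construct)
    near_misses: list[str] = []

    candidates: list[tuple[int, GuideCandidate]] = []
    for strand in ("+", "-"):
        seq = region if strand == "+" else reverse_complement(region)
        for p in match_iupac(config.pam_motif, seq):
            s0, s1 = p + pam_len, p + pam_len + sp_len
            if s1 > len(seq):
                continue
            # genomic span of the protospacer
            if strand == "+":
                g0, g1 = lo + s0, lo + s1
            else:
                g0, g1 = hi - s1, hi - s0
            if not (g0 < m < g1):
                near_misses.append(f"{strand}{g0}-{g1}")
                continue
            spacer = seq[s0:s1]
            protospacer_with_pam = seq[p:s1]
            # must be unique-cut in wild type region by construction and
            # absent from the recombinant
            if protospacer_with_pam in recombinant or reverse_complement(protospacer_with_pam) in recombinant:
                continue
            distance = abs((g0 + g1) // 2 - m)
            candidates.append(
                (
                    distance,
                    GuideCandidate(
                        locus_tag=construct.locus_tag,
                        pam_cds_offset=-1,
                        pam_fraction=float("nan"),
                        pam_sequence=seq[p : p + pam_len],
                        spacer=spacer,
                        genomic_pam_start=(lo + p) if strand == "+" else (hi - p - pam_len),
                        genomic_strand=strand,
                    ),
                )
            )
    if not candidates:
        raise ValueError(
            f"{construct.locus_tag}: no PAM places a {sp_len}-nt protospacer across "
            f"the insertion junction within {search_radius} nt; nearest non-spanning "
            f"sites: {', '.join(near_misses[:5]) or 'none'}"
        )
    candidates.sort(key=lambda t: (t[0], t[1].genomic_pam_start, t[1].genomic_strand))
    return candidates[0][1]


# ---------------------------------------------------------------------------
# Barseq counting
# ---------------------------------------------------------------------------


@dataclass
class BarcodeCountTable:
    """Per-barcode read counts for one sample."""

    counts: dict[str, int] = field(default_factory=dict)
    unassigned: int = 0

    @property
    def assigned(self) -> int:
        return sum(self.counts.values())

    @property
    def total(self) -> int:
        return self.assigned + self.unassigned

    def fractions(self) -> dict[str, float]:
        """Relative abundance over assigned reads (sums to 1)."""
        tot = self.assigned
        if tot == 0:
            return {bc: 0.0 for bc in self.counts}
        return {bc: c / tot for bc, c in self.counts.items()}

    def to_frame(self, sample: str = "sample") -> pd.DataFrame:
        fr = self.fractions()
        rows = [
            {"sample": sample, "barcode": bc, "count": c, "fraction": fr[bc]}
            for bc, c in sorted(self.counts.items(), key=lambda kv: -kv[1])
        ]
        return pd.DataFrame(rows, columns=["sample", "barcode", "count", "fraction"])


def _find_with_mismatches(read: str, flank: str, max_mm: int) -> int | None:
    """Leftmost position where *flank* matches *read* with <= max_mm
    mismatches (Hamming; indels are not tolerated)."""
    n, m = len(read), len(flank)
    for p in range(n - m + 1):
        if _hamming(read[p : p + m], flank) <= max_mm:
            return p
    return None


def count_barcodes(
    reads: str | Path | Iterable[str],
    expected: Sequence[str] | str = "discover",
    left_flank: str = DEFAULT_LEFT_FLANK,
    right_flank: str = DEFAULT_RIGHT_FLANK,
    max_flank_mismatches: int = 1,
    barcode_length: int = BARCODE_LENGTH,
) -> BarcodeCountTable:
    """Count barcodes in FASTQ reads (path) or an iterable of sequences.

    For each read: anchor the left flank (allowing up to
    *max_flank_mismatches* mismatches), take the next *barcode_length*
    bases as the barcode, and require the right flank immediately after
    (same mismatch budget).  Extracted barcodes are matched exactly
    against *expected*, or tallied as-is in ``"discover"`` mode.  Reads
    failing any step count as unassigned.
    """
    if isinstance(reads, (str, Path)):
        seqs: Iterable[str] = (str(rec.seq) for rec in SeqIO.parse(str(reads), "fastq"))
    else:
        seqs = reads
    discover = isinstance(expected, str) and expected == "discover"
    known = None if discover else set(expected)

    table = BarcodeCountTable()
    if known is not None:
        table.counts = {bc: 0 for bc in known}
    for seq in seqs:
        seq = seq.upper()
        p = _find_with_mismatches(seq, left_flank, max_flank_mismatches)
        if p is None:
            table.unassigned += 1
            continue
        b0 = p + len(left_flank)
        b1 = b0 + barcode_length
        if b1 + len(right_flank) > len(seq):
            table.unassigned += 1
            continue
        if _hamming(seq[b1 : b1 + len(right_flank)], right_flank) > max_flank_mismatches:
            table.unassigned += 1
            continue
        barcode = seq[b0:b1]
        if known is not None and barcode not in known:
            table.unassigned += 1
            continue
        table.counts[barcode] = table.counts.get(barcode, 0) + 1
    return table
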