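"""Cas12a CRISPRi guide (crRNA spacer) design.

The design rule implemented here, one guide per gene:

* scan the **coding strand** of each CDS for the Cas12a PAM ``TTTV``
  (V = A/C/G);
* keep PAM sites whose start offset, as a fraction of CDS length, lies in
  the window [0.20, 0.33] — far enough in to be robust to alternative
  start codons, close enough to the 5' end for an effective transcription
  roadblock;
* the 28 nt immediately 3' of the PAM on the coding strand become the
  spacer (protospacer); the spacer may run past the stop codon but must
  stay inside the genome;
* among in-window sites, the one closest to the start codon wins
  (deterministic earliest-usable-site tie-break).

Genes with no in-window PAM are reported untargetable rather than being
silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .genome_io import GeneFeature, Genome, coding_sequence, reverse_complement

__all__ = [
    "IUPAC_CODES",
    "DesignConfig",
    "GuideCandidate",
    "Untargetable",
    "DesignReport",
    "match_iupac",
    "design_guide",
    "design_genome",
]

# IUPAC nucleotide one-letter codes -> set of matching unambiguous bases.
# N in the *subject* sequence matches nothing (conservative: an unknown
# base is never assumed to satisfy a PAM).
IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}


def match_iupac(pattern: str, sequence: str) -> list[int]:
    """All 0-based positions where *pattern* (IUPAC) matches *sequence*.

    ``N`` in the subject never matches any pattern letter.
    """
    if not pattern:
        raise ValueError("pattern must be nonempty")
    pattern = pattern.upper()
    sequence = sequence.upper()
    sets = []
    for ch in pattern:
        try:
            sets.append(IUPAC_CODES[ch])
        except KeyError:
            raise ValueError(f"invalid IUPAC code {ch!r} in pattern") from None
    m = len(pattern)
    out = []
    for p in range(len(sequence) - m + 1):
        window = sequence[p : p + m]
        if all(b in s for b, s in zip(window, sets)):
            out.append(p)
    return out


@dataclass(frozen=True)
class DesignConfig:
    """Tunable design parameters (defaults reproduce the benchmark rule)."""

    pam_motif: str = "TTTV"
    spacer_length: int = 28
    window_lo: float = 0.20
    window_hi: float = 0.33
    strand_policy: str = "coding_strand_only"
    fallback: str = "none"  # or "extend_downstream"

    def __post_init__(self) -> None:
        if not (0 <= self.window_lo < self.window_hi <= 1):
            raise ValueError("require 0 <= window_lo < window_hi <= 1")
        if self.spacer_length <= 0:
            raise ValueError("spacer_length must be positive")
        if self.fallback not in ("none", "extend_downstream"):
            raise ValueError(f"unknown fallback {self.fallback!r}")
        if self.strand_policy != "coding_strand_only":
            raise ValueError("only coding_strand_only is supported")


@dataclass(frozen=True)
class GuideCandidate:
    """A designed crRNA spacer with its PAM and positional metadata."""

    locus_tag: str
    pam_cds_offset: int
    pam_fraction: float
    pam_sequence: str
    spacer: str
    genomic_pam_start: int
    genomic_strand: str
    gene_name: str | None = None


@dataclass(frozen=True)
class Untargetable:
    locus_tag: str
    reason: str
    gene_name: str | None = None


@dataclass
class DesignReport:
    """One guide per targetable gene plus the untargetable remainder."""

    guides: list[GuideCandidate] = field(default_factory=list)
    untargetable: list[Untargetable] = field(default_factory=list)

    @property
    def untargetable_tags(self) -> set[str]:
        return {u.locus_tag for u in self.untargetable}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g in self.guides:
            rows.append(
                {
                    "locus_tag": g.locus_tag,
                    "gene": g.gene_name or "",
                    "pam_genomic_start": g.genomic_pam_start,
                    "strand": g.genomic_strand,
                    "pam_seq": g.pam_sequence,
                    "pam_cds_offset": g.pam_cds_offset,
                    "pam_fraction": round(g.pam_fraction, 6),
                    "spacer": g.spacer,
                    "status": "targeted",
                    "reason": "",
                }
            )
        for u in self.untargetable:
            rows.append(
                {
                    "locus_tag": u.locus_tag,
                    "gene": u.gene_name or "",
                    "pam_genomic_start": "",
                    "strand": "",
                    "pam_seq": "",
                    "pam_cds_offset": "",
                    "pam_fraction": "",
                    "spacer": "",
                    "status": "untargetable",
                    "reason": u.reason,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "locus_tag", "gene", "pam_genomic_start", "strand", "pam_seq",
                "pam_cds_offset", "pam_fraction", "spacer", "status", "reason",
            ],
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _genomic_pam_start(feature: GeneFeature, cds_offset: int, pam_len: int) -> int:
    """Genomic coordinate of the PAM's first (5'-most in CDS frame) base."""
    if feature.strand == "+":
        return feature.start + cds_offset
    # minus strand: CDS offset o corresponds to genomic position end-1-o,
    # and the PAM occupies [end-o-pam_len, end-o) on the genome
    return feature.end - cds_offset - pam_len


def design_guide(
    genome: Genome, feature: GeneFeature, config: DesignConfig = DesignConfig()
) -> GuideCandidate | Untargetable:
    """Design one guide for *feature* or explain why none exists."""
    L = feature.length
    pam_len = len(config.pam_motif)
    if L <= config.spacer_length:
        return Untargetable(feature.locus_tag, "gene too short", feature.gene_name)
    cds = coding_sequence(genome, feature)
    lo, hi = config.window_lo, config.window_hi
    if config.fallback == "extend_downstream":
        hi = 1.0
    for p in match_iupac(config.pam_motif, cds):
        frac = p / L
        if frac < lo:
            continue
        if frac > hi:
            break
        spacer = _spacer_after_pam(genome, feature, p, pam_len, config.spacer_length)
        if spacer is None:
            continue  # spacer would run off the genome
        return GuideCandidate(
            locus_tag=feature.locus_tag,
            pam_cds_offset=p,
            pam_fraction=p / L,
            pam_sequence=cds[p : p + pam_len],
            spacer=spacer,
            genomic_pam_start=_genomic_pam_start(feature, p, pam_len),
            genomic_strand=feature.strand,
            gene_name=feature.gene_name,
        )
    return Untargetable(feature.locus_tag, "no PAM in window", feature.gene_name)


def _spacer_after_pam(
    genome: Genome, feature: GeneFeature, cds_offset: int, pam_len: int, spacer_len: int
) -> str | None:
    """The spacer_len bases 3' of the PAM on the coding strand, read from
    the genome (they may extend past the CDS end), or None if they would
    run outside the genome."""
    if feature.strand == "+":
        start = feature.start + cds_offset + pam_len
        end = start + spacer_len
        if end > len(genome):
            return None
        return genome.sequence[start:end]
    end = feature.end - cds_offset - pam_len
    start = end - spacer_len
    if start < 0:
        return None
    return reverse_complement(genome.sequence[start:end])


def design_genome(genome: Genome, config: DesignConfig = DesignConfig()) -> DesignReport:
    """Design one guide per annotated gene; purely deterministic."""
    if not genome.features:
        raise ValueError(f"{genome.accession}: genome has no features")
    report = DesignReport()
    for feature in genome.features:
        result = design_guide(genome, feature, config)
        if isinstance(result, GuideCandidate):
            report.guides.append(result)
        else:
            report.untargetable.append(result)
    return report
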