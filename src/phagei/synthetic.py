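"""Synthetic data with known ground truth, plus shipped benchmark fixtures.

Three simulators cover the inputs of the analysis pipeline:

* phage-like annotated genomes whose genes are ATG-initiated,
  stop-terminated ORFs on random strands, with Cas12a PAM sites
  (``TTTV``) optionally planted inside the guide-design window so the
  designer's hit/miss behaviour can be checked against construction;
* spot-titration plaque-count tables with Poisson counting noise around
  known true titers and EOPs;
* Barseq amplicon reads carrying 20-nt barcodes between fixed
  primer-binding flanks at known mixing proportions.

Every simulator is a pure function of its seed.  The module also loads
the transcribed essentiality tables for phages lambda and P1 and the
lambda lytic transcript map that ship with the package; those fixtures
are transcriptions of published measurements — including their internal
inconsistencies — and are never edited programmatically.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .assay import LAWN_CLEARED
from .barcoding import DEFAULT_LEFT_FLANK, DEFAULT_RIGHT_FLANK
from .genome_io import GeneFeature, Genome, reverse_complement
from .polarity import TranscriptUnit

__all__ = [
    "SimulationSpec",
    "generate_genome",
    "simulate_spot_counts",
    "simulate_barcode_reads",
    "write_fastq",
    "load_fixture",
    "fixture_call_map",
    "lambda_transcript_units",
    "lambda_call_maps",
]

STOP_CODONS = ("TAA", "TAG", "TGA")

FIXTURES = ("lambda_table1", "lambda_table1_pq", "p1_table2", "lambda_transcripts")


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of a simulated screen.

    Defaults describe a compact but realistic phage-like setting: 20
    genes of 150-900 nt, short intergenic gaps, balanced GC, every gene
    guaranteed an in-window PAM, a control stock of 1e10 PFU/mL titrated
    as 2-uL spots over a 10-fold dilution series (10^0..10^-8) in
    triplicate.  The high control titer keeps knockdowns down to an EOP
    of 1e-6 inside the countable range of the series.
    """

    seed: int = 0
    n_genes: int = 20
    gene_length_range: tuple[int, int] = (150, 900)
    intergenic_range: tuple[int, int] = (20, 120)
    gc_fraction: float = 0.5
    plant_pam_fraction: float = 1.0
    pam_free: bool = False
    true_eop: Mapping[str, float] | None = None
    control_titer: float = 1e10
    dilution_exponents: tuple[int, ...] = tuple(range(9))
    n_replicates: int = 3
    spot_volume_ul: float = 2.0
    window: tuple[float, float] = (0.20, 0.33)

    def __post_init__(self) -> None:
        if not (0 < self.gc_fraction < 1):
            raise ValueError("gc_fraction must lie in (0, 1)")
        if not (0 <= self.plant_pam_fraction <= 1):
            raise ValueError("plant_pam_fraction must lie in [0, 1]")
        if self.gene_length_range[0] < 60:
            raise ValueError(
                "genes shorter than 60 nt cannot hold a planted PAM plus a "
                "28-nt spacer; raise gene_length_range"
            )
        if self.true_eop is not None and any(v <= 0 for v in self.true_eop.values()):
            raise ValueError("all true EOPs must be positive")


def _random_codon(rng: np.random.Generator, gc: float, pam_free: bool) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
    bases = np.array(list("ACGT"))
    while True:
        codon = "".join(rng.choice(bases, size=3, p=p))
        if codon in STOP_CODONS:
            continue
        if pam_free and "TT" in codon:
            # excluding TT inside any codon makes a TTT run impossible
            # anywhere in the concatenated frame
            continue
        return codon


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(np.array(list("ACGT")), size=n, p=p))


def _make_gene(
    rng: np.random.Generator, length: int, gc: float, plant_pam: bool,
    pam_free: bool, window: tuple[float, float],
) -> str:
    """One ORF of *length* nt (multiple of 3): ATG + body + stop."""
    n_codons = length // 3
    codons = ["ATG"] + [
        _random_codon(rng, gc, pam_free) for _ in range(n_codons - 2)
    ] + [STOP_CODONS[rng.integers(len(STOP_CODONS))]]
    if plant_pam:
        lo = int(np.ceil(window[0] * length / 3))
        hi = int(np.floor(window[1] * length / 3))
        hi = min(hi, n_codons - 3)  # keep clear of the stop codon
        if lo > hi:
            raise ValueError(f"gene of {length} nt too short to plant an in-window PAM")
        i = int(rng.integers(lo, hi + 1))
        codons[i] = "TTT"
        v = "ACG"[rng.integers(3)]
        codons[i + 1] = v + _random_codon(rng, gc, pam_free=False)[1:]
        if codons[i + 1] in STOP_CODONS:  # e.g. landed on TGA via v='G'? impossible, but stay safe
            codons[i + 1] = v + "CC"
    return "".join(codons)


def generate_genome(spec: SimulationSpec) -> Genome:
    """Generate a phage-like annotated genome; deterministic given the seed."""
    rng = np.random.default_rng(spec.seed)
    lo_g, hi_g = spec.gene_length_range
    lo_i, hi_i = spec.intergenic_range
    n_plant = int(round(spec.plant_pam_fraction * spec.n_genes))
    planted = set(rng.choice(spec.n_genes, size=n_plant, replace=False))

    parts: list[str] = []
    features: list[GeneFeature] = []
    pos = 0
    for idx in range(spec.n_genes):
        gap = _random_seq(rng, int(rng.integers(lo_i, hi_i + 1)), spec.gc_fraction)
        parts.append(gap)
        pos += len(gap)
        length = 3 * int(rng.integers(lo_g // 3, hi_g // 3 + 1))
        cds = _make_gene(
            rng, length, spec.gc_fraction,
            plant_pam=idx in planted, pam_free=spec.pam_free, window=spec.window,
        )
        strand = "+" if rng.random() < 0.5 else "-"
        parts.append(cds if strand == "+" else reverse_complement(cds))
        features.append(
            GeneFeature(
                locus_tag=f"sim_{idx:03d}",
                start=pos,
                end=pos + length,
                strand=strand,
                gene_name=f"g{idx:03d}",
                product="simulated protein",
            )
        )
        pos += length
    tail = _random_seq(rng, int(rng.integers(lo_i, hi_i + 1)) + 40, spec.gc_fraction)
    parts.append(tail)
    return Genome(
        accession=f"SIM_{spec.seed:08d}",
        sequence="".join(parts),
        features=features,
        description="synthetic phage-like genome",
    )


def default_true_eop(genome: Genome, essential_fraction: float = 1 / 3,
                     essential_eop: float = 1e-5) -> dict[str, float]:
    """Ground-truth EOPs: the first third of genes knock down hard."""
    n_ess = int(round(essential_fraction * len(genome.features)))
    return {
        f.locus_tag: (essential_eop if i < n_ess else 1.0)
        for i, f in enumerate(genome.features)
    }


def simulate_spot_counts(
    spec: SimulationSpec,
    locus_tags: Sequence[str] | None = None,
    lawn_threshold: int = 300,
) -> pd.DataFrame:
    """Poisson spot-count table for all samples plus a nontargeting control.

    Expected count for sample with true EOP e at dilution 10^-k:
    ``e * control_titer * volume_mL * 10^-k``; draws above
    *lawn_threshold* are recorded as lawn-cleared.
    """
    if spec.true_eop is None:
        if locus_tags is None:
            raise ValueError("need spec.true_eop or locus_tags")
        true_eop = {t: 1.0 for t in locus_tags}
    else:
        true_eop = dict(spec.true_eop)
    rng = np.random.default_rng(spec.seed + 1)
    vol_ml = spec.spot_volume_ul / 1000.0
    rows = []
    samples = [("control", 1.0, 1)] + [(t, e, 0) for t, e in true_eop.items()]
    for sample, eop, is_ctrl in samples:
        titer = eop * spec.control_titer
        for rep in range(1, spec.n_replicates + 1):
            for k in spec.dilution_exponents:
                mean = titer * vol_ml * 10.0 ** -k
                n = int(rng.poisson(mean)) if mean < 1e7 else lawn_threshold + 1
                rows.append(
                    {
                        "sample_id": sample,
                        "dilution_exponent": k,
                        "plaques": LAWN_CLEARED if n > lawn_threshold else n,
                        "volume_uL": spec.spot_volume_ul,
                        "replicate_id": rep,
                        "control_flag": is_ctrl,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Barseq read simulation
# ---------------------------------------------------------------------------


def simulate_barcode_reads(
    proportions: Mapping[str, float],
    n_reads: int,
    seed: int,
    left_flank: str = DEFAULT_LEFT_FLANK,
    right_flank: str = DEFAULT_RIGHT_FLANK,
    read_length: int = 80,
    max_prefix: int = 10,
) -> list[str]:
    """Simulated amplicon reads: random prefix, left flank, barcode,
    right flank, random filler to *read_length*."""
    barcodes = list(proportions)
    p = np.array([proportions[b] for b in barcodes], dtype=float)
    p = p / p.sum()
    rng = np.random.default_rng(seed)
    choices = rng.choice(len(barcodes), size=n_reads, p=p)
    reads = []
    for c in choices:
        prefix = _random_seq(rng, int(rng.integers(0, max_prefix + 1)), 0.5)
        core = prefix + left_flank + barcodes[c] + right_flank
        filler = _random_seq(rng, max(0, read_length - len(core)), 0.5)
        reads.append((core + filler)[:read_length])
    return reads


def write_fastq(reads: Sequence[str], path: str | Path, quality: str = "I") -> None:
    with open(path, "w") as fh:
        for i, seq in enumerate(reads):
            fh.write(f"@read_{i}\n{seq}\n+\n{quality * len(seq)}\n")


# ---------------------------------------------------------------------------
# Shipped fixtures (transcribed published tables)
# ---------------------------------------------------------------------------


def load_fixture(name: str) -> pd.DataFrame:
    """Load a shipped fixture table by name.

    Names: ``lambda_table1``, ``lambda_table1_pq`` (the trans-
    complementation rerun block), ``p1_table2``, ``lambda_transcripts``.
    All columns are strings, transcribed as printed (censored entries
    like ``<2.0E-7`` included).
    """
    if name not in FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; available: {FIXTURES}")
    ref = resources.files("phagei").joinpath(f"data/{name}.tsv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def _row_key(row) -> str:
    gene = row.gene.strip()
    if gene and gene != "-":
        return gene
    return row.locus_tag.strip()


def fixture_call_map(table: pd.DataFrame, column: str = "call_this_work") -> dict[str, str]:
    """Map gene (or locus_tag where unnamed) -> E/NE call, skipping NT rows."""
    out = {}
    for row in table.itertuples(index=False):
        call = getattr(row, column).strip()
        if call in ("E", "NE"):
            out[_row_key(row)] = call
    return out


def lambda_transcript_units() -> list[TranscriptUnit]:
    """The three lambda lytic transcriptional units (pL, pR, pR')."""
    df = load_fixture("lambda_transcripts")
    units = []
    for name, grp in df.groupby("unit_name", sort=False):
        grp = grp.copy()
        grp["rank"] = grp["rank"].astype(int)
        units.append(TranscriptUnit(str(name), list(grp.sort_values("rank")["locus_tag"])))
    return units


def lambda_call_maps() -> tuple[dict[str, str], dict[str, str]]:
    """(base calls, pQ-rerun calls) for lambda.

    The rerun map is the base map updated with the trans-complementation
    block's calls (the nin-region genes re-measured with Q supplied from
    a plasmid); genes not re-assayed keep their base call.
    """
    base = fixture_call_map(load_fixture("lambda_table1"))
    rerun = dict(base)
    rerun.update(fixture_call_map(load_fixture("lambda_table1_pq")))
    return base, rerun
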