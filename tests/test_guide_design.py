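"""PAM scanning and the positional guide-selection rule."""

import pytest

from phagei.genome_io import GeneFeature, Genome, coding_sequence, reverse_complement
from phagei.guide_design import (
    IUPAC_CODES,
    DesignConfig,
    GuideCandidate,
    Untargetable,
    design_genome,
    design_guide,
    match_iupac,
)
from phagei import synthetic

from conftest import random_dna


def brute_force_matches(pattern, sequence):
    out = []
    for p in range(len(sequence) - len(pattern) + 1):
        if all(
            base in IUPAC_CODES[pc] for base, pc in zip(sequence[p : p + len(pattern)], pattern)
        ):
            out.append(p)
    return out


@pytest.mark.parametrize(
    "pattern,sequence,expected",
    [
        ("TTTV", "TTTT", []),          # V excludes T
        ("TTTV", "TTTAGG", [0]),       # A is in V
        ("TTTV", "TTTTTA", [2]),       # overlapping scan
        ("TTTV", "TTTNA", []),         # N in subject matches nothing
        ("N", "ACGT", [0, 1, 2, 3]),
    ],
)
def test_match_iupac_examples(pattern, sequence, expected):
    assert match_iupac(pattern, sequence) == expected


def test_match_iupac_rejects_invalid_code():
    with pytest.raises(ValueError, match="IUPAC"):
        match_iupac("TTXV", "ACGT")
    with pytest.raises(ValueError, match="nonempty"):
        match_iupac("", "ACGT")


def test_match_iupac_equals_brute_force_on_random_sequences(rng):
    for _ in range(50):
        seq = random_dna(rng, 500, alphabet="ACGTN")
        for pat in ("TTTV", "WSN", "TTYR"):
            assert match_iupac(pat, seq) == brute_force_matches(pat, seq)


def _genome_with_gene(cds, strand="+", pad=40):
    """Embed a coding sequence into a genome with A-pads on both sides."""
    insert = cds if strand == "+" else reverse_complement(cds)
    seq = "G" * pad + insert + "G" * pad
    feat = GeneFeature("g1", pad, pad + len(cds), strand)
    return Genome("T", seq, [feat]), feat


def test_planted_pam_spacer_matches_slicing_oracle():
    # 300-nt gene, single TTTC at CDS offset 75 (fraction 0.25)
    cds = "ATG" + "CAG" * 24 + "TTTC" + "GACCGA" * 38 + "A"
    assert len(cds) == 308  # fraction 75/308 ~ 0.244, inside the window
    assert cds.index("TTTC") == 75
    for strand in "+-":
        genome, feat = _genome_with_gene(cds, strand)
        g = design_guide(genome, feat)
        assert isinstance(g, GuideCandidate)
        assert g.pam_cds_offset == 75
        assert g.spacer == cds[79 : 79 + 28]  # bases 79..106 inclusive
        assert g.pam_sequence == "TTTC"


def test_gene_without_pam_is_untargetable():
    cds = "ATG" + "CAG" * 80 + "TGA"
    genome, feat = _genome_with_gene(cds)
    result = design_guide(genome, feat)
    assert isinstance(result, Untargetable)
    assert result.reason == "no PAM in window"


def test_pam_outside_window_is_untargetable_unless_fallback():
    # single PAM at 50% of the gene: out of the 20-33% window
    cds = "ATG" + "CAG" * 49 + "TTTA" + "CAG" * 49 + "TGA"
    genome, feat = _genome_with_gene(cds)
    assert isinstance(design_guide(genome, feat), Untargetable)
    fallback = DesignConfig(fallback="extend_downstream")
    g = design_guide(genome, feat, fallback)
    assert isinstance(g, GuideCandidate)
    assert g.pam_fraction > 0.33


def test_two_in_window_pams_earliest_wins():
    L = 300
    cds = ["C"] * L
    cds[0:3] = "ATG"
    for off in (90, 66):  # 0.30 and 0.22
        cds[off : off + 4] = "TTTA"
    cds = "".join(cds)
    genome, feat = _genome_with_gene(cds)
    g = design_guide(genome, feat)
    assert g.pam_cds_offset == 66


def test_short_gene_reports_reason():
    genome, feat = _genome_with_gene("ATGCCCTGA")
    result = design_guide(genome, feat)
    assert isinstance(result, Untargetable)
    assert result.reason == "gene too short"


def test_spacer_may_extend_past_cds_but_not_past_genome():
    # 33-nt gene with an in-window PAM at offset 9: the 28-nt spacer runs
    # 8 nt past the stop codon into downstream genomic sequence
    cds = "ATG" + "C" * 6 + "TTTA" + "C" * 17 + "TGA"
    assert len(cds) == 33 and cds.index("TTTA") == 9
    genome, feat = _genome_with_gene(cds, pad=10)
    g = design_guide(genome, feat)
    assert isinstance(g, GuideCandidate)
    assert g.spacer == (cds + "G" * 10)[13 : 13 + 28]
    # with no genomic context after the stop codon the spacer would run
    # off the genome, so the gene is untargetable
    tight = Genome("T", "G" * 10 + cds, [GeneFeature("g1", 10, 43, "+")])
    res = design_guide(tight, tight.feature("g1"))
    assert isinstance(res, Untargetable)


def test_design_report_spacers_reconstruct_from_genome(sim_genome):
    report = design_genome(sim_genome)
    assert not report.untargetable
    for g in report.guides:
        feat = sim_genome.feature(g.locus_tag)
        # reconstruct the spacer from genomic coordinates independently
        if g.genomic_strand == "+":
            s0 = g.genomic_pam_start + 4
            expected = sim_genome.sequence[s0 : s0 + 28]
            pam = sim_genome.sequence[g.genomic_pam_start : g.genomic_pam_start + 4]
        else:
            s1 = g.genomic_pam_start
            expected = reverse_complement(sim_genome.sequence[s1 - 28 : s1])
            pam = reverse_complement(sim_genome.sequence[s1 : s1 + 4])
        assert g.spacer == expected
        assert g.pam_sequence == pam
        cds = coding_sequence(sim_genome, feat)
        assert cds[g.pam_cds_offset : g.pam_cds_offset + 4] == g.pam_sequence


def test_design_is_deterministic_and_window_monotone(sim_genome):
    r1 = design_genome(sim_genome).to_frame()
    r2 = design_genome(sim_genome).to_frame()
    assert r1.equals(r2)
    # shrinking the window never makes an untargetable gene targetable
    wide = design_genome(sim_genome, DesignConfig(window_lo=0.10, window_hi=0.50))
    narrow = design_genome(sim_genome, DesignConfig(window_lo=0.20, window_hi=0.33))
    assert {g.locus_tag for g in narrow.guides} <= {g.locus_tag for g in wide.guides}


def test_design_report_covers_every_gene_exactly_once(sim_genome):
    report = design_genome(sim_genome)
    tags = [g.locus_tag for g in report.guides] + [u.locus_tag for u in report.untargetable]
    assert sorted(tags) == sorted(f.locus_tag for f in sim_genome.features)


def test_config_validation():
    with pytest.raises(ValueError):
        DesignConfig(window_lo=0.4, window_hi=0.3)
    with pytest.raises(ValueError):
        DesignConfig(spacer_length=0)
    with pytest.raises(ValueError):
        DesignConfig(fallback="bogus")
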