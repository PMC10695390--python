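"""Barcode construct geometry, counterselection guides, Barseq counting."""

import numpy as np
import pytest

from phagei import synthetic
from phagei.barcoding import (
    BarcodeConstruct,
    count_barcodes,
    design_construct,
    design_counterselection_guide,
    random_barcode_set,
    recombinant_sequence,
)
from phagei.genome_io import GeneFeature, Genome, reverse_complement

from conftest import random_dna

BC_A = "ACACTGTCCAGATTCGGATG"
BC_B = "GTGTCAAGGTCCTTAAGCAC"


@pytest.fixture(scope="module")
def genome():
    rng = np.random.default_rng(7)
    seq = random_dna(rng, 1200)
    # plant a PAM so a 28-nt protospacer spans the junction at 604
    seq = seq[:590] + "TTTA" + seq[594:]
    return Genome("BCT", seq, [GeneFeature("noness", 400, 800, "+", gene_name="res")])


class TestConstruct:
    def test_arms_are_exact_genome_slices(self, genome):
        c = design_construct(genome, genome.feature("noness"), seed=5)
        m = c.insertion_point
        assert m == 600  # midpoint of the feature
        assert c.upstream_arm == genome.sequence[m - 100 : m]
        assert c.downstream_arm == genome.sequence[m : m + 100]
        assert len(c.barcode) == 20
        assert c.full_sequence == (
            c.upstream_arm + c.left_flank + c.barcode + c.right_flank + c.downstream_arm
        )

    def test_same_seed_same_barcode(self, genome):
        a = design_construct(genome, genome.feature("noness"), seed=11)
        b = design_construct(genome, genome.feature("noness"), seed=11)
        assert a == b
        c = design_construct(genome, genome.feature("noness"), seed=12)
        assert c.barcode != a.barcode

    def test_insufficient_flank_is_an_error(self, genome):
        with pytest.raises(ValueError, match="context"):
            design_construct(genome, 30, seed=0)

    def test_essential_locus_warns(self, genome):
        with pytest.warns(UserWarning, match="essential"):
            design_construct(genome, genome.feature("noness"), seed=0, essential_call="E")

    def test_barcode_composition_filters(self):
        barcodes = random_barcode_set(30, seed=3)
        for bc in barcodes:
            gc = (bc.count("G") + bc.count("C")) / 20
            assert 0.25 <= gc <= 0.75
            assert all(b * 5 not in bc for b in "ACGT")
        for i, a in enumerate(barcodes):
            for b in barcodes[i + 1 :]:
                assert sum(x != y for x, y in zip(a, b)) >= 3


def _hits(haystack, query):
    return query in haystack or reverse_complement(query) in haystack


class TestCounterselection:
    def test_guide_spans_junction_and_misses_recombinant(self, genome):
        c = design_construct(genome, 604, seed=5)
        guide = design_counterselection_guide(genome, c)
        site = guide.pam_sequence + guide.spacer
        assert _hits(genome.sequence, site)
        assert not _hits(recombinant_sequence(genome, c), site)
        # the protospacer genomic span really straddles the insertion point
        if guide.genomic_strand == "+":
            s0 = guide.genomic_pam_start + 4
            assert s0 < c.insertion_point < s0 + 28
        else:
            s1 = guide.genomic_pam_start
            assert s1 - 28 < c.insertion_point < s1

    def test_no_spanning_pam_raises_with_alternatives(self):
        # PAM-free neighbourhood: no counterselection guide can exist
        seq = "ACGACGGCA" * 200
        g = Genome("NOPAM", seq)
        c = design_construct(g, 900, seed=1)
        with pytest.raises(ValueError, match="junction"):
            design_counterselection_guide(g, c)

    def test_recombination_inserts_construct_core(self, genome):
        c = design_construct(genome, 604, seed=8)
        rec = recombinant_sequence(genome, c)
        assert len(rec) == len(genome.sequence) + len(c.insert)
        assert c.full_sequence in rec


class TestBarseqCounting:
    def test_perfect_reads_count_perfectly(self):
        reads = synthetic.simulate_barcode_reads({BC_A: 1.0}, 100, seed=0)
        t = count_barcodes(reads, expected=[BC_A])
        assert t.counts[BC_A] == 100
        assert t.fractions()[BC_A] == 1.0
        assert t.unassigned == 0

    def test_two_flank_mismatches_unassigned(self):
        from phagei.barcoding import DEFAULT_LEFT_FLANK, DEFAULT_RIGHT_FLANK

        flank = list(DEFAULT_LEFT_FLANK)
        flank[2] = "A" if flank[2] != "A" else "C"
        flank[5] = "A" if flank[5] != "A" else "C"
        read = "GG" + "".join(flank) + BC_A + DEFAULT_RIGHT_FLANK + "AA"
        t = count_barcodes([read], expected=[BC_A])
        assert t.unassigned == 1 and t.counts[BC_A] == 0
        # a single mismatch is within the default budget
        read1 = "GG" + DEFAULT_LEFT_FLANK[:-1] + "A" + BC_A + DEFAULT_RIGHT_FLANK
        if DEFAULT_LEFT_FLANK[-1] == "A":
            read1 = "GG" + DEFAULT_LEFT_FLANK[:-1] + "C" + BC_A + DEFAULT_RIGHT_FLANK
        t1 = count_barcodes([read1], expected=[BC_A])
        assert t1.counts[BC_A] == 1

    def test_unknown_barcode_unassigned_in_expected_mode_but_counted_in_discover(self):
        reads = synthetic.simulate_barcode_reads({BC_B: 1.0}, 10, seed=1)
        assert count_barcodes(reads, expected=[BC_A]).unassigned == 10
        disc = count_barcodes(reads, expected="discover")
        assert disc.counts[BC_B] == 10

    def test_assigned_plus_unassigned_is_total_and_order_invariant(self, rng):
        reads = synthetic.simulate_barcode_reads({BC_A: 0.7, BC_B: 0.3}, 500, seed=4)
        reads += ["ACGT" * 20] * 17  # junk without flanks
        t = count_barcodes(reads, expected=[BC_A, BC_B])
        assert t.assigned + t.unassigned == len(reads)
        shuffled = list(reads)
        rng.shuffle(shuffled)
        t2 = count_barcodes(shuffled, expected=[BC_A, BC_B])
        assert t2.counts == t.counts and t2.unassigned == t.unassigned

    def test_seeded_mixture_recovered_within_binomial_noise(self):
        n = 2000
        reads = synthetic.simulate_barcode_reads({BC_A: 0.9, BC_B: 0.1}, n, seed=9)
        t = count_barcodes(reads, expected=[BC_A, BC_B])
        sd = np.sqrt(0.9 * 0.1 / n)
        assert abs(t.fractions()[BC_A] - 0.9) <= 3 * sd

    def test_fastq_round_trip(self, tmp_path):
        reads = synthetic.simulate_barcode_reads({BC_A: 1.0}, 25, seed=2)
        path = tmp_path / "reads.fastq"
        synthetic.write_fastq(reads, path)
        t = count_barcodes(path, expected=[BC_A])
        assert t.counts[BC_A] == 25

    def test_designed_construct_barcode_recovered_from_amplicons(self, genome):
        c = design_construct(genome, genome.feature("noness"), seed=33)
        reads = synthetic.simulate_barcode_reads(
            {c.barcode: 1.0}, 50, seed=3,
            left_flank=c.left_flank, right_flank=c.right_flank,
        )
        t = count_barcodes(reads, expected="discover",
                           left_flank=c.left_flank, right_flank=c.right_flank)
        assert t.counts == {c.barcode: 50}
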