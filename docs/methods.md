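# Methods notes

This note records the scientific and numerical choices behind `phagei`:
what each component assumes, which parameters matter, and where the
design was genuinely open.

## Guide design

Cas12a binds DNA at a `TTTV` PAM (V = A, C or G) and, as a
catalytically dead protein, stalls elongating RNA polymerase at the
bound site. The designer therefore works entirely on the **coding
strand** of each annotated CDS — the spacer is defined as the 28 nt
immediately 3′ of the PAM on the coding strand — and selects at most
one guide per gene:

* **PAM window.** A PAM is usable when its start offset, divided by the
  CDS length, lies in `[window_lo, window_hi]` = `[0.20, 0.33]`,
  inclusive at both bounds. The lower bound keeps the roadblock clear
  of the annotated start codon and any plausible alternative start; the
  upper bound keeps it 5′ enough to abolish most of the transcript.
  Window membership is evaluated at the *PAM start* offset: the rule
  "x% of the way through the gene" is ambiguous between PAM start, PAM
  end and spacer start, and PAM start is the simplest consistent
  reading. This convention is load-bearing for reproducing benchmark
  untargetable-gene sets, so it is a named config field rather than a
  constant.
* **Tie-break.** Among in-window PAMs the smallest CDS offset wins.
  Deterministic, and matches the "earliest usable site after 20%"
  intent. Design output is a pure function of (genome, config);
  repeated runs are byte-identical.
* **Spacer bounds.** The 28-nt spacer may run past the stop codon —
  knockdown needs the roadblock, not an intra-genic protospacer — but
  must lie within the genome; a PAM whose spacer would run off the
  sequence end is skipped.
* **Degenerate inputs.** Genes shorter than the spacer are untargetable
  with reason `gene too short`; genes with no in-window PAM get
  `no PAM in window`. `N` bases in the subject never satisfy any PAM
  letter (an unknown base is never assumed to be a PAM), and ambiguity
  codes other than N are rejected at genome load. An optional
  `fallback=extend_downstream` mode widens the window to
  `[window_lo, 1.0]` before giving up; it is off by default so strict
  benchmark counts stay reproducible.

Off-target scoring and guide-efficiency prediction are out of scope;
for 50–100 kb phage genomes, guide uniqueness is rarely limiting and no
validated phage-specific efficiency model exists.

## Oligo geometry

Forward oligo `AGAT + spacer + G` and reverse oligo
`GAAAC + revcomp(spacer)` (33 nt each) anneal into a duplex with a
29-bp paired core (spacer plus the terminal G·C) and two 4-nt
single-stranded 5′ extensions (`AGAT`, `GAAA`) for directional Golden
Gate ligation. Only these string invariants are asserted; the vector
map and ligation chemistry are deliberately not modelled — they belong
to the cloning protocol, and the tool's contract is that the strings it
emits have the right geometry.

## Titers, EOP, censoring and calls

Spot titration: 2 µL (`spot_volume_ul`) of each 10-fold dilution
(`10^-k`) is plated; `titer = plaques / (volume_mL · 10^-k)` in PFU/mL.

* **Countable range.** The least-diluted spot with 3–30 plaques is
  used. Counting rules for 2-µL spots are not standardized; 3–30 is a
  common small-spot convention (below 3 the Poisson error is large,
  above 30 plaques overlap) and the range is configurable. If no spot
  is countable but some have plaques, the least-diluted non-zero spot
  is used as a fallback rather than discarding the titration; if every
  spot is clear, the detection limit `1/(volume_mL · 10^-k_min)` at the
  most concentrated spot is returned as a censored upper bound. A
  series in which every spot clears the lawn is an error (dilute
  further), not a number.
* **EOP.** `EOP = titer_target / titer_control`, computed per
  replicate. Censoring propagates multiplicatively from the target; a
  censored *control* titration invalidates the assay. EOP is scale
  invariant in the joint titers.
* **Aggregation.** Mean and sample SD (n−1) over uncensored replicates
  only; censored bounds are never averaged with measured values (a
  bound and a measurement are different objects). If every replicate is
  censored, the mean of the bounds is reported, itself as a bound. A
  censored bound sitting more than 10× below the measured mean
  triggers a contradiction warning but does not change the estimate.
* **Calls.** E when mean (or bound) ≤ `threshold` = 10⁻³ — a plating
  defect of three orders of magnitude or more; NE when the measured
  mean ≥ 10·threshold; the decade in between is `intermediate`,
  reflecting partial defects such as a leaky endolysin knockdown. A
  censored bound *above* the threshold yields `intermediate`: an upper
  bound cannot establish nonessentiality. Raising the threshold can
  only move calls toward E (monotonicity, property-tested).

The shipped lambda/P1 fixture tables keep their printed calls verbatim,
including entries that disagree with the pure numeric rule (e.g. two
genes at EOP 1.2×10⁻² carrying opposite calls) and SD values larger
than their means. The fixtures are evidence, not opinion: the toolkit
reports its own numeric call next to a fixture label and flags
disagreement rather than editing the record.

## Polarity model

The model is purely ordinal: a transcriptional unit is an ordered gene
list (5′→3′), and a bound dCas12a in gene *i* is assumed to silence
genes *i, i+1, …* of that unit completely. Then:

* an E call is **informative** iff no non-complemented gene strictly
  downstream in the unit also calls E (at most one informative gene per
  unit per evaluation);
* an E call with a downstream E is **potentially polar** — the
  phenotype may belong to the downstream gene;
* an NE call with a downstream E is a **readthrough anomaly** — under
  the all-or-nothing roadblock assumption the knockdown should have
  been polar on the downstream requirement, so either the roadblock is
  weak or the transcript map is incomplete;
* genes carried by several units (common in P1) take the most
  conservative status across their units, because the roadblock acts on
  shared DNA and blocks every transcript through it;
* trans-complementation removes the supplied gene from consideration as
  a downstream blocker, letting upstream calls be re-evaluated; the
  complemented gene itself receives no status in that evaluation.

"Downstream essential" uses only the calls given to `interpret`, never
literature knowledge; reconciling a base table against a
complementation rerun (`polar_artifact` / `confirmed_essential` /
`unchanged`) is a separate explicit step. The shipped lambda transcript
fixture encodes only the three lytic units (pL from N through the early
left arm; pR from cro through Q; the pR′ late transcript through J and
the tail-fiber genes) because those carry the essentiality argument;
lysogenic transcripts are omitted, which is why the immunity-region
genes (cI, rexA, rexB) come back `unplaced`. Quantitative readthrough
or antitermination kinetics are out of scope — the model cannot explain
*why* a roadblock leaks, only flag that it did.

## Barcoding and Barseq

Constructs copy `arm_length` = 100 nt of genomic sequence verbatim on
each side of the insertion point (the midpoint of the chosen locus, or
an explicit coordinate) around `left_flank + barcode + right_flank`.
The 20-nt barcode is drawn from seeded randomness under composition
filters — GC fraction in [0.25, 0.75], no homopolymer ≥ 5, and minimum
pairwise Hamming distance 3 when drawing a set — standard
amplicon-sequencing hygiene for a "random" barcode; all filters are
configurable. The primer-binding flanks are opaque configurable
strings with arbitrary defaults: real primer choices are an
experimental decision, so the toolkit never hard-codes them.

The counterselection guide search scans **both strands** within
`search_radius` = 200 nt of the junction (cutting needs a target, not a
coding-strand orientation) and requires the protospacer's genomic span
to strictly contain the insertion point, then verifies the
protospacer+PAM string is absent from the in-silico recombinant. When
no PAM supports a junction-spanning spacer the error lists the nearest
non-spanning sites; a junction in a PAM-poor neighbourhood genuinely
has no counterselection guide, and callers should pick a different
insertion point.

Barcode counting anchors the left flank at the leftmost position within
`max_flank_mismatches` = 1 (Hamming only — an indel in a flank shifts
the barcode frame and the read is better discarded than miscounted),
takes the next 20 nt, and requires the right flank immediately after
under the same budget. The extracted 20-mer is matched **exactly**
against the expected set (or tallied as-is in discover mode); no error
correction is applied to the barcode itself. Counting is invariant to
read order, and assigned + unassigned = total always.

## Synthetic data

The generator emulates the screen's inputs at desk scale:

* **Genomes** — `n_genes` (default 20) ATG-initiated, stop-terminated
  ORFs of 150–900 nt on random strands, separated by 20–120 nt
  intergenic gaps, at a configurable GC fraction. Genes selected by
  `plant_pam_fraction` get a codon-aligned `TTTV` planted with its PAM
  start inside the design window, so designer hits are guaranteed by
  construction; `pam_free` mode instead builds genes from codons
  containing no `TT`, which provably excludes any `TTT` run and forces
  every gene untargetable. Planting writes a Phe codon (`TTT`)
  followed by a codon starting with A/C/G, which can never create an
  in-frame stop.
* **Titrations** — spot counts are Poisson around
  `EOP_true · control_titer · volume_mL · 10^-k`, with draws above 300
  recorded as lawn-cleared. The default control titer of 10¹⁰ PFU/mL
  with dilutions 10⁰..10⁻⁸ keeps targets down to EOP 10⁻⁶ inside the
  countable range of the series — matching the dynamic range a real
  screen needs to resolve a 5-log knockdown — while EOP ≲ 10⁻⁸ runs
  into the detection limit and exercises the censoring path.
* **Barseq reads** — a random 0–10 nt prefix, left flank, barcode,
  right flank, random filler to 80 nt.

Everything is a pure function of the seed. The simulations
deliberately omit plate-to-plate overdispersion, sequencing errors
inside reads, PCR chimeras, partial knockdown phenotypes and CRISPRi
escape mutants; passing recovery tests therefore show the *estimators*
are correct under Poisson/binomial sampling, not that real assays are
free of systematic error. Recovery tolerances are statistical, not
tuned: EOP grid recovery is asserted within 3 standard errors of the
replicate mean, and Barseq mixture recovery within 3 binomial SDs.

## Benchmark reproduction

The design rule is benchmarked against the RefSeq genomes of phage
lambda (NC_001416.1) and P1 (NC_005856.1): with defaults it should
target 67/73 lambda genes (missing exactly cII, ninD, ninE, ninH, Rz1
and lambdap35) and 114/117 P1 genes (missing upfM, pdcA and imcA) —
the untargetable rosters are read from the NT rows of the shipped
tables, not hard-coded. The GenBank records are fetched from NCBI on
demand and cached under `data/reference/`; they are not redistributed
with the package, so the benchmark tests require either network access
or a pre-populated cache, and report per-gene diagnostics on any
disagreement. Whether "lacks a canonical PAM site" means "none in the
20–33% window" or "none anywhere in the gene" is an open reading; the
strict-window interpretation is the default and is what the benchmark
asserts.

## Known limitations

* Origin-wrapping features on circular genomes are rejected rather than
  unwrapped; neither benchmark genome needs them.
* Compound (joined) CDS locations are rejected; phage CDSs here are
  simple spans.
* One guide per gene: no tiling, no multi-guide designs, no dCas9
  sgRNA support.
* The polarity model is qualitative; it cannot rank partial readthrough.
* Barcode matching does no error correction, so per-barcode counts are
  slight undercounts at realistic sequencing error rates; flank-anchored
  exact matching keeps false assignment negligible instead.
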