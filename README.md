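# phagei

Genome-wide CRISPRi gene-essentiality mapping for bacteriophages:
Cas12a guide design, cloning-oligo generation, efficiency-of-plating
(EOP) analysis, polarity-aware interpretation, and DNA-barcode
(Barseq) engineering support.

## The problem

Most phage genes have no experimentally assigned function, and even
deciding which genes a phage *needs* to form plaques is slow with
classical genetics. CRISPR interference offers a scalable alternative:
a catalytically dead Cas12a (dCas12a) loaded with a gene-specific crRNA
binds the phage DNA and acts as a transcription roadblock, knocking the
gene down without editing the genome. Plating the phage on a lawn
expressing each guide, one gene at a time, turns essentiality into a
simple plaque-counting assay. `phagei` implements the computational
side of that workflow for people running such screens:

* **Guide design** — scan each coding sequence (coding strand only) for
  the Cas12a PAM `TTTV`; accept PAM sites whose start offset lies
  between 20% and 33% of the CDS length (robust to alternative start
  codons, still close enough to the 5′ end to block transcription), and
  take the 28 nt immediately 3′ of the PAM as the spacer. Genes with no
  in-window PAM are reported untargetable.
* **Oligo generation** — each spacer becomes a Golden-Gate-compatible
  duplex: forward `AGAT + spacer + G`, reverse
  `GAAAC + revcomp(spacer)`, a 29-bp paired core with 4-nt 5′
  overhangs, plus a 96-well order sheet.
* **EOP analysis** — from 10-fold spot-titration plaque counts,
  `EOP = titer(test lawn) / titer(nontargeting control lawn)`.
  Zero-plaque titrations propagate as censored upper bounds (`<x`).
  Genes with mean EOP ≤ 10⁻³ (a ≥3-log plating defect) are called
  essential (E), ≥ 10⁻² nonessential (NE), in between intermediate.
* **Polarity interpretation** — a DNA roadblock silences every gene
  downstream on the same transcript, so an E readout is only
  *informative* for the last required gene of a transcriptional unit.
  Upstream E calls are flagged potentially polar; NE calls upstream of
  an essential gene are flagged as readthrough anomalies; supplying a
  downstream gene product in trans (e.g. the lambda antiterminator Q
  from a plasmid) re-evaluates the unit without that blocker.
* **Barcoding** — for nonessential loci, design recombination
  constructs (two 100-bp homology arms around a random 20-nt barcode
  between fixed primer-binding flanks), pick a counterselection guide
  whose protospacer spans the insertion junction (cuts wild type, not
  the recombinant), and count barcodes in amplicon-sequencing reads.

The package ships the transcribed essentiality tables for coliphages
lambda and P1 (including the Q-complementation rerun block and lambda's
three lytic transcriptional units) as fixtures, and a synthetic-data
module that generates annotated genomes with plantable PAM sites,
Poisson-noise titration tables, and barcode read sets with known truth.

## Worked example

```bash
phagei simulate --seed 9 --n-genes 6 --outdir sim
phagei design --genome sim/genome.gb --out design.tsv
phagei oligos --design design.tsv --out oligos.tsv
phagei eop --counts sim/counts.tsv --out eop.tsv
```

prints

```
synthetic genome and counts written to sim
6 guides designed, 0 untargetable (none)
6 oligo pairs written to oligos.tsv
6 genes: {'E': 2, 'NE': 4, 'intermediate': 0}
```

`design.tsv` holds one guide per gene, e.g.

```
locus_tag  gene  pam_genomic_start  strand  pam_seq  pam_cds_offset  pam_fraction  spacer                        status
sim_000    g000  290                +       TTTA     178             0.212664      CAGGCAGATCTTTGTCAGGTACGAATCT  targeted
```

— gene `sim_000` gets a `TTTA` PAM starting 178 nt into its CDS (21.3%
of the gene, inside the 20–33% window) and the 28-nt spacer that
follows it on the coding strand. The simulated screen gave the first
two genes a true EOP of 10⁻⁵ and the rest 1.0; `eop.tsv` recovers
exactly that:

```
locus_tag  gene  EOP_average  SD       call
sim_000          1.1E-05      1.4E-06  E
sim_001          1.2E-05      4.5E-06  E
sim_002          9.5E-01      4.4E-01  NE
```

The same stages run as a single pipeline (`phagei run --config
cfg.json`), which also applies the polarity interpretation when a
transcript-unit map is provided. On the shipped lambda fixtures the
interpretation reports that, of the 36 genes reading out essential,
only **N, P, Q and J** are informative — every other E call sits
upstream of another required gene on the same transcript — and flags
`orf-64` (nonessential readout upstream of essential late genes) as a
roadblock-readthrough anomaly.

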