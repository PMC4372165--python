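# dgrscope

Detection and characterization of **diversity-generating retroelements
(DGRs)** in microbial and viral genomes — including the archaeal and
archaeal-virus systems where DGRs were first found outside bacteria.

A DGR diversifies a target gene through error-prone retrohoming: the RNA of
a non-coding **template repeat (TR)** is reverse-transcribed by the
element's own reverse transcriptase (RT), with template **adenines**
misread essentially at random, and the mutagenized cDNA replaces the
**variable repeat (VR)** inside the target-protein (TP) gene. The
signature in genomic sequence is a pair of ~114-bp repeats near an RT gene
that differ from each other almost exclusively at positions that are A in
one copy — plus cis-acting elements: an IMH motif at the VR 3′ end with an
IMH* counterpart at the TR 3′ end (TGGGGT/TGGAAT in the archaeal systems),
and a short stem-loop with a constrained G-R-A loop inside the TP gene.

`dgrscope` implements the complete discovery pipeline:

- **seqcore** — FASTA/FASTQ/BED/GFF3 I/O, six-frame ORF scanning
  (genetic code 11), read QC (N-removal, 2.5% length tails, mean-quality
  cut, dereplication);
- **dgr_detect** — RT motif scan ([YF]x[DA]D catalytic core), seed-and-extend
  repeat discovery within ±5 kb of RT, and the TR/VR classifier: a copy is
  accepted as template when the pair shows **≥ 10 adenine-specific
  mismatches with respect to that copy and ≤ 2 non-adenine mismatches per
  100 bp** of aligned sequence;
- **cis_elements** — IMH/IMH* motif pairs, exhaustive maximal stem-loop
  enumeration, and Avd-like ORF selection by isoelectric point and
  molecular weight (pI = 9 ± 1, Mw = 10 ± 5 kDa);
- **diversity** — exact adenine-mutagenesis combinatorics: `4^A` nucleotide
  variants for `A` template adenines, and the protein repertoire
  `Π_codons |reachable amino acids|` with stop-codon risk tracking;
- **tetra** — tetranucleotide genome signatures (zero-order-Markov odds
  ratios over 5-kb windows, 500-bp step), non-metric MDS on Euclidean
  distances, 95% confidence ellipses, and compositional-outlier flagging
  (the horizontal-acquisition test for DGR RT genes);
- **synthetic_data** — genomes with planted cassettes and full ground
  truth, for end-to-end validation without external data.

## Worked example

Simulate a genome with one planted cassette, then detect it:

```bash
$ dgrscope simulate --seed 3 --out-prefix demo
wrote demo.fasta / .truth.json / .gff3 (1 cassette(s))

$ dgrscope detect demo.fasta --out-prefix demo_detect
1 cassette(s); wrote demo_detect.json, demo_detect.gff3, demo_detect.tsv
```

The TSV report (one row per cassette):

```
record_id        cassette  complete  rt_start  rt_end  tr_start  tr_end  vr_start  vr_end  n_adenines  n_nt_variants              n_diversifiable_codons  n_aay_codons  n_protein_variants   nonsense_risk
synthetic_seed3  0         True      25322     25775   24734     24849   24410     24525   41          4835703278458516698824704  27                      3             1358954496000000000  False
```

Reading the numbers: the detected template repeat carries 41 adenines, so
theoretical mutagenesis can emit 4^41 ≈ 4.8 × 10^24 distinct cDNAs;
translated through the target-protein reading frame those collapse to
~1.4 × 10^18 distinct protein variants across 27 diversifiable codons
(3 of them maximally-diversifiable AAY codons), and no substitution of any
template adenine can create a stop codon (`nonsense_risk False`). The JSON
report additionally locates the TGGGGT/TGGAAT IMH/IMH* pair at the repeat
3′ ends, the stem-6 GRA-loop hairpin inside the TP gene downstream of VR,
and an Avd-like ORF (pI 9.3, 8.9 kDa) between the TP and RT genes.

The diversification census is also available standalone:

```bash
$ dgrscope diversity --tr-seq AATAATAATAATAATAATAATAATAAT
{
  "n_adenines": 18,
  "n_nt_variants": "68719476736",
  "n_diversifiable_codons": 9,
  "n_aay_codons": 9,
  "n_protein_variants": "38443359375",
  "nonsense_risk": false
}
```

(nine AAY codons: each reaches 15 amino acids, 15^9 = 38 443 359 375.)

Other verbs: `dgrscope tetra <fasta>` for the genome-signature ordination,
`dgrscope cis` for standalone IMH/hairpin searches, `dgrscope run` for the
full pipeline with a YAML config.

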