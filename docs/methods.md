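# Methods

This note documents the models, numerical choices and validation strategy
behind `dgrscope`, in the spirit of a statistical-software methods page:
what each stage computes, which knobs matter, and what the synthetic
benchmarks do and do not demonstrate.

## Detection model

**RT candidates.** DGR reverse transcriptases are located by protein motif
rather than database homology, so detection is deterministic and runs
offline: any ORF of ≥ 100 aa whose translation matches the RT catalytic
core `[YF]x[DA]D` is a candidate. Known DGR RTs carry this motif; the
pattern is deliberately permissive because candidates are only *anchors* —
a false RT anchor without a qualifying repeat pair produces no cassette.
Users with externally annotated RT loci can bypass the scan with
`--rt-bed`.

**Repeat pairs.** Within ±5 kb of each anchor (`window_bp`), exact 12-mer
seeds shared by two positions (direct) or between the window and its
reverse complement (inverted) are extended ungapped. Extension is accepted
column-by-column while the running mismatch fraction of the whole
alignment stays ≤ `max_mismatch_frac` (0.25). Because that rule lets the
interior mismatch budget leak tens of bases into flanking background, each
boundary is then trimmed back to the strict maximum of a running score
with match +1 / mismatch −1.5. The penalty approximates the log-likelihood
ratio between the two regimes the boundary separates (~90% identity inside
a repeat at the detection limit, 25% chance identity outside); empirically
it crosses short interior mismatch clusters without overshooting, placing
boundaries within ±3 bp of planted truth for ~95% of detectable synthetic
cassettes. Ungapped alignment is sufficient because the classification
criteria are phrased per aligned column and indels within TR/VR are rare
in known DGRs; a gapped refinement pass is out of scope.

**TR/VR classification.** For a repeat pair, each copy is tested as the
putative template: copy X qualifies when the pair shows at least
`min_adenine_mm` (10) mismatch columns where X carries A, and at most
`max_other_per_100bp` (2) × aligned_len/100 mismatch columns where it does
not. The non-adenine allowance scales linearly with aligned length and is
a real-valued threshold; the adenine minimum is absolute. "With respect to
one strand" is operationalized as "with respect to one of the two copies",
both being tested; if both qualify the copy with more adenine-specific
mismatches is the template, and an exact tie is rejected as
`ambiguous-template` (with ≥ 10 adenine mismatches on both copies this
requires ≥ 1 kb of alignment, since each copy's adenine columns count
against the other's non-adenine budget). N matches nothing.

**Cassette assembly.** The target-protein gene is the ORF (any strand)
fully containing VR, the longest when several do; a cassette whose TR lies
inside its own TP is discarded (the template must be non-coding), and
cassettes sharing a VR interval are merged. A passing TR/VR call without
an RT anchor is emitted flagged `partial`, mirroring fragmentary elements
that retain only a target gene, VR and cis-elements. Cross-cassette
feature similarity uses Needleman-Wunsch global alignment (match +1,
mismatch −1, gap −2), identity = matches / columns × 100, with `NA` for
features absent from either cassette.

## Cis-elements

*IMH/IMH\**: the 3′-terminal 40 bp of VR and TR (plus 10 bp of downstream
flank) are scanned for a configured motif pair — default TGGGGT (IMH,
in VR) against TGGAAT (IMH*, in TR) — requiring offsets from the 3′ end to
agree within 5 bp; the 3′-most consistent hit wins. The 40-bp span and
5-bp slack are package choices; the defining constraint from the biology
is motif content and 3′-end placement.

*Stem-loops*: exhaustive enumeration of exact Watson-Crick stems
(4–12 bp) around loops of 3–8 nt. A reported hairpin is maximal: its stem
cannot grow outward and its loop cannot shrink into a longer stem. Loops
are classified GRA / GRNA / other. No thermodynamic scoring and no G·U or
mismatched pairs — the element is defined structurally here, not
energetically — so the finder can be (and is) tested against brute-force
enumeration for exact equality.

*Avd-like ORFs*: accessory variability determinant homologues are small
and basic; ORFs between RT and TP are kept when pI ∈ 9 ± 1 and
Mw ∈ 10 ± 5 kDa (the mass window is interpreted in kDa, consistent with
known Avd proteins). pI comes from bisection on the Henderson–Hasselbalch
net charge with a fixed pKa table (N-term 8.6, C-term 3.6, C 8.5, D 3.9,
E 4.1, H 6.5, K 10.8, R 12.5, Y 10.1), solved to |charge| < 1e-4; the
fixed table makes results exactly reproducible across environments. When
several ORFs qualify, the one closest to the window centers (scaled by the
half-widths) is attached to the cassette.

## Diversification counts

Every template adenine is treated as independently readable as any of the
four bases. For a VR-aligned template segment with `A` adenines the
nucleotide repertoire is exactly `4^A`. Per codon, all `4^k` substitutions
of its `k` adenine positions are enumerated and translated (code 11);
the protein repertoire is the exact product of per-codon reachable
amino-acid set sizes (stops excluded from the sets but recorded as a
`stop_reachable` flag, whose disjunction is the cassette's
`nonsense_risk`). A codon is *diversifiable* when it has ≥ 1 adenine and
≥ 2 reachable amino acids — so codons like TCA (all TCN = Ser) count as
adenine-bearing but not diversifiable. All counts are arbitrary-precision
integers end to end; the TSV/JSON writers emit them as exact decimal
strings. The product formula is exact (not an approximation) because
codons partition the sequence and substitutions act within codons; the
test suite nevertheless verifies it against full enumeration of all `4^A`
variants for random templates.

## Tetranucleotide signatures

Sequences are fragmented into 5-kb windows at a 500-bp step (trailing
partial windows dropped; shorter sequences skipped with a warning). Each
window yields the 256-vector of zero-order-Markov odds ratios
`observed(w) / (L′ · Π p(base))`, with mononucleotide frequencies taken
from the window's non-N bases and N-containing 4-mer positions skipped;
zero-expected (hence zero-observed) entries are set to the neutral value
1.0. Conservation `Σ observed = Σ expected = L′` holds identically.
Counting is single-strand and odds ratios are used raw (no log transform),
as the procedure is conventionally described; both are toggleable. One
consequence worth noting: a pure mononucleotide (GC) shift is normalized
away by construction — compositional outliers require higher-order
structure, which is exactly what makes the statistic a genome signature.

Windows are compared by Euclidean distance and embedded by non-metric MDS
(SMACOF with isotonic regression, 20 seeded random starts, normalized
Kruskal stress-1, via scikit-learn), coordinates centered; deterministic
for a fixed seed. Group summaries use the chi-square covariance
construction: center = mean, semi-axes = sqrt(eigenvalue × q) with
q = χ²₂(0.95) = 5.991, angle from the leading eigenvector. A window is a
compositional outlier when its squared Mahalanobis distance from the
genome group exceeds q; the per-group outlier fraction is the summary used
to ask whether RT genes sit outside their host genome's core signature.

## Synthetic genomes

The generator plants, on the forward strand of an iid background
(default 50 kb, GC 0.45), cassettes laid out TP … TR … Avd … RT within a
10-kb span: a TP gene hosting the codon-aligned VR (default 114 bp,
`repeat_len` must be a multiple of 3) with a stem-6 GRA-loop hairpin
downstream of VR, an intergenic TR, a small basic Avd-like ORF
(engineered to pI 8–10, 5–15 kDa) and an RT ORF carrying YADD. Each
planted ORF is preceded by an in-frame stop so the ORF scanner reproduces
its exact start.

VR derives from TR by the substitution model: each template adenine is,
with probability `p_adenine_sub` (0.40), replaced by a uniform draw over
the four bases — a draw of A is silent, so the per-adenine mismatch
probability is 3/4 of that — and non-adenine positions substitute with
probability `p_background_sub` (0). TR codons are sampled from the
stop-safe pool (no adenine substitution can create a stop), which makes
`nonsense_risk` provably false for planted cassettes; because that pool
excludes adenine-rich codons, the per-base adenine probability is
calibrated by bisection so the realized TR adenine fraction matches
`tr_adenine_frac` (0.30). The IMH*/IMH motifs occupy the two codons just
inside the repeat 3′ end, flanked by adenine-free first/last codons, so
repeat boundaries are crisp identity changepoints and the two forced
motif mismatches (the AAT→GGT adenines) lie inside the repeat. Truth
records carry all planted intervals plus mismatch counts *recounted from
the emitted sequence*. Identical config and seed give byte-identical
output.

**What the defaults imply.** At 114 bp × 0.30 adenines × 0.40 × 3/4 the
expected adenine-specific mismatch count is ≈ 10.3 — sitting on the ≥ 10
detection threshold, with a binomial standard deviation near 3. Roughly a
fifth to a quarter of planted cassettes therefore fall below the
threshold and are *correctly* not called; measured end-to-end recovery at
defaults is ~70–80% over 50 seeds, ~95% among cassettes that meet the
rule, with zero complete-cassette calls on matched negative genomes.
Passing synthetic tests shows the machinery is correct under this model;
it does not show robustness to features real data have and the generator
lacks: indels between repeat copies, non-uniform substitution spectra,
repeats split across contigs, coding-strand skews in the background, or
RT pseudogenes.

## Read QC

The filter chain applies, in order: removal of reads with ambiguous
bases; removal of the shortest and longest 2.5% (count = floor(0.025·n)
per tail, computed after the N filter, ties by input order); removal of
reads with mean quality more than 2 population standard deviations below
the mean of the remaining reads; exact-duplicate removal keeping the
first occurrence (a deliberate simplification of clustering-based
dereplication). The chain is not idempotent — the percentile and
quality cuts are relative to whatever set they see — so repeated
application keeps shaving tails; the tests pin the per-stage counting
contract instead.

## Known limitations

- Repeat alignment is ungapped; a cassette whose TR/VR differ by an indel
  will be truncated at the indel.
- RT detection by a single short motif trades specificity for
  database-independence; anchors are cheap, but `--rt-bed` is the route
  for curated loci.
- Partial-DGR discovery is anchor-driven: TR/VR pairs far from any RT
  motif hit (or supplied locus) are not searched genome-wide.
- The tetranucleotide stage follows the conventional recipe exactly;
  PERMANOVA-style significance testing and other k-mer orders are out of
  scope.
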