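"""Diversification potential of a TR/VR/target-gene triple.

During DGR retrohoming, adenines of the template-repeat RNA are read
unfaithfully, so every template adenine can appear as any of the four bases
in the integrated cDNA. The theoretical repertoire is therefore 4^A
nucleotide variants (A = template adenines in the VR-aligned segment), and
at the protein level the product over codons of the number of distinct
amino acids reachable by substituting that codon's adenines. All counts are
exact big integers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Optional, Sequence

from .seqcore import GenomeRecord, revcomp, translate

BASES = "ACGT"


@dataclass
class CodonDiversity:
    """Reachable amino-acid set of one template codon under adenine substitution."""

    codon_index: int
    tr_codon: str
    adenine_positions: tuple[int, ...]
    reachable_aa: frozenset[str]
    stop_reachable: bool
    is_aay: bool
    diversifiable: bool


@dataclass
class DiversitySummary:
    n_adenines: int
    n_nt_variants: int
    codons: list[CodonDiversity]
    n_diversifiable_codons: int
    n_aay_codons: int
    n_protein_variants: int
    nonsense_risk: bool
    skipped_edge_bases: tuple[int, int] = (0, 0)


def count_template_adenines(tr_segment: str) -> int:
    """Exact count of A in a template segment ({A,C,G,T} only; N raises)."""
    seg = tr_segment.upper()
    bad = set(seg) - set(BASES)
    if bad:
        raise ValueError(f"non-ACGT characters in template segment: {sorted(bad)}")
    return seg.count("A")


def nucleotide_variant_count(n_adenines: int) -> int:
    """4^n as an exact integer."""
    if n_adenines < 0:
        raise ValueError("adenine count cannot be negative")
    return 4 ** n_adenines


def codon_diversity(
    tr_segment: str, frame_offset: int = 0, genetic_code: int = 11
) -> list[CodonDiversity]:
    """Per-codon reachable amino acids under adenine substitution.

    Codons are read from ``frame_offset`` within the template segment;
    partial edge codons are skipped. For each codon every 4^k substitution
    of its k adenine positions is enumerated and translated.
    """
    if frame_offset not in (0, 1, 2):
        raise ValueError("frame_offset must be 0, 1 or 2")
    seg = tr_segment.upper()
    if len(seg) - frame_offset < 3:
        raise ValueError("segment too short for a complete codon at this offset")
    out = []
    n_codons = (len(seg) - frame_offset) // 3
    for ci in range(n_codons):
        codon = seg[frame_offset + 3 * ci : frame_offset + 3 * ci + 3]
        ad_pos = tuple(k for k in range(3) if codon[k] == "A")
        reachable: set[str] = set()
        stop = False
        for combo in product(BASES, repeat=len(ad_pos)):
            variant = list(codon)
            for k, b in zip(ad_pos, combo):
                variant[k] = b
            aa = translate("".join(variant), genetic_code)
            if aa == "*":
                stop = True
            else:
                reachable.add(aa)
        out.append(
            CodonDiversity(
                codon_index=ci,
                tr_codon=codon,
                adenine_positions=ad_pos,
                reachable_aa=frozenset(reachable),
                stop_reachable=stop,
                is_aay=codon in ("AAT", "AAC"),
                diversifiable=len(ad_pos) >= 1 and len(reachable) >= 2,
            )
        )
    return out


def protein_variant_count(codons: Sequence[CodonDiversity]) -> int:
    """Exact product of per-codon reachable amino-acid set sizes.

    Stops are excluded from the sets; codons that can only reach a stop
    contribute a factor of 0 (no viable variant through that codon).
    """
    total = 1
    for c in codons:
        total *= len(c.reachable_aa)
    return total


def summarize_diversity(
    tr_segment: str, frame_offset: int = 0, genetic_code: int = 11
) -> DiversitySummary:
    """Full adenine-mutagenesis census of a VR-aligned template segment."""
    n_a = count_template_adenines(tr_segment)
    codons = codon_diversity(tr_segment, frame_offset, genetic_code)
    trailing = (len(tr_segment) - frame_offset) % 3
    return DiversitySummary(
        n_adenines=n_a,
        n_nt_variants=nucleotide_variant_count(n_a),
        codons=codons,
        n_diversifiable_codons=sum(c.diversifiable for c in codons),
        n_aay_codons=sum(c.is_aay for c in codons),
        n_protein_variants=protein_variant_count(codons),
        nonsense_risk=any(c.stop_reachable for c in codons),
        skipped_edge_bases=(frame_offset, trailing),
    )


def cassette_tr_segment(cassette, record: GenomeRecord) -> tuple[str, int]:
    """The TR segment aligned to VR, oriented and framed by the target gene.

    Returns (oriented template segment, frame offset in the TP reading
    frame). Requires a passing TR/VR call and a TP gene; raises
    ``frame-unknown`` otherwise.
    """
    call = cassette.trvr
    tp = cassette.tp_orf
    if not call.passed or tp is None:
        raise ValueError("frame-unknown: cassette lacks a passing TR/VR call or a TP gene")
    tr, vr = call.tr, call.vr
    tr_seq = record.sequence[tr[0] : tr[1]]
    # orient TR the way VR reads within the genome forward strand
    if call.template_strand == "-":
        tr_seq = revcomp(tr_seq)
    if tp.strand == "+":
        # bases to skip so codon reading aligns with the TP frame
        frame = (tp.start - vr[0]) % 3
    else:
        tr_seq = revcomp(tr_seq)
        frame = (tp.end - vr[1]) % 3
    return tr_seq, frame


def summarize_cassette(cassette, record: GenomeRecord) -> DiversitySummary:
    tr_seq, frame = cassette_tr_segment(cassette, record)
    return summarize_diversity(tr_seq, frame)
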