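"""Core DGR detection.

A diversity-generating retroelement (DGR) is recognized by: a reverse
transcriptase (RT) gene; a nearby pair of repeats, the template repeat (TR)
and the variable repeat (VR), that differ from each other predominantly at
positions that are adenine in TR; and cis-acting elements (IMH/IMH* motifs,
a stem-loop). Detection proceeds RT -> repeat pairs within a +/-5 kb window
-> adenine-mismatch classification -> cassette assembly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

from Bio import Align

from . import cis_elements
from .seqcore import GenomeRecord, OrfFeature, revcomp

DEFAULT_RT_MOTIFS = {
    # The catalytic core of reverse transcriptases: Y/F-x-D/A-D.
    "RT_catalytic": r"[YF].[DA]D",
}


@dataclass
class RtCandidate:
    """An ORF flagged as a putative DGR reverse transcriptase."""

    orf: OrfFeature
    motif_hits: list[tuple[str, int]]
    score: int = 0

    def __post_init__(self) -> None:
        if not self.score:
            self.score = len({name for name, _ in self.motif_hits})


@dataclass
class RepeatPair:
    """Two aligned repeat copies (ungapped) found near an RT anchor.

    For ``inverted`` orientation the copyB row of ``alignment`` is the
    reverse complement of the genomic copyB interval, so alignment columns
    correspond position-wise in both orientations.
    """

    record_id: str
    copyA_start: int
    copyA_end: int
    copyB_start: int
    copyB_end: int
    orientation: str  # direct | inverted
    aligned_len: int
    alignment: tuple[str, str]

    def intervals(self) -> tuple[tuple[int, int], tuple[int, int]]:
        return (self.copyA_start, self.copyA_end), (self.copyB_start, self.copyB_end)


@dataclass
class MismatchProfile:
    """Per-column mismatch bookkeeping for a repeat pair.

    ``n_adenine_wrt_A`` counts mismatch columns where copyA carries A (the
    adenine-specific changes if copyA were the template), and similarly for
    copyB. N matches nothing.
    """

    positions: list[tuple[int, str, str]]
    n_adenine_wrt_A: int
    n_other_wrt_A: int
    n_adenine_wrt_B: int
    n_other_wrt_B: int
    aligned_len: int

    @property
    def n_mismatches(self) -> int:
        return len(self.positions)


@dataclass
class TrVrCall:
    tr: Optional[tuple[int, int]]
    vr: Optional[tuple[int, int]]
    template_strand: str
    profile: MismatchProfile
    passed: bool
    reasons: list[str] = field(default_factory=list)
    pair: Optional[RepeatPair] = None


@dataclass
class DgrCassette:
    """An assembled DGR element; ``complete`` requires RT plus a passing TR/VR call."""

    record_id: str
    rt: Optional[RtCandidate]
    trvr: TrVrCall
    tp_orf: Optional[OrfFeature] = None
    imh: Optional["cis_elements.ImhPair"] = None
    hairpin: Optional["cis_elements.Hairpin"] = None
    avd: Optional["cis_elements.AvdCandidate"] = None
    flags: list[str] = field(default_factory=list)
    complete: bool = False

    def __post_init__(self) -> None:
        self.complete = self.rt is not None and self.trvr.passed
        if self.rt is None and self.trvr.passed and "partial" not in self.flags:
            self.flags.append("partial")


# ---------------------------------------------------------------------------
# RT candidate scan
# ---------------------------------------------------------------------------

def scan_rt_candidates(
    orfs: Sequence[OrfFeature],
    motif_config: dict[str, str] | None = None,
    min_motifs: int = 1,
    min_protein_len: int = 100,
) -> list[RtCandidate]:
    """Flag ORFs whose proteins match reverse-transcriptase motif patterns.

    ``motif_config`` maps motif names to regular expressions over the amino
    acid alphabet; the default contains the RT catalytic [YF]x[DA]D core.
    Deterministic for fixed input.
    """
    motifs = motif_config if motif_config is not None else DEFAULT_RT_MOTIFS
    if not motifs:
        raise ValueError("motif_config must define at least one motif")
    out = []
    for orf in orfs:
        if len(orf.protein) < min_protein_len:
            continue
        hits = []
        for name, pattern in motifs.items():
            for m in re.finditer(pattern, orf.protein):
                hits.append((name, m.start()))
        if len({name for name, _ in hits}) >= min_motifs:
            out.append(RtCandidate(orf=orf, motif_hits=hits))
    return out


# ---------------------------------------------------------------------------
# Repeat pair discovery (seed and extend)
# ---------------------------------------------------------------------------

def _mismatch(a: str, b: str) -> bool:
    # N mismatches everything, including another N
    return a != b or a == "N"


def _extend_direct(region: str, i: int, j: int, seed_len: int, frac: float):
    """Ungapped two-sided extension of a direct seed at offsets (i, j), i < j.

    Extension proceeds while the running mismatch fraction over the whole
    current alignment stays <= frac; a score-peak trim (match +1, mismatch
    -1, outermost running-score maximum kept) then refines each boundary
    back onto the repeat.
    """
    n = len(region)
    diag = j - i
    # right extension: copyA may not run into copyB's start (a < j)
    a, b = i + seed_len, j + seed_len
    length, mm = seed_len, 0
    right_cols: list[bool] = []
    while b < n and a < j:
        is_mm = _mismatch(region[a], region[b])
        if (mm + is_mm) / (length + 1) > frac:
            break
        right_cols.append(is_mm)
        mm += is_mm
        length += 1
        a += 1
        b += 1
    r_keep = _peak_len(right_cols)
    endA = i + seed_len + r_keep
    # reset the mismatch budget to the kept (trimmed) alignment
    mm = sum(right_cols[:r_keep])
    length = seed_len + r_keep
    # left extension: copyB's start may not dip into copyA (b >= endA)
    a, b = i - 1, j - 1
    left_cols: list[bool] = []
    while a >= 0 and b >= endA:
        is_mm = _mismatch(region[a], region[b])
        if (mm + is_mm) / (length + 1) > frac:
            break
        left_cols.append(is_mm)
        mm += is_mm
        length += 1
        a -= 1
        b -= 1
    l_keep = _peak_len(left_cols)
    startA = i - l_keep
    startB = startA + diag
    endB = endA + diag
    return startA, endA, startB, endB


def _peak_len(cols: list[bool]) -> int:
    """Length of the prefix of ``cols`` through the first strict running-score
    maximum (match +1, mismatch -1.5).

    The score drifts upward inside a repeat (~90% identity at the detection
    limit) and downward in background (~25% chance identity), so the peak
    marks the repeat boundary; the -1.5 penalty approximates the
    log-likelihood ratio between those two regimes, crossing short interior
    mismatch clusters without overshooting into background."""
    best, best_at = 0.0, 0
    s = 0.0
    for k, is_mm in enumerate(cols, start=1):
        s += -1.5 if is_mm else 1.0
        if s > best:
            best, best_at = s, k
    return best_at


def _extend_inverted(region: str, i: int, j_end: int, seed_len: int, frac: float):
    """Extension of an inverted seed: region[i:i+seed_len] pairs with the
    reverse complement of region[j_end-seed_len:j_end]. Column k of the
    alignment compares region[i+k] with complement(region[j_end-1-k])."""
    n = len(region)
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}

    def col_mm(a_pos: int, b_pos: int) -> bool:
        x, y = region[a_pos], region[b_pos]
        if x not in comp or y not in comp:
            return True
        return comp[x] != y

    # right extension: a grows, b shrinks
    a, b = i + seed_len, j_end - seed_len - 1
    length, mm = seed_len, 0
    right_cols = []
    while b >= 0 and a < n and a <= b:
        is_mm = col_mm(a, b)
        if (mm + is_mm) / (length + 1) > frac:
            break
        right_cols.append(is_mm)
        mm += is_mm
        length += 1
        a += 1
        b -= 1
    r_keep_inv = _peak_len(right_cols)
    mm = sum(right_cols[:r_keep_inv])
    length = seed_len + r_keep_inv
    # left extension: a shrinks, b grows (arms diverge, no crossing possible)
    a, b = i - 1, j_end
    left_cols = []
    while a >= 0 and b < n:
        is_mm = col_mm(a, b)
        if (mm + is_mm) / (length + 1) > frac:
            break
        left_cols.append(is_mm)
        mm += is_mm
        length += 1
        a -= 1
        b += 1
    r_keep = r_keep_inv
    l_keep = _peak_len(left_cols)
    startA = i - l_keep
    endA = i + seed_len + r_keep
    startB = j_end - seed_len - r_keep
    endB = j_end + l_keep
    if endA > startB:
        # trimming one alignment column from the inner ends shrinks the
        # overlap by 2 (endA moves left, startB moves right)
        cut = (endA - startB + 1) // 2
        endA -= cut
        startB += cut
    return startA, endA, startB, endB


def find_repeat_pairs(
    record: GenomeRecord,
    anchor: RtCandidate,
    window_bp: int = 5000,
    min_repeat_len: int = 50,
    seed_len: int = 12,
    max_mismatch_frac: float = 0.25,
) -> list[RepeatPair]:
    """Discover repeat pairs within ``window_bp`` of the RT anchor.

    Exact ``seed_len``-mers shared by two window positions (direct) or by a
    position and the reverse complement (inverted) are extended ungapped
    while the running mismatch fraction stays below ``max_mismatch_frac``,
    then boundary-trimmed to the running-score peak (match +1, mismatch -1). Overlapping extensions on one
    diagonal are merged; self-trivial matches excluded; output sorted by
    copyA_start.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    if min_repeat_len < seed_len:
        raise ValueError("min_repeat_len must be >= seed_len")
    rt = anchor.orf
    if rt.start >= len(record) or rt.end > len(record):
        raise ValueError("anchor lies outside the record")
    w0 = max(0, rt.start - window_bp)
    w1 = min(len(record), rt.end + window_bp)
    region = record.sequence[w0:w1]
    n = len(region)

    kmer_pos: dict[str, list[int]] = {}
    for p in range(n - seed_len + 1):
        kmer = region[p : p + seed_len]
        if "N" in kmer:
            continue
        kmer_pos.setdefault(kmer, []).append(p)

    results: dict[tuple, RepeatPair] = {}

    # direct: group seed pairs by diagonal, skip seeds inside prior extensions
    diag_pairs: dict[int, list[tuple[int, int]]] = {}
    for kmer, positions in kmer_pos.items():
        if len(positions) < 2:
            continue
        for ii in range(len(positions)):
            for jj in range(ii + 1, len(positions)):
                i, j = positions[ii], positions[jj]
                if j - i < seed_len:
                    continue  # overlapping occurrences of one kmer
                diag_pairs.setdefault(j - i, []).append((i, j))
    for diag, pairs in diag_pairs.items():
        pairs.sort()
        covered_until = -1
        for i, j in pairs:
            if i < covered_until:
                continue
            sA, eA, sB, eB = _extend_direct(region, i, j, seed_len, max_mismatch_frac)
            covered_until = eA
            if eA - sA < min_repeat_len:
                continue
            key = ("direct", sA, eA, sB, eB)
            if key not in results:
                results[key] = RepeatPair(
                    record_id=record.id,
                    copyA_start=w0 + sA,
                    copyA_end=w0 + eA,
                    copyB_start=w0 + sB,
                    copyB_end=w0 + eB,
                    orientation="direct",
                    aligned_len=eA - sA,
                    alignment=(region[sA:eA], region[sB:eB]),
                )

    # inverted: group by anti-diagonal
    anti_pairs: dict[int, list[tuple[int, int]]] = {}
    for kmer, positions in kmer_pos.items():
        rc = revcomp(kmer)
        if rc not in kmer_pos:
            continue
        for i in positions:
            for q in kmer_pos[rc]:
                j_end = q + seed_len
                if j_end - seed_len < i + seed_len:
                    continue  # overlapping or reversed arrangement
                anti_pairs.setdefault(i + j_end, []).append((i, j_end))
    for anti, pairs in anti_pairs.items():
        pairs.sort()
        covered_until = -1
        for i, j_end in pairs:
            if i < covered_until:
                continue
            sA, eA, sB, eB = _extend_inverted(region, i, j_end, seed_len, max_mismatch_frac)
            covered_until = eA
            if eA - sA < min_repeat_len or eB - sB < min_repeat_len:
                continue
            if eA > sB:
                continue
            key = ("inverted", sA, eA, sB, eB)
            if key not in results:
                results[key] = RepeatPair(
                    record_id=record.id,
                    copyA_start=w0 + sA,
                    copyA_end=w0 + eA,
                    copyB_start=w0 + sB,
                    copyB_end=w0 + eB,
                    orientation="inverted",
                    aligned_len=eA - sA,
                    alignment=(region[sA:eA], revcomp(region[sB:eB])),
                )

    out = sorted(results.values(), key=lambda p: (p.copyA_start, p.copyB_start))
    return _merge_contained(out)


def _merge_contained(pairs: list[RepeatPair]) -> list[RepeatPair]:
    """Drop pairs whose both copies are contained in a longer pair's copies."""
    kept: list[RepeatPair] = []
    for p in sorted(pairs, key=lambda q: -q.aligned_len):
        contained = False
        for big in kept:
            if (
                big.orientation == p.orientation
                and big.copyA_start <= p.copyA_start
                and p.copyA_end <= big.copyA_end
                and big.copyB_start <= p.copyB_start
                and p.copyB_end <= big.copyB_end
            ):
                contained = True
                break
        if not contained:
            kept.append(p)
    kept.sort(key=lambda p: (p.copyA_start, p.copyB_start))
    return kept


# ---------------------------------------------------------------------------
# TR/VR classification
# ---------------------------------------------------------------------------

def mismatch_profile(pair: RepeatPair) -> MismatchProfile:
    sA, sB = pair.alignment
    positions = []
    adA = otA = adB = otB = 0
    for k, (a, b) in enumerate(zip(sA, sB)):
        if a == b and a != "N":
            continue
        positions.append((k, a, b))
        if a == "A":
            adA += 1
        else:
            otA += 1
        if b == "A":
            adB += 1
        else:
            otB += 1
    return MismatchProfile(
        positions=positions,
        n_adenine_wrt_A=adA,
        n_other_wrt_A=otA,
        n_adenine_wrt_B=adB,
        n_other_wrt_B=otB,
        aligned_len=pair.aligned_len,
    )


def classify_tr_vr(
    pair: RepeatPair,
    min_adenine_mm: int = 10,
    max_other_per_100bp: float = 2.0,
) -> TrVrCall:
    """Classify a repeat pair as TR/VR by the adenine-mismatch rule.

    A copy passes as template when it shows at least ``min_adenine_mm``
    adenine-specific mismatches and at most ``max_other_per_100bp`` per
    100 bp of aligned sequence non-adenine mismatches. Both copies are
    tested; exactly one passing copy becomes TR. If both pass, the copy with
    more adenine mismatches wins, a tie being rejected as
    ``ambiguous-template``.
    """
    prof = mismatch_profile(pair)
    allowed_other = max_other_per_100bp * prof.aligned_len / 100.0

    def check(n_ad: int, n_ot: int) -> list[str]:
        reasons = []
        if n_ad < min_adenine_mm:
            reasons.append(f"adenine-mismatches<{min_adenine_mm}")
        if n_ot > allowed_other:
            reasons.append("non-adenine-excess")
        return reasons

    reasons_A = check(prof.n_adenine_wrt_A, prof.n_other_wrt_A)
    reasons_B = check(prof.n_adenine_wrt_B, prof.n_other_wrt_B)
    pass_A, pass_B = not reasons_A, not reasons_B

    iA, iB = pair.intervals()
    strand_B = "+" if pair.orientation == "direct" else "-"

    if pass_A and pass_B:
        if prof.n_adenine_wrt_A > prof.n_adenine_wrt_B:
            return TrVrCall(iA, iB, "+", prof, True, pair=pair)
        if prof.n_adenine_wrt_B > prof.n_adenine_wrt_A:
            return TrVrCall(iB, iA, strand_B, prof, True, pair=pair)
        return TrVrCall(None, None, ".", prof, False, ["ambiguous-template"], pair=pair)
    if pass_A:
        return TrVrCall(iA, iB, "+", prof, True, pair=pair)
    if pass_B:
        return TrVrCall(iB, iA, strand_B, prof, True, pair=pair)
    # report reasons for the better copy (more adenine mismatches; tie -> copyA)
    reasons = reasons_A if prof.n_adenine_wrt_A >= prof.n_adenine_wrt_B else reasons_B
    return TrVrCall(None, None, ".", prof, False, reasons, pair=pair)


# ---------------------------------------------------------------------------
# Cassette assembly
# ---------------------------------------------------------------------------

def assemble_cassette(
    record: GenomeRecord,
    rt: Optional[RtCandidate],
    calls: Sequence[TrVrCall],
    orfs: Sequence[OrfFeature],
    cis: "cis_elements.CisConfig | None" = None,
) -> list[DgrCassette]:
    """Assemble cassettes from passing TR/VR calls anchored at ``rt``.

    The target-protein (TP) gene is the ORF containing VR (longest wins when
    several contain it); calls whose TR lies inside the chosen TP are
    rejected (a template repeat must be non-coding). Cassettes sharing a VR
    interval are merged (first kept). Cis-element searches (IMH/IMH* pair,
    stem-loop, Avd-like ORFs) are attached to each cassette.
    """
    cfg = cis or cis_elements.CisConfig()
    cassettes: list[DgrCassette] = []
    seen_vr: set[tuple[int, int]] = set()
    for call in calls:
        if not call.passed:
            continue
        vr, tr = call.vr, call.tr
        if vr in seen_vr:
            continue
        seen_vr.add(vr)
        containing = [o for o in orfs if o.start <= vr[0] and vr[1] <= o.end]
        tp = max(containing, key=lambda o: (len(o), -o.start)) if containing else None
        flags: list[str] = []
        if tp is None:
            flags.append("no-TP")
        elif tp.start <= tr[0] and tr[1] <= tp.end:
            # template repeat must not be coding within the same gene
            continue
        cassette = DgrCassette(
            record_id=record.id, rt=rt, trvr=call, tp_orf=tp, flags=flags
        )
        _attach_cis(cassette, record, orfs, cfg)
        cassettes.append(cassette)
    return cassettes


def _attach_cis(
    cassette: DgrCassette,
    record: GenomeRecord,
    orfs: Sequence[OrfFeature],
    cfg: "cis_elements.CisConfig",
) -> None:
    seq = record.sequence
    call = cassette.trvr
    vr, tr = call.vr, call.tr
    flank = cfg.imh_flank

    vr_with_flank = seq[vr[0] : min(len(seq), vr[1] + flank)]
    if call.template_strand == "-":
        tr_oriented = revcomp(seq[max(0, tr[0] - flank) : tr[1]])
    else:
        tr_oriented = seq[tr[0] : min(len(seq), tr[1] + flank)]
    imh = cis_elements.find_imh(
        vr_with_flank, tr_oriented, motif_pairs=cfg.motif_pairs, search_span=cfg.imh_span
    )
    if imh is not None:
        # lift VR-local interval onto the genome
        imh.imh_interval = (vr[0] + imh.imh_interval[0], vr[0] + imh.imh_interval[1])
    cassette.imh = imh

    tp = cassette.tp_orf
    if tp is not None and tp.strand == "+":
        hp_region = seq[vr[1] : tp.end]
        hp_off = vr[1]
    elif tp is not None:
        hp_region = revcomp(seq[tp.start : vr[0]])
        hp_off = None
    else:
        hp_region = seq[vr[1] : min(len(seq), vr[1] + 200)]
        hp_off = vr[1]
    hairpins = cis_elements.find_hairpins(
        hp_region,
        stem_min=cfg.stem_min,
        stem_max=cfg.stem_max,
        loop_min=cfg.loop_min,
        loop_max=cfg.loop_max,
    )
    if hairpins:
        hp = hairpins[0]
        if hp_off is not None:
            hp.start += hp_off
            hp.end += hp_off
        cassette.hairpin = hp

    if cassette.rt is not None and tp is not None:
        rt_orf = cassette.rt.orf
        lo = min(rt_orf.end, tp.end)
        hi = max(rt_orf.start, tp.start)
        between = [
            o
            for o in orfs
            if lo <= o.start and o.end <= hi and o is not tp and o is not rt_orf
        ]
        avds = cis_elements.find_avd_candidates(
            between,
            pi_center=cfg.avd_pi_center,
            pi_tol=cfg.avd_pi_tol,
            mw_center_kda=cfg.avd_mw_center,
            mw_tol_kda=cfg.avd_mw_tol,
        )
        if avds:
            # closest to the canonical Avd center (pI 9, 10 kDa), scaled by
            # the window half-widths
            cassette.avd = min(
                avds,
                key=lambda a: abs(a.pI - cfg.avd_pi_center) / cfg.avd_pi_tol
                + abs(a.mw_kda - cfg.avd_mw_center) / cfg.avd_mw_tol,
            )


# ---------------------------------------------------------------------------
# Cross-cassette similarity
# ---------------------------------------------------------------------------

def _feature_seq(c: DgrCassette, record: GenomeRecord, name: str) -> Optional[str]:
    if name == "TP":
        if c.tp_orf is None:
            return None
        return record.sequence[c.tp_orf.start : c.tp_orf.end]
    if name == "RT":
        if c.rt is None:
            return None
        return record.sequence[c.rt.orf.start : c.rt.orf.end]
    if name == "VR":
        return record.sequence[c.trvr.vr[0] : c.trvr.vr[1]] if c.trvr.vr else None
    if name == "TR":
        return record.sequence[c.trvr.tr[0] : c.trvr.tr[1]] if c.trvr.tr else None
    raise KeyError(name)


def percent_identity(
    a: str, b: str, match: float = 1.0, mismatch: float = -1.0, gap: float = -2.0
) -> float:
    """Global-alignment percent identity: matches / alignment columns x 100."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    aln = aligner.align(a, b)[0]
    counts = aln.counts()
    return counts.identities / aln.length * 100.0


def cassette_identity(
    c1: DgrCassette,
    c2: DgrCassette,
    record1: GenomeRecord,
    record2: GenomeRecord,
) -> dict[str, float | str]:
    """Pairwise percent identity for the TP, VR, TR and RT features.

    A feature absent from either cassette yields "NA" for that entry.
    """
    out: dict[str, float | str] = {}
    for name in ("TP", "VR", "TR", "RT"):
        s1 = _feature_seq(c1, record1, name)
        s2 = _feature_seq(c2, record2, name)
        out[name] = "NA" if s1 is None or s2 is None else percent_identity(s1, s2)
    return out
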