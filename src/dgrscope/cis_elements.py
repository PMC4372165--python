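"""Cis-acting DGR features: IMH/IMH* motifs, stem-loops, Avd-like ORFs.

The initiation-of-mutagenic-homing motif (IMH) sits at the 3' end of the
variable repeat with a cognate IMH* at the 3' end of the template repeat;
archaeal systems carry a TGGGGT IMH against a TGGAAT IMH*. A short inverted
repeat downstream of VR, inside the target gene, can fold into a
hairpin/cruciform, typically with a G-R-A trinucleotide or G-R-N-A
tetranucleotide loop. Accessory variability determinant (Avd) homologues are
small basic proteins; candidates are selected on isoelectric point and
molecular weight (pI = 9 +/- 1, Mw = 10 +/- 5 kDa).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .seqcore import OrfFeature, revcomp

DEFAULT_MOTIF_PAIRS = [("TGGGGT", "TGGAAT")]


@dataclass
class CisConfig:
    """Parameters for cis-element searches during cassette assembly."""

    motif_pairs: list[tuple[str, str]] = field(
        default_factory=lambda: list(DEFAULT_MOTIF_PAIRS)
    )
    imh_span: int = 40
    imh_flank: int = 10
    stem_min: int = 4
    stem_max: int = 12
    loop_min: int = 3
    loop_max: int = 8
    avd_pi_center: float = 9.0
    avd_pi_tol: float = 1.0
    avd_mw_center: float = 10.0
    avd_mw_tol: float = 5.0


@dataclass
class ImhPair:
    imh_interval: tuple[int, int]
    imh_motif: str
    imh_star_interval: tuple[int, int]
    imh_star_motif: str
    motif_pair_name: str


@dataclass
class Hairpin:
    stem_len: int
    loop_seq: str
    start: int
    end: int
    loop_class: str = ""

    def __post_init__(self) -> None:
        if not self.loop_class:
            self.loop_class = classify_loop(self.loop_seq)


@dataclass
class AvdCandidate:
    orf: OrfFeature
    pI: float
    mw_kda: float


# ---------------------------------------------------------------------------
# IMH / IMH*
# ---------------------------------------------------------------------------

def find_imh(
    vr_seq_with_flank: str,
    tr_seq_with_flank: str,
    motif_pairs: Sequence[tuple[str, str]] | None = None,
    search_span: int = 40,
    max_offset_diff: int = 5,
) -> Optional[ImhPair]:
    """Locate an IMH / IMH* motif pair near the repeat 3' ends.

    Scans the 3'-terminal ``search_span`` of each input for any configured
    (IMH, IMH*) pair; both motifs must occur at alignment-consistent offsets
    from the 3' end (absolute difference <= ``max_offset_diff``). The
    3'-most consistent hit is returned; absence is a valid result. Results
    are invariant to extra 5' context, and intervals refer to the input
    strings.
    """
    pairs = motif_pairs if motif_pairs is not None else DEFAULT_MOTIF_PAIRS
    vr = vr_seq_with_flank.upper()
    tr = tr_seq_with_flank.upper()
    v_off = max(0, len(vr) - search_span)
    t_off = max(0, len(tr) - search_span)
    v_region, t_region = vr[v_off:], tr[t_off:]

    best: Optional[ImhPair] = None
    best_tail = None
    for imh_m, star_m in pairs:
        v_hits = _find_all(v_region, imh_m)
        t_hits = _find_all(t_region, star_m)
        for vp in v_hits:
            tail_v = len(v_region) - (vp + len(imh_m))  # distance from 3' end
            for tp in t_hits:
                tail_t = len(t_region) - (tp + len(star_m))
                if abs(tail_v - tail_t) > max_offset_diff:
                    continue
                if best_tail is None or tail_v < best_tail:
                    best_tail = tail_v
                    best = ImhPair(
                        imh_interval=(v_off + vp, v_off + vp + len(imh_m)),
                        imh_motif=imh_m,
                        imh_star_interval=(t_off + tp, t_off + tp + len(star_m)),
                        imh_star_motif=star_m,
                        motif_pair_name=f"{imh_m}/{star_m}",
                    )
    return best


def _find_all(haystack: str, needle: str) -> list[int]:
    out, start = [], 0
    while True:
        p = haystack.find(needle, start)
        if p < 0:
            return out
        out.append(p)
        start = p + 1


# ---------------------------------------------------------------------------
# Hairpins
# ---------------------------------------------------------------------------

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _complementary(x: str, y: str) -> bool:
    return _COMP.get(x) == y


def classify_loop(loop: str) -> str:
    if len(loop) == 3 and loop[0] == "G" and loop[1] in "AG" and loop[2] == "A":
        return "GRA"
    if len(loop) == 4 and loop[0] == "G" and loop[1] in "AG" and loop[3] == "A":
        return "GRNA"
    return "other"


def find_hairpins(
    region_seq: str,
    stem_min: int = 4,
    stem_max: int = 12,
    loop_min: int = 3,
    loop_max: int = 8,
    require_loop_class: Optional[str] = None,
) -> list[Hairpin]:
    """Enumerate maximal exact-reverse-complement stem-loops.

    For every candidate loop interval the stem is grown outward as far as
    exact Watson-Crick pairing allows (capped at ``stem_max``); a hairpin is
    reported when the grown stem reaches ``stem_min``. Maximality: the stem
    is not outward-extendable below the cap, and the loop is not inward
    shrinkable (its terminal bases do not pair) unless already at
    ``loop_min``. Sorted by stem length descending, then position.
    """
    seq = region_seq.upper()
    n = len(seq)
    if n < 2 * stem_min + loop_min:
        raise ValueError("region shorter than the smallest possible stem-loop")
    found: list[Hairpin] = []
    for loop_len in range(loop_min, loop_max + 1):
        for ls in range(1, n - loop_len):  # loop start; stems need >=1 base each side
            le = ls + loop_len
            # loop must not be inward-shrinkable into a longer stem
            if loop_len - 2 >= loop_min and _complementary(seq[ls], seq[le - 1]):
                continue
            s = 0
            while (
                s < stem_max
                and ls - s - 1 >= 0
                and le + s < n
                and _complementary(seq[ls - s - 1], seq[le + s])
            ):
                s += 1
            if s < stem_min:
                continue
            # outward maximality (only binding below the cap)
            if s < stem_max and ls - s - 1 >= 0 and le + s < n:
                if _complementary(seq[ls - s - 1], seq[le + s]):
                    continue  # unreachable: growth loop would have continued
            hp = Hairpin(stem_len=s, loop_seq=seq[ls:le], start=ls - s, end=le + s)
            if require_loop_class is None or hp.loop_class == require_loop_class:
                found.append(hp)
    found.sort(key=lambda h: (-h.stem_len, h.start, len(h.loop_seq)))
    return found


# ---------------------------------------------------------------------------
# Avd candidates: isoelectric point and molecular weight
# ---------------------------------------------------------------------------

# Charge-model pKa values (fixed table so results are exactly reproducible)
PKA_POSITIVE = {"Nterm": 8.6, "K": 10.8, "R": 12.5, "H": 6.5}
PKA_NEGATIVE = {"Cterm": 3.6, "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1}

# Average residue masses (Da); water (18.02) is added per chain.
RESIDUE_MASS = {
    "G": 57.05, "A": 71.08, "S": 87.08, "P": 97.12, "V": 99.13,
    "T": 101.10, "C": 103.14, "L": 113.16, "I": 113.16, "N": 114.10,
    "D": 115.09, "Q": 128.13, "K": 128.17, "E": 129.12, "M": 131.19,
    "H": 137.14, "F": 147.18, "R": 156.19, "Y": 163.18, "W": 186.21,
}
WATER_MASS = 18.02


def net_charge(protein: str, ph: float) -> float:
    """Henderson-Hasselbalch net charge of a protein at the given pH."""
    counts: dict[str, int] = {}
    for aa in protein:
        counts[aa] = counts.get(aa, 0) + 1
    charge = 1.0 / (1.0 + 10 ** (ph - PKA_POSITIVE["Nterm"]))
    for aa in "KRH":
        if counts.get(aa):
            charge += counts[aa] / (1.0 + 10 ** (ph - PKA_POSITIVE[aa]))
    charge -= 1.0 / (1.0 + 10 ** (PKA_NEGATIVE["Cterm"] - ph))
    for aa in "DECY":
        if counts.get(aa):
            charge -= counts[aa] / (1.0 + 10 ** (PKA_NEGATIVE[aa] - ph))
    return charge


def isoelectric_point(protein: str, tol: float = 1e-4) -> float:
    """pI by bisection on the net-charge function (to |charge| < tol)."""
    _validate_protein(protein)
    lo, hi = 0.0, 14.0
    for _ in range(200):
        mid = (lo + hi) / 2.0
        c = net_charge(protein, mid)
        if abs(c) < tol:
            return mid
        if c > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def molecular_weight_kda(protein: str) -> float:
    """Average molecular weight in kDa (sum of residue masses + water)."""
    _validate_protein(protein)
    return (sum(RESIDUE_MASS[aa] for aa in protein) + WATER_MASS) / 1000.0


def _validate_protein(protein: str) -> None:
    if not protein:
        raise ValueError("empty protein")
    if "*" in protein:
        raise ValueError("protein contains an internal stop ('*')")
    bad = set(protein) - set(RESIDUE_MASS)
    if bad:
        raise ValueError(f"unknown residues: {sorted(bad)}")


def find_avd_candidates(
    orfs_between_rt_and_tp: Sequence[OrfFeature],
    pi_center: float = 9.0,
    pi_tol: float = 1.0,
    mw_center_kda: float = 10.0,
    mw_tol_kda: float = 5.0,
) -> list[AvdCandidate]:
    """Select Avd-like ORFs by isoelectric point and molecular weight windows."""
    out = []
    for orf in orfs_between_rt_and_tp:
        pi = isoelectric_point(orf.protein)
        mw = molecular_weight_kda(orf.protein)
        if abs(pi - pi_center) <= pi_tol and abs(mw - mw_center_kda) <= mw_tol_kda:
            out.append(AvdCandidate(orf=orf, pI=pi, mw_kda=mw))
    return out
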