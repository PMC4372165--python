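"""Synthetic genomes with planted DGR cassettes and ground truth.

Each cassette is laid out on the forward strand in the order
TP gene ... TR ... (Avd) ... RT, mirroring the architecture of archaeal
DGRs: a target-protein (TP) gene whose 3' region carries the variable
repeat (VR) capped by a TGGGGT IMH motif, a stem-loop just downstream of VR
inside the gene, an intergenic template repeat (TR) capped by the TGGAAT
IMH* motif, an optional small basic Avd-like ORF, and a reverse
transcriptase ORF bearing the catalytic YADD motif. VR is derived from TR
by the adenine-directed substitution model: every template adenine is,
with probability ``p_adenine_sub``, replaced by a uniform draw over the
four bases (a draw of A is a silent no-change, so 3/4 of draws mismatch).

The emitted truth records planted coordinates and realized mismatch counts
recounted directly from the final sequence, for recovery scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from . import cis_elements, diversity
from .seqcore import GenomeRecord, Read, revcomp, translate

IMH_MOTIF = "TGGGGT"      # at the VR 3' end
IMH_STAR_MOTIF = "TGGAAT"  # at the TR 3' end
HAIRPIN_ARM = "GGCAGC"
HAIRPIN_LOOP = "GAA"

_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = ["".join((a, b, c)) for a in "ACGT" for b in "ACGT" for c in "ACGT"]
_NONSTOP_CODONS = [c for c in _CODONS if c not in _STOPS]


def _stop_reachable(codon: str) -> bool:
    ad = [k for k in range(3) if codon[k] == "A"]
    from itertools import product

    for combo in product("ACGT", repeat=len(ad)):
        v = list(codon)
        for k, b in zip(ad, combo):
            v[k] = b
        if "".join(v) in _STOPS:
            return True
    return False


# codons that can never mutate into a stop via adenine substitution
_SAFE_CODONS = [c for c in _NONSTOP_CODONS if not _stop_reachable(c)]

# reverse-translation table (codon choices per amino acid, table 11)
_AA_CODONS: dict[str, list[str]] = {}
for c in _NONSTOP_CODONS:
    _AA_CODONS.setdefault(translate(c), []).append(c)


@dataclass
class SimConfig:
    """Generator parameters; the defaults define the simulated study conditions."""

    genome_len: int = 50_000
    gc: float = 0.45
    n_cassettes: int = 1
    repeat_len: int = 114
    tr_adenine_frac: float = 0.30
    p_adenine_sub: float = 0.40
    p_background_sub: float = 0.0
    plant_imh: bool = True
    plant_hairpin: bool = True
    plant_avd: bool = True
    plant_no_nonsense: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.gc, self.tr_adenine_frac, self.p_adenine_sub, self.p_background_sub):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.repeat_len < 50:
            raise ValueError("repeat_len must be >= 50")
        if self.repeat_len % 3 != 0:
            raise ValueError("repeat_len must be a multiple of 3 (codon-aligned planting)")
        if self.n_cassettes < 0:
            raise ValueError("n_cassettes must be >= 0")


@dataclass
class CassetteTruth:
    rt: tuple[int, int]
    tr: tuple[int, int]
    vr: tuple[int, int]
    tp: tuple[int, int]
    tp_frame: int
    imh: Optional[tuple[int, int]]
    imh_star: Optional[tuple[int, int]]
    hairpin: Optional[tuple[int, int]]
    avd: Optional[tuple[int, int]]
    realized_adenine_mismatches: int = 0
    realized_other_mismatches: int = 0
    tr_adenine_count: int = 0


@dataclass
class SyntheticTruth:
    config: SimConfig
    cassettes: list[CassetteTruth] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {"config": asdict(self.config), "cassettes": [asdict(c) for c in self.cassettes]}


# ---------------------------------------------------------------------------
# VR substitution model
# ---------------------------------------------------------------------------

def mutate_vr(
    tr_seq: str,
    p_adenine_sub: float,
    p_background_sub: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> tuple[str, dict[str, int]]:
    """Apply adenine-directed mutagenesis to a template sequence.

    Each A is independently, with probability ``p_adenine_sub``, replaced by
    a uniform draw over {A,C,G,T} (drawing A counts as no change); each
    non-A position is, with probability ``p_background_sub``, replaced by a
    uniform *different* base. Returns the variable-repeat sequence and the
    realized mismatch counts.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    bases = "ACGT"
    out = []
    n_ad = n_other = 0
    for ch in tr_seq.upper():
        if ch == "A":
            if rng.random() < p_adenine_sub:
                new = bases[rng.integers(4)]
                if new != "A":
                    n_ad += 1
                out.append(new)
            else:
                out.append(ch)
        else:
            if p_background_sub > 0 and rng.random() < p_background_sub:
                choices = [b for b in bases if b != ch]
                out.append(choices[rng.integers(3)])
                n_other += 1
            else:
                out.append(ch)
    return "".join(out), {"adenine": n_ad, "other": n_other}


# ---------------------------------------------------------------------------
# Component builders
# ---------------------------------------------------------------------------

def _random_background(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=probs)])


def _sample_tr(cfg: SimConfig, rng: np.random.Generator) -> str:
    """Template repeat sampled codon-wise from stop-safe codons with the
    configured adenine fraction.

    The IMH* motif occupies the two codons just before the last, i.e. it
    sits 3 bp inside the repeat 3' end; the first and last codons are
    adenine-free so the repeat boundaries are crisp identity changepoints
    rather than forced-mismatch columns.
    """
    pool = _SAFE_CODONS if cfg.plant_no_nonsense else _NONSTOP_CODONS
    n_codons = cfg.repeat_len // 3
    n_body = n_codons - 4 if cfg.plant_imh else n_codons - 2
    # Rejection against the stop-safe pool depletes adenine-rich codons, so
    # the per-base adenine probability is calibrated upward until the
    # post-rejection expectation hits the configured repeat-wide fraction
    # (the IMH* AAT codon contributes 2 fixed As; first/last codons none).
    target_a = cfg.tr_adenine_frac * cfg.repeat_len - (2 if cfg.plant_imh else 0)
    target_frac = min(max(target_a / (3 * n_body), 0.0), 0.85)
    probs = _calibrated_probs(target_frac, cfg.gc, pool)

    def draw(n: int, adenine_free: bool = False) -> list[str]:
        out = []
        while len(out) < n:
            codon = "".join(np.array(list("ACGT"))[rng.choice(4, size=3, p=probs)])
            if codon in pool and not (adenine_free and "A" in codon):
                out.append(codon)
        return out

    first = draw(1, adenine_free=True)
    last = draw(1, adenine_free=True)
    body = draw(n_body)
    if cfg.plant_imh:
        return "".join(first + body) + IMH_STAR_MOTIF + last[0]
    return "".join(first + body + last)


def _conditional_a_frac(p_a: float, gc: float, pool: list[str]) -> float:
    """Expected adenine fraction of a codon accepted from ``pool`` when bases
    are drawn iid with P(A)=p_a and C/G/T in background proportions."""
    rest = 1.0 - p_a
    tot = gc + (1 - gc) / 2
    p = {"A": p_a, "C": rest * (gc / 2) / tot, "G": rest * (gc / 2) / tot,
         "T": rest * ((1 - gc) / 2) / tot}
    num = den = 0.0
    for codon in pool:
        w = p[codon[0]] * p[codon[1]] * p[codon[2]]
        num += w * codon.count("A")
        den += w
    return num / (3.0 * den)


def _calibrated_probs(target_frac: float, gc: float, pool: list[str]) -> np.ndarray:
    """Base probabilities whose post-rejection adenine fraction equals
    ``target_frac`` (bisection on the raw adenine probability)."""
    lo, hi = 0.0, 0.95
    if _conditional_a_frac(hi, gc, pool) < target_frac:
        raise ValueError("requested adenine fraction not achievable with stop-safe codons")
    for _ in range(60):
        mid = (lo + hi) / 2
        if _conditional_a_frac(mid, gc, pool) < target_frac:
            lo = mid
        else:
            hi = mid
    p_a = (lo + hi) / 2
    rest = 1.0 - p_a
    tot = gc + (1 - gc) / 2
    probs = np.array([p_a, rest * (gc / 2) / tot, rest * (gc / 2) / tot,
                      rest * ((1 - gc) / 2) / tot])
    return probs / probs.sum()


def _codons_for(protein: str, rng: np.random.Generator) -> str:
    return "".join(_AA_CODONS[aa][rng.integers(len(_AA_CODONS[aa]))] for aa in protein)


def _random_protein(rng: np.random.Generator, length: int, alphabet: str = "AGSTVLINQPEF") -> str:
    letters = np.array(list(alphabet))
    return "".join(letters[rng.integers(len(alphabet), size=length)])


def _build_avd_protein(rng: np.random.Generator) -> str:
    """A small basic protein: ~88 residues, 6 Lys vs 5 Asp plus neutrals,
    shuffled; verified to sit inside the Avd windows (pI 8-10, 5-15 kDa)."""
    for _ in range(100):
        body = list("K" * 6 + "D" * 5 + _random_protein(rng, 76, "AGSTVLINQ"))
        rng.shuffle(body)
        prot = "M" + "".join(body)
        pi = cis_elements.isoelectric_point(prot)
        mw = cis_elements.molecular_weight_kda(prot)
        if 8.0 <= pi <= 10.0 and 5.0 <= mw <= 15.0:
            return prot
    raise RuntimeError("failed to engineer an Avd-like protein")


def _build_rt_protein(rng: np.random.Generator, length: int = 150) -> str:
    prot = list("M" + _random_protein(rng, length - 1))
    prot[60:64] = list("YADD")
    return "".join(prot)


# ---------------------------------------------------------------------------
# Genome generation
# ---------------------------------------------------------------------------

def generate_genome(config: SimConfig) -> tuple[GenomeRecord, SyntheticTruth]:
    """Generate a genome with ``n_cassettes`` planted DGR cassettes.

    Deterministic for a fixed config (byte-identical sequence and truth).
    Raises when the cassettes cannot fit into ``genome_len``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    genome = list(_random_background(rng, cfg.genome_len, cfg.gc))
    truth = SyntheticTruth(config=cfg)

    if cfg.n_cassettes == 0:
        return GenomeRecord(id=f"synthetic_seed{cfg.seed}", sequence="".join(genome)), truth

    slot = cfg.genome_len // cfg.n_cassettes
    seen_tr: set[str] = set()
    for ci in range(cfg.n_cassettes):
        cassette_seq, local = _build_cassette(cfg, rng, seen_tr)
        if len(cassette_seq) > 10_000:
            raise ValueError("cassette span exceeds 10 kb")
        if len(cassette_seq) + 200 > slot:
            raise ValueError(
                f"{cfg.n_cassettes} cassettes of {len(cassette_seq)} bp do not fit "
                f"into a genome of {cfg.genome_len} bp"
            )
        offset = ci * slot + (slot - len(cassette_seq)) // 2
        genome[offset : offset + len(cassette_seq)] = list(cassette_seq)
        truth.cassettes.append(_shift_truth(local, offset))

    seq = "".join(genome)
    for t in truth.cassettes:  # recount realized differences from the emitted sequence
        tr_seq = seq[t.tr[0] : t.tr[1]]
        vr_seq = seq[t.vr[0] : t.vr[1]]
        ad = ot = 0
        for x, y in zip(tr_seq, vr_seq):
            if x != y:
                if x == "A":
                    ad += 1
                else:
                    ot += 1
        t.realized_adenine_mismatches = ad
        t.realized_other_mismatches = ot
        t.tr_adenine_count = tr_seq.count("A")
    return GenomeRecord(id=f"synthetic_seed{cfg.seed}", sequence=seq), truth


def _build_cassette(
    cfg: SimConfig, rng: np.random.Generator, seen_tr: set[str]
) -> tuple[str, CassetteTruth]:
    """Assemble one cassette (local coordinates): TP ... TR ... Avd ... RT."""
    for _ in range(200):
        tr_seq = _sample_tr(cfg, rng)
        if tr_seq in seen_tr:
            continue
        vr_seq, _counts = mutate_vr(tr_seq, cfg.p_adenine_sub, cfg.p_background_sub, rng)
        if cfg.plant_imh:
            # IMH replaces IMH* in VR, 3 bp inside the repeat 3' end
            m0 = len(vr_seq) - 3 - len(IMH_MOTIF)
            vr_seq = vr_seq[:m0] + IMH_MOTIF + vr_seq[m0 + len(IMH_MOTIF) :]
        if not cfg.plant_no_nonsense and _has_stop_in_frame(vr_seq):
            continue
        break
    else:
        raise RuntimeError("could not sample a usable TR/VR pair")
    seen_tr.add(tr_seq)

    # --- TP gene: ATG + pre codons + VR + spacer + hairpin + post codons + stop.
    # Each planted ORF is preceded by an in-frame TAA guard so the ORF caller
    # starts it exactly at the planted ATG.
    pre = _codons_for(_random_protein(rng, 60), rng)
    spacer = _codons_for(_random_protein(rng, 4), rng)
    hairpin_seq = HAIRPIN_ARM + HAIRPIN_LOOP + revcomp(HAIRPIN_ARM) if cfg.plant_hairpin else ""
    post = _codons_for(_random_protein(rng, 10), rng)
    tp_core = "ATG" + pre + vr_seq + spacer + hairpin_seq + post + "TAA"
    tp_local = (3, 3 + len(tp_core))
    vr_local = (tp_local[0] + 3 + len(pre), tp_local[0] + 3 + len(pre) + len(vr_seq))
    hp_local = None
    if cfg.plant_hairpin:
        hp_start = vr_local[1] + len(spacer)
        hp_local = (hp_start, hp_start + len(hairpin_seq))

    gap1 = _random_background(rng, 150, cfg.gc)
    tr_local_start = 3 + len(tp_core) + len(gap1)
    gap2 = _random_background(rng, 100, cfg.gc)

    parts = ["TAA", tp_core, gap1, tr_seq, gap2]
    pos = tr_local_start + len(tr_seq) + len(gap2)

    avd_local = None
    if cfg.plant_avd:
        avd_prot = _build_avd_protein(rng)
        avd_seq = "ATG" + _codons_for(avd_prot[1:], rng) + "TAA"
        parts.extend(["TAA", avd_seq])
        avd_local = (pos + 3, pos + 3 + len(avd_seq))
        gap3 = _random_background(rng, 100, cfg.gc)
        parts.append(gap3)
        pos += 3 + len(avd_seq) + len(gap3)

    rt_prot = _build_rt_protein(rng)
    rt_seq = "ATG" + _codons_for(rt_prot[1:], rng) + "TAA"
    parts.extend(["TAA", rt_seq])
    rt_local = (pos + 3, pos + 3 + len(rt_seq))

    cassette_seq = "".join(parts)
    motif_off = 3 + len(IMH_MOTIF)  # motif ends 3 bp inside the repeat 3' end
    truth = CassetteTruth(
        rt=rt_local,
        tr=(tr_local_start, tr_local_start + len(tr_seq)),
        vr=vr_local,
        tp=tp_local,
        tp_frame=0,
        imh=(vr_local[1] - motif_off, vr_local[1] - 3) if cfg.plant_imh else None,
        imh_star=(
            (tr_local_start + len(tr_seq) - motif_off, tr_local_start + len(tr_seq) - 3)
            if cfg.plant_imh
            else None
        ),
        hairpin=hp_local,
        avd=avd_local,
    )
    return cassette_seq, truth


def _has_stop_in_frame(seq: str) -> bool:
    return any(seq[i : i + 3] in _STOPS for i in range(0, len(seq) - 2, 3))


def _shift_truth(t: CassetteTruth, off: int) -> CassetteTruth:
    def sh(iv):
        return None if iv is None else (iv[0] + off, iv[1] + off)

    return CassetteTruth(
        rt=sh(t.rt), tr=sh(t.tr), vr=sh(t.vr), tp=sh(t.tp), tp_frame=t.tp_frame,
        imh=sh(t.imh), imh_star=sh(t.imh_star), hairpin=sh(t.hairpin), avd=sh(t.avd),
    )


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

def generate_reads(
    record: GenomeRecord,
    n: int,
    read_len: int = 100,
    error_rate: float = 0.0,
    seed: int = 0,
    mean_quality: float = 30.0,
    sd_quality: float = 3.0,
    n_fraction: float = 0.0,
) -> list[Read]:
    """Uniformly placed reads from both strands with Gaussian-ish Phred
    qualities; a ``n_fraction`` of reads receives one ambiguous base."""
    if read_len > len(record):
        raise ValueError("read_len exceeds genome length")
    rng = np.random.default_rng(seed)
    reads = []
    for i in range(n):
        start = int(rng.integers(0, len(record) - read_len + 1))
        seq = record.sequence[start : start + read_len]
        if rng.random() < 0.5:
            seq = revcomp(seq)
        if error_rate > 0:
            seq = list(seq)
            for k in range(read_len):
                if rng.random() < error_rate:
                    seq[k] = "ACGT"[rng.integers(4)]
            seq = "".join(seq)
        if n_fraction > 0 and rng.random() < n_fraction:
            pos = int(rng.integers(read_len))
            seq = seq[:pos] + "N" + seq[pos + 1 :]
        quals = np.clip(
            np.round(rng.normal(mean_quality, sd_quality, size=read_len)), 2, 41
        ).astype(int)
        reads.append(Read(id=f"read_{i}", sequence=seq, qualities=list(quals)))
    return reads
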