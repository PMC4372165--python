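"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately re-derive results by exhaustive enumeration, sharing no
code path with the package implementation they check.
"""

from __future__ import annotations

from itertools import product

import numpy as np

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
_STOPS = {"TAA", "TAG", "TGA"}

# plain table-11 codon -> amino acid map, written out independently
_CODON_AA = {}
_BASES = "TCAG"
_AA_ORDER = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
for _i, (_b1, _b2, _b3) in enumerate(product(_BASES, repeat=3)):
    _CODON_AA[_b1 + _b2 + _b3] = _AA_ORDER[_i]


def oracle_translate(codon: str) -> str:
    return _CODON_AA[codon]


def oracle_orfs(seq: str, min_protein_len: int) -> set[tuple[int, int, str]]:
    """Six-frame ORF oracle: every (start,end,strand); one ORF per stop,
    keeping the most upstream start; N-containing codons act as barriers."""
    out = set()

    def scan(s: str, strand: str, L: int):
        starts = {"ATG", "GTG", "TTG"}
        for frame in range(3):
            candidates = []  # all start positions since last barrier/stop
            for i in range(frame, len(s) - 2, 3):
                codon = s[i : i + 3]
                if any(b not in "ACGT" for b in codon):
                    candidates = []
                    continue
                if codon in _STOPS:
                    if candidates:
                        st = min(candidates)
                        if (i - st) // 3 >= min_protein_len:
                            if strand == "+":
                                out.add((st, i + 3, "+"))
                            else:
                                out.add((L - (i + 3), L - st, "-"))
                    candidates = []
                elif codon in starts:
                    candidates.append(i)

    rc = "".join(_COMP.get(b, "N") for b in reversed(seq))
    scan(seq, "+", len(seq))
    scan(rc, "-", len(seq))
    return out


def oracle_hairpins(seq: str, stem_min: int, stem_max: int, loop_min: int, loop_max: int):
    """All maximal stem-loops by direct enumeration of (start, stem, loop)
    partitions: arms exact reverse complements, stem not outward-extendable
    (below the cap), loop not inward-shrinkable (above the floor)."""
    n = len(seq)
    found = set()
    for start in range(n):
        for stem in range(stem_min, stem_max + 1):
            for loop in range(loop_min, loop_max + 1):
                end = start + 2 * stem + loop
                if end > n:
                    continue
                arm1 = seq[start : start + stem]
                arm2 = seq[end - stem : end]
                rc1 = "".join(_COMP.get(b, "N") for b in reversed(arm1))
                if rc1 != arm2:
                    continue
                # outward extendable?
                if stem < stem_max and start - 1 >= 0 and end + 1 <= n:
                    if _COMP.get(seq[start - 1]) == seq[end]:
                        continue
                # inward shrinkable (loop terminal bases pair)?
                if loop - 2 >= loop_min:
                    ls, le = start + stem, start + stem + loop
                    if _COMP.get(seq[ls]) == seq[le - 1]:
                        continue
                found.add((start, end, stem, seq[start + stem : start + stem + loop]))
    return found


def oracle_protein_variants(segment: str) -> tuple[int, bool]:
    """Distinct stop-free protein variants and stop reachability by full
    enumeration of all 4^A nucleotide variants of a codon-aligned segment.

    Implemented with numpy repeat/tile so segments with up to ~12 adenines
    stay tractable; the enumeration is exactly the cartesian product of each
    codon's adenine-substitution variants (which partitions all 4^A
    nucleotide variants of the segment, trailing non-codon bases excluded).
    """
    n_codons = len(segment) // 3
    aa_codes = {aa: i for i, aa in enumerate(sorted(set(_CODON_AA.values())))}
    stop_code = aa_codes["*"]
    per_codon = []
    for ci in range(n_codons):
        codon = segment[3 * ci : 3 * ci + 3]
        ad = [k for k in range(3) if codon[k] == "A"]
        variants = []
        for combo in product("ACGT", repeat=len(ad)):
            v = list(codon)
            for k, b in zip(ad, combo):
                v[k] = b
            variants.append(aa_codes[_CODON_AA["".join(v)]])
        per_codon.append(np.array(variants, dtype=np.uint8))

    total = 1
    for v in per_codon:
        total *= len(v)
    arr = np.empty((total, n_codons), dtype=np.uint8)
    remaining = total
    before = 1
    for idx, v in enumerate(per_codon):
        remaining //= len(v)
        arr[:, idx] = np.tile(np.repeat(v, remaining), before)
        before *= len(v)
    has_stop = (arr == stop_code).any(axis=1)
    viable = arr[~has_stop]
    if len(viable) == 0:
        return 0, bool(has_stop.any())
    n_distinct = len(np.unique(viable, axis=0))
    return n_distinct, bool(has_stop.any())


def oracle_net_charge(protein: str, ph: float) -> float:
    """Independent Henderson-Hasselbalch charge sum (same published pKa set)."""
    pos = {"Nterm": 8.6, "K": 10.8, "R": 12.5, "H": 6.5}
    neg = {"Cterm": 3.6, "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1}
    q = 0.0
    groups = [("Nterm", 1)] + [(aa, protein.count(aa)) for aa in "KRH"]
    for name, n in groups:
        q += n * (1.0 / (1.0 + 10.0 ** (ph - pos[name])))
    groups = [("Cterm", 1)] + [(aa, protein.count(aa)) for aa in "DECY"]
    for name, n in groups:
        q -= n * (1.0 / (1.0 + 10.0 ** (neg[name] - ph)))
    return q


def oracle_repeat_pair_exists(window: str, min_len: int, max_frac: float) -> bool:
    """Does any pair of disjoint equal-length (= min_len) substrings match at
    mismatch fraction <= max_frac, in either orientation?"""
    n = len(window)
    rc = "".join(_COMP.get(b, "N") for b in reversed(window))
    limit = int(max_frac * min_len)
    for i in range(n - min_len + 1):
        a = window[i : i + min_len]
        for j in range(i + min_len, n - min_len + 1):
            b = window[j : j + min_len]
            if sum(x != y for x, y in zip(a, b)) <= limit:
                return True
            b_rc = rc[n - j - min_len : n - j]
            if sum(x != y for x, y in zip(a, b_rc)) <= limit:
                return True
    return False
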