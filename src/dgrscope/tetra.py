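"""Tetranucleotide composition signatures and ordination.

Sliding 5-kb windows (500-bp step) are summarized as 256-dimensional
zero-order-Markov odds-ratio vectors: observed 4-mer counts divided by the
expectation under independent mononucleotide frequencies. Window profiles
are compared by Euclidean distance, embedded by non-metric multidimensional
scaling (Kruskal stress-1), and groups are summarized by 95% confidence
ellipses; windows falling outside the genome group's ellipse are flagged as
compositional outliers (the signature of horizontally acquired sequence).
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.stats import chi2
from sklearn.manifold import MDS

logger = logging.getLogger(__name__)

TETRAMERS = ["".join(t) for t in itertools.product("ACGT", repeat=4)]
_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class TetraProfile:
    source_id: str
    window_start: int
    window_end: int
    odds: np.ndarray  # 256-vector, lexicographic AAAA..TTTT
    group: str = "genome"

    def __post_init__(self) -> None:
        self.odds = np.asarray(self.odds, dtype=float)
        if self.odds.shape != (256,):
            raise ValueError("odds vector must have length 256")
        if not np.all(np.isfinite(self.odds)) or np.any(self.odds < 0):
            raise ValueError("odds entries must be finite and non-negative")


@dataclass
class OrdinationResult:
    coords: np.ndarray  # n x 2, column-centered
    stress: float
    seed: int
    n_starts: int


@dataclass
class EllipseSpec:
    group: str
    center: np.ndarray
    semi_axes: np.ndarray
    angle: float
    level: float = 0.95
    n_points: int = 0


def fragment_windows(seq_len: int, window: int = 5000, step: int = 500) -> list[tuple[int, int]]:
    """Sliding-window intervals [0,w), [step,step+w), ...; trailing partial
    windows are dropped and sequences shorter than one window are skipped."""
    if window <= 0:
        raise ValueError("window must be positive")
    if not (0 < step <= window):
        raise ValueError("step must be in (0, window]")
    if seq_len < window:
        logger.warning("sequence of length %d shorter than window %d; skipped", seq_len, window)
        return []
    n = (seq_len - window) // step + 1
    return [(k * step, k * step + window) for k in range(n)]


def _encode(seq: str) -> np.ndarray:
    """Base codes A=0 C=1 G=2 T=3; anything else (N etc.) = -1."""
    codes = np.full(len(seq), -1, dtype=np.int64)
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    for base, code in _BASE_CODE.items():
        codes[arr == ord(base)] = code
    return codes


def tetra_odds(window_seq: str) -> np.ndarray:
    """Zero-order-Markov odds ratios for the 256 tetranucleotides.

    observed(w): count of w among 4-mer positions (positions containing N
    are skipped). expected(w) = L' * prod of the window's mononucleotide
    frequencies over w's bases, with L' the number of counted positions and
    frequencies taken over non-N bases. Entries with expected == 0 (hence
    observed == 0) are set to the neutral value 1.0. By construction
    sum(observed) == sum(expected) == L'.
    """
    codes = _encode(window_seq.upper())
    valid_bases = codes >= 0
    if valid_bases.sum() < 4:
        raise ValueError("window has fewer than 4 unambiguous bases")
    base_counts = np.bincount(codes[valid_bases], minlength=4)
    mono = base_counts / base_counts.sum()

    if len(codes) < 4:
        raise ValueError("window shorter than 4 bases")
    c0 = codes[:-3]
    c1 = codes[1:-2]
    c2 = codes[2:-1]
    c3 = codes[3:]
    ok = (c0 >= 0) & (c1 >= 0) & (c2 >= 0) & (c3 >= 0)
    kmer_codes = ((c0 * 4 + c1) * 4 + c2) * 4 + c3
    observed = np.bincount(kmer_codes[ok], minlength=256).astype(float)
    n_positions = int(ok.sum())
    if n_positions == 0:
        raise ValueError("window has no unambiguous 4-mer positions")

    idx = np.arange(256)
    probs = (
        mono[(idx >> 6) & 3] * mono[(idx >> 4) & 3] * mono[(idx >> 2) & 3] * mono[idx & 3]
    )
    expected = n_positions * probs
    odds = np.ones(256)
    nz = expected > 0
    odds[nz] = observed[nz] / expected[nz]
    if np.any(~nz & (observed > 0)):  # cannot occur: observed bases feed mono freqs
        raise AssertionError("observed 4-mer with zero expectation")
    return odds


def profile_sequence(
    seq: str, source_id: str, group: str = "genome", window: int = 5000, step: int = 500
) -> list[TetraProfile]:
    return [
        TetraProfile(source_id, s, e, tetra_odds(seq[s:e]), group)
        for s, e in fragment_windows(len(seq), window, step)
    ]


def concat_and_profile(
    feature_seqs: Sequence[str],
    label: str,
    window: int = 5000,
    step: int = 500,
    source_id: str | None = None,
) -> list[TetraProfile]:
    """Concatenate feature sequences (input order, no spacer) and profile the
    sliding windows of the joint sequence, tagged with ``label``."""
    if not feature_seqs:
        raise ValueError("no sequences to concatenate")
    joint = "".join(feature_seqs)
    if len(joint) < window:
        raise ValueError(
            f"concatenation ({len(joint)} bp) shorter than the window ({window} bp); "
            "use a smaller --window"
        )
    return profile_sequence(joint, source_id or label, group=label, window=window, step=step)


def nmds(
    profiles_or_odds,
    k: int = 2,
    seed: int = 0,
    n_starts: int = 20,
    max_iter: int = 300,
    tol: float = 1e-7,
) -> OrdinationResult:
    """Non-metric MDS on Euclidean distances between odds vectors.

    Kruskal stress-1 is minimized by SMACOF with isotonic regression over
    ``n_starts`` seeded random initializations; the lowest-stress solution
    is returned with column-centered coordinates. Deterministic for a fixed
    seed.
    """
    X = _as_matrix(profiles_or_odds)
    n = X.shape[0]
    if n < k + 2:
        raise ValueError(f"need at least {k + 2} points for a {k}-dimensional ordination")
    from scipy.spatial.distance import pdist, squareform

    D = squareform(pdist(X))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = MDS(
            n_components=k,
            metric=False,
            dissimilarity="precomputed",
            n_init=n_starts,
            max_iter=max_iter,
            eps=tol,
            random_state=seed,
            normalized_stress=True,
        )
        coords = model.fit_transform(D)
    coords = coords - coords.mean(axis=0, keepdims=True)
    return OrdinationResult(coords=coords, stress=float(model.stress_), seed=seed, n_starts=n_starts)


def _as_matrix(profiles_or_odds) -> np.ndarray:
    if isinstance(profiles_or_odds, np.ndarray):
        return np.asarray(profiles_or_odds, dtype=float)
    return np.vstack([p.odds for p in profiles_or_odds])


def confidence_ellipse(
    coords: np.ndarray, group_labels: Sequence[str], level: float = 0.95
) -> list[EllipseSpec]:
    """Per-group covariance confidence ellipses.

    Center = group mean; semi-axes = sqrt(eigenvalue * q) for the 2x2 sample
    covariance, q the chi-square(2) quantile at ``level``; angle from the
    leading eigenvector. Groups with fewer than 3 points are skipped with a
    warning.
    """
    coords = np.asarray(coords, float)
    labels = np.asarray(group_labels)
    q = chi2.ppf(level, df=2)
    out = []
    for g in dict.fromkeys(group_labels):  # preserves first-seen order
        pts = coords[labels == g]
        if len(pts) < 3:
            logger.warning("group %r has %d < 3 points; no ellipse", g, len(pts))
            continue
        center = pts.mean(axis=0)
        cov = np.cov(pts, rowvar=False, ddof=1)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        evals = np.clip(evals, 0.0, None)
        angle = float(np.arctan2(evecs[1, 0], evecs[0, 0]))
        out.append(
            EllipseSpec(
                group=str(g),
                center=center,
                semi_axes=np.sqrt(evals * q),
                angle=angle,
                level=level,
                n_points=len(pts),
            )
        )
    return out


def outlier_report(
    coords: np.ndarray,
    group_labels: Sequence[str],
    genome_group_label: str = "genome",
    level: float = 0.95,
) -> tuple[np.ndarray, dict[str, float]]:
    """Flag windows outside the genome group's confidence ellipse.

    A point is an outlier when its squared Mahalanobis distance from the
    genome-group mean (genome-group sample covariance) exceeds the
    chi-square(2) quantile at ``level``. Returns per-window flags and the
    flagged fraction per group.
    """
    coords = np.asarray(coords, float)
    labels = np.asarray(group_labels)
    core = coords[labels == genome_group_label]
    if len(core) < 3:
        raise ValueError(f"genome group {genome_group_label!r} needs >= 3 points")
    center = core.mean(axis=0)
    cov = np.cov(core, rowvar=False, ddof=1)
    inv = np.linalg.pinv(cov)
    d = coords - center
    d2 = np.einsum("ij,jk,ik->i", d, inv, d)
    flags = d2 > chi2.ppf(level, df=2)
    fractions = {
        str(g): float(flags[labels == g].mean()) for g in dict.fromkeys(group_labels)
    }
    return flags, fractions
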