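"""Sequence data model, standard-format I/O, ORF finding and read QC.

Coordinates are 0-based half-open throughout the package; the GFF3 writer
converts to 1-based inclusive on output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Data import CodonTable

IUPAC_DNA = set("ACGTRYSWKMBDHVN")
START_CODONS = ("ATG", "GTG", "TTG")

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GenomeRecord:
    """A genome, contig or assembly sequence."""

    id: str
    sequence: str
    description: str = ""
    topology: str = "linear"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError(f"record {self.id!r}: empty sequence")
        self.sequence = self.sequence.upper().replace("U", "T")
        for i, base in enumerate(self.sequence):
            if base not in IUPAC_DNA:
                raise ValueError(
                    f"record {self.id!r}: non-IUPAC character {base!r} at position {i}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class OrfFeature:
    """An open reading frame in forward genomic coordinates.

    ``start``/``end`` are 0-based half-open and include the stop codon when
    present; ``protein`` excludes the stop.
    """

    record_id: str
    start: int
    end: int
    strand: str
    protein: str
    partial: bool = False

    def __post_init__(self) -> None:
        if (self.end - self.start) % 3 != 0:
            raise ValueError("ORF length must be divisible by 3")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class Read:
    """A sequencing read with per-base Phred quality scores."""

    id: str
    sequence: str
    qualities: Sequence[int]

    def __post_init__(self) -> None:
        if len(self.qualities) != len(self.sequence):
            raise ValueError(f"read {self.id!r}: quality/sequence length mismatch")

    def mean_quality(self) -> float:
        return float(np.mean(self.qualities))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[GenomeRecord]:
    """Read a FASTA file into :class:`GenomeRecord` objects.

    Order is preserved, sequence uppercased, U mapped to T. Raises on empty
    files, duplicate ids and non-IUPAC characters.
    """
    records: list[GenomeRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(
            GenomeRecord(id=rec.id, sequence=str(rec.seq), description=rec.description)
        )
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[GenomeRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id}"
            if rec.description and rec.description != rec.id:
                header += f" {rec.description}"
            fh.write(header + "\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def read_fastq(path: str | Path) -> list[Read]:
    """Read a FASTQ (Sanger/Phred+33) file."""
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        reads.append(
            Read(
                id=rec.id,
                sequence=str(rec.seq).upper(),
                qualities=list(rec.letter_annotations["phred_quality"]),
            )
        )
    return reads


def write_fastq(reads: Iterable[Read], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = "".join(chr(q + 33) for q in r.qualities)
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{qual}\n")


def read_bed(path: str | Path) -> list[tuple[str, int, int, str]]:
    """Read a BED file; returns (chrom, start, end, name) tuples (0-based half-open)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed BED line: {line!r}")
            name = parts[3] if len(parts) > 3 else ""
            out.append((parts[0], int(parts[1]), int(parts[2]), name))
    return out


def write_gff3(features: Iterable[dict], path: str | Path) -> None:
    """Write features as GFF3 (converting internal 0-based half-open to 1-based inclusive).

    Each feature dict needs keys: seqid, type, start, end; optional source,
    score, strand, phase, attributes (dict).
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = f.get("attributes", {})
            attr_str = ";".join(f"{k}={v}" for k, v in attrs.items()) or "."
            fh.write(
                "\t".join(
                    [
                        str(f["seqid"]),
                        str(f.get("source", "dgrscope")),
                        str(f["type"]),
                        str(f["start"] + 1),
                        str(f["end"]),
                        str(f.get("score", ".")),
                        str(f.get("strand", ".")),
                        str(f.get("phase", ".")),
                        attr_str,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Translation and ORF finding
# ---------------------------------------------------------------------------

def _codon_table(genetic_code: int) -> CodonTable.CodonTable:
    return CodonTable.unambiguous_dna_by_id[genetic_code]


def translate(dna: str, genetic_code: int = 11) -> str:
    """Translate a DNA string (length divisible by 3) with stops rendered '*'.

    Uses the bacterial/archaeal code (table 11) by default. Ambiguous bases
    raise.
    """
    dna = dna.upper()
    if len(dna) % 3 != 0:
        raise ValueError("sequence length not divisible by 3")
    table = _codon_table(genetic_code)
    out = []
    for i in range(0, len(dna), 3):
        codon = dna[i : i + 3]
        if any(b not in "ACGT" for b in codon):
            raise ValueError(f"ambiguous base in codon {codon!r} at position {i}")
        if codon in table.stop_codons:
            out.append("*")
        else:
            out.append(table.forward_table[codon])
    return "".join(out)


def _scan_frame(seq: str, frame: int, min_protein_len: int, table) -> list[tuple[int, int, str]]:
    """One-frame forward scan; returns (start, end, protein) with end past the stop.

    One ORF per stop codon: from the first start codon after the previous
    stop (the longest reading). Codons containing N act as barriers that no
    ORF may span.
    """
    stops = set(table.stop_codons)
    results = []
    start_pos: int | None = None
    for i in range(frame, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        if "N" in codon or any(b not in "ACGT" for b in codon):
            start_pos = None  # barrier
            continue
        if codon in stops:
            if start_pos is not None:
                n_aa = (i - start_pos) // 3
                if n_aa >= min_protein_len:
                    prot = translate(seq[start_pos:i])
                    # internal stops cannot occur by construction
                    results.append((start_pos, i + 3, prot))
            start_pos = None
        elif start_pos is None and codon in START_CODONS:
            start_pos = i
    return results


def find_orfs(
    record: GenomeRecord, min_protein_len: int = 100, genetic_code: int = 11
) -> list[OrfFeature]:
    """Six-frame ORF scan.

    ORFs run from a start codon (ATG/GTG/TTG) to the next in-frame stop,
    taking the most upstream start per stop; minus-strand ORFs are reported
    in forward coordinates. Output sorted by start. Records shorter than 3 nt
    yield an empty list.
    """
    if min_protein_len < 1:
        raise ValueError("min_protein_len must be >= 1")
    seq = record.sequence
    if len(seq) < 3:
        return []
    table = _codon_table(genetic_code)
    orfs: list[OrfFeature] = []
    for frame in range(3):
        for s, e, prot in _scan_frame(seq, frame, min_protein_len, table):
            orfs.append(OrfFeature(record.id, s, e, "+", prot))
    rc = revcomp(seq)
    for frame in range(3):
        for s, e, prot in _scan_frame(rc, frame, min_protein_len, table):
            orfs.append(OrfFeature(record.id, len(seq) - e, len(seq) - s, "-", prot))
    orfs.sort(key=lambda o: (o.start, o.end, o.strand))
    return orfs


def orf_dna(orf: OrfFeature, record: GenomeRecord) -> str:
    """The coding-strand DNA of an ORF (stop codon included)."""
    s = record.sequence[orf.start : orf.end]
    return s if orf.strand == "+" else revcomp(s)


# ---------------------------------------------------------------------------
# Read QC
# ---------------------------------------------------------------------------

@dataclass
class QcReport:
    input: int = 0
    removed_ambiguous: int = 0
    removed_length: int = 0
    removed_quality: int = 0
    removed_duplicate: int = 0
    kept: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def qc_filter_reads(
    reads: Sequence[Read], tail_frac: float = 0.025, quality_sd: float = 2.0
) -> tuple[list[Read], QcReport]:
    """Read-QC filter chain, applied in order:

    1. remove reads containing ambiguous (N) bases;
    2. remove the shortest and longest ``tail_frac`` of the remainder
       (``floor(tail_frac * n)`` reads per tail, ties by input order);
    3. remove reads whose mean quality is more than ``quality_sd`` standard
       deviations below the mean of the remaining reads;
    4. remove exact duplicate sequences, keeping the first occurrence.

    Returns the kept reads (input order preserved) and a per-stage report.
    An empty kept list is a valid outcome, not an error.
    """
    if not reads:
        raise ValueError("qc_filter_reads requires a non-empty read list")
    report = QcReport(input=len(reads))

    kept = [r for r in reads if "N" not in r.sequence.upper()]
    report.removed_ambiguous = report.input - len(kept)

    if kept:
        n = len(kept)
        k = math.floor(tail_frac * n)
        if k > 0:
            order = sorted(range(n), key=lambda i: (len(kept[i].sequence), i))
            drop = set(order[:k]) | set(order[n - k :])
            kept = [r for i, r in enumerate(kept) if i not in drop]
        report.removed_length = n - len(kept)

    if kept:
        means = np.array([r.mean_quality() for r in kept])
        mu, sd = float(means.mean()), float(means.std())
        cutoff = mu - quality_sd * sd
        before = len(kept)
        kept = [r for r, m in zip(kept, means) if m >= cutoff]
        report.removed_quality = before - len(kept)

    seen: set[str] = set()
    dedup = []
    for r in kept:
        if r.sequence not in seen:
            seen.add(r.sequence)
            dedup.append(r)
    report.removed_duplicate = len(kept) - len(dedup)
    report.kept = len(dedup)
    return dedup, report
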