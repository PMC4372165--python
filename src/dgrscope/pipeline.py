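"""Pipeline orchestration: detect -> cis -> diversity -> (optional) tetra.

Produces a nested, machine-readable report; exact big-integer counts are
serialized as decimal strings so no precision is lost downstream.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import yaml

from . import cis_elements, dgr_detect, diversity, seqcore, tetra

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All stage parameters with the operation-signature defaults."""

    orf_min_protein_len: int = 50
    genetic_code: int = 11
    rt_min_protein_len: int = 100
    rt_min_motifs: int = 1
    window_bp: int = 5000
    min_repeat_len: int = 50
    seed_len: int = 12
    max_mismatch_frac: float = 0.25
    min_adenine_mm: int = 10
    max_other_per_100bp: float = 2.0
    imh_span: int = 40
    stem_min: int = 4
    stem_max: int = 12
    loop_min: int = 3
    loop_max: int = 8
    tetra_window: int = 5000
    tetra_step: int = 500
    nmds_starts: int = 20
    run_tetra: bool = False
    seed: int = 0
    out_prefix: str = "dgrscope"
    verbosity: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def cis_config(self) -> cis_elements.CisConfig:
        return cis_elements.CisConfig(
            imh_span=self.imh_span,
            stem_min=self.stem_min,
            stem_max=self.stem_max,
            loop_min=self.loop_min,
            loop_max=self.loop_max,
        )


def detect_record(
    record: seqcore.GenomeRecord,
    config: PipelineConfig,
    rt_loci: Optional[Sequence[tuple[int, int]]] = None,
) -> dict:
    """Run detection on one record; returns the per-record report entry.

    ``rt_loci`` optionally supplies RT intervals directly (e.g. from a BED
    file), bypassing the motif scan.
    """
    cfg = config
    orfs = seqcore.find_orfs(record, cfg.orf_min_protein_len, cfg.genetic_code)
    logger.info("record %s: %d ORFs >= %d aa", record.id, len(orfs), cfg.orf_min_protein_len)

    if rt_loci is not None:
        rts = []
        for s, e in rt_loci:
            matching = [o for o in orfs if o.start == s and o.end == e]
            orf = matching[0] if matching else _locus_orf(record, s, e)
            rts.append(dgr_detect.RtCandidate(orf=orf, motif_hits=[], score=1))
    else:
        rts = dgr_detect.scan_rt_candidates(
            orfs, min_motifs=cfg.rt_min_motifs, min_protein_len=cfg.rt_min_protein_len
        )
    logger.info("record %s: %d RT candidate(s)", record.id, len(rts))

    entry: dict = {
        "id": record.id,
        "length": len(record),
        "n_orfs": len(orfs),
        "rt_candidates": [
            {
                "start": r.orf.start,
                "end": r.orf.end,
                "strand": r.orf.strand,
                "score": r.score,
                "motif_hits": r.motif_hits,
            }
            for r in rts
        ],
        "repeat_pairs": 0,
        "trvr_calls": [],
        "cassettes": [],
    }

    cassettes: list[dgr_detect.DgrCassette] = []
    for rt in rts:
        pairs = dgr_detect.find_repeat_pairs(
            record,
            rt,
            window_bp=cfg.window_bp,
            min_repeat_len=cfg.min_repeat_len,
            seed_len=cfg.seed_len,
            max_mismatch_frac=cfg.max_mismatch_frac,
        )
        entry["repeat_pairs"] += len(pairs)
        calls = [
            dgr_detect.classify_tr_vr(p, cfg.min_adenine_mm, cfg.max_other_per_100bp)
            for p in pairs
        ]
        for call in calls:
            entry["trvr_calls"].append(
                {
                    "passed": call.passed,
                    "reasons": call.reasons,
                    "tr": call.tr,
                    "vr": call.vr,
                    "template_strand": call.template_strand,
                    "n_adenine_wrt_A": call.profile.n_adenine_wrt_A,
                    "n_adenine_wrt_B": call.profile.n_adenine_wrt_B,
                    "aligned_len": call.profile.aligned_len,
                }
            )
        cassettes.extend(
            dgr_detect.assemble_cassette(record, rt, calls, orfs, cfg.cis_config())
        )

    # deduplicate cassettes sharing a VR across anchors
    seen_vr = set()
    unique = []
    for c in cassettes:
        if c.trvr.vr in seen_vr:
            continue
        seen_vr.add(c.trvr.vr)
        unique.append(c)

    for c in unique:
        entry["cassettes"].append(_cassette_entry(c, record))

    if len(unique) > 1:
        idm = {}
        for i in range(len(unique)):
            for j in range(i + 1, len(unique)):
                idm[f"{i}-{j}"] = dgr_detect.cassette_identity(
                    unique[i], unique[j], record, record
                )
        entry["identity_matrix"] = idm
    return entry


def _locus_orf(record: seqcore.GenomeRecord, s: int, e: int) -> seqcore.OrfFeature:
    length = e - s - (e - s) % 3
    dna = record.sequence[s : s + length]
    try:
        prot = seqcore.translate(dna[:-3]) if length >= 6 else ""
    except ValueError:
        prot = ""
    return seqcore.OrfFeature(record.id, s, s + length, "+", prot.replace("*", "X"), partial=True)


def _cassette_entry(c: dgr_detect.DgrCassette, record: seqcore.GenomeRecord) -> dict:
    entry = {
        "complete": c.complete,
        "flags": c.flags,
        "rt": None if c.rt is None else [c.rt.orf.start, c.rt.orf.end],
        "tr": list(c.trvr.tr),
        "vr": list(c.trvr.vr),
        "template_strand": c.trvr.template_strand,
        "tp": None if c.tp_orf is None else [c.tp_orf.start, c.tp_orf.end, c.tp_orf.strand],
        "imh": None
        if c.imh is None
        else {
            "motif_pair": c.imh.motif_pair_name,
            "imh_interval": list(c.imh.imh_interval),
        },
        "hairpin": None
        if c.hairpin is None
        else {
            "stem_len": c.hairpin.stem_len,
            "loop_seq": c.hairpin.loop_seq,
            "loop_class": c.hairpin.loop_class,
            "start": c.hairpin.start,
            "end": c.hairpin.end,
        },
        "avd": None
        if c.avd is None
        else {
            "start": c.avd.orf.start,
            "end": c.avd.orf.end,
            "pI": round(c.avd.pI, 2),
            "mw_kda": round(c.avd.mw_kda, 2),
        },
        "diversity": None,
    }
    if c.complete and c.tp_orf is not None:
        summary = diversity.summarize_cassette(c, record)
        entry["diversity"] = {
            "n_adenines": summary.n_adenines,
            "n_nt_variants": str(summary.n_nt_variants),
            "n_diversifiable_codons": summary.n_diversifiable_codons,
            "n_aay_codons": summary.n_aay_codons,
            "n_protein_variants": str(summary.n_protein_variants),
            "nonsense_risk": summary.nonsense_risk,
        }
    return entry


def run_pipeline(
    fasta_paths: Sequence[str | Path],
    config: PipelineConfig | None = None,
    rt_bed: Optional[str | Path] = None,
) -> dict:
    """Full pipeline over one or more FASTA inputs; returns the report."""
    cfg = config or PipelineConfig()
    if not fasta_paths:
        raise ValueError("at least one input path is required")
    bed_by_chrom: dict[str, list[tuple[int, int]]] = {}
    if rt_bed is not None:
        for chrom, s, e, _name in seqcore.read_bed(rt_bed):
            bed_by_chrom.setdefault(chrom, []).append((s, e))

    report: dict = {"parameters": asdict(cfg), "records": []}
    all_records = []
    for path in fasta_paths:
        for record in seqcore.read_fasta(path):
            all_records.append(record)
            loci = bed_by_chrom.get(record.id) if rt_bed is not None else None
            report["records"].append(detect_record(record, cfg, rt_loci=loci))

    if cfg.run_tetra and all_records:
        profiles = []
        for rec in all_records:
            profiles.extend(
                tetra.profile_sequence(
                    rec.sequence, rec.id, "genome", cfg.tetra_window, cfg.tetra_step
                )
            )
        if len(profiles) >= 4:
            ordination = tetra.nmds(profiles, seed=cfg.seed, n_starts=cfg.nmds_starts)
            labels = [p.group for p in profiles]
            flags, fractions = tetra.outlier_report(ordination.coords, labels, "genome")
            report["tetra"] = {
                "n_windows": len(profiles),
                "stress": ordination.stress,
                "outlier_fraction": fractions,
            }
        else:
            report["tetra"] = {"n_windows": len(profiles), "stress": None}
    return report


# ---------------------------------------------------------------------------
# Output writers
# ---------------------------------------------------------------------------

def write_report(report: dict, out_prefix: str | Path, formats: Sequence[str] = ("json", "gff3", "tsv")) -> list[Path]:
    """Write the report as JSON / GFF3 / TSV next to ``out_prefix``."""
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    written = []
    if "json" in formats:
        p = out_prefix.with_suffix(".json")
        with open(p, "w") as fh:
            json.dump(report, fh, indent=2, default=str)
        written.append(p)
    if "gff3" in formats:
        p = out_prefix.with_suffix(".gff3")
        seqcore.write_gff3(_report_features(report), p)
        written.append(p)
    if "tsv" in formats:
        p = out_prefix.with_suffix(".tsv")
        _write_tsv(report, p)
        written.append(p)
    return written


def _report_features(report: dict):
    for rec in report.get("records", []):
        for ci, c in enumerate(rec["cassettes"]):
            attrs = {"ID": f"{rec['id']}.cassette{ci}", "complete": str(c["complete"])}
            if c["rt"]:
                yield {"seqid": rec["id"], "type": "DGR_RT", "start": c["rt"][0], "end": c["rt"][1], "strand": "+", "attributes": attrs | {"Name": "RT"}}
            yield {"seqid": rec["id"], "type": "DGR_TR", "start": c["tr"][0], "end": c["tr"][1], "strand": c["template_strand"], "attributes": attrs | {"Name": "TR"}}
            yield {"seqid": rec["id"], "type": "DGR_VR", "start": c["vr"][0], "end": c["vr"][1], "strand": "+", "attributes": attrs | {"Name": "VR"}}
            if c["tp"]:
                yield {"seqid": rec["id"], "type": "DGR_TP", "start": c["tp"][0], "end": c["tp"][1], "strand": c["tp"][2], "attributes": attrs | {"Name": "TP"}}
            if c["imh"]:
                yield {"seqid": rec["id"], "type": "DGR_IMH", "start": c["imh"]["imh_interval"][0], "end": c["imh"]["imh_interval"][1], "strand": "+", "attributes": attrs | {"Name": c["imh"]["motif_pair"]}}
            if c["hairpin"]:
                yield {"seqid": rec["id"], "type": "DGR_hairpin", "start": c["hairpin"]["start"], "end": c["hairpin"]["end"], "strand": "+", "attributes": attrs | {"Name": c["hairpin"]["loop_class"]}}
            if c["avd"]:
                yield {"seqid": rec["id"], "type": "DGR_avd_candidate", "start": c["avd"]["start"], "end": c["avd"]["end"], "strand": "+", "attributes": attrs | {"Name": "Avd"}}


TSV_COLUMNS = [
    "record_id", "cassette", "complete", "flags", "rt_start", "rt_end",
    "tr_start", "tr_end", "vr_start", "vr_end", "tp_start", "tp_end",
    "n_adenines", "n_nt_variants", "n_diversifiable_codons", "n_aay_codons",
    "n_protein_variants", "nonsense_risk", "has_imh", "has_hairpin",
]


def _write_tsv(report: dict, path: Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(TSV_COLUMNS)
        for rec in report.get("records", []):
            for ci, c in enumerate(rec["cassettes"]):
                div = c.get("diversity") or {}
                w.writerow(
                    [
                        rec["id"], ci, c["complete"], ",".join(c["flags"]) or ".",
                        c["rt"][0] if c["rt"] else ".", c["rt"][1] if c["rt"] else ".",
                        c["tr"][0], c["tr"][1], c["vr"][0], c["vr"][1],
                        c["tp"][0] if c["tp"] else ".", c["tp"][1] if c["tp"] else ".",
                        div.get("n_adenines", "."), div.get("n_nt_variants", "."),
                        div.get("n_diversifiable_codons", "."), div.get("n_aay_codons", "."),
                        div.get("n_protein_variants", "."), div.get("nonsense_risk", "."),
                        c["imh"] is not None, c["hairpin"] is not None,
                    ]
                )
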