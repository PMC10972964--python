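"""End-to-end annotation pipeline and germline-library export.

``run_annotate`` wires the stages together: scan both gene types on both
strands, classify functionality, cluster V families, assign names, and write
the TSV/GFF3/FASTA bundle.  ``export_germline_library`` compiles functional
and ORF genes (pseudogenes excluded) into per-chain FASTA files plus an
anchor-point table of the kind downstream aligners consume when building a
custom V(D)J reference.

CDR1/CDR2 boundaries cannot be computed without an external domain
alignment; the heuristic anchor builder places them at fixed V-domain
offsets and derives only CDR3Begin from the located 2nd-CYS motif.  Anchor
tables are therefore meant to be user-edited before use.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from .classifier import FunctionalityCall, classify_j, classify_v
from .config import ScanConfig
from .family_cluster import cluster_families, name_genes, name_j_genes
from .seq_core import Interval, NucSeq, revcomp, write_fasta, write_gff3, write_tsv
from .vj_finder import GeneCandidate, scan_j_genes, scan_v_genes

__all__ = ["AnchorSet", "GermlineEntry", "default_anchors",
           "export_germline_library", "run_annotate"]

log = logging.getLogger(__name__)

V_ANCHOR_KEYS = ("FR1Begin", "CDR1Begin", "FR2Begin", "CDR2Begin",
                 "FR3Begin", "CDR3Begin", "VEnd")
D_ANCHOR_KEYS = ("DBegin", "DEnd")
J_ANCHOR_KEYS = ("JBegin", "FR4Begin", "FR4End")

# fallback V-domain FR/CDR offsets (nt within the exported gene); CDR3Begin
# is replaced by the 2nd-CYS-derived position whenever the motif was located
_DEFAULT_V_OFFSETS = (0, 78, 114, 165, 195)


@dataclass(frozen=True)
class AnchorSet:
    """0-based anchor offsets within one exported gene sequence."""

    gene: str
    gene_type: str
    anchors: dict[str, int]

    def validate(self) -> None:
        keys = {"V": V_ANCHOR_KEYS, "D": D_ANCHOR_KEYS, "J": J_ANCHOR_KEYS}[
            self.gene_type
        ]
        missing = [k for k in keys if k not in self.anchors]
        if missing:
            raise ValueError(f"{self.gene}: missing anchors {missing}")
        values = [self.anchors[k] for k in keys]
        if any(b <= a for a, b in zip(values, values[1:])):
            raise ValueError(
                f"{self.gene}: anchors must be strictly increasing, got {values}"
            )


def default_anchors(name: str, candidate: GeneCandidate) -> AnchorSet:
    """Heuristic anchor set for a scanned candidate (user-editable)."""
    length = len(candidate.interval)
    if candidate.gene_type == "V":
        cdr3 = None
        for hit in candidate.motif_hits:
            if hit.name == "second_cys_motif":
                cdr3 = (hit.pos + 2) * 3  # nt offset of the 2nd-CYS codon
        if cdr3 is None or cdr3 >= length:
            cdr3 = max(length - 9, _DEFAULT_V_OFFSETS[-1] + 3)
        anchors = dict(zip(V_ANCHOR_KEYS[:-2], _DEFAULT_V_OFFSETS))
        anchors["CDR3Begin"] = cdr3
        anchors["VEnd"] = length
    elif candidate.gene_type == "J":
        fr4 = None
        for hit in candidate.motif_hits:
            if hit.name == "j_core":
                fr4 = hit.pos  # gene-local offset
        if fr4 is None or not 0 < fr4 < length:
            fr4 = max(1, length - 30)
        anchors = {"JBegin": 0, "FR4Begin": fr4, "FR4End": length}
    else:
        anchors = {"DBegin": 0, "DEnd": length}
    aset = AnchorSet(name, candidate.gene_type, anchors)
    aset.validate()
    return aset


@dataclass
class GermlineEntry:
    name: str
    chain: str
    gene_type: str
    seq: str
    call: FunctionalityCall
    anchors: AnchorSet


def export_germline_library(
    entries: list[GermlineEntry], out_dir: str | Path, prefix: str = "germline"
) -> list[Path]:
    """Write per-chain FASTA files plus the anchor TSV for F and ORF genes.

    Pseudogenes are excluded; output ordering is deterministic (chain, gene
    type, name).  Anchor violations raise, naming the offending gene.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    kept = [e for e in entries if e.call.call in ("F", "ORF")]
    for e in kept:
        e.anchors.validate()
    kept.sort(key=lambda e: (e.chain, e.gene_type, e.name))
    written: list[Path] = []
    for chain in sorted({e.chain for e in kept}):
        members = [e for e in kept if e.chain == chain]
        path = out_dir / f"{prefix}.{chain}.fa"
        write_fasta(
            [NucSeq(e.name, e.seq, f"{e.gene_type} {e.call.call}") for e in members],
            path,
        )
        written.append(path)
    rows = []
    for e in kept:
        row = {"gene": e.name, "chain": e.chain, "gene_type": e.gene_type,
               "functionality": e.call.call}
        row.update(e.anchors.anchors)
        rows.append(row)
    columns = ["gene", "chain", "gene_type", "functionality",
               *V_ANCHOR_KEYS, *D_ANCHOR_KEYS, *J_ANCHOR_KEYS]
    anchor_path = out_dir / f"{prefix}.anchors.tsv"
    write_tsv(rows, anchor_path, columns)
    written.append(anchor_path)
    return written


def _gene_sequence(seq: NucSeq, iv: Interval) -> str:
    sub = seq.seq[iv.start : iv.end]
    return revcomp(sub) if iv.strand == "-" else sub


@dataclass
class AnnotationBundle:
    candidates: list[GeneCandidate]
    calls: dict[str, FunctionalityCall]
    names: dict[str, str]
    families: list
    files: list[Path] = field(default_factory=list)


def run_annotate(
    seqs: list[NucSeq],
    chain: str = "TRA",
    config: ScanConfig | None = None,
    out_dir: str | Path | None = None,
    family_waivers: set[str] | None = None,
    family_threshold: float = 75.0,
) -> AnnotationBundle:
    """Scan -> classify -> cluster -> name -> export.

    The locus orientation toward the C gene is taken as the majority strand
    of the candidates (reverse for a typical chicken TCR locus).  Candidate
    working ids are ``{seq_id}:{start}-{end}({strand})``.
    """
    cfg = config or ScanConfig()
    candidates: list[GeneCandidate] = []
    for seq in seqs:
        candidates += scan_v_genes(seq, cfg)
        candidates += scan_j_genes(seq, cfg)
    candidates.sort(key=GeneCandidate.sort_key)
    log.info("scan: %d V / %d J candidates",
             sum(c.gene_type == "V" for c in candidates),
             sum(c.gene_type == "J" for c in candidates))
    if not candidates:
        bundle = AnnotationBundle([], {}, {}, [])
        if out_dir is not None:
            Path(out_dir).mkdir(parents=True, exist_ok=True)
            bundle.files.append(Path(out_dir) / "candidates.tsv")
            write_tsv([], bundle.files[-1],
                      ["gene", "seq_id", "start", "end", "strand", "type",
                       "functionality", "family", "name"])
        return bundle

    seq_by_id = {s.id: s for s in seqs}
    ids, calls, gene_seqs = [], {}, {}
    for cand in candidates:
        iv = cand.interval
        gid = f"{iv.seq_id}:{iv.start}-{iv.end}({iv.strand})"
        ids.append(gid)
        calls[gid] = classify_v(cand, config=cfg) if cand.gene_type == "V" else classify_j(cand, config=cfg)
        cand.functionality = calls[gid].call
        gene_seqs[gid] = _gene_sequence(seq_by_id[iv.seq_id], iv)
    counts = {c: sum(1 for v in calls.values() if v.call == c) for c in ("F", "ORF", "P")}
    log.info("classify: %s", counts)

    v_ids = [g for g, c in zip(ids, candidates) if c.gene_type == "V"]
    strand_votes = [c.strand for c in candidates]
    locus_strand = "-" if strand_votes.count("-") >= strand_votes.count("+") else "+"
    names: dict[str, str] = {}
    families = []
    if v_ids:
        families = cluster_families(
            [NucSeq(g, gene_seqs[g]) for g in v_ids],
            threshold=family_threshold,
            waivers=family_waivers,
        )
        positions = {
            g: c.interval for g, c in zip(ids, candidates) if c.gene_type == "V"
        }
        names.update(name_genes(families, chain, positions, calls, locus_strand))
    j_positions = {
        g: c.interval for g, c in zip(ids, candidates) if c.gene_type == "J"
    }
    if j_positions:
        names.update(name_j_genes(chain, j_positions, calls, locus_strand))
    for gid, cand in zip(ids, candidates):
        cand.name = names.get(gid, gid)
    log.info("cluster: %d V families", len(families))

    bundle = AnnotationBundle(candidates, calls, names, families)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        rows = []
        for gid, cand in zip(ids, candidates):
            iv = cand.interval
            rows.append(
                dict(gene=cand.name, seq_id=iv.seq_id, start=iv.start, end=iv.end,
                     strand=iv.strand, type=cand.gene_type,
                     functionality=calls[gid].call,
                     reasons=",".join(calls[gid].reasons),
                     family=cand.family_guess or "",
                     notes="; ".join(cand.notes))
            )
        tsv = out / "candidates.tsv"
        write_tsv(rows, tsv, ["gene", "seq_id", "start", "end", "strand", "type",
                              "functionality", "reasons", "family", "notes"])
        fasta = out / "candidates.fa"
        write_fasta(
            [NucSeq(cand.name, gene_seqs[gid],
                    f"{cand.gene_type} {calls[gid].call}")
             for gid, cand in zip(ids, candidates)],
            fasta,
        )
        gff = out / "candidates.gff3"
        write_gff3(candidates, gff)
        entries = [
            GermlineEntry(cand.name, chain, cand.gene_type, gene_seqs[gid],
                          calls[gid], default_anchors(cand.name, cand))
            for gid, cand in zip(ids, candidates)
        ]
        lib = export_germline_library(entries, out, prefix="germline")
        bundle.files = [tsv, fasta, gff, *lib]
    return bundle
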