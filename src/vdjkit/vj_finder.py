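"""The core germline scanner.

Slides over both strands of genomic DNA and emits V and J gene candidates
that satisfy the combined motif/ORF/RSS criteria, with a tentative family
assignment, plus a window-constrained D-segment scanner.

A V candidate is an open V-exon reading frame carrying the three conserved
V-domain anchors (1st-CYS, CONSERVED-TRP, 2nd-CYS motif) that runs into a
3' 23-class RSS, opened either by an in-frame ATG (single-exon leader, as in
chicken Valpha1 genes) or by an AG splice acceptor (spliced leader).  A J
candidate spans from the base after a 5' 12-class RSS heptamer to a GTRDGD
splice donor, contains the TTYGGNNNNGG core motif translating F-G, and is
stop-free in the core's reading frame.  D segments are short stretches
between a 5' 12-RSS and a 3' 23-RSS with at least one open reading frame;
because that pattern is weakly specific, D scanning requires an explicit
genomic window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .config import ScanConfig
from .motif_engine import (
    J_CORE,
    MotifHit,
    RssHit,
    SPLICE_DONOR,
    J_SECONDARY,
    find_conserved_v_anchors,
    find_rss,
    has_all_v_anchors,
)
from .seq_core import Interval, NucSeq, find_iupac, revcomp, translate

__all__ = [
    "GeneCandidate",
    "FAMILY_MOTIFS",
    "scan_v_genes",
    "scan_j_genes",
    "scan_d_segments",
    "assign_family",
]

# Tentative chicken V-family assignment motifs near the 5' end of the mature
# V protein; exact matches only — the list is definitional.
FAMILY_MOTIFS: dict[str, tuple[str, ...]] = {
    "TRAV1": ("QVQQ",),
    "TRAV2": ("VSQQ",),
    "TRAV3": ("LQYP",),
    "TRBV1": ("LQQT",),
    "TRBV2": ("EINQ",),
    "TRBV3": ("ITQW",),
    "TRGV1": ("QVLLQQ",),
    "TRGV2": ("PIQS",),
    "TRGV3": ("QAVPMQ", "QAAPVQ"),
    "TRGV4": ("LWQSP",),
    "TRDV1": ("ETSGGGV",),
    "TRDV2": ("LEASGGG",),
    "TRDV3": ("VEFGGDV",),
    "TRDV4": ("RIVEAG",),
    "TRDV5": ("EIHAKKSA",),
    "TRDVH1": ("QIEMVTT",),
}


@dataclass
class GeneCandidate:
    """A located V/D/J candidate in forward-strand coordinates."""

    interval: Interval
    gene_type: str  # V | D | J
    leader_mode: str = "none"  # single_exon | spliced | none
    leader_interval: Interval | None = None
    splice_acceptor_pos: int | None = None
    motif_hits: list[MotifHit] = field(default_factory=list)
    rss: RssHit | None = None
    rss_extra: list[RssHit] = field(default_factory=list)  # D genes: 3' RSS
    protein: str = ""
    family_guess: str | None = None
    notes: list[str] = field(default_factory=list)
    name: str | None = None
    functionality: str | None = None
    # boundary evidence recorded by the scanner / region evaluators; None
    # means "not examined" (e.g. D segments)
    boundary_cac: bool | None = None
    has_start: bool | None = None
    has_acceptor: bool | None = None

    @property
    def strand(self) -> str:
        return self.interval.strand

    def sort_key(self):
        iv = self.interval
        return (iv.seq_id, iv.start, iv.strand, iv.end)


def _frame_translations(s: str) -> list[str]:
    return [translate(s, f) for f in (0, 1, 2)]

def _exon_protein(frames: list[str], j: int, i: int) -> str:
    """Translation of s[j:i] in frame 0 from j (trailing partial codon dropped)."""
    f = j % 3
    k = j // 3
    return frames[f][k : k + (i - j) // 3]


def _find_all(sub: str, s: str) -> list[int]:
    out, pos = [], s.find(sub)
    while pos != -1:
        out.append(pos)
        pos = s.find(sub, pos + 1)
    return out


def _mirror_rss(rss: RssHit, seq_len: int) -> RssHit:
    iv = rss.interval.mirror(seq_len) if rss.interval else None
    return RssHit(
        seq_len - 1 - rss.cac_pos,
        rss.spacer_class,
        rss.spacer_len,
        rss.side,
        rss.heptamer,
        rss.spacer,
        rss.nonamer,
        iv,
    )


def _mirror_candidate(cand: GeneCandidate, seq_len: int) -> GeneCandidate:
    cand.interval = cand.interval.mirror(seq_len)
    if cand.leader_interval is not None:
        cand.leader_interval = cand.leader_interval.mirror(seq_len)
    if cand.splice_acceptor_pos is not None:
        cand.splice_acceptor_pos = seq_len - 1 - cand.splice_acceptor_pos
    if cand.rss is not None:
        cand.rss = _mirror_rss(cand.rss, seq_len)
    cand.rss_extra = [_mirror_rss(r, seq_len) for r in cand.rss_extra]
    return cand


# ---------------------------------------------------------------------------
# V genes


def _scan_v_strand(s: str, seq_id: str, cfg: ScanConfig) -> list[GeneCandidate]:
    frames = _frame_translations(s)
    out: list[GeneCandidate] = []
    for i in _find_all(cfg.heptamer_prefix, s):
        rss_hits = find_rss(s, i, "downstream_of_v", cfg, seq_id)
        if not rss_hits:
            continue
        # enumerate exon starts within the length window; the exon ends at
        # the base before the RSS heptamer
        best: tuple | None = None  # (exon_len, mode_rank, mode, anchors, protein)
        lo = max(0, i - cfg.v_exon_max)
        hi = i - cfg.v_exon_min
        for j in range(lo, hi + 1):
            modes = []
            if s[j : j + 3] == "ATG":
                modes.append("single_exon")
            if j >= 2 and s[j - 2 : j] == "AG":
                modes.append("spliced")
            for mode in modes:
                prot = _exon_protein(frames, j, i)
                if "*" in prot:
                    continue
                anchors = find_conserved_v_anchors(prot, cfg)
                if not has_all_v_anchors(anchors):
                    continue
                # same-RSS collapse: longest open leader wins; at equal
                # length a single-exon start outranks a spliced acceptor
                key = (i - j, 1 if mode == "single_exon" else 0, mode, anchors, prot)
                if best is None or key[:2] > best[:2]:
                    best = key
        if best is None:
            continue
        exon_len, _, mode, anchors, prot = best
        j = i - exon_len
        cand = GeneCandidate(
            interval=Interval(seq_id, j, i),
            gene_type="V",
            leader_mode=mode,
            splice_acceptor_pos=j - 2 if mode == "spliced" else None,
            motif_hits=list(anchors),
            rss=rss_hits[0],
            protein=prot,
            boundary_cac=True,
            has_start=mode == "single_exon",
            has_acceptor=mode == "spliced",
        )
        if mode == "single_exon":
            cand.notes.append("leader encoded within the V exon; cleavage site not predicted")
        assign_family(cand, cfg)
        out.append(cand)
    return out


def scan_v_genes(seq: NucSeq, config: ScanConfig | None = None) -> list[GeneCandidate]:
    """Scan both strands for V gene candidates.

    Reverse-strand candidates are reported with strand '-' in forward-strand
    coordinates.  Output is deterministically sorted by (seq_id, start,
    strand).
    """
    cfg = config or ScanConfig()
    s = seq.seq
    out = _scan_v_strand(s, seq.id, cfg)
    for cand in _scan_v_strand(revcomp(s), seq.id, cfg):
        out.append(_mirror_candidate(cand, len(s)))
    out.sort(key=GeneCandidate.sort_key)
    return out


# ---------------------------------------------------------------------------
# J genes


def _scan_j_strand(s: str, seq_id: str, cfg: ScanConfig) -> list[GeneCandidate]:
    frames = _frame_translations(s)
    out: list[GeneCandidate] = []
    core_len = len(J_CORE)
    for c in find_iupac(J_CORE, s):
        found = None
        # gene start b: abuts the 5' RSS, in frame with the core motif
        for b in range(c, c - cfg.j_len_max + core_len - 1, -3):
            if b < 0:
                break
            rss_hits = find_rss(s, b, "upstream_of_j", cfg, seq_id)
            if not rss_hits:
                continue
            search_to = b + cfg.j_len_max + len(SPLICE_DONOR)
            donors = [
                d for d in find_iupac(SPLICE_DONOR, s[c + core_len : search_to])
            ]
            secondaries = find_iupac(J_SECONDARY, s[c + core_len : search_to])
            for rel_d in donors:
                d = c + core_len + rel_d
                if not (cfg.j_len_min <= d - b <= cfg.j_len_max):
                    continue
                notes = []
                has_secondary = any(
                    c + core_len + p + len(J_SECONDARY) <= d for p in secondaries
                )
                if not has_secondary:
                    if not cfg.relax_j_secondary:
                        continue
                    notes.append("secondary motif TNNBNRT not found before donor")
                prot = _exon_protein(frames, b, d)
                if "*" in prot:
                    continue
                # motif positions are gene-local offsets (relative to the
                # gene start) so they are strand-invariant
                hits = [MotifHit("j_core", c - b, s[c : c + core_len])]
                hits += [
                    MotifHit("j_secondary", c + core_len + p - b,
                             s[c + core_len + p : c + core_len + p + len(J_SECONDARY)])
                    for p in secondaries
                    if c + core_len + p + len(J_SECONDARY) <= d
                ]
                hits.append(MotifHit("splice_donor", d - b, s[d : d + len(SPLICE_DONOR)]))
                found = GeneCandidate(
                    interval=Interval(seq_id, b, d),
                    gene_type="J",
                    motif_hits=hits,
                    rss=rss_hits[0],
                    protein=prot,
                    notes=notes,
                    boundary_cac=True,
                )
                break
            if found:
                break
        if found:
            out.append(found)
    # two core hits inside one span can emit duplicates; keep unique intervals
    uniq: dict[tuple, GeneCandidate] = {}
    for cand in out:
        uniq.setdefault((cand.interval.start, cand.interval.end), cand)
    return list(uniq.values())


def scan_j_genes(seq: NucSeq, config: ScanConfig | None = None) -> list[GeneCandidate]:
    """Scan both strands for J gene candidates (sorted, forward coordinates)."""
    cfg = config or ScanConfig()
    s = seq.seq
    out = _scan_j_strand(s, seq.id, cfg)
    for cand in _scan_j_strand(revcomp(s), seq.id, cfg):
        out.append(_mirror_candidate(cand, len(s)))
    out.sort(key=GeneCandidate.sort_key)
    return out


# ---------------------------------------------------------------------------
# D segments


def _frame_openness(segment: str) -> list[bool]:
    open_frames = []
    for f in (0, 1, 2):
        prot = translate(segment, f)
        open_frames.append("*" not in prot)
    return open_frames


def _scan_d_strand(s: str, seq_id: str, lo: int, hi: int, cfg: ScanConfig) -> list[GeneCandidate]:
    out = []
    for b in range(lo, hi):
        rss5 = find_rss(s, b, "upstream_of_j", cfg, seq_id)
        if not rss5:
            continue
        for e in range(b + cfg.d_len_min, min(b + cfg.d_len_max, hi) + 1):
            rss3 = find_rss(s, e, "downstream_of_v", cfg, seq_id)
            if not rss3:
                continue
            segment = s[b:e]
            openness = _frame_openness(segment)
            if not any(openness):
                continue
            out.append(
                GeneCandidate(
                    interval=Interval(seq_id, b, e),
                    gene_type="D",
                    rss=rss5[0],
                    rss_extra=[rss3[0]],
                    protein=translate(segment),
                    notes=[
                        "open_frames="
                        + ",".join(str(f) for f, ok in enumerate(openness) if ok)
                    ],
                )
            )
    return out


def scan_d_segments(
    seq: NucSeq, window: Interval, config: ScanConfig | None = None
) -> list[GeneCandidate]:
    """D candidates inside an explicit window: a 12-RSS reading into the
    segment from 5' and a 23-RSS from 3' flank a short segment with at least
    one stop-free frame (per-frame openness recorded in notes)."""
    cfg = config or ScanConfig()
    s = seq.seq
    if window.end > len(s):
        raise ValueError("window exceeds sequence length")
    out = _scan_d_strand(s, seq.id, window.start, window.end, cfg)
    rc = revcomp(s)
    m = window.mirror(len(s))
    for cand in _scan_d_strand(rc, seq.id, m.start, m.end, cfg):
        out.append(_mirror_candidate(cand, len(s)))
    out.sort(key=GeneCandidate.sort_key)
    return out


# ---------------------------------------------------------------------------
# Family assignment


def assign_family(candidate: GeneCandidate, config: ScanConfig | None = None) -> str | None:
    """Tentative family from an exact amino-acid motif near the mature V start.

    The motif must begin within ``family_motif_window`` aa of the mature
    protein; for single-exon candidates the uncleaved leader precedes the
    mature start, so the window is widened by ``single_exon_leader_aa``.
    Ambiguous or absent motifs yield ``None`` with a note.
    """
    if candidate.gene_type != "V":
        raise ValueError("family assignment applies to V candidates only")
    cfg = config or ScanConfig()
    window = cfg.family_motif_window
    if candidate.leader_mode == "single_exon":
        window += cfg.single_exon_leader_aa
    matches = []
    for family, motifs in FAMILY_MOTIFS.items():
        for motif in motifs:
            pos = candidate.protein.find(motif, 0, window + len(motif) - 1)
            if pos != -1:
                matches.append((family, motif, pos))
                break
    if len(matches) == 1:
        candidate.family_guess = matches[0][0]
    elif not matches:
        candidate.family_guess = None
        candidate.notes.append("no family motif near 5' end")
    else:
        candidate.family_guess = None
        candidate.notes.append(
            "ambiguous family motif: " + ",".join(m[0] for m in matches)
        )
    return candidate.family_guess
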