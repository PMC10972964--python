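"""Functionality classification of V and J genes.

Calls follow the IMGT-style F/ORF/P scheme:

* **P** (pseudogene): stop codon, frameshift, or an RSS whose heptamer does
  not begin with CAC.
* **ORF**: no stop/frameshift/CAC defect, but some other defining feature is
  altered (missing anchor residue, missing splice site, failed signal-peptide
  or RSS-score check).
* **F** (functional): every feature intact.

External predictors (signal-peptide, RSS information-content scoring) enter
only through pluggable hooks; without hooks those checks default to a
recorded permissive pass so a default run is deterministic and offline.
A structurally invalid RSS whose heptamer still begins with CAC (bad spacer
geometry or unrecognizable nonamer) is reported as ``rss_low_score`` — the
built-in structural validation acts as a crude score — keeping ``rss_no_cac``
strictly for the pseudogene-defining CAC defect.

Frameshifts are only assignable with expressed-read evidence or an external
high-identity consensus match; callers supply that evidence explicitly via
``frameshift_evidence``; otherwise the code is never emitted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

from .config import ScanConfig
from .motif_engine import find_conserved_v_anchors, find_rss, has_all_v_anchors
from .seq_core import Interval, NucSeq, find_iupac, revcomp, translate
from .motif_engine import J_CORE, SPLICE_DONOR, J_SECONDARY, MotifHit
from .vj_finder import GeneCandidate

__all__ = [
    "FunctionalityCall",
    "classify_v",
    "classify_j",
    "define_v_bounds",
    "evaluate_v_region",
    "evaluate_j_region",
]

P_REASONS = frozenset({"stop_codon", "frameshift", "rss_no_cac"})
VALID_REASONS = P_REASONS | {
    "missing_first_cys",
    "missing_trp",
    "missing_second_cys_motif",
    "missing_fg",
    "rss_low_score",
    "no_signal_peptide",
    "no_splice_donor",
    "no_splice_acceptor",
    "missing_lpart1",
}


@dataclass(frozen=True)
class FunctionalityCall:
    call: str  # F | ORF | P
    reasons: tuple[str, ...] = ()
    notes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.call not in ("F", "ORF", "P"):
            raise ValueError(f"bad call {self.call!r}")
        bad = set(self.reasons) - VALID_REASONS
        if bad:
            raise ValueError(f"unknown reason codes {sorted(bad)}")
        if self.call == "F" and self.reasons:
            raise ValueError("F call must carry no reasons")
        if self.call == "P" and not (set(self.reasons) & P_REASONS):
            raise ValueError("P call requires a pseudogene-defining reason")
        if self.call == "ORF" and (not self.reasons or set(self.reasons) & P_REASONS):
            raise ValueError("ORF call requires non-P reasons")

    def __str__(self) -> str:
        return self.call


def _finalize(reasons: list[str], notes: list[str]) -> FunctionalityCall:
    reasons = sorted(set(reasons))
    if set(reasons) & P_REASONS:
        call = "P"
    elif reasons:
        call = "ORF"
    else:
        call = "F"
    return FunctionalityCall(call, tuple(reasons), tuple(notes))


def classify_v(
    candidate: GeneCandidate,
    signal_peptide_hook: Callable | None = None,
    rss_score_hook: Callable | None = None,
    config: ScanConfig | None = None,
    frameshift_evidence: bool = False,
) -> FunctionalityCall:
    """Apply the V functionality rules.

    F requires: all three conserved anchors, a 3' 23-RSS beginning CAC, a
    leader whose signal peptide passes the (hooked) prediction, and neither
    stop codons nor frameshifts.
    """
    if candidate.gene_type != "V":
        raise ValueError("classify_v requires a V candidate")
    cfg = config or ScanConfig()
    reasons: list[str] = []
    notes: list[str] = []

    if "*" in candidate.protein:
        reasons.append("stop_codon")
    if frameshift_evidence:
        reasons.append("frameshift")

    names = {h.name for h in candidate.motif_hits}
    if "first_cys" not in names:
        reasons.append("missing_first_cys")
    if "conserved_trp" not in names:
        reasons.append("missing_trp")
    if "second_cys_motif" not in names:
        reasons.append("missing_second_cys_motif")

    if candidate.rss is None:
        if candidate.boundary_cac is False:
            reasons.append("rss_no_cac")
        else:
            reasons.append("rss_low_score")
            notes.append("RSS failed structural validation (spacer/nonamer geometry)")
    elif rss_score_hook is not None and cfg.rss_score_threshold is not None:
        score = rss_score_hook(
            candidate.rss.heptamer, candidate.rss.spacer, candidate.rss.nonamer
        )
        if score < cfg.rss_score_threshold:
            reasons.append("rss_low_score")

    if candidate.leader_mode == "spliced" and candidate.has_acceptor is False:
        reasons.append("no_splice_acceptor")
    if candidate.leader_mode == "single_exon" and candidate.has_start is False:
        reasons.append("missing_lpart1")

    if signal_peptide_hook is not None:
        leader = candidate.protein[: cfg.single_exon_leader_aa]
        result = signal_peptide_hook(leader)
        status = result.get("status") if isinstance(result, dict) else result
        if status == "fail":
            reasons.append("no_signal_peptide")
    else:
        notes.append("signal peptide check skipped (no hook); permissive pass")

    return _finalize(reasons, notes)


def classify_j(
    candidate: GeneCandidate,
    rss_score_hook: Callable | None = None,
    config: ScanConfig | None = None,
    frameshift_evidence: bool = False,
) -> FunctionalityCall:
    """Apply the J functionality rules: F requires the FG core motif, a 5'
    12-RSS beginning CAC, a 3' splice donor and no stop codons."""
    if candidate.gene_type != "J":
        raise ValueError("classify_j requires a J candidate")
    cfg = config or ScanConfig()
    reasons: list[str] = []
    notes: list[str] = []

    if "*" in candidate.protein:
        reasons.append("stop_codon")
    if frameshift_evidence:
        reasons.append("frameshift")

    names = {h.name for h in candidate.motif_hits}
    if "j_core" not in names:
        reasons.append("missing_fg")
    if "splice_donor" not in names:
        reasons.append("no_splice_donor")

    if candidate.rss is None:
        if candidate.boundary_cac is False:
            reasons.append("rss_no_cac")
        else:
            reasons.append("rss_low_score")
            notes.append("RSS failed structural validation (spacer/nonamer geometry)")
    elif rss_score_hook is not None and cfg.rss_score_threshold is not None:
        score = rss_score_hook(
            candidate.rss.heptamer, candidate.rss.spacer, candidate.rss.nonamer
        )
        if score < cfg.rss_score_threshold:
            reasons.append("rss_low_score")

    return _finalize(reasons, notes)


def define_v_bounds(candidate: GeneCandidate, cleavage_pos: int | None = None) -> Interval:
    """Mature V gene bounds: signal-peptide cleavage site (when an external
    prediction supplies it) to the base before the RSS heptamer.

    Fallbacks without a cleavage position: spliced mode starts at the first
    exon base after the AG acceptor; single-exon mode starts at the ATG.
    """
    if candidate.rss is None:
        raise ValueError("cannot define V bounds without a 3' RSS")
    iv = candidate.interval
    if cleavage_pos is not None:
        start = cleavage_pos
    elif candidate.leader_mode == "spliced" and candidate.splice_acceptor_pos is not None:
        start = candidate.splice_acceptor_pos + 2
    else:
        start = iv.start
    return Interval(iv.seq_id, start, iv.end, iv.strand)


# ---------------------------------------------------------------------------
# Permissive region evaluators: build a candidate from a known interval
# (e.g. a curated gene or a simulated truth row) without the scanner's
# hard filters, recording whatever features are present or absent.


def _sense_coords(seq: NucSeq, interval: Interval) -> tuple[str, int, int]:
    s = seq.seq
    if interval.strand == "+":
        return s, interval.start, interval.end
    rc = revcomp(s)
    m = interval.mirror(len(s))
    return rc, m.start, m.end


def evaluate_v_region(
    seq: NucSeq, interval: Interval, leader_mode: str, config: ScanConfig | None = None
) -> GeneCandidate:
    """Examine a V exon interval for every classifiable feature."""
    cfg = config or ScanConfig()
    sense, j, i = _sense_coords(seq, interval)
    prot = translate(sense[j:i])
    anchors = find_conserved_v_anchors(prot, cfg)
    rss_hits = find_rss(sense, i, "downstream_of_v", cfg, seq.id)
    cand = GeneCandidate(
        interval=Interval(seq.id, j, i),
        gene_type="V",
        leader_mode=leader_mode,
        splice_acceptor_pos=j - 2 if leader_mode == "spliced" and j >= 2 else None,
        motif_hits=list(anchors),
        rss=rss_hits[0] if rss_hits else None,
        protein=prot,
        boundary_cac=sense[i : i + len(cfg.heptamer_prefix)] == cfg.heptamer_prefix,
        has_start=sense[j : j + 3] == "ATG",
        has_acceptor=j >= 2 and sense[j - 2 : j] == "AG",
    )
    if interval.strand == "-":
        from .vj_finder import _mirror_candidate

        _mirror_candidate(cand, len(seq.seq))
    return cand


def evaluate_j_region(
    seq: NucSeq, interval: Interval, config: ScanConfig | None = None
) -> GeneCandidate:
    """Examine a J gene interval for every classifiable feature."""
    cfg = config or ScanConfig()
    sense, b, d = _sense_coords(seq, interval)
    body = sense[b:d]
    hits: list[MotifHit] = []  # gene-local motif offsets, as in the scanner
    core_positions = find_iupac(J_CORE, body)
    frame_anchor = b
    for p in core_positions:
        hits.append(MotifHit("j_core", p, body[p : p + len(J_CORE)]))
    if core_positions:
        frame_anchor = b + core_positions[0]
    for p in find_iupac(J_SECONDARY, body):
        hits.append(MotifHit("j_secondary", p, body[p : p + len(J_SECONDARY)]))
    donor = sense[d : d + len(SPLICE_DONOR)]
    from .seq_core import match_iupac

    if len(donor) == len(SPLICE_DONOR) and match_iupac(SPLICE_DONOR, donor):
        hits.append(MotifHit("splice_donor", d - b, donor))
    rss_hits = find_rss(sense, b, "upstream_of_j", cfg, seq.id)
    gtg = revcomp(cfg.heptamer_prefix)
    frame_start = b + (frame_anchor - b) % 3
    cand = GeneCandidate(
        interval=Interval(seq.id, b, d),
        gene_type="J",
        motif_hits=hits,
        rss=rss_hits[0] if rss_hits else None,
        protein=translate(sense[frame_start:d]),
        boundary_cac=b >= len(gtg) and sense[b - len(gtg) : b] == gtg,
    )
    if interval.strand == "-":
        from .vj_finder import _mirror_candidate

        _mirror_candidate(cand, len(seq.seq))
    return cand
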