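"""Anchor-motif detection: CAC-anchored RSSs, conserved V-domain residues,
J-segment nucleotide motifs and splice sites.

A recombination signal sequence (RSS) is a heptamer beginning ``CAC``, a 12-
or 23-nt spacer (each with a one-base tolerance) and a nonamer.  The heptamer
must abut the gene boundary and read away from the gene body on the gene's
sense strand.  Full heptamer/nonamer scoring is delegated to an external
scorer hook; here the nonamer is located with a degenerate consensus pattern
(``NCAAAANNN`` by default, matching the conserved A-tract) which is what
makes the spacer-length tolerance a falsifiable condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .config import ScanConfig
from .seq_core import Interval, find_iupac, match_iupac, revcomp, translate

__all__ = [
    "RssHit",
    "MotifHit",
    "SECOND_CYS_MOTIFS",
    "J_CORE",
    "J_SECONDARY",
    "SPLICE_DONOR",
    "find_rss",
    "find_conserved_v_anchors",
    "find_j_anchors",
]

# Conserved motif definitions (IUPAC for nucleotides, literal for protein)
SECOND_CYS_MOTIFS = ("YYC", "YFC", "YLC", "YHC", "YIC", "TFC")
J_CORE = "TTYGGNNNNGG"
J_SECONDARY = "TNNBNRT"
SPLICE_DONOR = "GTRDGD"


@dataclass(frozen=True)
class RssHit:
    """A CAC-anchored recombination signal.

    ``cac_pos`` is the forward-strand position (within the scanned sense
    sequence) of the heptamer's first base in RSS reading order; for a
    five-prime RSS the heptamer reads leftwards, so ``cac_pos`` is the last
    base before the gene boundary.
    """

    cac_pos: int
    spacer_class: int
    spacer_len: int
    side: str  # "five_prime" | "three_prime" relative to the gene
    heptamer: str = ""
    spacer: str = ""
    nonamer: str = ""
    interval: Interval | None = None

    def __post_init__(self) -> None:
        if self.side not in ("five_prime", "three_prime"):
            raise ValueError(f"bad RSS side {self.side!r}")
        if abs(self.spacer_len - self.spacer_class) > 1:
            raise ValueError(
                f"spacer_len {self.spacer_len} outside {self.spacer_class}+/-1"
            )


@dataclass(frozen=True)
class MotifHit:
    name: str
    pos: int
    matched_text: str


def find_rss(
    seq: str,
    anchor_pos: int,
    orientation: str,
    config: ScanConfig | None = None,
    seq_id: str = "",
) -> list[RssHit]:
    """RSS hits whose heptamer abuts a gene boundary.

    ``orientation`` is ``downstream_of_v`` (23-class RSS starting at
    ``anchor_pos``, the base after the V gene end) or ``upstream_of_j``
    (12-class RSS ending at ``anchor_pos``, the J gene start).  Hits are
    ordered by distance of the spacer length from its class.
    """
    cfg = config or ScanConfig()
    if orientation == "downstream_of_v":
        spacer_class, side = cfg.v_spacer_class, "three_prime"
    elif orientation == "upstream_of_j":
        spacer_class, side = cfg.j_spacer_class, "five_prime"
    else:
        raise ValueError(f"bad orientation {orientation!r}")

    hits: list[RssHit] = []
    for spacer_len in cfg.spacer_lengths(spacer_class):
        total = 7 + spacer_len + 9
        if side == "three_prime":
            block = seq[anchor_pos : anchor_pos + total]
            if len(block) < total:
                continue
            oriented = block
            iv = Interval(seq_id or "seq", anchor_pos, anchor_pos + total)
            cac_pos = anchor_pos
        else:
            if anchor_pos - total < 0:
                continue
            block = seq[anchor_pos - total : anchor_pos]
            oriented = revcomp(block)
            iv = Interval(seq_id or "seq", anchor_pos - total, anchor_pos)
            cac_pos = anchor_pos - 1
        heptamer, spacer, nonamer = (
            oriented[:7],
            oriented[7 : 7 + spacer_len],
            oriented[7 + spacer_len :],
        )
        if not heptamer.startswith(cfg.heptamer_prefix):
            continue
        if not match_iupac(cfg.nonamer_pattern, nonamer):
            continue
        hits.append(
            RssHit(cac_pos, spacer_class, spacer_len, side, heptamer, spacer, nonamer, iv)
        )
    hits.sort(key=lambda h: (abs(h.spacer_len - h.spacer_class), h.spacer_len))
    return hits


def find_conserved_v_anchors(protein: str, config: ScanConfig | None = None) -> list[MotifHit]:
    """Locate 1st-CYS, CONSERVED-TRP and the 2nd-CYS motif in a V translation.

    Windows are 1-based inclusive aa positions from the V exon start (see
    :class:`~vdjkit.config.ScanConfig`).  The 2nd-CYS motif reports the
    rightmost in-window occurrence of any of YYC/YFC/YLC/YHC/YIC/TFC.  All
    three present means the candidate passes the V anchor test.
    """
    cfg = config or ScanConfig()
    hits: list[MotifHit] = []

    cys_idx = None
    for i in range(cfg.first_cys_start - 1, min(cfg.first_cys_end, len(protein))):
        if protein[i] == "C":
            cys_idx = i
            break
    if cys_idx is not None:
        hits.append(MotifHit("first_cys", cys_idx, "C"))
        lo = cys_idx + cfg.trp_min_after_cys
        hi = min(cys_idx + cfg.trp_max_after_cys + 1, len(protein))
        for i in range(lo, hi):
            if protein[i] == "W":
                hits.append(MotifHit("conserved_trp", i, "W"))
                break

    best: MotifHit | None = None
    lo = cfg.second_cys_start - 1
    hi = min(cfg.second_cys_end, len(protein))  # 1-based inclusive start bound
    for i in range(lo, hi):
        tri = protein[i : i + 3]
        if tri in SECOND_CYS_MOTIFS:
            best = MotifHit("second_cys_motif", i, tri)
    if best is not None:
        hits.append(best)
    return hits


def has_all_v_anchors(hits: list[MotifHit]) -> bool:
    names = {h.name for h in hits}
    return {"first_cys", "conserved_trp", "second_cys_motif"} <= names


def find_j_anchors(seq: str, config: ScanConfig | None = None) -> list[MotifHit]:
    """J-segment motifs on the sense strand: core TTYGGNNNNGG (translating
    F-G in its own frame), secondary TNNBNRT and splice donor GTRDGD."""
    hits: list[MotifHit] = []
    for p in find_iupac(J_CORE, seq):
        text = seq[p : p + len(J_CORE)]
        if translate(text[:6]) == "FG":  # forced by the pattern, kept explicit
            hits.append(MotifHit("j_core", p, text))
    for p in find_iupac(J_SECONDARY, seq):
        hits.append(MotifHit("j_secondary", p, seq[p : p + len(J_SECONDARY)]))
    for p in find_iupac(SPLICE_DONOR, seq):
        hits.append(MotifHit("splice_donor", p, seq[p : p + len(SPLICE_DONOR)]))
    hits.sort(key=lambda h: (h.pos, h.name))
    return hits
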