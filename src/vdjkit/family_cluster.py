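"""V gene family clustering, consensus building and gene naming.

Families group V genes at >=75% nucleotide identity to the family consensus
(identity per the :mod:`~vdjkit.compare` formulas, rounded to one decimal).
The procedure seeds clusters by single linkage on pairwise identity, builds
each cluster's consensus from a center-star multiple alignment, reassigns
every gene to its best consensus, and iterates to a fixed point.  A waiver
list can pin individual sub-threshold genes to their best family — the
mechanism used for documented borderline members.

Gene names follow the convention ``[p|orf]TR{A,B,G,D}V{family}-{number}``
with members numbered densely in ascending order 5' to 3' toward the C gene
(descending forward-strand coordinate on a reverse-strand locus); J genes
are ``TR*J{number}`` in the same order.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from Bio import Align

from .compare import percent_identity
from .seq_core import Interval, NucSeq

__all__ = [
    "GeneFamily",
    "consensus_sequence",
    "center_star_alignment",
    "cluster_families",
    "name_genes",
    "name_j_genes",
]


@dataclass
class GeneFamily:
    name: str
    members: list[str]
    consensus: str
    member_identity: dict[str, float] = field(default_factory=dict)
    waived: set[str] = field(default_factory=set)


def consensus_sequence(rows: list[str]) -> str:
    """Per-column plurality consensus of equal-length gapped rows.

    Ties break alphabetically; columns in which gaps hold the majority are
    dropped from the consensus.
    """
    if not rows:
        raise ValueError("no rows")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise ValueError("ragged alignment rows")
    out = []
    half = len(rows) / 2
    for col in range(width):
        chars = [r[col] for r in rows]
        gaps = sum(1 for c in chars if c == "-")
        if gaps > half:
            continue
        counts = Counter(c for c in chars if c != "-")
        best = max(counts.items(), key=lambda kv: (kv[1], -ord(kv[0][0])))
        out.append(best[0])
    return "".join(out)


def _aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = 1
    al.mismatch_score = -1
    al.open_gap_score = -2
    al.extend_gap_score = -2
    return al


def center_star_alignment(seqs: list[str]) -> list[str]:
    """Multiple alignment by the center-star method.

    The center is the sequence with the highest summed identity to the rest;
    every other sequence is aligned to it pairwise and the gap patterns are
    merged into one master alignment.  Adequate for consensus building on
    within-family sequences (which are highly similar by construction).
    """
    if not seqs:
        raise ValueError("no sequences")
    if len(seqs) == 1:
        return [seqs[0]]
    totals = [
        sum(percent_identity(a, b) for j, b in enumerate(seqs) if i != j)
        for i, a in enumerate(seqs)
    ]
    center_idx = max(range(len(seqs)), key=lambda i: (totals[i], -i))
    center = seqs[center_idx]
    al = _aligner()

    master = center  # center row with accumulated gaps
    rows: list[tuple[int, str]] = [(center_idx, center)]
    for i, s in enumerate(seqs):
        if i == center_idx:
            continue
        best = al.align(center, s)[0]
        ac, am = str(best[0]), str(best[1])
        master, rows, new_row = _merge_into_master(master, rows, ac, am)
        rows.append((i, new_row))
    width = len(master)
    ordered = [""] * len(seqs)
    for idx, row in rows:
        ordered[idx] = row + "-" * (width - len(row))
    return ordered


def _merge_into_master(master, rows, aln_center, aln_member):
    """Merge one pairwise (center, member) alignment into the master MSA."""
    inserts_master: list[int] = []  # master columns where a gap must be added
    mi = ci = 0
    merged_master, merged_member = [], []
    while mi < len(master) or ci < len(aln_center):
        mc = master[mi] if mi < len(master) else None
        cc = aln_center[ci] if ci < len(aln_center) else None
        if mc is not None and mc == "-" and (cc is None or cc != "-"):
            merged_master.append("-")
            merged_member.append("-")
            mi += 1
        elif cc is not None and cc == "-" and (mc is None or mc != "-"):
            merged_master.append("-")
            merged_member.append(aln_member[ci])
            inserts_master.append(mi)
            ci += 1
        else:
            merged_master.append(mc if mc is not None else "-")
            merged_member.append(aln_member[ci] if ci < len(aln_member) else "-")
            mi += 1
            ci += 1
    # apply new gap columns to previously merged rows
    new_rows = []
    for idx, row in rows:
        shifted = []
        pos = 0
        for insert_at in sorted(inserts_master):
            shifted.append(row[pos:insert_at])
            shifted.append("-")
            pos = insert_at
        shifted.append(row[pos:])
        new_rows.append((idx, "".join(shifted)))
    return "".join(merged_master), new_rows, "".join(merged_member)


def family_consensus(seqs: list[str]) -> str:
    return consensus_sequence(center_star_alignment(seqs))


def cluster_families(
    genes: list[NucSeq],
    threshold: float = 75.0,
    waivers: set[str] | None = None,
    max_iter: int = 10,
) -> list[GeneFamily]:
    """Iterative family clustering at the given percent-identity threshold.

    Single-linkage seeding on pairwise identity, consensus per cluster,
    reassignment of every gene to its highest-identity consensus, repeated
    to a fixed point.  Genes below threshold to every consensus become
    singleton families unless waived, in which case they stay with their
    best family (recorded in ``waived``).  Deterministic and invariant to
    input order.
    """
    if not genes:
        raise ValueError("no genes to cluster")
    waivers = waivers or set()
    order = sorted(range(len(genes)), key=lambda i: genes[i].id)
    ids = [genes[i].id for i in order]
    seqs = [genes[i].seq for i in order]
    n = len(ids)

    # single-linkage seeding
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    pid = [[0.0] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            pid[i][j] = pid[j][i] = percent_identity(seqs[i], seqs[j])
            if pid[i][j] >= threshold:
                parent[find(i)] = find(j)

    assign = [find(i) for i in range(n)]
    labels = sorted(set(assign))
    assign = [labels.index(a) for a in assign]

    waived_now: set[str] = set()
    for _ in range(max_iter):
        clusters: dict[int, list[int]] = {}
        for i, a in enumerate(assign):
            clusters.setdefault(a, []).append(i)
        consensi = {
            a: family_consensus([seqs[i] for i in members])
            for a, members in sorted(clusters.items())
        }
        new_assign = list(assign)
        waived_now = set()
        next_label = max(clusters) + 1
        for i in range(n):
            # a waived gene must join its nearest real family: its own
            # singleton consensus (identity 100 to itself) is not a candidate
            skip = (
                assign[i]
                if ids[i] in waivers and len(clusters.get(assign[i], [])) == 1
                else None
            )
            scored = sorted(
                (
                    (percent_identity(seqs[i], cons), -a, a)
                    for a, cons in consensi.items()
                    if a != skip
                ),
                reverse=True,
            )
            if not scored:
                continue
            best_ident, _, best_a = scored[0]
            if best_ident >= threshold:
                new_assign[i] = best_a
            elif ids[i] in waivers:
                new_assign[i] = best_a
                waived_now.add(ids[i])
            elif len(clusters.get(assign[i], [])) == 1:
                new_assign[i] = assign[i]  # already a singleton
            else:
                new_assign[i] = next_label
                next_label += 1
        if new_assign == assign:
            break
        assign = new_assign

    clusters = {}
    for i, a in enumerate(assign):
        clusters.setdefault(a, []).append(i)
    families = []
    for k, (_, members) in enumerate(sorted(clusters.items(), key=lambda kv: min(kv[1]))):
        cons = family_consensus([seqs[i] for i in members])
        fam = GeneFamily(
            name=f"family{k + 1}",
            members=[ids[i] for i in members],
            consensus=cons,
            member_identity={ids[i]: percent_identity(seqs[i], cons) for i in members},
            waived={ids[i] for i in members if ids[i] in waived_now},
        )
        families.append(fam)
    return families


def _reading_order(positions: dict[str, Interval], locus_strand: str) -> list[str]:
    starts = {}
    for gid, iv in positions.items():
        key = (iv.start, iv.end)
        if key in starts.values():
            raise ValueError(f"duplicate genomic position for {gid}")
        starts[gid] = key
    reverse = locus_strand == "-"
    return sorted(positions, key=lambda g: positions[g].start, reverse=reverse)


def _prefix(call) -> str:
    c = str(call) if call is not None else "F"
    return {"P": "p", "ORF": "orf"}.get(c, "")


def name_genes(
    families: list[GeneFamily],
    chain: str,
    positions: dict[str, Interval],
    calls: dict[str, object] | None = None,
    locus_strand: str = "-",
    family_numbers: dict[str, int] | None = None,
) -> dict[str, str]:
    """Assign ``[p|orf]TR{chain}V{family}-{k}`` names.

    ``k`` runs in ascending genomic order 5'->3' toward the C gene; on a
    reverse-strand locus that is descending forward-strand coordinate.
    ``family_numbers`` can pin family numbers to established nomenclature;
    otherwise families are numbered by the position of their 5'-most member.
    """
    if chain not in ("TRA", "TRB", "TRG", "TRD"):
        raise ValueError(f"bad chain {chain!r}")
    calls = calls or {}
    reading = _reading_order(positions, locus_strand)
    rank = {g: i for i, g in enumerate(reading)}

    fam_of = {g: f for f in families for g in f.members}
    if family_numbers is None:
        fam_order = sorted(families, key=lambda f: min(rank[g] for g in f.members))
        family_numbers = {f.name: i + 1 for i, f in enumerate(fam_order)}

    names = {}
    counters: dict[str, int] = {}
    for g in reading:
        fam = fam_of.get(g)
        if fam is None:
            continue
        num = family_numbers[fam.name]
        counters[fam.name] = counters.get(fam.name, 0) + 1
        names[g] = f"{_prefix(calls.get(g))}{chain}V{num}-{counters[fam.name]}"
    return names


def name_j_genes(
    chain: str,
    positions: dict[str, Interval],
    calls: dict[str, object] | None = None,
    locus_strand: str = "-",
) -> dict[str, str]:
    """``TR*J{k}`` names in ascending order 5'->3' toward the C gene."""
    if chain not in ("TRA", "TRB", "TRG", "TRD"):
        raise ValueError(f"bad chain {chain!r}")
    calls = calls or {}
    return {
        g: f"{_prefix(calls.get(g))}{chain}J{i + 1}"
        for i, g in enumerate(_reading_order(positions, locus_strand))
    }
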