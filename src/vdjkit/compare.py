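"""Cross-annotation sequence comparison.

The comparison metric is a match-maximizing global alignment with free gaps
and no mismatch penalty: the maximum number of identically aligned positions
over all such alignments, which is exactly the longest-common-subsequence
(LCS) length of the two strings.  From it,

    percent identity = identical positions / length of shorter sequence * 100
    mismatches       = length of shorter sequence - identical positions

Note the quirk of normalizing by the shorter sequence: a string that is a
subsequence of the other scores 100% identity (e.g. ACGT vs AGT).
"""

from __future__ import annotations

from dataclasses import dataclass

from .seq_core import NucSeq

__all__ = [
    "MatchReport",
    "max_match_alignment",
    "percent_identity",
    "mismatches",
    "best_match_report",
]


@dataclass(frozen=True)
class MatchReport:
    query_id: str
    best_matches: tuple[str, ...]
    identical_positions: int
    percent_identity: float
    mismatches: int


def max_match_alignment(a: str, b: str) -> int:
    """Maximum identically aligned positions over all free-gap global
    alignments = LCS length.

    Exact bit-parallel row computation (each dynamic-programming row is held
    as a bit vector in one arbitrary-precision integer); no heuristics or
    banding.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    if len(b) < len(a):
        a, b = b, a  # the shorter string fills the bit vector
    m = len(a)
    mask = (1 << m) - 1
    pm: dict[str, int] = {}
    for i, ch in enumerate(a):
        pm[ch] = pm.get(ch, 0) | (1 << i)
    v = mask
    for ch in b:
        p = pm.get(ch, 0)
        u = v & p
        v = ((v + u) & mask) | (v & ~p)
    # each cleared bit marks one more matched position in the row profile
    return m - v.bit_count()


def percent_identity(a: str, b: str) -> float:
    """Identical positions over the shorter length, as a percentage
    (reported to one decimal place)."""
    ident = max_match_alignment(a, b)
    return round(ident / min(len(a), len(b)) * 100, 1)


def mismatches(a: str, b: str) -> int:
    """Length of the shorter sequence minus identically aligned positions."""
    return min(len(a), len(b)) - max_match_alignment(a, b)


def best_match_report(
    queries: list[NucSeq], references: list[NucSeq], min_length: int = 223
) -> list[MatchReport]:
    """Per query, every reference achieving the maximal percent identity.

    References shorter than ``min_length`` (full-length V gene filter) are
    excluded before comparison; ties are all reported.
    """
    refs = [r for r in references if len(r) >= min_length]
    if not refs:
        raise ValueError(
            f"no reference sequence of length >= {min_length} after filtering"
        )
    reports = []
    for q in queries:
        scored = [(percent_identity(q.seq, r.seq), r) for r in refs]
        best = max(s for s, _ in scored)
        winners = [r for s, r in scored if s == best]
        ident = max(max_match_alignment(q.seq, r.seq) for r in winners)
        shorter = min(len(q), min(len(r) for r in winners))
        reports.append(
            MatchReport(
                query_id=q.id,
                best_matches=tuple(r.id for r in winners),
                identical_positions=ident,
                percent_identity=best,
                mismatches=shorter - ident,
            )
        )
    return reports
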