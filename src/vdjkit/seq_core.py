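"""Sequence containers, IUPAC-aware matching, translation and file IO.

Coordinates are 0-based, half-open, always on the forward strand of the
input sequence; strand is carried as an attribute.  Conversion to the
1-based inclusive convention happens only in the GFF3 writer.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, TextIO

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "NucSeq",
    "Interval",
    "IUPAC_SETS",
    "iupac_to_regex",
    "match_iupac",
    "revcomp",
    "translate",
    "read_fasta",
    "write_fasta",
    "write_gff3",
    "write_tsv",
]

# Degeneracy sets of the IUPAC nucleotide code.  A window base must be a
# concrete base (A/C/G/T) to satisfy any pattern position: N in the subject
# never matches, which keeps assembly gaps from spawning candidates.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVN",
    "TGCAYRSWMKVHDBN",
)


@dataclass(frozen=True)
class NucSeq:
    """A named DNA sequence (uppercase canonical form)."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"sequence {self.id!r} is empty")
        object.__setattr__(self, "seq", self.seq.upper())
        bad = set(self.seq) - set(IUPAC_SETS)
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains non-IUPAC characters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True, order=True)
class Interval:
    """0-based half-open interval on the forward strand of ``seq_id``."""

    seq_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad interval [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def mirror(self, seq_len: int) -> "Interval":
        """The same interval expressed in coordinates of the reverse complement."""
        return Interval(
            self.seq_id,
            seq_len - self.end,
            seq_len - self.start,
            "-" if self.strand == "+" else "+",
        )


def match_iupac(pattern: str, window: str) -> bool:
    """True iff every window base lies in the degeneracy set of its pattern code.

    The window must consist of concrete bases; ``N`` in the window matches
    nothing (not even pattern ``N``).
    """
    if len(pattern) != len(window):
        raise ValueError(
            f"pattern length {len(pattern)} != window length {len(window)}"
        )
    for p, w in zip(pattern.upper(), window.upper()):
        if w not in "ACGT":
            return False
        try:
            allowed = IUPAC_SETS[p]
        except KeyError:
            raise ValueError(f"invalid IUPAC code {p!r} in pattern") from None
        if w not in allowed:
            return False
    return True


def iupac_to_regex(pattern: str) -> re.Pattern[str]:
    """Compile an IUPAC pattern into a regex over concrete bases only."""
    parts = []
    for p in pattern.upper():
        try:
            allowed = IUPAC_SETS[p]
        except KeyError:
            raise ValueError(f"invalid IUPAC code {p!r} in pattern") from None
        parts.append(
            next(iter(allowed)) if len(allowed) == 1 else "[" + "".join(sorted(allowed)) + "]"
        )
    return re.compile("".join(parts))


def find_iupac(pattern: str, seq: str) -> list[int]:
    """All (overlapping) start positions of an IUPAC pattern in ``seq``."""
    rx = iupac_to_regex(pattern)
    hits, pos = [], 0
    while True:
        m = rx.search(seq, pos)
        if m is None:
            return hits
        hits.append(m.start())
        pos = m.start() + 1


def revcomp(seq: str) -> str:
    """Reverse complement; IUPAC codes map to their partner code."""
    s = seq.upper()
    for i, c in enumerate(s):
        if c not in IUPAC_SETS:
            raise ValueError(f"invalid character {c!r} at position {i}")
    return s.translate(_COMPLEMENT)[::-1]


def translate(seq: str, frame: int = 0) -> str:
    """Translate with the standard code; '*' for stops, 'X' for ambiguous codons.

    The trailing partial codon is dropped.
    """
    if frame not in (0, 1, 2):
        raise ValueError(f"frame must be 0, 1 or 2, got {frame}")
    sub = seq[frame:]
    sub = sub[: len(sub) - len(sub) % 3]
    if not sub:
        return ""
    return str(Seq(sub).translate())


# ---------------------------------------------------------------------------
# File IO


def read_fasta(path: str | Path) -> list[NucSeq]:
    """Read a FASTA file; ids must be unique within the file."""
    records: list[NucSeq] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate id {rec.id!r} in {path}")
        seen.add(rec.id)
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id) :].strip()
        records.append(NucSeq(rec.id, str(rec.seq), desc))
    return records


def write_fasta(seqs: Iterable[NucSeq], path: str | Path, width: int = 60) -> None:
    recs = [
        SeqRecord(Seq(s.seq), id=s.id, description=s.description) for s in seqs
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


def _gff3_escape(value: str) -> str:
    return re.sub(r"[;=&,\t\n]", lambda m: "%%%02X" % ord(m.group()), value)


def write_gff3(candidates: Sequence, path: str | Path, source: str = "vdjkit") -> None:
    """Write annotated gene candidates as GFF3 (1-based inclusive columns 4/5).

    Each candidate becomes a ``gene`` feature; its RSS and leader, when
    present, are emitted as child features.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, cand in enumerate(sorted(candidates, key=lambda c: (c.interval.seq_id, c.interval.start, c.interval.strand))):
            iv = cand.interval
            gid = getattr(cand, "name", None) or f"{cand.gene_type}gene{i + 1:04d}"
            attrs = [f"ID={_gff3_escape(gid)}", f"gene_type={cand.gene_type}"]
            call = getattr(cand, "functionality", None)
            if call:
                attrs.append(f"functionality={_gff3_escape(str(call))}")
            fam = getattr(cand, "family_guess", None)
            if fam:
                attrs.append(f"family={_gff3_escape(fam)}")
            if getattr(cand, "leader_mode", None) and cand.leader_mode != "none":
                attrs.append(f"leader_mode={cand.leader_mode}")
            _gff3_line(fh, iv, source, "gene", ";".join(attrs))
            rss = getattr(cand, "rss", None)
            if rss is not None and getattr(rss, "interval", None) is not None:
                _gff3_line(
                    fh,
                    rss.interval,
                    source,
                    "recombination_signal_sequence",
                    f"Parent={_gff3_escape(gid)};spacer_class={rss.spacer_class};spacer_len={rss.spacer_len}",
                )
            leader = getattr(cand, "leader_interval", None)
            if leader is not None:
                _gff3_line(fh, leader, source, "signal_peptide_region",
                           f"Parent={_gff3_escape(gid)}")


def _gff3_line(fh: TextIO, iv: Interval, source: str, ftype: str, attrs: str) -> None:
    fh.write(
        "\t".join(
            [
                iv.seq_id,
                source,
                ftype,
                str(iv.start + 1),  # 0-based half-open -> 1-based inclusive
                str(iv.end),
                ".",
                iv.strand,
                ".",
                attrs,
            ]
        )
        + "\n"
    )


def write_tsv(rows: Sequence[dict], path: str | Path, columns: Sequence[str] | None = None) -> None:
    """Write a list of dict rows as a UTF-8 TSV with a header row."""
    if columns is None:
        columns = list(rows[0].keys()) if rows else []
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(str(row.get(c, "")) for c in columns) + "\n")
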