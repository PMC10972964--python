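"""Ground-truthed synthetic inputs.

Two generators:

* :func:`build_locus` — a genomic locus with planted V and J gene cassettes
  (configurable strands, leader modes and defects) embedded in i.i.d.
  background sequence.  Cassette anatomy follows the scanner's definitions
  exactly: a V cassette is ``[leader][V exon with anchors at recorded
  offsets][CAC heptamer + spacer + nonamer]``, a J cassette is
  ``[rc(nonamer) + rc(spacer) + rc(heptamer)][J body with core and secondary
  motifs][GTRDGD donor]``.  Each locus is certified after assembly: the
  scanners must recover exactly the planted defect-free genes, otherwise the
  locus is resampled.  That separates recall measurement from generator
  luck and guarantees the background holds no accidental complete cassette.

* :func:`build_repertoire` — per-sample clonotype tables with controlled V/J
  usage, Gaussian-like CDR3 length spectrum, planted public share, a planted
  convergence group and an optional chimera rate, together with the truth
  parameters needed to score recovery.

Everything is fully determined by the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ScanConfig
from .seq_core import Interval, NucSeq, find_iupac, revcomp, translate
from .vj_finder import FAMILY_MOTIFS, scan_j_genes, scan_v_genes

__all__ = ["LocusSpec", "RepertoireSpec", "build_locus", "build_repertoire"]

# stop codons in every reading frame: kills any ORF crossing it, so scanner
# leaders cannot extend past a planted cassette boundary
FRAME_BLOCKER = "TTAATTAATTAA"

HEPTAMER = "CACAGTG"
NONAMER = "ACAAAAACC"

# codon choices per amino acid (standard code), used for back-translation
_CODONS: dict[str, list[str]] = {}
for _b1 in "TCAG":
    for _b2 in "TCAG":
        for _b3 in "TCAG":
            _cod = _b1 + _b2 + _b3
            _aa = translate(_cod)
            _CODONS.setdefault(_aa, []).append(_cod)

# body alphabet excludes C and W so planted anchors are the only anchors,
# and excludes nothing else; CDR3s use the full 20-letter alphabet
_V_BODY_AA = "ADEFGHIKLNPQRSTVY"
_LEADER_AA = "AFILPSTV"
_CDR3_AA = "ACDEFGHIKLMNPQRSTVWY"

V_DEFECTS = {"stop_codon", "no_cac", "missing_anchor", "spacer_out_of_tolerance"}
J_DEFECTS = {"stop_codon", "no_cac", "missing_fg", "missing_donor",
             "spacer_out_of_tolerance"}


@dataclass
class LocusSpec:
    n_v: int = 5
    n_j: int = 4
    # None -> deterministic alternation; otherwise one entry per gene
    leader_modes: tuple[str, ...] | None = None
    strands: tuple[str, ...] | None = None
    v_defects: dict[int, str] = field(default_factory=dict)
    j_defects: dict[int, str] = field(default_factory=dict)
    families: tuple[str, ...] = ("TRAV1", "TRAV2")
    background_gc: float = 0.42
    gap: int = 400
    seed: int = 0


@dataclass
class RepertoireSpec:
    n_samples: int = 3
    # ~4,000-10,000 clonotypes per chain after downsampling is typical for
    # this kind of bulk experiment; with 10,000 UMIs most clonotypes then
    # carry a single molecule
    n_clonotypes: int = 6000
    umi_total: int = 10000
    chain: str = "TRA"
    v_genes: tuple[str, ...] = tuple(f"TRAV2-{i}" for i in range(1, 9)) + (
        "TRAV1-1", "TRAV1-2", "TRAV1-3", "TRAV3-1",
    )
    j_genes: tuple[str, ...] = tuple(f"TRAJ{i}" for i in range(1, 9))
    v_usage: tuple[float, ...] | None = None  # None -> Dirichlet(1) draw
    j_usage: tuple[float, ...] | None = None
    cdr3_len_mean: float = 14.5
    cdr3_len_sd: float = 2.0
    public_fraction: float = 0.10
    convergence_group_size: int = 12
    chimera_rate: float = 0.0
    chimera_v_genes: tuple[str, ...] = ("TRAV1-1", "TRAV2-2", "TRAV3-1")
    seed: int = 0


# ---------------------------------------------------------------------------
# locus generation


def _rand_dna(rng: np.random.Generator, n: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


def _back_translate(rng: np.random.Generator, protein: str) -> str:
    return "".join(_CODONS[aa][rng.integers(len(_CODONS[aa]))] for aa in protein)


def _mature_v_protein(rng: np.random.Generator, family: str, defect: str | None) -> str:
    """100-aa mature V protein: family motif at the start, 1st-CYS at aa 22,
    CONSERVED-TRP at aa 36, YYC motif at aa 95-97."""
    motif = FAMILY_MOTIFS[family][0]
    aa = [str(rng.choice(list(_V_BODY_AA))) for _ in range(100)]
    aa[: len(motif)] = list(motif)
    aa[21] = "C"
    aa[35] = "W"
    aa[94:97] = list("YYC")
    if defect == "missing_anchor":
        aa[96] = "A"  # 2nd-CYS motif becomes YYA
    return "".join(aa)


def _v_cassette(
    rng: np.random.Generator, mode: str, family: str, defect: str | None
) -> tuple[str, int, int]:
    """Returns (cassette, exon_start_offset, exon_len)."""
    mature = _mature_v_protein(rng, family, defect)
    if mode == "single_exon":
        leader = "M" + "".join(rng.choice(list(_LEADER_AA), size=14))
        exon_aa = leader + mature
        prefix = "ATG" + _back_translate(rng, exon_aa[1:])
    elif mode == "spliced":
        exon_aa = mature
        prefix = _back_translate(rng, exon_aa)
    else:
        raise ValueError(f"bad leader mode {mode!r}")
    exon = prefix + _rand_dna(rng, 2, 0.5)  # CDR3 stub: partial codon
    if defect == "stop_codon":
        # in-frame stop inside the body, clear of anchors and the family motif
        stop_at = (len(exon_aa) - 40) * 3
        exon = exon[:stop_at] + "TAA" + exon[stop_at + 3 :]
    heptamer = HEPTAMER if defect != "no_cac" else "AAC" + HEPTAMER[3:]
    spacer_len = 26 if defect == "spacer_out_of_tolerance" else 23
    rss = heptamer + _rand_dna(rng, spacer_len, 0.5) + NONAMER
    lead_in = FRAME_BLOCKER + ("AG" if mode == "spliced" else "")
    cassette = lead_in + exon + rss
    return cassette, len(lead_in), len(exon)


def _j_body(rng: np.random.Generator, defect: str | None) -> str:
    """51-nt J gene body (frame 0 from the start): CDR3 tail, core motif,
    secondary motif, filler — stop-free, single donor site downstream."""
    for _ in range(200):
        tail = _back_translate(rng, "".join(rng.choice(list(_V_BODY_AA), size=5)))
        core = "TT" + str(rng.choice(["C", "T"])) + "GG" + "".join(
            rng.choice(list("ACGT"), size=4)
        ) + "GG"
        secondary = "T" + _rand_dna(rng, 2, 0.5) + str(rng.choice(list("CGT"))) \
            + str(rng.choice(list("ACGT"))) + str(rng.choice(["A", "G"])) + "T"
        filler = _rand_dna(rng, 18, 0.5)
        body = tail + core + secondary + filler
        assert len(body) == 51
        if "*" in translate(body):
            continue
        if find_iupac("GTRDGD", body):  # premature donor would shift the 3' end
            continue
        if len(find_iupac("TTYGGNNNNGG", body)) != 1:
            continue
        if defect == "missing_fg":
            body = tail + "CT" + core[2:] + secondary + filler  # FG -> LG
            if "*" in translate(body):
                continue
        if defect == "stop_codon":
            body = tail[:6] + "TAA" + tail[9:] + body[15:]
        return body
    raise RuntimeError("could not build a clean J body")


def _j_cassette(rng: np.random.Generator, defect: str | None) -> tuple[str, int, int]:
    """Returns (cassette, gene_start_offset, gene_len)."""
    heptamer = HEPTAMER if defect != "no_cac" else "AAC" + HEPTAMER[3:]
    spacer_len = 15 if defect == "spacer_out_of_tolerance" else 12
    rss_sense = revcomp(heptamer + _rand_dna(rng, spacer_len, 0.5) + NONAMER)
    body = _j_body(rng, defect)
    donor = "GTAAGT" if defect != "missing_donor" else "GAAAGT"
    cassette = rss_sense + body + donor
    return cassette, len(rss_sense), len(body)


def build_locus(spec: LocusSpec, config: ScanConfig | None = None,
                max_attempts: int = 50) -> tuple[NucSeq, pd.DataFrame]:
    """Assemble a synthetic locus and its ground-truth table.

    The truth table has one row per planted gene: gene id, type, forward
    interval of the gene span, strand, leader mode, family and defect.  The
    assembled locus is certified: scanning it must recover exactly the
    defect-free genes at their recorded coordinates.
    """
    cfg = config or ScanConfig()
    for d in spec.v_defects.values():
        if d not in V_DEFECTS:
            raise ValueError(f"unknown V defect {d!r}")
    for d in spec.j_defects.values():
        if d not in J_DEFECTS:
            raise ValueError(f"unknown J defect {d!r}")

    rng = np.random.default_rng(spec.seed)
    for _attempt in range(max_attempts):
        parts: list[str] = []
        rows: list[dict] = []
        pos = 0

        def emit(chunk: str) -> None:
            nonlocal pos
            parts.append(chunk)
            pos += len(chunk)

        emit(_rand_dna(rng, spec.gap, spec.background_gc))
        for k in range(spec.n_v):
            mode = (
                spec.leader_modes[k]
                if spec.leader_modes
                else ("spliced" if k % 2 == 0 else "single_exon")
            )
            strand = spec.strands[k] if spec.strands else ("+" if k % 2 == 0 else "-")
            family = spec.families[k % len(spec.families)]
            defect = spec.v_defects.get(k)
            cassette, off, length = _v_cassette(rng, mode, family, defect)
            if strand == "+":
                start = pos + off
            else:
                cassette = revcomp(cassette)
                start = pos + len(cassette) - off - length
            rows.append(
                dict(gene=f"V{k + 1}", gene_type="V", start=start,
                     end=start + length, strand=strand, leader_mode=mode,
                     family=family, defect=defect or "")
            )
            emit(cassette)
            emit(_rand_dna(rng, spec.gap, spec.background_gc))
        for k in range(spec.n_j):
            strand = (
                spec.strands[spec.n_v + k]
                if spec.strands and len(spec.strands) > spec.n_v + k
                else ("+" if k % 2 == 0 else "-")
            )
            defect = spec.j_defects.get(k)
            cassette, off, length = _j_cassette(rng, defect)
            if strand == "+":
                start = pos + off
            else:
                cassette = revcomp(cassette)
                start = pos + len(cassette) - off - length
            rows.append(
                dict(gene=f"J{k + 1}", gene_type="J", start=start,
                     end=start + length, strand=strand, leader_mode="none",
                     family="", defect=defect or "")
            )
            emit(cassette)
            emit(_rand_dna(rng, spec.gap, spec.background_gc))

        seq = NucSeq(f"synlocus{spec.seed}", "".join(parts),
                     "synthetic locus with planted V/J cassettes")
        truth = pd.DataFrame(rows)

        expected_v = {
            (r.start, r.end, r.strand)
            for r in truth.itertuples()
            if r.gene_type == "V" and not r.defect
        }
        expected_j = {
            (r.start, r.end, r.strand)
            for r in truth.itertuples()
            if r.gene_type == "J" and not r.defect
        }
        found_v = {
            (c.interval.start, c.interval.end, c.strand) for c in scan_v_genes(seq, cfg)
        }
        found_j = {
            (c.interval.start, c.interval.end, c.strand) for c in scan_j_genes(seq, cfg)
        }
        if found_v == expected_v and found_j == expected_j:
            return seq, truth
    raise RuntimeError(
        f"could not assemble a certified locus for seed {spec.seed} "
        f"in {max_attempts} attempts"
    )


# ---------------------------------------------------------------------------
# repertoire generation


def _random_cdr3(rng: np.random.Generator, mean: float, sd: float) -> tuple[str, str]:
    length = max(5, int(round(rng.normal(mean, sd))))
    aa = "".join(rng.choice(list(_CDR3_AA), size=length))
    return _back_translate(rng, aa), aa


def build_repertoire(spec: RepertoireSpec) -> tuple[dict[str, pd.DataFrame], dict]:
    """Per-sample clonotype tables plus the truth parameters.

    Public clonotypes (identical V/J/CDR3) are planted in every sample with
    a combined expected repertoire share of ``public_fraction``; one CDR3
    amino-acid sequence is planted with ``convergence_group_size`` distinct
    synonymous nucleotide variants; chimeric rows carry a V call from
    another locus at rate ``chimera_rate``.
    """
    rng = np.random.default_rng(spec.seed)
    n_v, n_j = len(spec.v_genes), len(spec.j_genes)
    v_usage = (
        np.asarray(spec.v_usage, dtype=float)
        if spec.v_usage is not None
        else rng.dirichlet(np.ones(n_v))
    )
    v_usage = v_usage / v_usage.sum()
    j_usage = (
        np.asarray(spec.j_usage, dtype=float)
        if spec.j_usage is not None
        else rng.dirichlet(np.ones(n_j))
    )
    j_usage = j_usage / j_usage.sum()

    n_public = max(1, int(round(spec.n_clonotypes * spec.public_fraction)))
    if spec.n_clonotypes == 1:
        n_public = 0
    public = []
    for _ in range(n_public):
        nt, aa = _random_cdr3(rng, spec.cdr3_len_mean, spec.cdr3_len_sd)
        public.append(
            (
                str(rng.choice(spec.v_genes, p=v_usage)),
                str(rng.choice(spec.j_genes, p=j_usage)),
                nt,
                aa,
            )
        )

    # planted convergence group: one amino-acid CDR3, many synonymous nts
    conv_rows = []
    if spec.convergence_group_size > 1 and spec.n_clonotypes > spec.convergence_group_size:
        _, conv_aa = _random_cdr3(rng, spec.cdr3_len_mean, spec.cdr3_len_sd)
        variants: set[str] = set()
        while len(variants) < spec.convergence_group_size:
            variants.add(_back_translate(rng, conv_aa))
        conv_v = str(rng.choice(spec.v_genes, p=v_usage))
        conv_j = str(rng.choice(spec.j_genes, p=j_usage))
        conv_rows = [(conv_v, conv_j, nt, conv_aa) for nt in sorted(variants)]
    else:
        conv_aa = ""

    tables: dict[str, pd.DataFrame] = {}
    for s in range(spec.n_samples):
        n_private = spec.n_clonotypes - len(public) - len(conv_rows)
        rows = list(public) + list(conv_rows)
        for _ in range(n_private):
            nt, aa = _random_cdr3(rng, spec.cdr3_len_mean, spec.cdr3_len_sd)
            rows.append(
                (
                    str(rng.choice(spec.v_genes, p=v_usage)),
                    str(rng.choice(spec.j_genes, p=j_usage)),
                    nt,
                    aa,
                )
            )
        df = pd.DataFrame(rows, columns=["v_call", "j_call", "cdr3", "cdr3_aa"])
        # chimeric receptors: V call from a foreign locus
        if spec.chimera_rate > 0:
            chim = rng.random(len(df)) < spec.chimera_rate
            df.loc[chim, "v_call"] = rng.choice(spec.chimera_v_genes, size=int(chim.sum()))
        # UMI counts: every listed clonotype was observed at least once;
        # the remaining molecules spread multinomially with equal clonotype
        # weights (most clonotypes end up with a single UMI)
        if spec.umi_total < len(df):
            raise ValueError("umi_total must be >= number of clonotypes")
        probs = np.full(len(df), 1.0 / len(df))
        df["umi_count"] = 1 + rng.multinomial(spec.umi_total - len(df), probs)
        df.insert(0, "chain", spec.chain)
        df.insert(0, "sample_id", f"bird{s + 1}")
        tables[f"bird{s + 1}"] = df[
            ["sample_id", "chain", "v_call", "j_call", "cdr3", "cdr3_aa", "umi_count"]
        ]

    truth = dict(
        v_usage=dict(zip(spec.v_genes, v_usage)),
        j_usage=dict(zip(spec.j_genes, j_usage)),
        public_fraction=spec.public_fraction,
        convergence_aa=conv_aa,
        convergence_group_size=spec.convergence_group_size if conv_rows else 1,
        chimera_rate=spec.chimera_rate,
        cdr3_len_mean=spec.cdr3_len_mean,
        cdr3_len_sd=spec.cdr3_len_sd,
    )
    return tables, truth
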