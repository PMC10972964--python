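"""Post-clonotyping repertoire summary statistics.

Operates on clonotype tables (one row per clonotype) with columns
``sample_id, chain, v_call, j_call, cdr3, cdr3_aa, umi_count`` — the shape of
an AIRR-style export from an upstream aligner/assembler.  All frequencies
are UMI-weighted.  Clonotypes whose CDR3 contains a stop codon or whose
nucleotide CDR3 is not translatable (length not a multiple of three) are
non-expressed receptors and are excluded up front, with a logged count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "COLUMNS",
    "read_clonotype_table",
    "filter_productive",
    "downsample",
    "usage_and_pairing",
    "spectratype",
    "publicity",
    "convergence",
    "rank_abundance",
    "aa_composition",
    "flag_chimeras",
    "RepertoireSummary",
    "summarize",
]

log = logging.getLogger(__name__)

COLUMNS = ["sample_id", "chain", "v_call", "j_call", "cdr3", "cdr3_aa", "umi_count"]

CHAINS = ("TRA", "TRB", "TRG", "TRD")


def read_clonotype_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={c: str for c in COLUMNS[:-1]})
    missing = set(COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    df["umi_count"] = df["umi_count"].astype(int)
    if (df["umi_count"] < 1).any():
        raise ValueError(f"{path}: umi_count must be >= 1")
    return df[COLUMNS]


def filter_productive(df: pd.DataFrame) -> pd.DataFrame:
    """Drop clonotypes with stop codons or untranslatable CDR3 nucleotides."""
    bad = df["cdr3_aa"].str.contains(r"\*", regex=True) | (
        df["cdr3"].str.len() % 3 != 0
    )
    if bad.any():
        log.info("excluded %d non-expressed clonotypes", int(bad.sum()))
    return df[~bad].reset_index(drop=True)


def downsample(
    tables: dict[str, pd.DataFrame], seed: int
) -> dict[str, pd.DataFrame]:
    """Downsample every sample, within each chain, to the smallest sample's
    UMI total by drawing UMIs without replacement.  Seeded and reproducible."""
    if not tables:
        raise ValueError("no samples")
    for name, df in tables.items():
        if df.empty:
            raise ValueError(f"sample {name!r} is empty")
    rng = np.random.default_rng(seed)
    chains = sorted({c for df in tables.values() for c in df["chain"].unique()})
    out = {name: [] for name in tables}
    for chain in chains:
        per_sample = {
            name: df[df["chain"] == chain] for name, df in sorted(tables.items())
        }
        per_sample = {n: d for n, d in per_sample.items() if not d.empty}
        target = min(int(d["umi_count"].sum()) for d in per_sample.values())
        for name, d in per_sample.items():
            counts = d["umi_count"].to_numpy()
            kept = rng.multivariate_hypergeometric(counts, target)
            sub = d.copy()
            sub["umi_count"] = kept
            out[name].append(sub[sub["umi_count"] > 0])
    return {
        name: pd.concat(parts, ignore_index=True)
        for name, parts in out.items()
        if parts
    }


def _freqs(df: pd.DataFrame) -> pd.Series:
    total = df["umi_count"].sum()
    if total == 0:
        raise ValueError("empty repertoire")
    return df["umi_count"] / total


def usage_and_pairing(df: pd.DataFrame):
    """UMI-weighted V usage, J usage and V-J pairing frequencies.

    Unassigned calls (empty or NA) are grouped under ``other``.
    """
    if df.empty:
        raise ValueError("empty clonotype table")
    work = df.copy()
    for col in ("v_call", "j_call"):
        work[col] = work[col].fillna("other").replace("", "other")
    work["freq"] = _freqs(work)
    v_usage = work.groupby("v_call")["freq"].sum().to_dict()
    j_usage = work.groupby("j_call")["freq"].sum().to_dict()
    vj = work.groupby(["v_call", "j_call"])["freq"].sum().to_dict()
    return v_usage, j_usage, vj


def spectratype(df: pd.DataFrame) -> dict[int, float]:
    """CDR3 amino-acid length distribution, frequency weighted."""
    if df.empty:
        raise ValueError("empty clonotype table")
    work = df.copy()
    work["freq"] = _freqs(work)
    work["length"] = work["cdr3_aa"].str.len()
    return {int(k): float(v) for k, v in work.groupby("length")["freq"].sum().items()}


def _clonotype_key(df: pd.DataFrame, key: str) -> pd.Series:
    if key == "aa":
        return df["v_call"] + "|" + df["j_call"] + "|" + df["cdr3_aa"]
    if key == "nt":
        return df["v_call"] + "|" + df["j_call"] + "|" + df["cdr3"]
    raise ValueError(f"bad clonotype key {key!r}")


def publicity(tables: dict[str, pd.DataFrame], key: str = "aa"):
    """Clonotype sharing across samples.

    A clonotype is keyed by (V call, J call, CDR3) — amino-acid CDR3 by
    default, nucleotide optionally.  Returns ``(occurrence, shares)``:
    ``occurrence`` maps each key to the number of samples containing it;
    ``shares[sample][k]`` is the UMI-weighted share of that sample's
    repertoire held by clonotypes present in exactly ``k`` samples (shares
    sum to 1 per sample).  Clonotypes in all samples are the public ones.
    """
    if len(tables) < 2:
        raise ValueError("publicity needs at least two samples")
    keyed = {name: _clonotype_key(df, key) for name, df in tables.items()}
    occurrence: dict[str, int] = {}
    for name, keys in keyed.items():
        for k in set(keys):
            occurrence[k] = occurrence.get(k, 0) + 1
    shares: dict[str, dict[int, float]] = {}
    for name, df in sorted(tables.items()):
        work = df.copy()
        work["freq"] = _freqs(work)
        work["n_samples"] = keyed[name].map(occurrence)
        s = work.groupby("n_samples")["freq"].sum()
        shares[name] = {int(k): float(v) for k, v in s.items()}
    return occurrence, shares


def convergence(df: pd.DataFrame) -> dict[str, int]:
    """Distinct nucleotide CDR3 count per amino-acid CDR3."""
    if df.empty:
        raise ValueError("empty clonotype table")
    return {
        str(k): int(v)
        for k, v in df.groupby("cdr3_aa")["cdr3"].nunique().items()
    }


def rank_abundance(
    df: pd.DataFrame, boundaries: tuple[int, ...] = (10, 100, 1000)
) -> dict[str, float]:
    """Repertoire share per clonotype abundance-rank group.

    Clonotypes are ranked by UMI-weighted abundance; group boundaries default
    to decades (1-10, 11-100, 101-1000, rest).
    """
    if df.empty:
        raise ValueError("empty clonotype table")
    freqs = np.sort(_freqs(df).to_numpy())[::-1]
    shares: dict[str, float] = {}
    lo = 0
    for b in boundaries:
        if lo >= len(freqs):
            break
        shares[f"{lo + 1}-{b}"] = float(freqs[lo:b].sum())
        lo = b
    if lo < len(freqs):
        shares[f"{lo + 1}+"] = float(freqs[lo:].sum())
    return shares


def aa_composition(df: pd.DataFrame) -> dict[str, float]:
    """Frequency-weighted mean count of each amino acid per CDR3."""
    if df.empty:
        raise ValueError("empty clonotype table")
    freqs = _freqs(df).to_numpy()
    totals: dict[str, float] = {}
    for f, aa_seq in zip(freqs, df["cdr3_aa"]):
        for aa in aa_seq:
            totals[aa] = totals.get(aa, 0.0) + f
    return dict(sorted(totals.items()))


def gene_chain(gene_name: str) -> str | None:
    """Locus of origin of a gene name (``TRAV2-3`` -> ``TRA``)."""
    for chain in CHAINS:
        if gene_name.lstrip("porf").startswith(chain) or gene_name.startswith(chain):
            return chain
    return None


def flag_chimeras(df: pd.DataFrame, chain: str | None = None) -> pd.DataFrame:
    """Rows whose V call originates from a different locus than the table's
    chain — e.g. TRAV genes recombined onto delta DJ-C transcripts."""
    if df.empty:
        raise ValueError("empty clonotype table")
    if chain is None:
        chains = df["chain"].unique()
        if len(chains) != 1:
            raise ValueError("mixed-chain table; pass chain explicitly")
        chain = str(chains[0])
    v_chain = df["v_call"].map(lambda g: gene_chain(str(g)))
    return df[(v_chain.notna()) & (v_chain != chain)]


@dataclass
class RepertoireSummary:
    v_usage: dict[str, float]
    j_usage: dict[str, float]
    vj_matrix: dict[tuple[str, str], float]
    spectratype: dict[int, float]
    rank_groups: dict[str, float]
    convergence: dict[str, int]
    aa_composition: dict[str, float]
    publicity: dict[str, dict[int, float]] = field(default_factory=dict)
    n_chimeric: int = 0


def summarize(
    tables: dict[str, pd.DataFrame],
    chain: str,
    seed: int = 0,
    clonotype_key: str = "aa",
    do_downsample: bool = True,
) -> RepertoireSummary:
    """End-to-end summary: filter, downsample, pool, and compute every metric."""
    tables = {n: filter_productive(d[d["chain"] == chain]) for n, d in tables.items()}
    tables = {n: d for n, d in tables.items() if not d.empty}
    if not tables:
        raise ValueError(f"no productive clonotypes for chain {chain}")
    if do_downsample and len(tables) > 1:
        tables = downsample(tables, seed)
    pooled = pd.concat(tables.values(), ignore_index=True)
    v_usage, j_usage, vj = usage_and_pairing(pooled)
    pub = publicity(tables, clonotype_key)[1] if len(tables) > 1 else {}
    return RepertoireSummary(
        v_usage=v_usage,
        j_usage=j_usage,
        vj_matrix=vj,
        spectratype=spectratype(pooled),
        rank_groups=rank_abundance(pooled),
        convergence=convergence(pooled),
        aa_composition=aa_composition(pooled),
        publicity=pub,
        n_chimeric=len(flag_chimeras(pooled, chain)),
    )
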