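# Methods

## Scope and model

vdjkit locates germline V and J gene segments in genomic DNA from the
conserved biology of somatic V(D)J recombination, classifies their
functionality, groups V genes into families, and computes UMI-weighted
summary statistics over post-clonotyping repertoire tables. Read-level
processing (alignment, clonotype assembly, UMI error correction) is out of
scope: repertoire functions consume tables exported by an upstream
aligner/assembler.

All genomic coordinates are 0-based half-open on the forward strand, with
strand as an attribute; only the GFF3 writer converts to 1-based inclusive.
Reverse-strand scanning works on the reverse complement and mirrors
coordinates back, which makes strand symmetry a testable invariant rather
than a convention.

## RSS detection

An RSS is modelled as heptamer + spacer + nonamer, with the heptamer
required to begin `CAC` and to abut the gene boundary reading away from the
gene body on the gene's sense strand. Spacers are 23 ± 1 nt at V 3′ ends and
12 ± 1 nt at J 5′ ends. Full probabilistic heptamer/nonamer scoring (RIC-type
information content) is the job of an external scorer, exposed as a hook;
internally the nonamer is located by a degenerate IUPAC consensus
(`NCAAAANNN` by default, capturing the conserved A-tract; configurable).
This choice is what makes the spacer tolerance a falsifiable condition: with
no constraint on the nonamer, any spacer length can be "found" inside random
DNA, and a spacer of 26 nt would be indistinguishable from a legal one. The
single fixed `C` plus the A-tract in the default pattern reject ±2-shifted
alignments while costing ≈ 1/1000 per candidate position in background, so
genuine nonamer variation can be accommodated by widening the pattern in the
config without rewriting the scanner.

Pattern matching is strict on the subject side: `N` (or any ambiguity code)
in the scanned sequence satisfies no pattern position, including pattern
`N`. Assembly gaps therefore never spawn candidates. Soft-masked (lowercase)
input is uppercased and scanned; masking is not used as a filter.

## V and J scanning

For every `CAC` with a structurally valid 23-RSS, the V scanner enumerates
exon start points inside the exon-length window (240–360 nt by default):
in-frame `ATG` starts (single-exon leader, as in chicken Vα1 genes) and
positions preceded by an `AG` splice acceptor (spliced leader). A start is
accepted if the reading frame from it to the RSS is stop-free and the
translation carries all three V anchors inside their windows: 1st-CYS at aa
15–40 of the exon, CONSERVED-TRP 10–20 aa after it, and the rightmost
2nd-CYS motif starting at aa 80–115. The windows bracket typical V-domain
geometry for both leader modes (a ~15-aa in-exon leader shifts the cysteine
from ~aa 22 to ~aa 37, still inside the window) and are all configurable.
Candidates sharing the same 3′ RSS on one strand collapse to the one with
the longest open leader (ties prefer the single-exon reading); candidates on
opposite strands are always both kept. Manual curation in a real annotation
workflow resolves such overlaps by eye; automation needs a deterministic
rule, and "longest open leader" is the one implemented.

The J scanner starts from core-motif (`TTYGGNNNNGG`) hits. The gene start is
the in-frame position upstream of the core whose 5′ flank is a valid 12-RSS;
the gene end is the first `GTRDGD` splice donor after the core that keeps
the gene inside the length window (40–75 nt) and stop-free in the core's
frame. The secondary motif `TNNBNRT` must occur between the core and the
donor; `relax_j_secondary` demotes that requirement to a note. Its exact
positional role is not well established, so the requirement is an explicit,
documented assumption rather than biology settled enough to hard-code.

D segments (a 12-RSS reading into the segment, 8–25 open nucleotides, a
23-RSS out of it) match far too much background to scan blind; the API and
CLI require an explicit window, mirroring practice where D genes are
localized from expressed reads first. Per-frame openness is recorded in the
candidate notes because a D segment is used in multiple frames in vivo.

Family assignment is an exact-match lookup of chicken family motifs
(`QVQQ` → TRAV1 … `QIEMVTT` → TRDVH1) within the first 15 aa of the mature
protein; single-exon candidates get a 25-aa leader allowance because the
cleavage site is unknown without a signal-peptide predictor. Ambiguity or
absence yields no call plus a note — the motif table is definitional, so no
fuzzy matching is attempted.

## Functionality classification

`F` requires every feature intact; `stop_codon`, `frameshift` and
`rss_no_cac` define `P`; any other altered feature yields `ORF`. Reason
codes are machine-readable and validated against a closed vocabulary.
Two boundary cases deserve note:

* a structurally invalid RSS whose heptamer still begins `CAC` (bad spacer
  geometry, unrecognizable nonamer) is coded `rss_low_score` → ORF; the
  structural check is in effect a crude score, and `rss_no_cac` → P is
  reserved for the literal CAC defect that defines pseudogenes;
* frameshifts are only assignable from expressed-read evidence or a
  high-identity consensus comparison, so the code is emitted only when the
  caller passes `frameshift_evidence=True`; a default offline run never
  produces it.

Signal-peptide prediction and RSS scoring enter through hooks
(`signal_peptide_hook(leader) -> {status, cleavage_offset}`,
`rss_score_hook(heptamer, spacer, nonamer) -> score` against a config
threshold). Without hooks these checks pass permissively and the pass is
recorded in the call notes, keeping default runs deterministic and offline.
`evaluate_v_region`/`evaluate_j_region` build classifiable candidates from
known intervals (curated genes, simulator truth) without the scanner's hard
filters, so pseudogenes can be classified even though the scanner, by
design, never emits them.

## Identity, families, naming

Sequence identity is the match count of a match-maximizing global alignment
with free gaps — exactly the longest-common-subsequence length — normalized
by the shorter sequence and reported to one decimal. The implementation is
the exact bit-parallel LCS-length recurrence (one arbitrary-precision
integer per DP row); tests pin it to an exhaustive subsequence oracle and to
an independent aligner configured with match = 1 and no penalties. Two
consequences of this metric are documented rather than "fixed": a
subsequence scores 100% against its supersequence (hence the > 222 bp
full-length filter in best-match reports), and unrelated equal-length DNA
scores ≈ 65% (the Chvátal–Sankoff regime), so "unrelated" sits well below
the 75% family threshold but nowhere near 0%.

Family clustering seeds with single linkage at ≥ 75% pairwise identity,
builds each cluster's consensus (center-star multiple alignment, per-column
plurality with alphabetical tie-break, majority-gap columns dropped), then
reassigns every gene to its highest-identity consensus and iterates to a
fixed point (bounded at 10 iterations; deterministic tie-breaks make the
result input-order invariant). Genes below threshold to every consensus
become singleton families unless waived: a waiver pins a named gene to its
best family and records the sub-threshold identity, the mechanism for
documented borderline family members. Threshold comparisons use values
rounded to one decimal, matching the precision at which such identities are
conventionally reported.

Names follow `[p|orf]TR{A,B,G,D}V{family}-{k}` with `k` dense and ascending
5′→3′ toward the C gene — descending forward coordinate on a reverse-strand
locus — and `TR*J{k}` for J genes in the same order. Family numbers default
to the genomic order of each family's 5′-most member and can be pinned to
established nomenclature via a mapping.

## Repertoire statistics

All frequencies are UMI-weighted; frequency maps sum to 1 within 1e-9
(tested). Clonotypes with a stop codon in the CDR3 or an untranslatable
nucleotide CDR3 are dropped up front with a logged count — they are
non-expressed receptors. Downsampling draws, per chain, the smallest
sample's UMI total from each sample without replacement (multivariate
hypergeometric, seeded). Publicity keys clonotypes as (V call, J call, CDR3)
with amino-acid CDR3 by default and nucleotide as an option, since either
convention is defensible; per sample it reports the repertoire share held by
clonotypes found in exactly k samples. Convergence counts distinct
nucleotide CDR3s per amino-acid CDR3. Rank-abundance boundaries default to
decades (1–10, 11–100, 101–1000, rest) and are configurable, as any
particular grouping is a presentation choice. Chimera flagging compares the
locus prefix of the V call with the table's chain.

## Synthetic data: what it emulates, what it does not

`build_locus` plants V and J cassettes with the exact anatomy the scanner
tests for, at recorded coordinates, strands and leader modes, in i.i.d.
background (GC 0.42 by default, ~400 nt gaps). Three constructive guarantees
make recall/precision measurements exact: a stop-in-all-frames blocker
(`TTAATTAATTAA`) directly upstream of each V cassette prevents the
longest-leader rule from latching onto background starts; J bodies are
resampled until they contain exactly one core motif and no premature donor;
and each assembled locus is certified by re-scanning — the scanners must
recover exactly the planted defect-free genes, otherwise the locus is
rebuilt from the seeded stream. Defects (stop codon, CAC loss, anchor loss,
core-motif loss, donor loss, out-of-tolerance spacer) are planted per gene
index and recorded in the truth table.

The generator does **not** emulate repeat/homology-unit structure,
pseudogene debris, GC heterogeneity, or nonamer/heptamer sequence variation
beyond the planted consensus. Passing recall tests therefore demonstrate
correctness of the scanning logic under the modelled gene anatomy, not
performance on real chromosomes, where curation of additional hits and
misses is still expected.

`build_repertoire` draws per-sample clonotype tables: V/J calls i.i.d. from
usage weights (Dirichlet(1) by default, recorded as truth), CDR3 lengths
from a discretized normal (mean 14.5, sd 2.0 — an unbiased spectratype
centered at 14–15 aa; δ-style specs can shift it), nucleotide CDR3s
back-translated with uniform codon choice, ~10% planted public share
(identical clonotypes in all samples), one planted convergence group
(12 synonymous variants of one amino-acid CDR3), and an optional chimera
rate (δ-chain specs use 0.22, i.e. roughly every 4th–5th receptor). Each
sample holds 6,000 clonotypes and 10,000 UMIs by default — a typical
downsampled bulk-chain depth at which most clonotypes carry a single
UMI. Every listed clonotype carries at least one UMI (1 + multinomial
remainder): a clonotype table lists observed clonotypes by definition.
Real repertoires have power-law clonal structure, selection effects and
sequencing error; none of these are modelled, so recovery tests validate
the estimators' arithmetic and weighting, not robustness to those effects.

## Numerical and degenerate-input choices

* Translation uses the standard code; ambiguous codons give `X`, trailing
  partial codons are dropped.
* Consensus tie-breaks are alphabetical; identity values are rounded to one
  decimal before threshold comparison.
* Scanners return deterministically sorted output (seq id, start, strand);
  empty and degenerate inputs (empty FASTA, windows without `CAC`) return
  empty results rather than erroring, while contract violations (ragged
  alignment rows, empty sequences in alignment, non-V input to V-only
  operations) raise `ValueError`.
* All randomness flows through `numpy.random.default_rng(seed)`; the same
  seed reproduces loci, tables and downsampling byte-for-byte.

## Problem sizes used in the checks

The shipped checks run 50 loci (250 V, 200 J genes) for scanner
recall/precision, one locus with a defect per reason code for the
classifier, 1,000 random pairs of length ≤ 12 against the exhaustive LCS
oracle, 20 two-template replicates for family recovery, and three samples ×
10,000 UMIs for repertoire recovery. These sizes give tight recovery
targets (e.g. V-usage total variation < 0.03) while keeping the whole suite
around ten seconds.

## Known limitations

* Pseudogene discovery, L-PART1 location, CDR1/CDR2 boundaries and RSS/
  signal-peptide scoring genuinely require expressed reads or external
  predictors; the package exposes hooks, evaluators and editable anchor
  tables instead of pretending to compute them.
* The blind D-pattern is weakly specific by nature; window-restricted
  scanning is a deliberate guardrail, not a missing feature.
* The shorter-length-normalized identity is intentionally faithful to its
  definition, including its 100%-for-subsequence quirk; it is not a general
  sequence-similarity metric.
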