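# vdjkit

Discovery and annotation of germline V(D)J gene segments in genomic DNA, and
summary statistics for bulk T-cell receptor (TCR) repertoires — built for
avian (chicken-style) TCR loci, where reference annotation is sparse and V
genes may carry their leader peptide in a single exon.

## Who this is for

Immunogenetics groups annotating TCR/immunoglobulin loci in new genome
assemblies, and repertoire-sequencing groups that need a germline reference
plus post-clonotyping analytics. The package takes plain FASTA in and writes
TSV/GFF3/FASTA out; everything is also usable as a Python library.

## What it computes

**Gene discovery.** V(D)J genes are bounded by recombination signal
sequences (RSS): a heptamer beginning `CAC`, a 12- or 23-nt spacer (each
±1 nt), and an A-tract nonamer, paired under the 12/23 rule. A V candidate
is an open reading frame opened by an in-frame `ATG` (single-exon leader) or
an `AG` splice acceptor (spliced leader) that carries the three conserved
V-domain anchors — 1st-CYS, CONSERVED-TRP and a 2nd-CYS motif
(`YYC/YFC/YLC/YHC/YIC/TFC`) — and runs into a 3′ 23-RSS. A J candidate runs
from a 5′ 12-RSS to a `GTRDGD` splice donor, contains the core motif
`TTYGGNNNNGG` (translating the canonical F-G), and is stop-free in the core
reading frame. D segments are short open stretches between a 12-RSS and a
23-RSS, scanned only inside a user-supplied window. V families also get a
tentative call from a table of chicken family motifs near the mature 5′ end
(`QVQQ` → TRAV1, etc.).

**Functionality.** Genes are classed IMGT-style: `F` (all features intact),
`ORF` (open but a defining feature altered), `P` (stop codon, frameshift, or
an RSS without the `CAC` motif). External signal-peptide and RSS-score
predictors plug in as hooks; without them a run is fully offline and
deterministic.

**Families and comparison.** V genes cluster into families at ≥ 75%
nucleotide identity to the family consensus. Identity uses a
match-maximizing global alignment with free gaps:

```
identical positions = LCS(a, b)           (longest common subsequence)
percent identity    = identical positions / len(shorter) × 100
mismatches          = len(shorter) − identical positions
```

**Repertoire analytics** (UMI-weighted, from AIRR-style clonotype tables):
V/J usage and pairing, CDR3 spectratype, rank-abundance groups, publicity
(clonotypes shared across samples), convergence (distinct nucleotide CDR3s
per amino-acid CDR3), CDR3 amino-acid composition, chimeric-receptor
flagging, and seeded downsampling to the smallest sample.

## Worked example

Generate a ground-truthed synthetic locus (5 V + 4 J genes on mixed strands)
and annotate it:

```
$ vdjkit simulate locus --seed 42 --out sim
locus of 6201 nt with 9 planted genes -> sim
$ vdjkit annotate --fasta sim/locus.fa --chain TRA --out annotation
INFO vdjkit.annotate: scan: 5 V / 4 J candidates
INFO vdjkit.annotate: classify: {'F': 9, 'ORF': 0, 'P': 0}
INFO vdjkit.annotate: cluster: 5 V families
9 genes, 5 V families -> annotation
$ head -3 annotation/candidates.tsv
gene    seq_id     start  end   strand  type  functionality  reasons  family  notes
TRAV1-1 synlocus42 414    716   +       V     F                       TRAV1
TRAV2-1 synlocus42 1194   1541  -       V     F                       TRAV2   leader encoded within the V exon; cleavage site not predicted
```

All nine planted genes are recovered at their exact coordinates (compare
`sim/truth.tsv`), classified functional, numbered 5′→3′ toward the C gene,
and exported as `annotation/germline.TRA.fa` plus an anchor-point table
ready for a downstream aligner. The same pipeline runs unchanged on real
chromosome FASTA.

Other entry points: `vdjkit find` (raw candidate scan), `vdjkit cluster`
(family clustering of a gene FASTA), `vdjkit compare` (best-match identity
report), `vdjkit repertoire` (clonotype-table analytics),
`vdjkit export-germline`.

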