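import numpy as np
import pytest

from vdjkit.config import ScanConfig
from vdjkit.seq_core import Interval, NucSeq, revcomp
from vdjkit.synthetic import HEPTAMER, NONAMER, LocusSpec, build_locus
from vdjkit.vj_finder import (
    FAMILY_MOTIFS,
    GeneCandidate,
    assign_family,
    scan_d_segments,
    scan_j_genes,
    scan_v_genes,
)


def _truth_set(truth, gene_type):
    return {
        (r.start, r.end, r.strand)
        for r in truth.itertuples()
        if r.gene_type == gene_type and not r.defect
    }


def _found_set(cands):
    return {(c.interval.start, c.interval.end, c.strand) for c in cands}


def test_planted_locus_recovered_exactly(locus42):
    seq, truth = locus42
    assert _found_set(scan_v_genes(seq)) == _truth_set(truth, "V")
    assert _found_set(scan_j_genes(seq)) == _truth_set(truth, "J")


@pytest.mark.parametrize("seed", range(5))
def test_recall_across_seeds(seed):
    seq, truth = build_locus(LocusSpec(seed=seed))
    assert _found_set(scan_v_genes(seq)) == _truth_set(truth, "V")
    assert _found_set(scan_j_genes(seq)) == _truth_set(truth, "J")


def test_candidate_structure(locus42):
    seq, truth = locus42
    for cand in scan_v_genes(seq):
        assert cand.gene_type == "V"
        assert cand.rss is not None and cand.rss.spacer_class == 23
        assert cand.rss.side == "three_prime"
        assert "*" not in cand.protein
        names = {h.name for h in cand.motif_hits}
        assert {"first_cys", "conserved_trp", "second_cys_motif"} <= names
        assert cand.leader_mode in ("single_exon", "spliced")
    for cand in scan_j_genes(seq):
        assert cand.rss is not None and cand.rss.spacer_class == 12
        assert cand.rss.side == "five_prime"
        names = {h.name for h in cand.motif_hits}
        assert {"j_core", "splice_donor"} <= names
        assert "*" not in cand.protein
        assert cand.protein[5:7] == "FG"  # core motif translates F-G


def test_cac_ablated_sequence_yields_nothing():
    """The RSS heptamer is a necessary condition: no CAC, no candidates."""
    rng = np.random.default_rng(11)
    s = "".join(rng.choice(list("ACGT"), size=20000))
    s = s.replace("CAC", "AAA")
    # ablate the reverse strand's CACs too
    s = revcomp(revcomp(s).replace("CAC", "AAA"))
    s = s.replace("CAC", "AAA")
    seq = NucSeq("bg", s)
    assert scan_v_genes(seq) == []
    assert scan_j_genes(seq) == []


def test_defective_genes_not_reported(defect_locus):
    seq, truth = defect_locus
    assert _found_set(scan_v_genes(seq)) == _truth_set(truth, "V")
    assert _found_set(scan_j_genes(seq)) == _truth_set(truth, "J")
    # only the intact genes remain
    assert len(_truth_set(truth, "V")) == 1
    assert len(_truth_set(truth, "J")) == 0


def test_j_spacer_minus_one_tolerated():
    """A J gene behind an 11-nt spacer (12 - 1) is still reported."""
    rng = np.random.default_rng(12)
    from vdjkit.synthetic import _j_body

    body = _j_body(rng, None)
    rss = revcomp(HEPTAMER + "".join(rng.choice(list("ACGT"), size=11)) + NONAMER)
    pad = "".join(rng.choice(list("ACGT"), size=300)).replace("CAC", "ATA")
    s = pad + rss + body + "GTAAGT" + pad
    cands = scan_j_genes(NucSeq("x", s))
    start = len(pad) + len(rss)
    assert [(c.interval.start, c.interval.end) for c in cands] == [
        (start, start + len(body))
    ]
    assert cands[0].rss.spacer_len == 11


def test_strand_symmetry(locus42):
    """Scanning the reverse complement mirrors every candidate."""
    seq, _ = locus42
    rc = NucSeq(seq.id, revcomp(seq.seq))
    n = len(seq.seq)
    for scan in (scan_v_genes, scan_j_genes):
        fwd = {(c.interval.start, c.interval.end, c.strand) for c in scan(seq)}
        mirrored = {
            (n - c.interval.end, n - c.interval.start,
             "+" if c.strand == "-" else "-")
            for c in scan(rc)
        }
        assert fwd == mirrored


def test_scan_determinism(locus42):
    seq, _ = locus42
    a = [(c.interval, c.protein) for c in scan_v_genes(seq)]
    b = [(c.interval, c.protein) for c in scan_v_genes(seq)]
    assert a == b
    starts = [c.interval.start for c in scan_v_genes(seq)]
    assert starts == sorted(starts)


# ---------------------------------------------------------------------------
# D segments


def _d_locus(segment, rng):
    pad = "".join(rng.choice(list("ACGT"), size=60)).replace("CAC", "ATA")
    rss5 = revcomp(HEPTAMER + "".join(rng.choice(list("ACGT"), size=12)) + NONAMER)
    rss3 = HEPTAMER + "".join(rng.choice(list("ACGT"), size=23)) + NONAMER
    s = pad + rss5 + segment + rss3 + pad
    start = len(pad) + len(rss5)
    return NucSeq("d", s), start


def test_d_segment_constructed():
    rng = np.random.default_rng(13)
    seq, start = _d_locus("GGGACAGGGGGC", rng)
    cands = scan_d_segments(seq, Interval("d", 0, len(seq)))
    ours = [c for c in cands if c.strand == "+"]
    assert [(c.interval.start, c.interval.end) for c in ours] == [(start, start + 12)]
    assert ours[0].rss.spacer_class == 12
    assert ours[0].rss_extra[0].spacer_class == 23


def test_d_segment_frame_openness_noted():
    rng = np.random.default_rng(14)
    # TAA in frame 0 only; frames 1 and 2 stay open
    seq, start = _d_locus("TAAACAGGGGGC", rng)
    cands = [
        c for c in scan_d_segments(seq, Interval("d", 0, len(seq)))
        if c.strand == "+" and c.interval.start == start
    ]
    assert cands, "segment with one closed frame must still be reported"
    note = [n for n in cands[0].notes if n.startswith("open_frames=")][0]
    assert note == "open_frames=1,2"


def test_d_segment_window_without_cac_is_empty():
    rng = np.random.default_rng(15)
    s = "".join(rng.choice(list("ACGT"), size=400))
    s = s.replace("CAC", "ATA")
    s = revcomp(revcomp(s).replace("CAC", "ATA")).replace("CAC", "ATA")
    assert scan_d_segments(NucSeq("d", s), Interval("d", 0, len(s))) == []


# ---------------------------------------------------------------------------
# family assignment


def _v_candidate(protein, leader_mode="spliced"):
    return GeneCandidate(
        interval=Interval("x", 0, 300), gene_type="V",
        leader_mode=leader_mode, protein=protein,
    )


@pytest.mark.parametrize(
    "prefix,family",
    [("QVQQ", "TRAV1"), ("VSQQ", "TRAV2"), ("QAAPVQ", "TRGV3"),
     ("QAVPMQ", "TRGV3"), ("EIHAKKSA", "TRDV5"), ("QIEMVTT", "TRDVH1")],
)
def test_assign_family(prefix, family):
    cand = _v_candidate(prefix + "A" * 90)
    assert assign_family(cand) == family


def test_assign_family_no_motif():
    cand = _v_candidate("AAAA" + "H" * 90)
    assert assign_family(cand) is None
    assert any("no family motif" in n for n in cand.notes)


def test_assign_family_window(config):
    # motif beyond the search window of the mature protein is not counted
    cand = _v_candidate("A" * (config.family_motif_window + 5) + "QVQQ" + "A" * 60)
    assert assign_family(cand, config) is None
    # ... but a single-exon candidate gets the leader allowance
    cand2 = _v_candidate("A" * (config.family_motif_window + 5) + "QVQQ" + "A" * 60,
                         leader_mode="single_exon")
    assert assign_family(cand2, config) == "TRAV1"


def test_assign_family_rejects_non_v():
    cand = GeneCandidate(interval=Interval("x", 0, 50), gene_type="J")
    with pytest.raises(ValueError):
        assign_family(cand)


def test_family_motifs_complete():
    assert len(FAMILY_MOTIFS) == 16
    assert FAMILY_MOTIFS["TRGV3"] == ("QAVPMQ", "QAAPVQ")
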