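import numpy as np
import pandas as pd
import pytest

from vdjkit import repertoire as rep
from vdjkit.synthetic import RepertoireSpec, build_repertoire


def _table(rows):
    return pd.DataFrame(
        rows, columns=["sample_id", "chain", "v_call", "j_call", "cdr3", "cdr3_aa",
                       "umi_count"]
    )


@pytest.fixture
def toy():
    return _table(
        [
            ("s1", "TRA", "V1", "J1", "GCTGCTGCT", "AAA", 3),
            ("s1", "TRA", "V2", "J1", "TGTGCTTTT", "CAF", 1),
        ]
    )


def test_usage_and_pairing(toy):
    v, j, vj = rep.usage_and_pairing(toy)
    assert v == {"V1": 0.75, "V2": 0.25}
    assert j == {"J1": 1.0}
    assert vj == {("V1", "J1"): 0.75, ("V2", "J1"): 0.25}


def test_usage_groups_unassigned_as_other(toy):
    t = toy.copy()
    t.loc[0, "v_call"] = ""
    v, _, _ = rep.usage_and_pairing(t)
    assert v == {"other": 0.75, "V2": 0.25}


def test_usage_empty_error():
    with pytest.raises(ValueError):
        rep.usage_and_pairing(_table([]))


def test_spectratype():
    t = _table(
        [
            ("s1", "TRA", "V1", "J1", "A" * 39, "A" * 13, 2),
            ("s1", "TRA", "V1", "J1", "C" * 42, "G" * 14, 5),
            ("s1", "TRA", "V2", "J2", "G" * 42, "T" * 14, 3),
        ]
    )
    assert rep.spectratype(t) == {13: 0.2, 14: 0.8}
    single = _table([("s1", "TRA", "V1", "J1", "AAA", "K", 4)])
    assert rep.spectratype(single) == {1: 1.0}


def test_publicity_classification():
    def one(sample, key_aa, extra=()):
        rows = [(sample, "TRA", "V1", "J1", "GCT" * len(key_aa), key_aa, 2)]
        rows += [
            (sample, "TRA", "V9", "J9", nt, aa, 1) for nt, aa in extra
        ]
        return _table(rows)

    tables = {
        "s1": one("s1", "AAAA", [("TTTCCC", "FP")]),
        "s2": one("s2", "AAAA", [("AAATGG", "KW")]),
        "s3": one("s3", "AAAA"),
    }
    occurrence, shares = rep.publicity(tables)
    assert occurrence["V1|J1|AAAA"] == 3  # public: present in all samples
    assert occurrence["V9|J9|FP"] == 1  # private
    for sample, m in shares.items():
        assert sum(m.values()) == pytest.approx(1.0, abs=1e-9)
    assert shares["s1"] == {1: pytest.approx(1 / 3), 3: pytest.approx(2 / 3)}


def test_publicity_needs_two_samples(toy):
    with pytest.raises(ValueError):
        rep.publicity({"s1": toy})


def test_publicity_invariant_to_row_order_and_labels():
    tables, _ = build_repertoire(RepertoireSpec(seed=5, n_clonotypes=300, umi_total=900))
    occ1, shares1 = rep.publicity(tables)
    shuffled = {
        f"x{i}": df.sample(frac=1, random_state=1).reset_index(drop=True)
        for i, (_, df) in enumerate(sorted(tables.items()))
    }
    occ2, shares2 = rep.publicity(shuffled)
    assert occ1 == occ2
    for a, b in zip(sorted(shares1.values(), key=str), sorted(shares2.values(), key=str)):
        assert set(a) == set(b)
        for k in a:
            assert a[k] == pytest.approx(b[k], abs=1e-12)


def test_convergence():
    t = _table(
        [
            ("s1", "TRA", "V1", "J1", "GCTAAA", "AK", 1),
            ("s1", "TRA", "V1", "J1", "GCCAAA", "AK", 1),
            ("s1", "TRA", "V1", "J1", "TGGTGG", "WW", 1),
        ]
    )
    assert rep.convergence(t) == {"AK": 2, "WW": 1}


def test_rank_abundance():
    t = _table(
        [
            ("s1", "TRA", "V1", "J1", "AAA", "K", 4),
            ("s1", "TRA", "V1", "J1", "CCC", "P", 3),
            ("s1", "TRA", "V1", "J1", "GGG", "G", 2),
            ("s1", "TRA", "V1", "J1", "TTT", "F", 1),
        ]
    )
    assert rep.rank_abundance(t, boundaries=(2,)) == {
        "1-2": pytest.approx(0.7),
        "3+": pytest.approx(0.3),
    }


def test_aa_composition_single_clone():
    t = _table([("s1", "TRA", "V1", "J1", "GGAGGCGCA", "GGA", 1)])
    comp = rep.aa_composition(t)
    assert comp == {"A": pytest.approx(1.0), "G": pytest.approx(2.0)}


def test_flag_chimeras():
    t = _table(
        [
            ("s1", "TRD", "TRDV1-1", "TRDJ1", "GCT", "A", 5),
            ("s1", "TRD", "TRAV2-3", "TRDJ1", "TGT", "C", 2),
            ("s1", "TRD", "orfTRAV1-7", "TRDJ1", "TGG", "W", 1),
        ]
    )
    flagged = rep.flag_chimeras(t, "TRD")
    assert list(flagged["v_call"]) == ["TRAV2-3", "orfTRAV1-7"]


def test_filter_productive_excludes_stops_and_untranslatable():
    t = _table(
        [
            ("s1", "TRA", "V1", "J1", "GCTGCT", "AA", 1),
            ("s1", "TRA", "V1", "J1", "TAAGCT", "*A", 1),
            ("s1", "TRA", "V1", "J1", "GCTGC", "AX", 1),  # length % 3 != 0
        ]
    )
    kept = rep.filter_productive(t)
    assert list(kept["cdr3_aa"]) == ["AA"]


def test_downsample_to_smallest_sample():
    def sized(sample, total):
        n = total // 10
        return _table(
            [(sample, "TRA", "V1", "J1", "GCT", "A", 10) for _ in range(n)]
        )

    tables = {"a": sized("a", 100), "b": sized("b", 80), "c": sized("c", 120)}
    down = rep.downsample(tables, seed=3)
    assert {k: int(v["umi_count"].sum()) for k, v in down.items()} == {
        "a": 80, "b": 80, "c": 80,
    }
    again = rep.downsample(tables, seed=3)
    for k in tables:
        pd.testing.assert_frame_equal(down[k].reset_index(drop=True),
                                      again[k].reset_index(drop=True))


def test_downsample_single_sample_unchanged(toy):
    out = rep.downsample({"s1": toy}, seed=1)
    assert int(out["s1"]["umi_count"].sum()) == int(toy["umi_count"].sum())


def test_downsample_empty_sample_error(toy):
    with pytest.raises(ValueError):
        rep.downsample({"s1": toy, "s2": toy.iloc[0:0]}, seed=1)


def test_downsample_preserves_expected_usage():
    """Downsampling is unbiased: usage frequencies are preserved in
    expectation (averaged over seeded replicates)."""
    tables, truth = build_repertoire(
        RepertoireSpec(seed=8, n_clonotypes=400, umi_total=4000, n_samples=2)
    )
    big = {k: v for k, v in tables.items()}
    big["small"] = big["bird1"].assign(umi_count=1).head(200)
    before, _, _ = rep.usage_and_pairing(tables["bird1"])
    acc = {}
    reps = 60
    for s in range(reps):
        down = rep.downsample(big, seed=s)
        v, _, _ = rep.usage_and_pairing(down["bird1"])
        for k, val in v.items():
            acc[k] = acc.get(k, 0.0) + val / reps
    tv = 0.5 * sum(abs(acc.get(k, 0) - before.get(k, 0)) for k in set(acc) | set(before))
    assert tv < 0.02


def test_frequency_outputs_sum_to_one():
    tables, _ = build_repertoire(RepertoireSpec(seed=9, n_clonotypes=500, umi_total=2000))
    pooled = pd.concat(tables.values(), ignore_index=True)
    v, j, vj = rep.usage_and_pairing(pooled)
    for m in (v, j, vj, rep.spectratype(pooled)):
        assert sum(m.values()) == pytest.approx(1.0, abs=1e-9)
    assert sum(rep.rank_abundance(pooled).values()) == pytest.approx(1.0, abs=1e-9)


def test_summarize_end_to_end():
    tables, truth = build_repertoire(
        RepertoireSpec(seed=10, n_clonotypes=600, umi_total=3000)
    )
    summary = rep.summarize(tables, "TRA", seed=0)
    assert sum(summary.v_usage.values()) == pytest.approx(1.0, abs=1e-9)
    assert max(summary.convergence.values()) == truth["convergence_group_size"]
    assert summary.n_chimeric == 0
    assert set(summary.publicity) == set(tables)
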