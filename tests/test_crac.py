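import numpy as np
import pandas as pd
import pytest

from oracles import oracle_counts_from_truth
from stress5p import (
    Alignment,
    SimulationConfig,
    align_reads,
    build_toy_genome,
    compare_distributions,
    count_transcript_binding,
    fold_changes,
    make_binding_truth,
    normalize,
    select_top_transcripts,
    simulate_crac_reads,
)
from stress5p.crac import BindingTable
from stress5p.preprocess import ReadRecord


def _aln(chrom, strand, start, end, rid="r"):
    return Alignment(read_id=rid, chrom=chrom, strand=strand, start=start, end=end)


def test_fivep_boundary_on_both_strands(hand_bundle):
    """The 5' region is 5'UTR plus the first 150 CDS nt, half-open: a read
    whose crosslink-proximal base sits at CDS offset 150 (the 151st coding
    nucleotide) counts as total but not 5'."""
    # plus strand: span starts at 10, 5'UTR is 20 nt, so CDS offset 150 is
    # genomic 30 + 150
    cases = [
        ("+", 10 + 3),    # 5'UTR position 3
        ("+", 30 + 149),  # last base inside the window
        ("+", 30 + 150),  # first base beyond it
    ]
    table = None
    for strand, pos in cases:
        a = _aln("chr1", strand, pos, pos + 25)
        table = count_transcript_binding([a], hand_bundle, f"c{pos}_{strand}", table=table)
    t = {"c13_+": (1, 1), "c179_+": (1, 1), "c180_+": (1, 0)}
    for cond, (tot, fp) in t.items():
        assert table.total_counts(cond)["TPLUS"] == tot
        assert table.fivep_counts(cond)["TPLUS"] == fp
    # minus strand: transcript offset = span_end - 1 - pos; offset 20+150
    # (CDS offset 150) is genomic pos 750 - 1 - 170
    tminus = hand_bundle.get("TMINUS")
    inside = tminus.genomic_pos(20 + 149)
    outside = tminus.genomic_pos(20 + 150)
    tbl2 = count_transcript_binding([_aln("chr1", "-", inside - 24, inside + 1)], hand_bundle, "in")
    tbl2 = count_transcript_binding([_aln("chr1", "-", outside - 24, outside + 1)], hand_bundle, "out", table=tbl2)
    assert tbl2.fivep_counts("in")["TMINUS"] == 1
    assert tbl2.fivep_counts("out")["TMINUS"] == 0
    assert tbl2.total_counts("out")["TMINUS"] == 1


def test_reads_outside_transcripts_or_antisense_are_uncounted(hand_bundle):
    alns = [
        _aln("chr1", "+", 0, 9),        # intergenic
        _aln("chr1", "-", 10, 35),      # antisense to TPLUS
        _aln("chr1", "+", 365, 395),    # between transcripts
    ]
    table = count_transcript_binding(alns, hand_bundle, "c")
    assert table.counts[("c", "total")].sum() == 0
    assert table.mapped_reads["c"] == 3 and table.assigned_reads["c"] == 0


def test_counts_match_truth_table_oracle(small_bundle, small_truth):
    config = SimulationConfig(seed=40, n_reads=5_000)
    records, truth_table = simulate_crac_reads(small_truth, small_bundle, "control", config)
    reads = [ReadRecord(id=row.read_id, sequence=seq[9 : 9 + row.insert_len], qualities="I" * row.insert_len)
             for (rid, seq, _), row in zip(records, truth_table.itertuples())]
    alns, _ = align_reads(reads, small_bundle, seed=40)
    table = count_transcript_binding(alns, small_bundle, "control", seed=40)
    total, fivep = oracle_counts_from_truth(
        truth_table.to_dict("records"), small_bundle, {a.read_id for a in alns})
    for t in small_bundle.transcripts:
        assert table.total_counts("control")[t.id] == total.get(t.id, 0)
        assert table.fivep_counts("control")[t.id] == fivep.get(t.id, 0)
    assert table.counts[("control", "total")].sum() <= len(alns)


def test_condition_collision_rejected(hand_bundle):
    table = count_transcript_binding([], hand_bundle, "c")
    with pytest.raises(ValueError, match="already present"):
        count_transcript_binding([], hand_bundle, "c", table=table)


def _table(counts: dict, libsizes: dict) -> BindingTable:
    conds = sorted({c for c, _ in counts})
    ids = sorted({t for v in counts.values() for t in v})
    cols = {}
    for c in conds:
        for m in ("total", "fivep"):
            cols[(c, m)] = pd.Series({t: counts[(c, m)].get(t, 0) for t in ids})
    df = pd.DataFrame(cols)
    df.index.name = "transcript"
    df.columns = pd.MultiIndex.from_tuples(df.columns)
    t = BindingTable(counts=df)
    t.assigned_reads = dict(libsizes)
    t.mapped_reads = dict(libsizes)
    return t


def test_normalize_arithmetic():
    t = _table({("c", "total"): {"A": 7, "B": 0}, ("c", "fivep"): {"A": 2, "B": 0}}, {"c": 1000})
    normalize(t, pseudocount=3)
    assert t.rpm[("c", "total")]["A"] == pytest.approx((7 + 3) * 1e6 / 1000)
    assert t.rpm[("c", "total")]["B"] == pytest.approx(3e6 / 1000)  # pseudocount floor
    assert t.rpm[("c", "fivep")]["A"] == pytest.approx(5e6 / 1000)
    # independent recomputation over random tables
    rng = np.random.default_rng(41)
    counts = {("x", "total"): {}, ("x", "fivep"): {}}
    for i in range(20):
        tot = int(rng.integers(0, 500))
        counts[("x", "total")][f"T{i}"] = tot
        counts[("x", "fivep")][f"T{i}"] = int(rng.integers(0, tot + 1))
    t2 = _table(counts, {"x": 7777})
    normalize(t2, pseudocount=3)
    for i in range(20):
        for m in ("total", "fivep"):
            assert t2.rpm[("x", m)][f"T{i}"] == pytest.approx((counts[("x", m)][f"T{i}"] + 3) * 1e6 / 7777)
    with pytest.raises(ValueError, match="library"):
        normalize(_table({("c", "total"): {"A": 1}, ("c", "fivep"): {"A": 0}}, {"c": 0}))


def test_select_top_transcripts_ranking():
    t = _table(
        {
            ("control", "total"): {"A": 10, "B": 5},
            ("control", "fivep"): {"A": 0, "B": 0},
            ("mock", "total"): {"A": 0, "B": 9},
            ("mock", "fivep"): {"A": 0, "B": 0},
        },
        {"control": 1_000_000, "mock": 1_000_000},
    )
    normalize(t, pseudocount=0)
    assert select_top_transcripts(t, n=1) == ["B"]  # means 5 vs 7
    assert select_top_transcripts(t, n=10) == ["B", "A"]
    # brute-force sort oracle on a random table
    rng = np.random.default_rng(42)
    counts = {(c, m): {f"T{i}": int(rng.integers(0, 100)) for i in range(30)}
              for c in ("control", "mock") for m in ("total", "fivep")}
    t2 = _table(counts, {"control": 5000, "mock": 6000})
    normalize(t2)
    means = {
        f"T{i}": ((counts[("control", "total")][f"T{i}"] + 3) / 5000 + (counts[("mock", "total")][f"T{i}"] + 3) / 6000) / 2
        for i in range(30)
    }
    expected = sorted(means, key=lambda k: (-means[k], k))[:10]
    assert select_top_transcripts(t2, n=10) == expected


def test_fold_changes_limits():
    t = _table(
        {
            ("s", "total"): {"A": 20000}, ("s", "fivep"): {"A": 10000},
            ("r", "total"): {"A": 10000}, ("r", "fivep"): {"A": 10000},
        },
        {"s": 100000, "r": 100000},
    )
    normalize(t)
    fc = fold_changes(t, "s", "r", metric="fivep")
    assert fc["A"] == pytest.approx(0.0)
    fc_tot = fold_changes(t, "s", "r", metric="total")
    assert fc_tot["A"] == pytest.approx(1.0, abs=2e-3)  # counts >> pseudocount
    with pytest.raises(ValueError):
        fold_changes(t, "nope", "r")


def test_welch_t_test_conventions():
    assert compare_distributions([1.0, 1.0, 2.0], [1.0, 1.0, 2.0]) == (0.0, 1.0)
    t, p = compare_distributions([1.0, 1.0], [0.0, 0.0])
    assert np.isinf(t) and p == 0.0
    rng = np.random.default_rng(43)
    a = rng.normal(0, 1, 2000)
    b = rng.normal(-2, 1, 2000)
    t1, p1 = compare_distributions(a, b)
    assert p1 < 1e-15 and 0 <= p1 <= 1
    t2, p2 = compare_distributions(b, a)
    assert t2 == pytest.approx(-t1) and p2 == pytest.approx(p1)
    with pytest.raises(ValueError):
        compare_distributions([1.0], [1.0, 2.0])
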