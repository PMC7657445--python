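import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import oracle_collapse_keys, oracle_entropy, oracle_trim
from stress5p import (
    SimulationConfig,
    build_toy_genome,
    collapse_duplicates,
    demultiplex,
    entropy_filter,
    make_binding_truth,
    read_entropy,
    run_preprocess,
    simulate_crac_reads,
    trim_read,
)
from stress5p.preprocess import ReadRecord
from stress5p.simulate import DEFAULT_ADAPTER

ADAPTER = DEFAULT_ADAPTER


def R(seq, qual=None, rid="r", umi=""):
    return ReadRecord(id=rid, sequence=seq, qualities=qual or "I" * len(seq), umi=umi)


# ---------------------------------------------------------------------------
# demultiplex


def test_demultiplex_exact_match_and_prefix_removal():
    insert = "ACGTACGTACGTACGTACGT"
    reads = [R("TTT" + "GTGAGC" + insert, rid="ok"), R("TTT" + "GTGAGG" + insert, rid="bad")]
    out, unassigned, stats = demultiplex(reads, {"s1": "GTGAGC"})
    assert [r.id for r in out["s1"]] == ["ok"]
    assert out["s1"][0].umi == "TTT"
    assert out["s1"][0].sequence == insert
    assert len(out["s1"][0].qualities) == len(insert)
    assert [r.id for r in unassigned] == ["bad"]
    assert stats.unassigned == 1


def test_demultiplex_rejects_bad_barcode_tables():
    with pytest.raises(ValueError):
        demultiplex([], {"a": "ACGT", "b": "ACGT"})
    with pytest.raises(ValueError):
        demultiplex([], {"a": "ACGT", "b": "ACGTA"})


def test_demultiplex_counts_match_truth_tables():
    bundle = build_toy_genome(n_study=5, seed=20)
    truth = make_binding_truth(bundle, seed=20)
    barcodes = {"control": "GTGAGC", "mock": "CACTAG", "glucose_30s": "TGGACT"}
    reads, expected = [], {}
    for cond in barcodes:
        config = SimulationConfig(seed=20, n_reads=350, barcode_table=barcodes)
        records, table = simulate_crac_reads(truth, bundle, cond, config)
        expected[cond] = len(table)
        reads.extend(R(seq, qual, rid) for rid, seq, qual in records)
    out, unassigned, stats = demultiplex(reads, barcodes)
    assert not unassigned
    assert {s: len(v) for s, v in out.items()} == expected


# ---------------------------------------------------------------------------
# trimming


def test_trim_recovers_planted_insert():
    insert = "ACGTTGCAACGTTGCAACGTTGCAACGTAA"
    read = R(insert + ADAPTER + "GGTAC")
    out = trim_read(read, ADAPTER)
    assert out is not None and out.sequence == insert


def test_trim_requires_minimum_overlap():
    insert = "ACGTTGCAACGTTGCAACGT"
    read = R(insert + ADAPTER[:3])  # 3 nt overlap < 4: not trimmed
    assert trim_read(read, ADAPTER).sequence == insert + ADAPTER[:3]
    read4 = R(insert + ADAPTER[:4])
    assert trim_read(read4, ADAPTER).sequence == insert


def test_trim_quality_tail_and_uncalled_and_length_rules():
    seq = "ACGTACGTACGTACGTACGT"
    qual = "I" * 15 + "#" * 5  # Phred 2 tail
    assert trim_read(R(seq, qual), ADAPTER).sequence == seq[:15]
    assert trim_read(R("N" * 3 + seq[3:]), ADAPTER) is None  # 3 N > 2
    assert trim_read(R("ACGTACGTAC"), ADAPTER) is None  # < 11 nt
    assert trim_read(R("ACGTACGTACG"), ADAPTER).sequence == "ACGTACGTACG"


def test_trim_matches_brute_force_oracle_on_simulated_reads():
    bundle = build_toy_genome(n_study=6, seed=21)
    truth = make_binding_truth(bundle, seed=21)
    config = SimulationConfig(
        seed=21, n_reads=5_000, pcr_duplication_rate=0.3, contaminant_rate=0.1,
        barcode_table={"control": "GTGAGC"},
    )
    records, _ = simulate_crac_reads(truth, bundle, "control", config)
    demuxed, _, _ = demultiplex([R(s, q, i) for i, s, q in records], {"control": "GTGAGC"})
    for read in demuxed["control"]:
        expected = oracle_trim(read.sequence, read.qualities, ADAPTER)
        got = trim_read(read, ADAPTER)
        assert (got.sequence if got else None) == expected


@settings(deadline=None, derandomize=True, max_examples=200)
@given(st.text(alphabet="ACGTN", min_size=1, max_size=80))
def test_trim_agrees_with_oracle_and_is_idempotent(seq):
    read = R(seq)
    got = trim_read(read, ADAPTER)
    expected = oracle_trim(seq, "I" * len(seq), ADAPTER)
    assert (got.sequence if got else None) == expected
    if got is not None:
        again = trim_read(got, ADAPTER)
        # a trimmed read that still passes contains no further adapter match
        if again is not None:
            assert again.sequence == got.sequence


# ---------------------------------------------------------------------------
# duplicate collapsing


def test_collapse_keeps_first_per_umi_sequence_pair():
    reads = [
        R("ACGTACGTACGT", rid="a", umi="AAA"),
        R("ACGTACGTACGT", rid="b", umi="AAA"),  # exact duplicate
        R("ACGTACGTACGT", rid="c", umi="CCC"),  # same insert, new molecule
    ]
    kept, removed = collapse_duplicates(reads)
    assert [r.id for r in kept] == ["a", "c"] and removed == 1
    again, removed2 = collapse_duplicates(kept)
    assert [r.id for r in again] == ["a", "c"] and removed2 == 0


def test_collapse_matches_brute_force_distinct_count():
    bundle = build_toy_genome(n_study=4, seed=22)
    truth = make_binding_truth(bundle, seed=22)
    config = SimulationConfig(
        seed=22, n_reads=4_000, pcr_duplication_rate=0.5, barcode_table={"control": "GTGAGC"}
    )
    records, _ = simulate_crac_reads(truth, bundle, "control", config)
    demuxed, _, _ = demultiplex([R(s, q, i) for i, s, q in records], {"control": "GTGAGC"})
    kept, removed = collapse_duplicates(demuxed["control"])
    keys = oracle_collapse_keys((r.umi, r.sequence) for r in demuxed["control"])
    assert len(kept) == len(keys)
    assert removed == len(demuxed["control"]) - len(keys)


# ---------------------------------------------------------------------------
# entropy filter


def test_entropy_extremes():
    assert read_entropy("A" * 16) == 0.0  # one distinct 6-mer per window
    assert not entropy_filter(R("A" * 16))
    # 10-nt window with 5 distinct 6-mers, each once: entropy ln5/ln5 = 1
    assert read_entropy("ACGTAACGTA"[:10]) == pytest.approx(oracle_entropy("ACGTAACGTA"))
    assert read_entropy("ACGTTGCAGT") == pytest.approx(1.0)
    assert read_entropy("ACG") == 1.0  # shorter than k: kept
    with pytest.raises(ValueError):
        read_entropy("ACGTACGTAC", window=4, k=6)


def test_entropy_matches_brute_force_oracle():
    rng = np.random.default_rng(23)
    bases = np.array(list("ACGT"))
    reads = ["".join(bases[rng.integers(0, 4, size=int(rng.integers(6, 60)))]) for _ in range(1000)]
    reads += [str(b) * 30 for b in "ACGT" for _ in range(25)]
    for seq in reads:
        assert read_entropy(seq) == pytest.approx(oracle_entropy(seq))


def test_contaminant_removal_spares_genuine_reads():
    """>= 99% of planted low-complexity contaminants are removed and no
    error-free genuine read of window length or more is lost."""
    bundle = build_toy_genome(n_study=6, seed=24)
    truth = make_binding_truth(bundle, seed=24)
    config = SimulationConfig(
        seed=24, n_reads=5_000, contaminant_rate=0.1, barcode_table={"control": "GTGAGC"}
    )
    records, table = simulate_crac_reads(truth, bundle, "control", config)
    surviving, stats = run_preprocess([R(s, q, i) for i, s, q in records], {"control": "GTGAGC"})
    surviving_ids = {r.id for r in surviving["control"]}
    contam_ids = set(table.loc[table["category"] == "contaminant", "read_id"])
    assert len(contam_ids & surviving_ids) <= 0.01 * len(contam_ids)
    # genuine reads are never lost to the entropy filter or trimming; the
    # only admissible loss is a chance (UMI, insert) collision collapsed as
    # an apparent PCR duplicate, verifiable from the truth table
    genuine = table[(table["category"].isin(["fivep", "pervasive"])) & (table["insert_len"] >= 10)]
    surviving_keys = {(r.umi, r.sequence) for r in surviving["control"]}
    tx_seq = {t.id: bundle.transcript_seq(t) for t in bundle.transcripts}
    for row in genuine.itertuples():
        if row.read_id in surviving_ids:
            continue
        insert = tx_seq[row.transcript][row.offset : row.offset + row.insert_len]
        assert (row.umi, insert) in surviving_keys


def test_pipeline_conserves_read_counts():
    bundle = build_toy_genome(n_study=6, seed=25)
    truth = make_binding_truth(bundle, seed=25)
    config = SimulationConfig(
        seed=25, n_reads=3_000, pcr_duplication_rate=0.4, contaminant_rate=0.1,
        barcode_table={"control": "GTGAGC"},
    )
    records, _ = simulate_crac_reads(truth, bundle, "control", config)
    _, stats = run_preprocess([R(s, q, i) for i, s, q in records], {"control": "GTGAGC"})
    ss = stats.samples["control"]
    assert stats.total_input == stats.unassigned + ss.demux_assigned
    assert ss.demux_assigned == (
        ss.discarded_uncalled + ss.discarded_short + ss.duplicates_removed
        + ss.entropy_removed + ss.surviving
    )
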