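import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from stress5p import (
    SimulationConfig,
    build_toy_genome,
    make_binding_truth,
    simulate_crac_reads,
    simulate_rnaseq_reads,
    simulate_trapp_ratios,
)
from stress5p.simulate import rnaseq_read_weights
from stress5p.truth import StressModel

BC = {"control": "GTGAGC"}


def test_clean_reads_are_exact_transcript_substrings(small_bundle, small_truth):
    config = SimulationConfig(seed=3, n_reads=500)
    records, table = simulate_crac_reads(small_truth, small_bundle, "control", config)
    tx_seq = {t.id: small_bundle.transcript_seq(t) for t in small_bundle.transcripts}
    assert len(records) == 500
    for (rid, seq, qual), row in zip(records, table.to_dict("records")):
        assert len(seq) == len(qual) == config.read_length
        insert = seq[9 : 9 + row["insert_len"]]
        src = tx_seq[row["transcript"]]
        assert src[row["offset"] : row["offset"] + row["insert_len"]] == insert
        # read layout: UMI + barcode + insert + adapter
        assert seq[:3] == row["umi"]
        assert seq[3:9] == config.barcode_table["control"]
        after = seq[9 + row["insert_len"] :]
        assert after.startswith(config.adapter[: len(after)])


def test_fivep_component_share_matches_binomial_expectation():
    bundle = build_toy_genome(n_study=1, seed=8)
    truth = make_binding_truth(bundle, {"fivep_share": 0.8}, seed=8)
    config = SimulationConfig(seed=8, n_reads=50_000, barcode_table=BC)
    _, table = simulate_crac_reads(truth, bundle, "control", config)
    n5 = int((table["category"] == "fivep").sum())
    lo, hi = sps.binom.interval(0.99, 50_000, 0.8)
    assert lo <= n5 <= hi
    # 5'-component reads start inside the 5' region by construction
    region = bundle.transcripts[0].fivep_region_len()
    assert (table.loc[table["category"] == "fivep", "offset"] < region).all()


def test_pcr_duplicates_are_exact_copies_of_earlier_reads():
    bundle = build_toy_genome(n_study=5, seed=9)
    truth = make_binding_truth(bundle, seed=9)
    config = SimulationConfig(seed=9, n_reads=10_000, pcr_duplication_rate=0.5, barcode_table=BC)
    records, table = simulate_crac_reads(truth, bundle, "control", config)
    seqs = {rid: seq for rid, seq, _ in records}
    dups = table[table["category"] == "duplicate"]
    assert len(dups) > 3_000
    for row in dups.itertuples():
        assert seqs[row.read_id] == seqs[row.duplicate_of]
    # distinct-sequence count equals brute-force set cardinality
    distinct = {(seq[:3], seq) for _, seq, _ in records}
    assert len(distinct) <= len(records) - len(dups)


def test_contaminants_are_low_complexity():
    bundle = build_toy_genome(n_study=5, seed=10)
    truth = make_binding_truth(bundle, seed=10)
    config = SimulationConfig(seed=10, n_reads=2_000, contaminant_rate=0.1, barcode_table=BC)
    records, table = simulate_crac_reads(truth, bundle, "control", config)
    contam = table[table["category"] == "contaminant"]
    assert 120 < len(contam) < 280  # ~10%
    seqs = {rid: seq for rid, seq, _ in records}
    for row in contam.itertuples():
        insert = seqs[row.read_id][9 : 9 + row.insert_len]
        assert len(set(insert)) <= 2


def test_seeded_determinism_and_seed_sensitivity(small_bundle, small_truth, tmp_path):
    config = SimulationConfig(seed=5, n_reads=300)
    for name in ("a", "b"):
        simulate_crac_reads(
            small_truth, small_bundle, "control", config,
            out_fastq=tmp_path / f"{name}.fastq", out_truth=tmp_path / f"{name}.tsv",
        )
    assert (tmp_path / "a.fastq").read_bytes() == (tmp_path / "b.fastq").read_bytes()
    assert (tmp_path / "a.tsv").read_bytes() == (tmp_path / "b.tsv").read_bytes()
    other = simulate_crac_reads(small_truth, small_bundle, "control", SimulationConfig(seed=6, n_reads=300))[0]
    assert [r[1] for r in other] != [r[1] for r in simulate_crac_reads(small_truth, small_bundle, "control", config)[0]]


def test_read_counts_fit_mixture_chisquare(small_bundle, small_truth):
    """Distributional fidelity: per-transcript counts pass a chi-square
    goodness-of-fit test against the planted mixture at alpha=0.01."""
    config = SimulationConfig(seed=12, n_reads=20_000)
    _, table = simulate_crac_reads(small_truth, small_bundle, "control", config)
    probs = small_truth.read_probabilities("control")
    probs = probs[probs > 0]
    observed = table["transcript"].value_counts().reindex(probs.index, fill_value=0)
    _, p = sps.chisquare(observed, probs * len(table))
    assert p > 0.01


def test_rejects_too_short_reads(small_bundle, small_truth):
    config = SimulationConfig(seed=1, n_reads=10, read_length=19)
    with pytest.raises(ValueError, match="read_length"):
        simulate_crac_reads(small_truth, small_bundle, "control", config)


# ---------------------------------------------------------------------------
# RNA-seq


def _decay_model(mult: dict[str, float]) -> StressModel:
    conds = {"control": {"other": 1.0}, "stress": mult}
    return StressModel(retention={c: (1.0, 1.0) for c in conds}, decay=conds)


def test_spike_share_rises_as_study_mrna_decays():
    """Halving every study abundance with a constant spike doubles the
    spike's relative share; the closed-form expectation is
    s / (s + 0.5 * m) with s the spike mass and m the control study mass."""
    bundle = build_toy_genome(n_study=30, n_spike=3, seed=13)
    truth = make_binding_truth(bundle, stress_model=_decay_model({"other": 0.5}), seed=13)
    config = SimulationConfig(seed=13, n_reads=40_000, spike_fraction=0.02)
    shares = {}
    for cond in ("control", "stress"):
        w = rnaseq_read_weights(truth, bundle, cond, config)
        spike_ids = [t.id for t in bundle.spike_transcripts]
        shares[cond] = w.loc[spike_ids].sum() / w.sum()
        _, table = simulate_rnaseq_reads(truth, bundle, cond, config)
        observed = (table["species"] == "spike").mean()
        lo, hi = sps.binom.interval(0.999, len(table), shares[cond])
        assert lo / len(table) <= observed <= hi / len(table)
    assert shares["control"] == pytest.approx(0.02)
    s = 0.02 / 0.98 * 30  # spike mass planted against control study mass 30
    assert shares["stress"] == pytest.approx(s / (s + 0.5 * 30))


def test_rnaseq_edge_cases(small_bundle, small_truth, tmp_path):
    config = SimulationConfig(seed=2, n_reads=500, spike_fraction=0.0)
    _, table = simulate_rnaseq_reads(small_truth, small_bundle, "control", config)
    assert (table["species"] == "study").all()
    nospike = build_toy_genome(n_study=3, n_spike=0, seed=2)
    truth2 = make_binding_truth(nospike, seed=2)
    with pytest.raises(ValueError, match="spike"):
        simulate_rnaseq_reads(truth2, nospike, "control", SimulationConfig(seed=2, n_reads=10))
    for name in ("a", "b"):
        simulate_rnaseq_reads(small_truth, small_bundle, "control",
                              SimulationConfig(seed=4, n_reads=200),
                              out_fastq=tmp_path / f"{name}.fastq")
    assert (tmp_path / "a.fastq").read_bytes() == (tmp_path / "b.fastq").read_bytes()


# ---------------------------------------------------------------------------
# TRAPP ratios


def test_trapp_noise_free_matrix_equals_planted_effects():
    planted = [([0, 1], {2: -0.5, 4: -1.0, 8: -1.5, 12: -2.0, 16: -2.5}), ([2], 1.5)]
    tbl = simulate_trapp_ratios(5, planted, n_replicates=2, noise_sd=0.0, seed=1)
    wide = tbl.pivot_table(index="protein", columns="time_min", values="log2_ratio")
    assert wide.loc["P00001", 16] == pytest.approx(-2.5)
    assert wide.loc["P00003", 8] == pytest.approx(1.5)
    assert (wide.loc["P00004"] == 0).all()
    # replicates agree exactly at zero noise
    assert tbl.groupby(["protein", "time_min"])["log2_ratio"].nunique().max() == 1


def test_trapp_missingness_extremes():
    assert len(simulate_trapp_ratios(10, None, missingness=1.0, seed=1)) == 0
    full = simulate_trapp_ratios(10, None, n_replicates=3, missingness=0.0, seed=1)
    assert len(full) == 10 * 5 * 3
    with pytest.raises(ValueError):
        simulate_trapp_ratios(10, None, n_replicates=0)
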