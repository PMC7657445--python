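"""End-to-end recovery experiments on synthetic data.

Each function builds a toy genome, plants a known ground truth, pushes
simulated reads (or ratio tables) through the full pipeline and measures
how well the planted parameters are recovered.  These are the package's
standard self-checks; the problem sizes (tens of transcripts, 50-100k reads
per library) are chosen so each experiment completes in seconds while
leaving per-transcript counts deep enough for the estimators to be in their
asymptotic regime.

A note on normalization in :func:`retention_recovery`: per-library RPM
alone measures *relative* binding only -- a global loss of 5' occupancy
renormalizes the library and compresses the apparent fold change.  The
toy CRAC libraries therefore carry a stress-insensitive rRNA-like
background locus (as real CRAC libraries do), and fold changes are
normalized to the read count on that internal standard, which cancels the
renormalization exactly and makes the planted retention identifiable.
"""

from __future__ import annotations

import numpy as np

from .align import ExactMatchIndex, align_reads
from .crac import BindingTable, count_transcript_binding, fold_changes, normalize
from .genome import GenomeBundle, build_toy_genome
from .metagene import fivep_mass_ratio, fivep_pervasive_stats, startcodon_profile
from .preprocess import ReadRecord, run_preprocess
from .rnaseq import quantify_samples, regulon_summary, select_expressed, total_mrna_change
from .simulate import SimulationConfig, simulate_crac_reads, simulate_rnaseq_reads, simulate_trapp_ratios
from .trapp import aggregate_replicates, build_matrix, classify_changes, filter_presence, run_pca
from .truth import StressModel, make_binding_truth

_BC = ["GTGAGC", "CACTAG", "TGGACT", "ACTGCA", "GAACTC", "CTAGTG"]


def _records_to_reads(records) -> list[ReadRecord]:
    return [ReadRecord(id=r[0], sequence=r[1], qualities=r[2]) for r in records]


def crac_condition_pipeline(
    bundle: GenomeBundle,
    truth,
    conditions: list[str],
    config: SimulationConfig,
    library: str | dict = "assigned",
) -> BindingTable:
    """Simulate, preprocess, align and count one CRAC library per condition."""
    index = ExactMatchIndex(bundle)
    table: BindingTable | None = None
    for cond in conditions:
        records, _ = simulate_crac_reads(truth, bundle, cond, config)
        surviving, _ = run_preprocess(
            _records_to_reads(records), {cond: config.barcode_table[cond]}, adapter=config.adapter,
            umi_length=config.umi_length,
        )
        alns, _ = align_reads(surviving[cond], bundle, seed=config.seed, condition=cond, index=index)
        table = count_transcript_binding(alns, bundle, cond, table=table, seed=config.seed)
    assert table is not None
    return table


def retention_recovery(
    seed: int = 0,
    retentions: tuple[float, ...] = (0.1, 0.25, 0.5),
    n_reads: int = 50_000,
    n_transcripts: int = 20,
    background_share: float = 0.4,
) -> dict:
    """Plant 5'-component retentions, recover them as 5' log2 fold changes.

    One control library plus one library per retention (glucose-like stress:
    5' component scaled by the retention, pervasive component untouched).
    Fold changes are internal-standard normalized (see module docstring).
    Transcripts are long (CDS 1.8-3 kb) so the fixed 5' window is a minor
    fraction of the body: the 10% pervasive occupancy that falls inside the
    window is not scaled by the 5' retention, and on short transcripts that
    leak-through would dominate the planted signal.  Also reports the
    metagene 5'/downstream mass-ratio drop for the strongest planted loss.
    """
    conds = {f"ret_{int(round(100 * r)):02d}": r for r in retentions}
    model = StressModel(
        retention={"control": (1.0, 1.0), **{c: (r, 1.0) for c, r in conds.items()}},
        decay={c: {"other": 1.0} for c in ["control", *conds]},
    )
    bundle = build_toy_genome(
        n_study=n_transcripts, n_background=2, seed=seed, length_params={"cds": (1800, 3000)}
    )
    truth = make_binding_truth(
        bundle,
        {"fivep_share": 0.9, "pervasive_transcript_fraction": 0.0, "background_share": background_share},
        model,
        seed=seed,
    )
    config = SimulationConfig(
        seed=seed,
        n_reads=n_reads,
        barcode_table={c: b for c, b in zip(["control", *conds], _BC)},
    )
    table = crac_condition_pipeline(bundle, truth, ["control", *conds], config)
    bg_ids = [t.id for t in bundle.background_transcripts]
    internal_standard = {
        cond: int(table.counts.loc[bg_ids, (cond, "total")].sum()) for cond in table.conditions
    }
    normalize(table, pseudocount=3, library=internal_standard)
    mrna_ids = [t.id for t in bundle.study_transcripts if t.biotype == "mRNA"]

    out: dict = {"n_reads_per_library": n_reads, "median_fivep_log2fc": {}}
    for cond, r in conds.items():
        fc = fold_changes(table, cond, "control", metric="fivep", transcripts=mrna_ids)
        out["median_fivep_log2fc"][r] = float(fc.median())

    # metagene shape change for the strongest planted loss
    strongest = min(conds.items(), key=lambda kv: kv[1])[0]
    index = ExactMatchIndex(bundle)
    profiles = {}
    for cond in ("control", strongest):
        records, _ = simulate_crac_reads(truth, bundle, cond, config)
        surviving, _ = run_preprocess(
            _records_to_reads(records), {cond: config.barcode_table[cond]}, adapter=config.adapter
        )
        alns, _ = align_reads(surviving[cond], bundle, seed=config.seed, index=index)
        profiles[cond] = startcodon_profile(alns, bundle, mrna_ids)
    ratio_control = fivep_mass_ratio(profiles["control"])
    ratio_stress = fivep_mass_ratio(profiles[strongest])
    out["metagene_fivep_ratio"] = {"control": ratio_control, "stress": ratio_stress}
    out["metagene_fivep_ratio_fold_drop"] = float(ratio_control / ratio_stress)
    return out


def pervasive_recovery(
    seed: int = 0,
    planted_fractions: tuple[float, ...] = (0.66, 0.0),
    n_transcripts: int = 100,
    n_reads: int = 50_000,
) -> dict:
    """Plant Ded1-like pervasive binding on a fraction of transcripts and
    recover the pervasive fraction from counts.  Transcripts are >= ~1 kb so
    the 5' region is a minority of each transcript and the count-based
    classification is identifiable."""
    bundle = build_toy_genome(
        n_study=n_transcripts, seed=seed, length_params={"cds": (900, 1800)}
    )
    model = StressModel(retention={"control": (1.0, 1.0)}, decay={"control": {"other": 1.0}})
    out: dict = {"n_transcripts": n_transcripts, "recovered": {}, "planted": {}}
    for frac in planted_fractions:
        truth = make_binding_truth(
            bundle,
            {"fivep_share": 0.9, "pervasive_transcript_fraction": frac},
            model,
            seed=seed,
        )
        config = SimulationConfig(seed=seed, n_reads=n_reads, barcode_table={"control": _BC[0]})
        table = crac_condition_pipeline(bundle, truth, ["control"], config)
        _, fraction = fivep_pervasive_stats(table, "control")
        planted = float(truth.pervasive_planted.mean())
        out["planted"][frac] = planted
        out["recovered"][frac] = fraction
    return out


def spike_recovery(seed: int = 0, n_reads: int = 100_000, n_study: int = 60, n_spike: int = 5) -> dict:
    """Spike-in normalization recovery on two-species RNA-seq.

    Conditions: a uniform 2-fold mRNA depletion (spike-adjusted total ratio
    should be 0.5 while the unadjusted ratio stays ~1), a heat-shock-like
    regulon decay (RP/RiBi x 1/16, other x 0.9) and a cycloheximide-like
    rescue (all multipliers 1, ratios ~1)."""
    decay = {
        "control": {"other": 1.0},
        "uniform_half": {"other": 0.5},
        "heat": {"RP": 1 / 16, "RiBi": 1 / 16, "other": 0.9},
        "cyh": {"other": 1.0},
    }
    model = StressModel(retention={c: (1.0, 1.0) for c in decay}, decay=decay)
    bundle = build_toy_genome(n_study=n_study, n_spike=n_spike, seed=seed)
    truth = make_binding_truth(bundle, {"fivep_share": 0.9}, model, seed=seed)
    config = SimulationConfig(seed=seed, n_reads=n_reads, spike_fraction=0.02, barcode_table={})
    index = ExactMatchIndex(bundle)
    alns_by_sample = {}
    for cond in decay:
        records, _ = simulate_rnaseq_reads(truth, bundle, cond, config)
        alns, _ = align_reads(_records_to_reads(records), bundle, seed=seed, condition=cond, index=index)
        alns_by_sample[cond] = alns
    table = quantify_samples(alns_by_sample, bundle, reference="control", seed=seed)
    top = select_expressed(table, n=5000, bundle=bundle)
    summary = regulon_summary(table, bundle, "heat", "control", transcripts=top)
    return {
        "n_reads_per_library": n_reads,
        "scale_factors": {k: float(v) for k, v in table.scale_factors.items()},
        "adjusted_total_ratio_uniform_half": total_mrna_change(table, top, "uniform_half", "control"),
        "unadjusted_total_ratio_uniform_half": total_mrna_change(
            table, top, "uniform_half", "control", adjusted=False
        ),
        "adjusted_total_ratio_cyh": total_mrna_change(table, top, "cyh", "control"),
        "regulon_median_log2fc_heat": {
            reg: float(summary.loc[reg, "median"]) for reg in summary.index
        },
    }


def trapp_recovery(seed: int = 0, n_planted: int = 22, n_proteins: int = 338) -> dict:
    """SILAC time-course round trip.

    (a) ``n_planted`` proteins with >2-fold effects at 16 min, zero noise:
    classification must return exactly the planted set.  (b) 10,000 proteins
    at noise sd 0.1 with >= 0.3 log2 margin from the threshold:
    misclassification rate.  (c) a planted rank-1 matrix: PC1 explained
    variance."""
    rng = np.random.default_rng(seed)
    # (a) exact recovery at zero noise
    n_down = int(round(n_planted * 14 / 22))
    down = [int(i) for i in rng.choice(n_proteins, size=n_planted, replace=False)]
    up = down[n_down:]
    down = down[:n_down]
    ramp = {2: 0.3, 4: 0.6, 8: 1.0, 12: 1.4, 16: 1.8}
    planted = [
        (down, {t: -v for t, v in ramp.items()}),
        (up, {t: v * 0.8 for t, v in ramp.items()}),
    ]
    tbl = simulate_trapp_ratios(n_proteins, planted, n_replicates=4, noise_sd=0.0, seed=seed)
    agg = aggregate_replicates(filter_presence(build_matrix([tbl])))
    inc, dec = classify_changes(agg, "glucose", 16)
    proteins = [f"P{i + 1:05d}" for i in range(n_proteins)]
    planted_ids = {proteins[i] for i in down + up}
    exact = (inc | dec) == planted_ids and len(inc) + len(dec) == n_planted

    # (b) misclassification under noise with a planted margin
    n_big = 10_000
    n_changed = 500
    changed = list(range(n_changed))
    eff = 1.3  # |log2| margin 0.3 above the 2-fold threshold
    tbl2 = simulate_trapp_ratios(
        n_big,
        [(changed[: n_changed // 2], eff), (changed[n_changed // 2 :], -eff)],
        n_replicates=3,
        noise_sd=0.1,
        seed=(seed + 1) & 0x7FFFFFFF,
    )
    agg2 = aggregate_replicates(filter_presence(build_matrix([tbl2])))
    inc2, dec2 = classify_changes(agg2, "glucose", 16)
    big_ids = [f"P{i + 1:05d}" for i in range(n_big)]
    should_inc = set(big_ids[i] for i in changed[: n_changed // 2])
    should_dec = set(big_ids[i] for i in changed[n_changed // 2 :])
    errors = len(inc2 ^ should_inc) + len(dec2 ^ should_dec)
    misclassification = errors / n_big

    # (c) PCA on a planted rank-1 matrix
    base = rng.normal(0, 1, size=30)
    trend = {t: t / 16 for t in (2, 4, 8, 12, 16)}
    planted_rank1 = [([i], {t: float(base[i]) * v for t, v in trend.items()}) for i in range(30)]
    tbl3 = simulate_trapp_ratios(
        30, planted_rank1, n_replicates=3, noise_sd=0.0, seed=(seed + 2) & 0x7FFFFFFF
    )
    agg3 = aggregate_replicates(filter_presence(build_matrix([tbl3])))
    pca = run_pca(agg3, orientation="proteins")
    return {
        "exact_recovery": bool(exact),
        "n_classified": len(inc) + len(dec),
        "n_planted": n_planted,
        "misclassification_rate": misclassification,
        "pc1_explained_pct": float(pca.explained_variance[0] * 100),
    }
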