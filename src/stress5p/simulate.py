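"""Read-level and ratio-level simulators with ground-truth tables.

Every generator is deterministic given its configuration and seed, emits
plain-text outputs (FASTQ with constant Phred "I" qualities, TSV truth
tables), and records per-read provenance so that every downstream statistic
can be recomputed independently of the pipeline.

CRAC reads reproduce the structural features the preprocessing stage has to
undo: a 3-nt random tag (UMI) and a sample barcode at the 5' end, the 3'
sequencing adapter, exact PCR duplicates, and low-complexity contaminants.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import GenomeBundle
from .truth import BindingTruth

#: the 3' sequencing adapter ligated to CRAC inserts
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGGC"

DEFAULT_BARCODES: dict[str, str] = {
    "control": "GTGAGC",
    "mock": "CACTAG",
    "glucose_30s": "TGGACT",
    "glucose_16min": "ACTGCA",
    "heat_16min": "GAACTC",
    "heat_cyh_16min": "CTAGTG",
}

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """Shared knobs for the read simulators.

    ``spike_fraction`` is the molar share of the spike-in species in the
    *input* RNA of the reference condition (default 0.02, i.e. 2%); because
    the spike amount is held constant while study mRNAs decay, the spike's
    share of *reads* rises under stress -- the signal spike normalization
    recovers.
    """

    seed: int = 0
    n_reads: int = 50_000
    read_length: int = 75
    umi_length: int = 3
    barcode_table: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_BARCODES))
    adapter: str = DEFAULT_ADAPTER
    pcr_duplication_rate: float = 0.0
    contaminant_rate: float = 0.0
    spike_fraction: float = 0.02
    insert_length: tuple[int, int] = (20, 40)

    def __post_init__(self) -> None:
        for name in ("pcr_duplication_rate", "contaminant_rate", "spike_fraction"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must lie in [0, 1)")
        if self.n_reads < 1:
            raise ValueError("n_reads must be >= 1")
        lengths = {len(b) for b in self.barcode_table.values()}
        if len(self.barcode_table) and len(lengths) != 1:
            raise ValueError("all barcodes must have the same length")
        if len(set(self.barcode_table.values())) != len(self.barcode_table):
            raise ValueError("duplicate barcode sequences")

    @property
    def barcode_length(self) -> int:
        return len(next(iter(self.barcode_table.values()))) if self.barcode_table else 0


def _condition_rng(seed: int, *labels: str) -> np.random.Generator:
    """Seeded generator that differs between labelled streams but is stable
    across runs (labels are hashed with crc32, not Python's salted hash)."""
    tags = [zlib.crc32(lab.encode()) for lab in labels]
    return np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, *tags]))


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _low_complexity(rng: np.random.Generator, n: int) -> str:
    """Homopolymer or dinucleotide-repeat contaminant insert."""
    if rng.random() < 0.5:
        return str(_BASES[rng.integers(0, 4)]) * n
    a, b = _BASES[rng.choice(4, size=2, replace=False)]
    return ((a + b) * (n // 2 + 1))[:n]


def write_fastq(records: list[tuple[str, str, str]], path: str | Path) -> None:
    """Write (id, sequence, quality) triples as Phred+33 FASTQ."""
    with open(path, "w") as fh:
        for rid, seq, qual in records:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def simulate_crac_reads(
    truth: BindingTruth,
    bundle: GenomeBundle,
    condition: str,
    config: SimulationConfig,
    out_fastq: str | Path | None = None,
    out_truth: str | Path | None = None,
) -> tuple[list[tuple[str, str, str]], pd.DataFrame]:
    """Simulate one CRAC library for ``condition``.

    Each read is ``[UMI][barcode][genomic insert][adapter][random filler]``
    truncated to the configured read length, error-free and strand-matched to
    its source transcript.  Returns the FASTQ records and a truth table with
    one row per read (source transcript, transcript-coordinate offset of the
    insert 5' end, genomic coordinates, category, duplicate provenance).
    """
    if condition not in config.barcode_table:
        raise ValueError(f"no barcode configured for condition {condition!r}")
    barcode = config.barcode_table[condition]
    overhead = config.umi_length + len(barcode)
    if config.read_length < overhead + 11:
        raise ValueError("read_length too short: insert below the downstream minimum length")

    rng = _condition_rng(config.seed, "crac", condition)
    probs = truth.read_probabilities(condition)
    tx_ids = list(probs.index)
    tx = {t.id: t for t in bundle.transcripts}
    tx_seqs = {tid: bundle.transcript_seq(tx[tid]) for tid in tx_ids}
    cum = np.cumsum(probs.to_numpy())
    cum[-1] = 1.0
    fivep_frac = np.array([truth.fivep_fraction(tid, condition) for tid in tx_ids])
    region_len = np.array(
        [max(1, min(tx[tid].fivep_region_len(), tx[tid].length)) for tid in tx_ids]
    )
    lo, hi = config.insert_length
    max_insert = config.read_length - overhead

    records: list[tuple[str, str, str]] = []
    rows: list[dict] = []
    for i in range(config.n_reads):
        rid = f"{condition}.{i:06d}"
        if records and rng.random() < config.pcr_duplication_rate:
            j = int(rng.integers(0, len(records)))
            _, seq, qual = records[j]
            records.append((rid, seq, qual))
            row = dict(rows[j])
            row.update(read_id=rid, category="duplicate", duplicate_of=rows[j]["read_id"])
            rows.append(row)
            continue
        umi = _rand_seq(rng, config.umi_length)
        if rng.random() < config.contaminant_rate:
            ins = _low_complexity(rng, int(rng.integers(lo, hi + 1)))
            row = dict(
                read_id=rid, condition=condition, category="contaminant", transcript="",
                offset=-1, insert_len=len(ins), chrom="", strand="", genomic_pos=-1,
                umi=umi, duplicate_of="",
            )
        else:
            k = int(np.searchsorted(cum, rng.random(), side="right"))
            tid = tx_ids[k]
            t = tx[tid]
            comp = "fivep" if rng.random() < fivep_frac[k] else "pervasive"
            ilen = min(int(rng.integers(lo, hi + 1)), max_insert)
            if comp == "fivep":
                off = int(rng.integers(0, region_len[k]))
            else:
                # uniform over starts that fit a full-length insert
                off = int(rng.integers(0, max(1, t.length - ilen + 1)))
            ilen = min(ilen, t.length - off)
            ins = tx_seqs[tid][off : off + ilen]
            row = dict(
                read_id=rid, condition=condition, category=comp, transcript=tid,
                offset=off, insert_len=ilen, chrom=t.chrom, strand=t.strand,
                genomic_pos=t.genomic_pos(off), umi=umi, duplicate_of="",
            )
        seq = umi + barcode + ins + config.adapter
        if len(seq) < config.read_length:
            seq += _rand_seq(rng, config.read_length - len(seq))
        seq = seq[: config.read_length]
        records.append((rid, seq, "I" * len(seq)))
        rows.append(row)

    table = pd.DataFrame(rows)
    if out_fastq is not None:
        write_fastq(records, out_fastq)
    if out_truth is not None:
        table.to_csv(out_truth, sep="\t", index=False)
    return records, table


def spike_weight_per_transcript(truth: BindingTruth, bundle: GenomeBundle, config: SimulationConfig) -> float:
    """Constant molar weight per spike transcript such that the spike species
    holds ``spike_fraction`` of the reference-condition molar input."""
    n_spike = len(bundle.spike_transcripts)
    if n_spike == 0:
        raise ValueError("spike_fraction > 0 requires spike transcripts")
    mrna_ids = [t.id for t in bundle.study_transcripts if t.biotype == "mRNA"]
    ref = "control" if "control" in truth.abundance.columns else truth.abundance.columns[0]
    study_mass = float(truth.abundance.loc[mrna_ids, ref].sum())
    return config.spike_fraction / (1.0 - config.spike_fraction) * study_mass / n_spike


def rnaseq_read_weights(
    truth: BindingTruth, bundle: GenomeBundle, condition: str, config: SimulationConfig
) -> pd.Series:
    """Expected (unnormalized) molar read weight per transcript for RNA-seq."""
    mrnas = [t.id for t in bundle.study_transcripts if t.biotype == "mRNA"]
    weights = {tid: float(truth.abundance.loc[tid, condition]) for tid in mrnas}
    if config.spike_fraction > 0:
        w = spike_weight_per_transcript(truth, bundle, config)
        for t in bundle.spike_transcripts:
            weights[t.id] = w
    elif bundle.spike_transcripts:
        for t in bundle.spike_transcripts:
            weights[t.id] = 0.0
    return pd.Series(weights)


def simulate_rnaseq_reads(
    truth: BindingTruth,
    bundle: GenomeBundle,
    condition: str,
    config: SimulationConfig,
    out_fastq: str | Path | None = None,
    out_truth: str | Path | None = None,
) -> tuple[list[tuple[str, str, str]], pd.DataFrame]:
    """Simulate one RNA-seq library: plain reads (no UMI/barcode/adapter)
    sampled proportional to per-condition molar abundance, uniformly along
    each transcript."""
    if config.spike_fraction > 0 and not bundle.spike_transcripts:
        raise ValueError("spike_fraction > 0 but bundle has no spike transcripts")
    rng = _condition_rng(config.seed, "rnaseq", condition)
    weights = rnaseq_read_weights(truth, bundle, condition, config)
    weights = weights[weights > 0]
    cum = np.cumsum((weights / weights.sum()).to_numpy())
    cum[-1] = 1.0
    tx_ids = list(weights.index)
    tx = {t.id: t for t in bundle.transcripts}
    tx_seqs = {tid: bundle.transcript_seq(tx[tid]) for tid in tx_ids}

    records: list[tuple[str, str, str]] = []
    rows: list[dict] = []
    for i in range(config.n_reads):
        k = int(np.searchsorted(cum, rng.random(), side="right"))
        tid = tx_ids[k]
        t = tx[tid]
        rlen = min(config.read_length, t.length)
        off = int(rng.integers(0, t.length - rlen + 1))
        seq = tx_seqs[tid][off : off + rlen]
        rid = f"{condition}.rna.{i:06d}"
        records.append((rid, seq, "I" * len(seq)))
        rows.append(
            dict(
                read_id=rid, condition=condition, transcript=tid, species=t.species,
                offset=off, length=rlen, chrom=t.chrom, strand=t.strand,
            )
        )
    table = pd.DataFrame(rows)
    if out_fastq is not None:
        write_fastq(records, out_fastq)
    if out_truth is not None:
        table.to_csv(out_truth, sep="\t", index=False)
    return records, table


DEFAULT_TIME_POINTS = (2, 4, 8, 12, 16)


def simulate_trapp_ratios(
    n_proteins: int,
    planted: list[tuple[list[str] | list[int], dict[int, float] | float]] | None = None,
    n_replicates: int = 3,
    noise_sd: float = 0.1,
    missingness: float = 0.0,
    seed: int = 0,
    condition: str = "glucose",
    time_points: tuple[int, ...] = DEFAULT_TIME_POINTS,
    out_tsv: str | Path | None = None,
) -> pd.DataFrame:
    """Simulate a SILAC TRAPP time course as a long-format ratio table.

    Entries are ``planted effect + N(0, noise_sd)`` log2(stress/control)
    ratios, independently missing with probability ``missingness``.
    ``planted`` pairs a set of proteins (ids like ``P0001`` or integer
    indices) with either a constant log2 effect or a {time: effect} map;
    unplanted proteins have effect 0.  Columns match the TRAPP input
    contract: protein, condition, time_min, replicate, log2_ratio, peptides.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if not 0 <= missingness <= 1:
        raise ValueError("missingness must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    proteins = [f"P{i + 1:05d}" for i in range(n_proteins)]
    effects = pd.DataFrame(0.0, index=proteins, columns=list(time_points))
    for members, eff in planted or []:
        ids = [proteins[m] if isinstance(m, (int, np.integer)) else m for m in members]
        for t in time_points:
            val = eff.get(t, 0.0) if isinstance(eff, dict) else float(eff)
            effects.loc[ids, t] = val
    peptides = pd.Series(rng.integers(2, 16, size=n_proteins), index=proteins)

    rows = []
    for prot in proteins:
        for t in time_points:
            for rep in range(1, n_replicates + 1):
                if rng.random() < missingness:
                    continue
                value = effects.loc[prot, t] + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
                rows.append(
                    dict(
                        protein=prot, condition=condition, time_min=t, replicate=rep,
                        log2_ratio=float(value), peptides=int(peptides[prot]),
                    )
                )
    table = pd.DataFrame(
        rows, columns=["protein", "condition", "time_min", "replicate", "log2_ratio", "peptides"]
    )
    if out_tsv is not None:
        table.to_csv(out_tsv, sep="\t", index=False)
    return table
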