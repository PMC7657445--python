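"""Spike-in-anchored RNA-seq quantification.

Reads from a two-species pool (study organism plus a fixed spike-in species
at ~2% of the molar input) are counted per transcript; per-sample scale
factors anchor study-species abundances to the constant spike input, making
*global* mRNA-level changes measurable:

    scale_factor(s) = (spike/study share, reference) / (spike/study share, s)

so the reference sample has factor 1 and a sample that lost half its study
mRNA (doubling the spike's read share) gets factor 0.5.  Adjusted RPKM
values are plain RPKM times the sample's scale factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .align import Alignment
from .crac import TranscriptAssigner
from .genome import GenomeBundle

EPSILON_RPKM = 0.1  # pseudo-RPKM guarding log ratios of lowly expressed transcripts


def _split_counts(alignments: list[Alignment], bundle: GenomeBundle) -> tuple[int, int]:
    """(study_count, spike_count) by chromosome of the alignment."""
    spike = sum(1 for a in alignments if a.chrom in bundle.spike_chroms)
    return len(alignments) - spike, spike


def spike_scale_factors(
    alignments_by_sample: dict[str, list[Alignment]],
    bundle: GenomeBundle,
    reference: str,
) -> dict[str, float]:
    """Per-sample spike-in scale factors (reference sample = 1)."""
    if reference not in alignments_by_sample:
        raise ValueError(f"reference sample {reference!r} missing")
    shares: dict[str, float] = {}
    for sample, alns in alignments_by_sample.items():
        study, spike = _split_counts(alns, bundle)
        if spike == 0:
            raise ValueError(f"sample {sample!r} has zero spike-in reads")
        if study == 0:
            raise ValueError(f"sample {sample!r} has zero study reads")
        shares[sample] = spike / study
    return {s: shares[reference] / shares[s] for s in alignments_by_sample}


@dataclass
class AbundanceTable:
    """Per-transcript raw counts, RPKM and spike-adjusted RPKM per sample."""

    counts: pd.DataFrame  # transcripts x samples
    rpkm: pd.DataFrame
    adjusted_rpkm: pd.DataFrame
    scale_factors: dict[str, float]
    sample_stats: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def to_tsv(self, path) -> None:
        long = pd.concat(
            {"raw_count": self.counts, "rpkm": self.rpkm, "adjusted_rpkm": self.adjusted_rpkm},
            axis=1,
        ).stack(level=1, future_stack=True).reset_index()
        long.columns = ["transcript", "sample", *long.columns[2:]]
        long.sort_values(["transcript", "sample"]).to_csv(path, sep="\t", index=False)


def transcript_abundance(
    alignments: list[Alignment],
    bundle: GenomeBundle,
    sample: str,
    seed: int = 0,
    assigner: TranscriptAssigner | None = None,
) -> tuple[pd.Series, pd.Series]:
    """Raw counts and RPKM for one sample.

    Reads are assigned by the same crosslink-proximal 5'-base rule as CRAC
    counting; RPKM = count * 1e9 / (length_nt * mapped study reads).
    """
    if not alignments:
        raise ValueError(f"sample {sample!r} has zero mapped reads")
    assigner = assigner or TranscriptAssigner(bundle, seed=seed)
    counts: dict[str, int] = {}
    for a in alignments:
        t, _ = assigner.assign(a)
        if t is not None:
            counts[t.id] = counts.get(t.id, 0) + 1
    ids = pd.Index([t.id for t in bundle.transcripts], name="transcript")
    count = pd.Series(counts, dtype=float).reindex(ids, fill_value=0).astype(int)
    count.name = sample
    lengths = pd.Series({t.id: t.length for t in bundle.transcripts}).reindex(ids)
    study_reads, _ = _split_counts(alignments, bundle)
    if study_reads == 0:
        raise ValueError(f"sample {sample!r} has zero study-species reads")
    rpkm = count * 1e9 / (lengths * study_reads)
    rpkm.name = sample
    return count, rpkm


def quantify_samples(
    alignments_by_sample: dict[str, list[Alignment]],
    bundle: GenomeBundle,
    reference: str,
    seed: int = 0,
) -> AbundanceTable:
    """Counts, RPKM, spike scale factors and adjusted RPKM for all samples."""
    factors = spike_scale_factors(alignments_by_sample, bundle, reference)
    assigner = TranscriptAssigner(bundle, seed=seed)
    counts, rpkms, stats = {}, {}, {}
    for sample, alns in sorted(alignments_by_sample.items()):
        c, r = transcript_abundance(alns, bundle, sample, assigner=assigner)
        counts[sample] = c
        rpkms[sample] = r
        study, spike = _split_counts(alns, bundle)
        stats[sample] = dict(study_reads=study, spike_reads=spike, scale_factor=factors[sample])
    counts_df = pd.DataFrame(counts)
    rpkm_df = pd.DataFrame(rpkms)
    adjusted = rpkm_df * pd.Series(factors)
    return AbundanceTable(
        counts=counts_df,
        rpkm=rpkm_df,
        adjusted_rpkm=adjusted,
        scale_factors=factors,
        sample_stats=pd.DataFrame(stats).T,
    )


def select_expressed(
    table: AbundanceTable,
    n: int = 5000,
    samples: list[str] | None = None,
    bundle: GenomeBundle | None = None,
) -> list[str]:
    """Top ``n`` transcripts by mean adjusted RPKM across samples
    (descending, ties by transcript id).  When a bundle is supplied the
    ranking is restricted to study-species mRNAs (spike transcripts are a
    normalization standard, not part of the expressed set)."""
    samples = samples or table.samples
    if len(samples) < 2:
        raise ValueError("need >= 2 samples to rank expression")
    mean = table.adjusted_rpkm[samples].mean(axis=1)
    if bundle is not None:
        keep = [t.id for t in bundle.study_transcripts if t.biotype == "mRNA"]
        mean = mean.loc[[t for t in mean.index if t in set(keep)]]
    order = mean.to_frame("mean").reset_index().sort_values(["mean", "transcript"], ascending=[False, True])
    return order["transcript"].head(n).tolist()


def total_mrna_change(
    table: AbundanceTable,
    transcripts: list[str],
    stress: str,
    reference: str,
    adjusted: bool = True,
) -> float:
    """Σ adjusted RPKM (stress) / Σ adjusted RPKM (reference) over a
    transcript list -- the spike-anchored total-mRNA abundance change.
    With ``adjusted=False`` the un-normalized RPKM ratio is returned (which
    is blind to global shifts, by construction)."""
    if not transcripts:
        raise ValueError("empty transcript list")
    values = table.adjusted_rpkm if adjusted else table.rpkm
    denom = values.loc[transcripts, reference].sum()
    if denom == 0:
        raise ValueError("zero reference signal")
    return float(values.loc[transcripts, stress].sum() / denom)


def regulon_summary(
    table: AbundanceTable,
    bundle: GenomeBundle,
    stress: str,
    reference: str,
    eps: float = EPSILON_RPKM,
    transcripts: list[str] | None = None,
) -> pd.DataFrame:
    """Median/quartile per-transcript adjusted log2 fold changes per regulon
    (RP, RiBi, other), the summary behind regulon depletion violin plots."""
    regulon = pd.Series({t.id: t.regulon for t in bundle.transcripts if t.species == "study" and t.biotype == "mRNA"})
    if transcripts is not None:
        regulon = regulon.loc[[t for t in transcripts if t in regulon.index]]
    if regulon.empty:
        raise ValueError("no study mRNA transcripts to summarize")
    adj = table.adjusted_rpkm.loc[regulon.index]
    fc = np.log2((adj[stress] + eps) / (adj[reference] + eps))
    frame = pd.DataFrame({"regulon": regulon, "log2fc": fc})
    rows = {}
    for name, grp in frame.groupby("regulon"):
        if grp.empty:
            raise ValueError(f"empty regulon {name!r}")
        rows[name] = dict(
            n=len(grp),
            median=float(grp["log2fc"].median()),
            q1=float(grp["log2fc"].quantile(0.25)),
            q3=float(grp["log2fc"].quantile(0.75)),
        )
    return pd.DataFrame(rows).T.rename_axis("regulon")
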