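"""Transcript-level CRAC binding quantification.

Two metrics per transcript and condition, following the operational
definitions used for scanning initiation factors:

- *total binding*: reads whose crosslink-proximal (5'-most aligned) base
  falls anywhere within the transcript;
- *5' end binding*: the subset whose 5' base falls within the 5'UTR or the
  first 150 nt of coding sequence (the whole CDS when shorter).

Counts receive 3 pseudocounts and are scaled to reads per million.  The
library size used for RPM is configurable: ``"assigned"`` (transcript-
assigned reads, the default), ``"mapped"`` (all aligned reads, i.e. total
library size including the rRNA background), or an explicit per-condition
mapping (e.g. counts on a stable internal-standard locus).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats as sps

from .align import Alignment
from .genome import AnnotatedTranscript, GenomeBundle

FIVEP_CDS_WINDOW = 150


class TranscriptAssigner:
    """Assign alignments to transcripts by the crosslink-proximal base.

    The 5'-most aligned base (start on '+', end-1 on '-') is looked up in a
    per-(chrom, strand) interval tree of transcript spans; overlapping
    transcripts (not produced by the toy genome, but allowed) are resolved
    by a seeded uniform choice.
    """

    def __init__(self, bundle: GenomeBundle, seed: int = 0, sense_only: bool = True):
        self.bundle = bundle
        self.sense_only = sense_only
        self.rng = np.random.default_rng(seed)
        self.trees: dict[tuple[str, str], IntervalTree] = {}
        for t in bundle.transcripts:
            s, e = t.span
            for strand in ([t.strand] if sense_only else "+-"):
                self.trees.setdefault((t.chrom, strand), IntervalTree())[s:e] = t

    def assign(self, a: Alignment) -> tuple[AnnotatedTranscript | None, int]:
        """Returns (transcript, transcript-coordinate offset of the 5' base),
        or (None, -1) when the base lies in no transcript."""
        five_pos = a.start if a.strand == "+" else a.end - 1
        tree = self.trees.get((a.chrom, a.strand))
        if tree is None:
            return None, -1
        hits = sorted(tree[five_pos], key=lambda iv: iv.data.id)
        if not hits:
            return None, -1
        iv = hits[int(self.rng.integers(0, len(hits)))] if len(hits) > 1 else hits[0]
        t: AnnotatedTranscript = iv.data
        return t, t.offset_of(five_pos)


@dataclass
class BindingTable:
    """Per-transcript, per-condition binding counts and RPM values.

    ``counts`` has a transcript-id index and ``(condition, metric)`` columns
    with metric in {"total", "fivep"}; ``rpm`` mirrors it after
    :func:`normalize`.  ``library_size`` maps condition -> reads used for
    RPM; ``mapped_reads``/``assigned_reads`` record the raw accounting.
    """

    counts: pd.DataFrame
    mapped_reads: dict[str, int] = field(default_factory=dict)
    assigned_reads: dict[str, int] = field(default_factory=dict)
    library_size: dict[str, int] = field(default_factory=dict)
    rpm: pd.DataFrame | None = None
    pseudocount: int = 3

    @property
    def conditions(self) -> list[str]:
        return sorted({c for c, _ in self.counts.columns})

    def total_counts(self, condition: str) -> pd.Series:
        return self.counts[(condition, "total")]

    def fivep_counts(self, condition: str) -> pd.Series:
        return self.counts[(condition, "fivep")]

    def to_tsv(self, path) -> None:
        long = self.counts.stack(level=0, future_stack=True).reset_index()
        long.columns = ["transcript", "condition", *long.columns[2:]]
        long = long.rename(columns={"total": "total_count", "fivep": "fivep_count"})
        cols = ["transcript", "condition", "total_count", "fivep_count"]
        if self.rpm is not None:
            rl = self.rpm.stack(level=0, future_stack=True).reset_index()
            rl.columns = ["transcript", "condition", *rl.columns[2:]]
            rl = rl.rename(columns={"total": "total_rpm", "fivep": "fivep_rpm"})
            long = long.merge(rl, on=["transcript", "condition"])
            cols += ["total_rpm", "fivep_rpm"]
        long[cols].sort_values(["transcript", "condition"]).to_csv(path, sep="\t", index=False)


def count_transcript_binding(
    alignments: list[Alignment],
    bundle: GenomeBundle,
    condition: str,
    table: BindingTable | None = None,
    seed: int = 0,
    fivep_cds_window: int = FIVEP_CDS_WINDOW,
    assigner: TranscriptAssigner | None = None,
) -> BindingTable:
    """Count total and 5'-region binding for one condition, appending to an
    existing table when given (re-using a condition label is an error)."""
    ids = pd.Index([t.id for t in bundle.transcripts], name="transcript")
    if table is not None and condition in table.conditions:
        raise ValueError(f"condition {condition!r} already present in table")
    assigner = assigner or TranscriptAssigner(bundle, seed=seed)
    total: dict[str, int] = {}
    fivep: dict[str, int] = {}
    assigned = 0
    for a in alignments:
        t, off = assigner.assign(a)
        if t is None:
            continue
        assigned += 1
        total[t.id] = total.get(t.id, 0) + 1
        if off < t.fivep_region_len(fivep_cds_window):
            fivep[t.id] = fivep.get(t.id, 0) + 1
    cols = pd.DataFrame(
        {
            (condition, "total"): pd.Series(total, dtype=float).reindex(ids, fill_value=0).astype(int),
            (condition, "fivep"): pd.Series(fivep, dtype=float).reindex(ids, fill_value=0).astype(int),
        }
    )
    cols.columns = pd.MultiIndex.from_tuples(cols.columns)
    if table is None:
        table = BindingTable(counts=cols)
    else:
        table.counts = pd.concat([table.counts, cols], axis=1)
    table.mapped_reads[condition] = len(alignments)
    table.assigned_reads[condition] = assigned
    return table


def normalize(
    table: BindingTable,
    pseudocount: int = 3,
    library: str | dict[str, int] = "assigned",
) -> BindingTable:
    """Fill reads-per-million values: ``rpm = (count + pseudocount) * 1e6 /
    library_size``, applied to both the total and 5' metrics.

    ``library`` selects the library-size definition (see module docstring).
    """
    sizes: dict[str, int] = {}
    for cond in table.conditions:
        if isinstance(library, dict):
            size = int(library[cond])
        elif library == "assigned":
            size = table.assigned_reads.get(cond, 0)
        elif library == "mapped":
            size = table.mapped_reads.get(cond, 0)
        else:
            raise ValueError(f"unknown library mode {library!r}")
        if size <= 0:
            raise ValueError(f"zero library size for condition {cond!r}")
        sizes[cond] = size
    rpm = table.counts.astype(float).copy()
    for cond in table.conditions:
        for metric in ("total", "fivep"):
            rpm[(cond, metric)] = (table.counts[(cond, metric)] + pseudocount) * 1e6 / sizes[cond]
    table.rpm = rpm
    table.pseudocount = pseudocount
    table.library_size = sizes
    return table


def select_top_transcripts(
    table: BindingTable,
    ref_conditions: tuple[str, str] = ("control", "mock"),
    n: int = 2000,
) -> list[str]:
    """The ``n`` transcripts with the strongest reference binding, ranked by
    the mean total RPM over the two reference conditions (descending; ties
    broken by transcript id)."""
    if table.rpm is None:
        raise ValueError("normalize() the table first")
    for cond in ref_conditions:
        if cond not in table.conditions:
            raise ValueError(f"reference condition {cond!r} missing")
    mean = sum(table.rpm[(c, "total")] for c in ref_conditions) / len(ref_conditions)
    order = mean.to_frame("mean").reset_index().sort_values(
        ["mean", "transcript"], ascending=[False, True]
    )
    return order["transcript"].head(n).tolist()


def fold_changes(
    table: BindingTable,
    stress: str,
    reference: str,
    metric: str = "fivep",
    transcripts: list[str] | None = None,
) -> pd.Series:
    """Per-transcript log2(stress RPM / reference RPM) for one metric
    (pseudocounts are already inside the RPM values)."""
    if table.rpm is None:
        raise ValueError("normalize() the table first")
    if metric not in ("total", "fivep"):
        raise ValueError(f"unknown metric {metric!r}")
    for cond in (stress, reference):
        if cond not in table.conditions:
            raise ValueError(f"condition {cond!r} missing from table")
    ratio = table.rpm[(stress, metric)] / table.rpm[(reference, metric)]
    fc = np.log2(ratio)
    fc.name = f"log2fc_{metric}_{stress}_vs_{reference}"
    if transcripts is not None:
        fc = fc.loc[transcripts]
    return fc


def compare_distributions(fc_stress, fc_mock) -> tuple[float, float]:
    """Welch (unequal-variance) unpaired t test between two log2
    fold-change samples; returns (t statistic, two-sided p)."""
    a = np.asarray(fc_stress, dtype=float)
    b = np.asarray(fc_mock, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 values")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("samples must be finite")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return (np.inf if a.mean() > b.mean() else -np.inf), 0.0
    t, p = sps.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)
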