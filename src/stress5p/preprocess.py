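"""CRAC read preprocessing: demultiplexing, trimming, duplicate collapsing,
low-complexity filtering.

The stage mirrors the parameters of the original processing chain
(pyBarcodeFilter-style exact barcode demultiplexing; flexbar-style right-end
adapter removal with minimum overlap 4, at most 2 uncalled bases, quality
tail trimming and an 11-nt minimum length; UMI-aware collapsing of identical
sequences; a bbduk-style sliding-window k-mer entropy filter with
entropy 0.5, window 10, k 6) but is re-specified here as exact, testable
rules rather than calls to the original tools.

Entropy dialect (normative for this package): a read is scored by the
maximum over all length-``window`` windows of the Shannon entropy of the
window's k-mer frequency distribution, normalized by
``ln(min(window - k + 1, 4**k))`` so scores lie in [0, 1]; reads shorter
than ``window`` are scored on the full read, and reads shorter than ``k``
are kept.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from .simulate import DEFAULT_ADAPTER


@dataclass
class ReadRecord:
    """A sequencing read, optionally annotated with its UMI and sample."""

    id: str
    sequence: str
    qualities: str
    umi: str = ""
    sample: str | None = None

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(f"{self.id}: sequence/quality length mismatch")


@dataclass
class SampleStats:
    input_reads: int = 0
    demux_assigned: int = 0
    adapter_trimmed: int = 0
    discarded_uncalled: int = 0
    discarded_short: int = 0
    duplicates_removed: int = 0
    entropy_removed: int = 0
    surviving: int = 0


@dataclass
class PreprocessStats:
    """Per-sample read accounting across the preprocessing stages."""

    samples: dict[str, SampleStats] = field(default_factory=dict)
    unassigned: int = 0
    total_input: int = 0

    def sample(self, name: str) -> SampleStats:
        return self.samples.setdefault(name, SampleStats())

    def to_dict(self) -> dict:
        return {
            "total_input": self.total_input,
            "unassigned": self.unassigned,
            "samples": {k: vars(v) for k, v in sorted(self.samples.items())},
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# FASTQ I/O


def read_fastq(path: str | Path) -> Iterator[ReadRecord]:
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    with open(path) as fh:
        for title, seq, qual in FastqGeneralIterator(fh):
            yield ReadRecord(id=title.split()[0], sequence=seq, qualities=qual)


def write_fastq_records(records: Iterable[ReadRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{r.qualities}\n")


# ---------------------------------------------------------------------------
# stages


def demultiplex(
    reads: Iterable[ReadRecord],
    barcodes: dict[str, str],
    umi_length: int = 3,
    stats: PreprocessStats | None = None,
) -> tuple[dict[str, list[ReadRecord]], list[ReadRecord], PreprocessStats]:
    """Assign reads to samples by exact barcode match.

    The read layout is ``[UMI (umi_length)][barcode][insert...]``; a read is
    assigned to sample *s* iff the barcode field equals ``barcodes[s]``
    exactly.  The UMI is recorded on the read and the UMI+barcode prefix is
    removed from sequence and qualities.
    """
    if not barcodes:
        raise ValueError("no barcodes supplied")
    lengths = {len(b) for b in barcodes.values()}
    if len(lengths) != 1:
        raise ValueError("barcodes must all have the same length")
    if len(set(barcodes.values())) != len(barcodes):
        raise ValueError("duplicate barcode sequences")
    bc_len = lengths.pop()
    lookup = {b: s for s, b in barcodes.items()}

    stats = stats or PreprocessStats()
    out: dict[str, list[ReadRecord]] = {s: [] for s in barcodes}
    unassigned: list[ReadRecord] = []
    for read in reads:
        stats.total_input += 1
        bc = read.sequence[umi_length : umi_length + bc_len]
        sample = lookup.get(bc)
        if sample is None:
            stats.unassigned += 1
            unassigned.append(read)
            continue
        ss = stats.sample(sample)
        ss.input_reads += 1
        ss.demux_assigned += 1
        cut = umi_length + bc_len
        out[sample].append(
            ReadRecord(
                id=read.id,
                sequence=read.sequence[cut:],
                qualities=read.qualities[cut:],
                umi=read.sequence[:umi_length],
                sample=sample,
            )
        )
    return out, unassigned, stats


def _adapter_cut_position(seq: str, adapter: str, min_overlap: int) -> int | None:
    """Leftmost position where the adapter starts: either the full adapter
    occurs internally, or a prefix of the adapter (>= min_overlap nt, exact
    match) forms a suffix of the read."""
    for i in range(len(seq)):
        m = min(len(adapter), len(seq) - i)
        if m >= min_overlap and seq[i : i + m] == adapter[:m]:
            return i
    return None


def trim_read(
    read: ReadRecord,
    adapter: str = DEFAULT_ADAPTER,
    min_overlap: int = 4,
    max_uncalled: int = 2,
    min_length: int = 11,
    qual_threshold: int = 20,
) -> ReadRecord | None:
    """Adapter/quality trimming; returns None for a discarded read.

    Order of operations: (1) discard reads with more than ``max_uncalled``
    N bases; (2) remove the maximal 3' suffix whose bases are all below
    ``qual_threshold`` (Phred+33); (3) remove the adapter at the right end
    (leftmost exact match of a >= ``min_overlap`` adapter prefix against a
    read suffix, or of the full adapter internally); (4) discard reads
    shorter than ``min_length`` after trimming.
    """
    if len(adapter) < min_overlap:
        raise ValueError("adapter shorter than min_overlap")
    if read.sequence.count("N") > max_uncalled:
        return None
    seq, qual = read.sequence, read.qualities
    end = len(seq)
    while end > 0 and ord(qual[end - 1]) - 33 < qual_threshold:
        end -= 1
    seq, qual = seq[:end], qual[:end]
    cut = _adapter_cut_position(seq, adapter, min_overlap)
    if cut is not None:
        seq, qual = seq[:cut], qual[:cut]
    if len(seq) < min_length:
        return None
    return ReadRecord(id=read.id, sequence=seq, qualities=qual, umi=read.umi, sample=read.sample)


def collapse_duplicates(reads: Iterable[ReadRecord]) -> tuple[list[ReadRecord], int]:
    """Keep the first read per distinct (UMI, sequence) pair, preserving
    first-occurrence order; identical inserts with different UMIs are
    independent molecules and are both retained."""
    seen: set[tuple[str, str]] = set()
    kept: list[ReadRecord] = []
    removed = 0
    for read in reads:
        key = (read.umi, read.sequence)
        if key in seen:
            removed += 1
        else:
            seen.add(key)
            kept.append(read)
    return kept, removed


def read_entropy(sequence: str, window: int = 10, k: int = 6) -> float:
    """Maximum windowed k-mer entropy of a read, normalized to [0, 1].

    Returns 1.0 for reads shorter than ``k`` (always kept).
    """
    if k > window:
        raise ValueError("k must not exceed window")
    n = len(sequence)
    if n < k:
        return 1.0
    win = min(window, n)
    max_kmers = win - k + 1
    norm = math.log(min(max_kmers, 4**k))
    if norm == 0.0:
        # a single k-mer per window carries no distributional information
        return 0.0
    best = 0.0
    for start in range(0, n - win + 1):
        counts: dict[str, int] = {}
        for j in range(start, start + win - k + 1):
            kmer = sequence[j : j + k]
            counts[kmer] = counts.get(kmer, 0) + 1
        total = win - k + 1
        h = -sum(c / total * math.log(c / total) for c in counts.values())
        best = max(best, h / norm)
        if best >= 1.0:
            break
    return best


def entropy_filter(read: ReadRecord, threshold: float = 0.5, window: int = 10, k: int = 6) -> bool:
    """Keep a read iff its windowed entropy score reaches ``threshold``."""
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    return read_entropy(read.sequence, window=window, k=k) >= threshold


# ---------------------------------------------------------------------------
# pipeline


def run_preprocess(
    reads: Iterable[ReadRecord],
    barcodes: dict[str, str],
    adapter: str = DEFAULT_ADAPTER,
    umi_length: int = 3,
    min_overlap: int = 4,
    max_uncalled: int = 2,
    min_length: int = 11,
    qual_threshold: int = 20,
    entropy_threshold: float = 0.5,
    entropy_window: int = 10,
    entropy_k: int = 6,
) -> tuple[dict[str, list[ReadRecord]], PreprocessStats]:
    """Full preprocessing chain: demultiplex -> trim -> collapse -> entropy.

    Per sample the conservation invariant holds:
    ``demux_assigned = discarded_uncalled + discarded_short +
    duplicates_removed + entropy_removed + surviving``.
    """
    by_sample, _, stats = demultiplex(reads, barcodes, umi_length=umi_length)
    surviving: dict[str, list[ReadRecord]] = {}
    for sample, sample_reads in by_sample.items():
        ss = stats.sample(sample)
        trimmed: list[ReadRecord] = []
        for read in sample_reads:
            if read.sequence.count("N") > max_uncalled:
                ss.discarded_uncalled += 1
                continue
            out = trim_read(
                read, adapter=adapter, min_overlap=min_overlap, max_uncalled=max_uncalled,
                min_length=min_length, qual_threshold=qual_threshold,
            )
            if out is None:
                ss.discarded_short += 1
                continue
            if len(out.sequence) < len(read.sequence):
                ss.adapter_trimmed += 1
            trimmed.append(out)
        collapsed, removed = collapse_duplicates(trimmed)
        ss.duplicates_removed = removed
        kept: list[ReadRecord] = []
        for read in collapsed:
            if entropy_filter(read, threshold=entropy_threshold, window=entropy_window, k=entropy_k):
                kept.append(read)
            else:
                ss.entropy_removed += 1
        ss.surviving = len(kept)
        surviving[sample] = kept
    return surviving, stats
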