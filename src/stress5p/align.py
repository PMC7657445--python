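"""Exact-match read placement and strand-specific coverage tracks.

The aligner places a read at every genomic position where it matches the
forward or reverse-complement strand exactly; reads matching more than one
locus are assigned to exactly one, chosen uniformly at random from a seeded
generator and flagged as multimapped (the random multi-mapper policy used
for CRAC data).  The simulator emits error-free reads, so exact matching is
lossless here; coordinate-sorted SAM/BAM from a real aligner can be imported
instead via :func:`read_sam`.

Internally all coordinates are 0-based half-open; BED6 and bedGraph output
keep that convention, GFF3 conversion happens in :mod:`stress5p.genome`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

from .genome import GenomeBundle, revcomp
from .preprocess import ReadRecord

_INDEX_K = 12


@dataclass(frozen=True)
class Alignment:
    """One placed read; ``end - start`` equals the insert length."""

    read_id: str
    chrom: str
    strand: str
    start: int
    end: int
    multimapped: bool = False
    sample: str | None = None
    condition: str | None = None


class ExactMatchIndex:
    """Seed-and-verify exact substring index over a genome (k-mer seeds)."""

    def __init__(self, bundle: GenomeBundle, k: int = _INDEX_K):
        if not bundle.chromosomes or all(len(s) == 0 for s in bundle.chromosomes.values()):
            raise ValueError("empty genome")
        self.bundle = bundle
        self.k = k
        self._seeds: dict[str, list[tuple[str, int]]] = {}
        for chrom, seq in sorted(bundle.chromosomes.items()):
            for i in range(len(seq) - k + 1):
                self._seeds.setdefault(seq[i : i + k], []).append((chrom, i))

    def _scan(self, query: str) -> list[tuple[str, int]]:
        hits = []
        for chrom, seq in sorted(self.bundle.chromosomes.items()):
            i = seq.find(query)
            while i != -1:
                hits.append((chrom, i))
                i = seq.find(query, i + 1)
        return hits

    def occurrences(self, query: str) -> list[tuple[str, str, int]]:
        """All (chrom, strand, start) exact occurrences of ``query``."""
        out: list[tuple[str, str, int]] = []
        for strand, q in (("+", query), ("-", revcomp(query))):
            if len(q) >= self.k:
                cands = self._seeds.get(q[: self.k], [])
                hits = [
                    (c, i) for c, i in cands
                    if self.bundle.chromosomes[c][i : i + len(q)] == q
                ]
            else:
                hits = self._scan(q)
            out.extend((c, strand, i) for c, i in hits)
        out.sort()
        return out


def align_reads(
    reads: Iterable[ReadRecord],
    bundle: GenomeBundle,
    seed: int = 0,
    condition: str | None = None,
    index: ExactMatchIndex | None = None,
) -> tuple[list[Alignment], int]:
    """Place reads on the genome; returns (alignments, unmapped count)."""
    idx = index or ExactMatchIndex(bundle)
    rng = np.random.default_rng(seed)
    cache: dict[str, list[tuple[str, str, int]]] = {}
    alignments: list[Alignment] = []
    unmapped = 0
    for read in reads:
        hits = cache.get(read.sequence)
        if hits is None:
            hits = idx.occurrences(read.sequence)
            cache[read.sequence] = hits
        if not hits:
            unmapped += 1
            continue
        multi = len(hits) > 1
        chrom, strand, start = hits[int(rng.integers(0, len(hits)))] if multi else hits[0]
        alignments.append(
            Alignment(
                read_id=read.id, chrom=chrom, strand=strand, start=start,
                end=start + len(read.sequence), multimapped=multi,
                sample=read.sample, condition=condition,
            )
        )
    return alignments, unmapped


@dataclass
class CoverageTrack:
    """Per-base, per-strand read coverage with a normalization factor."""

    data: dict[tuple[str, str], np.ndarray]
    scale_factor: float = 1.0
    units: str = "raw"

    def raw(self, chrom: str, strand: str) -> np.ndarray:
        return self.data[(chrom, strand)]

    def scaled(self, chrom: str, strand: str) -> np.ndarray:
        return self.data[(chrom, strand)] * self.scale_factor


def compute_coverage(
    alignments: list[Alignment],
    bundle: GenomeBundle,
    normalization: str = "raw",
    scale_factor: float | None = None,
) -> CoverageTrack:
    """Per-base coverage tallies.

    ``normalization``: ``"raw"`` (factor 1), ``"rpm"`` (factor 1e6 / aligned
    reads), or ``"spike"`` (externally supplied factor from spike-in
    normalization, see :mod:`stress5p.rnaseq`).
    """
    data = {
        (chrom, strand): np.zeros(len(seq), dtype=float)
        for chrom, seq in bundle.chromosomes.items()
        for strand in "+-"
    }
    for a in alignments:
        arr = data.get((a.chrom, a.strand))
        if arr is None:
            raise ValueError(f"alignment on unknown chromosome {a.chrom}")
        arr[a.start : a.end] += 1
    if normalization == "raw":
        factor = 1.0
    elif normalization == "rpm":
        if not alignments:
            raise ValueError("RPM normalization requested with zero aligned reads")
        factor = 1e6 / len(alignments)
    elif normalization == "spike":
        if scale_factor is None:
            raise ValueError("spike normalization requires an explicit scale_factor")
        factor = float(scale_factor)
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    return CoverageTrack(data=data, scale_factor=factor, units=normalization)


def find_summits(
    track: CoverageTrack,
    chrom: str,
    strand: str,
    region: tuple[int, int],
    top_k: int = 1,
    min_separation: int = 10,
) -> list[tuple[int, float]]:
    """Greedy summit selection: repeatedly take the highest remaining
    position, suppressing candidates within ``min_separation`` nt of an
    already selected summit; ties broken by smaller coordinate."""
    s, e = region
    if e <= s:
        raise ValueError("empty region")
    arr = track.scaled(chrom, strand)[s:e]
    order = sorted(range(len(arr)), key=lambda i: (-arr[i], i))
    chosen: list[tuple[int, float]] = []
    for i in order:
        if arr[i] <= 0:  # uncovered positions are not summits
            break
        pos = s + i
        if any(abs(pos - p) < min_separation for p, _ in chosen):
            continue
        chosen.append((pos, float(arr[i])))
        if len(chosen) == top_k:
            break
    return chosen


# ---------------------------------------------------------------------------
# I/O


def read_sam(path: str | Path, condition: str | None = None) -> list[Alignment]:
    """Import mapped reads from SAM/BAM via pysam."""
    import pysam

    alignments: list[Alignment] = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                continue
            alignments.append(
                Alignment(
                    read_id=rec.query_name,
                    chrom=rec.reference_name,
                    strand="-" if rec.is_reverse else "+",
                    start=rec.reference_start,
                    end=rec.reference_end,
                    multimapped=rec.has_tag("NH") and rec.get_tag("NH") > 1,
                    condition=condition,
                )
            )
    return alignments


def read_bed6(path: str | Path, condition: str | None = None) -> list[Alignment]:
    """Load alignments written by :func:`write_bed6`."""
    alignments: list[Alignment] = []
    with open(path) as fh:
        for line in fh:
            chrom, start, end, name, _, strand = line.rstrip("\n").split("\t")[:6]
            alignments.append(
                Alignment(
                    read_id=name, chrom=chrom, strand=strand,
                    start=int(start), end=int(end), condition=condition,
                )
            )
    return alignments


def write_bed6(alignments: list[Alignment], path: str | Path) -> None:
    with open(path, "w") as fh:
        for a in alignments:
            fh.write(f"{a.chrom}\t{a.start}\t{a.end}\t{a.read_id}\t0\t{a.strand}\n")


def write_bedgraph(track: CoverageTrack, strand: str, path: str | Path) -> None:
    """Scaled coverage for one strand as bedGraph (zero runs omitted)."""
    with open(path, "w") as fh:
        for (chrom, s), arr in sorted(track.data.items()):
            if s != strand:
                continue
            vals = arr * track.scale_factor
            i = 0
            n = len(vals)
            while i < n:
                j = i + 1
                while j < n and vals[j] == vals[i]:
                    j += 1
                if vals[i] != 0:
                    fh.write(f"{chrom}\t{i}\t{j}\t{vals[i]:g}\n")
                i = j
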