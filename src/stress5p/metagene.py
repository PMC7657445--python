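"""Start-codon metagene profiles, binned per-transcript heatmaps and the
5'-versus-pervasive binding statistic.

The metagene averages per-transcript *normalized* positional densities with
equal weight (so highly bound transcripts do not dominate); a pooled-count
mode is available.  The pervasive statistic follows the count comparison
used to characterize Ded1: a transcript binds "pervasively" iff it has at
least as many reads at downstream sites (5' base beyond the 5'UTR + first
150 nt of CDS) as at the 5' end.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .align import Alignment
from .crac import FIVEP_CDS_WINDOW, BindingTable, TranscriptAssigner
from .genome import GenomeBundle


@dataclass
class MetageneProfile:
    """Average read-density profile anchored at the start codon.

    ``offsets`` run from -upstream to +downstream-1, with offset 0 the A of
    the AUG; ``density`` sums to 1 whenever any in-window reads exist.
    """

    offsets: np.ndarray
    density: np.ndarray
    n_transcripts: int

    def mass(self, lo: int, hi: int) -> float:
        """Total density mass over offsets in [lo, hi)."""
        sel = (self.offsets >= lo) & (self.offsets < hi)
        return float(self.density[sel].sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"offset": self.offsets, "density": self.density})


def startcodon_profile(
    alignments: list[Alignment],
    bundle: GenomeBundle,
    transcripts: list[str],
    window: tuple[int, int] = (200, 500),
    pooled: bool = False,
    assigner: TranscriptAssigner | None = None,
) -> MetageneProfile:
    """Metagene of read 5'-base positions around the start codon.

    Per transcript, read 5' bases are tallied at offsets relative to the
    first CDS base (clipped to transcript bounds; upstream coverage is
    limited by the 5'UTR length), each transcript's vector is normalized to
    sum 1, vectors are averaged with equal weight over transcripts with at
    least one in-window read, and the average is renormalized.  With
    ``pooled=True`` raw counts are summed across transcripts instead.
    """
    if not transcripts:
        raise ValueError("empty transcript list")
    upstream, downstream = window
    offsets = np.arange(-upstream, downstream)
    wanted = set(transcripts)
    assigner = assigner or TranscriptAssigner(bundle, seed=0)
    tallies: dict[str, np.ndarray] = {tid: np.zeros(len(offsets)) for tid in transcripts}
    tx = {t.id: t for t in bundle.transcripts}
    for tid in transcripts:
        if tx[tid].cds_len == 0:
            raise ValueError(f"{tid} has no CDS annotation")
    for a in alignments:
        t, off = assigner.assign(a)
        if t is None or t.id not in wanted:
            continue
        rel = off - t.utr5_len
        if -upstream <= rel < downstream:
            tallies[t.id][rel + upstream] += 1

    used = 0
    acc = np.zeros(len(offsets))
    for vec in tallies.values():
        s = vec.sum()
        if s == 0:
            continue
        used += 1
        acc += vec if pooled else vec / s
    if used and acc.sum() > 0:
        acc = acc / acc.sum()
    return MetageneProfile(offsets=offsets, density=acc, n_transcripts=used)


def fivep_mass_ratio(profile: MetageneProfile, boundary: int = FIVEP_CDS_WINDOW) -> float:
    """Ratio of profile mass 5' of ``boundary`` to the mass downstream of it.

    Because the profile is normalized to sum 1, loss of 5' binding shows up
    as a shift of mass, so the scale-free readout is this 5'/downstream
    odds ratio rather than the (bounded) 5' mass fraction itself.
    """
    lo = int(profile.offsets[0])
    hi = int(profile.offsets[-1]) + 1
    up = profile.mass(lo, boundary)
    down = profile.mass(boundary, hi)
    if down == 0:
        return np.inf if up > 0 else np.nan
    return up / down


def fivep_pervasive_stats(
    table: BindingTable,
    condition: str,
    mode: str = "counts",
    bundle: GenomeBundle | None = None,
) -> tuple[pd.DataFrame, float]:
    """Per-transcript 5'/downstream binding ratios and the pervasive fraction.

    ``downstream = total - fivep`` (raw counts, no pseudocounts);
    ``ratio = fivep / max(downstream, 1)``; a transcript is *pervasive* iff
    downstream >= fivep (inclusive: "at least as much" downstream binding).
    ``pervasive_fraction`` is computed over transcripts with >= 1 read.
    In ``mode="density"`` the comparison divides each count by its region
    length (requires ``bundle``); reported separately, never mixed.
    """
    if condition not in table.conditions:
        raise ValueError(f"condition {condition!r} absent from table")
    total = table.total_counts(condition)
    fivep = table.fivep_counts(condition)
    downstream = total - fivep
    if mode == "counts":
        cmp_fivep, cmp_down = fivep.astype(float), downstream.astype(float)
    elif mode == "density":
        if bundle is None:
            raise ValueError("density mode requires the genome bundle")
        flen = pd.Series({t.id: max(1, t.fivep_region_len()) for t in bundle.transcripts})
        dlen = pd.Series({t.id: max(1, t.length - t.fivep_region_len()) for t in bundle.transcripts})
        cmp_fivep = fivep / flen.reindex(fivep.index)
        cmp_down = downstream / dlen.reindex(downstream.index)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    stats = pd.DataFrame(
        {
            "fivep": fivep,
            "downstream": downstream,
            "ratio": fivep / downstream.clip(lower=1),
            "pervasive": cmp_down >= cmp_fivep,
        }
    )
    covered = stats[total >= 1]
    fraction = float(covered["pervasive"].mean()) if len(covered) else np.nan
    return stats, fraction


@dataclass
class TranscriptHeatmap:
    """Row-normalized binned binding densities, rows sorted by descending
    5'/pervasive ratio (ties by transcript id)."""

    matrix: np.ndarray
    row_ids: list[str]
    ratios: np.ndarray
    bins: int


def heatmap_matrix(
    alignments: list[Alignment],
    bundle: GenomeBundle,
    transcripts: list[str],
    bins: int = 50,
    assigner: TranscriptAssigner | None = None,
) -> TranscriptHeatmap:
    """Bin read 5' bases into ``bins`` equal-length bins per transcript."""
    if bins < 2:
        raise ValueError("bins must be >= 2")
    if not transcripts:
        raise ValueError("empty transcript list")
    tx = {t.id: t for t in bundle.transcripts}
    min_len = min(tx[tid].length for tid in transcripts)
    eff_bins = bins
    if min_len < bins:
        warnings.warn(f"shortest transcript ({min_len} nt) shorter than {bins} bins; clipping")
        eff_bins = min_len
    assigner = assigner or TranscriptAssigner(bundle, seed=0)
    wanted = set(transcripts)
    counts = {tid: np.zeros(eff_bins) for tid in transcripts}
    fivep = {tid: 0 for tid in transcripts}
    downstream = {tid: 0 for tid in transcripts}
    for a in alignments:
        t, off = assigner.assign(a)
        if t is None or t.id not in wanted:
            continue
        b = min(eff_bins - 1, int(off * eff_bins / t.length))
        counts[t.id][b] += 1
        if off < t.fivep_region_len():
            fivep[t.id] += 1
        else:
            downstream[t.id] += 1

    ratios = {tid: fivep[tid] / max(downstream[tid], 1) for tid in transcripts}
    order = sorted(transcripts, key=lambda tid: (-ratios[tid], tid))
    rows = []
    for tid in order:
        vec = counts[tid]
        s = vec.sum()
        rows.append(vec / s if s > 0 else vec)
    return TranscriptHeatmap(
        matrix=np.vstack(rows),
        row_ids=order,
        ratios=np.array([ratios[tid] for tid in order]),
        bins=eff_bins,
    )
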