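"""Independent brute-force reference implementations used as test oracles.

These deliberately re-derive each rule from its written definition with the
most naive algorithm available (full enumeration, Counter-based tallies,
eigendecomposition), sharing no code with the package implementation.
"""

from __future__ import annotations

import math
from collections import Counter

import numpy as np


def oracle_trim(seq: str, qual: str, adapter: str, min_overlap: int = 4,
                max_uncalled: int = 2, min_length: int = 11, qual_threshold: int = 20):
    """Reference trimming: returns the surviving sequence or None."""
    if sum(1 for b in seq if b == "N") > max_uncalled:
        return None
    # quality tail: keep the longest prefix ending in a good-quality base
    keep = 0
    for i, q in enumerate(qual):
        if ord(q) - 33 >= qual_threshold:
            keep = i + 1
    seq = seq[:keep]
    # enumerate every (position, overlap) adapter placement, take leftmost
    best = None
    for i in range(len(seq)):
        for m in range(min_overlap, len(adapter) + 1):
            if i + m <= len(seq) and seq[i:i + m] == adapter[:m]:
                if m == len(adapter) or i + m == len(seq):
                    best = i if best is None else min(best, i)
    if best is not None:
        seq = seq[:best]
    return seq if len(seq) >= min_length else None


def oracle_entropy(seq: str, window: int = 10, k: int = 6) -> float:
    """Reference windowed k-mer entropy score in [0, 1]."""
    if len(seq) < k:
        return 1.0
    win = min(window, len(seq))
    denom = math.log(min(win - k + 1, 4 ** k))
    if denom == 0:
        return 0.0
    scores = []
    for start in range(len(seq) - win + 1):
        chunk = seq[start:start + win]
        kmers = Counter(chunk[j:j + k] for j in range(len(chunk) - k + 1))
        n = sum(kmers.values())
        h = -sum((c / n) * math.log(c / n) for c in kmers.values())
        scores.append(h / denom)
    return max(scores)


def oracle_collapse_keys(pairs):
    """Distinct (umi, sequence) pairs."""
    return set(pairs)


def oracle_counts_from_truth(truth_rows, bundle, aligned_ids, cds_window: int = 150):
    """Per-transcript (total, fivep) counts by direct interval assignment of
    each read's true insert 5' offset, restricted to aligned read ids."""
    total: Counter = Counter()
    fivep: Counter = Counter()
    tx = {t.id: t for t in bundle.transcripts}
    for row in truth_rows:
        if row["read_id"] not in aligned_ids or not row["transcript"]:
            continue
        t = tx[row["transcript"]]
        total[t.id] += 1
        if row["offset"] < t.utr5_len + min(cds_window, t.cds_len):
            fivep[t.id] += 1
    return total, fivep


def oracle_coverage(alignments, chrom_lengths):
    """Per-base coverage by explicit iteration over every covered base."""
    cov = {(c, s): np.zeros(n) for c, n in chrom_lengths.items() for s in "+-"}
    for a in alignments:
        for pos in range(a.start, a.end):
            cov[(a.chrom, a.strand)][pos] += 1
    return cov


def oracle_summits(values, region, top_k, min_separation):
    """Exhaustive greedy summit search on a plain list."""
    s, e = region
    chosen = []
    candidates = [(float(values[i]), i) for i in range(s, e) if values[i] > 0]
    while len(chosen) < top_k:
        best = None
        for h, pos in candidates:
            if any(abs(pos - p) < min_separation for p, _ in chosen):
                continue
            if best is None or h > best[0] or (h == best[0] and pos < best[1]):
                best = (h, pos)
        if best is None:
            break
        chosen.append((best[1], best[0]))
    return chosen


def oracle_pca_scores(X: np.ndarray):
    """PCA via eigendecomposition of the covariance matrix (independent of
    the SVD route): returns (scores, explained fractions)."""
    Xc = X - X.mean(axis=0, keepdims=True)
    cov = Xc.T @ Xc
    w, V = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    w = np.clip(w, 0, None)
    return Xc @ V, w / w.sum()
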