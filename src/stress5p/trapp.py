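"""SILAC TRAPP time-course analysis.

Protein-level log2(stress/control) RNA-association ratios across a stress
time course (2, 4, 8, 12 and 16 min by default) are filtered for
identification confidence (>= 2 peptides) and replicate presence (>= 2
replicates at every scoped time point), aggregated by the per-cell median,
classified by a strict 2-fold change threshold at 16 min, and summarized by
principal-component analysis (column-mean centering, no scaling -- raw
log2 ratios are already on a comparable scale).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ["protein", "condition", "time_min", "replicate", "log2_ratio", "peptides"]


@dataclass
class SilacMatrix:
    """Long-format protein x (condition, time, replicate) ratio container."""

    data: pd.DataFrame  # columns: REQUIRED_COLUMNS

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        key = ["protein", "condition", "time_min", "replicate"]
        if self.data.duplicated(key).any():
            raise ValueError("duplicate (protein, condition, time, replicate) entries")
        if not np.isfinite(self.data["log2_ratio"].to_numpy()).all():
            raise ValueError("stored ratios must be finite")

    @property
    def proteins(self) -> list[str]:
        return sorted(self.data["protein"].unique())

    def cells(self) -> list[tuple[str, int]]:
        """All (condition, time) cells present in the data."""
        return sorted({(c, int(t)) for c, t in zip(self.data["condition"], self.data["time_min"])})


def build_matrix(
    ratio_tables: list[pd.DataFrame | str | Path],
    min_peptides: int = 2,
) -> SilacMatrix:
    """Assemble replicate ratio tables into one matrix, dropping proteins
    identified with fewer than ``min_peptides`` peptides (low confidence)."""
    frames = []
    for t in ratio_tables:
        df = t if isinstance(t, pd.DataFrame) else pd.read_csv(t, sep="\t")
        frames.append(df[REQUIRED_COLUMNS].copy())
    data = pd.concat(frames, ignore_index=True)
    data = data[data["peptides"] >= min_peptides].reset_index(drop=True)
    return SilacMatrix(data=data)


def filter_presence(
    matrix: SilacMatrix,
    min_replicates: int = 2,
    scope: list[tuple[str, int]] | None = None,
) -> SilacMatrix:
    """Keep a protein iff it has >= ``min_replicates`` non-missing values at
    *every* (condition, time) cell in ``scope`` (default: all cells)."""
    scope = scope or matrix.cells()
    if not scope:
        raise ValueError("empty scope")
    df = matrix.data
    counts = (
        df.groupby(["protein", "condition", "time_min"])["log2_ratio"].count().unstack(["condition", "time_min"])
    )
    want = [c for c in counts.columns if (c[0], int(c[1])) in set(scope)]
    ok = (counts[want].fillna(0) >= min_replicates).all(axis=1)
    keep = set(ok[ok].index)
    return SilacMatrix(data=df[df["protein"].isin(keep)].reset_index(drop=True))


def aggregate_replicates(matrix: SilacMatrix) -> pd.DataFrame:
    """Protein x (condition, time) matrix of per-cell replicate medians."""
    agg = matrix.data.groupby(["protein", "condition", "time_min"])["log2_ratio"].median()
    return agg.unstack(["condition", "time_min"]).sort_index(axis=1)


def classify_changes(
    aggregated: pd.DataFrame,
    condition: str,
    time_min: int = 16,
    fold_threshold: float = 2.0,
) -> tuple[set[str], set[str]]:
    """Proteins with *greater than* ``fold_threshold``-fold change in RNA
    association at ``time_min``: strictly above log2(threshold) (increased)
    or strictly below -log2(threshold) (decreased).  Values exactly at the
    boundary are not classified."""
    if fold_threshold <= 1:
        raise ValueError("fold_threshold must be > 1")
    col = aggregated[(condition, time_min)].dropna()
    cut = np.log2(fold_threshold)
    increased = set(col[col > cut].index)
    decreased = set(col[col < -cut].index)
    return increased, decreased


@dataclass
class PCAResult:
    scores: pd.DataFrame  # rows x components
    loadings: pd.DataFrame  # components x columns
    explained_variance: np.ndarray  # fractions, non-increasing


def run_pca(aggregated: pd.DataFrame, orientation: str = "samples") -> PCAResult:
    """PCA of the aggregated ratio matrix via SVD.

    ``orientation="samples"``: rows are (condition, time) samples and each
    protein is a feature (the sample-clustering view); ``"proteins"``: rows
    are proteins (the per-protein response view).  Columns are mean-centered,
    not scaled.  Sign convention: within each component, the
    largest-magnitude loading is positive.  Requires a complete matrix
    (filter to complete cases first; imputation is deliberately not offered).
    """
    if aggregated.isna().to_numpy().any():
        raise ValueError("matrix contains missing values; apply complete-case filtering first")
    if orientation == "samples":
        X = aggregated.T
    elif orientation == "proteins":
        X = aggregated
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need at least 2 rows and 2 columns")
    values = X.to_numpy(dtype=float)
    centered = values - values.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(centered, full_matrices=False)
    for i in range(len(S)):
        j = int(np.argmax(np.abs(Vt[i])))
        if Vt[i, j] < 0:
            Vt[i] *= -1
            U[:, i] *= -1
    total = (S**2).sum()
    explained = S**2 / total if total > 0 else np.zeros_like(S)
    comps = [f"PC{i + 1}" for i in range(len(S))]
    return PCAResult(
        scores=pd.DataFrame(U * S, index=X.index, columns=comps),
        loadings=pd.DataFrame(Vt, index=comps, columns=X.columns),
        explained_variance=explained,
    )
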