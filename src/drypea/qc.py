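"""SNP matrix quality control and K-nearest-neighbour imputation.

Filtering removes monomorphic markers, markers below a minor-allele
frequency floor (allele-based, computed over non-missing calls before any
imputation), and markers whose missing-call fraction exceeds a threshold.
Imputation replaces each missing call by the modal call among the K
nearest lines under the simple-matching distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from drypea.genotypes import GenotypeMatrix

__all__ = ["FilterReport", "filter_markers", "knn_impute", "matching_distance"]


@dataclass
class FilterReport:
    """Marker counts removed per rule and retained.

    A marker failing several rules is charged to the first rule in the
    order monomorphic -> MAF -> missing rate.
    """

    n_input: int
    n_monomorphic: int
    n_low_maf: int
    n_high_missing: int
    n_retained: int

    def __post_init__(self) -> None:
        removed = self.n_monomorphic + self.n_low_maf + self.n_high_missing
        if removed + self.n_retained != self.n_input:
            raise ValueError("filter report counts do not add up")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rule": ["input", "monomorphic", "low_maf", "high_missing", "retained"],
                "n_markers": [
                    self.n_input,
                    self.n_monomorphic,
                    self.n_low_maf,
                    self.n_high_missing,
                    self.n_retained,
                ],
            }
        )


def filter_markers(
    g: GenotypeMatrix,
    maf_min: float = 0.025,
    missing_max: float = 0.2,
    genotype_based_maf: bool = False,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Retain polymorphic markers with MAF >= ``maf_min`` and missing
    fraction <= ``missing_max``; marker order is preserved.

    MAF is allele-based by default: the alternate-allele frequency over
    non-missing calls, a heterozygote contributing one copy of each
    allele. With ``genotype_based_maf`` heterozygotes are excluded and the
    frequency is computed over homozygous calls only.
    """
    if not 0 <= maf_min <= 1 or not 0 <= missing_max <= 1:
        raise ValueError("maf_min and missing_max must be in [0, 1]")
    calls = g.calls
    n_obs = calls.notna().sum(axis=0)
    miss = calls.isna().mean(axis=0)
    if genotype_based_maf:
        hom = calls.where(calls != 1.0)
        p = hom.mean(axis=0, skipna=True) / 2.0
    else:
        p = calls.mean(axis=0, skipna=True) / 2.0
    maf = np.minimum(p, 1.0 - p)
    nun = calls.nunique(axis=0, dropna=True)
    mono = (nun <= 1) | (n_obs == 0)
    low_maf = ~mono & (maf < maf_min)
    high_missing = ~mono & ~low_maf & (miss > missing_max)
    keep = ~(mono | low_maf | high_missing)
    report = FilterReport(
        n_input=g.n_markers,
        n_monomorphic=int(mono.sum()),
        n_low_maf=int(low_maf.sum()),
        n_high_missing=int(high_missing.sum()),
        n_retained=int(keep.sum()),
    )
    if report.n_retained == 0:
        raise ValueError("empty matrix after filtering")
    return g.subset(markers=calls.columns[keep]), report


def matching_distance(calls: np.ndarray) -> np.ndarray:
    """Pairwise simple-matching distance between lines.

    distance = 1 - (matching calls / jointly non-missing calls), with
    calls compared as categories {0, 1, 2}. Pairs with no jointly observed
    marker get distance NaN.
    """
    n = calls.shape[0]
    obs = ~np.isnan(calls)
    # chunked to keep memory modest on large matrices
    dist = np.empty((n, n))
    for i in range(n):
        both = obs[i][None, :] & obs
        match = both & (calls[i][None, :] == calls)
        denom = both.sum(axis=1).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            dist[i] = 1.0 - match.sum(axis=1) / denom
        dist[i, denom == 0] = np.nan
    return dist


def knn_impute(g: GenotypeMatrix, k: int = 4) -> GenotypeMatrix:
    """Impute missing calls from the K nearest lines.

    For each missing call the imputed value is the modal call among the k
    nearest lines (simple-matching distance) that carry a call at that
    marker; neighbour search widens past k when nearer neighbours are
    themselves missing there. Distance ties break by line order, modal
    ties toward the lower call code. Observed calls are never altered.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > g.n_lines - 1:
        raise ValueError("k exceeds the number of candidate neighbour lines")
    calls = g.calls.to_numpy().copy()
    all_missing = np.isnan(calls).all(axis=1)
    if all_missing.any():
        bad = list(g.line_ids[all_missing])
        raise ValueError(f"lines with all calls missing: {bad}")
    if not np.isnan(calls).any():
        return g.copy()
    dist = matching_distance(calls)
    n = calls.shape[0]
    # stable order: by distance then line index; self excluded via +inf
    d_self = dist.copy()
    np.fill_diagonal(d_self, np.inf)
    d_self[np.isnan(d_self)] = np.inf
    neighbor_order = np.argsort(d_self, axis=1, kind="stable")
    out = calls.copy()
    miss_rows, miss_cols = np.where(np.isnan(calls))
    for i, j in zip(miss_rows, miss_cols):
        votes = []
        for rank, nb in enumerate(neighbor_order[i]):
            if np.isinf(d_self[i, nb]):
                break
            v = calls[nb, j]
            if not np.isnan(v):
                votes.append(v)
            # the k nearest lines vote; widen only while no vote was cast
            if rank + 1 >= k and votes:
                break
        if not votes:
            raise ValueError(
                f"no neighbour carries a call at marker {g.marker_ids[j]!r} "
                f"for line {g.line_ids[i]!r}"
            )
        vals, counts = np.unique(votes, return_counts=True)
        out[i, j] = vals[np.argmax(counts)]  # ties -> lower code (vals sorted)
    df = pd.DataFrame(out, index=g.calls.index, columns=g.calls.columns)
    pos = None if g.positions is None else g.positions.copy()
    return GenotypeMatrix(df, g.populations.copy(), pos)
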