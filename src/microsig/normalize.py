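"""Library-size normalization and expression filtering.

Implements counts-per-million and FPKM scaling, trimmed-mean-of-M-values
(TMM) between-sample normalization factors, per-sample rank-minmax
normalization to [0, 1] for cross-platform comparison, and the subgroup
expression filter that gates genes into differential expression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import CountMatrix, ExpressionMatrix, GeneAnnotation

__all__ = [
    "NormalizationFactors",
    "compute_cpm",
    "tmm_factors",
    "compute_fpkm",
    "rank_minmax_normalize",
    "subgroup_expression_filter",
]


@dataclass(frozen=True)
class NormalizationFactors:
    """Per-sample positive scaling factors, centred to geometric mean 1."""

    factors: pd.Series
    reference: str

    def __post_init__(self) -> None:
        if (self.factors <= 0).any():
            raise ValueError("normalization factors must be positive")
        logmean = np.log(self.factors.to_numpy()).mean()
        if abs(logmean) > 1e-9:
            raise ValueError("factors must be centred to geometric mean 1")


def _effective_libsizes(counts: CountMatrix, factors: NormalizationFactors | None) -> pd.Series:
    lib = counts.library_sizes.astype(float)
    if (lib <= 0).any():
        bad = sorted(lib.index[lib <= 0])
        raise ValueError(f"zero library size for sample(s): {bad}")
    if factors is not None:
        lib = lib * factors.factors.loc[lib.index]
    return lib


def compute_cpm(counts: CountMatrix, factors: NormalizationFactors | None = None) -> ExpressionMatrix:
    """Counts per million: count * 1e6 / (library size * factor)."""
    lib = _effective_libsizes(counts, factors)
    vals = counts.counts.to_numpy(dtype=float) * 1e6 / lib.to_numpy()[None, :]
    return ExpressionMatrix(
        pd.DataFrame(vals, index=counts.genes, columns=counts.samples), "CPM", counts.meta
    )


def compute_fpkm(
    counts: CountMatrix,
    annot: GeneAnnotation,
    factors: NormalizationFactors | None = None,
) -> ExpressionMatrix:
    """FPKM: count * 1e9 / (gene length bp * library size * factor)."""
    missing = [g for g in counts.genes if g not in annot.lengths.index]
    if missing:
        raise ValueError(f"genes lacking annotated length: {missing[:10]}{'...' if len(missing) > 10 else ''}")
    lib = _effective_libsizes(counts, factors)
    lengths = annot.lengths.loc[counts.genes].to_numpy(dtype=float)
    vals = counts.counts.to_numpy(dtype=float) * 1e9 / (lengths[:, None] * lib.to_numpy()[None, :])
    return ExpressionMatrix(
        pd.DataFrame(vals, index=counts.genes, columns=counts.samples), "FPKM", counts.meta
    )


# ---------------------------------------------------------------------------
# TMM
# ---------------------------------------------------------------------------


def _quantile_libscaled(col: np.ndarray, lib: float, p: float = 0.75) -> float:
    return float(np.quantile(col, p)) / lib


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    m_trim: float,
    a_trim: float,
) -> float:
    """Log2 TMM factor of one sample against the reference.

    Genes with a zero count in either sample are excluded pairwise; the M
    (log ratio) and A (log abundance) values are each two-sided trimmed by
    rank, and the factor is the precision-weighted mean of the surviving M
    values, with weights from the asymptotic binomial (delta-method)
    variance of M.
    """
    keep = (obs > 0) & (ref > 0)
    if not keep.any():
        raise ValueError("sample shares no expressed genes with the reference")
    o, r = obs[keep], ref[keep]
    po, pr = o / lib_obs, r / lib_ref
    m = np.log2(po / pr)
    a = 0.5 * np.log2(po * pr)
    # delta-method variance of M for binomial sampling of counts
    v = (lib_obs - o) / (lib_obs * o) + (lib_ref - r) / (lib_ref * r)
    n = len(m)
    lo_m = np.floor(n * m_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * a_trim) + 1
    hi_a = n + 1 - lo_a
    rm = rankdata(m)
    ra = rankdata(a)
    kept = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not kept.any():
        return 0.0
    f = float(np.sum(m[kept] / v[kept]) / np.sum(1.0 / v[kept]))
    if abs(f) < 1e-6:  # numerically indistinguishable from no shift
        f = 0.0
    return f


def tmm_factors(
    counts: CountMatrix,
    ref: str | None = None,
    m_trim: float = 0.30,
    a_trim: float = 0.05,
) -> NormalizationFactors:
    """Trimmed-mean-of-M-values normalization factors.

    The automatic reference is the sample whose upper-quartile
    library-scaled count is closest to the mean upper quartile across
    samples.  Returned factors are centred so their product is 1; dividing
    each library size by its factor equalises the trimmed mean expression
    ratio between samples.
    """
    if counts.counts.shape[1] < 2:
        raise ValueError("TMM requires at least two samples")
    lib = counts.library_sizes.astype(float)
    if (lib <= 0).any():
        raise ValueError("zero library size")
    mat = counts.counts.to_numpy(dtype=float)
    if ref is None:
        q = np.array([_quantile_libscaled(mat[:, j], lib.iloc[j]) for j in range(mat.shape[1])])
        ref_idx = int(np.argmin(np.abs(q - q.mean())))
        ref = str(counts.samples[ref_idx])
    elif ref not in counts.samples:
        raise ValueError(f"reference sample {ref!r} not in matrix")
    ref_idx = list(counts.samples).index(ref)
    logf = np.zeros(mat.shape[1])
    for j in range(mat.shape[1]):
        if j == ref_idx:
            continue
        logf[j] = _tmm_pair(mat[:, j], mat[:, ref_idx], lib.iloc[j], lib.iloc[ref_idx], m_trim, a_trim)
    logf -= logf.mean()  # geometric-mean centring
    return NormalizationFactors(pd.Series(np.exp2(logf), index=counts.samples), ref)


# ---------------------------------------------------------------------------
# Rank-minmax normalization
# ---------------------------------------------------------------------------


def rank_minmax_normalize(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Per-sample rank normalization to [0, 1].

    Within each sample, genes are ranked ascending by expression (ties get
    the average rank) and ranks are min-max rescaled so the least-expressed
    gene maps to 0 and the most-expressed to 1.  A constant column has no
    ordering information and maps to 0.5 everywhere.
    """
    if expr.values.shape[0] < 2:
        raise ValueError("rank normalization needs at least two genes")
    out = np.empty(expr.values.shape, dtype=float)
    vals = expr.values.to_numpy(dtype=float)
    for j in range(vals.shape[1]):
        r = rankdata(vals[:, j], method="average")
        span = r.max() - r.min()
        out[:, j] = 0.5 if span == 0 else (r - r.min()) / span
    return ExpressionMatrix(
        pd.DataFrame(out, index=expr.genes, columns=expr.samples), "RANK01", expr.meta
    )


# ---------------------------------------------------------------------------
# Subgroup expression filter
# ---------------------------------------------------------------------------


def subgroup_expression_filter(
    counts: CountMatrix,
    subgroups: pd.Series | str = "subgroup",
    min_cpm: float = 10.0,
    factors: NormalizationFactors | None = None,
) -> pd.Series:
    """Boolean gene mask: CPM strictly above ``min_cpm`` in every sample of
    at least one subgroup.

    ``subgroups`` is either a metadata column name or a per-sample label
    series.  By default the CPM is computed on raw library sizes; pass TMM
    ``factors`` to filter on effective library sizes instead.
    """
    labels = counts.labels(subgroups) if isinstance(subgroups, str) else subgroups.loc[counts.samples]
    if labels.isna().any():
        raise ValueError("every sample must carry a subgroup label")
    cpm = compute_cpm(counts, factors).values
    mask = pd.Series(False, index=counts.genes)
    for g in labels.unique():
        members = labels.index[labels == g]
        if len(members) == 0:
            raise ValueError(f"empty subgroup {g!r}")
        mask |= (cpm[members] > min_cpm).all(axis=1)
    return mask
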