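"""Precision-weighted moderated-t differential expression for counts.

The model follows the voom / empirical-Bayes approach: counts are
transformed to log2-CPM with a half-count offset, a locally weighted
regression of the square-root residual standard deviation on average
log2-count supplies per-observation precision weights, gene-wise weighted
least squares gives contrast estimates, and residual variances are shrunk
toward a global prior fitted by moment matching on log variances (the
trigamma equation) before computing moderated t statistics.  False
discovery rate control is Benjamini-Hochberg within each contrast.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .io import CountMatrix, DEResult
from .normalize import NormalizationFactors

__all__ = [
    "VoomFit",
    "LinearFit",
    "ModerationState",
    "voom_transform",
    "fit_linear_models",
    "ebayes_moderate",
    "bh_adjust",
    "de_genes",
    "run_voom_de",
]


@dataclass(frozen=True)
class VoomFit:
    """Log2-CPM values with per-observation precision weights."""

    y: pd.DataFrame                      # genes x samples, log2-CPM (offset 0.5)
    weights: pd.DataFrame                # same shape, > 0
    trend: Callable[[np.ndarray], np.ndarray]  # sqrt-sd as a function of log2-count
    groups: pd.Series                    # per-sample group label

    def __post_init__(self) -> None:
        w = self.weights.to_numpy()
        if not np.isfinite(w).all() or (w <= 0).any():
            raise ValueError("voom weights must be positive and finite")


@dataclass(frozen=True)
class LinearFit:
    """Gene-wise weighted least-squares fit on a group-means design."""

    coef: pd.DataFrame        # genes x groups (group mean log2-CPM)
    s2: pd.Series             # residual variance per gene
    df_residual: int
    cov_unscaled: np.ndarray  # genes x groups x groups, (X'WX)^-1 per gene
    groups: tuple[str, ...]
    amean: pd.Series          # average log2-CPM per gene


@dataclass(frozen=True)
class ModerationState:
    """Empirical-Bayes variance shrinkage state.

    Posterior variance is the prior-weighted combination
    ``(d0*s0^2 + d*s^2) / (d0 + d)``; ``d0`` may be infinite when all gene
    variances are consistent with a single value.
    """

    s2: pd.Series
    df_residual: float
    df_prior: float
    s2_prior: float
    s2_post: pd.Series

    def __post_init__(self) -> None:
        lo = np.minimum(self.s2, self.s2_prior) - 1e-9
        hi = np.maximum(self.s2, self.s2_prior) + 1e-9
        if ((self.s2_post < lo) | (self.s2_post > hi)).any():
            raise ValueError("posterior variance must lie between s^2 and the prior")


def _design_matrix(groups: pd.Series) -> tuple[np.ndarray, tuple[str, ...]]:
    levels = tuple(dict.fromkeys(groups))
    X = np.column_stack([(groups == g).to_numpy(dtype=float) for g in levels])
    return X, levels


def voom_transform(
    counts: CountMatrix,
    groups: pd.Series | str = "subgroup",
    factors: NormalizationFactors | None = None,
    span: float = 0.5,
) -> VoomFit:
    """Transform counts to log2-CPM and attach mean-variance precision weights.

    ``y = log2((count + 0.5) / (libsize*factor + 1) * 1e6)``.  A gene-wise
    group-means fit yields residual standard deviations whose square roots
    are smoothed against average log2-count by lowess (span 0.5); the
    fitted trend, evaluated at each observation's fitted log2-count, gives
    ``weight = trend^-4``.  The trend is floored at the smallest positive
    fitted value so degenerate genes (zero residual sd) keep finite weights.
    """
    labels = counts.labels(groups) if isinstance(groups, str) else groups.loc[counts.samples]
    sizes = labels.value_counts()
    small = sizes[sizes < 2]
    if len(small):
        raise ValueError(f"group(s) with fewer than 2 samples: {sorted(small.index)}")
    lib = counts.library_sizes.astype(float)
    if factors is not None:
        lib = lib * factors.factors.loc[lib.index]
    mat = counts.counts.to_numpy(dtype=float)
    y = np.log2((mat + 0.5) / (lib.to_numpy()[None, :] + 1.0) * 1e6)

    X, levels = _design_matrix(labels)
    # group-means fit: closed form, per-group averages
    coef = np.stack([y[:, labels.to_numpy() == g].mean(axis=1) for g in levels], axis=1)
    fitted = coef @ X.T
    resid = y - fitted
    df_res = y.shape[1] - len(levels)
    if df_res <= 0:
        raise ValueError("no residual degrees of freedom: need more samples than groups")
    sigma = np.sqrt((resid**2).sum(axis=1) / df_res)

    # mean log2-count and fitted log2-count (shift log2-CPM back to count scale)
    log2_offset = np.log2(lib.to_numpy() + 1.0).mean() - np.log2(1e6)
    sx = y.mean(axis=1) + log2_offset
    sy = np.sqrt(sigma)
    lo = lowess(sy, sx, frac=span, return_sorted=True)
    lx, ly = lo[:, 0], lo[:, 1]
    floor = ly[ly > 0].min() if (ly > 0).any() else 1e-4
    ly = np.maximum(ly, floor)

    def trend(x: np.ndarray) -> np.ndarray:
        return np.interp(x, lx, ly)  # constant extrapolation beyond the range

    fitted_count = fitted + (np.log2(lib.to_numpy() + 1.0) - np.log2(1e6))[None, :]
    w = trend(fitted_count) ** -4
    idx, cols = counts.genes, counts.samples
    return VoomFit(
        pd.DataFrame(y, index=idx, columns=cols),
        pd.DataFrame(w, index=idx, columns=cols),
        trend,
        labels,
    )


def fit_linear_models(fit: VoomFit) -> LinearFit:
    """Gene-wise weighted least squares on the group-means design.

    Returns group-mean estimates, residual variances with their shared
    residual degrees of freedom, and the unscaled coefficient covariance
    needed to form contrast standard errors.
    """
    X, levels = _design_matrix(fit.groups)
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is rank deficient")
    df_res = n - p
    y = fit.y.to_numpy()
    w = fit.weights.to_numpy()
    G = y.shape[0]
    coef = np.empty((G, p))
    cov = np.empty((G, p, p))
    s2 = np.empty(G)
    for g in range(G):
        Wx = X * w[g][:, None]
        xtwx = X.T @ Wx
        xtwy = Wx.T @ y[g]
        ci = np.linalg.inv(xtwx)
        b = ci @ xtwy
        r = y[g] - X @ b
        coef[g] = b
        cov[g] = ci
        s2[g] = float(np.sum(w[g] * r * r) / df_res)
    idx = fit.y.index
    return LinearFit(
        pd.DataFrame(coef, index=idx, columns=list(levels)),
        pd.Series(s2, index=idx),
        df_res,
        cov,
        levels,
        pd.Series(y.mean(axis=1), index=idx),
    )


def _trigamma_inverse(y: float) -> float:
    # Newton iteration on trigamma(x) = y; trigamma is convex decreasing.
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif) / x < 1e-10:
            break
    return x


def ebayes_moderate(s2: pd.Series, df: float | Sequence[float]) -> ModerationState:
    """Shrink gene variances toward a scaled-F prior fitted by moment matching.

    With ``z = log s^2``, the prior degrees of freedom ``d0`` and prior
    variance ``s0^2`` solve the digamma/trigamma moment equations of the
    implied scaled-F distribution; the trigamma equation is solved by
    Newton iteration.  Identical variances (zero excess spread) give
    ``d0 = inf`` and every posterior equals the common value.
    """
    if len(s2) < 2:
        raise ValueError("need at least two genes to moderate variances")
    d = np.broadcast_to(np.asarray(df, dtype=float), (len(s2),))
    if (d <= 0).any():
        raise ValueError("residual degrees of freedom must be positive")
    s2v = s2.to_numpy(dtype=float)
    ok = s2v > 0
    if ok.sum() < 2:
        raise ValueError("need at least two positive variances")
    z = np.log(s2v[ok])
    e = z - special.digamma(d[ok] / 2.0) + np.log(d[ok] / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(np.mean(special.polygamma(1, d[ok] / 2.0)))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s02 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        # no excess spread beyond sampling noise: infinite prior df, and the
        # common variance is simply the average
        d0 = np.inf
        s02 = float(np.mean(s2v[ok]))
    if np.isinf(d0):
        post = np.full(len(s2), s02)
    else:
        post = (d0 * s02 + d * s2v) / (d0 + d)
    return ModerationState(s2, float(d[0]), d0, s02, pd.Series(post, index=s2.index))


def bh_adjust(p: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order preserving)."""
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        return arr.copy()
    if np.isnan(arr).any() or (arr < 0).any() or (arr > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def contrast_de(
    lmfit: LinearFit,
    moderation: ModerationState,
    numerator: str,
    denominator: str,
) -> DEResult:
    """Moderated-t table for the contrast ``numerator - denominator``.

    log2fc > 0 means higher expression in the numerator group.  The t
    statistic uses the posterior variance and ``df_residual + df_prior``
    degrees of freedom.
    """
    for g in (numerator, denominator):
        if g not in lmfit.groups:
            raise ValueError(f"group {g!r} not in fitted design {lmfit.groups}")
    c = np.array([1.0 if g == numerator else (-1.0 if g == denominator else 0.0) for g in lmfit.groups])
    logfc = lmfit.coef.to_numpy() @ c
    unscaled = np.sqrt(np.einsum("i,gij,j->g", c, lmfit.cov_unscaled, c))
    se = unscaled * np.sqrt(moderation.s2_post.to_numpy())
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, logfc / se, 0.0)
    df_total = lmfit.df_residual + moderation.df_prior
    if np.isinf(df_total):
        pvals = 2.0 * stats.norm.sf(np.abs(t))
    else:
        pvals = 2.0 * stats.t.sf(np.abs(t), df_total)
    table = pd.DataFrame(
        {
            "log2fc": logfc,
            "t": t,
            "pvalue": pvals,
            "adj_pvalue": bh_adjust(pvals),
            "mean_expr": lmfit.amean.to_numpy(),
        },
        index=lmfit.coef.index,
    )
    return DEResult(table, (numerator, denominator))


def run_voom_de(
    counts: CountMatrix,
    groups: pd.Series | str,
    contrast: tuple[str, str],
    factors: NormalizationFactors | None = None,
) -> DEResult:
    """Convenience chain: voom -> WLS -> moderation -> one contrast."""
    fit = voom_transform(counts, groups, factors)
    lmf = fit_linear_models(fit)
    mod = ebayes_moderate(lmf.s2, lmf.df_residual)
    return contrast_de(lmf, mod, *contrast)


def de_genes(
    res: DEResult,
    alpha: float = 0.01,
    fc_threshold: float | None = None,
) -> tuple[set[str], set[str]]:
    """Split a DE table into up- and down-regulated gene sets.

    Significance is ``adjusted p < alpha``; with a fold-change threshold,
    up additionally requires ``2^log2fc > fc_threshold`` (strict) and down
    the symmetric condition.  ``fc_threshold=None`` imposes no FC gate, as
    used for the regional contrasts.
    """
    t = res.table
    sig = t["adj_pvalue"] < alpha
    if fc_threshold is None:
        up = sig & (t["log2fc"] > 0)
        down = sig & (t["log2fc"] < 0)
    else:
        lfc = np.log2(fc_threshold)
        up = sig & (t["log2fc"] > lfc)
        down = sig & (t["log2fc"] < -lfc)
    return set(t.index[up]), set(t.index[down])
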