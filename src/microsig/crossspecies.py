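"""Cross-species transcriptome comparison on rank-normalized expression.

Species datasets are mapped to a common human-gene key space (summing FPKM
where several species genes match one human gene), restricted to genes with
matching human homologues in every species, and rank-minmax normalized per
sample so expression levels are comparable across platforms and species.
On this merged matrix the module computes expressed-gene filters, pairwise
species correlations of mean profiles, and k-means conservation clusters of
signature gene lists.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import ExpressionMatrix
from .netclust import Clustering, kmeans_cluster
from .normalize import rank_minmax_normalize

__all__ = [
    "MergedSpeciesMatrix",
    "collapse_orthologues",
    "build_merged_matrix",
    "expressed_gene_filter",
    "species_pairwise_correlation",
    "conservation_clusters",
    "refilter_external_signature",
]


@dataclass(frozen=True)
class MergedSpeciesMatrix:
    """Rank-normalized expression over human genes shared by all species."""

    values: pd.DataFrame      # genes x samples, RANK01
    species_of: pd.Series     # sample -> species label
    species_means: pd.DataFrame  # genes x species, mean RANK01 per species

    def __post_init__(self) -> None:
        v = self.values.to_numpy()
        if (v < -1e-12).any() or (v > 1 + 1e-12).any():
            raise ValueError("merged matrix values must lie in [0, 1]")
        missing = [s for s in self.values.columns if s not in self.species_of.index]
        if missing:
            raise ValueError(f"samples without a species label: {missing}")

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(self.species_means.columns)

    @property
    def genes(self) -> pd.Index:
        return self.values.index


def collapse_orthologues(
    fpkm: ExpressionMatrix,
    ortho: Mapping[str, frozenset[str] | set[str]],
) -> tuple[ExpressionMatrix, int]:
    """Re-key a species FPKM matrix by human orthologue, summing duplicates.

    Every species gene contributes its FPKM to each human gene it maps to;
    genes absent from the relation or mapping to nothing are dropped, and
    the number dropped is returned alongside the collapsed matrix.
    """
    if not ortho:
        raise ValueError("orthologue relation is empty")
    rows: dict[str, np.ndarray] = {}
    dropped = 0
    vals = fpkm.values
    for gene in vals.index:
        targets = ortho.get(gene, frozenset())
        if not targets:
            dropped += 1
            continue
        row = vals.loc[gene].to_numpy(dtype=float)
        for h in targets:
            if h in rows:
                rows[h] = rows[h] + row
            else:
                rows[h] = row.copy()
    out = pd.DataFrame.from_dict(rows, orient="index", columns=vals.columns).sort_index()
    out.index.name = "human_gene"
    return ExpressionMatrix(out, fpkm.scale, fpkm.meta), dropped


def build_merged_matrix(
    datasets: Sequence[tuple[str, ExpressionMatrix]],
) -> MergedSpeciesMatrix:
    """Merge collapsed per-species FPKM matrices into one RANK01 matrix.

    Rows are restricted to human genes present in every species *before*
    rank normalization, so ranks are computed on the comparable gene set.
    """
    if len(datasets) < 2:
        raise ValueError("need at least two species")
    common: pd.Index | None = None
    for _, em in datasets:
        common = em.values.index if common is None else common.intersection(em.values.index)
    assert common is not None
    if len(common) == 0:
        raise ValueError("no human genes shared by all species")
    common = common.sort_values()
    blocks, species_of = [], {}
    for sp, em in datasets:
        blk = em.values.loc[common]
        blocks.append(blk)
        for s in blk.columns:
            if s in species_of:
                raise ValueError(f"duplicate sample id across species: {s!r}")
            species_of[s] = sp
    merged = pd.concat(blocks, axis=1)
    ranked = rank_minmax_normalize(ExpressionMatrix(merged, "FPKM"))
    sp_series = pd.Series(species_of)
    means = {
        sp: ranked.values[[s for s in ranked.samples if species_of[s] == sp]].mean(axis=1)
        for sp in dict.fromkeys(sp_series)
    }
    return MergedSpeciesMatrix(ranked.values, sp_series, pd.DataFrame(means))


def expressed_gene_filter(m: MergedSpeciesMatrix, thresh: float = 0.5) -> list[str]:
    """Genes whose mean rank expression exceeds ``thresh`` in >=1 species."""
    keep = (m.species_means > thresh).any(axis=1)
    return list(m.species_means.index[keep])


def species_pairwise_correlation(
    m: MergedSpeciesMatrix,
    species_a: str,
    species_b: str,
    thresh: float = 0.5,
) -> float:
    """Pearson r of the two species' mean rank profiles over genes highly
    expressed (mean > ``thresh``) in *both* species."""
    for sp in (species_a, species_b):
        if sp not in m.species:
            raise ValueError(f"species {sp!r} not in merged matrix {m.species}")
    ma, mb = m.species_means[species_a], m.species_means[species_b]
    qual = (ma > thresh) & (mb > thresh)
    if qual.sum() < 3:
        raise ValueError(f"only {int(qual.sum())} genes qualify; need >= 3")
    r = np.corrcoef(ma[qual], mb[qual])[0, 1]
    return float(r)


def conservation_clusters(
    m: MergedSpeciesMatrix,
    signature: Iterable[str],
    k: int = 5,
    seed: int = 0,
    conserved_thresh: float = 0.5,
) -> tuple[Clustering, pd.DataFrame, int]:
    """K-means clusters of signature genes on the merged RANK01 matrix.

    Returns the clustering, a per-cluster table of species-mean expression
    with a ``conserved`` flag (minimum species mean >= ``conserved_thresh``,
    i.e. the cluster is expressed in every species), and the count of
    signature genes dropped for lacking an orthologue in the merged matrix.
    """
    sig = list(dict.fromkeys(signature))
    present = [g for g in sig if g in m.values.index]
    dropped = len(sig) - len(present)
    if len(present) < k:
        raise ValueError(f"only {len(present)} signature genes in merged matrix; need >= {k}")
    clustering = kmeans_cluster(m.values.loc[present], k, seed)
    rows = []
    for cid in range(1, clustering.n_clusters + 1):
        members = clustering.members(cid)
        means = m.species_means.loc[members].mean(axis=0)
        rows.append(
            {
                "cluster": cid,
                "n_genes": len(members),
                **{f"mean_{sp}": float(means[sp]) for sp in m.species},
                "conserved": bool(means.min() >= conserved_thresh),
            }
        )
    return clustering, pd.DataFrame(rows).set_index("cluster"), dropped


def refilter_external_signature(
    de_table: pd.DataFrame,
    comparisons: Sequence[str],
    alpha: float = 0.001,
    fc: float = 2.0,
) -> set[str]:
    """Re-apply significance and fold-change gates to an external DE table.

    ``de_table`` must carry, for every comparison ``c`` in ``comparisons``,
    columns ``adj_pvalue_<c>`` and ``fc_<c>`` (linear fold change).  A gene
    is kept only if it meets ``adj p < alpha`` and ``FC > fc`` in every
    listed comparison.
    """
    if not comparisons:
        raise ValueError("no comparisons listed")
    keep = pd.Series(True, index=de_table.index)
    for c in comparisons:
        pc, fcc = f"adj_pvalue_{c}", f"fc_{c}"
        missing = [col for col in (pc, fcc) if col not in de_table.columns]
        if missing:
            raise ValueError(f"DE table missing column(s): {missing}")
        keep &= (de_table[pc] < alpha) & (de_table[fcc] > fc)
    return set(de_table.index[keep])
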