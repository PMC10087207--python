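"""Analysis parameter bundle.

Every numeric threshold used anywhere in the pipeline lives here, so a run
is fully described by one :class:`Params` instance plus the input paths and
a seed.  Defaults are the study settings: a gene must exceed 10 CPM in every
sample of at least one subgroup to enter the analysis; differential
expression is called at BH-adjusted p < 0.01 with fold-change gates of 4
(microglia vs. tissue) and 3 (microglia vs. macrophage); reference-atlas
exclusion removes genes over 2 FPKM in a non-microglial cell type unless
microglia exceed that cell type fourfold; gene co-expression graphs use
Pearson r >= 0.84 on genes with >= 1 FPKM, components of >= 10 nodes, and
Markov clustering at inflation 1.8; regional sample networks use r > 0.94;
the cross-species sample network uses r > 0.35 with k-nearest-neighbour 6 on
rank-normalized expression, an expressed-gene cutoff of 0.5, and k-means
with k = 5; over-representation analysis requires overlap >= 3, p < 0.01 and
fold enrichment >= 1.5; the external human signature is refiltered at
adjusted p < 0.001 and fold change > 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Any, Mapping


@dataclass(frozen=True)
class Params:
    # expression filter
    min_cpm: float = 10.0
    # differential expression
    alpha_de: float = 0.01
    fc_vs_tissue: float = 4.0
    fc_vs_macrophage: float = 3.0
    # reference-atlas exclusion (core signature)
    atlas_expr_thresh: float = 2.0
    atlas_fold_thresh: float = 4.0
    # regional analysis
    regional_lowexpr: float = 2.0
    regional_contam: float = 2.0
    # gene-gene co-expression network
    r_gene: float = 0.84
    min_fpkm_network: float = 1.0
    min_component: int = 10
    mcl_inflation: float = 1.8
    # sample-sample networks
    r_sample: float = 0.94
    r_species: float = 0.35
    knn: int = 6
    # cross-species comparison
    rank_expr_thresh: float = 0.5
    kmeans_k: int = 5
    conserved_thresh: float = 0.5
    # over-representation analysis
    ora_min_overlap: int = 3
    ora_p: float = 0.01
    ora_min_enrichment: float = 1.5
    # refilter of the external (fold-change derived) human signature
    galatro_alpha: float = 0.001
    galatro_fc: float = 2.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not v > 0:
                raise ValueError(f"parameter {f.name} must be positive, got {v!r}")
        for name in ("alpha_de", "ora_p", "galatro_alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {v!r}")

    def with_overrides(self, overrides: Mapping[str, Any] | None = None, **kw: Any) -> "Params":
        """Return a copy with the given fields replaced; unknown names raise."""
        merged = dict(overrides or {})
        merged.update(kw)
        known = {f.name for f in fields(self)}
        unknown = set(merged) - known
        if unknown:
            raise ValueError(f"unknown parameter(s): {sorted(unknown)}")
        return replace(self, **merged)

    def to_dict(self) -> dict[str, Any]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


DEFAULT_PARAMS = Params()
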