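"""Signature-derivation logic.

A cell population's core signature is the intersection of its upregulated
gene sets against two comparators (a systemic macrophage population and the
surrounding tissue), refined by a reference-atlas exclusion filter that
removes genes plausibly contributed by contaminating non-microglial cells.
The module also derives the complementary macrophage-enriched signature
(minus pan-immune markers), characterizes regional expression variation via
pairwise contrasts, and applies the regional contamination filter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .diffexpr import de_genes, run_voom_de
from .io import (
    CountMatrix,
    ExpressionMatrix,
    FilterStep,
    GeneSignature,
    ReferenceAtlas,
)
from .params import DEFAULT_PARAMS, Params

__all__ = [
    "RegionalTable",
    "atlas_exclusion",
    "core_signature",
    "macrophage_signature",
    "regional_variation",
    "regional_contamination_filter",
    "signature_overlap",
    "IG_PREFIXES",
]

# symbol-prefix heuristic for immunoglobulin-related genes; a user-supplied
# list always takes precedence
IG_PREFIXES = ("IGH", "IGK", "IGL", "JCHAIN")


@dataclass(frozen=True)
class RegionalTable:
    """Per regionally-variant gene: region mean FPKM, top region, and the
    pairwise contrasts in which it reached significance."""

    table: pd.DataFrame  # columns: mean_<region>..., top_region, contrasts
    regions: tuple[str, ...]

    def __post_init__(self) -> None:
        mean_cols = [f"mean_{r}" for r in self.regions]
        missing = [c for c in mean_cols + ["top_region", "contrasts"] if c not in self.table.columns]
        if missing:
            raise ValueError(f"regional table missing column(s): {missing}")
        if len(self.table):
            means = self.table[mean_cols]
            argmax = means.to_numpy().argmax(axis=1)
            top = [self.regions[i] for i in argmax]
            if list(self.table["top_region"]) != top:
                raise ValueError("top_region must be the argmax of the region means")

    @property
    def genes(self) -> pd.Index:
        return self.table.index

    def top_region_counts(self) -> pd.Series:
        return self.table["top_region"].value_counts()


def atlas_exclusion(
    genes: Iterable[str],
    atlas: ReferenceAtlas,
    expr_thresh: float = DEFAULT_PARAMS.atlas_expr_thresh,
    fold_thresh: float = DEFAULT_PARAMS.atlas_fold_thresh,
    strict_max: bool = False,
) -> tuple[list[str], dict[str, str]]:
    """Remove genes expressed by non-microglial reference cell types.

    A gene is removed iff, for some species and some non-microglial cell
    type, the reference expression exceeds ``expr_thresh`` FPKM *and*
    microglial expression in that species is less than ``fold_thresh`` times
    that cell type's expression.  Genes absent from the atlas cannot be
    assessed and are kept (flagged "unassessed").  ``strict_max=True``
    evaluates both conditions against the maximum non-microglial value per
    species instead of per cell type.
    """
    atlas.require_microglia()
    kept: list[str] = []
    removed: dict[str, str] = {}
    vals = atlas.values
    for gene in genes:
        if gene not in vals.index:
            kept.append(gene)
            removed.setdefault("__unassessed__", "")
            continue
        reason = None
        for sp in atlas.species:
            mg = float(vals.loc[gene, (sp, "microglia")])
            others = atlas.nonmicroglia_cell_types(sp)
            if strict_max and others:
                top_ct = max(others, key=lambda c: float(vals.loc[gene, (sp, c)]))
                others = (top_ct,)
            for ct in others:
                x = float(vals.loc[gene, (sp, ct)])
                if x > expr_thresh and mg < fold_thresh * x:
                    reason = f"{sp}:{ct} fpkm={x:.3g} microglia={mg:.3g}"
                    break
            if reason:
                break
        if reason:
            removed[gene] = reason
        else:
            kept.append(gene)
    removed.pop("__unassessed__", None)
    return kept, removed


def core_signature(
    up_vs_macrophage: Iterable[str],
    up_vs_tissue: Iterable[str],
    atlas: ReferenceAtlas,
    params: Params = DEFAULT_PARAMS,
    strict_max: bool = False,
) -> GeneSignature:
    """Derive the core microglial signature.

    Members are genes upregulated in microglia against *both* comparators
    that survive the reference-atlas exclusion.  Provenance records the
    intersection step and every atlas removal with the triggering cell.
    An empty intersection yields a valid empty signature.
    """
    a, b = set(up_vs_macrophage), set(up_vs_tissue)
    common = a & b
    step1 = FilterStep(
        "intersection",
        {"n_up_vs_macrophage": len(a), "n_up_vs_tissue": len(b), "n_common": len(common)},
        tuple(sorted((a | b) - common)),
    )
    kept, removed = atlas_exclusion(
        sorted(common), atlas, params.atlas_expr_thresh, params.atlas_fold_thresh, strict_max
    )
    step2 = FilterStep(
        "atlas_exclusion",
        {
            "expr_thresh": params.atlas_expr_thresh,
            "fold_thresh": params.atlas_fold_thresh,
            "strict_max": strict_max,
        },
        tuple(sorted(removed)),
        removed,
    )
    return GeneSignature(tuple(kept), "microglia", (step1, step2))


def macrophage_signature(
    up_in_macrophage: Iterable[str],
    immune_marker_sets: Mapping[str, Iterable[str]],
    ig_genes: Iterable[str] | None = None,
) -> GeneSignature:
    """Macrophage-enriched signature after removing pan-immune markers.

    Genes appearing in any non-macrophage immune marker set (T cell, B
    cell, plasma cell, ...) are removed, then immunoglobulin-related genes.
    When ``ig_genes`` is not supplied a symbol-prefix heuristic
    (:data:`IG_PREFIXES`) stands in, and the provenance labels it as such.
    """
    members = sorted(set(up_in_macrophage))
    steps: list[FilterStep] = []
    marker_removed: dict[str, str] = {}
    for name, genes in immune_marker_sets.items():
        hit = set(genes) & set(members)
        for g in hit:
            marker_removed.setdefault(g, name)
    members = [g for g in members if g not in marker_removed]
    steps.append(
        FilterStep(
            "immune_marker_exclusion",
            {"sets": sorted(immune_marker_sets)},
            tuple(sorted(marker_removed)),
            marker_removed,
        )
    )
    if ig_genes is None:
        ig_hit = {g for g in members if g.upper().startswith(IG_PREFIXES)}
        ig_params: dict[str, object] = {"mode": "prefix_heuristic", "prefixes": list(IG_PREFIXES)}
    else:
        ig_hit = set(ig_genes) & set(members)
        ig_params = {"mode": "explicit_list", "n_listed": len(set(ig_genes))}
    members = [g for g in members if g not in ig_hit]
    steps.append(FilterStep("immunoglobulin_exclusion", ig_params, tuple(sorted(ig_hit))))
    return GeneSignature(tuple(members), "macrophage", tuple(steps))


def regional_variation(
    fpkm: ExpressionMatrix,
    counts: CountMatrix,
    regions: pd.Series | str = "region",
    params: Params = DEFAULT_PARAMS,
) -> RegionalTable:
    """Find genes varying across brain regions via pairwise contrasts.

    Each pair of regions is contrasted with the moderated-t pipeline at
    ``alpha_de`` with no fold-change gate; the variant set is the union of
    genes significant in at least one contrast.  For each variant gene, the
    per-region mean FPKM is recorded and the region of highest mean noted.
    """
    labels = counts.labels(regions) if isinstance(regions, str) else regions.loc[counts.samples]
    levels = tuple(sorted(labels.unique()))
    if len(levels) < 3:
        raise ValueError(f"regional analysis needs >=3 regions, got {levels}")
    for r in levels:
        if (labels == r).sum() < 2:
            raise ValueError(f"region {r!r} has fewer than 2 samples")
    hits: dict[str, list[str]] = {}
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            a, b = levels[i], levels[j]
            pair_samples = labels.index[labels.isin([a, b])]
            sub = counts.subset_samples(list(pair_samples))
            res = run_voom_de(sub, labels.loc[pair_samples], (a, b))
            up, down = de_genes(res, params.alpha_de, fc_threshold=None)
            for g in up | down:
                hits.setdefault(g, []).append(f"{a}_vs_{b}")
    genes = sorted(hits)
    mean_cols = {}
    for r in levels:
        cols = labels.index[labels == r]
        cols = [c for c in cols if c in fpkm.samples]
        mean_cols[f"mean_{r}"] = fpkm.values.loc[genes, cols].mean(axis=1)
    table = pd.DataFrame(mean_cols, index=pd.Index(genes, name="gene"))
    if len(table):
        argmax = table.to_numpy().argmax(axis=1)
        table["top_region"] = [levels[i] for i in argmax]
    else:
        table["top_region"] = pd.Series(dtype=str)
    table["contrasts"] = [",".join(sorted(hits[g])) for g in genes]
    return RegionalTable(table, levels)


def regional_contamination_filter(
    table: RegionalTable,
    atlas: ReferenceAtlas,
    thresh: float = DEFAULT_PARAMS.regional_contam,
) -> RegionalTable:
    """Drop regionally-variant genes likely driven by contaminating cells.

    A gene is dropped iff, in some atlas species, microglial expression is
    below ``thresh`` FPKM while some non-microglial cell type exceeds it.
    Genes absent from the atlas are retained.
    """
    atlas.require_microglia()
    vals = atlas.values
    keep = []
    for gene in table.genes:
        drop = False
        if gene in vals.index:
            for sp in atlas.species:
                mg = float(vals.loc[gene, (sp, "microglia")])
                if mg < thresh and any(
                    float(vals.loc[gene, (sp, ct)]) > thresh
                    for ct in atlas.nonmicroglia_cell_types(sp)
                ):
                    drop = True
                    break
        keep.append(not drop)
    return RegionalTable(table.table.loc[keep], table.regions)


def signature_overlap(
    a: GeneSignature | Iterable[str],
    b: GeneSignature | RegionalTable | Iterable[str],
) -> tuple[set[str], int, int]:
    """Intersection of two gene collections plus both input sizes."""

    def as_set(x) -> set[str]:
        if isinstance(x, GeneSignature):
            return set(x.members)
        if isinstance(x, RegionalTable):
            return set(x.genes)
        return set(x)

    sa, sb = as_set(a), as_set(b)
    return sa & sb, len(sa), len(sb)
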