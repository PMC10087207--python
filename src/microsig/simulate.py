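"""Synthetic bulk RNA-seq data with planted ground truth.

The count simulator emulates the study design the pipeline targets: sorted
microglia from three brain regions (n = 8 each), alveolar macrophages
(n = 3) and whole hippocampal tissue (n = 4), with negative-binomial counts,
lognormal library-size variation and a 1/mean dispersion trend.  Gene
classes are planted at known effect sizes: core-signature genes (enriched
in microglia over both macrophages and tissue), atlas-contaminated genes
(same count profile but flagged by the reference atlas), tissue-shared
genes (enriched over macrophages only), macrophage-enriched genes, and
region-variable genes laid out along a rostro-caudal gradient with
cerebellum most distinct.  A companion simulator produces multi-species
FPKM datasets with one-to-many orthologue maps and planted
conserved/species-specific signature genes.  All simulators are pure
functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (
    NONMICROGLIA_CELL_TYPES,
    CountMatrix,
    ExpressionMatrix,
    GeneAnnotation,
    ReferenceAtlas,
)

__all__ = [
    "SimConfig",
    "MultiSpeciesConfig",
    "SimTruth",
    "simulate_counts",
    "simulate_atlas",
    "simulate_multispecies",
    "annotation_from_truth",
]

REGIONS = ("cerebellum", "frontal_cortex", "hippocampus")
# rostro-caudal neighbour used for the gradient: a region-enriched gene
# leaks a fraction of its shift into the adjacent region, making
# hippocampus intermediate and cerebellum most distinct
_GRADIENT_NEIGHBOUR = {
    "cerebellum": "hippocampus",
    "frontal_cortex": "hippocampus",
    "hippocampus": "frontal_cortex",
}


@dataclass(frozen=True)
class SimConfig:
    """Study-design and noise settings for the count simulator."""

    n_genes: int = 12000
    n_core: int = 250
    n_contaminated: int = 200
    n_tissue_shared: int = 150
    n_macrophage: int = 200
    n_regional: int = 150
    n_microglia_per_region: int = 8
    n_macrophage_samples: int = 3
    n_tissue_samples: int = 4
    regions: tuple[str, ...] = REGIONS
    # effect sizes (log2): 8-fold for cell-type enrichment; regional shifts
    # cycle through 2.3-4-fold so the significance gate is exercised near
    # its boundary
    core_log2fc: float = 3.0
    macrophage_log2fc: float = 3.0
    regional_log2fc: tuple[float, ...] = (1.2, 1.6, 2.0)
    regional_region_weights: tuple[float, ...] = (0.55, 0.35, 0.10)
    gradient_frac: float = 0.3
    # baseline expression (log2 relative abundance)
    baseline_mean: float = 4.0
    baseline_sd: float = 2.0
    planted_baseline_mean: float = 5.0
    planted_baseline_sd: float = 1.0
    planted_baseline_min: float = 3.5
    # library sizes and dispersion trend  phi = (a/mu + b) * lognormal(sd)
    mean_libsize: float = 5e6
    libsize_log_sd: float = 0.25
    dispersion_a: float = 3.0
    dispersion_b: float = 0.05
    dispersion_log_sd: float = 0.25

    def __post_init__(self) -> None:
        for name in (
            "n_genes",
            "n_core",
            "n_contaminated",
            "n_tissue_shared",
            "n_macrophage",
            "n_regional",
            "n_microglia_per_region",
            "n_macrophage_samples",
            "n_tissue_samples",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        planted = self.n_core + self.n_contaminated + self.n_tissue_shared + self.n_macrophage + self.n_regional
        if planted > self.n_genes:
            raise ValueError("planted gene classes exceed n_genes")
        if len(self.regional_region_weights) != len(self.regions):
            raise ValueError("one region weight per region required")


@dataclass(frozen=True)
class SimTruth:
    """Ground truth of one simulation: per-gene class labels and effects."""

    gene_table: pd.DataFrame   # class, baseline_log2, region, shift_log2, dispersion, length
    library_sizes: pd.Series
    seed: int
    config: object

    def genes_of(self, cls: str) -> list[str]:
        t = self.gene_table
        return list(t.index[t["class"] == cls])


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Negative binomial via gamma-Poisson; phi = 0 degrades to Poisson."""
    out = np.empty(mean.shape)
    zero = phi <= 0
    if zero.any():
        out[zero] = rng.poisson(mean[zero])
    if (~zero).any():
        lam = rng.gamma(shape=1.0 / phi[~zero], scale=mean[~zero] * phi[~zero])
        out[~zero] = rng.poisson(lam)
    return out.astype(np.int64)


def simulate_counts(config: SimConfig = SimConfig(), seed: int = 0) -> tuple[CountMatrix, SimTruth]:
    """Simulate the full study design; returns counts plus ground truth.

    Counts are NB(mean = libsize * q, dispersion phi) where the relative
    abundances ``q`` renormalize per sample after class shifts are applied
    on the log2 scale, and ``phi = (a/mu + b)`` with lognormal gene-level
    noise.  Identical (config, seed) pairs reproduce bit-identical output.
    """
    rng = np.random.default_rng(seed)
    cfg = config
    genes = [f"G{i:05d}" for i in range(cfg.n_genes)]

    # class assignment: planted classes first, remainder null
    classes = np.array(["null"] * cfg.n_genes, dtype=object)
    pos = 0
    blocks = [
        ("core", cfg.n_core),
        ("contaminated", cfg.n_contaminated),
        ("tissue_shared", cfg.n_tissue_shared),
        ("macrophage", cfg.n_macrophage),
        ("regional", cfg.n_regional),
    ]
    for name, n in blocks:
        classes[pos : pos + n] = name
        pos += n

    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, cfg.n_genes)
    planted = classes != "null"
    baseline[planted] = np.clip(
        rng.normal(cfg.planted_baseline_mean, cfg.planted_baseline_sd, planted.sum()),
        cfg.planted_baseline_min,
        None,
    )

    region_assign = np.array([""] * cfg.n_genes, dtype=object)
    shift = np.zeros(cfg.n_genes)
    is_reg = classes == "regional"
    n_reg = int(is_reg.sum())
    if n_reg:
        w = np.asarray(cfg.regional_region_weights, dtype=float)
        region_assign[is_reg] = rng.choice(cfg.regions, size=n_reg, p=w / w.sum())
        shift[is_reg] = np.resize(cfg.regional_log2fc, n_reg)
    shift[classes == "core"] = cfg.core_log2fc
    shift[classes == "contaminated"] = cfg.core_log2fc
    shift[classes == "tissue_shared"] = cfg.core_log2fc
    shift[classes == "macrophage"] = cfg.macrophage_log2fc

    # samples
    sample_ids, subgroup, region_label, source = [], [], [], []
    for i in range(cfg.n_macrophage_samples):
        sample_ids.append(f"mac_{i+1}")
        subgroup.append("macrophage")
        region_label.append("")
        source.append("alveolar_macrophage")
    for r in cfg.regions:
        for i in range(cfg.n_microglia_per_region):
            sample_ids.append(f"mg_{r}_{i+1}")
            subgroup.append(f"microglia_{r}")
            region_label.append(r)
            source.append("microglia")
    for i in range(cfg.n_tissue_samples):
        sample_ids.append(f"tis_{i+1}")
        subgroup.append("tissue")
        region_label.append("hippocampus")
        source.append("hippocampus_tissue")
    meta = pd.DataFrame(
        {"subgroup": subgroup, "region": region_label, "cell_source": source},
        index=pd.Index(sample_ids, name="sample"),
    )

    # per-sample log2 shifts
    log2q = np.tile(baseline[:, None], (1, len(sample_ids)))
    for j, sid in enumerate(sample_ids):
        src, reg = source[j], region_label[j]
        in_microglia = src == "microglia"
        in_tissue = src == "hippocampus_tissue"
        in_mac = src == "alveolar_macrophage"
        if in_microglia:
            log2q[classes == "core", j] += shift[classes == "core"]
            log2q[classes == "contaminated", j] += shift[classes == "contaminated"]
            log2q[classes == "tissue_shared", j] += shift[classes == "tissue_shared"]
            full = is_reg & (region_assign == reg)
            log2q[full, j] += shift[full]
            neighbour = is_reg & (np.vectorize(_GRADIENT_NEIGHBOUR.get)(np.where(is_reg, region_assign, "cerebellum")) == reg) if n_reg else np.zeros(cfg.n_genes, bool)
            log2q[neighbour & ~full, j] += cfg.gradient_frac * shift[neighbour & ~full]
        elif in_tissue:
            log2q[classes == "tissue_shared", j] += shift[classes == "tissue_shared"]
        elif in_mac:
            log2q[classes == "macrophage", j] += shift[classes == "macrophage"]

    q = np.exp2(log2q)
    q /= q.sum(axis=0)[None, :]

    lib = np.round(
        cfg.mean_libsize * np.exp(rng.normal(0.0, cfg.libsize_log_sd, len(sample_ids)))
    )
    mu = q * lib[None, :]
    mu_mean = mu.mean(axis=1)
    phi_gene = (cfg.dispersion_a / np.maximum(mu_mean, 1e-8) + cfg.dispersion_b) * np.exp(
        rng.normal(0.0, cfg.dispersion_log_sd, cfg.n_genes)
    )
    counts = _nb_sample(rng, mu, np.tile(phi_gene[:, None], (1, len(sample_ids))))

    lengths = np.round(rng.uniform(500, 5000, cfg.n_genes))
    truth = SimTruth(
        pd.DataFrame(
            {
                "class": classes,
                "baseline_log2": baseline,
                "region": region_assign,
                "shift_log2": shift,
                "dispersion": phi_gene,
                "length": lengths,
            },
            index=pd.Index(genes, name="gene"),
        ),
        pd.Series(lib, index=sample_ids, name="library_size"),
        seed,
        cfg,
    )
    cm = CountMatrix(
        pd.DataFrame(counts, index=pd.Index(genes, name="gene"), columns=sample_ids), meta
    )
    return cm, truth


def annotation_from_truth(truth: SimTruth) -> GeneAnnotation:
    """Gene annotation (lengths) matching a simulated count matrix."""
    return GeneAnnotation(truth.gene_table["length"].astype(float))


def simulate_atlas(
    truth: SimTruth,
    species: Sequence[str] = ("human", "mouse"),
    noise_sd: float = 0.1,
) -> ReferenceAtlas:
    """Reference atlas consistent with the planted gene classes.

    Atlas-contaminated genes receive high non-microglial and low microglial
    FPKM in both species, so they fail both the core-signature exclusion
    rule and the regional contamination filter; every other gene gets an
    atlas-clean profile (microglia-high, non-microglia below threshold).
    Deterministic for a given truth (the atlas rng derives from its seed).
    """
    rng = np.random.default_rng(truth.seed + 1_000_003)
    genes = truth.gene_table.index
    contaminated = truth.gene_table["class"] == "contaminated"
    cols = pd.MultiIndex.from_product([list(species), ["microglia", *NONMICROGLIA_CELL_TYPES]])
    vals = pd.DataFrame(0.0, index=genes, columns=cols)
    n = len(genes)
    for sp in species:
        noise = lambda size: np.exp(rng.normal(0.0, noise_sd, size))  # noqa: E731
        mg = np.where(contaminated, 0.5, 25.0) * noise(n)
        vals[(sp, "microglia")] = mg
        for ct in NONMICROGLIA_CELL_TYPES:
            vals[(sp, ct)] = np.where(contaminated, 20.0, 0.5) * noise(n)
    return ReferenceAtlas(vals)


@dataclass(frozen=True)
class MultiSpeciesConfig:
    """Settings for the cross-species FPKM simulator."""

    n_human_genes: int = 2000
    n_conserved: int = 60
    n_species_specific: int = 40          # per species
    species: tuple[str, ...] = ("human", "mouse", "pig")
    samples_per_species: Mapping[str, int] = field(
        default_factory=lambda: {"human": 6, "mouse": 17, "pig": 6}
    )
    many_to_one_frac: float = 0.10        # human genes mapped by 2 species genes
    unmapped_frac: float = 0.05           # extra species genes with no human match
    shared_log_sd: float = 2.0            # spread of the shared latent (log2)
    species_dev_sd: float = 1.2           # species deviation for background genes
    conserved_dev_sd: float = 0.2
    sample_noise_sd: float = 0.5
    conserved_boost: float = 4.0
    specific_boost: float = 5.0
    specific_penalty: float = 4.0         # log2 suppression outside the home species

    def __post_init__(self) -> None:
        if len(self.species) < 2:
            raise ValueError("need at least two species")
        if self.n_conserved + self.n_species_specific * len(self.species) > self.n_human_genes:
            raise ValueError("planted cross-species classes exceed n_human_genes")
        for sp in self.species:
            if self.samples_per_species.get(sp, 0) < 1:
                raise ValueError(f"species {sp!r} needs at least one sample")


def simulate_multispecies(
    config: MultiSpeciesConfig = MultiSpeciesConfig(), seed: int = 0
) -> tuple[list[tuple[str, ExpressionMatrix]], dict[str, dict[str, frozenset[str]]], SimTruth]:
    """Simulate per-species FPKM matrices keyed by species gene ids.

    Background genes share a latent log2 profile with species deviations;
    conserved signature genes are high in every species with small
    deviations; species-specific genes are high in exactly one species.  A
    configurable fraction of human genes is represented by two species
    genes (splitting the FPKM, to exercise orthologue summing) and a
    fraction of species genes carries no human match.
    """
    rng = np.random.default_rng(seed)
    cfg = config
    hgenes = [f"HS{i:05d}" for i in range(cfg.n_human_genes)]
    classes = np.array(["background"] * cfg.n_human_genes, dtype=object)
    classes[: cfg.n_conserved] = "conserved"
    pos = cfg.n_conserved
    for sp in cfg.species:
        classes[pos : pos + cfg.n_species_specific] = f"specific_{sp}"
        pos += cfg.n_species_specific

    shared = rng.normal(2.0, cfg.shared_log_sd, cfg.n_human_genes)
    shared[classes == "conserved"] += cfg.conserved_boost

    matrices: list[tuple[str, ExpressionMatrix]] = []
    maps: dict[str, dict[str, frozenset[str]]] = {}
    for sp in cfg.species:
        dev_sd = np.where(classes == "conserved", cfg.conserved_dev_sd, cfg.species_dev_sd)
        dev = rng.normal(0.0, 1.0, cfg.n_human_genes) * dev_sd
        level = shared + dev
        level[classes == f"specific_{sp}"] += cfg.specific_boost
        for other in cfg.species:
            if other != sp:
                level[classes == f"specific_{other}"] -= cfg.specific_penalty
        nsamp = cfg.samples_per_species[sp]
        noise = rng.normal(0.0, cfg.sample_noise_sd, (cfg.n_human_genes, nsamp))
        fpkm_h = np.exp2(level[:, None] + noise)

        # orthologue map: most human genes 1:1, a fraction mapped by 2
        # species genes (FPKM split), plus unmapped extras
        n_two = int(round(cfg.many_to_one_frac * cfg.n_human_genes))
        two = set(rng.choice(cfg.n_human_genes, size=n_two, replace=False).tolist())
        rows, gids, rel = [], [], {}
        for i, h in enumerate(hgenes):
            if i in two:
                frac = rng.uniform(0.2, 0.8)
                for suffix, f in (("a", frac), ("b", 1.0 - frac)):
                    gid = f"{sp}_{h}_{suffix}"
                    gids.append(gid)
                    rows.append(fpkm_h[i] * f)
                    rel[gid] = frozenset({h})
            else:
                gid = f"{sp}_{h}"
                gids.append(gid)
                rows.append(fpkm_h[i])
                rel[gid] = frozenset({h})
        n_unmapped = int(round(cfg.unmapped_frac * cfg.n_human_genes))
        for u in range(n_unmapped):
            gid = f"{sp}_orphan{u:04d}"
            gids.append(gid)
            rows.append(np.exp2(rng.normal(2.0, 1.0) + rng.normal(0, cfg.sample_noise_sd, nsamp)))
            rel[gid] = frozenset()
        cols = [f"{sp}_s{j+1}" for j in range(nsamp)]
        df = pd.DataFrame(np.vstack(rows), index=gids, columns=cols)
        sp_meta = pd.DataFrame({"species": sp}, index=pd.Index(cols, name="sample"))
        matrices.append((sp, ExpressionMatrix(df, "FPKM", sp_meta)))
        maps[sp] = rel

    truth = SimTruth(
        pd.DataFrame({"class": classes}, index=pd.Index(hgenes, name="gene")),
        pd.Series(dtype=float),
        seed,
        cfg,
    )
    return matrices, maps, truth
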