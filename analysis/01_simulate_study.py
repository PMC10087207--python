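#!/usr/bin/env python
"""Generate the synthetic study that stands in for the deposited RNA-seq data.

Emulates the study design — alveolar macrophages (n=3), microglia from
cerebellum, frontal cortex and hippocampus (n=8 per region), hippocampal
whole tissue (n=4) — with 12,000 genes and planted ground truth: 250
core-signature genes, 200 atlas-contaminated genes, 150 tissue-shared
genes, 200 macrophage-enriched genes and 150 region-variable genes on a
rostro-caudal gradient.  Also generates the three-species FPKM datasets
with orthologue maps.  Inputs for the later steps land in scratch/study/;
a class summary goes to results/.
"""

from pathlib import Path

from microsig.io import write_atlas, write_count_matrix, write_expression_matrix, write_gmt, write_orthologue_map
from microsig.simulate import (
    MultiSpeciesConfig,
    SimConfig,
    annotation_from_truth,
    simulate_atlas,
    simulate_counts,
    simulate_multispecies,
)

SEED = 1
ROOT = Path(__file__).resolve().parents[1]
STUDY = ROOT / "scratch" / "study"
RESULTS = ROOT / "results"


def main() -> None:
    STUDY.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)

    cfg = SimConfig()
    counts, truth = simulate_counts(cfg, seed=SEED)
    write_count_matrix(counts, STUDY / "counts.tsv", STUDY / "meta.tsv")
    annotation_from_truth(truth).lengths.rename("length").to_frame().to_csv(
        STUDY / "annotation.tsv", sep="\t", index_label="gene"
    )
    write_atlas(simulate_atlas(truth), STUDY / "atlas.tsv")
    truth.gene_table.to_csv(STUDY / "truth.tsv", sep="\t", index_label="gene")
    # a minimal pan-immune marker GMT for the macrophage-signature filter
    write_gmt(
        {"tcell_markers": {"CD2", "CD8A"}, "bcell_markers": {"CD19", "PVRIG"}},
        STUDY / "immune.gmt",
    )

    ms_cfg = MultiSpeciesConfig()
    mats, maps, ms_truth = simulate_multispecies(ms_cfg, seed=SEED)
    for sp, em in mats:
        write_expression_matrix(em, STUDY / f"fpkm_{sp}.tsv")
        write_orthologue_map(maps[sp], STUDY / f"orthologues_{sp}.tsv")
    ms_truth.gene_table.to_csv(STUDY / "truth_multispecies.tsv", sep="\t", index_label="gene")

    summary = truth.gene_table["class"].value_counts().rename("n_genes").to_frame()
    summary.to_csv(RESULTS / "01_planted_classes.tsv", sep="\t", index_label="class")
    print(f"simulated {counts.counts.shape[0]} genes x {counts.counts.shape[1]} samples (seed {SEED})")
    print(summary)
    print(f"inputs in {STUDY}")


if __name__ == "__main__":
    main()
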