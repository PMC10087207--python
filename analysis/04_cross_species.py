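#!/usr/bin/env python
"""Compare microglial transcriptomes across species on rank-normalized data.

Collapses each species' FPKM matrix onto human orthologues (summing where
several genes map to one human gene), restricts to genes shared by all
species, rank-minmax normalizes per sample, then: filters to genes with
mean normalized expression >0.5 in at least one species, computes pairwise
species correlations on genes expressed by both, builds the sample network
(r>0.35, knn 6) and clusters it, and runs k-means (k=5) conservation
clustering of the planted conserved + pig-specific signature.  Reads
scratch/study/; writes tables to results/.
"""

from pathlib import Path

import pandas as pd

from microsig.crossspecies import (
    build_merged_matrix,
    collapse_orthologues,
    conservation_clusters,
    expressed_gene_filter,
    species_pairwise_correlation,
)
from microsig.io import ExpressionMatrix, read_expression_matrix, read_orthologue_map
from microsig.netclust import mcl_cluster, sample_graph
from microsig.params import DEFAULT_PARAMS as P

ROOT = Path(__file__).resolve().parents[1]
STUDY = ROOT / "scratch" / "study"
RESULTS = ROOT / "results"
SEED = 1
SPECIES = ("human", "mouse", "pig")


def main() -> None:
    truth = pd.read_csv(STUDY / "truth_multispecies.tsv", sep="\t", index_col=0)
    datasets = []
    for sp in SPECIES:
        em = read_expression_matrix(STUDY / f"fpkm_{sp}.tsv", "FPKM")
        rel = read_orthologue_map(STUDY / f"orthologues_{sp}.tsv")
        collapsed, dropped = collapse_orthologues(em, rel)
        print(f"{sp}: {em.values.shape[0]} genes -> {collapsed.values.shape[0]} human-keyed "
              f"({dropped} unmapped dropped)")
        datasets.append((sp, collapsed))
    merged = build_merged_matrix(datasets)
    print(f"merged matrix: {merged.values.shape[0]} genes shared by all species, "
          f"{merged.values.shape[1]} samples")

    expressed = expressed_gene_filter(merged, P.rank_expr_thresh)
    print(f"genes with mean rank expression >{P.rank_expr_thresh} in >=1 species: {len(expressed)}")

    rows = []
    for i in range(len(SPECIES)):
        for j in range(i + 1, len(SPECIES)):
            r = species_pairwise_correlation(merged, SPECIES[i], SPECIES[j], P.rank_expr_thresh)
            rows.append((f"{SPECIES[i]}_vs_{SPECIES[j]}", round(r, 4)))
            print(f"Pearson r {SPECIES[i]} vs {SPECIES[j]} (genes >0.5 in both): {r:.3f}")
    pd.DataFrame(rows, columns=["pair", "pearson_r"]).to_csv(
        RESULTS / "04_species_correlations.tsv", sep="\t", index=False
    )

    net = sample_graph(ExpressionMatrix(merged.values, "RANK01"), expressed,
                       r_min=P.r_species, knn=P.knn)
    cl = mcl_cluster(net, P.mcl_inflation)
    assign = pd.DataFrame({"cluster": cl.assignments, "species": merged.species_of})
    assign.to_csv(RESULTS / "04_sample_clusters.tsv", sep="\t", index_label="sample")
    pure = all(len(set(assign.loc[assign.cluster == c, "species"])) == 1
               for c in assign.cluster.unique())
    print(f"sample network: {cl.n_clusters} clusters; single-species clusters: {pure}")

    sig = (list(truth.index[truth["class"] == "conserved"])
           + list(truth.index[truth["class"] == "specific_pig"]))
    clustering, table, dropped = conservation_clusters(merged, sig, P.kmeans_k, SEED,
                                                       P.conserved_thresh)
    table.to_csv(RESULTS / "04_conservation_clusters.tsv", sep="\t")
    clustering.assignments.rename("cluster").to_frame().to_csv(
        RESULTS / "04_conservation_assignments.tsv", sep="\t", index_label="gene"
    )
    print(f"conservation clustering of {len(sig)} signature genes ({dropped} without orthologue):")
    print(table.round(3))


if __name__ == "__main__":
    main()
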