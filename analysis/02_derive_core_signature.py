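#!/usr/bin/env python
"""Derive the core microglial signature and the macrophage counter-signature.

Filters genes to >10 CPM in every sample of at least one subgroup, runs the
precision-weighted moderated-t contrasts (microglia vs. alveolar
macrophages at FC>3; hippocampal microglia vs. hippocampal tissue at FC>4;
both at adjusted p<0.01), intersects the upregulated sets, and applies the
reference-atlas exclusion filter.  Reports how well the planted truth is
recovered.  Reads scratch/study/; writes signature lists and a derivation
summary to results/.
"""

from pathlib import Path

import pandas as pd

from microsig.diffexpr import de_genes, run_voom_de
from microsig.io import read_atlas, read_count_matrix, read_gmt
from microsig.normalize import subgroup_expression_filter
from microsig.params import DEFAULT_PARAMS as P
from microsig.signatures import core_signature, macrophage_signature

ROOT = Path(__file__).resolve().parents[1]
STUDY = ROOT / "scratch" / "study"
RESULTS = ROOT / "results"


def main() -> None:
    counts = read_count_matrix(STUDY / "counts.tsv", STUDY / "meta.tsv")
    atlas = read_atlas(STUDY / "atlas.tsv")
    immune = read_gmt(STUDY / "immune.gmt")
    truth = pd.read_csv(STUDY / "truth.tsv", sep="\t", index_col=0)

    mask = subgroup_expression_filter(counts, "subgroup", P.min_cpm)
    filt = counts.subset_genes(list(mask.index[mask]))
    print(f"expression filter: {int(mask.sum())}/{len(mask)} genes kept (>10 CPM in a full subgroup)")

    src = counts.meta["cell_source"]
    cells = list(src.index[src.isin(["microglia", "alveolar_macrophage"])])
    res_mac = run_voom_de(filt.subset_samples(cells), src.loc[cells],
                          ("microglia", "alveolar_macrophage"))
    up_mac, down_mac = de_genes(res_mac, P.alpha_de, P.fc_vs_macrophage)
    hip = list(src.index[(src == "microglia") & (counts.meta["region"] == "hippocampus")])
    tis = list(src.index[src == "hippocampus_tissue"])
    res_tis = run_voom_de(filt.subset_samples(hip + tis), src.loc[hip + tis],
                          ("microglia", "hippocampus_tissue"))
    up_tis, _ = de_genes(res_tis, P.alpha_de, P.fc_vs_tissue)
    print(f"up in microglia vs macrophage (FC>{P.fc_vs_macrophage:g}): {len(up_mac)}")
    print(f"up in microglia vs tissue (FC>{P.fc_vs_tissue:g}): {len(up_tis)}")
    print(f"common to both contrasts: {len(up_mac & up_tis)}")

    sig = core_signature(up_mac, up_tis, atlas, P)
    removed = next(s for s in sig.provenance if s.name == "atlas_exclusion").removed
    print(f"atlas exclusion removed {len(removed)}; core signature = {len(sig)} genes")
    mac_sig = macrophage_signature(down_mac, immune)
    print(f"macrophage signature after immune-marker exclusion: {len(mac_sig)} genes")

    members = set(sig.members)
    core_truth = set(truth.index[truth["class"] == "core"])
    contam = set(truth.index[truth["class"] == "contaminated"])
    print(f"planted core recovered: {len(members & core_truth)}/{len(core_truth)}; "
          f"contaminants admitted: {len(members & contam)}")

    sig.to_json(RESULTS / "02_core_signature.provenance.json")
    pd.Series(sorted(members), name="gene").to_csv(
        RESULTS / "02_core_signature.tsv", sep="\t", index=False
    )
    pd.Series(sorted(mac_sig.members), name="gene").to_csv(
        RESULTS / "02_macrophage_signature.tsv", sep="\t", index=False
    )
    res_mac.table.to_csv(STUDY / "de_microglia_vs_macrophage.tsv", sep="\t", index_label="gene")
    res_tis.table.to_csv(STUDY / "de_microglia_vs_tissue.tsv", sep="\t", index_label="gene")
    summary = pd.DataFrame(
        [
            ("genes_after_expression_filter", int(mask.sum())),
            ("up_vs_macrophage", len(up_mac)),
            ("up_vs_tissue", len(up_tis)),
            ("common_both_contrasts", len(up_mac & up_tis)),
            ("atlas_excluded", len(removed)),
            ("core_signature_size", len(sig)),
            ("macrophage_signature_size", len(mac_sig)),
            ("planted_core_recovered", len(members & core_truth)),
            ("contaminants_admitted", len(members & contam)),
        ],
        columns=["quantity", "value"],
    )
    summary.to_csv(RESULTS / "02_signature_summary.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
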