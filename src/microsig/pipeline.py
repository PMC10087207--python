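"""End-to-end pipeline orchestration with provenance export.

Runs the stages in analysis order — expression filter, TMM, differential
expression, signature derivation, regional characterization, co-expression
networks, and (when multi-species inputs are supplied) the cross-species
comparison — writing every table as TSV with a provenance header (tool
version, config hash, seed).  Deterministic given config + seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .crossspecies import (
    build_merged_matrix,
    collapse_orthologues,
    conservation_clusters,
    expressed_gene_filter,
    species_pairwise_correlation,
)
from .diffexpr import de_genes, run_voom_de
from .io import (
    CountMatrix,
    ExpressionMatrix,
    read_atlas,
    read_count_matrix,
    read_expression_matrix,
    read_gene_annotation,
    read_gmt,
    read_orthologue_map,
)
from .netclust import gene_gene_graph, hypergeom_ora, mcl_cluster, sample_graph
from .normalize import compute_fpkm, subgroup_expression_filter, tmm_factors
from .params import DEFAULT_PARAMS, Params
from .signatures import (
    core_signature,
    macrophage_signature,
    regional_contamination_filter,
    regional_variation,
)

log = logging.getLogger("microsig")

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and its cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class RunConfig:
    counts: str
    meta: str
    annotation: str
    atlas: str
    out_dir: str
    seed: int = 0
    immune_gmt: str | None = None
    # optional cross-species inputs: species -> (fpkm tsv, orthologue map tsv)
    species_inputs: Mapping[str, tuple[str, str]] = field(default_factory=dict)
    cross_species_signature: tuple[str, ...] = ()
    params: Params = DEFAULT_PARAMS
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text())
        params = DEFAULT_PARAMS.with_overrides(doc.pop("params", {}) or {})
        species = {
            sp: (v["fpkm"], v["orthologues"]) for sp, v in (doc.pop("species_inputs", {}) or {}).items()
        }
        sig = tuple(doc.pop("cross_species_signature", []) or [])
        return cls(params=params, species_inputs=species, cross_species_signature=sig, **doc)

    def digest(self) -> str:
        # out_dir and log level do not affect the analysis and are excluded,
        # so reruns into different directories hash identically
        payload = {
            k: (dict(v) if isinstance(v, Mapping) else v)
            for k, v in self.__dict__.items()
            if k not in ("params", "out_dir", "log_level")
        }
        payload["params"] = self.params.to_dict()
        return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _header(cfg: RunConfig) -> str:
    return f"# microsig {__version__} config_hash={cfg.digest()} seed={cfg.seed}\n"


def _write_tsv(df: pd.DataFrame, path: Path, cfg: RunConfig, index_label: str = "gene") -> None:
    with open(path, "w") as fh:
        fh.write(_header(cfg))
        df.to_csv(fh, sep="\t", index_label=index_label)


def _write_gene_list(genes, path: Path, cfg: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(_header(cfg))
        fh.write("gene\n")
        for g in genes:
            fh.write(f"{g}\n")


def _stage(name: str):
    def deco(fn):
        def wrapper(*a, **kw):
            try:
                return fn(*a, **kw)
            except PipelineError:
                raise
            except Exception as e:  # noqa: BLE001 - re-raised with stage context
                raise PipelineError(name, e) from e

        return wrapper

    return deco


def _log_filter(name: str, n_in: int, n_kept: int) -> None:
    log.info("%s: input=%d removed=%d retained=%d", name, n_in, n_in - n_kept, n_kept)


@_stage("load_inputs")
def _load(cfg: RunConfig):
    for p in (cfg.counts, cfg.meta, cfg.annotation, cfg.atlas):
        if not Path(p).exists():
            raise FileNotFoundError(p)
    counts = read_count_matrix(cfg.counts, cfg.meta)
    annot = read_gene_annotation(cfg.annotation)
    atlas = read_atlas(cfg.atlas)
    immune = read_gmt(cfg.immune_gmt) if cfg.immune_gmt else {}
    return counts, annot, atlas, immune


def run_pipeline(cfg: RunConfig) -> dict[str, Any]:
    """Run every stage and write the output bundle under ``cfg.out_dir``.

    Returns a dict of in-memory results keyed by stage for programmatic use.
    """
    logging.basicConfig(level=cfg.log_level)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(
        yaml.safe_dump(
            {
                **{k: v for k, v in cfg.__dict__.items() if k not in ("params", "species_inputs")},
                "species_inputs": {k: list(v) for k, v in cfg.species_inputs.items()},
                "params": cfg.params.to_dict(),
                "config_hash": cfg.digest(),
            },
            sort_keys=True,
        )
    )
    p = cfg.params
    results: dict[str, Any] = {}

    counts, annot, atlas, immune = _load(cfg)

    @_stage("expression_filter")
    def stage_filter():
        mask = subgroup_expression_filter(counts, "subgroup", p.min_cpm)
        _log_filter("subgroup_expression_filter", len(mask), int(mask.sum()))
        return counts.subset_genes(list(mask.index[mask]))

    filtered = stage_filter()

    @_stage("tmm")
    def stage_tmm():
        return tmm_factors(filtered)

    factors = stage_tmm()
    results["tmm_factors"] = factors

    @_stage("fpkm")
    def stage_fpkm():
        return compute_fpkm(counts, annot)

    fpkm = stage_fpkm()

    @_stage("differential_expression")
    def stage_de():
        src = counts.meta["cell_source"]
        cell_samples = list(src.index[src.isin(["microglia", "alveolar_macrophage"])])
        mg_vs_mac = run_voom_de(
            filtered.subset_samples(cell_samples),
            src.loc[cell_samples],
            ("microglia", "alveolar_macrophage"),
            factors=None,
        )
        hip = list(src.index[(src == "microglia") & (counts.meta["region"] == "hippocampus")])
        tis = list(src.index[src == "hippocampus_tissue"])
        mg_vs_tissue = run_voom_de(
            filtered.subset_samples(hip + tis),
            src.loc[hip + tis],
            ("microglia", "hippocampus_tissue"),
            factors=None,
        )
        return mg_vs_mac, mg_vs_tissue

    mg_vs_mac, mg_vs_tissue = stage_de()
    _write_tsv(mg_vs_mac.table, out / "de_microglia_vs_macrophage.tsv", cfg)
    _write_tsv(mg_vs_tissue.table, out / "de_microglia_vs_tissue.tsv", cfg)
    results["de"] = {"microglia_vs_macrophage": mg_vs_mac, "microglia_vs_tissue": mg_vs_tissue}

    @_stage("signatures")
    def stage_signatures():
        up_mac, down_mac = de_genes(mg_vs_mac, p.alpha_de, p.fc_vs_macrophage)
        up_tis, _ = de_genes(mg_vs_tissue, p.alpha_de, p.fc_vs_tissue)
        log.info("up in microglia vs macrophage: %d; vs tissue: %d", len(up_mac), len(up_tis))
        core = core_signature(up_mac, up_tis, atlas, p)
        _log_filter("atlas_exclusion", len(up_mac & up_tis), len(core))
        mac = macrophage_signature(down_mac, immune)
        _log_filter("immune_marker_exclusion", len(down_mac), len(mac))
        return core, mac

    core, mac = stage_signatures()
    _write_gene_list(core.members, out / "core_signature.tsv", cfg)
    core.to_json(out / "core_signature.provenance.json")
    _write_gene_list(mac.members, out / "macrophage_signature.tsv", cfg)
    mac.to_json(out / "macrophage_signature.provenance.json")
    results["core_signature"] = core
    results["macrophage_signature"] = mac

    @_stage("regional")
    def stage_regional():
        src = counts.meta["cell_source"]
        mg = list(src.index[src == "microglia"])
        table = regional_variation(fpkm, filtered.subset_samples(mg), "region", p)
        filtered_table = regional_contamination_filter(table, atlas, p.regional_contam)
        _log_filter("regional_contamination_filter", len(table.genes), len(filtered_table.genes))
        return filtered_table

    regional = stage_regional()
    _write_tsv(regional.table, out / "regional_variation.tsv", cfg)
    results["regional"] = regional

    @_stage("networks")
    def stage_networks():
        src = counts.meta["cell_source"]
        mg = list(src.index[src == "microglia"])
        mg_fpkm = ExpressionMatrix(fpkm.values[mg], "FPKM", counts.meta.loc[mg])
        gg = gene_gene_graph(mg_fpkm, p.r_gene, p.min_fpkm_network, p.min_component)
        clustering = mcl_cluster(gg, p.mcl_inflation) if gg.graph.number_of_nodes() else None
        ora = None
        if clustering is not None:
            cluster_sets = {
                f"cluster_{cid}": clustering.members(cid)
                for cid in range(1, clustering.n_clusters + 1)
            }
            query = [g for g in regional.genes if g in gg.graph.nodes]
            if query:
                ora = hypergeom_ora(
                    query, list(gg.graph.nodes), cluster_sets,
                    p.ora_min_overlap, p.ora_p, p.ora_min_enrichment,
                )
        log_fpkm = ExpressionMatrix(
            pd.DataFrame(
                np.log2(mg_fpkm.values.to_numpy() + 1.0),
                index=mg_fpkm.genes, columns=mg_fpkm.samples,
            ),
            "LOG2FPKM", mg_fpkm.meta,
        )
        sg = sample_graph(log_fpkm, list(regional.genes), p.r_sample) if len(regional.genes) >= 2 else None
        return gg, clustering, ora, sg

    gg, gene_clusters, ora, sg = stage_networks()
    _write_tsv(gg.edge_list(), out / "gene_network_edges.tsv", cfg, index_label="edge")
    if gene_clusters is not None:
        _write_tsv(gene_clusters.assignments.rename("cluster").to_frame(), out / "gene_clusters.tsv", cfg)
    if ora is not None:
        _write_tsv(ora, out / "regional_cluster_ora.tsv", cfg, index_label="set")
    if sg is not None:
        _write_tsv(sg.edge_list(), out / "sample_network_edges.tsv", cfg, index_label="edge")
    results["gene_network"] = gg
    results["gene_clusters"] = gene_clusters
    results["regional_ora"] = ora
    results["sample_network"] = sg

    if cfg.species_inputs:

        @_stage("cross_species")
        def stage_cross():
            datasets = []
            for sp, (fpkm_path, map_path) in cfg.species_inputs.items():
                em = read_expression_matrix(fpkm_path, "FPKM")
                rel = read_orthologue_map(map_path)
                collapsed, dropped = collapse_orthologues(em, rel)
                log.info("%s: collapsed to %d human genes (%d unmapped dropped)", sp, len(collapsed.genes), dropped)
                datasets.append((sp, collapsed))
            merged = build_merged_matrix(datasets)
            expressed = expressed_gene_filter(merged, p.rank_expr_thresh)
            _log_filter("expressed_gene_filter", len(merged.genes), len(expressed))
            corrs = {}
            sps = merged.species
            for i in range(len(sps)):
                for j in range(i + 1, len(sps)):
                    corrs[f"{sps[i]}_vs_{sps[j]}"] = species_pairwise_correlation(
                        merged, sps[i], sps[j], p.rank_expr_thresh
                    )
            net = sample_graph(
                ExpressionMatrix(merged.values, "RANK01"), expressed, p.r_species, p.knn
            )
            cons = None
            if cfg.cross_species_signature:
                clustering, table, dropped = conservation_clusters(
                    merged, cfg.cross_species_signature, p.kmeans_k, cfg.seed, p.conserved_thresh
                )
                cons = (clustering, table, dropped)
            return merged, expressed, corrs, net, cons

        merged, expressed, corrs, net, cons = stage_cross()
        _write_gene_list(expressed, out / "crossspecies_expressed_genes.tsv", cfg)
        _write_tsv(
            pd.Series(corrs, name="pearson_r").to_frame(), out / "species_correlations.tsv", cfg,
            index_label="pair",
        )
        _write_tsv(net.edge_list(), out / "crossspecies_sample_edges.tsv", cfg, index_label="edge")
        if cons is not None:
            clustering, table, dropped = cons
            _write_tsv(table, out / "conservation_clusters.tsv", cfg, index_label="cluster")
            _write_tsv(
                clustering.assignments.rename("cluster").to_frame(),
                out / "conservation_assignments.tsv", cfg,
            )
        results["cross_species"] = {
            "merged": merged,
            "expressed": expressed,
            "correlations": corrs,
            "sample_network": net,
            "conservation": cons,
        }

    log.info("pipeline complete: outputs in %s", out)
    return results
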