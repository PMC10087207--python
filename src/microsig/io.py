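"""Domain containers and readers/writers for every external format the
pipeline touches.

All tabular exchange is plain TSV (UTF-8, header row, no quoting of
identifiers); gene sets travel as GMT; signature provenance is exported as
JSON.  Containers are thin frozen wrappers over pandas objects that enforce
the pipeline's invariants at construction time, so downstream code can
assume identifiers are unique, counts are non-negative integers and
metadata covers every sample.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "ExpressionMatrix",
    "GeneAnnotation",
    "DEResult",
    "FilterStep",
    "GeneSignature",
    "ReferenceAtlas",
    "read_count_matrix",
    "write_count_matrix",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_gmt",
    "write_gmt",
    "read_orthologue_map",
    "write_orthologue_map",
    "read_gene_annotation",
    "read_atlas",
    "write_atlas",
]

SCALES = ("FPKM", "CPM", "LOG2FPKM", "RANK01")

NONMICROGLIA_CELL_TYPES = ("astrocyte", "neuron", "oligodendrocyte", "endothelial")


def _check_unique(values: Iterable[str], what: str) -> None:
    s = pd.Index(values)
    if s.has_duplicates:
        dups = sorted(s[s.duplicated()].unique())
        raise ValueError(f"duplicate {what} identifier(s): {dups}")


@dataclass(frozen=True)
class CountMatrix:
    """Integer gene-by-sample read counts plus per-sample metadata.

    ``counts`` is genes x samples; ``meta`` is indexed by sample and may
    carry ``subgroup``, ``region`` and ``species`` labels.  Library sizes
    are the column sums and are recomputed, never stored.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.counts.index, "gene")
        _check_unique(self.counts.columns, "sample")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.allclose(vals, np.round(vals), atol=0):
                raise ValueError("count matrix contains non-integer entries")
            object.__setattr__(self, "counts", self.counts.astype(np.int64))
            vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValueError("count matrix contains negative entries")
        missing = [s for s in self.counts.columns if s not in self.meta.index]
        if missing:
            raise ValueError(f"samples missing from metadata: {missing}")
        object.__setattr__(self, "meta", self.meta.loc[list(self.counts.columns)])

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def subset_samples(self, samples: Sequence[str]) -> "CountMatrix":
        return CountMatrix(self.counts[list(samples)], self.meta.loc[list(samples)])

    def subset_genes(self, genes: Sequence[str]) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(genes)], self.meta)

    def labels(self, column: str) -> pd.Series:
        if column not in self.meta.columns:
            raise KeyError(f"metadata has no column {column!r}")
        return self.meta[column]


@dataclass(frozen=True)
class ExpressionMatrix:
    """Real-valued gene-by-sample expression with an explicit scale tag."""

    values: pd.DataFrame
    scale: str
    meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale {self.scale!r}; expected one of {SCALES}")
        _check_unique(self.values.index, "gene")
        _check_unique(self.values.columns, "sample")
        vals = self.values.to_numpy(dtype=float)
        if self.scale == "LOG2FPKM":
            if not np.isfinite(vals).all():
                raise ValueError("LOG2FPKM values must be finite (apply a pseudocount)")
        else:
            if (vals < 0).any():
                raise ValueError(f"{self.scale} values must be non-negative")
        if self.scale == "RANK01" and (vals > 1 + 1e-12).any():
            raise ValueError("RANK01 values must lie in [0, 1]")
        if self.meta is not None:
            missing = [s for s in self.values.columns if s not in self.meta.index]
            if missing:
                raise ValueError(f"samples missing from metadata: {missing}")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns


@dataclass(frozen=True)
class GeneAnnotation:
    """Gene lengths (merged exonic bp), display names and orthology.

    ``orthologues`` maps each species gene to the (possibly empty) set of
    human genes it matches; ``unmapped`` lists genes seen in the map with no
    human match.
    """

    lengths: pd.Series
    names: pd.Series | None = None
    orthologues: Mapping[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_unique(self.lengths.index, "gene")
        if (self.lengths <= 0).any():
            bad = sorted(self.lengths.index[self.lengths <= 0])
            raise ValueError(f"non-positive gene length(s): {bad}")

    @property
    def unmapped(self) -> frozenset[str]:
        return frozenset(g for g, hs in self.orthologues.items() if not hs)


@dataclass(frozen=True)
class DEResult:
    """Per-gene differential expression statistics for one contrast.

    ``table`` columns: log2fc, t, pvalue, adj_pvalue, mean_expr.  The sign
    convention: log2fc > 0 means higher expression in ``contrast[0]``.
    """

    table: pd.DataFrame
    contrast: tuple[str, str]

    _REQUIRED = ("log2fc", "t", "pvalue", "adj_pvalue", "mean_expr")

    def __post_init__(self) -> None:
        missing = [c for c in self._REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"DE table missing column(s): {missing}")
        adj, raw = self.table["adj_pvalue"], self.table["pvalue"]
        if len(self.table) and (adj + 1e-12 < raw).any():
            raise ValueError("adjusted p-values must dominate raw p-values")
        if len(self.table) and ((adj < 0) | (adj > 1)).any():
            raise ValueError("adjusted p-values outside [0, 1]")

    @property
    def genes(self) -> pd.Index:
        return self.table.index


@dataclass(frozen=True)
class FilterStep:
    """One provenance entry: a named filter, its parameters, and the genes
    it removed."""

    name: str
    params: Mapping[str, object]
    removed: tuple[str, ...]
    reasons: Mapping[str, str] = field(default_factory=dict)


@dataclass(frozen=True)
class GeneSignature:
    """An ordered enriched gene set with full derivation provenance."""

    members: tuple[str, ...]
    direction: str
    provenance: tuple[FilterStep, ...] = ()

    def __post_init__(self) -> None:
        _check_unique(self.members, "signature gene")
        removed = set().union(*(set(s.removed) for s in self.provenance)) if self.provenance else set()
        clash = removed & set(self.members)
        if clash:
            raise ValueError(f"signature members also listed as removed: {sorted(clash)}")

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.members)

    def to_json(self, path: str | Path) -> None:
        doc = {
            "direction": self.direction,
            "members": list(self.members),
            "provenance": [
                {
                    "filter": s.name,
                    "params": dict(s.params),
                    "removed": list(s.removed),
                    "reasons": dict(s.reasons),
                }
                for s in self.provenance
            ],
        }
        Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GeneSignature":
        doc = json.loads(Path(path).read_text())
        steps = tuple(
            FilterStep(s["filter"], s["params"], tuple(s["removed"]), s.get("reasons", {}))
            for s in doc["provenance"]
        )
        return cls(tuple(doc["members"]), doc["direction"], steps)


@dataclass(frozen=True)
class ReferenceAtlas:
    """Per-cell-type, per-species FPKM reference used by exclusion filters.

    ``values`` rows are genes; columns are a (species, cell_type)
    MultiIndex.  Cell types follow brain-atlas convention: microglia plus
    the non-microglial parenchymal/vascular types.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if not isinstance(self.values.columns, pd.MultiIndex):
            raise ValueError("atlas columns must be a (species, cell_type) MultiIndex")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("atlas FPKM values must be non-negative")

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(self.values.columns.get_level_values(0)))

    def cell_types(self, species: str) -> tuple[str, ...]:
        cols = self.values[species].columns
        return tuple(cols)

    def require_microglia(self) -> None:
        for sp in self.species:
            if "microglia" not in self.cell_types(sp):
                raise ValueError(f"atlas species {sp!r} lacks a microglia column")

    def nonmicroglia_cell_types(self, species: str) -> tuple[str, ...]:
        return tuple(c for c in self.cell_types(species) if c != "microglia")


# ---------------------------------------------------------------------------
# TSV / GMT readers and writers
# ---------------------------------------------------------------------------


def read_count_matrix(path: str | Path, meta_path: str | Path) -> CountMatrix:
    """Read a genes-x-samples integer TSV plus a per-sample metadata TSV.

    The matrix's first column holds gene ids; metadata's first column holds
    sample ids.  Duplicated identifiers, non-integer or negative entries and
    samples absent from the metadata are rejected with located errors.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    for v in df.dtypes:
        if not np.issubdtype(v, np.number):
            raise ValueError(f"non-numeric column in count matrix {path}")
    vals = df.to_numpy()
    if not np.allclose(vals, np.round(vals), atol=0):
        raise ValueError(f"non-integer counts in {path}")
    _check_unique(meta.index, "metadata sample")
    return CountMatrix(df.astype(np.int64), meta)


def write_count_matrix(cm: CountMatrix, path: str | Path, meta_path: str | Path) -> None:
    cm.counts.to_csv(path, sep="\t", index_label="gene")
    cm.meta.to_csv(meta_path, sep="\t", index_label="sample")


def read_expression_matrix(path: str | Path, scale: str, meta_path: str | Path | None = None) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", index_col=0) if meta_path else None
    return ExpressionMatrix(df.astype(float), scale, meta)


def write_expression_matrix(em: ExpressionMatrix, path: str | Path) -> None:
    em.values.to_csv(path, sep="\t", index_label="gene")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT file: per line, set name, description, then members.

    Members within a line are deduplicated (set semantics); empty sets and
    lines with fewer than three fields are rejected with the line number.
    """
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name = parts[0]
            members = {m for m in parts[2:] if m}
            if not members:
                raise ValueError(f"{path}:{lineno}: gene set {name!r} is empty")
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            sets[name] = members
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path, descriptions: Mapping[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for name in sets:
            desc = (descriptions or {}).get(name, "na")
            members = sorted(set(sets[name]))
            if not members:
                raise ValueError(f"refusing to write empty gene set {name!r}")
            fh.write("\t".join([name, desc, *members]) + "\n")


def read_orthologue_map(path: str | Path) -> dict[str, frozenset[str]]:
    """Read a two-column species-gene -> human-gene TSV into a relation.

    Repeated species genes accumulate human targets; an empty human id
    records the gene as unmapped (empty set).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise ValueError(f"orthologue map {path} needs two columns (species gene, human gene)")
    rel: dict[str, set[str]] = {}
    for g, h in zip(df.iloc[:, 0], df.iloc[:, 1]):
        rel.setdefault(g, set())
        if h:
            rel[g].add(h)
    return {g: frozenset(hs) for g, hs in rel.items()}


def write_orthologue_map(rel: Mapping[str, Iterable[str]], path: str | Path) -> None:
    rows = []
    for g in sorted(rel):
        hs = sorted(set(rel[g]))
        if hs:
            rows.extend((g, h) for h in hs)
        else:
            rows.append((g, ""))
    pd.DataFrame(rows, columns=["gene", "human_gene"]).to_csv(path, sep="\t", index=False)


def read_gene_annotation(path: str | Path, orthologue_path: str | Path | None = None) -> GeneAnnotation:
    """Read gene annotation TSV with columns gene, length and optionally name."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "length" not in df.columns:
        raise ValueError(f"annotation {path} lacks a 'length' column")
    names = df["name"].astype(str) if "name" in df.columns else None
    rel = read_orthologue_map(orthologue_path) if orthologue_path else {}
    return GeneAnnotation(df["length"].astype(float), names, rel)


def read_atlas(path: str | Path) -> ReferenceAtlas:
    """Read a long-format atlas TSV (gene, species, cell_type, fpkm)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "species": str, "cell_type": str})
    need = {"gene", "species", "cell_type", "fpkm"}
    if not need.issubset(df.columns):
        raise ValueError(f"atlas {path} missing column(s): {sorted(need - set(df.columns))}")
    wide = df.pivot_table(index="gene", columns=["species", "cell_type"], values="fpkm", aggfunc="mean")
    return ReferenceAtlas(wide.fillna(0.0))


def write_atlas(atlas: ReferenceAtlas, path: str | Path) -> None:
    vals = atlas.values.copy()
    vals.columns = vals.columns.set_names(["species", "cell_type"])
    long = vals.stack(["species", "cell_type"], future_stack=True).rename("fpkm").reset_index()
    long.columns = ["gene", "species", "cell_type", "fpkm"]
    long.to_csv(path, sep="\t", index=False)
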