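"""File formats and configuration.

Reads GTF/GFF annotations (via gffutils), Biomart-dialect homology TSVs,
replicate expression TSVs (``cell_type:replicate`` column headers), GMT
gene-set collections and YAML pipeline configs; writes every result table
as TSV with a header, stable column order and deterministic row order.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, fields
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd
import yaml

from .expression import ExpressionMatrix
from .orthology import GeneModel, HomologyPair
from .simulate import ComparisonTruth

__all__ = [
    "FormatError", "ConfigError", "DEFAULT_HOMOLOGY_DIALECT", "PipelineConfig",
    "read_gtf", "write_gtf", "read_homology", "read_homology_frame",
    "write_homology", "read_expression", "write_expression",
    "read_library_sizes", "write_library_sizes", "read_gene_list",
    "write_truth", "read_truth", "read_gmt", "write_gmt",
]

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """Malformed input file; message names the file and the defect."""


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


# ---------------------------------------------------------------- GTF


def read_gtf(path: str | Path) -> list[GeneModel]:
    """Parse a GTF into one GeneModel per gene.

    ``exonic_length`` is the union of all exon intervals across all of the
    gene's transcripts; ``transcript_count`` counts transcript features.
    Genes with no exon features are skipped with a warning; malformed
    lines raise a FormatError carrying the line number.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    for lineno, line in enumerate(lines, start=1):
        if not line or line.startswith("#"):
            continue
        if len(line.split("\t")) != 9:
            raise FormatError(f"{path}:{lineno}: expected 9 tab-separated fields")
    if not any(line and not line.startswith("#") for line in lines):
        logger.warning("%s: empty annotation", path)
        return []
    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True, disable_infer_transcripts=True,
    )
    genes = []
    for g in db.features_of_type("gene"):
        exons = [(e.start, e.end) for e in db.children(g, featuretype="exon")]
        if not exons:
            logger.warning("gene %s has no exons; skipped", g.id)
            continue
        n_tx = len(list(db.children(g, featuretype="transcript")))
        genes.append(GeneModel(
            gene_id=g.id,
            gene_name=(g.attributes.get("gene_name") or [g.id])[0],
            chromosome=g.seqid,
            start=g.start,
            end=g.end,
            strand=g.strand if g.strand in "+-" else "+",
            exon_intervals=tuple(sorted(set(exons))),
            transcript_count=max(n_tx, 1),
        ))
    genes.sort(key=lambda g: (g.chromosome, g.start, g.gene_id))
    return genes


def write_gtf(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Write genes as GTF with gene/transcript/exon features.

    Each gene gets ``transcript_count`` transcripts sharing the same exon
    set (transcript variants of one exon model)."""
    with open(path, "w") as fh:
        for g in sorted(genes, key=lambda g: (g.chromosome, g.start, g.gene_id)):
            attrs = f'gene_id "{g.gene_id}"; gene_name "{g.gene_name}";'
            fh.write("\t".join([g.chromosome, "sim", "gene", str(g.start),
                                str(g.end), ".", g.strand, ".", attrs]) + "\n")
            for t in range(g.transcript_count):
                tid = f"{g.gene_id}.t{t + 1}"
                tattrs = attrs + f' transcript_id "{tid}";'
                fh.write("\t".join([g.chromosome, "sim", "transcript", str(g.start),
                                    str(g.end), ".", g.strand, ".", tattrs]) + "\n")
                for s, e in g.exon_intervals:
                    fh.write("\t".join([g.chromosome, "sim", "exon", str(s),
                                        str(e), ".", g.strand, ".", tattrs]) + "\n")


# ---------------------------------------------------------------- homology TSV

DEFAULT_HOMOLOGY_DIALECT: dict[str, str] = {
    "ref_gene_id": "Gene stable ID",
    "ref_gene_name": "Gene name",
    "query_gene_id": "Query gene stable ID",
    "query_gene_name": "Query gene name",
    "homology_type": "Query homology type",
    "percent_identity": "%id. target query gene identical to reference gene",
    "goc_score": "Query gene-order conservation score",
    "wga_score": "Query whole-genome alignment coverage",
}

_REQUIRED_HOMOLOGY = ("ref_gene_id", "query_gene_id", "percent_identity")


def read_homology_frame(path: str | Path,
                        dialect: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Homology TSV as a frame with internal column names.

    Columns not covered by the dialect are preserved as pass-through."""
    dialect = dict(DEFAULT_HOMOLOGY_DIALECT if dialect is None else dialect)
    df = pd.read_csv(path, sep="\t", dtype={dialect[k]: str for k in
                                            ("ref_gene_id", "query_gene_id")
                                            if dialect.get(k) is not None})
    for key in _REQUIRED_HOMOLOGY:
        if dialect.get(key) not in df.columns:
            raise FormatError(
                f"{path}: required column {dialect.get(key)!r} (role {key}) missing"
            )
    rename = {v: k for k, v in dialect.items() if v in df.columns}
    return df.rename(columns=rename)


def read_homology(path: str | Path,
                  dialect: Mapping[str, str] | None = None) -> list[HomologyPair]:
    """One HomologyPair per input row; no deduplication at this stage."""
    df = read_homology_frame(path, dialect)
    pairs = []
    for row in df.itertuples(index=False):
        d = row._asdict()

        def opt(key):
            v = d.get(key)
            return None if v is None or pd.isna(v) or v == "" else v

        pairs.append(HomologyPair(
            ref_gene_id=str(d["ref_gene_id"]),
            query_gene_id=str(d["query_gene_id"]),
            ref_gene_name=str(opt("ref_gene_name") or ""),
            query_gene_name=str(opt("query_gene_name") or ""),
            homology_type=opt("homology_type"),
            percent_identity=float(d["percent_identity"]),
            goc_score=None if opt("goc_score") is None else float(d["goc_score"]),
            wga_score=None if opt("wga_score") is None else float(d["wga_score"]),
        ))
    return pairs


def write_homology(
    pairs: Sequence[HomologyPair],
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    transcript_counts: Mapping[str, int] | None = None,
) -> None:
    """Write a Biomart-dialect homology TSV.

    With ``transcript_counts`` (ref gene id -> count), each pair row is
    repeated once per reference transcript variant, mimicking the
    per-transcript redundancy of real Biomart exports."""
    dialect = dict(DEFAULT_HOMOLOGY_DIALECT if dialect is None else dialect)
    rows = []
    for p in sorted(pairs, key=lambda p: (p.ref_gene_id, p.query_gene_id)):
        reps = (transcript_counts or {}).get(p.ref_gene_id, 1)
        for _ in range(max(reps, 1)):
            rows.append({
                dialect["ref_gene_id"]: p.ref_gene_id,
                dialect["ref_gene_name"]: p.ref_gene_name,
                dialect["query_gene_id"]: p.query_gene_id,
                dialect["query_gene_name"]: p.query_gene_name,
                dialect["homology_type"]: p.homology_type or "",
                dialect["percent_identity"]: p.percent_identity,
                dialect["goc_score"]: "" if p.goc_score is None else p.goc_score,
                dialect["wga_score"]: "" if p.wga_score is None else p.wga_score,
            })
    pd.DataFrame(rows, columns=list(dialect.values())).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------- expression TSV


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Expression TSV: gene_id index plus one ``cell_type:replicate`` column each."""
    df = matrix.values.copy()
    df.columns = [f"{ct}:{rep}" for ct, rep in df.columns]
    df.index.name = "gene_id"
    df.sort_index().to_csv(path, sep="\t")


def read_expression(
    path: str | Path,
    species: str,
    reference_type: str,
    value_kind: str = "rpkm",
    library_sizes: pd.Series | None = None,
    gene_lengths: pd.Series | None = None,
) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    cols = []
    for c in df.columns:
        if ":" not in c:
            raise FormatError(f"{path}: column {c!r} not in 'cell_type:replicate' form")
        ct, rep = c.split(":", 1)
        cols.append((ct, rep))
    df.columns = pd.MultiIndex.from_tuples(cols, names=("cell_type", "replicate"))
    return ExpressionMatrix(
        species=species, values=df, reference_type=reference_type,
        value_kind=value_kind, library_sizes=library_sizes,
        gene_lengths=gene_lengths,
    )


def write_library_sizes(matrix: ExpressionMatrix, path: str | Path) -> None:
    s = matrix.library_sizes.copy()
    s.index = [f"{ct}:{rep}" for ct, rep in s.index]
    s.rename("library_size").rename_axis("column").to_csv(path, sep="\t")


def read_library_sizes(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col="column")
    s = df["library_size"]
    s.index = pd.MultiIndex.from_tuples(
        [tuple(c.split(":", 1)) for c in s.index], names=("cell_type", "replicate"))
    return s


def read_gene_list(path: str | Path) -> list[str]:
    """One gene id/name per line (first TSV column); '#' comments skipped."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line.split("\t")[0])
    return out


# ---------------------------------------------------------------- truth


def write_truth(truth: ComparisonTruth, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth.pairs.sort_values(["ref_gene_id", "query_gene_id"]).to_csv(
        outdir / "truth_pairs.tsv", sep="\t", index=False)
    truth.genes_a.sort_values("gene_id").to_csv(
        outdir / "truth_genes_a.tsv", sep="\t", index=False)
    truth.genes_b.sort_values("gene_id").to_csv(
        outdir / "truth_genes_b.tsv", sep="\t", index=False)
    meta = {"cell_types_a": list(truth.cell_types_a),
            "cell_types_b": list(truth.cell_types_b)}
    (outdir / "truth_meta.yaml").write_text(yaml.safe_dump(meta))


def read_truth(outdir: str | Path) -> ComparisonTruth:
    outdir = Path(outdir)
    meta = yaml.safe_load((outdir / "truth_meta.yaml").read_text())
    kw = dict(sep="\t", keep_default_na=False,
              na_values=[])  # '' stays '', bools parsed below
    pairs = pd.read_csv(outdir / "truth_pairs.tsv", sep="\t")
    genes_a = pd.read_csv(outdir / "truth_genes_a.tsv", **kw)
    genes_b = pd.read_csv(outdir / "truth_genes_b.tsv", **kw)
    for df in (genes_a, genes_b):
        for col in ("tf", "orphan", "missing_expression"):
            df[col] = df[col].astype(str).str.lower() == "true"
        df["base_id"] = df["base_id"].astype(int)
    return ComparisonTruth(
        pairs=pairs, genes_a=genes_a, genes_b=genes_b,
        cell_types_a=tuple(meta["cell_types_a"]),
        cell_types_b=tuple(meta["cell_types_b"]),
    )


# ---------------------------------------------------------------- GMT


def read_gmt(path: str | Path) -> tuple[dict[str, list[str]], dict[str, str]]:
    """GMT: one set per line — id, description, then member genes."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise FormatError(f"{path}:{lineno}: GMT line needs id, description, members")
        sets[parts[0]] = [g for g in parts[2:] if g]
        descriptions[parts[0]] = parts[1]
    return sets, descriptions


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path,
              descriptions: Mapping[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for sid in sorted(sets):
            desc = (descriptions or {}).get(sid, "")
            fh.write("\t".join([sid, desc, *sorted(sets[sid])]) + "\n")


# ---------------------------------------------------------------- config


@dataclass
class PipelineConfig:
    """All paths, thresholds and declarations driving the full pipeline."""

    annotation_a: str = ""
    annotation_b: str = ""
    homology: str = ""
    expression_a: str = ""
    expression_b: str = ""
    library_sizes_a: str | None = None
    library_sizes_b: str | None = None
    value_kind: str = "counts"
    reference_a: str = "HC"
    reference_b: str = "IHC"
    populations: tuple[str, ...] = ("nsSC", "PC", "DC")
    unique_cell_types: tuple[str, ...] | None = None
    tf_list: str | None = None
    deafness_list: str | None = None
    gmt: str | None = None
    truth_dir: str | None = None
    rpkm_cutoff: float = 0.10
    fdr_cutoff: float = 0.10
    lfc_threshold: float = 1.0
    pseudocount: float = 0.01
    use_fdr_in_expressed_call: bool = True
    exon_weight: float = 0.75
    pid_threshold: float = 50.0
    goc_threshold: float = 75.0
    wga_threshold: float = 75.0
    match_strand: bool = False
    seed: int = 0
    outdir: str = "results"

    _PATH_FIELDS = ("annotation_a", "annotation_b", "homology",
                    "expression_a", "expression_b", "library_sizes_a",
                    "library_sizes_b", "tf_list", "deafness_list", "gmt")

    def validate(self) -> None:
        for name in ("annotation_a", "annotation_b", "homology",
                     "expression_a", "expression_b"):
            p = getattr(self, name)
            if not p:
                raise ConfigError(f"config field {name!r} is required")
            if not Path(p).exists():
                raise ConfigError(f"config field {name!r}: path {p} does not exist")
        for name in self._PATH_FIELDS:
            p = getattr(self, name)
            if p and not Path(p).exists():
                raise ConfigError(f"config field {name!r}: path {p} does not exist")
        if self.value_kind not in ("counts", "rpkm"):
            raise ConfigError("value_kind must be 'counts' or 'rpkm'")
        if self.value_kind == "counts" and not (self.library_sizes_a and self.library_sizes_b):
            raise ConfigError("library_sizes_a/b required when value_kind='counts'")
        for name, lo, hi in (("rpkm_cutoff", 0, None), ("fdr_cutoff", 0, 1),
                             ("pseudocount", 0, None), ("pid_threshold", 0, 100),
                             ("goc_threshold", 0, 100), ("wga_threshold", 0, 100)):
            v = getattr(self, name)
            if v < lo or (hi is not None and v > hi):
                raise ConfigError(f"config field {name!r} = {v} out of range")
        if not 0.5 < self.exon_weight <= 1:
            raise ConfigError("exon_weight must lie in (0.5, 1]")

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["populations"] = list(self.populations)
        if self.unique_cell_types is not None:
            d["unique_cell_types"] = list(self.unique_cell_types)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config field(s): {sorted(unknown)}")
        if "populations" in d:
            d["populations"] = tuple(d["populations"])
        if d.get("unique_cell_types") is not None:
            d["unique_cell_types"] = tuple(d["unique_cell_types"])
        return cls(**d)
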