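"""Paired synthetic genomes with planted orthology and expression structure.

The generator emulates the downstream products of a two-species inner-ear
RNA-seq comparison without any sequence data: two genome annotations with
conserved gene order, a homology graph with one-to-one / many-to-one /
many-to-many components (species A carries extra paralog copies, as the
zebrafish lineage does), per-pair percent-identity and WGA scores drawn
from configurable Beta distributions, and replicate expression matrices
with planted differential expression, planted single-cell-type unique
expression, and planted transcription-factor labels. Every planted label
is emitted in a ComparisonTruth bundle so each downstream stage can be
tested for exact recovery.

Structural choices that matter for gene-order conservation:

* paralog copies are tandem duplications (placed adjacent to their source
  gene), which leaves every one-to-one gene's 2-up/2-down orthologous
  neighbourhood intact;
* orphan (species-unique) genes are interleaved at random positions; they
  never occupy GOC neighbour slots because neighbourhoods are taken over
  ortholog-participating genes only;
* rearrangement relocates a configured fraction of species-B ortholog
  genes to random positions, degrading GOC through the full
  {0, 25, 50, 75, 100} range.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .orthology import (
    GeneModel,
    HomologyPair,
    call_high_confidence,
)

__all__ = ["SimConfig", "SimConfigError", "ComparisonTruth", "simulate_genomes",
           "simulate_expression", "simulate_bundle"]


class SimConfigError(ValueError):
    """Invalid simulation configuration; message names the offending field."""


_PROB_FIELDS = (
    "paralog_expansion_prob", "paralog_expansion_prob_b", "orphan_prob_a",
    "orphan_prob_b", "rearrangement_rate", "de_fraction",
    "unique_expression_fraction", "tf_fraction", "missing_expression_prob",
    "multi_variant_prob",
)


@dataclass
class SimConfig:
    """Study conditions for the paired-genome simulation.

    Defaults model the comparison the package targets: species A is the
    regeneration-competent fish-like genome (extra paralog copies, hair
    cells HC as reference vs non-sensory supporting cells nsSC), species B
    the mammal-like genome (inner hair cells IHC as reference vs OHC and
    the PC/DC supporting cells); three replicates per cell type.
    """

    n_base_genes: int = 300
    n_chromosomes_a: int = 4
    n_chromosomes_b: int = 4
    paralog_expansion_prob: float = 0.20
    paralog_expansion_prob_b: float = 0.05
    orphan_prob_a: float = 0.15
    orphan_prob_b: float = 0.15
    rearrangement_rate: float = 0.10
    pid_distribution: tuple[float, float] = (6.0, 2.0)   # Beta(a, b) * 100
    wga_distribution: tuple[float, float] = (5.0, 2.0)   # Beta(a, b) * 100
    cell_types_a: tuple[str, ...] = ("HC", "nsSC")
    cell_types_b: tuple[str, ...] = ("IHC", "OHC", "PC", "DC")
    reference_a: str = "HC"
    reference_b: str = "IHC"
    n_replicates: int = 3
    de_fraction: float = 0.10
    unique_expression_fraction: float = 0.05
    tf_fraction: float = 0.10
    missing_expression_prob: float = 0.02
    multi_variant_prob: float = 0.25
    log2fc_effect: float = 2.0
    expression_lognormal_mu_sigma: tuple[float, float] = (3.0, 1.0)
    nb_dispersion: float = 0.10
    library_size: int = 20_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_base_genes", "n_chromosomes_a", "n_chromosomes_b"):
            if int(getattr(self, name)) < 1:
                raise SimConfigError(f"{name} must be a positive integer")
        for name in _PROB_FIELDS:
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise SimConfigError(f"{name} = {v} outside [0, 1]")
        if self.n_replicates < 2:
            raise SimConfigError("n_replicates must be >= 2")
        for side, cts, ref in (("a", self.cell_types_a, self.reference_a),
                               ("b", self.cell_types_b, self.reference_b)):
            if len(cts) < 2:
                raise SimConfigError(f"cell_types_{side} needs >= 2 cell types")
            if len(set(cts)) != len(cts):
                raise SimConfigError(f"cell_types_{side} contains duplicates")
            if ref not in cts:
                raise SimConfigError(f"reference_{side} {ref!r} not in cell_types_{side}")
        if set(self.cell_types_a) & set(self.cell_types_b):
            raise SimConfigError("cell_types_a and cell_types_b must not overlap")
        if self.nb_dispersion < 0:
            raise SimConfigError("nb_dispersion must be >= 0")
        if self.log2fc_effect < 0:
            raise SimConfigError("log2fc_effect must be >= 0")
        if self.library_size <= 0:
            raise SimConfigError("library_size must be > 0")

    @property
    def all_cell_types(self) -> tuple[str, ...]:
        return tuple(self.cell_types_a) + tuple(self.cell_types_b)


@dataclass
class ComparisonTruth:
    """Planted ground truth emitted alongside the simulated data.

    ``pairs`` has one row per homology edge (true class, drawn %ID/WGA,
    placement-induced GOC, expected high-confidence flag); ``genes_a`` /
    ``genes_b`` one row per gene (base-gene lineage, DE label vs the
    species reference, unique-expression cell type or '', TF flag, orphan
    flag, missing-expression flag).
    """

    pairs: pd.DataFrame
    genes_a: pd.DataFrame
    genes_b: pd.DataFrame
    cell_types_a: tuple[str, ...] = ()
    cell_types_b: tuple[str, ...] = ()

    def class_counts(self) -> pd.Series:
        return self.pairs["homology_class"].value_counts()

    def de_genes(self, species: str, direction: str) -> set[str]:
        df = self.genes_a if species == "a" else self.genes_b
        return set(df.loc[df["de_label"] == direction, "gene_id"])

    def unique_genes(self, cell_type: str) -> set[str]:
        out = set()
        for df in (self.genes_a, self.genes_b):
            out |= set(df.loc[df["unique_cell_type"] == cell_type, "gene_id"])
        return out


def _draw_gene(rng: np.random.Generator, gene_id: str, name: str, chrom: str,
               cursor: int, transcript_count: int) -> tuple[GeneModel, int]:
    n_exons = int(rng.integers(2, 9))
    exon_lens = rng.integers(150, 1501, n_exons)
    intron_lens = rng.integers(100, 2001, max(n_exons - 1, 0))
    intervals = []
    pos = cursor
    for i, el in enumerate(exon_lens):
        intervals.append((pos, pos + int(el) - 1))
        pos = intervals[-1][1] + 1
        if i < len(intron_lens):
            pos += int(intron_lens[i])
    strand = "+" if rng.random() < 0.5 else "-"
    gene = GeneModel(
        gene_id=gene_id, gene_name=name, chromosome=chrom,
        start=intervals[0][0], end=intervals[-1][1], strand=strand,
        exon_intervals=tuple(intervals), transcript_count=transcript_count,
    )
    next_cursor = gene.end + 1 + int(rng.integers(500, 2000))
    return gene, next_cursor


def _build_annotation(rng, items: list[tuple[str, str]], n_chromosomes: int,
                      multi_variant_prob: float) -> list[GeneModel]:
    """items: ordered (gene_id, gene_name); split contiguously into chromosomes."""
    genes = []
    chunks = np.array_split(np.arange(len(items)), n_chromosomes)
    for c, idx in enumerate(chunks, start=1):
        cursor = 1
        for i in idx:
            gid, name = items[int(i)]
            tc = 1 + (int(rng.integers(1, 4)) if rng.random() < multi_variant_prob else 0)
            gene, cursor = _draw_gene(rng, gid, name, f"chr{c}", cursor, tc)
            genes.append(gene)
    return genes


def _brute_force_goc(pairs: list[dict], genes_a: list[GeneModel],
                     genes_b: list[GeneModel]) -> list[int]:
    """Placement-induced GOC per pair by direct neighbourhood enumeration,
    over the order restricted to genes carrying homology edges."""
    ref_ids = {p["ref_gene_id"] for p in pairs}
    query_ids = {p["query_gene_id"] for p in pairs}
    omap: dict[str, set[str]] = {}
    for p in pairs:
        omap.setdefault(p["ref_gene_id"], set()).add(p["query_gene_id"])

    def chrom_orders(genes, keep):
        by = {}
        for g in sorted(genes, key=lambda g: (g.chromosome, g.start, g.gene_id)):
            if g.gene_id in keep:
                by.setdefault(g.chromosome, []).append(g.gene_id)
        return by

    orders_a = chrom_orders(genes_a, ref_ids)
    orders_b = chrom_orders(genes_b, query_ids)
    loc_a = {g: (c, i) for c, ids in orders_a.items() for i, g in enumerate(ids)}
    loc_b = {g: (c, i) for c, ids in orders_b.items() for i, g in enumerate(ids)}
    out = []
    for p in pairs:
        ca, ia = loc_a[p["ref_gene_id"]]
        cb, ib = loc_b[p["query_gene_id"]]
        nbs = orders_a[ca][max(0, ia - 2):ia] + orders_a[ca][ia + 1:ia + 3]
        window = set(orders_b[cb][max(0, ib - 2):ib] + orders_b[cb][ib + 1:ib + 3])
        out.append(25 * sum(1 for nb in nbs if omap.get(nb, set()) & window))
    return out


def simulate_genomes(config: SimConfig):
    """Generate paired annotations, the homology edge list, and truth labels.

    Returns ``(annotation_a, annotation_b, homology_pairs, truth)``; homology
    pairs carry drawn %ID/WGA but no class or GOC — those are planted in the
    truth table for downstream recovery checks.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_base_genes
    copies_a = 1 + (rng.random(n) < config.paralog_expansion_prob).astype(int)
    copies_b = 1 + (rng.random(n) < config.paralog_expansion_prob_b).astype(int)

    def gene_ids(side: str, i: int, k: int) -> tuple[str, str]:
        stem = f"{i:05d}" + ("" if k == 0 else f"d{k}")
        if side == "a":
            return f"GA{stem}", f"ga{stem}"      # fish-style lower-case name
        return f"GB{stem}", f"Gb{stem}"          # mammal-style capitalised name

    # Shared base order; tandem duplicates sit adjacent to their source.
    items_a = [gene_ids("a", i, k) for i in range(n) for k in range(copies_a[i])]
    items_b = [gene_ids("b", i, k) for i in range(n) for k in range(copies_b[i])]

    n_orph_a = int(rng.binomial(n, config.orphan_prob_a))
    n_orph_b = int(rng.binomial(n, config.orphan_prob_b))
    orph_a = [(f"OA{i:05d}", f"oa{i:05d}") for i in range(n_orph_a)]
    orph_b = [(f"OB{i:05d}", f"Ob{i:05d}") for i in range(n_orph_b)]
    for item in orph_a:
        items_a.insert(int(rng.integers(0, len(items_a) + 1)), item)
    for item in orph_b:
        items_b.insert(int(rng.integers(0, len(items_b) + 1)), item)

    # Rearrangement: relocate a fraction of species-B ortholog genes.
    orth_b_ids = {gene_ids("b", i, k)[0] for i in range(n) for k in range(copies_b[i])}
    n_move = int(round(config.rearrangement_rate * len(orth_b_ids)))
    if n_move:
        movable = [j for j, it in enumerate(items_b) if it[0] in orth_b_ids]
        for j in sorted(rng.choice(movable, size=n_move, replace=False), reverse=True):
            item = items_b.pop(int(j))
            items_b.insert(int(rng.integers(0, len(items_b) + 1)), item)

    annotation_a = _build_annotation(rng, items_a, config.n_chromosomes_a,
                                     config.multi_variant_prob)
    annotation_b = _build_annotation(rng, items_b, config.n_chromosomes_b,
                                     config.multi_variant_prob)

    # Homology edges: complete bipartite between each base gene's copies.
    pa, pb = config.pid_distribution, config.wga_distribution
    raw, truth_rows = [], []
    for i in range(n):
        ca, cb = copies_a[i], copies_b[i]
        if ca > 1 and cb > 1:
            cls = "many2many"
        elif ca > 1 or cb > 1:
            cls = "many2one"
        else:
            cls = "one2one"
        for ka in range(ca):
            aid, aname = gene_ids("a", i, ka)
            for kb in range(cb):
                bid, bname = gene_ids("b", i, kb)
                pid = 100 * float(rng.beta(pa[0], pa[1]))
                wga = 100 * float(rng.beta(pb[0], pb[1]))
                raw.append(HomologyPair(
                    ref_gene_id=aid, query_gene_id=bid,
                    ref_gene_name=aname, query_gene_name=bname,
                    percent_identity=pid, wga_score=wga,
                ))
                truth_rows.append({
                    "ref_gene_id": aid, "query_gene_id": bid, "base_id": i,
                    "homology_class": cls, "percent_identity": pid,
                    "wga_score": wga,
                })

    goc = _brute_force_goc(truth_rows, annotation_a, annotation_b)
    for row, g in zip(truth_rows, goc):
        row["goc_score"] = float(g)
        row["high_confidence"] = call_high_confidence(HomologyPair(
            ref_gene_id=row["ref_gene_id"], query_gene_id=row["query_gene_id"],
            percent_identity=row["percent_identity"],
            goc_score=row["goc_score"], wga_score=row["wga_score"],
        ))

    # Planted expression labels on base genes carrying homology edges.
    orth_bases = np.arange(n)
    shuffled = rng.permutation(orth_bases)
    n_unique = int(round(config.unique_expression_fraction * n))
    n_de = int(round(config.de_fraction * n))
    unique_bases = set(shuffled[:n_unique].tolist())
    de_bases = shuffled[n_unique:n_unique + n_de].tolist()
    rest = shuffled[n_unique + n_de:].tolist()
    de_dir = {b: ("up" if rng.random() < 0.5 else "down") for b in de_bases}
    unique_ct = {b: config.all_cell_types[int(rng.integers(0, len(config.all_cell_types)))]
                 for b in unique_bases}
    missing_bases = {b for b in rest if rng.random() < config.missing_expression_prob}
    missing_side = {b: ("a" if rng.random() < 0.5 else "b") for b in missing_bases}
    tf_bases = {int(b) for b in orth_bases if rng.random() < config.tf_fraction}

    def gene_table(side, annotation):
        rows = []
        for g in annotation:
            orphan = g.gene_id.startswith("O")
            base = -1 if orphan else int(g.gene_id[2:7])
            rows.append({
                "gene_id": g.gene_id, "gene_name": g.gene_name, "base_id": base,
                "de_label": de_dir.get(base, "null") if not orphan else "null",
                "unique_cell_type": unique_ct.get(base, "") if not orphan else "",
                "tf": (not orphan) and base in tf_bases,
                "orphan": orphan,
                "missing_expression": (not orphan) and missing_side.get(base) == side,
            })
        return pd.DataFrame(rows)

    truth = ComparisonTruth(
        pairs=pd.DataFrame(truth_rows),
        genes_a=gene_table("a", annotation_a),
        genes_b=gene_table("b", annotation_b),
        cell_types_a=tuple(config.cell_types_a),
        cell_types_b=tuple(config.cell_types_b),
    )
    return annotation_a, annotation_b, raw, truth


def _nb_counts(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial draws with var = mu + dispersion * mu^2 (Poisson at 0)."""
    counts = np.zeros(mu.shape, dtype=np.int64)
    pos = mu > 0
    if dispersion > 0:
        size = 1.0 / dispersion
        p = size / (size + mu[pos])
        counts[pos] = rng.negative_binomial(size, p)
    else:
        counts[pos] = rng.poisson(mu[pos])
    return counts


def simulate_expression(config: SimConfig, annotation_a: Sequence[GeneModel],
                        annotation_b: Sequence[GeneModel], truth: ComparisonTruth):
    """Replicate count matrices for both species with the planted structure.

    Per-gene baseline mean RPKM is log-normal and shared across a base
    gene's copies in both species; planted up/down genes are shifted by
    +/- log2fc_effect in every non-reference cell type; unique-expression
    genes have zero mean outside their designated cell type; counts are
    negative-binomial around length- and depth-scaled means. Genes whose
    base was planted as missing-expression are absent from that species'
    matrix entirely.
    """
    from .expression import ExpressionMatrix

    if tuple(truth.cell_types_a) != tuple(config.cell_types_a) or \
       tuple(truth.cell_types_b) != tuple(config.cell_types_b):
        raise SimConfigError("cell-type lists inconsistent between config and truth")

    rng = np.random.default_rng([config.seed, 7])
    mu, sigma = config.expression_lognormal_mu_sigma
    base_mean: dict[int, float] = {}

    # Draw base means in deterministic base order first so matrix row sets
    # (which differ with missing-expression planting) cannot shift draws;
    # orphans draw lazily in annotation order, also deterministic.
    for b in range(config.n_base_genes):
        base_mean[b] = float(rng.lognormal(mu, sigma))

    def mean_for(base: int) -> float:
        if base >= 0:
            return base_mean[base]
        return float(rng.lognormal(mu, sigma))

    def build(side, annotation, genes_df, cell_types, reference):
        keep = genes_df.loc[~genes_df["missing_expression"]]
        info = keep.set_index("gene_id")
        genes = [g for g in annotation if g.gene_id in info.index]
        lengths = pd.Series({g.gene_id: g.exonic_length for g in genes})
        cols = pd.MultiIndex.from_tuples(
            [(ct, f"rep{r+1}") for ct in cell_types for r in range(config.n_replicates)],
            names=("cell_type", "replicate"),
        )
        lib = pd.Series(
            np.round(rng.uniform(0.8, 1.2, len(cols)) * config.library_size),
            index=cols,
        )
        mean_rpkm = np.zeros((len(genes), len(cell_types)))
        for gi, g in enumerate(genes):
            row = info.loc[g.gene_id]
            m = mean_for(int(row["base_id"]))
            uct = row["unique_cell_type"]
            for ci, ct in enumerate(cell_types):
                if uct:
                    mean_rpkm[gi, ci] = m if ct == uct else 0.0
                elif row["de_label"] == "up" and ct != reference:
                    mean_rpkm[gi, ci] = m * 2 ** config.log2fc_effect
                elif row["de_label"] == "down" and ct != reference:
                    mean_rpkm[gi, ci] = m / 2 ** config.log2fc_effect
                else:
                    mean_rpkm[gi, ci] = m
        counts = np.zeros((len(genes), len(cols)), dtype=np.int64)
        for j, (ct, _rep) in enumerate(cols):
            ci = cell_types.index(ct)
            mu_counts = mean_rpkm[:, ci] * lengths.values * lib.iloc[j] / 1e9
            counts[:, j] = _nb_counts(rng, mu_counts, config.nb_dispersion)
        values = pd.DataFrame(counts, index=[g.gene_id for g in genes], columns=cols)
        return ExpressionMatrix(
            species=side, values=values, reference_type=reference,
            value_kind="counts", library_sizes=lib, gene_lengths=lengths,
        )

    matrix_a = build("a", annotation_a, truth.genes_a,
                     list(config.cell_types_a), config.reference_a)
    matrix_b = build("b", annotation_b, truth.genes_b,
                     list(config.cell_types_b), config.reference_b)
    return matrix_a, matrix_b


def simulate_bundle(config: SimConfig):
    """Genomes + expression in one call; returns
    (annotation_a, annotation_b, raw_pairs, truth, matrix_a, matrix_b)."""
    ann_a, ann_b, raw, truth = simulate_genomes(config)
    matrix_a, matrix_b = simulate_expression(config, ann_a, ann_b, truth)
    return ann_a, ann_b, raw, truth, matrix_a, matrix_b
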