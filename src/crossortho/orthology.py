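"""Cross-species ortholog table construction and confidence scoring.

Builds the reference→query ortholog table between two species from a
Biomart-style homology export plus genome annotations: transcript-row
deduplication, relationship classification on the bipartite homology
graph (one-to-one / many-to-one / many-to-many), the gene-order
conservation (GOC) score on the {0, 25, 50, 75, 100} lattice, the
whole-genome-alignment (WGA) coverage score, and the high-confidence
ortholog call (percent identity >= 50 and GOC >= 75 and/or WGA >= 75).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

__all__ = [
    "GeneModel",
    "HomologyPair",
    "OrthologTable",
    "GenomeOrder",
    "StructuralError",
    "deduplicate_transcript_rows",
    "classify_relationships",
    "collapse_query_redundancy",
    "relationship_tallies",
    "goc_score",
    "compute_goc",
    "wga_score",
    "call_high_confidence",
    "annotate_high_confidence",
    "build_ortholog_table",
]

HOMOLOGY_CLASSES = ("one2one", "many2one", "many2many")

# Inclusive thresholds, as printed ("GOC score >= 75 and/or WGA score >= 75,
# and percent identity >= 50").
PID_THRESHOLD = 50.0
GOC_THRESHOLD = 75.0
WGA_THRESHOLD = 75.0


class StructuralError(ValueError):
    """Raised when the homology graph or annotation violates structural rules."""


def _union_length(intervals: Sequence[tuple[int, int]]) -> int:
    """Total length (bp, 1-based inclusive) of the union of intervals."""
    total = 0
    last_end = None
    for start, end in sorted(intervals):
        if last_end is None or start > last_end:
            total += end - start + 1
            last_end = end
        elif end > last_end:
            total += end - last_end
            last_end = end
    return total


@dataclass(frozen=True)
class GeneModel:
    """One gene's coordinates and exon structure.

    Coordinates are 1-based inclusive (GTF convention). ``exonic_length``
    is the length of the union of all exon intervals across transcripts;
    this is the gene length L used by RPKM normalisation.
    """

    gene_id: str
    gene_name: str
    chromosome: str
    start: int
    end: int
    strand: str
    exon_intervals: tuple[tuple[int, int], ...]
    transcript_count: int = 1
    exonic_length: int = field(default=0)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")
        for s, e in self.exon_intervals:
            if s < self.start or e > self.end or s > e:
                raise ValueError(f"gene {self.gene_id}: exon ({s},{e}) outside gene body")
        if self.exonic_length == 0:
            object.__setattr__(self, "exonic_length", _union_length(self.exon_intervals))
        if self.exonic_length <= 0:
            raise ValueError(f"gene {self.gene_id}: exonic_length must be > 0")


@dataclass
class HomologyPair:
    """One reference-query ortholog pair with its confidence scores."""

    ref_gene_id: str
    query_gene_id: str
    ref_gene_name: str = ""
    query_gene_name: str = ""
    homology_type: str | None = None
    percent_identity: float | None = None
    goc_score: float | None = None
    wga_score: float | None = None
    high_confidence: bool | None = None

    def __post_init__(self) -> None:
        if self.percent_identity is not None and not 0 <= self.percent_identity <= 100:
            raise ValueError(
                f"pair {self.ref_gene_id}-{self.query_gene_id}: "
                f"percent_identity {self.percent_identity} outside [0, 100]"
            )
        if self.goc_score is not None and self.goc_score not in (0, 25, 50, 75, 100):
            raise ValueError(
                f"pair {self.ref_gene_id}-{self.query_gene_id}: "
                f"goc_score {self.goc_score} not in {{0,25,50,75,100}}"
            )

    @property
    def pair_id(self) -> str:
        return f"{self.ref_gene_id}|{self.query_gene_id}"


def deduplicate_transcript_rows(pairs: Iterable[HomologyPair]) -> list[HomologyPair]:
    """Drop repeated (ref, query) rows, keeping the first occurrence.

    Biomart exports repeat each gene pair once per transcript variant of the
    reference gene; scores are identical across those rows, so keeping the
    first is order-insensitive in practice.
    """
    seen: set[tuple[str, str]] = set()
    out = []
    for p in pairs:
        key = (p.ref_gene_id, p.query_gene_id)
        if key not in seen:
            seen.add(key)
            out.append(p)
    return out


def classify_relationships(pairs: Sequence[HomologyPair]) -> list[HomologyPair]:
    """Assign one2one / many2one / many2many by bipartite component structure.

    Within each connected component of the reference-query gene graph:
    every gene on both sides has degree 1 -> one2one; genes of degree > 1
    on exactly one side -> many2one; on both sides -> many2many. All edges
    of a component share one label. Classification never trusts the
    homology-type column of the input.
    """
    g = nx.Graph()
    for p in pairs:
        if p.ref_gene_id == p.query_gene_id:
            raise StructuralError(
                f"self-loop / same-species edge: {p.ref_gene_id} paired with itself"
            )
        g.add_edge(("ref", p.ref_gene_id), ("query", p.query_gene_id))
    labels: dict[tuple[str, str], str] = {}
    for comp in nx.connected_components(g):
        ref_multi = any(s == "ref" and g.degree((s, n)) > 1 for s, n in comp)
        query_multi = any(s == "query" and g.degree((s, n)) > 1 for s, n in comp)
        if ref_multi and query_multi:
            cls = "many2many"
        elif ref_multi or query_multi:
            cls = "many2one"
        else:
            cls = "one2one"
        for node in comp:
            labels[node] = cls
    return [replace(p, homology_type=labels[("ref", p.ref_gene_id)]) for p in pairs]


def relationship_tallies(pairs: Sequence[HomologyPair]) -> pd.DataFrame:
    """Count distinct genes per species per homology class (Table-1 shape)."""
    rows = {}
    for species, key in (("ref", "ref_gene_id"), ("query", "query_gene_id")):
        by_class = {c: set() for c in HOMOLOGY_CLASSES}
        for p in pairs:
            if p.homology_type is None:
                raise ValueError("pairs must be classified before tallying")
            by_class[p.homology_type].add(getattr(p, key))
        rows[species] = {c: len(s) for c, s in by_class.items()}
        rows[species]["total_orthologs"] = len({getattr(p, key) for p in pairs})
    return pd.DataFrame(rows).T[list(HOMOLOGY_CLASSES) + ["total_orthologs"]]


def collapse_query_redundancy(
    pairs: Sequence[HomologyPair],
) -> tuple[set[str], set[str]]:
    """Distinct ortholog gene sets per species.

    Redundant query genes that correspond to multiple reference paralogs
    collapse to one, so the reference ortholog count is >= the query count.
    Returns ``(ref_gene_ids, query_gene_ids)``.
    """
    return {p.ref_gene_id for p in pairs}, {p.query_gene_id for p in pairs}


class GenomeOrder:
    """Chromosomal gene order for GOC neighbourhood lookups.

    Genes are ordered by (chromosome, start, gene_id); the gene_id tie-break
    makes ordering deterministic for identical starts. When ``restrict_to``
    is given, only those genes occupy positions in the order — neighbour
    slots are then the nearest *orthologous* genes, so species-unique genes
    interleaved in the annotation do not consume neighbour positions.
    """

    def __init__(self, genes: Iterable[GeneModel], restrict_to: set[str] | None = None):
        kept = [g for g in genes if restrict_to is None or g.gene_id in restrict_to]
        self._genes = {g.gene_id: g for g in kept}
        if len(self._genes) != len(kept):
            dupes = len(kept) - len(self._genes)
            raise StructuralError(f"{dupes} duplicated gene_id(s) in annotation")
        self._chrom: dict[str, list[str]] = {}
        self._pos: dict[str, tuple[str, int]] = {}
        by_chrom: dict[str, list[GeneModel]] = {}
        for g in kept:
            by_chrom.setdefault(g.chromosome, []).append(g)
        for chrom, gs in by_chrom.items():
            gs.sort(key=lambda g: (g.start, g.gene_id))
            ids = [g.gene_id for g in gs]
            self._chrom[chrom] = ids
            for i, gid in enumerate(ids):
                self._pos[gid] = (chrom, i)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._pos

    def gene(self, gene_id: str) -> GeneModel:
        return self._genes[gene_id]

    def neighbors(self, gene_id: str, flank: int = 2) -> list[str]:
        """Up to ``flank`` genes upstream and downstream on the same chromosome."""
        if gene_id not in self._pos:
            raise KeyError(f"gene {gene_id!r} absent from annotation order")
        chrom, i = self._pos[gene_id]
        ids = self._chrom[chrom]
        return ids[max(0, i - flank) : i] + ids[i + 1 : i + 1 + flank]

    def window(self, gene_id: str, flank: int = 2) -> set[str]:
        return set(self.neighbors(gene_id, flank))


def goc_score(
    gene_id: str,
    partner_id: str,
    ortholog_map: Mapping[str, set[str]],
    order_a: GenomeOrder,
    order_b: GenomeOrder,
    flank: int = 2,
    match_strand: bool = False,
) -> int:
    """Gene-order conservation score for one ortholog pair.

    Each of the gene's <= 4 chromosomal neighbours (2 upstream, 2 downstream)
    contributes 25 points when any of its orthologs lies within the partner
    gene's own 2-up/2-down neighbourhood; a full four-neighbour match scores
    100. Genes near a chromosome end have fewer candidate neighbours and the
    absent slots count as non-matches, keeping the score on the
    {0, 25, 50, 75, 100} lattice.

    ``ortholog_map`` maps species-A gene ids to the set of species-B ortholog
    ids. With ``match_strand`` a neighbour match additionally requires the
    neighbour and its matched ortholog to lie on the same strand (off by
    default; orientation is not part of the published score description).
    """
    window = order_b.window(partner_id, flank)
    score = 0
    for nb in order_a.neighbors(gene_id, flank):
        partners = ortholog_map.get(nb, set()) & window
        if match_strand:
            nb_strand = order_a.gene(nb).strand
            partners = {p for p in partners if order_b.gene(p).strand == nb_strand}
        if partners:
            score += 25
    return score


def compute_goc(
    pairs: Sequence[HomologyPair],
    annotation_a: Iterable[GeneModel],
    annotation_b: Iterable[GeneModel],
    orthologs_only: bool = True,
    match_strand: bool = False,
) -> list[HomologyPair]:
    """GOC scores for all pairs from the two annotations.

    With ``orthologs_only`` (default), the gene order is restricted to genes
    that participate in the homology map before neighbourhoods are taken.
    """
    ref_ids = {p.ref_gene_id for p in pairs}
    query_ids = {p.query_gene_id for p in pairs}
    order_a = GenomeOrder(annotation_a, restrict_to=ref_ids if orthologs_only else None)
    order_b = GenomeOrder(annotation_b, restrict_to=query_ids if orthologs_only else None)
    omap: dict[str, set[str]] = {}
    for p in pairs:
        omap.setdefault(p.ref_gene_id, set()).add(p.query_gene_id)
    out = []
    for p in pairs:
        score = goc_score(
            p.ref_gene_id, p.query_gene_id, omap, order_a, order_b,
            match_strand=match_strand,
        )
        out.append(replace(p, goc_score=float(score)))
    return out


def wga_score(
    exon_cov_ref: float,
    intron_cov_ref: float,
    exon_cov_query: float,
    intron_cov_query: float,
    exon_weight: float = 0.75,
) -> float:
    """Whole-genome-alignment coverage score, 0-100.

    Per gene: ``100 * (w * exon_coverage + (1 - w) * intron_coverage)`` with
    exon coverage weighted more heavily (w in (0.5, 1], default 0.75); the
    pair score is the arithmetic mean of the two per-gene scores.
    """
    if not 0.5 < exon_weight <= 1:
        raise ValueError(f"exon_weight {exon_weight} outside (0.5, 1]")
    for name, cov in (
        ("exon_cov_ref", exon_cov_ref),
        ("intron_cov_ref", intron_cov_ref),
        ("exon_cov_query", exon_cov_query),
        ("intron_cov_query", intron_cov_query),
    ):
        if not 0 <= cov <= 1:
            raise ValueError(f"{name} = {cov} outside [0, 1]")
    w = exon_weight
    ref = 100 * (w * exon_cov_ref + (1 - w) * intron_cov_ref)
    query = 100 * (w * exon_cov_query + (1 - w) * intron_cov_query)
    return (ref + query) / 2


def call_high_confidence(
    pair: HomologyPair,
    pid_threshold: float = PID_THRESHOLD,
    goc_threshold: float = GOC_THRESHOLD,
    wga_threshold: float = WGA_THRESHOLD,
) -> bool:
    """High-confidence ortholog rule: %ID >= 50 AND (GOC >= 75 OR WGA >= 75).

    All thresholds inclusive. A missing GOC or WGA score fails its clause;
    with both missing the pair is never high-confidence.
    """
    if pair.percent_identity is None:
        raise ValueError(f"pair {pair.pair_id}: percent_identity required")
    if pair.percent_identity < pid_threshold:
        return False
    goc_ok = pair.goc_score is not None and pair.goc_score >= goc_threshold
    wga_ok = pair.wga_score is not None and pair.wga_score >= wga_threshold
    return goc_ok or wga_ok


def annotate_high_confidence(pairs: Sequence[HomologyPair], **thresholds) -> list[HomologyPair]:
    return [replace(p, high_confidence=call_high_confidence(p, **thresholds)) for p in pairs]


@dataclass
class OrthologTable:
    """The classified, scored ortholog table plus per-species tallies."""

    pairs: list[HomologyPair]
    ref_universe: set[str] = field(default_factory=set)
    query_universe: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        ref_orth, query_orth = collapse_query_redundancy(self.pairs)
        self.ref_universe |= ref_orth
        self.query_universe |= query_orth

    @property
    def pair_ids(self) -> set[str]:
        return {p.pair_id for p in self.pairs}

    def by_pair_id(self) -> dict[str, HomologyPair]:
        return {p.pair_id: p for p in self.pairs}

    def to_frame(self) -> pd.DataFrame:
        cols = [
            "ref_gene_id", "ref_gene_name", "query_gene_id", "query_gene_name",
            "homology_type", "percent_identity", "goc_score", "wga_score",
            "high_confidence",
        ]
        df = pd.DataFrame([{c: getattr(p, c) for c in cols} for p in self.pairs])
        if df.empty:
            df = pd.DataFrame(columns=cols)
        return df.sort_values(["ref_gene_id", "query_gene_id"]).reset_index(drop=True)

    def tally_frame(self) -> pd.DataFrame:
        """Relationship tallies in the shape of a classification table:
        per species, genes per class, total orthologs, unique (non-ortholog)
        genes, and the protein-coding total (orthologs + unique)."""
        t = relationship_tallies(self.pairs)
        ref_orth, query_orth = collapse_query_redundancy(self.pairs)
        t.loc["ref", "unique_genes"] = len(self.ref_universe - ref_orth)
        t.loc["query", "unique_genes"] = len(self.query_universe - query_orth)
        t["total_protein_coding"] = t["total_orthologs"] + t["unique_genes"]
        return t.astype(int)


def build_ortholog_table(
    raw_pairs: Sequence[HomologyPair],
    annotation_a: Sequence[GeneModel],
    annotation_b: Sequence[GeneModel],
    recompute_goc: bool = True,
    orthologs_only: bool = True,
    match_strand: bool = False,
    **thresholds,
) -> OrthologTable:
    """Full table construction: dedupe -> classify -> score -> confidence call.

    ``recompute_goc`` derives GOC from the annotations' gene order (the
    default); otherwise any GOC column present in the input is trusted.
    """
    pairs = deduplicate_transcript_rows(raw_pairs)
    pairs = classify_relationships(pairs)
    if recompute_goc:
        pairs = compute_goc(
            pairs, annotation_a, annotation_b,
            orthologs_only=orthologs_only, match_strand=match_strand,
        )
    pairs = annotate_high_confidence(pairs, **thresholds)
    return OrthologTable(
        pairs,
        ref_universe={g.gene_id for g in annotation_a},
        query_universe={g.gene_id for g in annotation_b},
    )
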