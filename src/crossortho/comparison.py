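"""Cross-species merged expression table and shared/unique gene-set algebra.

Species tables are joined through the ortholog table (set keys are
ortholog-pair ids so many-to-one mappings survive), never normalised onto
a single scale. On the merged table: three-set Venn partitions of up/down
gene sets, common-regulated calls across supporting-cell populations,
high-confidence filtering, unique expression across the six analysed cell
types, and transcription-factor / deafness-gene list overlays.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix, expression_summary
from .orthology import OrthologTable

__all__ = [
    "MergedOrthologExpression",
    "SetReport",
    "IntegrityError",
    "merge_expression",
    "venn3",
    "common_regulated",
    "filter_high_confidence",
    "unique_expression",
    "overlay_annotation",
]

logger = logging.getLogger(__name__)


class IntegrityError(ValueError):
    """Cross-table consistency violation (duplicate genes, unknown pairs)."""


@dataclass
class MergedOrthologExpression:
    """One row per ortholog pair with both species' expression results.

    ``table`` (index: pair_id) carries gene ids/names, homology type, the
    high-confidence flag, per-cell-type ``mean_rpkm.<ct>`` / ``expressed.<ct>``
    columns, and per-contrast ``log2fc.<ct>`` / ``q.<ct>`` / ``call.<ct>``
    columns for every non-reference cell type of either species. Pairs
    lacking expression data in either species sit in ``excluded`` and never
    enter downstream set analyses.
    """

    table: pd.DataFrame
    excluded: pd.DataFrame
    cell_types_a: tuple[str, ...]
    cell_types_b: tuple[str, ...]
    reference_a: str
    reference_b: str

    @property
    def n_analyzed(self) -> int:
        return len(self.table)

    @property
    def n_excluded(self) -> int:
        return len(self.excluded)

    @property
    def contrast_cell_types(self) -> tuple[str, ...]:
        out = [ct for ct in self.cell_types_a if ct != self.reference_a]
        out += [ct for ct in self.cell_types_b if ct != self.reference_b]
        return tuple(out)

    def call_set(self, cell_type: str, direction: str) -> set[str]:
        """Pair ids called ``direction`` in the ``cell_type`` vs reference contrast."""
        col = f"call.{cell_type}"
        if col not in self.table.columns:
            raise KeyError(f"no contrast for cell type {cell_type!r}")
        return set(self.table.index[self.table[col] == direction])

    def high_confidence_ids(self) -> set[str]:
        return set(self.table.index[self.table["high_confidence"].astype(bool)])


def _species_frame(matrix: ExpressionMatrix, de: pd.DataFrame, summary: pd.DataFrame,
                   reference: str) -> pd.DataFrame:
    """Per-gene wide frame: summary columns plus per-contrast DE columns."""
    out = summary.copy()
    for ct, sub in de.groupby("cell_type"):
        sub = sub.set_index("gene_id")
        if sub.index.duplicated().any():
            raise IntegrityError(f"duplicated gene rows in DE table for {ct}")
        out[f"log2fc.{ct}"] = sub["log2fc"]
        out[f"q.{ct}"] = sub["fdr_q"]
        out[f"call.{ct}"] = sub["call"]
    return out


def merge_expression(
    ortholog_table: OrthologTable,
    matrix_a: ExpressionMatrix,
    matrix_b: ExpressionMatrix,
    de_a: pd.DataFrame,
    de_b: pd.DataFrame,
    rpkm_cutoff: float = 0.10,
    fdr_cutoff: float = 0.10,
    use_fdr: bool = True,
) -> MergedOrthologExpression:
    """Join both species' expression results onto the ortholog table.

    Inner join on ortholog pairs; a pair missing from either species'
    expression matrix is flagged and excluded from all downstream set
    analyses (its ids are kept in ``excluded`` for reporting). Cell-type
    names must be unique across the two species.
    """
    cts_a, cts_b = tuple(matrix_a.cell_types), tuple(matrix_b.cell_types)
    if set(cts_a) & set(cts_b):
        raise IntegrityError("cell-type names overlap between species")
    for m in (matrix_a, matrix_b):
        if m.values.index.duplicated().any():
            raise IntegrityError(f"duplicated gene ids in expression matrix {m.species!r}")

    frame_a = _species_frame(matrix_a, de_a,
                             expression_summary(matrix_a, rpkm_cutoff, fdr_cutoff, use_fdr),
                             matrix_a.reference_type)
    frame_b = _species_frame(matrix_b, de_b,
                             expression_summary(matrix_b, rpkm_cutoff, fdr_cutoff, use_fdr),
                             matrix_b.reference_type)

    pairs = ortholog_table.to_frame()
    if pairs.empty:
        logger.warning("empty ortholog table: merged expression table is empty")
    pairs["pair_id"] = pairs["ref_gene_id"] + "|" + pairs["query_gene_id"]
    pairs = pairs.set_index("pair_id")

    have_a = pairs["ref_gene_id"].isin(frame_a.index)
    have_b = pairs["query_gene_id"].isin(frame_b.index)
    analyzed = pairs[have_a & have_b].copy()
    excluded = pairs[~(have_a & have_b)].copy()
    excluded["missing_in"] = np.where(
        ~excluded["ref_gene_id"].isin(frame_a.index) & ~excluded["query_gene_id"].isin(frame_b.index),
        "both", np.where(~excluded["ref_gene_id"].isin(frame_a.index), "ref", "query"),
    )

    left = frame_a.reindex(analyzed["ref_gene_id"]).set_axis(analyzed.index)
    right = frame_b.reindex(analyzed["query_gene_id"]).set_axis(analyzed.index)
    table = pd.concat([analyzed, left, right], axis=1).sort_index()
    return MergedOrthologExpression(
        table=table, excluded=excluded.sort_index(),
        cell_types_a=cts_a, cell_types_b=cts_b,
        reference_a=matrix_a.reference_type, reference_b=matrix_b.reference_type,
    )


@dataclass
class SetReport:
    """Exact 7-region partition of three named gene sets.

    Region keys are sorted tuples of the population names whose sets the
    region's members belong to (and no others); the regions are pairwise
    disjoint and their union is the union of the three inputs.
    """

    names: tuple[str, str, str]
    regions: dict[tuple[str, ...], set[str]]
    high_confidence_counts: dict[tuple[str, ...], int] = field(default_factory=dict)

    def counts(self) -> dict[tuple[str, ...], int]:
        return {k: len(v) for k, v in self.regions.items()}

    def total(self) -> int:
        return sum(len(v) for v in self.regions.values())

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for key in sorted(self.regions, key=lambda k: (len(k), k)):
            rows.append({
                "region": "&".join(key),
                "n": len(self.regions[key]),
                "n_high_confidence": self.high_confidence_counts.get(key, 0),
                "members": ";".join(sorted(self.regions[key])),
            })
        return pd.DataFrame(rows)


def venn3(
    set_a: Iterable[str],
    set_b: Iterable[str],
    set_c: Iterable[str],
    names: tuple[str, str, str] = ("A", "B", "C"),
    high_confidence: Iterable[str] | None = None,
) -> SetReport:
    """Three-set Venn partition into its 7 disjoint regions."""
    sets = dict(zip(names, (set(set_a), set(set_b), set(set_c))))
    hc = set(high_confidence) if high_confidence is not None else set()
    regions: dict[tuple[str, ...], set[str]] = {}
    for r in (1, 2, 3):
        for inside in combinations(names, r):
            members = set.intersection(*(sets[n] for n in inside))
            for n in names:
                if n not in inside:
                    members -= sets[n]
            regions[tuple(inside)] = members
    report = SetReport(names=tuple(names), regions=regions)
    if high_confidence is not None:
        report.high_confidence_counts = {k: len(v & hc) for k, v in regions.items()}
    return report


def common_regulated(
    merged: MergedOrthologExpression,
    direction: str,
    populations: Sequence[str],
) -> set[str]:
    """Pairs whose DE call equals ``direction`` in every listed population.

    Populations are contrast cell types (each tested against its species'
    reference hair-cell type), e.g. ('nsSC', 'PC', 'DC') for the three
    supporting-cell populations.
    """
    if direction not in ("up", "down"):
        raise ValueError(f"direction {direction!r} must be 'up' or 'down'")
    if not populations:
        raise KeyError("at least one population required")
    out: set[str] | None = None
    for pop in populations:
        s = merged.call_set(pop, direction)
        out = s if out is None else out & s
    return out


def filter_high_confidence(
    pair_ids: Iterable[str],
    ortholog_table: OrthologTable,
) -> set[str]:
    """Subset of pairs flagged high-confidence in the ortholog table."""
    flags = {p.pair_id: bool(p.high_confidence) for p in ortholog_table.pairs}
    ids = set(pair_ids)
    unknown = ids - flags.keys()
    if unknown:
        raise IntegrityError(
            f"{len(unknown)} pair(s) absent from ortholog table, e.g. "
            f"{sorted(unknown)[:3]}"
        )
    return {i for i in ids if flags[i]}


def unique_expression(
    merged: MergedOrthologExpression,
    cell_types: Sequence[str] | None = None,
) -> dict[str, set[str]]:
    """Pairs expressed in exactly one of the analysed cell types.

    A pair is assigned to cell type T iff its expressed flag is true in T
    and false in every other listed cell type, so the output sets are
    pairwise disjoint. ``cell_types`` defaults to all six analysed types
    (both species); control tissues can be included or left out here.
    """
    if cell_types is None:
        cell_types = list(merged.cell_types_a) + list(merged.cell_types_b)
    if len(cell_types) < 2:
        raise ValueError("unique-expression analysis needs >= 2 cell types")
    flags = {}
    for ct in cell_types:
        col = f"expressed.{ct}"
        if col not in merged.table.columns:
            raise KeyError(f"no expressed flag for cell type {ct!r}")
        flags[ct] = merged.table[col].astype(bool)
    mat = pd.DataFrame(flags)
    exactly_one = mat.sum(axis=1) == 1
    return {
        ct: set(mat.index[exactly_one & mat[ct]])
        for ct in cell_types
    }


def overlay_annotation(
    pair_ids: Iterable[str],
    annotation: Iterable[str],
    merged: MergedOrthologExpression,
    key: str = "ref_gene_id",
    rank_by: str | None = None,
    top_n: int | None = None,
    min_match_rate: float = 0.0,
) -> pd.DataFrame:
    """Filter a result set by an annotation list (TF or deafness genes).

    ``key`` selects which column the annotation entries name (ref/query
    gene id or name). When the fraction of annotation entries found in the
    merged table falls below ``min_match_rate``, a warning reports the
    likely id-vs-name key mismatch. With ``rank_by`` (a contrast cell
    type), rows are sorted by descending log2 fold change, ties broken by
    pair id; ``top_n`` truncates after ranking.
    """
    ids = set(pair_ids)
    ann = set(annotation)
    sub = merged.table.loc[sorted(ids & set(merged.table.index))]
    matched_keys = set(sub[key]) & ann if len(sub) else set()
    universe_keys = set(merged.table[key])
    match_rate = (len(ann & universe_keys) / len(ann)) if ann else 0.0
    if ann and match_rate < min_match_rate:
        logger.warning(
            "annotation match rate %.2f below floor %.2f on key %r — "
            "possible gene-id vs gene-name mismatch", match_rate, min_match_rate, key,
        )
    out = sub[sub[key].isin(ann)].copy()
    out["match_rate"] = match_rate
    if rank_by is not None:
        col = f"log2fc.{rank_by}"
        if col not in out.columns:
            raise KeyError(f"no log2fc column for contrast cell type {rank_by!r}")
        order = sorted(out.index, key=lambda i: (-out.loc[i, col], i))
        out = out.loc[order]
    if top_n is not None:
        out = out.head(top_n)
    return out
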