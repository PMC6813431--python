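"""End-to-end pipeline driver: orthology -> expression -> comparison -> enrichment.

Reads everything declared in a PipelineConfig, writes each stage's TSVs to
the output directory plus a provenance manifest (config hash, seed, package
version, per-stage row counts), and — when a planted-truth directory is
configured — a recovery report scoring the pipeline against the truth.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .comparison import (
    common_regulated,
    filter_high_confidence,
    merge_expression,
    unique_expression,
    overlay_annotation,
    venn3,
)
from .enrichment import GeneSetCollection, enrich
from .expression import differential_expression
from .io import (
    PipelineConfig,
    read_expression,
    read_gene_list,
    read_gmt,
    read_gtf,
    read_homology,
    read_library_sizes,
    read_truth,
)
from .orthology import build_ortholog_table

__all__ = ["PipelineStageError", "run_pipeline", "recovery_report"]

logger = logging.getLogger(__name__)


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; message names the stage and the cause."""


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 — rewrap with stage name
                raise PipelineStageError(f"stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


def _config_hash(config: PipelineConfig) -> str:
    canon = yaml.safe_dump(
        {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(config).items()},
        sort_keys=True,
    )
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and write results + manifest under ``config.outdir``.

    Returns the manifest dict. Deterministic: identical inputs and config
    produce byte-identical outputs."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    @_stage("orthology")
    def stage_orthology():
        ann_a = read_gtf(config.annotation_a)
        ann_b = read_gtf(config.annotation_b)
        raw = read_homology(config.homology)
        table = build_ortholog_table(
            raw, ann_a, ann_b,
            match_strand=config.match_strand,
            pid_threshold=config.pid_threshold,
            goc_threshold=config.goc_threshold,
            wga_threshold=config.wga_threshold,
        )
        table.to_frame().to_csv(outdir / "ortholog_table.tsv", sep="\t", index=False)
        table.tally_frame().rename_axis("species").to_csv(
            outdir / "relationship_tallies.tsv", sep="\t")
        counts["homology_rows_raw"] = len(raw)
        counts["ortholog_pairs"] = len(table.pairs)
        return ann_a, ann_b, table

    @_stage("expression")
    def stage_expression(ann_a, ann_b):
        def load(path, species, reference, lib_path, ann):
            lib = read_library_sizes(lib_path) if lib_path else None
            lengths = pd.Series({g.gene_id: g.exonic_length for g in ann})
            m = read_expression(path, species, reference, config.value_kind,
                                library_sizes=lib, gene_lengths=lengths)
            return m.to_rpkm()

        matrix_a = load(config.expression_a, "a", config.reference_a,
                        config.library_sizes_a, ann_a)
        matrix_b = load(config.expression_b, "b", config.reference_b,
                        config.library_sizes_b, ann_b)
        de_a = differential_expression(
            matrix_a, config.pseudocount, config.lfc_threshold,
            config.fdr_cutoff, config.rpkm_cutoff)
        de_b = differential_expression(
            matrix_b, config.pseudocount, config.lfc_threshold,
            config.fdr_cutoff, config.rpkm_cutoff)
        de_a.to_csv(outdir / "de_a.tsv", sep="\t", index=False)
        de_b.to_csv(outdir / "de_b.tsv", sep="\t", index=False)
        counts["genes_a"] = len(matrix_a.gene_ids)
        counts["genes_b"] = len(matrix_b.gene_ids)
        return matrix_a, matrix_b, de_a, de_b

    @_stage("comparison")
    def stage_comparison(table, matrix_a, matrix_b, de_a, de_b):
        merged = merge_expression(
            table, matrix_a, matrix_b, de_a, de_b,
            rpkm_cutoff=config.rpkm_cutoff, fdr_cutoff=config.fdr_cutoff,
            use_fdr=config.use_fdr_in_expressed_call)
        merged.table.rename_axis("pair_id").to_csv(outdir / "merged.tsv", sep="\t")
        merged.excluded.rename_axis("pair_id").to_csv(outdir / "excluded.tsv", sep="\t")
        counts["merged_pairs_analyzed"] = merged.n_analyzed
        counts["merged_pairs_excluded"] = merged.n_excluded

        pops = list(config.populations)
        hc_ids = merged.high_confidence_ids()
        results: dict[str, set[str]] = {}
        for direction in ("up", "down"):
            per_pop = [merged.call_set(p, direction) for p in pops]
            if len(pops) == 3:
                venn3(*per_pop, names=tuple(pops),
                      high_confidence=hc_ids).to_frame().to_csv(
                    outdir / f"venn_{direction}.tsv", sep="\t", index=False)
            common = common_regulated(merged, direction, pops)
            common_hc = filter_high_confidence(common, table)
            results[f"common_{direction}"] = common
            pd.DataFrame({
                "pair_id": sorted(common),
                "high_confidence": [p in common_hc for p in sorted(common)],
            }).to_csv(outdir / f"common_{direction}.tsv", sep="\t", index=False)
            counts[f"common_{direction}"] = len(common)
            counts[f"common_{direction}_high_confidence"] = len(common_hc)

        uniq = unique_expression(merged, config.unique_cell_types)
        rows = [{"cell_type": ct, "pair_id": p}
                for ct in uniq for p in sorted(uniq[ct])]
        pd.DataFrame(rows, columns=["cell_type", "pair_id"]).to_csv(
            outdir / "unique_expression.tsv", sep="\t", index=False)
        for ct, s in uniq.items():
            counts[f"unique_{ct}"] = len(s)

        for label, path in (("tf", config.tf_list), ("deafness", config.deafness_list)):
            if path:
                ann_list = read_gene_list(path)
                key = "ref_gene_id" if ann_list and ann_list[0].startswith("G") else "ref_gene_name"
                overlay = overlay_annotation(
                    set(merged.table.index), ann_list, merged, key=key,
                    rank_by=pops[0] if pops else None)
                overlay.rename_axis("pair_id").to_csv(
                    outdir / f"{label}_overlay.tsv", sep="\t")
                counts[f"{label}_overlay"] = len(overlay)
        return merged, results

    @_stage("enrichment")
    def stage_enrichment(merged, results):
        if not config.gmt:
            return
        sets, desc = read_gmt(config.gmt)
        universe = set(merged.table.index)
        collection = GeneSetCollection.from_dict(sets, universe, desc)
        for name, query in results.items():
            if not query or len(collection) == 0:
                continue
            enr = enrich(query, collection, fdr_cutoff=None)
            enr.to_csv(outdir / f"enrichment_{name}.tsv", sep="\t", index=False)
            counts[f"enrichment_{name}"] = int((enr["fdr_q"] <= 0.05).sum())

    ann_a, ann_b, table = stage_orthology()
    matrix_a, matrix_b, de_a, de_b = stage_expression(ann_a, ann_b)
    merged, results = stage_comparison(table, matrix_a, matrix_b, de_a, de_b)
    stage_enrichment(merged, results)

    manifest = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "version": __version__,
        "row_counts": counts,
    }
    if config.truth_dir:
        report = recovery_report(config, table, merged, outdir)
        manifest["recovery"] = report
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _truth_missing_pairs(truth) -> int:
    """Pairs touching at least one planted missing-expression gene."""
    missing = set(truth.genes_a.loc[truth.genes_a["missing_expression"], "gene_id"])
    missing |= set(truth.genes_b.loc[truth.genes_b["missing_expression"], "gene_id"])
    tp = truth.pairs
    return int((tp["ref_gene_id"].isin(missing)
                | tp["query_gene_id"].isin(missing)).sum())


def recovery_report(config: PipelineConfig, table, merged, outdir: Path) -> dict:
    """Score pipeline output against the simulator's planted truth."""
    truth = read_truth(config.truth_dir)
    tp = truth.pairs.copy()
    tp["pair_id"] = tp["ref_gene_id"] + "|" + tp["query_gene_id"]
    tp = tp.set_index("pair_id")
    by_id = table.by_pair_id()

    shared = [pid for pid in tp.index if pid in by_id]
    class_ok = sum(by_id[p].homology_type == tp.loc[p, "homology_class"] for p in shared)
    hc_ok = sum(bool(by_id[p].high_confidence) == bool(tp.loc[p, "high_confidence"])
                for p in shared)

    # DE recovery on the first configured population's contrast (species A).
    # Pairs with planted unique expression are excluded from the DE metric:
    # a gene expressed only in the contrast cell type is genuinely (and
    # extremely) regulated, but by the unique-expression mechanism, which
    # is scored separately.
    pop = config.populations[0]
    ref_of = {pid: by_id[pid].ref_gene_id for pid in merged.table.index}
    uniq_planted_genes = set(
        truth.genes_a.loc[truth.genes_a["unique_cell_type"] != "", "gene_id"])
    uniq_pairs = {p for p, r in ref_of.items() if r in uniq_planted_genes}
    called_up = merged.call_set(pop, "up") - uniq_pairs
    called_down = merged.call_set(pop, "down") - uniq_pairs
    true_up = truth.de_genes("a", "up")
    true_down = truth.de_genes("a", "down")
    analyzed_true_up = {p for p, r in ref_of.items() if r in true_up}
    analyzed_true_down = {p for p, r in ref_of.items() if r in true_down}

    def prf(called, truth_set):
        tp_n = len(called & truth_set)
        recall = tp_n / len(truth_set) if truth_set else float("nan")
        precision = tp_n / len(called) if called else float("nan")
        return {"recall": recall, "precision": precision,
                "n_called": len(called), "n_true": len(truth_set)}

    uniq = unique_expression(merged, config.unique_cell_types)
    uniq_stats = {}
    for ct, found in uniq.items():
        planted = {p for p, r in ref_of.items()
                   if r in truth.unique_genes(ct)} | {
                   p for p in merged.table.index
                   if by_id[p].query_gene_id in truth.unique_genes(ct)}
        if planted:
            uniq_stats[ct] = len(found & planted) / len(planted)

    report = {
        "n_truth_pairs": int(len(tp)),
        "n_pairs_recovered": len(shared),
        "homology_class_accuracy": class_ok / len(shared) if shared else float("nan"),
        "high_confidence_accuracy": hc_ok / len(shared) if shared else float("nan"),
        "de_up": prf(called_up, analyzed_true_up),
        "de_down": prf(called_down, analyzed_true_down),
        "unique_expression_recall": uniq_stats,
        "n_excluded_missing_data": merged.n_excluded,
        "n_truth_missing_pairs": _truth_missing_pairs(truth),
    }
    (outdir / "recovery.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
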