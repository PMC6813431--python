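import pytest

from crossortho.comparison import merge_expression
from crossortho.expression import differential_expression
from crossortho.orthology import GeneModel, build_ortholog_table
from crossortho.simulate import SimConfig, simulate_bundle


def make_gene(gene_id, chrom, start, length=1000, name=None, strand="+"):
    """Single-exon gene helper for hand-built fixtures."""
    return GeneModel(
        gene_id=gene_id, gene_name=name or gene_id.lower(), chromosome=chrom,
        start=start, end=start + length - 1, strand=strand,
        exon_intervals=((start, start + length - 1),),
    )


def make_order(ids, chrom="chr1", spacing=10_000):
    """Genes placed in the given order along one chromosome."""
    return [make_gene(g, chrom, 1 + i * spacing) for i, g in enumerate(ids)]


@pytest.fixture(scope="session")
def strong_effect_bundle():
    """Simulation under strong, well-replicated planted effects.

    log2 effect of 3 with five replicates and low count dispersion — the
    regime where planted differential expression should be essentially
    fully recoverable at the default thresholds.
    """
    config = SimConfig(n_base_genes=300, seed=11, log2fc_effect=3.0,
                       n_replicates=5, nb_dispersion=0.05)
    ann_a, ann_b, raw, truth, matrix_a, matrix_b = simulate_bundle(config)
    table = build_ortholog_table(raw, ann_a, ann_b)
    de_a = differential_expression(matrix_a.to_rpkm())
    de_b = differential_expression(matrix_b.to_rpkm())
    merged = merge_expression(table, matrix_a, matrix_b, de_a, de_b)
    return {
        "config": config, "ann_a": ann_a, "ann_b": ann_b, "raw": raw,
        "truth": truth, "matrix_a": matrix_a, "matrix_b": matrix_b,
        "table": table, "de_a": de_a, "de_b": de_b, "merged": merged,
    }


@pytest.fixture(scope="session")
def default_bundle():
    """Small simulation under the default study conditions."""
    config = SimConfig(n_base_genes=120, seed=5)
    ann_a, ann_b, raw, truth, matrix_a, matrix_b = simulate_bundle(config)
    table = build_ortholog_table(raw, ann_a, ann_b)
    return {
        "config": config, "ann_a": ann_a, "ann_b": ann_b, "raw": raw,
        "truth": truth, "matrix_a": matrix_a, "matrix_b": matrix_b,
        "table": table,
    }
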