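"""Merged table semantics and shared/unique gene-set algebra."""

import itertools

import numpy as np
import pandas as pd
import pytest

from crossortho.comparison import (
    IntegrityError,
    MergedOrthologExpression,
    SetReport,
    common_regulated,
    filter_high_confidence,
    merge_expression,
    overlay_annotation,
    unique_expression,
    venn3,
)
from crossortho.expression import differential_expression
from crossortho.orthology import HomologyPair, OrthologTable, build_ortholog_table

from conftest import make_order


def venn_oracle(a, b, c, names=("A", "B", "C")):
    """Membership-vector enumeration over the union."""
    sets = dict(zip(names, (set(a), set(b), set(c))))
    out = {}
    for x in set(a) | set(b) | set(c):
        key = tuple(n for n in names if x in sets[n])
        out.setdefault(key, set()).add(x)
    return out


class TestVenn:
    def test_identical_sets_fill_only_triple_region(self):
        r = venn3({"x", "y"}, {"x", "y"}, {"x", "y"})
        assert r.regions[("A", "B", "C")] == {"x", "y"}
        assert sum(map(len, r.regions.values())) == 2

    def test_disjoint_sets_fill_only_singleton_regions(self):
        r = venn3({"a"}, {"b"}, {"c"})
        assert r.regions[("A",)] == {"a"}
        assert r.regions[("B",)] == {"b"}
        assert r.regions[("C",)] == {"c"}
        assert all(not r.regions[k] for k in r.regions if len(k) > 1)

    def test_matches_enumeration_oracle_on_random_sets(self):
        rng = np.random.default_rng(3)
        universe = [f"g{i}" for i in range(20)]
        for _ in range(200):
            a, b, c = (set(rng.choice(universe, rng.integers(0, 15), replace=False))
                       for _ in range(3))
            got = {k: v for k, v in venn3(a, b, c).regions.items() if v}
            assert got == venn_oracle(a, b, c)

    def test_partition_sums_to_union(self):
        rng = np.random.default_rng(4)
        universe = [f"g{i}" for i in range(30)]
        for _ in range(50):
            a, b, c = (set(rng.choice(universe, rng.integers(0, 25), replace=False))
                       for _ in range(3))
            r = venn3(a, b, c)
            assert r.total() == len(a | b | c)
            regions = list(r.regions.values())
            for x, y in itertools.combinations(regions, 2):
                assert not x & y

    def test_high_confidence_subcounts(self):
        r = venn3({"x", "y"}, {"x"}, set(), high_confidence={"x"})
        assert r.high_confidence_counts[("A", "B")] == 1
        assert r.high_confidence_counts[("A",)] == 0


@pytest.fixture(scope="module")
def merged(strong_effect_bundle):
    return strong_effect_bundle["merged"]


class TestMerge:
    def test_missing_expression_pairs_flagged_and_excluded(self, strong_effect_bundle):
        merged = strong_effect_bundle["merged"]
        truth = strong_effect_bundle["truth"]
        missing_genes = set(
            truth.genes_a.loc[truth.genes_a["missing_expression"], "gene_id"]
        ) | set(truth.genes_b.loc[truth.genes_b["missing_expression"], "gene_id"])
        expected_excluded = {
            f"{r.ref_gene_id}|{r.query_gene_id}" for r in truth.pairs.itertuples()
            if r.ref_gene_id in missing_genes or r.query_gene_id in missing_genes}
        assert set(merged.excluded.index) == expected_excluded
        assert merged.n_analyzed == len(truth.pairs) - len(expected_excluded)
        assert not set(merged.table.index) & expected_excluded

    def test_empty_ortholog_table_gives_empty_merge(self, strong_effect_bundle):
        b = strong_effect_bundle
        empty = OrthologTable(pairs=[])
        merged = merge_expression(empty, b["matrix_a"], b["matrix_b"],
                                  b["de_a"], b["de_b"])
        assert merged.n_analyzed == 0 and merged.n_excluded == 0

    def test_duplicate_gene_rows_rejected(self, strong_effect_bundle):
        b = strong_effect_bundle
        m = b["matrix_a"]
        dup = m.values.iloc[[0] + list(range(len(m.values)))]
        bad = type(m)(species=m.species, values=dup, reference_type=m.reference_type,
                      value_kind="rpkm")
        with pytest.raises(IntegrityError):
            merge_expression(b["table"], bad.to_rpkm(), b["matrix_b"],
                             b["de_a"], b["de_b"])


class TestCommonRegulated:
    def test_requires_direction_in_all_populations(self, merged):
        pops = ("nsSC", "PC", "DC")
        for direction in ("up", "down"):
            common = common_regulated(merged, direction, pops)
            for pop in pops:
                assert common <= merged.call_set(pop, direction)

    def test_monotone_nesting(self, merged):
        s1 = common_regulated(merged, "down", ("nsSC",))
        s2 = common_regulated(merged, "down", ("nsSC", "PC"))
        s3 = common_regulated(merged, "down", ("nsSC", "PC", "DC"))
        assert s3 <= s2 <= s1

    def test_planted_pan_population_de_recovered(self, strong_effect_bundle):
        merged = strong_effect_bundle["merged"]
        truth = strong_effect_bundle["truth"]
        ref_of = dict(zip(merged.table.index, merged.table["ref_gene_id"]))
        for direction in ("up", "down"):
            planted = truth.de_genes("a", direction)
            planted_pairs = {p for p, r in ref_of.items() if r in planted}
            common = common_regulated(merged, direction, ("nsSC", "PC", "DC"))
            recall = len(common & planted_pairs) / len(planted_pairs)
            assert recall >= 0.95

    def test_unknown_population_raises(self, merged):
        with pytest.raises(KeyError):
            common_regulated(merged, "up", ("nope",))


class TestHighConfidenceFilter:
    def test_filter_matches_truth_threshold_rule(self, strong_effect_bundle):
        table = strong_effect_bundle["table"]
        truth = strong_effect_bundle["truth"]
        ids = {p.pair_id for p in table.pairs}
        got = filter_high_confidence(ids, table)
        want = {f"{r.ref_gene_id}|{r.query_gene_id}"
                for r in truth.pairs.itertuples() if r.high_confidence}
        assert got == want

    def test_commutes_with_intersection(self, strong_effect_bundle):
        table = strong_effect_bundle["table"]
        rng = np.random.default_rng(5)
        ids = sorted(p.pair_id for p in table.pairs)
        for _ in range(50):
            a = set(rng.choice(ids, 40, replace=False))
            b = set(rng.choice(ids, 40, replace=False))
            assert filter_high_confidence(a & b, table) == \
                filter_high_confidence(a, table) & filter_high_confidence(b, table)

    def test_unknown_pair_raises(self, strong_effect_bundle):
        with pytest.raises(IntegrityError):
            filter_high_confidence({"no|pair"}, strong_effect_bundle["table"])


class TestUniqueExpression:
    def test_sets_are_pairwise_disjoint_and_exclusive(self, merged):
        uniq = unique_expression(merged)
        for a, b in itertools.combinations(uniq.values(), 2):
            assert not a & b
        # a pair expressed in two cell types belongs to no unique set
        cts = list(merged.cell_types_a) + list(merged.cell_types_b)
        flags = merged.table[[f"expressed.{ct}" for ct in cts]].astype(bool)
        multi = set(flags.index[flags.sum(axis=1) >= 2])
        assert not multi & set().union(*uniq.values())

    def test_planted_unique_genes_recovered(self, strong_effect_bundle):
        merged = strong_effect_bundle["merged"]
        truth = strong_effect_bundle["truth"]
        uniq = unique_expression(merged)
        checked = 0
        for ct, found in uniq.items():
            genes = truth.unique_genes(ct)
            planted = {p for p in merged.table.index
                       if merged.table.loc[p, "ref_gene_id"] in genes
                       or merged.table.loc[p, "query_gene_id"] in genes}
            if planted:
                assert len(found & planted) / len(planted) >= 0.95
                checked += len(planted)
        assert checked >= 5

    def test_needs_at_least_two_cell_types(self, merged):
        with pytest.raises(ValueError):
            unique_expression(merged, cell_types=["nsSC"])


class TestOverlay:
    def test_empty_annotation_gives_empty_subset(self, merged):
        out = overlay_annotation(set(merged.table.index), [], merged)
        assert len(out) == 0

    def test_planted_tf_flags_recovered(self, strong_effect_bundle):
        merged = strong_effect_bundle["merged"]
        truth = strong_effect_bundle["truth"]
        tf_ids = set(truth.genes_a.loc[truth.genes_a["tf"], "gene_id"])
        out = overlay_annotation(set(merged.table.index), tf_ids, merged,
                                 key="ref_gene_id")
        want = set(merged.table.index[merged.table["ref_gene_id"].isin(tf_ids)])
        assert set(out.index) == want

    def test_top_n_ranking_deterministic_with_ties(self, merged):
        ids = set(merged.table.index)
        ann = set(merged.table["ref_gene_id"])
        big = overlay_annotation(ids, ann, merged, key="ref_gene_id",
                                 rank_by="nsSC", top_n=10 ** 6)
        assert len(big) == len(ids)
        lfc = big["log2fc.nsSC"].values
        assert (np.diff(lfc) <= 1e-12).all()
        small = overlay_annotation(ids, ann, merged, key="ref_gene_id",
                                   rank_by="nsSC", top_n=5)
        assert list(small.index) == list(big.index[:5])

    def test_mismatched_key_style_warns(self, merged, caplog):
        import logging
        with caplog.at_level(logging.WARNING):
            overlay_annotation(set(merged.table.index), {"not-a-real-name"},
                               merged, key="ref_gene_name", min_match_rate=0.5)
        assert any("match rate" in r.message for r in caplog.records)
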