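"""Ortholog table construction: dedup, classification, GOC/WGA, confidence."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from crossortho.orthology import (
    GeneModel,
    GenomeOrder,
    HomologyPair,
    StructuralError,
    build_ortholog_table,
    call_high_confidence,
    classify_relationships,
    collapse_query_redundancy,
    compute_goc,
    deduplicate_transcript_rows,
    goc_score,
    relationship_tallies,
    wga_score,
)

from conftest import make_gene, make_order


def pair(ref, query, **kw):
    return HomologyPair(ref_gene_id=ref, query_gene_id=query, **kw)


class TestDeduplication:
    def test_transcript_rows_collapse_to_one(self):
        pairs = [pair("A1", "B1")] * 4
        assert len(deduplicate_transcript_rows(pairs)) == 1

    def test_paralog_edges_are_not_transcript_redundancy(self):
        pairs = [pair("A1", "B1"), pair("A1", "B2")]
        assert len(deduplicate_transcript_rows(pairs)) == 2

    def test_first_occurrence_kept(self):
        pairs = [pair("A1", "B1", percent_identity=60.0),
                 pair("A1", "B1", percent_identity=60.0)]
        out = deduplicate_transcript_rows(pairs)
        assert out[0] is pairs[0]


def brute_force_classes(edges):
    """Independent component analysis: BFS on adjacency dicts."""
    adj = {}
    for a, b in edges:
        adj.setdefault(("A", a), set()).add(("B", b))
        adj.setdefault(("B", b), set()).add(("A", a))
    label = {}
    seen = set()
    for start in adj:
        if start in seen:
            continue
        comp, frontier = set(), [start]
        while frontier:
            n = frontier.pop()
            if n in comp:
                continue
            comp.add(n)
            frontier.extend(adj[n])
        seen |= comp
        multi_a = any(s == "A" and len(adj[(s, g)]) > 1 for s, g in comp)
        multi_b = any(s == "B" and len(adj[(s, g)]) > 1 for s, g in comp)
        cls = ("many2many" if multi_a and multi_b
               else "many2one" if multi_a or multi_b else "one2one")
        for n in comp:
            label[n] = cls
    return {(a, b): label[("A", a)] for a, b in edges}


class TestClassification:
    def test_single_edge_is_one2one(self):
        out = classify_relationships([pair("A1", "B1")])
        assert out[0].homology_type == "one2one"

    def test_shared_query_gene_is_many2one_with_asymmetric_tallies(self):
        out = classify_relationships([pair("A1", "B1"), pair("A2", "B1")])
        assert {p.homology_type for p in out} == {"many2one"}
        t = relationship_tallies(out)
        assert t.loc["ref", "many2one"] == 2
        assert t.loc["query", "many2one"] == 1

    def test_many2many_needs_multi_degree_on_both_sides(self):
        out = classify_relationships(
            [pair("A1", "B1"), pair("A1", "B2"), pair("A2", "B1")])
        assert {p.homology_type for p in out} == {"many2many"}

    def test_same_id_edge_rejected(self):
        with pytest.raises(StructuralError):
            classify_relationships([pair("X1", "X1")])

    def test_matches_component_oracle_on_random_bipartite_graphs(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n_a, n_b = rng.integers(1, 16, 2)
            n_edges = int(rng.integers(1, 31))
            edges = {(f"A{rng.integers(n_a)}", f"B{rng.integers(n_b)}")
                     for _ in range(n_edges)}
            expected = brute_force_classes(edges)
            out = classify_relationships([pair(a, b) for a, b in sorted(edges)])
            assert {(p.ref_gene_id, p.query_gene_id): p.homology_type
                    for p in out} == expected

    def test_matches_oracle_on_all_k33_subgraphs(self):
        """Exhaustive: every edge-subset of the complete bipartite 3x3 graph."""
        all_edges = [(f"A{i}", f"B{j}") for i in range(3) for j in range(3)]
        for mask in range(1, 2 ** 9):
            edges = [e for k, e in enumerate(all_edges) if mask >> k & 1]
            expected = brute_force_classes(edges)
            out = classify_relationships([pair(a, b) for a, b in edges])
            assert {(p.ref_gene_id, p.query_gene_id): p.homology_type
                    for p in out} == expected


class TestCollapse:
    def test_distinct_counts(self):
        ref, query = collapse_query_redundancy([pair("A1", "B1"), pair("A2", "B1")])
        assert (len(ref), len(query)) == (2, 1)

    def test_one2one_counts_equal(self):
        pairs = [pair(f"A{i}", f"B{i}") for i in range(5)]
        ref, query = collapse_query_redundancy(pairs)
        assert len(ref) == len(query) == 5


def brute_goc(gene, partner, omap, genes_a, genes_b):
    """Oracle: direct slicing of per-chromosome orthologous gene orders."""
    keep_a = set(omap)
    keep_b = {q for qs in omap.values() for q in qs}

    def orders(genes, keep):
        out = {}
        for g in sorted(genes, key=lambda g: (g.chromosome, g.start, g.gene_id)):
            if g.gene_id in keep:
                out.setdefault(g.chromosome, []).append(g.gene_id)
        return out

    oa, ob = orders(genes_a, keep_a), orders(genes_b, keep_b)
    ca, ia = next((c, ids.index(gene)) for c, ids in oa.items() if gene in ids)
    cb, ib = next((c, ids.index(partner)) for c, ids in ob.items() if partner in ids)
    nbs = oa[ca][max(0, ia - 2):ia] + oa[ca][ia + 1:ia + 3]
    window = set(ob[cb][max(0, ib - 2):ib] + ob[cb][ib + 1:ib + 3])
    return 25 * sum(1 for nb in nbs if omap.get(nb, set()) & window)


class TestGOC:
    def test_fully_conserved_neighborhood_scores_100(self):
        ids = [f"A{i}" for i in range(9)]
        genes_a = make_order(ids)
        genes_b = make_order([f"B{i}" for i in range(9)])
        omap = {f"A{i}": {f"B{i}"} for i in range(9)}
        oa, ob = GenomeOrder(genes_a), GenomeOrder(genes_b)
        assert goc_score("A4", "B4", omap, oa, ob) == 100

    def test_single_conserved_neighbor_scores_25(self):
        genes_a = make_order([f"A{i}" for i in range(9)])
        # only A3's ortholog stays near the partner; the rest go far away
        genes_b = make_order(["B0", "B1", "B3", "B4", "B8"], chrom="chr1") + \
            make_order(["B2", "B5", "B6", "B7"], chrom="chr2")
        omap = {f"A{i}": {f"B{i}"} for i in range(9)}
        oa, ob = GenomeOrder(genes_a), GenomeOrder(genes_b)
        assert goc_score("A4", "B4", omap, oa, ob) == 25

    def test_chromosome_end_genes_keep_denominator_of_four(self):
        genes_a = make_order([f"A{i}" for i in range(5)])
        genes_b = make_order([f"B{i}" for i in range(5)])
        omap = {f"A{i}": {f"B{i}"} for i in range(5)}
        oa, ob = GenomeOrder(genes_a), GenomeOrder(genes_b)
        # first gene has only two (downstream) neighbours -> at most 50
        assert goc_score("A0", "B0", omap, oa, ob) == 50

    def test_score_on_lattice_and_matches_oracle_on_random_genomes(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = int(rng.integers(4, 20))
            n_chrom = int(rng.integers(1, 3))
            ids_a = [f"A{i}" for i in range(n)]
            ids_b = [f"B{i}" for i in range(n)]
            perm = rng.permutation(n)
            genes_a, genes_b = [], []
            for k, i in enumerate(range(n)):
                genes_a.append(make_gene(ids_a[i], f"chr{i % n_chrom}", 1 + k * 5000))
            for k, i in enumerate(perm):
                genes_b.append(make_gene(ids_b[i], f"chr{k % n_chrom}", 1 + k * 5000))
            omap = {}
            for i in range(n):
                if rng.random() < 0.8:
                    omap.setdefault(ids_a[i], set()).add(ids_b[i])
                if rng.random() < 0.2:
                    omap.setdefault(ids_a[i], set()).add(ids_b[int(rng.integers(n))])
            keep_b = {q for qs in omap.values() for q in qs}
            oa = GenomeOrder(genes_a, restrict_to=set(omap))
            ob = GenomeOrder(genes_b, restrict_to=keep_b)
            for a, qs in omap.items():
                for b in qs:
                    got = goc_score(a, b, omap, oa, ob)
                    assert got in (0, 25, 50, 75, 100)
                    assert got == brute_goc(a, b, omap, genes_a, genes_b)

    def test_invariant_under_gene_id_relabeling(self):
        genes_a = make_order([f"A{i}" for i in range(7)])
        genes_b = make_order([f"B{i}" for i in range(7)])
        omap = {f"A{i}": {f"B{i}"} for i in range(7)}
        base = goc_score("A3", "B3", omap, GenomeOrder(genes_a), GenomeOrder(genes_b))
        ren_a = [make_gene(f"X{i}", g.chromosome, g.start)
                 for i, g in enumerate(genes_a)]
        ren_b = [make_gene(f"Y{i}", g.chromosome, g.start)
                 for i, g in enumerate(genes_b)]
        omap2 = {f"X{i}": {f"Y{i}"} for i in range(7)}
        assert goc_score("X3", "Y3", omap2, GenomeOrder(ren_a), GenomeOrder(ren_b)) == base

    def test_missing_gene_raises_lookup_error(self):
        order = GenomeOrder(make_order(["A0", "A1", "A2"]))
        with pytest.raises(KeyError):
            order.neighbors("nope")


class TestWGA:
    def test_full_coverage_scores_100(self):
        assert wga_score(1, 1, 1, 1) == 100

    def test_zero_coverage_scores_0(self):
        assert wga_score(0, 0, 0, 0) == 0

    def test_weighted_arithmetic(self):
        # per gene: 100 * (0.75*0.8 + 0.25*0.4) = 70; mean of equal genes = 70
        assert wga_score(0.8, 0.4, 0.8, 0.4, exon_weight=0.75) == pytest.approx(70)

    def test_pair_score_averages_the_two_genes(self):
        assert wga_score(1, 1, 0, 0) == pytest.approx(50)

    @pytest.mark.parametrize("bad", [-0.1, 1.1])
    def test_coverage_domain_checked(self, bad):
        with pytest.raises(ValueError):
            wga_score(bad, 0.5, 0.5, 0.5)

    def test_exon_weight_must_exceed_intron_weight(self):
        with pytest.raises(ValueError):
            wga_score(1, 1, 1, 1, exon_weight=0.5)


class TestHighConfidence:
    @pytest.mark.parametrize("pid,goc,wga,expected", [
        (60.0, 100.0, None, True),    # GOC clause alone suffices
        (49.0, 100.0, 100.0, False),  # %ID clause fails
        (50.0, 75.0, 0.0, True),      # inclusive boundaries
        (50.0, 0.0, 75.0, True),      # WGA clause alone suffices
        (50.0, 50.0, 74.9, False),
        (50.0, None, None, False),    # both scores missing -> never confident
        (100.0, None, 75.0, True),
    ])
    def test_rule_table(self, pid, goc, wga, expected):
        p = pair("A1", "B1", percent_identity=pid, goc_score=goc, wga_score=wga)
        assert call_high_confidence(p) is expected

    @settings(max_examples=200, derandomize=True)
    @given(
        pid=st.floats(0, 100), goc=st.sampled_from([None, 0.0, 25.0, 50.0, 75.0, 100.0]),
        wga=st.one_of(st.none(), st.floats(0, 100)),
        bump=st.floats(0, 50),
    )
    def test_monotone_in_every_score(self, pid, goc, wga, bump):
        base = call_high_confidence(pair("A1", "B1", percent_identity=pid,
                                         goc_score=goc, wga_score=wga))
        raised = pair("A1", "B1",
                      percent_identity=min(pid + bump, 100),
                      goc_score=goc,
                      wga_score=None if wga is None else min(wga + bump, 100))
        assert not (base and not call_high_confidence(raised))


class TestEndToEnd:
    def test_simulator_dedup_recovers_truth_edge_count(self, default_bundle):
        """Per-transcript row duplication collapses back to the planted edges."""
        raw, truth = default_bundle["raw"], default_bundle["truth"]
        tc = {g.gene_id: g.transcript_count for g in default_bundle["ann_a"]}
        inflated = [p for p in raw for _ in range(tc[p.ref_gene_id])]
        assert len(deduplicate_transcript_rows(inflated)) == len(truth.pairs)

    def test_internal_genes_score_100_without_rearrangement_or_expansion(self):
        """Conserved order with interleaved orphans: full GOC for every
        internal gene. Orphans must not consume neighbour slots."""
        from crossortho.simulate import SimConfig, simulate_genomes
        cfg = SimConfig(n_base_genes=150, rearrangement_rate=0.0,
                        paralog_expansion_prob=0.0, paralog_expansion_prob_b=0.0,
                        seed=3)
        ann_a, ann_b, raw, truth = simulate_genomes(cfg)
        table = build_ortholog_table(raw, ann_a, ann_b)
        assert {p.homology_type for p in table.pairs} == {"one2one"}
        one2one = {p.ref_gene_id: p for p in table.pairs if p.homology_type == "one2one"}
        ref_ids = {p.ref_gene_id for p in table.pairs}
        query_ids = {p.query_gene_id for p in table.pairs}
        oa = GenomeOrder(ann_a, restrict_to=ref_ids)
        ob = GenomeOrder(ann_b, restrict_to=query_ids)
        checked = 0
        for rid, p in one2one.items():
            if len(oa.neighbors(rid)) == 4 and len(ob.neighbors(p.query_gene_id)) == 4:
                assert p.goc_score == 100, rid
                checked += 1
        assert checked > 20

    def test_tally_frame_is_internally_consistent(self, default_bundle):
        t = default_bundle["table"].tally_frame()
        assert (t["total_orthologs"] + t["unique_genes"]
                == t["total_protein_coding"]).all()
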