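import networkx as nx
import numpy as np
import pytest

from repeatscape import align, cluster_engine, synthetic
from repeatscape.cluster_engine import AlignmentHit, ClusterSet
from repeatscape.seqio import SequenceRecord, revcomp

import oracles
from conftest import random_seq


def _records(seqs):
    return [SequenceRecord(f"r{i}", s) for i, s in enumerate(seqs)]


class TestPairwiseHits:
    def test_identical_reads_full_length_hit(self, rng):
        s = random_seq(rng, 100)
        (hit,) = cluster_engine.pairwise_hits(_records([s, s]))
        assert hit.score == 100
        assert hit.length == 100
        assert hit.identity == 100.0

    def test_reverse_complement_equivalent_to_forward(self, rng):
        s = random_seq(rng, 100)
        (fwd,) = cluster_engine.pairwise_hits(_records([s, s]))
        (rev,) = cluster_engine.pairwise_hits(_records([s, revcomp(s)]))
        assert (rev.score, rev.length, rev.identity) == (
            fwd.score, fwd.length, fwd.identity
        )

    def test_shared_block_hit_matches_dp_oracle(self, rng):
        block = random_seq(rng, 60)
        a = random_seq(rng, 20) + block + random_seq(rng, 20)
        b = random_seq(rng, 25) + block + random_seq(rng, 15)
        hits = cluster_engine.pairwise_hits(
            _records([a, b]), min_len=55, min_identity=90.0, min_coverage=0.55
        )
        assert len(hits) == 1
        assert hits[0].length >= 60
        assert hits[0].score == oracles.sw_score_strands(a, b)

    def test_dissimilar_reads_emit_nothing(self, rng):
        hits = cluster_engine.pairwise_hits(
            _records([random_seq(rng, 100), random_seq(rng, 100)])
        )
        assert hits == []


class TestBuildGraph:
    def test_no_hits_all_unclustered(self):
        sim = cluster_engine.build_graph([], all_read_ids=["a", "b", "c"])
        assert sim.graph.number_of_nodes() == 0
        assert sim.unclustered == ["a", "b", "c"]

    def test_triangle(self):
        hits = [
            AlignmentHit("a", "b", 60, 99.0, 55),
            AlignmentHit("a", "c", 60, 99.0, 50),
            AlignmentHit("b", "c", 60, 99.0, 45),
        ]
        sim = cluster_engine.build_graph(hits, all_read_ids="abc")
        assert sim.graph.number_of_edges() == 3
        assert sim.unclustered == []

    def test_duplicate_hit_keeps_max_score(self):
        hits = [
            AlignmentHit("a", "b", 60, 99.0, 40),
            AlignmentHit("b", "a", 60, 99.0, 70),
        ]
        sim = cluster_engine.build_graph(hits)
        assert sim.graph["a"]["b"]["weight"] == 70


class TestLouvain:
    def _two_cliques(self):
        g = nx.Graph()
        for base in (0, 4):
            for i in range(4):
                for j in range(i + 1, 4):
                    g.add_edge(base + i, base + j, weight=1.0)
        return g

    def test_two_disjoint_cliques_optimal(self):
        cs = cluster_engine.louvain(self._two_cliques(), seed=0)
        assert cs.modularity == pytest.approx(0.5)
        groups = sorted(sorted(v) for v in cs.clusters.values())
        assert groups == [[0, 1, 2, 3], [4, 5, 6, 7]]

    def test_single_edge_single_community(self):
        g = nx.Graph()
        g.add_edge("x", "y", weight=2.0)
        cs = cluster_engine.louvain(g, seed=0)
        assert len(cs.clusters) == 1
        assert cs.modularity == pytest.approx(0.0)

    def test_reported_q_matches_independent_formula(self, rng):
        g = nx.gnp_random_graph(20, 0.25, seed=7)
        for u, v in g.edges:
            g[u][v]["weight"] = float(rng.uniform(0.5, 2.0))
        cs = cluster_engine.louvain(g, seed=1)
        edges = {(u, v): g[u][v]["weight"] for u, v in g.edges}
        q = oracles.modularity(edges, list(g.nodes), cs.clusters.values())
        assert cs.modularity == pytest.approx(q, abs=1e-12)

    def test_matches_exhaustive_optimum_on_small_graphs(self, rng):
        wins = 0
        for trial in range(50):
            n = int(rng.integers(4, 9))
            g = nx.gnp_random_graph(n, 0.5, seed=int(rng.integers(0, 10 ** 6)))
            if g.number_of_edges() == 0:
                g.add_edge(0, 1)
            for u, v in g.edges:
                g[u][v]["weight"] = float(rng.uniform(0.5, 2.0))
            cs = cluster_engine.louvain(g, seed=trial)
            edges = {(u, v): g[u][v]["weight"] for u, v in g.edges}
            qmax = oracles.max_modularity(edges, list(g.nodes))
            if cs.modularity >= qmax - 1e-9:
                wins += 1
        assert wins == 50

    def test_deterministic_given_seed(self, rng):
        g = nx.gnp_random_graph(30, 0.2, seed=3)
        for u, v in g.edges:
            g[u][v]["weight"] = float(rng.uniform(0.5, 2.0))
        a = cluster_engine.louvain(g, seed=5)
        b = cluster_engine.louvain(g, seed=5)
        assert a.clusters == b.clusters

    def test_empty_graph_is_error(self):
        with pytest.raises(ValueError):
            cluster_engine.louvain(nx.Graph(), seed=0)


class TestMergeByMates:
    def _clusters(self, groups):
        return ClusterSet(
            clusters={f"CL{i}": sorted(g) for i, g in enumerate(groups)},
            modularity=0.0,
        )

    def test_two_links_merge(self):
        cs = self._clusters([["r1a", "r2a"], ["r1b", "r2b"]])
        merged = cluster_engine.merge_by_mates(
            cs, [("r1a", "r1b"), ("r2a", "r2b")], min_links=2
        )
        assert len(merged.clusters) == 1
        assert merged.merge_log[0]["links"] == 2

    def test_below_threshold_unchanged(self):
        cs = self._clusters([["r1a", "r2a"], ["r1b", "r2b"]])
        merged = cluster_engine.merge_by_mates(
            cs, [("r1a", "r1b"), ("r2a", "r2b")], min_links=3
        )
        assert len(merged.clusters) == 2

    def test_chain_merges_transitively_like_oracle(self):
        groups = [["a1", "a2"], ["b1", "b2"], ["c1", "c2"]]
        links = [("a1", "b1"), ("a2", "b2"), ("b1", "c1"), ("b2", "c2")]
        cs = self._clusters(groups)
        merged = cluster_engine.merge_by_mates(cs, links, min_links=2)
        expect = oracles.transitive_merge(
            {i: g for i, g in enumerate(groups)}, links, 2
        )
        got = sorted(sorted(v) for v in merged.clusters.values())
        want = sorted(sorted(g) for g in expect)
        assert got == want

    def test_random_cases_match_bruteforce(self, rng):
        for trial in range(20):
            n_groups = int(rng.integers(2, 6))
            groups = [
                [f"g{i}n{j}" for j in range(int(rng.integers(1, 4)))]
                for i in range(n_groups)
            ]
            nodes = [x for g in groups for x in g]
            links = [
                tuple(rng.choice(nodes, 2, replace=False))
                for _ in range(int(rng.integers(0, 8)))
            ]
            ml = int(rng.integers(1, 3))
            merged = cluster_engine.merge_by_mates(
                self._clusters(groups), links, min_links=ml
            )
            expect = oracles.transitive_merge(
                {i: g for i, g in enumerate(groups)}, links, ml
            )
            got = sorted(sorted(v) for v in merged.clusters.values())
            want = sorted(sorted(g) for g in expect)
            assert got == want, (groups, links, ml)


class TestFamilyRecall:
    def test_planted_family_reads_form_one_cluster(self):
        """Easy case: one 5-copy family at 1% divergence, full recall."""
        spec = synthetic.GenomeSpec(
            genome_length=20_000,
            families=(synthetic.FamilySpec("RLG_x", "Gypsy", 1000, 5,
                                           divergence=0.01),),
            seed=2,
        )
        genome, ledger, _ = synthetic.make_genome(spec)
        pairs, origins = synthetic.simulate_reads(
            genome, coverage=3.0, seed=2, error_rate=0.0
        )
        spans = {}
        for fam, coords in ledger.copies.items():
            for s, e, _ in coords:
                spans[(s, e)] = fam
        family_reads = set()
        for o, (r1, r2) in zip(origins, pairs):
            for rec, key in ((r1, "r1"), (r2, "r2")):
                s, e, _ = o[key]
                if any(s >= cs and e <= ce for cs, ce in spans):
                    family_reads.add(rec.identifier)
        records = [r for p in pairs for r in p]
        sim = cluster_engine.similarity_graph(records)
        cs = cluster_engine.louvain(sim, seed=2)
        cs = cluster_engine.merge_by_mates(
            cs, [(a.identifier, b.identifier) for a, b in pairs], min_links=2
        )
        containing = {
            cid for cid, members in cs.clusters.items()
            if family_reads & set(members)
        }
        assert len(containing) == 1
        # conservation through every stage
        total = sum(len(m) for m in cs.clusters.values()) + len(cs.unclustered)
        assert total == len(records)
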