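"""All-vs-all read similarity, Louvain clustering and mate-link merging.

Reads that share canonical k-mers are aligned pairwise (both strands);
qualifying hits become edges of a weighted undirected graph whose
communities — found by seeded Louvain modularity maximization — are the
read clusters.  Clusters spanned by enough mate pairs are merged, which
reconnects fragments of long repeat families that the short read
length splits apart.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import networkx as nx
import numpy as np

from repeatscape import align
from repeatscape.preprocess import ReadSet
from repeatscape.seqio import SequenceRecord


@dataclass(frozen=True)
class AlignmentHit:
    """Best qualifying local alignment between two reads."""

    query_id: str
    subject_id: str
    length: int
    identity: float
    score: int


@dataclass
class SimilarityGraph:
    """Weighted undirected read graph plus the reads left isolated."""

    graph: nx.Graph
    unclustered: list[str] = field(default_factory=list)


@dataclass
class ClusterSet:
    """A partition of graph nodes with its modularity and merge history."""

    clusters: dict[str, list[str]]
    modularity: float
    merge_log: list[dict] = field(default_factory=list)
    unclustered: list[str] = field(default_factory=list)

    def sizes(self) -> dict[str, int]:
        return {cid: len(nodes) for cid, nodes in self.clusters.items()}


def pairwise_hits(
    reads: Union[ReadSet, Sequence[SequenceRecord]],
    min_len: int = 55,
    min_identity: float = 90.0,
    min_coverage: float = 0.55,
    scoring: align.Scoring = align.Scoring(),
    seed_k: int = 12,
    min_seed_hits: int = 1,
    band: int = 12,
) -> list[AlignmentHit]:
    """All-vs-all best local alignments passing all three thresholds.

    Candidate pairs are those sharing at least ``min_seed_hits``
    canonical ``seed_k``-mers; each candidate is aligned on the strand
    the seeds indicate, banded to ``band`` diagonals around the seed
    match, and emits at most one hit.  ``min_coverage`` is the aligned
    fraction of the shorter read.  Deterministic given inputs.
    """
    records = list(reads.reads()) if isinstance(reads, ReadSet) else list(reads)
    seqs = [r.sequence for r in records]
    ii, jj, _, scores, matches, lengths = align.pairwise_align(
        seqs, k=seed_k, min_shared=min_seed_hits, band=band, scoring=scoring
    )
    hits: list[AlignmentHit] = []
    for p in range(len(ii)):
        L = int(lengths[p])
        if L == 0:
            continue
        identity = 100.0 * matches[p] / L
        shorter = min(len(seqs[ii[p]]), len(seqs[jj[p]]))
        if L >= min_len and identity >= min_identity and L / shorter >= min_coverage:
            hits.append(
                AlignmentHit(
                    query_id=records[ii[p]].identifier,
                    subject_id=records[jj[p]].identifier,
                    length=L,
                    identity=identity,
                    score=int(scores[p]),
                )
            )
    return hits


def similarity_graph(
    reads: Union[ReadSet, Sequence[SequenceRecord]],
    min_len: int = 55,
    min_identity: float = 90.0,
    min_coverage: float = 0.55,
    scoring: align.Scoring = align.Scoring(),
    seed_k: int = 12,
    min_seed_hits: int = 1,
    band: int = 12,
) -> SimilarityGraph:
    """pairwise_hits + build_graph in one array-native pass (same result)."""
    records = list(reads.reads()) if isinstance(reads, ReadSet) else list(reads)
    lens = np.array([len(r.sequence) for r in records], dtype=np.int64)
    ii, jj, _, scores, matches, lengths = align.pairwise_align(
        [r.sequence for r in records], k=seed_k, min_shared=min_seed_hits,
        band=band, scoring=scoring,
    )
    L = lengths.astype(np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        identity = np.where(lengths > 0, 100.0 * matches / np.maximum(lengths, 1), 0.0)
        coverage = L / np.minimum(lens[ii], lens[jj])
    keep = (lengths >= min_len) & (identity >= min_identity) & (coverage >= min_coverage)
    g = nx.Graph()
    ids = [r.identifier for r in records]
    g.add_weighted_edges_from(
        (ids[i], ids[j], float(w))
        for i, j, w in zip(ii[keep], jj[keep], scores[keep])
    )
    unclustered = [r for r in ids if r not in g]
    return SimilarityGraph(graph=g, unclustered=unclustered)


def build_graph(
    hits: Iterable[AlignmentHit], all_read_ids: Optional[Iterable[str]] = None
) -> SimilarityGraph:
    """One max-score edge per read pair; isolated reads tallied separately."""
    g = nx.Graph()
    for hit in hits:
        if hit.query_id == hit.subject_id:
            continue
        u, v = hit.query_id, hit.subject_id
        if g.has_edge(u, v):
            if hit.score > g[u][v]["weight"]:
                g[u][v]["weight"] = hit.score
        else:
            g.add_edge(u, v, weight=hit.score)
    unclustered: list[str] = []
    if all_read_ids is not None:
        unclustered = [r for r in all_read_ids if r not in g]
    return SimilarityGraph(graph=g, unclustered=unclustered)


# ---------------------------------------------------------------------------
# Louvain
# ---------------------------------------------------------------------------

def modularity(graph: nx.Graph, communities: Iterable[Iterable]) -> float:
    """Weighted Newman modularity Q of a node partition."""
    m2 = 2.0 * graph.size(weight="weight")
    if m2 == 0:
        raise ValueError("modularity undefined for a graph without edges")
    q = 0.0
    for com in communities:
        com = set(com)
        inside = 0.0
        tot = 0.0
        for u in com:
            tot += graph.degree(u, weight="weight")
            for v, data in graph[u].items():
                if v in com:
                    inside += data["weight"]
        q += inside / m2 - (tot / m2) ** 2
    return q


def _louvain_level(adj: list[dict[int, float]], degrees: list[float], m2: float,
                   order: list[int],
                   init: Optional[list[int]] = None) -> list[int]:
    """One Louvain level: greedy node moves until no move improves Q.

    Starts from singleton communities, or from ``init`` when given.
    """
    n = len(adj)
    node2com = list(range(n)) if init is None else list(init)
    com_tot = [0.0] * n
    for u in range(n):
        com_tot[node2com[u]] += degrees[u]
    improved = True
    while improved:
        improved = False
        for u in order:
            cu = node2com[u]
            ku = degrees[u]
            # weights from u to each neighboring community (self-loops excluded)
            neigh: dict[int, float] = {}
            for v, w in adj[u].items():
                if v != u:
                    neigh[node2com[v]] = neigh.get(node2com[v], 0.0) + w
            com_tot[cu] -= ku
            w_cu = neigh.get(cu, 0.0)
            # equal-gain moves keep the lowest community index (sorted scan)
            best_com, best_gain = cu, 0.0
            base = w_cu - com_tot[cu] * ku / m2
            for com in sorted(neigh):
                gain = (neigh[com] - com_tot[com] * ku / m2) - base
                if gain > best_gain + 1e-12:
                    best_gain = gain
                    best_com = com
            com_tot[best_com] += ku
            if best_com != cu:
                node2com[u] = best_com
                improved = True
    return node2com


def _aggregate(adj: list[dict[int, float]], node2com: list[int]
               ) -> tuple[list[dict[int, float]], list[list[int]]]:
    coms = sorted(set(node2com))
    remap = {c: i for i, c in enumerate(coms)}
    members: list[list[int]] = [[] for _ in coms]
    for u, c in enumerate(node2com):
        members[remap[c]].append(u)
    new_adj: list[dict[int, float]] = [dict() for _ in coms]
    for u, nbrs in enumerate(adj):
        cu = remap[node2com[u]]
        for v, w in nbrs.items():
            cv = remap[node2com[v]]
            new_adj[cu][cv] = new_adj[cu].get(cv, 0.0) + w
    return new_adj, members


def _louvain_run(adj: list[dict[int, float]], m2: float, rng: random.Random
                 ) -> list[int]:
    """Full two-phase Louvain; returns original-node community indices."""
    n0 = len(adj)
    assignment = list(range(n0))
    while True:
        # aggregated self-loops store twice the internal weight, so the plain
        # row sum already equals the weighted degree
        degrees = [sum(nbrs.values()) for nbrs in adj]
        order = list(range(len(adj)))
        rng.shuffle(order)
        node2com = _louvain_level(adj, degrees, m2, order)
        if len(set(node2com)) == len(adj):
            break  # no node moved: partition is locally optimal
        adj, members = _aggregate(adj, node2com)
        old2new = [0] * len(node2com)
        for new_c, group in enumerate(members):
            for old_c in group:
                old2new[old_c] = new_c
        assignment = [old2new[assignment[v]] for v in range(n0)]
    return assignment


def louvain(
    graph: Union[SimilarityGraph, nx.Graph],
    seed: int = 0,
    resolution: float = 1.0,
    restarts: Optional[int] = None,
) -> ClusterSet:
    """Seeded Louvain community detection on the similarity graph.

    Node visit order is shuffled by ``seed``; equal-gain moves prefer
    the lower-indexed community, so results are deterministic.  Small
    graphs (<= 200 nodes) are restarted from several seeded orders and
    the best-Q partition kept; large graphs run once.  Only resolution
    1.0 is supported.
    """
    if resolution != 1.0:
        raise ValueError("only resolution 1.0 is supported")
    sim = graph if isinstance(graph, SimilarityGraph) else SimilarityGraph(graph)
    g = sim.graph
    if g.number_of_edges() == 0:
        raise ValueError("Louvain requires a graph with at least one edge")
    nodes = sorted(g.nodes())
    idx = {node: i for i, node in enumerate(nodes)}
    adj: list[dict[int, float]] = [dict() for _ in nodes]
    for u, v, data in g.edges(data=True):
        w = float(data.get("weight", 1.0))
        adj[idx[u]][idx[v]] = w
        adj[idx[v]][idx[u]] = w
    m2 = sum(sum(nbrs.values()) for nbrs in adj)
    small = len(nodes) <= 200
    if restarts is None:
        restarts = 10 if small else 1
    degrees = [sum(nbrs.values()) for nbrs in adj]

    def q_of(assignment: list[int]) -> float:
        part: dict[int, list[str]] = {}
        for node, com in zip(nodes, assignment):
            part.setdefault(com, []).append(node)
        return modularity(g, part.values())

    best_assignment: Optional[list[int]] = None
    best_q = -np.inf
    for r in range(restarts):
        rng = random.Random(seed + r)
        assignment = _louvain_run([d.copy() for d in adj], m2, rng)
        q = q_of(assignment)
        if small:
            # iterated local search: greedy Louvain cannot escape some
            # local optima by single moves, so kick a couple of nodes and
            # re-optimize, keeping the best partition seen
            cur = assignment
            for _ in range(15):
                kicked = list(cur)
                for node in rng.sample(range(len(nodes)),
                                       min(2, len(nodes))):
                    kicked[node] = rng.randrange(len(nodes))
                order = list(range(len(nodes)))
                rng.shuffle(order)
                cand = _louvain_level(adj, degrees, m2, order, init=kicked)
                q_cand = q_of(cand)
                if q_cand > q + 1e-12:
                    q = q_cand
                    cur = cand
            assignment = cur
        if q > best_q + 1e-12:
            best_q = q
            best_assignment = assignment
    part = {}
    for node, com in zip(nodes, best_assignment):
        part.setdefault(com, []).append(node)
    # label clusters by decreasing size, ties by smallest member node
    groups = sorted(part.values(), key=lambda grp: (-len(grp), min(grp)))
    clusters = {f"CL{i}": sorted(grp) for i, grp in enumerate(groups)}
    return ClusterSet(
        clusters=clusters,
        modularity=best_q,
        unclustered=list(sim.unclustered),
    )


# ---------------------------------------------------------------------------
# Mate-link merging
# ---------------------------------------------------------------------------

def merge_by_mates(
    clusters: ClusterSet,
    reads: Union[ReadSet, Iterable[tuple[str, str]]],
    min_links: int = 2,
) -> ClusterSet:
    """Merge clusters connected by at least ``min_links`` mate pairs.

    Unions are applied transitively and re-evaluated until fixpoint, so
    a chain A-B, B-C with qualifying links merges into one cluster even
    if A and C share no direct links.
    """
    if isinstance(reads, ReadSet):
        mate_pairs = [(r1.identifier, r2.identifier) for r1, r2 in reads.pairs]
    else:
        mate_pairs = list(reads)
    groups: dict[str, set[str]] = {cid: set(m) for cid, m in clusters.clusters.items()}
    merge_log: list[dict] = list(clusters.merge_log)
    changed = True
    while changed:
        changed = False
        node2group: dict[str, str] = {}
        for gid, members in groups.items():
            for node in members:
                node2group[node] = gid
        links: dict[tuple[str, str], int] = {}
        for a, b in mate_pairs:
            ga, gb = node2group.get(a), node2group.get(b)
            if ga is None or gb is None or ga == gb:
                continue
            key = (ga, gb) if ga < gb else (gb, ga)
            links[key] = links.get(key, 0) + 1
        parent = {gid: gid for gid in groups}

        def find(x: str) -> str:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for (ga, gb), count in sorted(links.items()):
            if count >= min_links:
                ra, rb = find(ga), find(gb)
                if ra != rb:
                    keep, drop = (ra, rb) if ra < rb else (rb, ra)
                    parent[drop] = keep
                    merge_log.append({"merged": [ga, gb], "links": count})
                    changed = True
        if changed:
            new_groups: dict[str, set[str]] = {}
            for gid, members in groups.items():
                root = find(gid)
                new_groups.setdefault(root, set()).update(members)
            groups = new_groups
    ordered = sorted(groups.values(), key=lambda grp: (-len(grp), min(grp)))
    relabeled = {f"CL{i}": sorted(grp) for i, grp in enumerate(ordered)}
    return ClusterSet(
        clusters=relabeled,
        modularity=clusters.modularity,
        merge_log=merge_log,
        unclustered=list(clusters.unclustered),
    )
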