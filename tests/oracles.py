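"""Independent brute-force oracles used only by the tests.

These are deliberately naive re-derivations (full O(nm) dynamic
programs, exhaustive partition enumeration, direct tallies) kept
separate from the package so that agreement between the two is
meaningful.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter

NEG = float("-inf")


def sw_score(a: str, b: str, match=1, mismatch=-3, gap_open=-5, gap_extend=-2):
    """Best local alignment score, full Gotoh DP (gap k costs open+(k-1)ext)."""
    n, m = len(a), len(b)
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] + gap_open, E[i][j - 1] + gap_extend)
            F[i][j] = max(H[i - 1][j] + gap_open, F[i - 1][j] + gap_extend)
            s = match if (a[i - 1] == b[j - 1] and a[i - 1] in "ACGT") else mismatch
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def sw_score_strands(a: str, b: str, **kw) -> float:
    return max(sw_score(a, b, **kw), sw_score(a, revcomp(b), **kw))


def entropy3(seq: str) -> float:
    """Trinucleotide entropy score, independent direct tally."""
    kmers = [seq[i:i + 3] for i in range(len(seq) - 2)]
    total = len(kmers)
    counts = Counter(kmers)
    h = -sum((c / total) * math.log(c / total) for c in counts.values())
    hmax = math.log(min(64, total))
    return 100.0 * h / hmax if hmax > 0 else (0.0 if len(counts) == 1 else 100.0)


def set_partitions(items):
    """All set partitions (Bell enumeration) of a list."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def modularity(edges: dict, nodes: list, partition) -> float:
    """Weighted Newman modularity computed from scratch."""
    m2 = 2.0 * sum(edges.values())
    deg = {u: 0.0 for u in nodes}
    for (u, v), w in edges.items():
        deg[u] += w
        deg[v] += w
    q = 0.0
    for group in partition:
        group = set(group)
        inside = sum(w for (u, v), w in edges.items() if u in group and v in group)
        tot = sum(deg[u] for u in group)
        q += 2.0 * inside / m2 - (tot / m2) ** 2
    return q


def max_modularity(edges: dict, nodes: list) -> float:
    """Exhaustive maximum modularity over all partitions (<= 9 nodes)."""
    assert len(nodes) <= 9
    return max(modularity(edges, nodes, p) for p in set_partitions(list(nodes)))


def transitive_merge(groups: dict, links: dict, min_links: int) -> list[frozenset]:
    """Brute-force fixpoint of the mate-link merge rule."""
    groups = {k: frozenset(v) for k, v in groups.items()}
    current = list(groups.values())
    changed = True
    while changed:
        changed = False
        for a, b in itertools.combinations(range(len(current)), 2):
            ga, gb = current[a], current[b]
            n = sum(
                1 for x, y in links
                if (x in ga and y in gb) or (x in gb and y in ga)
            )
            if n >= min_links:
                merged = ga | gb
                current = [g for k, g in enumerate(current) if k not in (a, b)]
                current.append(merged)
                changed = True
                break
    return current
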