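"""Cluster annotation against a repeat library and genome composition.

Each read in a cluster votes for the family of its single best-scoring
qualifying library hit; the cluster takes the plurality family.  The
genomic fraction of a family is the read-weighted share of its clusters
scaled by the supporting-vote fraction, so family fractions, the
unannotated remainder and unclustered reads always sum to one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from repeatscape import align, cluster_engine, preprocess
from repeatscape.cluster_engine import ClusterSet
from repeatscape.preprocess import Pair
from repeatscape.seqio import RepeatLibraryEntry, SequenceRecord

UNANNOTATED = "unannotated"
UNCLUSTERED = "unclustered"


@dataclass
class ClusterAnnotation:
    cluster_id: str
    family: str
    superfamily: str
    te_class: str
    hit_fraction: float
    vote_breakdown: dict[str, int] = field(default_factory=dict)


def family_votes(
    seqs: Sequence[str],
    library: Sequence[RepeatLibraryEntry],
    min_len: int = 55,
    min_identity: float = 90.0,
    scoring: align.Scoring = align.Scoring(),
) -> np.ndarray:
    """Per-read library vote: index of the best qualifying hit, or -1.

    Each read votes for its single best-scoring qualifying library
    alignment; score ties go to the entry earlier in the library.
    """
    qq, rr, _, sc, mt, ln = align.map_candidates(
        [str(s) for s in seqs], [e.sequence for e in library], scoring=scoring
    )
    votes = np.full(len(seqs), -1, dtype=np.int64)
    if len(qq) == 0:
        return votes
    identity = 100.0 * mt / np.maximum(ln, 1)
    mask = (ln >= min_len) & (identity >= min_identity)
    if not mask.any():
        return votes
    qs, rs, ss = qq[mask], rr[mask], sc[mask]
    order = np.lexsort((rs, -ss, qs))  # per read: best score first, then library order
    qs, rs = qs[order], rs[order]
    uq, first = np.unique(qs, return_index=True)
    votes[uq] = rs[first]
    return votes


def _tally(
    cluster_id: str,
    vote_idx: np.ndarray,
    library: Sequence[RepeatLibraryEntry],
    cluster_size: int,
) -> ClusterAnnotation:
    votes: dict[str, int] = {}
    first_seen: dict[str, int] = {}
    for li in vote_idx:
        if li < 0:
            continue
        fam = library[li].family
        votes[fam] = votes.get(fam, 0) + 1
        first_seen.setdefault(fam, int(li))
    if not votes:
        return ClusterAnnotation(cluster_id, UNANNOTATED, UNANNOTATED, UNANNOTATED,
                                 0.0, {})
    winner = min(votes, key=lambda f: (-votes[f], first_seen[f]))
    entry = library[first_seen[winner]]
    return ClusterAnnotation(
        cluster_id=cluster_id,
        family=winner,
        superfamily=entry.superfamily,
        te_class=entry.te_class,
        hit_fraction=votes[winner] / cluster_size,
        vote_breakdown=dict(sorted(votes.items())),
    )


def annotate_cluster(
    cluster_id: str,
    cluster_reads: Sequence[SequenceRecord],
    library: Sequence[RepeatLibraryEntry],
    min_len: int = 55,
    min_identity: float = 90.0,
    scoring: align.Scoring = align.Scoring(),
) -> ClusterAnnotation:
    """Plurality-vote annotation of one cluster.

    A cluster with no qualifying hits is "unannotated" with
    hit_fraction 0.  Plurality ties go to the family appearing first in
    the library.
    """
    if not cluster_reads:
        raise ValueError("cannot annotate an empty cluster")
    votes = family_votes([r.sequence for r in cluster_reads], library,
                         min_len, min_identity, scoring)
    return _tally(cluster_id, votes, library, len(cluster_reads))


def annotate_clusters(
    clusters: ClusterSet,
    reads_by_id: dict[str, SequenceRecord],
    library: Sequence[RepeatLibraryEntry],
    min_len: int = 55,
    min_identity: float = 90.0,
    scoring: align.Scoring = align.Scoring(),
) -> dict[str, ClusterAnnotation]:
    """Annotate every cluster with one shared alignment pass."""
    order: list[str] = []
    spans: list[tuple[str, int, int]] = []
    for cid, members in clusters.clusters.items():
        spans.append((cid, len(order), len(order) + len(members)))
        order.extend(members)
    votes = family_votes([reads_by_id[r].sequence for r in order], library,
                         min_len, min_identity, scoring)
    return {
        cid: _tally(cid, votes[lo:hi], library, hi - lo)
        for cid, lo, hi in spans
    }


def composition(
    clusters: ClusterSet,
    annotations: dict[str, ClusterAnnotation],
    total_sampled_reads: int,
) -> pd.DataFrame:
    """Single-replicate genomic fractions per family.

    Returns a DataFrame indexed by family with columns superfamily,
    te_class and fraction.  The (1 - hit_fraction) residue of every
    annotated cluster and all reads of unannotated clusters accrue to
    the "unannotated" row; reads outside any cluster accrue to
    "unclustered".  Fractions sum to 1 exactly.
    """
    clustered = sum(len(m) for m in clusters.clusters.values())
    if clustered + len(clusters.unclustered) != total_sampled_reads:
        raise ValueError(
            f"cluster sizes ({clustered}) + unclustered "
            f"({len(clusters.unclustered)}) != total reads ({total_sampled_reads})"
        )
    rows: dict[str, dict] = {}
    unannotated = 0.0
    for cid, members in clusters.clusters.items():
        ann = annotations[cid]
        share = len(members) / total_sampled_reads
        if ann.family == UNANNOTATED:
            unannotated += share
            continue
        frac = share * ann.hit_fraction
        unannotated += share * (1.0 - ann.hit_fraction)
        row = rows.setdefault(
            ann.family,
            {"superfamily": ann.superfamily, "te_class": ann.te_class, "fraction": 0.0},
        )
        row["fraction"] += frac
    rows[UNANNOTATED] = {
        "superfamily": UNANNOTATED, "te_class": UNANNOTATED, "fraction": unannotated,
    }
    rows[UNCLUSTERED] = {
        "superfamily": UNCLUSTERED, "te_class": UNCLUSTERED,
        "fraction": len(clusters.unclustered) / total_sampled_reads,
    }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "family"
    return df.sort_values("fraction", ascending=False)


def superfamily_composition(comp: pd.DataFrame) -> pd.Series:
    """Aggregate a family composition to superfamily fractions."""
    return comp.groupby("superfamily")["fraction"].sum().sort_values(ascending=False)


def _spawn_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(child.generate_state(1)[0] % (2 ** 31)) for child in ss.spawn(n)]


def run_replicate(
    pairs: list[Pair],
    library: Sequence[RepeatLibraryEntry],
    k: int,
    seed: int,
    min_len: int = 55,
    min_identity: float = 90.0,
    min_coverage: float = 0.55,
    merge_links: int = 100,
    scoring: align.Scoring = align.Scoring(),
) -> pd.DataFrame:
    """One sample -> cluster -> merge -> annotate -> composition pass."""
    readset = preprocess.sample_pairs(pairs, k, seed)
    records = list(readset.reads())
    sim = cluster_engine.similarity_graph(
        records, min_len=min_len, min_identity=min_identity,
        min_coverage=min_coverage, scoring=scoring,
    )
    if sim.graph.number_of_edges() == 0:
        clusters = ClusterSet(clusters={}, modularity=float("nan"),
                              unclustered=list(sim.unclustered))
    else:
        clusters = cluster_engine.louvain(sim, seed=seed)
        clusters = cluster_engine.merge_by_mates(clusters, readset, min_links=merge_links)
    anns = annotate_clusters(
        clusters, {r.identifier: r for r in records}, library,
        min_len=min_len, min_identity=min_identity, scoring=scoring,
    )
    return composition(clusters, anns, total_sampled_reads=len(records))


def replicate_composition(
    pairs: list[Pair],
    library: Sequence[RepeatLibraryEntry],
    k: int,
    replicates: int = 3,
    seeds: Optional[Sequence[int]] = None,
    seed: int = 0,
    **kwargs,
) -> pd.DataFrame:
    """Mean +/- SD composition table over replicate sampling runs.

    Returns a DataFrame indexed by family with columns superfamily,
    te_class, rep0..rep{n-1}, mean and sd (sample SD; not available for
    a single replicate).
    """
    if seeds is None:
        seeds = _spawn_seeds(seed, replicates)
    if len(seeds) != replicates:
        raise ValueError("need one seed per replicate")
    reps = []
    for i, s in enumerate(seeds):
        try:
            reps.append(run_replicate(pairs, library, k, s, **kwargs))
        except Exception as exc:  # noqa: BLE001 - tag with replicate index
            raise RuntimeError(f"replicate {i} (seed {s}) failed") from exc
    families: dict[str, dict] = {}
    for rep in reps:
        for fam, row in rep.iterrows():
            families.setdefault(
                fam, {"superfamily": row["superfamily"], "te_class": row["te_class"]}
            )
    table = pd.DataFrame.from_dict(families, orient="index")
    table.index.name = "family"
    for i, rep in enumerate(reps):
        table[f"rep{i}"] = [
            rep["fraction"].get(fam, 0.0) for fam in table.index
        ]
    repcols = [f"rep{i}" for i in range(replicates)]
    table["mean"] = table[repcols].mean(axis=1)
    if replicates >= 2:
        sd = table[repcols].std(axis=1, ddof=1)
        # identical replicates must report exactly zero spread, not an ulp
        sd[table[repcols].max(axis=1) == table[repcols].min(axis=1)] = 0.0
        table["sd"] = sd
    else:
        table["sd"] = np.nan
    return table.sort_values("mean", ascending=False)


def coverage_titration(
    pairs: list[Pair],
    library: Sequence[RepeatLibraryEntry],
    coverage_levels: Sequence[float],
    replicates: int = 3,
    seed: int = 0,
    **kwargs,
) -> pd.DataFrame:
    """Coefficient of variation of family fractions per sampling level.

    ``coverage_levels`` are fractions of the available pair population
    to sample.  For each level the composition is replicated and each
    family's CV = sd/mean computed across replicates; the summary row
    value is the mean CV over families with nonzero mean (zero-mean
    families are excluded).  Returns a tidy DataFrame with columns
    level, family, mean, sd, cv plus one "__summary__" family row per
    level.
    """
    out = []
    master = _spawn_seeds(seed, len(coverage_levels))
    for level, level_seed in zip(coverage_levels, master):
        k = max(1, int(round(level * len(pairs))))
        table = replicate_composition(
            pairs, library, k, replicates=replicates, seed=level_seed, **kwargs
        )
        fams = table.index.difference([UNANNOTATED, UNCLUSTERED])
        cvs = []
        for fam in fams:
            mean, sd = table.loc[fam, "mean"], table.loc[fam, "sd"]
            if mean > 0:
                cv = sd / mean
                cvs.append(cv)
                out.append({"level": level, "family": fam,
                            "mean": mean, "sd": sd, "cv": cv})
        out.append({
            "level": level, "family": "__summary__",
            "mean": np.nan, "sd": np.nan,
            "cv": float(np.mean(cvs)) if cvs else np.nan,
        })
    return pd.DataFrame(out)
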