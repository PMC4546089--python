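"""Read filtering, contaminant screening and paired-aware subsampling.

Filtering mirrors a PRINSEQ-style policy: minimum length, minimum mean
Phred quality, trinucleotide-entropy low-complexity screen, right-end
N trimming, maximum N percentage and an IUPAC-alphabet check.  A pair
is kept only if both mates pass; the rejection log counts removals per
cause.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional

import numpy as np

from repeatscape import align
from repeatscape.seqio import SequenceRecord

Pair = tuple[SequenceRecord, SequenceRecord]


@dataclass(frozen=True)
class FilterPolicy:
    """Thresholds for the quality/complexity filter (defaults per pipeline)."""

    min_len: int = 40
    min_mean_qual: float = 15.0
    entropy_threshold: float = 60.0
    trim_ns_right: int = 10
    max_n_percent: float = 20.0
    drop_non_iupac: bool = True

    def __post_init__(self) -> None:
        if self.min_len < 1:
            raise ValueError("min_len must be >= 1")
        if not 0 <= self.entropy_threshold <= 100:
            raise ValueError("entropy_threshold must be in [0, 100]")
        if not 0 <= self.max_n_percent <= 100:
            raise ValueError("max_n_percent must be in [0, 100]")


@dataclass
class ReadSet:
    """Mate pairs together with the provenance needed to reproduce them."""

    pairs: list[Pair]
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.pairs)

    def reads(self) -> Iterator[SequenceRecord]:
        for r1, r2 in self.pairs:
            yield r1
            yield r2


class UndefinedScoreError(ValueError):
    """Entropy is undefined for sequences shorter than 3 bases."""


def entropy_score(sequence: str) -> float:
    """Trinucleotide Shannon-entropy complexity score on a 0-100 scale.

    Overlapping 3-mers are tallied; the score is 100 * H3 / Hmax with
    H3 the natural-log Shannon entropy of the 3-mer frequencies and
    Hmax = ln(min(64, L - 2)).  A homopolymer scores 0, a sequence
    whose 3-mers are all distinct scores 100.
    """
    L = len(sequence)
    if L < 3:
        raise UndefinedScoreError(f"sequence of length {L} has no trinucleotides")
    counts = Counter(sequence[i:i + 3] for i in range(L - 2))
    total = L - 2
    h3 = max(0.0, -sum((c / total) * math.log(c / total) for c in counts.values()))
    hmax = math.log(min(64, total))
    if hmax == 0:
        return 0.0 if len(counts) == 1 else 100.0
    return 100.0 * h3 / hmax


_IUPAC = set("ACGTN")


def _trim_right_ns(rec: SequenceRecord, max_trim: int) -> SequenceRecord:
    """Strip up to ``max_trim`` trailing N's (qualities trimmed in step)."""
    n = 0
    seq = rec.sequence
    while n < max_trim and n < len(seq) and seq[-1 - n] == "N":
        n += 1
    if n == 0:
        return rec
    qual = rec.quality[:-n] if rec.quality is not None else None
    return SequenceRecord(rec.identifier, seq[:-n], qual)


def _mate_failure(rec: SequenceRecord, policy: FilterPolicy) -> Optional[str]:
    """First failed test for one mate, or None if it passes all."""
    if len(rec) < policy.min_len:
        return "min_len"
    if policy.drop_non_iupac and any(c not in _IUPAC for c in rec.sequence):
        return "non_iupac"
    if rec.sequence:
        n_pct = 100.0 * rec.sequence.count("N") / len(rec)
        if n_pct > policy.max_n_percent:
            return "max_n_percent"
    if rec.quality is not None and np.mean(rec.quality) < policy.min_mean_qual:
        return "min_qual"
    if len(rec) < 3 or entropy_score(rec.sequence) < policy.entropy_threshold:
        return "low_complexity"
    return None


def filter_reads(
    pairs: Iterable[Pair], policy: FilterPolicy = FilterPolicy()
) -> tuple[list[Pair], dict[str, int]]:
    """Apply the filter policy pair-wise.

    Both mates are right-N-trimmed first; a pair survives only if both
    mates then pass every enabled test.  Returns the surviving pairs in
    input order and a per-cause rejection log (a rejected pair is
    counted once, under the first failing mate's first failing test).
    """
    kept: list[Pair] = []
    log: dict[str, int] = {"input": 0, "kept": 0}
    for r1, r2 in pairs:
        log["input"] += 1
        t1 = _trim_right_ns(r1, policy.trim_ns_right)
        t2 = _trim_right_ns(r2, policy.trim_ns_right)
        cause = _mate_failure(t1, policy) or _mate_failure(t2, policy)
        if cause is None:
            kept.append((t1, t2))
            log["kept"] += 1
        else:
            log[cause] = log.get(cause, 0) + 1
    return kept, log


class EmptyContaminantSet(ValueError):
    """An empty contaminant database is an error, not a no-op screen."""


def screen_contaminants(
    pairs: Iterable[Pair],
    contaminants: list[SequenceRecord],
    min_identity: float = 90.0,
    min_len: int = 50,
    seed_k: int = 12,
) -> tuple[list[Pair], int]:
    """Drop pairs where either mate aligns to any contaminant sequence.

    A mate is contaminant-derived when a local alignment to some
    contaminant reaches both ``min_len`` aligned columns and
    ``min_identity`` percent identity (both strands searched).  Returns
    (kept pairs, number of dropped pairs).
    """
    if not contaminants:
        raise EmptyContaminantSet("contaminant set is empty")
    index = align.KmerIndex([c.sequence for c in contaminants], k=seed_k)

    def dirty(rec: SequenceRecord) -> bool:
        for ci in index.candidates(rec.sequence):
            hit = align.best_local_alignment(rec.sequence, contaminants[ci].sequence)
            if hit and hit.length >= min_len and hit.identity >= min_identity:
                return True
        return False

    kept: list[Pair] = []
    dropped = 0
    for r1, r2 in pairs:
        if dirty(r1) or dirty(r2):
            dropped += 1
        else:
            kept.append((r1, r2))
    return kept, dropped


def sample_pairs(pairs: list[Pair], k: int, seed: int) -> ReadSet:
    """Uniform sample of ``k`` mate pairs without replacement.

    Mates are never split.  The canonical output order is ascending
    input position, so identical seed and input give byte-identical
    downstream files.
    """
    n = len(pairs)
    if k > n:
        raise ValueError(f"requested {k} pairs but only {n} available")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(n, size=k, replace=False))
    chosen = [pairs[i] for i in idx]
    return ReadSet(pairs=chosen, provenance={"seed": seed, "k": k, "population": n})
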