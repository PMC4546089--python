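"""Coverage-based genome-size estimation from transcript mapping.

Reads are mapped to a single-copy transcript reference; per-transcript
depth is Cov_i = N / L (N = total aligned read bases, L = transcript
length).  The genome size is

    Cval = P * (n * l / mean(Cov_i))

with P the ploidy, n the total read count, l the read length and the
mean taken after dropping the top 10% of transcripts by coverage
(which absorbs multi-copy or repeat-contaminated transcripts).  Only
alignments over the length and identity thresholds (defaults 60 bp,
70%) contribute.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import math

import numpy as np
import pandas as pd

from repeatscape import align
from repeatscape.seqio import SequenceRecord


@dataclass
class TranscriptCoverage:
    transcript_id: str
    L: int
    N: int

    @property
    def cov(self) -> float:
        return self.N / self.L


@dataclass
class GenomeSizeEstimate:
    P: int
    n: int
    l: float
    mean_cov: float

    @property
    def cval(self) -> float:
        return self.P * (self.n * self.l / self.mean_cov)


def _best_alignments(
    reads: Sequence[SequenceRecord],
    transcripts: Sequence[SequenceRecord],
    scoring: align.Scoring,
    seed_k: int,
) -> list[list[tuple[int, int, int, float]]]:
    """Per read: candidate alignments (t_idx, score, length, identity)."""
    qq, rr, _, sc, mt, ln = align.map_candidates(
        [r.sequence for r in reads], [t.sequence for t in transcripts],
        k=seed_k, scoring=scoring,
    )
    out: list[list[tuple[int, int, int, float]]] = [[] for _ in reads]
    for p in range(len(qq)):
        if ln[p] > 0:
            out[qq[p]].append(
                (int(rr[p]), int(sc[p]), int(ln[p]), 100.0 * mt[p] / ln[p])
            )
    return out


def map_to_transcripts(
    reads: Sequence[SequenceRecord],
    transcripts: Sequence[SequenceRecord],
    min_aln_len: int = 60,
    min_identity: float = 70.0,
    scoring: align.Scoring = align.Scoring(),
    seed_k: int = 12,
    _precomputed: Optional[list[list[tuple[int, int, int, float]]]] = None,
) -> list[TranscriptCoverage]:
    """Best-hit read mapping and per-transcript coverage accumulation.

    Each read contributes the aligned length of its single best-scoring
    qualifying alignment to exactly one transcript; score ties go to
    the transcript earlier in the input (lowest index).
    """
    if not transcripts:
        raise ValueError("transcript set is empty")
    per_read = _precomputed
    if per_read is None:
        per_read = _best_alignments(reads, transcripts, scoring, seed_k)
    N = np.zeros(len(transcripts), dtype=np.int64)
    for hits in per_read:
        best: Optional[tuple[int, int, int, float]] = None
        for ti, score, length, identity in hits:
            if length >= min_aln_len and identity >= min_identity:
                if best is None or score > best[1]:
                    best = (ti, score, length, identity)
        if best is not None:
            N[best[0]] += best[2]
    return [
        TranscriptCoverage(t.identifier, len(t), int(N[i]))
        for i, t in enumerate(transcripts)
    ]


def trimmed_mean_cov(
    coverages: Sequence[TranscriptCoverage], trim_top: float = 0.10
) -> float:
    """Mean per-transcript depth after dropping the deepest transcripts.

    Zero-coverage transcripts are excluded first; then the top
    ceil(trim_top * count) transcripts by coverage are removed and the
    rest averaged.  If trimming would empty the set, nothing is trimmed
    and a warning is issued.
    """
    covs = sorted((c.cov for c in coverages if c.cov > 0), reverse=True)
    if not covs:
        raise ValueError("all transcript coverages are zero; cannot estimate")
    drop = math.ceil(trim_top * len(covs))
    if drop >= len(covs):
        warnings.warn(
            "trimming would remove every transcript; using untrimmed mean",
            stacklevel=2,
        )
        drop = 0
    return float(np.mean(covs[drop:]))


def estimate_cval(P: int, n: int, l: float, mean_cov: float) -> GenomeSizeEstimate:
    """Cval = P * (n * l / mean_cov), exact arithmetic."""
    if P <= 0 or n <= 0 or l <= 0:
        raise ValueError("P, n and l must be positive")
    if mean_cov <= 0:
        raise ValueError("mean coverage must be positive")
    return GenomeSizeEstimate(P=P, n=n, l=l, mean_cov=mean_cov)


def estimate_genome_size(
    reads: Sequence[SequenceRecord],
    transcripts: Sequence[SequenceRecord],
    ploidy: int = 1,
    min_aln_len: int = 60,
    min_identity: float = 70.0,
    trim_top: float = 0.10,
    scoring: align.Scoring = align.Scoring(),
) -> GenomeSizeEstimate:
    """End-to-end estimate from reads and a transcript reference."""
    covs = map_to_transcripts(reads, transcripts, min_aln_len, min_identity, scoring)
    mean_cov = trimmed_mean_cov(covs, trim_top)
    mean_read_len = float(np.mean([len(r) for r in reads]))
    return estimate_cval(ploidy, len(reads), mean_read_len, mean_cov)


def threshold_grid(
    reads: Sequence[SequenceRecord],
    transcripts: Sequence[SequenceRecord],
    truth: float,
    lengths: Sequence[int] = tuple(range(50, 101, 10)),
    identities: Sequence[float] = tuple(range(50, 101, 10)),
    ploidy: int = 1,
    trim_top: float = 0.10,
    scoring: align.Scoring = align.Scoring(),
) -> pd.DataFrame:
    """|Cval - truth| over a grid of alignment length/identity thresholds.

    Alignments are computed once at the loosest settings and re-filtered
    per grid point.  Returns a tidy DataFrame (min_aln_len,
    min_identity, cval, abs_error) with the argmin first.
    """
    per_read = _best_alignments(reads, transcripts, scoring, seed_k=12)
    mean_read_len = float(np.mean([len(r) for r in reads]))
    rows = []
    for L in lengths:
        for ident in identities:
            covs = map_to_transcripts(
                reads, transcripts, min_aln_len=L, min_identity=ident,
                _precomputed=per_read,
            )
            try:
                mean_cov = trimmed_mean_cov(covs, trim_top)
                cval = estimate_cval(ploidy, len(reads), mean_read_len, mean_cov).cval
            except ValueError:
                cval = np.nan
            rows.append({
                "min_aln_len": L, "min_identity": ident, "cval": cval,
                "abs_error": abs(cval - truth) if np.isfinite(cval) else np.inf,
            })
    df = pd.DataFrame(rows)
    return df.sort_values("abs_error", kind="stable").reset_index(drop=True)
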