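"""Generators for every input the pipeline consumes, with truth ledgers.

A synthetic genome is i.i.d. background sequence into which mutated
copies of randomly drawn TE-family consensus sequences are planted at
non-overlapping positions, optionally together with single-copy
transcript sequences.  Paired-end reads, pure-birth trees and Brownian
trait evolution cover the remaining inputs.  Every generator records
its ground truth so recovery tests can compare estimates against what
was actually planted.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence

import dendropy
import numpy as np

from repeatscape.preprocess import Pair
from repeatscape.seqio import (
    RepeatLibraryEntry,
    SequenceRecord,
    classify_superfamily,
    revcomp,
)

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class FamilySpec:
    """One planted TE family: consensus size, copy number and mutation rates."""

    name: str
    superfamily: str
    consensus_length: int
    copy_number: int
    divergence: float = 0.02
    indel_rate: float = 0.001

    def __post_init__(self) -> None:
        if not 0 <= self.divergence < 0.5:
            raise ValueError("divergence must be in [0, 0.5)")
        if self.indel_rate < 0:
            raise ValueError("indel rate must be >= 0")


@dataclass(frozen=True)
class GenomeSpec:
    genome_length: int
    families: tuple[FamilySpec, ...] = ()
    background_gc: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        planted = sum(f.copy_number * f.consensus_length for f in self.families)
        if planted > self.genome_length:
            raise ValueError(
                f"planted repeat bases ({planted}) exceed genome length "
                f"({self.genome_length})"
            )


@dataclass
class TruthLedger:
    """Ground truth of a synthetic genome (and optionally its reads/tree)."""

    genome_length: int
    family_fractions: dict[str, float] = field(default_factory=dict)
    superfamilies: dict[str, str] = field(default_factory=dict)
    copies: dict[str, list[tuple[int, int, str]]] = field(default_factory=dict)
    transcript_coords: dict[str, tuple[int, int, str]] = field(default_factory=dict)
    background_fraction: float = 1.0
    extras: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TruthLedger":
        d = json.loads(text)
        d["copies"] = {k: [tuple(c) for c in v] for k, v in d["copies"].items()}
        d["transcript_coords"] = {
            k: tuple(v) for k, v in d["transcript_coords"].items()
        }
        return cls(**d)


def _random_seq(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=length, p=p)])


def _mutate(rng: np.random.Generator, seq: str, divergence: float,
            indel_rate: float) -> str:
    """Substitutions at ``divergence`` per base plus single-base indels."""
    chars = np.array(list(seq))
    subs = rng.random(len(chars)) < divergence
    if subs.any():
        codes = np.searchsorted(_BASES, chars[subs])
        shift = rng.integers(1, 4, size=int(subs.sum()))
        chars[subs] = _BASES[(codes + shift) % 4]
    if indel_rate <= 0:
        return "".join(chars)
    out: list[str] = []
    for c in chars:
        r = rng.random()
        if r < indel_rate / 2:
            continue  # deletion
        out.append(c)
        if indel_rate / 2 <= r < indel_rate:
            out.append(str(_BASES[rng.integers(0, 4)]))  # insertion
    return "".join(out)


def make_genome(
    spec: GenomeSpec,
    transcripts: Optional[Sequence[SequenceRecord]] = None,
    max_retries: int = 1000,
) -> tuple[str, TruthLedger, list[RepeatLibraryEntry]]:
    """Background genome with planted TE copies and optional transcripts.

    Copies are placed uniformly at non-overlapping positions (rejection
    sampling), each independently mutated and inserted on a random
    strand.  Returns the sequence, the truth ledger (0-based half-open
    copy coordinates, per-family fractions) and the clean consensus
    library.
    """
    rng = np.random.default_rng(spec.seed)
    genome = np.array(list(_random_seq(rng, spec.genome_length, spec.background_gc)))
    occupied: list[tuple[int, int]] = []
    ledger = TruthLedger(genome_length=spec.genome_length)
    library: list[RepeatLibraryEntry] = []

    def place(seq: str, label: str, strand: str) -> tuple[int, int]:
        L = len(seq)
        for _ in range(max_retries):
            start = int(rng.integers(0, spec.genome_length - L + 1))
            end = start + L
            if all(end <= s or start >= e for s, e in occupied):
                occupied.append((start, end))
                genome[start:end] = list(seq)
                return start, end
        raise RuntimeError(
            f"could not place {label} without overlap after {max_retries} "
            "retries; lower the repeat density"
        )

    for fam in spec.families:
        consensus = _random_seq(rng, fam.consensus_length, spec.background_gc)
        library.append(
            RepeatLibraryEntry(
                name=fam.name, superfamily=fam.superfamily, family=fam.name,
                te_class=classify_superfamily(fam.superfamily),
                sequence=consensus,
            )
        )
        coords: list[tuple[int, int, str]] = []
        planted_bases = 0
        for _ in range(fam.copy_number):
            copy = _mutate(rng, consensus, fam.divergence, fam.indel_rate)
            strand = "+" if rng.random() < 0.5 else "-"
            inserted = copy if strand == "+" else revcomp(copy)
            start, end = place(inserted, fam.name, strand)
            coords.append((start, end, strand))
            planted_bases += end - start
        ledger.copies[fam.name] = coords
        ledger.family_fractions[fam.name] = planted_bases / spec.genome_length
        ledger.superfamilies[fam.name] = fam.superfamily
    if transcripts:
        for t in transcripts:
            start, end = place(t.sequence, t.identifier, "+")
            ledger.transcript_coords[t.identifier] = (start, end, "+")
    ledger.background_fraction = 1.0 - sum(ledger.family_fractions.values())
    return "".join(genome), ledger, library


def simulate_reads(
    genome: str,
    coverage: float = 1.0,
    read_len: int = 100,
    insert_mean: int = 400,
    insert_sd: int = 40,
    error_rate: float = 0.005,
    seed: int = 0,
    base_quality: int = 35,
    id_prefix: str = "p",
) -> tuple[list[Pair], list[dict]]:
    """Paired-end reads with uniform substitution errors.

    The number of pairs is round(coverage * genome_length / (2 *
    read_len)); fragments are uniform; the second mate is the reverse
    complement of the fragment end.  Returns the pairs and a per-pair
    origin ledger (true source interval of each mate).
    """
    G = len(genome)
    if insert_mean <= read_len:
        raise ValueError("insert_mean must exceed read_len")
    if insert_mean > G:
        raise ValueError("insert size exceeds genome length")
    rng = np.random.default_rng(seed)
    n_pairs = int(round(coverage * G / (2 * read_len)))
    pairs: list[Pair] = []
    origins: list[dict] = []
    qual = [base_quality] * read_len

    def with_errors(seq: str) -> str:
        chars = np.array(list(seq))
        err = rng.random(len(chars)) < error_rate
        if err.any():
            codes = np.searchsorted(_BASES, chars[err])
            shift = rng.integers(1, 4, size=int(err.sum()))
            chars[err] = _BASES[(codes + shift) % 4]
        return "".join(chars)

    for i in range(n_pairs):
        insert = int(round(rng.normal(insert_mean, insert_sd)))
        insert = max(read_len, min(insert, G))
        start = int(rng.integers(0, G - insert + 1))
        end = start + insert
        r1 = with_errors(genome[start:start + read_len])
        r2 = with_errors(revcomp(genome[end - read_len:end]))
        pairs.append((
            SequenceRecord(f"{id_prefix}{i}.1", r1, list(qual)),
            SequenceRecord(f"{id_prefix}{i}.2", r2, list(qual)),
        ))
        origins.append({
            "pair": i,
            "r1": (start, start + read_len, "+"),
            "r2": (end - read_len, end, "-"),
        })
    return pairs, origins


def make_transcripts(
    count: int,
    length_range: tuple[int, int] = (300, 2000),
    gc: float = 0.45,
    seed: int = 0,
) -> list[SequenceRecord]:
    """Random single-copy transcript sequences for genome-size estimation."""
    if count < 1:
        raise ValueError("need at least one transcript")
    rng = np.random.default_rng(seed)
    lo, hi = length_range
    return [
        SequenceRecord(f"tx{i}", _random_seq(rng, int(rng.integers(lo, hi + 1)), gc))
        for i in range(count)
    ]


# ---------------------------------------------------------------------------
# Trees and traits
# ---------------------------------------------------------------------------

def simulate_tree_and_traits(
    n_tips: int,
    birth_rate: float = 1.0,
    bm_sigma2: float = 1.0,
    seed: int = 0,
    root_value: float = 0.0,
) -> tuple[dendropy.Tree, dict[str, float]]:
    """Pure-birth (Yule) tree with a Brownian trait evolved along it.

    Tips are labeled t1..tn.  The tree is ultrametric; each child trait
    value is parent + Normal(0, bm_sigma2 * branch_length).
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    rng = np.random.default_rng(seed)

    class _B:
        __slots__ = ("birth", "children", "end", "label")

        def __init__(self, birth: float):
            self.birth = birth
            self.children: list[_B] = []
            self.end: Optional[float] = None
            self.label: Optional[str] = None

    root = _B(0.0)
    active = [root]
    t = 0.0
    while len(active) < n_tips:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        node = active[int(rng.integers(0, len(active)))]
        node.end = t
        node.children = [_B(t), _B(t)]
        active.remove(node)
        active.extend(node.children)
    t += rng.exponential(1.0 / (birth_rate * len(active)))
    for i, node in enumerate(active):
        node.end = t
        node.label = f"t{i + 1}"

    def newick(node: "_B", is_root: bool = False) -> str:
        if not node.children:
            return f"{node.label}:{node.end - node.birth:.10f}"
        inner = ",".join(newick(c) for c in node.children)
        # the stem below the first split carries no information; omit it
        return f"({inner})" if is_root else f"({inner}):{node.end - node.birth:.10f}"

    tree = dendropy.Tree.get(data=newick(root, is_root=True) + ";",
                             schema="newick", suppress_internal_node_taxa=True)

    traits: dict[str, float] = {}

    def evolve(node: "_B", value: float) -> None:
        bl = node.end - node.birth
        value = value + (rng.normal(0.0, math.sqrt(bm_sigma2 * bl))
                         if bm_sigma2 > 0 and bl > 0 else 0.0)
        if not node.children:
            traits[node.label] = value
        for child in node.children:
            evolve(child, value)

    for child in root.children or [root]:
        evolve(child, root_value)
    if not root.children:  # n_tips == 1 cannot happen, guard anyway
        traits[root.label] = root_value
    return tree, traits


# ---------------------------------------------------------------------------
# Canned study conditions
# ---------------------------------------------------------------------------

def planted_superfamily_spec(seed: int = 0, genome_length: int = 1_000_000,
                             divergence: float = 0.02) -> GenomeSpec:
    """A 1 Mb genome with three superfamilies at 30% / 15% / 5%.

    The fractions mirror a Gypsy-dominated plant genome with a smaller
    Copia component and a minor non-LTR family; half the genome is
    single-copy background.
    """
    def fam(name: str, superfamily: str, frac: float) -> FamilySpec:
        copies = int(frac * genome_length / 1000)
        return FamilySpec(name=name, superfamily=superfamily,
                          consensus_length=1000, copy_number=copies,
                          divergence=divergence)

    return GenomeSpec(
        genome_length=genome_length,
        families=(
            fam("RLG_syn1", "Gypsy", 0.30),
            fam("RLC_syn1", "Copia", 0.15),
            fam("RIL_syn1", "L1", 0.05),
        ),
        seed=seed,
    )
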