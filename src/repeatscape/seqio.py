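"""Readers and writers for the external formats the pipeline touches.

FASTA/FASTQ (Phred+33, gzip-transparent), the tab-delimited repeat
library dialect, Newick trees and TSV trait tables.  No science lives
here.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Optional, TextIO, Union

import dendropy

PathLike = Union[str, Path]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N self-complements)."""
    return seq.translate(_COMPLEMENT)[::-1]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class SequenceRecord:
    """A named nucleotide sequence, optionally with Phred qualities."""

    identifier: str
    sequence: str
    quality: Optional[list[int]] = None

    def __post_init__(self) -> None:
        if not self.identifier:
            raise FormatError("sequence record with empty identifier")
        self.sequence = self.sequence.upper()
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise FormatError(
                f"record {self.identifier!r}: sequence length "
                f"{len(self.sequence)} != quality length {len(self.quality)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class RepeatLibraryEntry:
    """One consensus in a repeat library: name, superfamily, family, class."""

    name: str
    superfamily: str
    family: str
    te_class: str
    sequence: str


def _open_text(path: PathLike) -> TextIO:
    """Open plain or gzipped text, sniffing the gzip magic bytes."""
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path, "rt")


# ---------------------------------------------------------------------------
# FASTQ / FASTA
# ---------------------------------------------------------------------------

def _fastq_records(handle: TextIO, source: str) -> Iterator[SequenceRecord]:
    offset = 0
    while True:
        header = handle.readline()
        if not header:
            return
        header = header.rstrip("\n")
        if not header.startswith("@"):
            raise FormatError(f"{source}: record {offset}: header {header!r} lacks '@'")
        seq = handle.readline().rstrip("\n")
        plus = handle.readline()
        qual = handle.readline().rstrip("\n")
        if not plus.startswith("+"):
            raise FormatError(f"{source}: record {offset}: missing '+' separator")
        if len(seq) != len(qual):
            raise FormatError(
                f"{source}: record {offset}: sequence/quality length mismatch"
            )
        ident = header[1:].split()[0] if len(header) > 1 else ""
        yield SequenceRecord(ident, seq, [ord(c) - 33 for c in qual])
        offset += 1


def read_fastq(
    path: PathLike, paired_with: Optional[PathLike] = None
) -> Iterator[Union[SequenceRecord, tuple[SequenceRecord, SequenceRecord]]]:
    """Stream FASTQ records, or synchronized mate pairs when two files are given.

    Gzip input is autodetected from the magic bytes.  Qualities are
    decoded as Phred+33.  With ``paired_with``, a length mismatch
    between the files raises a pairing error naming the pair index.
    """
    if paired_with is None:
        with _open_text(path) as fh:
            yield from _fastq_records(fh, str(path))
        return
    with _open_text(path) as fh1, _open_text(paired_with) as fh2:
        it1 = _fastq_records(fh1, str(path))
        it2 = _fastq_records(fh2, str(paired_with))
        index = 0
        while True:
            r1 = next(it1, None)
            r2 = next(it2, None)
            if r1 is None and r2 is None:
                return
            if r1 is None or r2 is None:
                raise FormatError(
                    f"desynchronized mates: one file ended after pair {index}"
                )
            yield r1, r2
            index += 1


def write_fastq(records: Iterable[SequenceRecord], path: PathLike) -> None:
    with open(path, "wt") as fh:
        for rec in records:
            if rec.quality is None:
                raise FormatError(f"record {rec.identifier!r} has no qualities")
            qual = "".join(chr(q + 33) for q in rec.quality)
            fh.write(f"@{rec.identifier}\n{rec.sequence}\n+\n{qual}\n")


def read_fasta(path: PathLike) -> Iterator[SequenceRecord]:
    """Stream FASTA records (gzip-transparent)."""
    with _open_text(path) as fh:
        ident: Optional[str] = None
        chunks: list[str] = []
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if ident is not None:
                    yield SequenceRecord(ident, "".join(chunks))
                ident = line[1:].split()[0] if len(line) > 1 else ""
                chunks = []
            elif line:
                chunks.append(line)
        if ident is not None:
            yield SequenceRecord(ident, "".join(chunks))


def write_fasta(records: Iterable[SequenceRecord], path_or_handle) -> None:
    own = isinstance(path_or_handle, (str, Path))
    fh = open(path_or_handle, "wt") if own else path_or_handle
    try:
        for rec in records:
            fh.write(f">{rec.identifier}\n{rec.sequence}\n")
    finally:
        if own:
            fh.close()


# ---------------------------------------------------------------------------
# Repeat library
# ---------------------------------------------------------------------------

def load_classification_table() -> dict[str, str]:
    """Superfamily -> TE class map shipped as editable package data."""
    table: dict[str, str] = {}
    text = resources.files("repeatscape").joinpath("data/te_classes.tsv").read_text()
    for line in text.splitlines():
        if not line or line.startswith("#"):
            continue
        superfamily, te_class = line.split("\t")
        table[superfamily] = te_class
    return table


def classify_superfamily(superfamily: str, table: Optional[dict[str, str]] = None) -> str:
    """Map a superfamily name to its TE class; unknowns map to "unknown"."""
    if table is None:
        table = load_classification_table()
    return table.get(superfamily, "unknown")


def read_repeat_library(path: PathLike) -> list[RepeatLibraryEntry]:
    """Parse a repeat library FASTA with ">name\\tsuperfamily\\tfamily" headers.

    A bare ">name" header is tolerated and assigns superfamily and
    family "unknown".  Headers with two fields (or more than three) and
    duplicate names are format errors.
    """
    table = load_classification_table()
    entries: list[RepeatLibraryEntry] = []
    seen: set[str] = set()
    with _open_text(path) as fh:
        name = superfamily = family = None
        chunks: list[str] = []

        def flush() -> None:
            if name is None:
                return
            if name in seen:
                raise FormatError(f"duplicate repeat-library name {name!r}")
            seen.add(name)
            entries.append(
                RepeatLibraryEntry(
                    name=name,
                    superfamily=superfamily,
                    family=family,
                    te_class=classify_superfamily(superfamily, table),
                    sequence="".join(chunks).upper(),
                )
            )

        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                flush()
                fields = line[1:].split("\t")
                if len(fields) == 1:
                    name, superfamily, family = fields[0], "unknown", "unknown"
                elif len(fields) == 3:
                    name, superfamily, family = fields
                else:
                    raise FormatError(
                        f"repeat-library header {line!r} has {len(fields)} "
                        "tab-separated fields, expected 3 (or a bare name)"
                    )
                chunks = []
            elif line:
                chunks.append(line)
        flush()
    return entries


def write_repeat_library(entries: Iterable[RepeatLibraryEntry], path: PathLike) -> None:
    with open(path, "wt") as fh:
        for e in entries:
            fh.write(f">{e.name}\t{e.superfamily}\t{e.family}\n{e.sequence}\n")


# ---------------------------------------------------------------------------
# Newick trees and trait tables
# ---------------------------------------------------------------------------

def read_newick(source: Union[PathLike, str]) -> dendropy.Tree:
    """Read a Newick tree from a path or a literal string.

    Duplicate tip labels are rejected; branch lengths are preserved.
    """
    text = source if isinstance(source, str) and source.strip().startswith("(") else None
    if text is None:
        text = Path(source).read_text()
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:  # noqa: BLE001 - normalize parser errors
        raise FormatError(f"invalid newick ({exc})") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    dupes = {l for l in labels if labels.count(l) > 1}
    if dupes:
        raise FormatError(f"duplicate tip labels: {sorted(dupes)}")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise FormatError("negative branch length")
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


def read_trait_table(path: PathLike) -> "pd.DataFrame":
    """TSV trait table: header line, first column = tip label."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise FormatError("duplicate tip labels in trait table")
    return df
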