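"""Strict readers and writers for the plain-text formats the pipeline touches.

FASTA carries reference loci, consensus sequences and alignments; FASTQ
carries the skim read libraries; newick carries gene trees and species trees
(internal-node labels read as support values); a RAxML-style partition file
records the column range each locus occupies in a concatenated matrix.

All coordinates are 0-based half-open internally; the 1-based inclusive
convention of partition files exists only at the I/O boundary.
"""

from __future__ import annotations

import gzip
import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy

# Sequence alphabet: bases, N, gap, and the IUPAC ambiguity codes.
IUPAC_CODES = set("ACGTNRYSWKMBDHV")
FASTA_ALPHABET = IUPAC_CODES | {"-", "?"}
READ_ALPHABET = set("ACGTN")

_ID_RE = re.compile(r"^\S+$")


@dataclass(frozen=True)
class SequenceRecord:
    """A named DNA sequence (reference locus, consensus, or alignment row)."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id or not _ID_RE.match(self.id):
            raise ValueError(f"sequence id must be a non-empty token, got {self.id!r}")
        if not self.seq:
            raise ValueError(f"empty sequence for record {self.id!r}")
        bad = set(self.seq) - FASTA_ALPHABET
        if bad:
            raise ValueError(
                f"illegal characters {sorted(bad)} in sequence {self.id!r}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class ReadRecord:
    """A single sequencing read, optionally with its quality string."""

    id: str
    seq: str
    qual: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("read id must be non-empty")
        bad = set(self.seq) - READ_ALPHABET
        if bad:
            raise ValueError(f"illegal characters {sorted(bad)} in read {self.id!r}")
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise ValueError(
                f"read {self.id!r}: quality length {len(self.qual)} != "
                f"sequence length {len(self.seq)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class PartitionTable:
    """Ordered, contiguous 1-based inclusive locus coordinates in a supermatrix."""

    entries: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        expected_start = 1
        seen: set[str] = set()
        for locus_id, start, end in self.entries:
            if locus_id in seen:
                raise ValueError(f"duplicate locus {locus_id!r} in partition table")
            seen.add(locus_id)
            if start != expected_start:
                raise ValueError(
                    f"partition {locus_id!r} starts at {start}, expected "
                    f"{expected_start} (entries must be contiguous from 1)"
                )
            if end < start:
                raise ValueError(f"partition {locus_id!r}: end {end} < start {start}")
            expected_start = end + 1

    @property
    def span(self) -> int:
        return self.entries[-1][2] if self.entries else 0

    @classmethod
    def from_lengths(cls, lengths: Iterable[tuple[str, int]]) -> "PartitionTable":
        entries = []
        pos = 1
        for locus_id, length in lengths:
            entries.append((locus_id, pos, pos + length - 1))
            pos += length
        return cls(tuple(entries))


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Parse a FASTA file into uppercase :class:`SequenceRecord`s.

    Wrapped sequence lines are joined; duplicate ids and empty sequences are
    hard errors naming the offending record.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    header: str | None = None
    chunks: list[str] = []

    def flush() -> None:
        nonlocal header, chunks
        if header is None:
            return
        seq = "".join(chunks).upper()
        if not seq:
            raise ValueError(f"empty sequence for record {header!r} in {path}")
        if header in seen:
            raise ValueError(f"duplicate sequence id {header!r} in {path}")
        seen.add(header)
        records.append(SequenceRecord(header, seq))
        header, chunks = None, []

    with _open_text(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].split()[0] if len(line) > 1 else ""
                if not header:
                    raise ValueError(f"FASTA header with no id in {path}")
            else:
                if header is None:
                    raise ValueError(f"sequence data before any header in {path}")
                chunks.append(line)
        flush()
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 80) -> None:
    with _open_text(path, "wt") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def read_fastq(path: str | Path) -> list[ReadRecord]:
    """Parse 4-line FASTQ records; gzip is detected from a ``.gz`` suffix."""
    reads: list[ReadRecord] = []
    with _open_text(path) as fh:
        while True:
            head = fh.readline()
            if not head:
                break
            head = head.rstrip("\n")
            if not head.startswith("@"):
                raise ValueError(f"malformed FASTQ header {head!r} in {path}")
            rid = head[1:].split()[0]
            seq = fh.readline().rstrip("\n").upper()
            plus = fh.readline()
            qual = fh.readline().rstrip("\n")
            if not plus.startswith("+"):
                raise ValueError(f"missing '+' separator for read {rid!r} in {path}")
            if len(qual) != len(seq):
                raise ValueError(
                    f"read {rid!r}: quality length {len(qual)} != "
                    f"sequence length {len(seq)} in {path}"
                )
            reads.append(ReadRecord(rid, seq, qual))
    return reads


def write_fastq(reads: Iterable[ReadRecord], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for read in reads:
            qual = read.qual if read.qual is not None else "I" * len(read.seq)
            fh.write(f"@{read.id}\n{read.seq}\n+\n{qual}\n")


def read_newick(path: str | Path) -> list[dendropy.Tree]:
    """Read one tree per newick line; numeric internal-node labels become support.

    Raises ``ValueError`` on malformed newick (e.g. unbalanced parentheses),
    reporting the character offset of the failure.
    """
    trees: list[dendropy.Tree] = []
    text = Path(path).read_text()
    for chunk in text.split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        _check_balanced(chunk)
        tree = dendropy.Tree.get(
            data=chunk + ";",
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
        _labels_to_support(tree)
        trees.append(tree)
    return trees


def parse_newick(newick: str) -> dendropy.Tree:
    """Parse a single newick string (convenience twin of :func:`read_newick`)."""
    _check_balanced(newick)
    tree = dendropy.Tree.get(
        data=newick if newick.rstrip().endswith(";") else newick + ";",
        schema="newick",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
    _labels_to_support(tree)
    return tree


def _check_balanced(newick: str) -> None:
    depth = 0
    for offset, ch in enumerate(newick):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise ValueError(f"unbalanced ')' at offset {offset} in newick string")
    if depth != 0:
        raise ValueError(
            f"unbalanced parentheses in newick string ({depth} unclosed '(' "
            f"at offset {len(newick)})"
        )


def _labels_to_support(tree: dendropy.Tree) -> None:
    for node in tree.internal_nodes():
        if node.label is not None:
            try:
                node.edge.support = float(node.label)
            except ValueError:
                pass


def write_partitions(table: PartitionTable, path: str | Path) -> None:
    """Write ``DNA, <locus> = <start>-<end>`` lines, one per partition entry."""
    with _open_text(path, "wt") as fh:
        for locus_id, start, end in table.entries:
            fh.write(f"DNA, {locus_id} = {start}-{end}\n")


def read_partitions(path: str | Path) -> PartitionTable:
    entries = []
    with _open_text(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            m = re.match(r"DNA,\s*(\S+)\s*=\s*(\d+)-(\d+)$", line)
            if not m:
                raise ValueError(f"malformed partition line {line!r}")
            entries.append((m.group(1), int(m.group(2)), int(m.group(3))))
    return PartitionTable(tuple(entries))
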