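"""Per-locus alignment assembly, filtering, statistics and concatenation.

Consensus sequences are reference-projected, so the consensuses of one locus
across samples are columnwise homologous by construction and can be stacked
into an alignment without an external aligner. This module applies the
coverage filter (-C: a sequence joins the locus alignment only when its
completeness reaches the threshold), edge trimming (-T) and edge filling,
computes per-locus descriptors (variable sites, parsimony-informative sites,
missing data), extracts SNP columns, filters loci, and concatenates loci into
a supermatrix with partition bookkeeping.

Site classification: a variable site carries >= 2 distinct unambiguous bases
(A/C/G/T); a parsimony-informative site carries >= 2 distinct unambiguous
bases each present in >= 2 rows. N, '-', '?' and IUPAC ambiguity codes never
create variability. Missing cells are N, '-' and '?'.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .consensus_calling import ConsensusRecord
from .seq_io import PartitionTable, SequenceRecord

logger = logging.getLogger(__name__)

MISSING_CHARS = frozenset("N-?")
_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)
_MISSING_BYTES = np.frombuffer(b"N-?", dtype=np.uint8)


@dataclass
class LocusAlignment:
    """One locus across samples; rows are an ordered sample -> sequence map."""

    locus_id: str
    rows: dict[str, str]

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError(
                f"locus {self.locus_id!r}: unequal row lengths {sorted(lengths)}"
            )

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def to_array(self) -> np.ndarray:
        """(n_rows, length) uint8 view of the alignment."""
        if not self.rows:
            return np.zeros((0, 0), dtype=np.uint8)
        return np.frombuffer(
            "".join(self.rows.values()).encode(), dtype=np.uint8
        ).reshape(self.n_rows, self.length)

    @classmethod
    def from_array(
        cls, locus_id: str, sample_ids: Sequence[str], arr: np.ndarray
    ) -> "LocusAlignment":
        rows = {
            sid: arr[i].tobytes().decode() for i, sid in enumerate(sample_ids)
        }
        return cls(locus_id, rows)

    def to_records(self) -> list[SequenceRecord]:
        return [SequenceRecord(sid, seq) for sid, seq in self.rows.items()]


@dataclass
class ConcatenatedMatrix:
    """Supermatrix: per-locus alignments joined side by side."""

    rows: dict[str, str]
    partitions: PartitionTable
    missing_pct: float

    @property
    def length(self) -> int:
        return self.partitions.span

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def slice_locus(self, locus_id: str) -> LocusAlignment:
        """Recover one input locus alignment from the supermatrix."""
        for lid, start, end in self.partitions.entries:
            if lid == locus_id:
                return LocusAlignment(
                    locus_id, {s: seq[start - 1 : end] for s, seq in self.rows.items()}
                )
        raise KeyError(f"locus {locus_id!r} not in partition table")


@dataclass
class LocusDescriptors:
    """Per-locus alignment summary used by the downstream diagnostics."""

    locus_id: str
    aligned_bp: int
    n_sequences: int
    variable_sites: int
    pis: int
    missing_pct: float
    coverage_mean: float = float("nan")
    coverage_sd: float = float("nan")
    depth_median: float = float("nan")

    def __post_init__(self) -> None:
        if not (self.pis <= self.variable_sites <= self.aligned_bp):
            raise ValueError(
                f"locus {self.locus_id!r}: pis {self.pis} <= variable "
                f"{self.variable_sites} <= aligned_bp {self.aligned_bp} violated"
            )


def normalize_missing(seq: str) -> str:
    """'?' is accepted on input as a missing synonym and normalized to N."""
    return seq.replace("?", "N")


def assemble_locus(
    consensuses: Sequence[ConsensusRecord], min_coverage: float = 0.1
) -> LocusAlignment:
    """Stack the consensuses of one locus whose coverage reaches -C.

    Rows are ordered by sample id; an empty alignment (every sample below
    threshold) is a normal outcome, dropped later by :func:`filter_loci`.
    """
    loci = {c.locus_id for c in consensuses}
    if len(loci) > 1:
        raise ValueError(f"mixed loci in assemble_locus: {sorted(loci)}")
    locus_id = consensuses[0].locus_id if consensuses else ""
    kept = sorted(
        (c for c in consensuses if c.coverage >= min_coverage),
        key=lambda c: c.sample_id,
    )
    return LocusAlignment(
        locus_id, {c.sample_id: normalize_missing(c.seq) for c in kept}
    )


def _occupancy(arr: np.ndarray) -> np.ndarray:
    """Per-column fraction of rows holding a non-missing character."""
    if arr.size == 0:
        return np.zeros(arr.shape[1] if arr.ndim == 2 else 0)
    missing = np.isin(arr, _MISSING_BYTES)
    return 1.0 - missing.mean(axis=0)


def trim_edges(aln: LocusAlignment, min_occupancy: float = 0.5) -> LocusAlignment:
    """Drop leading/trailing columns whose occupancy is below the threshold;
    interior columns are never touched (-T)."""
    if not 0.0 < min_occupancy <= 1.0:
        raise ValueError("min_occupancy must be in (0, 1]")
    if aln.n_rows == 0 or aln.length == 0:
        return aln
    occ = _occupancy(aln.to_array())
    keep = occ >= min_occupancy
    if not keep.any():
        return LocusAlignment(aln.locus_id, {s: "" for s in aln.rows})
    first, last = int(np.argmax(keep)), int(len(keep) - 1 - np.argmax(keep[::-1]))
    rows = {s: seq[first : last + 1] for s, seq in aln.rows.items()}
    return LocusAlignment(aln.locus_id, rows)


def fill_edges(aln: LocusAlignment) -> LocusAlignment:
    """Replace leading and trailing '-' runs with N in every row: gaps at
    alignment edges are absence of data, not inferred indels."""
    rows = {}
    for sid, seq in aln.rows.items():
        stripped = seq.strip("-")
        if not stripped:
            rows[sid] = "N" * len(seq)
            continue
        lead = len(seq) - len(seq.lstrip("-"))
        trail = len(seq) - len(seq.rstrip("-"))
        rows[sid] = "N" * lead + stripped + "N" * trail
    return LocusAlignment(aln.locus_id, rows)


def _site_classes(arr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Boolean (variable, parsimony-informative) vectors per column."""
    n_rows, n_cols = arr.shape
    if n_rows == 0 or n_cols == 0:
        z = np.zeros(n_cols, dtype=bool)
        return z, z
    base_counts = np.stack([(arr == b).sum(axis=0) for b in _BASE_BYTES])
    distinct = (base_counts > 0).sum(axis=0)
    variable = distinct >= 2
    pis = (base_counts >= 2).sum(axis=0) >= 2
    return variable, pis


def align_stats(aln: LocusAlignment) -> LocusDescriptors:
    """Per-locus descriptors: length, rows, variable sites, PIS, missing %."""
    arr = aln.to_array()
    variable, pis = _site_classes(arr)
    n_cells = arr.size
    missing = int(np.isin(arr, _MISSING_BYTES).sum()) if n_cells else 0
    return LocusDescriptors(
        locus_id=aln.locus_id,
        aligned_bp=aln.length,
        n_sequences=aln.n_rows,
        variable_sites=int(variable.sum()),
        pis=int(pis.sum()),
        missing_pct=100.0 * missing / n_cells if n_cells else 0.0,
    )


def attach_consensus_stats(
    desc: LocusDescriptors, consensuses: Sequence[ConsensusRecord]
) -> LocusDescriptors:
    """Fill the coverage/depth descriptor fields from the consensus records
    that entered the alignment."""
    if not consensuses:
        return desc
    covs = np.array([c.coverage for c in consensuses])
    depths = np.array([c.depth_median for c in consensuses])
    desc.coverage_mean = float(covs.mean())
    desc.coverage_sd = float(covs.std(ddof=1)) if covs.size > 1 else 0.0
    desc.depth_median = float(np.median(depths))
    return desc


def extract_snps(aln: LocusAlignment) -> LocusAlignment:
    """Keep only variable columns, preserving order (idempotent)."""
    arr = aln.to_array()
    if arr.size == 0:
        return LocusAlignment(aln.locus_id, {s: "" for s in aln.rows})
    variable, _ = _site_classes(arr)
    return LocusAlignment.from_array(
        aln.locus_id, list(aln.rows), arr[:, variable]
    )


def occupancy_column_filter(
    aln: LocusAlignment, min_occupancy: float
) -> LocusAlignment:
    """Drop every column (edges and interior) below the occupancy threshold —
    a generic stand-in for external alignment post-filtering tools."""
    if not 0.0 < min_occupancy <= 1.0:
        raise ValueError("min_occupancy must be in (0, 1]")
    arr = aln.to_array()
    if arr.size == 0:
        return aln
    keep = _occupancy(arr) >= min_occupancy
    return LocusAlignment.from_array(aln.locus_id, list(aln.rows), arr[:, keep])


def filter_loci(
    alignments: Sequence[LocusAlignment],
    min_rows: int = 0,
    min_length: int = 0,
) -> list[LocusAlignment]:
    """Keep loci with enough rows and columns; log every removal with its
    reason."""
    if min_rows < 0 or min_length < 0:
        raise ValueError("thresholds must be >= 0")
    kept = []
    for aln in alignments:
        if aln.n_rows < min_rows:
            logger.info(
                "locus %s removed: %d rows < %d", aln.locus_id, aln.n_rows, min_rows
            )
        elif aln.length < min_length:
            logger.info(
                "locus %s removed: length %d < %d", aln.locus_id, aln.length, min_length
            )
        else:
            kept.append(aln)
    if not kept:
        logger.warning("all %d loci removed by filter_loci", len(alignments))
    return kept


def concatenate(
    alignments: Sequence[LocusAlignment],
    samples: Sequence[str] | None = None,
) -> ConcatenatedMatrix:
    """Join locus alignments side by side into a supermatrix.

    Samples absent from a locus are filled with N across that partition; the
    partition table records each locus's 1-based inclusive column range in
    input order.
    """
    empty = [a.locus_id for a in alignments if a.length == 0]
    if empty:
        logger.info("dropping %d empty loci before concatenation", len(empty))
        alignments = [a for a in alignments if a.length > 0]
    if samples is None:
        seen: dict[str, None] = {}
        for aln in alignments:
            for sid in aln.rows:
                seen[sid] = None
        samples = sorted(seen)
    parts = PartitionTable.from_lengths(
        [(aln.locus_id, aln.length) for aln in alignments]
    )
    chunks: dict[str, list[str]] = {sid: [] for sid in samples}
    for aln in alignments:
        blank = "N" * aln.length
        for sid in samples:
            chunks[sid].append(aln.rows.get(sid, blank))
    rows = {sid: "".join(parts_list) for sid, parts_list in chunks.items()}
    total = len(samples) * parts.span
    if total:
        missing = sum(
            seq.count("N") + seq.count("-") + seq.count("?") for seq in rows.values()
        )
        missing_pct = 100.0 * missing / total
    else:
        missing_pct = 0.0
    return ConcatenatedMatrix(rows, parts, missing_pct)
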