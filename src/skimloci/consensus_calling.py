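"""Depth-thresholded consensus calling from pileups, in reference coordinates.

A base is kept in the consensus only when its pileup depth reaches the minimum
depth ``d``; sub-threshold positions are masked as N. When a clear second
allele is present (frequency >= ``het_fraction`` of the site depth) the
two-fold IUPAC ambiguity code is emitted, mirroring the behaviour of the
bcftools/vcfutils/seqtk consensus route for heterozygous sites. Coverage of a
consensus is its completeness: the fraction of reference positions recovered
as non-N characters. Depth summary statistics (median, sample sd) are taken
over positions with depth >= 1, the interpretation under which partially
covered loci can show the low integer depth medians typical of genome skims.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .read_mapping import BASES, DEL_ROW, LocusPileup

# Two-fold ambiguity codes, keyed by the unordered base pair.
AMBIGUITY_2FOLD = {
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("GC"): "S",
    frozenset("AT"): "W",
    frozenset("GT"): "K",
    frozenset("AC"): "M",
}


@dataclass(frozen=True)
class ConsensusRecord:
    """One sample x locus reference-projected consensus with its statistics."""

    sample_id: str
    locus_id: str
    seq: str
    coverage: float
    depth_median: float
    depth_sd: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.coverage <= 1.0 + 1e-12:
            raise ValueError(f"coverage {self.coverage} outside [0, 1]")

    @property
    def n_recovered(self) -> int:
        """Number of non-N positions (recovered base pairs)."""
        return len(self.seq) - self.seq.count("N")


def call_site(
    counts: Mapping[str, int] | np.ndarray,
    min_depth: int,
    het_fraction: float = 0.25,
) -> str:
    """Call one consensus character from A/C/G/T counts at a site.

    N below ``min_depth``; the two-fold IUPAC code when the second allele
    reaches ``het_fraction`` of the depth (a 50/50 tie therefore yields the
    code); otherwise the majority base, ties broken in A<C<G<T order.
    """
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    if isinstance(counts, np.ndarray):
        vec = [int(c) for c in counts[:4]]
    else:
        vec = [int(counts.get(b, 0)) for b in BASES]
    depth = sum(vec)
    if depth < min_depth:
        return "N"
    order = sorted(range(4), key=lambda i: (-vec[i], BASES[i]))
    top, second = order[0], order[1]
    if vec[second] > 0 and vec[second] >= het_fraction * depth:
        return AMBIGUITY_2FOLD[frozenset({BASES[top], BASES[second]})]
    return BASES[top]


_AMB_TABLE = np.zeros((4, 4), dtype=np.uint8)
for _pair, _code in AMBIGUITY_2FOLD.items():
    _a, _b = sorted(_pair)
    _i, _j = BASES.index(_a), BASES.index(_b)
    _AMB_TABLE[_i, _j] = _AMB_TABLE[_j, _i] = ord(_code)
_BASE_ORDS = np.frombuffer(b"ACGT", dtype=np.uint8)


def consensus_string(
    counts: np.ndarray, min_depth: int, het_fraction: float = 0.25
) -> str:
    """Vectorized consensus over a (5, L) pileup count array; column-wise
    identical to :func:`call_site` plus the majority-deletion rule."""
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    base_counts = counts[:4]
    dels = counts[DEL_ROW]
    L = base_counts.shape[1]
    if L == 0:
        return ""
    depth = base_counts.sum(axis=0)
    cols = np.arange(L)
    top = base_counts.argmax(axis=0)  # first max wins: A<C<G<T tie order
    rest = base_counts.copy()
    rest[top, cols] = -1
    second = rest.argmax(axis=0)
    second_count = base_counts[second, cols]
    ambiguous = (second_count > 0) & (second_count >= het_fraction * depth)
    chars = np.where(ambiguous, _AMB_TABLE[top, second], _BASE_ORDS[top])
    chars = np.where(depth < min_depth, np.uint8(ord("N")), chars)
    del_call = (dels > depth) & (dels + depth >= min_depth)
    chars = np.where(del_call, np.uint8(ord("-")), chars)
    return chars.astype(np.uint8).tobytes().decode()


def consensus_locus(
    pileup: LocusPileup,
    sample_id: str,
    min_depth: int = 2,
    het_fraction: float = 0.25,
) -> ConsensusRecord:
    """Call the full consensus for one locus.

    Positions where deletions outnumber base observations are emitted as '-'
    (provided total support reaches ``min_depth``) and count as recovered for
    coverage, since a deletion is a positive observation, not missing data.
    """
    seq = consensus_string(pileup.counts, min_depth, het_fraction)
    coverage = (len(seq) - seq.count("N")) / len(seq) if seq else 0.0
    _, med, sd = depth_profile(pileup)
    return ConsensusRecord(sample_id, pileup.locus_id, seq, coverage, med, sd)


def depth_profile(pileup: LocusPileup) -> tuple[np.ndarray, float, float]:
    """Per-position depth vector plus (median, sample sd) over covered
    positions (depth >= 1); both 0 when nothing is covered, sd 0 for a single
    covered position."""
    depth = pileup.depth
    covered = depth[depth >= 1]
    if covered.size == 0:
        return depth, 0.0, 0.0
    med = float(np.median(covered))
    sd = float(np.std(covered, ddof=1)) if covered.size > 1 else 0.0
    return depth, med, sd


@dataclass(frozen=True)
class SiteTableRow:
    locus_id: str
    pos: int  # 1-based
    depth: int
    ref_base: str
    called_base: str
    count_a: int
    count_c: int
    count_g: int
    count_t: int
    count_del: int


SITE_TABLE_HEADER = "locus\tpos\tdepth\tref\tcall\tA\tC\tG\tT\tdel"


def export_site_table(
    pileups: Mapping[str, LocusPileup],
    calls: Mapping[str, ConsensusRecord],
    refs,
    path: str | Path,
) -> None:
    """Plain-text per-site table (the pipeline's text analog of a VCF),
    sorted by (locus, position)."""
    with open(path, "w") as fh:
        fh.write(SITE_TABLE_HEADER + "\n")
        for locus_id in sorted(pileups):
            pile = pileups[locus_id]
            cons = calls[locus_id]
            ref_seq = refs[locus_id].seq
            c = pile.counts
            depth = pile.depth
            for pos in range(pile.length):
                fh.write(
                    f"{locus_id}\t{pos + 1}\t{int(depth[pos])}\t{ref_seq[pos]}\t"
                    f"{cons.seq[pos]}\t{c[0, pos]}\t{c[1, pos]}\t{c[2, pos]}\t"
                    f"{c[3, pos]}\t{c[DEL_ROW, pos]}\n"
                )


def read_site_table(path: str | Path) -> list[SiteTableRow]:
    rows = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header != SITE_TABLE_HEADER:
            raise ValueError(f"malformed site table {path}")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            rows.append(
                SiteTableRow(f[0], int(f[1]), int(f[2]), f[3], f[4],
                             int(f[5]), int(f[6]), int(f[7]), int(f[8]), int(f[9]))
            )
    return rows
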