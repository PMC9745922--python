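"""Stage-oriented pipeline driver: mapping (m) -> site calling (s) ->
consensus generation (c) -> alignment generation (a).

Each stage writes plain-text artifacts under the output directory and later
stages resume from them, so a run may execute any contiguous prefix of stages
or pick up where a previous run stopped. A manifest records every parameter
and input checksum; a log keeps per-stage counts. Re-running a stage with the
same inputs and parameters reproduces its outputs byte for byte.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import consensus_calling as cc
from . import locus_alignments as la
from . import read_mapping as rm
from . import seq_io
from .descriptors_stats import LibrarySummary, library_table, summarize_library

logger = logging.getLogger(__name__)

STAGE_ORDER = "msca"


@dataclass(frozen=True)
class RunConfig:
    """One pipeline invocation: stages to run plus every assembly knob."""

    refs_path: str | Path
    reads_dir: str | Path
    out_dir: str | Path
    stages: str = "msca"  # contiguous subsequence of m, s, c, a
    min_depth: int = 2  # -d
    min_coverage: float = 0.1  # -C
    trim: bool = False  # -T
    trim_occupancy: float = 0.5
    het_fraction: float = 0.25
    scoring: rm.ScoringScheme = field(default_factory=rm.ScoringScheme)
    min_rows: int = 0
    min_length: int = 0
    write_site_tables: bool = True
    write_sam: bool = False

    def __post_init__(self) -> None:
        if self.min_depth < 1:
            raise ValueError("min_depth (-d) must be >= 1")
        if not 0.0 <= self.min_coverage <= 1.0:
            raise ValueError("min_coverage (-C) must be in [0, 1]")
        if not self.stages:
            raise ValueError("at least one stage must be selected")
        bad = set(self.stages) - set(STAGE_ORDER)
        if bad:
            raise ValueError(f"unknown stages {sorted(bad)}")
        idx = [STAGE_ORDER.index(s) for s in self.stages]
        if idx != sorted(idx) or idx != list(range(idx[0], idx[-1] + 1)):
            raise ValueError(
                f"stages must form a contiguous run of '{STAGE_ORDER}', got {self.stages!r}"
            )


def _find_libraries(reads_dir: Path) -> dict[str, Path]:
    libs: dict[str, Path] = {}
    for ext in ("*.fastq", "*.fq", "*.fastq.gz", "*.fq.gz"):
        for path in sorted(reads_dir.glob(ext)):
            stem = path.name
            for suffix in (".fastq.gz", ".fq.gz", ".fastq", ".fq"):
                if stem.endswith(suffix):
                    stem = stem[: -len(suffix)]
                    break
            libs.setdefault(stem, path)
    if not libs:
        raise FileNotFoundError(f"no FASTQ libraries found in {reads_dir}")
    return libs


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def _require(path: Path, produced_by: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"missing {path}; run stage '{produced_by}' first"
        )
    return path


def load_sample_pileups(
    out: Path, refs: rm.ReferenceSet, samples: Iterable[str]
) -> dict[str, dict[str, rm.LocusPileup]]:
    """Rebuild per-sample pileups from the mapping stage's placement tables."""
    pileups = {}
    for sid in samples:
        ptab = _require(out / "mapping" / f"{sid}.placements.tsv", "m")
        placements = rm.read_placements(ptab)
        pileups[sid] = rm.compute_pileup(placements, refs)
    return pileups


def _consensus_all(
    pileups: Mapping[str, Mapping[str, rm.LocusPileup]],
    min_depth: int,
    het_fraction: float,
) -> dict[str, dict[str, cc.ConsensusRecord]]:
    return {
        sid: {
            locus: cc.consensus_locus(pile, sid, min_depth, het_fraction)
            for locus, pile in sorted(per_sample.items())
        }
        for sid, per_sample in pileups.items()
    }


def assemble_matrix(
    consensuses: Mapping[str, Mapping[str, cc.ConsensusRecord]],
    refs: rm.ReferenceSet,
    min_coverage: float,
    trim: bool = False,
    trim_occupancy: float = 0.5,
    min_rows: int = 0,
    min_length: int = 0,
) -> tuple[list[la.LocusAlignment], la.ConcatenatedMatrix, list[la.LocusDescriptors]]:
    """Consensuses -> filtered per-locus alignments -> supermatrix + stats."""
    alignments: list[la.LocusAlignment] = []
    descriptors: list[la.LocusDescriptors] = []
    for locus_id in refs.ids:
        recs = [
            consensuses[sid][locus_id]
            for sid in sorted(consensuses)
            if locus_id in consensuses[sid]
        ]
        aln = la.assemble_locus(recs, min_coverage) if recs else la.LocusAlignment(locus_id, {})
        aln = la.fill_edges(aln)
        if trim and aln.n_rows:
            aln = la.trim_edges(aln, trim_occupancy)
        alignments.append(aln)
    kept = la.filter_loci(
        [a for a in alignments if a.n_rows > 0 and a.length > 0],
        min_rows=min_rows,
        min_length=min_length,
    )
    for aln in kept:
        desc = la.align_stats(aln)
        la.attach_consensus_stats(
            desc,
            [
                consensuses[sid][aln.locus_id]
                for sid in aln.rows
                if aln.locus_id in consensuses[sid]
            ],
        )
        descriptors.append(desc)
    matrix = la.concatenate(kept)
    return kept, matrix, descriptors


def run_pipeline(config: RunConfig) -> Path:
    """Execute the selected stages; returns the output directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path)
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("skimloci")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        return _run_stages(config, out)
    finally:
        root.removeHandler(handler)
        handler.close()


def _run_stages(config: RunConfig, out: Path) -> Path:
    refs_path = Path(config.refs_path)
    reads_dir = Path(config.reads_dir)
    refs = rm.ReferenceSet(seq_io.read_fasta(refs_path))
    libraries = _find_libraries(reads_dir)
    samples = sorted(libraries)

    manifest = out / "manifest.txt"
    with open(manifest, "w") as fh:
        fh.write(f"stages={config.stages}\n")
        fh.write(f"min_depth={config.min_depth}\n")
        fh.write(f"min_coverage={config.min_coverage}\n")
        fh.write(f"trim={config.trim}\n")
        fh.write(f"trim_occupancy={config.trim_occupancy}\n")
        fh.write(f"het_fraction={config.het_fraction}\n")
        fh.write(
            "scoring=A:{0.match_score},B:{0.mismatch_penalty},O:{0.gap_open},"
            "E:{0.gap_extend},k:{0.seed_length},f:{0.min_score_frac}\n".format(
                config.scoring
            )
        )
        fh.write(f"min_rows={config.min_rows}\n")
        fh.write(f"min_length={config.min_length}\n")
        fh.write(f"refs={refs_path} sha256:{_checksum(refs_path)}\n")
        for sid in samples:
            fh.write(f"library.{sid}={libraries[sid]} sha256:{_checksum(libraries[sid])}\n")

    read_counts: dict[str, int] = {}

    if "m" in config.stages:
        map_dir = out / "mapping"
        map_dir.mkdir(exist_ok=True)
        index = rm.build_index(refs, config.scoring.seed_length)
        for sid in samples:
            reads = seq_io.read_fastq(libraries[sid])
            read_counts[sid] = len(reads)
            placements = rm.map_library(reads, index, refs, config.scoring)
            rm.write_placements(placements, map_dir / f"{sid}.placements.tsv")
            if config.write_sam:
                rm.write_sam(placements, refs, map_dir / f"{sid}.sam")
            logger.info("stage m: %s %d/%d mapped", sid, len(placements), len(reads))
        (map_dir / "read_counts.tsv").write_text(
            "sample\tn_reads\n"
            + "".join(f"{sid}\t{read_counts[sid]}\n" for sid in samples)
        )

    pileups: dict[str, dict[str, rm.LocusPileup]] | None = None

    if "s" in config.stages:
        pileups = load_sample_pileups(out, refs, samples)
        site_dir = out / "sites"
        site_dir.mkdir(exist_ok=True)
        calls = _consensus_all(pileups, config.min_depth, config.het_fraction)
        for sid in samples:
            if config.write_site_tables:
                cc.export_site_table(
                    pileups[sid], calls[sid], refs, site_dir / f"{sid}.sites.tsv"
                )
            with open(site_dir / f"{sid}.depth.tsv", "w") as fh:
                fh.write("locus\tdepth_median\tdepth_sd\tcovered_positions\n")
                for locus in refs.ids:
                    vec, med, sd = cc.depth_profile(pileups[sid][locus])
                    fh.write(f"{locus}\t{med}\t{sd}\t{int((vec >= 1).sum())}\n")
            logger.info("stage s: %s site tables written", sid)

    if "c" in config.stages:
        if pileups is None:
            pileups = load_sample_pileups(out, refs, samples)
        cons_dir = out / "consensus"
        cons_dir.mkdir(exist_ok=True)
        calls = _consensus_all(pileups, config.min_depth, config.het_fraction)
        for sid in samples:
            recs = [
                seq_io.SequenceRecord(f"{sid}|{locus}", c.seq)
                for locus, c in calls[sid].items()
            ]
            seq_io.write_fasta(recs, cons_dir / f"{sid}.fasta")
            with open(cons_dir / f"{sid}.stats.tsv", "w") as fh:
                fh.write("locus\tcoverage\tdepth_median\tdepth_sd\n")
                for locus, c in calls[sid].items():
                    fh.write(f"{locus}\t{c.coverage:.6f}\t{c.depth_median}\t{c.depth_sd:.6f}\n")
            logger.info("stage c: %s consensus written", sid)

    if "a" in config.stages:
        cons_dir = out / "consensus"
        consensuses: dict[str, dict[str, cc.ConsensusRecord]] = {}
        for sid in samples:
            fasta = _require(cons_dir / f"{sid}.fasta", "c")
            stats_path = _require(cons_dir / f"{sid}.stats.tsv", "c")
            stats = pd.read_csv(stats_path, sep="\t").set_index("locus")
            per_sample = {}
            for rec in seq_io.read_fasta(fasta):
                _, locus = rec.id.split("|", 1)
                row = stats.loc[locus]
                per_sample[locus] = cc.ConsensusRecord(
                    sid, locus, rec.seq,
                    float(row["coverage"]), float(row["depth_median"]),
                    float(row["depth_sd"]),
                )
            consensuses[sid] = per_sample
        kept, matrix, descriptors = assemble_matrix(
            consensuses, refs,
            config.min_coverage, config.trim, config.trim_occupancy,
            config.min_rows, config.min_length,
        )
        aln_dir = out / "alignments"
        aln_dir.mkdir(exist_ok=True)
        for aln in kept:
            seq_io.write_fasta(aln.to_records(), aln_dir / f"{aln.locus_id}.fasta")
        seq_io.write_fasta(
            [seq_io.SequenceRecord(sid, seq) for sid, seq in matrix.rows.items()],
            out / "concatenated.fasta",
        )
        seq_io.write_partitions(matrix.partitions, out / "partitions.txt")
        desc_df = pd.DataFrame(
            [
                {
                    "locus": d.locus_id,
                    "aligned_bp": d.aligned_bp,
                    "n_sequences": d.n_sequences,
                    "variable_sites": d.variable_sites,
                    "pis": d.pis,
                    "missing_pct": d.missing_pct,
                    "coverage_mean": d.coverage_mean,
                    "coverage_sd": d.coverage_sd,
                    "depth_median": d.depth_median,
                }
                for d in descriptors
            ]
        )
        desc_df.to_csv(out / "locus_descriptors.tsv", sep="\t", index=False)
        rc_path = out / "mapping" / "read_counts.tsv"
        counts = (
            pd.read_csv(rc_path, sep="\t").set_index("sample")["n_reads"].to_dict()
            if rc_path.exists()
            else {}
        )
        summaries = [
            summarize_library(
                list(consensuses[sid].values()), counts.get(sid, 0)
            )
            for sid in samples
        ]
        library_table(summaries).to_csv(out / "library_summary.tsv", sep="\t", index=False)
        logger.info(
            "stage a: %d loci, %d x %d matrix, %.1f%% missing",
            len(kept), matrix.n_rows, matrix.length, matrix.missing_pct,
        )
    return out


def sweep_stats(
    pileups: Mapping[str, Mapping[str, rm.LocusPileup]],
    refs: rm.ReferenceSet,
    min_depth: int,
    min_coverage: float,
    het_fraction: float = 0.25,
    trim: bool = False,
    trim_occupancy: float = 0.5,
) -> dict[str, float]:
    """Assembly summary for one (d, C) setting, computed in memory."""
    calls = _consensus_all(pileups, min_depth, het_fraction)
    kept, matrix, descriptors = assemble_matrix(
        calls, refs, min_coverage, trim, trim_occupancy
    )
    loci_per_sample = [
        sum(
            1
            for locus, c in calls[sid].items()
            if c.coverage >= min_coverage and c.n_recovered > 0
        )
        for sid in sorted(calls)
    ]
    # missing % over the full library roster (samples dropped from the matrix
    # count as all-N rows): monotone in d and C by construction, unlike the
    # retained-terminals percentage when a terminal drops out
    n_samples = len(calls)
    if matrix.length and n_samples:
        retained_missing = matrix.missing_pct / 100.0 * matrix.n_rows * matrix.length
        dropped = (n_samples - matrix.n_rows) * matrix.length
        missing_total = 100.0 * (retained_missing + dropped) / (n_samples * matrix.length)
    else:
        missing_total = 100.0
    return {
        "d": min_depth,
        "C": min_coverage,
        "loci_mean": float(np.mean(loci_per_sample)),
        "loci_min": int(np.min(loci_per_sample)),
        "loci_max": int(np.max(loci_per_sample)),
        "n_loci": len(kept),
        "terminals": matrix.n_rows,
        "aligned_bp": matrix.length,
        "variable_sites": int(sum(d.variable_sites for d in descriptors)),
        "pis": int(sum(d.pis for d in descriptors)),
        "missing_pct": matrix.missing_pct,
        "missing_pct_total": missing_total,
    }


def parameter_sweep(
    config: RunConfig,
    grid: Sequence[tuple[int, float]],
) -> pd.DataFrame:
    """One summary row per (d, C) setting, resuming from the mapping stage's
    outputs on disk (run stage m first)."""
    out = Path(config.out_dir)
    refs = rm.ReferenceSet(seq_io.read_fasta(config.refs_path))
    samples = sorted(_find_libraries(Path(config.reads_dir)))
    pileups = load_sample_pileups(out, refs, samples)
    rows = [
        sweep_stats(
            pileups, refs, d, C, config.het_fraction, config.trim,
            config.trim_occupancy,
        )
        for d, C in grid
    ]
    return pd.DataFrame(rows)
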