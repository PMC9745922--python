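"""Synthetic genome-skim datasets with known truth.

The simulator emulates the data regime of a shallow skimming study: a known
phylogeny, low-copy loci evolved on it under Jukes-Cantor, and short reads
sheared uniformly from each sample's loci at a configurable expected depth, so
per-position depth follows Poisson expectations (the Lander-Waterman picture)
and consensus coverage at a minimum depth d follows the Poisson tail
1 - sum_{i<d} e^{-c} c^i / i!. References are taken from the simulated root
sequence — a stand-in for mapping against references derived from a related
taxon's transcriptome — so every tip's reads map against a relative, not
itself. Per-sample target depths may differ, mirroring the unequal library
sizes of real studies. All randomness flows from the mandatory seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np

from .read_mapping import revcomp
from .seq_io import ReadRecord, SequenceRecord, parse_newick, write_fasta, write_fastq

BASES = "ACGT"
_BASE_ARR = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition knobs for one synthetic dataset.

    Defaults mirror a 16-library shallow-skim study scaled to desk size:
    16 taxa, 50 loci of 500 bp, 100-bp reads, expected depth 3 (the regime
    where per-library depth medians land between 1 and 5), divergence of a
    few percent between tips, and a 0.1% sequencing error rate.
    """

    n_taxa: int = 16
    n_loci: int = 50
    locus_length: int = 500
    substitutions_per_site: float = 0.05
    read_length: int = 100
    target_depth: float | Mapping[str, float] = 3.0
    sequencing_error_rate: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 4:
            raise ValueError("n_taxa must be >= 4")
        for name in ("n_loci", "locus_length", "read_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.read_length > self.locus_length:
            raise ValueError("read_length must be <= locus_length")
        if not 0.0 <= self.sequencing_error_rate <= 0.1:
            raise ValueError("sequencing_error_rate must be in [0, 0.1]")
        if self.substitutions_per_site < 0:
            raise ValueError("substitutions_per_site must be >= 0")

    def depth_for(self, sample_id: str) -> float:
        if isinstance(self.target_depth, Mapping):
            return float(self.target_depth[sample_id])
        return float(self.target_depth)


@dataclass
class TruthSet:
    """Ground truth: the generating tree, every sample's true locus sequences,
    and each read's origin (sample, locus, 0-based start, strand)."""

    tree: dendropy.Tree
    sequences: dict[str, dict[str, str]]  # sample -> locus -> seq
    read_origins: dict[str, tuple[str, str, int, str]]


def sample_ids(n_taxa: int) -> list[str]:
    return [f"s{i + 1:02d}" for i in range(n_taxa)]


def locus_ids(n_loci: int) -> list[str]:
    return [f"L{i + 1:03d}" for i in range(n_loci)]


#: Minimum branch length (before unit-depth normalization) as a fraction of
#: the mean edge length: keeps every internal edge statistically identifiable
#: at the simulated sequence volumes instead of letting the exponential draw
#: produce effectively zero-length edges no method could recover.
MIN_EDGE_FRACTION = 0.15


def simulate_tree(n_taxa: int, seed: int) -> dendropy.Tree:
    """Random Yule (pure-birth) topology with iid floored-exponential branch
    lengths (mean 1), deterministic per seed."""
    if n_taxa < 4:
        raise ValueError("n_taxa must be >= 4")
    rng = np.random.default_rng(seed)
    labels = sample_ids(n_taxa)
    # grow a topology as nested lists: start from a cherry, split random tips
    tips: list[list] = []
    root: list = [None, None]
    leaf_slots: list[tuple[list, int]] = [(root, 0), (root, 1)]
    while len(leaf_slots) < n_taxa:
        i = int(rng.integers(len(leaf_slots)))
        parent, pos = leaf_slots.pop(i)
        node: list = [None, None]
        parent[pos] = node
        leaf_slots.append((node, 0))
        leaf_slots.append((node, 1))
    shuffled = list(labels)
    rng.shuffle(shuffled)
    it = iter(shuffled)

    def fill(node):
        for pos in (0, 1):
            if node[pos] is None:
                node[pos] = next(it)
            else:
                fill(node[pos])

    fill(root)

    def edge_length() -> float:
        return MIN_EDGE_FRACTION + rng.exponential(1.0 - MIN_EDGE_FRACTION)

    def to_newick(node) -> str:
        if isinstance(node, str):
            return f"{node}:{edge_length():.6f}"
        left, right = node
        return f"({to_newick(left)},{to_newick(right)}):{edge_length():.6f}"

    newick = f"({to_newick(root[0])},{to_newick(root[1])});"
    tree = parse_newick(newick)
    # normalize to unit mean root-to-tip depth: substitutions_per_site then
    # directly sets the expected tip-to-reference divergence
    depths = []
    for leaf in tree.leaf_node_iter():
        d, node = 0.0, leaf
        while node.parent_node is not None:
            d += node.edge.length or 0.0
            node = node.parent_node
        depths.append(d)
    scale = float(np.mean(depths))
    if scale > 0:
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length /= scale
    return tree


def _jc_mutate(seq_arr: np.ndarray, branch_subs: float, rng: np.random.Generator) -> np.ndarray:
    """Jukes-Cantor substitution along a branch with expected ``branch_subs``
    substitutions per site: P(differ) = 3/4 (1 - exp(-4 d / 3))."""
    if branch_subs <= 0:
        return seq_arr.copy()
    p_diff = 0.75 * (1.0 - np.exp(-4.0 * branch_subs / 3.0))
    out = seq_arr.copy()
    hit = rng.random(out.size) < p_diff
    n_hit = int(hit.sum())
    if n_hit:
        # new base uniform among the three others
        shift = rng.integers(1, 4, size=n_hit)
        out[hit] = (out[hit] + shift) % 4
    return out


def evolve_loci(
    tree: dendropy.Tree, config: SimulationConfig
) -> tuple[dict[str, str], dict[str, dict[str, str]]]:
    """Evolve every locus down the tree under Jukes-Cantor.

    Returns (root sequences per locus, per-sample per-locus tip sequences).
    Branch lengths are scaled by ``substitutions_per_site`` so the tree's unit
    branch length corresponds to that much expected divergence.
    """
    rng = np.random.default_rng((config.seed, 1))
    loci = locus_ids(config.n_loci)
    root_seqs: dict[str, str] = {}
    tip_seqs: dict[str, dict[str, str]] = {}
    decode = _BASE_ARR
    for locus in loci:
        root_arr = rng.integers(0, 4, size=config.locus_length).astype(np.int8)
        root_seqs[locus] = decode[root_arr].tobytes().decode()
        state: dict[int, np.ndarray] = {id(tree.seed_node): root_arr}
        for node in tree.preorder_node_iter():
            if node is tree.seed_node:
                continue
            parent_arr = state[id(node.parent_node)]
            d = (node.edge.length or 0.0) * config.substitutions_per_site
            arr = _jc_mutate(parent_arr, d, rng)
            state[id(node)] = arr
            if node.is_leaf():
                tip_seqs.setdefault(node.taxon.label, {})[locus] = (
                    decode[arr].tobytes().decode()
                )
    return root_seqs, tip_seqs


def shear_reads(
    sequences: Mapping[str, str],
    sample_id: str,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[ReadRecord], dict[str, tuple[str, str, int, str]]]:
    """Shear one sample's loci into error-bearing reads at the target depth.

    Per locus, round(depth x L / read_length) reads start uniformly in
    [0, L - read_length]; each base errs to a uniformly chosen different base
    with the configured probability, and each read is emitted from either
    strand with probability 1/2.
    """
    if rng is None:
        import zlib

        rng = np.random.default_rng((config.seed, 2, zlib.crc32(sample_id.encode())))
    depth = config.depth_for(sample_id)
    rl = config.read_length
    reads: list[ReadRecord] = []
    origins: dict[str, tuple[str, str, int, str]] = {}
    counter = 0
    for locus, seq in sequences.items():
        L = len(seq)
        n_reads = int(round(depth * L / rl))
        if n_reads == 0:
            continue
        starts = rng.integers(0, L - rl + 1, size=n_reads)
        arr_all = np.frombuffer(seq.encode(), dtype=np.uint8)
        code = np.zeros(256, dtype=np.int8)
        for i, b in enumerate(BASES):
            code[ord(b)] = i
        for start in starts:
            frag = arr_all[start : start + rl]
            codes = code[frag].astype(np.int8)
            if config.sequencing_error_rate > 0:
                err = rng.random(rl) < config.sequencing_error_rate
                n_err = int(err.sum())
                if n_err:
                    codes = codes.copy()
                    codes[err] = (codes[err] + rng.integers(1, 4, size=n_err)) % 4
            read_seq = _BASE_ARR[codes].tobytes().decode()
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "-":
                read_seq = revcomp(read_seq)
            rid = f"{sample_id}.{counter}"
            counter += 1
            reads.append(ReadRecord(rid, read_seq, "I" * rl))
            origins[rid] = (sample_id, locus, int(start), strand)
    return reads, origins


def generate_dataset(
    config: SimulationConfig, out_dir: str | Path | None = None
) -> tuple[list[SequenceRecord], dict[str, list[ReadRecord]], TruthSet]:
    """End-to-end bundle: references (root sequences), per-sample read
    libraries, and the truth set; optionally written to ``out_dir`` as
    refs.fasta, <sample>.fastq and a truth/ subdirectory."""
    tree = simulate_tree(config.n_taxa, config.seed)
    root_seqs, tip_seqs = evolve_loci(tree, config)
    refs = [SequenceRecord(locus, seq) for locus, seq in root_seqs.items()]
    libraries: dict[str, list[ReadRecord]] = {}
    origins: dict[str, tuple[str, str, int, str]] = {}
    for i, sid in enumerate(sample_ids(config.n_taxa)):
        rng = np.random.default_rng((config.seed, 2, i))
        reads, ori = shear_reads(tip_seqs[sid], sid, config, rng)
        libraries[sid] = reads
        origins.update(ori)
    truth = TruthSet(tree=tree, sequences=tip_seqs, read_origins=origins)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(refs, out / "refs.fasta")
        for sid, reads in libraries.items():
            write_fastq(reads, out / f"{sid}.fastq")
        truth_dir = out / "truth"
        truth_dir.mkdir(exist_ok=True)
        (truth_dir / "tree.nwk").write_text(
            tree.as_string(schema="newick", suppress_rooting=True)
        )
        for sid, loci in tip_seqs.items():
            write_fasta(
                [SequenceRecord(lid, s) for lid, s in loci.items()],
                truth_dir / f"{sid}.fasta",
            )
        with open(out / "config.txt", "w") as fh:
            for key in (
                "n_taxa", "n_loci", "locus_length", "substitutions_per_site",
                "read_length", "sequencing_error_rate", "seed",
            ):
                fh.write(f"{key}={getattr(config, key)}\n")
            if isinstance(config.target_depth, Mapping):
                for sid in sample_ids(config.n_taxa):
                    fh.write(f"target_depth.{sid}={config.target_depth[sid]}\n")
            else:
                fh.write(f"target_depth={config.target_depth}\n")
    return refs, libraries, truth


def truth_pileup_depth(
    origins: Mapping[str, tuple[str, str, int, str]],
    sample_id: str,
    locus_lengths: Mapping[str, int],
    read_length: int,
) -> dict[str, np.ndarray]:
    """Per-locus depth vectors computed directly from read origins (no
    mapping), for calibration checks against the Poisson coverage law."""
    depth = {
        locus: np.zeros(L, dtype=np.int64) for locus, L in locus_lengths.items()
    }
    for _, (sid, locus, start, _strand) in origins.items():
        if sid != sample_id:
            continue
        depth[locus][start : start + read_length] += 1
    return depth


def poisson_coverage(c: float, min_depth: int) -> float:
    """Expected consensus coverage at minimum depth d under Poisson(c) depth:
    P(depth >= d) = 1 - sum_{i<d} e^-c c^i / i!."""
    from scipy import stats as sps

    return float(sps.poisson.sf(min_depth - 1, c))
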