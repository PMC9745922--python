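import numpy as np
import pytest

from skimloci.read_mapping import (
    KmerIndex,
    ReadPlacement,
    ReferenceSet,
    ScoringScheme,
    build_index,
    compute_pileup,
    map_library,
    map_read,
    parse_cigar,
    read_placements,
    revcomp,
    write_placements,
    write_sam,
)
from skimloci.seq_io import ReadRecord, SequenceRecord

RNG = np.random.default_rng(7)


def random_seq(n, rng=RNG):
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture(scope="module")
def refset():
    rng = np.random.default_rng(3)
    return ReferenceSet(
        [SequenceRecord(f"L{i}", random_seq(120, rng)) for i in range(3)]
    )


class TestIndex:
    def test_position_count(self):
        # L - k + 1 indexed positions for a single locus
        refs = ReferenceSet([SequenceRecord("L1", random_seq(30))])
        idx = build_index(refs, 11)
        n_positions = sum(len(idx.lookup(kmer)) for kmer in
                          {refs["L1"].seq[i:i+11] for i in range(20)})
        assert n_positions == 30 - 11 + 1

    def test_shared_kmer_lists_both_loci(self):
        shared = random_seq(15)
        refs = ReferenceSet(
            [SequenceRecord("A", shared + random_seq(20)),
             SequenceRecord("B", random_seq(20) + shared)]
        )
        idx = build_index(refs, 15)
        hits = idx.lookup(shared)
        assert {(locus, off) for locus, off in hits} == {("A", 0), ("B", 20)}

    def test_short_locus_zero_seeds(self, caplog):
        refs = ReferenceSet([SequenceRecord("tiny", "ACGTACGT")])
        idx = build_index(refs, 11)
        assert len(idx) == 0


class TestMapRead:
    def test_exact_substring_placement(self, refset):
        idx = build_index(refset, 11)
        read = ReadRecord("r", refset["L1"].seq[10:40])
        p = map_read(read, idx, refset)
        assert (p.locus_id, p.ref_start, p.strand) == ("L1", 10, "+")
        assert p.cigar_string() == "30M"
        assert p.score == 30  # A=1 over 30 matches

    def test_one_mismatch_score(self, refset):
        idx = build_index(refset, 11)
        seq = list(refset["L1"].seq[10:40])
        seq[25] = "A" if seq[25] != "A" else "C"
        p = map_read(ReadRecord("r", "".join(seq)), idx, refset)
        assert p.ref_start == 10
        assert p.score == 29 - 4  # 29 matches, one mismatch at B=4
        assert p.cigar_string() == "30M"

    def test_reverse_strand(self, refset):
        idx = build_index(refset, 11)
        p = map_read(ReadRecord("r", revcomp(refset["L2"].seq[5:45])), idx, refset)
        assert (p.locus_id, p.ref_start, p.strand) == ("L2", 5, "-")
        assert p.aligned_seq == refset["L2"].seq[5:45]

    def test_no_shared_kmer_unmapped(self, refset):
        idx = build_index(refset, 11)
        # a read over a disjoint alphabet pattern unlikely in the references
        assert map_read(ReadRecord("r", "A" * 40), idx, refset) is None

    def test_deletion_read_gets_gapped_cigar(self, refset):
        idx = build_index(refset, 11)
        ref = refset["L0"].seq
        read = ref[10:40] + ref[43:73]  # 3-bp deletion relative to reference
        p = map_read(ReadRecord("r", read), idx, refset)
        assert p is not None
        assert p.ref_start == 10
        assert ("D", 3) in p.cigar
        assert sum(n for op, n in p.cigar if op in "MI") == len(read)

    def test_exhaustive_substring_oracle(self, refset):
        """Any error-free read holding a locus-unique k-mer maps to the true
        (locus, offset), verified against exhaustive substring search."""
        idx = build_index(refset, 11)
        rng = np.random.default_rng(11)
        for _ in range(50):
            locus = refset.ids[rng.integers(3)]
            start = int(rng.integers(0, 120 - 35))
            read_seq = refset[locus].seq[start : start + 35]
            # oracle: all (locus, offset) where the read occurs verbatim
            occurrences = [
                (rec.id, i)
                for rec in refset
                for i in range(len(rec.seq) - 35 + 1)
                if rec.seq[i : i + 35] == read_seq
            ]
            p = map_read(ReadRecord("r", read_seq), idx, refset)
            assert p is not None
            assert (p.locus_id, p.ref_start) == min(occurrences)

    def test_deterministic_library_mapping(self, refset):
        idx = build_index(refset, 11)
        rng = np.random.default_rng(5)
        reads = [
            ReadRecord(f"r{i}", refset["L1"].seq[j : j + 30])
            for i, j in enumerate(rng.integers(0, 90, size=10))
        ]
        first = map_library(reads, idx, refset)
        second = map_library(reads, idx, refset)
        assert first == second
        assert map_library([], idx, refset) == []

    def test_mix_of_mappable_and_unmappable(self, refset):
        idx = build_index(refset, 11)
        reads = [
            ReadRecord("ok1", refset["L0"].seq[0:30]),
            ReadRecord("bad", "A" * 30),
            ReadRecord("ok2", refset["L2"].seq[50:80]),
        ]
        placements = map_library(reads, idx, refset)
        assert [p.read_id for p in placements] == ["ok1", "ok2"]


class TestPileup:
    def test_single_read_depth_profile(self):
        refs = ReferenceSet([SequenceRecord("L", random_seq(50))])
        p = ReadPlacement("r", "L", 0, (("M", 30),), "+", 30, refs["L"].seq[:30])
        pile = compute_pileup([p], refs)["L"]
        assert pile.depth[:30].tolist() == [1] * 30
        assert pile.depth[30:].sum() == 0

    def test_agreeing_overlap_counts_two(self):
        refs = ReferenceSet([SequenceRecord("L", random_seq(50))])
        seq = refs["L"].seq
        ps = [
            ReadPlacement("a", "L", 0, (("M", 30),), "+", 30, seq[:30]),
            ReadPlacement("b", "L", 20, (("M", 30),), "+", 30, seq[20:50]),
        ]
        pile = compute_pileup(ps, refs)["L"]
        assert pile.depth[20:30].tolist() == [2] * 10
        assert int(pile.depth.max()) <= 2  # never more than the read count

    def test_deletion_cigar_projection(self):
        """10M1D10M: the skipped reference base gets a deletion count and no
        base-call depth (hand projection of the cigar)."""
        refs = ReferenceSet([SequenceRecord("L", random_seq(30))])
        seq = refs["L"].seq[:10] + refs["L"].seq[11:21]
        p = ReadPlacement("r", "L", 0, parse_cigar("10M1D10M"), "+", 13, seq)
        pile = compute_pileup([p], refs)["L"]
        assert pile.deletions[10] == 1
        assert pile.depth[10] == 0
        assert pile.depth[:10].tolist() == [1] * 10
        assert pile.depth[11:21].tolist() == [1] * 10

    def test_total_base_conservation(self, refset, tmp_path):
        idx = build_index(refset, 11)
        rng = np.random.default_rng(9)
        reads = []
        for i in range(40):
            locus = refset.ids[rng.integers(3)]
            start = int(rng.integers(0, 90))
            reads.append(ReadRecord(f"r{i}", refset[locus].seq[start : start + 30]))
        placements = map_library(reads, idx, refset)
        piles = compute_pileup(placements, refset)
        total_m = sum(
            n for p in placements for op, n in p.cigar if op == "M"
        )
        total_counts = sum(int(p.counts[:4].sum()) for p in piles.values())
        assert total_counts == total_m

    def test_placement_past_end_raises(self):
        refs = ReferenceSet([SequenceRecord("L", "ACGTACGTACGT")])
        p = ReadPlacement("r", "L", 8, (("M", 10),), "+", 10, "ACGTACGTAC")
        with pytest.raises(ValueError, match="r"):
            compute_pileup([p], refs)


class TestIO:
    def test_placements_round_trip(self, refset, tmp_path):
        idx = build_index(refset, 11)
        reads = [ReadRecord("r1", refset["L1"].seq[4:40])]
        placements = map_library(reads, idx, refset)
        path = tmp_path / "p.tsv"
        write_placements(placements, path)
        assert read_placements(path) == placements

    def test_sam_export_minimal(self, refset, tmp_path):
        idx = build_index(refset, 11)
        p = map_read(ReadRecord("r1", refset["L0"].seq[0:30]), idx, refset)
        path = tmp_path / "out.sam"
        write_sam([p], refset, path)
        lines = path.read_text().splitlines()
        assert lines[0].startswith("@HD")
        assert sum(1 for line in lines if line.startswith("@SQ")) == 3
        fields = lines[-1].split("\t")
        assert len(fields) == 11
        assert fields[2] == "L0" and fields[3] == "1" and fields[5] == "30M"


class TestScoringScheme:
    @pytest.mark.parametrize("kwargs", [
        {"match_score": 0}, {"mismatch_penalty": -1},
        {"seed_length": 9}, {"min_score_frac": 1.5},
    ])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ScoringScheme(**kwargs)
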