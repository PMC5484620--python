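import numpy as np
import pytest

from larpclip.alignment_io import (
    AlignedRead,
    MappingPolicy,
    SamRecord,
    best_stratum_place,
    count_t_to_c,
    distribute_multimappers,
    find_mismatches,
    make_aligned_read,
    read_bed,
    read_sam,
    write_bed,
    write_sam,
)

BASES = "ACGT"


class TestCountTToC:
    @pytest.mark.parametrize(
        "ref,read,expected",
        [
            ("ATTG", "ACCG", 2),
            ("ATTG", "ATTG", 0),
            ("TG", "GG", 0),  # T->G is not a conversion
            ("TNTN", "CNCC", 2),  # N never counts
        ],
    )
    def test_examples(self, ref, read, expected):
        assert count_t_to_c(read, ref) == expected

    def test_read_must_fit_window(self):
        with pytest.raises(ValueError):
            count_t_to_c("ACGTA", "ACGT")
        with pytest.raises(ValueError):
            count_t_to_c("AC", "ACGT", offset=3)

    def test_matches_per_base_diff_oracle(self, rng):
        """Agreement with a brute-force per-base comparison on random pairs."""
        for _ in range(1000):
            n = int(rng.integers(1, 60))
            ref = "".join(rng.choice(list(BASES + "N"), size=n))
            read = "".join(rng.choice(list(BASES + "N"), size=n))
            oracle = sum(
                1 for r, q in zip(ref, read) if r == "T" and q == "C"
            )
            assert count_t_to_c(read, ref) == oracle


class TestMultimappers:
    def _read(self, rid, tid, start=0):
        return AlignedRead(rid, tid, start, start + 10)

    def test_even_split(self):
        reads = [self._read("r1", f"T{i}") for i in range(4)]
        out = distribute_multimappers(reads)
        assert all(r.weight == pytest.approx(0.25) for r in out)

    def test_unique_read_full_weight(self):
        (r,) = distribute_multimappers([self._read("r1", "T0")])
        assert r.weight == 1.0

    def test_weights_sum_to_one_per_read(self):
        reads = [self._read("r1", f"T{i}") for i in range(3)]
        out = distribute_multimappers(reads)
        assert abs(sum(r.weight for r in out) - 1.0) < 1e-12

    def test_library_weight_conservation(self, rng):
        """Sum of weights over all placements equals the number of reads."""
        reads = []
        n_reads = 200
        for i in range(n_reads):
            k = int(rng.integers(1, 6))
            reads.extend(self._read(f"r{i}", f"T{j}") for j in range(k))
        out = distribute_multimappers(reads)
        assert sum(r.weight for r in out) == pytest.approx(n_reads, abs=1e-9)

    def test_zero_placements_dropped(self, caplog):
        out = distribute_multimappers({"r1": []})
        assert out == []


def naive_scan(read, transcripts, max_mm):
    """O(reads x genome) oracle: score every offset, keep the best stratum."""
    hits = []
    for tid, seq in transcripts.items():
        for s in range(len(seq) - len(read) + 1):
            mm = sum(1 for a, b in zip(read, seq[s : s + len(read)]) if a != b)
            if mm <= max_mm:
                hits.append((tid, s, mm))
    if not hits:
        return []
    best = min(h[2] for h in hits)
    return sorted(h[:2] for h in hits if h[2] == best)


class TestBestStratumPlace:
    def test_exact_match_single_hit(self):
        tx = {"T0": "AAAACGTACGTAAAA"}
        hits = best_stratum_place("ACGTACGT", tx)
        assert len(hits) == 1
        assert (hits[0].transcript_id, hits[0].start) == ("T0", 3)
        assert hits[0].mismatches == []

    def test_best_stratum_excludes_worse_hits(self):
        read = "ACGTACGTAC"
        tx = {"A": "TT" + read + "TT", "B": "TT" + read[:-1] + "G" + "TT"}
        hits = best_stratum_place(read, tx)
        assert {h.transcript_id for h in hits} == {"A"}

    def test_too_many_mismatches_everywhere_empty(self):
        tx = {"T0": "A" * 50}
        assert best_stratum_place("CCCCCCCCCC", tx) == []

    def test_max_hits_truncation(self):
        tx = {"T0": "ACGT" * 20}
        hits = best_stratum_place("ACGTACGT", tx, MappingPolicy(max_hits=3))
        assert len(hits) == 3

    def test_agrees_with_naive_scan(self, rng):
        """Exhaustive-scan oracle agreement on random small instances."""
        for _ in range(25):
            tx = {
                f"T{i}": "".join(rng.choice(list(BASES), size=int(rng.integers(50, 200))))
                for i in range(3)
            }
            donor = tx["T0"]
            s = int(rng.integers(0, len(donor) - 20))
            read = list(donor[s : s + 20])
            for p in rng.choice(20, size=int(rng.integers(0, 3)), replace=False):
                read[p] = str(rng.choice(list(BASES)))
            read = "".join(read)
            got = sorted((h.transcript_id, h.start) for h in best_stratum_place(read, tx))
            assert got == naive_scan(read, tx, 3)


class TestSamRoundTrip:
    def test_round_trip_preserves_reads(self, tmp_path, rng):
        ref = "".join(rng.choice(list(BASES), size=300))
        refs = {"T0": ref}
        records = []
        for i in range(100):
            s = int(rng.integers(0, 270))
            seq = list(ref[s : s + 30])
            if i % 3 == 0:
                seq[5] = "C" if seq[5] != "C" else "G"
            records.append(SamRecord(f"r{i}", "T0", s, "".join(seq)))
        path = tmp_path / "rt.sam"
        write_sam(path, records, {"T0": 300})
        reads = read_sam(path, refs, distribute=False)
        expected = [make_aligned_read(r, ref) for r in records]
        got = {(r.read_id, r.start, tuple(r.mismatches)) for r in reads}
        want = {(r.read_id, r.start, tuple(r.mismatches)) for r in expected}
        assert got == want

    def test_sam_pos_is_one_based(self, tmp_path):
        refs = {"T0": "ACGTACGTAC"}
        path = tmp_path / "pos.sam"
        write_sam(path, [SamRecord("r0", "T0", 0, "ACGT")], {"T0": 10})
        line = [l for l in path.read_text().splitlines() if not l.startswith("@")][0]
        assert line.split("\t")[3] == "1"
        (read,) = read_sam(path, refs)
        assert read.start == 0

    def test_unknown_reference_raises(self, tmp_path):
        path = tmp_path / "bad.sam"
        path.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:T1\tLN:100\n"
            "r0\t0\tT1\t1\t255\t4M\t*\t0\t0\tACGT\t*\n"
        )
        with pytest.raises(ValueError, match="T1"):
            read_sam(path, {"T0": "ACGT" * 25})

    def test_write_sam_rejects_unknown_reference(self, tmp_path):
        with pytest.raises(ValueError, match="TX9"):
            write_sam(tmp_path / "x.sam", [SamRecord("r", "TX9", 0, "AC")], {"T0": 10})


def test_bed_round_trip(tmp_path):
    intervals = [("T0", 5, 25, "site0", 3.5, "+"), ("T1", 0, 10, "site1", ".", "+")]
    path = tmp_path / "x.bed"
    write_bed(path, intervals)
    got = read_bed(path)
    assert [(c, s, e) for c, s, e, *_ in got] == [("T0", 5, 25), ("T1", 0, 10)]


def test_mismatch_positions_inside_span():
    with pytest.raises(ValueError):
        AlignedRead("r", "T0", 10, 20, mismatches=[(25, "T", "C")])
    with pytest.raises(ValueError):
        AlignedRead("r", "T0", 10, 10)


def test_find_mismatches_skips_n():
    # N in either sequence is a no-call, not a mismatch
    assert find_mismatches("ANCG", "AACG", 0) == []
    assert find_mismatches("ATCG", "AACG", 0) == [(1, "A", "T")]
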