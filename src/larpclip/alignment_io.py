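"""Alignment I/O and desk-scale read placement.

Alignments live in transcript space and are ungapped: the mapping policy
mirrors a mismatch-only aligner run (up to ``max_mismatches`` mismatches,
best stratum only, at most ``max_hits`` placements per read). Mismatches,
including the T-to-C conversions that mark crosslink sites, are recovered
by comparing the read sequence to the reference rather than trusting
auxiliary tags, so minimal SAM records suffice.

Internally all coordinates are 0-based half-open; SAM is written/read
1-based per the standard.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pysam

logger = logging.getLogger(__name__)

Mismatch = tuple[int, str, str]  # (transcript position, ref base, read base)


class SamRecord(NamedTuple):
    """Minimal placement record: what a SAM line carries for our reads."""

    read_id: str
    transcript_id: str
    start: int  # 0-based
    seq: str


@dataclass(slots=True)
class AlignedRead:
    """One ungapped read placement with recovered per-base mismatches."""

    read_id: str
    transcript_id: str
    start: int
    end: int
    mismatches: list[Mismatch] = field(default_factory=list)
    t_to_c_count: int = 0
    weight: float = 1.0
    library_id: str = ""

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"{self.read_id}: empty or inverted span")
        for pos, _, _ in self.mismatches:
            if not self.start <= pos < self.end:
                raise ValueError(f"{self.read_id}: mismatch at {pos} outside span")


@dataclass(frozen=True)
class MappingPolicy:
    """Best-stratum, mismatch-only placement policy."""

    max_mismatches: int = 3
    max_hits: int = 100
    best_stratum_only: bool = True

    def __post_init__(self) -> None:
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")
        if self.max_hits < 1:
            raise ValueError("max_hits must be >= 1")


def count_t_to_c(read_seq: str, ref_window: str, offset: int = 0) -> int:
    """Number of positions where the reference reads T and the read reads C.

    ``offset`` is the read's start within ``ref_window``. N never counts.
    """
    if offset < 0 or offset + len(read_seq) > len(ref_window):
        raise ValueError(
            f"read (len {len(read_seq)}) at offset {offset} does not fit "
            f"inside reference window (len {len(ref_window)})"
        )
    ref = ref_window[offset : offset + len(read_seq)]
    return sum(1 for r, q in zip(ref, read_seq) if r == "T" and q == "C")


def find_mismatches(read_seq: str, ref_seq: str, start: int) -> list[Mismatch]:
    """Per-base diff of a read against the reference it is placed on.

    Positions where either base is N are no-calls and excluded.
    """
    window = ref_seq[start : start + len(read_seq)]
    if len(window) != len(read_seq):
        raise ValueError("read extends past the reference end")
    return [
        (start + i, r, q)
        for i, (r, q) in enumerate(zip(window, read_seq))
        if r != q and r != "N" and q != "N"
    ]


def make_aligned_read(
    rec: SamRecord, ref_seq: str, library_id: str = ""
) -> AlignedRead:
    mm = find_mismatches(rec.seq, ref_seq, rec.start)
    ttc = sum(1 for _, r, q in mm if r == "T" and q == "C")
    return AlignedRead(
        read_id=rec.read_id,
        transcript_id=rec.transcript_id,
        start=rec.start,
        end=rec.start + len(rec.seq),
        mismatches=mm,
        t_to_c_count=ttc,
        library_id=library_id,
    )


def distribute_multimappers(
    placements: Mapping[str, Sequence[AlignedRead]] | Iterable[AlignedRead],
) -> list[AlignedRead]:
    """Assign each placement of a k-way mapped read the weight 1/k.

    Accepts either a mapping read_id -> placements or a flat iterable
    (grouped by read_id internally). Reads with zero placements are
    dropped and logged. Weights of each read's placements sum to 1.
    """
    if not isinstance(placements, Mapping):
        grouped: dict[str, list[AlignedRead]] = defaultdict(list)
        for r in placements:
            grouped[r.read_id].append(r)
        placements = grouped
    out: list[AlignedRead] = []
    for read_id, group in placements.items():
        if not group:
            logger.warning("read %s has zero placements; dropped", read_id)
            continue
        w = 1.0 / len(group)
        for r in group:
            r.weight = w
            out.append(r)
    return out


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def best_stratum_place(
    read_seq: str,
    transcripts: Mapping[str, str],
    policy: MappingPolicy = MappingPolicy(),
) -> list[AlignedRead]:
    """Exhaustive ungapped scan returning the best mismatch stratum.

    Stand-in for an index-based aligner at desk scale: every offset of
    every transcript is scored; all placements tied at the minimum
    mismatch count are returned (if the minimum is within policy bounds),
    truncated to ``max_hits`` in (transcript, position) order.
    """
    L = len(read_seq)
    q = _encode(read_seq)
    hits: list[tuple[str, int, int]] = []  # (tid, start, n_mismatch)
    for tid, seq in transcripts.items():
        if len(seq) < L:
            continue
        t = _encode(seq)
        # sliding-window mismatch counts via a strided view
        win = np.lib.stride_tricks.sliding_window_view(t, L)
        nmm = (win != q).sum(axis=1)
        for start in np.flatnonzero(nmm <= policy.max_mismatches):
            hits.append((tid, int(start), int(nmm[start])))
    if not hits:
        return []
    best = min(h[2] for h in hits)
    if policy.best_stratum_only:
        hits = [h for h in hits if h[2] == best]
    hits.sort(key=lambda h: (h[0], h[1]))
    hits = hits[: policy.max_hits]
    return [
        make_aligned_read(SamRecord("read", tid, start, read_seq), transcripts[tid])
        for tid, start, _ in hits
    ]


# --- SAM ------------------------------------------------------------------


def write_sam(
    path: str | Path,
    records: Iterable[SamRecord],
    reference_lengths: Mapping[str, int],
) -> None:
    """Write minimal single-end SAM; secondary placements get flag 256."""
    seen: set[str] = set()
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for name, length in reference_lengths.items():
            fh.write(f"@SQ\tSN:{name}\tLN:{length}\n")
        for rec in records:
            if rec.transcript_id not in reference_lengths:
                raise ValueError(f"unknown reference name: {rec.transcript_id}")
            flag = 256 if rec.read_id in seen else 0
            seen.add(rec.read_id)
            fh.write(
                f"{rec.read_id}\t{flag}\t{rec.transcript_id}\t{rec.start + 1}"
                f"\t255\t{len(rec.seq)}M\t*\t0\t0\t{rec.seq}\t*\n"
            )


def read_sam(
    path: str | Path,
    references: Mapping[str, str],
    library_id: str = "",
    distribute: bool = True,
) -> list[AlignedRead]:
    """Parse a SAM into AlignedReads, recovering mismatches vs the reference.

    Unmapped records are skipped; reverse-strand and gapped (indel) records
    are rejected with a warning (sense-strand, ungapped libraries assumed).
    Records naming an unknown reference raise. With ``distribute`` the
    multimapper weights (1/k per k-way read) are set.
    """
    reads: list[AlignedRead] = []
    unknown: set[str] = set()
    n_reverse = n_gapped = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped:
                continue
            if rec.is_reverse:
                n_reverse += 1
                continue
            if any(op != 0 for op, _ in rec.cigartuples or []):
                n_gapped += 1
                continue
            tid = rec.reference_name
            if tid not in references:
                unknown.add(tid)
                continue
            reads.append(
                make_aligned_read(
                    SamRecord(rec.query_name, tid, rec.reference_start, rec.query_sequence),
                    references[tid],
                    library_id=library_id,
                )
            )
    if unknown:
        raise ValueError(f"records reference absent transcripts: {sorted(unknown)}")
    if n_reverse:
        logger.warning("%d reverse-strand records discarded", n_reverse)
    if n_gapped:
        logger.warning("%d gapped records rejected (ungapped policy)", n_gapped)
    if distribute:
        reads = distribute_multimappers(reads)
    return reads


# --- BED ------------------------------------------------------------------


def write_bed(
    path: str | Path,
    intervals: Iterable[tuple[str, int, int, str, float | str, str]],
) -> None:
    """BED6 writer (0-based half-open, as BED demands)."""
    with open(path, "w") as fh:
        for chrom, start, end, name, score, strand in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score}\t{strand}\n")


def read_bed(path: str | Path) -> list[tuple[str, int, int, str, str, str]]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            name = f[3] if len(f) > 3 else "."
            score = f[4] if len(f) > 4 else "."
            strand = f[5] if len(f) > 5 else "."
            out.append((chrom, start, end, name, score, strand))
    return out
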