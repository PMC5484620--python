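"""Sequence-composition statistics around binding sites.

Covers pyrimidine/G content of bound vs unbound region remainders
(Welch's two-tailed t-test), longest-pyrimidine-run motif summaries over
site sequences extended by a fixed flank, 5'TOP classification and
site/TOP overlap, enriched-hexamer counting against a shuffled background,
and positional (5'-most vs 3'-most window) pyrimidine profiles of 5'UTRs.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .model import UTR3, UTR5, TranscriptModel
from .sitecall import BindingSite

logger = logging.getLogger(__name__)

_PYR = frozenset("CT")


@dataclass(slots=True)
class CompositionTest:
    """Welch two-sample comparison of per-region composition fractions."""

    group_a: np.ndarray
    group_b: np.ndarray
    mean_a: float
    mean_b: float
    t: float
    df: float
    p: float


@dataclass(slots=True)
class TopCall:
    transcript_id: str
    is_top: bool
    top_run_length: int


def pyrimidine_fraction(seq: str) -> float:
    """(#C + #T) / (length - #N); N bases are excluded from the denominator."""
    if not seq:
        raise ValueError("empty sequence")
    n_n = seq.count("N")
    denom = len(seq) - n_n
    if denom == 0:
        raise ValueError("all-N sequence: composition undefined")
    return sum(1 for b in seq if b in _PYR) / denom


def g_fraction(seq: str) -> float:
    """#G / (length - #N)."""
    if not seq:
        raise ValueError("empty sequence")
    denom = len(seq) - seq.count("N")
    if denom == 0:
        raise ValueError("all-N sequence: composition undefined")
    return seq.count("G") / denom


def welch_t_test(a: Sequence[float], b: Sequence[float]) -> CompositionTest:
    """Welch's unequal-variance t-test, two-tailed.

    t = (mean_a - mean_b) / sqrt(s2a/na + s2b/nb); degrees of freedom by
    Welch-Satterthwaite; p from the t distribution. Zero variance in both
    groups: p = 1 (t = 0) when the means agree, p = 0 otherwise (logged).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    ma, mb = float(a.mean()), float(b.mean())
    se2 = va / a.size + vb / b.size
    if se2 == 0:
        logger.warning("zero variance in both groups; degenerate Welch test")
        t = 0.0 if ma == mb else float("inf") * np.sign(ma - mb)
        return CompositionTest(a, b, ma, mb, t, float(a.size + b.size - 2),
                               1.0 if ma == mb else 0.0)
    t = (ma - mb) / np.sqrt(se2)
    df = se2**2 / (
        (va / a.size) ** 2 / (a.size - 1) + (vb / b.size) ** 2 / (b.size - 1)
    )
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return CompositionTest(a, b, ma, mb, float(t), float(df), p)


def _bound_union(sites: Sequence[BindingSite], lo: int, hi: int) -> list[tuple[int, int]]:
    spans = sorted(
        (max(s.start, lo), min(s.end, hi))
        for s in sites
        if max(s.start, lo) < min(s.end, hi)
    )
    merged: list[tuple[int, int]] = []
    for s, e in spans:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def bound_vs_unbound_composition(
    sites: Sequence[BindingSite],
    transcripts: Sequence[TranscriptModel],
    scope: str = UTR5,
) -> CompositionTest:
    """Composition of bound segments vs the unbound remainder, per region.

    For every transcript with >= 1 site assigned to ``scope``, the bound
    segment is the union of its site spans clipped to the region and the
    unbound part is the remainder of the same region. The metric is the
    pyrimidine fraction for the 5'UTR scope and the G fraction for the
    3'UTR scope. The two collections are compared with an unpaired Welch
    test. Transcripts whose region is entirely bound contribute only to
    the bound group (logged).
    """
    if scope == UTR5:
        metric = pyrimidine_fraction
    elif scope == UTR3:
        metric = g_fraction
    else:
        raise ValueError(f"unsupported scope: {scope}")
    by_tid: dict[str, list[BindingSite]] = {}
    for s in sites:
        if s.region == scope:
            by_tid.setdefault(s.transcript_id, []).append(s)
    bound_vals: list[float] = []
    unbound_vals: list[float] = []
    n_tx = 0
    for t in transcripts:
        if t.transcript_id not in by_tid:
            continue
        lo, hi = t.region_bounds()[scope]
        merged = _bound_union(by_tid[t.transcript_id], lo, hi)
        if not merged:
            continue
        n_tx += 1
        bound_seq = "".join(t.seq[s:e] for s, e in merged)
        bound_vals.append(metric(bound_seq))
        unbound_parts = []
        prev = lo
        for s, e in merged:
            if s > prev:
                unbound_parts.append(t.seq[prev:s])
            prev = e
        if prev < hi:
            unbound_parts.append(t.seq[prev:hi])
        unbound_seq = "".join(unbound_parts)
        if unbound_seq:
            unbound_vals.append(metric(unbound_seq))
        else:
            logger.info(
                "%s: %s entirely bound; excluded from unbound group",
                t.transcript_id, scope,
            )
    if n_tx < 2:
        raise ValueError(
            f"need >= 2 transcripts with bound {scope} segments, got {n_tx}"
        )
    return welch_t_test(bound_vals, unbound_vals)


# --- motif stand-in ---------------------------------------------------------


def max_pyrimidine_run(seq: str) -> int:
    """Length of the longest contiguous run of C/T."""
    if not seq:
        raise ValueError("empty sequence")
    best = cur = 0
    for b in seq:
        cur = cur + 1 if b in _PYR else 0
        best = max(best, cur)
    return best


def site_sequences(
    sites: Sequence[BindingSite],
    transcripts: Sequence[TranscriptModel],
    extend: int = 15,
    region: str | None = None,
) -> list[tuple[BindingSite, str]]:
    """Site sequences extended by ``extend`` nt up/downstream (clipped)."""
    by_tid = {t.transcript_id: t for t in transcripts}
    out = []
    for s in sites:
        if region is not None and s.region != region:
            continue
        t = by_tid[s.transcript_id]
        lo = max(0, s.start - extend)
        hi = min(t.length, s.end + extend)
        out.append((s, t.seq[lo:hi]))
    return out


def summarize_runs(
    sites: Sequence[BindingSite],
    transcripts: Sequence[TranscriptModel],
    k: int = 6,
    extend: int = 15,
    region: str | None = None,
) -> tuple[float, int]:
    """Fraction of (extended) site sequences with a pyrimidine run >= k."""
    seqs = [seq for _, seq in site_sequences(sites, transcripts, extend, region)]
    if not seqs:
        return float("nan"), 0
    hits = sum(1 for s in seqs if max_pyrimidine_run(s) >= k)
    return hits / len(seqs), len(seqs)


def enriched_hexamers(
    site_seqs: Sequence[str],
    seed: int = 0,
    n_shuffles: int = 10,
    top: int = 10,
) -> list[tuple[str, float]]:
    """Hexamers over-represented in site sequences vs shuffled background.

    Each site sequence is shuffled ``n_shuffles`` times (preserving base
    composition) to form the background; returns the ``top`` hexamers by
    observed/expected ratio (pseudocount 1).
    """
    rng = np.random.default_rng(seed)
    fg: Counter[str] = Counter()
    bg: Counter[str] = Counter()
    for seq in site_seqs:
        for i in range(len(seq) - 5):
            fg[seq[i : i + 6]] += 1
        letters = list(seq)
        for _ in range(n_shuffles):
            rng.shuffle(letters)
            sh = "".join(letters)
            for i in range(len(sh) - 5):
                bg[sh[i : i + 6]] += 1
    scores = [
        (kmer, (count + 1) / (bg[kmer] / n_shuffles + 1))
        for kmer, count in fg.items()
    ]
    scores.sort(key=lambda kv: (-kv[1], kv[0]))
    return scores[:top]


# --- 5'TOP ------------------------------------------------------------------


def classify_top(
    transcripts: Sequence[TranscriptModel], min_run: int = 4
) -> list[TopCall]:
    """5'TOP call: cap base C followed by >= min_run pyrimidines.

    top_run_length is the maximal pyrimidine run starting at the cap
    (counting the initial C).
    """
    calls = []
    for t in transcripts:
        run = 0
        for b in t.seq:
            if b in _PYR:
                run += 1
            else:
                break
        is_top = t.seq[0] == "C" and run >= 1 + min_run
        calls.append(TopCall(t.transcript_id, is_top, run))
    return calls


def top_overlap(
    sites: Sequence[BindingSite], top_calls: Sequence[TopCall]
) -> tuple[float, int]:
    """Fraction of 5'UTR sites on TOP transcripts that touch the TOP run.

    Overlap means >= 1 nt intersection between the site span and the
    [0, top_run_length) interval. Returns (fraction, number of sites
    considered); nan when no 5'UTR site sits on a TOP transcript.
    """
    tops = {c.transcript_id: c.top_run_length for c in top_calls if c.is_top}
    considered = [
        s for s in sites if s.region == UTR5 and s.transcript_id in tops
    ]
    if not considered:
        return float("nan"), 0
    n_ov = sum(1 for s in considered if s.start < tops[s.transcript_id] and s.end > 0)
    return n_ov / len(considered), len(considered)


# --- positional profile -----------------------------------------------------


def positional_pyrimidine_profile(
    group_a: Sequence[str],
    group_b: Sequence[str],
    window: int = 25,
) -> dict[str, CompositionTest]:
    """Pyrimidine content at the 5'-most vs 3'-most ends of 5'UTRs.

    For every 5'UTR of length >= 2 x window (shorter UTRs are excluded and
    logged), the pyrimidine fraction of the first and last ``window`` nt is
    taken; the two gene groups are compared per window with Welch's test.
    Returns {"five_prime": test, "three_prime": test}.
    """
    def windows(seqs: Sequence[str]) -> tuple[list[float], list[float]]:
        first, last = [], []
        skipped = 0
        for s in seqs:
            if len(s) < 2 * window:
                skipped += 1
                continue
            first.append(pyrimidine_fraction(s[:window]))
            last.append(pyrimidine_fraction(s[-window:]))
        if skipped:
            logger.info("%d 5'UTRs shorter than 2x window excluded", skipped)
        return first, last

    fa, la = windows(group_a)
    fb, lb = windows(group_b)
    if not fa or not fb:
        raise ValueError("all 5'UTRs in a group are shorter than 2x window")
    return {
        "five_prime": welch_t_test(fa, fb),
        "three_prime": welch_t_test(la, lb),
    }


# --- reporting --------------------------------------------------------------


def write_test_tsv(
    path: str | Path, tests: Mapping[str, CompositionTest], header_note: str = ""
) -> None:
    with open(path, "w") as fh:
        if header_note:
            fh.write(f"# {header_note}\n")
        fh.write("test\tn_a\tn_b\tmean_a\tmean_b\tt\tdf\tp\n")
        for name, ct in tests.items():
            fh.write(
                f"{name}\t{ct.group_a.size}\t{ct.group_b.size}"
                f"\t{ct.mean_a:.6g}\t{ct.mean_b:.6g}\t{ct.t:.6g}"
                f"\t{ct.df:.6g}\t{ct.p:.6g}\n"
            )


def write_site_fasta(
    path: str | Path,
    sites: Sequence[BindingSite],
    transcripts: Sequence[TranscriptModel],
    extend: int = 15,
    region: str | None = None,
) -> None:
    """Extended site sequences as FASTA (for external motif finders)."""
    with open(path, "w") as fh:
        for i, (s, seq) in enumerate(site_sequences(sites, transcripts, extend, region)):
            fh.write(f">site{i:05d} {s.transcript_id}:{s.start}-{s.end} {s.region}\n")
            fh.write(seq + "\n")
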