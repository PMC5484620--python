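"""Transcript abundance from mRNA-seq: RPKM, replicate averaging, concordance.

Only perfectly matching reads count toward expression; a read mapping to k
positions contributes weight 1/k to each (even multimapper distribution),
and a library's "total mapped reads" is the sum of those weights. RPKM is

    RPKM = (count / (total_mapped / 1e6)) / (length / 1000)

Gene expression equals its single transcript's RPKM.
"""

from __future__ import annotations

import logging
from collections import Counter
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .model import TranscriptModel

logger = logging.getLogger(__name__)


def compute_rpkm(count: float, total_mapped: float, length: int) -> float:
    """Reads per kilobase of transcript per million mapped reads."""
    if total_mapped <= 0:
        raise ValueError("total_mapped must be > 0")
    if length <= 0:
        raise ValueError("length must be > 0")
    return (count / (total_mapped / 1e6)) / (length / 1000.0)


def replicate_concordance(
    rep1: Sequence[float], rep2: Sequence[float]
) -> tuple[float, float]:
    """Pearson r and R^2 between replicate RPKM vectors.

    Zero variance in either vector leaves r undefined: (nan, nan) is
    returned and logged; downstream averaging proceeds regardless.
    """
    a = np.asarray(rep1, dtype=float)
    b = np.asarray(rep2, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("replicate vectors must have equal length >= 3")
    if a.std() == 0 or b.std() == 0:
        logger.warning("zero variance in a replicate; correlation undefined")
        return float("nan"), float("nan")
    r = float(np.corrcoef(a, b)[0, 1])
    return r, r * r


def quantify_library(
    sam_path: str | Path, transcripts: Sequence[TranscriptModel]
) -> tuple[dict[str, float], float]:
    """Weighted perfect-match read counts per transcript for one library.

    Streams the SAM once, keeping only ungapped forward records whose
    sequence equals the reference substring (perfect matches). A read with
    k perfect placements contributes 1/k to each. Returns (counts, total
    weight = number of counted reads).
    """
    refs = {t.transcript_id: t.seq for t in transcripts}
    placements: list[tuple[str, str]] = []  # (read_id, transcript_id)
    k_per_read: Counter[str] = Counter()
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.is_reverse:
                continue
            ref = refs.get(rec.reference_name)
            if ref is None:
                raise ValueError(f"unknown reference name: {rec.reference_name}")
            s = rec.reference_start
            seq = rec.query_sequence
            if ref[s : s + len(seq)] != seq:
                continue  # imperfect: excluded from expression
            placements.append((rec.query_name, rec.reference_name))
            k_per_read[rec.query_name] += 1
    counts: dict[str, float] = {t.transcript_id: 0.0 for t in transcripts}
    for read_id, tid in placements:
        counts[tid] += 1.0 / k_per_read[read_id]
    total = float(len(k_per_read))
    return counts, total


def expression_table(
    transcripts: Sequence[TranscriptModel],
    replicate_sams: Sequence[str | Path],
) -> pd.DataFrame:
    """Per-transcript expression across replicate libraries.

    Columns: transcript_id, gene_id, length, count_rep<i>, rpkm_rep<i>,
    rpkm_mean, expressed (count > 0 in >= 1 replicate). Replicate
    concordance is logged for every pair and attached as ``df.attrs``.
    """
    data: dict[str, list | np.ndarray] = {
        "transcript_id": [t.transcript_id for t in transcripts],
        "gene_id": [t.gene_id for t in transcripts],
        "length": [t.length for t in transcripts],
    }
    rpkm_cols = []
    for i, sam in enumerate(replicate_sams, start=1):
        counts, total = quantify_library(sam, transcripts)
        cvec = np.array([counts[t.transcript_id] for t in transcripts])
        data[f"count_rep{i}"] = cvec
        data[f"rpkm_rep{i}"] = np.array(
            [compute_rpkm(c, total, t.length) for c, t in zip(cvec, transcripts)]
        )
        rpkm_cols.append(f"rpkm_rep{i}")
    df = pd.DataFrame(data)
    df["rpkm_mean"] = df[rpkm_cols].mean(axis=1)
    count_cols = [c for c in df.columns if c.startswith("count_rep")]
    df["expressed"] = (df[count_cols] > 0).any(axis=1)
    df.attrs["concordance"] = {}
    for i in range(len(rpkm_cols)):
        for j in range(i + 1, len(rpkm_cols)):
            r, r2 = replicate_concordance(df[rpkm_cols[i]], df[rpkm_cols[j]])
            df.attrs["concordance"][(rpkm_cols[i], rpkm_cols[j])] = (r, r2)
            logger.info(
                "replicate concordance %s vs %s: r=%.6f R^2=%.6f",
                rpkm_cols[i], rpkm_cols[j], r, r2,
            )
    return df


def rpkm_map(df: pd.DataFrame, by_gene: bool = False) -> dict[str, float]:
    """transcript_id (or gene_id) -> replicate-mean RPKM."""
    key = "gene_id" if by_gene else "transcript_id"
    return dict(zip(df[key], df["rpkm_mean"]))


def write_expression_tsv(path: str | Path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
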