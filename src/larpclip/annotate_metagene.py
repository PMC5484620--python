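"""Region assignment, per-category coverage tables, and metagene profiles.

Sites are labeled with the transcript region (5'UTR / CDS / 3'UTR) holding
the largest share of their span; binding coverage is summed per gene
category x region x condition; metagene profiles spread each site's
coverage over a fixed number of bins on a normalized (0..1) transcript
axis, with the mean fractional UTR/CDS junction positions as boundary
marks. The coverage currency is the expression-normalized site score,
falling back to RPM (flagged) where expression was unavailable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import CATEGORIES, CDS, REGIONS, UTR3, UTR5, TranscriptModel
from .sitecall import BindingSite

logger = logging.getLogger(__name__)

_TIE_ORDER = {UTR5: 0, CDS: 1, UTR3: 2}


@dataclass(slots=True)
class MetageneProfile:
    """Binned binding coverage along normalized transcript length."""

    n_bins: int
    weights: np.ndarray
    boundary_utr5_cds: float  # mean fractional 5'UTR/CDS junction
    boundary_cds_utr3: float  # mean fractional CDS/3'UTR junction
    category: str
    condition: str


def assign_region(site: BindingSite, transcript: TranscriptModel) -> str:
    """Region holding the largest share of the site span.

    Ties are broken 5'UTR > CDS > 3'UTR.
    """
    if site.start < 0 or site.end > transcript.length:
        raise ValueError(
            f"site {site.start}-{site.end} outside transcript "
            f"{transcript.transcript_id} (length {transcript.length})"
        )
    shares = []
    for region, (rs, re) in transcript.region_bounds().items():
        ov = max(0, min(site.end, re) - max(site.start, rs))
        shares.append((-ov, _TIE_ORDER[region], region))
    shares.sort()
    return shares[0][2]


def annotate_sites(
    sites: Sequence[BindingSite], transcripts: Sequence[TranscriptModel]
) -> list[BindingSite]:
    """Set every site's region label in place; returns the same list."""
    by_tid = {t.transcript_id: t for t in transcripts}
    for s in sites:
        s.region = assign_region(s, by_tid[s.transcript_id])
    return list(sites)


def region_coverage_table(
    sites: Sequence[BindingSite],
    transcripts: Sequence[TranscriptModel],
    categories: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Summed binding coverage per (category, region, condition).

    Coverage per site is its expression-normalized score, or RPM where
    normalization was undefined (the ``used_rpm_fallback`` attr flags any
    fallback). Percentages sum to 100 within each (category, condition).
    Genes without a category are grouped under non_TR with a warning.
    """
    by_tid = {t.transcript_id: t for t in transcripts}
    if categories is None:
        categories = {t.gene_id: t.category for t in transcripts}
    rows = []
    fallback = False
    for s in sites:
        if not s.region:
            raise ValueError("sites must be annotated before tabulation")
        t = by_tid[s.transcript_id]
        cat = categories.get(t.gene_id)
        if cat is None:
            logger.warning("gene %s uncategorized; grouped under non_TR", t.gene_id)
            cat = "non_TR"
        fallback = fallback or s.norm_score is None
        rows.append((cat, s.region, s.condition, s.coverage_value()))
    df = pd.DataFrame(rows, columns=["category", "region", "condition", "coverage"])
    conditions = sorted(df["condition"].unique()) if len(df) else []
    full = pd.MultiIndex.from_product(
        [list(CATEGORIES), list(REGIONS), conditions],
        names=["category", "region", "condition"],
    )
    agg = (
        df.groupby(["category", "region", "condition"])["coverage"].sum()
        .reindex(full, fill_value=0.0)
        .reset_index()
        if len(df)
        else pd.DataFrame(columns=["category", "region", "condition", "coverage"])
    )
    if len(agg):
        totals = agg.groupby(["category", "condition"])["coverage"].transform("sum")
        agg["pct"] = np.where(totals > 0, 100.0 * agg["coverage"] / totals, 0.0)
    else:
        agg["pct"] = []
    agg.attrs["used_rpm_fallback"] = fallback
    if fallback:
        logger.warning("expression-normalized score unavailable for some sites; RPM used")
    return agg


def metagene_profile(
    sites: Sequence[BindingSite],
    transcripts: Sequence[TranscriptModel],
    category: str,
    n_bins: int = 100,
    categories: Mapping[str, str] | None = None,
    condition: str = "",
) -> MetageneProfile:
    """Aggregate binding coverage along normalized transcript length.

    Each transcript's axis is scaled to [0, 1]; each site's coverage is
    spread over the bins it overlaps in proportion to the overlap, so the
    bin mass equals the summed site coverage exactly. A category with no
    sites yields an all-zero profile.
    """
    if n_bins < 10:
        raise ValueError("n_bins must be >= 10")
    if categories is None:
        categories = {t.gene_id: t.category for t in transcripts}
    by_tid = {t.transcript_id: t for t in transcripts}
    cat_tx = [t for t in transcripts if categories.get(t.gene_id) == category]
    weights = np.zeros(n_bins)
    for s in sites:
        t = by_tid[s.transcript_id]
        if categories.get(t.gene_id) != category:
            continue
        if condition and s.condition and s.condition != condition:
            continue
        lo = s.start / t.length * n_bins
        hi = s.end / t.length * n_bins
        value = s.coverage_value()
        span = hi - lo
        first, last = int(np.floor(lo)), int(np.ceil(hi))
        for b in range(first, min(last, n_bins)):
            ov = min(hi, b + 1) - max(lo, b)
            if ov > 0:
                weights[b] += value * ov / span
    if cat_tx:
        b1 = float(np.mean([t.utr5_len / t.length for t in cat_tx]))
        b2 = float(np.mean([(t.utr5_len + t.cds_len) / t.length for t in cat_tx]))
    else:
        b1 = b2 = float("nan")
    return MetageneProfile(n_bins, weights, b1, b2, category, condition)


def write_coverage_tsv(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_profile_tsv(path: str | Path, profile: MetageneProfile) -> None:
    with open(path, "w") as fh:
        fh.write(
            f"# category={profile.category} condition={profile.condition} "
            f"utr5_cds={profile.boundary_utr5_cds:.4f} "
            f"cds_utr3={profile.boundary_cds_utr3:.4f}\n"
        )
        fh.write("bin\tweight\n")
        for i, w in enumerate(profile.weights):
            fh.write(f"{i}\t{w:.6g}\n")


def plot_metagene(
    profiles: Sequence[MetageneProfile], path: str | Path
) -> None:
    """Optional visual: one curve per (category, condition), junction marks
    as vertical lines. The axis is whole-transcript normalized length (the
    regions are not separately rescaled)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    for p in profiles:
        x = (np.arange(p.n_bins) + 0.5) / p.n_bins
        ax.plot(x, p.weights, label=f"{p.category} {p.condition}".strip())
        if np.isfinite(p.boundary_utr5_cds):
            ax.axvline(p.boundary_utr5_cds, ls=":", lw=0.8, color="grey")
            ax.axvline(p.boundary_cds_utr3, ls=":", lw=0.8, color="grey")
    ax.set_xlabel("normalized transcript position")
    ax.set_ylabel("binding coverage")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
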