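"""Binding-site calling from conversion-bearing PAR-CLIP reads.

Reads with at most ``max_t_to_c_per_read`` T-to-C mismatches are clustered
into peaks by >= 1 nt overlap (half-open intervals: (10,20) and (20,30) do
not overlap). Each cluster's weighted per-base coverage is smoothed with a
truncated Gaussian kernel and the cluster span trimmed to the contiguous
run of smoothed coverage above a floor that contains the coverage maximum.
Clusters with at least one conversion-bearing read are retained as binding
sites, scored as RPM (member weight sum per million mapped reads) and,
where expression is available, RPM / gene RPKM x 1000.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .alignment_io import AlignedRead, write_bed

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CallerParams:
    max_t_to_c_per_read: int = 2
    min_conversion_reads: int = 1
    rpm_threshold: float = 1.0
    smoothing_sigma: float = 5.0
    smoothing_floor: float = 0.5

    def __post_init__(self) -> None:
        for name in (
            "max_t_to_c_per_read",
            "min_conversion_reads",
            "rpm_threshold",
            "smoothing_sigma",
            "smoothing_floor",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(slots=True)
class Cluster:
    transcript_id: str
    start: int
    end: int
    reads: list[AlignedRead] = field(default_factory=list)


@dataclass(slots=True)
class BindingSite:
    transcript_id: str
    start: int
    end: int
    read_count: float  # weighted
    conversion_read_count: int
    rpm: float
    norm_score: float | None  # RPM / gene RPKM x 1000; None when undefined
    region: str = ""
    condition: str = ""

    @property
    def norm_defined(self) -> bool:
        return self.norm_score is not None

    def coverage_value(self) -> float:
        """Scoring currency: expression-normalized where defined, else RPM."""
        return self.norm_score if self.norm_score is not None else self.rpm


def cluster_reads(
    reads: Sequence[AlignedRead], params: CallerParams = CallerParams()
) -> list[Cluster]:
    """Merge conversion-filtered reads of one transcript into peaks.

    Clusters are maximal sets of reads connected (pairwise or transitively)
    by >= 1 nt overlap; a cluster's span is the union of member spans.
    """
    kept = [r for r in reads if r.t_to_c_count <= params.max_t_to_c_per_read]
    if not kept:
        return []
    tids = {r.transcript_id for r in kept}
    if len(tids) > 1:
        raise ValueError(f"cluster_reads expects one transcript, got {sorted(tids)}")
    kept.sort(key=lambda r: (r.start, r.end))
    clusters: list[Cluster] = []
    cur = Cluster(kept[0].transcript_id, kept[0].start, kept[0].end, [kept[0]])
    for r in kept[1:]:
        if r.start < cur.end:  # half-open: touching spans do not overlap
            cur.end = max(cur.end, r.end)
            cur.reads.append(r)
        else:
            clusters.append(cur)
            cur = Cluster(r.transcript_id, r.start, r.end, [r])
    clusters.append(cur)
    return clusters


def _gaussian_kernel(sigma: float) -> np.ndarray:
    """Unit-mass Gaussian truncated at 4 sigma; a delta when sigma == 0."""
    if sigma <= 0:
        return np.array([1.0])
    half = int(np.ceil(4 * sigma))
    x = np.arange(-half, half + 1, dtype=float)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def smoothed_coverage(
    cluster: Cluster, params: CallerParams = CallerParams()
) -> tuple[int, np.ndarray, np.ndarray]:
    """(origin, raw coverage, smoothed coverage) over the padded span.

    The arrays start at transcript coordinate ``origin`` and extend one
    kernel half-width beyond the raw span on each side, so the smoothed
    profile holds the kernel's entire mass: sums of the two arrays agree
    to floating-point precision before any trimming.
    """
    kernel = _gaussian_kernel(params.smoothing_sigma)
    pad = (len(kernel) - 1) // 2
    origin = cluster.start - pad
    n = (cluster.end - cluster.start) + 2 * pad
    cov = np.zeros(n)
    for r in cluster.reads:
        cov[r.start - origin : r.end - origin] += r.weight
    smoothed = np.convolve(cov, kernel, mode="same")
    return origin, cov, smoothed


def smooth_cluster(
    cluster: Cluster, params: CallerParams = CallerParams()
) -> tuple[int, int] | None:
    """Smoothed cluster boundaries, or None if everything is below floor.

    Boundaries delimit the maximal contiguous run of smoothed coverage
    >= ``smoothing_floor`` that contains the coverage maximum.
    """
    if not cluster.reads:
        raise ValueError("empty cluster")
    origin, _, smoothed = smoothed_coverage(cluster, params)
    above = smoothed >= params.smoothing_floor
    if not above.any():
        logger.info(
            "cluster %s:%d-%d dropped: smoothed coverage below floor",
            cluster.transcript_id, cluster.start, cluster.end,
        )
        return None
    peak = int(np.argmax(smoothed))
    lo = peak
    while lo > 0 and above[lo - 1]:
        lo -= 1
    hi = peak + 1
    while hi < len(above) and above[hi]:
        hi += 1
    return origin + lo, origin + hi


def filter_and_score(
    clusters: Sequence[Cluster],
    library_mapped_total: float,
    expression: Mapping[str, float] | None,
    params: CallerParams = CallerParams(),
    condition: str = "",
) -> list[BindingSite]:
    """Retain clusters with conversion evidence and score them.

    rpm = sum of member weights / (library total / 1e6); retained iff the
    cluster holds >= min_conversion_reads reads with a T-to-C conversion
    and rpm >= rpm_threshold. norm_score = rpm / gene RPKM x 1000; a zero
    or missing RPKM leaves the site retained with norm_score undefined.
    """
    if library_mapped_total <= 0:
        raise ValueError("library_mapped_total must be > 0")
    sites: list[BindingSite] = []
    for c in clusters:
        conv = sum(1 for r in c.reads if r.t_to_c_count >= 1)
        if conv < params.min_conversion_reads:
            continue
        weight = sum(r.weight for r in c.reads)
        rpm = weight / (library_mapped_total / 1e6)
        if rpm < params.rpm_threshold:
            continue
        bounds = smooth_cluster(c, params)
        if bounds is None:
            continue
        rpkm = expression.get(c.transcript_id) if expression else None
        if rpkm is None or rpkm <= 0:
            norm = None
            logger.info(
                "site %s:%d-%d: expression unavailable or zero; "
                "norm_score undefined", c.transcript_id, *bounds,
            )
        else:
            norm = rpm / rpkm * 1000.0
        sites.append(
            BindingSite(
                transcript_id=c.transcript_id,
                start=bounds[0],
                end=bounds[1],
                read_count=weight,
                conversion_read_count=conv,
                rpm=rpm,
                norm_score=norm,
                condition=condition,
            )
        )
    return sites


def call_sites(
    reads_by_transcript: Mapping[str, Sequence[AlignedRead]],
    library_mapped_total: float,
    expression: Mapping[str, float] | None,
    params: CallerParams = CallerParams(),
    condition: str = "",
    transcript_lengths: Mapping[str, int] | None = None,
) -> list[BindingSite]:
    """Cluster, smooth, filter and score per transcript; concatenated sites.

    Smoothing can push boundaries past the transcript ends; when lengths
    are supplied, site spans are clipped back to the transcript.
    """
    sites: list[BindingSite] = []
    for tid in sorted(reads_by_transcript):
        clusters = cluster_reads(list(reads_by_transcript[tid]), params)
        called = filter_and_score(
            clusters, library_mapped_total, expression, params, condition
        )
        if transcript_lengths is not None:
            L = transcript_lengths[tid]
            for s in called:
                s.start = max(0, s.start)
                s.end = min(L, s.end)
        sites.extend(called)
    return sites


def group_reads_by_transcript(
    reads: Sequence[AlignedRead],
) -> dict[str, list[AlignedRead]]:
    out: dict[str, list[AlignedRead]] = {}
    for r in reads:
        out.setdefault(r.transcript_id, []).append(r)
    return out


def suggest_rpm_threshold(rpms: Sequence[float]) -> float:
    """Knee of the descending RPM curve (max distance to the chord).

    Helper for choosing the otherwise-empirical RPM cutoff; returns the
    RPM value at the knee.
    """
    v = np.sort(np.asarray(rpms, dtype=float))[::-1]
    if v.size < 3:
        return float(v.min()) if v.size else 0.0
    x = np.arange(v.size, dtype=float)
    x0, y0, x1, y1 = x[0], v[0], x[-1], v[-1]
    denom = np.hypot(x1 - x0, y1 - y0)
    dist = np.abs((y1 - y0) * x - (x1 - x0) * v + x1 * y0 - y1 * x0) / denom
    return float(v[int(np.argmax(dist))])


def write_sites_bed(path: str | Path, sites: Sequence[BindingSite]) -> None:
    """BED6+ export: extra columns read_count, conversion_read_count, rpm,
    region, condition; the BED score column carries norm_score ('.' when
    undefined)."""
    with open(path, "w") as fh:
        for i, s in enumerate(sites):
            score = f"{s.norm_score:.6g}" if s.norm_score is not None else "."
            fh.write(
                f"{s.transcript_id}\t{s.start}\t{s.end}\tsite{i:05d}\t{score}\t+"
                f"\t{s.read_count:.6g}\t{s.conversion_read_count}\t{s.rpm:.6g}"
                f"\t{s.region or '.'}\t{s.condition or '.'}\n"
            )


def write_sites_tsv(path: str | Path, sites: Sequence[BindingSite]) -> None:
    with open(path, "w") as fh:
        fh.write(
            "transcript_id\tstart\tend\tread_count\tconversion_read_count"
            "\trpm\tnorm_score\tregion\tcondition\n"
        )
        for s in sites:
            norm = f"{s.norm_score:.6g}" if s.norm_score is not None else "NA"
            fh.write(
                f"{s.transcript_id}\t{s.start}\t{s.end}\t{s.read_count:.6g}"
                f"\t{s.conversion_read_count}\t{s.rpm:.6g}\t{norm}"
                f"\t{s.region or '.'}\t{s.condition or '.'}\n"
            )
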