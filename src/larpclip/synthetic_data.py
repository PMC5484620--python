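"""Ground-truth simulator for PAR-CLIP and mRNA-seq libraries.

Emulates the experimental design the pipeline targets: a transcriptome of
RP (ribosomal protein), other translation-related (TR_other) and non-TR
genes; RP mRNAs start with a 5'TOP (cap-site C followed by a pyrimidine
run) and carry a pyrimidine-enriched sequence (PES) footprint abutting the
5'UTR/CDS junction; every transcript carries a GA-rich 3'UTR footprint and
non-TR transcripts additionally a CDS footprint. Crosslinked protein
footprints emit reads whose covered Ts read as C with a configurable
conversion rate — the T-to-C signature PAR-CLIP relies on. 5'UTR footprints
on RP/TR transcripts are occupied only when mTOR is inhibited (mTOR_off),
mirroring the condition-dependent relocation the pipeline is built to
detect. mRNA-seq replicates are independent multinomial draws from a shared
log-normal abundance vector.

Everything is deterministic given ``SimulationSpec.seed``.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .alignment_io import AlignedRead, SamRecord, write_bed
from .model import CDS, UTR3, UTR5, TranscriptModel

logger = logging.getLogger(__name__)

CONDITIONS = ("mTOR_on", "mTOR_off")

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def default_occupancy() -> dict[tuple[str, str], float]:
    """Expected reads per footprint by (category, region).

    5'UTR values apply only when the footprint is condition-active
    (mTOR_off); occupancy itself is condition-independent.
    """
    return {
        ("RP", UTR5): 60.0,
        ("TR_other", UTR5): 60.0,
        ("RP", UTR3): 40.0,
        ("TR_other", UTR3): 40.0,
        ("non_TR", CDS): 40.0,
        ("non_TR", UTR3): 40.0,
    }


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one simulated study (both libraries, one condition)."""

    n_transcripts: int = 300
    fraction_rp: float = 0.2
    fraction_tr_other: float = 0.2
    utr5_len: tuple[int, int] = (60, 200)
    cds_len: tuple[int, int] = (300, 900)
    utr3_len: tuple[int, int] = (150, 500)
    pes_len: int = 20
    pes_pyrimidine_rate: float = 0.9
    top_run_len: int = 5
    footprint_len: int = 25
    condition: str = "mTOR_off"
    occupancy: Mapping[tuple[str, str], float] | None = None
    conversion_rate: float = 0.30
    background_read_rate: float = 0.2  # reads per kb of transcript
    seq_error_rate: float = 0.001
    multimap_fraction: float = 0.05
    abundance_mu: float = 1.0
    abundance_sigma: float = 1.0
    n_replicates: int = 2
    mrnaseq_reads: int = 500_000
    read_len: int = 30
    seed: int = 7

    def validate(self) -> None:
        for name in (
            "fraction_rp",
            "fraction_tr_other",
            "pes_pyrimidine_rate",
            "conversion_rate",
            "seq_error_rate",
            "multimap_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.fraction_rp + self.fraction_tr_other > 1.0:
            raise ValueError("fraction_rp + fraction_tr_other exceeds 1")
        for name in ("utr5_len", "cds_len", "utr3_len"):
            lo, hi = getattr(self, name)
            if lo < 1 or hi < lo:
                raise ValueError(f"{name}=({lo},{hi}) is not a positive range")
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        if self.occupancy is not None and any(v < 0 for v in self.occupancy.values()):
            raise ValueError("occupancy values must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        # region capacity for the planted features
        if self.utr5_len[0] < 1 + self.top_run_len + self.pes_len:
            raise ValueError(
                "5'UTR length range too short to hold the 5'TOP plus the PES "
                f"footprint (need >= {1 + self.top_run_len + self.pes_len} nt)"
            )
        if self.utr3_len[0] < self.footprint_len + 4:
            raise ValueError(
                "3'UTR length range too short to hold the requested footprint "
                f"(need >= {self.footprint_len + 4} nt)"
            )
        if self.cds_len[0] < 2 * (self.footprint_len + 10):
            raise ValueError(
                "CDS length range too short to hold the requested footprint "
                f"(need >= {2 * (self.footprint_len + 10)} nt)"
            )

    def resolved_occupancy(self) -> dict[tuple[str, str], float]:
        return dict(self.occupancy) if self.occupancy is not None else default_occupancy()

    def with_condition(self, condition: str) -> "SimulationSpec":
        return replace(self, condition=condition)


@dataclass(slots=True)
class PlantedSite:
    """One planted protein footprint: the truth a caller should recover."""

    transcript_id: str
    region: str
    start: int
    end: int
    category: str
    active_in: tuple[str, ...]  # conditions under which the footprint emits reads

    def active(self, condition: str) -> bool:
        return condition in self.active_in


@dataclass(slots=True)
class TruthTable:
    planted_sites: list[PlantedSite]
    true_abundance: dict[str, float]
    multimap_copies: list[tuple[str, int]] = field(default_factory=list)
    cassette_len: int = 0

    def active_sites(self, condition: str) -> list[PlantedSite]:
        return [s for s in self.planted_sites if s.active(condition)]


def _rng(spec: SimulationSpec, *stream: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed, *stream])


# --- transcriptome ----------------------------------------------------------


def generate_transcriptome(
    spec: SimulationSpec,
) -> tuple[list[TranscriptModel], TruthTable]:
    """Build the transcript set with planted features and its truth table.

    Category counts follow the spec fractions with nearest-integer rounding
    (Python ``round``, ties to even). RP transcripts get a 5'TOP start and,
    like TR_other transcripts, a PES footprint ending exactly at the
    5'UTR/CDS junction (active only under mTOR_off). All transcripts get a
    GA-rich 3'UTR footprint; non-TR transcripts additionally a CDS
    footprint (active in both conditions).
    """
    spec.validate()
    rng = _rng(spec, 0)
    n = spec.n_transcripts
    n_rp = round(n * spec.fraction_rp)
    n_tr = round(n * spec.fraction_tr_other)
    cats = ["RP"] * n_rp + ["TR_other"] * n_tr + ["non_TR"] * (n - n_rp - n_tr)

    transcripts: list[TranscriptModel] = []
    planted: list[PlantedSite] = []
    fp = spec.footprint_len

    for i, cat in enumerate(cats):
        tid = f"TX{i:04d}"
        gid = f"GENE{i:04d}"
        u5 = int(rng.integers(spec.utr5_len[0], spec.utr5_len[1] + 1))
        cd = int(rng.integers(spec.cds_len[0], spec.cds_len[1] + 1))
        u3 = int(rng.integers(spec.utr3_len[0], spec.utr3_len[1] + 1))
        L = u5 + cd + u3
        seq = rng.choice(_BASES, size=L)

        if cat == "RP":
            # 5'TOP: cap-site C then a pyrimidine run
            seq[0] = b"C"
            seq[1 : 1 + spec.top_run_len] = rng.choice(
                np.frombuffer(b"CT", dtype="S1"), size=spec.top_run_len
            )
        if cat in ("RP", "TR_other"):
            # PES abutting the 5'UTR/CDS junction
            ps, pe = u5 - spec.pes_len, u5
            pyr = rng.random(spec.pes_len) < spec.pes_pyrimidine_rate
            pick = rng.integers(0, 2, size=spec.pes_len)
            pes = np.where(
                pyr,
                np.where(pick == 0, b"C", b"T"),
                np.where(pick == 0, b"A", b"G"),
            )
            seq[ps:pe] = pes
            planted.append(PlantedSite(tid, UTR5, ps, pe, cat, ("mTOR_off",)))
        else:
            # CDS footprint in the second half of the CDS (positional only)
            lo = u5 + cd // 2
            hi = u5 + cd - fp - 2
            cs = int(rng.integers(lo, hi + 1))
            planted.append(PlantedSite(tid, CDS, cs, cs + fp, cat, CONDITIONS))

        # GA-rich 3'UTR footprint for every category
        lo = u5 + cd + 2
        hi = L - fp - 2
        gs = int(rng.integers(lo, hi + 1))
        ga = rng.choice(
            _BASES, size=fp, p=[0.4, 0.1, 0.4, 0.1]
        )  # A, C, G, T — G+A rich, T-poor but not T-free
        seq[gs : gs + fp] = ga
        planted.append(PlantedSite(tid, UTR3, gs, gs + fp, cat, CONDITIONS))

        transcripts.append(
            TranscriptModel(tid, gid, cat, seq.tobytes().decode("ascii"), u5, cd, u3)
        )

    # duplicated cassette -> controlled k-way multimapping
    n_mm = round(spec.multimap_fraction * n)
    copies: list[tuple[str, int]] = []
    cas_len = spec.read_len + 10
    if n_mm >= 2:
        cassette = rng.choice(_BASES, size=cas_len).tobytes().decode("ascii")
        hosts = [t for t in transcripts if t.category == "non_TR"][:n_mm]
        for t in hosts:
            pos = t.utr5_len + 5  # start of CDS, clear of the planted CDS footprint
            t.seq = t.seq[:pos] + cassette + t.seq[pos + cas_len :]
            copies.append((t.transcript_id, pos))

    ab = rng.lognormal(spec.abundance_mu, spec.abundance_sigma, size=n)
    ab /= ab.sum()
    truth = TruthTable(
        planted_sites=planted,
        true_abundance={t.transcript_id: float(a) for t, a in zip(transcripts, ab)},
        multimap_copies=copies,
        cassette_len=cas_len if copies else 0,
    )
    for s in planted:  # containment invariant, checked at source
        t = transcripts[int(s.transcript_id[2:])]
        rs, re = t.region_bounds()[s.region]
        assert rs <= s.start < s.end <= re
    return transcripts, truth


# --- read simulation --------------------------------------------------------


def _apply_seq_errors(
    read: np.ndarray, rate: float, rng: np.random.Generator
) -> None:
    if rate <= 0:
        return
    hits = np.flatnonzero(rng.random(read.size) < rate)
    for p in hits:
        choices = _BASES[_BASES != read[p]]
        read[p] = rng.choice(choices)


def _multimap_records(
    rec: SamRecord, truth: TruthTable
) -> list[SamRecord]:
    """Expand a record into one per cassette copy if it lies inside one."""
    if not truth.multimap_copies:
        return [rec]
    for tid, cs in truth.multimap_copies:
        if (
            rec.transcript_id == tid
            and rec.start >= cs
            and rec.start + len(rec.seq) <= cs + truth.cassette_len
        ):
            off = rec.start - cs
            return [
                SamRecord(rec.read_id, other_tid, other_cs + off, rec.seq)
                for other_tid, other_cs in truth.multimap_copies
            ]
    return [rec]


def simulate_parclip(
    transcripts: Sequence[TranscriptModel],
    truth: TruthTable,
    spec: SimulationSpec,
) -> list[SamRecord]:
    """Emit PAR-CLIP placements for one condition.

    Footprint reads are drawn Poisson(occupancy) per condition-active
    planted site, positioned so the read midpoint is uniform over the
    footprint; every reference T inside the footprint covered by the read
    converts to C independently with ``conversion_rate``. Background reads
    are uniform over each transcript at ``background_read_rate`` per kb and
    carry conversions only through sequencing error. Reads falling entirely
    within a duplicated cassette are emitted once per copy (multimappers).
    """
    cond = spec.condition
    rng = _rng(spec, 1, CONDITIONS.index(cond))
    occ = spec.resolved_occupancy()
    by_tid = {t.transcript_id: t for t in transcripts}
    rl = spec.read_len
    out: list[SamRecord] = []
    counter = 0

    for site in truth.planted_sites:
        if not site.active(cond):
            continue
        mean = occ.get((site.category, site.region), 0.0)
        n_reads = int(rng.poisson(mean))
        t = by_tid[site.transcript_id]
        ref = np.frombuffer(t.seq.encode("ascii"), dtype="S1")
        t_positions = [
            p for p in range(site.start, site.end) if t.seq[p] == "T"
        ]
        for _ in range(n_reads):
            mid = int(rng.integers(site.start, site.end))
            start = min(max(mid - rl // 2, 0), t.length - rl)
            read = ref[start : start + rl].copy()
            for p in t_positions:
                if start <= p < start + rl and rng.random() < spec.conversion_rate:
                    read[p - start] = b"C"
            _apply_seq_errors(read, spec.seq_error_rate, rng)
            rec = SamRecord(
                f"PC{counter:07d}", t.transcript_id, start, read.tobytes().decode()
            )
            counter += 1
            out.extend(_multimap_records(rec, truth))

    for t in transcripts:
        n_bg = int(rng.poisson(spec.background_read_rate * t.length / 1000.0))
        if t.length < rl:
            continue
        ref = np.frombuffer(t.seq.encode("ascii"), dtype="S1")
        for _ in range(n_bg):
            start = int(rng.integers(0, t.length - rl + 1))
            read = ref[start : start + rl].copy()
            _apply_seq_errors(read, spec.seq_error_rate, rng)
            rec = SamRecord(
                f"PC{counter:07d}", t.transcript_id, start, read.tobytes().decode()
            )
            counter += 1
            out.extend(_multimap_records(rec, truth))
    return out


def simulate_mrnaseq(
    transcripts: Sequence[TranscriptModel],
    truth: TruthTable,
    spec: SimulationSpec,
) -> list[list[SamRecord]]:
    """Replicate mRNA-seq libraries: independent multinomial draws.

    Per replicate, ``mrnaseq_reads`` reads are allocated to transcripts
    with probability proportional to abundance x number of read start
    positions, then placed uniformly. Only sequencing errors are applied
    (no crosslink signature).
    """
    if spec.mrnaseq_reads < 1:
        raise ValueError("mrnaseq_reads must be >= 1")
    rl = spec.read_len
    ab = np.array([truth.true_abundance[t.transcript_id] for t in transcripts])
    nstarts = np.array([max(t.length - rl + 1, 0) for t in transcripts])
    p = ab * nstarts
    if p.sum() <= 0:
        raise ValueError("no transcript can hold a read of the requested length")
    p /= p.sum()

    libraries: list[list[SamRecord]] = []
    for rep in range(spec.n_replicates):
        rng = _rng(spec, 2, CONDITIONS.index(spec.condition), rep)
        counts = rng.multinomial(spec.mrnaseq_reads, p)
        recs: list[SamRecord] = []
        counter = 0
        for t, c in zip(transcripts, counts):
            if c == 0:
                continue
            starts = rng.integers(0, t.length - rl + 1, size=c)
            n_err = rng.binomial(rl, spec.seq_error_rate, size=c)
            for s, ne in zip(starts, n_err):
                s = int(s)
                seq = t.seq[s : s + rl]
                if ne > 0:
                    read = np.frombuffer(seq.encode("ascii"), dtype="S1").copy()
                    for pos in rng.choice(rl, size=ne, replace=False):
                        choices = _BASES[_BASES != read[pos]]
                        read[pos] = rng.choice(choices)
                    seq = read.tobytes().decode()
                rec = SamRecord(f"MR{rep}_{counter:07d}", t.transcript_id, s, seq)
                counter += 1
                recs.extend(_multimap_records(rec, truth))
        libraries.append(recs)
    return libraries


# --- truth-based evaluation -------------------------------------------------


def estimate_conversion_rate(
    reads: Iterable[AlignedRead],
    truth: TruthTable,
    transcripts: Sequence[TranscriptModel],
    condition: str,
) -> tuple[float, int]:
    """Estimate the T-to-C conversion rate from truth-matched reads.

    Over every (read, reference-T) pair where the T lies inside a
    condition-active planted footprint covered by the read, returns the
    fraction read as C and the number of covered Ts.
    """
    by_tid = {t.transcript_id: t for t in transcripts}
    sites: dict[str, list[PlantedSite]] = {}
    for s in truth.active_sites(condition):
        sites.setdefault(s.transcript_id, []).append(s)
    n_t = n_c = 0
    for r in reads:
        for s in sites.get(r.transcript_id, ()):
            lo, hi = max(r.start, s.start), min(r.end, s.end)
            if lo >= hi:
                continue
            t = by_tid[r.transcript_id]
            converted = {p for p, rb, qb in r.mismatches if rb == "T" and qb == "C"}
            for p in range(lo, hi):
                if t.seq[p] == "T":
                    n_t += 1
                    n_c += p in converted
    return (n_c / n_t if n_t else float("nan")), n_t


def site_recovery(
    called: Sequence, truth: TruthTable, condition: str
) -> tuple[float, float]:
    """Sensitivity and precision of called sites against active footprints.

    A planted footprint is recovered if any called site on the same
    transcript overlaps it by >= 1 nt; a called site is a true positive if
    it overlaps any active footprint.
    """
    active = truth.active_sites(condition)
    def overlaps(a_start, a_end, b_start, b_end):
        return max(a_start, b_start) < min(a_end, b_end)

    recovered = sum(
        any(
            c.transcript_id == s.transcript_id and overlaps(c.start, c.end, s.start, s.end)
            for c in called
        )
        for s in active
    )
    true_pos = sum(
        any(
            c.transcript_id == s.transcript_id and overlaps(c.start, c.end, s.start, s.end)
            for s in active
        )
        for c in called
    )
    sens = recovered / len(active) if active else float("nan")
    prec = true_pos / len(called) if called else float("nan")
    return sens, prec


def expected_region_fractions(
    transcripts: Sequence[TranscriptModel],
    truth: TruthTable,
    spec: SimulationSpec,
    condition: str,
    max_t_to_c: int = 2,
) -> dict[tuple[str, str], float]:
    """Truth-table expectation of the region-coverage percentages.

    Computed from the generative model alone, never from reads: per active
    footprint the expected number of *retained* reads is the occupancy
    times the mean (over uniform read midpoints) probability that a read's
    covered footprint Ts carry at most ``max_t_to_c`` conversions — the
    same 0-2 conversion filter the caller applies. Site coverage currency
    is expression-normalized, so each footprint's expectation is divided
    by the transcript's expected relative RPKM (abundance-proportional;
    shared scale factors cancel within a category). Returns
    (category, region) -> expected percentage within the category.
    """
    from scipy.stats import binom

    occ = spec.resolved_occupancy()
    by_tid = {t.transcript_id: t for t in transcripts}
    rl = spec.read_len
    num: dict[tuple[str, str], float] = {}
    for site in truth.active_sites(condition):
        t = by_tid[site.transcript_id]
        mean_occ = occ.get((site.category, site.region), 0.0)
        if mean_occ == 0:
            continue
        t_pos = np.array(
            [p for p in range(site.start, site.end) if t.seq[p] == "T"]
        )
        keep = []
        for mid in range(site.start, site.end):
            s = min(max(mid - rl // 2, 0), t.length - rl)
            n_cov = int(((t_pos >= s) & (t_pos < s + rl)).sum()) if t_pos.size else 0
            keep.append(float(binom.cdf(max_t_to_c, n_cov, spec.conversion_rate)))
        expected_kept = mean_occ * float(np.mean(keep))
        # expected relative RPKM: abundance x start positions / length
        rel_rpkm = (
            truth.true_abundance[t.transcript_id]
            * max(t.length - rl + 1, 1)
            / t.length
        )
        key = (site.category, site.region)
        num[key] = num.get(key, 0.0) + expected_kept / rel_rpkm
    out: dict[tuple[str, str], float] = {}
    for (cat, region), v in num.items():
        total = sum(val for (c, _), val in num.items() if c == cat)
        out[(cat, region)] = 100.0 * v / total
    return out


# --- companion annotation tables -------------------------------------------

_TRANSLATION_TERMS = {
    "RP": ["GO:0006412", "GO:0003735"],
    "TR_other": ["GO:0006412", "GO:0006413", "GO:0006414"],
}
_OTHER_TERMS = [
    "GO:0006915", "GO:0007049", "GO:0006281", "GO:0006355", "GO:0016192",
    "GO:0006468", "GO:0055085", "GO:0006629", "GO:0007165", "GO:0006351",
    "GO:0008380", "GO:0006457",
]


def synthetic_go_annotation(
    transcripts: Sequence[TranscriptModel], spec: SimulationSpec
) -> dict[str, set[str]]:
    """Gene -> GO term sets consistent with the planted categories.

    RP/TR genes carry translation-related terms; every gene also draws two
    terms from a pool of unrelated processes.
    """
    rng = _rng(spec, 3)
    ann: dict[str, set[str]] = {}
    for t in transcripts:
        terms = set(rng.choice(_OTHER_TERMS, size=2, replace=False))
        terms.update(_TRANSLATION_TERMS.get(t.category, ()))
        ann[t.gene_id] = terms
    return ann


def synthetic_te_table(
    transcripts: Sequence[TranscriptModel], spec: SimulationSpec
) -> dict[str, float]:
    """Gene -> translation-efficiency fold change (inhibited / growing).

    RP and TR genes mostly drop more than 1.5-fold; others hover near 1.
    """
    rng = _rng(spec, 4)
    te: dict[str, float] = {}
    for t in transcripts:
        if t.category in ("RP", "TR_other"):
            log2fc = rng.normal(-1.2, 0.5)
        else:
            log2fc = rng.normal(0.0, 0.3)
        te[t.gene_id] = float(2.0 ** log2fc)
    return te


# --- text writers -----------------------------------------------------------


def write_truth_bed(path: str | Path, truth: TruthTable) -> None:
    write_bed(
        path,
        (
            (
                s.transcript_id,
                s.start,
                s.end,
                f"{s.category}:{s.region}:{'+'.join(s.active_in)}",
                0,
                "+",
            )
            for s in truth.planted_sites
        ),
    )


def write_truth_tsv(path: str | Path, truth: TruthTable) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["transcript_id", "region", "start", "end", "category", "active_in"])
        for s in truth.planted_sites:
            w.writerow(
                [s.transcript_id, s.region, s.start, s.end, s.category, ",".join(s.active_in)]
            )
        w.writerow([])
        w.writerow(["transcript_id", "true_abundance", "", "", "", ""])
        for tid, a in truth.true_abundance.items():
            w.writerow([tid, f"{a:.8g}", "", "", "", ""])


def write_go_annotation(path: str | Path, ann: Mapping[str, set[str]]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["gene_id", "term_id"])
        for gene in sorted(ann):
            for term in sorted(ann[gene]):
                w.writerow([gene, term])


def write_te_table(path: str | Path, te: Mapping[str, float]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["gene_id", "fold_change"])
        for gene in sorted(te):
            w.writerow([gene, f"{te[gene]:.6g}"])
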