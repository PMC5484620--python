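"""Transcript-space data model shared by every stage.

A transcript is a contiguous sequence in its own coordinate system
(0-based, half-open) partitioned into 5'UTR / CDS / 3'UTR. One transcript
per gene is assumed throughout; gene-level quantities (RPKM, GO terms)
are carried by the transcript's ``gene_id``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

UTR5 = "UTR5"
CDS = "CDS"
UTR3 = "UTR3"
REGIONS = (UTR5, CDS, UTR3)

# GFF3 feature names for transcript-space region annotation
_GFF_TYPES = {UTR5: "five_prime_UTR", CDS: "CDS", UTR3: "three_prime_UTR"}
_GFF_TYPES_INV = {v: k for k, v in _GFF_TYPES.items()}

CATEGORIES = ("RP", "TR_other", "non_TR")


@dataclass(slots=True)
class TranscriptModel:
    """One transcript: sequence, gene identity, category, region boundaries."""

    transcript_id: str
    gene_id: str
    category: str
    seq: str
    utr5_len: int
    cds_len: int
    utr3_len: int

    def __post_init__(self) -> None:
        total = self.utr5_len + self.cds_len + self.utr3_len
        if total != len(self.seq):
            raise ValueError(
                f"{self.transcript_id}: region lengths sum to {total}, "
                f"sequence is {len(self.seq)} nt"
            )

    @property
    def length(self) -> int:
        return len(self.seq)

    def region_bounds(self) -> dict[str, tuple[int, int]]:
        """Half-open (start, end) per region in transcript coordinates."""
        a = self.utr5_len
        b = self.utr5_len + self.cds_len
        return {UTR5: (0, a), CDS: (a, b), UTR3: (b, self.length)}

    def region_seq(self, region: str) -> str:
        s, e = self.region_bounds()[region]
        return self.seq[s:e]


def write_fasta(path: str | Path, transcripts: Iterable[TranscriptModel]) -> None:
    records = [
        SeqRecord(Seq(t.seq), id=t.transcript_id, description="")
        for t in transcripts
    ]
    SeqIO.write(records, str(path), "fasta")


def write_region_tsv(path: str | Path, transcripts: Iterable[TranscriptModel]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(
            ["transcript_id", "gene_id", "category", "utr5_len", "cds_len", "utr3_len"]
        )
        for t in transcripts:
            w.writerow(
                [t.transcript_id, t.gene_id, t.category, t.utr5_len, t.cds_len, t.utr3_len]
            )


def write_region_gff(path: str | Path, transcripts: Iterable[TranscriptModel]) -> None:
    """Transcript-space GFF3: one five_prime_UTR/CDS/three_prime_UTR row each."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for t in transcripts:
            for region, (s, e) in t.region_bounds().items():
                if e == s:
                    continue
                fh.write(
                    "\t".join(
                        [
                            t.transcript_id,
                            "larpclip",
                            _GFF_TYPES[region],
                            str(s + 1),  # GFF is 1-based inclusive
                            str(e),
                            ".",
                            "+",
                            ".",
                            f"ID={t.transcript_id}.{region};gene_id={t.gene_id}",
                        ]
                    )
                    + "\n"
                )


def load_transcripts(
    fasta: str | Path, regions: str | Path
) -> list[TranscriptModel]:
    """Assemble transcript models from a FASTA plus a region TSV or GFF."""
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta), "fasta")}
    regions = Path(regions)
    if regions.suffix.lower() in {".gff", ".gff3", ".gtf"}:
        meta = _read_region_gff(regions)
    else:
        meta = _read_region_tsv(regions)
    out = []
    for tid, seq in seqs.items():
        if tid not in meta:
            raise ValueError(f"transcript {tid} missing from region annotation")
        gene_id, category, u5, cd, u3 = meta[tid]
        out.append(TranscriptModel(tid, gene_id, category, seq, u5, cd, u3))
    return out


def _read_region_tsv(path: Path) -> dict[str, tuple[str, str, int, int, int]]:
    meta = {}
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            meta[row["transcript_id"]] = (
                row.get("gene_id", row["transcript_id"]),
                row.get("category", "non_TR"),
                int(row["utr5_len"]),
                int(row["cds_len"]),
                int(row["utr3_len"]),
            )
    return meta


def _read_region_gff(path: Path) -> dict[str, tuple[str, str, int, int, int]]:
    spans: dict[str, dict[str, int]] = {}
    genes: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            tid, ftype, start, end, attrs = f[0], f[2], int(f[3]), int(f[4]), f[8]
            if ftype not in _GFF_TYPES_INV:
                continue
            region = _GFF_TYPES_INV[ftype]
            spans.setdefault(tid, {UTR5: 0, CDS: 0, UTR3: 0})[region] = end - start + 1
            for kv in attrs.split(";"):
                if kv.startswith("gene_id="):
                    genes[tid] = kv.split("=", 1)[1]
    return {
        tid: (genes.get(tid, tid), "non_TR", d[UTR5], d[CDS], d[UTR3])
        for tid, d in spans.items()
    }


def write_categories(path: str | Path, transcripts: Iterable[TranscriptModel]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["gene_id", "category"])
        for t in transcripts:
            w.writerow([t.gene_id, t.category])


def read_categories(path: str | Path) -> dict[str, str]:
    out = {}
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out[row["gene_id"]] = row["category"]
    return out


def categories_of(transcripts: Iterable[TranscriptModel]) -> Mapping[str, str]:
    return {t.gene_id: t.category for t in transcripts}
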