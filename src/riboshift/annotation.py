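"""Transcript models and the coordinate convention used throughout the package.

Every downstream module works in *transcript space*: 0-based, half-open
coordinates along the mature transcript, with three regions partitioning
``[0, length)``::

    [0, cds_start)          5'UTR   (may be empty)
    [cds_start, cds_end)    CDS     (stop codon included, BED thick style)
    [cds_end, length)       3'UTR   (may be empty)

Genome-space annotations (BED12, GTF) are converted to this convention on
read; alignments are expected to be in transcript space already.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

REGIONS = ("utr5", "cds", "utr3")

__all__ = [
    "REGIONS",
    "AnnotationError",
    "TranscriptModel",
    "TranscriptIndex",
    "region_of",
    "read_annotation",
    "read_bed12",
    "read_gtf",
    "write_bed12",
    "attach_sequences",
    "canonical_transcripts",
]


class AnnotationError(ValueError):
    """Raised for malformed or inconsistent annotation input."""


@dataclass
class TranscriptModel:
    """One transcript with its region boundaries in transcript space.

    ``flagged`` is set when the CDS length is not a multiple of 3 — the
    record is kept (frame statistics on it are still defined relative to
    ``cds_start``) but marked so callers can exclude it.
    """

    transcript_id: str
    gene_id: str
    length: int
    cds_start: int
    cds_end: int
    sequence: str | None = None
    flagged: bool = field(default=False)

    def __post_init__(self) -> None:
        if not (0 <= self.cds_start < self.cds_end <= self.length):
            raise AnnotationError(
                f"{self.transcript_id}: CDS [{self.cds_start}, {self.cds_end}) "
                f"violates 0 <= cds_start < cds_end <= length ({self.length})"
            )
        if self.sequence is not None and len(self.sequence) != self.length:
            raise AnnotationError(
                f"{self.transcript_id}: sequence length {len(self.sequence)} "
                f"!= annotated length {self.length}"
            )
        if (self.cds_end - self.cds_start) % 3 != 0:
            self.flagged = True

    @property
    def utr5_len(self) -> int:
        return self.cds_start

    @property
    def cds_len(self) -> int:
        return self.cds_end - self.cds_start

    @property
    def utr3_len(self) -> int:
        return self.length - self.cds_end


def region_of(tx: TranscriptModel, pos: int) -> str:
    """Region label ('utr5'/'cds'/'utr3') of a 0-based transcript offset."""
    if not 0 <= pos < tx.length:
        raise AnnotationError(
            f"{tx.transcript_id}: position {pos} outside [0, {tx.length})"
        )
    if pos < tx.cds_start:
        return "utr5"
    if pos < tx.cds_end:
        return "cds"
    return "utr3"


class TranscriptIndex:
    """Vectorised view of a transcript set for array-based region lookups."""

    def __init__(self, models: Sequence[TranscriptModel]):
        ids = [m.transcript_id for m in models]
        if len(set(ids)) != len(ids):
            dups = pd.Index(ids)[pd.Index(ids).duplicated()].unique().tolist()
            raise AnnotationError(f"duplicate transcript ids: {dups}")
        self.models = list(models)
        self.ids = pd.Index(ids, name="transcript_id")
        self.length = np.asarray([m.length for m in models], dtype=np.int64)
        self.cds_start = np.asarray([m.cds_start for m in models], dtype=np.int64)
        self.cds_end = np.asarray([m.cds_end for m in models], dtype=np.int64)
        self.gene_id = np.asarray([m.gene_id for m in models], dtype=object)

    def __len__(self) -> int:
        return len(self.models)

    def __getitem__(self, transcript_id: str) -> TranscriptModel:
        return self.models[self.ids.get_loc(transcript_id)]

    def rows_of(self, transcript_ids: Iterable[str]) -> np.ndarray:
        """Integer rows for an array of transcript ids (-1 for unknown)."""
        return self.ids.get_indexer(pd.Index(transcript_ids))

    def regions_at(self, rows: np.ndarray, pos: np.ndarray) -> np.ndarray:
        """Region code (0=5'UTR, 1=CDS, 2=3'UTR) for position arrays."""
        return np.where(
            pos < self.cds_start[rows], 0, np.where(pos < self.cds_end[rows], 1, 2)
        )


# ---------------------------------------------------------------------------
# BED12
# ---------------------------------------------------------------------------

def _bed_block_layout(fields: Sequence[str], lineno: int) -> tuple[int, list[int], list[int]]:
    try:
        chrom_start = int(fields[1])
        n_blocks = int(fields[9])
        sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
        starts = [int(x) for x in fields[11].rstrip(",").split(",")]
    except ValueError as exc:
        raise AnnotationError(f"line {lineno}: malformed BED12 numeric field ({exc})")
    if len(sizes) != n_blocks or len(starts) != n_blocks:
        raise AnnotationError(
            f"line {lineno}: blockCount={n_blocks} does not match "
            f"blockSizes/blockStarts lengths"
        )
    return chrom_start, sizes, starts


def _genome_boundary_to_plus_offset(
    gpos: int, block_gstarts: Sequence[int], sizes: Sequence[int], lineno: int
) -> int:
    """Map a genomic boundary coordinate into a plus-strand transcript offset."""
    cum = 0
    for gstart, size in zip(block_gstarts, sizes):
        if gpos <= gstart:
            return cum
        if gpos <= gstart + size:
            return cum + (gpos - gstart)
        cum += size
    raise AnnotationError(f"line {lineno}: thick coordinate {gpos} beyond blocks")


def read_bed12(path: str | Path, skip_noncoding: bool = True) -> list[TranscriptModel]:
    """Read BED12 transcript annotation into transcript-space models.

    The BED ``name`` field is the transcript id, optionally ``tx|gene``;
    when no gene is given the transcript id doubles as the gene id.
    Records with ``thickStart == thickEnd`` (no CDS) are skipped with a
    warning unless ``skip_noncoding`` is False, in which case they error.
    """
    models: list[TranscriptModel] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise AnnotationError(
                    f"line {lineno}: expected 12 tab-separated BED fields, "
                    f"got {len(fields)}"
                )
            chrom_start, sizes, starts = _bed_block_layout(fields, lineno)
            name = fields[3]
            tx_id, _, gene = name.partition("|")
            gene_id = gene or tx_id
            if tx_id in seen:
                raise AnnotationError(f"line {lineno}: duplicate transcript id {tx_id!r}")
            seen.add(tx_id)
            strand = fields[5]
            try:
                thick_start = int(fields[6])
                thick_end = int(fields[7])
            except ValueError as exc:
                raise AnnotationError(f"line {lineno}: malformed thick field ({exc})")
            length = sum(sizes)
            if thick_start == thick_end:
                if skip_noncoding:
                    warnings.warn(f"skipping non-coding BED record {tx_id!r}")
                    seen.discard(tx_id)
                    continue
                raise AnnotationError(f"line {lineno}: record {tx_id!r} has no CDS")
            gstarts = [chrom_start + s for s in starts]
            lo = _genome_boundary_to_plus_offset(thick_start, gstarts, sizes, lineno)
            hi = _genome_boundary_to_plus_offset(thick_end, gstarts, sizes, lineno)
            if strand == "-":
                cds_start, cds_end = length - hi, length - lo
            else:
                cds_start, cds_end = lo, hi
            if not (0 <= cds_start < cds_end <= length):
                raise AnnotationError(
                    f"line {lineno}: CDS [{cds_start}, {cds_end}) outside "
                    f"transcript of length {length}"
                )
            models.append(
                TranscriptModel(tx_id, gene_id, length, cds_start, cds_end)
            )
    return models


def write_bed12(models: Iterable[TranscriptModel], path: str | Path) -> None:
    """Write models as single-exon plus-strand BED12 (chrom = transcript id)."""
    with open(path, "w") as fh:
        for m in models:
            name = m.transcript_id if m.gene_id == m.transcript_id else (
                f"{m.transcript_id}|{m.gene_id}"
            )
            fh.write(
                "\t".join(
                    [
                        m.transcript_id,
                        "0",
                        str(m.length),
                        name,
                        "0",
                        "+",
                        str(m.cds_start),
                        str(m.cds_end),
                        "0",
                        "1",
                        f"{m.length},",
                        "0,",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

def read_gtf(path: str | Path) -> list[TranscriptModel]:
    """Read a GTF annotation (exon + CDS features, 1-based closed).

    Transcript length is the sum of exon lengths; the coding interval is
    the union of CDS and (if present) stop_codon features, mapped into
    transcript space, so the stop codon is included as in BED practice.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    exons: dict[str, list] = {}
    cds: dict[str, list] = {}
    meta: dict[str, tuple[str, str]] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS", "stop_codon"):
            continue
        tx_id = feat.attributes.get("transcript_id", [None])[0]
        if tx_id is None:
            raise AnnotationError(f"GTF feature without transcript_id at {feat.start}")
        gene_id = feat.attributes.get("gene_id", [tx_id])[0]
        meta[tx_id] = (gene_id, feat.strand)
        target = exons if feat.featuretype == "exon" else cds
        # convert to 0-based half-open
        target.setdefault(tx_id, []).append((feat.start - 1, feat.end))

    models = []
    for tx_id, ex in exons.items():
        gene_id, strand = meta[tx_id]
        ex = sorted(ex)
        length = sum(e - s for s, e in ex)
        if tx_id not in cds:
            warnings.warn(f"skipping non-coding GTF transcript {tx_id!r}")
            continue
        c_lo = min(s for s, _ in cds[tx_id])
        c_hi = max(e for _, e in cds[tx_id])
        gstarts = [s for s, _ in ex]
        sizes = [e - s for s, e in ex]
        lo = _genome_boundary_to_plus_offset(c_lo, gstarts, sizes, 0)
        hi = _genome_boundary_to_plus_offset(c_hi, gstarts, sizes, 0)
        if strand == "-":
            cds_start, cds_end = length - hi, length - lo
        else:
            cds_start, cds_end = lo, hi
        if tx_id in {m.transcript_id for m in models}:
            raise AnnotationError(f"duplicate transcript id {tx_id!r} in GTF")
        models.append(TranscriptModel(tx_id, gene_id, length, cds_start, cds_end))
    return models


def read_annotation(path: str | Path, format: str | None = None) -> list[TranscriptModel]:
    """Read BED12 or GTF annotation; the format is inferred from the suffix."""
    if format is None:
        suffix = Path(path).suffix.lower()
        format = {"bed": "bed12", "bed12": "bed12", "gtf": "gtf"}.get(
            suffix.lstrip("."), None
        )
        if format is None:
            raise AnnotationError(f"cannot infer annotation format from {path!r}")
    if format == "bed12":
        return read_bed12(path)
    if format == "gtf":
        return read_gtf(path)
    raise AnnotationError(f"unknown annotation format {format!r}")


def attach_sequences(
    models: Sequence[TranscriptModel], fasta: str | Path
) -> list[TranscriptModel]:
    """Attach transcript sequences from a FASTA keyed by transcript id."""
    from Bio import SeqIO

    seqs: Mapping[str, str] = {
        rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta), "fasta")
    }
    out = []
    for m in models:
        seq = seqs.get(m.transcript_id)
        if seq is not None and len(seq) != m.length:
            raise AnnotationError(
                f"{m.transcript_id}: FASTA length {len(seq)} != annotation {m.length}"
            )
        out.append(
            TranscriptModel(
                m.transcript_id, m.gene_id, m.length, m.cds_start, m.cds_end, seq
            )
        )
    return out


def canonical_transcripts(models: Sequence[TranscriptModel]) -> dict[str, TranscriptModel]:
    """One transcript per gene: longest CDS, ties broken by transcript id."""
    best: dict[str, TranscriptModel] = {}
    for m in models:
        cur = best.get(m.gene_id)
        if (
            cur is None
            or m.cds_len > cur.cds_len
            or (m.cds_len == cur.cds_len and m.transcript_id < cur.transcript_id)
        ):
            best[m.gene_id] = m
    return best
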