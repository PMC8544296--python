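"""Read filtering, P-site assignment, region/frame statistics, RPKM and TE.

Quantification follows the standard ribosome-profiling bookkeeping:

* reads shorter than 20 nt are discarded;
* each ribosome-protected fragment (RPF) is reduced to its P-site,
  inferred as the read 5' end plus a fixed, length-dependent offset
  (default 12 nt for ~30-nt mammalian footprints);
* translation level is the CDS-restricted RPKM of RPF P-sites, mRNA level
  the whole-transcript RPKM of RNA-seq reads, and translation efficiency
  (TE) their ratio, defined only above an mRNA expression floor.

Library size for RPKM is the number of length-filtered reads assigned to
any transcript in that library.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import TranscriptIndex, TranscriptModel, canonical_transcripts

DEFAULT_MIN_READ_LENGTH = 20
DEFAULT_PSITE_OFFSET = 12

__all__ = [
    "DEFAULT_MIN_READ_LENGTH",
    "DEFAULT_PSITE_OFFSET",
    "NoUsableReadsError",
    "Alignment",
    "filter_reads",
    "psite",
    "assign_psites",
    "region_counts",
    "rna_counts",
    "region_distribution",
    "frame_distribution",
    "length_histogram",
    "rpkm",
    "translation_efficiency",
    "gene_quant",
]


class NoUsableReadsError(ValueError):
    """Raised when a positional statistic is requested with zero usable reads."""


@dataclass(frozen=True)
class Alignment:
    """One read placement in transcript space (convenience scalar form)."""

    transcript_id: str
    start: int
    read_length: int
    sample_id: str = ""
    library: str = "rpf"


def filter_reads(reads: pd.DataFrame, min_len: int = DEFAULT_MIN_READ_LENGTH) -> pd.DataFrame:
    """Drop reads shorter than ``min_len`` nucleotides, preserving order."""
    return reads[reads["read_length"] >= min_len]


def _offset_for(read_length: int, offsets: Mapping[int, int] | None,
                default: int = DEFAULT_PSITE_OFFSET) -> int:
    if offsets is None:
        return default
    return offsets.get(int(read_length), default)


def psite(read: Alignment, offsets: Mapping[int, int] | None = None,
          default_offset: int = DEFAULT_PSITE_OFFSET) -> int:
    """P-site transcript offset of one read: 5' end plus the length offset."""
    return read.start + _offset_for(read.read_length, offsets, default_offset)


def _psite_array(reads: pd.DataFrame, offsets: Mapping[int, int] | None,
                 default_offset: int) -> np.ndarray:
    lengths = reads["read_length"].to_numpy()
    off = np.full(lengths.shape, default_offset, dtype=np.int64)
    if offsets:
        for ln, o in offsets.items():
            off[lengths == ln] = o
    return reads["start"].to_numpy() + off


def assign_psites(
    reads: pd.DataFrame,
    txs: TranscriptIndex,
    offsets: Mapping[int, int] | None = None,
    default_offset: int = DEFAULT_PSITE_OFFSET,
) -> pd.DataFrame:
    """P-site and region for every read whose P-site lies on its transcript.

    Returns a frame with columns ``tx_row, psite, region`` (region codes
    0=5'UTR, 1=CDS, 2=3'UTR).  Reads on unknown transcripts or whose
    P-site falls off the transcript end are excluded.
    """
    rows = txs.rows_of(reads["transcript_id"])
    ps = _psite_array(reads, offsets, default_offset)
    ok = rows >= 0
    ok &= (ps >= 0) & (ps < np.where(ok, txs.length[np.where(ok, rows, 0)], 0))
    rows, ps = rows[ok], ps[ok]
    return pd.DataFrame(
        {"tx_row": rows, "psite": ps, "region": txs.regions_at(rows, ps)}
    )


def region_counts(
    reads: pd.DataFrame,
    txs: TranscriptIndex,
    offsets: Mapping[int, int] | None = None,
    default_offset: int = DEFAULT_PSITE_OFFSET,
) -> pd.DataFrame:
    """Per-transcript RPF P-site counts in 5'UTR / CDS / 3'UTR.

    One row per transcript in ``txs`` (zero rows included) with columns
    ``transcript_id, n_utr5, n_cds, n_utr3``.
    """
    ps = assign_psites(reads, txs, offsets, default_offset)
    flat = np.bincount(ps["tx_row"] * 3 + ps["region"], minlength=len(txs) * 3)
    mat = flat.reshape(len(txs), 3)
    return pd.DataFrame(
        {"transcript_id": txs.ids,
         "n_utr5": mat[:, 0], "n_cds": mat[:, 1], "n_utr3": mat[:, 2]}
    )


def rna_counts(reads: pd.DataFrame, txs: TranscriptIndex) -> pd.DataFrame:
    """Per-transcript RNA-seq read counts (a read counts once per transcript)."""
    rows = txs.rows_of(reads["transcript_id"])
    counts = np.bincount(rows[rows >= 0], minlength=len(txs))
    return pd.DataFrame({"transcript_id": txs.ids, "n_reads": counts})


def region_distribution(
    reads: pd.DataFrame,
    txs: TranscriptIndex,
    offsets: Mapping[int, int] | None = None,
    default_offset: int = DEFAULT_PSITE_OFFSET,
) -> dict[str, float]:
    """Percentage of RPF P-sites in each region, over all usable reads."""
    ps = assign_psites(reads, txs, offsets, default_offset)
    n = len(ps)
    if n == 0:
        raise NoUsableReadsError("no reads with a valid P-site")
    counts = np.bincount(ps["region"], minlength=3)
    return {
        "utr5": 100.0 * counts[0] / n,
        "cds": 100.0 * counts[1] / n,
        "utr3": 100.0 * counts[2] / n,
    }


def frame_distribution(
    reads: pd.DataFrame,
    txs: TranscriptIndex,
    offsets: Mapping[int, int] | None = None,
    default_offset: int = DEFAULT_PSITE_OFFSET,
) -> dict[int, float]:
    """Percentage of CDS P-sites in each reading frame relative to the start.

    Frame 0 ("correct frame") means the P-site is in phase with the
    annotated start codon: ``(psite - cds_start) % 3 == 0``.
    """
    ps = assign_psites(reads, txs, offsets, default_offset)
    in_cds = ps[ps["region"] == 1]
    n = len(in_cds)
    if n == 0:
        raise NoUsableReadsError("no reads with a P-site in a CDS")
    frames = (in_cds["psite"].to_numpy() - txs.cds_start[in_cds["tx_row"]]) % 3
    counts = np.bincount(frames, minlength=3)
    return {f: 100.0 * counts[f] / n for f in (0, 1, 2)}


def length_histogram(reads: pd.DataFrame) -> dict[int, int]:
    """Exact multiset histogram of read lengths."""
    vc = reads["read_length"].value_counts().sort_index()
    return {int(k): int(v) for k, v in vc.items()}


def rpkm(count, feature_len, lib_size):
    """Reads per kilobase of feature per million library reads.

    Accepts scalars or arrays; ``feature_len`` and ``lib_size`` must be
    positive.
    """
    feature_len = np.asarray(feature_len, dtype=float)
    lib_size_arr = np.asarray(lib_size, dtype=float)
    if np.any(feature_len <= 0):
        raise ValueError("feature_len must be > 0")
    if np.any(lib_size_arr <= 0):
        raise ValueError("lib_size must be > 0")
    out = np.asarray(count, dtype=float) / (feature_len / 1e3) / (lib_size_arr / 1e6)
    return float(out) if out.ndim == 0 else out


def translation_efficiency(ribo_rpkm, rna_fpkm, floor: float = 1.0):
    """TE = CDS RPF RPKM / transcript RNA FPKM; NaN below the mRNA floor."""
    ribo = np.asarray(ribo_rpkm, dtype=float)
    rna = np.asarray(rna_fpkm, dtype=float)
    te = np.where(rna >= floor, ribo / np.where(rna >= floor, rna, 1.0), np.nan)
    return float(te) if te.ndim == 0 else te


def gene_quant(
    models: Sequence[TranscriptModel],
    rpf_reads: Mapping[str, pd.DataFrame],
    rna_reads: Mapping[str, pd.DataFrame],
    offsets: Mapping[int, int] | None = None,
    default_offset: int = DEFAULT_PSITE_OFFSET,
    te_floor: float = 1.0,
    min_read_length: int = DEFAULT_MIN_READ_LENGTH,
) -> pd.DataFrame:
    """Per-gene, per-sample RNA FPKM, CDS RPF RPKM and TE.

    ``rpf_reads`` / ``rna_reads`` map sample id -> alignment frame.  Gene
    values come from the canonical transcript (longest CDS).  Library size
    is the number of length-filtered reads assigned to known transcripts
    in that library.
    """
    canon = canonical_transcripts(models)
    canon_models = sorted(canon.values(), key=lambda m: m.gene_id)
    txs = TranscriptIndex(canon_models)
    cds_len = txs.cds_end - txs.cds_start
    tx_len = txs.length

    if set(rpf_reads) != set(rna_reads):
        raise ValueError(
            "rpf_reads and rna_reads must cover the same samples; "
            f"difference: {set(rpf_reads) ^ set(rna_reads)}"
        )
    records = []
    samples = sorted(rpf_reads)
    for sample in samples:
        rpf = filter_reads(rpf_reads[sample], min_read_length)
        rna = filter_reads(rna_reads[sample], min_read_length)
        rpf_lib = int((txs.rows_of(rpf["transcript_id"]) >= 0).sum())
        rna_lib = int((txs.rows_of(rna["transcript_id"]) >= 0).sum())
        rc = region_counts(rpf, txs, offsets, default_offset)
        nc = rna_counts(rna, txs)
        ribo = rpkm(rc["n_cds"].to_numpy(), cds_len, max(rpf_lib, 1))
        mrna = rpkm(nc["n_reads"].to_numpy(), tx_len, max(rna_lib, 1))
        te = translation_efficiency(ribo, mrna, te_floor)
        records.append(
            pd.DataFrame(
                {
                    "gene_id": txs.gene_id,
                    "transcript_id": txs.ids,
                    "sample_id": sample,
                    "rna_fpkm": mrna,
                    "ribo_rpkm": ribo,
                    "te": te,
                }
            )
        )
    return pd.concat(records, ignore_index=True)
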