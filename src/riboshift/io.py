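"""Reading and writing transcript-space alignments.

Alignments are kept as pandas DataFrames with columns
``transcript_id, start, read_length`` (0-based transcript start).  Two
on-disk forms are supported: a minimal three-column TSV, and SAM/BAM in
transcript space (reference = transcript), read through pysam.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .annotation import TranscriptModel

ALN_COLUMNS = ["transcript_id", "start", "read_length"]

__all__ = [
    "ALN_COLUMNS",
    "read_alignments",
    "read_alignments_tsv",
    "read_alignments_sam",
    "write_alignments_tsv",
    "write_alignments_sam",
    "empty_alignments",
]


def empty_alignments() -> pd.DataFrame:
    return pd.DataFrame(
        {"transcript_id": pd.Series(dtype=object),
         "start": pd.Series(dtype=np.int64),
         "read_length": pd.Series(dtype=np.int64)}
    )


def read_alignments_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"transcript_id": str})
    missing = [c for c in ALN_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing alignment columns {missing}")
    return df[ALN_COLUMNS].astype({"start": np.int64, "read_length": np.int64})


def read_alignments_sam(path: str | Path) -> pd.DataFrame:
    """Read mapped reads from a transcript-space SAM/BAM file."""
    import pysam

    rows_tx, rows_start, rows_len = [], [], []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh.fetch(until_eof=True):
            if rec.is_unmapped:
                continue
            rows_tx.append(rec.reference_name)
            rows_start.append(rec.reference_start)
            rows_len.append(rec.query_length or rec.infer_read_length() or 0)
    return pd.DataFrame(
        {"transcript_id": rows_tx,
         "start": np.asarray(rows_start, dtype=np.int64),
         "read_length": np.asarray(rows_len, dtype=np.int64)}
    )


def read_alignments(path: str | Path) -> pd.DataFrame:
    suffix = Path(path).suffix.lower()
    if suffix in (".sam", ".bam"):
        return read_alignments_sam(path)
    return read_alignments_tsv(path)


def write_alignments_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df[ALN_COLUMNS].to_csv(path, sep="\t", index=False)


def write_alignments_sam(
    df: pd.DataFrame, models: Sequence[TranscriptModel], path: str | Path
) -> None:
    """Write alignments as plain-text SAM with one @SQ line per transcript."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": m.transcript_id, "LN": m.length} for m in models],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        tid = {m.transcript_id: i for i, m in enumerate(models)}
        for i, (tx, start, length) in enumerate(
            zip(df["transcript_id"], df["start"], df["read_length"])
        ):
            rec = pysam.AlignedSegment(out.header)
            rec.query_name = f"r{i}"
            rec.reference_id = tid[tx]
            rec.reference_start = int(start)
            rec.mapping_quality = 255
            rec.cigarstring = f"{int(length)}M"
            rec.query_sequence = "N" * int(length)
            rec.flag = 0
            out.write(rec)
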