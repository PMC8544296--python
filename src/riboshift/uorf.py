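"""Upstream ORF detection, start-context scoring and 5'UTR->CDS shift scores.

A uORF is any AUG upstream of the annotated start codon, paired with the
first in-frame stop (UAA/UAG/UGA) found scanning 3' through the whole
transcript; a uORF whose stop lies past the annotated start (or that has
no stop at all) overlaps the CDS, the configuration that represses
main-ORF translation under the delayed-reinitiation model.

Start-codon strength uses the classical two-position Kozak rule: a purine
at -3 and a G at +4 (first base after the AUG) give a strong context,
one of the two an adequate context, neither a weak one.

The shift score quantifies ribosome density moving out of the 5'UTR into
the CDS between conditions:

    log2_shift = log2((n_cds + pc) / (n_utr5 + pc))_treat
               - log2((n_cds + pc) / (n_utr5 + pc))_ctrl

A positive value is the signature of uORF bypass and translational
induction under stress.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import TranscriptModel

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
PURINES = frozenset("AG")

__all__ = [
    "UORF",
    "ShiftScore",
    "find_uorfs",
    "kozak_score",
    "cap_distance",
    "shift_score",
    "shift_table",
]


@dataclass(frozen=True)
class UORF:
    transcript_id: str
    uaug_pos: int
    stop_pos: int | None  # one past the stop codon; None = no in-frame stop
    overlaps_cds: bool
    kozak: str  # strong | adequate | weak
    cap_distance: int

    @property
    def length(self) -> int | None:
        """uORF length in nt including the stop codon; None without a stop."""
        return None if self.stop_pos is None else self.stop_pos - self.uaug_pos


def _normalise(seq: str) -> str:
    return seq.upper().replace("U", "T")


def kozak_score(sequence: str, uaug_pos: int) -> str:
    """Ordinal Kozak context of an AUG: purine at -3 and G at +4 = strong.

    Position +4 is the first base after the AUG (A of AUG = +1).  A
    flanking position that runs off the sequence counts as not satisfying
    its condition.
    """
    seq = _normalise(sequence)
    minus3 = seq[uaug_pos - 3] if uaug_pos >= 3 else None
    plus4 = seq[uaug_pos + 3] if uaug_pos + 3 < len(seq) else None
    good = (minus3 in PURINES if minus3 else False) + (plus4 == "G")
    return ("weak", "adequate", "strong")[good]


def find_uorfs(tx: TranscriptModel) -> list[UORF]:
    """All AUG-initiated uORFs upstream of the annotated start codon.

    Every AUG with position < cds_start is reported, paired with the
    first in-frame stop anywhere downstream in the transcript; output is
    sorted by position.  Identical for T- and U-containing sequences.
    """
    if tx.sequence is None:
        raise ValueError(f"{tx.transcript_id}: sequence required for uORF detection")
    if tx.cds_start == 0:
        return []
    seq = _normalise(tx.sequence)
    if re.search("[^ACGT]", seq):
        warnings.warn(
            f"{tx.transcript_id}: non-ACGT/U characters present; "
            "codons containing them are ignored"
        )
    out: list[UORF] = []
    for m in re.finditer("ATG", seq):
        pos = m.start()
        if pos >= tx.cds_start:
            break
        stop_pos: int | None = None
        for i in range(pos + 3, len(seq) - 2, 3):
            if seq[i : i + 3] in STOP_CODONS:
                stop_pos = i + 3
                break
        overlaps = stop_pos is None or stop_pos > tx.cds_start
        out.append(
            UORF(
                transcript_id=tx.transcript_id,
                uaug_pos=pos,
                stop_pos=stop_pos,
                overlaps_cds=overlaps,
                kozak=kozak_score(seq, pos),
                cap_distance=pos,
            )
        )
    return out


def cap_distance(uorf: UORF) -> int:
    """Distance in nt from the transcript 5' end (cap) to the uAUG."""
    return uorf.uaug_pos


@dataclass(frozen=True)
class ShiftScore:
    transcript_id: str
    ratio_ctrl: float
    ratio_treat: float
    log2_shift: float


def shift_score(
    counts_ctrl: pd.Series | dict,
    counts_treat: pd.Series | dict,
    pseudocount: float = 1.0,
) -> ShiftScore:
    """CDS:5'UTR RPF ratio in each condition and its log2 change.

    ``counts_*`` carry n_utr5 / n_cds (and transcript_id) for the same
    transcript; the pseudocount keeps both ratios finite.
    """
    tx_c = counts_ctrl.get("transcript_id", "")
    tx_t = counts_treat.get("transcript_id", "")
    if tx_c and tx_t and tx_c != tx_t:
        raise ValueError(f"condition counts refer to different transcripts: {tx_c} vs {tx_t}")
    r_ctrl = (counts_ctrl["n_cds"] + pseudocount) / (counts_ctrl["n_utr5"] + pseudocount)
    r_treat = (counts_treat["n_cds"] + pseudocount) / (counts_treat["n_utr5"] + pseudocount)
    return ShiftScore(
        transcript_id=tx_c or tx_t,
        ratio_ctrl=float(r_ctrl),
        ratio_treat=float(r_treat),
        log2_shift=float(np.log2(r_treat) - np.log2(r_ctrl)),
    )


def shift_table(
    counts_ctrl: pd.DataFrame, counts_treat: pd.DataFrame, pseudocount: float = 1.0
) -> pd.DataFrame:
    """Vectorised shift scores for all transcripts present in both conditions."""
    a = counts_ctrl.set_index("transcript_id")
    b = counts_treat.set_index("transcript_id")
    common = a.index.intersection(b.index)
    dropped = len(a.index.union(b.index)) - len(common)
    if dropped:
        warnings.warn(f"shift_table: {dropped} transcripts absent in one condition, skipped")
    rc = (a.loc[common, "n_cds"] + pseudocount) / (a.loc[common, "n_utr5"] + pseudocount)
    rt = (b.loc[common, "n_cds"] + pseudocount) / (b.loc[common, "n_utr5"] + pseudocount)
    return pd.DataFrame(
        {
            "transcript_id": common,
            "ratio_ctrl": rc.to_numpy(),
            "ratio_treat": rt.to_numpy(),
            "log2_shift": np.log2(rt.to_numpy()) - np.log2(rc.to_numpy()),
        }
    )
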