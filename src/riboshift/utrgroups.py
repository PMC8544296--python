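"""5'UTR occupancy index and the group analyses built on it.

The 5'UTR index of a transcript is the fraction of its RPF reads that
fall in the 5'UTR.  Only transcripts with at least one 5'UTR read enter
the analysis.  Two group views are provided:

* the change in 5'UTR index (treatment - control) compared across
  TE classes (up / unchanged / down) with a one-way ANOVA;
* a median split of transcripts into high_UTR / low_UTR halves by control
  5'UTR index, comparing the log2 TE change between halves with a
  two-sample t-test.

Under uORF-mediated translational induction the translationally
up-regulated class loses 5'UTR density, and the high_UTR half gains more
TE than the low_UTR half.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "GroupComparison",
    "utr5_index",
    "utr5_index_change",
    "split_high_low",
    "compare_groups",
]


@dataclass(frozen=True)
class GroupComparison:
    """Result of a classical multi-group location test."""

    test: str
    statistic: float
    pvalue: float
    group_sizes: tuple[int, ...]
    degenerate: bool = False


def utr5_index(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-transcript 5'UTR index from RPF region counts.

    ``counts`` has columns transcript_id, n_utr5, n_cds, n_utr3 (one
    condition or sample).  Transcripts with zero total reads are skipped
    with a log notice; transcripts with zero 5'UTR reads are excluded by
    the selection rule.
    """
    total = (counts["n_utr5"] + counts["n_cds"] + counts["n_utr3"]).to_numpy()
    n_zero = int((total == 0).sum())
    if n_zero:
        logger.info("utr5_index: skipping %d transcripts with zero reads", n_zero)
    keep = counts["n_utr5"].to_numpy() > 0
    sub = counts.loc[keep]
    sub_total = total[keep]
    return pd.DataFrame(
        {
            "transcript_id": sub["transcript_id"].to_numpy(),
            "utr5_reads": sub["n_utr5"].to_numpy(),
            "total_reads": sub_total,
            "utr5_index": sub["n_utr5"].to_numpy() / sub_total,
        }
    )


def utr5_index_change(
    counts_ctrl: pd.DataFrame, counts_treat: pd.DataFrame
) -> pd.DataFrame:
    """Per-transcript index in each condition and its change (treat - ctrl).

    Transcripts must satisfy the >0 5'UTR-read rule in both conditions.
    """
    a = utr5_index(counts_ctrl).set_index("transcript_id")
    b = utr5_index(counts_treat).set_index("transcript_id")
    common = a.index.intersection(b.index)
    return pd.DataFrame(
        {
            "transcript_id": common,
            "utr5_index_ctrl": a.loc[common, "utr5_index"].to_numpy(),
            "utr5_index_treat": b.loc[common, "utr5_index"].to_numpy(),
            "delta_utr5_index": (
                b.loc[common, "utr5_index"] - a.loc[common, "utr5_index"]
            ).to_numpy(),
        }
    )


def split_high_low(records: pd.DataFrame, column: str = "utr5_index") -> pd.DataFrame:
    """Median split into equal low_UTR / high_UTR halves.

    Records are ordered by (index, transcript_id); the lower ceil(n/2)
    go to low_UTR, so records tied at the median fall to low_UTR first.
    Group sizes differ by at most 1.
    """
    if len(records) < 2:
        raise ValueError("need at least 2 records to split")
    vals = records[column].to_numpy()
    if np.all(vals == vals[0]):
        raise ValueError("all indices identical; high/low split is meaningless")
    order = np.lexsort((records["transcript_id"].to_numpy(), vals))
    n_low = (len(records) + 1) // 2
    group = np.empty(len(records), dtype=object)
    group[order[:n_low]] = "low_UTR"
    group[order[n_low:]] = "high_UTR"
    out = records.copy()
    out["group"] = group
    return out


def compare_groups(groups: dict[str, np.ndarray], test: str = "anova") -> GroupComparison:
    """Classical location test across groups.

    ``test`` is 'anova' (one-way, any number of groups), 't_test'
    (two groups, equal-variance by default), 'welch' or 'mannwhitney'.
    If every value across all groups is identical the comparison is
    degenerate: statistic/p-value are NaN and the result is flagged.
    """
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    for name, arr in zip(groups, arrays):
        if arr.size == 0:
            raise ValueError(f"group {name!r} is empty")
        if test in ("anova", "t_test", "welch") and arr.size < 2:
            raise ValueError(f"group {name!r} has < 2 values for a variance-based test")
    sizes = tuple(a.size for a in arrays)
    allvals = np.concatenate(arrays)
    if np.all(allvals == allvals[0]):
        return GroupComparison(test, float("nan"), float("nan"), sizes, degenerate=True)
    if test == "anova":
        stat, p = stats.f_oneway(*arrays)
    elif test in ("t_test", "welch"):
        if len(arrays) != 2:
            raise ValueError("t-test requires exactly 2 groups")
        stat, p = stats.ttest_ind(arrays[0], arrays[1], equal_var=(test == "t_test"))
    elif test == "mannwhitney":
        if len(arrays) != 2:
            raise ValueError("Mann-Whitney requires exactly 2 groups")
        stat, p = stats.mannwhitneyu(arrays[0], arrays[1], alternative="two-sided")
    else:
        raise ValueError(f"unknown test {test!r}")
    return GroupComparison(test, float(stat), float(p), sizes)
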