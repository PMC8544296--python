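"""Three-way differential calls at the mRNA, ribosome-footprint and TE levels.

With two biological replicates per condition there is little power for
per-gene inference, so the default classifier is a fold-change rule on
condition means: a gene is ``up`` when log2(treatment/control) >= theta,
``down`` when <= -theta, ``unchanged`` otherwise, and ``not_assessed``
when it fails the expression floor in both conditions (TE level: when TE
is undefined in either condition).  An optional two-sample t-test on log
values is provided for volcano-style output but never gates the call.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

LEVELS = ("rna", "ribo", "te")
CLASSES = ("up", "unchanged", "down", "not_assessed")

_LEVEL_COLUMN = {"rna": "rna_fpkm", "ribo": "ribo_rpkm", "te": "te"}

__all__ = ["LEVELS", "CLASSES", "classify", "te_change", "summary_counts", "log_t_test"]


def te_change(te_treat: float, te_ctrl: float) -> float:
    """log2 TE ratio treatment/control; NaN propagates (undefined TE)."""
    te_treat = float(te_treat)
    te_ctrl = float(te_ctrl)
    if np.isnan(te_treat) or np.isnan(te_ctrl):
        return float("nan")
    with np.errstate(divide="ignore", invalid="ignore"):
        return float(np.log2(te_treat) - np.log2(te_ctrl))


def classify(
    quants: pd.DataFrame,
    conditions: Mapping[str, str],
    level: str,
    control: str,
    treatment: str,
    theta: float = 1.0,
    floor: float = 1.0,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Classify every gene as up / unchanged / down / not_assessed.

    Parameters
    ----------
    quants
        Long gene-quant table (gene_id, sample_id, rna_fpkm, ribo_rpkm, te).
    conditions
        sample_id -> condition name.
    level
        'rna' (transcription), 'ribo' (translation) or 'te'.
    theta
        log2 fold-change threshold (default 1 = 2-fold).
    floor
        Expression floor on the level's condition means; genes below it in
        both conditions are not assessed.
    pseudocount
        Added to both condition means before the ratio (rna/ribo levels
        only; the TE level uses the raw TE ratio).
    """
    if level not in LEVELS:
        raise ValueError(f"level must be one of {LEVELS}")
    col = _LEVEL_COLUMN[level]
    df = quants.copy()
    df["condition"] = df["sample_id"].map(conditions)
    if df["condition"].isna().any():
        missing = df.loc[df["condition"].isna(), "sample_id"].unique().tolist()
        raise ValueError(f"samples without a condition label: {missing}")
    for cond in (control, treatment):
        if cond not in set(df["condition"]):
            raise ValueError(f"condition {cond!r} absent from the sample sheet")

    means = (
        df[df["condition"].isin([control, treatment])]
        .groupby(["gene_id", "condition"], sort=True)[col]
        .mean()
        .unstack("condition")
    )
    mean_ctrl = means[control]
    mean_treat = means[treatment]

    if level == "te":
        assessed = mean_ctrl.notna() & mean_treat.notna()
        with np.errstate(divide="ignore", invalid="ignore"):
            log2fc = np.log2(mean_treat) - np.log2(mean_ctrl)
    else:
        assessed = (mean_ctrl >= floor) | (mean_treat >= floor)
        log2fc = np.log2(mean_treat + pseudocount) - np.log2(mean_ctrl + pseudocount)

    cls = np.where(
        ~assessed,
        "not_assessed",
        np.where(log2fc >= theta, "up", np.where(log2fc <= -theta, "down", "unchanged")),
    )
    out = pd.DataFrame(
        {
            "gene_id": means.index,
            "level": level,
            "mean_ctrl": mean_ctrl.to_numpy(),
            "mean_treat": mean_treat.to_numpy(),
            "log2fc": np.where(assessed, log2fc, np.nan),
            "class": cls,
            "passed_floor": assessed.to_numpy(),
        }
    ).reset_index(drop=True)
    return out


def summary_counts(calls: pd.DataFrame) -> dict[str, int]:
    """Class tallies for one classification table."""
    vc = calls["class"].value_counts()
    return {c: int(vc.get(c, 0)) for c in CLASSES}


def log_t_test(
    quants: pd.DataFrame,
    conditions: Mapping[str, str],
    level: str,
    control: str,
    treatment: str,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-gene two-sample t-test on log2 values (volcano output only)."""
    col = _LEVEL_COLUMN[level]
    df = quants.copy()
    df["condition"] = df["sample_id"].map(conditions)
    rows = []
    for gene, g in df.groupby("gene_id", sort=True):
        a = np.log2(g.loc[g["condition"] == treatment, col].to_numpy() + pseudocount)
        b = np.log2(g.loc[g["condition"] == control, col].to_numpy() + pseudocount)
        if len(a) < 2 or len(b) < 2 or np.isnan(a).any() or np.isnan(b).any():
            t, p = np.nan, np.nan
        else:
            t, p = stats.ttest_ind(a, b, equal_var=True)
        rows.append((gene, t, p))
    return pd.DataFrame(rows, columns=["gene_id", "t", "p"])
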