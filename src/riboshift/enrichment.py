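"""Generic over-representation analysis (ORA) against user-supplied gene sets.

For a query of n genes drawn from a universe of N genes, a set with K
members in the universe and k hits in the query is scored with the
upper-tail hypergeometric probability P(X >= k); Benjamini-Hochberg
step-up adjustment is applied across all tested sets.  Gene sets are read
from GMT files; no ontology data ships with the package.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = ["GeneSet", "read_gmt", "write_gmt", "ora"]


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    members: frozenset[str]
    description: str = ""

    def __post_init__(self):
        if not self.members:
            raise ValueError(f"gene set {self.set_id!r} has no members")


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read gene sets from GMT (set id, description, members, tab-separated)."""
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >= 3 fields")
            members = frozenset(g for g in fields[2:] if g)
            if not members:
                raise ValueError(f"{path}:{lineno}: gene set {fields[0]!r} is empty")
            sets.append(GeneSet(fields[0], members, fields[1]))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.set_id, s.description, *sorted(s.members)]) + "\n")


def ora(
    query: Sequence[str],
    sets: Sequence[GeneSet] | Mapping[str, Iterable[str]],
    universe: Sequence[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each gene set.

    Duplicate ids are collapsed; the query is intersected with the
    universe, and each set's K is its overlap with the universe.  Sets
    with no universe overlap are not tested.  Results are sorted by raw
    p-value, with BH-adjusted values in ``fdr``.
    """
    uni = set(universe)
    q = set(query) & uni
    if not uni:
        raise ValueError("empty universe")
    if not set(query):
        raise ValueError("empty query")
    if not q:
        raise ValueError("query has no genes in the universe")
    if isinstance(sets, Mapping):
        sets = [GeneSet(sid, frozenset(m)) for sid, m in sets.items()]

    N, n = len(uni), len(q)
    rows = []
    for s in sets:
        members = s.members & uni
        K = len(members)
        if K == 0:
            continue
        k = len(members & q)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append((s.set_id, k, n, K, N, min(p, 1.0)))
    if not rows:
        return pd.DataFrame(columns=["set_id", "k", "n", "K", "N", "p", "fdr"])
    out = pd.DataFrame(rows, columns=["set_id", "k", "n", "K", "N", "p"])
    out["fdr"] = multipletests(out["p"], method="fdr_bh")[1]
    return out.sort_values(["p", "set_id"], kind="mergesort").reset_index(drop=True)
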