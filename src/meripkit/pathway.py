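"""Hypergeometric over-representation of gene lists against gene sets.

The universe defaults to the genes that carry a tested consensus peak
(conditioning on detectability) rather than the whole annotation; the
p-value for a set with ``K`` members, query size ``n`` and overlap ``k``
is the exact upper tail P(X >= k) of Hypergeometric(N, K, n), corrected
across sets by Benjamini-Hochberg.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import read_gmt


@dataclass
class GeneSetCollection:
    """Named gene sets harmonized against a gene universe."""

    sets: dict[str, set[str]]
    universe: set[str]

    def __post_init__(self) -> None:
        if any(not name for name in self.sets):
            raise ValueError("empty gene-set name")
        self.sets = {name: set(genes) & self.universe
                     for name, genes in self.sets.items()}

    @classmethod
    def from_gmt(cls, path: str | Path, universe: Iterable[str]) -> "GeneSetCollection":
        return cls(read_gmt(path), set(universe))


def hypergeom_enrich(query: Iterable[str],
                     collection: GeneSetCollection) -> pd.DataFrame:
    """Exact over-representation test of ``query`` against every set.

    Query genes outside the universe are dropped with a warning. Returns
    a frame sorted by p with columns set_name, k, K, n, N, p, q.
    """
    query = set(query)
    outside = query - collection.universe
    if outside:
        warnings.warn(f"{len(outside)} query genes outside the universe dropped")
        query &= collection.universe
    if not query:
        raise ValueError("empty query after harmonization")
    N, n = len(collection.universe), len(query)
    rows = []
    for name, members in collection.sets.items():
        K = len(members)
        k = len(query & members)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((name, k, K, n, N, min(p, 1.0)))
    df = pd.DataFrame(rows, columns=["set_name", "k", "K", "n", "N", "p"])
    if len(df):
        df["q"] = multipletests(df["p"], method="fdr_bh")[1]
    else:
        df["q"] = []
    return df.sort_values("p", kind="stable").reset_index(drop=True)
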