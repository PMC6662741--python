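"""Over-representation analysis against gene-set collections.

A generic hypergeometric ORA stand-in for commercial pathway tools: the
knowledge base is an input (GMT), the statistic is the one-sided
hypergeometric tail, and multiplicity is handled by Benjamini-Hochberg.
The background universe defaults to all identified proteins, the standard
choice for proteomics enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets restricted to a background universe.

    Sets are intersected with the background on construction; sets that
    become empty are dropped.
    """

    sets: Mapping[str, frozenset[str]]
    background: frozenset[str]

    @classmethod
    def from_dict(
        cls, sets: Mapping[str, Iterable[str]], background: Iterable[str]
    ) -> "GeneSetCollection":
        bg = frozenset(g.upper() for g in background)
        restricted = {
            name: frozenset(g.upper() for g in genes) & bg for name, genes in sets.items()
        }
        return cls(
            sets={n: s for n, s in restricted.items() if s},
            background=bg,
        )


def ora_test(
    query: Iterable[str], target: Iterable[str], background: Iterable[str]
) -> float:
    """One-sided hypergeometric tail probability P(overlap >= observed).

    ``query`` must be contained in ``background``; the target set is
    restricted to the background before testing.
    """
    bg = {g.upper() for g in background}
    q = {g.upper() for g in query}
    if not q <= bg:
        raise ValueError("query gene set must be a subset of the background")
    t = {g.upper() for g in target} & bg
    k = len(q & t)
    # survival function at k-1 gives P(X >= k)
    return float(hypergeom.sf(k - 1, len(bg), len(t), len(q)))


def enrich_collection(
    query: Iterable[str], collection: GeneSetCollection
) -> pd.DataFrame:
    """ORA over every set in the collection with BH-adjusted q-values.

    Rows sorted by ascending p, ties broken by set name; output is invariant
    to the iteration order of the collection.
    """
    q = {g.upper() for g in query}
    names = sorted(collection.sets)
    rows = []
    for name in names:
        target = collection.sets[name]
        overlap = q & target
        p = ora_test(q, target, collection.background)
        rows.append(
            {
                "set": name,
                "size": len(target),
                "overlap": len(overlap),
                "p": p,
                "members": ";".join(sorted(overlap)),
            }
        )
    df = pd.DataFrame(rows, columns=["set", "size", "overlap", "p", "members"])
    if len(df):
        df["q"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    else:
        df["q"] = pd.Series(dtype=float)
    df = df[["set", "size", "overlap", "p", "q", "members"]]
    return df.sort_values(["p", "set"], kind="mergesort").reset_index(drop=True)
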