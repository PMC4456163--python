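"""Over-representation analysis of a gene list against named gene sets.

One-sided hypergeometric upper-tail test per set, Benjamini-Hochberg across
sets.  Gene sets are read from and written to the tab-separated GMT dialect
(name, description, members...).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust


@dataclass
class GeneSetCollection:
    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def restrict(self, universe: set[str]) -> "GeneSetCollection":
        return GeneSetCollection(
            sets={name: members & universe for name, members in self.sets.items()},
            descriptions=dict(self.descriptions),
        )


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file; duplicate members within a set are deduplicated."""
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields")
            name, desc, *members = fields
            if not name:
                raise ValueError(f"{path}:{lineno}: empty set name")
            sets[name] = set(members)
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name in collection.sets:
            desc = collection.descriptions.get(name, "")
            members = sorted(collection.sets[name])
            fh.write("\t".join([name, desc, *members]) + "\n")


def ora(query_ids, collection: GeneSetCollection, universe) -> pd.DataFrame:
    """Hypergeometric over-representation of the query in each set.

    With universe size N, set size K, query size n and overlap x the p-value
    is P(X >= x) for X ~ Hypergeometric(N, K, n); BH-adjusted across sets.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query = set(query_ids) & universe
    restricted = collection.restrict(universe)
    N, n = len(universe), len(query)
    rows = []
    for name, members in restricted.sets.items():
        K = len(members)
        x = len(query & members)
        p = float(stats.hypergeom.sf(x - 1, N, K, n))
        rows.append((name, K, x, min(1.0, p)))
    df = pd.DataFrame(rows, columns=["set", "size", "overlap", "p"]).set_index("set")
    df["padj"] = bh_adjust(df["p"].to_numpy()) if len(df) else []
    return df.sort_values(["p", "set"])
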