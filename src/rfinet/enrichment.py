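"""Hypergeometric over-representation analysis (ORA) against GMT gene sets."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from rfinet.diffexpr import bh_adjust


@dataclass
class GeneSetCollection:
    """Named gene sets with descriptions, as read from a GMT file."""

    sets: dict = field(default_factory=dict)          # name -> frozenset of gene ids
    descriptions: dict = field(default_factory=dict)  # name -> description

    def __len__(self):
        return len(self.sets)

    def add(self, name: str, members, description: str = "") -> None:
        members = frozenset(members)
        if not members:
            raise ValueError(f"gene set {name!r} is empty")
        self.sets[name] = members
        self.descriptions[name] = description


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file (name <TAB> description <TAB> member ...)."""
    coll = GeneSetCollection()
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:60]!r}")
            coll.add(parts[0], [g for g in parts[2:] if g], parts[1])
    return coll


def write_gmt(coll: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name in coll.sets:
            members = "\t".join(sorted(coll.sets[name]))
            fh.write(f"{name}\t{coll.descriptions.get(name, '')}\t{members}\n")


def ora_hypergeometric(
    query,
    sets: GeneSetCollection,
    universe,
    fdr_threshold: float = 0.10,
) -> pd.DataFrame:
    """Hypergeometric upper-tail over-representation test for a gene list.

    For each set, with N = |universe|, K = |set & universe|, n = |query| and
    k = |query & set|, p = P(X >= k) for X ~ Hypergeom(N, K, n).  Sets with
    fewer than 2 members in the universe are skipped.  Query genes outside the
    universe are dropped with a warning.  BH adjustment is across tested sets;
    rows are sorted by (q, p, name) and flagged ``significant`` at
    ``fdr_threshold``.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("universe must be nonempty")
    query = set(query)
    stray = query - universe
    if stray:
        warnings.warn(f"ora: {len(stray)} query genes outside the universe dropped")
        query &= universe
    if not query:
        warnings.warn("ora: empty query, no enrichment computed")
        return _empty_result()

    N, n = len(universe), len(query)
    rows = []
    for name, members in sets.sets.items():
        in_universe = members & universe
        K = len(in_universe)
        if K < 2:
            continue
        k = len(query & in_universe)
        # P(X >= k), exact hypergeometric upper tail
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        p = min(max(p, np.finfo(float).tiny), 1.0)
        rows.append((name, sets.descriptions.get(name, ""), N, K, n, k, p))
    if not rows:
        return _empty_result()
    df = pd.DataFrame(
        rows, columns=["set", "description", "N", "K", "n", "k", "pvalue"]
    )
    df["qvalue"] = bh_adjust(df["pvalue"].to_numpy())
    df["significant"] = df["qvalue"] < fdr_threshold
    df = df.sort_values(["qvalue", "pvalue", "set"], kind="mergesort").reset_index(
        drop=True
    )
    return df


def _empty_result() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["set", "description", "N", "K", "n", "k", "pvalue", "qvalue", "significant"]
    )
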