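"""Hypergeometric over-representation analysis of a hit list against GMT sets."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .association import bh_fdr

log = logging.getLogger(__name__)

__all__ = ["GeneSetCollection", "read_gmt", "ora"]


@dataclass
class GeneSetCollection:
    """Named gene sets plus the background universe they are tested against."""

    sets: dict[str, set[str]]
    universe: set[str]


def read_gmt(path, universe=None) -> GeneSetCollection:
    """Parse a GMT file (name, description, members...) into a collection.

    Duplicate members within a line are stored once. ``universe``
    defaults to the union of all set members.
    """
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields"
                )
            name, _desc, *members = fields
            sets[name] = {m for m in members if m}
    if not sets:
        log.warning("GMT file %s contained no gene sets", path)
    uni = set(universe) if universe is not None else set().union(*sets.values()) if sets else set()
    return GeneSetCollection(sets=sets, universe=uni)


def ora(
    hits,
    collection: GeneSetCollection,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation test per gene set.

    p = P[X >= k] drawing n hits from a universe of N genes of which K
    belong to the set (overlaps restricted to the universe; hits outside
    it are dropped with a logged count). BH q across all sets tested.
    """
    if not collection.universe:
        raise ValueError("empty universe")
    universe = collection.universe
    hits = set(hits)
    outside = hits - universe
    if outside:
        log.info("%d hit genes outside the universe dropped", len(outside))
    hits &= universe
    N, n = len(universe), len(hits)
    rows = []
    for name, members in collection.sets.items():
        in_uni = members & universe
        K = len(in_uni)
        k = len(in_uni & hits)
        # survival function at k-1 gives P[X >= k]
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append((name, K, k, n, N, min(p, 1.0)))
    out = pd.DataFrame(
        rows, columns=["set_name", "genes_in_group", "overlap", "hits", "universe", "p"]
    )
    out["q"] = bh_fdr(out["p"].to_numpy()) if len(out) else []
    out["significant"] = out["q"] < q_threshold
    return out.sort_values(["p", "set_name"], kind="stable").reset_index(drop=True)
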