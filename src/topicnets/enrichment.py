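"""Hypergeometric gene-set enrichment of topic genes.

For a query gene set against each set of a GMT collection, the p-value is
the upper-tail hypergeometric probability of observing at least the overlap
by chance given the background universe; p-values are Benjamini-Hochberg
adjusted and sets with adjusted p below the cutoff (default 0.01) are
flagged enriched. The reported ratio is overlap divided by set size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named gene sets over a background universe of gene symbols."""

    sets: dict[str, set[str]]
    universe: set[str]

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            extra = members - self.universe
            if extra:
                raise ValueError(f"gene set {name!r} has members outside the universe: {sorted(extra)[:5]}")


def read_gmt(path: str | Path, universe: set[str] | None = None) -> GeneSetCollection:
    """Read a GMT file (set name, description, members per tab-separated line).

    The background universe defaults to the union of all set members; pass
    ``universe`` (e.g. the corpus vocabulary) to override, in which case set
    members outside it are dropped with a warning.
    """
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            logger.warning("skipping short GMT line: %r", line[:60])
            continue
        name, _desc, *members = fields
        sets[name] = {m.strip().upper() for m in members if m.strip()}
    if not sets:
        raise ValueError(f"no gene sets found in {path}")
    union = set().union(*sets.values())
    if universe is None:
        universe = union
    else:
        universe = {g.upper() for g in universe}
        dropped = union - universe
        if dropped:
            logger.warning("%d gene-set members outside supplied universe dropped", len(dropped))
            sets = {n: m & universe for n, m in sets.items()}
            sets = {n: m for n, m in sets.items() if m}
    return GeneSetCollection(sets=sets, universe=universe)


def enrich(
    query: set[str],
    collection: GeneSetCollection,
    alpha_adj: float = 0.01,
) -> pd.DataFrame:
    """Rank gene sets by hypergeometric over-representation of the query.

    Returns a DataFrame sorted by raw p ascending with columns set_name,
    overlap, set_size, ratio, p, p_adjusted (Benjamini-Hochberg), enriched
    (p_adjusted < alpha_adj) and molecules (the overlapping symbols).
    Query genes outside the universe are dropped with a warning.
    """
    if not query:
        raise ValueError("query gene set is empty")
    if not collection.sets:
        raise ValueError("gene-set collection is empty")
    query = {g.upper() for g in query}
    outside = query - collection.universe
    if outside:
        logger.warning("%d query gene(s) outside the universe dropped", len(outside))
        query -= outside
    if not query:
        raise ValueError("no query genes remain inside the universe")
    M, N = len(collection.universe), len(query)
    rows = []
    for name, members in collection.sets.items():
        overlap = sorted(query & members)
        k, n = len(overlap), len(members)
        p = float(hypergeom.sf(k - 1, M, n, N))  # P(X >= k)
        rows.append(
            {"set_name": name, "overlap": k, "set_size": n,
             "ratio": k / n, "p": p, "molecules": ",".join(overlap)}
        )
    table = pd.DataFrame(rows)
    table["p_adjusted"] = multipletests(table["p"], method="fdr_bh")[1]
    table["enriched"] = table["p_adjusted"] < alpha_adj
    table = table.sort_values(["p", "set_name"], kind="mergesort").reset_index(drop=True)
    return table[["set_name", "overlap", "set_size", "ratio", "p", "p_adjusted", "enriched", "molecules"]]
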