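"""Flat-term over-representation analysis (ORA) with BH correction.

Given a query gene set (typically the core targets) and a term-to-gene
map read from a GMT file, each term is scored by the hypergeometric upper
tail: with a universe of N genes of which K belong to the term, the
probability that a random query of size n overlaps the term in at least k
genes. P values are Benjamini-Hochberg adjusted across all tested terms
and rows are sorted by (p_adj, p_raw, term id) — the term id being the
deterministic tie-break. Selection follows the conventional FDR < 0.05
cutoff (strict) followed by the top 20 rows.

Term collections are treated as flat sets: ontology DAG structure and
pathway hierarchies are deliberately not propagated — the statistic is
the computation here, not the ontology.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from scipy import stats

from statsmodels.stats.multitest import multipletests

from .target_assembly import TargetSet

logger = logging.getLogger(__name__)

__all__ = ["TermMap", "hypergeom_tail", "ora", "select_top"]


@dataclass
class TermMap:
    """Term id -> (name, member genes), plus the gene universe.

    ``universe`` defaults to the union of all term members (the
    "annotated" universe). Every term must be non-empty and contained in
    the universe.
    """

    terms: dict[str, tuple[str, frozenset[str]]]
    universe: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.universe:
            members: set[str] = set()
            for _, genes in self.terms.values():
                members |= genes
            self.universe = frozenset(members)
        for term_id, (_, genes) in self.terms.items():
            if not genes:
                raise ValueError(f"term {term_id} has no members")
            if not genes <= self.universe:
                raise ValueError(f"term {term_id} has members outside the universe")

    @classmethod
    def from_gmt(cls, path: str | Path) -> "TermMap":
        """Read a GMT file: term id, description, then member genes."""
        terms: dict[str, tuple[str, frozenset[str]]] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line.strip():
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    logger.warning("%s line %d: fewer than 3 columns, skipped", path, lineno)
                    continue
                term_id, name = fields[0].strip(), fields[1].strip()
                genes = frozenset(
                    g.strip().upper() for g in fields[2:] if g.strip()
                )
                if genes:
                    terms[term_id] = (name, genes)
        return cls(terms=terms)

    def to_gmt(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for term_id in sorted(self.terms):
                name, genes = self.terms[term_id]
                fh.write("\t".join([term_id, name, *sorted(genes)]) + "\n")


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    N is the universe size, K the term size, n the query size and k the
    observed overlap. Computed via scipy's log-space survival function.
    """
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(K, n)):
        raise ValueError(f"invalid hypergeometric arguments k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return min(max(p, 0.0), 1.0)


def ora(
    query: TargetSet | Iterable[str],
    terms: TermMap,
    universe_mode: str = "annotated",
    custom_universe: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Over-representation of the query in every term with overlap >= 1.

    Returns a DataFrame with columns term_id, name, k, K, n, N, p_raw,
    p_adj and genes (comma-joined sorted overlap), sorted ascending by
    (p_adj, p_raw, term_id). Query genes outside the universe are dropped;
    a query disjoint from the universe yields an empty table with a
    warning.
    """
    if universe_mode == "annotated":
        universe = set(terms.universe)
    elif universe_mode == "custom":
        if custom_universe is None:
            raise ValueError("universe_mode='custom' requires custom_universe")
        universe = {str(g).strip().upper() for g in custom_universe}
    else:
        raise ValueError(f"unknown universe_mode {universe_mode!r}")

    q = {str(g).strip().upper() for g in query} & universe
    columns = ["term_id", "name", "k", "K", "n", "N", "p_raw", "p_adj", "genes"]
    if not q:
        logger.warning("query has no genes in the universe; empty enrichment table")
        return pd.DataFrame(columns=columns)

    n, N = len(q), len(universe)
    rows = []
    for term_id in sorted(terms.terms):
        name, members = terms.terms[term_id]
        members = members & universe
        overlap = members & q
        if not overlap:
            continue
        k, K = len(overlap), len(members)
        rows.append(
            {
                "term_id": term_id,
                "name": name,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "p_raw": hypergeom_tail(k, K, n, N),
                "genes": ",".join(sorted(overlap)),
            }
        )
    if not rows:
        return pd.DataFrame(columns=columns)
    table = pd.DataFrame(rows)
    table["p_adj"] = multipletests(table["p_raw"].to_numpy(), method="fdr_bh")[1]
    table = table.sort_values(
        ["p_adj", "p_raw", "term_id"], kind="mergesort"
    ).reset_index(drop=True)
    return table[columns]


def select_top(table: pd.DataFrame, fdr_max: float = 0.05, top_k: int = 20) -> pd.DataFrame:
    """Rows with p_adj < fdr_max (strict), then the first top_k in order."""
    passed = table[table["p_adj"] < fdr_max]
    return passed.head(top_k).reset_index(drop=True)
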