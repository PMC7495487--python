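"""PPI graph construction, centralities, and the median-threshold hub screen.

The protein-protein interaction network over the composite targets is read
from a STRING-dialect edge list (node, node, combined score on the 0-1000
scale), restricted to the target set, and stripped of unconnected nodes.
Hub ("core") targets are then screened in a single pass by three
topological centralities:

* degree centrality (DC) — number of neighbours;
* betweenness centrality (BC) — Brandes pair-dependency sum, endpoints
  excluded, normalized by 2/((n-1)(n-2));
* closeness centrality (CC) — Wasserman-Faust component-corrected form,
  ((r-1)/(n-1)) * ((r-1)/sum of distances), comparable across components.

A node is a core target when DC >= 2 x median(DC), BC >= median(BC) and
CC >= median(CC), all inclusive, with medians taken over the cleaned
network. Confidence scores gate edges but never weight paths — the
centralities are purely topological.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import networkx as nx
import pandas as pd

from .target_assembly import TargetSet

logger = logging.getLogger(__name__)

__all__ = [
    "ScreenThresholds",
    "load_edges",
    "drop_isolated",
    "centralities",
    "screen_thresholds",
    "screen_core",
    "induced_subgraph",
]

DEFAULT_SCORE_MIN = 400  # STRING "medium confidence"


@dataclass(frozen=True)
class ScreenThresholds:
    """Inclusive lower bounds for the core-target screen."""

    dc_min: float
    bc_min: float
    cc_min: float

    def __post_init__(self) -> None:
        for name, v in (("dc_min", self.dc_min), ("bc_min", self.bc_min), ("cc_min", self.cc_min)):
            if not (v >= 0 and v == v):
                raise ValueError(f"{name} must be finite and non-negative, got {v}")


def _canon(symbol: str) -> str:
    return symbol.strip().upper()


def load_edges(
    path: str | Path,
    restrict_to: TargetSet | Iterable[str] | None = None,
    score_min: int = DEFAULT_SCORE_MIN,
) -> tuple[nx.Graph, list[str]]:
    """Read a STRING-dialect edge list into a simple undirected graph.

    Each line carries two node symbols and optionally a combined score
    (integer 0-1000); an initial header line is auto-detected and skipped.
    Edges are kept only when the score clears ``score_min`` and, if
    ``restrict_to`` is given, both endpoints belong to it (the returned
    graph's node set then equals ``restrict_to``, isolated nodes included).
    Self-loops are dropped; duplicate edges collapse keeping the maximum
    score. Malformed lines are skipped with a line-numbered warning.

    Returns the graph and the list of warnings.
    """
    allowed = None
    if restrict_to is not None:
        allowed = {_canon(s) for s in restrict_to}
    g = nx.Graph()
    if allowed is not None:
        g.add_nodes_from(sorted(allowed))
    warnings: list[str] = []

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 2:
                warnings.append(f"line {lineno}: fewer than 2 columns, skipped")
                continue
            u, v = _canon(fields[0]), _canon(fields[1])
            score = None
            if len(fields) >= 3 and fields[2] != "":
                try:
                    score = int(float(fields[2]))
                except ValueError:
                    if lineno == 1:
                        continue  # header line
                    warnings.append(f"line {lineno}: non-numeric score, skipped")
                    continue
                if not (0 <= score <= 1000):
                    warnings.append(f"line {lineno}: score {score} outside 0-1000, skipped")
                    continue
            if u == v:
                warnings.append(f"line {lineno}: self-loop {u}, dropped")
                continue
            if score is not None and score < score_min:
                continue
            if allowed is not None and (u not in allowed or v not in allowed):
                continue
            if g.has_edge(u, v):
                prev = g[u][v].get("score")
                if score is not None and (prev is None or score > prev):
                    g[u][v]["score"] = score
            else:
                if score is None:
                    g.add_edge(u, v)
                else:
                    g.add_edge(u, v, score=score)
    if g.number_of_edges() == 0:
        warnings.append("edge list yielded zero edges after filtering")
    for w in warnings:
        logger.warning("%s: %s", path, w)
    return g, warnings


def drop_isolated(graph: nx.Graph) -> tuple[nx.Graph, list[str]]:
    """Remove degree-0 nodes; returns the cleaned graph and removed nodes."""
    removed = sorted(nx.isolates(graph))
    g = graph.copy()
    g.remove_nodes_from(removed)
    if removed:
        logger.info("dropped %d unconnected node(s): %s", len(removed), removed)
    return g, removed


def centralities(graph: nx.Graph) -> pd.DataFrame:
    """Compute DC, normalized BC and Wasserman-Faust CC for every node.

    Returns a DataFrame indexed by node (sorted) with columns ``dc``
    (integer degree), ``bc`` and ``cc`` (both in [0, 1]). Requires a
    non-empty graph.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("centralities undefined on an empty graph")
    dc = dict(graph.degree())
    bc = nx.betweenness_centrality(graph, normalized=True)
    cc = nx.closeness_centrality(graph, wf_improved=True)
    nodes = sorted(graph.nodes())
    return pd.DataFrame(
        {
            "dc": [dc[v] for v in nodes],
            "bc": [bc[v] for v in nodes],
            "cc": [cc[v] for v in nodes],
        },
        index=pd.Index(nodes, name="node"),
    )


def screen_thresholds(table: pd.DataFrame) -> ScreenThresholds:
    """Derive the screen's thresholds from centrality medians.

    DC threshold is twice the median degree; BC and CC thresholds are the
    medians themselves. The median of an even count is the midpoint of the
    central pair.
    """
    if len(table) == 0:
        raise ValueError("cannot take medians of an empty centrality table")
    return ScreenThresholds(
        dc_min=2.0 * statistics.median(table["dc"]),
        bc_min=float(statistics.median(table["bc"])),
        cc_min=float(statistics.median(table["cc"])),
    )


def screen_core(table: pd.DataFrame, thresholds: ScreenThresholds) -> TargetSet:
    """Select core targets: dc, bc and cc all at or above their thresholds.

    A single pass over the table — medians are never recomputed on the
    survivors.
    """
    mask = (
        (table["dc"] >= thresholds.dc_min)
        & (table["bc"] >= thresholds.bc_min)
        & (table["cc"] >= thresholds.cc_min)
    )
    survivors = {str(v) for v in table.index[mask]}
    if not survivors:
        logger.warning("core screen retained no nodes")
    return TargetSet(
        label="core",
        symbols=survivors,
        provenance={s: {"ppi-screen"} for s in survivors},
    )


def induced_subgraph(graph: nx.Graph, nodeset: Iterable[str]) -> nx.Graph:
    """Subgraph on ``nodeset`` ∩ graph nodes with all internal edges."""
    keep = {_canon(s) for s in nodeset} & set(graph.nodes())
    return graph.subgraph(keep).copy()
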