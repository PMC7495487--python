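"""Assembly and export of the multipartite display networks.

Three undirected association networks summarize the pipeline for
visualization: Herb-Component-Target (H-C-T), Target-Organ (T-O, built by
:mod:`netpharm.organ_localization`) and Target-Pathway (T-P). Nodes carry
a ``role`` attribute (herb, compound, target, organ or pathway) and edges
may only join adjacent roles (herb-compound, compound-target,
target-organ, target-pathway); a violation is a hard error. Each network
stores a per-network ``degree`` attribute — node prominence in a figure
reflects that figure's own graph, not the PPI graph.

Exports: GraphML plus Cytoscape-importable node/edge TSVs, both
round-tripping losslessly.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ROLES",
    "ALLOWED_ROLE_PAIRS",
    "validate_multipartite",
    "build_hct",
    "build_tp",
    "export",
    "read_graphml",
    "read_tsv_network",
]

ROLES = ("herb", "compound", "target", "organ", "pathway")
ALLOWED_ROLE_PAIRS = frozenset(
    {
        frozenset(("herb", "compound")),
        frozenset(("compound", "target")),
        frozenset(("target", "organ")),
        frozenset(("target", "pathway")),
    }
)


def validate_multipartite(g: nx.Graph) -> None:
    """Check role tags and the adjacent-roles edge constraint; raise on violation."""
    for node, data in g.nodes(data=True):
        role = data.get("role")
        if role not in ROLES:
            raise ValueError(f"node {node!r} has invalid role {role!r}")
    for u, v in g.edges():
        ru, rv = g.nodes[u]["role"], g.nodes[v]["role"]
        if frozenset((ru, rv)) not in ALLOWED_ROLE_PAIRS:
            raise ValueError(f"edge {u}-{v} joins non-adjacent roles {ru}/{rv}")


def _annotate_degrees(g: nx.Graph) -> None:
    for node, deg in g.degree():
        g.nodes[node]["degree"] = int(deg)


def _add_role_node(g: nx.Graph, node: str, role: str) -> None:
    if node in g and g.nodes[node].get("role") != role:
        raise ValueError(
            f"node id {node!r} used with two roles: {g.nodes[node].get('role')} and {role}"
        )
    g.add_node(node, role=role)


def build_hct(
    herb: str,
    compounds: Iterable[str],
    compound_targets: Mapping[str, Iterable[str]],
) -> nx.Graph:
    """Build the Herb-Component-Target network.

    One herb node linked to every compound; each compound linked to its
    targets. A compound with an empty target list keeps its node with a
    warning. Node count is 1 + |compounds| + |targets touched| and edge
    count |compounds| + sum of target-list sizes (target lists are
    per-compound deduplicated sets).
    """
    g = nx.Graph()
    _add_role_node(g, herb, "herb")
    for comp in compounds:
        comp = str(comp)
        _add_role_node(g, comp, "compound")
        g.add_edge(herb, comp)
        targets = sorted({str(t).strip().upper() for t in compound_targets.get(comp, ())})
        if not targets:
            logger.warning("compound %s has an empty target list", comp)
            continue
        for t in targets:
            _add_role_node(g, t, "target")
            g.add_edge(comp, t)
    validate_multipartite(g)
    _annotate_degrees(g)
    return g


def build_tp(core_targets: Iterable[str], enrich_table: pd.DataFrame) -> nx.Graph:
    """Build the Target-Pathway network from an enrichment top table.

    An edge joins a core target and a pathway term iff the target appears
    in that term's overlap gene list. Terms with an empty overlap among
    the core targets never appear.
    """
    core = {str(t).strip().upper() for t in core_targets}
    g = nx.Graph()
    for _, row in enrich_table.iterrows():
        genes = {s for s in str(row["genes"]).split(",") if s} & core
        if not genes:
            continue
        term = str(row["term_id"])
        _add_role_node(g, term, "pathway")
        g.nodes[term]["name"] = str(row.get("name", term))
        for t in sorted(genes):
            _add_role_node(g, t, "target")
            g.add_edge(t, term)
    validate_multipartite(g)
    _annotate_degrees(g)
    return g


def export(
    g: nx.Graph, out_prefix: str | Path, formats: Iterable[str] = ("graphml", "tsv")
) -> dict[str, Path]:
    """Write the network as GraphML and/or Cytoscape-dialect TSVs.

    TSV export produces ``<prefix>.nodes.tsv`` (id, role, degree) and
    ``<prefix>.edges.tsv`` (source, target, interaction), where
    interaction is the sorted role pair, e.g. ``compound-target``.
    """
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    validate_multipartite(g)
    _annotate_degrees(g)
    written: dict[str, Path] = {}
    for fmt in formats:
        if fmt == "graphml":
            path = out_prefix.with_suffix(".graphml")
            nx.write_graphml(g, path)
            written["graphml"] = path
        elif fmt == "tsv":
            nodes_path = out_prefix.parent / (out_prefix.name + ".nodes.tsv")
            edges_path = out_prefix.parent / (out_prefix.name + ".edges.tsv")
            nodes = pd.DataFrame(
                [
                    {"id": n, "role": d["role"], "degree": d["degree"]}
                    for n, d in sorted(g.nodes(data=True))
                ],
                columns=["id", "role", "degree"],
            )
            edges = pd.DataFrame(
                [
                    {
                        "source": u,
                        "target": v,
                        "interaction": "-".join(
                            sorted((g.nodes[u]["role"], g.nodes[v]["role"]))
                        ),
                    }
                    for u, v in sorted(map(lambda e: tuple(sorted(e)), g.edges()))
                ],
                columns=["source", "target", "interaction"],
            )
            nodes.to_csv(nodes_path, sep="\t", index=False)
            edges.to_csv(edges_path, sep="\t", index=False)
            written["nodes_tsv"] = nodes_path
            written["edges_tsv"] = edges_path
        else:
            raise ValueError(f"unknown export format {fmt!r}")
    return written


def read_graphml(path: str | Path) -> nx.Graph:
    """Read back a GraphML export (role and degree attributes preserved)."""
    g = nx.read_graphml(path)
    out = nx.Graph()
    for n, d in g.nodes(data=True):
        out.add_node(str(n), **{k: (int(v) if k == "degree" else v) for k, v in d.items()})
    out.add_edges_from((str(u), str(v)) for u, v in g.edges())
    return out


def read_tsv_network(nodes_path: str | Path, edges_path: str | Path) -> nx.Graph:
    """Reassemble a network from its node/edge TSV export."""
    nodes = pd.read_csv(nodes_path, sep="\t", dtype=str).fillna("")
    edges = pd.read_csv(edges_path, sep="\t", dtype=str)
    g = nx.Graph()
    for _, row in nodes.iterrows():
        g.add_node(str(row["id"]), role=row["role"], degree=int(row["degree"]))
    for _, row in edges.iterrows():
        g.add_edge(str(row["source"]), str(row["target"]))
    return g
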