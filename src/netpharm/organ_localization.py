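"""Tissue-atlas localization of targets and the target-organ network.

Implements the above-average expression rule used with microarray tissue
atlases (BioGPS style): collapse probes to genes by arithmetic mean, then
assign a gene to every tissue whose mean expression strictly exceeds the
gene's overall mean across ALL atlas tissues. The display network is
restricted afterwards to a curated organ panel (by default 17
immune-related organs and tissues), mirroring the compute-then-restrict
order: the overall mean is never taken over the panel alone.

Genes absent from the atlas are carried in an explicit ``missing`` set and
surface in the audit rather than silently disappearing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .target_assembly import TargetSet

logger = logging.getLogger(__name__)

__all__ = [
    "TissueExpression",
    "probe_average",
    "assign_tissues",
    "build_target_organ_network",
    "default_organ_panel",
]


@dataclass
class TissueExpression:
    """Gene x tissue non-negative expression (probe-collapsed means)."""

    values: pd.DataFrame
    missing: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("tissue expression values must be non-negative")
        if self.values.shape[1] < 1:
            raise ValueError("tissue expression needs at least one tissue column")

    @property
    def tissue_panel(self) -> list[str]:
        return [str(t) for t in self.values.columns]


def default_organ_panel() -> list[str]:
    """The bundled 17-organ immune panel (overridable via a panel file)."""
    text = (
        resources.files("netpharm.data")
        .joinpath("immune_organ_panel.txt")
        .read_text()
    )
    return [
        line.strip()
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    ]


def probe_average(
    probe_matrix: pd.DataFrame,
    probe_map: Mapping[str, str],
    query_genes: Iterable[str] | None = None,
) -> TissueExpression:
    """Collapse a probe x tissue matrix to gene level by arithmetic mean.

    ``probe_map`` maps probe ids to gene symbols; probes absent from the
    map are discarded. When ``query_genes`` is given, genes with no probe
    at all are recorded in the result's ``missing`` set (atlas gaps).
    """
    if not probe_map:
        raise ValueError("probe map is empty")
    genes = pd.Series(
        {p: str(g).strip().upper() for p, g in probe_map.items()}, name="gene"
    )
    usable = probe_matrix.index.intersection(genes.index)
    collapsed = probe_matrix.loc[usable].groupby(genes.loc[usable]).mean()
    collapsed.index.name = "gene"
    missing: set[str] = set()
    if query_genes is not None:
        missing = {str(g).strip().upper() for g in query_genes} - set(collapsed.index)
        if missing:
            logger.warning("%d gene(s) absent from the atlas: %s", len(missing), sorted(missing))
    return TissueExpression(values=collapsed, missing=missing)


def assign_tissues(expr: TissueExpression, gene: str) -> set[str]:
    """Tissues where the gene's expression strictly exceeds its overall mean.

    The overall mean runs over every atlas tissue. Genes in the ``missing``
    set yield the empty set (with an audit log entry); genes unknown to the
    atlas entirely raise ``KeyError``.
    """
    gene = str(gene).strip().upper()
    if gene in expr.missing:
        logger.info("gene %s has no atlas profile; assigned to no tissue", gene)
        return set()
    if gene not in expr.values.index:
        raise KeyError(f"gene {gene} not present in the tissue atlas")
    row = expr.values.loc[gene]
    return {str(t) for t, v in row.items() if v > row.mean()}


def build_target_organ_network(
    expr: TissueExpression,
    targets: TargetSet | Iterable[str],
    panel: Iterable[str] | None = None,
) -> tuple[nx.Graph, dict[str, int], list[dict]]:
    """Bipartite gene-organ network restricted to a curated organ panel.

    An edge (gene, organ) exists iff the organ is in the panel and the
    gene's expression there strictly exceeds the gene's overall atlas
    mean. Organs with no assigned gene are excluded from the node set.

    Returns the graph (node attribute ``role`` in {"target", "organ"}),
    per-organ target counts, and an audit list noting genes missing from
    the atlas.
    """
    panel_list = default_organ_panel() if panel is None else [str(t) for t in panel]
    if not panel_list:
        raise ValueError("organ panel is empty")
    panel_set = set(panel_list)

    g = nx.Graph()
    counts: dict[str, int] = {}
    audit: list[dict] = []
    for gene in sorted({str(t).strip().upper() for t in targets}):
        if gene in expr.missing or gene not in expr.values.index:
            audit.append({"gene": gene, "status": "missing-from-atlas"})
            continue
        assigned = assign_tissues(expr, gene) & panel_set
        if not assigned:
            audit.append({"gene": gene, "status": "no-panel-organ"})
            continue
        g.add_node(gene, role="target")
        for organ in sorted(assigned):
            g.add_node(organ, role="organ")
            g.add_edge(gene, organ)
            counts[organ] = counts.get(organ, 0) + 1
    return g, counts, audit
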