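"""Seeded generators producing pipeline inputs with known ground truth.

Every generator draws from an independent random stream derived from the
global seed and a fixed per-generator tag (`numpy.random.SeedSequence`
spawn keys), so adding or reordering generator calls never perturbs
another generator's output, and a fixed seed reproduces each fixture
bit-for-bit.

The generators emulate, with planted and therefore verifiable structure,
each input family the pipeline consumes:

* compound tables with a controllable ADME pass fraction and a
  literature-whitelist stratum;
* pairs of target lists with an exactly requested intersection size;
* log2 expression studies with planted differentially expressed genes,
  Gaussian noise, and additive per-(gene, batch) effects;
* random interaction graphs with a planted dense hub module;
* tissue atlases with planted tissue-specific genes and atlas gaps;
* GMT term maps with one planted enriched term.

All requested cardinalities are honored exactly and re-checked after
generation.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .diffexpr import ExpressionStudy
from .enrichment import TermMap
from .organ_localization import TissueExpression

__all__ = [
    "gene_symbols",
    "gen_compound_table",
    "gen_target_universe",
    "gen_expression",
    "gen_ppi",
    "gen_tissue_matrix",
    "gen_term_map",
]

# fixed spawn keys: one independent stream per generator
_STREAM_TAGS = {
    "compounds": 1,
    "targets": 2,
    "expression": 3,
    "ppi": 4,
    "tissue": 5,
    "terms": 6,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    seed = int(seed)
    if seed < 0:
        raise ValueError("seed must be non-negative")
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(_STREAM_TAGS[stream],))
    return np.random.default_rng(ss)


def gene_symbols(n: int, start: int = 1) -> list[str]:
    """Synthetic uppercase gene symbols G000001, G000002, ..."""
    return [f"G{i:06d}" for i in range(start, start + n)]


# ---------------------------------------------------------------------------
# compound tables


def gen_compound_table(
    n_total: int, n_pass: int, n_whitelist_rescue: int, seed: int
) -> pd.DataFrame:
    """Compound table with exact pass / whitelist-rescue / fail strata.

    Exactly ``n_pass`` rows satisfy OB >= 30 and DL >= 0.18; exactly
    ``n_whitelist_rescue`` rows fail both thresholds and carry
    ``whitelisted=True``; the remaining rows fail at least one threshold
    and are unflagged. Ground-truth columns ``passes_adme`` and
    ``whitelisted`` are included so tests can verify the strata; the
    whitelist itself is ``table.loc[table.whitelisted, "name"]``.
    """
    for name, v in (
        ("n_total", n_total),
        ("n_pass", n_pass),
        ("n_whitelist_rescue", n_whitelist_rescue),
    ):
        if v < 0:
            raise ValueError(f"{name} must be non-negative")
    if n_pass + n_whitelist_rescue > n_total:
        raise ValueError("n_pass + n_whitelist_rescue exceeds n_total")
    rng = _rng(seed, "compounds")

    rows = []
    for i in range(n_total):
        if i < n_pass:
            ob = round(float(rng.uniform(30.5, 95.0)), 2)
            dl = round(float(rng.uniform(0.19, 0.95)), 3)
            stratum = "pass"
        elif i < n_pass + n_whitelist_rescue:
            ob = round(float(rng.uniform(1.0, 29.0)), 2)
            dl = round(float(rng.uniform(0.01, 0.17)), 3)
            stratum = "rescue"
        else:
            mode = int(rng.integers(3))
            lo_ob = round(float(rng.uniform(1.0, 29.0)), 2)
            hi_ob = round(float(rng.uniform(30.5, 95.0)), 2)
            lo_dl = round(float(rng.uniform(0.01, 0.17)), 3)
            hi_dl = round(float(rng.uniform(0.19, 0.95)), 3)
            ob, dl = [(lo_ob, hi_dl), (hi_ob, lo_dl), (lo_ob, lo_dl)][mode]
            stratum = "fail"
        rows.append(
            {
                "compound_id": f"CMP{i + 1:03d}",
                "name": f"compound-{i + 1:03d}",
                "ob": ob,
                "dl": dl,
                "smiles": "",
                "sources": "synthetic",
                "whitelisted": stratum == "rescue",
                "passes_adme": stratum == "pass",
            }
        )
    order = rng.permutation(n_total)
    table = pd.DataFrame([rows[i] for i in order]).reset_index(drop=True)

    assert int(((table.ob >= 30) & (table.dl >= 0.18)).sum()) == n_pass
    assert int(table.whitelisted.sum()) == n_whitelist_rescue
    assert not (table.whitelisted & table.passes_adme).any()
    return table


# ---------------------------------------------------------------------------
# target universes


def gen_target_universe(
    n_universe: int, n_a: int, n_b: int, n_overlap: int, seed: int
) -> tuple[set[str], set[str]]:
    """Two symbol sets of exact sizes with an exact intersection size."""
    for name, v in (
        ("n_universe", n_universe),
        ("n_a", n_a),
        ("n_b", n_b),
        ("n_overlap", n_overlap),
    ):
        if v < 0:
            raise ValueError(f"{name} must be non-negative")
    if n_overlap > min(n_a, n_b):
        raise ValueError("n_overlap exceeds min(n_a, n_b)")
    if n_a + n_b - n_overlap > n_universe:
        raise ValueError("universe too small for the requested sets")
    rng = _rng(seed, "targets")
    universe = np.array(gene_symbols(n_universe))
    perm = rng.permutation(n_universe)
    shared = universe[perm[:n_overlap]]
    a_only = universe[perm[n_overlap : n_a]]
    b_only = universe[perm[n_a : n_a + n_b - n_overlap]]
    a = set(shared) | set(a_only)
    b = set(shared) | set(b_only)
    assert len(a) == n_a and len(b) == n_b and len(a & b) == n_overlap
    return a, b


# ---------------------------------------------------------------------------
# expression studies


def gen_expression(
    n_genes: int,
    n_case: int,
    n_control: int,
    n_de: int,
    lfc: float,
    sigma: float,
    batch_shift: float,
    n_batches: int,
    seed: int,
    genes: list[str] | None = None,
) -> tuple[ExpressionStudy, list[str]]:
    """Log2 expression study with planted DE genes and batch effects.

    Planted genes have true mean difference ``lfc`` (case minus control)
    on the log2 scale; residual noise is Gaussian with standard deviation
    ``sigma``; each (gene, batch) pair receives an additive shift drawn
    N(0, batch_shift^2). Samples are assigned to batches round-robin
    within each group, so batches are balanced across groups.

    Returns the study and the ground-truth list of planted DE genes.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if n_de > n_genes:
        raise ValueError("n_de exceeds n_genes")
    if n_batches < 1:
        raise ValueError("need at least one batch")
    if n_case < 1 or n_control < 1:
        raise ValueError("need at least one sample per group")
    if batch_shift < 0:
        raise ValueError("batch_shift must be non-negative")
    rng = _rng(seed, "expression")

    if genes is None:
        genes = gene_symbols(n_genes)
    elif len(genes) != n_genes:
        raise ValueError("len(genes) must equal n_genes")
    samples = [f"case_{i + 1:03d}" for i in range(n_case)] + [
        f"ctrl_{i + 1:03d}" for i in range(n_control)
    ]
    groups = pd.Series(
        ["case"] * n_case + ["control"] * n_control, index=samples, name="group"
    )
    batch_ids = [i % n_batches for i in range(n_case)] + [
        i % n_batches for i in range(n_control)
    ]
    batches = pd.Series(
        [f"batch{b + 1}" for b in batch_ids], index=samples, name="batch"
    )

    base = rng.normal(8.0, 1.0, size=n_genes)
    values = base[:, None] + rng.normal(0.0, sigma, size=(n_genes, len(samples)))
    de_idx = np.sort(rng.choice(n_genes, size=n_de, replace=False))
    values[de_idx, :n_case] += lfc
    if batch_shift > 0 and n_batches > 1:
        effects = rng.normal(0.0, batch_shift, size=(n_genes, n_batches))
        values += effects[:, batch_ids]

    matrix = pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=samples)
    study = ExpressionStudy(matrix=matrix, groups=groups, batches=batches)
    return study, [genes[i] for i in de_idx]


# ---------------------------------------------------------------------------
# interaction graphs


def gen_ppi(
    n_nodes: int,
    model: str,
    edge_param: float,
    n_hub: int,
    hub_density: float,
    seed: int,
    nodes: list[str] | None = None,
) -> tuple[nx.Graph, list[str]]:
    """Random simple graph with a planted dense hub module.

    The background is either an Erdos-Renyi G(n, p) graph
    (``model="erdos"``, ``edge_param`` = p) or a preferential-attachment
    graph (``model="preferential"``, ``edge_param`` = attachment count m).
    A module of ``n_hub`` nodes is then wired pairwise with probability
    ``hub_density`` and, preferentially, to the remaining nodes with
    probability ``hub_density / 20`` per hub/non-hub pair.

    Returns the graph (nodes named with synthetic gene symbols unless
    ``nodes`` is supplied) and the planted hub list.
    """
    if n_hub > n_nodes:
        raise ValueError("n_hub exceeds n_nodes")
    if n_hub > 0 and not (0.0 <= hub_density <= 1.0):
        raise ValueError("hub_density must lie in [0, 1]")
    rng = _rng(seed, "ppi")
    graph_seed = int(rng.integers(2**31))

    if model == "erdos":
        if not (0.0 <= edge_param <= 1.0):
            raise ValueError("erdos edge probability must lie in [0, 1]")
        g = nx.gnp_random_graph(n_nodes, edge_param, seed=graph_seed)
    elif model == "preferential":
        m = int(edge_param)
        if m < 1 or m >= max(n_nodes, 2):
            raise ValueError("preferential attachment count must satisfy 1 <= m < n")
        g = nx.barabasi_albert_graph(n_nodes, m, seed=graph_seed)
    else:
        raise ValueError(f"unknown graph model {model!r}")

    hub_idx = sorted(int(i) for i in rng.choice(n_nodes, size=n_hub, replace=False))
    for ai in range(len(hub_idx)):
        for bi in range(ai + 1, len(hub_idx)):
            if rng.random() < hub_density:
                g.add_edge(hub_idx[ai], hub_idx[bi])
    non_hub = [v for v in range(n_nodes) if v not in set(hub_idx)]
    p_out = hub_density / 20.0
    for h in hub_idx:
        for v in non_hub:
            if rng.random() < p_out:
                g.add_edge(h, v)

    if nodes is None:
        nodes = gene_symbols(n_nodes)
    elif len(nodes) != n_nodes:
        raise ValueError("len(nodes) must equal n_nodes")
    mapping = {i: nodes[i] for i in range(n_nodes)}
    g = nx.relabel_nodes(g, mapping)
    hubs = [mapping[i] for i in hub_idx]
    return g, hubs


# ---------------------------------------------------------------------------
# tissue atlases


def gen_tissue_matrix(
    genes: Iterable[str],
    n_tissues: int,
    planted: Mapping[str, str],
    fold: float,
    seed: int,
    missing_fraction: float = 0.0,
    tissue_names: list[str] | None = None,
) -> TissueExpression:
    """Tissue atlas with planted tissue-specific genes and atlas gaps.

    Background values are positive with mild multiplicative noise. For
    each planted (gene, tissue) pair the tissue's value is raised to
    ``fold`` times the gene's background mean, guaranteeing (and
    re-checking) that the tissue strictly exceeds the gene's overall mean
    when ``fold > 1``. A ``missing_fraction`` of the non-planted genes is
    omitted entirely and recorded in the ``missing`` set.
    """
    genes = [str(g).strip().upper() for g in genes]
    if fold <= 1.0:
        raise ValueError("fold must exceed 1 for a planted tissue to stand out")
    if not (0.0 <= missing_fraction < 1.0):
        raise ValueError("missing_fraction must lie in [0, 1)")
    rng = _rng(seed, "tissue")
    if tissue_names is None:
        tissue_names = [f"tissue_{i + 1:02d}" for i in range(n_tissues)]
    elif len(tissue_names) != n_tissues:
        raise ValueError("len(tissue_names) must equal n_tissues")
    planted = {str(g).strip().upper(): str(t) for g, t in planted.items()}
    unknown = set(planted) - set(genes)
    if unknown:
        raise ValueError(f"planted genes not in gene list: {sorted(unknown)}")
    bad_tissue = set(planted.values()) - set(tissue_names)
    if bad_tissue:
        raise ValueError(f"planted tissues not in tissue list: {sorted(bad_tissue)}")

    n_missing = int(round(missing_fraction * len(genes)))
    candidates = [g for g in genes if g not in planted]
    if n_missing > len(candidates):
        raise ValueError("missing_fraction leaves no room outside planted genes")
    missing = set(
        np.array(candidates)[
            rng.choice(len(candidates), size=n_missing, replace=False)
        ]
    ) if n_missing else set()

    kept = [g for g in genes if g not in missing]
    baseline = rng.uniform(2.0, 8.0, size=len(kept))
    values = baseline[:, None] * rng.uniform(0.7, 1.3, size=(len(kept), n_tissues))
    df = pd.DataFrame(values, index=pd.Index(kept, name="gene"), columns=tissue_names)
    for g, t in planted.items():
        df.loc[g, t] = fold * baseline[kept.index(g)]
        row = df.loc[g]
        assert row[t] > row.mean(), "planted tissue failed to exceed the gene mean"
    return TissueExpression(values=df, missing=missing)


# ---------------------------------------------------------------------------
# term maps


def gen_term_map(
    n_terms: int,
    universe: Iterable[str],
    planted_term_size: int,
    planted_overlap_with_query: int,
    n_query: int,
    seed: int,
    term_size_range: tuple[int, int] = (10, 40),
) -> tuple[TermMap, set[str], str]:
    """GMT-style term map with exactly one planted enriched term.

    Returns ``(term_map, query, planted_term_id)``. The planted term
    shares exactly ``planted_overlap_with_query`` genes with the returned
    query; the remaining terms are drawn uniformly from the universe
    (redrawn in the rare case one lands on the planted overlap count, so
    the planted overlap is unique).
    """
    universe = sorted({str(g).strip().upper() for g in universe})
    N = len(universe)
    if n_terms < 1:
        raise ValueError("need at least one term")
    if not (0 < planted_term_size <= N):
        raise ValueError("planted_term_size must lie in (0, N]")
    if not (0 < n_query <= N):
        raise ValueError("n_query must lie in (0, N]")
    if planted_overlap_with_query > min(planted_term_size, n_query):
        raise ValueError("requested overlap exceeds term or query size")
    if planted_term_size - planted_overlap_with_query > N - n_query:
        raise ValueError("universe too small outside the query for the planted term")
    lo, hi = term_size_range
    if not (1 <= lo <= hi <= N):
        raise ValueError("invalid term_size_range")
    rng = _rng(seed, "terms")

    uni = np.array(universe)
    query = set(uni[rng.choice(N, size=n_query, replace=False)])
    inside = np.array(sorted(query))
    outside = np.array(sorted(set(universe) - query))
    planted_members = set(
        inside[rng.choice(len(inside), size=planted_overlap_with_query, replace=False)]
    )
    n_rest = planted_term_size - planted_overlap_with_query
    if n_rest:
        planted_members |= set(
            outside[rng.choice(len(outside), size=n_rest, replace=False)]
        )

    terms: dict[str, tuple[str, frozenset[str]]] = {}
    planted_id = "TERM0001"
    terms[planted_id] = ("planted enriched term", frozenset(planted_members))
    for i in range(2, n_terms + 1):
        for _ in range(100):
            size = int(rng.integers(lo, hi + 1))
            members = set(uni[rng.choice(N, size=size, replace=False)])
            if len(members & query) != planted_overlap_with_query:
                break
        terms[f"TERM{i:04d}"] = (f"random term {i}", frozenset(members))
    tm = TermMap(terms=terms, universe=frozenset(universe))
    assert len(tm.terms[planted_id][1] & query) == planted_overlap_with_query
    return tm, query, planted_id
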