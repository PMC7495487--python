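"""Generators honor requested cardinalities exactly and are seed-stable."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from netpharm.synthetic_data import (
    gen_compound_table,
    gen_expression,
    gen_ppi,
    gen_target_universe,
    gen_term_map,
    gen_tissue_matrix,
    gene_symbols,
)


@pytest.mark.parametrize(
    "n_total,n_pass,n_rescue",
    [(29, 9, 1), (5, 5, 0), (10, 0, 0), (12, 4, 3)],
)
def test_compound_table_strata_exact(n_total, n_pass, n_rescue):
    table = gen_compound_table(n_total, n_pass, n_rescue, seed=1)
    assert len(table) == n_total
    passes = (table.ob >= 30) & (table.dl >= 0.18)
    assert int(passes.sum()) == n_pass
    rescued = table[table.whitelisted]
    assert len(rescued) == n_rescue
    # rescue rows fail both thresholds; other failures fail at least one
    assert ((rescued.ob < 30) & (rescued.dl < 0.18)).all()
    rest = table[~passes & ~table.whitelisted]
    assert ((rest.ob < 30) | (rest.dl < 0.18)).all()


def test_compound_table_rejects_bad_counts():
    with pytest.raises(ValueError):
        gen_compound_table(5, 4, 2, seed=1)
    with pytest.raises(ValueError):
        gen_compound_table(5, -1, 0, seed=1)


@pytest.mark.parametrize(
    "n_universe,n_a,n_b,n_overlap",
    [(2000, 933, 913, 184), (10, 3, 3, 3), (10, 3, 3, 0), (50, 20, 30, 5)],
)
def test_target_universe_cardinalities_exact(n_universe, n_a, n_b, n_overlap):
    a, b = gen_target_universe(n_universe, n_a, n_b, n_overlap, seed=7)
    assert (len(a), len(b), len(a & b)) == (n_a, n_b, n_overlap)
    if n_overlap == min(n_a, n_b) == n_a == n_b:
        assert a == b


def test_target_universe_infeasible():
    with pytest.raises(ValueError):
        gen_target_universe(10, 8, 8, 2, seed=1)  # union would need 14 symbols
    with pytest.raises(ValueError):
        gen_target_universe(10, 3, 3, 4, seed=1)


def test_expression_planted_truth_and_batches():
    study, de_genes = gen_expression(200, 10, 10, 20, 2.0, 0.5, 1.0, 2, seed=11)
    assert len(de_genes) == 20
    assert study.matrix.shape == (200, 20)
    assert set(study.batches.unique()) == {"batch1", "batch2"}
    # every batch is balanced across groups
    tab = pd.crosstab(study.groups, study.batches)
    assert (tab.loc["case"] == tab.loc["control"]).all()
    # planted genes carry the requested mean difference (up to noise)
    case, ctrl = study.case_samples, study.control_samples
    diff = study.matrix[case].mean(axis=1) - study.matrix[ctrl].mean(axis=1)
    assert diff.loc[de_genes].mean() == pytest.approx(2.0, abs=0.2)
    others = diff.drop(index=de_genes)
    assert abs(others.mean()) < 0.2


def test_expression_parameter_errors():
    with pytest.raises(ValueError):
        gen_expression(10, 3, 3, 0, 1.0, 0.0, 0.0, 1, seed=1)
    with pytest.raises(ValueError):
        gen_expression(10, 3, 3, 11, 1.0, 0.5, 0.0, 1, seed=1)


def test_ppi_degenerate_graphs():
    g, hubs = gen_ppi(5, "erdos", 1.0, 0, 0.0, seed=1)
    assert g.number_of_edges() == 10 and hubs == []  # K5
    g, _ = gen_ppi(4, "erdos", 0.0, 0, 0.0, seed=1)
    assert g.number_of_edges() == 0


def test_ppi_planted_hub_module_is_dense():
    g, hubs = gen_ppi(180, "preferential", 2, 40, 0.8, seed=5)
    assert len(hubs) == 40 and g.number_of_nodes() == 180
    assert nx.number_of_selfloops(g) == 0
    sub = g.subgraph(hubs)
    density = nx.density(sub)
    assert density == pytest.approx(0.8, abs=0.1)
    hub_deg = np.mean([g.degree(v) for v in hubs])
    other_deg = np.mean([g.degree(v) for v in g.nodes if v not in set(hubs)])
    assert hub_deg > 3 * other_deg


def test_ppi_parameter_errors():
    with pytest.raises(ValueError):
        gen_ppi(10, "erdos", 1.5, 0, 0.0, seed=1)
    with pytest.raises(ValueError):
        gen_ppi(10, "erdos", 0.5, 11, 0.5, seed=1)
    with pytest.raises(ValueError):
        gen_ppi(10, "preferential", 2, 5, 1.5, seed=1)


def test_tissue_matrix_planted_and_missing():
    genes = gene_symbols(20)
    planted = {genes[0]: "tissue_03", genes[1]: "tissue_01"}
    expr = gen_tissue_matrix(genes, 10, planted, fold=10.0, seed=3, missing_fraction=0.1)
    assert len(expr.missing) == 2
    assert not set(planted) & expr.missing
    for g, t in planted.items():
        row = expr.values.loc[g]
        assert row[t] > row.mean()
    assert (expr.values.to_numpy() >= 0).all()


def test_term_map_planted_overlap_exact():
    universe = gene_symbols(1000)
    tm, query, planted_id = gen_term_map(50, universe, 25, 20, 40, seed=9)
    assert len(query) == 40
    _, members = tm.terms[planted_id]
    assert len(members) == 25 and len(members & query) == 20
    # the planted overlap count is unique among terms
    overlaps = [len(m & query) for tid, (_, m) in tm.terms.items() if tid != planted_id]
    assert 20 not in overlaps


@pytest.mark.parametrize("which", ["compounds", "universe", "expression", "ppi", "tissue", "terms"])
def test_generators_deterministic_under_seed(which):
    """Identical seed reproduces each fixture bit-for-bit."""
    if which == "compounds":
        a = gen_compound_table(29, 9, 1, seed=4).to_csv()
        b = gen_compound_table(29, 9, 1, seed=4).to_csv()
    elif which == "universe":
        a = gen_target_universe(100, 40, 40, 10, seed=4)
        b = gen_target_universe(100, 40, 40, 10, seed=4)
    elif which == "expression":
        s1, d1 = gen_expression(50, 5, 5, 5, 1.0, 0.5, 0.5, 2, seed=4)
        s2, d2 = gen_expression(50, 5, 5, 5, 1.0, 0.5, 0.5, 2, seed=4)
        a = (s1.matrix.to_csv(), d1)
        b = (s2.matrix.to_csv(), d2)
    elif which == "ppi":
        g1, h1 = gen_ppi(40, "preferential", 2, 8, 0.7, seed=4)
        g2, h2 = gen_ppi(40, "preferential", 2, 8, 0.7, seed=4)
        a = (sorted(g1.edges()), h1)
        b = (sorted(g2.edges()), h2)
    elif which == "tissue":
        genes = gene_symbols(10)
        a = gen_tissue_matrix(genes, 5, {genes[0]: "tissue_01"}, 5.0, seed=4).values.to_csv()
        b = gen_tissue_matrix(genes, 5, {genes[0]: "tissue_01"}, 5.0, seed=4).values.to_csv()
    else:
        u = gene_symbols(200)
        t1, q1, p1 = gen_term_map(20, u, 10, 5, 15, seed=4)
        t2, q2, p2 = gen_term_map(20, u, 10, 5, 15, seed=4)
        a = (sorted((k, sorted(v[1])) for k, v in t1.terms.items()), sorted(q1), p1)
        b = (sorted((k, sorted(v[1])) for k, v in t2.terms.items()), sorted(q2), p2)
    assert a == b


def test_streams_independent_across_generators():
    """A generator's output does not depend on other generators running."""
    a1, b1 = gen_target_universe(100, 40, 40, 10, seed=5)
    gen_compound_table(10, 5, 1, seed=5)  # interleaved call, same seed
    a2, b2 = gen_target_universe(100, 40, 40, 10, seed=5)
    assert a1 == a2 and b1 == b2
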