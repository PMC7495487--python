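"""Graph loading, centralities vs brute-force oracles, and the core screen."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from netpharm.ppi_topology import (
    ScreenThresholds,
    centralities,
    drop_isolated,
    induced_subgraph,
    load_edges,
    screen_core,
    screen_thresholds,
)
from netpharm.synthetic_data import gen_ppi
from netpharm.target_assembly import union_dedup

from oracles import brute_betweenness, brute_closeness


def _write_edges(tmp_path, lines, name="edges.tsv"):
    path = tmp_path / name
    path.write_text("\n".join(lines) + "\n")
    return path


def test_load_edges_restricts_and_keeps_isolates(tmp_path):
    path = _write_edges(
        tmp_path,
        ["node1\tnode2\tcombined_score", "A\tB\t900", "B\tD\t900", "C\tD\t900"],
    )
    g, _ = load_edges(path, restrict_to=["A", "B", "C"])
    assert set(g.nodes) == {"A", "B", "C"}
    assert set(map(frozenset, g.edges)) == {frozenset({"A", "B"})}
    assert g.degree("C") == 0


def test_load_edges_collapses_duplicates_keeping_max_score(tmp_path):
    path = _write_edges(tmp_path, ["A\tB\t500", "B\tA\t700"])
    g, _ = load_edges(path)
    assert g.number_of_edges() == 1 and g["A"]["B"]["score"] == 700


def test_load_edges_drops_self_loops_and_low_scores(tmp_path):
    path = _write_edges(tmp_path, ["A\tA\t990", "A\tB\t150", "A\tC\t800"])
    g, warnings = load_edges(path, score_min=400)
    assert set(map(frozenset, g.edges)) == {frozenset({"A", "C"})}
    assert any("self-loop" in w for w in warnings)


def test_load_edges_warns_on_malformed_line(tmp_path):
    path = _write_edges(tmp_path, ["A\tB\t500", "justonefield", "C\tD\tnotanumber"])
    g, warnings = load_edges(path)
    assert g.number_of_edges() == 1
    assert any("line 2" in w for w in warnings)
    assert any("line 3" in w for w in warnings)


def test_drop_isolated():
    g = nx.Graph()
    g.add_nodes_from("ABCD")
    g.add_edge("A", "B")
    cleaned, removed = drop_isolated(g)
    assert set(cleaned.nodes) == {"A", "B"} and removed == ["C", "D"]
    connected = nx.path_graph(4)
    same, removed = drop_isolated(connected)
    assert removed == [] and same.number_of_nodes() == 4


def test_centrality_hand_values_path():
    g = nx.Graph([("A", "B"), ("B", "C")])
    tab = centralities(g)
    assert tab.loc["B", "dc"] == 2
    assert tab.loc["B", "bc"] == pytest.approx(1.0)
    assert tab.loc["B", "cc"] == pytest.approx(1.0)
    assert tab.loc["A", "cc"] == pytest.approx(2 / 3)


def test_centrality_hand_values_star():
    g = nx.star_graph(4)  # center 0, leaves 1..4
    tab = centralities(g)
    assert tab.loc[0, "bc"] == pytest.approx(1.0)  # raw 6 scaled by 2/(4*3)


def test_centrality_hand_values_cycle_and_clique():
    c4 = centralities(nx.cycle_graph(4))
    assert np.allclose(c4["bc"], 1 / 6)
    k5 = centralities(nx.complete_graph(5))
    assert np.allclose(k5["bc"], 0.0) and np.allclose(k5["cc"], 1.0)


def test_centralities_match_brute_force_on_random_graphs():
    """Spot-check against the BFS enumeration oracle (full sweep in acceptance)."""
    rng = np.random.default_rng(0)
    for _ in range(20):
        n = int(rng.integers(4, 26))
        p = float(rng.uniform(0.1, 0.6))
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        tab = centralities(g)
        bc = brute_betweenness(g)
        cc = brute_closeness(g)
        for v in g.nodes:
            assert tab.loc[v, "bc"] == pytest.approx(bc[v], abs=1e-9)
            assert tab.loc[v, "cc"] == pytest.approx(cc[v], abs=1e-9)


def test_centralities_reject_empty_graph():
    with pytest.raises(ValueError):
        centralities(nx.Graph())


def test_thresholds_odd_and_even_medians():
    tab = pd.DataFrame(
        {"dc": [1, 2, 3, 4, 5], "bc": [0.0] * 5, "cc": [0.0] * 5},
        index=list("ABCDE"),
    )
    assert screen_thresholds(tab).dc_min == 6.0
    tab_even = pd.DataFrame(
        {"dc": [1, 1, 2, 2], "bc": [0.0] * 4, "cc": [0.0] * 4}, index=list("ABCD")
    )
    assert screen_thresholds(tab_even).dc_min == 3.0


def test_screen_core_inclusive_and_antitone():
    tab = pd.DataFrame(
        {
            "dc": [10, 5, 3, 1, 1, 1, 1],
            "bc": [0.5] * 7,
            "cc": [0.5] * 7,
        },
        index=list("ABCDEFG"),
    )
    thr = screen_thresholds(tab)  # median dc = 1 -> dc_min = 2
    core = screen_core(tab, thr)
    assert core.symbols == {"A", "B", "C"}
    # all-zero thresholds keep everything
    assert len(screen_core(tab, ScreenThresholds(0, 0, 0))) == 7
    # raising any threshold never adds survivors
    stricter = ScreenThresholds(thr.dc_min + 3, thr.bc_min, thr.cc_min)
    assert screen_core(tab, stricter).symbols <= core.symbols


def test_screen_single_pass_no_median_recomputation():
    """Thresholds come from the full table; survivors of a second pass
    with the ORIGINAL thresholds are unchanged (the screen is one-shot)."""
    g, _ = gen_ppi(60, "preferential", 2, 10, 0.9, seed=2)
    tab = centralities(g)
    thr = screen_thresholds(tab)
    core = screen_core(tab, thr)
    again = screen_core(tab.loc[sorted(core.symbols)], thr)
    assert again.symbols == core.symbols


def test_induced_subgraph():
    k4 = nx.complete_graph(4)
    sub = induced_subgraph(nx.relabel_nodes(k4, str), ["0", "1", "2"])
    assert sub.number_of_nodes() == 3 and sub.number_of_edges() == 3
    empty = induced_subgraph(nx.relabel_nodes(k4, str), ["X"])
    assert empty.number_of_nodes() == 0


def test_planted_hub_recovery_single_seed():
    g, hubs = gen_ppi(180, "preferential", 2, 40, 0.8, seed=5)
    g, _ = drop_isolated(g)
    tab = centralities(g)
    core = screen_core(tab, screen_thresholds(tab)).symbols
    truth = set(hubs)
    jaccard = len(core & truth) / len(core | truth)
    assert jaccard >= 0.5


def test_full_fixture_graph_screen(fixture_run):
    """On the simulated 184-target study two unconnected targets drop and
    the core screen lands inside the cleaned network."""
    stage = fixture_run["report"]["stages"]["ppi_topology"]
    assert stage["n_nodes"] == 182 and stage["n_unconnected_removed"] == 2
    assert 0 < stage["n_core"] <= 182
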