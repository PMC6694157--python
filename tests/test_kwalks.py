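import numpy as np
import networkx as nx
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pathextend.kwalks import (
    SelectionRule,
    extend_pathway,
    limited_kwalks,
    select_extension,
    transition_matrix,
)
from pathextend.scca import WeightedNetwork


def net_from_edges(weighted_edges, phenotype="case"):
    return WeightedNetwork(
        phenotype, {frozenset((a, b)): w for a, b, w in weighted_edges}
    )


def mc_passages(tm, seeds, L, n_walks, seed=0):
    """Monte-Carlo oracle: simulate truncated absorbed walks, count entries.

    Returns (edge mean, edge SE, node mean) of per-walk traversal counts,
    averaged uniformly over start seeds.
    """
    rng = np.random.default_rng(seed)
    n = len(tm.nodes)
    idx = tm.index
    seed_idx = [idx[s] for s in sorted(set(seeds) & set(tm.nodes))]
    cum = np.cumsum(tm.P, axis=1)
    edge_keys = sorted({tuple(sorted(e)) for e in np.argwhere(tm.P > 0)})
    ekey = {e: i for i, e in enumerate(edge_keys)}
    edge_sums = np.zeros(len(edge_keys))
    edge_sqsums = np.zeros(len(edge_keys))
    node_sums = np.zeros(n)
    for s in seed_idx:
        absorbing = set(seed_idx) - {s}
        counts = np.zeros((n_walks, len(edge_keys)), dtype=np.int16)
        ncounts = np.zeros((n_walks, n), dtype=np.int16)
        current = np.full(n_walks, s)
        active = np.ones(n_walks, dtype=bool)
        for _ in range(L):
            if not active.any():
                break
            cur = current[active]
            u = rng.random(cur.size)
            nxt = np.array([int(np.searchsorted(cum[c], x)) for c, x in zip(cur, u)])
            for w_i, (c, t) in zip(np.where(active)[0], zip(cur, nxt)):
                counts[w_i, ekey[tuple(sorted((c, t)))]] += 1
                ncounts[w_i, t] += 1
            current[active] = nxt
            active[active] = ~np.isin(nxt, list(absorbing))
        edge_sums += counts.mean(axis=0)
        edge_sqsums += counts.var(axis=0) / n_walks  # variance of the mean
        node_sums += ncounts.mean(axis=0)
    S = len(seed_idx)
    edge_mean = edge_sums / S
    edge_se = np.sqrt(edge_sqsums) / S
    return (
        {(tm.nodes[a], tm.nodes[b]): edge_mean[ekey[(a, b)]] for a, b in edge_keys},
        {(tm.nodes[a], tm.nodes[b]): edge_se[ekey[(a, b)]] for a, b in edge_keys},
        {g: node_sums[i] / S for g, i in idx.items()},
    )


# ---------------------------------------------------------------------------
# transition matrix
# ---------------------------------------------------------------------------


def test_transition_normalisation():
    net = net_from_edges([("A", "B", 2.0), ("A", "C", 3.0)])
    tm = transition_matrix(net)
    i = tm.index
    assert tm.P[i["A"], i["B"]] == pytest.approx(0.4)
    assert tm.P[i["A"], i["C"]] == pytest.approx(0.6)


def test_uniform_weights_regular_graph():
    cycle = [("A", "B", 1.0), ("B", "C", 1.0), ("C", "D", 1.0), ("D", "A", 1.0)]
    tm = transition_matrix(net_from_edges(cycle))
    assert np.allclose(tm.P[tm.P > 0], 0.5)  # 2-regular: all P_ij = 1/2


def test_rows_sum_to_one(default_networks):
    for net in default_networks.values():
        tm = transition_matrix(net)
        assert np.allclose(tm.P.sum(axis=1), 1.0, atol=1e-10)


@given(
    st.dictionaries(
        st.tuples(st.sampled_from("ABCDEF"), st.sampled_from("ABCDEF")).filter(lambda t: t[0] != t[1]),
        st.floats(0.0, 1.0),
        min_size=1,
        max_size=12,
    )
)
@settings(deadline=None, max_examples=60, derandomize=True)
def test_transition_rows_stochastic_for_arbitrary_weights(raw):
    weights = {frozenset(k): v for k, v in raw.items()}
    if not any(v > 0 for v in weights.values()):
        return  # no walkable edge; transition matrix undefined
    tm = transition_matrix(WeightedNetwork("case", weights))
    assert (tm.P >= 0).all()
    assert np.allclose(tm.P.sum(axis=1), 1.0, atol=1e-10)


def test_zero_weight_node_excluded():
    net = net_from_edges([("A", "B", 1.0), ("B", "C", 0.0)])
    tm = transition_matrix(net)
    assert "C" not in tm.nodes
    assert np.allclose(tm.P.sum(axis=1), 1.0, atol=1e-10)


# ---------------------------------------------------------------------------
# limited walks
# ---------------------------------------------------------------------------


def test_path_graph_expected_passages_exact():
    """A-B-C, uniform weights, seeds {A, C}: from A, B is entered at t=1
    with probability 1 and again at t=3 with probability 1/2 (after the
    B->A->B detour); from C symmetrically.  Expected entries into B = 1.5."""
    net = net_from_edges([("A", "B", 1.0), ("B", "C", 1.0)])
    tm = transition_matrix(net)
    rel = limited_kwalks(tm, {"A", "C"}, L=3)
    assert rel.node_relevance["B"] == pytest.approx(1.5, abs=1e-12)
    mc_edges, mc_se, mc_nodes = mc_passages(tm, {"A", "C"}, L=3, n_walks=100_000)
    assert abs(mc_nodes["B"] - 1.5) < 0.02


def test_all_nodes_seeds_gives_zero_nonseed_relevance():
    net = net_from_edges([("A", "B", 1.0), ("B", "C", 1.0), ("C", "A", 1.0)])
    tm = transition_matrix(net)
    rel = limited_kwalks(tm, {"A", "B", "C"}, L=10)
    # every first step is an absorption; only seeds accumulate entries
    assert all(rel.node_relevance[g] > 0 for g in "ABC")
    ext = select_extension(rel, {"A", "B", "C"})
    assert ext == set()


def test_expected_counts_match_monte_carlo(rng):
    """Forward recursion vs 1e4-walk simulation on random small graphs."""
    for trial in range(5):
        n = int(rng.integers(5, 13))
        g = nx.gnp_random_graph(n, 0.45, seed=int(rng.integers(2**31)))
        if not nx.is_connected(g):
            g = nx.compose(g, nx.path_graph(n))
        net = net_from_edges(
            [(f"n{a}", f"n{b}", float(rng.uniform(0.1, 1.0))) for a, b in g.edges()]
        )
        tm = transition_matrix(net)
        seeds = set(list(tm.nodes)[:3])
        L = 5
        rel = limited_kwalks(tm, seeds, L)
        mc_edges, mc_se, mc_nodes = mc_passages(tm, seeds, L, n_walks=10_000, seed=trial)
        for (a, b), mean in mc_edges.items():
            expected = rel.edge_relevance.get(frozenset((a, b)), 0.0)
            se = max(mc_se[(a, b)], 1e-4)
            assert abs(expected - mean) < 3.5 * se, (a, b, expected, mean, se)


def test_conservation_of_start_mass():
    net = net_from_edges([("A", "B", 1.0), ("B", "C", 2.0), ("C", "A", 0.5), ("C", "D", 1.0)])
    tm = transition_matrix(net)
    seeds = {"A", "C"}
    rel = limited_kwalks(tm, seeds, L=1)
    # at t=0 each start seed emits exactly one unit of probability mass
    total_first_step = sum(rel.edge_relevance.values())
    assert total_first_step == pytest.approx(1.0)  # averaged over 2 starts


def test_relevance_monotone_in_walk_limit():
    net = net_from_edges([("A", "B", 1.0), ("B", "C", 1.0), ("C", "D", 1.0), ("D", "A", 1.0)])
    tm = transition_matrix(net)
    prev = None
    for L in (1, 2, 4, 8, 16):
        rel = limited_kwalks(tm, {"A", "C"}, L)
        if prev is not None:
            for edge, val in prev.edge_relevance.items():
                assert rel.edge_relevance.get(edge, 0.0) >= val - 1e-12
        prev = rel


def test_fewer_than_two_mapped_seeds_skipped():
    net = net_from_edges([("A", "B", 1.0)])
    tm = transition_matrix(net)
    rel = limited_kwalks(tm, {"A", "Z"}, L=5)
    assert rel.empty


# ---------------------------------------------------------------------------
# selection
# ---------------------------------------------------------------------------


def _rel(scores, seeds=("S1", "S2")):
    from pathextend.kwalks import RelevanceScores

    return RelevanceScores(list(seeds), 3, dict(scores), {}, dict(scores))


def test_top_k_zero_empty():
    rel = _rel({"X": 1.0, "Y": 0.5})
    assert select_extension(rel, {"S1", "S2"}, SelectionRule(kind="top_k", k=0)) == set()


def test_tie_break_lexicographic():
    rel = _rel({"B": 1.0, "A": 1.0, "C": 0.1})
    chosen = select_extension(rel, {"S1", "S2"}, SelectionRule(kind="top_k", k=1))
    assert chosen == {"A"}


def test_cut_node_on_every_seed_path_ranked_first():
    """Star: every seed-seed walk passes the hub, so the hub dominates."""
    edges = [("HUB", f"S{i}", 1.0) for i in range(4)]
    edges += [("HUB", "X", 0.2), ("X", "Y", 0.5)]
    net = net_from_edges(edges)
    tm = transition_matrix(net)
    seeds = {f"S{i}" for i in range(4)}
    rel = limited_kwalks(tm, seeds, L=3)
    ranking = sorted(
        ((g, r) for g, r in rel.seed_delivery.items() if g not in seeds),
        key=lambda t: (-t[1], t[0]),
    )
    assert ranking[0][0] == "HUB"
    assert select_extension(rel, seeds, SelectionRule()) >= {"HUB"}


# ---------------------------------------------------------------------------
# pathway extension
# ---------------------------------------------------------------------------


def test_extension_union_and_mapped_subset():
    edges = [("P1", "P2", 1.0), ("P1", "A", 0.9), ("A", "P2", 0.9), ("P2", "B", 0.8), ("B", "P1", 0.8)]
    net_case = net_from_edges(edges, "case")
    ctrl = edges + [("P1", "C", 0.9), ("C", "P2", 0.9)]
    net_ctrl = net_from_edges(ctrl, "control")
    ext = extend_pathway(("PW", "test", ["P1", "P2", "ZZ"]), net_case, net_ctrl)
    assert ext.mapped_genes == {"P1", "P2"}
    assert ext.final_genes == ext.mapped_genes | ext.extension_case | ext.extension_control
    assert ext.mapped_genes <= ext.final_genes


def test_identical_networks_identical_extensions():
    edges = [("P1", "P2", 1.0), ("P1", "A", 0.9), ("A", "P2", 0.9), ("A", "B", 0.3)]
    net = net_from_edges(edges, "case")
    net2 = net_from_edges(edges, "control")
    ext = extend_pathway(("PW", "t", ["P1", "P2"]), net, net2)
    assert ext.extension_case == ext.extension_control


def test_under_mapped_pathway_kept_at_originals():
    net = net_from_edges([("P1", "A", 1.0), ("A", "B", 1.0)], "case")
    net2 = net_from_edges([("P1", "A", 1.0), ("A", "B", 1.0)], "control")
    ext = extend_pathway(("PW", "t", ["P1", "QQ"]), net, net2)
    assert ext.extension_case == set() and ext.extension_control == set()
    assert ext.final_genes == {"P1"}
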