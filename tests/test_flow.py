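"""Current-flow solver: closed forms, conservation, oracle equivalence."""

import numpy as np
import pytest

from aflow.contacts import ContactGraph
from aflow.errors import ConnectivityError, UsageError
from aflow.flow import (
    FlowNetwork,
    compare_states,
    compute_information_flow,
    interactor_flow,
    solve_potentials,
)
from aflow.synthetic import make_toy_graph


def graph_from_edges(labels, edges, kinds=None):
    n = len(labels)
    idx = {lab: i for i, lab in enumerate(labels)}
    w = np.zeros((n, n))
    for a, b, g in edges:
        w[idx[a], idx[b]] = w[idx[b], idx[a]] = g
    return ContactGraph(node_labels=list(labels), weights=w, n_frames_used=1,
                        node_kinds=kinds)


def pinv_flow_oracle(graph, sources, sinks):
    """Throughflow via dense Moore–Penrose pseudoinverse of the Laplacian."""
    w = graph.weights
    lap = np.diag(w.sum(axis=1)) - w
    b = np.zeros(graph.n_nodes)
    for s in sources:
        b[graph.index(s)] += 1.0 / len(sources)
    for t in sinks:
        b[graph.index(t)] -= 1.0 / len(sinks)
    v = np.linalg.pinv(lap) @ b
    current = w * (v[:, None] - v[None, :])
    out = {}
    for i, lab in enumerate(graph.node_labels):
        if lab in sources or lab in sinks:
            out[lab] = abs(current[i].sum())
        else:
            out[lab] = 0.5 * np.abs(current[i]).sum()
    return out, v


class TestSolvePotentials:
    def test_ohms_law_single_edge(self):
        g = graph_from_edges(["a", "b"], [("a", "b", 0.5)])
        v = solve_potentials(FlowNetwork(g, ["a"], ["b"]))
        assert v["a"] - v["b"] == pytest.approx(2.0, abs=1e-12)
        assert v["b"] == 0.0  # grounded sink

    def test_series_resistances_add(self):
        g = graph_from_edges(["a", "b", "c"], [("a", "b", 1.0), ("b", "c", 1.0)])
        v = solve_potentials(FlowNetwork(g, ["a"], ["c"]))
        assert v["a"] - v["c"] == pytest.approx(2.0, abs=1e-12)

    def test_disconnected_terminals_error(self):
        g = graph_from_edges(["a", "b", "c", "d"],
                             [("a", "b", 1.0), ("c", "d", 1.0)])
        with pytest.raises(ConnectivityError, match="component"):
            solve_potentials(FlowNetwork(g, ["a"], ["d"]))

    def test_source_sink_validation(self):
        g = graph_from_edges(["a", "b"], [("a", "b", 1.0)])
        with pytest.raises(UsageError):
            FlowNetwork(g, ["a"], ["a"])
        with pytest.raises(UsageError):
            FlowNetwork(g, [], ["b"])
        with pytest.raises(UsageError):
            FlowNetwork(g, ["zz"], ["b"])


class TestInformationFlow:
    def test_single_path_interior_carries_all(self):
        g = graph_from_edges(["A", "B", "C"], [("A", "B", 1.0), ("B", "C", 1.0)])
        r = compute_information_flow(FlowNetwork(g, ["A"], ["C"]))
        assert r.throughflow["B"] == pytest.approx(1.0, abs=1e-12)
        assert r.throughflow["A"] == pytest.approx(1.0, abs=1e-12)

    def test_current_divider_quarter_three_quarters(self):
        g = make_toy_graph("parallel", g1=0.25, g2=0.75)
        r = compute_information_flow(FlowNetwork(g, ["S"], ["T"]))
        assert r.throughflow["M1"] == pytest.approx(0.25, abs=1e-10)
        assert r.throughflow["M2"] == pytest.approx(0.75, abs=1e-10)

    def test_balanced_wheatstone_bridge_carries_nothing(self):
        g = make_toy_graph("wheatstone", arm=0.5, bridge=0.3)
        r = compute_information_flow(FlowNetwork(g, ["S"], ["T"]))
        assert abs(r.edge_currents[("M1", "M2")]) < 1e-10

    def test_matches_pseudoinverse_oracle_on_random_graphs(self):
        for seed in range(30):
            g = make_toy_graph("random", seed=seed)
            labels = g.node_labels
            sources, sinks = [labels[0]], [labels[-1]]
            r = compute_information_flow(FlowNetwork(g, sources, sinks))
            oracle, _ = pinv_flow_oracle(g, sources, sinks)
            for lab in labels:
                assert r.throughflow[lab] == pytest.approx(oracle[lab], abs=1e-8)

    def test_gauge_invariance_currents_equal_pinv(self):
        g = make_toy_graph("random", seed=42)
        sources, sinks = [g.node_labels[0]], [g.node_labels[-1]]
        r = compute_information_flow(FlowNetwork(g, sources, sinks))
        _, v_pinv = pinv_flow_oracle(g, sources, sinks)
        v_grounded = np.array([r.potentials[lab] for lab in g.node_labels])
        shift = v_grounded - v_pinv
        np.testing.assert_allclose(shift, shift[0], atol=1e-9)

    def test_conservation_unit_current(self):
        for seed in range(10):
            g = make_toy_graph("random", seed=seed)
            labels = g.node_labels
            net = FlowNetwork(g, labels[:2], labels[-2:])
            r = compute_information_flow(net)
            v = np.array([r.potentials[lab] for lab in labels])
            current = g.weights * (v[:, None] - v[None, :])
            net_out = current.sum(axis=1)
            for i, lab in enumerate(labels):
                if lab in net.sources or lab in net.sinks:
                    continue
                assert abs(net_out[i]) < 1e-9  # Kirchhoff current law
            src_total = sum(net_out[g.index(s)] for s in net.sources)
            snk_total = sum(net_out[g.index(t)] for t in net.sinks)
            assert src_total == pytest.approx(1.0, abs=1e-9)
            assert snk_total == pytest.approx(-1.0, abs=1e-9)

    def test_throughflow_bounds_interior(self):
        for seed in range(10):
            g = make_toy_graph("random", seed=seed)
            labels = g.node_labels
            r = compute_information_flow(FlowNetwork(g, [labels[0]], [labels[-1]]))
            for lab in labels[1:-1]:
                assert -1e-12 <= r.throughflow[lab] <= 1.0 + 1e-9

    def test_effective_resistance_series_and_parallel(self):
        g = make_toy_graph("series", n=3)
        r = compute_information_flow(FlowNetwork(g, ["n0"], ["n2"]))
        assert r.effective_resistance == pytest.approx(2.0, abs=1e-10)
        g1, g2 = 0.25, 0.75
        gp = make_toy_graph("parallel", g1=g1, g2=g2)
        rp = compute_information_flow(FlowNetwork(gp, ["S"], ["T"]))
        expected = 1.0 / (g1 / 2 + g2 / 2)  # harmonic combination of branches
        assert rp.effective_resistance == pytest.approx(expected, abs=1e-10)

    def test_rayleigh_monotonicity(self):
        """Raising any single conductance never raises effective resistance."""
        rng = np.random.default_rng(5)
        for seed in range(5):
            g = make_toy_graph("random", seed=seed)
            labels = g.node_labels
            net = FlowNetwork(g, [labels[0]], [labels[-1]])
            base = compute_information_flow(net).effective_resistance
            edges = [(i, j) for i in range(g.n_nodes) for j in range(i + 1, g.n_nodes)
                     if g.weights[i, j] > 0]
            for i, j in edges:
                w2 = g.weights.copy()
                w2[i, j] = w2[j, i] = min(1.0, w2[i, j] * float(rng.uniform(1.1, 2.0)))
                g2 = ContactGraph(node_labels=labels, weights=w2, n_frames_used=1)
                r2 = compute_information_flow(FlowNetwork(g2, [labels[0]], [labels[-1]]))
                assert r2.effective_resistance <= base + 1e-10

    def test_bypass_never_increases_exclusive_node_flow(self):
        """Adding a parallel source–sink route cannot raise a chain node's flow."""
        labels = ["S", "m1", "m2", "T", "p"]
        base_edges = [("S", "m1", 0.8), ("m1", "m2", 0.8), ("m2", "T", 0.8)]
        g1 = graph_from_edges(labels[:4], base_edges)
        r1 = compute_information_flow(FlowNetwork(g1, ["S"], ["T"]))
        g2 = graph_from_edges(labels, base_edges + [("S", "p", 0.5), ("p", "T", 0.5)])
        r2 = compute_information_flow(FlowNetwork(g2, ["S"], ["T"]))
        for lab in ("m1", "m2"):
            assert r2.throughflow[lab] <= r1.throughflow[lab] + 1e-12


class TestInteractorFlow:
    def _kinds(self, labels, interactors):
        return ["interactor" if l in interactors else "residue" for l in labels]

    def test_sole_bridge_carries_unit_flow(self):
        labels = ["S", "X", "T"]
        g = graph_from_edges(labels, [("S", "X", 0.7), ("X", "T", 0.7)],
                             kinds=self._kinds(labels, {"X"}))
        r = compute_information_flow(FlowNetwork(g, ["S"], ["T"]))
        assert interactor_flow(r, "X") == pytest.approx(1.0, abs=1e-12)

    def test_dead_end_interactor_carries_nothing(self):
        labels = ["S", "m", "T", "X"]
        g = graph_from_edges(
            labels,
            [("S", "m", 1.0), ("m", "T", 1.0), ("m", "X", 0.9)],
            kinds=self._kinds(labels, {"X"}),
        )
        r = compute_information_flow(FlowNetwork(g, ["S"], ["T"]))
        assert interactor_flow(r, "X") == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_parallel_interactors_split_evenly(self):
        labels = ["S", "X1", "X2", "T"]
        g = graph_from_edges(
            labels,
            [("S", "X1", 0.6), ("X1", "T", 0.6), ("S", "X2", 0.6), ("X2", "T", 0.6)],
            kinds=self._kinds(labels, {"X1", "X2"}),
        )
        r = compute_information_flow(FlowNetwork(g, ["S"], ["T"]))
        assert interactor_flow(r, "X1") == pytest.approx(0.5, abs=1e-12)
        assert interactor_flow(r, "X2") == pytest.approx(0.5, abs=1e-12)

    def test_unknown_label_raises(self):
        labels = ["S", "X", "T"]
        g = graph_from_edges(labels, [("S", "X", 0.7), ("X", "T", 0.7)],
                             kinds=self._kinds(labels, {"X"}))
        r = compute_information_flow(FlowNetwork(g, ["S"], ["T"]))
        with pytest.raises(KeyError):
            interactor_flow(r, "Y")
        with pytest.raises(UsageError):
            interactor_flow(r, "S")


class TestCompareStates:
    def _result_with_flow(self, flows):
        labels = list(flows)
        n = len(labels)
        from aflow.flow import FlowResult
        return FlowResult(
            node_labels=labels, potentials={l: 0.0 for l in labels},
            throughflow=dict(flows), edge_currents={},
            effective_resistance=1.0, sources=frozenset({labels[0]}),
            sinks=frozenset({labels[-1]}),
        )

    def test_identical_replicates_zero_sem(self):
        r = self._result_with_flow({"a": 0.3, "b": 0.5})
        table = compare_states({"apo": [r, r, r]}, reference="apo")
        assert (table["sem"] == 0.0).all()

    def test_sem_hand_computed(self):
        reps = [self._result_with_flow({"a": v, "b": 0.1}) for v in (0.4, 0.5, 0.6)]
        table = compare_states({"apo": reps}, reference="apo")
        row = table[table.node_label == "a"].iloc[0]
        assert row["mean"] == pytest.approx(0.5)
        assert row["sem"] == pytest.approx(0.1 / np.sqrt(3), abs=1e-6)  # ≈ 0.0577

    def test_missing_reference_is_usage_error(self):
        r = self._result_with_flow({"a": 0.3, "b": 0.5})
        with pytest.raises(UsageError):
            compare_states({"apo": [r]}, reference="holo")

    def test_empty_condition_is_usage_error(self):
        r = self._result_with_flow({"a": 0.3, "b": 0.5})
        with pytest.raises(UsageError):
            compare_states({"apo": [r], "holo": []}, reference="apo")

    def test_absent_interactor_reported_missing_not_zero(self):
        apo = self._result_with_flow({"a": 0.3, "b": 0.5})
        holo = self._result_with_flow({"a": 0.2, "b": 0.5, "L:CLR1": 0.8})
        table = compare_states({"apo": [apo], "holo": [holo]}, reference="apo")
        apo_rows = table[table.condition == "apo"]
        assert "L:CLR1" not in set(apo_rows.node_label)
        holo_clr = table[(table.condition == "holo") & (table.node_label == "L:CLR1")]
        assert len(holo_clr) == 1
        assert np.isnan(holo_clr.iloc[0]["delta"])  # no reference value exists

    def test_delta_vs_reference(self):
        apo = self._result_with_flow({"a": 0.3, "b": 0.5})
        holo = self._result_with_flow({"a": 0.5, "b": 0.5})
        table = compare_states({"apo": [apo], "holo": [holo]}, reference="apo")
        row = table[(table.condition == "holo") & (table.node_label == "a")].iloc[0]
        assert row["delta"] == pytest.approx(0.2)
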