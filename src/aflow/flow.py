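"""Current-flow "information flow" through a contact network.

The contact graph is treated as a resistor network: edge weights are
conductances, one unit of current is injected equally across the source
nodes (+1/|S| each) and extracted equally across the sinks (−1/|T| each),
and node potentials solve the graph-Laplacian system L v = b.  The flow
through an interior node k is half the sum of absolute currents on its
incident edges, F_k = ½ Σ_j |w_kj (v_k − v_j)| — the current-flow
betweenness of the node for this source/sink pair.  For source and sink
nodes the reported value is the magnitude of net injected/extracted
current.  All flows are per unit injected current, so values are directly
comparable across ligand-occupancy states.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import spsolve

from .contacts import ContactGraph
from .errors import ConnectivityError, NumericalError, UsageError

#: residual tolerance ‖Lv − b‖∞ for the grounded solve
RESIDUAL_TOL = 1e-9


@dataclass(frozen=True)
class FlowNetwork:
    """A contact graph with disjoint, nonempty source and sink label sets."""

    graph: ContactGraph
    sources: frozenset[str]
    sinks: frozenset[str]

    def __init__(self, graph: ContactGraph, sources, sinks) -> None:
        object.__setattr__(self, "graph", graph)
        object.__setattr__(self, "sources", frozenset(sources))
        object.__setattr__(self, "sinks", frozenset(sinks))
        if not self.sources or not self.sinks:
            raise UsageError("sources and sinks must be nonempty")
        overlap = self.sources & self.sinks
        if overlap:
            raise UsageError(f"sources and sinks overlap: {sorted(overlap)}")
        known = set(graph.node_labels)
        missing = (self.sources | self.sinks) - known
        if missing:
            raise UsageError(f"labels not in graph: {sorted(missing)}")


@dataclass
class FlowResult:
    """Potentials, edge currents and per-node throughflow for unit injection."""

    node_labels: list[str]
    potentials: dict[str, float]
    throughflow: dict[str, float]
    edge_currents: dict[tuple[str, str], float]  # (i, j) with i→j positive
    effective_resistance: float
    sources: frozenset[str]
    sinks: frozenset[str]
    node_kinds: dict[str, str] = field(default_factory=dict)
    total_injected: float = 1.0

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "node_label": lab,
                "kind": self.node_kinds.get(lab, ""),
                "potential": self.potentials[lab],
                "throughflow": self.throughflow[lab],
            }
            for lab in self.node_labels
        ]
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.6g")


def _component_of(network: FlowNetwork) -> np.ndarray:
    """Indices of the connected component holding all sources and sinks."""
    g = network.graph
    adj = sp.csr_matrix(g.weights > 0)
    n_comp, labels = connected_components(adj, directed=False)
    terminals = network.sources | network.sinks
    comp_ids = {labels[g.index(t)] for t in terminals}
    if len(comp_ids) > 1:
        groups: dict[int, list[str]] = {}
        for t in sorted(terminals):
            groups.setdefault(int(labels[g.index(t)]), []).append(t)
        raise ConnectivityError(
            "sources and sinks span multiple connected components: "
            + "; ".join(f"component {c}: {v}" for c, v in sorted(groups.items()))
        )
    return np.flatnonzero(labels == comp_ids.pop())


def solve_potentials(network: FlowNetwork) -> dict[str, float]:
    """Node potentials for unit current, source set → sink set.

    Solves L v = b on the component containing the terminals with the
    gauge fixed by grounding the lexicographically first sink (v = 0).
    Nodes outside that component carry no current and get potential 0.
    """
    g = network.graph
    comp = _component_of(network)
    sub = g.weights[np.ix_(comp, comp)]
    lap = sp.csr_matrix(np.diag(sub.sum(axis=1)) - sub)
    local = {int(gi): k for k, gi in enumerate(comp)}
    b = np.zeros(len(comp))
    for s in network.sources:
        b[local[g.index(s)]] += 1.0 / len(network.sources)
    for t in network.sinks:
        b[local[g.index(t)]] -= 1.0 / len(network.sinks)
    ground = local[g.index(min(network.sinks))]
    keep = np.array([i for i in range(len(comp)) if i != ground], dtype=int)
    v = np.zeros(len(comp))
    if keep.size:
        reduced = lap[np.ix_(keep, keep)]
        try:
            v_keep = spsolve(reduced.tocsc(), b[keep])
        except Exception as exc:  # pragma: no cover - scipy raises rarely here
            raise NumericalError(f"grounded Laplacian solve failed: {exc}") from exc
        if not np.all(np.isfinite(v_keep)):
            raise NumericalError("singular reduced Laplacian system")
        v[keep] = v_keep
    residual = np.abs(lap @ v - b).max()
    if residual > RESIDUAL_TOL:
        raise NumericalError(
            f"potential solve residual {residual:.3e} exceeds {RESIDUAL_TOL:.0e}"
        )
    out = {lab: 0.0 for lab in g.node_labels}
    for gi, vi in zip(comp, v):
        out[g.node_labels[int(gi)]] = float(vi)
    return out


def compute_information_flow(network: FlowNetwork) -> FlowResult:
    """Full current-flow solution: potentials, edge currents, throughflow."""
    g = network.graph
    potentials = solve_potentials(network)
    v = np.array([potentials[lab] for lab in g.node_labels])
    current = g.weights * (v[:, None] - v[None, :])  # i_ij > 0 flows i→j
    labels = g.node_labels
    edge_currents: dict[tuple[str, str], float] = {}
    n = len(labels)
    for i in range(n):
        for j in range(i + 1, n):
            if g.weights[i, j] > 0:
                edge_currents[(labels[i], labels[j])] = float(current[i, j])
    abs_out = 0.5 * np.abs(current).sum(axis=1)
    net_out = current.sum(axis=1)
    throughflow = {}
    for i, lab in enumerate(labels):
        if lab in network.sources or lab in network.sinks:
            throughflow[lab] = float(abs(net_out[i]))
        else:
            throughflow[lab] = float(abs_out[i])
    src_pot = np.mean([potentials[s] for s in network.sources])
    sink_pot = np.mean([potentials[t] for t in network.sinks])
    kinds = dict(zip(labels, g.node_kinds)) if g.node_kinds else {}
    return FlowResult(
        node_labels=list(labels),
        potentials=potentials,
        throughflow=throughflow,
        edge_currents=edge_currents,
        effective_resistance=float(src_pot - sink_pot),
        sources=network.sources,
        sinks=network.sinks,
        node_kinds=kinds,
    )


def interactor_flow(result: FlowResult, interactor_label: str) -> float:
    """Throughflow of a named interactor (ligand/lipid) node."""
    if interactor_label not in result.throughflow:
        raise KeyError(f"no node labelled {interactor_label!r}")
    kind = result.node_kinds.get(interactor_label)
    if kind is not None and kind != "interactor":
        raise UsageError(f"node {interactor_label!r} is a {kind} node, not an interactor")
    return result.throughflow[interactor_label]


def compare_states(
    results: Mapping[str, Sequence[FlowResult]],
    reference: str,
) -> pd.DataFrame:
    """Per-node mean, SEM and delta-vs-reference across occupancy states.

    ``results`` maps condition name → one FlowResult per replicate.  Nodes
    absent from a condition (e.g. an unbound interactor) are reported as
    missing (NaN), not as zero.  SEM = sd/√n over replicates; NaN for n = 1.
    Delta = mean(condition) − mean(reference).
    """
    if reference not in results:
        raise UsageError(f"reference condition {reference!r} not among {sorted(results)}")
    for cond, reps in results.items():
        if not reps:
            raise UsageError(f"condition {cond!r} has no replicates")
    all_labels: list[str] = []
    for reps in results.values():
        for r in reps:
            for lab in r.node_labels:
                if lab not in all_labels:
                    all_labels.append(lab)
    stats: dict[str, dict[str, tuple[float, float]]] = {}
    for cond, reps in results.items():
        per_node: dict[str, tuple[float, float]] = {}
        for lab in all_labels:
            vals = [r.throughflow[lab] for r in reps if lab in r.throughflow]
            if not vals:
                continue
            arr = np.asarray(vals, dtype=float)
            mean = float(arr.mean())
            sem = float(arr.std(ddof=1) / np.sqrt(len(arr))) if len(arr) > 1 else float("nan")
            per_node[lab] = (mean, sem)
        stats[cond] = per_node
    rows = []
    for cond in results:
        for lab in all_labels:
            if lab not in stats[cond]:
                continue
            mean, sem = stats[cond][lab]
            ref_mean = stats[reference].get(lab, (float("nan"),))[0]
            rows.append({
                "condition": cond,
                "node_label": lab,
                "mean": mean,
                "sem": sem,
                "delta": mean - ref_mean,
            })
    return pd.DataFrame(rows)
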