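"""Time-averaged smoothed heavy-atom contact graphs.

An edge weight between two nodes is the time average, over trajectory
frames, of a smoothed step function of the minimum heavy-atom distance
between the nodes:

    s(d) = 1/2 · erfc((d − c) / (σ √2))

i.e. a Heaviside step at the cutoff ``c`` softened by a Gaussian of
standard deviation ``σ``.  With the defaults c = 4.5 Å and σ = 1.38 Å a
pair exactly at the cutoff scores 0.5, a pair one σ inside scores ≈ 0.84,
and far pairs decay to zero.  Weights are therefore contact frequencies in
[0, 1] and serve directly as edge conductances for the flow analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import erfc, erfcinv
from scipy.spatial.distance import cdist

from .errors import EmptyInputError, FormatError, UsageError
from .structure import Node, NodeMap, TrajectoryEnsemble

_SQRT2 = np.sqrt(2.0)


@dataclass(frozen=True)
class ContactParams:
    """Smoothed-contact parameters, in Å.

    c: midpoint of the smoothed step (default 4.5 Å = 0.45 nm).
    sigma: SD of the Gaussian smoothing (default 1.38 Å = 0.138 nm).
    prune_below: time-averaged weights below this are stored as exact 0.
    """

    c: float = 4.5
    sigma: float = 1.38
    prune_below: float = 1e-4

    def __post_init__(self) -> None:
        if self.c <= 0:
            raise UsageError(f"cutoff c must be > 0, got {self.c}")
        if self.sigma <= 0:
            raise UsageError(f"sigma must be > 0, got {self.sigma}")
        if not (0 <= self.prune_below < 1):
            raise UsageError(f"prune_below must be in [0, 1), got {self.prune_below}")


def smoothed_contact_weight(d, params: ContactParams = ContactParams()):
    """s(d) = ½·erfc((d − c)/(σ√2)); vectorized, nonincreasing, s(c) = ½."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise UsageError("distances must be nonnegative")
    out = 0.5 * erfc((d - params.c) / (params.sigma * _SQRT2))
    return float(out) if out.ndim == 0 else out


def inverse_contact_weight(w: float, params: ContactParams = ContactParams()) -> float:
    """Distance at which the smoothed contact equals ``w`` (0 < w < 1)."""
    if not 0 < w < 1:
        raise UsageError(f"weight must be in (0, 1), got {w}")
    return params.c + params.sigma * _SQRT2 * float(erfcinv(2.0 * w))


def node_pair_distance(frame_coords: np.ndarray, node_i: Node, node_j: Node) -> float:
    """Minimum heavy-atom Euclidean distance between two distinct nodes."""
    if node_i.label == node_j.label:
        raise UsageError(f"node_pair_distance called with node {node_i.label!r} twice")
    a = frame_coords[list(node_i.member_atoms)]
    b = frame_coords[list(node_j.member_atoms)]
    return float(cdist(a, b).min())


@dataclass
class ContactGraph:
    """Symmetric nonnegative edge-weight matrix over node labels."""

    node_labels: list[str]
    weights: np.ndarray  # (n, n) symmetric, zero diagonal, entries in [0, 1]
    n_frames_used: int
    params: ContactParams = field(default_factory=ContactParams)
    node_kinds: list[str] | None = None  # parallel to node_labels

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        n = len(self.node_labels)
        if w.shape != (n, n):
            raise UsageError(f"weights shape {w.shape} does not match {n} labels")
        if not np.allclose(w, w.T, atol=0, rtol=0):
            raise UsageError("weight matrix must be exactly symmetric")
        if np.any(np.diag(w) != 0):
            raise UsageError("weight matrix diagonal must be zero")
        if w.min() < 0 or w.max() > 1:
            raise UsageError("weights must lie in [0, 1]")
        self.weights = w
        if self.node_kinds is not None and len(self.node_kinds) != n:
            raise UsageError("node_kinds length must match node_labels")

    @property
    def n_nodes(self) -> int:
        return len(self.node_labels)

    def index(self, label: str) -> int:
        try:
            return self.node_labels.index(label)
        except ValueError:
            raise KeyError(label) from None

    def weight(self, label_i: str, label_j: str) -> float:
        return float(self.weights[self.index(label_i), self.index(label_j)])

    # -- serialization ----------------------------------------------------
    def to_edge_csv(self, path: str | Path) -> None:
        """Weighted edge list (node_i, node_j, weight); loads back bit-exactly."""
        lines = ["node_i,node_j,weight"]
        n = self.n_nodes
        for i in range(n):
            for j in range(i + 1, n):
                w = self.weights[i, j]
                if w > 0:
                    lines.append(f"{self.node_labels[i]},{self.node_labels[j]},{w:.17g}")
        # isolated nodes still need to appear; record them with weight 0 self rows
        header = "# nodes: " + ";".join(self.node_labels)
        kinds = "# kinds: " + ";".join(self.node_kinds) if self.node_kinds else "# kinds:"
        meta = (
            f"# params: c={self.params.c!r} sigma={self.params.sigma!r} "
            f"prune={self.params.prune_below!r} frames={self.n_frames_used}"
        )
        Path(path).write_text("\n".join([header, kinds, meta] + lines) + "\n")

    @classmethod
    def from_edge_csv(cls, path: str | Path) -> "ContactGraph":
        lines = Path(path).read_text().splitlines()
        if len(lines) < 4 or not lines[0].startswith("# nodes: "):
            raise FormatError(f"{path}: not a contact-graph edge list")
        labels = lines[0][len("# nodes: "):].split(";")
        kinds_s = lines[1][len("# kinds:"):].strip()
        kinds = kinds_s.split(";") if kinds_s else None
        meta = dict(
            kv.split("=") for kv in lines[2][len("# params: "):].split() if "=" in kv
        )
        params = ContactParams(
            c=float(meta["c"]), sigma=float(meta["sigma"]), prune_below=float(meta["prune"])
        )
        n = len(labels)
        idx = {lab: i for i, lab in enumerate(labels)}
        w = np.zeros((n, n))
        for line in lines[4:] if lines[3].startswith("node_i") else lines[3:]:
            if not line or line.startswith("node_i"):
                continue
            a, b, ws = line.split(",")
            w[idx[a], idx[b]] = w[idx[b], idx[a]] = float(ws)
        return cls(node_labels=labels, weights=w, n_frames_used=int(meta["frames"]),
                   params=params, node_kinds=kinds)

    def to_matrix_file(self, path: str | Path) -> None:
        """Dense matrix as text; loads back bit-exactly."""
        header = ";".join(self.node_labels)
        np.savetxt(path, self.weights, fmt="%.17g", header=header, delimiter=",")

    @classmethod
    def from_matrix_file(cls, path: str | Path,
                         params: ContactParams = ContactParams(),
                         n_frames_used: int = 0) -> "ContactGraph":
        lines = Path(path).read_text().splitlines()
        labels = lines[0].lstrip("# ").split(";")
        w = np.loadtxt(path, delimiter=",", ndmin=2)
        return cls(node_labels=labels, weights=w, params=params,
                   n_frames_used=n_frames_used)


def _min_distance_matrix(frame: np.ndarray, nodes: Sequence[Node]) -> np.ndarray:
    """Per-frame minimum heavy-atom distance between every node pair."""
    atom_idx = np.concatenate([np.array(n.member_atoms, dtype=int) for n in nodes])
    owner = np.concatenate([
        np.full(len(n.member_atoms), k, dtype=int) for k, n in enumerate(nodes)
    ])
    pts = frame[atom_idx]
    d_atoms = cdist(pts, pts)
    n = len(nodes)
    dmin = np.full((n, n), np.inf)
    np.minimum.at(dmin, (owner[:, None], owner[None, :]), d_atoms)
    np.fill_diagonal(dmin, 0.0)
    return dmin


def build_contact_graph(
    traj: TrajectoryEnsemble,
    node_map: NodeMap,
    params: ContactParams = ContactParams(),
) -> ContactGraph:
    """w_ij = (1/T) Σ_t s(d_ij(t)), then pruned below ``params.prune_below``.

    Smoothing is applied per frame and then time-averaged, so a weight is
    the mean smoothed-contact occupancy of the pair.  Deterministic for
    fixed inputs; frame order does not matter.
    """
    if len(node_map) == 0:
        raise EmptyInputError("node map has no nodes")
    if traj.n_frames < 1:
        raise EmptyInputError("trajectory has no frames")
    for node in node_map.nodes:
        for i in node.member_atoms:
            if i < 0 or i >= traj.topology.n_atoms:
                raise UsageError(f"node {node.label!r} references atom {i} outside topology")
    n = len(node_map)
    T = traj.n_frames
    if T * n * n <= 2 ** 27:  # ~1 GiB of float64 scratch
        per_frame = np.empty((T, n, n))
        for t, frame in enumerate(traj.coords_block):
            dmin = _min_distance_matrix(frame, node_map.nodes)
            s = 0.5 * erfc((dmin - params.c) / (params.sigma * _SQRT2))
            np.fill_diagonal(s, 0.0)
            per_frame[t] = s
        # summing the sorted per-frame terms makes the average exactly
        # invariant under frame permutation
        per_frame.sort(axis=0)
        w = per_frame.sum(axis=0) / T
    else:  # streaming Kahan accumulation for very large frame × node counts
        acc = np.zeros((n, n))
        comp = np.zeros((n, n))
        for frame in traj.coords_block:
            dmin = _min_distance_matrix(frame, node_map.nodes)
            s = 0.5 * erfc((dmin - params.c) / (params.sigma * _SQRT2))
            np.fill_diagonal(s, 0.0)
            y = s - comp
            t_ = acc + y
            comp = (t_ - acc) - y
            acc = t_
        w = acc / T
    w[w < params.prune_below] = 0.0
    w = 0.5 * (w + w.T)  # symmetrize away accumulation round-off
    np.fill_diagonal(w, 0.0)
    return ContactGraph(
        node_labels=node_map.labels,
        weights=w,
        n_frames_used=traj.n_frames,
        params=params,
        node_kinds=[nd.kind for nd in node_map.nodes],
    )
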