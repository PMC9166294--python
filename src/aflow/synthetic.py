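"""Synthetic systems with known ground truth.

Everything the analysis pipeline consumes can be generated here without
external downloads:

* Gaussian elastic-network ensembles whose per-node fluctuations follow
  the closed form RMSF_i = √(3·(kT/γ)·(Γ⁺)_ii), for validating RMSF code;
* contact systems with a single constructed bottleneck between a source
  patch and a sink patch (every unit of injected current must cross it);
* two-route systems with an exactly tunable flow split r/(1+r);
* a four-condition ligand-occupancy series (none / site A / site B / both)
  with constructed qualitative flow orderings;
* small toy conductance graphs (series, parallel, Wheatstone, random).

Synthetic residues are single-heavy-atom pseudo-residues except where a
node needs spatial extent, in which case three-atom residues/beads are
used so that minimum-distance and centroid conventions are both
exercised.  Every generator is a pure function of its spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

import yaml

from .contacts import ContactGraph, ContactParams, build_contact_graph, inverse_contact_weight
from .errors import SpecError, UsageError
from .structure import (
    AtomRecord,
    NodeMap,
    StructureModel,
    TrajectoryEnsemble,
    build_node_map,
    write_model_pdb,
)

#: default SD (Å) of the frame-to-frame positional jitter used to realize
#: persistent / absent contacts with controlled intermediate weights
JITTER_SD = 0.2


# ---------------------------------------------------------------------------
# building blocks


def _atom(idx: int, name: str, element: str, resnum: int, resname: str,
          chain: str, xyz) -> AtomRecord:
    return AtomRecord(
        atom_index=idx, atom_name=name, element=element,
        residue_number=resnum, residue_name=resname, chain_id=chain,
        coords=np.asarray(xyz, dtype=float),
    )


def _single_atom_residues(positions: np.ndarray, chain: str = "A",
                          first_resnum: int = 1, resname: str = "GLY",
                          start_index: int = 0) -> list[AtomRecord]:
    return [
        _atom(start_index + k, "CA", "C", first_resnum + k, resname, chain, xyz)
        for k, xyz in enumerate(positions)
    ]


@dataclass
class SyntheticSystem:
    """A generated trajectory plus its node partition and ground truth."""

    name: str
    structure: StructureModel
    trajectory: TrajectoryEnsemble
    node_map: NodeMap
    sources: list[str]
    sinks: list[str]
    interactor_selectors: list[dict] = field(default_factory=list)
    ground_truth: dict = field(default_factory=dict)

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Emit a multi-model PDB trajectory and a YAML ground-truth sidecar."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        traj_path = outdir / f"{self.name}.pdb"
        write_model_pdb(self.structure, self.trajectory.coords_block, traj_path)
        gt_path = outdir / f"{self.name}_ground_truth.yaml"
        payload = {
            "system": self.name,
            "sources": self.sources,
            "sinks": self.sinks,
            "interactor_selectors": self.interactor_selectors,
            "ground_truth": _plain(self.ground_truth),
        }
        gt_path.write_text(yaml.safe_dump(payload, sort_keys=True))
        return {"trajectory": traj_path, "ground_truth": gt_path}


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def _jittered_frames(base: np.ndarray, n_frames: int, sd: float,
                     rng: np.random.Generator) -> np.ndarray:
    return base[None, :, :] + rng.normal(0.0, sd, size=(n_frames,) + base.shape)


# ---------------------------------------------------------------------------
# elastic-network (GNM-style) sampler


@dataclass(frozen=True)
class ENMSpec:
    """Elastic-network sampling spec.

    ``kt_over_gamma`` (Å²) scales the fluctuation amplitude; the Kirchhoff
    matrix uses unit springs between nodes within ``enm_cutoff`` Å.
    """

    reference_coords: np.ndarray  # (N, 3) Å
    enm_cutoff: float = 10.0
    kt_over_gamma: float = 1.0
    n_frames: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        ref = np.asarray(self.reference_coords, dtype=float)
        if ref.ndim != 2 or ref.shape[1] != 3 or ref.shape[0] < 2:
            raise SpecError("reference_coords must be (N >= 2, 3)")
        object.__setattr__(self, "reference_coords", ref)
        if self.enm_cutoff <= 0:
            raise SpecError("enm_cutoff must be positive")
        if self.n_frames < 2:
            raise SpecError("n_frames must be >= 2")


def kirchhoff_matrix(coords: np.ndarray, cutoff: float) -> np.ndarray:
    """Γ: −1 for pairs within cutoff, contact degree on the diagonal."""
    coords = np.asarray(coords, dtype=float)
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
    contact = (d <= cutoff) & ~np.eye(len(coords), dtype=bool)
    gamma = -contact.astype(float)
    np.fill_diagonal(gamma, contact.sum(axis=1))
    return gamma


def sample_enm_trajectory(spec: ENMSpec) -> tuple[TrajectoryEnsemble, np.ndarray]:
    """Gaussian samples with per-coordinate covariance (kT/γ)·Γ⁺.

    Returns the trajectory and the theoretical per-node RMSF vector
    √(3·(kT/γ)·(Γ⁺)_ii).  Raises :class:`SpecError` if the network is
    disconnected (more than one zero eigenvalue of Γ).
    """
    ref = spec.reference_coords
    n = ref.shape[0]
    gamma = kirchhoff_matrix(ref, spec.enm_cutoff)
    evals, evecs = np.linalg.eigh(gamma)
    tol = 1e-9 * max(evals.max(), 1.0)
    n_zero = int(np.sum(evals < tol))
    if n_zero != 1:
        raise SpecError(
            f"elastic network is disconnected: Kirchhoff matrix has {n_zero} "
            "zero eigenvalues (expected exactly 1)"
        )
    lam = evals[1:]
    modes = evecs[:, 1:]
    pinv_diag = (modes ** 2 / lam).sum(axis=1)
    theoretical_rmsf = np.sqrt(3.0 * spec.kt_over_gamma * pinv_diag)
    rng = np.random.default_rng(spec.seed)
    z = rng.standard_normal((3, n - 1, spec.n_frames))
    amp = np.sqrt(spec.kt_over_gamma / lam)
    coords = np.repeat(ref[None, :, :], spec.n_frames, axis=0)
    for axis in range(3):
        disp = modes @ (amp[:, None] * z[axis])  # (N, n_frames)
        coords[:, :, axis] += disp.T
    structure = StructureModel(atoms=_single_atom_residues(ref))
    traj = TrajectoryEnsemble(coords_block=coords, topology=structure)
    return traj, theoretical_rmsf


def enm_chain_coords(n: int, spacing: float = 3.8) -> np.ndarray:
    """A slightly kinked chain, a convenient elastic-network reference."""
    t = np.arange(n, dtype=float)
    return np.stack([spacing * t, 1.5 * np.sin(0.9 * t), 1.0 * np.cos(1.3 * t)], axis=1)


# ---------------------------------------------------------------------------
# bottleneck pathway system


@dataclass(frozen=True)
class PathwaySystemSpec:
    """Spec for the constructed source→bridge→sink contact system."""

    n_source: int = 3
    n_sink: int = 3
    n_bridge: int = 3
    background_nodes: int = 4
    contact_persistence: float = 1.0
    seed: int = 0
    n_frames: int = 20
    jitter_sd: float = JITTER_SD

    def __post_init__(self) -> None:
        if min(self.n_source, self.n_sink, self.n_bridge) < 1:
            raise SpecError("n_source, n_sink and n_bridge must all be >= 1")
        if self.background_nodes < 0:
            raise SpecError("background_nodes must be >= 0")
        if not 0 < self.contact_persistence <= 1:
            raise SpecError("contact_persistence must be in (0, 1]")
        if self.n_frames < 2:
            raise SpecError("n_frames must be >= 2")


def generate_bottleneck_system(spec: PathwaySystemSpec) -> SyntheticSystem:
    """Source patch ↔ bridge chain ↔ sink patch, plus dead-end background.

    Patch atoms are stacked 4 Å apart (persistent contacts); the bridge
    chain runs at 5 Å steps, so the direct source–sink distance is at
    least 10 Å and prunes to zero: all current must cross the bridge,
    whose nodes therefore each carry the full unit throughflow.
    Background nodes hang off the source patch as a dead-end chain and
    carry (essentially) none.
    """
    step_patch, step_bridge = 4.0, 5.0
    positions: list[np.ndarray] = []
    roles: list[str] = []
    for k in range(spec.n_source):
        positions.append(np.array([0.0, step_patch * k, 0.0]))
        roles.append("source")
    for j in range(1, spec.n_bridge + 1):
        positions.append(np.array([step_bridge * j, 0.0, 0.0]))
        roles.append("bridge")
    x_end = step_bridge * (spec.n_bridge + 1)
    for k in range(spec.n_sink):
        positions.append(np.array([x_end, step_patch * k, 0.0]))
        roles.append("sink")
    for m in range(spec.background_nodes):
        positions.append(np.array([-step_bridge * (m + 1), -step_bridge * (m + 1), 0.0]))
        roles.append("background")
    base = np.array(positions)
    structure = StructureModel(atoms=_single_atom_residues(base))
    node_map = build_node_map(structure)
    labels = node_map.labels
    by_role = {
        role: [lab for lab, r in zip(labels, roles) if r == role]
        for role in ("source", "bridge", "sink", "background")
    }
    # no-bypass consistency check on the noiseless geometry
    static = TrajectoryEnsemble(coords_block=base[None, :, :], topology=structure)
    g0 = build_contact_graph(static, node_map)
    for s in by_role["source"]:
        for t in by_role["sink"]:
            if g0.weight(s, t) > 0:
                raise SpecError(
                    f"constructed geometry creates a source–sink bypass {s}–{t}"
                )
    rng = np.random.default_rng(spec.seed)
    coords = _jittered_frames(base, spec.n_frames, spec.jitter_sd, rng)
    if spec.contact_persistence < 1:
        bridge_idx = [i for i, r in enumerate(roles) if r == "bridge"]
        broken = rng.random(spec.n_frames) > spec.contact_persistence
        coords[np.ix_(np.flatnonzero(broken), bridge_idx)] += np.array([0.0, 0.0, 25.0])
    traj = TrajectoryEnsemble(coords_block=coords, topology=structure)
    return SyntheticSystem(
        name="bottleneck",
        structure=structure,
        trajectory=traj,
        node_map=node_map,
        sources=by_role["source"],
        sinks=by_role["sink"],
        ground_truth={
            "bridge_labels": by_role["bridge"],
            "background_labels": by_role["background"],
            "expected_bridge_throughflow": 1.0,
        },
    )


# ---------------------------------------------------------------------------
# two-route flow-split system


def generate_two_path_system(
    ratio: float,
    n_mid: int = 2,
    weight_hi: float = 0.3,
    n_frames: int = 2,
    seed: int = 0,
) -> SyntheticSystem:
    """Two disjoint source→sink routes with conductance ratio ``ratio``.

    Route edges carry uniform time-averaged weights g and ratio·g (g
    chosen so the heavier route weighs ``weight_hi``); with equal edge
    counts the current split is exactly 1/(1+r) vs r/(1+r).  Routes run
    along lanes offset ±5 Å in y, so every cross-route atom pair is ≥ 10 Å
    apart and prunes to zero; route nodes are three-atom residues whose
    spatial extent keeps non-adjacent pairs out of contact range.
    """
    if ratio <= 0:
        raise SpecError(f"ratio must be > 0, got {ratio}")
    if n_mid < 1:
        raise SpecError("n_mid must be >= 1")
    if not 0 < weight_hi <= 0.35:
        raise SpecError("weight_hi must be in (0, 0.35] to keep routes separable")
    g = weight_hi / max(1.0, ratio)
    w_a, w_b = g, g * ratio  # route A carries 1/(1+r), route B r/(1+r)
    d_a = inverse_contact_weight(w_a)
    d_b = inverse_contact_weight(w_b)
    lane = 5.0
    s0 = 3.0  # baseline intra-node atom spacing

    def footprint(d: float, s_int: float) -> float:
        return 2.0 * np.sqrt(d * d - lane * lane) + 2.0 * n_mid * s_int + (n_mid - 1) * d

    length = max(footprint(d_a, s0), footprint(d_b, s0))

    def stretch(d: float) -> float:
        return (length - 2.0 * np.sqrt(d * d - lane * lane) - (n_mid - 1) * d) / (2.0 * n_mid)

    atoms: list[AtomRecord] = []
    atoms.append(_atom(0, "CA", "C", 1, "GLY", "A", (0.0, 0.0, 0.0)))        # S
    atoms.append(_atom(1, "CA", "C", 2, "GLY", "A", (length, 0.0, 0.0)))     # T
    idx = 2

    def add_route(d: float, y: float, first_resnum: int) -> list[str]:
        nonlocal idx
        s_int = stretch(d)
        if s_int < 1.0:
            raise SpecError("route geometry collapsed; lower ratio or raise n_mid")
        x1 = np.sqrt(d * d - lane * lane)
        route_labels = []
        for k in range(n_mid):
            x = x1 + k * (2 * s_int + d)
            resnum = first_resnum + k
            for name, dx in (("N", 0.0), ("CA", s_int), ("C", 2 * s_int)):
                el = "N" if name == "N" else "C"
                atoms.append(_atom(idx, name, el, resnum, "GLY", "A", (x + dx, y, 0.0)))
                idx += 1
            route_labels.append(f"A:GLY{resnum}")
        return route_labels

    route_a = add_route(d_a, +lane, 11)
    route_b = add_route(d_b, -lane, 11 + n_mid)
    structure = StructureModel(atoms=atoms)
    node_map = build_node_map(structure)
    base = structure.coords()
    static = TrajectoryEnsemble(coords_block=base[None, :, :], topology=structure)
    g0 = build_contact_graph(static, node_map)
    expected_edges = set()
    for route in (route_a, route_b):
        chain = ["A:GLY1"] + route + ["A:GLY2"]
        for u, v in zip(chain, chain[1:]):
            expected_edges.add(frozenset((u, v)))
    actual_edges = {
        frozenset((g0.node_labels[i], g0.node_labels[j]))
        for i in range(g0.n_nodes) for j in range(i + 1, g0.n_nodes)
        if g0.weights[i, j] > 0
    }
    if actual_edges != expected_edges:
        raise SpecError(
            "two-path geometry produced unexpected contacts: "
            f"{sorted(map(sorted, actual_edges ^ expected_edges))}"
        )
    coords = np.repeat(base[None, :, :], n_frames, axis=0)
    traj = TrajectoryEnsemble(coords_block=coords, topology=structure)
    return SyntheticSystem(
        name="two_path",
        structure=structure,
        trajectory=traj,
        node_map=node_map,
        sources=["A:GLY1"],
        sinks=["A:GLY2"],
        ground_truth={
            "route_a_labels": route_a,
            "route_b_labels": route_b,
            "split_route_a": 1.0 / (1.0 + ratio),
            "split_route_b": ratio / (1.0 + ratio),
            "edge_weight_route_a": w_a,
            "edge_weight_route_b": w_b,
        },
    )


# ---------------------------------------------------------------------------
# four-condition occupancy series


STATE_NAMES = ("none", "A_only", "B_only", "both")


def generate_state_series(
    seed: int = 0,
    n_frames: int = 20,
    jitter_sd: float = JITTER_SD,
    dangling_site_b: bool = False,
) -> dict[str, SyntheticSystem]:
    """Four occupancy states of a source→sink chain with two ligand sites.

    The backbone S–p1–p2–p3–T always connects source to sink.  Interactor
    A (a three-atom bead) lies on the path, bridging p1/p2/p3 in parallel
    with the backbone; interactor B bridges a weakly coupled side region
    (q1, q2) around the same segment.  By construction:

    * flow through A exceeds flow through B when both are bound, and
    * flow through A decreases from the A-only state to the both state,
      because B opens a parallel route.

    With ``dangling_site_b`` the side region loses its second anchor, so B
    becomes a dead end and carries no current in the B-only state.
    """
    backbone = [
        ("S", (0.0, 0.0, 0.0)),
        ("p1", (5.0, 0.0, 0.0)),
        ("p2", (10.0, 0.0, 0.0)),
        ("p3", (15.0, 0.0, 0.0)),
        ("T", (20.0, 0.0, 0.0)),
    ]
    side = [("q1", (5.0, -7.0, 0.0))]
    if not dangling_site_b:
        side.append(("q2", (15.0, -7.0, 0.0)))
    h_a = float(np.sqrt(4.5 ** 2 - 2.0 ** 2))  # site A bead 4.5 Å off p1/p3
    bead_a = [(7.0, h_a, 0.0), (10.0, h_a, 0.0), (13.0, h_a, 0.0)]
    if dangling_site_b:
        bead_b = [(5.0, -10.0, 0.0), (5.0, -13.0, 0.0), (5.0, -16.0, 0.0)]
    else:
        bead_b = [(8.0, -7.0, 0.0), (10.0, -7.0, 0.0), (12.0, -7.0, 0.0)]
    systems: dict[str, SyntheticSystem] = {}
    rng_master = np.random.default_rng(seed)
    state_seeds = {name: int(s) for name, s in
                   zip(STATE_NAMES, rng_master.integers(0, 2 ** 31 - 1, len(STATE_NAMES)))}
    for state in STATE_NAMES:
        atoms: list[AtomRecord] = []
        idx = 0
        for resnum, (_tag, xyz) in enumerate(backbone + side, start=1):
            atoms.append(_atom(idx, "CA", "C", resnum, "GLY", "A", xyz))
            idx += 1
        with_a = state in ("A_only", "both")
        with_b = state in ("B_only", "both")
        for present, resnum, bead in ((with_a, 101, bead_a), (with_b, 102, bead_b)):
            if not present:
                continue
            for k, xyz in enumerate(bead):
                name = ("C1", "C2", "O1")[k]
                el = "O" if name.startswith("O") else "C"
                atoms.append(_atom(idx, name, el, resnum, "CLR", "L", xyz))
                idx += 1
        structure = StructureModel(atoms=atoms)
        node_map = build_node_map(structure, [{"residue_name": "CLR"}])
        base = structure.coords()
        rng = np.random.default_rng(state_seeds[state])
        coords = _jittered_frames(base, n_frames, jitter_sd, rng)
        traj = TrajectoryEnsemble(coords_block=coords, topology=structure)
        systems[state] = SyntheticSystem(
            name=f"states_{state}",
            structure=structure,
            trajectory=traj,
            node_map=node_map,
            sources=["A:GLY1"],
            sinks=["A:GLY5"],
            interactor_selectors=[{"residue_name": "CLR"}],
            ground_truth={
                "site_a_label": "L:CLR101" if with_a else None,
                "site_b_label": "L:CLR102" if with_b else None,
                "orderings": [
                    "flow(A | both) > flow(B | both)",
                    "flow(A | both) < flow(A | A_only)",
                ],
            },
        )
    return systems


# ---------------------------------------------------------------------------
# toy conductance graphs


def make_toy_graph(kind: str, seed: Optional[int] = None, **kwargs) -> ContactGraph:
    """Small named conductance graphs used as flow-solver fixtures.

    kinds: ``series`` (chain of n nodes, unit edges), ``parallel`` (two
    2-edge branches with branch conductances g1, g2), ``wheatstone``
    (four equal arms plus a bridge edge), ``random`` (seeded connected
    graph with 5–12 nodes).
    """
    params = ContactParams()
    if kind == "series":
        n = int(kwargs.pop("n", 3))
        if kwargs:
            raise UsageError(f"unknown arguments {sorted(kwargs)}")
        labels = [f"n{i}" for i in range(n)]
        w = np.zeros((n, n))
        for i in range(n - 1):
            w[i, i + 1] = w[i + 1, i] = 1.0
    elif kind == "parallel":
        g1 = float(kwargs.pop("g1", 0.25))
        g2 = float(kwargs.pop("g2", 0.75))
        if kwargs:
            raise UsageError(f"unknown arguments {sorted(kwargs)}")
        labels = ["S", "M1", "M2", "T"]
        w = np.zeros((4, 4))
        for i, j, g in ((0, 1, g1), (1, 3, g1), (0, 2, g2), (2, 3, g2)):
            w[i, j] = w[j, i] = g
    elif kind == "wheatstone":
        arm = float(kwargs.pop("arm", 0.5))
        bridge = float(kwargs.pop("bridge", 0.3))
        if kwargs:
            raise UsageError(f"unknown arguments {sorted(kwargs)}")
        labels = ["S", "M1", "M2", "T"]
        w = np.zeros((4, 4))
        for i, j, g in ((0, 1, arm), (0, 2, arm), (1, 3, arm), (2, 3, arm), (1, 2, bridge)):
            w[i, j] = w[j, i] = g
    elif kind == "random":
        if kwargs:
            raise UsageError(f"unknown arguments {sorted(kwargs)}")
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 13))
        labels = [f"n{i}" for i in range(n)]
        w = np.zeros((n, n))
        for i in range(1, n):  # random spanning tree keeps the graph connected
            j = int(rng.integers(0, i))
            w[i, j] = w[j, i] = float(rng.uniform(0.05, 1.0))
        for _ in range(int(rng.integers(0, n))):
            i, j = int(rng.integers(0, n)), int(rng.integers(0, n))
            if i != j and w[i, j] == 0:
                w[i, j] = w[j, i] = float(rng.uniform(0.05, 1.0))
    else:
        raise UsageError(f"unknown toy graph kind {kind!r}")
    return ContactGraph(node_labels=labels, weights=w, n_frames_used=1, params=params)
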