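"""Trajectory observables: superposition, RMSF, distances, H-bonds, ligand drift.

These are the activation metrics used alongside the network analysis:
per-residue root mean square fluctuation after rigid-body superposition,
inter-residue Cα distance distributions (outward helix movement), hydrogen
bond occupancy (donor–acceptor distance with an optional D–H···A angle when
hydrogens are present), and the stability of a bound ligand relative to the
protein frame.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .errors import UsageError
from .structure import Node, NodeMap, StructureModel, TrajectoryEnsemble


class GeometryError(UsageError):
    """Degenerate point configuration for superposition."""


@dataclass(frozen=True)
class AlignmentResult:
    """Least-squares rigid superposition: x_aligned = x @ rotation.T + translation."""

    rotation: np.ndarray  # (3, 3) proper orthogonal
    translation: np.ndarray  # (3,)
    rmsd: float

    def transform(self, points: np.ndarray) -> np.ndarray:
        return points @ self.rotation.T + self.translation


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: Optional[np.ndarray] = None,
) -> AlignmentResult:
    """Optimal proper rotation + translation minimizing weighted RMSD.

    Reflections are excluded by the usual determinant sign correction.
    Requires ≥ 3 non-collinear points.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise UsageError("mobile and reference must both be (n, 3)")
    n = mobile.shape[0]
    if n < 3:
        raise GeometryError(f"need at least 3 points, got {n}")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() == 0:
            raise UsageError("weights must be nonnegative with positive sum")
    wn = w / w.sum()
    mob_c = mobile - wn @ mobile
    ref_c = reference - wn @ reference
    cov = (mob_c * wn[:, None]).T @ ref_c
    u, s, vt = np.linalg.svd(cov)
    if s[1] < 1e-12 * max(s[0], 1e-300):
        raise GeometryError("points are collinear; rotation is underdetermined")
    sign = np.sign(np.linalg.det(u @ vt))
    d = np.diag([1.0, 1.0, sign if sign != 0 else 1.0])
    rotation = (u @ d @ vt).T  # applied as x @ R.T
    translation = (wn @ reference) - (wn @ mobile) @ rotation.T
    aligned = mobile @ rotation.T + translation
    rmsd = float(np.sqrt((wn * ((aligned - reference) ** 2).sum(axis=1)).sum()))
    return AlignmentResult(rotation=rotation, translation=translation, rmsd=rmsd)


def _align_frames(
    coords: np.ndarray, reference: np.ndarray, fit_idx: np.ndarray
) -> np.ndarray:
    """Superpose every frame on ``reference`` using the fit selection."""
    out = np.empty_like(coords)
    for t, frame in enumerate(coords):
        ali = kabsch_superpose(frame[fit_idx], reference[fit_idx])
        out[t] = ali.transform(frame)
    return out


def compute_rmsf(
    traj: TrajectoryEnsemble,
    atom_indices: Sequence[int],
    align: bool = True,
    align_indices: Optional[Sequence[int]] = None,
) -> np.ndarray:
    """Per-atom RMSF_i = √(mean_t ‖r_i(t) − ⟨r_i⟩‖²) after superposition.

    With ``align`` the frames are superposed on an iterated mean structure
    (two passes: mean of raw frames, then mean of the first-pass-aligned
    frames) using ``align_indices`` (default: the analyzed atoms).
    """
    if traj.n_frames < 2:
        raise UsageError("RMSF needs at least 2 frames")
    sel = np.asarray(atom_indices, dtype=int)
    if sel.size == 0:
        raise UsageError("empty atom selection")
    coords = traj.coords_block
    if align:
        fit = np.asarray(align_indices if align_indices is not None else sel, dtype=int)
        mean0 = coords.mean(axis=0)
        pass1 = _align_frames(coords, mean0, fit)
        mean1 = pass1.mean(axis=0)
        coords = _align_frames(coords, mean1, fit)
    pts = coords[:, sel, :]
    mean = pts.mean(axis=0)
    return np.sqrt(((pts - mean) ** 2).sum(axis=2).mean(axis=0))


def rmsf_profile(
    traj: TrajectoryEnsemble,
    node_map: NodeMap,
    align: bool = True,
) -> dict[str, float]:
    """RMSF of each residue node's anchor (Cα), aligned on all residue anchors."""
    residue_nodes = [n for n in node_map.nodes if n.kind == "residue"]
    if not residue_nodes:
        raise UsageError("node map has no residue nodes")
    anchors = np.array([n.anchor_atom for n in residue_nodes], dtype=int)
    values = compute_rmsf(traj, anchors, align=align, align_indices=anchors)
    return {n.label: float(v) for n, v in zip(residue_nodes, values)}


@dataclass
class DistanceSeries:
    """Per-frame distance between two atoms plus a density histogram."""

    atom_a: int
    atom_b: int
    values: np.ndarray  # Å per frame
    bin_edges: np.ndarray
    density: np.ndarray  # sums to 1 when multiplied by bin width


def pair_distance_series(
    traj: TrajectoryEnsemble,
    atom_a: int,
    atom_b: int,
    bin_width: float = 0.5,
) -> DistanceSeries:
    """Euclidean distance per frame; histogram with bins anchored at 0."""
    if atom_a == atom_b:
        raise UsageError("atom_a and atom_b must differ")
    if bin_width <= 0:
        raise UsageError("bin_width must be positive")
    d = np.linalg.norm(
        traj.coords_block[:, atom_a, :] - traj.coords_block[:, atom_b, :], axis=1
    )
    upper = (np.floor(d.max() / bin_width) + 1) * bin_width
    edges = np.arange(0.0, upper + 0.5 * bin_width, bin_width)
    density, edges = np.histogram(d, bins=edges, density=True)
    return DistanceSeries(atom_a=atom_a, atom_b=atom_b, values=d,
                          bin_edges=edges, density=density)


@dataclass(frozen=True)
class HBondCriteria:
    """Donor–acceptor heavy-atom cutoff (default 3.0 Å) and D–H···A angle.

    The angle criterion (default 150°) applies only when the donor has an
    attached hydrogen in the topology; otherwise the distance criterion
    alone decides.
    """

    da_cutoff: float = 3.0
    dha_angle_min: float = 150.0

    def __post_init__(self) -> None:
        if self.da_cutoff <= 0:
            raise UsageError("da_cutoff must be positive")
        if not 0 < self.dha_angle_min <= 180:
            raise UsageError("dha_angle_min must be in (0, 180]")


def _attached_hydrogens(structure: StructureModel, donor: int,
                        frame0: np.ndarray, bond_cut: float = 1.25) -> list[int]:
    d_atom = structure.atoms[donor]
    out = []
    for a in structure.atoms:
        if a.is_heavy:
            continue
        if (a.chain_id, a.residue_number) != (d_atom.chain_id, d_atom.residue_number):
            continue
        if np.linalg.norm(frame0[a.atom_index] - frame0[donor]) <= bond_cut:
            out.append(a.atom_index)
    return out


def hbond_occupancy(
    traj: TrajectoryEnsemble,
    donors: Sequence[int],
    acceptors: Sequence[int],
    criteria: HBondCriteria = HBondCriteria(),
) -> dict[tuple[int, int], float]:
    """Fraction of frames each donor–acceptor pair satisfies the criteria.

    A frame counts when the donor–acceptor heavy-atom distance is within
    the cutoff and, if the donor carries hydrogens, at least one D–H···A
    angle meets the minimum.
    """
    if len(donors) == 0 or len(acceptors) == 0:
        raise UsageError("donor and acceptor selections must be nonempty")
    coords = traj.coords_block
    frame0 = coords[0]
    hydrogens = {d: _attached_hydrogens(traj.topology, d, frame0) for d in donors}
    out: dict[tuple[int, int], float] = {}
    for d in donors:
        for a in acceptors:
            if d == a:
                continue
            dist = np.linalg.norm(coords[:, d, :] - coords[:, a, :], axis=1)
            ok = dist <= criteria.da_cutoff
            hs = hydrogens[d]
            if hs:
                angle_ok = np.zeros(traj.n_frames, dtype=bool)
                for h in hs:
                    v1 = coords[:, d, :] - coords[:, h, :]
                    v2 = coords[:, a, :] - coords[:, h, :]
                    cosang = (v1 * v2).sum(axis=1) / (
                        np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1)
                    )
                    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
                    angle_ok |= ang >= criteria.dha_angle_min
                ok &= angle_ok
            out[(d, a)] = float(ok.mean())
    return out


def ligand_displacement(
    traj: TrajectoryEnsemble,
    interactor_node: Node,
    protein_atom_indices: Sequence[int],
) -> dict[str, np.ndarray]:
    """Ligand drift per frame, in the protein frame of reference.

    Each frame is superposed on frame 0 using the protein selection; the
    ligand's heavy-atom center-of-geometry displacement and its RMSD
    versus frame 0 (without further fitting) are then reported.
    """
    if traj.n_frames < 2:
        raise UsageError("ligand stability needs at least 2 frames")
    lig = np.asarray(interactor_node.member_atoms, dtype=int)
    if lig.size == 0:
        raise UsageError("interactor node has no atoms")
    prot = np.asarray(protein_atom_indices, dtype=int)
    ref = traj.coords_block[0]
    aligned = _align_frames(traj.coords_block, ref, prot)
    lig_ref = aligned[0][lig]
    com_ref = lig_ref.mean(axis=0)
    com_disp = np.empty(traj.n_frames)
    rmsd = np.empty(traj.n_frames)
    for t in range(traj.n_frames):
        pts = aligned[t][lig]
        com_disp[t] = np.linalg.norm(pts.mean(axis=0) - com_ref)
        rmsd[t] = np.sqrt(((pts - lig_ref) ** 2).sum(axis=1).mean())
    return {"com_displacement": com_disp, "ligand_rmsd": rmsd}
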