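"""Structures, trajectories and the residue/interactor node partition.

The network analysis views a simulated membrane protein as a set of nodes:
one node per amino-acid residue (all of its heavy atoms) and one node per
selected ligand/lipid molecule (an "interactor" node, e.g. one cholesterol).
This module reads coordinate data, builds that partition, and writes
annotated outputs (per-node CSV tables and B-factor-encoded PDB files).

Internal length unit is Å throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .errors import (
    EmptyInputError,
    FormatError,
    InputError,
    TopologyMismatchError,
    UsageError,
)

#: Three-letter codes treated as amino acids (standard 20 plus common
#: protonation/tautomer variants and selenomethionine).
AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "HSD", "HSE", "HSP", "HID", "HIE", "HIP", "CYX", "MSE", "SEC", "PYL",
}

ONE_LETTER = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}

#: Residue names that are never nodes: waters and monoatomic ions.
WATER_NAMES = {"HOH", "WAT", "TIP3", "TIP4", "SOL", "H2O"}
ION_NAMES = {
    "NA", "CL", "K", "MG", "CA", "ZN", "MN", "FE", "CU", "NI", "CO",
    "LI", "RB", "CS", "BR", "IOD", "F", "CD", "SR", "BA", "SOD", "CLA", "POT",
}

#: Two-letter elements used to disambiguate atom-name-based element
#: inference in legacy PDB files lacking the element column.
_TWO_LETTER_ELEMENTS = {
    "BR", "CL", "FE", "MG", "MN", "ZN", "NA", "CU", "NI", "CO", "SE",
    "CD", "LI", "RB", "CS", "SR", "BA", "AL", "SI",
}


@dataclass(frozen=True)
class AtomRecord:
    """One atom of a structure.

    ``residue_number`` follows the author numbering of the input file.
    ``is_heavy`` is false exactly for hydrogen (and deuterium).
    """

    atom_index: int
    atom_name: str
    element: str
    residue_number: int
    residue_name: str
    chain_id: str
    coords: np.ndarray  # shape (3,), Å

    @property
    def is_heavy(self) -> bool:
        return self.element not in ("H", "D")


@dataclass
class StructureModel:
    """An ordered list of atoms plus the derived residue grouping."""

    atoms: list[AtomRecord]

    def __post_init__(self) -> None:
        seen: set[tuple[str, int, str, str]] = set()
        for a in self.atoms:
            if not np.all(np.isfinite(a.coords)):
                raise FormatError(f"non-finite coordinates for atom {a.atom_index}")
            key = (a.chain_id, a.residue_number, a.residue_name, a.atom_name)
            if key in seen:
                raise FormatError(
                    f"duplicate atom {a.atom_name} in residue "
                    f"{a.chain_id}:{a.residue_name}{a.residue_number}"
                )
            seen.add(key)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array in file order."""
        return np.array([a.coords for a in self.atoms], dtype=float)

    def residues(self) -> list[tuple[tuple[str, int, str], list[AtomRecord]]]:
        """Group atoms by (chain_id, residue_number, residue_name), file order."""
        order: list[tuple[str, int, str]] = []
        groups: dict[tuple[str, int, str], list[AtomRecord]] = {}
        for a in self.atoms:
            key = (a.chain_id, a.residue_number, a.residue_name)
            if key not in groups:
                groups[key] = []
                order.append(key)
            groups[key].append(a)
        return [(k, groups[k]) for k in order]


@dataclass
class TrajectoryEnsemble:
    """frames × atoms × 3 coordinate block tied to a topology.

    One ensemble holds a single replicate; replicate series are lists of
    ensembles sharing a topology.
    """

    coords_block: np.ndarray  # (n_frames, n_atoms, 3), Å
    topology: StructureModel
    replicate_id: int = 0
    frame_times: Optional[np.ndarray] = None  # ns

    def __post_init__(self) -> None:
        self.coords_block = np.asarray(self.coords_block, dtype=float)
        if self.coords_block.ndim != 3 or self.coords_block.shape[2] != 3:
            raise UsageError("coords_block must have shape (frames, atoms, 3)")
        if self.coords_block.shape[0] < 1:
            raise EmptyInputError("trajectory has no frames")
        if self.coords_block.shape[1] != self.topology.n_atoms:
            raise TopologyMismatchError(
                f"trajectory has {self.coords_block.shape[1]} atoms per frame, "
                f"topology has {self.topology.n_atoms}"
            )
        if self.frame_times is not None:
            t = np.asarray(self.frame_times, dtype=float)
            if t.shape[0] != self.coords_block.shape[0]:
                raise UsageError("frame_times length must equal n_frames")
            if np.any(np.diff(t) <= 0):
                raise UsageError("frame_times must be strictly increasing")
            self.frame_times = t

    @property
    def n_frames(self) -> int:
        return self.coords_block.shape[0]


@dataclass(frozen=True)
class Node:
    """A network node: a residue or one interactor (ligand/lipid) molecule."""

    label: str
    kind: str  # "residue" | "interactor"
    member_atoms: tuple[int, ...]  # heavy atoms only, topology indices
    anchor_atom: int  # Cα for residues, first heavy atom for interactors
    chain_id: str = ""
    residue_number: int = 0
    residue_name: str = ""


@dataclass
class NodeMap:
    """Ordered partition of heavy atoms into residue and interactor nodes."""

    nodes: list[Node]

    def __post_init__(self) -> None:
        seen: set[int] = set()
        labels: set[str] = set()
        for n in self.nodes:
            if n.label in labels:
                raise UsageError(f"duplicate node label {n.label!r}")
            labels.add(n.label)
            for i in n.member_atoms:
                if i in seen:
                    raise UsageError(f"atom {i} assigned to more than one node")
                seen.add(i)

    @property
    def labels(self) -> list[str]:
        return [n.label for n in self.nodes]

    def __getitem__(self, label: str) -> Node:
        for n in self.nodes:
            if n.label == label:
                return n
        raise KeyError(label)

    def __len__(self) -> int:
        return len(self.nodes)


# ---------------------------------------------------------------------------
# PDB reading


def _infer_element(raw_name: str, resname: str) -> str:
    """Element from the 4-character atom-name field of a PDB line.

    Legacy files lack the element column; the convention is that two-letter
    elements start in column 13, one-letter elements in column 14.  Falls
    back to the first alphabetic character, with a two-letter lookup table
    for ions and metals.
    """
    name = raw_name.strip()
    if not name:
        raise FormatError("empty atom name")
    two = name[:2].upper()
    # column-13 occupancy signals a two-letter element, but "HG11"-style
    # hydrogen names in 4-character fields also start at column 13
    if len(raw_name) >= 1 and raw_name[0] != " " and two in _TWO_LETTER_ELEMENTS:
        if resname.strip().upper() in ION_NAMES or two == "SE" or two == "FE":
            return two.capitalize()
    for ch in name:
        if ch.isalpha():
            if ch.upper() == "D":  # deuterium
                return "D"
            return ch.upper()
    raise FormatError(f"cannot infer element from atom name {raw_name!r}")


def _parse_float_field(text: str, what: str, lineno: int) -> float:
    s = text.strip()
    if not s:
        raise FormatError(f"line {lineno}: blank {what} field")
    try:
        return float(s)
    except ValueError as exc:
        raise FormatError(f"line {lineno}: unparseable {what} field {text!r}") from exc


def _parse_atom_line(line: str, lineno: int, index: int) -> AtomRecord:
    if len(line) < 54:
        raise FormatError(f"line {lineno}: coordinate record too short")
    raw_name = line[12:16]
    resname = line[17:20].strip()
    chain = line[21].strip() or "A"
    try:
        resnum = int(line[22:26])
    except ValueError as exc:
        raise FormatError(f"line {lineno}: unparseable residue number") from exc
    x = _parse_float_field(line[30:38], "x-coordinate", lineno)
    y = _parse_float_field(line[38:46], "y-coordinate", lineno)
    z = _parse_float_field(line[46:54], "z-coordinate", lineno)
    element = line[76:78].strip().capitalize() if len(line) >= 78 else ""
    if not element:
        element = _infer_element(raw_name, resname)
    return AtomRecord(
        atom_index=index,
        atom_name=raw_name.strip(),
        element=element,
        residue_number=resnum,
        residue_name=resname,
        chain_id=chain,
        coords=np.array([x, y, z], dtype=float),
    )


def _parse_pdb_models(text: str) -> list[list[AtomRecord]]:
    """All models of a PDB file, each as a list of AtomRecord."""
    models: list[list[AtomRecord]] = []
    current: list[AtomRecord] = []
    in_model = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec == "MODEL":
            if current:
                models.append(current)
                current = []
            in_model = True
        elif rec == "ENDMDL":
            models.append(current)
            current = []
            in_model = False
        elif rec in ("ATOM", "HETATM"):
            if len(line) >= 17 and line[16] not in (" ", "A"):
                continue  # keep only the primary alternate location
            current.append(_parse_atom_line(line, lineno, len(current)))
    if current or not models:
        if current:
            models.append(current)
    return [m for m in models if m]


def read_structure(path: str | Path) -> StructureModel:
    """Read a PDB file; a multi-model file contributes its first model.

    Raises :class:`FormatError` (naming the offending line) on malformed
    coordinate records and :class:`EmptyInputError` if no atoms are found.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    models = _parse_pdb_models(path.read_text())
    if not models:
        raise EmptyInputError(f"{path}: no ATOM/HETATM records")
    return StructureModel(atoms=models[0])


def _read_pdb_frames(path: Path) -> np.ndarray:
    models = _parse_pdb_models(path.read_text())
    if not models:
        raise EmptyInputError(f"{path}: no ATOM/HETATM records")
    counts = {len(m) for m in models}
    if len(counts) != 1:
        raise TopologyMismatchError(f"{path}: models have differing atom counts {sorted(counts)}")
    return np.array([[a.coords for a in m] for m in models], dtype=float)


def _read_binary_frames(path: Path, n_atoms: int) -> np.ndarray:
    """XTC/DCD frames via MDAnalysis (coordinates returned in Å)."""
    try:
        import MDAnalysis.coordinates as mdc
    except ImportError as exc:  # pragma: no cover
        raise InputError(
            f"{path}: reading {path.suffix} trajectories requires MDAnalysis"
        ) from exc
    reader_cls = {".xtc": mdc.XTC.XTCReader, ".dcd": mdc.DCD.DCDReader}.get(path.suffix.lower())
    if reader_cls is None:
        raise InputError(f"{path}: unsupported trajectory format {path.suffix!r}")
    frames = []
    with reader_cls(str(path)) as reader:
        for ts in reader:
            frames.append(np.array(ts.positions, dtype=float))
    return np.array(frames)


def read_trajectory(
    topology: StructureModel,
    paths: Sequence[str | Path],
    stride: int = 1,
    replicate_id: int = 0,
) -> TrajectoryEnsemble:
    """Concatenate trajectory files in path order, then apply ``stride``.

    Multi-model PDB files are read natively; ``.xtc``/``.dcd`` go through
    MDAnalysis.  Every frame must match the topology atom count.
    """
    if stride < 1:
        raise UsageError(f"stride must be >= 1, got {stride}")
    if not paths:
        raise EmptyInputError("no trajectory files given")
    blocks = []
    for p in paths:
        p = Path(p)
        if not p.exists():
            raise InputError(f"no such file: {p}")
        if p.suffix.lower() in (".pdb", ".ent"):
            block = _read_pdb_frames(p)
        else:
            block = _read_binary_frames(p, topology.n_atoms)
        for fi, frame in enumerate(block):
            if frame.shape[0] != topology.n_atoms:
                raise TopologyMismatchError(
                    f"{p}, frame {fi}: {frame.shape[0]} atoms, "
                    f"topology has {topology.n_atoms}"
                )
        blocks.append(block)
    coords = np.concatenate(blocks, axis=0)[::stride]
    return TrajectoryEnsemble(coords_block=coords, topology=topology, replicate_id=replicate_id)


# ---------------------------------------------------------------------------
# Node partition


def _matches(selector: Mapping[str, object], chain: str, resnum: int, resname: str) -> bool:
    if selector.get("residue_name") not in (None, resname):
        return False
    if selector.get("chain_id") not in (None, chain):
        return False
    if selector.get("residue_number") not in (None, resnum):
        return False
    return True


def node_label(chain: str, resname: str, resnum: int) -> str:
    return f"{chain}:{resname}{resnum}"


def build_node_map(
    structure: StructureModel,
    interactor_selectors: Iterable[Mapping[str, object]] = (),
) -> NodeMap:
    """Partition heavy atoms into residue nodes and interactor nodes.

    One node per amino-acid residue; one node per ligand molecule matched by
    a selector (``{"residue_name": ..., "chain_id": ..., "residue_number": ...}``,
    the last two optional).  Waters, ions and unselected hetero molecules are
    excluded.  Hydrogens belong to no node.
    """
    selectors = list(interactor_selectors)
    for sel in selectors:
        unknown = set(sel) - {"residue_name", "chain_id", "residue_number"}
        if unknown:
            raise UsageError(f"unknown selector keys: {sorted(unknown)}")
        rn = sel.get("residue_name")
        if rn in AMINO_ACIDS:
            raise UsageError(
                f"selector residue_name {rn!r} is an amino acid; interactor "
                "selectors may only name hetero molecules"
            )
        if rn in WATER_NAMES or rn in ION_NAMES:
            raise UsageError(f"{rn!r} (water/ion) cannot be an interactor node")
    nodes: list[Node] = []
    for (chain, resnum, resname), atoms in structure.residues():
        heavy = [a for a in atoms if a.is_heavy]
        is_aa = resname in AMINO_ACIDS
        selected = any(_matches(s, chain, resnum, resname) for s in selectors)
        if is_aa and selected:
            raise UsageError(
                f"selector matches amino-acid residue {chain}:{resname}{resnum}"
            )
        if not (is_aa or selected):
            continue
        if not heavy:
            raise InputError(
                f"residue {chain}:{resname}{resnum} has no heavy atoms"
            )
        if is_aa:
            anchor = next((a.atom_index for a in heavy if a.atom_name == "CA"),
                          heavy[0].atom_index)
            kind = "residue"
        else:
            anchor = heavy[0].atom_index
            kind = "interactor"
        nodes.append(Node(
            label=node_label(chain, resname, resnum),
            kind=kind,
            member_atoms=tuple(a.atom_index for a in heavy),
            anchor_atom=anchor,
            chain_id=chain,
            residue_number=resnum,
            residue_name=resname,
        ))
    return NodeMap(nodes=nodes)


# ---------------------------------------------------------------------------
# Writing


def _round_half_away(value: float, decimals: int = 2) -> float:
    scale = 10 ** decimals
    return math.copysign(math.floor(abs(value) * scale + 0.5) / scale, value)


def _format_bfactor(value: float) -> str:
    v = _round_half_away(value, 2)
    text = f"{v:6.2f}"
    if len(text) > 6:
        raise UsageError(
            f"value {value} does not fit the 6-character B-factor field; "
            "use scaling='minmax'"
        )
    return text


def _minmax_scale(values: dict[str, float]) -> dict[str, float]:
    vals = np.array(list(values.values()), dtype=float)
    lo, hi = vals.min(), vals.max()
    if hi == lo:
        return {k: 0.0 for k in values}
    return {k: (v - lo) / (hi - lo) * 99.99 for k, v in values.items()}


def _pdb_atom_line(a: AtomRecord, serial: int, bfactor: str) -> str:
    record = "ATOM  " if a.residue_name in AMINO_ACIDS else "HETATM"
    name = a.atom_name
    # standard alignment: one-letter elements start in column 14
    if len(name) < 4 and len(a.element) == 1:
        name = " " + name
    x, y, z = a.coords
    return (
        f"{record}{serial:5d} {name:<4s} {a.residue_name:<3s} {a.chain_id:1s}"
        f"{a.residue_number:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{bfactor}"
        f"          {a.element:>2s}"
    )


def write_bfactor_pdb(
    structure: StructureModel,
    node_map: NodeMap,
    per_node_values: Mapping[str, float],
    path: str | Path | None = None,
    scaling: str = "none",
) -> str:
    """Encode per-node values in the B-factor column of a PDB file.

    Every atom of a node carries the node's value; atoms outside all nodes
    get 0.00.  ``scaling="minmax"`` maps values linearly onto [0, 99.99]
    (maximum exactly 99.99).  Returns the PDB text; writes it when ``path``
    is given.
    """
    for label, v in per_node_values.items():
        if not np.isfinite(v):
            raise UsageError(f"non-finite value for node {label!r}")
    if scaling == "minmax":
        values = _minmax_scale(dict(per_node_values))
    elif scaling == "none":
        values = dict(per_node_values)
    else:
        raise UsageError(f"unknown scaling {scaling!r}")
    atom_value: dict[int, float] = {}
    for node in node_map.nodes:
        if node.label in values:
            for i in node.member_atoms:
                atom_value[i] = values[node.label]
    lines = []
    for serial, a in enumerate(structure.atoms, start=1):
        b = _format_bfactor(atom_value.get(a.atom_index, 0.0))
        lines.append(_pdb_atom_line(a, serial, b))
    lines.append("END")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def write_model_pdb(
    structure: StructureModel,
    coords_block: np.ndarray | None = None,
    path: str | Path | None = None,
) -> str:
    """Write a (multi-model) PDB: one MODEL per frame of ``coords_block``."""
    coords_block = (
        structure.coords()[None, :, :] if coords_block is None
        else np.asarray(coords_block, dtype=float)
    )
    lines: list[str] = []
    for fi, frame in enumerate(coords_block, start=1):
        if frame.shape[0] != structure.n_atoms:
            raise TopologyMismatchError(
                f"frame {fi - 1}: {frame.shape[0]} atoms, topology has {structure.n_atoms}"
            )
        lines.append(f"MODEL     {fi:4d}")
        for serial, a in enumerate(structure.atoms, start=1):
            moved = AtomRecord(
                atom_index=a.atom_index, atom_name=a.atom_name, element=a.element,
                residue_number=a.residue_number, residue_name=a.residue_name,
                chain_id=a.chain_id, coords=frame[a.atom_index],
            )
            lines.append(_pdb_atom_line(moved, serial, f"{0.0:6.2f}"))
        lines.append("ENDMDL")
    lines.append("END")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def write_node_table(
    node_map: NodeMap,
    per_node_values: Mapping[str, float],
    path: str | Path,
    value_name: str = "value",
) -> None:
    """Per-node value table: node_label, kind, chain, resnum, value."""
    import pandas as pd

    rows = [
        {
            "node_label": n.label,
            "kind": n.kind,
            "chain": n.chain_id,
            "resnum": n.residue_number,
            value_name: per_node_values[n.label],
        }
        for n in node_map.nodes
        if n.label in per_node_values
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6g")
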