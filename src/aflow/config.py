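"""Run configuration: YAML loading, validation, unit normalization.

Lengths in the configuration may carry a unit suffix ("0.45 nm",
"4.5 A", "4.5 Å"); everything is stored in Å.  Residues are referenced
as "D99" (one-letter code + author number), a bare number, or
"chain:number"; per-chain integer numbering offsets reconcile different
construct numberings and are applied before resolution.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import yaml

from .contacts import ContactParams
from .errors import ConfigError
from .observables import HBondCriteria
from .structure import ONE_LETTER, NodeMap, StructureModel

_LENGTH_RE = re.compile(r"^\s*([-+0-9.eE]+)\s*(nm|angstrom|ang|Å|A)?\s*$")


def parse_length(value, key: str = "length") -> float:
    """A length in Å from a number or a suffixed string ('0.45 nm' → 4.5)."""
    if isinstance(value, (int, float)):
        return float(value)
    m = _LENGTH_RE.match(str(value))
    if not m:
        raise ConfigError(f"cannot parse {key} value {value!r}")
    unit = m.group(2) or "A"
    if unit == "nm":
        # decimal shift keeps "0.138 nm" bit-identical to "1.38"
        from decimal import Decimal, InvalidOperation
        try:
            return float(Decimal(m.group(1)) * 10)
        except InvalidOperation as exc:
            raise ConfigError(f"cannot parse {key} value {value!r}") from exc
    return float(m.group(1))


@dataclass(frozen=True)
class ResidueRef:
    """A residue reference: optional chain, optional one-letter code, number."""

    number: int
    chain_id: Optional[str] = None
    one_letter: Optional[str] = None

    @classmethod
    def parse(cls, value) -> "ResidueRef":
        if isinstance(value, int):
            return cls(number=value)
        text = str(value).strip()
        chain = None
        if ":" in text:
            chain, text = text.split(":", 1)
        m = re.match(r"^([A-Za-z]?)(\d+)$", text)
        if not m:
            raise ConfigError(f"cannot parse residue reference {value!r}")
        letter = m.group(1).upper() or None
        if letter is not None and letter not in ONE_LETTER:
            raise ConfigError(f"unknown one-letter residue code in {value!r}")
        return cls(number=int(m.group(2)), chain_id=chain, one_letter=letter)


@dataclass(frozen=True)
class AtomRef:
    """'chain:resnum:atom_name' atom reference."""

    chain_id: str
    residue_number: int
    atom_name: str

    @classmethod
    def parse(cls, value) -> "AtomRef":
        parts = str(value).split(":")
        if len(parts) != 3:
            raise ConfigError(f"atom reference {value!r} is not 'chain:resnum:name'")
        return cls(chain_id=parts[0], residue_number=int(parts[1]), atom_name=parts[2])


@dataclass
class ReplicateSpec:
    topology: Path
    trajectories: list[Path]
    replicate_id: int


@dataclass
class RunConfig:
    conditions: dict[str, list[ReplicateSpec]]
    source_residues: list[ResidueRef]
    sink_residues: list[ResidueRef]
    interactor_selectors: list[dict] = field(default_factory=list)
    contact: ContactParams = field(default_factory=ContactParams)
    hbond: HBondCriteria = field(default_factory=HBondCriteria)
    hbond_pairs: list[tuple[AtomRef, AtomRef]] = field(default_factory=list)
    distance_pairs: list[tuple[AtomRef, AtomRef]] = field(default_factory=list)
    numbering_offset: dict[str, int] = field(default_factory=dict)
    stride: int = 1
    base_seed: int = 0
    output_dir: Path = Path("aflow_out")
    reference_condition: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.conditions:
            raise ConfigError("config must define at least one condition")
        if not self.source_residues or not self.sink_residues:
            raise ConfigError("source_residues and sink_residues must be nonempty")
        src = {(r.chain_id, r.number) for r in self.source_residues}
        snk = {(r.chain_id, r.number) for r in self.sink_residues}
        if src & snk:
            raise ConfigError("source and sink residues overlap")
        if self.stride < 1:
            raise ConfigError("stride must be >= 1")


_TOP_KEYS = {
    "conditions", "source_residues", "sink_residues", "interactors",
    "contact", "hbond", "hbond_pairs", "distance_pairs", "numbering_offset",
    "stride", "base_seed", "output_dir", "reference_condition",
}


def _contact_params(section: Mapping) -> ContactParams:
    known = {"cutoff", "c", "sigma", "prune", "prune_below"}
    unknown = set(section) - known
    if unknown:
        raise ConfigError(f"unknown contact key(s): {sorted(unknown)}")
    c = parse_length(section.get("cutoff", section.get("c", 4.5)), "contact cutoff")
    sigma = parse_length(section.get("sigma", 1.38), "contact sigma")
    prune = float(section.get("prune", section.get("prune_below", 1e-4)))
    return ContactParams(c=c, sigma=sigma, prune_below=prune)


def _hbond_criteria(section: Mapping) -> HBondCriteria:
    known = {"cutoff", "da_cutoff", "angle", "dha_angle_min"}
    unknown = set(section) - known
    if unknown:
        raise ConfigError(f"unknown hbond key(s): {sorted(unknown)}")
    cutoff = parse_length(section.get("cutoff", section.get("da_cutoff", 3.0)), "hbond cutoff")
    angle = float(section.get("angle", section.get("dha_angle_min", 150.0)))
    return HBondCriteria(da_cutoff=cutoff, dha_angle_min=angle)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration, applying defaults.

    Unknown keys raise :class:`ConfigError` naming the key.  Relative data
    paths are resolved against the config file's directory.
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: not parseable YAML: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"{path}: unknown config key(s): {sorted(unknown)}")
    base = path.parent

    def respath(p) -> Path:
        p = Path(p)
        return p if p.is_absolute() else base / p

    conditions: dict[str, list[ReplicateSpec]] = {}
    for cond, reps in (raw.get("conditions") or {}).items():
        if not isinstance(reps, list) or not reps:
            raise ConfigError(f"condition {cond!r} must list at least one replicate")
        out = []
        for k, rep in enumerate(reps):
            unknown = set(rep) - {"topology", "trajectories", "replicate_id"}
            if unknown:
                raise ConfigError(f"condition {cond!r}: unknown replicate key(s) {sorted(unknown)}")
            if "topology" not in rep or "trajectories" not in rep:
                raise ConfigError(f"condition {cond!r}: replicate needs topology and trajectories")
            out.append(ReplicateSpec(
                topology=respath(rep["topology"]),
                trajectories=[respath(t) for t in rep["trajectories"]],
                replicate_id=int(rep.get("replicate_id", k)),
            ))
        conditions[cond] = out
    pair_of = lambda entry, a, b: (AtomRef.parse(entry[a]), AtomRef.parse(entry[b]))
    try:
        return RunConfig(
            conditions=conditions,
            source_residues=[ResidueRef.parse(r) for r in raw.get("source_residues", [])],
            sink_residues=[ResidueRef.parse(r) for r in raw.get("sink_residues", [])],
            interactor_selectors=list(raw.get("interactors", [])),
            contact=_contact_params(raw.get("contact", {}) or {}),
            hbond=_hbond_criteria(raw.get("hbond", {}) or {}),
            hbond_pairs=[pair_of(e, "donor", "acceptor") for e in raw.get("hbond_pairs", [])],
            distance_pairs=[pair_of(e, "a", "b") for e in raw.get("distance_pairs", [])],
            numbering_offset={str(k): int(v) for k, v in (raw.get("numbering_offset") or {}).items()},
            stride=int(raw.get("stride", 1)),
            base_seed=int(raw.get("base_seed", 0)),
            output_dir=respath(raw.get("output_dir", "aflow_out")),
            reference_condition=raw.get("reference_condition"),
        )
    except KeyError as exc:
        raise ConfigError(f"{path}: missing key {exc}") from exc


def resolve_residue(
    node_map: NodeMap,
    ref: ResidueRef,
    numbering_offset: Mapping[str, int] = (),
) -> str:
    """Node label for a residue reference, after per-chain offset application.

    The offset maps the reference numbering onto the file numbering:
    file_resnum = ref.number + offset[chain].
    """
    offsets = dict(numbering_offset)
    matches = []
    for n in node_map.nodes:
        if n.kind != "residue":
            continue
        if ref.chain_id is not None and n.chain_id != ref.chain_id:
            continue
        target = ref.number + offsets.get(n.chain_id, 0)
        if n.residue_number == target:
            matches.append(n)
    if not matches:
        chain = ref.chain_id or "any chain"
        raise ConfigError(
            f"residue {ref.one_letter or ''}{ref.number} not resolvable ({chain})"
        )
    if len(matches) > 1:
        raise ConfigError(
            f"residue reference {ref.number} is ambiguous across chains "
            f"{[m.chain_id for m in matches]}; qualify it with a chain"
        )
    node = matches[0]
    if ref.one_letter is not None:
        expected = ONE_LETTER[ref.one_letter]
        if node.residue_name != expected:
            raise ConfigError(
                f"residue {node.chain_id}:{node.residue_number} is "
                f"{node.residue_name}, expected {expected} from {ref.one_letter}{ref.number}"
            )
    return node.label


def resolve_atom(structure: StructureModel, ref: AtomRef,
                 numbering_offset: Mapping[str, int] = ()) -> int:
    offsets = dict(numbering_offset)
    target = ref.residue_number + offsets.get(ref.chain_id, 0)
    for a in structure.atoms:
        if (a.chain_id == ref.chain_id and a.residue_number == target
                and a.atom_name == ref.atom_name):
            return a.atom_index
    raise ConfigError(
        f"atom {ref.chain_id}:{ref.residue_number}:{ref.atom_name} not found"
    )
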