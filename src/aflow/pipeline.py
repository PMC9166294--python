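"""Config-driven end-to-end runs.

For every condition × replicate: read topology and trajectory, build the
node partition and contact graph, solve the source→sink information flow,
and compute the activation observables; then aggregate replicates
(mean ± SEM) and compare conditions against a reference.  All outputs are
plain CSV/JSON written with fixed float formatting, so a rerun on the
same inputs reproduces identical bytes; a JSON manifest records the
config hash, package version, seeds and per-file checksums.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig, resolve_atom, resolve_residue
from .contacts import build_contact_graph
from .errors import AflowError, UsageError
from .flow import FlowNetwork, FlowResult, compare_states, compute_information_flow
from .observables import (
    hbond_occupancy,
    ligand_displacement,
    pair_distance_series,
    rmsf_profile,
)
from .structure import build_node_map, read_structure, read_trajectory, write_node_table

_FLOAT_FMT = "%.6g"


def aggregate_replicates(tables: Sequence[Mapping[str, float]]) -> pd.DataFrame:
    """Per-node mean and SEM (sd/√n) across replicate tables.

    All tables must cover the same node set; SEM is reported as missing
    (NaN) for a single replicate rather than 0.
    """
    if not tables:
        raise UsageError("no replicate tables to aggregate")
    keys = set(tables[0])
    for k, t in enumerate(tables[1:], start=1):
        if set(t) != keys:
            diff = sorted(keys ^ set(t))
            raise UsageError(f"replicate {k} node set differs; symmetric difference: {diff}")
    rows = []
    n = len(tables)
    for label in tables[0]:
        vals = np.array([t[label] for t in tables], dtype=float)
        sem = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
        rows.append({"node_label": label, "mean": float(vals.mean()), "sem": sem})
    return pd.DataFrame(rows)


@dataclass
class PipelineResult:
    output_dir: Path
    flows: dict[str, list[FlowResult]]
    rmsf: dict[str, list[dict[str, float]]]
    state_table: pd.DataFrame
    manifest: dict
    errors: list[str] = field(default_factory=list)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_hash(config: RunConfig) -> str:
    blob = repr(config).encode()
    return hashlib.sha256(blob).hexdigest()


def _reference_condition(config: RunConfig) -> str:
    if config.reference_condition is not None:
        return config.reference_condition
    for preferred in ("apo", "none"):
        if preferred in config.conditions:
            return preferred
    return sorted(config.conditions)[0]


def run_pipeline(config: RunConfig, keep_going: bool = False) -> PipelineResult:
    """Run every analysis stage for every condition and replicate.

    Stage failures are reported with condition/replicate context; by
    default the first failure stops the run, with ``keep_going`` the
    remaining replicates are still processed.
    """
    out_root = Path(config.output_dir)
    out_root.mkdir(parents=True, exist_ok=True)
    flows: dict[str, list[FlowResult]] = {}
    rmsf_tables: dict[str, list[dict[str, float]]] = {}
    written: list[Path] = []
    errors: list[str] = []
    for cond, reps in config.conditions.items():
        flows[cond] = []
        rmsf_tables[cond] = []
        for rep in reps:
            ctx = f"condition {cond!r}, replicate {rep.replicate_id}"
            try:
                written += _run_replicate(config, cond, rep, out_root,
                                          flows[cond], rmsf_tables[cond])
            except AflowError as exc:
                msg = f"{ctx}: {exc}"
                if keep_going:
                    errors.append(msg)
                    continue
                raise type(exc)(msg) from exc
    populated = {c: f for c, f in flows.items() if f}
    if not populated:
        raise AflowError("no replicate completed successfully: " + "; ".join(errors))
    reference = _reference_condition(config)
    if reference not in populated:
        reference = sorted(populated)[0]
    state_table = compare_states(populated, reference=reference)
    state_path = out_root / "flow_states.csv"
    state_table.to_csv(state_path, index=False, float_format=_FLOAT_FMT)
    written.append(state_path)
    for cond, tables in rmsf_tables.items():
        if not tables:
            continue
        agg = aggregate_replicates(tables)
        p = out_root / f"rmsf_{cond}.csv"
        agg.to_csv(p, index=False, float_format=_FLOAT_FMT)
        written.append(p)
    manifest = {
        "software": {"name": "aflow", "version": __version__},
        "config_hash": _config_hash(config),
        "base_seed": config.base_seed,
        "stride": config.stride,
        "reference_condition": reference,
        "conditions": {
            c: [r.replicate_id for r in reps] for c, reps in config.conditions.items()
        },
        "inputs": {
            str(r.topology): _sha256(r.topology)
            for reps in config.conditions.values() for r in reps
        },
        "outputs": {str(p.relative_to(out_root)): _sha256(p) for p in sorted(set(written))},
        "errors": errors,
    }
    manifest_path = out_root / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return PipelineResult(
        output_dir=out_root, flows=flows, rmsf=rmsf_tables,
        state_table=state_table, manifest=manifest, errors=errors,
    )


def _run_replicate(
    config: RunConfig,
    cond: str,
    rep,
    out_root: Path,
    flow_acc: list[FlowResult],
    rmsf_acc: list[dict[str, float]],
) -> list[Path]:
    outdir = out_root / cond / f"rep{rep.replicate_id}"
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    structure = read_structure(rep.topology)
    traj = read_trajectory(structure, rep.trajectories, stride=config.stride,
                           replicate_id=rep.replicate_id)
    node_map = build_node_map(structure, config.interactor_selectors)
    graph = build_contact_graph(traj, node_map, config.contact)
    p = outdir / "contact_edges.csv"
    graph.to_edge_csv(p)
    written.append(p)
    sources = [resolve_residue(node_map, r, config.numbering_offset)
               for r in config.source_residues]
    sinks = [resolve_residue(node_map, r, config.numbering_offset)
             for r in config.sink_residues]
    flow = compute_information_flow(FlowNetwork(graph, sources, sinks))
    p = outdir / "flow.csv"
    flow.to_csv(p)
    written.append(p)
    flow_acc.append(flow)
    rmsf = rmsf_profile(traj, node_map)
    p = outdir / "rmsf.csv"
    write_node_table(node_map, rmsf, p, value_name="rmsf_A")
    written.append(p)
    rmsf_acc.append(rmsf)
    for a_ref, b_ref in config.distance_pairs:
        a = resolve_atom(structure, a_ref, config.numbering_offset)
        b = resolve_atom(structure, b_ref, config.numbering_offset)
        series = pair_distance_series(traj, a, b)
        tag = f"{a_ref.chain_id}{a_ref.residue_number}{a_ref.atom_name}-" \
              f"{b_ref.chain_id}{b_ref.residue_number}{b_ref.atom_name}"
        p = outdir / f"distance_{tag}.csv"
        pd.DataFrame({"frame": np.arange(traj.n_frames), "distance_A": series.values}) \
            .to_csv(p, index=False, float_format=_FLOAT_FMT)
        written.append(p)
        p = outdir / f"distance_hist_{tag}.csv"
        pd.DataFrame({
            "bin_left": series.bin_edges[:-1],
            "bin_right": series.bin_edges[1:],
            "density": series.density,
        }).to_csv(p, index=False, float_format=_FLOAT_FMT)
        written.append(p)
    if config.hbond_pairs:
        rows = []
        for d_ref, a_ref in config.hbond_pairs:
            d = resolve_atom(structure, d_ref, config.numbering_offset)
            a = resolve_atom(structure, a_ref, config.numbering_offset)
            occ = hbond_occupancy(traj, [d], [a], config.hbond)
            rows.append({
                "donor": f"{d_ref.chain_id}:{d_ref.residue_number}:{d_ref.atom_name}",
                "acceptor": f"{a_ref.chain_id}:{a_ref.residue_number}:{a_ref.atom_name}",
                "occupancy": occ[(d, a)],
            })
        p = outdir / "hbonds.csv"
        pd.DataFrame(rows).to_csv(p, index=False, float_format=_FLOAT_FMT)
        written.append(p)
    protein_atoms = [i for n in node_map.nodes if n.kind == "residue"
                     for i in n.member_atoms]
    for node in node_map.nodes:
        if node.kind != "interactor" or traj.n_frames < 2:
            continue
        drift = ligand_displacement(traj, node, protein_atoms)
        p = outdir / f"ligand_{node.label.replace(':', '_')}.csv"
        pd.DataFrame({
            "frame": np.arange(traj.n_frames),
            "com_displacement_A": drift["com_displacement"],
            "ligand_rmsd_A": drift["ligand_rmsd"],
        }).to_csv(p, index=False, float_format=_FLOAT_FMT)
        written.append(p)
    return written
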