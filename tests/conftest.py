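"""Shared fixtures: tiny hand-written PDB texts and programmatic structures."""

from __future__ import annotations

import numpy as np
import pytest

from aflow.structure import AtomRecord, StructureModel

#: heavy-atom names of a cholesterol (CLR) residue: 27 carbons + 1 oxygen
CLR_HEAVY_ATOMS = [f"C{i}" for i in range(1, 28)] + ["O1"]


def pdb_line(serial, name, resname, chain, resnum, x, y, z, element=None, record="ATOM"):
    el = (element or name[0]).rjust(2)
    nm = name if len(name) == 4 else f" {name:<3s}"
    return (f"{record:<6s}{serial:5d} {nm:<4s} {resname:<3s} {chain}{resnum:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {el}")


def make_atoms(specs, start_index=0):
    """AtomRecords from (name, element, resnum, resname, chain, xyz) tuples."""
    return [
        AtomRecord(atom_index=start_index + i, atom_name=name, element=el,
                   residue_number=resnum, residue_name=resname, chain_id=chain,
                   coords=np.asarray(xyz, dtype=float))
        for i, (name, el, resnum, resname, chain, xyz) in enumerate(specs)
    ]


def make_clr_specs(resnum, chain="L", origin=(0.0, 0.0, 0.0), spacing=1.5):
    """A compact 28-heavy-atom cholesterol-like molecule on a 3D grid."""
    ox, oy, oz = origin
    specs = []
    for i, name in enumerate(CLR_HEAVY_ATOMS):
        x = ox + spacing * (i % 4)
        y = oy + spacing * ((i // 4) % 4)
        z = oz + spacing * (i // 16)
        specs.append((name, "O" if name.startswith("O") else "C",
                      resnum, "CLR", chain, (x, y, z)))
    return specs


@pytest.fixture
def peptide_with_clr():
    """5-residue one-atom-per-residue peptide plus one CLR molecule."""
    specs = [("CA", "C", i + 1, "GLY", "A", (4.0 * i, 0.0, 0.0)) for i in range(5)]
    specs += make_clr_specs(101, origin=(0.0, 8.0, 0.0))
    return StructureModel(atoms=make_atoms(specs))


@pytest.fixture
def tiny_pdb_text():
    lines = [
        pdb_line(1, "N", "ALA", "A", 1, 0.0, 0.0, 0.0, "N"),
        pdb_line(2, "CA", "ALA", "A", 2, 1.5, 0.0, 0.0, "C"),
        pdb_line(3, "C", "ALA", "A", 3, 3.0, 0.0, 0.0, "C"),
    ]
    return "\n".join(lines) + "\nEND\n"
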