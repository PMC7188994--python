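"""Shared fixtures: tiny hand-written PDB files and small synthetic systems."""

from __future__ import annotations

import numpy as np
import pytest

import saxsemble as sx


def pdb_atom_line(
    serial: int,
    name: str,
    resname: str,
    chain: str,
    resid: int,
    x: float,
    y: float,
    z: float,
    *,
    element: str = "C",
    occupancy: float = 1.0,
    b: float = 10.0,
    altloc: str = " ",
    hetero: bool = False,
    icode: str = " ",
) -> str:
    record = "HETATM" if hetero else "ATOM  "
    name_field = name if len(name) == 4 else f" {name:<3}"
    return (
        f"{record}{serial:>5} {name_field}{altloc}{resname:<3} {chain}"
        f"{resid:>4}{icode}   {x:8.3f}{y:8.3f}{z:8.3f}{occupancy:6.2f}"
        f"{b:6.2f}          {element:>2}"
    )


@pytest.fixture
def tiny_pdb(tmp_path):
    """Three backbone atoms of one glycine, no MODEL records."""
    lines = [
        pdb_atom_line(1, "N", "GLY", "A", 1, 1.000, 2.000, 3.000, element="N"),
        pdb_atom_line(2, "CA", "GLY", "A", 1, 2.500, 2.000, 3.000),
        pdb_atom_line(3, "C", "GLY", "A", 1, 3.200, 3.300, 3.000),
        "END",
    ]
    path = tmp_path / "tiny.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def three_residue_pdb(tmp_path):
    """Three residues with Cα atoms at x = 0, 3.8, 7.6 plus a PLP ligand."""
    lines = []
    serial = 1
    for i, x in enumerate((0.0, 3.8, 7.6), start=1):
        lines.append(pdb_atom_line(serial, "CA", "ALA", "A", i, x, 0.0, 0.0))
        serial += 1
    for j, (nm, el) in enumerate([("C4A", "C"), ("O3", "O"), ("P", "P")]):
        lines.append(
            pdb_atom_line(
                serial, nm, "PLP", "A", 101, 10.0 + j, 5.0, 0.0,
                element=el, hetero=True,
            )
        )
        serial += 1
    lines.append("END")
    path = tmp_path / "three.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def two_model_pdb(tmp_path):
    lines = ["MODEL        1"]
    lines.append(pdb_atom_line(1, "CA", "GLY", "A", 1, 0.0, 0.0, 0.0))
    lines.append(pdb_atom_line(2, "CA", "GLY", "A", 2, 3.8, 0.0, 0.0))
    lines.append(pdb_atom_line(3, "CA", "GLY", "A", 3, 3.8, 3.8, 0.0))
    lines.append("ENDMDL")
    lines.append("MODEL        2")
    lines.append(pdb_atom_line(1, "CA", "GLY", "A", 1, 0.0, 0.0, 1.0))
    lines.append(pdb_atom_line(2, "CA", "GLY", "A", 2, 3.8, 0.0, 1.0))
    lines.append(pdb_atom_line(3, "CA", "GLY", "A", 3, 3.8, 3.8, 1.0))
    lines.append("ENDMDL")
    lines.append("END")
    path = tmp_path / "twomodel.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def altloc_pdb(tmp_path):
    """One residue whose CA has two alternate locations, B more occupied."""
    lines = [
        pdb_atom_line(1, "N", "ALA", "A", 1, 0.0, 0.0, 0.0, element="N"),
        pdb_atom_line(2, "CA", "ALA", "A", 1, 1.0, 0.0, 0.0,
                      altloc="A", occupancy=0.4),
        pdb_atom_line(3, "CA", "ALA", "A", 1, 2.0, 0.0, 0.0,
                      altloc="B", occupancy=0.6),
        pdb_atom_line(4, "C", "ALA", "A", 1, 3.0, 1.0, 0.0),
        "END",
    ]
    path = tmp_path / "altloc.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture(scope="session")
def hinge_states():
    """Open/intermediate/closed hinge conformers sharing one atom ordering."""
    return [sx.make_hinge_protein(20, a) for a in (165.0, 110.0, 55.0)]


@pytest.fixture(scope="session")
def small_planted_ensemble(hinge_states):
    """100-frame two-state ensemble with planted 60/40 populations."""
    ensemble, truth = sx.make_state_ensemble(
        hinge_states[:2], [0.6, 0.4], n_frames=100, jitter_sigma=0.1, seed=11
    )
    return ensemble, truth


@pytest.fixture(scope="session")
def marker_observable():
    return sx.DistanceObservable(
        label="cat-sub",
        selector_a=sx.AtomSelector(residue_names="CAT", atom_names="SG"),
        selector_b=sx.AtomSelector(residue_names="SUB", atom_names="SG"),
        convention="named-atom-pair",
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260921)
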