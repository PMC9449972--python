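"""Shared fixtures: tiny peak series and synthetic PDB structures.

All structure fixtures are generated programmatically (idealised geometry);
none is a real deposited structure.
"""

from __future__ import annotations

import io
import math

import numpy as np
import pytest

from hsqcmelt.peaks import PeakRecord, assemble_series


def make_record(res=1, rtype="A", t=295.0, dh=8.0, dn=120.0, pi=1.0e6):
    return PeakRecord(res, rtype, t, dh, dn, pi)


@pytest.fixture
def small_series():
    """3 residues x 4 temperatures, complete, simple linear drifts."""
    records = []
    for res, (dh0, dn0, slope) in enumerate(
        [(8.0, 120.0, 0.01), (7.5, 115.0, 0.0), (8.8, 125.0, -0.02)], start=1
    ):
        for k, t in enumerate([295.0, 297.0, 299.0, 301.0]):
            records.append(
                make_record(res, "A", t, dh0 + slope * k, dn0 + 0.1 * k,
                            1.0e6 + 1e4 * k)
            )
    return assemble_series(records)


def format_pdb(atoms, chain="A"):
    """Minimal fixed-column PDB text from (name, resname, resseq, x, y, z,
    element) tuples."""
    lines = []
    for serial, (name, resname, resseq, x, y, z, element) in enumerate(
        atoms, start=1
    ):
        name_field = f" {name:<3}" if len(name) < 4 else name
        lines.append(
            f"ATOM  {serial:5d} {name_field}"
            f" {resname:>3} {chain}{resseq:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
            f"          {element:>2}"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


def helix_pdb_text(n_residues=20, resname="ALA"):
    """Synthetic idealised poly-alanine alpha-helix (not a real structure).

    Backbone and C-beta atoms placed on helical wheels: 1.5 A rise and 100
    degrees twist per residue; adequate geometry for distance, clustering
    and surface-area tests.
    """
    atoms = []
    offsets = {  # (radius A, angle offset deg, z offset A, element)
        "N": (1.6, -28.0, -0.6, "N"),
        "CA": (2.3, 0.0, 0.0, "C"),
        "C": (2.0, 28.0, 0.55, "C"),
        "O": (2.0, 44.0, 1.4, "O"),
        "CB": (3.4, -5.0, -0.4, "C"),
    }
    names = ["N", "CA", "C", "O"] + (["CB"] if resname != "GLY" else [])
    for i in range(n_residues):
        base_angle = math.radians(100.0 * i)
        z0 = 1.5 * i
        for name in names:
            r, dphi, dz, element = offsets[name]
            phi = base_angle + math.radians(dphi)
            atoms.append(
                (name, resname, i + 1,
                 r * math.cos(phi), r * math.sin(phi), z0 + dz, element)
            )
    return format_pdb(atoms)


@pytest.fixture
def helix_model():
    from hsqcmelt.structure import read_structure

    return read_structure(io.StringIO(helix_pdb_text(20)))


@pytest.fixture
def dipeptide_model():
    """Two-residue synthetic fixture for SASA convergence checks."""
    from hsqcmelt.structure import read_structure

    atoms = [
        ("N", "ALA", 1, 0.0, 0.0, 0.0, "N"),
        ("CA", "ALA", 1, 1.46, 0.0, 0.0, "C"),
        ("C", "ALA", 1, 2.0, 1.4, 0.0, "C"),
        ("O", "ALA", 1, 1.3, 2.4, 0.0, "O"),
        ("CB", "ALA", 1, 2.0, -0.8, 1.2, "C"),
        ("N", "GLY", 2, 3.3, 1.5, 0.0, "N"),
        ("CA", "GLY", 2, 4.0, 2.7, 0.3, "C"),
        ("C", "GLY", 2, 5.5, 2.5, 0.3, "C"),
        ("O", "GLY", 2, 6.1, 1.5, 0.7, "O"),
    ]
    return read_structure(io.StringIO(format_pdb(atoms)))
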