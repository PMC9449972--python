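"""Mapping melt statistics onto a 3D structure.

Residues flagged by the shift/intensity analyses are interpreted spatially:
how buried are they (solvent-accessible surface area), how close are they to
each other (minimum inter-residue distances), do they form localised
structural clusters (single-linkage components under a distance cutoff), and
what do they look like painted onto the structure (per-residue metric
exported into the B-factor column for molecular viewers).

Structures are read from standard PDB files (one model, one chain, waters
and hetero groups excluded by default) through Biopython.  An integer
numbering offset reconciles the structure's residue numbering with the
pipeline's canonical mature-sequence numbering:
``pipeline_number = structure_number + offset``.

SASA is computed with a deterministic Shrake–Rupley algorithm: every atom's
sphere of radius (van der Waals + probe) is sampled with a fixed
golden-spiral point set (seedless, so results are bit-reproducible), a point
counting as accessible when it lies outside every other atom's expanded
sphere.  The van der Waals radii are a packaged Bondi-type table; areas are
reported in nm² with the conventional water-probe radius of 0.14 nm.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TextIO

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from Bio.PDB import PDBParser, PDBIO, Select
from Bio.PDB.Structure import Structure as _BioStructure

__all__ = [
    "DEFAULT_PROBE_RADIUS_NM",
    "DEFAULT_SPHERE_POINTS",
    "DEFAULT_CLUSTER_CUTOFF",
    "StructureModel",
    "SasaResult",
    "SpatialClusters",
    "load_radii",
    "read_structure",
    "golden_spiral_points",
    "sasa",
    "residue_min_distance",
    "spatial_clusters",
    "export_bfactor_map",
]

DEFAULT_PROBE_RADIUS_NM = 0.14
DEFAULT_SPHERE_POINTS = 960
DEFAULT_CLUSTER_CUTOFF = 6.0  # angstrom
DEFAULT_RADIUS = 1.70  # fallback vdW radius, angstrom

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}


def load_radii(path: str | Path | None = None) -> dict[str, float]:
    """Load the element -> van der Waals radius (Å) table.

    Without ``path`` the packaged Bondi-type table is used.
    """
    if path is None:
        text = (
            resources.files("hsqcmelt").joinpath("data/vdw_radii.txt").read_text()
        )
    else:
        text = Path(path).read_text()
    radii: dict[str, float] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        element, value = line.split()
        radii[element.upper()] = float(value)
    return radii


@dataclass
class StructureModel:
    """A parsed single-chain structure in pipeline numbering.

    ``atoms`` has one row per heavy (or all, if hydrogens are present) atom:
    ``residue`` (pipeline numbering), ``resname`` (three-letter), ``atom``,
    ``element``, ``x``, ``y``, ``z`` (Å).  ``numbering_offset`` records the
    offset that was added to the file's residue numbers.  The underlying
    Biopython structure is retained for faithful PDB export.
    """

    atoms: pd.DataFrame
    chain_id: str
    numbering_offset: int
    radii: dict[str, float] = field(default_factory=load_radii)
    _bio_structure: _BioStructure | None = field(default=None, repr=False)

    @property
    def residues(self) -> list[int]:
        return sorted(self.atoms["residue"].unique().tolist())

    def residue_name(self, residue: int) -> str:
        sel = self.atoms.loc[self.atoms["residue"] == residue, "resname"]
        if sel.empty:
            raise KeyError(f"residue {residue} not in structure")
        return sel.iloc[0]

    def coordinates(self) -> np.ndarray:
        return self.atoms[["x", "y", "z"]].to_numpy()

    def atom_radii(self) -> np.ndarray:
        """Per-atom vdW radii; unknown elements get the fallback radius."""
        out = np.empty(len(self.atoms))
        unknown: set[str] = set()
        for i, el in enumerate(self.atoms["element"]):
            r = self.radii.get(el.upper())
            if r is None:
                unknown.add(el)
                r = DEFAULT_RADIUS
            out[i] = r
        if unknown:
            warnings.warn(
                f"no vdW radius for element(s) {sorted(unknown)}; using the "
                f"default {DEFAULT_RADIUS} Å",
                stacklevel=2,
            )
        return out

    def transformed(self, rotation: np.ndarray, translation: np.ndarray
                    ) -> "StructureModel":
        """Copy with coordinates rigidly transformed (x' = R x + t)."""
        atoms = self.atoms.copy()
        xyz = atoms[["x", "y", "z"]].to_numpy() @ np.asarray(rotation).T
        xyz = xyz + np.asarray(translation)
        atoms[["x", "y", "z"]] = xyz
        return StructureModel(
            atoms, self.chain_id, self.numbering_offset, self.radii, None
        )


@dataclass
class SasaResult:
    """Per-residue solvent-accessible surface area in nm²."""

    per_residue: dict[int, float]
    probe_radius_nm: float
    n_sphere_points: int

    @property
    def total(self) -> float:
        return float(sum(self.per_residue.values()))


@dataclass
class SpatialClusters:
    """Single-linkage partition of a flagged residue set."""

    flagged: list[int]
    cutoff: float
    selection: str
    clusters: list[list[int]]

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)


class _ChainSelect(Select):
    def __init__(self, chain_id: str):
        self.chain_id = chain_id

    def accept_chain(self, chain):  # pragma: no cover - Biopython callback
        return chain.id == self.chain_id


def read_structure(
    source: str | Path | TextIO,
    offset: int = 0,
    *,
    chain: str | None = None,
    model_index: int = 0,
    include_hetero: bool = False,
    radii: dict[str, float] | None = None,
) -> StructureModel:
    """Parse a PDB file into a :class:`StructureModel`.

    One model and one chain are selected (``chain=None`` takes the first
    chain of the model).  Waters and hetero groups are excluded unless
    ``include_hetero``.  ``offset`` is added to every residue number so the
    model's numbering matches the peak lists (e.g. a file whose first
    modelled residue 7 should be called 7 in mature numbering needs
    ``offset=0``; a file renumbered to start at 1 needs ``offset=+6``).
    """
    parser = PDBParser(QUIET=True)
    if isinstance(source, (str, Path)):
        bio = parser.get_structure("model", str(source))
    else:
        bio = parser.get_structure("model", source)
    models = list(bio.get_models())
    if not models:
        raise ValueError("no models found in PDB input")
    model = models[model_index]
    chains = list(model.get_chains())
    if not chains:
        raise ValueError("no chains found in PDB input")
    if chain is None:
        selected = chains[0]
    else:
        match = [c for c in chains if c.id == chain]
        if not match:
            raise ValueError(
                f"chain {chain!r} not found (available: {[c.id for c in chains]})"
            )
        selected = match[0]
    rows = []
    for residue in selected:
        hetflag, resseq, _icode = residue.id
        if hetflag != " " and not include_hetero:
            continue
        if residue.get_resname() == "HOH":
            continue
        for atom in residue:
            element = (atom.element or "").strip().upper()
            if not element:
                element = atom.get_name().strip()[0].upper()
            x, y, z = atom.coord
            if not np.all(np.isfinite(atom.coord)):
                raise ValueError(
                    f"non-finite coordinates at residue {resseq} atom "
                    f"{atom.get_name()}"
                )
            rows.append(
                (resseq + offset, residue.get_resname(), atom.get_name(),
                 element, float(x), float(y), float(z))
            )
    if not rows:
        raise ValueError("no ATOM records parsed from PDB input")
    atoms = pd.DataFrame(
        rows, columns=["residue", "resname", "atom", "element", "x", "y", "z"]
    )
    return StructureModel(
        atoms=atoms,
        chain_id=selected.id,
        numbering_offset=offset,
        radii=radii or load_radii(),
        _bio_structure=bio,
    )


def golden_spiral_points(n: int) -> np.ndarray:
    """``n`` quasi-uniform points on the unit sphere (deterministic).

    Fibonacci/golden-spiral lattice: latitudes split the sphere into equal-
    area bands, longitudes advance by the golden angle.
    """
    if n < 1:
        raise ValueError("need at least one sphere point")
    i = np.arange(n)
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = i * math.pi * (3.0 - math.sqrt(5.0))
    r = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def sasa(
    model: StructureModel,
    probe_radius: float = DEFAULT_PROBE_RADIUS_NM,
    n_sphere_points: int = DEFAULT_SPHERE_POINTS,
) -> SasaResult:
    """Shrake–Rupley per-residue SASA.

    ``probe_radius`` is in nm (default 0.14, a water probe); coordinates and
    vdW radii are in Å internally, output in nm².  Each atom's expanded
    sphere (vdW + probe) is sampled with the same fixed golden-spiral point
    set; a sample point is accessible iff it lies outside every neighbouring
    atom's expanded sphere, and each accessible point carries an equal share
    of the atom's expanded-sphere area.
    """
    probe_a = probe_radius * 10.0  # nm -> angstrom
    coords = model.coordinates()
    radii = model.atom_radii() + probe_a
    n_atoms = len(coords)
    unit = golden_spiral_points(n_sphere_points)
    tree = cKDTree(coords)
    max_r = radii.max()
    atom_area = np.zeros(n_atoms)
    for i in range(n_atoms):
        pts = coords[i] + radii[i] * unit
        neighbours = tree.query_ball_point(coords[i], radii[i] + max_r)
        accessible = np.ones(n_sphere_points, dtype=bool)
        for j in neighbours:
            if j == i:
                continue
            d2 = np.einsum(
                "ij,ij->i", pts - coords[j], pts - coords[j]
            )
            accessible &= d2 >= radii[j] ** 2
            if not accessible.any():
                break
        atom_area[i] = (
            4.0 * math.pi * radii[i] ** 2 * accessible.sum() / n_sphere_points
        )
    per_residue: dict[int, float] = {}
    for res, area in zip(model.atoms["residue"], atom_area):
        per_residue[int(res)] = per_residue.get(int(res), 0.0) + float(area)
    # angstrom^2 -> nm^2
    per_residue = {r: a / 100.0 for r, a in per_residue.items()}
    return SasaResult(per_residue, probe_radius, n_sphere_points)


def _atom_selection(
    model: StructureModel, residue: int, selection: str
) -> np.ndarray:
    rows = model.atoms[model.atoms["residue"] == residue]
    if rows.empty:
        raise KeyError(f"residue {residue} not in structure")
    if selection == "CA":
        sel = rows[rows["atom"] == "CA"]
    elif selection == "all_heavy":
        sel = rows[rows["element"] != "H"]
    elif selection == "side_chain_heavy":
        sel = rows[
            (rows["element"] != "H") & (~rows["atom"].isin(BACKBONE_ATOMS))
        ]
        if sel.empty:  # glycine (no heavy side chain): fall back to CA
            sel = rows[rows["atom"] == "CA"]
    else:
        raise ValueError(f"unknown atom selection {selection!r}")
    if sel.empty:
        raise KeyError(
            f"residue {residue}: no atoms under selection {selection!r}"
        )
    return sel[["x", "y", "z"]].to_numpy()


def residue_min_distance(
    model: StructureModel,
    res_a: int,
    res_b: int,
    selection: str = "side_chain_heavy",
) -> float:
    """Minimum pairwise distance (Å) between two residues' atom sets.

    ``selection`` is ``side_chain_heavy`` (heavy atoms outside the backbone;
    glycine falls back to Cα), ``all_heavy`` or ``CA``.
    """
    a = _atom_selection(model, res_a, selection)
    b = _atom_selection(model, res_b, selection)
    diffs = a[:, None, :] - b[None, :, :]
    return float(np.sqrt((diffs**2).sum(axis=2)).min())


def spatial_clusters(
    model: StructureModel,
    flagged: Iterable[int],
    cutoff: float = DEFAULT_CLUSTER_CUTOFF,
    selection: str = "side_chain_heavy",
) -> SpatialClusters:
    """Single-linkage spatial clustering of a flagged residue set.

    Two flagged residues are linked when their minimum inter-residue
    distance under ``selection`` is at most ``cutoff`` Å; clusters are the
    connected components of that graph (so any two residues in different
    clusters are farther apart than the cutoff under single linkage).
    Clusters are sorted by size descending, then by lowest member.
    """
    flagged = sorted(set(flagged))
    if not flagged:
        raise ValueError("flagged residue set is empty")
    missing = [r for r in flagged if r not in set(model.residues)]
    if missing:
        raise KeyError(f"flagged residue(s) not in structure: {missing}")
    k = len(flagged)
    rows, cols = [], []
    for i in range(k):
        for j in range(i + 1, k):
            d = residue_min_distance(model, flagged[i], flagged[j], selection)
            if d <= cutoff:
                rows.extend([i, j])
                cols.extend([j, i])
    graph = csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(k, k)
    )
    n_comp, labels = connected_components(graph, directed=False)
    clusters: dict[int, list[int]] = {}
    for res, lab in zip(flagged, labels):
        clusters.setdefault(int(lab), []).append(res)
    ordered = sorted(clusters.values(), key=lambda c: (-len(c), min(c)))
    return SpatialClusters(flagged, cutoff, selection, ordered)


def export_bfactor_map(
    model: StructureModel,
    metric: Mapping[int, float],
    destination: str | Path | TextIO,
    sentinel: float = -1.0,
) -> None:
    """Write a PDB copy with a per-residue metric in the B-factor column.

    Values are written with the standard fixed-column two-decimal format;
    residues without a value get the ``sentinel`` (default −1.00), so
    viewers can grey them out.  Requires the model to have been read from a
    PDB file (the parsed structure is reused for faithful output).
    """
    if model._bio_structure is None:
        raise ValueError(
            "export requires a model parsed from PDB input "
            "(no underlying structure to write)"
        )
    defined = [r for r in metric if r in set(model.residues)]
    if not defined:
        raise ValueError("metric defines no residue present in the model")
    bio = model._bio_structure
    for chain in bio.get_chains():
        if chain.id != model.chain_id:
            continue
        for residue in chain:
            resseq = residue.id[1] + model.numbering_offset
            value = float(metric.get(resseq, sentinel))
            for atom in residue:
                atom.set_bfactor(value)
    writer = PDBIO()
    writer.set_structure(bio)
    if isinstance(destination, (str, Path)):
        writer.save(str(destination), select=_ChainSelect(model.chain_id))
    else:
        writer.save(destination, select=_ChainSelect(model.chain_id))
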