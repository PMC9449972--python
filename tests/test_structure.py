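"""Structure parsing, SASA, distances, clustering and B-factor export."""

import io
import math

import numpy as np
import pytest

from hsqcmelt.structure import (
    StructureModel,
    export_bfactor_map,
    golden_spiral_points,
    load_radii,
    read_structure,
    residue_min_distance,
    sasa,
    spatial_clusters,
)

from conftest import format_pdb, helix_pdb_text


def single_atom_model(element="C", name="CA", resname="ALA"):
    text = format_pdb([(name, resname, 1, 0.0, 0.0, 0.0, element)])
    return read_structure(io.StringIO(text))


class TestReadStructure:
    def test_minimal_single_residue_fixture(self):
        model = single_atom_model()
        assert model.residues == [1]
        assert model.residue_name(1) == "ALA"
        np.testing.assert_allclose(model.coordinates(), [[0.0, 0.0, 0.0]])

    def test_offset_arithmetic(self):
        text = format_pdb([("CA", "SER", 7, 1.0, 2.0, 3.0, "C")])
        model = read_structure(io.StringIO(text), offset=6)
        assert model.residues == [13]

    def test_water_excluded(self):
        text = format_pdb(
            [("CA", "ALA", 1, 0, 0, 0, "C"), ("O", "HOH", 2, 9, 9, 9, "O")]
        )
        model = read_structure(io.StringIO(text))
        assert model.residues == [1]

    def test_no_atoms_is_an_error(self):
        with pytest.raises(ValueError):
            read_structure(io.StringIO("END\n"))

    def test_unknown_element_warns_and_gets_default_radius(self):
        text = format_pdb([("XX", "LIG", 1, 0, 0, 0, "X")])
        model = read_structure(io.StringIO(text))
        with pytest.warns(UserWarning, match="no vdW radius"):
            radii = model.atom_radii()
        assert radii[0] == 1.70

    def test_packaged_radii_table_loads(self):
        radii = load_radii()
        assert radii["C"] == 1.70 and radii["N"] == 1.55


class TestGoldenSpiral:
    def test_points_lie_on_unit_sphere(self):
        pts = golden_spiral_points(960)
        np.testing.assert_allclose(np.linalg.norm(pts, axis=1), 1.0,
                                   atol=1e-12)

    def test_quasi_uniform_mean_near_origin(self):
        pts = golden_spiral_points(960)
        assert np.linalg.norm(pts.mean(axis=0)) < 1e-3


class TestSasa:
    def test_isolated_atom_matches_sphere_area(self):
        # carbon r=1.70 A + probe 1.4 A: 4*pi*3.1^2 = 120.76 A^2
        model = single_atom_model("C")
        result = sasa(model, probe_radius=0.14, n_sphere_points=960)
        expected = 4 * math.pi * 3.1**2 / 100.0  # nm^2
        assert result.per_residue[1] == pytest.approx(expected, rel=5e-3)
        assert expected == pytest.approx(1.2076, abs=1e-4)

    def test_two_distant_atoms_are_additive(self):
        text = format_pdb(
            [("CA", "ALA", 1, 0, 0, 0, "C"), ("CA", "ALA", 2, 50, 0, 0, "C")]
        )
        model = read_structure(io.StringIO(text))
        result = sasa(model)
        single = sasa(single_atom_model()).per_residue[1]
        assert result.per_residue[1] == pytest.approx(single, rel=1e-12)
        assert result.per_residue[2] == pytest.approx(single, rel=1e-12)
        assert result.total == pytest.approx(2 * single, rel=1e-12)

    def test_fully_caged_atom_is_buried(self):
        # central C enclosed by an octahedron-plus of tightly packed spheres
        cage = [
            ("C" + str(i), "LIG", 2, *(2.2 * np.array(v)), "C")
            for i, v in enumerate(
                [
                    (1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                    (0, 0, 1), (0, 0, -1),
                    (0.707, 0.707, 0), (-0.707, 0.707, 0),
                    (0.707, -0.707, 0), (-0.707, -0.707, 0),
                    (0.707, 0, 0.707), (-0.707, 0, 0.707),
                    (0.707, 0, -0.707), (-0.707, 0, -0.707),
                    (0, 0.707, 0.707), (0, -0.707, 0.707),
                    (0, 0.707, -0.707), (0, -0.707, -0.707),
                ]
            )
        ]
        text = format_pdb([("CA", "ALA", 1, 0.0, 0.0, 0.0, "C")] + cage)
        model = read_structure(io.StringIO(text))
        result = sasa(model)
        assert result.per_residue[1] == 0.0

    def test_rigid_motion_invariance(self, helix_model):
        base = sasa(helix_model)
        theta = 0.7
        rot = np.array(
            [
                [math.cos(theta), -math.sin(theta), 0],
                [math.sin(theta), math.cos(theta), 0],
                [0, 0, 1],
            ]
        )
        moved = helix_model.transformed(rot, np.array([11.0, -3.0, 5.0]))
        shifted = sasa(moved)
        # the fixed sampling lattice makes rotation invariance approximate:
        # tight on the whole chain, looser per residue
        assert shifted.total == pytest.approx(base.total, rel=5e-3)
        for res in base.per_residue:
            assert shifted.per_residue[res] == pytest.approx(
                base.per_residue[res], rel=3e-2, abs=1e-3
            )

    def test_sphere_point_convergence(self, dipeptide_model):
        """Quadrupling the sphere sampling shrinks the change in total SASA."""
        totals = {
            n: sasa(dipeptide_model, n_sphere_points=n).total
            for n in (60, 240, 960, 3840)
        }
        d1 = abs(totals[240] - totals[60])
        d2 = abs(totals[960] - totals[240])
        d3 = abs(totals[3840] - totals[960])
        assert d2 <= d1 and d3 <= d2

    def test_matches_independent_shrake_rupley_oracle(self, helix_model):
        """Cross-check against Biopython's Shrake–Rupley with identical
        radii and probe (different fixed point sets: small tolerance)."""
        from Bio.PDB import PDBParser
        from Bio.PDB.SASA import ShrakeRupley

        ours = sasa(helix_model, probe_radius=0.14, n_sphere_points=960)
        parser = PDBParser(QUIET=True)
        bio = parser.get_structure("helix", io.StringIO(helix_pdb_text(20)))
        sr = ShrakeRupley(
            probe_radius=1.4, n_points=960,
            radii_dict={"C": 1.70, "N": 1.55, "O": 1.52},
        )
        sr.compute(bio[0], level="R")
        for residue in bio[0]["A"]:
            res = residue.id[1]
            theirs = residue.sasa / 100.0  # A^2 -> nm^2
            assert ours.per_residue[res] == pytest.approx(
                theirs, rel=0.02, abs=0.005
            )


class TestResidueDistance:
    def test_two_single_atom_residues(self):
        text = format_pdb(
            [("CB", "ALA", 1, 0, 0, 0, "C"), ("CB", "ALA", 2, 3, 0, 0, "C")]
        )
        model = read_structure(io.StringIO(text))
        assert residue_min_distance(model, 1, 2) == pytest.approx(3.0)

    def test_residue_against_itself_is_zero(self, helix_model):
        assert residue_min_distance(helix_model, 5, 5) == 0.0

    def test_glycine_falls_back_to_ca(self):
        text = format_pdb(
            [
                ("N", "GLY", 1, 0, 0, 0, "N"),
                ("CA", "GLY", 1, 1.5, 0, 0, "C"),
                ("CB", "ALA", 2, 6.5, 0, 0, "C"),
            ]
        )
        model = read_structure(io.StringIO(text))
        assert residue_min_distance(model, 1, 2) == pytest.approx(5.0)

    def test_missing_residue_named_in_error(self, helix_model):
        with pytest.raises(KeyError, match="99"):
            residue_min_distance(helix_model, 1, 99)

    def test_symmetry_and_triangle_inequality_under_ca(self, helix_model):
        rng = np.random.default_rng(17)
        for _ in range(30):
            a, b, c = rng.choice(helix_model.residues, 3, replace=False)
            dab = residue_min_distance(helix_model, a, b, "CA")
            dba = residue_min_distance(helix_model, b, a, "CA")
            assert dab == pytest.approx(dba)
            dac = residue_min_distance(helix_model, a, c, "CA")
            dcb = residue_min_distance(helix_model, c, b, "CA")
            assert dab <= dac + dcb + 1e-9


class TestSpatialClusters:
    @staticmethod
    def _beads(positions):
        atoms = [
            ("CB", "ALA", i + 1, x, y, z, "C")
            for i, (x, y, z) in enumerate(positions)
        ]
        return read_structure(io.StringIO(format_pdb(atoms)))

    def test_all_far_apart_gives_singletons(self):
        model = self._beads([(0, 0, 0), (20, 0, 0), (0, 20, 0)])
        result = spatial_clusters(model, [1, 2, 3], cutoff=6.0)
        assert result.clusters == [[1], [2], [3]]

    def test_chain_pair_plus_isolate(self):
        model = self._beads([(0, 0, 0), (4, 0, 0), (30, 0, 0)])
        result = spatial_clusters(model, [1, 2, 3], cutoff=6.0)
        assert result.clusters == [[1, 2], [3]]

    def test_matches_connected_components_oracle(self):
        rng = np.random.default_rng(18)
        for _ in range(50):
            positions = rng.uniform(0, 25, size=(20, 3))
            model = self._beads(positions)
            flagged = list(range(1, 21))
            result = spatial_clusters(model, flagged, cutoff=8.0)
            # brute-force union-find over pairwise distances
            parent = {r: r for r in flagged}

            def find(r):
                while parent[r] != r:
                    parent[r] = parent[parent[r]]
                    r = parent[r]
                return r

            for i in flagged:
                for j in flagged:
                    if i < j and np.linalg.norm(
                        positions[i - 1] - positions[j - 1]
                    ) <= 8.0:
                        parent[find(i)] = find(j)
            oracle = {}
            for r in flagged:
                oracle.setdefault(find(r), set()).add(r)
            expected = sorted(
                (sorted(c) for c in oracle.values()),
                key=lambda c: (-len(c), c[0]),
            )
            assert result.clusters == expected

    def test_lowering_cutoff_only_refines(self):
        rng = np.random.default_rng(19)
        positions = rng.uniform(0, 18, size=(15, 3))
        model = self._beads(positions)
        flagged = list(range(1, 16))
        coarse = spatial_clusters(model, flagged, cutoff=10.0)
        fine = spatial_clusters(model, flagged, cutoff=5.0)
        coarse_map = {
            r: ci for ci, cl in enumerate(coarse.clusters) for r in cl
        }
        for cl in fine.clusters:  # each fine cluster sits in one coarse one
            assert len({coarse_map[r] for r in cl}) == 1

    def test_empty_flag_set_rejected(self, helix_model):
        with pytest.raises(ValueError):
            spatial_clusters(helix_model, [])


class TestBfactorExport:
    def test_round_trip_to_two_decimals(self, helix_model, tmp_path):
        metric = {res: res * 0.13 for res in helix_model.residues}
        out = tmp_path / "painted.pdb"
        export_bfactor_map(helix_model, metric, out)
        text = out.read_text()
        for line in text.splitlines():
            if line.startswith("ATOM"):
                res = int(line[22:26])
                b = float(line[60:66])
                assert b == pytest.approx(round(metric[res], 2), abs=5e-3)

    def test_unassigned_residue_gets_sentinel(self, helix_model, tmp_path):
        out = tmp_path / "sentinel.pdb"
        export_bfactor_map(helix_model, {1: 0.5}, out)
        for line in out.read_text().splitlines():
            if line.startswith("ATOM") and int(line[22:26]) != 1:
                assert float(line[60:66]) == -1.00

    def test_zero_metric_writes_zero(self, helix_model, tmp_path):
        out = tmp_path / "zero.pdb"
        export_bfactor_map(
            helix_model, {r: 0.0 for r in helix_model.residues}, out
        )
        assert " 0.00" in out.read_text()

    def test_metric_with_no_known_residue_rejected(self, helix_model,
                                                   tmp_path):
        with pytest.raises(ValueError):
            export_bfactor_map(helix_model, {999: 1.0}, tmp_path / "x.pdb")
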