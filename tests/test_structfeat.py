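import numpy as np
import pytest

from conftest import rigid_motion, transform_record
from rristack.structfeat import (
    GeometryConfig,
    atom_asa,
    complex_geometry,
    cx,
    dpx,
    golden_spiral_points,
    half_sphere_exposure,
    residue_asa_rasa,
    secondary_structure,
)
from rristack.structio import Atom, Residue
from rristack.synthgen import build_backbone, _ATOM_ORDER, _ELEMENT


def make_residue(chain, index, aa, atom_specs):
    atoms = [Atom(n, e, np.asarray(c, dtype=float)) for n, e, c in atom_specs]
    return Residue(chain, index, aa, atoms, seq_position=index)


def backbone_residues(n, helical, chain="A"):
    out = []
    for i, rd in enumerate(build_backbone(n, helical)):
        atoms = [(name, _ELEMENT[name], rd[name]) for name in _ATOM_ORDER]
        out.append(make_residue(chain, i, "A", atoms))
    return out


class TestAtomAsa:
    def test_isolated_carbon_matches_sphere_area(self):
        # closed form: 4 pi (1.7 + 1.4)^2
        asa = atom_asa(np.zeros((1, 3)), ["C"])
        expected = 4 * np.pi * 3.1 ** 2
        assert asa[0] == pytest.approx(expected, rel=0.01)

    def test_caged_atom_fully_buried(self):
        # 26-atom cage at 2 A grid spacing around the origin
        offsets = [
            (x, y, z)
            for x in (-2.0, 0.0, 2.0)
            for y in (-2.0, 0.0, 2.0)
            for z in (-2.0, 0.0, 2.0)
            if (x, y, z) != (0.0, 0.0, 0.0)
        ]
        coords = np.vstack([[0.0, 0.0, 0.0], offsets])
        asa = atom_asa(coords, ["C"] * len(coords))
        assert asa[0] == 0.0

    def test_symmetric_pair_equal_asa(self):
        coords = np.array([[2.0, 0.0, 0.0], [-2.0, 0.0, 0.0]])
        asa = atom_asa(coords, ["C", "C"])
        assert asa[0] == pytest.approx(asa[1], rel=1e-9)

    def test_quadrature_convergence(self):
        rng = np.random.default_rng(11)
        coords = rng.normal(scale=4.0, size=(40, 3))
        elements = ["C", "N", "O", "S"] * 10
        coarse = atom_asa(coords, elements, n_points=960).sum()
        fine = atom_asa(coords, elements, n_points=3840).sum()
        assert abs(coarse - fine) / fine < 0.02

    def test_spiral_points_on_unit_sphere(self):
        pts = golden_spiral_points(500)
        np.testing.assert_allclose(np.linalg.norm(pts, axis=1), 1.0,
                                   atol=1e-12)


class TestResidueAsaRasa:
    def test_isolated_residue_definition(self):
        res = make_residue("A", 0, "G", [("CA", "C", (0, 0, 0))])
        asa_atoms = atom_asa(np.zeros((1, 3)), ["C"])
        asa, rasa = residue_asa_rasa([res], asa_atoms)
        assert rasa[0] == pytest.approx(asa[0] / 104.0)

    def test_buried_residue_low_rasa(self):
        # central glycine CA wrapped in two dense shells of cage atoms
        shells = np.vstack([
            golden_spiral_points(120) * 4.0,
            golden_spiral_points(220) * 6.5,
        ])
        center = make_residue("A", 0, "G", [("CA", "C", (0, 0, 0))])
        cage = make_residue("A", 1, "A", [
            (f"C{k}", "C", c) for k, c in enumerate(shells)
        ])
        coords = np.vstack([[0.0, 0.0, 0.0], shells])
        asa_atoms = atom_asa(coords, ["C"] * len(coords))
        _, rasa = residue_asa_rasa([center, cage], asa_atoms)
        assert rasa[0] < 0.05


class TestDpx:
    def test_all_accessible_zero(self):
        coords = np.array([[0.0, 0, 0], [8.0, 0, 0]])
        asa = atom_asa(coords, ["C", "C"])
        assert (asa > 0).all()
        np.testing.assert_array_equal(dpx(coords, asa), [0.0, 0.0])

    def test_buried_atom_distance_to_accessible(self):
        coords = np.array([[0.0, 0, 0], [3.0, 0, 0], [5.0, 0, 0]])
        fake_asa = np.array([0.0, 0.0, 10.0])  # only last atom accessible
        depths = dpx(coords, fake_asa)
        assert depths[0] == pytest.approx(5.0)
        assert depths[1] == pytest.approx(2.0)
        assert depths[2] == 0.0

    def test_matches_brute_force_oracle(self, small_complex):
        record, _ = small_complex
        coords = np.vstack([
            r.coord_matrix()
            for c in record.chains for r in c.residues if r.resolved
        ])
        elements = [
            a.element
            for c in record.chains for r in c.residues if r.resolved
            for a in r.atoms
        ]
        asa = atom_asa(coords, elements)
        fast = dpx(coords, asa)
        accessible = coords[asa > 0]
        for i in range(len(coords)):
            if asa[i] > 0:
                expected = 0.0
            else:
                expected = np.linalg.norm(accessible - coords[i],
                                          axis=1).min()
            assert fast[i] == pytest.approx(expected, abs=1e-9)

    def test_degenerate_all_buried_is_zero(self):
        coords = np.zeros((3, 3))
        assert dpx(coords, np.zeros(3)).tolist() == [0.0, 0.0, 0.0]


class TestCx:
    def test_isolated_atom_value(self):
        # (4/3 pi 10^3 - 20.1) / 20.1
        value = cx(np.zeros((1, 3)))[0]
        assert value == pytest.approx(207.397, abs=0.05)

    def test_matches_brute_force_count(self, small_complex):
        record, _ = small_complex
        coords = np.vstack([
            r.coord_matrix()
            for c in record.chains for r in c.residues if r.resolved
        ])
        values = cx(coords)
        v_sphere = 4 / 3 * np.pi * 1000.0
        for i in range(0, len(coords), 17):
            count = (np.linalg.norm(coords - coords[i], axis=1) <= 10.0).sum()
            expected = max((v_sphere - count * 20.1) / (count * 20.1), 0.0)
            assert values[i] == pytest.approx(expected, rel=1e-9)


class TestSecondaryStructure:
    def test_ideal_helix_interior_is_helical(self):
        residues = backbone_residues(12, np.ones(12, dtype=bool))
        states = secondary_structure(residues)
        interior = states[2:-2]
        assert sum(s == "H" for s in interior) / len(interior) >= 0.8

    def test_isolated_extended_strand_is_coil(self):
        residues = backbone_residues(10, np.zeros(10, dtype=bool))
        assert secondary_structure(residues) == ["C"] * 10

    def test_antiparallel_ladder_marks_strands(self):
        # two explicitly built antiparallel strands: paired residues donate
        # and accept mutual backbone hydrogen bonds across a 4.9 A rung
        h, n = 4.9, 8
        residues = []
        for i in range(n):
            x, up = 3.5 * i, (1.0 if i % 2 == 0 else -1.0)
            residues.append(make_residue("A", i, "V", [
                ("N", "N", (x - 1.2, 0, 0)), ("CA", "C", (x, 0, 0)),
                ("C", "C", (x + 1.2, 0, 0)),
                ("O", "O", (x + 1.2, 1.23 * up, 0)),
            ]))
        for j in range(n, 2 * n):
            x = 3.5 * (2 * n - 1 - j)
            down = -1.0 if j % 2 == 1 else 1.0
            residues.append(make_residue("A", j, "V", [
                ("N", "N", (x + 1.2, h, 0)), ("CA", "C", (x, h, 0)),
                ("C", "C", (x - 1.2, h, 0)),
                ("O", "O", (x - 1.2, h + 1.23 * down, 0)),
            ]))
        # hand oracle: rung energy from the electrostatic model
        energy = 0.084 * 332 * (
            1 / (h - 1.23) + 1 / (h - 1) - 1 / (h - 2.23) - 1 / h
        )
        assert energy < -0.5
        states = secondary_structure(residues)
        for idx in (2, 4, 6, 9, 11, 13):
            assert states[idx] == "E"
        assert "H" not in states

    def test_missing_backbone_defaults_to_coil(self):
        residues = [make_residue("A", 0, "A", [("CA", "C", (0, 0, 0))])]
        assert secondary_structure(residues) == ["C"]


class TestHalfSphereExposure:
    def test_isolated_residue_zero(self):
        res = make_residue("A", 0, "A", [
            ("CA", "C", (0, 0, 0)), ("CB", "C", (0, 0, 1.5)),
        ])
        np.testing.assert_array_equal(half_sphere_exposure([res])[0], [0, 0])

    def test_neighbor_along_cb_counts_up(self):
        center = make_residue("A", 0, "A", [
            ("CA", "C", (0, 0, 0)), ("CB", "C", (0, 0, 1.5)),
        ])
        above = make_residue("A", 1, "A", [("CA", "C", (0, 0, 5.0))])
        below = make_residue("A", 2, "A", [("CA", "C", (0, 0, -5.0))])
        hse = half_sphere_exposure([center, above, below])
        assert hse[0].tolist() == [1.0, 1.0]

    def test_partition_property(self, small_complex):
        record, _ = small_complex
        residues = record.partner_residues("receptor")
        hse = half_sphere_exposure(residues, radius=13.0)
        ca = np.array([r.atom("CA").coords for r in residues])
        for i in range(len(residues)):
            d = np.linalg.norm(ca - ca[i], axis=1)
            within = ((d <= 13.0) & (d > 0)).sum()
            assert hse[i].sum() == within


class TestRigidMotionInvariance:
    def test_all_geometric_features_invariant(self, small_complex):
        record, _ = small_complex
        base = complex_geometry(record)
        rot, shift = rigid_motion(np.random.default_rng(5))
        moved = transform_record(record, rot, shift)
        other = complex_geometry(moved)
        assert base.keys() == other.keys()
        for key in base:
            a, b = base[key].to_array(), other[key].to_array()
            np.testing.assert_allclose(a, b, rtol=1e-6, atol=1e-9)

    def test_unbound_mode_ignores_partner(self, small_complex):
        record, _ = small_complex
        bound = complex_geometry(record)
        unbound = complex_geometry(record, GeometryConfig(unbound=True))
        # interface residues gain accessibility once the partner is removed
        total_bound = sum(b.asa for b in bound.values())
        total_unbound = sum(b.asa for b in unbound.values())
        assert total_unbound > total_bound
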