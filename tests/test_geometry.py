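import math

import numpy as np
import pytest

from tsakit.errors import DegenerateGeometryError, InsufficientPairsError, MissingAtomError
from tsakit.geometry import (
    DEFAULT_DISTANCE_PAIRS,
    RigidTransform,
    atom_distance,
    displacement_table,
    distance_table,
    kabsch_superpose,
    pair_calpha,
    superpose_structures,
)
from tsakit.simulate import make_structure_pair, make_toy_complex, random_transform
from tsakit.structure_io import AtomQuery


class TestAtomDistance:
    def test_coincident_points(self):
        assert atom_distance([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_pythagorean(self):
        assert atom_distance([0, 0, 0], [3, 4, 0]) == pytest.approx(5.0)

    def test_against_brute_force(self):
        # oracle: explicit sum of squared component differences
        rng = np.random.default_rng(42)
        for _ in range(1000):
            a, b = rng.normal(0, 50, size=(2, 3))
            brute = math.sqrt(sum((ai - bi) ** 2 for ai, bi in zip(a, b)))
            assert atom_distance(a, b) == pytest.approx(brute, abs=1e-12)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            atom_distance([np.inf, 0, 0], [0, 0, 0])


class TestRigidTransform:
    def test_rejects_reflection(self):
        with pytest.raises(ValueError):
            RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))

    def test_rejects_non_orthonormal(self):
        with pytest.raises(ValueError):
            RigidTransform(np.eye(3) * 2.0, np.zeros(3))

    def test_compose_inverse_is_identity(self):
        rng = np.random.default_rng(7)
        tr = random_transform(rng)
        ident = tr.compose(tr.inverse())
        np.testing.assert_allclose(ident.rotation, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(ident.translation, 0.0, atol=1e-12)


class TestKabsch:
    def test_identity_on_equal_inputs(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(0, 10, size=(20, 3))
        res = kabsch_superpose(pts, pts)
        assert res.rmsd <= 1e-10
        np.testing.assert_allclose(res.transform.rotation, np.eye(3), atol=1e-10)
        np.testing.assert_allclose(res.transform.translation, 0.0, atol=1e-10)

    def test_known_transform_recovery(self):
        rng = np.random.default_rng(11)
        ref = rng.normal(0, 10, size=(50, 3))
        true = random_transform(rng)
        mobile = true.inverse().apply(ref)  # so that true maps mobile -> ref
        res = kabsch_superpose(ref, mobile)
        assert res.rmsd <= 1e-8
        composed = res.transform.compose(true.inverse())
        np.testing.assert_allclose(composed.rotation @ true.rotation.T
                                   if False else res.transform.rotation,
                                   true.rotation, atol=1e-8)
        np.testing.assert_allclose(res.transform.translation, true.translation,
                                   atol=1e-8)

    def test_degenerate_collinear(self):
        line = np.outer(np.arange(5, dtype=float), [1.0, 0.0, 0.0])
        with pytest.raises(DegenerateGeometryError):
            kabsch_superpose(line, line)

    def test_too_few_pairs(self):
        pts = np.eye(3)[:2]
        with pytest.raises(InsufficientPairsError):
            kabsch_superpose(pts, pts)

    def test_reflection_guard_determinant_plus_one(self):
        rng = np.random.default_rng(3)
        ref = rng.normal(0, 5, size=(30, 3))
        mirrored = ref * np.array([-1.0, 1.0, 1.0])
        res = kabsch_superpose(ref, mirrored)
        assert np.linalg.det(res.transform.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_rmsd_recomputable_from_transform(self):
        rng = np.random.default_rng(5)
        ref = rng.normal(0, 10, size=(40, 3))
        mobile = ref + rng.normal(0, 0.5, size=ref.shape)
        res = kabsch_superpose(ref, mobile)
        dev = ref - res.transform.apply(mobile)
        assert res.rmsd == pytest.approx(np.sqrt((dev**2).sum(axis=1).mean()))

    def test_rmsd_minimality_under_rotation_perturbation(self):
        rng = np.random.default_rng(17)
        ref = rng.normal(0, 10, size=(60, 3))
        mobile = ref + rng.normal(0, 0.3, size=ref.shape)
        res = kabsch_superpose(ref, mobile)
        centroid = mobile.mean(axis=0)
        base = res.rmsd
        for _ in range(100):
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            angle = 1e-3
            k = np.array([[0, -axis[2], axis[1]],
                          [axis[2], 0, -axis[0]],
                          [-axis[1], axis[0], 0]])
            delta = (np.eye(3) + np.sin(angle) * k
                     + (1 - np.cos(angle)) * (k @ k))
            rot = res.transform.rotation @ delta
            moved = (mobile - centroid) @ rot.T + res.transform.apply(centroid)
            rmsd = np.sqrt(((ref - moved) ** 2).sum() / len(ref))
            assert rmsd >= base - 1e-12


class TestPairCalpha:
    def test_identical_structures_pair_every_calpha(self):
        ref, _ = make_structure_pair(25, RigidTransform.identity(), seed=0)
        a, b, residues = pair_calpha(ref, ref)
        assert len(residues) == 25
        np.testing.assert_allclose(a, b)

    def test_missing_residues_absent_from_pairs(self):
        ref, mobile = make_structure_pair(20, RigidTransform.identity(), seed=1)
        truncated = type(mobile)(label=mobile.label,
                                 atoms=[x for x in mobile.atoms if x.res_seq > 5])
        _, _, residues = pair_calpha(ref, truncated)
        assert len(residues) == 15
        assert all(r[1] > 5 for r in residues)

    def test_shared_count_is_set_intersection(self):
        # oracle: independent set intersection on residue numbers
        rng = np.random.default_rng(9)
        ref, mobile = make_structure_pair(30, RigidTransform.identity(), seed=2)
        keep_ref = set(rng.choice(30, size=22, replace=False) + 1)
        keep_mob = set(rng.choice(30, size=24, replace=False) + 1)
        ref2 = type(ref)(label="r", atoms=[a for a in ref.atoms if a.res_seq in keep_ref])
        mob2 = type(mobile)(label="m", atoms=[a for a in mobile.atoms if a.res_seq in keep_mob])
        _, _, residues = pair_calpha(ref2, mob2)
        assert len(residues) == len(keep_ref & keep_mob)

    def test_insufficient_pairs(self):
        ref, mobile = make_structure_pair(10, RigidTransform.identity(), seed=3)
        mob2 = type(mobile)(label="m", atoms=[a for a in mobile.atoms if a.res_seq > 8])
        with pytest.raises(InsufficientPairsError):
            pair_calpha(ref, mob2)


def _offset_complex(shift_atom=None, shift=(0.0, 0.0, 0.0), offset=(0.0, 0.0, 0.0)):
    """Toy complex with ligand core + Tyr255/Glu277 side chains."""
    base = [
        ("CA", ("A", 10, "GLY", False), (0.0, 0.0, 0.0)),
        ("CA", ("A", 11, "GLY", False), (3.8, 0.0, 0.0)),
        ("CA", ("A", 12, "GLY", False), (5.0, 3.0, 0.0)),
        ("CA", ("A", 13, "GLY", False), (2.0, 5.0, 1.0)),
        ("CA", ("A", 255, "TYR", False), (8.0, 2.0, 1.0)),
        ("OH", ("A", 255, "TYR", False), (6.5, 1.0, 2.0)),
        ("CA", ("A", 277, "GLU", False), (9.0, 6.0, 2.0)),
        ("CD", ("A", 277, "GLU", False), (7.5, 5.0, 2.5)),
        ("OE1", ("A", 277, "GLU", False), (7.0, 4.2, 3.3)),
        ("OE2", ("A", 277, "GLU", False), (6.9, 5.2, 1.6)),
        ("S18", ("A", 402, "SUL", True), (4.0, 2.0, 2.0)),
        ("N17", ("A", 402, "SUL", True), (4.5, 3.0, 2.8)),
        ("N19", ("A", 402, "SUL", True), (4.8, 0.9, 2.7)),
        ("O20", ("A", 402, "SUL", True), (3.0, 1.5, 3.0)),
        ("O21", ("A", 402, "SUL", True), (3.3, 2.9, 1.1)),
        ("C13", ("A", 402, "SUL", True), (5.5, 3.5, 1.9)),
        ("C14", ("A", 402, "SUL", True), (6.4, 4.0, 3.0)),
        ("O15", ("A", 402, "SUL", True), (6.1, 4.1, 4.2)),
        ("O16", ("A", 402, "SUL", True), (7.5, 4.4, 2.6)),
    ]
    spec = []
    for name, res, pos in base:
        p = np.asarray(pos) + np.asarray(offset)
        if name == shift_atom:
            p = p + np.asarray(shift)
        spec.append((name, res, tuple(p)))
    return make_toy_complex(spec)


class TestDisplacementTable:
    def test_self_displacements_all_zero(self):
        st = _offset_complex()
        rows = displacement_table(st, st)
        assert len(rows) == 13
        assert all(row.displacement == pytest.approx(0.0, abs=1e-12) for row in rows)

    def test_single_moved_atom_050(self):
        # oracle by construction: only Tyr255 OH moved by (0.3, 0.4, 0)
        ref = _offset_complex()
        mobile = _offset_complex(shift_atom="OH", shift=(0.3, 0.4, 0.0))
        rows = displacement_table(ref, mobile)
        by_label = {r.label: r.displacement for r in rows}
        assert by_label["Tyr 255, OH"] == pytest.approx(0.5, abs=1e-9)
        for label, value in by_label.items():
            if label != "Tyr 255, OH":
                assert value == pytest.approx(0.0, abs=1e-9)

    def test_unresolvable_label_names_structure(self):
        ref = _offset_complex()
        mobile = make_toy_complex([(n, r, p) for n, r, p in [
            ("CA", ("A", 10, "GLY", False), (0.0, 0.0, 0.0)),
            ("CA", ("A", 11, "GLY", False), (3.8, 0.0, 0.0)),
            ("CA", ("A", 12, "GLY", False), (5.0, 3.0, 0.0)),
            ("S18", ("A", 402, "SUL", True), (4.0, 2.0, 2.0)),
            ("N17", ("A", 402, "SUL", True), (4.5, 3.0, 2.8)),
            ("N19", ("A", 402, "SUL", True), (4.8, 0.9, 2.7)),
        ]], label="partial")
        with pytest.raises(MissingAtomError, match="partial"):
            displacement_table(ref, mobile)


class TestDistanceTable:
    def test_zn_s18_constructed(self, toy_zn_complex):
        rows = distance_table(toy_zn_complex, [
            ("S18", "Zn2+", AtomQuery(name="ZN", res_name="ZN")),
        ])
        assert rows[0].ligand_atom == "S18"
        assert rows[0].distance == pytest.approx(3.08)

    def test_full_16_row_mock_matches_brute_force(self):
        st = _full_site_complex()
        rows = distance_table(st)
        assert len(rows) == 16
        # oracle: direct arithmetic on the construction coordinates
        positions = {(a.name, a.res_seq): a.position for a in st.atoms}
        for row, (lig_name, _, query) in zip(rows, DEFAULT_DISTANCE_PAIRS):
            lig = positions[(lig_name, 402)]
            partner = next(p for (n, r), p in positions.items()
                           if n == query.name and (query.res_seq in (None, r)))
            expected = math.sqrt(float(((lig - partner) ** 2).sum()))
            assert row.distance == pytest.approx(expected, abs=1e-12)

    def test_missing_atom_names_row(self, toy_zn_complex):
        with pytest.raises(MissingAtomError, match="O16"):
            distance_table(toy_zn_complex, [
                ("O16", "TYR 255[OH]",
                 AtomQuery(name="OH", res_seq=255, res_name="TYR")),
            ])

    def test_symmetry_in_argument_order(self, toy_zn_complex):
        a = distance_table(toy_zn_complex, [
            ("S18", "Zn2+", AtomQuery(name="ZN", res_name="ZN"))])[0].distance
        zn = next(x for x in toy_zn_complex.atoms if x.name == "ZN")
        s18 = next(x for x in toy_zn_complex.atoms if x.name == "S18")
        assert a == pytest.approx(atom_distance(zn.position, s18.position))


def _full_site_complex():
    rng = np.random.default_rng(2024)
    spec = []
    res_atoms = [
        ("NH1", 129, "ARG"), ("NH2", 129, "ARG"), ("ND2", 146, "ASN"),
        ("NH1", 147, "ARG"), ("NH2", 147, "ARG"), ("O", 205, "THR"),
        ("OH", 255, "TYR"), ("OE1", 277, "GLU"), ("OE2", 277, "GLU"),
    ]
    for name, seq, res in res_atoms:
        spec.append((name, ("A", seq, res, False), tuple(rng.normal(0, 4, 3))))
    for i in range(6):  # C-alpha scaffold so the structure is well-formed
        spec.append(("CA", ("A", 10 + i, "GLY", False), tuple(rng.normal(0, 8, 3))))
    for name in ("S18", "N17", "N19", "O20", "O21", "C13", "C14", "O15", "O16"):
        spec.append((name, ("A", 402, "SUL", True), tuple(rng.normal(0, 3, 3))))
    spec.append(("ZN", ("A", 401, "ZN", True), (0.0, 0.0, 0.0)))
    return make_toy_complex(spec, label="site")


class TestFrameInvariance:
    def test_tables_invariant_under_common_rigid_motion(self):
        rng = np.random.default_rng(33)
        common = random_transform(rng)
        ref = _offset_complex()
        mobile = _offset_complex(shift_atom="OE2", shift=(0.2, -0.1, 0.4))

        def moved(st):
            atoms = []
            for a in st.atoms:
                rec = type(a)(serial=a.serial, name=a.name, alt_loc=a.alt_loc,
                              res_name=a.res_name, chain_id=a.chain_id,
                              res_seq=a.res_seq, i_code=a.i_code,
                              position=common.apply(a.position),
                              occupancy=a.occupancy, b_factor=a.b_factor,
                              element=a.element, is_hetero=a.is_hetero)
                atoms.append(rec)
            return type(st)(label=st.label, atoms=atoms)

        rows_before = displacement_table(ref, mobile)
        rows_after = displacement_table(moved(ref), moved(mobile))
        for a, b in zip(rows_before, rows_after):
            assert a.displacement == pytest.approx(b.displacement, abs=1e-9)

        site = _full_site_complex()
        d_before = distance_table(site)
        d_after = distance_table(moved(site))
        for a, b in zip(d_before, d_after):
            assert a.distance == pytest.approx(b.distance, abs=1e-9)


class TestSuperposeStructures:
    def test_mean_sq_calpha_displacement_equals_rmsd_sq(self):
        rng = np.random.default_rng(4)
        tr = random_transform(rng)
        ref, mobile = make_structure_pair(80, tr, jitter_sd=0.3, seed=12)
        res = superpose_structures(ref, mobile)
        ref_xyz, mob_xyz, _ = pair_calpha(ref, mobile)
        moved = res.transform.apply(mob_xyz)
        msd = float(((ref_xyz - moved) ** 2).sum(axis=1).mean())
        assert msd == pytest.approx(res.rmsd**2, rel=1e-12)

    def test_n_pairs_matches_paired_residues(self):
        ref, mobile = make_structure_pair(40, RigidTransform.identity(), seed=5)
        res = superpose_structures(ref, mobile)
        assert res.n_pairs == len(res.paired_residues) == 40
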