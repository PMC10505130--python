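"""Spin-group distance treatments, square-well penalties, Karplus rule,
and restraint-file parsing."""
import math

import numpy as np
import pytest
from hypothesis import given, settings as hsettings, strategies as st

from macroconf.chem import Conformer, InputError, load_molecule
from macroconf.restraints import (
    DistanceRestraint,
    RestraintSet,
    SpinGroup,
    TorsionRestraint,
    distance_penalty,
    effective_distance,
    karplus_j,
    parse_restraints,
    phi_restraint_from_j,
    spin_group,
    torsion_penalty,
    total_restraint_energy,
    write_restraints,
)


@pytest.fixture
def propane_conf():
    """Propane with hand-placed coordinates; H positions are overwritten per test."""
    mol = load_molecule("CCC")
    coords = np.random.default_rng(1).normal(scale=3, size=(mol.num_atoms, 3))
    return Conformer(mol, coords)


def place(conf, positions):
    c = conf.coords.copy()
    for idx, xyz in positions.items():
        c[idx] = xyz
    return Conformer(conf.molecule, c)


def h_indices(mol):
    return [i for i in range(mol.num_atoms) if mol.is_hydrogen(i)]


class TestEffectiveDistance:
    def test_singletons_collapse_all_methods(self, propane_conf):
        hs = h_indices(propane_conf.molecule)
        conf = place(propane_conf, {hs[0]: [0, 0, 0], hs[1]: [3.0, 0, 0]})
        for method in ("qmin", "r6", "center"):
            r = DistanceRestraint(
                group_a=SpinGroup((hs[0],)), group_b=SpinGroup((hs[1],)),
                upper=10.0, method=method,
            )
            assert effective_distance(conf, r) == pytest.approx(3.0, abs=1e-9)

    def test_two_member_group_oracle(self, propane_conf):
        # pair distances 3.0 and 5.0: qmin = 3.0, r6 = ((3^-6+5^-6)/2)^(-1/6)
        hs = h_indices(propane_conf.molecule)
        conf = place(
            propane_conf,
            {hs[0]: [0, 0, 0], hs[1]: [3.0, 0, 0], hs[2]: [5.0, 0, 0]},
        )
        qmin_r = DistanceRestraint(
            group_a=SpinGroup((hs[0],)), group_b=SpinGroup((hs[1], hs[2])),
            upper=10.0, method="qmin",
        )
        r6_r = DistanceRestraint(
            group_a=SpinGroup((hs[0],)), group_b=SpinGroup((hs[1], hs[2])),
            upper=10.0, method="r6",
        )
        assert effective_distance(conf, qmin_r) == pytest.approx(3.0, abs=1e-9)
        expected = ((3.0**-6 + 5.0**-6) / 2.0) ** (-1.0 / 6.0)
        assert expected == pytest.approx(3.3419, abs=1e-3)
        assert effective_distance(conf, r6_r) == pytest.approx(expected, rel=1e-12)

    def test_equal_distances_degenerate(self, propane_conf):
        hs = h_indices(propane_conf.molecule)
        conf = place(
            propane_conf,
            {hs[0]: [0, 0, 0], hs[1]: [4.0, 0, 0], hs[2]: [0, 4.0, 0]},
        )
        ga, gb = SpinGroup((hs[0],)), SpinGroup((hs[1], hs[2]))
        q = effective_distance(conf, DistanceRestraint(group_a=ga, group_b=gb, upper=9, method="qmin"))
        r6 = effective_distance(conf, DistanceRestraint(group_a=ga, group_b=gb, upper=9, method="r6"))
        assert q == pytest.approx(4.0, abs=1e-9)
        assert r6 == pytest.approx(4.0, abs=1e-9)

    def test_center_adds_pseudoatom_corrections(self, propane_conf):
        hs = h_indices(propane_conf.molecule)
        conf = place(
            propane_conf,
            {hs[0]: [0, 0, 0], hs[1]: [4.0, 1.0, 0], hs[2]: [4.0, -1.0, 0]},
        )
        r = DistanceRestraint(
            group_a=SpinGroup((hs[0],), delta=0.5),
            group_b=SpinGroup((hs[1], hs[2]), delta=1.0),
            upper=10.0, method="center",
        )
        assert effective_distance(conf, r) == pytest.approx(4.0 + 1.5, abs=1e-9)

    def test_qmin_bounded_by_r6_on_random_geometries(self, rng):
        # qmin <= r_eff for any geometry: the minimum pairwise distance
        # dominates the r^-6 sum from below
        mol = load_molecule("CCC")
        hs = h_indices(mol)
        for _ in range(1000):
            coords = rng.normal(scale=4.0, size=(mol.num_atoms, 3))
            conf = Conformer(mol, coords)
            na = int(rng.integers(1, 4))
            nb = int(rng.integers(1, 4))
            ga = SpinGroup(tuple(hs[:na]))
            gb = SpinGroup(tuple(hs[4 : 4 + nb]))
            q = effective_distance(conf, DistanceRestraint(group_a=ga, group_b=gb, upper=99, method="qmin"))
            r6 = effective_distance(conf, DistanceRestraint(group_a=ga, group_b=gb, upper=99, method="r6"))
            assert q <= r6 + 1e-9

    def test_r6_matches_direct_summation_oracle(self, rng):
        mol = load_molecule("CCC")
        hs = h_indices(mol)
        for _ in range(1000):
            coords = rng.normal(scale=4.0, size=(mol.num_atoms, 3))
            conf = Conformer(mol, coords)
            ga = SpinGroup(tuple(hs[:3]))
            gb = SpinGroup(tuple(hs[3:6]))
            r = DistanceRestraint(group_a=ga, group_b=gb, upper=99, method="r6")
            total = 0.0
            for a in ga.atoms:
                for b in gb.atoms:
                    total += np.linalg.norm(coords[a] - coords[b]) ** -6.0
            oracle = (total / (len(ga) * len(gb))) ** (-1.0 / 6.0)
            assert effective_distance(conf, r) == pytest.approx(oracle, rel=1e-9)

    def test_permutation_invariance(self, propane_conf):
        hs = h_indices(propane_conf.molecule)
        conf = propane_conf
        a = DistanceRestraint(
            group_a=SpinGroup(tuple(hs[:3])), group_b=SpinGroup(tuple(hs[3:6])),
            upper=99, method="r6",
        )
        b = DistanceRestraint(
            group_a=SpinGroup(tuple(reversed(hs[:3]))), group_b=SpinGroup(tuple(reversed(hs[3:6]))),
            upper=99, method="r6",
        )
        assert effective_distance(conf, a) == pytest.approx(effective_distance(conf, b), abs=1e-12)


class TestPenalties:
    def _restraint(self, conf, d_upper, weight=10.0):
        hs = h_indices(conf.molecule)
        return DistanceRestraint(
            group_a=SpinGroup((hs[0],)), group_b=SpinGroup((hs[1],)),
            upper=d_upper, weight=weight,
        )

    def test_zero_inside_well(self, propane_conf):
        hs = h_indices(propane_conf.molecule)
        conf = place(propane_conf, {hs[0]: [0, 0, 0], hs[1]: [3.0, 0, 0]})
        assert distance_penalty(conf, self._restraint(conf, 4.0)) == 0.0

    def test_quadratic_outside(self, propane_conf):
        hs = h_indices(propane_conf.molecule)
        conf = place(propane_conf, {hs[0]: [0, 0, 0], hs[1]: [4.5, 0, 0]})
        assert distance_penalty(conf, self._restraint(conf, 4.0, weight=10.0)) == pytest.approx(2.5, abs=1e-9)

    def test_c1_continuity_at_well_edge(self, propane_conf):
        # central finite difference of the penalty wrt the effective distance
        # must vanish at the boundary
        hs = h_indices(propane_conf.molecule)
        r = self._restraint(propane_conf, 4.0, weight=50.0)
        eps = 1e-7
        vals = []
        for d in (4.0 - eps, 4.0 + eps):
            conf = place(propane_conf, {hs[0]: [0, 0, 0], hs[1]: [d, 0, 0]})
            vals.append(distance_penalty(conf, r))
        assert abs(vals[1] - vals[0]) / (2 * eps) < 1e-5

    def test_torsion_penalty_examples(self, butane):
        from macroconf.search import embed_conformer
        from rdkit.Chem import rdMolTransforms

        conf = embed_conformer(butane, seed=1)
        m = conf.to_rdkit()

        def with_angle(angle):
            from macroconf.search import _rdkit_with_coords

            rdm = _rdkit_with_coords(butane, conf.coords)
            rdMolTransforms.SetDihedralDeg(rdm.GetConformer(), 0, 1, 2, 3, angle)
            return Conformer(butane, rdm.GetConformer().GetPositions())

        t = TorsionRestraint(atoms=(0, 1, 2, 3), target=60.0, tolerance=20.0, k=10.0)
        assert torsion_penalty(with_angle(60.0), t) == pytest.approx(0.0, abs=1e-9)
        assert torsion_penalty(with_angle(75.0), t) == pytest.approx(0.0, abs=1e-9)
        expected = 10.0 * math.radians(15.0) ** 2
        assert expected == pytest.approx(0.685, abs=1e-3)
        assert torsion_penalty(with_angle(95.0), t) == pytest.approx(expected, abs=1e-6)
        # periodicity
        assert torsion_penalty(with_angle(95.0 - 360.0), t) == pytest.approx(expected, abs=1e-6)
        # interval form crossing the +-180 seam
        ti = TorsionRestraint(atoms=(0, 1, 2, 3), interval=(160.0, -160.0), k=10.0)
        assert torsion_penalty(with_angle(175.0), ti) == 0.0
        assert torsion_penalty(with_angle(-175.0), ti) == 0.0
        assert torsion_penalty(with_angle(150.0), ti) == pytest.approx(
            10.0 * math.radians(10.0) ** 2, abs=1e-6
        )

    def test_total_energy_additivity(self, propane_conf, rng):
        hs = h_indices(propane_conf.molecule)
        conf = Conformer(propane_conf.molecule, rng.normal(scale=3, size=propane_conf.coords.shape))
        rs = RestraintSet(
            distance=[
                DistanceRestraint(group_a=SpinGroup((hs[0],)), group_b=SpinGroup((hs[1],)), upper=1.0),
                DistanceRestraint(group_a=SpinGroup((hs[2],)), group_b=SpinGroup((hs[3],)), upper=0.5, lower=0.2),
            ],
            torsion=[TorsionRestraint(atoms=(0, 1, 2, 3), target=0.0, tolerance=1.0)],
        )
        total, report = total_restraint_energy(conf, rs)
        by_parts = sum(distance_penalty(conf, r) for r in rs.distance) + sum(
            torsion_penalty(conf, t) for t in rs.torsion
        )
        assert total == pytest.approx(by_parts, abs=1e-9)
        assert len(report) == 3

    def test_cross_molecule_restraint_rejected(self, propane_conf):
        rs = RestraintSet(
            distance=[
                DistanceRestraint(
                    group_a=SpinGroup((propane_conf.molecule.num_atoms + 5,)),
                    group_b=SpinGroup((0,)),
                    upper=3.0,
                )
            ]
        )
        with pytest.raises(InputError):
            total_restraint_energy(propane_conf, rs)


class TestKarplus:
    @pytest.mark.parametrize(
        "phi,expected",
        [(-120.0, 9.87), (150.0, 1.60), (60.0, 6.35)],
    )
    def test_values(self, phi, expected):
        assert karplus_j(phi) == pytest.approx(expected, abs=1e-9)

    def test_phi_rule(self):
        quad = (0, 1, 2, 3)
        r = phi_restraint_from_j(9.2, quad)
        assert r is not None and r.interval == (-155.0, -95.0)
        assert phi_restraint_from_j(7.0, quad) is None
        assert phi_restraint_from_j(8.0, quad) is None  # strict inequality
        with pytest.raises(InputError):
            phi_restraint_from_j(-1.0, quad)


class TestParsing:
    def test_native_line(self, tmp_path):
        path = tmp_path / "r.tsv"
        path.write_text("H12 | H34,H35 | 0.0 | 4.5 | qmin\n")
        rs = parse_restraints(str(path))
        assert len(rs.distance) == 1
        r = rs.distance[0]
        assert r.group_a.atoms == (12,)
        assert r.group_b.atoms == (34, 35)
        assert r.upper == 4.5 and r.method == "qmin"

    def test_round_trip_identical(self, tmp_path):
        src = tmp_path / "src.tsv"
        src.write_text(
            "H1 | H2,H3 | 0.0 | 4.5 | r6 | 50.0 | 0.0 | 1.0\n"
            "H4 | H5 | 1.8 | 3.2 | center | 25.0 | 0.0 | 0.0\n"
            "TOR | 0,1,2,3 | -155.0 | -95.0 | 20.0\n"
        )
        rs = parse_restraints(str(src))
        out = tmp_path / "out.tsv"
        write_restraints(rs, str(out))
        rs2 = parse_restraints(str(out))
        assert rs2 == rs

    def test_upl_with_pseudoatom_expansion(self, tmp_path):
        upl = tmp_path / "a.upl"
        upl.write_text("1 ALA QB 3 GLY HN 4.8\n")
        name_map = {(1, "QB"): (10, 11, 12), (3, "HN"): (30,)}
        rs = parse_restraints(str(upl), dialect="upl-lol", atom_name_map=name_map)
        assert len(rs.distance) == 1
        assert rs.distance[0].group_a.atoms == (10, 11, 12)
        assert rs.distance[0].group_b.atoms == (30,)
        assert rs.distance[0].upper == 4.8

    def test_upl_lol_merged_bounds(self, tmp_path):
        upl = tmp_path / "a.upl"
        lol = tmp_path / "a.lol"
        upl.write_text("1 ALA HN 2 GLY HN 5.0\n")
        lol.write_text("1 ALA HN 2 GLY HN 2.2\n")
        name_map = {(1, "HN"): (3,), (2, "HN"): (9,)}
        rs = parse_restraints(str(upl), dialect="upl-lol", atom_name_map=name_map, lol_path=str(lol))
        assert rs.distance[0].lower == 2.2 and rs.distance[0].upper == 5.0

    def test_unknown_atom_name_cites_line(self, tmp_path):
        upl = tmp_path / "a.upl"
        upl.write_text("1 ALA QQ 2 GLY HN 5.0\n")
        with pytest.raises(InputError, match="line 1"):
            parse_restraints(str(upl), dialect="upl-lol", atom_name_map={(2, "HN"): (9,)})

    def test_empty_file_empty_set(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("")
        rs = parse_restraints(str(path))
        assert len(rs) == 0


class TestSpinGroupDefaults:
    def test_methyl_methylene_aromatic_deltas(self):
        mol = load_molecule("Cc1ccccc1CC")  # methyl + aromatic + methylene
        rd = mol.rdmol
        methyl = [a.GetIdx() for a in rd.GetAtoms() if a.GetAtomicNum() == 1][:3]
        # methyl protons share one carbon parent
        methyl_parent = rd.GetAtomWithIdx(methyl[0]).GetNeighbors()[0].GetIdx()
        methyl = [
            a.GetIdx()
            for a in rd.GetAtomWithIdx(methyl_parent).GetNeighbors()
            if a.GetAtomicNum() == 1
        ]
        assert spin_group(mol, methyl).delta == 1.0
        # aromatic protons on different carbons
        arom_h = [
            a.GetIdx()
            for a in rd.GetAtoms()
            if a.GetAtomicNum() == 1 and a.GetNeighbors()[0].GetIsAromatic()
        ]
        assert spin_group(mol, arom_h[:2]).delta == 2.0
        assert spin_group(mol, [methyl[0]]).delta == 0.0

    def test_non_hydrogen_rejected(self):
        mol = load_molecule("CC")
        with pytest.raises(InputError):
            spin_group(mol, [0, 1])


@given(angle=st.floats(-720, 720), shift=st.integers(-3, 3))
@hsettings(max_examples=200, deadline=None, derandomize=True)
def test_torsion_well_violation_is_periodic(angle, shift):
    from macroconf.restraints import _circular_violation_deg

    well = (-30.0, 45.0)
    v1 = _circular_violation_deg(angle, well)
    v2 = _circular_violation_deg(angle + 360.0 * shift, well)
    assert v1 == pytest.approx(v2, abs=1e-9)
    assert v1 >= 0.0
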