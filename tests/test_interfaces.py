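"""SASA quadrature against closed forms and oracles; burial; polar contacts."""

import math

import numpy as np
import pytest

from fabkit.geometry import RigidTransform
from fabkit.interfaces import (
    VH_VL,
    InterfaceSpec,
    buried_asa,
    contact_occupancy,
    detect_hbonds,
    detect_saltbridges,
    golden_spiral_points,
    interface_residues,
    shrake_rupley,
)
from fabkit.structure_io import apply_domain_map
from fabkit.synth_fixtures import ToyFabSpec, make_contact_fixture, make_toy_fab
from fabkit.tables import hbond_acceptor_atoms, hbond_donor_atoms


def grid_sasa(coords, radii, probe=1.4, n_theta=80, n_phi=160):
    """Independent latitude-longitude quadrature oracle for SASA."""
    coords = np.asarray(coords, float)
    expanded = np.asarray(radii, float) + probe
    theta = (np.arange(n_theta) + 0.5) * math.pi / n_theta
    phi = (np.arange(n_phi) + 0.5) * 2 * math.pi / n_phi
    T, P = np.meshgrid(theta, phi, indexing="ij")
    unit = np.column_stack(
        [(np.sin(T) * np.cos(P)).ravel(), (np.sin(T) * np.sin(P)).ravel(), np.cos(T).ravel()]
    )
    weights = np.repeat(np.sin(theta), n_phi)
    weights = weights / weights.sum()
    out = np.empty(len(coords))
    for i in range(len(coords)):
        pts = coords[i] + expanded[i] * unit
        exposed = np.ones(len(pts), dtype=bool)
        for j in range(len(coords)):
            if j == i:
                continue
            if np.linalg.norm(coords[j] - coords[i]) < expanded[i] + expanded[j]:
                exposed &= ((pts - coords[j]) ** 2).sum(axis=1) >= expanded[j] ** 2
        out[i] = 4 * math.pi * expanded[i] ** 2 * (weights * exposed).sum()
    return out


class TestShrakeRupley:
    def test_single_sphere_closed_form(self):
        area = shrake_rupley(np.zeros((1, 3)), np.array([1.6]), probe_radius=1.4)
        assert area[0] == pytest.approx(4 * math.pi * 3.0**2, rel=0.01)

    def test_distant_atoms_additive(self):
        coords = np.array([[0.0, 0, 0], [100.0, 0, 0]])
        radii = np.array([1.6, 1.4])
        areas = shrake_rupley(coords, radii)
        singles = [shrake_rupley(coords[i : i + 1], radii[i : i + 1])[0] for i in range(2)]
        assert areas.sum() == pytest.approx(sum(singles), rel=1e-12)

    def test_two_sphere_cap_closed_form(self):
        # equal expanded radii R=3, centers d=2 apart:
        # per-sphere exposed area = 2 pi R (R + d/2)
        R, d = 3.0, 2.0
        coords = np.array([[0.0, 0, 0], [d, 0, 0]])
        radii = np.full(2, R - 1.4)
        areas = shrake_rupley(coords, radii, probe_radius=1.4)
        expected = 2 * math.pi * R * (R + d / 2)
        assert areas[0] == pytest.approx(expected, rel=0.01)
        assert areas[1] == pytest.approx(expected, rel=0.01)

    def test_quadrature_convergence(self, rng):
        coords = rng.normal(scale=3.0, size=(50, 3))
        radii = rng.uniform(1.2, 1.9, 50)
        a960 = shrake_rupley(coords, radii, n_points=960)
        a4000 = shrake_rupley(coords, radii, n_points=4000)
        assert abs(a960.sum() - a4000.sum()) / a4000.sum() < 0.01

    def test_against_grid_oracle(self, rng):
        for _ in range(5):
            n = int(rng.integers(5, 21))
            coords = rng.normal(scale=2.5, size=(n, 3))
            radii = rng.uniform(1.2, 1.9, n)
            mine = shrake_rupley(coords, radii)
            oracle = grid_sasa(coords, radii)
            assert mine.sum() == pytest.approx(oracle.sum(), rel=0.02)

    def test_golden_spiral_deterministic_and_unit(self):
        pts = golden_spiral_points(960)
        np.testing.assert_allclose(np.linalg.norm(pts, axis=1), 1.0, atol=1e-12)
        np.testing.assert_array_equal(pts, golden_spiral_points(960))

    def test_rigid_invariance(self, rng):
        coords = rng.normal(scale=3.0, size=(30, 3))
        radii = rng.uniform(1.2, 1.9, 30)
        base = shrake_rupley(coords, radii)
        for _ in range(5):
            t = RigidTransform.random(rng)
            moved = shrake_rupley(t.apply(coords), radii)
            np.testing.assert_allclose(moved, base, rtol=1e-9, atol=1e-9)


class TestBuriedAsa:
    def test_contacting_interface_positive(self, static_fab):
        fab, _ = static_fab
        assert buried_asa(fab, VH_VL, 0, n_points=400) > 10.0

    def test_symmetric_in_side_order(self, static_fab):
        fab, _ = static_fab
        flipped = InterfaceSpec("LV", ("VL",), ("VH",))
        a = buried_asa(fab, VH_VL, 0, n_points=400)
        b = buried_asa(fab, flipped, 0, n_points=400)
        assert a == pytest.approx(b, abs=1e-9)

    def test_distant_sides_zero(self):
        st, dmap, _ = make_toy_fab(ToyFabSpec(seed=3, fv_only=True, contact_gap=80.0))
        fab = apply_domain_map(st, dmap)
        assert buried_asa(fab, VH_VL, 0, n_points=400) == pytest.approx(0.0, abs=1e-9)

    def test_nonnegative_under_jitter(self):
        st, dmap, _ = make_toy_fab(ToyFabSpec(seed=13, n_frames=3, jitter_sigma=0.3))
        fab = apply_domain_map(st, dmap)
        for m in range(3):
            assert buried_asa(fab, VH_VL, m, n_points=400) >= 0.0


class TestInterfaceResidues:
    def test_distant_sides_empty(self):
        st, dmap, _ = make_toy_fab(ToyFabSpec(seed=3, fv_only=True, contact_gap=80.0))
        fab = apply_domain_map(st, dmap)
        side_a, side_b = interface_residues(fab, VH_VL, 0, n_points=400)
        assert side_a == [] and side_b == []

    def test_contact_system_lists_both_sides(self, static_fab):
        fab, _ = static_fab
        side_a, side_b = interface_residues(fab, VH_VL, 0, n_points=400)
        assert len(side_a) > 0 and len(side_b) > 0
        assert all(r.chain_id == "H" for r in side_a)
        assert all(r.chain_id == "L" for r in side_b)

    def test_threshold_excludes_small_deltas(self, static_fab):
        fab, _ = static_fab
        loose_a, _ = interface_residues(fab, VH_VL, 0, min_delta=0.1, n_points=400)
        strict_a, _ = interface_residues(fab, VH_VL, 0, min_delta=1e9, n_points=400)
        assert strict_a == []
        assert len(loose_a) > 0


def brute_force_contacts(fab, spec, model_index, kind, d_max):
    """Exhaustive all-pairs oracle for cross-interface contact detection."""
    coords = fab.structure.coords[model_index]
    sites = fab.structure.sites
    found = set()
    for side_d, side_a in ((spec.side_a, spec.side_b), (spec.side_b, spec.side_a)):
        ia = fab.atom_indices(*side_d)
        ib = fab.atom_indices(*side_a)
        for i in ia:
            for j in ib:
                si, sj = sites[i], sites[j]
                if kind == "hbond":
                    ok = (
                        si.atom_name in hbond_donor_atoms(si.res_name)
                        and sj.atom_name in hbond_acceptor_atoms(sj.res_name)
                    )
                else:
                    from fabkit.tables import NEGATIVE_ATOMS, POSITIVE_ATOMS

                    ok = si.atom_name in POSITIVE_ATOMS.get(si.res_name, ()) and (
                        sj.atom_name in NEGATIVE_ATOMS.get(sj.res_name, ())
                    )
                if ok and np.linalg.norm(coords[i] - coords[j]) <= d_max:
                    found.add(((si.residue, si.atom_name), (sj.residue, sj.atom_name)))
    return found


class TestContacts:
    @pytest.mark.parametrize(
        "kind,distance,angle,expected",
        [
            ("hbond", 2.9, 160.0, 1),
            ("hbond", 3.6, 160.0, 0),   # beyond heavy-atom cutoff
            ("hbond", 2.9, 100.0, 0),   # D-H...A angle below 120
            ("none", 2.9, 160.0, 0),    # carbon is not a donor
        ],
    )
    def test_hbond_criteria(self, kind, distance, angle, expected):
        st, dmap = make_contact_fixture(kind, distance, angle)
        fab = apply_domain_map(st, dmap)
        hbonds = detect_hbonds(fab, VH_VL, 0)
        assert len(hbonds) == expected
        if expected:
            assert hbonds[0].distance == pytest.approx(distance, abs=1e-6)
            assert hbonds[0].angle == pytest.approx(angle, abs=1e-6)

    @pytest.mark.parametrize(
        "distance,expected", [(3.2, 1), (4.5, 0)]
    )
    def test_saltbridge_criteria(self, distance, expected):
        st, dmap = make_contact_fixture("saltbridge", distance)
        fab = apply_domain_map(st, dmap)
        bridges = detect_saltbridges(fab, VH_VL, 0)
        assert len(bridges) == expected

    def test_same_charge_not_a_saltbridge(self):
        # the GLU side has OE1/OE2 but the padding has no basic atoms nearby:
        # flipping the search to look for negative-negative is impossible by
        # construction, so verify via the fixture: GLU-GLU system yields none
        st, dmap = make_contact_fixture("saltbridge", 3.2)
        fab = apply_domain_map(st, dmap)
        bridges = detect_saltbridges(fab, VH_VL, 0)
        assert all(
            {c.donor[1]} <= {"NZ"} and c.acceptor[1] in ("OE1", "OE2") for c in bridges
        )

    def test_occupancy_fraction(self):
        distances = [2.9] * 5 + [4.5] * 5
        st, dmap = make_contact_fixture("hbond", 2.9, 160.0, distances=distances)
        fab = apply_domain_map(st, dmap)
        contacts = contact_occupancy(fab, VH_VL, kinds=("hbond",))
        assert len(contacts) == 1
        assert contacts[0].occupancy == pytest.approx(0.5)

    def test_always_present_occupancy_one(self):
        st, dmap = make_contact_fixture("hbond", 2.9, 160.0, distances=[2.9] * 4)
        fab = apply_domain_map(st, dmap)
        contacts = contact_occupancy(fab, VH_VL, kinds=("hbond",))
        assert contacts[0].occupancy == pytest.approx(1.0)

    def test_never_present_absent_from_report(self):
        st, dmap = make_contact_fixture("hbond", 4.6, 160.0, distances=[4.6] * 3)
        fab = apply_domain_map(st, dmap)
        assert contact_occupancy(fab, VH_VL, kinds=("hbond",)) == []

    def test_matches_brute_force_on_random_fixtures(self, rng):
        # KD-tree pair search must agree exactly with exhaustive enumeration
        for trial in range(50):
            st, dmap, _ = make_toy_fab(
                ToyFabSpec(
                    seed=int(rng.integers(0, 10_000)),
                    domain_size=20,
                    jitter_sigma=1.0,
                    contact_gap=float(rng.uniform(1.0, 6.0)),
                )
            )
            fab = apply_domain_map(st, dmap)
            got = {
                (c.donor, c.acceptor) for c in detect_hbonds(fab, VH_VL, 0)
            }
            expected = brute_force_contacts(fab, VH_VL, 0, "hbond", 3.5)
            assert got == expected
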