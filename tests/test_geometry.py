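"""Superposition, frame registration, orientation angles, and elbow angle."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from fabkit.errors import CoverageError, DegenerateGeometryError
from fabkit.geometry import (
    RigidTransform,
    elbow_angle,
    fit_domain_frame,
    kabsch_superpose,
    pseudo_dyad,
    signed_dihedral,
    vhvl_orientation,
)
from fabkit.reference import default_reference
from fabkit.structure_io import apply_domain_map
from fabkit.synth_fixtures import ToyFabSpec, make_reference_domain, make_toy_fab


def quaternion_superpose(mobile, target):
    """Independent oracle: Horn's quaternion method for optimal rotation."""
    mc = mobile - mobile.mean(axis=0)
    tc = target - target.mean(axis=0)
    M = mc.T @ tc
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    K = np.array(
        [
            [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
            [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
            [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
            [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
        ]
    )
    vals, vecs = np.linalg.eigh(K)
    q = vecs[:, -1]  # w, x, y, z
    R = Rotation.from_quat([q[1], q[2], q[3], q[0]]).as_matrix()
    rmsd = np.sqrt(((mc @ R.T - tc) ** 2).sum(axis=1).mean())
    return R, float(rmsd)


def transformed_fab(fab, rng):
    """Apply one random global rigid transform to every model."""
    t = RigidTransform.random(rng)
    moved = np.einsum("mij,kj->mik", fab.structure.coords, t.rotation) + t.translation
    return apply_domain_map(fab.structure.with_coords(moved), fab.domain_map)


class TestKabsch:
    def test_identity_case(self, rng):
        pts = rng.normal(size=(10, 3))
        transform, rmsd = kabsch_superpose(pts, pts)
        np.testing.assert_allclose(transform.rotation, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(transform.translation, 0.0, atol=1e-12)
        assert rmsd < 1e-12

    def test_pure_rotation_recovered(self, rng):
        pts = rng.normal(size=(10, 3))
        Rz90 = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        transform, rmsd = kabsch_superpose(pts, pts @ Rz90.T)
        # trace of a 90-degree rotation is 1 + 2 cos 90 = 1
        assert np.trace(transform.rotation) == pytest.approx(1.0, abs=1e-9)
        assert rmsd < 1e-12

    def test_mirror_image_gets_proper_rotation(self, rng):
        pts = rng.normal(size=(4, 3))
        mirrored = pts * np.array([1.0, 1.0, -1.0])
        transform, rmsd = kabsch_superpose(pts, mirrored)
        assert np.linalg.det(transform.rotation) == pytest.approx(1.0, abs=1e-9)
        assert rmsd > 0.05
        _R_oracle, rmsd_oracle = quaternion_superpose(pts, mirrored)
        assert rmsd == pytest.approx(rmsd_oracle, abs=1e-9)

    def test_agrees_with_quaternion_oracle(self, rng):
        for _ in range(1000):
            n = int(rng.integers(3, 12))
            mobile = rng.normal(size=(n, 3)) * rng.uniform(0.5, 5)
            target = rng.normal(size=(n, 3)) * rng.uniform(0.5, 5)
            _t, rmsd = kabsch_superpose(mobile, target)
            _R, rmsd_oracle = quaternion_superpose(mobile, target)
            assert abs(rmsd - rmsd_oracle) < 1e-9

    def test_weights_shift_the_fit(self, rng):
        pts = rng.normal(size=(6, 3))
        target = pts.copy()
        target[0] += [2.0, 0, 0]
        w = np.array([100.0, 1, 1, 1, 1, 1])
        _t, rmsd_weighted = kabsch_superpose(pts, target, weights=w)
        _t, rmsd_plain = kabsch_superpose(pts, target)
        assert rmsd_weighted != pytest.approx(rmsd_plain)

    def test_collinear_raises(self):
        line = np.outer(np.arange(5.0), [1.0, 0, 0])
        with pytest.raises(DegenerateGeometryError):
            kabsch_superpose(line, line)


class TestDomainFrame:
    def test_self_registration_is_exact(self):
        ref = default_reference()
        calphas = {pos: ref.coords[i] for i, pos in enumerate(ref.positions)}
        frame = fit_domain_frame(calphas)
        np.testing.assert_allclose(frame.origin, ref.origin, atol=1e-9)
        np.testing.assert_allclose(frame.v1, ref.v1, atol=1e-9)
        np.testing.assert_allclose(frame.v2, ref.v2, atol=1e-9)

    def test_equivariance_under_known_transform(self, rng):
        ref = default_reference()
        t = RigidTransform.random(rng)
        calphas = {
            pos: t.apply(ref.coords[i]) for i, pos in enumerate(ref.positions)
        }
        frame = fit_domain_frame(calphas)
        np.testing.assert_allclose(frame.origin, t.apply(ref.origin), atol=1e-9)
        np.testing.assert_allclose(frame.v1, t.rotation @ ref.v1, atol=1e-9)
        np.testing.assert_allclose(frame.v2, t.rotation @ ref.v2, atol=1e-9)

    def test_origin_stable_under_jitter(self, rng):
        # sigma=0.2 A noise keeps the fitted origin within 0.2 A of truth
        ref = default_reference()
        worst = 0.0
        for _ in range(100):
            calphas = {
                pos: ref.coords[i] + rng.normal(0, 0.2, 3)
                for i, pos in enumerate(ref.positions)
            }
            frame = fit_domain_frame(calphas)
            worst = max(worst, float(np.linalg.norm(frame.origin - ref.origin)))
        assert worst < 0.2

    def test_missing_positions_dropped_pairwise(self):
        ref = default_reference()
        calphas = {pos: ref.coords[i] for i, pos in enumerate(ref.positions)}
        for pos in ref.coreset[:3]:  # still above 80% coverage
            del calphas[pos]
        frame = fit_domain_frame(calphas)
        assert np.linalg.norm(frame.origin - ref.origin) < 0.5

    def test_low_coverage_raises_with_missing_list(self):
        ref = default_reference()
        keep = ref.coreset[: int(0.5 * len(ref.coreset))]
        calphas = {pos: ref.coords[ref.positions.index(pos)] for pos in keep}
        with pytest.raises(CoverageError) as err:
            fit_domain_frame(calphas)
        assert len(err.value.missing) == len(ref.coreset) - len(keep)


class TestOrientation:
    def test_rigid_invariance(self, static_fab, rng):
        fab, _ = static_fab
        base = vhvl_orientation(fab, 0)
        for _ in range(10):
            moved = transformed_fab(fab, rng)
            o = vhvl_orientation(moved, 0)
            for name in ("HL", "HC1", "HC2", "LC1", "LC2", "dc"):
                assert getattr(o, name) == pytest.approx(getattr(base, name), abs=1e-9)

    def test_hl_twist_changes_only_hl(self):
        st, dmap, truth = make_toy_fab(ToyFabSpec(n_frames=2, seed=2, hl_twist=("ramp", 0, 10)))
        fab = apply_domain_map(st, dmap)
        o0, o1 = vhvl_orientation(fab, 0), vhvl_orientation(fab, 1)
        assert o1.HL - o0.HL == pytest.approx(10.0, abs=1e-9)
        for name in ("HC1", "HC2", "LC1", "LC2", "dc"):
            assert getattr(o1, name) == pytest.approx(getattr(o0, name), abs=1e-9)

    def test_dc_shift_changes_only_dc(self):
        st, dmap, truth = make_toy_fab(ToyFabSpec(n_frames=2, seed=2, dc_offset=("ramp", 0, 5)))
        fab = apply_domain_map(st, dmap)
        o0, o1 = vhvl_orientation(fab, 0), vhvl_orientation(fab, 1)
        assert o1.dc - o0.dc == pytest.approx(5.0, abs=1e-9)
        for name in ("HL", "HC1", "HC2", "LC1", "LC2"):
            assert getattr(o1, name) == pytest.approx(getattr(o0, name), abs=1e-9)

    def test_hl_antisymmetry_of_domain_twist(self):
        # twisting VH by +d (equivalently the whole Fv by -d around the same
        # axis then VL by +d) changes HL the same way as twisting VL by +d
        st, dmap, _ = make_toy_fab(ToyFabSpec(n_frames=2, seed=9, hl_twist=("ramp", 0, 7)))
        fab = apply_domain_map(st, dmap)
        d_vl = vhvl_orientation(fab, 1).HL - vhvl_orientation(fab, 0).HL

        st2, dmap2, _ = make_toy_fab(ToyFabSpec(n_frames=2, seed=9, hl_twist=("ramp", 0, -7)))
        fab2 = apply_domain_map(st2, dmap2)
        d_vl_neg = vhvl_orientation(fab2, 1).HL - vhvl_orientation(fab2, 0).HL
        assert d_vl == pytest.approx(7.0, abs=1e-9)
        assert d_vl_neg == pytest.approx(-7.0, abs=1e-9)

    def test_matches_generator_truth(self):
        st, dmap, truth = make_toy_fab(
            ToyFabSpec(n_frames=5, seed=4, hl_twist=("gaussian", 0.0, 3.0))
        )
        fab = apply_domain_map(st, dmap)
        for m in range(5):
            assert vhvl_orientation(fab, m).HL == pytest.approx(truth.hl[m], abs=1e-6)


class TestPseudoDyad:
    def test_exact_twofold(self, rng):
        a = {(i + 1, None): c for i, c in enumerate(rng.normal(size=(15, 3)) * 5)}
        Rz = Rotation.from_euler("z", 180, degrees=True).as_matrix()
        b = {pos: Rz @ c for pos, c in a.items()}
        dyad = pseudo_dyad(a, b)
        assert dyad.angle == pytest.approx(180.0, abs=1e-9)
        assert abs(dyad.axis[2]) == pytest.approx(1.0, abs=1e-9)
        assert not dyad.warning

    def test_jittered_twofold(self, rng):
        pts = rng.normal(size=(30, 3)) * 5
        Rz = Rotation.from_euler("z", 180, degrees=True).as_matrix()
        a = {(i + 1, None): c for i, c in enumerate(pts)}
        b = {pos: Rz @ c + rng.normal(0, 0.1, 3) for pos, c in a.items()}
        dyad = pseudo_dyad(a, b)
        assert dyad.angle == pytest.approx(180.0, abs=1.0)
        axis_dev = math.degrees(math.acos(min(1.0, abs(dyad.axis[2]))))
        assert axis_dev < 1.0

    def test_identity_sets_warning(self, rng):
        a = {(i + 1, None): c for i, c in enumerate(rng.normal(size=(12, 3)))}
        dyad = pseudo_dyad(a, a)
        assert dyad.angle == pytest.approx(0.0, abs=1e-6)
        assert dyad.warning


class TestElbow:
    def test_straight_construction_reads_180(self, static_fab):
        fab, truth = static_fab
        assert elbow_angle(fab, 0) == pytest.approx(180.0, abs=1e-9)

    def test_applied_rotation_recovered(self):
        for delta in (25.0, -25.0, 60.0, -60.0):
            st, dmap, truth = make_toy_fab(
                ToyFabSpec(n_frames=2, seed=6, elbow_rot=("ramp", 0, delta))
            )
            fab = apply_domain_map(st, dmap)
            assert elbow_angle(fab, 1) == pytest.approx(truth.elbow[1], abs=1e-6)
            assert elbow_angle(fab, 1) - elbow_angle(fab, 0) == pytest.approx(-delta, abs=1e-6)

    def test_reflex_angles_representable(self):
        st, dmap, truth = make_toy_fab(ToyFabSpec(n_frames=2, seed=6, elbow_rot=("ramp", 0, -40)))
        fab = apply_domain_map(st, dmap)
        assert elbow_angle(fab, 1) == pytest.approx(220.0, abs=1e-6)

    def test_rigid_invariance(self, rng):
        st, dmap, _ = make_toy_fab(ToyFabSpec(n_frames=1, seed=6, elbow_rot=20.0))
        fab = apply_domain_map(st, dmap)
        base = elbow_angle(fab, 0)
        for _ in range(10):
            assert elbow_angle(transformed_fab(fab, rng), 0) == pytest.approx(base, abs=1e-9)


class TestDihedral:
    def test_quarter_turn_sign_convention(self):
        # looking down the +x axis: +90 degrees from +z arm to +y arm
        p = signed_dihedral([0, 0, 1], [0, 0, 0], [1, 0, 0], [1, 1, 0])
        assert abs(p) == pytest.approx(90.0, abs=1e-12)

    def test_collinear_raises(self):
        with pytest.raises(DegenerateGeometryError):
            signed_dihedral([0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0])
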