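"""Muscle-path geometry: sphere/ellipsoid wrapping, moment arms."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import glenosim as gs
from glenosim.geometry import Frame
from glenosim.muscles import MuscleElement
from glenosim.wrapping import (MusclePathSpec, WrapSurface,
                               build_wrap_for_implant, moment_arm, solve_path)

from conftest import make_single_hinge

Z = np.array([0.0, 0.0, 1.0])


def _frames():
    return {"ground": Frame.identity()}


def _sphere(r, center=(0.0, 0.0, 0.0)):
    return {"w": WrapSurface("w", "sphere", "ground", center, np.full(3, r))}


def _path(p1, p2, wrap=True):
    return MusclePathSpec(("ground", p1), ("ground", p2),
                          wrap_assignments=["w"] if wrap else [])


def sphere_wrap_closed_form(p1, p2, c, r):
    """Independent closed-form oracle: tangent + arc length in the
    plane through p1, p2 and the centre."""
    v1, v2 = np.asarray(p1) - c, np.asarray(p2) - c
    d1, d2 = np.linalg.norm(v1), np.linalg.norm(v2)
    alpha = np.arccos(v1 @ v2 / (d1 * d2))
    arc = alpha - np.arccos(r / d1) - np.arccos(r / d2)
    return np.sqrt(d1**2 - r**2) + np.sqrt(d2**2 - r**2) + r * arc


class TestSphereWrap:
    def test_symmetric_wrap_matches_closed_form(self):
        r = 0.03
        b = 0.01                      # segment passes below centre
        a = np.sqrt((2 * r) ** 2 - b ** 2)   # endpoints at distance 2r
        p1, p2 = np.array([-a, -b, 0.0]), np.array([a, -b, 0.0])
        sol = solve_path(_path(p1, p2), _frames(), _sphere(r))
        assert sol.wrapped["w"]
        expected = sphere_wrap_closed_form(p1, p2, np.zeros(3), r)
        assert sol.length == pytest.approx(expected, abs=1e-9)

    def test_clear_line_of_sight_is_straight(self):
        p1, p2 = np.array([-0.1, 0.05, 0.0]), np.array([0.1, 0.05, 0.0])
        sol = solve_path(_path(p1, p2), _frames(), _sphere(0.03))
        assert not sol.wrapped["w"]
        assert sol.length == pytest.approx(np.linalg.norm(p2 - p1), abs=1e-12)

    def test_length_continuous_across_grazing_radius(self):
        # endpoints fixed; radius crosses the grazing condition at
        # r = 0.02: no jump across the wrapped/unwrapped boundary
        p1, p2 = np.array([-0.1, -0.02, 0.0]), np.array([0.1, -0.02, 0.0])
        eps = 1e-7
        below = solve_path(_path(p1, p2), _frames(), _sphere(0.02 - eps))
        above = solve_path(_path(p1, p2), _frames(), _sphere(0.02 + eps))
        assert not below.wrapped["w"] and above.wrapped["w"]
        assert abs(above.length - below.length) < 1e-6
        # and the length varies smoothly through the whole sweep
        radii = np.linspace(0.0195, 0.0205, 101)
        lengths = [solve_path(_path(p1, p2), _frames(), _sphere(r)).length
                   for r in radii]
        assert np.abs(np.diff(lengths)).max() < 1e-6

    def test_grazing_tie_breaks_to_unwrapped(self):
        p1, p2 = np.array([-0.1, -0.02, 0.0]), np.array([0.1, -0.02, 0.0])
        sol = solve_path(_path(p1, p2), _frames(), _sphere(0.02))
        assert not sol.wrapped["w"]

    def test_endpoint_inside_sphere_raises(self):
        with pytest.raises(ValueError, match="inside"):
            solve_path(_path((0.01, 0.0, 0.0), (0.2, -0.05, 0.0)), _frames(),
                       _sphere(0.03), muscle_name="deltoid_x")

    def test_waypoints_do_not_penetrate_surface(self):
        r = 0.03
        sol = solve_path(_path((-0.1, -0.01, 0.0), (0.1, -0.012, 0.005)),
                         _frames(), _sphere(r))
        assert sol.wrapped["w"]
        clearance = np.linalg.norm(sol.waypoints_world, axis=1) - r
        assert clearance.min() >= -1e-9


class TestEllipsoidWrap:
    def _ellipsoid(self):
        return {"w": WrapSurface("w", "ellipsoid", "ground", (0, 0, 0),
                                 np.array([0.0375, 0.0375, 0.014]))}

    def test_reduces_to_sphere_solution_for_equal_radii(self):
        r = 0.03
        ell = {"w": WrapSurface("w", "ellipsoid", "ground", (0, 0, 0), np.full(3, r))}
        p1, p2 = np.array([-0.1, -0.01, 0.0]), np.array([0.1, -0.01, 0.0])
        got = solve_path(_path(p1, p2), _frames(), ell).length
        exact = solve_path(_path(p1, p2), _frames(), _sphere(r)).length
        # the on-surface portion is a discretized polyline, accurate to
        # the chord-vs-arc error (~1e-5 at implant scale)
        assert got == pytest.approx(exact, abs=5e-5)
        assert got <= exact  # chords never exceed the true arc

    def test_wrapped_longer_than_straight_and_clears_surface(self):
        wraps = self._ellipsoid()
        p1, p2 = np.array([-0.1, 0.01, 0.0]), np.array([0.1, 0.005, 0.002])
        sol = solve_path(_path(p1, p2), _frames(), wraps)
        assert sol.wrapped["w"]
        assert sol.length >= np.linalg.norm(p2 - p1) - 1e-12
        scaled = sol.waypoints_world / wraps["w"].radii
        assert (np.linalg.norm(scaled, axis=1) - 1.0).min() >= -1e-9

    def test_endpoint_inside_ellipsoid_raises(self):
        with pytest.raises(ValueError, match="inside"):
            solve_path(_path((0.0, 0.0, 0.005), (0.2, 0.0, 0.0)),
                       _frames(), self._ellipsoid())


class TestPathInvariants:
    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.integers(0, 10_000))
    def test_length_invariant_under_rigid_scene_transform(self, seed):
        rng = np.random.default_rng(seed)
        rigid = Frame.from_rotvec(rng.uniform(-2, 2, 3), rng.uniform(-1, 1, 3))
        p1, p2 = rng.uniform(-0.2, -0.08, 3), rng.uniform(0.08, 0.2, 3)
        base = solve_path(_path(p1, p2), _frames(), _sphere(0.05))
        moved = solve_path(_path(p1, p2), {"ground": rigid}, _sphere(0.05))
        assert moved.length == pytest.approx(base.length, abs=1e-9)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.integers(0, 10_000))
    def test_wrapped_length_never_below_euclidean(self, seed):
        rng = np.random.default_rng(seed)
        p1 = rng.uniform(-0.25, 0.25, 3)
        p2 = rng.uniform(-0.25, 0.25, 3)
        r = 0.06
        if np.linalg.norm(p1) <= r + 1e-3 or np.linalg.norm(p2) <= r + 1e-3 \
                or np.linalg.norm(p2 - p1) < 1e-3:
            return
        sol = solve_path(_path(p1, p2), _frames(), _sphere(r))
        assert sol.length >= np.linalg.norm(p2 - p1) - 1e-12


def _hinge_muscle(origin, insertion, wrap=False):
    return MuscleElement("m", "other", 100.0, 1.0, 0.0,
                         MusclePathSpec(("ground", origin), ("arm", insertion),
                                        wrap_assignments=["w"] if wrap else []))


class TestMomentArm:
    def test_straight_muscle_arm_is_perpendicular_distance(self):
        model = make_single_hinge()
        d = 0.13
        # muscle parallel to the arm at perpendicular distance d
        model.muscles = [_hinge_muscle((0.0, d, 0.0), (0.3, d, 0.0))]
        arm = moment_arm(model, model.zero_q(), model.muscles[0], 0)
        assert arm == pytest.approx(d, abs=1e-6)

    def test_muscle_not_crossing_joint_has_zero_arm(self):
        model = make_single_hinge()
        mus = MuscleElement("m", "other", 100.0, 1.0, 0.0,
                            MusclePathSpec(("ground", (0.0, 0.1, 0.0)),
                                           ("ground", (0.1, 0.3, 0.0))))
        model.muscles = [mus]
        assert moment_arm(model, model.zero_q(), mus, 0) == pytest.approx(0.0, abs=1e-12)

    def test_wrapped_arm_matches_geometric_perpendicular_distance(self):
        # deltoid-like: wrap sphere centred on the hinge; the moment arm
        # equals the perpendicular distance from the joint centre to the
        # straight (tangent) segment at the joint.
        model = make_single_hinge()
        r = 0.05
        model.wraps = {"w": WrapSurface("w", "sphere", "ground", (0, 0, 0),
                                        np.full(3, r))}
        mus = _hinge_muscle((-0.2, 0.02, 0.0), (0.25, 0.01, 0.0), wrap=True)
        model.muscles = [mus]
        q = model.named_q(q=0.15)
        sol = solve_path(mus.path, model.forward_kinematics(q), model.wraps)
        assert sol.wrapped["w"]
        # geometric oracle: distance from the hinge centre to the last
        # tangent line (the joint-spanning segment)
        (b1, a1), (b2, a2) = sol.anchors[-2:]
        u = (a2 - a1) / np.linalg.norm(a2 - a1)
        geometric = abs(np.cross(a1 - 0.0, u)[2])
        fd = moment_arm(model, q, mus, 0)
        assert fd == pytest.approx(geometric, abs=1e-5)

    def test_arm_bounded_by_path_extent(self, ns_model):
        q = ns_model.named_q(gh_elevation=np.deg2rad(45))
        frames = ns_model.forward_kinematics(q)
        centre = (frames["scapula"] @ Frame(np.eye(3), (-0.010, -0.040, 0.020))).translation
        for mus in ns_model.muscles[:6]:
            sol = solve_path(mus.path, frames, ns_model.wraps, mus.name)
            bound = max(np.linalg.norm(p - centre) for p in sol.waypoints_world)
            for dof in range(ns_model.n_dof):
                assert abs(moment_arm(ns_model, q, mus, dof)) <= bound + 1e-9

    def test_step_outside_valid_range_rejected(self, ns_model):
        with pytest.raises(ValueError, match="step"):
            moment_arm(ns_model, ns_model.zero_q(), ns_model.muscles[0], 0, h=1.0)


class TestImplantWrapBuilder:
    def test_rsp_sphere_diameter_56mm(self):
        w = build_wrap_for_implant("RSP")
        assert w.kind == "sphere"
        np.testing.assert_allclose(w.radii, 0.028)

    def test_dbsp_ellipsoid_75_75_28mm(self):
        w = build_wrap_for_implant("DBSP")
        assert w.kind == "ellipsoid"
        np.testing.assert_allclose(2 * w.radii, [0.075, 0.075, 0.028])

    def test_zero_inflation_recovers_raw_implant_dimensions(self):
        assert 2 * build_wrap_for_implant("RSP", 0.0).radius == pytest.approx(0.036)
        np.testing.assert_allclose(2 * build_wrap_for_implant("DBSP", 0.0).radii,
                                   [0.055, 0.055, 0.028])

    def test_unknown_implant_rejected(self):
        with pytest.raises(ValueError, match="unknown implant"):
            build_wrap_for_implant("ASP")
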