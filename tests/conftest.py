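"""Shared fixtures: toy chains with closed-form mechanics and the three
shoulder models (built once per session)."""
import numpy as np
import pytest

import glenosim as gs
from glenosim.chain import BodySegment, ChainModel, JointSpec
from glenosim.geometry import Frame
from glenosim.muscles import MuscleElement
from glenosim.wrapping import MusclePathSpec

X, Y, Z = np.eye(3)


def make_single_hinge(mass=1.5, length=0.4, hand_mass=0.0, axis=Z,
                      gravity=(0.0, -9.81, 0.0)):
    """Ground + one arm on a hinge at the origin.  At q=0 the arm lies
    along +x; a rotation by q about +z raises the tip toward +y."""
    bodies = [BodySegment("ground", 0.0),
              BodySegment("arm", mass, (length / 2, 0.0, 0.0),
                          attached_point_loads=([((length, 0.0, 0.0), hand_mass)]
                                                if hand_mass else []))]
    joints = [JointSpec("hinge", "hinge", "ground", "arm", axes=[np.asarray(axis, float)],
                        coord_names=["q"])]
    return ChainModel(bodies, joints, gravity=gravity, gh_joint_name="hinge",
                      name="single_hinge", gh_coord_names=["q"])


def make_planar_two_muscle(base_rotation=np.eye(3), mass_scale=1.0):
    """Planar toy for free-body checks: hinge about z, arm along +x,
    an 'elevator' muscle from above and a 'depressor' from below, both
    with simple attachment geometry solvable by hand.  ``base_rotation``
    rigidly rotates the whole scene together with gravity."""
    R0 = np.asarray(base_rotation, float)
    m = 2.0 * mass_scale
    L = 0.35
    bodies = [BodySegment("ground", 0.0),
              BodySegment("arm", m, (L / 2, 0.0, 0.0))]
    joints = [JointSpec("hinge", "hinge", "ground", "arm",
                        parent_frame_offset=Frame(R0, (0.0, 0.0, 0.0)),
                        axes=[Z], coord_names=["q"])]
    mus = [
        MuscleElement("elevator", "other", f_max=2000.0, l_opt=0.33, l_slack=0.0,
                      path=MusclePathSpec(("ground", R0 @ (0.0, 0.25, 0.0)),
                                          ("arm", (0.20, 0.0, 0.0)))),
        MuscleElement("depressor", "other", f_max=2000.0, l_opt=0.33, l_slack=0.0,
                      path=MusclePathSpec(("ground", R0 @ (0.0, -0.25, 0.0)),
                                          ("arm", (0.22, 0.0, 0.0)))),
    ]
    gravity = R0 @ np.array([0.0, -9.81, 0.0])
    return ChainModel(bodies, joints, muscles=mus, gravity=gravity,
                      gh_joint_name="hinge", name="planar_toy", gh_coord_names=["q"])


def make_random_chain(rng, depth):
    """Random serial chain of the four joint kinds for property tests."""
    kinds = rng.choice(["fixed", "hinge", "gimbal", "ball"], size=depth)
    bodies = [BodySegment("b0", 0.0)]
    joints = []
    for i, kind in enumerate(kinds):
        n_axes = {"fixed": 0, "hinge": 1, "gimbal": 2, "ball": 3}[kind]
        axes = []
        while len(axes) < n_axes:
            a = rng.normal(size=3)
            n = np.linalg.norm(a)
            if n > 1e-3:
                axes.append(a / n)
        bodies.append(BodySegment(f"b{i+1}", float(rng.uniform(0.1, 2.0)),
                                  rng.uniform(-0.2, 0.2, 3)))
        joints.append(JointSpec(
            f"j{i}", kind, f"b{i}", f"b{i+1}",
            parent_frame_offset=Frame.from_rotvec(rng.uniform(-1, 1, 3),
                                                  rng.uniform(-0.3, 0.3, 3)),
            child_frame_offset=Frame.from_rotvec(rng.uniform(-1, 1, 3),
                                                 rng.uniform(-0.3, 0.3, 3)),
            axes=axes))
    return ChainModel(bodies, joints)


@pytest.fixture(scope="session")
def ns_model():
    return gs.build_natural_shoulder()


@pytest.fixture(scope="session")
def rsp_model():
    return gs.build_rsp()


@pytest.fixture(scope="session")
def dbsp_model():
    return gs.build_dbsp()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260924)
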