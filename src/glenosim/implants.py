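"""Builders for the three shoulder configurations and the friction
contribution estimate.

The three models — natural shoulder (NS), reverse shoulder prosthesis
(RSP) and dual-bearing shoulder prosthesis (DBSP) — share one skeleton,
one muscle set (identical attachment coordinates and Hill parameters)
and differ only in the gleno-humeral joint structure and the wrap
surface that deflects the deltoid:

* NS:   ball joint at the anatomical humeral-head centre; the deltoid
        wraps the humeral head (24 mm radius sphere on the humerus).
* RSP:  ball joint with the centre of rotation medialized onto the
        glenoid face, 18 mm above the inferior glenoid rim; 56 mm
        spherical wrap (36 mm glenosphere inflated by half the deltoid
        thickness) fixed to the scapula.  Supraspinatus deactivated.
* DBSP: five-joint assembly scapula → glenoid ring (fixed, tilted 10°
        downward) → PE bearing (hinge about the ring axis) → ball head
        (gimbal, centre offset along the ring axis) → offset adapter
        (fixed) → humerus (fixed); 75×75×28 mm ellipsoid wrap fixed to
        the ring.  Supraspinatus deactivated.  The joint reaction force
        is reported at the scapula–ring fixed joint.

All geometry here is synthetic — plausible anthropometric coordinates,
NOT anatomical ground truth from any cadaver dataset.  Group maximum
isometric forces are calibrated so that each group's Σf_max matches the
force/activation ratios implied by the packaged reference table.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np

from .chain import BodySegment, ChainModel, Configuration, JointSpec
from .geometry import Frame, rotation_about
from .muscles import MuscleElement, deactivate_supraspinatus
from .wrapping import MusclePathSpec, WrapSurface, build_wrap_for_implant, solve_path

X, Y, Z = np.eye(3)

# ---------------------------------------------------------------------------
# implant geometry


@dataclass
class ImplantGeometry:
    """Dimensions of the prosthetic joints (metres / degrees)."""

    variant: str = "NS"
    glenosphere_diameter: float = 0.036          # RSP
    glenoid_ring_outer_diameter: float = 0.055   # DBSP
    ring_tilt_deg: float = 10.0                  # DBSP, downward
    cor_above_inferior_rim: float = 0.018        # RSP, on the AP midline
    dual_cor_offset: np.ndarray = None           # DBSP hinge→gimbal COR, m
    friction_coefficient: float = 0.05

    def __post_init__(self) -> None:
        if self.dual_cor_offset is None:
            # offset magnitude is not published; 10 mm along the ring axis
            # is the declared default assumption (configurable)
            self.dual_cor_offset = np.array([0.0, 0.0, 0.010])
        self.dual_cor_offset = np.asarray(self.dual_cor_offset, float)
        if self.glenosphere_diameter <= 0 or self.glenoid_ring_outer_diameter <= 0:
            raise ValueError("implant diameters must be positive")
        if not (0.0 <= self.friction_coefficient <= 0.2):
            raise ValueError("friction coefficient outside plausible range [0, 0.2]")
        if self.variant == "DBSP" and np.linalg.norm(self.dual_cor_offset) == 0:
            raise ValueError("DBSP centres of rotation must be distinct")


@dataclass
class FrictionEstimate:
    friction_moment: float   # N·m
    joint_moment: float      # N·m
    ratio_percent: float


def friction_moment_ratio(mu: float, bearing_radius: float, jrf: float,
                          joint_moment: float) -> FrictionEstimate:
    """Conservative Coulomb bound on the friction contribution to the
    joint moment: M_f = μ·JRF·r at the outer bearing radius."""
    if mu < 0:
        raise ValueError("friction coefficient must be >= 0")
    if bearing_radius <= 0:
        raise ValueError("bearing radius must be > 0")
    if joint_moment <= 0:
        raise ValueError("joint moment must be > 0")
    mf = mu * jrf * bearing_radius
    return FrictionEstimate(mf, joint_moment, 100.0 * mf / joint_moment)


# ---------------------------------------------------------------------------
# shared skeleton geometry (all coordinates in metres, local frames)

_SC_OFFSET = (0.010, 0.010, 0.020)        # thorax → sternoclavicular
_AC_OFFSET = (0.000, 0.010, 0.130)        # clavicle → acromioclavicular
_GH_SCAP = np.array([-0.010, -0.040, 0.020])   # AC → humeral-head centre
_GLENOID_CENTRE_SCAP = np.array([-0.010, -0.040, -0.005])
_GLENOID_INFERIOR_RIM = _GLENOID_CENTRE_SCAP + np.array([0.0, -0.016, 0.0])
_HUMERUS_LENGTH = 0.310
_FOREARM_LENGTH = 0.245

HAND_LOAD_POINT = np.array([0.0, -0.070, 0.0])

GH_COORDS = ("gh_plane", "gh_elevation", "gh_axial")
SCAPULA_COORD = "scapula_upward_rotation"

_DELTOID_ELEMENTS = {"anterior_deltoid": 4, "middle_deltoid": 4, "posterior_deltoid": 7}
_CUFF_ELEMENTS = {"subscapularis": 11, "infraspinatus": 6, "teres_minor": 3,
                  "supraspinatus": 4}

# group Σ f_max (N), calibrated to the reference table's force/activation
# ratios (e.g. anterior deltoid ≈ 136.3/0.27 ≈ 505 N)
GROUP_FMAX_TOTAL = {
    "anterior_deltoid": 505.0,
    "middle_deltoid": 1190.0,
    "posterior_deltoid": 1580.0,
    "supraspinatus": 620.0,
    "infraspinatus": 1420.0,
    "teres_minor": 500.0,
    "subscapularis": 1430.0,
}

_GROUP_L_OPT = {
    "anterior_deltoid": 0.14, "middle_deltoid": 0.14, "posterior_deltoid": 0.14,
    "supraspinatus": 0.08, "infraspinatus": 0.09, "teres_minor": 0.08,
    "subscapularis": 0.10,
}


def _bodies(hand_load_kg: float) -> List[BodySegment]:
    return [
        BodySegment("thorax", 30.0, (0.0, -0.15, 0.0)),
        BodySegment("head", 4.5, (0.0, 0.12, 0.0)),
        BodySegment("clavicle", 0.20, (0.0, 0.0, 0.06)),
        BodySegment("scapula", 0.70, (-0.04, -0.06, -0.04)),
        BodySegment("humerus", 2.03, (0.0, -0.135, 0.0)),
        BodySegment("ulna", 0.65, (0.0, -0.100, 0.0)),
        BodySegment("radius", 0.55, (0.0, -0.090, 0.0)),
        BodySegment("hand", 0.45, (0.0, -0.060, 0.0),
                    attached_point_loads=([(HAND_LOAD_POINT, hand_load_kg)]
                                          if hand_load_kg > 0 else [])),
    ]


def _arm_joints(elbow_flexion_deg: float) -> List[JointSpec]:
    """Elbow and wrist are fixed during the simulations; the elbow
    flexion angle is a build-time parameter of the fixed joint."""
    elbow_rot = rotation_about(Z, np.deg2rad(elbow_flexion_deg))
    return [
        JointSpec("elbow", "fixed", "humerus", "ulna",
                  parent_frame_offset=Frame(np.eye(3), (0.0, -_HUMERUS_LENGTH, 0.0)),
                  child_frame_offset=Frame(elbow_rot, (0.0, 0.0, 0.0))),
        JointSpec("radioulnar", "fixed", "ulna", "radius",
                  parent_frame_offset=Frame(np.eye(3), (0.0, -0.020, 0.010))),
        JointSpec("wrist", "fixed", "radius", "hand",
                  parent_frame_offset=Frame(np.eye(3), (0.0, -(_FOREARM_LENGTH - 0.020), -0.010))),
    ]


def _trunk_joints() -> List[JointSpec]:
    return [
        JointSpec("neck", "fixed", "thorax", "head",
                  parent_frame_offset=Frame(np.eye(3), (0.0, 0.10, 0.0))),
        JointSpec("sternoclavicular", "fixed", "thorax", "clavicle",
                  parent_frame_offset=Frame(np.eye(3), _SC_OFFSET)),
        JointSpec("scapula_hinge", "hinge", "clavicle", "scapula",
                  parent_frame_offset=Frame(np.eye(3), _AC_OFFSET),
                  axes=[-X], coord_names=[SCAPULA_COORD], driven=True),
    ]


def _spread(base: np.ndarray, direction: np.ndarray, n: int, width: float):
    """n points spread symmetrically about ``base`` along ``direction``."""
    base = np.asarray(base, float)
    direction = np.asarray(direction, float)
    if n == 1:
        return [base.copy()]
    offs = np.linspace(-width / 2, width / 2, n)
    return [base + o * direction for o in offs]


def _muscle_paths() -> Dict[str, List[Tuple[Tuple[str, np.ndarray], Tuple[str, np.ndarray]]]]:
    """(origin, insertion) per element for the 7 studied groups.

    Synthetic coordinates: clavicular origins for the anterior deltoid,
    acromial for the middle, scapular-spine for the posterior; cuff
    origins on the scapular fossae with insertions on the tubercles.
    """
    paths: Dict[str, list] = {}
    paths["anterior_deltoid"] = [
        (("clavicle", o), ("humerus", i))
        for o, i in zip(_spread((0.018, 0.005, 0.105), Z, 4, 0.030),
                        _spread((0.009, -0.133, 0.005), X, 4, 0.006))]
    paths["middle_deltoid"] = [
        (("scapula", o), ("humerus", i))
        for o, i in zip(_spread((-0.005, 0.005, 0.022), X, 4, 0.014),
                        _spread((0.002, -0.137, 0.008), X, 4, 0.006))]
    paths["posterior_deltoid"] = [
        (("scapula", o), ("humerus", i))
        for o, i in zip(_spread((-0.040, 0.000, -0.033), np.array([-0.5, -0.1, -0.8]), 7, 0.055),
                        _spread((-0.005, -0.133, 0.007), X, 7, 0.008))]
    paths["supraspinatus"] = [
        (("scapula", o), ("humerus", i))
        for o, i in zip(_spread((-0.048, -0.025, -0.045), np.array([-1.0, 0.0, -0.3]), 4, 0.030),
                        _spread((0.004, 0.018, 0.016), X, 4, 0.008))]
    paths["infraspinatus"] = [
        (("scapula", o), ("humerus", i))
        for o, i in zip(_spread((-0.055, -0.085, -0.040), Y, 6, 0.035),
                        _spread((-0.016, 0.008, 0.014), Y, 6, 0.010))]
    paths["teres_minor"] = [
        (("scapula", o), ("humerus", i))
        for o, i in zip(_spread((-0.035, -0.110, -0.020), Y, 3, 0.020),
                        _spread((-0.017, -0.004, 0.012), Y, 3, 0.008))]
    paths["subscapularis"] = [
        (("scapula", o), ("humerus", i))
        for o, i in zip(_spread((0.004, -0.085, -0.050), np.array([0.0, 0.8, -0.6]), 11, 0.060),
                        _spread((0.017, 0.004, 0.006), Y, 11, 0.014))]
    return paths


def _build_muscles(wrap_name: Optional[str],
                   params: Optional[Dict[str, Tuple[float, float]]] = None
                   ) -> List[MuscleElement]:
    muscles: List[MuscleElement] = []
    paths = _muscle_paths()
    for group in (*_DELTOID_ELEMENTS, *_CUFF_ELEMENTS):
        n = {**_DELTOID_ELEMENTS, **_CUFF_ELEMENTS}[group]
        fmax = GROUP_FMAX_TOTAL[group] / n
        for k, (origin, insertion) in enumerate(paths[group]):
            name = f"{group}_{k + 1}"
            wrapped = group in _DELTOID_ELEMENTS and wrap_name is not None
            l_opt, l_slack = (params or {}).get(name, (_GROUP_L_OPT[group], 0.0))
            muscles.append(MuscleElement(
                name=name, group=group, f_max=fmax, l_opt=l_opt, l_slack=l_slack,
                path=MusclePathSpec(origin, insertion,
                                    wrap_assignments=[wrap_name] if wrapped else [])))
    return muscles


def _calibrate_lengths(model: ChainModel, elevation_deg: float = 45.0) -> Dict[str, Tuple[float, float]]:
    """Fix l_slack so each element sits at its optimal fiber length at
    mid-range elevation (45° with the accompanying scapular rhythm)."""
    q = model.named_q(gh_elevation=np.deg2rad(elevation_deg),
                      scapula_upward_rotation=np.deg2rad((elevation_deg - 30.0) / 2.0))
    frames = model.forward_kinematics(q)
    params = {}
    for m in model.muscles:
        L = solve_path(m.path, frames, model.wraps, m.name).length
        l_opt = _GROUP_L_OPT[m.group]
        if L > l_opt:
            params[m.name] = (l_opt, L - l_opt)
        else:
            params[m.name] = (L, 0.0)
        m.l_opt, m.l_slack = params[m.name]
    return params


_NS_PARAM_CACHE: Optional[Dict[str, Tuple[float, float]]] = None


def _ns_muscle_params() -> Dict[str, Tuple[float, float]]:
    """Hill parameters are calibrated once on the NS geometry and reused
    unchanged by the prosthesis models."""
    global _NS_PARAM_CACHE
    if _NS_PARAM_CACHE is None:
        model = _assemble_ns(hand_load_kg=2.0, elbow_flexion_deg=0.0, params=None)
        _NS_PARAM_CACHE = _calibrate_lengths(model)
    return dict(_NS_PARAM_CACHE)


# ---------------------------------------------------------------------------
# builders


def _assemble_ns(hand_load_kg: float, elbow_flexion_deg: float, params) -> ChainModel:
    wrap = WrapSurface("humeral_head_wrap", "sphere", "humerus",
                       center_local=(0.0, 0.0, 0.0),
                       radii=np.full(3, 0.024),
                       active_muscles=[f"{g}_{k+1}" for g, n in _DELTOID_ELEMENTS.items()
                                       for k in range(n)])
    joints = [
        *_trunk_joints(),
        JointSpec("gh_ball", "ball", "scapula", "humerus",
                  parent_frame_offset=Frame(np.eye(3), _GH_SCAP),
                  axes=[Z, -X, Y], coord_names=list(GH_COORDS)),
        *_arm_joints(elbow_flexion_deg),
    ]
    return ChainModel(_bodies(hand_load_kg), joints,
                      muscles=_build_muscles("humeral_head_wrap", params),
                      wraps={wrap.name: wrap},
                      gh_joint_name="gh_ball", name="NS",
                      gh_coord_names=list(GH_COORDS))


def build_natural_shoulder(hand_load_kg: float = 2.0,
                           elbow_flexion_deg: float = 0.0) -> ChainModel:
    """Natural shoulder: gleno-humeral ball joint, all 7 studied muscle
    groups active (deltoid 4/4/7 elements, cuff 11/6/3/4)."""
    return _assemble_ns(hand_load_kg, elbow_flexion_deg, _ns_muscle_params())


def build_rsp(hand_load_kg: float = 2.0, elbow_flexion_deg: float = 0.0,
              geometry: Optional[ImplantGeometry] = None) -> ChainModel:
    """Reverse shoulder prosthesis: ball joint at the medialized
    glenosphere centre, 56 mm spherical wrap, supraspinatus inactive."""
    geo = geometry or ImplantGeometry(variant="RSP")
    cor_scap = _GLENOID_INFERIOR_RIM + np.array([0.0, geo.cor_above_inferior_rim, 0.0])
    wrap = build_wrap_for_implant(
        "RSP", body="scapula", center_local=cor_scap,
        name="rsp_glenosphere_wrap",
        active_muscles=[f"{g}_{k+1}" for g, n in _DELTOID_ELEMENTS.items()
                        for k in range(n)])
    joints = [
        *_trunk_joints(),
        JointSpec("gh_ball", "ball", "scapula", "humerus",
                  parent_frame_offset=Frame(np.eye(3), cor_scap),
                  axes=[Z, -X, Y], coord_names=list(GH_COORDS)),
        *_arm_joints(elbow_flexion_deg),
    ]
    model = ChainModel(_bodies(hand_load_kg), joints,
                       muscles=_build_muscles("rsp_glenosphere_wrap", _ns_muscle_params()),
                       wraps={wrap.name: wrap},
                       gh_joint_name="gh_ball", name="RSP",
                       gh_coord_names=list(GH_COORDS))
    return deactivate_supraspinatus(model)


def build_dbsp(hand_load_kg: float = 2.0, elbow_flexion_deg: float = 0.0,
               geometry: Optional[ImplantGeometry] = None) -> ChainModel:
    """Dual-bearing prosthesis: scapula → ring (fixed, 10° downward
    tilt) → PE bearing (hinge about the ring axis) → ball head (gimbal,
    offset centre) → offset adapter (fixed) → humerus (fixed); 75/75/28
    mm ellipsoid wrap on the ring; supraspinatus inactive.  JRF is
    reported at the scapula–ring joint."""
    geo = geometry or ImplantGeometry(variant="DBSP")
    tilt = rotation_about(X, np.deg2rad(geo.ring_tilt_deg))  # ring axis tips downward
    wrap = build_wrap_for_implant(
        "DBSP", body="glenoid_ring", center_local=(0.0, 0.0, 0.0),
        name="dbsp_ring_wrap",
        active_muscles=[f"{g}_{k+1}" for g, n in _DELTOID_ELEMENTS.items()
                        for k in range(n)])
    # inflate only the two in-plane axes; ring outer diameter stays the
    # mechanical bearing dimension used by the friction bound
    joints = [
        *_trunk_joints(),
        JointSpec("scapula_ring", "fixed", "scapula", "glenoid_ring",
                  parent_frame_offset=Frame(tilt, _GLENOID_CENTRE_SCAP)),
        JointSpec("ring_bearing", "hinge", "glenoid_ring", "pe_bearing",
                  axes=[Z], coord_names=[GH_COORDS[0]]),
        JointSpec("bearing_ballhead", "gimbal", "pe_bearing", "ball_head",
                  parent_frame_offset=Frame(np.eye(3), geo.dual_cor_offset),
                  axes=[-X, Y], coord_names=list(GH_COORDS[1:])),
        JointSpec("ballhead_adapter", "fixed", "ball_head", "offset_adapter",
                  parent_frame_offset=Frame(np.eye(3), (0.0, 0.0, 0.012))),
        JointSpec("adapter_humerus", "fixed", "offset_adapter", "humerus",
                  parent_frame_offset=Frame(np.eye(3), (0.0, 0.0, 0.002)),
                  child_frame_offset=Frame(tilt.T)),
        *_arm_joints(elbow_flexion_deg),
    ]
    bodies = _bodies(hand_load_kg) + [
        BodySegment("glenoid_ring", 0.05),
        BodySegment("pe_bearing", 0.02),
        BodySegment("ball_head", 0.05),
        BodySegment("offset_adapter", 0.03),
    ]
    model = ChainModel(bodies, joints,
                       muscles=_build_muscles("dbsp_ring_wrap", _ns_muscle_params()),
                       wraps={wrap.name: wrap},
                       gh_joint_name="scapula_ring", name="DBSP",
                       gh_coord_names=list(GH_COORDS))
    return deactivate_supraspinatus(model)


BUILDERS = {"ns": build_natural_shoulder, "rsp": build_rsp, "dbsp": build_dbsp}


def build_model(variant: str, **kwargs) -> ChainModel:
    try:
        return BUILDERS[variant.lower()](**kwargs)
    except KeyError:
        raise ValueError(f"unknown variant {variant!r}; expected ns, rsp or dbsp") from None


def bearing_radius(variant: str, geometry: Optional[ImplantGeometry] = None) -> float:
    """Outer bearing radius used by the conservative friction bound."""
    geo = geometry or ImplantGeometry(variant=variant.upper())
    if variant.lower() == "rsp":
        return geo.glenosphere_diameter / 2
    if variant.lower() == "dbsp":
        return geo.glenoid_ring_outer_diameter / 2
    raise ValueError("friction bound applies to the prosthesis models only")
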