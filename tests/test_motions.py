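"""Protocol trajectories, synthetic markers, IK and the time stretch."""
import numpy as np
import pytest

import glenosim as gs
from glenosim.motions import (ELBOW_FLEXION_DEG, MotionSpec, QSeries,
                              default_marker_set, generate_trajectory,
                              inverse_kinematics, minimum_jerk,
                              passes_quasi_static, peak_angular_acceleration,
                              synthesize_markers, time_stretch)


class TestMotionSpec:
    def test_protocol_ranges(self):
        assert (MotionSpec("ABD").angle_start, MotionSpec("ABD").angle_end) == (0, 120)
        assert (MotionSpec("SCP").angle_start, MotionSpec("SCP").angle_end) == (0, 120)
        assert (MotionSpec("IR").angle_start, MotionSpec("IR").angle_end) == (0, 40)
        assert (MotionSpec("ER").angle_start, MotionSpec("ER").angle_end) == (40, 0)

    def test_er_direction_switch(self):
        spec = MotionSpec("ER", er_reversed=False)
        assert (spec.angle_start, spec.angle_end) == (0, 40)

    def test_unknown_motion_rejected(self):
        with pytest.raises(ValueError, match="unknown motion"):
            MotionSpec("FLX")

    def test_timestamps_strictly_increasing(self):
        t = MotionSpec("ABD", n_steps=10).timestamps
        assert np.all(np.diff(t) > 0)


class TestTrajectoryGeneration:
    def test_abduction_drives_only_elevation(self, ns_model):
        series = generate_trajectory(ns_model, MotionSpec("ABD", n_steps=9,
                                                          scapular_rhythm=False))
        elev = series.values[:, ns_model.coord_index("gh_elevation")]
        assert elev[0] == pytest.approx(0.0, abs=1e-12)
        assert elev[-1] == pytest.approx(np.deg2rad(120), abs=1e-9)
        assert np.all(np.diff(elev) >= -1e-12)
        for other in ("gh_plane", "gh_axial"):
            assert np.abs(series.values[:, ns_model.coord_index(other)]).max() < 1e-9

    def test_two_steps_gives_exactly_endpoints(self, ns_model):
        series = generate_trajectory(ns_model, MotionSpec("IR", n_steps=2))
        ax = series.values[:, ns_model.coord_index("gh_axial")]
        np.testing.assert_allclose(ax, [0.0, np.deg2rad(40)], atol=1e-9)

    def test_minimum_jerk_boundary_derivatives_vanish(self):
        s = np.linspace(0, 1, 1001)
        v = np.gradient(minimum_jerk(s), s)
        assert abs(v[0]) < 1e-4 and abs(v[-1]) < 1e-4

    def test_scapular_rhythm_engages_above_30_degrees(self, ns_model):
        series = generate_trajectory(ns_model, MotionSpec("ABD", n_steps=21))
        elev = np.rad2deg(series.values[:, ns_model.coord_index("gh_elevation")])
        scap = np.rad2deg(series.values[:, ns_model.coord_index("scapula_upward_rotation")])
        np.testing.assert_allclose(scap, np.maximum(0.0, elev - 30.0) / 2.0, atol=1e-9)

    def test_dbsp_realizes_same_humerus_orientation(self, ns_model, dbsp_model):
        """Different joint parameterizations, same motion: the humerus
        orientation relative to the scapula must agree."""
        for motion in ("ABD", "SCP"):
            s_ns = generate_trajectory(ns_model, MotionSpec(motion, n_steps=7))
            s_db = generate_trajectory(dbsp_model, MotionSpec(motion, n_steps=7))
            for i in (3, 6):
                f_ns = ns_model.forward_kinematics(s_ns.values[i])
                f_db = dbsp_model.forward_kinematics(s_db.values[i])
                r_ns = f_ns["scapula"].rotation.T @ f_ns["humerus"].rotation
                r_db = f_db["scapula"].rotation.T @ f_db["humerus"].rotation
                np.testing.assert_allclose(r_ns, r_db, atol=1e-9)


class TestSyntheticMarkers:
    def test_noise_free_markers_on_model_landmarks(self, ns_model):
        series = generate_trajectory(ns_model, MotionSpec("ABD", n_steps=5))
        mk = synthesize_markers(ns_model, series, 0.0)
        frames = ns_model.forward_kinematics(series.values[2])
        for name, body, p in mk.markers:
            np.testing.assert_allclose(mk.trajectories[name][2],
                                       frames[body].transform_point(p), atol=1e-12)

    def test_fixed_seed_bit_identical(self, ns_model):
        series = generate_trajectory(ns_model, MotionSpec("ABD", n_steps=5))
        a = synthesize_markers(ns_model, series, 0.002, seed=7)
        b = synthesize_markers(ns_model, series, 0.002, seed=7)
        for name, _, _ in a.markers:
            np.testing.assert_array_equal(a.trajectories[name], b.trajectories[name])

    def test_empirical_noise_sd_matches_request(self, ns_model):
        # static pose repeated: the sample SD over 10^4 frames must land
        # within 5% of the requested noise level
        series = QSeries(np.arange(10_000) * 0.01,
                         np.tile(ns_model.zero_q().q, (10_000, 1)),
                         list(ns_model.coord_names))
        mk = synthesize_markers(ns_model, series, 0.002, seed=3)
        sds = [mk.trajectories[n][:, k].std() for n, _, _ in mk.markers[:3]
               for k in range(3)]
        assert np.all(np.abs(np.array(sds) / 0.002 - 1.0) < 0.05)

    def test_negative_noise_rejected(self, ns_model):
        series = generate_trajectory(ns_model, MotionSpec("ABD", n_steps=3))
        with pytest.raises(ValueError):
            synthesize_markers(ns_model, series, -0.001)


class TestInverseKinematics:
    @pytest.mark.parametrize("motion", ["ABD", "SCP", "IR", "ER"])
    def test_noise_free_round_trip_recovers_trajectory(self, ns_model, motion):
        model = gs.build_natural_shoulder(
            elbow_flexion_deg=ELBOW_FLEXION_DEG[motion])
        series = generate_trajectory(model, MotionSpec(motion, n_steps=11))
        mk = synthesize_markers(model, series, 0.0)
        res = inverse_kinematics(model, mk)
        assert res.converged.all()
        assert np.abs(res.series.values - series.values).max() <= 1e-6

    def test_dbsp_round_trip(self, dbsp_model):
        series = generate_trajectory(dbsp_model, MotionSpec("ABD", n_steps=9))
        mk = synthesize_markers(dbsp_model, series, 0.0)
        res = inverse_kinematics(dbsp_model, mk)
        assert np.abs(res.series.values - series.values).max() <= 1e-6

    def test_static_pose_zero_noise_zero_residual(self, ns_model):
        q = ns_model.named_q(gh_elevation=np.deg2rad(40))
        series = QSeries([0.0, 1.0], np.tile(q.q, (2, 1)), list(ns_model.coord_names))
        mk = synthesize_markers(ns_model, series, 0.0)
        res = inverse_kinematics(ns_model, mk)
        assert res.rms_errors.max() < 1e-10

    def test_noisy_recovery_unbiased_over_seeds(self, ns_model):
        """2 mm marker noise at a well-conditioned pose: the recovered
        elevation angle is unbiased (|mean error| < 0.2°) and the RMS
        marker residual sits near the injected noise level."""
        q_true = ns_model.named_q(gh_elevation=np.deg2rad(40),
                                  scapula_upward_rotation=np.deg2rad(5))
        series = QSeries([0.0], q_true.q[None, :], list(ns_model.coord_names))
        idx = ns_model.coord_index("gh_elevation")
        errors, rms = [], []
        for seed in range(100):
            mk = synthesize_markers(ns_model, series, 0.002, seed=seed)
            res = inverse_kinematics(ns_model, mk, q0=q_true.q)
            errors.append(res.series.values[0, idx] - q_true.q[idx])
            rms.append(res.rms_errors[0])
        assert abs(np.rad2deg(np.mean(errors))) < 0.2
        assert 0.0005 < np.mean(rms) < 0.004

    def test_too_few_markers_rejected(self, ns_model):
        series = generate_trajectory(ns_model, MotionSpec("ABD", n_steps=3))
        mk = synthesize_markers(ns_model, series, 0.0,
                                markers=default_marker_set(ns_model)[:4])
        mk.markers = [m for m in mk.markers if m[1] == "thorax"]
        with pytest.raises(ValueError, match="3 markers"):
            inverse_kinematics(ns_model, mk)

    def test_residual_invariant_under_global_rigid_motion(self, ns_model):
        """Moving the model root and the observed markers by the same
        rigid transform leaves the IK residual unchanged."""
        import copy

        from glenosim.geometry import Frame
        series = QSeries([0.0], ns_model.named_q(
            gh_elevation=np.deg2rad(30)).q[None, :], list(ns_model.coord_names))
        mk = synthesize_markers(ns_model, series, 0.002, seed=11)
        base = inverse_kinematics(ns_model, mk, q0=series.values[0]).rms_errors[0]

        move = Frame.from_rotvec((0.2, 0.1, -0.3), (0.5, -0.2, 0.8))
        model2 = copy.deepcopy(ns_model)
        for j in model2.joints:        # shift everything hanging off the root
            if j.parent_body == model2.root:
                j.parent_frame_offset = move @ j.parent_frame_offset
        markers2 = [(n, b, move.transform_point(p) if b == model2.root else p)
                    for n, b, p in mk.markers]
        mk2 = type(mk)(markers2,
                       {n: move.transform_points(mk.trajectories[n])
                        for n, _, _ in mk.markers},
                       mk.times, mk.rate)
        moved = inverse_kinematics(model2, mk2, q0=series.values[0]).rms_errors[0]
        assert moved == pytest.approx(base, rel=1e-6)


class TestTimeStretch:
    def test_factor_one_is_identity(self, ns_model):
        series = generate_trajectory(ns_model, MotionSpec("ABD", n_steps=5))
        out = time_stretch(series, 1.0)
        np.testing.assert_array_equal(out.times, series.times)
        np.testing.assert_array_equal(out.values, series.values)

    def test_acceleration_scales_with_inverse_factor_squared(self, ns_model):
        series = generate_trajectory(ns_model, MotionSpec("ABD", n_steps=21))
        a0 = peak_angular_acceleration(series)
        a1 = peak_angular_acceleration(time_stretch(series, 1000.0))
        assert a1 == pytest.approx(1e-6 * a0, rel=1e-9)

    def test_stretches_compose(self, ns_model):
        series = generate_trajectory(ns_model, MotionSpec("ABD", n_steps=5))
        ab = time_stretch(time_stretch(series, 10.0), 50.0)
        once = time_stretch(series, 500.0)
        np.testing.assert_allclose(ab.times, once.times, rtol=1e-12)

    def test_noisy_ik_passes_quasi_static_filter_only_after_stretch(self, ns_model):
        series = generate_trajectory(ns_model, MotionSpec("ABD", n_steps=60))
        mk = synthesize_markers(ns_model, series, 0.002, seed=1)
        noisy = inverse_kinematics(ns_model, mk).series
        assert not passes_quasi_static(noisy)
        assert passes_quasi_static(time_stretch(noisy, 1000.0))

    def test_invalid_factor_rejected(self, ns_model):
        series = generate_trajectory(ns_model, MotionSpec("ABD", n_steps=3))
        with pytest.raises(ValueError):
            time_stretch(series, 0.0)
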