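"""Kalman filtering, observation-centric association, and video tracking."""

import numpy as np
import pytest

from oracles import ReferenceKalman
from satsn.datamodel import BoundingBox, Detection, Keypoint
from satsn.tracker import (KalmanState, Track, TrackerConfig, associate,
                           box_to_z, count_id_switches, giou, init_state, iou,
                           kf_predict, kf_update, ocm_cost, ocr_pass,
                           oru_reupdate, track_video, virtual_trajectory,
                           z_to_box)


def _det(t, x1, y1, x2, y2, score=0.9, gt_id=None):
    return Detection(t, BoundingBox(x1, y1, x2, y2), score,
                     Keypoint(x1, y1, 2), gt_id=gt_id)


class TestBoxOverlap:
    def test_identical_boxes(self):
        a = BoundingBox(3, 4, 10, 12)
        assert iou(a, a) == 1.0
        assert giou(a, a) == 1.0

    def test_known_overlap(self):
        assert iou(BoundingBox(0, 0, 2, 2), BoundingBox(1, 1, 3, 3)) \
            == pytest.approx(1 / 7)

    def test_disjoint(self):
        a, b = BoundingBox(0, 0, 1, 1), BoundingBox(3, 0, 4, 1)
        assert iou(a, b) == 0.0
        assert giou(a, b) < 0.0

    def test_symmetry_and_giou_bound(self, rng):
        for _ in range(50):
            x1, y1, x3, y3 = rng.uniform(0, 50, size=4)
            a = BoundingBox(x1, y1, x1 + rng.uniform(1, 20), y1 + rng.uniform(1, 20))
            b = BoundingBox(x3, y3, x3 + rng.uniform(1, 20), y3 + rng.uniform(1, 20))
            assert iou(a, b) == pytest.approx(iou(b, a))
            assert giou(a, b) == pytest.approx(giou(b, a))
            assert giou(a, b) <= iou(a, b) + 1e-12


class TestKalman:
    def test_zero_velocity_zero_q_keeps_position(self):
        st = init_state(BoundingBox(10, 10, 30, 40))
        st.Q = np.zeros((7, 7))
        out = kf_predict(st)
        assert np.allclose(out.x[:4], st.x[:4])

    def test_velocity_moves_center(self):
        st = init_state(BoundingBox(10, 10, 30, 40))
        st.x[4] = 2.0
        out = kf_predict(st)
        assert out.x[0] == pytest.approx(st.x[0] + 2.0)

    def test_twenty_step_predict_matches_matrix_power(self):
        st = init_state(BoundingBox(5, 5, 25, 45))
        st.x[4:6] = (1.5, -0.5)
        cur = st
        for _ in range(20):
            cur = kf_predict(cur)
        expected = np.linalg.matrix_power(st.F, 20) @ st.x
        assert np.allclose(cur.x, expected, atol=1e-10)

    def test_predict_grows_covariance_trace(self):
        st = init_state(BoundingBox(10, 10, 30, 40))
        assert np.trace(kf_predict(st).P) >= np.trace(st.P)

    def test_update_unit_gain(self):
        """P = I, R = I: K = 0.5 on observed dims, x' = x + (z - Hx)/2."""
        st = init_state(BoundingBox(10, 10, 30, 40))
        st.P = np.eye(7)
        st.R = np.eye(4)
        z = st.x[:4] + np.array([2.0, -2.0, 4.0, 0.1])
        out = kf_update(st, z)
        assert np.allclose(out.x[:4], st.x[:4] + 0.5 * (z - st.x[:4]))
        assert np.trace(out.P) <= np.trace(st.P)

    def test_zero_gain_keeps_state(self):
        st = init_state(BoundingBox(10, 10, 30, 40))
        st.P = np.zeros((7, 7))
        out = kf_update(st, st.x[:4] + 5.0)
        assert np.allclose(out.x, st.x)

    def test_matches_reference_filter(self, rng):
        """Full predict/update pipeline equals a textbook filter to 1e-8."""
        st = init_state(BoundingBox(20, 30, 60, 90))
        ref = ReferenceKalman(st.x, st.P, st.F, st.H, st.Q, st.R)
        cur = st
        for _ in range(50):
            cur = kf_predict(cur)
            ref.predict()
            z = ref.x[:4] + rng.normal(0, 1, size=4)
            z[2] = abs(z[2]) + 1.0
            z[3] = abs(z[3]) + 0.1
            cur = kf_update(cur, z)
            ref.update(z)
            assert np.allclose(cur.x, ref.x, atol=1e-8)
            assert np.allclose(cur.P, ref.P, atol=1e-8)

    def test_covariance_stays_symmetric_psd(self, rng):
        st = init_state(BoundingBox(20, 30, 60, 90))
        cur = st
        for _ in range(1000):
            cur = kf_predict(cur)
            z = cur.x[:4] + rng.normal(0, 2, size=4)
            z[2] = max(z[2], 1.0)
            z[3] = max(z[3], 0.1)
            cur = kf_update(cur, z)
            assert np.allclose(cur.P, cur.P.T)
            assert np.linalg.eigvalsh(cur.P).min() >= -1e-9

    def test_box_z_round_trip(self):
        b = np.array([12.0, 20.0, 50.0, 44.0])
        assert np.allclose(z_to_box(box_to_z(b)), b)


class TestVirtualTrajectory:
    def test_midpoint(self):
        z1 = np.array([0.0, 0.0, 10.0, 10.0])
        z2 = np.array([20.0, 0.0, 30.0, 10.0])
        mid = virtual_trajectory(z1, 0, z2, 10, 5)
        assert np.allclose(mid, (z1 + z2) / 2)

    def test_near_t1_limit(self):
        z1 = np.array([0.0, 0.0, 10.0, 10.0])
        z2 = np.array([100.0, 0.0, 110.0, 10.0])
        assert np.allclose(virtual_trajectory(z1, 0, z2, 100, 1), z1 + (z2 - z1) / 100)

    def test_constant_velocity_exact(self):
        v = np.array([3.0, -1.0, 3.0, -1.0])
        z = lambda t: np.array([10.0, 10.0, 30.0, 25.0]) + v * t
        for t in range(1, 8):
            assert np.allclose(virtual_trajectory(z(0), 0, z(8), 8, t), z(t))

    def test_outside_gap_rejected(self):
        z1 = np.array([0.0, 0.0, 1.0, 1.0])
        for t in (0, 8, 9):
            with pytest.raises(ValueError):
                virtual_trajectory(z1, 0, z1, 8, t)


def _track_from_obs(obs, track_id=1):
    """Build a track whose filter has digested a list of (t, box)."""
    st = init_state(obs[0][1])
    tr = Track(track_id=track_id, state=st, history=[(obs[0][0], np.asarray(obs[0][1], dtype=float))],
               snapshot=(obs[0][0], st.copy()))
    for t, box in obs[1:]:
        tr.state = kf_predict(tr.state)
        tr.state = kf_update(tr.state, box_to_z(box))
        tr.history.append((t, np.asarray(box, dtype=float)))
        tr.snapshot = (t, tr.state.copy())
    return tr


class TestOru:
    def _constant_velocity_obs(self, n, v=4.0):
        return [(t, np.array([10.0 + v * t, 20.0, 40.0 + v * t, 50.0]))
                for t in range(n)]

    def test_gap_one_equals_plain_update(self):
        obs = self._constant_velocity_obs(10)
        t2 = 10
        z2 = np.array([10.0 + 4.0 * t2, 20.0, 40.0 + 4.0 * t2, 50.0])
        tr_a = _track_from_obs(obs)
        tr_b = _track_from_obs(obs)
        oru_reupdate(tr_a, z2, t2)
        tr_b.state = kf_update(kf_predict(tr_b.state), box_to_z(z2))
        assert np.allclose(tr_a.state.x, tr_b.state.x, atol=1e-12)

    def test_oru_beats_coasting_after_gap(self):
        """Noiseless constant-velocity target, 8-frame gap."""
        obs = self._constant_velocity_obs(12)
        t2 = 19  # 8 missing frames: 12..18
        truth = np.array([10.0 + 4.0 * t2, 20.0, 40.0 + 4.0 * t2, 50.0])
        tr = _track_from_obs(obs)
        coast = tr.state.copy()
        for _ in range(8):
            coast = kf_predict(coast)
        coast_err = np.abs(z_to_box(coast.x[:4]) - truth).max()
        oru_reupdate(tr, truth, t2)
        oru_err = np.abs(tr.state.box - truth).max()
        assert oru_err < coast_err

    def test_oru_shrinks_covariance_versus_coasting(self):
        obs = self._constant_velocity_obs(12)
        tr = _track_from_obs(obs)
        coast = tr.state.copy()
        for _ in range(8):
            coast = kf_predict(coast)
        z2 = np.array([10.0 + 4.0 * 19, 20.0, 40.0 + 4.0 * 19, 50.0])
        oru_reupdate(tr, z2, 19)
        assert np.trace(tr.state.P) < np.trace(coast.P)

    def test_deterministic(self):
        obs = self._constant_velocity_obs(12)
        z2 = np.array([90.0, 20.0, 120.0, 50.0])
        a = _track_from_obs(obs)
        b = _track_from_obs(obs)
        oru_reupdate(a, z2, 19)
        oru_reupdate(b, z2, 19)
        assert np.array_equal(a.state.x, b.state.x)

    def test_missing_snapshot_rejected(self):
        tr = _track_from_obs(self._constant_velocity_obs(3))
        tr.snapshot = None
        with pytest.raises(ValueError, match="posterior"):
            oru_reupdate(tr, np.array([0.0, 0.0, 1.0, 1.0]), 10)


class TestOcmCost:
    def test_lambda_zero_is_pure_iou(self):
        tr = _track_from_obs([(t, np.array([10.0 + t, 10.0, 30.0 + t, 30.0]))
                              for t in range(5)])
        det = _det(5, 16, 10, 36, 30)
        assert ocm_cost(tr, det, 0.0, 3) == pytest.approx(1.0 - iou(tr.state.box, det.box))

    def test_direction_consistent_candidate_cheaper(self):
        """Track moving +x: equal-IoU candidates ahead vs behind differ in cost."""
        tr = _track_from_obs([(t, np.array([10.0 + 2 * t, 10.0, 30.0 + 2 * t, 30.0]))
                              for t in range(6)])
        cx = tr.history[-1][1]
        ahead = _det(6, cx[0] + 3, 10, cx[2] + 3, 30)
        behind = _det(6, cx[0] - 3, 10, cx[2] - 3, 30)
        lam = 0.2
        # momentum term only: subtract the IoU parts
        c_ahead = ocm_cost(tr, ahead, lam, 3) - (1 - iou(tr.state.box, ahead.box))
        c_behind = ocm_cost(tr, behind, lam, 3) - (1 - iou(tr.state.box, behind.box))
        assert c_ahead < c_behind
        assert c_ahead == pytest.approx(0.0, abs=1e-9)  # exactly on the motion ray

    def test_short_history_no_momentum(self):
        tr = _track_from_obs([(0, np.array([10.0, 10.0, 30.0, 30.0]))])
        det = _det(1, 12, 10, 32, 30)
        assert ocm_cost(tr, det, 0.5, 3) == pytest.approx(1.0 - iou(tr.state.box, det.box))


class TestAssociate:
    def test_single_overlap_matched(self):
        tr = _track_from_obs([(0, np.array([10.0, 10.0, 30.0, 30.0]))])
        matches, um_t, um_d = associate([tr], [_det(1, 11, 10, 31, 30)], TrackerConfig())
        assert matches == [(0, 0)] and not um_t and not um_d

    def test_no_detections(self):
        tr = _track_from_obs([(0, np.array([10.0, 10.0, 30.0, 30.0]))])
        matches, um_t, um_d = associate([tr], [], TrackerConfig())
        assert matches == [] and um_t == [0] and um_d == []

    def test_crossing_resolved_by_momentum(self):
        """Two tracks converging head-on; both candidates overlap both
        predictions, and the momentum term picks the consistent pairing."""
        right = _track_from_obs([(t, np.array([10.0 + 3 * t, 10.0, 40.0 + 3 * t, 34.0]))
                                 for t in range(8)], track_id=1)
        left = _track_from_obs([(t, np.array([60.0 - 3 * t, 12.0, 90.0 - 3 * t, 36.0]))
                                for t in range(8)], track_id=2)
        d_right = _det(8, 10.0 + 3 * 8, 10, 40.0 + 3 * 8, 34)
        d_left = _det(8, 60.0 - 3 * 8, 12, 90.0 - 3 * 8, 36)
        cfg = TrackerConfig(lambda_momentum=0.5)
        matches, _, _ = associate([right, left], [d_right, d_left], cfg)
        assert sorted(matches) == [(0, 0), (1, 1)]

    def test_low_iou_rejected_post_assignment(self):
        tr = _track_from_obs([(0, np.array([10.0, 10.0, 30.0, 30.0]))])
        far = _det(1, 200, 200, 220, 220)
        matches, um_t, um_d = associate([tr], [far], TrackerConfig())
        assert matches == [] and um_t == [0] and um_d == [0]


class TestOcrPass:
    def test_empty_inputs(self):
        assert ocr_pass([], [], [], [], TrackerConfig()) == []

    def test_below_threshold_not_matched(self):
        tr = _track_from_obs([(0, np.array([10.0, 10.0, 30.0, 30.0]))])
        far = _det(1, 500, 500, 520, 520)
        assert ocr_pass([tr], [far], [0], [0], TrackerConfig()) == []

    def test_stationary_dropout_recovered_with_same_id(self):
        """5-frame detector dropout on a stationary object: one track."""
        dets = [_det(t, 50, 50, 80, 90, gt_id=1) for t in range(30) if not 10 <= t < 15]
        records = track_video(dets, TrackerConfig())
        assert {r.track_id for r in records} == {1}
        assert count_id_switches(records) == 0


class TestTrackVideo:
    def test_single_agent_single_track(self):
        dets = [_det(t, 10 + 2 * t, 20, 40 + 2 * t, 50, gt_id=7) for t in range(100)]
        records = track_video(dets)
        assert {r.track_id for r in records} == {1}
        assert count_id_switches(records) == 0

    def test_three_agents_three_tracks(self):
        dets = []
        for t in range(40):
            dets.append(_det(t, 10 + t, 20, 40 + t, 50, gt_id=1))
            dets.append(_det(t, 10 + t, 100, 40 + t, 130, gt_id=2))
            dets.append(_det(t, 200 - t, 20, 230 - t, 50, gt_id=3))
        records = track_video(dets)
        assert len({r.track_id for r in records}) == 3
        assert count_id_switches(records) == 0

    def test_deterministic(self):
        rng = np.random.default_rng(8)
        dets = [_det(t, 10 + 2 * t + rng.normal(0, 0.5), 20, 40 + 2 * t, 50)
                for t in range(50)]
        a = track_video(dets)
        b = track_video(dets)
        assert len(a) == len(b)
        assert all(ra.frame == rb.frame and ra.track_id == rb.track_id
                   and np.allclose(ra.box, rb.box) for ra, rb in zip(a, b))

    def test_empty_stream(self):
        assert track_video([]) == []

    def test_crossing_occlusion_ablation(self):
        """Crossing + occlusion: full tracker keeps identities, the ablated
        (no momentum / re-update / recovery) tracker switches at least once."""
        from satsn.experiments import crossing_ablation
        res = crossing_ablation(seed=0)
        assert res["id_switches_full"] == 0
        assert res["id_switches_ablated"] >= 1
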