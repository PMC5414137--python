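import numpy as np
import pytest

from conftest import hand_obs, make_frame
from mjtkinect.config import MjtConfig
from mjtkinect.object_events import (BeanDropState, count_stacked,
                                     count_turned_cards, detect_bean_drop,
                                     detect_checkers, detect_green_markers,
                                     update_card_tracks)
from mjtkinect.recording_io import Calibration
from mjtkinect.scene_geometry import BoardModel, CanModel, DepthReference
from oracles import green_marker_pipeline

CFG = MjtConfig()


def _rgb(h=64, w=64, base=(170, 165, 160)):
    rgb = np.empty((h, w, 3), np.uint8)
    rgb[:] = base
    return rgb


class TestGreenMarkers:
    def test_pure_gray_has_no_markers(self, cal2):
        rgb = _rgb(base=(128, 128, 128))   # strict inequality: R=G=B never green
        assert detect_green_markers(rgb, None, cal2) == []

    def test_single_patch_centroid(self, cal2):
        rgb = _rgb()
        rgb[20:26, 30:36] = (50, 200, 50)
        (cen,) = detect_green_markers(rgb, None, cal2)
        assert cen == pytest.approx((22.5, 32.5))

    def test_patch_near_hand_excluded(self, cal2):
        rgb = _rgb()
        rgb[20:26, 30:36] = (50, 200, 50)
        # hand pixel 4 px (= 8 mm) from the patch centroid
        hand = hand_obs([(22, 37)])
        assert detect_green_markers(rgb, hand, cal2) == []
        far = hand_obs([(22, 50)])   # 35 mm away
        assert len(detect_green_markers(rgb, far, cal2)) == 1

    @pytest.mark.parametrize("seed", range(15))
    def test_pipeline_matches_brute_force_oracle(self, cal2, seed):
        """Mask + median + size filter + hand exclusion vs a per-pixel oracle."""
        rng = np.random.default_rng(seed)
        h, w = rng.integers(8, 33, size=2)
        rgb = rng.integers(0, 256, size=(h, w, 3)).astype(np.uint8)
        if rng.random() < 0.5:
            hand_coords = rng.integers(0, min(h, w), size=(5, 2))
            hand = hand_obs(hand_coords)
        else:
            hand_coords, hand = None, None
        got = sorted(detect_green_markers(rgb, hand, cal2))
        want = green_marker_pipeline(rgb, None if hand_coords is None
                                     else np.asarray(hand_coords), cal2.mm_per_px)
        assert len(got) == len(want)
        if got:
            np.testing.assert_allclose(np.asarray(got), np.asarray(want))


class TestCardTracks:
    def test_confirmation_needs_15_frames(self, cal2):
        tracks = []
        for f in range(14):
            update_card_tracks(tracks, [(10.0, 10.0)], f, cal2)
        assert count_turned_cards(tracks) == 0
        update_card_tracks(tracks, [(10.0, 10.0)], 14, cal2)
        assert count_turned_cards(tracks) == 1
        assert tracks[0].confirmed_frame == 14

    def test_nearby_centroids_join_one_track(self, cal2):
        tracks = []
        update_card_tracks(tracks, [(10.0, 10.0)], 0, cal2)
        update_card_tracks(tracks, [(10.0, 12.0)], 1, cal2)   # 4 mm away
        assert len(tracks) == 1 and tracks[0].support_frames == 2
        update_card_tracks(tracks, [(10.0, 13.6)], 2, cal2)   # 5.2 mm from the mean
        assert len(tracks) == 2

    def test_five_stable_markers_give_five_cards(self, cal2):
        # markers 51 mm apart (25.5 px), each seen 15 frames
        cents = [(30.0, 10.0 + k * 25.5) for k in range(5)]
        tracks = []
        for f in range(15):
            update_card_tracks(tracks, cents, f, cal2)
        assert count_turned_cards(tracks) == 5

    def test_count_invariant_to_frame_order(self, cal2):
        rng = np.random.default_rng(0)
        cents = [(30.0, 10.0 + k * 30.0) for k in range(4)]
        frames = list(range(20))
        rng.shuffle(frames)
        tracks = []
        for f in frames:
            update_card_tracks(tracks, cents, f, cal2)
        assert count_turned_cards(tracks) == 4


def _can(center=(32.0, 32.0), radius_px=10.0, shape=(64, 64)):
    return CanModel(center=center, radius_mm=radius_px * 2.0, radius_px=radius_px,
                    rim_mask=np.zeros(shape, bool))


def _hand_near_can(dist_mm=-10.0, can=None, mm_per_px=2.0):
    """A hand observation whose distal centroid sits at the given signed rim
    distance, with pixels far from the can interior."""
    can = can or _can()
    r = can.radius_px + dist_mm / mm_per_px
    dc = (can.center[0] + r, can.center[1])
    return hand_obs([(60, 60)], distal=dc)


class TestBeanDrop:
    def _frames(self, blob_px=None):
        prev = _rgb(base=(50, 45, 40))
        cur = prev.copy()
        if blob_px:
            for (r, c) in blob_px:
                cur[r, c] = (235, 230, 224)
        return prev, cur

    def _blob(self, n, r0=30, c0=30, width=4):
        # a compact 4-connected group of n pixels near the can centre
        return [(r0 + i // width, c0 + i % width) for i in range(n)]

    def test_identical_frames_no_drop(self, cal2):
        prev, cur = self._frames()
        state = detect_bean_drop(prev, cur, _can(), _hand_near_can(), 100.0,
                                 BeanDropState(), cal2, frame_index=5)
        assert state.drops == []

    def test_drop_then_unarmed_then_rearm(self, cal2):
        can = _can()
        hand = _hand_near_can()
        prev, cur = self._frames(self._blob(10))
        state = BeanDropState()
        state = detect_bean_drop(prev, cur, can, hand, 100.0, state, cal2, frame_index=5)
        assert state.drops == [5] and not state.armed
        # identical transient while unarmed: still one drop
        state = detect_bean_drop(prev, cur, can, hand, 100.0, state, cal2, frame_index=6)
        assert state.drops == [5]
        # hand returns to within 30 mm of the ridge: re-armed
        state = detect_bean_drop(prev, prev, can, hand, 25.0, state, cal2, frame_index=7)
        assert state.armed
        state = detect_bean_drop(prev, cur, can, hand, 100.0, state, cal2, frame_index=8)
        assert state.drops == [5, 8]

    @pytest.mark.parametrize("n,expect", [(4, 0), (5, 1), (50, 1), (51, 0), (60, 0)])
    def test_group_size_band_5_to_50(self, n, expect):
        # 1 mm/px keeps even a 51-px compact group under the 15 mm length cap,
        # so only the pixel-count band decides
        cal1 = Calibration(mm_per_px=1.0)
        prev, cur = self._frames(self._blob(n, width=8))
        hand = _hand_near_can(mm_per_px=1.0)
        state = detect_bean_drop(prev, cur, _can(), hand, 100.0,
                                 BeanDropState(), cal1, frame_index=1)
        assert len(state.drops) == expect

    def test_length_under_15mm_required(self, cal2):
        # 8 px in a 1×8 line = 16 mm at 2 mm/px: too long; 7 px = 14 mm: fine
        long_blob = [(30, 28 + i) for i in range(8)]
        prev, cur = self._frames(long_blob)
        state = detect_bean_drop(prev, cur, _can(), _hand_near_can(), 100.0,
                                 BeanDropState(), cal2, frame_index=1)
        assert state.drops == []
        prev, cur = self._frames(long_blob[:7])
        state = detect_bean_drop(prev, cur, _can(), _hand_near_can(), 100.0,
                                 BeanDropState(), cal2, frame_index=1)
        assert len(state.drops) == 1

    def test_blob_outside_can_ignored(self, cal2):
        prev, cur = self._frames(self._blob(10, r0=50, c0=50))
        state = detect_bean_drop(prev, cur, _can(), _hand_near_can(), 100.0,
                                 BeanDropState(), cal2, frame_index=1)
        assert state.drops == []

    def test_hand_far_from_rim_blocks_detection(self, cal2):
        prev, cur = self._frames(self._blob(10))
        far = _hand_near_can(dist_mm=60.0)
        state = detect_bean_drop(prev, cur, _can(), far, 100.0,
                                 BeanDropState(), cal2, frame_index=1)
        assert state.drops == []

    def test_hand_pixels_excluded_from_difference(self, cal2):
        blob = self._blob(10)
        prev, cur = self._frames(blob)
        hand = hand_obs(blob, distal=_hand_near_can().distal_centroid)
        state = detect_bean_drop(prev, cur, _can(), hand, 100.0,
                                 BeanDropState(), cal2, frame_index=1)
        assert state.drops == []

    @pytest.mark.parametrize("seed", range(10))
    def test_state_machine_invariants_random_sequences(self, cal2, seed):
        """Never more than five drops; never a drop while unarmed."""
        rng = np.random.default_rng(seed)
        can = _can()
        hand = _hand_near_can()
        state = BeanDropState()
        for i in range(80):
            blob = self._blob(10) if rng.random() < 0.5 else None
            prev, cur = self._frames(blob)
            ridge = float(rng.choice([10.0, 100.0]))
            was_armed = state.armed
            before = len(state.drops)
            state = detect_bean_drop(prev, cur, can, hand, ridge, state, cal2,
                                     frame_index=i)
            if len(state.drops) > before:
                assert was_armed or ridge < 30.0
            assert len(state.drops) <= 5
        assert sorted(state.drops) == state.drops


def _board(h=64, w=64, surface=1200.0, board_depth=1181.0):
    region = np.zeros((h, w), bool)
    region[10:50, 5:60] = True
    ridge = np.zeros((h, w), bool)
    return BoardModel(ridge_mask=ridge, ridge_axis=((12.0, 5.0), (12.0, 59.0)),
                      board_region=region, board_surface_depth_mm=board_depth,
                      ridge_top_depth_mm=1130.0)


class TestCheckers:
    def _setup(self, cal, stack_height=6.0, disc_r_px=7):
        board = _board()
        ref = DepthReference(ref_depth=np.full((64, 64), board.board_surface_depth_mm),
                             n_ref=15)
        depth = np.full((64, 64), board.board_surface_depth_mm, np.float64)
        rr, cc = np.mgrid[0:64, 0:64]
        disc = (rr - 30) ** 2 + (cc - 30) ** 2 <= disc_r_px ** 2
        depth[disc] = board.board_surface_depth_mm - stack_height
        return make_frame(depth.astype(np.uint16)), ref, board

    def test_frame_identical_to_reference_no_entries(self, cal2):
        board = _board()
        ref = DepthReference(np.full((64, 64), 1181.0), 15)
        frame = make_frame(np.full((64, 64), 1181, np.uint16))
        assert detect_checkers(frame, ref, board, None, cal2) == []

    def test_disc_logged_with_height(self, cal2):
        frame, ref, board = self._setup(cal2)
        hand = hand_obs([(5, 60)])         # ~100 mm away
        entries = detect_checkers(frame, ref, board, hand, cal2)
        assert len(entries) == 1
        assert entries[0][1] == pytest.approx(6.0)

    def test_hand_within_30mm_suppresses(self, cal2):
        frame, ref, board = self._setup(cal2)
        hand = hand_obs([(30, 47)])        # 10 px = 20 mm from the disc edge
        assert detect_checkers(frame, ref, board, hand, cal2) == []

    @pytest.mark.parametrize("extent_mm,expect", [(14, 0), (15, 1), (60, 1), (61, 0)])
    def test_extent_band_boundaries(self, extent_mm, expect):
        cal = Calibration(mm_per_px=1.0)
        region = np.zeros((96, 96), bool)
        region[5:90, 5:90] = True
        board = BoardModel(ridge_mask=np.zeros((96, 96), bool),
                           ridge_axis=((6.0, 5.0), (6.0, 89.0)),
                           board_region=region, board_surface_depth_mm=1181.0,
                           ridge_top_depth_mm=1130.0)
        ref = DepthReference(np.full((96, 96), 1181.0), 15)
        depth = np.full((96, 96), 1181, np.float64)
        depth[30:33, 10:10 + extent_mm] = 1181 - 10
        frame = make_frame(depth.astype(np.uint16))
        assert len(detect_checkers(frame, ref, board, None, cal)) == expect

    def test_elevation_threshold_strict_5mm(self, cal2):
        frame, ref, board = self._setup(cal2, stack_height=5.0)
        assert detect_checkers(frame, ref, board, None, cal2) == []
        frame, ref, board = self._setup(cal2, stack_height=6.0)
        assert len(detect_checkers(frame, ref, board, None, cal2)) == 1


class TestCountStacked:
    @pytest.mark.parametrize("height,expect", [
        (24.0, 4),    # exact stack of four
        (20.0, 3),    # in both [9,27] and [12,36]; nearer to 18 than 24
        (6.0, 1),
        (2.0, 0),     # below every interval
        (12.0, 2),    # boundary of n=4 interval but nearest to 2x6
        (15.0, 2),    # tie between n=2 (|15-12|=3) and n=3 (|15-18|=3): smaller n
        (36.0, 4),    # inclusive upper bound of (6 ± 3)·4 = [12, 36]
        (36.5, 0),
    ])
    def test_interval_assignment(self, height, expect):
        assert count_stacked(height, D=6.0) == expect

    def test_monotone_on_clean_stacking_trajectory(self):
        counts = [count_stacked(h) for h in (6.0, 12.0, 18.0, 24.0)]
        assert counts == sorted(counts) == [1, 2, 3, 4]
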