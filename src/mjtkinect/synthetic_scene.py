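"""Synthetic top-down RGB-D scenes of the three subtests.

The simulator renders what a downward-looking depth camera mounted ~1200 mm
above the table would see: a flat tabletop ending at a front edge (beyond it
the subject's side, rendered 700 mm deeper), the subtest items at the
standard layout (cards 51 mm apart and 127 mm from the edge; the board with
its 508×13×51 mm ridge 127 mm from the edge; the 100 mm open can centrally
in front of the board; four 30 mm checkers in a row touching the board), and
a hand rendered as a rigid 80×120 mm elliptical blob whose distal tip follows
scripted waypoints at a scripted height above the table.  Every detector in
the pipeline uses only connected-pixel geometry, so blob realism is
unnecessary.

Ground truth times are computed from the script alone (trajectory geometry
plus the detectors' own rules); the rendered frames never feed back into
the ground truth, so end-to-end tests are not circular.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import DEFAULT_CONFIG, MjtConfig
from .recording_io import Calibration, Recording, RgbdFrame, TimesTable, save_recording
from .subtest_timing import detect_start

__all__ = ["SceneScript", "GroundTruth", "simulate", "make_script",
           "make_fixture_suite", "simulate_times_panel", "HAND_SEMI_AXES_MM"]

HAND_SEMI_AXES_MM = (60.0, 40.0)   # proximal-distal, left-right semi-axes
FLOOR_OFFSET_MM = 700.0            # beyond-edge region is this much deeper

# colors (R, G, B); neutral surfaces are warm-tinted (R > G > B), as real
# tables and cards are — an exactly channel-equal gray would let iid sensor
# noise flip individual pixels into the strict R<G∧B<G green mask
_TABLE_RGB = (176, 170, 163)
_FLOOR_RGB = (126, 120, 113)
_CARD_RGB = (240, 235, 228)
_MARKER_RGB = (60, 200, 60)
_BOARD_RGB = (150, 110, 80)
_RIDGE_RGB = (120, 85, 60)
_CAN_RGB = (50, 45, 40)            # dark open-can interior
_BEAN_RGB = (70, 50, 40)
_CHECKER_RGB = (150, 40, 40)
_HAND_RGB = (205, 170, 140)
_BLOB_RGB = (235, 230, 224)        # bean flashing past the dark can interior

_EVENT_KINDS = {"card": {"card_flip"}, "feeding": {"bean_drop"},
                "stacking": {"checker_place"}}


@dataclass
class SceneScript:
    """Full description of one simulated subtest recording."""

    subtest: str
    n_frames: int
    hand_waypoints: list                  # (frame, row_px, col_px, height_mm) of the distal tip
    events: list                          # (frame, kind, params)
    image_shape: tuple = (240, 320)
    table_depth_mm: float = 1200.0
    mm_per_px: float = 4.0
    frame_rate: float = 30.0
    depth_noise_mm: float = 2.0
    rgb_noise: float = 3.0
    seed: int = 0

    def __post_init__(self):
        if self.subtest not in _EVENT_KINDS:
            raise ValueError(f"unknown subtest {self.subtest!r}")
        frames = [w[0] for w in self.hand_waypoints]
        if any(b <= a for a, b in zip(frames, frames[1:])):
            raise ValueError("waypoint frames must be strictly increasing")
        allowed = _EVENT_KINDS[self.subtest]
        for f, kind, _ in self.events:
            if kind not in allowed:
                raise ValueError(f"event {kind!r} incompatible with subtest {self.subtest!r}")
            if not (0 <= f < self.n_frames):
                raise ValueError("event frame outside the recording span")
        limit = {"card": 5, "feeding": 5, "stacking": 4}[self.subtest]
        if len(self.events) > limit:
            raise ValueError(f"at most {limit} events for subtest {self.subtest!r}")

    @property
    def calibration(self) -> Calibration:
        return Calibration(mm_per_px=self.mm_per_px, sensor_height_mm=self.table_depth_mm)


@dataclass
class GroundTruth:
    """Script-derived reference times, per the visual-inspection definitions."""

    movement_onset_frame: int
    event_frames: list
    end_frame: int
    frame_rate: float
    start_s: float = field(init=False)
    end_s: float = field(init=False)
    total_s: float = field(init=False)

    def __post_init__(self):
        self.start_s = self.movement_onset_frame / self.frame_rate
        self.end_s = self.end_frame / self.frame_rate
        self.total_s = (self.end_frame - self.movement_onset_frame) / self.frame_rate

    def to_dict(self):
        return {"movement_onset_frame": int(self.movement_onset_frame),
                "event_frames": [int(e) for e in self.event_frames],
                "end_frame": int(self.end_frame), "frame_rate": self.frame_rate,
                "start_s": self.start_s, "end_s": self.end_s, "total_s": self.total_s}


# ---------------------------------------------------------------------------
# layout: everything in table-plane mm, y = distance from the front edge
# (increasing away from the subject), x = offset from the image centre line.

class _Layout:
    def __init__(self, script: SceneScript, cfg: MjtConfig):
        h, w = script.image_shape
        self.shape = script.image_shape
        self.mmpp = script.mm_per_px
        self.edge_row = int(round(h * 0.875))
        self.center_col = w / 2.0
        self.table_depth = script.table_depth_mm
        self.cfg = cfg
        rr, cc = np.mgrid[0:h, 0:w]
        self.y = (self.edge_row - rr) * self.mmpp    # mm from the front edge
        self.x = (cc - self.center_col) * self.mmpp  # mm from the centre line

        off = cfg.item_offset_mm                      # 127 mm
        # cards: five 127 mm wide × 76 mm deep, 51 mm gaps, centred
        span = 5 * 127.0 + 4 * cfg.card_spacing_mm
        self.card_centers = [(-span / 2 + 63.5 + k * (127.0 + cfg.card_spacing_mm), off + 38.0)
                             for k in range(5)]       # (x, y) of card centres
        self.card_size = (127.0, 76.0)                # (x extent, y extent)
        self.marker_size = 30.0
        # board and ridge
        self.board_y = (off, off + cfg.board_width_mm)            # 127..413
        self.board_x_half = 1054.0 / 2
        ridge_mid = off + cfg.board_width_mm / 2                  # 270
        self.ridge_y = (ridge_mid - 6.5, ridge_mid + 6.5)
        self.ridge_x_half = cfg.ridge_length_mm / 2               # 254
        self.ridge_height = cfg.ridge_height_mm + cfg.board_height_mm  # 70 above table
        # beans rest against the proximal side of the ridge
        self.bean_y = self.ridge_y[0] - 5.0
        self.bean_xs = [-102.0, -51.0, 0.0, 51.0, 102.0]
        # open can centrally in front of the board
        self.can_center = (0.0, off / 2)              # (x, y)
        self.can_radius = cfg.can_diameter_mm / 2
        # checkers: side by side, touching the board, centred
        r = cfg.checker_diameter_mm / 2
        self.source_y = off - r                       # 112
        self.source_xs = [-45.0, -15.0, 15.0, 45.0]
        self.stack_pos = (0.0, off + 30.0)            # (x, y) on the board
        self.checker_r = r

    # -- mm→px helpers ---------------------------------------------------
    def row_of(self, y_mm: float) -> float:
        return self.edge_row - y_mm / self.mmpp

    def col_of(self, x_mm: float) -> float:
        return self.center_col + x_mm / self.mmpp

    def rect(self, x0, x1, y0, y1) -> np.ndarray:
        return (self.x >= x0) & (self.x <= x1) & (self.y >= y0) & (self.y <= y1)

    def disc(self, x, y, radius) -> np.ndarray:
        return (self.x - x) ** 2 + (self.y - y) ** 2 <= radius ** 2

    # -- static scene at a given event state ------------------------------
    def render_static(self, subtest, flipped=(), stack_n=0, sources_gone=()):
        h, w = self.shape
        depth = np.full((h, w), self.table_depth, dtype=float)
        rgb = np.empty((h, w, 3), dtype=float)
        rgb[:] = _TABLE_RGB
        beyond = self.y <= 0       # edge_row itself is the first off-table row
        depth[beyond] = self.table_depth + FLOOR_OFFSET_MM
        rgb[beyond] = _FLOOR_RGB

        if subtest == "card":
            dx, dy = self.card_size
            for k, (cx, cy) in enumerate(self.card_centers):
                card = self.rect(cx - dx / 2, cx + dx / 2, cy - dy / 2, cy + dy / 2)
                rgb[card] = _CARD_RGB
                if k in flipped:
                    m = self.marker_size / 2
                    marker = self.rect(cx - m, cx + m, cy - m, cy + m)
                    rgb[marker] = _MARKER_RGB
        else:
            board = self.rect(-self.board_x_half, self.board_x_half, *self.board_y)
            depth[board] = self.table_depth - self.cfg.board_height_mm
            rgb[board] = _BOARD_RGB
            ridge = self.rect(-self.ridge_x_half, self.ridge_x_half, *self.ridge_y)
            depth[ridge] = self.table_depth - self.ridge_height
            rgb[ridge] = _RIDGE_RGB
            if subtest == "feeding":
                can = self.disc(*self.can_center, self.can_radius)
                rgb[can] = _CAN_RGB           # dark opening; depth left at table level
                for bx in self.bean_xs:
                    bean = self.rect(bx - 7.5, bx + 7.5, self.bean_y - 3, self.bean_y + 3)
                    rgb[bean] = _BEAN_RGB
            else:  # stacking
                for k, sx in enumerate(self.source_xs):
                    if k in sources_gone:
                        continue
                    src = self.disc(sx, self.source_y, self.checker_r)
                    depth[src] = self.table_depth - self.cfg.checker_height_mm
                    rgb[src] = _CHECKER_RGB
                if stack_n > 0:
                    st = self.disc(*self.stack_pos, self.checker_r)
                    depth[st] = (self.table_depth - self.cfg.board_height_mm
                                 - stack_n * self.cfg.checker_height_mm)
                    rgb[st] = _CHECKER_RGB
        return rgb, depth

    def hand_coords(self, tip_row: float, tip_col: float):
        """Pixel coordinates of the elliptical hand blob, clipped to the
        table side of the edge (the part every detector can see)."""
        a, b = HAND_SEMI_AXES_MM[0] / self.mmpp, HAND_SEMI_AXES_MM[1] / self.mmpp
        cr, ccol = tip_row + a, tip_col
        r0 = max(0, int(np.floor(cr - a)))
        r1 = min(self.shape[0] - 1, int(np.ceil(cr + a)))
        c0 = max(0, int(np.floor(ccol - b)))
        c1 = min(self.shape[1] - 1, int(np.ceil(ccol + b)))
        if r1 < r0 or c1 < c0:
            return np.empty(0, int), np.empty(0, int)
        rr, cc = np.mgrid[r0:r1 + 1, c0:c1 + 1]
        inside = ((rr - cr) / a) ** 2 + ((cc - ccol) / b) ** 2 <= 1.0
        return rr[inside], cc[inside]

    def hand_visible_coords(self, tip_row, tip_col):
        rr, cc = self.hand_coords(tip_row, tip_col)
        keep = rr < self.edge_row
        return rr[keep], cc[keep]


def _tip_track(script: SceneScript):
    """Per-frame distal-tip (row, col, height) by linear waypoint interpolation."""
    wp = np.asarray([(f, r, c, h) for f, r, c, h in script.hand_waypoints], dtype=float)
    t = np.arange(script.n_frames, dtype=float)
    rows = np.interp(t, wp[:, 0], wp[:, 1])
    cols = np.interp(t, wp[:, 0], wp[:, 2])
    heights = np.interp(t, wp[:, 0], wp[:, 3])
    return rows, cols, heights


# ---------------------------------------------------------------------------

def simulate(script: SceneScript, cfg: MjtConfig = DEFAULT_CONFIG):
    """Render a scripted recording and compute its ground truth.

    Returns ``(Recording, GroundTruth)``; the ground truth is ``None`` for an
    event-less script (nothing ever finishes, so no end time exists).  Two
    simulations of an identical script are bit-identical.
    """
    layout = _Layout(script, cfg)
    rows, cols, heights = _tip_track(script)
    rng = np.random.default_rng(script.seed)
    h, w = script.image_shape

    events = sorted(script.events, key=lambda e: e[0])
    flipped, sources_gone = set(), set()
    stack_n = 0
    drop_frames = {f for f, kind, _ in events if kind == "bean_drop"}
    state_events = [(f, kind, params) for f, kind, params in events if kind != "bean_drop"]
    ev_i = 0
    static_rgb, static_depth = layout.render_static(script.subtest)
    blob_mask = None

    frames = []
    for i in range(script.n_frames):
        while ev_i < len(state_events) and state_events[ev_i][0] <= i:
            _, kind, params = state_events[ev_i]
            if kind == "card_flip":
                flipped.add(params["card"])
            elif kind == "checker_place":
                stack_n = params["n"]
                sources_gone.add(params["n"] - 1)
            ev_i += 1
            static_rgb, static_depth = layout.render_static(
                script.subtest, flipped=flipped, stack_n=stack_n,
                sources_gone=sources_gone)
        rgb = static_rgb.copy()
        depth = static_depth.copy()
        if i in drop_frames:
            if blob_mask is None:
                blob_mask = layout.disc(layout.can_center[0] - 2.0,
                                        layout.can_center[1] + 3.0, 6.0)
            rgb[blob_mask] = _BLOB_RGB
        rr, cc = layout.hand_coords(rows[i], cols[i])
        hand_depth = script.table_depth_mm - heights[i]
        nearer = hand_depth < depth[rr, cc]
        rr, cc = rr[nearer], cc[nearer]
        depth[rr, cc] = hand_depth
        rgb[rr, cc] = _HAND_RGB
        if script.depth_noise_mm > 0:
            depth = depth + rng.standard_normal((h, w)) * script.depth_noise_mm
        if script.rgb_noise > 0:
            rgb = rgb + rng.standard_normal((h, w, 3)) * script.rgb_noise
        frames.append(RgbdFrame(
            rgb=np.clip(np.rint(rgb), 0, 255).astype(np.uint8),
            depth=np.clip(np.rint(depth), 0, 65535).astype(np.uint16),
            index=i))
    rec = Recording(frames, frame_rate=script.frame_rate,
                    meta={"subtest": script.subtest, "seed": script.seed})
    gt = ground_truth_from_script(script, cfg) if script.events else None
    return rec, gt


# ---------------------------------------------------------------------------
# ground truth (script-only; mirrors the detection rules on the
# scripted geometry, never on rendered pixels)

def _distal_centroid_of(rr, cc, mmpp, band_mm):
    r_min = rr.min()
    band = (rr - r_min) * mmpp <= band_mm
    return float(rr[band].mean()), float(cc[band].mean())


def ground_truth_from_script(script: SceneScript, cfg: MjtConfig = DEFAULT_CONFIG) -> GroundTruth:
    layout = _Layout(script, cfg)
    rows, cols, heights = _tip_track(script)
    mmpp = script.mm_per_px
    n = script.n_frames

    hand_px = [layout.hand_visible_coords(rows[i], cols[i]) for i in range(n)]
    dc = np.array([_distal_centroid_of(rr, cc, mmpp, cfg.distal_band_mm)
                   for rr, cc in hand_px])
    events = sorted(script.events, key=lambda e: e[0])
    event_frames = [f for f, _, _ in events]

    if script.subtest == "card":
        series = (layout.edge_row - dc[:, 0]) * mmpp
        onset = detect_start(series, cfg.card_cross_mm, "exceeds", cfg)
        shape = script.image_shape
        confirms = []
        for f, kind, params in events:
            cx, cy = layout.card_centers[params["card"]]
            m = layout.marker_size / 2
            marker = layout.rect(cx - m, cx + m, cy - m, cy + m)
            support = 0
            conf = None
            for fr in range(f, n):
                rr, cc = hand_px[fr]
                # mirror of the detector: centroid of the marker pixels not
                # covered by the hand, excluded when within 10 mm of the hand
                vis = marker.copy()
                vis[rr, cc] = False
                vr, vc = np.nonzero(vis)
                if vr.size < cfg.marker_min_px:
                    continue
                cen = (vr.mean(), vc.mean())
                d_mm = (np.hypot(rr - cen[0], cc - cen[1]).min() * mmpp
                        if rr.size else np.inf)
                if d_mm >= cfg.marker_hand_excl_mm:
                    support += 1
                    if support >= cfg.track_confirm_frames:
                        conf = fr
                        break
            if conf is None:
                raise ValueError("script ends before the last card can be confirmed")
            confirms.append(conf)
        end = max(confirms)

    elif script.subtest == "feeding":
        series = (layout.edge_row - dc[:, 0]) * mmpp
        onset = detect_start(series, cfg.feeding_cross_mm, "exceeds", cfg)
        center = np.array([layout.row_of(layout.can_center[1]),
                           layout.col_of(layout.can_center[0])])
        rim = (np.hypot(dc[:, 0] - center[0], dc[:, 1] - center[1])
               - layout.can_radius / mmpp) * mmpp
        f5 = event_frames[-1]
        after = np.flatnonzero(rim[f5:] > cfg.feeding_end_rim_mm)
        if after.size == 0:
            raise ValueError("script ends before the hand retreats from the can")
        end = int(f5 + after[0])

    else:  # stacking
        board_prox_row = int(np.floor(layout.row_of(layout.board_y[0])))
        point = np.array([board_prox_row + cfg.stacking_point_offset_mm / mmpp,
                          layout.col_of(0.0)])
        series = np.hypot(dc[:, 0] - point[0], dc[:, 1] - point[1]) * mmpp
        onset = detect_start(series, cfg.stacking_cross_mm, "falls_below", cfg)
        st = layout.disc(*layout.stack_pos, layout.checker_r)
        srr, scc = np.nonzero(st)
        p4 = event_frames[-1]
        consecutive = 0
        end = None
        for fr in range(max(p4, cfg.n_ref_frames), n):
            rr, cc = hand_px[fr]
            if rr.size:
                d_mm = np.sqrt((srr[:, None] - rr[None, :]) ** 2
                               + (scc[:, None] - cc[None, :]) ** 2).min() * mmpp
            else:
                d_mm = np.inf
            consecutive = consecutive + 1 if d_mm > cfg.checker_hand_mm else 0
            if consecutive >= cfg.stack_consecutive:
                end = fr
                break
        if end is None:
            raise ValueError("script ends before five consecutive clear detections")

    return GroundTruth(movement_onset_frame=int(onset), event_frames=event_frames,
                       end_frame=int(end), frame_rate=script.frame_rate)


# ---------------------------------------------------------------------------
# default scripts

def make_script(subtest: str, seed: int = 0, *, image_shape=(240, 320),
                mm_per_px: float = 4.0, depth_noise_mm: float = 2.0,
                rgb_noise: float = 3.0, frame_rate: float = 30.0,
                cfg: MjtConfig = DEFAULT_CONFIG) -> SceneScript:
    """A complete, slightly randomised script for one subtest.

    The randomness (seeded) jitters the movement onset and the event spacing
    by a few frames; the scene geometry is always the standard layout.
    """
    rng = np.random.default_rng(seed)
    lay = _Layout(SceneScript(subtest=subtest, n_frames=1,
                              hand_waypoints=[(0, 0, 0, 45)], events=[],
                              image_shape=image_shape, mm_per_px=mm_per_px,
                              frame_rate=frame_rate, seed=seed), cfg)

    def P(x_mm, y_mm):
        # tip position: row of the distal tip, col
        return lay.row_of(y_mm), lay.col_of(x_mm)

    t0 = int(20 + rng.integers(0, 6))
    wps, events = [], []

    if subtest == "card":
        flips = []
        f = t0 + 32
        for _ in range(5):
            flips.append(f)
            f += int(33 + rng.integers(-3, 4))
        start = P(0, 30)
        wps = [(0, *start, 45.0), (t0, *start, 45.0)]
        for k, fk in enumerate(flips):
            cx, cy = lay.card_centers[k]
            # dwell with the tip at the card's distal edge: the marker is then
            # fully covered while the hand is on the card, so the ambiguous
            # partially-covered phase is only the brief retreat sweep
            pos = P(cx, cy + 30)
            wps.append((fk - 2, *pos, 45.0))
            wps.append((fk + 3, *pos, 45.0))
            events.append((fk, "card_flip", {"card": k}))
        wps.append((flips[-1] + 12, *P(lay.card_centers[-1][0] - 60, 40), 45.0))
        n_frames = flips[-1] + 34

    elif subtest == "feeding":
        drops = []
        f = t0 + 48
        for _ in range(5):
            drops.append(f)
            f += int(30 + rng.integers(-2, 3))
        start = P(0, 30)
        # drop position: tip short of the can so the hand (which extends
        # proximally from the tip) does not cover the can opening
        rim = P(0.0, 40.0)
        wps = [(0, *start, 45.0), (t0, *start, 45.0)]
        for k, dk in enumerate(drops):
            bean = P(lay.bean_xs[k], lay.bean_y)
            wps.append((dk - 16, *bean, 60.0))
            wps.append((dk - 14, *bean, 60.0))
            wps.append((dk - 2, *rim, 60.0))
            wps.append((dk + 2, *rim, 60.0))
            events.append((dk, "bean_drop", {}))
        wps.append((drops[-1] + 12, *P(-80.0, 30.0), 45.0))
        n_frames = drops[-1] + 22

    else:  # stacking
        places = []
        f = t0 + 30
        for _ in range(4):
            places.append(f)
            f += int(26 + rng.integers(-2, 3))
        start = P(0, 30)
        stack = P(*lay.stack_pos)
        wps = [(0, *start, 45.0), (t0, *start, 45.0)]
        for k, pk in enumerate(places):
            src = P(lay.source_xs[k], lay.source_y)
            wps.append((pk - 10, *src, 45.0))
            wps.append((pk - 8, *src, 45.0))       # grab
            wps.append((pk - 1, *stack, 60.0))
            wps.append((pk + 2, *stack, 60.0))     # place
            events.append((pk, "checker_place", {"n": k + 1}))
        wps.append((places[-1] + 12, *P(0.0, 40.0), 45.0))
        n_frames = places[-1] + 26

    return SceneScript(subtest=subtest, n_frames=n_frames, hand_waypoints=wps,
                       events=events, image_shape=image_shape, mm_per_px=mm_per_px,
                       frame_rate=frame_rate, depth_noise_mm=depth_noise_mm,
                       rgb_noise=rgb_noise, seed=seed)


def make_fixture_suite(out_dir, seeds, subtests=("card", "feeding", "stacking"),
                       cfg: MjtConfig = DEFAULT_CONFIG) -> dict:
    """Write one small recording per subtest per seed plus a ground-truth
    manifest; returns the manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"recordings": []}
    for subtest in subtests:
        for seed in seeds:
            script = make_script(subtest, seed=seed, cfg=cfg)
            rec, gt = simulate(script, cfg)
            name = f"{subtest}_{seed}.npz"
            save_recording(rec, out_dir / name)
            manifest["recordings"].append({
                "path": name, "subtest": subtest, "seed": int(seed),
                "n_frames": len(rec), "ground_truth": gt.to_dict()})
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


# ---------------------------------------------------------------------------
# synthetic timing panels for the statistics layer

def simulate_times_panel(n_subjects: int, bias_s: float = 0.2,
                         sd_within_s: float = 0.3, sd_between_s: float = 0.1,
                         practice_effect_s: float = 1.0, seed: int = 0,
                         subtest: str = "card", base_time_s: float = 8.0) -> TimesTable:
    """A synthetic subject × repetition × hand timing panel.

    Ground-truth totals are subject-level times minus a practice effect on the
    second repetition.  The automatic method adds ``bias_s`` plus a
    subject-specific offset (SD ``sd_between_s``) plus per-observation noise
    (SD ``sd_within_s``); the therapist adds a −0.35 s reaction-time bias with
    the same noise structure.  Used for parameter-recovery tests of the
    agreement statistics.
    """
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2")
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_subjects):
        sid = f"S{i + 1:03d}"
        subj_eff = rng.normal(0.0, 1.0)
        kin_off = rng.normal(0.0, sd_between_s)
        ther_off = rng.normal(0.0, sd_between_s)
        for hand, hand_eff in (("most", 0.0), ("least", -1.0)):
            for rep in (1, 2):
                truth = (base_time_s + subj_eff + hand_eff
                         - practice_effect_s * (rep - 1))
                truth = max(truth, 1.0)
                meas = {
                    "ground_truth": truth,
                    "kinect": truth + bias_s + kin_off + rng.normal(0.0, sd_within_s),
                    "therapist": truth - 0.35 + ther_off + rng.normal(0.0, sd_within_s),
                }
                for method, total in meas.items():
                    start = 1.0
                    rows.append({"subject_id": sid, "repetition": rep, "hand": hand,
                                 "subtest": subtest, "method": method,
                                 "start_s": start, "end_s": start + total,
                                 "total_s": total})
    return TimesTable(pd.DataFrame(rows))
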