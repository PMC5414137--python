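"""The three subtest state machines: start detection, event accumulation,
finish detection, and result assembly.

Start times for all three subtests share one rule: find the first frame at
which the hand's distance to a subtest-specific reference satisfies the
crossing condition (e.g. exceeds 127 mm from the table edge for card
turning), then walk backwards through the contiguous run of frames whose
per-frame displacement toward the target is at least 3 mm; the earliest frame
of that run is the movement onset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .config import DEFAULT_CONFIG, MjtConfig
from .errors import HandGapError, StartNotDetectedError, SubtestIncompleteError
from .hand_tracking import (DistanceSeries, detect_hand, distance_series,
                            reference_distance_mm)
from .object_events import (BeanDropState, CheckerLog, count_stacked,
                            count_turned_cards, detect_bean_drop,
                            detect_checkers, detect_green_markers,
                            update_card_tracks)
from .recording_io import Calibration, Recording
from .scene_geometry import (build_depth_reference, detect_board, detect_can,
                             detect_table)

__all__ = ["SubtestResult", "detect_start", "consecutive_end",
           "run_card_turning", "run_simulated_feeding",
           "run_stacking_checkers", "run_subtest"]


def consecutive_end(flags, k: int):
    """Index of the k-th element of the first run of k consecutive True
    flags, or None.  A False anywhere resets the run (the stacking finish
    rule: five consecutive fourth-interval detections)."""
    run = 0
    for i, f in enumerate(flags):
        run = run + 1 if f else 0
        if run >= k:
            return i
    return None


@dataclass
class SubtestResult:
    subtest: str
    start_frame: int
    end_frame: int
    frame_rate: float
    events: list = field(default_factory=list)
    diagnostics: list = field(default_factory=list)

    @property
    def start_s(self) -> float:
        return self.start_frame / self.frame_rate

    @property
    def end_s(self) -> float:
        return self.end_frame / self.frame_rate

    @property
    def total_s(self) -> float:
        return (self.end_frame - self.start_frame) / self.frame_rate

    def to_dict(self) -> dict:
        return {
            "subtest": self.subtest,
            "start_frame": int(self.start_frame),
            "end_frame": int(self.end_frame),
            "start_s": self.start_s,
            "end_s": self.end_s,
            "total_s": self.total_s,
            "events": [int(e) for e in self.events],
            "diagnostics": list(self.diagnostics),
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)


def _fill_gaps(values: np.ndarray, max_gap: int) -> np.ndarray:
    """Linearly interpolate NaN gaps; interior gaps longer than ``max_gap``
    raise.  Leading/trailing gaps are filled with the nearest valid value."""
    values = np.asarray(values, dtype=float)
    ok = np.isfinite(values)
    if ok.all():
        return values
    if not ok.any():
        raise HandGapError("hand never detected")
    idx = np.flatnonzero(ok)
    # longest interior run of NaNs
    run, longest = 0, 0
    for i in range(idx[0], idx[-1] + 1):
        run = 0 if ok[i] else run + 1
        longest = max(longest, run)
    if longest > max_gap:
        raise HandGapError(f"hand absent for {longest} consecutive frames (max {max_gap})")
    out = np.interp(np.arange(len(values)), idx, values[idx])
    return out


def detect_start(series: DistanceSeries | np.ndarray, crossing_threshold_mm: float,
                 crossing_direction: str, cfg: MjtConfig = DEFAULT_CONFIG,
                 diagnostics: list | None = None) -> int:
    """Movement-onset frame for one subtest.

    ``crossing_direction`` is ``"exceeds"`` or ``"falls_below"``.  Let c be
    the first frame satisfying the crossing condition; the start frame is the
    earliest frame of the contiguous run of frames up to c whose per-frame
    displacement toward the target is at least ``onset_mm_per_frame``
    (inclusive).  An instantaneous jump (empty run) returns c with a warning.
    """
    values = series.values if isinstance(series, DistanceSeries) else np.asarray(series, float)
    s = _fill_gaps(values, cfg.max_gap_frames)
    if crossing_direction == "exceeds":
        cond = s > crossing_threshold_mm
        disp = np.diff(s, prepend=s[0])          # + = toward the target
    elif crossing_direction == "falls_below":
        cond = s < crossing_threshold_mm
        disp = -np.diff(s, prepend=s[0])
    else:
        raise ValueError("crossing_direction must be 'exceeds' or 'falls_below'")
    hits = np.flatnonzero(cond)
    if hits.size == 0:
        raise StartNotDetectedError(
            f"subtest start not detected: distance never {crossing_direction} "
            f"{crossing_threshold_mm} mm")
    c = int(hits[0])
    k = c
    while k >= 1 and disp[k] >= cfg.onset_mm_per_frame:
        k -= 1
    if k == c:
        if diagnostics is not None:
            diagnostics.append(f"instantaneous crossing at frame {c}; start set to crossing frame")
        return c
    return k + 1


# ---------------------------------------------------------------------------

def run_card_turning(rec: Recording, cal: Calibration,
                     cfg: MjtConfig = DEFAULT_CONFIG) -> SubtestResult:
    """Card Turning: start when the hand sets off toward the cards (crossing
    127 mm from the table edge), finish when the fifth green-marker track is
    confirmed."""
    diagnostics = []
    table = detect_table(rec[0].depth, cal, cfg)
    tracks = []
    distances = np.full(len(rec), np.nan)
    end_frame = None
    for i, frame in enumerate(rec.frames):
        obs = detect_hand(frame, table, None, cal, cfg)
        diagnostics.extend(obs.diagnostics)
        if obs.present:
            distances[i] = reference_distance_mm(
                obs.distal_centroid, ("edge", table.edge_row), cal)
        centroids = detect_green_markers(frame.rgb, obs, cal, cfg)
        update_card_tracks(tracks, centroids, i, cal, cfg)
        if count_turned_cards(tracks) >= cfg.n_cards:
            end_frame = i
            break
    if end_frame is None:
        raise SubtestIncompleteError("card", f"only {count_turned_cards(tracks)} of "
                                     f"{cfg.n_cards} cards confirmed",
                                     count=count_turned_cards(tracks))
    start = detect_start(distances[:end_frame + 1], cfg.card_cross_mm, "exceeds",
                         cfg, diagnostics)
    end_frame = max(start, end_frame - cfg.end_latency_frames)
    events = sorted(tr.confirmed_frame for tr in tracks if tr.confirmed)[:cfg.n_cards]
    return SubtestResult(subtest="card", start_frame=start, end_frame=end_frame,
                         frame_rate=rec.frame_rate, events=events,
                         diagnostics=diagnostics)


def _can_search_region(board, table, cal: Calibration, cfg: MjtConfig, shape):
    """Square window centred on the ridge-axis midpoint, shifted proximally;
    the can sits centrally in front of the board."""
    (r0, c0), (r1, c1) = board.ridge_axis
    mid_r, mid_c = (r0 + r1) / 2.0, (c0 + c1) / 2.0
    mid_r += cfg.can_search_offset_mm / cal.mm_per_px
    half = (cfg.can_search_window_mm / 2.0) / cal.mm_per_px
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    region = (np.abs(rr - mid_r) <= half) & (np.abs(cc - mid_c) <= half)
    return region & ~board.board_region


def run_simulated_feeding(rec: Recording, cal: Calibration,
                          cfg: MjtConfig = DEFAULT_CONFIG) -> SubtestResult:
    """Simulated Feeding: start when the hand sets off past 147 mm from the
    table edge; finish when five beans have dropped and the hand has retreated
    more than 20 mm outside the can rim."""
    diagnostics = []
    table = detect_table(rec[0].depth, cal, cfg)
    board = detect_board(rec[0].depth, table, cal, cfg)
    region = _can_search_region(board, table, cal, cfg, rec[0].shape)
    can = detect_can(rec[0].rgb, region, cal, cfg)

    (ar0, ac0), (ar1, ac1) = board.ridge_axis
    state = BeanDropState(max_drops=cfg.n_beans)
    distances = np.full(len(rec), np.nan)
    end_frame = None
    prev_rgb = None
    for i, frame in enumerate(rec.frames):
        obs = detect_hand(frame, table, board, cal, cfg)
        diagnostics.extend(obs.diagnostics)
        ridge_dist = None
        rim_dist = None
        if obs.present:
            distances[i] = reference_distance_mm(
                obs.distal_centroid, ("edge", table.edge_row), cal)
            ridge_dist = _point_segment_distance_mm(
                obs.distal_centroid, (ar0, ac0), (ar1, ac1), cal)
            rim_dist = reference_distance_mm(obs.distal_centroid, ("circle", can), cal)
        if prev_rgb is not None:
            detect_bean_drop(prev_rgb, frame.rgb, can, obs, ridge_dist, state,
                             cal, cfg, frame_index=i)
        prev_rgb = frame.rgb
        if len(state.drops) >= cfg.n_beans and rim_dist is not None and \
                rim_dist > cfg.feeding_end_rim_mm:
            end_frame = i
            break
    if end_frame is None:
        raise SubtestIncompleteError("feeding", f"only {len(state.drops)} of "
                                     f"{cfg.n_beans} beans detected",
                                     count=len(state.drops))
    start = detect_start(distances[:end_frame + 1], cfg.feeding_cross_mm, "exceeds",
                         cfg, diagnostics)
    return SubtestResult(subtest="feeding", start_frame=start, end_frame=end_frame,
                         frame_rate=rec.frame_rate, events=list(state.drops),
                         diagnostics=diagnostics)


def _point_segment_distance_mm(p, a, b, cal: Calibration) -> float:
    p, a, b = (np.asarray(x, dtype=float) for x in (p, a, b))
    ab = b - a
    denom = float(ab @ ab)
    t = 0.0 if denom == 0 else float(np.clip((p - a) @ ab / denom, 0.0, 1.0))
    return float(np.linalg.norm(p - (a + t * ab))) * cal.mm_per_px


def run_stacking_checkers(rec: Recording, cal: Calibration,
                          cfg: MjtConfig = DEFAULT_CONFIG) -> SubtestResult:
    """Stacking Checkers: start when the hand closes to 63.5 mm of the point
    15 mm in front of the middle of the board's proximal edge; finish at the
    fifth consecutive frame with a checker detection in the fourth stack
    interval."""
    diagnostics = []
    ref = build_depth_reference(rec, cfg.n_ref_frames)
    table = detect_table(rec[0].depth, cal, cfg)
    board = detect_board(rec[0].depth, table, cal, cfg)

    # static-reference sanity check
    drift = float(np.mean(np.abs(rec[cfg.n_ref_frames - 1].depth.astype(float)
                                 - rec[0].depth.astype(float))))
    if drift > cfg.ref_static_mm:
        diagnostics.append(f"reference frames not static: mean |Δdepth| = {drift:.1f} mm")

    rows = np.nonzero(board.board_region.any(axis=1))[0]
    proximal_edge_row = int(rows.max())
    (ar0, ac0), (ar1, ac1) = board.ridge_axis
    mid_col = (ac0 + ac1) / 2.0
    point = (proximal_edge_row + cfg.stacking_point_offset_mm / cal.mm_per_px, mid_col)

    distances = np.full(len(rec), np.nan)
    log = CheckerLog()
    flags = []           # per analysed frame: any detection in the fourth interval?
    seen_counts = {}
    end_frame = None
    for i, frame in enumerate(rec.frames):
        obs = detect_hand(frame, table, board, cal, cfg)
        diagnostics.extend(obs.diagnostics)
        if obs.present:
            distances[i] = reference_distance_mm(obs.distal_centroid, ("point", point), cal)
        if i < cfg.n_ref_frames:
            continue
        entries = detect_checkers(frame, ref, board, obs, cal, cfg)
        counts = []
        for fidx, height in entries:
            log.append(fidx, height)
            counts.append(count_stacked(height, cfg.checker_height_mm))
        for n in counts:
            if n > 0 and n not in seen_counts:
                seen_counts[n] = i
        flags.append(cfg.n_checkers in counts)
        if len(flags) >= cfg.stack_consecutive and all(flags[-cfg.stack_consecutive:]):
            end_frame = i
            break
    if end_frame is None:
        raise SubtestIncompleteError(
            "stacking", f"never saw {cfg.stack_consecutive} consecutive "
            f"interval-{cfg.n_checkers} detections", count=max(seen_counts, default=0))
    start = detect_start(distances[:end_frame + 1], cfg.stacking_cross_mm,
                         "falls_below", cfg, diagnostics)
    events = [seen_counts[n] for n in sorted(seen_counts)]
    return SubtestResult(subtest="stacking", start_frame=start, end_frame=end_frame,
                         frame_rate=rec.frame_rate, events=events,
                         diagnostics=diagnostics)


_RUNNERS = {
    "card": run_card_turning,
    "feeding": run_simulated_feeding,
    "stacking": run_stacking_checkers,
}


def run_subtest(rec: Recording, subtest: str, cal: Calibration,
                cfg: MjtConfig = DEFAULT_CONFIG) -> SubtestResult:
    try:
        runner = _RUNNERS[subtest]
    except KeyError:
        raise ValueError(f"unknown subtest: {subtest!r}") from None
    return runner(rec, cal, cfg)
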