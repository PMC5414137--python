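"""Task-event detectors: turned cards, beans dropped into the can, and
checkers stacked on the board.

Card turns are found as persistent green-marker centroids in the RGB image
(the marker side of a card faces down until the card is flipped, so a stable
marker track implies a turned card).  Bean drops are transient small groups
in the frame-difference image inside the can rim, gated by a one-bean-at-a-
time state machine.  Checker stacking is read from depth: groups elevated
above the board surface relative to a static reference image, whose mean
height selects one of four stack-count intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .config import DEFAULT_CONFIG, MjtConfig
from .recording_io import Calibration, RgbdFrame
from .scene_geometry import (FOUR_CONNECTED, BoardModel, CanModel,
                             DepthReference, group_extent_mm)
from .hand_tracking import HandObservation

__all__ = [
    "MarkerTrack", "BeanDropState", "CheckerLog",
    "detect_green_markers", "update_card_tracks", "count_turned_cards",
    "detect_bean_drop", "detect_checkers", "count_stacked",
]


# ---------------------------------------------------------------------------
# card turning

@dataclass
class MarkerTrack:
    """A clustered green-marker centroid with its per-frame support."""

    centroid: tuple
    frames: set                         # frame indices in which it was seen
    first_frame: int
    last_frame: int
    confirmed_frame: int | None = None  # frame at which support reached the threshold
    _sum: np.ndarray = None             # running centroid sum over observations
    _n_obs: int = 1

    @property
    def support_frames(self) -> int:
        return len(self.frames)

    @property
    def confirmed(self) -> bool:
        return self.confirmed_frame is not None


def detect_green_markers(rgb: np.ndarray, hand: HandObservation | None,
                         cal: Calibration, cfg: MjtConfig = DEFAULT_CONFIG) -> list:
    """Centroids of green-marker groups in one RGB frame.

    The green mask keeps pixels whose R and B values are strictly lower than
    G; a 5×5 median filter removes speckle; 4-connected groups of at least
    ``marker_min_px`` pixels survive; groups whose centroid lies within
    ``marker_hand_excl_mm`` of any hand pixel are excluded (the hand is busy
    flipping that card).
    """
    rgb = np.asarray(rgb)
    r, g, b = rgb[..., 0].astype(int), rgb[..., 1].astype(int), rgb[..., 2].astype(int)
    mask = (r < g) & (b < g)
    mask = ndimage.median_filter(mask.astype(np.uint8), size=5).astype(bool)
    labels, n = ndimage.label(mask, structure=FOUR_CONNECTED)
    if n == 0:
        return []
    flat = labels.ravel()
    sizes = np.bincount(flat, minlength=n + 1)
    rr_grid, cc_grid = np.nonzero(mask)
    lab_at = labels[rr_grid, cc_grid]
    rsum = np.bincount(lab_at, weights=rr_grid, minlength=n + 1)
    csum = np.bincount(lab_at, weights=cc_grid, minlength=n + 1)
    keep = np.flatnonzero(sizes >= cfg.marker_min_px)
    keep = keep[keep > 0]
    if keep.size == 0:
        return []
    cents = np.column_stack([rsum[keep] / sizes[keep], csum[keep] / sizes[keep]])
    if hand is not None and hand.present:
        d_px, _ = cKDTree(hand.coords).query(cents)
        cents = cents[d_px * cal.mm_per_px >= cfg.marker_hand_excl_mm]
    return [tuple(c) for c in cents]


def update_card_tracks(tracks: list, centroids: list, frame_index: int,
                       cal: Calibration, cfg: MjtConfig = DEFAULT_CONFIG) -> list:
    """Assign the frame's marker centroids to tracks.

    A centroid joins the nearest existing track if it lies strictly within
    ``track_join_mm`` of it, otherwise it opens a new track.  Tracks whose
    running-mean centroids drift to within ``track_join_mm`` of each other
    are merged (centroids closer than that are one card, and duplicates
    would otherwise split the support count).  A track seen in
    ``track_confirm_frames`` distinct frames is a confirmed turned card;
    tracks are never deleted.
    """
    def _confirm(tr):
        if tr.confirmed_frame is None and tr.support_frames >= cfg.track_confirm_frames:
            tr.confirmed_frame = frame_index

    for cen in centroids:
        best, best_d = None, np.inf
        for tr in tracks:
            d = np.hypot(cen[0] - tr.centroid[0], cen[1] - tr.centroid[1]) * cal.mm_per_px
            if d < best_d:
                best, best_d = tr, d
        if best is not None and best_d < cfg.track_join_mm:
            best._sum = best._sum + np.asarray(cen)
            best._n_obs += 1
            best.frames.add(frame_index)
            best.centroid = tuple(best._sum / best._n_obs)
            best.last_frame = frame_index
            _confirm(best)
        else:
            tr = MarkerTrack(centroid=tuple(cen), frames={frame_index},
                             first_frame=frame_index, last_frame=frame_index,
                             _sum=np.asarray(cen, dtype=float))
            _confirm(tr)
            tracks.append(tr)

    # merge pass: tracks are pairwise >= track_join_mm apart afterwards
    merged = True
    while merged:
        merged = False
        for i in range(len(tracks)):
            for j in range(i + 1, len(tracks)):
                a, b = tracks[i], tracks[j]
                d = np.hypot(a.centroid[0] - b.centroid[0],
                             a.centroid[1] - b.centroid[1]) * cal.mm_per_px
                if d < cfg.track_join_mm:
                    a._sum = a._sum + b._sum
                    a._n_obs = a._n_obs + b._n_obs
                    a.frames |= b.frames
                    a.centroid = tuple(a._sum / a._n_obs)
                    a.first_frame = min(a.first_frame, b.first_frame)
                    a.last_frame = max(a.last_frame, b.last_frame)
                    if a.confirmed_frame is None:
                        a.confirmed_frame = b.confirmed_frame
                    elif b.confirmed_frame is not None:
                        a.confirmed_frame = min(a.confirmed_frame, b.confirmed_frame)
                    _confirm(a)
                    tracks.pop(j)
                    merged = True
                    break
            if merged:
                break
    return tracks


def count_turned_cards(tracks: list) -> int:
    return sum(1 for tr in tracks if tr.confirmed)


# ---------------------------------------------------------------------------
# simulated feeding

@dataclass
class BeanDropState:
    """Bean-drop accumulator: at most five drops, one per arm/re-arm cycle."""

    drops: list = field(default_factory=list)
    armed: bool = True
    max_drops: int = 5


def _merged_difference_groups(diff_mask: np.ndarray, cal: Calibration, merge_mm: float):
    """4-connected groups of the difference mask, with groups whose centroids
    lie strictly within ``merge_mm`` of each other merged (transitively)."""
    labels, n = ndimage.label(diff_mask, structure=FOUR_CONNECTED)
    if n == 0:
        return []
    rr_all, cc_all = np.nonzero(diff_mask)
    lab_at = labels[rr_all, cc_all]
    order = np.argsort(lab_at, kind="stable")
    rr_all, cc_all, lab_at = rr_all[order], cc_all[order], lab_at[order]
    bounds = np.searchsorted(lab_at, np.arange(1, n + 2))
    groups = []
    for lab in range(1, n + 1):
        sl = slice(bounds[lab - 1], bounds[lab])
        rr, cc = rr_all[sl], cc_all[sl]
        groups.append({"rr": rr, "cc": cc,
                       "centroid": np.array([rr.mean(), cc.mean()])})
    parent = list(range(len(groups)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            d = np.linalg.norm(groups[i]["centroid"] - groups[j]["centroid"]) * cal.mm_per_px
            if d < merge_mm:
                parent[find(i)] = find(j)
    merged = {}
    for i, g in enumerate(groups):
        merged.setdefault(find(i), []).append(g)
    out = []
    for parts in merged.values():
        rr = np.concatenate([p["rr"] for p in parts])
        cc = np.concatenate([p["cc"] for p in parts])
        out.append({
            "n_px": rr.size,
            "centroid": (float(rr.mean()), float(cc.mean())),
            "extent_mm": group_extent_mm(rr, cc, cal),
        })
    return out


def detect_bean_drop(prev_rgb: np.ndarray, cur_rgb: np.ndarray, can: CanModel,
                     hand: HandObservation | None, ridge_dist_mm: float,
                     state: BeanDropState, cal: Calibration,
                     cfg: MjtConfig = DEFAULT_CONFIG,
                     frame_index: int = 0) -> BeanDropState:
    """Advance the bean-drop state machine by one frame pair.

    A drop is recorded iff the state is armed and the grayscale absolute
    difference of the two frames (hand pixels excluded) contains a merged
    group of 5–50 pixels, shorter than 15 mm, whose centroid lies inside the
    can rim, while the hand is within 50 mm of the rim.  After a drop the
    machine disarms; it re-arms when the hand returns to within 30 mm of the
    board ridge (the next bean cannot be picked up from anywhere else).
    """
    if not state.armed and ridge_dist_mm is not None and \
            ridge_dist_mm < cfg.bean_rearm_ridge_mm:
        state.armed = True
    if len(state.drops) >= state.max_drops:
        return state

    if not state.armed:
        return state
    # hand-to-rim gate: without a hand near the can no bean can be arriving
    if hand is None or not hand.present:
        return state
    from .hand_tracking import reference_distance_mm
    rim_dist = reference_distance_mm(hand.distal_centroid, ("circle", can), cal)
    if not rim_dist < cfg.bean_hand_rim_mm:
        return state

    gray_prev = np.asarray(prev_rgb, dtype=float).mean(axis=2)
    gray_cur = np.asarray(cur_rgb, dtype=float).mean(axis=2)
    diff = np.abs(gray_cur - gray_prev)
    mask = diff > cfg.bean_diff_threshold
    if hand.present:
        mask[hand.coords[:, 0], hand.coords[:, 1]] = False
    for g in _merged_difference_groups(mask, cal, cfg.bean_merge_mm):
        if not (cfg.bean_min_px <= g["n_px"] <= cfg.bean_max_px):
            continue
        if not g["extent_mm"] < cfg.bean_max_extent_mm:
            continue
        d_center = np.hypot(g["centroid"][0] - can.center[0],
                            g["centroid"][1] - can.center[1])
        if d_center >= can.radius_px:
            continue
        state.drops.append(frame_index)
        state.armed = False
        break
    return state


# ---------------------------------------------------------------------------
# stacking checkers

@dataclass
class CheckerLog:
    """Per-frame (frame_index, mean height above the board) records."""

    entries: list = field(default_factory=list)  # (frame_index, height_mm)

    def append(self, frame_index: int, height_mm: float):
        self.entries.append((frame_index, float(height_mm)))


def detect_checkers(frame: RgbdFrame, ref: DepthReference, board: BoardModel,
                    hand: HandObservation | None, cal: Calibration,
                    cfg: MjtConfig = DEFAULT_CONFIG) -> list:
    """Checker-group detections for one frame: list of (frame_index, height_mm).

    Foreground pixels are those inside the board footprint that rose more than
    ``checker_elev_mm`` above the static depth reference.  4-connected groups
    with a longest extent between 0.5 and 2 checker diameters (inclusive),
    centroid inside the board footprint, and strictly more than
    ``checker_hand_mm`` from every hand pixel are logged with their mean
    height above the board surface.
    """
    depth = frame.depth.astype(float)
    elev = ref.ref_depth - depth          # + = nearer to sensor than the reference
    fg = (elev > cfg.checker_elev_mm) & board.board_region
    labels, n = ndimage.label(fg, structure=FOUR_CONNECTED)
    if n == 0:
        return []
    lo = cfg.checker_extent_lo * cfg.checker_diameter_mm
    hi = cfg.checker_extent_hi * cfg.checker_diameter_mm
    tree = cKDTree(hand.coords) if (hand is not None and hand.present) else None
    out = []
    slices = ndimage.find_objects(labels)
    for lab in range(1, n + 1):
        sl = slices[lab - 1]
        rr, cc = np.nonzero(labels[sl] == lab)
        rr, cc = rr + sl[0].start, cc + sl[1].start
        ext = group_extent_mm(rr, cc, cal)
        if not (lo <= ext <= hi):
            continue
        cen = (int(round(rr.mean())), int(round(cc.mean())))
        if not board.board_region[cen[0], cen[1]]:
            continue
        if tree is not None:
            d_px, _ = tree.query(np.column_stack([rr, cc]))
            if not (d_px.min() * cal.mm_per_px > cfg.checker_hand_mm):
                continue
        height = float((board.board_surface_depth_mm - depth[rr, cc]).mean())
        out.append((frame.index, height))
    return out


def count_stacked(entry_height_mm: float, D: float = 6.0) -> int:
    """Stack count from one checker-log height.

    The four candidate intervals are (D ± 0.5·D)·n for n = 1..4; among the
    intervals containing the height, the n whose expected stack height D·n is
    nearest wins (ties to the smaller n).  A height outside every interval
    counts as 0 and is ignored by the finish logic.
    """
    best, best_err = 0, np.inf
    for n in range(1, 5):
        if 0.5 * D * n <= entry_height_mm <= 1.5 * D * n:
            err = abs(entry_height_mm - D * n)
            if err < best_err:
                best, best_err = n, err
    return best
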