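"""Per-frame hand segmentation and the distal-centroid distance series.

The hand is any 4-connected group of at least ``min_hand_px`` pixels that are
more than 30 mm nearer to the sensor than the surface directly beneath them
(table top, board top, or ridge top, depending on where the pixel lies) and
that lie inside the table region.  With several qualifying groups the largest
is taken and a diagnostic is recorded.

All timing logic tracks the *distal centroid*: the centroid of the hand
pixels that lie within 10 mm (along the proximal–distal row axis) of the hand
pixel farthest from the table's front edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .config import DEFAULT_CONFIG, MjtConfig
from .recording_io import Calibration, Recording, RgbdFrame
from .scene_geometry import FOUR_CONNECTED, BoardModel, TableModel

__all__ = ["HandObservation", "DistanceSeries", "detect_hand",
           "distal_centroid", "distance_series", "local_surface_map"]


@dataclass
class HandObservation:
    """Hand segmentation result for one frame; ``present=False`` is a valid
    outcome and leaves the geometric fields as ``None``."""

    frame_index: int
    present: bool
    coords: np.ndarray | None = None        # (N, 2) array of (row, col)
    centroid: tuple | None = None
    distal_centroid: tuple | None = None
    diagnostics: list = field(default_factory=list)

    @property
    def n_pixels(self) -> int:
        return 0 if self.coords is None else len(self.coords)

    def mask(self, shape) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        if self.present:
            m[self.coords[:, 0], self.coords[:, 1]] = True
        return m


@dataclass
class DistanceSeries:
    """Per-frame distance (mm) from the distal centroid to a reference;
    NaN marks frames where the hand was absent."""

    values: np.ndarray
    reference: object

    def __len__(self):
        return len(self.values)


def local_surface_map(shape, table: TableModel, board: BoardModel | None) -> np.ndarray:
    """Per-pixel depth of the supporting surface: ridge top where the ridge
    is, board top over the board footprint, table top elsewhere."""
    surf = np.full(shape, table.surface_depth_mm, dtype=float)
    if board is not None:
        surf[board.board_region] = board.board_surface_depth_mm
        surf[board.ridge_mask] = board.ridge_top_depth_mm
    return surf


def detect_hand(frame: RgbdFrame, table: TableModel, board: BoardModel | None,
                cal: Calibration, cfg: MjtConfig = DEFAULT_CONFIG) -> HandObservation:
    depth = frame.depth.astype(float)
    surf = local_surface_map(depth.shape, table, board)
    cand = (depth < surf - cfg.hand_height_mm) & table.table_mask
    labels, n = ndimage.label(cand, structure=FOUR_CONNECTED)
    obs = HandObservation(frame_index=frame.index, present=False)
    if n == 0:
        return obs
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    qualifying = np.flatnonzero(sizes >= cfg.min_hand_px) + 1
    if qualifying.size == 0:
        return obs
    if qualifying.size > 1:
        obs.diagnostics.append(
            f"frame {frame.index}: {qualifying.size} qualifying components, taking the largest")
    best = qualifying[np.argmax(sizes[qualifying - 1])]
    rr, cc = np.nonzero(labels == best)
    obs.present = True
    obs.coords = np.column_stack([rr, cc])
    obs.centroid = (float(rr.mean()), float(cc.mean()))
    obs.distal_centroid = distal_centroid(obs, table.edge_row, cal, cfg)
    return obs


def distal_centroid(hand: HandObservation, edge_row: int, cal: Calibration,
                    cfg: MjtConfig = DEFAULT_CONFIG) -> tuple:
    """Centroid of the hand pixels within ``distal_band_mm`` (row distance) of
    the hand pixel most distal to the table's front edge.

    Under the top-down orientation the front edge is at the bottom of the
    image, so "most distal" is the smallest row index.
    """
    if not hand.present:
        raise ValueError("distal_centroid requires a present hand")
    rows = hand.coords[:, 0]
    r_min = rows.min()
    band = (rows - r_min) * cal.mm_per_px <= cfg.distal_band_mm
    sel = hand.coords[band]
    return (float(sel[:, 0].mean()), float(sel[:, 1].mean()))


def reference_distance_mm(dc: tuple, reference, cal: Calibration) -> float:
    """Distance in table-plane mm from a distal centroid to a reference.

    ``reference`` is ``("edge", edge_row)`` (perpendicular distance, 0 mm at
    the edge), ``("point", (row, col))`` (Euclidean), or ``("circle", can)``
    (signed distance to the rim, positive outside).
    """
    kind = reference[0]
    if kind == "edge":
        return (reference[1] - dc[0]) * cal.mm_per_px
    if kind == "point":
        pr, pc = reference[1]
        return float(np.hypot(dc[0] - pr, dc[1] - pc)) * cal.mm_per_px
    if kind == "circle":
        can = reference[1]
        d_center = float(np.hypot(dc[0] - can.center[0], dc[1] - can.center[1]))
        return (d_center - can.radius_px) * cal.mm_per_px
    raise ValueError(f"unknown reference kind: {kind}")


def distance_series(rec: Recording, reference, table: TableModel,
                    board: BoardModel | None, cal: Calibration,
                    cfg: MjtConfig = DEFAULT_CONFIG,
                    observations: list | None = None) -> DistanceSeries:
    """Per-frame distal-centroid distance to ``reference``; hand-absent frames
    are NaN gaps.  Precomputed per-frame observations may be supplied to avoid
    segmenting twice."""
    values = np.full(len(rec), np.nan)
    for i, frame in enumerate(rec.frames):
        obs = observations[i] if observations is not None else \
            detect_hand(frame, table, board, cal, cfg)
        if obs.present:
            values[i] = reference_distance_mm(obs.distal_centroid, reference, cal)
    return DistanceSeries(values=values, reference=reference)
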