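"""Detection of the static scene: table, board with ridge, open can, and the
depth reference image.

All detectors run on single images from the start of a recording.  The scene
is viewed top-down, so "proximal" (the subject's side, in front of the table's
front edge) is toward the bottom of the image (larger row index).

Coordinate convention: (row, col), 0-based, row 0 at the top of the image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.draw import circle_perimeter
from skimage.feature import canny
from skimage.transform import hough_circle, hough_circle_peaks

from .config import DEFAULT_CONFIG, MjtConfig
from .errors import (AmbiguousRidgeError, CanNotFoundError, EdgeNotFoundError,
                     RidgeNotFoundError)
from .recording_io import Calibration, Recording

__all__ = [
    "TableModel", "BoardModel", "CanModel", "DepthReference",
    "detect_table", "detect_board", "detect_can", "build_depth_reference",
    "FOUR_CONNECTED",
]

# 4-connectivity: a pixel is connected to the pixels exactly above, below,
# left and right of it.
FOUR_CONNECTED = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass
class TableModel:
    surface_depth_mm: float
    edge_row: int
    table_mask: np.ndarray  # bool H×W, True on the table side of the edge

    def to_dict(self):
        return {"surface_depth_mm": self.surface_depth_mm, "edge_row": int(self.edge_row)}


@dataclass
class BoardModel:
    ridge_mask: np.ndarray        # bool H×W, ridge-top pixels
    ridge_axis: tuple             # ((r0, c0), (r1, c1)) endpoints, float pixels
    board_region: np.ndarray      # bool H×W, reconstructed board footprint
    board_surface_depth_mm: float
    ridge_top_depth_mm: float

    def to_dict(self):
        (r0, c0), (r1, c1) = self.ridge_axis
        return {
            "ridge_axis": [[float(r0), float(c0)], [float(r1), float(c1)]],
            "board_surface_depth_mm": float(self.board_surface_depth_mm),
            "ridge_top_depth_mm": float(self.ridge_top_depth_mm),
        }


@dataclass
class CanModel:
    center: tuple        # (row, col), float pixels
    radius_mm: float
    radius_px: float
    rim_mask: np.ndarray  # bool H×W, one-pixel rim circle

    def to_dict(self):
        return {"center": [float(self.center[0]), float(self.center[1])],
                "radius_mm": float(self.radius_mm)}


@dataclass
class DepthReference:
    ref_depth: np.ndarray  # float H×W, per-pixel mean of the first n_ref frames
    n_ref: int


def group_extent_mm(coords_r, coords_c, cal: Calibration) -> float:
    """Longest bounding-box side of a pixel group, in millimetres.

    An axis-aligned bar of N pixels measures N × mm_per_px, i.e. the pixel
    count is taken as the covered length.
    """
    dr = int(coords_r.max()) - int(coords_r.min()) + 1
    dc = int(coords_c.max()) - int(coords_c.min()) + 1
    return max(dr, dc) * cal.mm_per_px


def detect_table(depth: np.ndarray, cal: Calibration,
                 cfg: MjtConfig = DEFAULT_CONFIG) -> TableModel:
    """Estimate the tabletop depth and the front-edge row.

    The tabletop level is the median of all depth pixels (the table dominates
    the field of view, so the median is robust to any object covering less
    than half of the image).  The binary split classifies a pixel as
    table-side when its depth lies strictly within ``table_split_mm`` of the
    tabletop plane; the front edge is the per-column first table→off-table
    transition scanned toward the bottom of the image, restricted to the
    bottom half, summarised by the median across columns.
    """
    depth = np.asarray(depth, dtype=float)
    h, w = depth.shape
    surface = float(np.median(depth))
    table_side = np.abs(depth - surface) < cfg.table_split_mm

    half = h // 2
    # transition row r: table at r-1, off-table at r, for r in [half, h);
    # edge_row is the first off-table row.
    region = table_side[half - 1:, :]
    trans = region[:-1, :] & ~region[1:, :]          # shape (h-half, w)
    any_trans = trans.any(axis=0)
    if not any_trans.any():
        raise EdgeNotFoundError("edge not found in the bottom half of the image")
    first = np.argmax(trans, axis=0) + half
    edge_row = int(np.median(first[any_trans]))
    mask = np.zeros((h, w), dtype=bool)
    mask[:edge_row, :] = True
    return TableModel(surface_depth_mm=surface, edge_row=edge_row, table_mask=mask)


def detect_board(depth: np.ndarray, table: TableModel, cal: Calibration,
                 cfg: MjtConfig = DEFAULT_CONFIG) -> BoardModel:
    """Detect the board ridge and reconstruct the board footprint.

    Pixels nearer to the sensor than ``board_split_mm`` above the tabletop are
    grouped 4-connected; a group whose longest extent lies within
    ``ridge_length_tol`` of the nominal 508 mm ridge length (inclusive at both
    bounds) is the ridge.  Zero passing groups raise
    :class:`RidgeNotFoundError`; more than one raise
    :class:`AmbiguousRidgeError` — a silent guess would corrupt all
    downstream timing.

    The board top sits only 19 mm above the table, close to sensor noise, so
    the footprint is reconstructed geometrically: a rectangle spanning the
    ridge axis, extended half of the 286 mm board width to each side.  The
    board surface depth is measured from the footprint pixels when enough are
    available and falls back to the nominal 19 mm offset otherwise.
    """
    depth = np.asarray(depth, dtype=float)
    surface = table.surface_depth_mm
    cand = (depth < surface - cfg.board_split_mm) & table.table_mask
    labels, n = ndimage.label(cand, structure=FOUR_CONNECTED)
    lo = cfg.ridge_length_mm * (1 - cfg.ridge_length_tol)
    hi = cfg.ridge_length_mm * (1 + cfg.ridge_length_tol)
    eps = 1e-6      # the band is inclusive; keep exact boundaries robust to FP
    passing = []
    for lab in range(1, n + 1):
        rr, cc = np.nonzero(labels == lab)
        ext = group_extent_mm(rr, cc, cal)
        if lo - eps <= ext <= hi + eps:
            passing.append((lab, rr, cc))
    if not passing:
        raise RidgeNotFoundError(
            f"ridge not found: no group with extent in [{lo:.1f}, {hi:.1f}] mm")
    if len(passing) > 1:
        raise AmbiguousRidgeError(f"ambiguous ridge: {len(passing)} groups pass the length filter")

    lab, rr, cc = passing[0]
    ridge_mask = labels == lab
    ridge_top = float(np.median(depth[ridge_mask]))

    # principal axis of the ridge pixels
    pts = np.column_stack([rr, cc]).astype(float)
    center = pts.mean(axis=0)
    d = pts - center
    cov = d.T @ d
    evals, evecs = np.linalg.eigh(cov)
    u = evecs[:, np.argmax(evals)]          # unit vector along the ridge
    t = d @ u
    p0 = center + u * t.min()
    p1 = center + u * t.max()
    axis_len_px = float(t.max() - t.min()) + 1.0

    # board footprint: rectangle along the axis, ± half board width across it
    v = np.array([-u[1], u[0]])
    half_w_px = (cfg.board_width_mm / 2.0) / cal.mm_per_px
    h, w = depth.shape
    rgrid, cgrid = np.mgrid[0:h, 0:w]
    rel_r = rgrid - center[0]
    rel_c = cgrid - center[1]
    along = rel_r * u[0] + rel_c * u[1]
    across = rel_r * v[0] + rel_c * v[1]
    board_region = (np.abs(along) <= axis_len_px / 2.0) & \
                   (np.abs(across) <= half_w_px) & table.table_mask

    # measure the board top where possible, else use the nominal height
    meas_mask = board_region & ~ndimage.binary_dilation(ridge_mask, structure=FOUR_CONNECTED,
                                                        iterations=2)
    meas = depth[meas_mask]
    meas = meas[(meas < surface - cfg.checker_elev_mm) & (meas > surface - cfg.board_split_mm)]
    if meas.size >= 50:
        board_surface = float(np.median(meas))
    else:
        board_surface = surface - cfg.board_height_mm

    return BoardModel(ridge_mask=ridge_mask, ridge_axis=(tuple(p0), tuple(p1)),
                      board_region=board_region, board_surface_depth_mm=board_surface,
                      ridge_top_depth_mm=ridge_top)


def detect_can(rgb: np.ndarray, search_region: np.ndarray, cal: Calibration,
               cfg: MjtConfig = DEFAULT_CONFIG) -> CanModel:
    """Locate the open can with the Circle Hough Transform.

    All circles found in the configured radius window whose centre lies in
    ``search_region`` are scored; the circle whose diameter in millimetres is
    closest to the nominal 100 mm can diameter wins, ties broken by the higher
    Hough accumulator vote.
    """
    gray = np.asarray(rgb, dtype=float).mean(axis=2) / 255.0
    region = np.asarray(search_region, dtype=bool)
    edges = canny(gray, sigma=1.0, mask=region)
    rmin, rmax = cfg.can_radius_window_px
    rmax = min(int(rmax), max(gray.shape))
    radii = np.arange(int(rmin), int(rmax) + 1)
    if radii.size == 0 or not edges.any():
        raise CanNotFoundError("can not found: no edges in the search region")
    acc = hough_circle(edges, radii)
    votes, ccs, rrs, rads = hough_circle_peaks(acc, radii, total_num_peaks=12)
    best = None
    for vote, cc, rr, rad in zip(votes, ccs, rrs, rads):
        if not (0 <= rr < region.shape[0] and 0 <= cc < region.shape[1]):
            continue
        if not region[int(rr), int(cc)]:
            continue
        diam_mm = 2.0 * float(rad) * cal.mm_per_px
        key = (abs(diam_mm - cfg.can_diameter_mm), -float(vote))
        if best is None or key < best[0]:
            best = (key, float(rr), float(cc), float(rad))
    if best is None:
        raise CanNotFoundError("can not found: no Hough circle in the search region")
    _, rr, cc, rad = best
    rim = np.zeros(region.shape, dtype=bool)
    pr, pc = circle_perimeter(int(round(rr)), int(round(cc)), int(round(rad)),
                              shape=region.shape)
    rim[pr, pc] = True
    return CanModel(center=(rr, cc), radius_mm=rad * cal.mm_per_px,
                    radius_px=rad, rim_mask=rim)


def build_depth_reference(rec: Recording, n_ref: int = 15) -> DepthReference:
    """Per-pixel arithmetic mean depth over the first ``n_ref`` frames."""
    if n_ref < 1:
        raise ValueError("n_ref must be >= 1")
    if len(rec) < n_ref:
        raise ValueError(f"recording has {len(rec)} frames, need {n_ref} for the reference")
    stack = np.stack([rec[i].depth.astype(float) for i in range(n_ref)])
    return DepthReference(ref_depth=stack.mean(axis=0), n_ref=n_ref)
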