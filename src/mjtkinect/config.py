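"""Configuration of every numeric constant used by the detectors.

All thresholds are stated in millimetres at the table plane (the instrument's
item dimensions are metric); pixel counts are stated as pixel counts.  The
defaults are the package's standard operating points; every one
of them can be overridden from a YAML or JSON file so that alternative
conventions can be reproduced.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass
class MjtConfig:
    # -- sensor / geometry ------------------------------------------------
    frame_rate: float = 30.0          # frames per second
    mm_per_px: float = 2.0            # pixel scale at the table plane
    sensor_height_mm: float = 1200.0  # nominal sensor-to-table distance

    # -- table detection --------------------------------------------------
    table_split_mm: float = 300.0     # off-plane band half-width for the binary split

    # -- board / ridge detection ------------------------------------------
    board_split_mm: float = 50.0      # segmentation level above the table surface
    ridge_length_mm: float = 508.0    # nominal ridge length
    ridge_length_tol: float = 0.20    # ± fractional acceptance band
    board_width_mm: float = 286.0
    board_height_mm: float = 19.0
    ridge_height_mm: float = 51.0

    # -- open-can detection -----------------------------------------------
    can_diameter_mm: float = 100.0
    can_radius_window_px: tuple = (10, 80)   # Hough radius candidates, pixels
    can_search_window_mm: float = 300.0      # square search window side
    can_search_offset_mm: float = 150.0      # proximal offset from ridge midpoint

    # -- hand detection ---------------------------------------------------
    hand_height_mm: float = 30.0      # minimum elevation above the local surface
    min_hand_px: int = 50             # minimum connected-component size (inclusive)
    distal_band_mm: float = 10.0      # distal band for the tracked centroid
    max_gap_frames: int = 5           # tolerated consecutive hand-absent frames

    # -- card detection ---------------------------------------------------
    marker_min_px: int = 10           # minimum green-marker group size (inclusive)
    marker_hand_excl_mm: float = 10.0 # markers closer than this to the hand are ignored
    track_join_mm: float = 5.0        # centroid clustering radius
    track_confirm_frames: int = 15    # support needed to confirm a turned card
    n_cards: int = 5
    card_spacing_mm: float = 51.0
    item_offset_mm: float = 127.0     # card row / board distance from the table edge

    # -- bean detection ---------------------------------------------------
    bean_diff_threshold: float = 25.5   # 10% of the 0–255 grayscale range, strict >
    bean_merge_mm: float = 5.0
    bean_min_px: int = 5
    bean_max_px: int = 50
    bean_max_extent_mm: float = 15.0    # strict <
    bean_hand_rim_mm: float = 50.0      # hand must be closer than this to the rim
    bean_rearm_ridge_mm: float = 30.0   # re-arm when the hand returns to the ridge
    n_beans: int = 5

    # -- checker detection ------------------------------------------------
    n_ref_frames: int = 15            # frames averaged into the depth reference
    checker_height_mm: float = 6.0    # D, height of one checker
    checker_diameter_mm: float = 30.0
    checker_elev_mm: float = 5.0      # minimum elevation above the board (strict >)
    checker_extent_lo: float = 0.5    # extent band, × diameter (inclusive)
    checker_extent_hi: float = 2.0
    checker_hand_mm: float = 30.0     # minimum distance to any hand pixel (strict >)
    n_checkers: int = 4
    stack_consecutive: int = 5        # consecutive interval-4 detections to finish
    ref_static_mm: float = 3.0        # mean |Δdepth| warning level for the reference

    # -- start / finish detection -----------------------------------------
    card_cross_mm: float = 127.0      # hand crosses the proximal card edge
    feeding_cross_mm: float = 147.0   # 20 mm past the proximal board edge
    stacking_cross_mm: float = 63.5   # within 3.5 mm of the outer checkers
    stacking_point_offset_mm: float = 15.0  # start point in front of the board edge
    onset_mm_per_frame: float = 3.0   # minimum sustained displacement (inclusive)
    feeding_end_rim_mm: float = 20.0  # hand must retreat past this rim distance
    end_latency_frames: int = 0       # optional back-dating of the card end time

    # ----------------------------------------------------------------------
    def replace(self, **kw) -> "MjtConfig":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["can_radius_window_px"] = list(self.can_radius_window_px)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "MjtConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "can_radius_window_px" in d:
            d["can_radius_window_px"] = tuple(d["can_radius_window_px"])
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "MjtConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data or {})

    def to_file(self, path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2))
        else:
            path.write_text(yaml.safe_dump(self.to_dict()))


DEFAULT_CONFIG = MjtConfig()
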