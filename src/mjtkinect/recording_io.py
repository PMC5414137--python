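"""Reading and writing RGB-D recordings and timing tables.

A recording is an ordered sequence of paired frames: an 8-bit RGB image and a
16-bit depth image whose pixel values are distances from the sensor in
millimetres.  On disk a recording is either a directory of losslessly
compressed PNGs (``rgb_0000.png`` / ``depth_0000.png`` …) or a single NPZ
archive with arrays ``rgb`` (T×H×W×3) and ``depth`` (T×H×W).

The module also owns the pixel↔millimetre calibration used by every detector:
at a ~1200 mm mounting height a single planar scale at the table plane is an
adequate model, so ``px_to_mm`` is plain linear scaling.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .errors import CorruptRecordingError, EmptyRecordingError, TimesTableError

__all__ = [
    "RgbdFrame", "Recording", "Calibration", "TimesTable",
    "load_recording", "save_recording", "px_to_mm", "mm_to_px",
    "read_times_csv", "write_times_csv",
]

MIN_IMAGE_SIDE = 64


@dataclass
class RgbdFrame:
    """One time point: RGB image, depth image (mm) and frame ordinal."""

    rgb: np.ndarray
    depth: np.ndarray
    index: int
    time_s: float = 0.0

    def __post_init__(self):
        self.rgb = np.asarray(self.rgb)
        self.depth = np.asarray(self.depth)
        if self.rgb.ndim != 3 or self.rgb.shape[2] != 3:
            raise ValueError("rgb must be H×W×3")
        if self.depth.shape != self.rgb.shape[:2]:
            raise ValueError("rgb and depth must share H×W")
        h, w = self.depth.shape
        if h < MIN_IMAGE_SIDE or w < MIN_IMAGE_SIDE:
            raise ValueError(f"images must be at least {MIN_IMAGE_SIDE}×{MIN_IMAGE_SIDE}")
        if np.any(self.depth < 0):
            raise ValueError("depth values must be >= 0")

    @property
    def shape(self):
        return self.depth.shape


@dataclass
class Recording:
    """An ordered frame sequence with its frame rate and provenance."""

    frames: list
    frame_rate: float = 30.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")
        for i, f in enumerate(self.frames):
            if f.index != i:
                raise ValueError(f"frame indices must be consecutive from 0, got {f.index} at {i}")
            f.time_s = i / self.frame_rate

    def __len__(self):
        return len(self.frames)

    def __getitem__(self, i):
        return self.frames[i]

    def depth_stack(self) -> np.ndarray:
        return np.stack([f.depth for f in self.frames])

    def rgb_stack(self) -> np.ndarray:
        return np.stack([f.rgb for f in self.frames])


@dataclass(frozen=True)
class Calibration:
    """Planar pixel scale at the table plane plus the nominal mounting height."""

    mm_per_px: float = 2.0
    sensor_height_mm: float = 1200.0

    def __post_init__(self):
        if self.mm_per_px <= 0:
            raise ValueError("mm_per_px must be > 0")


def px_to_mm(d_px, cal: Calibration):
    """Convert a pixel distance at the table plane to millimetres (linear)."""
    return np.asarray(d_px, dtype=float) * cal.mm_per_px if np.ndim(d_px) else float(d_px) * cal.mm_per_px


def mm_to_px(d_mm, cal: Calibration) -> int:
    """Convert millimetres to an integer pixel count, rounding half-up."""
    return int(np.floor(d_mm / cal.mm_per_px + 0.5))


# ---------------------------------------------------------------------------
# recordings on disk

_FRAME_RE = re.compile(r"(rgb|depth)_(\d+)\.png$")


def save_recording(rec: Recording, path) -> None:
    """Write a recording as paired PNGs in a directory or as one NPZ archive.

    A ``path`` ending in ``.npz`` selects the archive format; anything else is
    treated as a directory.  Round trip through :func:`load_recording` is
    bit-exact (16-bit grayscale PNG for depth, 8-bit PNG for RGB).
    """
    if len(rec) == 0:
        raise EmptyRecordingError("cannot save an empty recording")
    path = Path(path)
    if path.suffix == ".npz":
        path.parent.mkdir(parents=True, exist_ok=True)
        np.savez_compressed(
            path,
            rgb=rec.rgb_stack().astype(np.uint8),
            depth=rec.depth_stack().astype(np.uint16),
            frame_rate=np.float64(rec.frame_rate),
        )
        return
    path.mkdir(parents=True, exist_ok=True)
    for f in rec.frames:
        iio.imwrite(path / f"rgb_{f.index:04d}.png", np.asarray(f.rgb, dtype=np.uint8))
        iio.imwrite(path / f"depth_{f.index:04d}.png", np.asarray(f.depth, dtype=np.uint16))


def load_recording(path, frame_rate: float = 30.0) -> Recording:
    """Load a recording saved by :func:`save_recording`.

    Directories must contain ``rgb_<index>.png`` / ``depth_<index>.png`` pairs
    with a sortable numeric index; a missing or mismatched pair raises
    :class:`CorruptRecordingError` naming the first bad index.
    """
    path = Path(path)
    if path.is_file() and path.suffix == ".npz":
        with np.load(path) as z:
            if "rgb" not in z or "depth" not in z:
                raise CorruptRecordingError(0, "archive lacks 'rgb'/'depth' arrays")
            rgb, depth = z["rgb"], z["depth"]
            rate = float(z["frame_rate"]) if "frame_rate" in z else frame_rate
        if rgb.shape[0] == 0:
            raise EmptyRecordingError(f"empty recording archive: {path}")
        frames = [RgbdFrame(rgb=rgb[i], depth=depth[i], index=i) for i in range(rgb.shape[0])]
        return Recording(frames, frame_rate=rate, meta={"source": str(path)})

    if not path.is_dir():
        raise EmptyRecordingError(f"no recording at {path}")
    rgb_idx, depth_idx = {}, {}
    for p in path.iterdir():
        m = _FRAME_RE.search(p.name)
        if m:
            (rgb_idx if m.group(1) == "rgb" else depth_idx)[int(m.group(2))] = p
    if not rgb_idx and not depth_idx:
        raise EmptyRecordingError(f"empty recording directory: {path}")
    indices = sorted(rgb_idx.keys() | depth_idx.keys())
    for want, got in enumerate(indices):
        if got != want:
            raise CorruptRecordingError(want, f"corrupt recording: missing frame index {want}")
    frames = []
    for i in indices:
        if i not in rgb_idx or i not in depth_idx:
            raise CorruptRecordingError(i)
        rgb = iio.imread(rgb_idx[i])
        depth = iio.imread(depth_idx[i])
        try:
            frames.append(RgbdFrame(rgb=rgb, depth=depth.astype(np.uint16), index=i))
        except ValueError as e:
            raise CorruptRecordingError(i, f"corrupt recording at index {i}: {e}") from e
    return Recording(frames, frame_rate=frame_rate, meta={"source": str(path)})


# ---------------------------------------------------------------------------
# timing tables

TIMES_COLUMNS = ["subject_id", "repetition", "hand", "subtest", "method",
                 "start_s", "end_s", "total_s"]
_HANDS = {"most", "least"}
_SUBTESTS = {"card", "feeding", "stacking"}
_METHODS = {"therapist", "kinect", "ground_truth"}
_TOTAL_ATOL = 1e-9


class TimesTable:
    """Long-format table of subtest times: one row per
    (subject, repetition, hand, subtest, method)."""

    def __init__(self, df: pd.DataFrame):
        self.df = self.validate(df)

    @staticmethod
    def validate(df: pd.DataFrame) -> pd.DataFrame:
        for col in TIMES_COLUMNS:
            if col not in df.columns:
                raise TimesTableError(f"missing column: {col}")
        df = df[TIMES_COLUMNS].copy()
        df["repetition"] = df["repetition"].astype(int)
        for col in ("start_s", "end_s", "total_s"):
            df[col] = df[col].astype(float)
        bad = ~df["hand"].isin(_HANDS)
        if bad.any():
            raise TimesTableError(f"invalid hand value in row {int(np.flatnonzero(bad)[0])}")
        bad = ~df["subtest"].isin(_SUBTESTS)
        if bad.any():
            raise TimesTableError(f"invalid subtest value in row {int(np.flatnonzero(bad)[0])}")
        bad = ~df["method"].isin(_METHODS)
        if bad.any():
            raise TimesTableError(f"invalid method value in row {int(np.flatnonzero(bad)[0])}")
        resid = np.abs(df["total_s"] - (df["end_s"] - df["start_s"]))
        bad = (resid > _TOTAL_ATOL) | (df["total_s"] < 0)
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise TimesTableError(f"total_s != end_s - start_s in row {row}")
        return df.reset_index(drop=True)

    def __len__(self):
        return len(self.df)

    def __eq__(self, other):
        return isinstance(other, TimesTable) and self.df.equals(other.df)

    def select(self, **kw) -> "TimesTable":
        df = self.df
        for k, v in kw.items():
            df = df[df[k] == v]
        return TimesTable(df.reset_index(drop=True)) if len(df) else TimesTable(
            pd.DataFrame(columns=TIMES_COLUMNS).astype(self.df.dtypes.to_dict()))


def read_times_csv(path) -> TimesTable:
    df = pd.read_csv(path, float_precision="round_trip")
    return TimesTable(df)


def write_times_csv(tbl: TimesTable, path) -> None:
    # 17 significant digits guarantee an exact IEEE-double round trip
    tbl.df.to_csv(path, index=False, float_format="%.17g")
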