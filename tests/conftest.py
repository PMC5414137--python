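import numpy as np
import pytest

from mjtkinect.config import MjtConfig
from mjtkinect.hand_tracking import HandObservation
from mjtkinect.recording_io import Calibration, Recording, RgbdFrame
from mjtkinect.scene_geometry import TableModel


@pytest.fixture
def cal2() -> Calibration:
    return Calibration(mm_per_px=2.0)


@pytest.fixture
def cfg() -> MjtConfig:
    return MjtConfig()


def make_frame(depth, rgb=None, index=0) -> RgbdFrame:
    depth = np.asarray(depth)
    if rgb is None:
        rgb = np.full(depth.shape + (3,), 128, dtype=np.uint8)
    return RgbdFrame(rgb=rgb, depth=depth, index=index)


def make_recording(depths, rgbs=None, frame_rate=30.0) -> Recording:
    frames = []
    for i, d in enumerate(depths):
        rgb = None if rgbs is None else rgbs[i]
        frames.append(make_frame(d, rgb=rgb, index=i))
    return Recording(frames, frame_rate=frame_rate)


def flat_table(h=80, w=80, surface=1200.0, edge_row=70) -> TableModel:
    mask = np.zeros((h, w), dtype=bool)
    mask[:edge_row, :] = True
    return TableModel(surface_depth_mm=surface, edge_row=edge_row, table_mask=mask)


def hand_obs(coords, frame_index=0, distal=None) -> HandObservation:
    coords = np.asarray(coords)
    obs = HandObservation(frame_index=frame_index, present=True, coords=coords)
    obs.centroid = (float(coords[:, 0].mean()), float(coords[:, 1].mean()))
    obs.distal_centroid = distal if distal is not None else obs.centroid
    return obs
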