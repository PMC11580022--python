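import numpy as np
import pytest

from memtide import drag


def build_track(frames, contours) -> drag.DragTrack:
    """Assemble a DragTrack from the frames/contours table pair."""
    track_frames = []
    for i, row in enumerate(frames.itertuples(index=False)):
        track_frames.append(drag.DragFrame(
            time=row.time_s,
            contour=contours[contours["frame"] == i][
                ["x_um", "y_um"]].to_numpy(),
            base=np.array([row.base_x_um, row.base_y_um]),
            bead_center=np.array([row.bead_x_um, row.bead_y_um]),
            total_force=row.force_pN))
    return drag.DragTrack(frames=track_frames)


@pytest.fixture
def track_builder():
    return build_track


def circle_contour(radius=5.0, n=64, center=(0.0, 0.0)):
    ang = 2.0 * np.pi * np.arange(n) / n
    return np.column_stack([center[0] + radius * np.cos(ang),
                            center[1] + radius * np.sin(ang)])


@pytest.fixture
def circle():
    return circle_contour
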