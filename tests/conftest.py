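import numpy as np
import pytest

import gedikit as gk


@pytest.fixture(scope="session")
def timelapse_small():
    """A modest death-assay simulation shared by segmentation/tracking tests."""
    cfg = gk.SimulationConfig(seed=11, n_cells=40, fov_shape=(400, 400))
    stack, truth = gk.simulate_timelapse(cfg)
    return stack, truth, cfg


@pytest.fixture(scope="session")
def foci_stack_live():
    """Live 53BP1-style foci simulation (red reporter channel)."""
    cfg = gk.SimulationConfig(
        seed=21,
        n_cells=60,
        fov_shape=(700, 700),
        cell_radius_px=20,
        timepoints_h=(0.0, 3.0, 9.0, 20.0),
        radiation_dose_Gy=4.0,
    )
    stack, truth = gk.simulate_foci_images(cfg, marker="red")
    return stack, truth, cfg


@pytest.fixture(scope="session")
def calibration_default():
    """Threshold calibration from simulated baseline/lethal-dose imaging."""
    base = gk.SimulationConfig(n_cells=100, fov_shape=(512, 512))
    return gk.calibrate_from_simulation(base, n_cells=100, seed=99)


def match_tracks_to_truth(tracks, truth, timepoint_h):
    """Map each track to the nearest ground-truth cell at a frame time."""
    from scipy.spatial import cKDTree

    tp = truth.per_timepoint
    frame = tp[(tp["timepoint_h"] == timepoint_h) & tp["present"]]
    tree = cKDTree(np.c_[frame["row"], frame["col"]])
    out = {}
    for tr in tracks:
        for m in tr.measurements:
            if m.timepoint_h == timepoint_h:
                d, idx = tree.query(m.centroid)
                out[tr.cell_id] = (int(frame["cell_id"].iloc[idx]), float(d))
                break
    return out
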