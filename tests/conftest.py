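"""Shared simulated fixtures: small wells and plates generated at test time."""

import numpy as np
import pytest

import micropattern as mp


@pytest.fixture(scope="session")
def single_colony():
    """One complete colony, 500 nuclei, default noise."""
    cfg = mp.SimConfig(n_colonies_per_well=1, nuclei_per_colony=500, seed=42)
    image, truth = mp.generate_well(cfg, "A1", seed=42, line="ctrl")
    return cfg, image, truth


@pytest.fixture(scope="session")
def segmented_single(single_colony):
    cfg, image, truth = single_colony
    seg = mp.detect_nuclei(image)
    seg.table = mp.measure_intensities(image, seg)
    return cfg, image, truth, seg


@pytest.fixture(scope="session")
def five_colony_well():
    """Five well-separated colonies, lighter nuclei load for speed."""
    cfg = mp.SimConfig(n_colonies_per_well=5, nuclei_per_colony=400, seed=7)
    image, truth = mp.generate_well(cfg, "A1", seed=7, line="ctrl")
    return cfg, image, truth


@pytest.fixture(scope="session")
def noiseless_single():
    cfg = mp.SimConfig(n_colonies_per_well=1, nuclei_per_colony=300,
                       noise_sd=0.0, seed=11)
    image, truth = mp.generate_well(cfg, "A1", seed=11, line="ctrl")
    return cfg, image, truth


@pytest.fixture(scope="session")
def small_plate():
    """Two lines (one control) across three wells, reduced colony load."""
    layout = mp.PlateLayout(
        wells={
            "A1": mp.WellInfo("uoxz_4", "uoxz", "exp1", "rep1"),
            "A2": mp.WellInfo("uoxz_4", "uoxz", "exp1", "rep2"),
            "B1": mp.WellInfo("ffdc_5", "ffdc", "exp1", "rep1"),
        },
        channels={0: "DAPI", 1: "SOX2", 2: "BRA", 3: "SOX17"},
        pixel_size_um=2.0,
        control_line="uoxz_4",
    )
    cfg = mp.SimConfig(
        n_colonies_per_well=4, nuclei_per_colony=500, seed=3,
        plate_layout={w: {"line": info.line} for w, info in layout.wells.items()},
        donor_effects={"ffdc_5": {"SOX17": mp.DonorEffect(center_shift_um=-200.0)}},
    )
    images, truth = mp.generate_plate(cfg, seed=3)
    return cfg, layout, images, truth


@pytest.fixture(scope="session")
def small_plate_result(small_plate):
    cfg, layout, images, truth = small_plate
    result = mp.run_pipeline(images, layout)
    return cfg, layout, truth, result


def match_to_truth(detected_xy: np.ndarray, truth_xy: np.ndarray):
    """Nearest-neighbour match of detections to ground-truth nuclei.

    Returns the distance from each truth point to its nearest detection.
    """
    from scipy.spatial import cKDTree
    tree = cKDTree(detected_xy)
    d, _ = tree.query(truth_xy)
    return d
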