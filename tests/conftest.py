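"""Shared fixtures: a rendered phantom stack and a calibrated lambda table."""

import warnings

import pytest

from toothbox.division import calibrate_lambdas, default_lambda_table
from toothbox.geometry import block_teeth
from toothbox.phantom import PhantomConfig, generate_stack


@pytest.fixture(scope="session")
def phantom():
    """Default full-dentition phantom: (config, stack, truth)."""
    cfg = PhantomConfig(seed=7)
    stack, truth = generate_stack(cfg)
    return cfg, stack, truth


def calibration_samples(truth, slice_indices):
    """(block box, tooth -> truth box) samples from phantom ground truth."""
    samples = []
    for sl in slice_indices:
        for bid, bbox in truth.block_boxes[sl].items():
            teeth = {t: truth.boxes[sl][t] for t in block_teeth(bid)}
            samples.append((bbox, teeth))
    return samples


@pytest.fixture(scope="session")
def calibrated_table(phantom):
    """Lambda table calibrated against one lower and one upper crown slice."""
    _, _, truth = phantom
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table, achieved = calibrate_lambdas(
            calibration_samples(truth, (10, 25)),
            default_lambda_table(),
            target_mean_iou=0.99,
        )
    assert achieved > 0.9  # sanity: downstream tests assume a usable table
    return table
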