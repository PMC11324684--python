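import numpy as np
import pytest

from ismn.segmentation import SegmentationConfig
from ismn.synthgen import CellSpec, generate_cell


@pytest.fixture(scope="session")
def seg_cfg():
    return SegmentationConfig()


def easy_spec(rng, mn_count=None, stages=("G1", "S", "G2")):
    """A noise-free, well-separated cell spec (detection-friendly)."""
    k = int(rng.integers(0, 4)) if mn_count is None else mn_count
    return CellSpec(
        cycle_stage=stages[int(rng.integers(0, len(stages)))],
        mn_count=k,
        mn_diameters_um=tuple(float(x) for x in rng.uniform(1.5, 3.0, size=k)),
        focus_sigma_px=0.8,
        noise_sd=0.0,
        seed=int(rng.integers(2**31)),
    )


@pytest.fixture(scope="session")
def plain_cell():
    """One MN-free G1 cell with default noise, plus its ground truth."""
    spec = CellSpec(seed=123)
    return generate_cell(spec)


@pytest.fixture(scope="session")
def mn_cell():
    """A G1 cell with two well-separated micronuclei, noise-free."""
    spec = CellSpec(
        mn_count=2, mn_diameters_um=(2.0, 2.5), noise_sd=0.0, seed=321
    )
    return generate_cell(spec)
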