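"""Shared fixtures: small synthetic tissues and derived stacks."""

import numpy as np
import pytest

from furrowquant import synthgen


@pytest.fixture(scope="session")
def cylinder_tissue():
    """4x4 grid of columnar cells, 26 slices long, noiseless."""
    program = synthgen.ShapeProgram.columnar(area=36.0, length=26.0,
                                             n_frames=1)
    cfg = synthgen.TissueConfig(
        shape_program=program, grid_shape=(4, 4), cell_footprint=7.0,
        n_slices=30, dz=1.0, pixel_size=0.2, noise_sd=0.0, seed=0)
    return synthgen.make_tissue(cfg)


@pytest.fixture(scope="session")
def membrane_grid_5x5():
    """5x5 noiseless membrane grid where cells tile the full footprint."""
    program = synthgen.ShapeProgram.columnar(area=36.0, length=12.0,
                                             n_frames=1)
    cfg = synthgen.TissueConfig(
        shape_program=program, grid_shape=(5, 5), cell_footprint=6.0,
        n_slices=14, dz=1.0, pixel_size=0.2, noise_sd=0.0, seed=0)
    return synthgen.make_tissue(cfg)


@pytest.fixture()
def half_masks():
    """Factory: (AR, NR) = left/right half masks for a given (h, w)."""

    def make(shape):
        h, w = shape
        ar = np.zeros((h, w), bool)
        ar[:, : w // 2] = True
        return ar, ~ar

    return make
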