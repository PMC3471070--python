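"""Shared fixtures: small phantoms and fitted orientation-sample fields.

Heavy objects are session-scoped and reused across test modules; everything
is generated programmatically (no stored binary fixtures).
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy import ndimage

from tractquant.core import ball_mask, default_scheme
from tractquant.phantom import make_tract_field, simulate_dwi
from tractquant.tensors import fit_ball_and_stick
from tractquant.tracking import ROISet

GRID = (40, 40, 40)
TUBE_START = np.array([5.0, 20.0, 20.0])
TUBE_END = np.array([35.0, 20.0, 20.0])
TUBE_RADIUS = 2.0


@pytest.fixture(scope="session")
def scheme():
    return default_scheme()


@pytest.fixture(scope="session")
def straight_tube():
    """Straight x-aligned tube phantom: (field, tract_mask)."""
    field, mask = make_tract_field(
        np.stack([TUBE_START, TUBE_END]), TUBE_RADIUS, GRID
    )
    return field, mask


@pytest.fixture(scope="session")
def tube_dwi_noiseless(straight_tube, scheme):
    field, _ = straight_tube
    return simulate_dwi(field, scheme, noise_sigma=0.0)


@pytest.fixture(scope="session")
def tube_samples_noiseless(tube_dwi_noiseless, straight_tube):
    """Ball-and-stick orientation samples on the (dilated) noiseless tube."""
    _, mask = straight_tube
    fitmask = ndimage.binary_dilation(mask, iterations=1)
    return fit_ball_and_stick(tube_dwi_noiseless, fitmask, n_samples=50, rng_seed=1)


@pytest.fixture(scope="session")
def tube_rois():
    seed = ball_mask(GRID, TUBE_START, 1.2)
    target = ball_mask(GRID, TUBE_END, 2.8)
    zeros = np.zeros(GRID, bool)
    return ROISet(seed=seed, targets={"end": target}, exclusion=zeros.copy(),
                  csf=zeros.copy(), gm=zeros.copy())
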