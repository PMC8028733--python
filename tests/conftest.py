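import numpy as np
import pytest

from radiotme.datatypes import DceStudy


def make_study(curves, mask=None, times=(0, 1, 2, 3), spacing=(1.0, 1.0, 1.0),
               baseline=100.0):
    """Build a study whose in-mask voxels follow the given enhancement
    curves.

    ``curves`` maps archetype key -> length-4 enhancement sequence; voxels
    are assigned archetypes round-robin over the mask unless ``curves`` has
    a single entry.
    """
    if mask is None:
        mask = np.zeros((5, 6, 6), dtype=bool)
        mask[1:4, 1:5, 1:5] = True
    mask = np.asarray(mask, dtype=bool)
    keys = list(curves)
    assign = np.zeros(mask.shape, dtype=int)
    assign[mask] = np.arange(int(mask.sum())) % len(keys)
    phases = np.full((4,) + mask.shape, baseline, dtype=float)
    for k, key in enumerate(keys):
        e = np.asarray(curves[key], dtype=float)
        sel = mask & (assign == k)
        for ph in range(4):
            phases[ph][sel] = baseline * (1.0 + e[ph])
    return DceStudy(phases=phases, spacing=spacing, times=times, mask=mask)


@pytest.fixture
def homogeneous_study():
    """Every in-mask voxel enhances with E = (0, 1, 0.8, 0.6)."""
    return make_study({"a": (0.0, 1.0, 0.8, 0.6)})


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
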