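import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracle module

from vertefem.synth import BONE, PMMA_CAP, LabeledVolume, SynthParams, synth_vertebra


def make_block(shape, density=1.0, spacing=(2.0, 2.0, 2.0), cap_thickness=0):
    """Homogeneous rectangular block, optionally with PMMA caps at both ends."""
    labels = np.full(shape, BONE, dtype=np.uint8)
    if cap_thickness:
        labels[:, :, :cap_thickness] = PMMA_CAP
        labels[:, :, -cap_thickness:] = PMMA_CAP
    dens = np.full(shape, float(density))
    return LabeledVolume(density=dens, labels=labels, spacing=spacing,
                         metadata={"shell_thickness": 1, "cap_thickness": cap_thickness,
                                   "specimen_id": "BLOCK", "donor_id": "D0"})


@pytest.fixture(scope="session")
def default_params():
    return SynthParams(seed=7)


@pytest.fixture(scope="session")
def specimen(default_params):
    """One coarse synthetic vertebra shared across read-only tests."""
    return synth_vertebra(default_params)
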