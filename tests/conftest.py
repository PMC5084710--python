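import numpy as np
import pytest
from hypothesis import settings

import apexkit as ak

settings.register_profile("ci", derandomize=True, max_examples=30, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_volume():
    """A tiny noise-free apical dome with 5 planted divisions."""
    params = ak.MeristemSimParams.small(seed=11, noise_sd=0.0)
    vol, inten, frame, truth = ak.generate_meristem(params)
    return vol, inten, frame, truth


@pytest.fixture(scope="session")
def toy_genome_sim():
    """Deterministic toy genome with jittered replicate peaks."""
    return ak.generate_genome_and_peaks(ak.GenomeSimParams(seed=21))


def two_block_volume(intensity_left=100.0, intensity_right=100.0, spacing=(1.0, 1.0, 1.0)):
    """Two 2x2x2 cells sharing a 2x2 face, surrounded by background."""
    labels = np.zeros((4, 4, 6), dtype=np.int32)
    labels[1:3, 1:3, 1:3] = 1
    labels[1:3, 1:3, 3:5] = 2
    values = np.zeros((4, 4, 6), dtype=float)
    values[1:3, 1:3, 2] = intensity_left  # voxels flanking the shared face
    values[1:3, 1:3, 3] = intensity_right
    vol = ak.LabeledVolume(labels=labels, spacing=spacing)
    inten = ak.IntensityVolume(values=values, spacing=spacing)
    return vol, inten
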