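import numpy as np
import pytest

import gmrftex as g


@pytest.fixture(scope="session")
def phantom():
    """Default high-contrast 64x64 phantom, seed 1."""
    return g.make_phantom(seed=1)


@pytest.fixture(scope="session")
def segmented(phantom):
    """Full pipeline segmentation of the session phantom: (init, labels, model)."""
    init = g.gmm_initialize_mri(phantom.mri, seed=1)
    labels, model = g.segment(phantom.mri, init, seed=1)
    return init, labels, model


@pytest.fixture(scope="session")
def nbh():
    return g.build_neighborhood(20)


def accuracy(pred, truth, mask):
    return float((pred.labels[mask] == truth.labels[mask]).mean())


@pytest.fixture(scope="session")
def single_label_field():
    """All-WM 64x64 label field for single-texture simulations."""
    arr = np.full((64, 64), g.LABELS.index("WM"), dtype=np.int64)
    return g.LabelField(arr, g.LABELS)
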