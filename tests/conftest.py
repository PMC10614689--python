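import numpy as np
import pytest

from fuspet import reference


@pytest.fixture(scope="session")
def c4_plasma():
    return reference.plasma_means("C4")


@pytest.fixture(scope="session")
def mut_plasma():
    return reference.plasma_means("C4FcMUT")


@pytest.fixture(scope="session")
def all_tissue_sets():
    """All (format, region) cohort-mean tissue parameter sets."""
    return {
        (fmt, region): reference.tissue_means(fmt, region)
        for fmt in reference.FORMATS
        for region in reference.REGIONS
    }


@pytest.fixture(scope="session")
def week_grid():
    """Dense one-week grid (minutes over the first hour, then 3-min steps)."""
    return np.unique(np.concatenate([np.linspace(0, 1, 361), np.linspace(1, 168, 3341)]))
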