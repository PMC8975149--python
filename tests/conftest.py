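import numpy as np
import pytest

from canet import phantoms, volumes

#: coarse preprocessing grid used with the tiny backbone: an 80 mm crop
#: becomes 10 x 32 x 32
TINY_SPACING = (8.0, 2.5, 2.5)

#: coarse native grid for cheap phantom generation in structural tests
COARSE_GEN_SPACING = (5.0, 1.6, 1.6)


def preprocess_series(series_list, target_spacing=TINY_SPACING):
    return [
        volumes.LongitudinalSeries(
            volumes=[volumes.preprocess(v, target_spacing) for v in s.volumes],
            patient_id=s.patient_id,
            label=s.label,
        )
        for s in series_list
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_cohort():
    """8 benign + 8 malignant phantom series on a cheap grid, raw HU."""
    cfg = phantoms.PhantomConfig(
        n_benign=8, n_malignant=8, spacing=COARSE_GEN_SPACING, seed=11
    )
    series, _ = phantoms.generate_dataset(cfg)
    return series


@pytest.fixture(scope="session")
def small_cohort_tiny(small_cohort):
    """The same cohort preprocessed onto the tiny 10 x 32 x 32 grid."""
    return preprocess_series(small_cohort)
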