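import numpy as np
import pytest

from discseg import dataio, phantom


@pytest.fixture(scope="session")
def small_cohort():
    """113-sample phantom cohort at desk scale (128 px slices), seed-fixed."""
    return phantom.generate_cohort_samples(
        n_patients=10, n_controls=10, slices_per_subject=(4, 7),
        seed=1, image_size=(128, 128),
    )


@pytest.fixture(scope="session")
def small_roi():
    scale = 128 / 512
    return dataio.ROISpec.centered(
        (128, 128), height=round(161 * scale), width=round(184 * scale)
    )


@pytest.fixture(scope="session")
def patch_arrays(small_cohort, small_roi):
    """(x_train, y_train, x_test, y_test) 64x64 patches from the 'both' split."""
    split = dataio.split_dataset(small_cohort, 0.8, seed=1, stratum="both")
    tr = [dataio.preprocess_sample(small_cohort[i], small_roi, (64, 64)) for i in split.train]
    te = [dataio.preprocess_sample(small_cohort[i], small_roi, (64, 64)) for i in split.test]
    x_tr, y_tr = dataio.patches_to_arrays(tr)
    x_te, y_te = dataio.patches_to_arrays(te)
    return x_tr, y_tr, x_te, y_te


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
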