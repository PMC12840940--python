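import numpy as np
import pytest

from plumfusion.preprocess import calibrate_reflectance, make_chain
from plumfusion.regression import train_test_split_ids
from plumfusion.synthetic import (
    SSCGenParams,
    SpectralForwardModel,
    generate_spectra,
    sample_ssc,
)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_cohort():
    """The 120-fruit synthetic cohort at the default study conditions."""
    return sample_ssc(SSCGenParams(seed=0))


@pytest.fixture(scope="session")
def preprocessed_split(default_cohort):
    """Calibrated, SG+SNV-preprocessed spectra with the shared 7:3 split.

    Returns (X_train, X_test, y_train, y_test, wavelengths).
    """
    tab = default_cohort
    raw, dark, white = generate_spectra(tab, seed=0)
    refl = calibrate_reflectance(raw, dark, white)
    y = tab.set_index("sample_id")["ssc_brix"]
    train_ids, test_ids = train_test_split_ids(refl.sample_ids, 0.7, 0)
    chain = make_chain("SG+SNV")
    X_tr = chain.fit_transform(refl.subset(train_ids).intensities)
    X_te = chain.transform(refl.subset(test_ids).intensities)
    return X_tr, X_te, y.loc[train_ids].to_numpy(), y.loc[test_ids].to_numpy(), refl.wavelengths


@pytest.fixture()
def noiseless_forward():
    """Forward model with every stochastic component switched off."""
    return SpectralForwardModel(
        ssc_nuisance_sd=0.0,
        band_noise_sd=0.0,
        baseline_drift_sd=0.0,
        scatter_multiplier_sd=0.0,
        additive_offset_sd=0.0,
        noise_sd=0.0,
    )
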