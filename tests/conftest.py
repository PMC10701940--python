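import numpy as np
import pytest

from chemocal import reference_design, simulate_dataset


@pytest.fixture(scope="session")
def design():
    return reference_design()


@pytest.fixture(scope="session")
def clean_spectra(design):
    """Noise-free mixture spectra of the full 25-run design."""
    return simulate_dataset(design, noise_sd=0.0)


@pytest.fixture(scope="session")
def noisy_spectra(design):
    """Mixture spectra at the default 0.002 a.u. noise level."""
    return simulate_dataset(design, noise_sd=0.002, seed=1)


@pytest.fixture(scope="session")
def cal_val(design, noisy_spectra):
    cal_ids = sorted(design.calibration_ids)
    val_ids = sorted(design.validation_ids)
    return (
        noisy_spectra.rows(cal_ids),
        design.calibration,
        noisy_spectra.rows(val_ids),
        design.validation,
    )


@pytest.fixture(scope="session")
def clean_cal_val(design, clean_spectra):
    cal_ids = sorted(design.calibration_ids)
    val_ids = sorted(design.validation_ids)
    return (
        clean_spectra.rows(cal_ids),
        design.calibration,
        clean_spectra.rows(val_ids),
        design.validation,
    )
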