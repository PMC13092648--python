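import numpy as np
import pytest

import ihmtquant as iq


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Default three-compartment phantom without noise (prescribed ihMTR
    11.5 / 9.0 / 8.0 % for fiber / PMJ / myocardium)."""
    spec = iq.default_phantom_spec(noise_sigma=0.0, n_mt_reps=3, n_m0_reps=2)
    mtset, mask, truth = iq.generate_phantom(spec)
    return spec, mtset, mask, truth


@pytest.fixture(scope="session")
def polarized_image():
    """Synthetic polarized-light image, 70/30 Type I/III split, ~26k collagen
    pixels."""
    truth = iq.HistologyTruth(frac_collagen=40.0, type1_frac=70.0,
                              type3_frac=30.0, seed=11)
    return iq.generate_polarized_histology(truth, size=(256, 256))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
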