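import numpy as np
import pytest

from exoct import phantom
from exoct.measure import measure_slice


@pytest.fixture(scope="session")
def clean_axial_sample():
    """One noise-free axial phantom with watermark strokes."""
    return phantom.render_phantom(
        phantom.random_spec("axial", seed=3, noise_sd=0.0, n_watermarks=2)
    )


@pytest.fixture(scope="session")
def clean_sagittal_sample():
    return phantom.render_phantom(
        phantom.random_spec("sagittal", seed=4, noise_sd=0.0, n_watermarks=2)
    )


@pytest.fixture(scope="session")
def noisy_corpora():
    """The default-condition measurement corpus: 50 phantoms per view."""
    return {
        view: phantom.generate_corpus(view, 50, seed=11) for view in ("axial", "sagittal")
    }


@pytest.fixture(scope="session")
def corpus_measurements(noisy_corpora):
    """Oracle-mask pipeline measurements paired with ground truth, per view."""
    out = {}
    for view, corpus in noisy_corpora.items():
        auto, truth = [], []
        for sample in corpus:
            meas = measure_slice(
                sample.slice, sample.eye_mask_true, phantom.rim_config_for(sample.spec)
            )
            for eye in sample.distance_true_px:
                auto.append(meas.distances_px[eye])
                truth.append(sample.distance_true_px[eye])
        out[view] = (np.array(auto), np.array(truth))
    return out
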