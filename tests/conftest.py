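import numpy as np
import pandas as pd
import pytest

from anxeeg import (GeneratorConfig, apply_fir, concat_epochs,
                    design_bandpass_fir, generate_dataset, segment_epochs)
from anxeeg.spectral import BAND_ORDER, PAIRS, feature_columns
from anxeeg.synth import EFFECT_CHANNELS, ArtifactRates


@pytest.fixture(scope="session")
def fir_spec():
    return design_bandpass_fir(4, 45, 15, "hanning", 128)


@pytest.fixture(scope="session")
def small_recordings():
    """6 subjects x 2 trials x 6 s with artifacts, uniform class prevalence."""
    cfg = GeneratorConfig(n_subjects=6, n_trials=2, trial_seconds=6.0,
                          class_prevalence=(0.25, 0.25, 0.25, 0.25),
                          effect_size=2.0, seed=11)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def small_epochs(small_recordings, fir_spec):
    return concat_epochs([segment_epochs(apply_fir(r, fir_spec))
                          for r in small_recordings])


def make_band_feature_frame(n, seed, effect, bands=("theta", "beta")):
    """Feature table where only the given bands' MP columns carry class signal;
    every other column is independent standard normal noise."""
    rng = np.random.default_rng(seed)
    cols = feature_columns(EFFECT_CHANNELS, BAND_ORDER, PAIRS)
    y = rng.integers(0, 2, n)
    X = rng.normal(size=(n, len(cols)))
    for j, c in enumerate(cols):
        kind, _, band = c.split("_")
        if band in bands and kind == "MP":
            X[:, j] += effect * y
    return pd.DataFrame(X, columns=cols), np.where(y == 1, "high", "low")


@pytest.fixture(scope="session")
def clean_rates():
    return ArtifactRates(blink_rate=0, emg_rate=0, line_amplitude=0)
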