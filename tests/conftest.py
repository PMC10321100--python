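import numpy as np
import pandas as pd
import pytest

from eureka_eeg.epochs import EpochSet
from eureka_eeg.montage import default_montage, montage_1020
from eureka_eeg.synthdata import Oscillation, SynthSpec, generate_epochs


@pytest.fixture(scope="session")
def li_montage():
    return montage_1020()


@pytest.fixture(scope="session")
def dense_montage():
    return default_montage()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_epochs(data, fs=250.0, tmin=-1.0, condition="Aha", stage="third", rt=1.0):
    """Wrap a raw (trials, channels, samples) array in an EpochSet."""
    n = data.shape[0]
    meta = pd.DataFrame(
        {
            "condition": [condition] * n,
            "stage": [stage] * n,
            "alignment": ["stimulus"] * n,
            "rt": [rt] * n,
        }
    )
    names = [f"ch{i}" for i in range(data.shape[1])]
    return EpochSet(data=data, fs=fs, ch_names=names, tmin=tmin, meta=meta)


@pytest.fixture(scope="session")
def coupled_epochs():
    """Small four-cell synthetic set with an always-on alpha coupling."""
    ch = ("C3", "C4", "Fz", "P3", "P4")
    spec = SynthSpec(
        n_trials_per_cell=12,
        channels=ch,
        fs=250.0,
        bands=(Oscillation(channels=ch, f_lo=8, f_hi=12, amplitude=2.0),),
        coupling=(
            Oscillation(channels=("C3", "C4"), f_lo=9, f_hi=11, amplitude=6.0,
                        kappa=8.0, window=(0.0, 0.6)),
        ),
        noise_amplitude=3.0,
        seed=77,
    )
    return generate_epochs(spec)
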