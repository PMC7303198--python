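import numpy as np
import pandas as pd
import pytest

from mmnkit import design
from mmnkit.containers import EVENT_COLUMNS, RawEEG


@pytest.fixture(scope="session")
def stimuli():
    return design.default_stimuli()


@pytest.fixture(scope="session")
def default_sequence(stimuli):
    s = stimuli[0]
    return design.generate_condition_sequence(
        s, list(design.deviants_for(s, stimuli).values()), seed=42
    )


@pytest.fixture()
def tiny_raw():
    """2-channel, 1 s, 1000 Hz recording with three stimulus events."""
    rng = np.random.default_rng(0)
    data = rng.normal(0, 10, size=(2, 1000))
    events = pd.DataFrame(
        {
            "sample": [100, 400, 700],
            "index": [0, 1, 2],
            "stimulus": ["NOTsal", "NOTsal", "NOTkal"],
            "role": ["SD", "SD", "FD"],
            "condition": ["NOTsal"] * 3,
            "onset_ms": [100.0, 400.0, 700.0],
            "token": [1, 2, 3],
        },
        columns=EVENT_COLUMNS,
    )
    return RawEEG(
        data=data,
        srate=1000.0,
        ch_names=["FCz", "Cz"],
        ch_types=["scalp", "scalp"],
        events=events,
        reference="Fpz",
    )


def small_noiseless_config(n_participants=2, seed=3):
    """Scaled-down pipeline configuration with all nuisance terms off and
    the (identity-on-clean-data) filter stage disabled, so the analysis
    chain is exactly linear from injected template to extracted measure."""
    from mmnkit.pipeline import test_profile

    cfg = test_profile()
    cfg["design"]["counts"] = {"SD": 96, "FD": 12, "TD": 12}
    cfg["preprocess"]["band_hz"] = None
    cfg["preprocess"]["notch_hz"] = None
    cfg["preprocess"]["ocular_method"] = "none"
    cfg["sim"].update(
        dict(pink_sd_uv=0.0, eog_pink_sd_uv=0.0, line_amp_uv=0.0, blink_rate_per_min=0.0)
    )
    cfg["study"] = {"n_participants": n_participants, "seed": seed}
    return cfg


@pytest.fixture(scope="session")
def noiseless_study():
    """One cached noiseless end-to-end study run shared across tests."""
    from mmnkit.pipeline import run_study

    cfg = small_noiseless_config()
    return cfg, run_study(cfg, master_seed=3)
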