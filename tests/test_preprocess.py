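"""Filtering, downsampling, ocular removal, epoching, baseline/rejection."""

import numpy as np
import pandas as pd
import pytest

from mmnkit import design, simulate
from mmnkit.containers import EVENT_COLUMNS, RawEEG
from mmnkit.preprocess import (
    Epochs,
    PreprocessError,
    baseline_and_reject,
    downsample,
    epoch,
    filter_continuous,
    remove_ocular_artifacts,
    rereference_mastoids,
    zero_phase_gain,
)


def _raw_from(data, srate=1000.0, events=None, ch_types=None):
    n = data.shape[0]
    names = [f"ch{i}" for i in range(n)]
    if events is None:
        events = pd.DataFrame(columns=EVENT_COLUMNS)
    return RawEEG(data=data, srate=srate, ch_names=names,
                  ch_types=ch_types or ["scalp"] * n, events=events)


def _fft_amp(x, srate, freq):
    spec = np.abs(np.fft.rfft(x)) / len(x) * 2
    f = np.fft.rfftfreq(len(x), 1 / srate)
    return spec[np.argmin(np.abs(f - freq))]


class TestFilter:
    def test_dc_removed(self):
        raw = _raw_from(np.full((1, 20_000), 13.0))
        out = filter_continuous(raw)
        assert abs(out.data.mean()) < 0.01

    def test_50hz_attenuated_at_least_20db(self):
        t = np.arange(40_000) / 1000.0
        raw = _raw_from(10 * np.sin(2 * np.pi * 50 * t)[None, :])
        out = filter_continuous(raw)
        ratio = _fft_amp(out.data[0], 1000.0, 50.0) / _fft_amp(raw.data[0], 1000.0, 50.0)
        assert 20 * np.log10(ratio) <= -20

    def test_10hz_passband_within_5pct(self):
        t = np.arange(40_000) / 1000.0
        raw = _raw_from(10 * np.sin(2 * np.pi * 10 * t)[None, :])
        out = filter_continuous(raw)
        amp = _fft_amp(out.data[0], 1000.0, 10.0)
        assert amp == pytest.approx(10.0, rel=0.05)

    def test_zero_phase_symmetric_pulse_not_shifted(self):
        x = np.zeros((1, 20_000))
        t = np.arange(20_000)
        x[0] = np.exp(-0.5 * ((t - 10_000) / 50.0) ** 2)
        out = filter_continuous(_raw_from(x), band_hz=(0.5, 70.0), notch_hz=None)
        assert abs(int(np.argmax(out.data[0])) - 10_000) <= 1

    def test_band_edges_beyond_nyquist_raise(self):
        raw = _raw_from(np.zeros((1, 1000)), srate=100.0)
        with pytest.raises(PreprocessError, match="Nyquist"):
            filter_continuous(raw, band_hz=(0.5, 70.0), notch_hz=None)

    def test_matches_forward_backward_iir_in_interior(self):
        """The spectral zero-phase realization agrees with scipy's
        sosfiltfilt away from the record edges."""
        from scipy import signal as sps

        rng = np.random.default_rng(0)
        x = rng.normal(0, 5, size=(2, 60_000))
        out = filter_continuous(_raw_from(x)).data
        ref = x.copy()
        for edges, order, btype in (((0.5, 70.0), 2, "bandpass"), ((48.0, 52.0), 1, "bandstop")):
            sos = sps.butter(order, list(edges), btype=btype, fs=1000.0, output="sos")
            ref = sps.sosfiltfilt(sos, ref, axis=-1)
        interior = slice(10_000, 50_000)
        err = np.abs(out[:, interior] - ref[:, interior]).max()
        assert err < 0.05 * x.std()


class TestDownsample:
    def test_sample_count_and_event_rescale(self):
        ev = pd.DataFrame(
            {"sample": [12_000], "index": [0], "stimulus": ["NOTsal"], "role": ["SD"],
             "condition": ["NOTsal"], "onset_ms": [12_000.0], "token": [1]},
            columns=EVENT_COLUMNS,
        )
        raw = _raw_from(np.zeros((1, 1_944_000)), events=ev)
        out = downsample(raw, 250.0)
        assert out.n_samples == 486_000
        assert out.events["sample"].iloc[0] == 3_000
        assert out.srate == 250.0

    def test_10hz_amplitude_preserved(self):
        t = np.arange(40_000) / 1000.0
        raw = _raw_from(10 * np.sin(2 * np.pi * 10 * t)[None, :])
        filt = filter_continuous(raw)
        out = downsample(filt, 250.0)
        amp = _fft_amp(out.data[0], 250.0, 10.0)
        assert amp == pytest.approx(10.0, rel=0.05)

    def test_non_integer_factor_rejected(self):
        raw = _raw_from(np.zeros((1, 1000)))
        with pytest.raises(PreprocessError, match="integer"):
            downsample(raw, 300.0)


def _blinky_raw(stimuli, blink_rate=20.0, seed=4, montage=None):
    cfg = simulate.SimConfig(
        montage=montage or simulate.reduced_montage(),
        pink_sd_uv=2.0, eog_pink_sd_uv=1.0, line_amp_uv=0.0,
        blink_rate_per_min=blink_rate, seed=seed,
    )
    s = stimuli[0]
    seq = design.generate_condition_sequence(
        s, list(design.deviants_for(s, stimuli).values()),
        counts={"SD": 40, "FD": 5, "TD": 5}, seed=seed, block_size=None,
    )
    raw = simulate.simulate_subject(seq, cfg)
    return downsample(filter_continuous(raw), 250.0)


class TestOcularRemoval:
    def test_no_blinks_identity_like(self, stimuli):
        raw = _blinky_raw(stimuli, blink_rate=0.0)
        out, report = remove_ocular_artifacts(raw, method="ica_auto", seed=0)
        for i in raw.picks("scalp"):
            r = np.corrcoef(raw.data[i], out.data[i])[0, 1]
            assert r >= 0.99
        assert report.n_removed == 0

    @pytest.mark.parametrize("method", ["ica_auto", "eog_regression"])
    def test_blink_correlation_drops(self, stimuli, method):
        raw = _blinky_raw(stimuli, blink_rate=20.0)
        fp = raw.channel_index("Fp1")
        veog = raw.channel_index("EOGvu")
        before = abs(np.corrcoef(raw.data[fp], raw.data[veog])[0, 1])
        assert before >= 0.6
        out, report = remove_ocular_artifacts(raw, method=method, seed=0)
        after = abs(np.corrcoef(out.data[fp], raw.data[veog])[0, 1])
        assert after <= 0.2
        if method == "ica_auto":
            assert report.n_removed >= 1

    def test_component_count_equals_head_channel_count(self, stimuli):
        # with a 63-head-channel montage the decomposition has 63 components
        montage = simulate.standard_montage()
        extra = [simulate.Channel(n, "scalp", x, y) for n, x, y in
                 [("F9", -5.0, 5.0), ("F10", 5.0, 5.0), ("P9", -5.0, 1.0), ("P10", 5.0, 1.0)]]
        montage = montage[:57] + extra + montage[57:]
        raw = _blinky_raw(stimuli, blink_rate=20.0, montage=montage)
        raw.data = raw.data[:, :3000]  # short stretch: only the count matters here
        raw.events = raw.events.iloc[0:0]
        out, report = remove_ocular_artifacts(raw, method="ica_auto", seed=0, max_iter=30)
        assert report.n_components == 63

    def test_too_few_channels_rejected(self):
        raw = _raw_from(np.random.default_rng(0).normal(size=(5, 2000)),
                        ch_types=["scalp"] * 4 + ["eog"])
        with pytest.raises(PreprocessError, match=">= 8"):
            remove_ocular_artifacts(raw, method="ica_auto")

    def test_determinism(self, stimuli):
        raw = _blinky_raw(stimuli, blink_rate=20.0)
        a, _ = remove_ocular_artifacts(raw, method="ica_auto", seed=3)
        b, _ = remove_ocular_artifacts(raw, method="ica_auto", seed=3)
        np.testing.assert_array_equal(a.data, b.data)


def _epochs_raw():
    """250 Hz raw with events every 300 samples (1200 ms trials)."""
    rng = np.random.default_rng(0)
    n_tr = 10
    data = rng.normal(0, 5, size=(4, 300 * n_tr)).astype(float)
    samples = np.arange(n_tr) * 300
    ev = pd.DataFrame(
        {"sample": samples, "index": np.arange(n_tr), "stimulus": "NOTsal", "role": "SD",
         "condition": "NOTsal", "onset_ms": samples * 4.0, "token": 1},
        columns=EVENT_COLUMNS,
    )
    return RawEEG(data=data, srate=250.0, ch_names=["FCz", "Cz", "M1", "M2"],
                  ch_types=["scalp", "scalp", "mastoid", "mastoid"], events=ev)


class TestEpoching:
    def test_counts_samples_and_edge_flagging(self):
        raw = _epochs_raw()
        ep = epoch(raw)
        assert ep.n_trials == 10
        assert ep.data.shape[2] == 275  # half-open [-100, 1000) ms at 250 Hz
        # first event at sample 0 has no pre-stimulus data
        assert not ep.metadata["kept"].iloc[0]
        assert ep.metadata["reason"].iloc[0] == "edge"
        assert ep.metadata["kept"].iloc[1:].all()
        # an event whose window runs past the end of the record is flagged
        raw2 = _epochs_raw()
        raw2.data = raw2.data[:, :-100]
        ep2 = epoch(raw2)
        assert not ep2.metadata["kept"].iloc[-1]
        assert ep2.metadata["reason"].iloc[-1] == "edge"

    def test_baseline_mean_zero_on_kept_trials(self):
        ep = baseline_and_reject(epoch(_epochs_raw()))
        t = ep.times_ms
        bmask = (t >= -100) & (t < 0)
        kept = ep.metadata["kept"].to_numpy()
        means = ep.data[kept][:, :, bmask].mean(axis=2)
        assert np.abs(means).max() < 1e-9

    def test_spike_trial_rejected_with_reason(self):
        raw = _epochs_raw()
        raw.data[0, 300 * 4 + 50] += 200.0  # scalp spike in trial 4
        ep = baseline_and_reject(epoch(raw), threshold_uv=75.0)
        assert not ep.metadata["kept"].iloc[4]
        assert ep.metadata["reason"].iloc[4] == "amplitude"

    def test_mastoid_spike_not_rejected(self):
        raw = _epochs_raw()
        raw.data[2, 300 * 4 + 50] += 200.0  # mastoid channel excluded from criterion
        ep = baseline_and_reject(epoch(raw), threshold_uv=75.0)
        assert ep.metadata["kept"].iloc[4]

    def test_rejection_monotone_in_threshold(self):
        raw = _epochs_raw()
        raw.data[0] *= 6.0
        kept = [
            baseline_and_reject(epoch(raw), threshold_uv=th).metadata["kept"].sum()
            for th in (100.0, 75.0, 50.0, 25.0)
        ]
        assert all(a >= b for a, b in zip(kept, kept[1:]))

    def test_noiseless_low_amplitude_zero_rejections(self, stimuli):
        cfg = simulate.noiseless(simulate.SimConfig(montage=simulate.reduced_montage()))
        s = stimuli[0]
        seq = design.generate_condition_sequence(
            s, list(design.deviants_for(s, stimuli).values()),
            counts={"SD": 20, "FD": 3, "TD": 3}, seed=0, block_size=None)
        raw = downsample(simulate.simulate_subject(seq, cfg), 250.0)
        ep = baseline_and_reject(epoch(raw), threshold_uv=75.0)
        assert (ep.metadata["reason"] == "amplitude").sum() == 0


class TestRereference:
    def test_constant_offset_invariance(self):
        ep = baseline_and_reject(epoch(_epochs_raw()), threshold_uv=None)
        shifted = ep.copy()
        shifted.data = shifted.data + 7.5
        a = rereference_mastoids(ep)
        b = rereference_mastoids(shifted)
        np.testing.assert_allclose(a.data, b.data, atol=1e-9)

    def test_mastoid_average_is_zero_after(self):
        out = rereference_mastoids(epoch(_epochs_raw()))
        m = 0.5 * (out.data[:, 2] + out.data[:, 3])
        assert np.abs(m).max() < 1e-9
        assert out.reference == "linked-mastoids"

    def test_missing_mastoid_raises(self):
        raw = _epochs_raw()
        raw.ch_names[2] = "TP9"
        with pytest.raises(PreprocessError, match="mastoid"):
            rereference_mastoids(epoch(raw))


class TestEpochsContainer:
    def test_hdf5_roundtrip(self, tmp_path):
        ep = baseline_and_reject(epoch(_epochs_raw()))
        path = tmp_path / "epochs.h5"
        ep.to_hdf5(path)
        back = Epochs.from_hdf5(path)
        np.testing.assert_allclose(back.data, ep.data)
        assert list(back.metadata["kept"]) == list(ep.metadata["kept"])
        assert back.ch_names == ep.ch_names
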