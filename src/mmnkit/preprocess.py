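"""Continuous-data cleaning and epoching.

The canonical stage order is: band-pass/notch filter -> downsample ->
ocular artifact removal -> epoch -> DC/baseline correction -> amplitude
rejection -> mastoid re-reference.  Filtering is zero-phase (forward-
backward IIR) so that MMN peak latency, an outcome measure, is not shifted
by the filter.  Epoch windows are half-open ``[tmin, tmax)`` on the sample
grid: a -100..1000 ms window at 250 Hz yields 275 samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .containers import RawEEG

DEFAULT_BAND_HZ = (0.5, 70.0)
DEFAULT_NOTCH_HZ = (48.0, 52.0)
DEFAULT_TARGET_SRATE = 250.0
DEFAULT_EPOCH_WINDOW_MS = (-100.0, 1000.0)
DEFAULT_BASELINE_MS = (-100.0, 0.0)
DEFAULT_REJECT_UV = 75.0
DEFAULT_EOG_CORR_THRESHOLD = 0.7


class PreprocessError(ValueError):
    pass


def zero_phase_gain(
    freqs_hz: np.ndarray,
    srate: float,
    band_hz: tuple[float, float] | None,
    notch_hz: tuple[float, float] | None,
) -> np.ndarray:
    """Squared-magnitude response of the 4th-order Butterworth band-pass and
    2nd-order band-stop notch at the given frequencies (the zero-phase
    transfer function realized by :func:`filter_continuous`)."""
    nyq = srate / 2.0
    gain = np.ones_like(freqs_hz, dtype=float)
    for edges, order, btype in ((band_hz, 2, "bandpass"), (notch_hz, 1, "bandstop")):
        if edges is None:
            continue
        lo, hi = edges
        if not (0 < lo < hi < nyq):
            raise PreprocessError(
                f"{btype} edges {edges} must satisfy 0 < lo < hi < Nyquist ({nyq})"
            )
        sos = sps.butter(order, [lo, hi], btype=btype, fs=srate, output="sos")
        _, h = sps.sosfreqz(sos, worN=freqs_hz, fs=srate)
        gain *= np.abs(h) ** 2
    return gain


def filter_continuous(
    raw: RawEEG,
    band_hz: tuple[float, float] | None = DEFAULT_BAND_HZ,
    notch_hz: tuple[float, float] | None = DEFAULT_NOTCH_HZ,
) -> RawEEG:
    """Zero-phase band-pass (4th-order Butterworth) + band-stop notch
    (2nd-order) on every channel; ``None`` disables a stage.

    The squared-magnitude response is applied spectrally, which matches
    forward-backward IIR filtering everywhere except within a filter
    settling time of the record edges and shifts no latencies (the gain is
    real).  Continuous recordings here are minutes long, so the edge region
    is a negligible fraction of the data.
    """
    out = raw.copy()
    if band_hz is None and notch_hz is None:
        return out
    from scipy import fft as sfft

    n = raw.n_samples
    freqs = np.fft.rfftfreq(n, d=1.0 / raw.srate)
    gain = zero_phase_gain(freqs, raw.srate, band_hz, notch_hz)
    spec = sfft.rfft(out.data, axis=-1)
    spec *= gain.astype(out.data.dtype)
    out.data = sfft.irfft(spec, n=n, axis=-1)
    return out


def downsample(raw: RawEEG, target_srate: float = DEFAULT_TARGET_SRATE) -> RawEEG:
    """Decimate by sample picking (the preceding 70 Hz low-pass is the
    anti-alias filter); event indices are rescaled to the nearest sample."""
    factor = raw.srate / target_srate
    if abs(factor - round(factor)) > 1e-9:
        raise PreprocessError(
            f"srate {raw.srate} not an integer multiple of target {target_srate}"
        )
    factor = int(round(factor))
    n_keep = raw.n_samples - (raw.n_samples % factor)
    out = raw.copy()
    out.data = raw.data[:, :n_keep:factor].copy()
    out.srate = target_srate
    if len(out.events):
        out.events = out.events.copy()
        out.events["sample"] = (
            np.round(out.events["sample"].to_numpy() / factor).astype(int)
        )
    return out


@dataclass
class OcularReport:
    method: str
    n_components: int = 0
    removed: list[int] = field(default_factory=list)
    max_abs_correlation: float = 0.0

    @property
    def n_removed(self) -> int:
        return len(self.removed)


def remove_ocular_artifacts(
    raw: RawEEG,
    method: str = "ica_auto",
    threshold: float = DEFAULT_EOG_CORR_THRESHOLD,
    seed: int = 0,
    max_iter: int = 200,
) -> tuple[RawEEG, OcularReport]:
    """Remove ocular activity from scalp/mastoid channels.

    ``ica_auto``: FastICA into as many components as head channels;
    components whose time course correlates with any EOG channel at
    |r| >= ``threshold`` are zeroed out (an automated surrogate for manual
    component selection).  ``eog_regression``: subtract the least-squares
    projection of the EOG channels.  ``none``: identity.
    """
    head = np.concatenate([raw.picks("scalp"), raw.picks("mastoid")])
    head = np.sort(head)
    eog = raw.picks("eog")
    out = raw.copy()
    if method == "none":
        return out, OcularReport(method="none")
    if len(eog) == 0:
        raise PreprocessError(f"method {method!r} requires EOG channels")

    if method == "eog_regression":
        X = raw.data[eog] - raw.data[eog].mean(axis=1, keepdims=True)
        Y = raw.data[head]
        beta, *_ = np.linalg.lstsq(X.T, Y.T, rcond=None)
        out.data[head] = Y - beta.T @ X
        return out, OcularReport(method="eog_regression", n_components=len(eog))

    if method == "ica_auto":
        if len(head) < 8:
            raise PreprocessError(
                f"ica_auto needs >= 8 scalp/mastoid channels, got {len(head)}"
            )
        from sklearn.decomposition import FastICA

        Y = raw.data[head].T  # samples x channels
        ica = FastICA(
            n_components=len(head),
            random_state=int(seed),
            whiten="unit-variance",
            max_iter=max_iter,
            tol=1e-4,
        )
        import warnings

        with warnings.catch_warnings():
            warnings.filterwarnings("ignore", message=".*did not converge.*")
            S = ica.fit_transform(Y)  # samples x components
        E = raw.data[eog].T
        Sc = S - S.mean(axis=0)
        Ec = E - E.mean(axis=0)
        Sn = Sc / np.where(Sc.std(axis=0) == 0, 1, Sc.std(axis=0))
        En = Ec / np.where(Ec.std(axis=0) == 0, 1, Ec.std(axis=0))
        corr = (Sn.T @ En) / Y.shape[0]  # components x eog
        max_abs = np.abs(corr).max(axis=1)
        removed = np.where(max_abs >= threshold)[0]
        S_clean = S.copy()
        S_clean[:, removed] = 0.0
        Y_clean = ica.inverse_transform(S_clean)
        out.data[head] = Y_clean.T
        return out, OcularReport(
            method="ica_auto",
            n_components=len(head),
            removed=[int(i) for i in removed],
            max_abs_correlation=float(max_abs.max()) if len(max_abs) else 0.0,
        )

    raise PreprocessError(f"unknown ocular-removal method {method!r}")


@dataclass
class Epochs:
    """Epoched data (trials x channels x samples, µV) with trial metadata.

    ``metadata`` carries the event columns plus ``kept`` and ``reason``;
    trials that could not be extracted or failed the amplitude criterion
    are flagged, never silently dropped.
    """

    data: np.ndarray
    window_ms: tuple[float, float]
    srate: float
    ch_names: list[str]
    ch_types: list[str]
    metadata: pd.DataFrame
    reference: str = "Fpz"

    def __post_init__(self) -> None:
        if self.data.shape[0] != len(self.metadata):
            raise ValueError("metadata rows must equal number of trials")
        t = self.times_ms
        if not (t[0] <= 0 <= t[-1]):
            raise ValueError("epoch window must contain time 0")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def times_ms(self) -> np.ndarray:
        start = int(round(self.window_ms[0] / 1000.0 * self.srate))
        return (np.arange(self.data.shape[2]) + start) / self.srate * 1000.0

    def channel_index(self, name: str) -> int:
        try:
            return self.ch_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not present") from None

    def picks(self, kind: str) -> np.ndarray:
        return np.array([i for i, t in enumerate(self.ch_types) if t == kind], dtype=int)

    def copy(self) -> "Epochs":
        return Epochs(
            data=self.data.copy(),
            window_ms=self.window_ms,
            srate=self.srate,
            ch_names=list(self.ch_names),
            ch_types=list(self.ch_types),
            metadata=self.metadata.copy(),
            reference=self.reference,
        )

    def to_hdf5(self, path: str | Path) -> None:
        """Save to an HDF5 container (datasets: data; attrs: layout; metadata
        as a TSV-encoded string)."""
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data, compression="gzip", compression_opts=1)
            f.attrs["window_ms"] = self.window_ms
            f.attrs["srate"] = self.srate
            f.attrs["ch_names"] = [n.encode() for n in self.ch_names]
            f.attrs["ch_types"] = [t.encode() for t in self.ch_types]
            f.attrs["reference"] = self.reference
            f.attrs["metadata_tsv"] = self.metadata.to_csv(sep="\t", index=False)

    @classmethod
    def from_hdf5(cls, path: str | Path) -> "Epochs":
        import io

        import h5py

        with h5py.File(path, "r") as f:
            meta = pd.read_csv(io.StringIO(f.attrs["metadata_tsv"]), sep="\t")
            return cls(
                data=f["data"][...],
                window_ms=tuple(f.attrs["window_ms"]),
                srate=float(f.attrs["srate"]),
                ch_names=[n.decode() if isinstance(n, bytes) else n for n in f.attrs["ch_names"]],
                ch_types=[t.decode() if isinstance(t, bytes) else t for t in f.attrs["ch_types"]],
                metadata=meta,
                reference=str(f.attrs["reference"]),
            )


def epoch(raw: RawEEG, window_ms: tuple[float, float] = DEFAULT_EPOCH_WINDOW_MS) -> Epochs:
    """Extract half-open ``[tmin, tmax)`` epochs around each event sample.

    Events whose window does not fit inside the recording are flagged
    (``kept=False, reason='edge'``) with zeroed data.
    """
    start = int(round(window_ms[0] / 1000.0 * raw.srate))
    stop = int(round(window_ms[1] / 1000.0 * raw.srate))
    n_samp = stop - start
    if n_samp <= 0:
        raise PreprocessError(f"empty epoch window {window_ms}")
    n_trials = len(raw.events)
    data = np.zeros((n_trials, raw.n_channels, n_samp), dtype=raw.data.dtype)
    kept = np.ones(n_trials, dtype=bool)
    reason = np.array([""] * n_trials, dtype=object)
    samples = raw.events["sample"].to_numpy(dtype=int)
    for i, s in enumerate(samples):
        s0, s1 = s + start, s + stop
        if s0 < 0 or s1 > raw.n_samples:
            kept[i] = False
            reason[i] = "edge"
            continue
        data[i] = raw.data[:, s0:s1]
    meta = raw.events.reset_index(drop=True).copy()
    meta["kept"] = kept
    meta["reason"] = reason
    return Epochs(
        data=data,
        window_ms=window_ms,
        srate=raw.srate,
        ch_names=list(raw.ch_names),
        ch_types=list(raw.ch_types),
        metadata=meta,
        reference=raw.reference,
    )


def baseline_and_reject(
    ep: Epochs,
    baseline_ms: tuple[float, float] = DEFAULT_BASELINE_MS,
    threshold_uv: float | None = DEFAULT_REJECT_UV,
) -> Epochs:
    """DC removal (subtract epoch mean) then baseline correction (subtract
    the pre-stimulus-interval mean), followed by amplitude rejection:
    trials whose post-correction absolute amplitude exceeds ``threshold_uv``
    on any scalp electrode are flagged (mastoids/EOG excluded from the
    criterion)."""
    t = ep.times_ms
    b0, b1 = baseline_ms
    if b0 < t[0] - 1e-9 or b1 > t[-1] + 1e-9:
        raise PreprocessError(f"baseline {baseline_ms} outside epoch window")
    bmask = (t >= b0) & (t < b1)
    if not bmask.any():
        raise PreprocessError("baseline interval contains no samples")
    out = ep.copy()
    out.data = out.data - out.data.mean(axis=2, keepdims=True)
    out.data = out.data - out.data[:, :, bmask].mean(axis=2, keepdims=True)
    if threshold_uv is not None:
        scalp = out.picks("scalp")
        peak = np.abs(out.data[:, scalp, :]).max(axis=(1, 2))
        bad = peak > threshold_uv
        kept = out.metadata["kept"].to_numpy(dtype=bool)
        reason = out.metadata["reason"].to_numpy(dtype=object)
        newly = bad & kept
        kept[newly] = False
        reason[newly] = "amplitude"
        out.metadata["kept"] = kept
        out.metadata["reason"] = reason
    return out


def rereference_mastoids(ep: Epochs, mastoids: tuple[str, str] = ("M1", "M2")) -> Epochs:
    """Subtract the average-mastoid trace from every channel."""
    try:
        i1, i2 = ep.channel_index(mastoids[0]), ep.channel_index(mastoids[1])
    except KeyError as e:
        raise PreprocessError(f"mastoid channel missing: {e}") from None
    out = ep.copy()
    ref = 0.5 * (out.data[:, i1, :] + out.data[:, i2, :])
    out.data = out.data - ref[:, None, :]
    out.reference = "linked-mastoids"
    return out
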