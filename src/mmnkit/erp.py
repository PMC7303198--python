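"""Averaging, identical-stimulus difference waves, MMN peak and amplitudes.

Deviant and standard trials are averaged after time-locking to the onset
of the auditory deviation: stimulus onset for temporal deviants, the
/t/-onset (250 ms by default) for formal deviants; the standard is always
time-locked to the same moment as the deviant it is compared with.  The
MMN peak is the most negative local minimum of the FCz difference wave in
a primary search window, subject to a frontocentral-topography check; a
wider fallback window and a flagged global minimum stand in for the manual
inspection step of a human analyst.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import Epochs

#: Peak search windows, ms relative to deviation onset.
PRIMARY_WINDOWS_MS = {"FD": (100.0, 300.0), "TD": (200.0, 350.0)}
FALLBACK_WINDOWS_MS = {"FD": (80.0, 300.0), "TD": (120.0, 370.0)}

FRONTOCENTRAL = ["Fz", "F1", "F2", "F3", "F4", "FCz", "FC1", "FC2", "FC3", "FC4"]
CENTROPARIETAL = ["Cz", "C1", "C2", "C3", "C4", "CPz", "CP1", "CP2", "CP3", "CP4"]
DEFAULT_ROIS = {"FC": FRONTOCENTRAL, "CP": CENTROPARIETAL}

#: Reduced-montage ROIs for scaled-down runs.
REDUCED_ROIS = {
    "FC": ["Fz", "F1", "F2", "FCz", "FC1", "FC2"],
    "CP": ["Cz", "C1", "C2", "CPz", "CP1", "CP2"],
}

DEFAULT_PEAK_HALFWIDTH_MS = 24.0


class ERPError(ValueError):
    pass


@dataclass
class ERPWave:
    """Trial-averaged waveform (channels x samples, µV) on a time axis
    relative to the lock point."""

    data: np.ndarray
    times_ms: np.ndarray
    srate: float
    ch_names: list[str]
    ch_types: list[str]
    lock: str  # 'stimulus_onset' | 'deviation_onset'
    lock_offset_ms: float
    n_trials: int
    labels: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_trials <= 0:
            raise ERPError("ERPWave requires n_trials > 0")
        if self.data.shape != (len(self.ch_names), len(self.times_ms)):
            raise ERPError("data shape does not match channels x times")

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.data[self.ch_names.index(name)]
        except ValueError:
            raise ERPError(f"channel {name!r} not present") from None


@dataclass
class MMNMeasure:
    """Per analysis cell: FCz peak latency plus mean amplitudes (standard
    and deviant separately) per electrode and per ROI."""

    labels: dict
    peak_latency_ms: float
    window_used: str  # 'primary' | 'fallback'
    qc_flag: bool
    amp_standard: dict[str, float]
    amp_deviant: dict[str, float]
    roi_standard: dict[str, float]
    roi_deviant: dict[str, float]
    n_trials_standard: int = 0
    n_trials_deviant: int = 0


def timelock_average(
    ep: Epochs,
    trial_indices: np.ndarray,
    lock_offset_ms: float = 0.0,
    labels: dict | None = None,
    lock: str = "deviation_onset",
) -> ERPWave:
    """Pointwise mean over the given trials, with the time axis re-zeroed at
    ``lock_offset_ms`` after stimulus onset (0 for temporal deviants, the
    /t/-onset for formal deviants; the standard of a comparison gets the
    same offset as its deviant)."""
    trial_indices = np.asarray(trial_indices, dtype=int)
    if trial_indices.size == 0:
        raise ERPError(f"empty trial selection for cell {labels}")
    avg = ep.data[trial_indices].mean(axis=0)
    return ERPWave(
        data=avg,
        times_ms=ep.times_ms - lock_offset_ms,
        srate=ep.srate,
        ch_names=list(ep.ch_names),
        ch_types=list(ep.ch_types),
        lock=lock,
        lock_offset_ms=lock_offset_ms,
        n_trials=int(trial_indices.size),
        labels=labels or {},
    )


def difference_wave(dev: ERPWave, std: ERPWave) -> ERPWave:
    """Deviant minus standard of the identical stimulus, same lock."""
    if dev.labels.get("stimulus") != std.labels.get("stimulus"):
        raise ERPError(
            f"difference wave requires identical stimuli, got "
            f"{dev.labels.get('stimulus')!r} vs {std.labels.get('stimulus')!r}"
        )
    if dev.data.shape != std.data.shape or abs(dev.lock_offset_ms - std.lock_offset_ms) > 1e-9:
        raise ERPError("deviant and standard waves are not sample-aligned")
    labels = dict(dev.labels)
    labels["contrast"] = "deviant-standard"
    return ERPWave(
        data=dev.data - std.data,
        times_ms=dev.times_ms.copy(),
        srate=dev.srate,
        ch_names=list(dev.ch_names),
        ch_types=list(dev.ch_types),
        lock=dev.lock,
        lock_offset_ms=dev.lock_offset_ms,
        n_trials=min(dev.n_trials, std.n_trials),
        labels=labels,
    )


def _window_mask(times: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    return (times >= window[0] - 1e-9) & (times <= window[1] + 1e-9)


def _roi_mean_around(
    wave: ERPWave, chans: list[str], center_idx: int, halfwidth_ms: float
) -> float:
    half = int(round(halfwidth_ms / 1000.0 * wave.srate))
    i0 = max(0, center_idx - half)
    i1 = min(wave.data.shape[1], center_idx + half + 1)
    rows = [wave.ch_names.index(c) for c in chans if c in wave.ch_names]
    if not rows:
        raise ERPError(f"no ROI channels present among {chans}")
    return float(wave.data[np.ix_(rows, np.arange(i0, i1))].mean())


def detect_mmn_peak(
    diff: ERPWave,
    deviant_type: str,
    channel: str = "FCz",
    primary_ms: tuple[float, float] | None = None,
    fallback_ms: tuple[float, float] | None = None,
    rois: dict[str, list[str]] | None = None,
    halfwidth_ms: float = DEFAULT_PEAK_HALFWIDTH_MS,
    topography_check: bool = True,
) -> tuple[float, str, bool]:
    """Find the MMN peak latency on the FCz difference wave.

    Returns ``(latency_ms, window_used, qc_flag)``.  Candidates are interior
    local minima; a candidate passes the topography check when the
    frontocentral ROI mean within +/- ``halfwidth_ms`` is more negative than
    the centroparietal one.  The most negative passing candidate wins (ties
    to the earlier latency); failing the primary window the fallback window
    is searched; failing that, the global minimum of the fallback window is
    returned with ``qc_flag=True``.
    """
    primary = primary_ms or PRIMARY_WINDOWS_MS[deviant_type]
    fallback = fallback_ms or FALLBACK_WINDOWS_MS[deviant_type]
    rois = rois or DEFAULT_ROIS
    t = diff.times_ms
    for name, win in (("primary", primary), ("fallback", fallback)):
        if win[0] < t[0] - 1e-9 or win[1] > t[-1] + 1e-9:
            raise ERPError(f"{name} window {win} outside wave span ({t[0]:.0f}..{t[-1]:.0f} ms)")
    x = diff.channel(channel)

    def _passes(idx: int) -> bool:
        if not topography_check:
            return True
        fc = _roi_mean_around(diff, rois["FC"], idx, halfwidth_ms)
        cp = _roi_mean_around(diff, rois["CP"], idx, halfwidth_ms)
        return fc < cp

    interior = np.zeros(len(x), dtype=bool)
    interior[1:-1] = (x[1:-1] <= x[:-2]) & (x[1:-1] <= x[2:])
    for window_name, win in (("primary", primary), ("fallback", fallback)):
        cand = np.flatnonzero(interior & _window_mask(t, win))
        cand = [i for i in cand if _passes(i)]
        if cand:
            best = min(cand, key=lambda i: (x[i], t[i]))
            return float(t[best]), window_name, False
    fb = np.flatnonzero(_window_mask(t, fallback))
    best = fb[np.argmin(x[fb])]
    return float(t[best]), "fallback", True


def mean_amplitudes(
    std: ERPWave,
    dev: ERPWave,
    peak_latency_ms: float,
    halfwidth_ms: float = DEFAULT_PEAK_HALFWIDTH_MS,
    rois: dict[str, list[str]] | None = None,
    window_used: str = "primary",
    qc_flag: bool = False,
) -> MMNMeasure:
    """Mean amplitudes +/- ``halfwidth_ms`` around the FCz-derived peak
    latency, per electrode and per ROI, separately for the standard and
    deviant waveforms (13 samples at 250 Hz for +/- 24 ms, endpoints
    inclusive)."""
    rois = rois or DEFAULT_ROIS
    t = dev.times_ms
    half = int(round(halfwidth_ms / 1000.0 * dev.srate))
    center = int(np.argmin(np.abs(t - peak_latency_ms)))
    if center - half < 0 or center + half >= len(t):
        raise ERPError(
            f"peak latency {peak_latency_ms} ms +/- {halfwidth_ms} ms outside the wave"
        )
    sl = slice(center - half, center + half + 1)
    for roi, chans in rois.items():
        missing = [c for c in chans if c not in dev.ch_names]
        if missing:
            raise ERPError(f"ROI {roi} electrodes missing: {missing}")

    def _per_electrode(w: ERPWave) -> dict[str, float]:
        return {
            name: float(w.data[i, sl].mean())
            for i, name in enumerate(w.ch_names)
            if w.ch_types[i] in ("scalp", "mastoid")
        }

    amp_std = _per_electrode(std)
    amp_dev = _per_electrode(dev)
    roi_std = {roi: float(np.mean([amp_std[c] for c in chans])) for roi, chans in rois.items()}
    roi_dev = {roi: float(np.mean([amp_dev[c] for c in chans])) for roi, chans in rois.items()}
    return MMNMeasure(
        labels=dict(dev.labels),
        peak_latency_ms=float(peak_latency_ms),
        window_used=window_used,
        qc_flag=qc_flag,
        amp_standard=amp_std,
        amp_deviant=amp_dev,
        roi_standard=roi_std,
        roi_deviant=roi_dev,
        n_trials_standard=std.n_trials,
        n_trials_deviant=dev.n_trials,
    )


def wave_to_frame(wave: ERPWave) -> pd.DataFrame:
    """Channels x time matrix as a tidy table (first column time_ms), for
    TSV export of grand averages and difference waves."""
    out = pd.DataFrame(wave.data.T, columns=wave.ch_names)
    out.insert(0, "time_ms", wave.times_ms)
    return out


def grand_average(waves: list[ERPWave]) -> ERPWave:
    """Unweighted mean over per-subject waves (equals the mean of subject
    averages by linearity)."""
    if not waves:
        raise ERPError("grand_average needs at least one wave")
    ref = waves[0]
    for w in waves[1:]:
        if w.data.shape != ref.data.shape or w.ch_names != ref.ch_names:
            raise ERPError("waves are not alignable for grand averaging")
    labels = dict(ref.labels)
    labels["n_subjects"] = len(waves)
    return ERPWave(
        data=np.mean([w.data for w in waves], axis=0),
        times_ms=ref.times_ms.copy(),
        srate=ref.srate,
        ch_names=list(ref.ch_names),
        ch_types=list(ref.ch_types),
        lock=ref.lock,
        lock_offset_ms=ref.lock_offset_ms,
        n_trials=sum(w.n_trials for w in waves),
        labels=labels,
    )


def measures_to_frame(measures: list[MMNMeasure]) -> pd.DataFrame:
    """Long-format table: one row per cell x electrode plus ROI rows."""
    rows = []
    for m in measures:
        base = {
            **m.labels,
            "peak_latency_ms": m.peak_latency_ms,
            "window_used": m.window_used,
            "qc_flag": m.qc_flag,
        }
        for ch in m.amp_standard:
            rows.append(
                {**base, "site": ch, "site_kind": "electrode",
                 "amp_standard_uv": m.amp_standard[ch], "amp_deviant_uv": m.amp_deviant[ch]}
            )
        for roi in m.roi_standard:
            rows.append(
                {**base, "site": roi, "site_kind": "roi",
                 "amp_standard_uv": m.roi_standard[roi], "amp_deviant_uv": m.roi_deviant[roi]}
            )
    return pd.DataFrame(rows)
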