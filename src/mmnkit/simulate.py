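"""Synthetic multichannel EEG for an oddball sequence with known ground truth.

The simulator stands in for real recordings: it renders, for every trial,
a topography-weighted sum of obligatory auditory components (N1/P2 locked
to each syllable onset) plus -- on deviant trials only -- an MMN deflection
modeled as a negative Gaussian pulse centered at deviation onset + true
latency, with a frontocentral scalp distribution peaked at FCz.  Nuisance
terms: per-channel pink (1/f) noise, 50 Hz line noise, and stereotyped
ocular blinks that project to the EOG channels and, attenuated, to frontal
scalp.  All free parameters live in :class:`SimConfig`; the injected MMN
amplitudes/latencies are the ground truth that downstream recovery tests
measure against.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import EVENT_COLUMNS, RawEEG
from .design import OddballSequence, PHONPROB_LEVELS, SYLSTR_LEVELS, StimulusSpec, default_stimuli
from .erp import FALLBACK_WINDOWS_MS

# re-exported here because file IO belongs to this module's surface
from .brainvision import (  # noqa: F401
    read_brainvision,
    read_raw_binary,
    write_brainvision,
    write_raw_binary,
)


class SimConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class Channel:
    name: str
    kind: str  # 'scalp' | 'mastoid' | 'eog'
    x: float = 0.0  # lateral grid position (negative = left)
    y: float = 0.0  # anterior(+)/posterior(-) grid position


def standard_montage() -> list[Channel]:
    """57 scalp + 2 mastoid + 4 EOG channels, 10% system names.

    Fpz (online reference) and AFz (ground) are not recorded.  Grid
    coordinates are schematic (row/lateral indices), used only for the
    radial topography model.
    """
    lat9 = [("7", -4.0), ("5", -3.0), ("3", -2.0), ("1", -1.0), ("z", 0.0),
            ("2", 1.0), ("4", 2.0), ("6", 3.0), ("8", 4.0)]
    chans: list[Channel] = [
        Channel("Fp1", "scalp", -1.0, 7.0), Channel("Fp2", "scalp", 1.0, 7.0),
        Channel("AF3", "scalp", -2.0, 6.0), Channel("AF4", "scalp", 2.0, 6.0),
    ]
    rows = [
        ("F", 5.0, None), ("FC", 4.0, ("FT7", "FT8")), ("C", 3.0, ("T7", "T8")),
        ("CP", 2.0, ("TP7", "TP8")), ("P", 1.0, None),
    ]
    for prefix, y, temporal in rows:
        for suffix, x in lat9:
            name = f"{prefix}{suffix}"
            if temporal is not None and suffix in ("7", "8"):
                name = temporal[0] if suffix == "7" else temporal[1]
            chans.append(Channel(name, "scalp", x, y))
    chans += [
        Channel("PO7", "scalp", -3.0, 0.0), Channel("PO3", "scalp", -1.5, 0.0),
        Channel("POz", "scalp", 0.0, 0.0), Channel("PO4", "scalp", 1.5, 0.0),
        Channel("PO8", "scalp", 3.0, 0.0),
        Channel("O1", "scalp", -1.0, -1.0), Channel("Oz", "scalp", 0.0, -1.0),
        Channel("O2", "scalp", 1.0, -1.0),
    ]
    assert len(chans) == 57
    chans += [Channel("M1", "mastoid", -5.0, 2.0), Channel("M2", "mastoid", 5.0, 2.0)]
    chans += [
        Channel("EOGvu", "eog", -1.0, 8.5), Channel("EOGvl", "eog", -1.0, 8.0),
        Channel("EOGhl", "eog", -5.0, 7.0), Channel("EOGhr", "eog", 5.0, 7.0),
    ]
    return chans


def reduced_montage() -> list[Channel]:
    """16 scalp + 2 mastoid + 4 EOG channels for scaled-down runs; keeps the
    midline frontocentral/centroparietal rows the MMN measures rely on."""
    keep = {
        "Fp1", "Fp2", "F1", "Fz", "F2", "FC1", "FCz", "FC2",
        "C1", "Cz", "C2", "CP1", "CPz", "CP2", "Pz", "Oz",
    }
    return [c for c in standard_montage() if c.kind != "scalp" or c.name in keep]


@dataclass
class GaussianComponent:
    """One Gaussian-envelope ERP component (negative amplitude = negativity)."""

    amplitude_uv: float
    latency_ms: float  # center relative to its locking point
    fwhm_ms: float


def default_mmn_truth() -> dict[tuple[str, str, str], GaussianComponent]:
    """Ground-truth MMN per (phonprob, sylstr, deviant role) cell.

    Defaults emulate the study's qualitative pattern: a robust MMN in every
    cell (-2.5 µV), formal deviants peaking earlier for high than for low
    phonotactic probability (160 vs 200 ms after /t/-onset, a 40 ms
    effect), temporal deviants at 250 ms after stimulus onset with no
    latency effect.
    """
    truth = {}
    for pp in PHONPROB_LEVELS:
        for ss in SYLSTR_LEVELS:
            lat_fd = 160.0 if pp == "HPP" else 200.0
            truth[(pp, ss, "FD")] = GaussianComponent(-2.5, lat_fd, 60.0)
            truth[(pp, ss, "TD")] = GaussianComponent(-2.5, 250.0, 60.0)
    return truth


@dataclass
class SimConfig:
    """All free parameters of the synthetic-EEG generator (amplitudes µV,
    latencies/widths ms, rates Hz)."""

    srate: float = 1000.0
    montage: list[Channel] = field(default_factory=standard_montage)
    mmn: dict[tuple[str, str, str], GaussianComponent] = field(default_factory=default_mmn_truth)
    #: obligatory responses locked to each syllable onset
    obligatory: list[GaussianComponent] = field(
        default_factory=lambda: [
            GaussianComponent(-1.0, 100.0, 80.0),  # N1
            GaussianComponent(0.8, 200.0, 120.0),  # P2
        ]
    )
    syllable_onsets_ms: tuple[float, ...] = (0.0, 300.0)
    topo_sigma: float = 3.0  # grid units of radial falloff from FCz
    mastoid_weight: float = 0.0
    pink_sd_uv: float = 8.0
    line_freq_hz: float = 50.0
    line_amp_uv: float = 1.0
    blink_rate_per_min: float = 4.0
    blink_amp_uv: float = 150.0
    blink_width_ms: float = 250.0
    blink_scalp_gain: float = 0.5  # blink fraction reaching the most frontal scalp row
    eog_pink_sd_uv: float = 4.0
    seed: int = 0

    def validate(self, stimuli: list[StimulusSpec] | None = None) -> None:
        if self.srate <= 2 * 70.0:
            raise SimConfigError(f"srate {self.srate} must exceed twice the 70 Hz analysis band edge")
        names = [c.name for c in self.montage]
        if len(set(names)) != len(names):
            raise SimConfigError("duplicate channel names in montage")
        stimuli = stimuli or default_stimuli()
        by_attr = {(s.phonprob, s.sylstr): s for s in stimuli}
        for (pp, ss, role), comp in self.mmn.items():
            lo, hi = FALLBACK_WINDOWS_MS[role]
            if not (lo <= comp.latency_ms <= hi):
                raise SimConfigError(
                    f"MMN latency {comp.latency_ms} ms for cell {(pp, ss, role)} outside "
                    f"the {role} fallback search window {lo}-{hi} ms"
                )
            stim = by_attr.get((pp, ss))
            if stim is not None:
                onset = stim.deviation_onset_ms(role)
                if onset + comp.latency_ms >= stim.duration_ms + 200.0:
                    raise SimConfigError(
                        f"MMN for cell {(pp, ss, role)} centered {onset + comp.latency_ms} ms "
                        "after stimulus onset, beyond the stimulus window"
                    )

    def topography(self) -> np.ndarray:
        """Per-channel weight of the auditory/MMN sources: Gaussian radial
        falloff from FCz, 1 at FCz, ``mastoid_weight`` at mastoids, 0 at EOG."""
        fcz = next((c for c in self.montage if c.name == "FCz"), None)
        if fcz is None:
            raise SimConfigError("montage must contain FCz")
        w = np.zeros(len(self.montage))
        for i, c in enumerate(self.montage):
            if c.kind == "scalp":
                d2 = (c.x - fcz.x) ** 2 + (c.y - fcz.y) ** 2
                w[i] = np.exp(-d2 / (2 * self.topo_sigma**2))
            elif c.kind == "mastoid":
                w[i] = self.mastoid_weight
        return w

    def blink_topography(self) -> np.ndarray:
        """Blink projection: full template on vertical EOG (inverted below
        the eye), small on horizontal EOG, exponential front-to-back decay
        over the scalp scaled by ``blink_scalp_gain``."""
        w = np.zeros(len(self.montage))
        ymax = max(c.y for c in self.montage if c.kind == "scalp")
        for i, c in enumerate(self.montage):
            if c.kind == "scalp":
                w[i] = self.blink_scalp_gain * np.exp(-(ymax - c.y) / 2.0)
            elif c.kind == "eog":
                w[i] = {"EOGvu": 1.0, "EOGvl": -0.6, "EOGhl": 0.15, "EOGhr": 0.15}.get(c.name, 0.5)
        return w


def gaussian_pulse(
    t_ms: np.ndarray, center_ms: float, fwhm_ms: float, amplitude_uv: float
) -> np.ndarray:
    """Gaussian-envelope pulse, hard-zeroed beyond 6 sigma so that placement
    in continuous data and direct evaluation agree exactly."""
    sigma = fwhm_ms / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    t_ms = np.asarray(t_ms, dtype=float)
    out = amplitude_uv * np.exp(-0.5 * ((t_ms - center_ms) / sigma) ** 2)
    out[np.abs(t_ms - center_ms) > 6 * sigma] = 0.0
    return out


def mmn_template(cfg: SimConfig, cell: tuple[str, str, str], t_ms: np.ndarray) -> np.ndarray:
    """The injected MMN waveform of a cell on a time axis relative to
    deviation onset (the exact deviant-minus-standard difference at FCz in
    a noiseless simulation)."""
    comp = cfg.mmn[cell]
    return gaussian_pulse(t_ms, comp.latency_ms, comp.fwhm_ms, comp.amplitude_uv)


def _add_pulse(signal: np.ndarray, srate: float, center_ms: float, fwhm_ms: float, amp: float) -> None:
    sigma = fwhm_ms / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    half_ms = 6 * sigma
    i0 = max(0, int(np.ceil((center_ms - half_ms) / 1000.0 * srate)))
    i1 = min(signal.shape[-1], int(np.floor((center_ms + half_ms) / 1000.0 * srate)) + 1)
    if i1 <= i0:
        return
    t = np.arange(i0, i1) / srate * 1000.0
    signal[i0:i1] += amp * np.exp(-0.5 * ((t - center_ms) / sigma) ** 2)


def pink_noise(
    rng: np.random.Generator,
    n_channels: int,
    n_samples: int,
    srate: float,
    dtype=np.float64,
) -> np.ndarray:
    """Per-channel 1/f-amplitude noise, unit standard deviation."""
    from scipy import fft as sfft

    white = rng.standard_normal((n_channels, n_samples), dtype=dtype)
    spec = sfft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / srate)
    shaping = np.zeros_like(freqs, dtype=dtype)
    shaping[1:] = 1.0 / np.sqrt(freqs[1:], dtype=dtype)
    spec *= shaping
    out = sfft.irfft(spec, n=n_samples, axis=-1)
    sd = out.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    out /= sd
    return out


def simulate_subject(
    seq: OddballSequence,
    cfg: SimConfig | None = None,
    stimuli: list[StimulusSpec] | None = None,
    seed: int | None = None,
) -> RawEEG:
    """Render continuous raw EEG (µV) for one condition block sequence.

    Reproducible under ``seed`` (falls back to ``cfg.seed``).  Total
    duration is n_trials x trial_duration.
    """
    cfg = cfg or SimConfig()
    stimuli = stimuli or default_stimuli()
    cfg.validate(stimuli)
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    by_id = {s.id: s for s in stimuli}

    n_trials = len(seq)
    n_samples = int(round(n_trials * seq.trial_duration_ms / 1000.0 * cfg.srate))
    n_ch = len(cfg.montage)
    names = [c.name for c in cfg.montage]
    kinds = [c.kind for c in cfg.montage]

    # single neural source time course, projected through the topography
    source = np.zeros(n_samples)
    for ev in seq.trials:
        stim = by_id[ev.stimulus]
        for syl in cfg.syllable_onsets_ms:
            for comp in cfg.obligatory:
                _add_pulse(source, cfg.srate, ev.onset_ms + syl + comp.latency_ms,
                           comp.fwhm_ms, comp.amplitude_uv)
        if ev.role in ("FD", "TD"):
            comp = cfg.mmn[(stim.phonprob, stim.sylstr, ev.role)]
            center = ev.onset_ms + stim.deviation_onset_ms(ev.role) + comp.latency_ms
            _add_pulse(source, cfg.srate, center, comp.fwhm_ms, comp.amplitude_uv)

    # stochastic runs are rendered in single precision (µV-scale noise dwarfs
    # float32 rounding); noiseless runs keep float64 for exact template checks
    stochastic = cfg.pink_sd_uv > 0 or cfg.eog_pink_sd_uv > 0 or cfg.line_amp_uv > 0
    dtype = np.float32 if stochastic else np.float64
    data = np.outer(cfg.topography(), source).astype(dtype, copy=False)

    if cfg.pink_sd_uv > 0 or cfg.eog_pink_sd_uv > 0:
        noise = pink_noise(rng, n_ch, n_samples, cfg.srate, dtype=dtype)
        sds = np.array([cfg.eog_pink_sd_uv if k == "eog" else cfg.pink_sd_uv for k in kinds])
        noise *= sds[:, None].astype(dtype)
        data += noise
        del noise
    if cfg.line_amp_uv > 0:
        t = np.arange(n_samples, dtype=dtype) / dtype(cfg.srate)
        phases = rng.uniform(0, 2 * np.pi, size=n_ch)
        head = np.array([1.0 if k in ("scalp", "mastoid") else 0.2 for k in kinds])
        wt = (2 * np.pi * cfg.line_freq_hz * t).astype(dtype)
        sin_wt, cos_wt = np.sin(wt), np.cos(wt)
        amp = cfg.line_amp_uv * head
        data += (amp * np.cos(phases)).astype(dtype)[:, None] * sin_wt
        data += (amp * np.sin(phases)).astype(dtype)[:, None] * cos_wt
    if cfg.blink_rate_per_min > 0 and cfg.blink_amp_uv != 0:
        duration_min = n_samples / cfg.srate / 60.0
        n_blinks = rng.poisson(cfg.blink_rate_per_min * duration_min)
        times_ms = np.sort(rng.uniform(0, n_samples / cfg.srate * 1000.0, size=n_blinks))
        blink = np.zeros(n_samples)
        for tm in times_ms:
            _add_pulse(blink, cfg.srate, tm, cfg.blink_width_ms, cfg.blink_amp_uv)
        data += np.outer(cfg.blink_topography(), blink)

    events = pd.DataFrame(
        {
            "sample": [int(round(ev.onset_ms / 1000.0 * cfg.srate)) for ev in seq.trials],
            "index": [ev.index for ev in seq.trials],
            "stimulus": [ev.stimulus for ev in seq.trials],
            "role": [ev.role for ev in seq.trials],
            "condition": [ev.condition for ev in seq.trials],
            "onset_ms": [ev.onset_ms for ev in seq.trials],
            "token": [ev.token for ev in seq.trials],
        },
        columns=EVENT_COLUMNS,
    )
    return RawEEG(data=data, srate=cfg.srate, ch_names=names, ch_types=kinds,
                  events=events, reference="Fpz")


def ground_truth_table(cfg: SimConfig | None = None) -> pd.DataFrame:
    """One row per phonprob x sylstr x deviant-type cell with the injected
    MMN amplitude and latency (relative to deviation onset)."""
    cfg = cfg or SimConfig()
    rows = [
        {
            "phonprob": pp,
            "sylstr": ss,
            "deviant_type": role,
            "amplitude_uv": comp.amplitude_uv,
            "latency_ms": comp.latency_ms,
            "fwhm_ms": comp.fwhm_ms,
        }
        for (pp, ss, role), comp in sorted(cfg.mmn.items())
    ]
    return pd.DataFrame(rows)


def noiseless(cfg: SimConfig | None = None, obligatory: bool = True) -> SimConfig:
    """A copy of ``cfg`` with every stochastic nuisance term switched off."""
    cfg = cfg or SimConfig()
    return replace(
        cfg,
        pink_sd_uv=0.0,
        eog_pink_sd_uv=0.0,
        line_amp_uv=0.0,
        blink_rate_per_min=0.0,
        obligatory=list(cfg.obligatory) if obligatory else [],
    )
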