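"""BrainVision-style (.vhdr/.vmrk/.eeg) and raw float32 + JSON file IO.

The writer emits the classic three-file layout: an INI-style text header
(.vhdr), a text marker file (.vmrk) and little-endian multiplexed int16
binary data (.eeg) at a fixed amplitude resolution (default 0.1 µV per
bit).  Trial metadata (role, stimulus, condition, token) is encoded in the
marker description as ``role:stimulus:condition:token`` so a round trip
preserves the event table exactly.  A raw float32 + JSON-header fallback
(`write_raw_binary`/`read_raw_binary`) stores data losslessly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import EVENT_COLUMNS, RawEEG

DEFAULT_RESOLUTION_UV = 0.1


class BrainVisionParseError(ValueError):
    """Malformed header/marker file; message carries file and line number."""


def _marker_description(row: pd.Series) -> str:
    return f"{row['role']}:{row['stimulus']}:{row['condition']}:{int(row['token'])}"


def write_brainvision(
    raw: RawEEG, basename: str | Path, resolution_uv: float = DEFAULT_RESOLUTION_UV
) -> Path:
    """Write ``raw`` to ``basename``.vhdr/.vmrk/.eeg; returns the .vhdr path."""
    base = Path(basename)
    base.parent.mkdir(parents=True, exist_ok=True)
    vhdr, vmrk, eeg = base.with_suffix(".vhdr"), base.with_suffix(".vmrk"), base.with_suffix(".eeg")

    scaled = np.round(raw.data / resolution_uv)
    if np.any(np.abs(scaled) > 32767):
        scaled = np.clip(scaled, -32768, 32767)
    ints = scaled.astype("<i2")
    # multiplexed: sample-major, channel-minor
    ints.T.tofile(eeg)

    lines = [
        "Brain Vision Data Exchange Header File Version 1.0",
        "; Written by mmnkit",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={eeg.name}",
        f"MarkerFile={vmrk.name}",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={raw.n_channels}",
        f"SamplingInterval={1e6 / raw.srate:g}",
        "",
        "[Binary Infos]",
        "BinaryFormat=INT_16",
        "",
        "[Channel Infos]",
        "; Ch<idx>=<name>,<reference>,<resolution in µV>,<unit>",
    ]
    for i, name in enumerate(raw.ch_names):
        lines.append(f"Ch{i + 1}={name},,{resolution_uv:g},µV")
    lines += [
        "",
        "[Comment]",
        f"Reference={raw.reference}",
        "ChannelTypes=" + ",".join(raw.ch_types),
    ]
    vhdr.write_text("\n".join(lines) + "\n", encoding="utf-8")

    mlines = [
        "Brain Vision Data Exchange Marker File, Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={eeg.name}",
        "",
        "[Marker Infos]",
        "; Mk<idx>=<type>,<description>,<position>,<points>,<channel>",
        "Mk1=New Segment,,1,1,0,00000000000000000000",
    ]
    for k, (_, row) in enumerate(raw.events.iterrows(), start=2):
        mlines.append(
            f"Mk{k}=Stimulus,{_marker_description(row)},{int(row['sample']) + 1},1,0"
        )
    vmrk.write_text("\n".join(mlines) + "\n", encoding="utf-8")
    return vhdr


def _parse_ini(path: Path) -> dict[str, dict[str, tuple[str, int]]]:
    """Parse an INI-ish BrainVision text file into
    {section: {key: (value, line_number)}}; raise with line numbers."""
    if not path.exists():
        raise BrainVisionParseError(f"{path}: file not found")
    sections: dict[str, dict[str, tuple[str, int]]] = {}
    current: str | None = None
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), start=1):
        s = line.strip()
        if not s or s.startswith(";"):
            continue
        if s.startswith("[") :
            if not s.endswith("]"):
                raise BrainVisionParseError(f"{path}:{lineno}: unterminated section header {s!r}")
            current = s[1:-1]
            sections[current] = {}
            continue
        if "=" not in s:
            if lineno == 1:  # signature line
                continue
            raise BrainVisionParseError(f"{path}:{lineno}: expected key=value, got {s!r}")
        if current is None:
            raise BrainVisionParseError(f"{path}:{lineno}: key=value outside any section")
        key, val = s.split("=", 1)
        sections[current][key.strip()] = (val.strip(), lineno)
    return sections


def _get(sections, section, key, path):
    try:
        return sections[section][key][0]
    except KeyError:
        raise BrainVisionParseError(f"{path}: missing [{section}] {key}") from None


def read_brainvision(basename: str | Path) -> RawEEG:
    """Read a .vhdr/.vmrk/.eeg triple written by :func:`write_brainvision`."""
    base = Path(basename)
    vhdr = base if base.suffix == ".vhdr" else base.with_suffix(".vhdr")
    hdr = _parse_ini(vhdr)

    fmt = _get(hdr, "Binary Infos", "BinaryFormat", vhdr)
    if fmt != "INT_16":
        raise BrainVisionParseError(f"{vhdr}: unsupported BinaryFormat {fmt!r}")
    orient = _get(hdr, "Common Infos", "DataOrientation", vhdr)
    if orient != "MULTIPLEXED":
        raise BrainVisionParseError(f"{vhdr}: unsupported DataOrientation {orient!r}")
    n_ch = int(_get(hdr, "Common Infos", "NumberOfChannels", vhdr))
    srate = 1e6 / float(_get(hdr, "Common Infos", "SamplingInterval", vhdr))

    ch_names, resolutions = [], []
    chinfo = hdr.get("Channel Infos", {})
    for i in range(1, n_ch + 1):
        key = f"Ch{i}"
        if key not in chinfo:
            raise BrainVisionParseError(f"{vhdr}: missing [Channel Infos] {key}")
        val, lineno = chinfo[key]
        parts = val.split(",")
        if len(parts) < 3:
            raise BrainVisionParseError(f"{vhdr}:{lineno}: malformed channel entry {val!r}")
        ch_names.append(parts[0])
        resolutions.append(float(parts[2]) if parts[2] else 1.0)

    comment = hdr.get("Comment", {})
    reference = comment.get("Reference", ("Fpz", 0))[0]
    if "ChannelTypes" in comment:
        ch_types = comment["ChannelTypes"][0].split(",")
        if len(ch_types) != n_ch:
            raise BrainVisionParseError(f"{vhdr}: ChannelTypes length != NumberOfChannels")
    else:
        ch_types = ["scalp"] * n_ch

    eeg = vhdr.parent / _get(hdr, "Common Infos", "DataFile", vhdr)
    if not eeg.exists():
        raise BrainVisionParseError(f"{eeg}: data file not found")
    nbytes = eeg.stat().st_size
    if nbytes % (2 * n_ch) != 0:
        raise BrainVisionParseError(
            f"{eeg}: size mismatch: {nbytes} bytes is not a whole number of "
            f"{n_ch}-channel int16 sample frames"
        )
    ints = np.fromfile(eeg, dtype="<i2").reshape(-1, n_ch).T
    data = ints.astype(float) * np.asarray(resolutions)[:, None]

    vmrk = vhdr.parent / _get(hdr, "Common Infos", "MarkerFile", vhdr)
    events = _read_vmrk(vmrk, srate)
    if len(events) and events["sample"].iloc[-1] >= data.shape[1]:
        raise BrainVisionParseError(f"{vmrk}: marker position beyond end of data")
    return RawEEG(
        data=data, srate=srate, ch_names=ch_names, ch_types=ch_types,
        events=events, reference=reference,
    )


def _read_vmrk(vmrk: Path, srate: float) -> pd.DataFrame:
    sections = _parse_ini(vmrk)
    rows = []
    markers = sections.get("Marker Infos", {})
    for key, (val, lineno) in sorted(markers.items(), key=lambda kv: kv[1][1]):
        parts = val.split(",")
        if len(parts) < 5:
            raise BrainVisionParseError(f"{vmrk}:{lineno}: malformed marker {val!r}")
        mtype, desc, pos = parts[0], parts[1], parts[2]
        if mtype != "Stimulus":
            continue
        fields = desc.split(":")
        if len(fields) != 4:
            raise BrainVisionParseError(
                f"{vmrk}:{lineno}: marker description {desc!r} is not role:stimulus:condition:token"
            )
        sample = int(pos) - 1
        rows.append(
            {
                "sample": sample,
                "index": len(rows),
                "stimulus": fields[1],
                "role": fields[0],
                "condition": fields[2],
                "onset_ms": sample / srate * 1000.0,
                "token": int(fields[3]),
            }
        )
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def write_events_vmrk(events: pd.DataFrame, path: str | Path, srate: float = 1000.0) -> Path:
    """Write a bare event table (design export) as a BrainVision marker file."""
    path = Path(path)
    lines = [
        "Brain Vision Data Exchange Marker File, Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        "",
        "[Marker Infos]",
        "Mk1=New Segment,,1,1,0,00000000000000000000",
    ]
    for k, (_, row) in enumerate(events.iterrows(), start=2):
        sample = int(round(row["onset_ms"] / 1000.0 * srate)) if "sample" not in row else int(row["sample"])
        lines.append(f"Mk{k}=Stimulus,{_marker_description(row)},{sample + 1},1,0")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


# ---------------------------------------------------------------------------
# Lossless raw float32 + JSON header fallback
# ---------------------------------------------------------------------------

def write_raw_binary(raw: RawEEG, basename: str | Path) -> Path:
    """Write ``basename``.json (header) + .f32 (float32 channels x samples,
    C order) + .events.tsv; returns the .json path."""
    base = Path(basename)
    base.parent.mkdir(parents=True, exist_ok=True)
    hdr = {
        "srate": raw.srate,
        "ch_names": raw.ch_names,
        "ch_types": raw.ch_types,
        "reference": raw.reference,
        "n_channels": raw.n_channels,
        "n_samples": raw.n_samples,
        "dtype": "float32",
        "order": "C",
        "units": "uV",
    }
    jpath = base.with_suffix(".json")
    jpath.write_text(json.dumps(hdr, indent=1), encoding="utf-8")
    raw.data.astype("<f4").tofile(base.with_suffix(".f32"))
    raw.events.to_csv(base.with_suffix(".events.tsv"), sep="\t", index=False)
    return jpath


def read_raw_binary(basename: str | Path) -> RawEEG:
    base = Path(basename)
    jpath = base if base.suffix == ".json" else base.with_suffix(".json")
    if not jpath.exists():
        raise BrainVisionParseError(f"{jpath}: header not found")
    hdr = json.loads(jpath.read_text(encoding="utf-8"))
    f32 = jpath.with_suffix(".f32")
    expected = hdr["n_channels"] * hdr["n_samples"] * 4
    if f32.stat().st_size != expected:
        raise BrainVisionParseError(
            f"{f32}: size mismatch: expected {expected} bytes, found {f32.stat().st_size}"
        )
    data = np.fromfile(f32, dtype="<f4").reshape(hdr["n_channels"], hdr["n_samples"]).astype(float)
    epath = jpath.with_suffix(".events.tsv")
    events = pd.read_csv(epath, sep="\t") if epath.exists() else pd.DataFrame(columns=EVENT_COLUMNS)
    return RawEEG(
        data=data, srate=hdr["srate"], ch_names=hdr["ch_names"], ch_types=hdr["ch_types"],
        events=events, reference=hdr.get("reference", "Fpz"),
    )
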