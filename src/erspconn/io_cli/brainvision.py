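"""BrainVision triplet reader and fixture writer.

Reads the .vhdr INI-style header, .vmrk markers and the multiplexed .eeg
binary (IEEE float32 or int16 with per-channel resolution scaling); all
channel data are returned scaled to µV.  The writer emits the same dialects
for round-trip tests.
"""
from __future__ import annotations

import re
from pathlib import Path

import numpy as np

from ..errors import DataError
from ..types import RawRecording

__all__ = ["read_brainvision", "write_brainvision"]

_FORMATS = {
    "IEEE_FLOAT_32": np.dtype("<f4"),
    "INT_16": np.dtype("<i2"),
}


def _parse_ini(text: str) -> dict[str, dict[str, str]]:
    sections: dict[str, dict[str, str]] = {}
    current: dict[str, str] | None = None
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith(";") or line.startswith("#"):
            continue
        m = re.match(r"^\[(.+)\]$", line)
        if m:
            current = sections.setdefault(m.group(1), {})
            continue
        if current is not None and "=" in line:
            key, _, value = line.partition("=")
            current[key.strip()] = value.strip()
    return sections


def _read_text(path: Path) -> str:
    raw = path.read_bytes()
    try:
        return raw.decode("utf-8")
    except UnicodeDecodeError:
        return raw.decode("latin-1")


def read_brainvision(path_vhdr: str | Path) -> RawRecording:
    """Read a .vhdr/.vmrk/.eeg triplet into a RawRecording (µV).

    Marker sample positions are taken verbatim from the .vmrk file; only
    markers of type Stimulus/Response/Marker become events, named by their
    description field.
    """
    vhdr = Path(path_vhdr)
    if not vhdr.exists():
        raise DataError(f"header file {vhdr} not found")
    header = _parse_ini(_read_text(vhdr))
    common = header.get("Common Infos", {})
    binary = header.get("Binary Infos", {})
    chan_info = header.get("Channel Infos", {})

    data_file = vhdr.parent / common.get("DataFile", vhdr.stem + ".eeg")
    marker_file = vhdr.parent / common.get("MarkerFile", vhdr.stem + ".vmrk")
    if not data_file.exists():
        raise DataError(f"data file {data_file} missing (sibling of {vhdr.name})")

    orientation = common.get("DataOrientation", "MULTIPLEXED").upper()
    if orientation != "MULTIPLEXED":
        raise DataError(f"unsupported DataOrientation {orientation!r}")
    try:
        n_channels = int(common["NumberOfChannels"])
        sampling_interval_us = float(common["SamplingInterval"])
    except KeyError as exc:
        raise DataError(f"header misses required key {exc}") from exc
    fs = 1e6 / sampling_interval_us

    fmt = binary.get("BinaryFormat", "IEEE_FLOAT_32")
    if fmt not in _FORMATS:
        raise DataError(
            f"unknown BinaryFormat {fmt!r}; supported: {sorted(_FORMATS)}"
        )
    dtype = _FORMATS[fmt]

    labels, resolutions = [], []
    for k in range(1, n_channels + 1):
        entry = chan_info.get(f"Ch{k}")
        if entry is None:
            raise DataError(f"header misses Ch{k} entry")
        parts = entry.split(",")
        labels.append(parts[0])
        res = parts[2] if len(parts) > 2 and parts[2] else "1"
        resolutions.append(float(res))
    resolutions = np.array(resolutions)

    flat = np.fromfile(data_file, dtype=dtype)
    if flat.size % n_channels:
        raise DataError(
            f"data size {flat.size} not divisible by {n_channels} channels"
        )
    data = flat.reshape(-1, n_channels).T.astype(np.float64)
    data *= resolutions[:, None]

    events: list[tuple[int, str]] = []
    if marker_file.exists():
        markers = _parse_ini(_read_text(marker_file)).get("Marker Infos", {})
        for key in sorted(markers, key=lambda k: int(k[2:]) if k[2:].isdigit() else 0):
            parts = markers[key].split(",")
            if len(parts) < 3:
                continue
            mtype, desc, pos = parts[0], parts[1], parts[2]
            if mtype in ("Stimulus", "Response", "Marker") and desc:
                events.append((int(pos), desc))
    return RawRecording(data, fs, labels, events)


def write_brainvision(
    path_vhdr: str | Path,
    raw: RawRecording,
    binary_format: str = "IEEE_FLOAT_32",
    resolution_uv: float = 0.1,
) -> Path:
    """Write a RawRecording as a BrainVision triplet (fixture writer).

    For ``INT_16`` the data are quantized with the given per-channel
    resolution (µV per LSB) and clipped to the int16 range.
    """
    if binary_format not in _FORMATS:
        raise DataError(
            f"unknown BinaryFormat {binary_format!r}; supported: {sorted(_FORMATS)}"
        )
    vhdr = Path(path_vhdr)
    base = vhdr.stem
    eeg = vhdr.with_suffix(".eeg")
    vmrk = vhdr.with_suffix(".vmrk")

    if binary_format == "IEEE_FLOAT_32":
        payload = raw.data.T.astype("<f4")
        resolutions = np.ones(raw.n_channels)
    else:
        scaled = np.round(raw.data / resolution_uv)
        payload = np.clip(scaled, -32768, 32767).T.astype("<i2")
        resolutions = np.full(raw.n_channels, resolution_uv)
    payload.tofile(eeg)

    lines = [
        "Brain Vision Data Exchange Header File Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={eeg.name}",
        f"MarkerFile={vmrk.name}",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={raw.n_channels}",
        f"SamplingInterval={1e6 / raw.fs:g}",
        "",
        "[Binary Infos]",
        f"BinaryFormat={binary_format}",
        "",
        "[Channel Infos]",
    ]
    for k, (label, res) in enumerate(zip(raw.labels, resolutions), start=1):
        lines.append(f"Ch{k}={label},,{res:g},µV")
    vhdr.write_text("\n".join(lines) + "\n", encoding="utf-8")

    mlines = [
        "Brain Vision Data Exchange Marker File, Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={eeg.name}",
        "",
        "[Marker Infos]",
        "Mk1=New Segment,,0,1,0",
    ]
    for k, (sample, name) in enumerate(raw.events, start=2):
        mlines.append(f"Mk{k}=Stimulus,{name},{sample},1,0")
    vmrk.write_text("\n".join(mlines) + "\n", encoding="utf-8")
    return vhdr
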