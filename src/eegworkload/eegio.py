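"""Continuous EEG container I/O.

Native container: ``<stem>.dat`` (float32 little-endian, sample-major
channel-multiplexed) + ``<stem>.json`` header (labels, rate, n_samples)
+ ``<stem>.events.csv`` (sample, trial_id, code).  Round-trips are
lossless within float32.

BrainVision (.vhdr/.vmrk/.eeg) import is read-only and supports the
multiplexed INT_16 / IEEE_FLOAT_32 dialects, applying the per-channel
µV resolution from the header.
"""

from __future__ import annotations

import configparser
import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "EEGRecording",
    "Event",
    "FormatError",
    "ChannelLookupError",
    "write_recording",
    "read_recording",
    "import_brainvision",
]


class FormatError(ValueError):
    """Container file violates the expected on-disk format."""


class ChannelLookupError(KeyError):
    """A requested channel label is absent from the recording."""


@dataclass(frozen=True)
class Event:
    sample: int
    trial_id: int
    code: int


@dataclass
class EEGRecording:
    """Continuous multi-channel recording with stimulus events.

    ``data`` is channels x samples in µV; ``events`` mark stimulus
    onsets (0-based sample index of the first stimulus sample).
    """

    channel_labels: list[str]
    sampling_rate: float
    data: np.ndarray
    events: list[Event] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be a channels x samples matrix")
        if self.data.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"{len(self.channel_labels)} labels but {self.data.shape[0]} data rows"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        n = self.data.shape[1]
        for ev in self.events:
            if not 0 <= ev.sample < n:
                raise ValueError(f"event sample {ev.sample} outside [0, {n})")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise ChannelLookupError(
                f"channel {label!r} not in recording (have {self.channel_labels})"
            ) from None

    def channel(self, label: str) -> np.ndarray:
        return self.data[self.channel_index(label)]


def _paths(path: Path) -> tuple[Path, Path, Path]:
    stem = path.with_suffix("") if path.suffix == ".dat" else path
    return (
        stem.with_suffix(".dat"),
        stem.with_suffix(".json"),
        Path(str(stem) + ".events.csv"),
    )


def write_recording(rec: EEGRecording, path: str | Path) -> Path:
    """Write the native three-file container; returns the ``.dat`` path."""
    dat, hdr, ev = _paths(Path(path))
    dat.parent.mkdir(parents=True, exist_ok=True)
    # sample-major multiplexed: frame n = all channels at sample n
    rec.data.T.astype("<f4").tofile(dat)
    hdr.write_text(
        json.dumps(
            {
                "format": "eegworkload-native",
                "version": 1,
                "channel_labels": rec.channel_labels,
                "sampling_rate": rec.sampling_rate,
                "n_samples": rec.n_samples,
                "dtype": "float32le",
                "order": "multiplexed",
            },
            indent=1,
        )
    )
    pd.DataFrame(
        [(e.sample, e.trial_id, e.code) for e in rec.events],
        columns=["sample", "trial_id", "code"],
    ).to_csv(ev, index=False)
    return dat


def read_recording(path: str | Path) -> EEGRecording:
    """Read a native container written by :func:`write_recording`."""
    dat, hdr, ev = _paths(Path(path))
    for f in (dat, hdr, ev):
        if not f.exists():
            raise FileNotFoundError(f"missing container file: {f}")
    header = json.loads(hdr.read_text())
    labels = list(header["channel_labels"])
    n_samples = int(header["n_samples"])
    n_channels = len(labels)
    expected = n_samples * n_channels * 4
    found = dat.stat().st_size
    if found != expected:
        raise FormatError(
            f"{dat}: expected {expected} bytes "
            f"({n_channels} ch x {n_samples} samples x 4), found {found}"
        )
    raw = np.fromfile(dat, dtype="<f4").reshape(n_samples, n_channels).T
    events_df = pd.read_csv(ev) if ev.stat().st_size else pd.DataFrame()
    events = [
        Event(int(r.sample), int(r.trial_id), int(r.code))
        for r in events_df.itertuples()
    ]
    return EEGRecording(labels, float(header["sampling_rate"]), raw, events)


# --- BrainVision import ----------------------------------------------------

_BV_DTYPES = {"INT_16": "<i2", "IEEE_FLOAT_32": "<f4"}


def _read_bv_ini(path: Path) -> configparser.ConfigParser:
    cp = configparser.ConfigParser(strict=False)
    cp.optionxform = str  # keys are case-sensitive (Ch1 vs ch1)
    text = path.read_text(encoding="utf-8", errors="replace")
    # strip the signature line ("Brain Vision Data Exchange ... File")
    lines = [ln for ln in text.splitlines() if not ln.startswith("Brain Vision")]
    cp.read_string("\n".join(lines))
    return cp


def import_brainvision(vhdr_path: str | Path) -> EEGRecording:
    """Import a BrainVision recording (.vhdr + .eeg + .vmrk).

    Only the multiplexed binary INT_16 / IEEE_FLOAT_32 dialects are
    supported; anything else raises :class:`FormatError`.  Stimulus
    markers become events; BrainVision 1-based marker positions are
    converted to 0-based sample indices.
    """
    vhdr_path = Path(vhdr_path)
    cp = _read_bv_ini(vhdr_path)
    common = cp["Common Infos"]
    fmt = common.get("DataFormat", "BINARY")
    orient = common.get("DataOrientation", "MULTIPLEXED")
    if fmt.upper() != "BINARY" or orient.upper() != "MULTIPLEXED":
        raise FormatError(
            f"unsupported BrainVision dialect: DataFormat={fmt}, "
            f"DataOrientation={orient} (only BINARY/MULTIPLEXED supported)"
        )
    binfmt = cp["Binary Infos"].get("BinaryFormat", "INT_16")
    if binfmt not in _BV_DTYPES:
        raise FormatError(f"unsupported BinaryFormat: {binfmt}")
    n_channels = int(common["NumberOfChannels"])
    # header stores the sampling interval in microseconds
    rate = 1e6 / float(common["SamplingInterval"])

    labels, resolutions = [], []
    for i in range(1, n_channels + 1):
        entry = cp["Channel Infos"][f"Ch{i}"]
        parts = entry.split(",")
        labels.append(parts[0])
        res = parts[2] if len(parts) > 2 and parts[2] else "1"
        resolutions.append(float(res))

    eeg_path = vhdr_path.parent / common["DataFile"]
    raw = np.fromfile(eeg_path, dtype=_BV_DTYPES[binfmt])
    if raw.size % n_channels:
        raise FormatError(
            f"{eeg_path}: {raw.size} values not divisible by {n_channels} channels"
        )
    data = raw.reshape(-1, n_channels).T.astype(np.float64)
    data *= np.asarray(resolutions)[:, None]

    events: list[Event] = []
    marker_file = common.get("MarkerFile")
    if marker_file:
        mk = _read_bv_ini(vhdr_path.parent / marker_file)
        if "Marker Infos" in mk:
            trial = 0
            for key in sorted(
                mk["Marker Infos"], key=lambda k: int(re.sub(r"\D", "", k) or 0)
            ):
                parts = mk["Marker Infos"][key].split(",")
                mtype, desc, pos = parts[0], parts[1], int(parts[2])
                if mtype != "Stimulus":
                    continue
                code_m = re.search(r"(\d+)", desc)
                code = int(code_m.group(1)) if code_m else 0
                events.append(Event(sample=pos - 1, trial_id=trial, code=code))
                trial += 1
    return EEGRecording(labels, rate, data, events)
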