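"""Spectral brain-workload scoring.

Pipeline: zero-phase 0.1-30 Hz band-pass -> stimulus-locked 2-s epochs
(-0.5 to +1.5 s) of correct, artifact-free trials -> per-epoch tapered
FFT power spectra (Tukey taper covering 10% of the segment, zero-padded
to the next power of two; 0.488 Hz bins for 2-s/500-Hz epochs) ->
averaged spectra -> absolute band powers (theta 4-8 Hz at Fz, alpha
8-12 Hz at Pz) -> TAR = theta_Fz / alpha_Pz.

Spectra are power-normalized: the spectrum of a unit-amplitude in-band
sinusoid sums to ~0.5 µV² over its band, and for the untapered variant
the bins sum exactly to the epoch's mean squared amplitude (Parseval).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .eegio import EEGRecording, Event

__all__ = [
    "Epoch",
    "PowerSpectrum",
    "WorkloadScore",
    "InsufficientDataError",
    "EpochConsistencyError",
    "THETA_BAND",
    "ALPHA_BAND",
    "DEFAULT_WINDOW",
    "DEFAULT_ARTIFACT_THRESHOLD",
    "bandpass_filter",
    "extract_epochs",
    "epoch_power_spectrum",
    "band_power",
    "compute_tar",
]

THETA_BAND = (4.0, 8.0)
ALPHA_BAND = (8.0, 12.0)
#: epoch window relative to stimulus onset, seconds
DEFAULT_WINDOW = (-0.5, 1.5)
#: peak-to-peak artifact rejection threshold, µV
DEFAULT_ARTIFACT_THRESHOLD = 150.0
#: fraction of the epoch covered by the raised-cosine taper
TAPER_FRACTION = 0.1


class InsufficientDataError(ValueError):
    """Not enough valid trials/epochs to compute the requested quantity."""


class EpochConsistencyError(ValueError):
    """Trial log and recording events disagree."""


@dataclass(frozen=True)
class Epoch:
    """A stimulus-locked segment of selected channels."""

    trial_id: int
    channel_labels: tuple[str, ...]
    data: np.ndarray  # channels x samples, µV
    sampling_rate: float

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def channel(self, label: str) -> np.ndarray:
        return self.data[self.channel_labels.index(label)]


@dataclass(frozen=True)
class PowerSpectrum:
    channel: str
    frequencies: np.ndarray  # Hz, uniform grid from 0
    power: np.ndarray  # µV² per bin

    @property
    def resolution(self) -> float:
        return float(self.frequencies[1] - self.frequencies[0])


@dataclass(frozen=True)
class WorkloadScore:
    """TAR with its constituent band powers and per-epoch series."""

    theta_fz: float
    alpha_pz: float
    tar: float
    n_epochs: int
    theta_per_epoch: np.ndarray = field(default=None, repr=False)
    alpha_per_epoch: np.ndarray = field(default=None, repr=False)


def bandpass_filter(
    rec: EEGRecording, low: float = 0.1, high: float = 30.0, order: int = 4
) -> EEGRecording:
    """Zero-phase Butterworth band-pass applied per channel.

    Returns a new recording; events are carried over unchanged.
    """
    nyq = rec.sampling_rate / 2.0
    if not (0 < low < high < nyq):
        raise ValueError(
            f"invalid band ({low}, {high}) Hz for rate {rec.sampling_rate} Hz"
        )
    sos = signal.butter(order, [low, high], btype="bandpass", fs=rec.sampling_rate, output="sos")
    # pad several time constants of the low cutoff so edge transients decay
    padlen = min(rec.n_samples - 1, int(round(3.0 * rec.sampling_rate / low)))
    filtered = signal.sosfiltfilt(sos, rec.data, axis=1, padlen=padlen)
    return EEGRecording(
        list(rec.channel_labels), rec.sampling_rate, filtered, list(rec.events)
    )


def extract_epochs(
    rec: EEGRecording,
    trials,
    window: tuple[float, float] = DEFAULT_WINDOW,
    artifact_threshold: float = DEFAULT_ARTIFACT_THRESHOLD,
    channels: tuple[str, ...] = ("Fz", "Pz"),
) -> list[Epoch]:
    """Stimulus-locked epochs of correct, artifact-free trials.

    ``trials`` is a sequence with ``trial_id`` and ``correct``
    attributes (e.g. :class:`~eegworkload.synth.TrialResult`).  A trial
    yields an epoch iff it was answered correctly, the window lies fully
    inside the recording, and the peak-to-peak amplitude stays below
    ``artifact_threshold`` on every analysis channel.
    """
    pre, post = window
    if post <= pre:
        raise ValueError(f"empty epoch window {window}")
    rate = rec.sampling_rate
    n_epoch = int(round((post - pre) * rate))
    idx = [rec.channel_index(c) for c in channels]
    event_by_trial = {ev.trial_id: ev for ev in rec.events}

    missing = [t.trial_id for t in trials if t.trial_id not in event_by_trial]
    if missing:
        raise EpochConsistencyError(
            f"trials without event markers: {missing[:10]}"
            + ("..." if len(missing) > 10 else "")
        )

    epochs = []
    for t in trials:
        if not t.correct:
            continue
        onset = event_by_trial[t.trial_id].sample
        start = onset + int(round(pre * rate))
        stop = start + n_epoch
        if start < 0 or stop > rec.n_samples:
            continue
        seg = rec.data[idx, start:stop]
        ptp = seg.max(axis=1) - seg.min(axis=1)
        if np.any(ptp >= artifact_threshold):
            continue
        epochs.append(Epoch(t.trial_id, tuple(channels), seg.copy(), rate))
    return epochs


def _next_pow2(n: int) -> int:
    return 1 << (int(n - 1)).bit_length()


def taper(n: int, fraction: float = TAPER_FRACTION) -> np.ndarray:
    """Raised-cosine (Hanning-edged) taper over ``fraction`` of the segment.

    ``fraction/2`` of the samples rise at each edge, the middle is flat —
    i.e. a Tukey window with shape parameter ``fraction``.
    """
    return signal.windows.tukey(n, alpha=fraction)


def epoch_power_spectrum(
    epoch: Epoch,
    channel: str,
    taper_fraction: float = TAPER_FRACTION,
) -> PowerSpectrum:
    """Tapered, zero-padded FFT power spectrum of one epoch channel.

    The segment is demeaned, multiplied by the edge taper and zero-padded
    to the next power of two (1024 points for a 1000-sample epoch, giving
    500/1024 ≈ 0.488 Hz bins at 500 Hz).  Per-bin power is scaled by
    2 / (N_fft · Σw²) so that bins are in µV² and, with a boxcar taper,
    sum exactly to the segment's mean squared amplitude.
    """
    x = np.asarray(epoch.channel(channel), dtype=np.float64)
    n = x.size
    if n < 2:
        raise ValueError("epoch must contain at least 2 samples")
    x = x - x.mean()
    w = taper(n, taper_fraction) if taper_fraction > 0 else np.ones(n)
    nfft = _next_pow2(n)
    spec = np.fft.rfft(x * w, n=nfft)
    # mean-square normalization: with w = boxcar, sum(power) == mean(x**2)
    power = 2.0 * np.abs(spec) ** 2 / (nfft * np.sum(w**2))
    power[0] /= 2.0
    if nfft % 2 == 0:
        power[-1] /= 2.0
    freqs = np.fft.rfftfreq(nfft, d=1.0 / epoch.sampling_rate)
    return PowerSpectrum(channel=channel, frequencies=freqs, power=power)


def band_power(spectrum: PowerSpectrum, band: tuple[float, float]) -> float:
    """Sum of bin powers whose center lies in [lo, hi)."""
    lo, hi = band
    if not (0 <= lo < hi):
        raise ValueError(f"invalid band {band}")
    if hi > spectrum.frequencies[-1]:
        raise ValueError(
            f"band {band} exceeds spectrum range (max {spectrum.frequencies[-1]:.1f} Hz)"
        )
    mask = (spectrum.frequencies >= lo) & (spectrum.frequencies < hi)
    if not mask.any():
        raise ValueError(f"band {band} contains no frequency bins")
    return float(spectrum.power[mask].sum())


def _mean_spectrum(epochs, channel: str) -> PowerSpectrum:
    spectra = [epoch_power_spectrum(ep, channel) for ep in epochs]
    power = np.mean([s.power for s in spectra], axis=0)
    return PowerSpectrum(channel, spectra[0].frequencies, power)


def compute_tar(
    epochs,
    theta_channel: str = "Fz",
    alpha_channel: str = "Pz",
    theta_band: tuple[float, float] = THETA_BAND,
    alpha_band: tuple[float, float] = ALPHA_BAND,
    method: str = "ratio_of_means",
) -> WorkloadScore:
    """Theta/alpha brain-workload score from a set of epochs.

    Per-epoch spectra are averaged into mean spectra per channel; the
    score is theta power at ``theta_channel`` over alpha power at
    ``alpha_channel``.  ``method='mean_of_ratios'`` instead averages the
    per-epoch theta/alpha ratios.
    """
    epochs = list(epochs)
    if not epochs:
        raise InsufficientDataError("no epochs available for TAR computation")
    theta_series = np.array(
        [band_power(epoch_power_spectrum(ep, theta_channel), theta_band) for ep in epochs]
    )
    alpha_series = np.array(
        [band_power(epoch_power_spectrum(ep, alpha_channel), alpha_band) for ep in epochs]
    )
    theta_fz = float(theta_series.mean())
    alpha_pz = float(alpha_series.mean())
    if alpha_pz <= 0:
        raise InsufficientDataError("zero alpha power: TAR undefined")
    if method == "ratio_of_means":
        tar = theta_fz / alpha_pz
    elif method == "mean_of_ratios":
        if np.any(alpha_series <= 0):
            raise InsufficientDataError("zero per-epoch alpha power: TAR undefined")
        tar = float(np.mean(theta_series / alpha_series))
    else:
        raise ValueError(f"unknown TAR method: {method!r}")
    return WorkloadScore(
        theta_fz=theta_fz,
        alpha_pz=alpha_pz,
        tar=tar,
        n_epochs=len(epochs),
        theta_per_epoch=theta_series,
        alpha_per_epoch=alpha_series,
    )
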