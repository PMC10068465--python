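"""Sensor-space preprocessing: line-noise removal, artifact-channel rejection,
and ripple-band filtering.

The cleaning chain assumed here is deliberately small: line noise is removed by
regressing out sinusoids at the line frequency and its harmonics (the classic
"DFT filter"), channels whose z-scored amplitude spends too much time beyond a
hard bound are flagged as bad, and the ripple band (80-250 Hz) is isolated with
a zero-phase FIR band-pass.  Ocular/cardiac ICA cleaning is an upstream concern
and is not part of this package: pass in pre-cleaned or synthetic data.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

LOBES = ("frontal", "temporal", "parietal", "occipital")

#: Neuromag-style 306-channel split: 78 frontal / 78 temporal / 78 parietal /
#: 72 occipital.  Used when no explicit channel->lobe table is supplied.
DEFAULT_LOBE_COUNTS = {"frontal": 78, "temporal": 78, "parietal": 78, "occipital": 72}

RIPPLE_BAND = (80.0, 250.0)


def default_lobe_map(channel_names: list[str]) -> dict[str, str]:
    """Assign channels to the four lobes in contiguous blocks.

    For 306 channels the block sizes are the standard 78/78/78/72 split; for
    other channel counts the same proportions are used (largest-remainder
    rounding) so the map always covers every channel.
    """
    n = len(channel_names)
    total = sum(DEFAULT_LOBE_COUNTS.values())
    raw = {k: v * n / total for k, v in DEFAULT_LOBE_COUNTS.items()}
    counts = {k: int(np.floor(v)) for k, v in raw.items()}
    rem = n - sum(counts.values())
    for k in sorted(raw, key=lambda k: raw[k] - counts[k], reverse=True)[:rem]:
        counts[k] += 1
    lobe_map = {}
    i = 0
    for lobe in LOBES:
        for _ in range(counts[lobe]):
            lobe_map[channel_names[i]] = lobe
            i += 1
    return lobe_map


@dataclass
class Recording:
    """Multichannel time series plus the metadata downstream stages need.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Field amplitude in arbitrary units.
    fs : float
        Sampling rate in Hz.
    channel_names : list of str
    lobe_map : dict
        channel name -> one of {"frontal", "temporal", "parietal", "occipital"}.
    bad_channels : set of str
        Channels excluded from all downstream stages.
    """

    data: np.ndarray
    fs: float
    channel_names: list[str] = field(default_factory=list)
    lobe_map: dict[str, str] = field(default_factory=dict)
    bad_channels: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not self.channel_names:
            self.channel_names = [f"MEG{i:04d}" for i in range(self.data.shape[0])]
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError("channel_names length must match data rows")
        if not self.lobe_map:
            self.lobe_map = default_lobe_map(self.channel_names)
        missing = set(self.channel_names) - set(self.lobe_map)
        if missing:
            raise ValueError(f"lobe_map missing channels: {sorted(missing)[:5]}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def good_indices(self) -> np.ndarray:
        return np.array(
            [i for i, ch in enumerate(self.channel_names) if ch not in self.bad_channels],
            dtype=int,
        )

    def copy_with(self, **kw) -> "Recording":
        return dataclasses.replace(self, **kw)


def remove_line_noise(rec: Recording, line_freq: float = 50.0, harmonics: int = 2) -> Recording:
    """Remove power-line interference by least-squares sinusoid regression.

    Fits sine and cosine components at ``line_freq`` and its first
    ``harmonics - 1`` harmonics over the whole record and subtracts them
    (the discrete-Fourier-transform filter used by fieldtrip's ``dftfilter``).
    Attenuation of a stationary line component is essentially complete; all
    other frequencies are untouched up to the regressors' leakage.
    """
    if line_freq >= rec.fs / 2:
        raise ValueError(f"line frequency {line_freq} Hz at or above Nyquist ({rec.fs / 2} Hz)")
    harmonics = max(1, int(harmonics))
    t = np.arange(rec.n_samples) / rec.fs
    cols = []
    for h in range(1, harmonics + 1):
        f = line_freq * h
        if f >= rec.fs / 2:
            break
        cols.append(np.cos(2 * np.pi * f * t))
        cols.append(np.sin(2 * np.pi * f * t))
    X = np.column_stack(cols)  # (n_samples, 2*h)
    # one shared pseudoinverse for all channels
    beta, *_ = np.linalg.lstsq(X, rec.data.T, rcond=None)
    cleaned = rec.data - (X @ beta).T
    return rec.copy_with(data=cleaned)


def reject_channels(
    rec: Recording, z_abs_limit: float = 5.0, frac_limit: float = 0.001
) -> Recording:
    """Flag artifact channels from their own z-score statistics.

    A channel is bad iff the fraction of samples with ``|z| > z_abs_limit``
    exceeds ``frac_limit`` (z computed against the channel's own mean/SD).
    Zero-variance (dead) channels are flagged rather than crashing the
    z-scoring.  The operation is idempotent: statistics are computed from the
    raw data, not from previously surviving channels.
    """
    if rec.n_channels < 2:
        raise ValueError("need at least 2 channels")
    bad = set(rec.bad_channels)
    mu = rec.data.mean(axis=1, keepdims=True)
    sd = rec.data.std(axis=1, keepdims=True)
    for i, ch in enumerate(rec.channel_names):
        if sd[i, 0] == 0:
            bad.add(ch)
            continue
        frac = np.mean(np.abs((rec.data[i] - mu[i]) / sd[i]) > z_abs_limit)
        if frac > frac_limit:
            bad.add(ch)
    if len(bad) == rec.n_channels:
        raise ValueError("no usable channels: every channel was flagged as artifact")
    return rec.copy_with(bad_channels=bad)


def _ripple_fir(fs: float, band: tuple[float, float]) -> np.ndarray:
    # Cutoffs pushed ~8 Hz outside the nominal band so the band edges sit in
    # the flat passband; the Hamming transition (~13 Hz at 257 taps / 1 kHz)
    # then puts band +/- 20% well into the stopband.
    lo, hi = band
    margin = 0.1 * lo
    numtaps = int(round(4 * fs / 16.0)) | 1
    return signal.firwin(
        numtaps, [max(lo - margin, 1.0), min(hi + margin, fs / 2 - 1.0)],
        pass_zero=False, fs=fs,
    )


def bandpass_ripple(rec: Recording, band: tuple[float, float] = RIPPLE_BAND) -> Recording:
    """Zero-phase FIR band-pass to the ripple band (default 80-250 Hz)."""
    lo, hi = band
    if not (0 < lo < hi < rec.fs / 2):
        raise ValueError(f"band {band} must satisfy 0 < low < high < Nyquist")
    taps = _ripple_fir(rec.fs, (lo, hi))
    out = signal.filtfilt(taps, [1.0], rec.data, axis=1)
    return rec.copy_with(data=out)


def bandpass_array(x: np.ndarray, fs: float, band: tuple[float, float] = RIPPLE_BAND) -> np.ndarray:
    """Band-pass a raw array with the same zero-phase FIR as `bandpass_ripple`."""
    x = np.asarray(x, dtype=float)
    taps = _ripple_fir(fs, band)
    padlen = min(3 * len(taps), x.shape[-1] - 1)
    return signal.filtfilt(taps, [1.0], x, axis=-1, padlen=padlen)
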