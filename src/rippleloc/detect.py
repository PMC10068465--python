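"""Automatic ripple detection with a dynamic peak-points-distribution-curve
(PPDC) threshold.

Pipeline per channel: the raw (line-noise-cleaned) trace is cut into 0.6 s
sliding windows (50% overlap); each window is wavelet-denoised (db4, soft
universal threshold) and then band-passed to 80-250 Hz; the peaks of the
rectified trace are ranked from highest to lowest to form the PPDC; a
straight line is fitted to the 30%-60% rank segment of that curve and the
detection threshold is the fitted line extrapolated to the top rank, raised
by 5%.  Runs of four or more consecutive supra-threshold peaks whose spacing
is compatible with 80-250 Hz oscillation and whose amplitude envelope rises
and falls smoothly (unimodal) are reported as ripple events; events found in
overlapping windows are merged.

Because the PPDC threshold is re-fitted in every window it adapts to local
signal level: multiplying a window by any k > 0 multiplies the threshold by
exactly k.  A per-window relative threshold alone cannot reject the
oscillatory events that band-limited background noise produces by itself, so
candidate peaks must additionally clear an RMS floor: a multiple (default
10x) of the channel's median per-window ripple-band RMS, the robust estimate
of that channel's background level.  Scaling an entire recording rescales
both gates, so detection decisions are unchanged by global amplitude scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import signal

from .preprocess import RIPPLE_BAND, Recording, bandpass_array

# Peak convention: peaks are local maxima of the rectified band-passed trace
# with a minimum spacing of one 250 Hz period (4 ms).  The spacing floor
# suppresses the half-cycle double peaks of rectification, so surviving
# inter-peak intervals of a ripple fall in [4, 12.5] ms (one period of
# 250-80 Hz) and the event's mean frequency is 1 / median(interval).
MIN_PEAK_PERIOD_S = 1.0 / 250.0
MAX_PEAK_PERIOD_S = 1.0 / 80.0

DEFAULT_WINDOW_S = 0.6
DEFAULT_FIT_RANGE = (0.30, 0.60)
DEFAULT_MULTIPLIER = 1.05
MIN_PEAKS_FOR_PPDC = 10
MIN_RUN_PEAKS = 4
ENVELOPE_TOL = 0.20
RMS_FLOOR_FACTOR = 10.0


@dataclass
class RippleEvent:
    """A detected ripple: where, when, and its peak train."""

    channel: str
    onset: float
    offset: float
    peak_times: list[float]
    peak_amplitudes: list[float]
    freq_hz: float | None = None

    @property
    def n_peaks(self) -> int:
        return len(self.peak_times)

    @property
    def mean_freq(self) -> float:
        """Oscillation frequency in Hz.

        The detector stores a zero-crossing estimate (``freq_hz``); when
        absent, falls back to the median inter-peak interval.  Rectified
        peak trains below 125 Hz keep both half-cycle peaks, so the
        fallback reads intervals as half-periods when the full-period
        reading would fall under the ripple band.
        """
        if self.freq_hz is not None:
            return self.freq_hz
        if self.n_peaks < 2:
            return float("nan")
        med = float(np.median(np.diff(self.peak_times)))
        full = 1.0 / med
        half = 1.0 / (2.0 * med)
        return half if half >= 80.0 else full

    def validate(self) -> None:
        if self.n_peaks < MIN_RUN_PEAKS:
            raise ValueError("ripple event needs >= 4 peaks")
        if not self.offset > self.onset:
            raise ValueError("offset must exceed onset")


@dataclass
class PPDCModel:
    """Ranked-peak distribution curve and the threshold fitted from it.

    ``sorted_peaks`` holds peak amplitudes ranked highest to lowest; a least
    squares line over (rank, amplitude) restricted to ``fit_range`` (the
    30%-60% rank segment by default) gives ``slope``/``intercept``; the
    detection threshold is ``multiplier * intercept``, i.e. the fitted line
    extrapolated to rank 0 and raised 5%.
    """

    sorted_peaks: np.ndarray
    fit_range: tuple[int, int]
    slope: float
    intercept: float
    threshold: float
    degenerate: bool = False


def denoise_db4(window: np.ndarray, level: int = 4) -> np.ndarray:
    """Wavelet soft-threshold denoising with Daubechies-4.

    Decomposes to `level` levels, estimates the noise scale sigma by the
    median absolute deviation rule (sigma = MAD / 0.6745) using the smallest
    MAD across detail levels — for white noise every level carries the same
    sigma, while narrowband signal content can only inflate some levels, so
    the minimum is robust against in-band oscillations leaking into the
    finest scale.  Applies the universal threshold sigma * sqrt(2 ln N) to
    every detail level (hard, which avoids the shrinkage bias that soft
    thresholding puts on every retained oscillation coefficient) and
    reconstructs.
    """
    x = np.asarray(window, dtype=float)
    n = x.shape[-1]
    if n < 2**level:
        raise ValueError(f"window of {n} samples too short for level-{level} db4 decomposition")
    coeffs = pywt.wavedec(x, "db4", level=level)
    sigma = min(np.median(np.abs(c)) for c in coeffs[1:]) / 0.6745
    if sigma == 0:
        return x.copy()
    thr = sigma * np.sqrt(2.0 * np.log(n))
    coeffs = [coeffs[0]] + [pywt.threshold(c, thr, mode="hard") for c in coeffs[1:]]
    out = pywt.waverec(coeffs, "db4")
    return out[..., :n]


def _find_peaks(x: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Peak sample indices and amplitudes of the rectified trace."""
    rect = np.abs(x)
    dist = max(1, int(np.ceil(MIN_PEAK_PERIOD_S * fs)))
    idx, _ = signal.find_peaks(rect, distance=dist)
    return idx, rect[idx]


def build_ppdc(
    window: np.ndarray,
    fs: float,
    fit_range: tuple[float, float] = DEFAULT_FIT_RANGE,
    multiplier: float = DEFAULT_MULTIPLIER,
) -> PPDCModel:
    """Fit the peak-points distribution curve of one window.

    Windows with fewer than 10 peaks are marked degenerate and skipped by the
    detector.
    """
    _, amps = _find_peaks(np.asarray(window, dtype=float), fs)
    order = np.sort(amps)[::-1]
    n = order.size
    if n < MIN_PEAKS_FOR_PPDC:
        return PPDCModel(order, (0, 0), float("nan"), float("nan"), float("nan"), degenerate=True)
    lo = int(np.floor(fit_range[0] * n))
    hi = max(lo + 2, int(np.ceil(fit_range[1] * n)))
    ranks = np.arange(lo, min(hi, n), dtype=float)
    seg = order[lo:min(hi, n)]
    slope, intercept = np.polyfit(ranks, seg, 1)
    threshold = multiplier * intercept
    return PPDCModel(order, (lo, min(hi, n)), float(slope), float(intercept), float(threshold))


def _unimodal_run(amps: np.ndarray, tol: float = ENVELOPE_TOL) -> tuple[int, int]:
    """Longest unimodal stretch around the maximum of a peak-amplitude run.

    Grows left from the argmax while each step back stays within a
    (1 - tol) non-decreasing envelope, and right while non-increasing within
    (1 + tol).  Returns [start, stop) bounds.
    """
    m = int(np.argmax(amps))
    start = m
    while start > 0 and amps[start] >= amps[start - 1] * (1.0 - tol) and amps[start - 1] <= amps[m]:
        start -= 1
    stop = m + 1
    while stop < len(amps) and amps[stop] <= amps[stop - 1] * (1.0 + tol) and amps[stop] <= amps[m]:
        stop += 1
    return start, stop


def _detect_in_window(
    x: np.ndarray,
    fs: float,
    t0: float,
    channel: str,
    fit_range: tuple[float, float],
    multiplier: float,
    amp_floor: float,
) -> list[RippleEvent]:
    model = build_ppdc(x, fs, fit_range, multiplier)
    if model.degenerate or not np.isfinite(model.threshold) or model.threshold <= 0:
        return []
    idx, amps = _find_peaks(x, fs)
    times = t0 + idx / fs
    supra = amps > max(model.threshold, amp_floor)
    max_gap = MAX_PEAK_PERIOD_S + 0.5 / fs
    events: list[RippleEvent] = []
    i = 0
    n = len(idx)
    while i < n:
        if not supra[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and supra[j + 1] and (times[j + 1] - times[j]) <= max_gap:
            j += 1
        run = slice(i, j + 1)
        if j - i + 1 >= MIN_RUN_PEAKS:
            a, b = _unimodal_run(amps[run])
            a += i
            b += i
            if b - a >= MIN_RUN_PEAKS:
                # zero-crossing frequency over the peak train's extent
                seg = x[idx[a] : idx[b - 1] + 1]
                dur = (idx[b - 1] - idx[a]) / fs
                zc = int(np.count_nonzero(np.diff(np.signbit(seg))))
                freq = zc / (2.0 * dur) if dur > 0 and zc > 0 else None
                ev = RippleEvent(
                    channel=channel,
                    onset=float(times[a]),
                    offset=float(times[b - 1]),
                    peak_times=[float(t) for t in times[a:b]],
                    peak_amplitudes=[float(v) for v in amps[a:b]],
                    freq_hz=freq,
                )
                events.append(ev)
        i = j + 1
    return events


def _merge_channel_events(events: list[RippleEvent]) -> list[RippleEvent]:
    """Merge events from overlapping windows sharing > 50% temporal overlap."""
    if not events:
        return []
    events = sorted(events, key=lambda e: (e.onset, e.offset))
    merged = [events[0]]
    for ev in events[1:]:
        cur = merged[-1]
        inter = min(cur.offset, ev.offset) - max(cur.onset, ev.onset)
        shorter = min(cur.offset - cur.onset, ev.offset - ev.onset)
        if inter > 0 and (shorter <= 0 or inter / max(shorter, 1e-12) > 0.5):
            # union the peak trains, deduplicating peaks closer than 1 ms
            pts = sorted(zip(cur.peak_times + ev.peak_times, cur.peak_amplitudes + ev.peak_amplitudes))
            keep_t: list[float] = []
            keep_a: list[float] = []
            for t, a in pts:
                # peaks closer than the minimum peak spacing are duplicates
                # of the same peak seen from two overlapping windows
                if keep_t and t - keep_t[-1] < MIN_PEAK_PERIOD_S - 1e-9:
                    keep_a[-1] = max(keep_a[-1], a)
                else:
                    keep_t.append(t)
                    keep_a.append(a)
            merged[-1] = RippleEvent(
                channel=cur.channel,
                onset=min(cur.onset, ev.onset),
                offset=max(cur.offset, ev.offset),
                peak_times=keep_t,
                peak_amplitudes=keep_a,
                freq_hz=(cur if cur.n_peaks >= ev.n_peaks else ev).freq_hz,
            )
        else:
            merged.append(ev)
    return merged


def detect_ripples(
    rec: Recording,
    window_s: float = DEFAULT_WINDOW_S,
    overlap_frac: float = 0.5,
    fit_range: tuple[float, float] = DEFAULT_FIT_RANGE,
    multiplier: float = DEFAULT_MULTIPLIER,
    band: tuple[float, float] = RIPPLE_BAND,
    rms_floor_factor: float = RMS_FLOOR_FACTOR,
    denoise: bool = True,
    prefiltered: bool = False,
) -> list[RippleEvent]:
    """Detect ripples on every good channel of a preprocessed recording.

    ``rec`` should be the line-noise-cleaned broadband recording: each
    window is db4-denoised first and then band-passed to ``band``.  Pass
    ``prefiltered=True`` when ``rec`` is already band-passed (band-passing
    is then skipped; denoising on a band-limited trace is nearly a no-op).
    Returns the merged event list sorted by channel then onset; an empty
    list when nothing is found.
    """
    win = int(round(window_s * rec.fs))
    step = max(1, int(round(win * (1.0 - overlap_frac))))
    out: list[RippleEvent] = []
    for ci in rec.good_indices():
        ch = rec.channel_names[ci]
        x = rec.data[ci]
        starts = list(range(0, max(1, rec.n_samples - win + 1), step))
        traces: list[np.ndarray] = []
        for start in starts:
            seg = x[start : start + win]
            if seg.size < win // 2:
                starts = starts[: len(traces)]
                break
            if denoise:
                seg = denoise_db4(seg)
            if not prefiltered:
                seg = bandpass_array(seg, rec.fs, band)
            traces.append(seg)
        if not traces:
            continue
        floor = rms_floor_factor * float(np.median([t.std() for t in traces]))
        ch_events: list[RippleEvent] = []
        for start, seg in zip(starts, traces):
            ch_events.extend(
                _detect_in_window(
                    seg, rec.fs, start / rec.fs, ch, fit_range, multiplier, floor
                )
            )
        out.extend(_merge_channel_events(ch_events))
    out.sort(key=lambda e: (e.channel, e.onset))
    return out


def ripple_count_rate(events: list[RippleEvent], duration_s: float) -> float:
    """Event count normalized to events per 10 minutes."""
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    return len(events) * 600.0 / duration_s
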