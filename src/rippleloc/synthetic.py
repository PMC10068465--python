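"""Ground-truth MEG simulation: band-limited sensor noise, injected ripple
bursts, and dipolar sources projected through a known lead field.

Every downstream stage of the toolkit is testable against the ground truth
returned here.  Bursts are Hann-windowed sinusoids (a smooth rise-and-fall
envelope, the shape the detector's oscillation-trend rule expects of a real
ripple); background noise is white or pink (1/f spectral shaping of white
Gaussian noise); sources are waveforms mixed into the sensors through the
lead-field matrix of a toy forward model.  All outputs are deterministic
functions of the spec plus its seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .detect import RippleEvent
from .preprocess import Recording, default_lobe_map

RIPPLE_FREQ_RANGE = (80.0, 250.0)

# Acquisition defaults: 306-channel Neuromag-style array sampled at 1 kHz.
DEFAULT_N_CHANNELS = 306
DEFAULT_FS = 1000.0
N_ROIS = 90


@dataclass
class RipplePlanEntry:
    channel: int
    onset: float           # s
    freq: float            # Hz, within [80, 250]
    n_cycles: int
    amplitude: float       # peak amplitude as multiple of background RMS


@dataclass
class SourcePlanEntry:
    grid_index: int
    waveform: np.ndarray   # (n_samples,) source time course


@dataclass
class SimulationSpec:
    """Everything that determines one synthetic recording."""

    duration: float
    n_channels: int = DEFAULT_N_CHANNELS
    fs: float = DEFAULT_FS
    ripple_plan: list[RipplePlanEntry] = field(default_factory=list)
    source_plan: list[SourcePlanEntry] = field(default_factory=list)
    noise_model: str = "pink"            # {"pink", "white"}
    noise_amplitude: float = 1.0         # RMS of the background noise
    seed: int = 0

    def validate(self) -> None:
        if self.fs < 2 * RIPPLE_FREQ_RANGE[1]:
            raise ValueError(f"fs={self.fs} cannot represent the ripple band (need >= 500 Hz)")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.noise_model not in ("pink", "white"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        for r in self.ripple_plan:
            if not (RIPPLE_FREQ_RANGE[0] <= r.freq <= RIPPLE_FREQ_RANGE[1]):
                raise ValueError(
                    f"burst frequency {r.freq} Hz outside ripple band {RIPPLE_FREQ_RANGE}"
                )
            if not (0 <= r.channel < self.n_channels):
                raise ValueError(f"burst channel {r.channel} out of range")
            if r.onset < 0 or r.onset + r.n_cycles / r.freq > self.duration:
                raise ValueError(f"burst at t={r.onset}s does not fit inside the recording")


@dataclass
class SourceModel:
    """Forward model: lead field, source grid, parcellation, resection mask."""

    lead_field: np.ndarray          # (n_channels, n_sources), fixed orientation
    grid_coords: np.ndarray         # (n_sources, 3) in a unit volume
    roi_labels: np.ndarray          # (n_sources,) int labels in 1..90
    resection: set[int] = field(default_factory=set)   # ROI labels

    @property
    def n_sources(self) -> int:
        return self.lead_field.shape[1]

    def grid_spacing(self) -> float:
        """Median nearest-neighbour distance of the source grid."""
        from scipy.spatial import cKDTree

        d, _ = cKDTree(self.grid_coords).query(self.grid_coords, k=2)
        return float(np.median(d[:, 1]))

    def roi_centroids(self) -> dict[int, np.ndarray]:
        return {
            int(l): self.grid_coords[self.roi_labels == l].mean(axis=0)
            for l in np.unique(self.roi_labels)
        }


@dataclass
class GroundTruth:
    true_events: list[RippleEvent]
    true_source_indices: list[int]
    lead_field: np.ndarray | None = None


def pink_noise(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    """1/f-shaped Gaussian noise, unit RMS per channel."""
    n_ch, n = shape
    white = rng.standard_normal((n_ch, n))
    f = np.fft.rfftfreq(n)
    scale = np.ones_like(f)
    scale[1:] = 1.0 / np.sqrt(f[1:])
    scale[0] = 0.0
    x = np.fft.irfft(np.fft.rfft(white, axis=1) * scale, n=n, axis=1)
    rms = x.std(axis=1, keepdims=True)
    rms[rms == 0] = 1.0
    return x / rms


def _hann_burst(freq: float, n_cycles: int, fs: float) -> np.ndarray:
    n = max(2, int(round(n_cycles / freq * fs)))
    t = np.arange(n) / fs
    return np.hanning(n) * np.sin(2 * np.pi * freq * t)


def simulate_recording(spec: SimulationSpec) -> tuple[Recording, GroundTruth]:
    """Generate one recording plus its ground truth.

    Sensor data = noise + injected Hann-windowed ripple bursts (amplitudes
    quoted relative to the channel's background RMS) [+ lead-field-projected
    sources when a source plan is given, see :func:`simulate_sources`].
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * spec.fs))
    shape = (spec.n_channels, n)
    if spec.noise_amplitude > 0:
        noise = pink_noise(rng, shape) if spec.noise_model == "pink" else rng.standard_normal(shape)
        data = spec.noise_amplitude * noise
    else:
        data = np.zeros(shape)
    background_rms = spec.noise_amplitude if spec.noise_amplitude > 0 else 1.0

    names = [f"MEG{i:04d}" for i in range(spec.n_channels)]
    events: list[RippleEvent] = []
    seen: dict[int, list[tuple[float, float]]] = {}
    for r in spec.ripple_plan:
        burst = _hann_burst(r.freq, r.n_cycles, spec.fs) * (r.amplitude * background_rms)
        i0 = int(round(r.onset * spec.fs))
        dur = burst.size / spec.fs
        for (a, b) in seen.get(r.channel, []):
            if r.onset < b and a < r.onset + dur:
                warnings.warn(
                    f"overlapping bursts on channel {r.channel} near t={r.onset:.3f}s; "
                    "both injected and recorded",
                    stacklevel=2,
                )
        seen.setdefault(r.channel, []).append((r.onset, r.onset + dur))
        data[r.channel, i0 : i0 + burst.size] += burst
        peak_period = 1.0 / r.freq
        peak_times = [r.onset + (k + 0.25) * peak_period for k in range(r.n_cycles)]
        events.append(
            RippleEvent(
                channel=names[r.channel],
                onset=r.onset,
                offset=r.onset + dur,
                peak_times=peak_times,
                peak_amplitudes=[float(r.amplitude * background_rms)] * r.n_cycles,
            )
        )
    rec = Recording(data=data, fs=spec.fs, channel_names=names, lobe_map=default_lobe_map(names))
    return rec, GroundTruth(true_events=events, true_source_indices=[])


def simulate_sources(
    spec: SimulationSpec, source_model: SourceModel
) -> tuple[Recording, GroundTruth]:
    """Like :func:`simulate_recording` but mixes the source plan through the
    lead field: ``sensors = lead_field @ sources + noise`` (exact when the
    noise amplitude is zero)."""
    if spec.n_channels != source_model.lead_field.shape[0]:
        raise ValueError("spec.n_channels must match lead-field rows")
    rec, gt = simulate_recording(spec)
    n = rec.n_samples
    for s in spec.source_plan:
        if not (0 <= s.grid_index < source_model.n_sources):
            raise ValueError(f"source grid index {s.grid_index} out of range")
        w = np.zeros(n)
        m = min(n, len(s.waveform))
        w[:m] = np.asarray(s.waveform, dtype=float)[:m]
        rec.data += np.outer(source_model.lead_field[:, s.grid_index], w)
        gt.true_source_indices.append(s.grid_index)
    gt.lead_field = source_model.lead_field
    return rec, gt


def make_toy_forward_model(
    n_channels: int,
    n_sources: int,
    geometry: str = "spherical-toy",
    seed: int = 0,
    n_rois: int = N_ROIS,
) -> SourceModel:
    """Build a self-contained toy forward model for testing localization.

    ``spherical-toy``: sensors on a sphere of radius 1.2 looking at dipolar
    sources on a regular lattice inside the unit ball; gains follow the
    magnetic field of a point dipole projected on the sensor normal.
    ``random-orthogonal``: lead-field columns from the QR factorization of a
    Gaussian matrix (orthonormal, guaranteed full column rank), grid points
    uniform in the unit cube.

    The parcellation assigns every grid point to the nearest of ``n_rois``
    centroids drawn from the grid itself, so every label 1..n_rois owns at
    least one point.
    """
    if n_sources < 1:
        raise ValueError("need at least one source")
    rng = np.random.default_rng(seed)
    if geometry == "random-orthogonal":
        if n_sources > n_channels:
            warnings.warn("n_sources > n_channels: lead field cannot be full column rank")
            g = rng.standard_normal((n_channels, n_sources))
            lf = g / np.linalg.norm(g, axis=0, keepdims=True)
        else:
            q, _ = np.linalg.qr(rng.standard_normal((n_channels, n_sources)))
            lf = q
        coords = rng.uniform(-0.5, 0.5, size=(n_sources, 3))
    elif geometry == "spherical-toy":
        # regular lattice inside the unit ball
        m = int(np.ceil(n_sources ** (1 / 3)))
        while True:
            ax = np.linspace(-0.6, 0.6, m)
            gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
            pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
            pts = pts[np.linalg.norm(pts, axis=1) <= 0.8]
            if len(pts) >= n_sources:
                break
            m += 1
        coords = pts[:n_sources]
        # sensors spread on a sphere of radius 1.2 (Fibonacci lattice)
        k = np.arange(n_channels)
        phi = np.arccos(1 - 2 * (k + 0.5) / n_channels)
        theta = np.pi * (1 + 5**0.5) * k
        sens = 1.2 * np.column_stack(
            [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
        )
        normals = sens / np.linalg.norm(sens, axis=1, keepdims=True)
        ori = rng.standard_normal((n_sources, 3))
        ori /= np.linalg.norm(ori, axis=1, keepdims=True)
        lf = np.empty((n_channels, n_sources))
        for j in range(n_sources):
            r = sens - coords[j]
            d = np.linalg.norm(r, axis=1, keepdims=True)
            rhat = r / d
            # point magnetic dipole: B ~ (3(m.rhat)rhat - m)/d^3
            b = (3 * (rhat @ ori[j])[:, None] * rhat - ori[j]) / d**3
            lf[:, j] = np.einsum("ij,ij->i", b, normals)
        if n_sources > n_channels:
            warnings.warn("n_sources > n_channels: lead field cannot be full column rank")
    else:
        raise ValueError(f"unknown geometry {geometry!r}")

    n_rois_eff = min(n_rois, n_sources)
    centroid_idx = rng.choice(n_sources, size=n_rois_eff, replace=False)
    centroids = coords[centroid_idx]
    d2 = ((coords[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    labels = d2.argmin(axis=1) + 1
    return SourceModel(lead_field=lf, grid_coords=coords, roi_labels=labels.astype(int))


def band_noise(rng: np.random.Generator, n: int, fs: float = 1000.0) -> np.ndarray:
    """Unit-RMS ripple-band (80-250 Hz) Gaussian noise."""
    from .preprocess import bandpass_array

    x = bandpass_array(rng.standard_normal(n + 200), fs)[100:-100]
    return x / x.std()


@dataclass
class PlantedHub:
    """Ground truth of a planted-hub network scenario."""

    windows: np.ndarray            # (n_events, n_channels, n_samples)
    chain_sites: list[int]         # grid indices, hub first
    chain_rois: list[int]          # ROI labels along the chain
    hub_roi: int
    resection: set[int]
    main_site_per_event: list[int]  # index into chain_sites


def simulate_planted_hub(
    source_model: SourceModel,
    n_events: int = 24,
    chain_len: int = 5,
    coupling: float = 0.88,
    sub_amp: float = 0.6,
    snr: float = 40.0,
    delay_s: float = 0.006,
    p_hub: float = 0.5,
    fs: float = 1000.0,
    window_s: float = 0.3,
    seed: int = 0,
) -> PlantedHub:
    """Simulate ripple windows whose sources form a propagation chain.

    A hub grid point (the epileptogenic site, its ROI = the resection) drives
    a spatial chain of neighbouring grid points in distinct ROIs: each link
    carries a copy of its predecessor delayed by ``delay_s`` (about the first
    zero of the ripple-band autocorrelation, so simultaneously active sources
    stay near-uncorrelated in time and the beamformer reconstructs each
    faithfully) mixed with fresh ripple-band noise so that the
    magnitude-squared coherence between adjacent sites is ``coupling`` and
    falls off geometrically along the chain — a path graph at the 0.7
    threshold, whose interior nodes carry the betweenness.  In each event one
    chain site (the hub with probability ``p_hub``, else a random relay) is
    the dominant generator; relays therefore capture propagated ripples that
    localize just outside the resection.
    """
    rng = np.random.default_rng(seed)
    n = int(round(window_s * fs))
    d = max(1, int(round(delay_s * fs)))
    from scipy.spatial import cKDTree

    tree = cKDTree(source_model.grid_coords)
    # walk to nearest unvisited grid points in distinct ROIs
    start = int(rng.integers(source_model.n_sources))
    chain = [start]
    used_rois = {int(source_model.roi_labels[start])}
    while len(chain) < chain_len:
        _, idx = tree.query(source_model.grid_coords[chain[-1]], k=min(12, source_model.n_sources))
        nxt = [
            i for i in np.atleast_1d(idx)
            if i not in chain and int(source_model.roi_labels[i]) not in used_rois
        ]
        if not nxt:
            break
        chain.append(int(nxt[0]))
        used_rois.add(int(source_model.roi_labels[chain[-1]]))
    rois = [int(source_model.roi_labels[c]) for c in chain]
    env = np.hanning(n)
    lf = source_model.lead_field
    cols = [lf[:, c] / np.linalg.norm(lf[:, c]) for c in chain]
    windows = []
    mains = []
    for _ in range(n_events):
        wf = [env * band_noise(rng, n, fs)]
        for _j in range(1, len(chain)):
            prev_delayed = np.concatenate([np.zeros(d), wf[-1][:-d]])
            jit = env * band_noise(rng, n, fs)
            wf.append(np.sqrt(coupling) * prev_delayed + np.sqrt(1.0 - coupling) * jit)
        main = 0 if rng.random() < p_hub else int(rng.integers(1, len(chain)))
        mains.append(main)
        amps = [sub_amp] * len(chain)
        amps[main] = 1.0
        sig = np.zeros((lf.shape[0], n))
        for col, w, a in zip(cols, wf, amps):
            sig += np.outer(col, a * w)
        windows.append(sig + rng.standard_normal(sig.shape) / snr)
    return PlantedHub(
        windows=np.stack(windows),
        chain_sites=chain,
        chain_rois=rois,
        hub_roi=rois[0],
        resection={rois[0]},
        main_site_per_event=mains,
    )


@dataclass
class GroupSpec:
    rate_per_10min: float
    n_subjects: int


def simulate_cohort(
    group_specs: dict[str, GroupSpec],
    seed: int = 0,
    duration: float = 600.0,
    n_channels: int = DEFAULT_N_CHANNELS,
    fs: float = DEFAULT_FS,
    noise_amplitude: float = 1.0,
    burst_amplitude: float = 5.0,
    waveforms: bool = True,
) -> Iterator[tuple[Recording | None, GroundTruth, str]]:
    """Yield per-subject recordings for labelled groups.

    Each subject's ripple count is drawn from a Poisson process at the group
    rate (events per 10 min), bursts land on random channels at random times
    and frequencies.  With ``waveforms=False`` only the ground-truth event
    bookkeeping is generated (the Recording slot is None) — useful for
    count-level cohort statistics where waveform synthesis at scale is
    unnecessary.
    """
    for name, g in group_specs.items():
        if g.rate_per_10min <= 0:
            raise ValueError(f"group {name!r}: rate must be positive")
        if g.n_subjects <= 0:
            raise ValueError(f"group {name!r}: n_subjects must be positive")
    rng = np.random.default_rng(seed)
    for name, g in group_specs.items():
        lam = g.rate_per_10min * duration / 600.0
        for _ in range(g.n_subjects):
            count = int(rng.poisson(lam))
            plan = []
            max_cycles = 8
            margin = max_cycles / RIPPLE_FREQ_RANGE[0]
            for _ in range(count):
                plan.append(
                    RipplePlanEntry(
                        channel=int(rng.integers(n_channels)),
                        onset=float(rng.uniform(0.1, duration - margin - 0.1)),
                        freq=float(rng.uniform(100.0, 220.0)),
                        n_cycles=max_cycles,
                        amplitude=burst_amplitude,
                    )
                )
            spec = SimulationSpec(
                duration=duration,
                n_channels=n_channels,
                fs=fs,
                ripple_plan=plan,
                noise_amplitude=noise_amplitude,
                seed=int(rng.integers(2**31 - 1)),
            )
            if waveforms:
                rec, gt = simulate_recording(spec)
            else:
                names = [f"MEG{i:04d}" for i in range(n_channels)]
                evs = [
                    RippleEvent(
                        channel=names[p.channel],
                        onset=p.onset,
                        offset=p.onset + p.n_cycles / p.freq,
                        peak_times=[p.onset + (k + 0.25) / p.freq for k in range(p.n_cycles)],
                        peak_amplitudes=[p.amplitude] * p.n_cycles,
                    )
                    for p in plan
                ]
                rec, gt = None, GroundTruth(true_events=evs, true_source_indices=[])
            yield rec, gt, name
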