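"""Scalp-level discriminative features of detected ripples.

Three families of features separate epilepsy subtypes at the sensor level:

* the four-lobe distribution of ripple-detecting channels,
* omega spatial complexity — exp of the Shannon entropy of normalized
  covariance eigenvalues of a 0.3 s segment (1 = fully synchronized field,
  m = m fully independent channels),
* coherence-graph clustering: magnitude-squared coherence averaged over the
  ripple band, thresholded at 0.7 into an undirected graph, per-node
  clustering coefficients C_k = 2e / (n (n-1)) and their standardization
  C_s = (C_k - C_A) / C_A against the all-channel mean C_A.

Plus a thin one-way ANOVA + Bonferroni wrapper for group comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .detect import RippleEvent
from .preprocess import LOBES, Recording

COHERENCE_THRESHOLD = 0.7
OMEGA_WINDOW_S = 0.3


def lobe_distribution(
    events: list[RippleEvent], lobe_map: dict[str, str]
) -> dict[str, float]:
    """Fraction of ripple-detecting channels falling in each lobe.

    Each channel counts once no matter how many events it carries; the four
    fractions sum to 1 whenever at least one event exists.
    """
    channels = {e.channel for e in events}
    missing = channels - set(lobe_map)
    if missing:
        raise ValueError(f"lobe_map missing channels: {sorted(missing)[:5]}")
    counts = {lobe: 0 for lobe in LOBES}
    for ch in channels:
        counts[lobe_map[ch]] += 1
    total = sum(counts.values())
    if total == 0:
        return {lobe: 0.0 for lobe in LOBES}
    return {lobe: counts[lobe] / total for lobe in LOBES}


def eigen_spectrum(segment: np.ndarray) -> np.ndarray:
    """Normalized eigenvalues of the channel covariance of a segment."""
    x = np.asarray(segment, dtype=float)
    x = x - x.mean(axis=1, keepdims=True)
    cov = x @ x.T / x.shape[1]
    lam = np.linalg.eigvalsh(cov)
    lam = np.clip(lam, 0.0, None)
    s = lam.sum()
    if s <= 0:
        raise ValueError("degenerate covariance: all-zero segment")
    return lam / s


def omega_complexity(segment: np.ndarray) -> float:
    """Omega spatial complexity of a channels x samples segment.

    Omega = exp(-sum_i lam'_i ln lam'_i) over the normalized covariance
    eigenvalues lam'.  Bounded in [1, m]; invariant to global scaling and to
    channel permutation.  Zero eigenvalues contribute nothing (0 ln 0 := 0).
    """
    if np.asarray(segment).shape[0] < 2:
        raise ValueError("need at least 2 channels")
    lam = eigen_spectrum(segment)
    nz = lam[lam > 0]
    return float(np.exp(-(nz * np.log(nz)).sum()))


@dataclass
class CoherenceMatrix:
    """Band-averaged magnitude-squared coherence between all channel pairs."""

    values: np.ndarray          # (n, n), symmetric, unit diagonal, in [0, 1]
    n_segments: int
    band: tuple[float, float]


def coherence_matrix(
    segments: np.ndarray,
    fs: float,
    band: tuple[float, float] = (80.0, 250.0),
    welch_fallback: bool = False,
) -> CoherenceMatrix:
    """Magnitude-squared coherence with cross-spectra averaged over segments.

    ``segments``: (n_segments, n_channels, n_samples) — typically one 0.3 s
    window per detected ripple.  C_xy(f) = |S_xy|^2 / (S_xx S_yy) with the
    spectra averaged over segments (Hann taper), then averaged over the band.

    A single segment makes coherence identically 1 (degenerate); by default
    that raises.  ``welch_fallback=True`` instead splits the lone segment into
    three half-overlapping sub-windows and averages those.
    """
    seg = np.asarray(segments, dtype=float)
    if seg.ndim != 3:
        raise ValueError("segments must be (n_segments, n_channels, n_samples)")
    if seg.shape[0] < 2:
        if not welch_fallback:
            raise ValueError(
                "coherence degenerate (identically 1) with a single segment; "
                "need >= 2 ripple windows or welch_fallback=True"
            )
        n = seg.shape[2]
        sub = max(8, n // 2)
        step = max(1, sub // 2)
        pieces = [seg[0, :, s : s + sub] for s in range(0, n - sub + 1, step)]
        seg = np.stack(pieces[:3] if len(pieces) >= 2 else pieces * 2)
    n_seg, n_ch, n_samp = seg.shape
    taper = np.hanning(n_samp)
    spec = np.fft.rfft(seg * taper, axis=2)          # (n_seg, n_ch, n_f)
    freqs = np.fft.rfftfreq(n_samp, d=1.0 / fs)
    sxy = np.einsum("scf,sdf->cdf", spec, spec.conj()) / n_seg
    auto = np.real(np.einsum("ccf->cf", sxy))
    denom = auto[:, None, :] * auto[None, :, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        cxy = np.abs(sxy) ** 2 / denom
    cxy = np.nan_to_num(cxy, nan=0.0)
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    if not in_band.any():
        raise ValueError(f"no FFT bins inside band {band}")
    c = cxy[:, :, in_band].mean(axis=2)
    c = np.clip((c + c.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(c, 1.0)
    return CoherenceMatrix(values=c, n_segments=n_seg, band=band)


def ripple_windows(
    rec: Recording, events: list[RippleEvent], window_s: float = OMEGA_WINDOW_S
) -> np.ndarray:
    """Stack (n_events, n_channels, window) segments centered on each event."""
    if not events:
        raise ValueError("no events to window")
    win = int(round(window_s * rec.fs))
    good = rec.good_indices()
    out = np.zeros((len(events), good.size, win))
    for k, ev in enumerate(events):
        mid = 0.5 * (ev.onset + ev.offset)
        i0 = int(round(mid * rec.fs)) - win // 2
        a = max(0, i0)
        b = min(rec.n_samples, i0 + win)
        out[k, :, a - i0 : a - i0 + (b - a)] = rec.data[np.ix_(good, np.arange(a, b))]
    return out


@dataclass
class NodeClustering:
    """Per-node clustering of the thresholded coherence graph."""

    C_k: np.ndarray                     # per-node clustering coefficient
    C_A: float                          # mean over all channels
    degrees: np.ndarray
    adjacency: np.ndarray
    C_s_defined: bool = True

    def C_s(self, node: int) -> float:
        if not self.C_s_defined:
            raise ValueError("C_s undefined: average clustering coefficient is 0")
        return standardize_clustering(float(self.C_k[node]), self.C_A)


def clustering_coefficients(
    C: CoherenceMatrix | np.ndarray,
    threshold: float = COHERENCE_THRESHOLD,
    weighted: bool = False,
) -> NodeClustering:
    """Clustering coefficients of the coherence graph thresholded at 0.7.

    An edge exists iff coherence strictly exceeds the threshold.  For node k
    with n neighbours and e edges among them, C_k = 2e / (n (n-1)); nodes with
    fewer than two neighbours get C_k = 0.  ``weighted=True`` uses the
    geometric-mean triangle-intensity generalization on the thresholded
    coherence weights instead of binary counts.
    """
    m = C.values if isinstance(C, CoherenceMatrix) else np.asarray(C, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("need a square matrix")
    if not np.allclose(m, m.T, atol=1e-9):
        raise ValueError("coherence matrix must be symmetric")
    n = m.shape[0]
    adj = (m > threshold).astype(float)
    np.fill_diagonal(adj, 0.0)
    deg = adj.sum(axis=1).astype(int)
    if weighted:
        w = np.where(adj > 0, m, 0.0)
        np.fill_diagonal(w, 0.0)
        wmax = w.max() if w.max() > 0 else 1.0
        w13 = np.cbrt(w / wmax)
        tri = np.diagonal(w13 @ w13 @ w13)
        with np.errstate(invalid="ignore", divide="ignore"):
            ck = np.where(deg >= 2, tri / (deg * (deg - 1)), 0.0)
    else:
        tri = np.diagonal(adj @ adj @ adj)  # 2e per node
        with np.errstate(invalid="ignore", divide="ignore"):
            ck = np.where(deg >= 2, tri / (deg * (deg - 1)), 0.0)
    ca = float(ck.mean())
    return NodeClustering(
        C_k=ck, C_A=ca, degrees=deg, adjacency=adj.astype(bool), C_s_defined=ca > 0
    )


def standardize_clustering(C_k: float, C_A: float) -> float:
    """C_s = (C_k - C_A) / C_A; undefined when the network average is <= 0."""
    if C_A <= 0:
        raise ValueError("C_s undefined for non-positive average clustering coefficient")
    return (C_k - C_A) / C_A


@dataclass
class CohortStats:
    F: float
    p: float
    pairwise: dict[tuple[str, str], float]   # Bonferroni-adjusted p-values
    significant: bool                         # p < 0.05


def cohort_stats(groups: dict[str, np.ndarray], alpha: float = 0.05) -> CohortStats:
    """One-way ANOVA across groups plus Bonferroni-adjusted pairwise t-tests."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in arrays.items():
        if v.size < 2:
            raise ValueError(f"group {k!r} needs at least 2 subjects")
    vals = list(arrays.values())
    if all(np.allclose(v, vals[0].mean()) for v in vals) and all(v.std() == 0 for v in vals):
        f, p = 0.0, 1.0
    else:
        f, p = stats.f_oneway(*vals)
        if np.isnan(f):
            f, p = 0.0, 1.0
    names = list(arrays)
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    m = len(pairs)
    pairwise = {}
    for a, b in pairs:
        if arrays[a].std() == 0 and arrays[b].std() == 0:
            praw = 1.0 if np.isclose(arrays[a].mean(), arrays[b].mean()) else 0.0
        else:
            praw = stats.ttest_ind(arrays[a], arrays[b]).pvalue
        pairwise[(a, b)] = float(min(1.0, praw * m))
    return CohortStats(F=float(f), p=float(p), pairwise=pairwise, significant=bool(p < alpha))
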