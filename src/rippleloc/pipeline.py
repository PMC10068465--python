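"""Configuration, file I/O, logging, and end-to-end cohort orchestration.

All tunable constants of the analysis chain live in one :class:`PipelineConfig`
(YAML round-trippable).  :func:`run_pipeline` executes the full chain —
simulate/load -> preprocess -> detect -> scalp features -> Tucker-LCMV
localization -> ROI network -> cohort statistics — writing per-subject feature
rows as TSV and group statistics as JSON, deterministically under fixed seeds.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import detect as _detect
from . import localize as _localize
from . import network as _network
from . import preprocess as _pre
from . import scalp as _scalp
from . import synthetic as _syn

log = logging.getLogger("rippleloc")


@dataclass
class PipelineConfig:
    """Every analysis constant in one place (defaults = the study settings)."""

    band: tuple[float, float] = (80.0, 250.0)
    window_s: float = 0.6                       # detector sliding window
    feature_window_s: float = 0.3               # omega / coherence / source window
    ppdc_fit_range: tuple[float, float] = (0.30, 0.60)
    ppdc_multiplier: float = 1.05
    coherence_threshold: float = 0.7
    tucker_energy_frac: float = 0.95
    tucker_max_iter: int = 50
    tucker_tol: float = 1e-6
    lcmv_reg_frac: float = 0.05
    top_k: int = 10
    line_freq: float = 50.0
    z_abs_limit: float = 5.0
    frac_limit: float = 0.001
    seed: int = 0
    out_dir: str = "rippleloc_out"

    def validate(self) -> None:
        lo, hi = self.band
        if not 0 < lo < hi:
            raise ValueError(f"invalid band {self.band}")
        if not 0 <= self.ppdc_fit_range[0] < self.ppdc_fit_range[1] <= 1:
            raise ValueError("ppdc fit range must be within [0, 1]")
        if not 0 < self.coherence_threshold < 1:
            raise ValueError("coherence threshold must be in (0, 1)")
        if not 0 < self.tucker_energy_frac <= 1:
            raise ValueError("tucker energy fraction must be in (0, 1]")
        if self.window_s <= 0 or self.feature_window_s <= 0:
            raise ValueError("window lengths must be positive")
        if not 1 <= self.top_k <= 90:
            raise ValueError("top_k must be in 1..90")

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["band"] = list(d["band"])
        d["ppdc_fit_range"] = list(d["ppdc_fit_range"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["band"] = tuple(d["band"])
        d["ppdc_fit_range"] = tuple(d["ppdc_fit_range"])
        cfg = cls(**d)
        cfg.validate()
        return cfg


# ---------------------------------------------------------------------------
# Recording I/O
# ---------------------------------------------------------------------------

def write_recording(rec: _pre.Recording, path: str | Path, fmt: str = "tsv-matrix") -> None:
    """Write a Recording as FIF (via mne) or as a TSV matrix + JSON sidecar."""
    path = Path(path)
    if fmt == "fif":
        import mne

        info = mne.create_info(rec.channel_names, rec.fs, ch_types="mag")
        raw = mne.io.RawArray(rec.data, info, verbose="error")
        raw.info["bads"] = sorted(rec.bad_channels)
        raw.save(path, overwrite=True, verbose="error")
    elif fmt == "tsv-matrix":
        with open(path, "w") as f:
            for name, row in zip(rec.channel_names, rec.data):
                f.write(name + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")
        sidecar = {
            "fs": rec.fs,
            "lobe_map": rec.lobe_map,
            "bad_channels": sorted(rec.bad_channels),
        }
        Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    else:
        raise ValueError(f"unknown format {fmt!r} (fif or tsv-matrix)")


def read_recording(path: str | Path, fmt: str | None = None) -> _pre.Recording:
    """Read FIF/EDF (via mne) or a TSV matrix with its JSON sidecar."""
    path = Path(path)
    if fmt is None:
        suffix = path.suffix.lower()
        fmt = {".fif": "fif", ".edf": "edf", ".tsv": "tsv-matrix"}.get(suffix)
        if fmt is None:
            raise ValueError(f"cannot infer format from {path.name!r}")
    if fmt in ("fif", "edf"):
        import mne

        reader = mne.io.read_raw_fif if fmt == "fif" else mne.io.read_raw_edf
        raw = reader(path, preload=True, verbose="error")
        rec = _pre.Recording(
            data=raw.get_data(),
            fs=float(raw.info["sfreq"]),
            channel_names=list(raw.ch_names),
            bad_channels=set(raw.info["bads"]),
        )
        return rec
    if fmt == "tsv-matrix":
        sidecar_path = Path(str(path) + ".json")
        if not sidecar_path.exists():
            raise ValueError(f"tsv-matrix requires a sidecar {sidecar_path.name} with fs")
        sidecar = json.loads(sidecar_path.read_text())
        if "fs" not in sidecar:
            raise ValueError("sidecar missing required 'fs'")
        names, rows = [], []
        for i, line in enumerate(path.read_text().splitlines()):
            parts = line.split("\t")
            names.append(parts[0])
            row = np.array([float(v) for v in parts[1:]])
            if rows and row.size != rows[0].size:
                raise ValueError(f"truncated or ragged tsv-matrix at row {i}")
            rows.append(row)
        return _pre.Recording(
            data=np.vstack(rows),
            fs=float(sidecar["fs"]),
            channel_names=names,
            lobe_map=sidecar.get("lobe_map", {}),
            bad_channels=set(sidecar.get("bad_channels", [])),
        )
    raise ValueError(f"unknown format {fmt!r}")


def write_source_model(sm: _syn.SourceModel, path: str | Path) -> None:
    """Write a forward model as a lead-field TSV plus a JSON metadata sidecar."""
    path = Path(path)
    with open(path, "w") as f:
        for row in sm.lead_field:
            f.write("\t".join(repr(float(v)) for v in row) + "\n")
    meta = {
        "grid_coords": [[float(v) for v in p] for p in sm.grid_coords],
        "roi_labels": [int(v) for v in sm.roi_labels],
        "resection": sorted(int(v) for v in sm.resection),
    }
    Path(str(path) + ".json").write_text(json.dumps(meta, indent=1))


def read_source_model(path: str | Path) -> _syn.SourceModel:
    path = Path(path)
    sidecar = Path(str(path) + ".json")
    if not sidecar.exists():
        raise ValueError(f"source model requires a metadata sidecar {sidecar.name}")
    meta = json.loads(sidecar.read_text())
    lf = np.array([[float(v) for v in line.split("\t")]
                   for line in path.read_text().splitlines()])
    return _syn.SourceModel(
        lead_field=lf,
        grid_coords=np.asarray(meta["grid_coords"], dtype=float),
        roi_labels=np.asarray(meta["roi_labels"], dtype=int),
        resection=set(meta.get("resection", [])),
    )


def read_events(path: str | Path) -> list[_detect.RippleEvent]:
    """Read the tab-separated event table written by :func:`write_events`."""
    lines = Path(path).read_text().splitlines()
    events = []
    for line in lines[1:]:
        ch, onset, offset, n_peaks, freq = line.split("\t")
        onset, offset, n_peaks = float(onset), float(offset), int(n_peaks)
        freq_hz = float(freq) if freq.lower() != "nan" else None
        # reconstruct a nominal peak train spanning [onset, offset]
        step = (offset - onset) / max(n_peaks - 1, 1)
        events.append(_detect.RippleEvent(
            channel=ch, onset=onset, offset=offset,
            peak_times=[onset + k * step for k in range(n_peaks)],
            peak_amplitudes=[1.0] * n_peaks, freq_hz=freq_hz,
        ))
    return events


def write_events(events: list[_detect.RippleEvent], path: str | Path) -> None:
    with open(path, "w") as f:
        f.write("channel\tonset_s\toffset_s\tn_peaks\tmean_freq_Hz\n")
        for e in events:
            f.write(f"{e.channel}\t{e.onset:.6f}\t{e.offset:.6f}\t{e.n_peaks}\t{e.mean_freq:.3f}\n")


# ---------------------------------------------------------------------------
# Per-subject analysis and cohort orchestration
# ---------------------------------------------------------------------------

@dataclass
class SubjectResult:
    subject: str
    group: str
    rate_per_10min: float
    lobe_fractions: dict[str, float]
    mean_omega: float
    mean_cs: float
    n_events: int
    in_resection_lcmv: float = float("nan")
    in_resection_tucker: float = float("nan")
    in_resection_combined: float = float("nan")


def analyze_subject(
    rec: _pre.Recording,
    cfg: PipelineConfig,
    subject: str = "S00",
    group: str = "",
    source_model: _syn.SourceModel | None = None,
    preprocessed: bool = False,
) -> SubjectResult:
    """Run the full scalp (and optionally source) chain on one recording."""
    if not preprocessed:
        rec = _pre.remove_line_noise(rec, cfg.line_freq)
        rec = _pre.reject_channels(rec, cfg.z_abs_limit, cfg.frac_limit)
    banded = _pre.bandpass_ripple(rec, cfg.band)
    events = _detect.detect_ripples(
        rec, cfg.window_s, fit_range=cfg.ppdc_fit_range,
        multiplier=cfg.ppdc_multiplier, band=cfg.band,
    )
    rate = _detect.ripple_count_rate(events, rec.duration)
    log.info("subject %s: %d events (%.2f per 10 min)", subject, len(events), rate)
    lobes = _scalp.lobe_distribution(events, rec.lobe_map)
    mean_omega = float("nan")
    mean_cs = float("nan")
    if events:
        wins = _scalp.ripple_windows(banded, events, cfg.feature_window_s)
        omegas = []
        for k in range(wins.shape[0]):
            try:
                omegas.append(_scalp.omega_complexity(wins[k]))
            except ValueError:
                pass
        if omegas:
            mean_omega = float(np.mean(omegas))
        try:
            C = _scalp.coherence_matrix(wins, rec.fs, cfg.band, welch_fallback=True)
            clust = _scalp.clustering_coefficients(C, cfg.coherence_threshold)
            if clust.C_s_defined:
                good = list(rec.good_indices())
                name_to_pos = {rec.channel_names[g]: p for p, g in enumerate(good)}
                cs_vals = [
                    clust.C_s(name_to_pos[e.channel])
                    for e in events
                    if e.channel in name_to_pos
                ]
                if cs_vals:
                    mean_cs = float(np.mean(cs_vals))
        except ValueError as err:
            log.warning("subject %s: coherence skipped (%s)", subject, err)
    res = SubjectResult(
        subject=subject,
        group=group,
        rate_per_10min=rate,
        lobe_fractions=lobes,
        mean_omega=mean_omega,
        mean_cs=mean_cs,
        n_events=len(events),
    )
    if source_model is not None and len(events) >= 2 and source_model.resection:
        plain = _localize.tucker_lcmv(
            banded, events, source_model, cfg.feature_window_s,
            cfg.tucker_energy_frac, cfg.lcmv_reg_frac, denoise=False,
        )
        denoised = _localize.tucker_lcmv(
            banded, events, source_model, cfg.feature_window_s,
            cfg.tucker_energy_frac, cfg.lcmv_reg_frac, denoise=True,
        )
        res.in_resection_lcmv = _localize.resection_overlap(plain, source_model.resection)
        res.in_resection_tucker = _localize.resection_overlap(denoised, source_model.resection)
        wins = _scalp.ripple_windows(banded, events, cfg.feature_window_s)
        roi_wins = _network.roi_series_per_window(wins, source_model, cfg.lcmv_reg_frac)
        C = _network.roi_coherence(roi_wins, rec.fs, cfg.band)
        ranking = _network.betweenness_ranking(C, cfg.coherence_threshold, cfg.top_k)
        adjacent = _network.resection_adjacent_labels(source_model, source_model.resection)
        res.in_resection_combined = _network.combined_localization(
            denoised, ranking, source_model.resection, adjacent
        )
        log.info(
            "subject %s: in-resection LCMV %.2f / Tucker %.2f / combined %.2f",
            subject, res.in_resection_lcmv, res.in_resection_tucker, res.in_resection_combined,
        )
    return res


def write_feature_table(results: list[SubjectResult], path: str | Path) -> None:
    cols = [
        "subject", "group", "rate_per_10min", "n_events",
        "frac_frontal", "frac_temporal", "frac_parietal", "frac_occipital",
        "mean_omega", "mean_cs",
        "in_resection_lcmv", "in_resection_tucker", "in_resection_combined",
    ]
    with open(path, "w") as f:
        f.write("\t".join(cols) + "\n")
        for r in results:
            row = [
                r.subject, r.group, f"{r.rate_per_10min:.6f}", str(r.n_events),
                *(f"{r.lobe_fractions[l]:.6f}" for l in _pre.LOBES),
                f"{r.mean_omega:.6f}", f"{r.mean_cs:.6f}",
                f"{r.in_resection_lcmv:.6f}", f"{r.in_resection_tucker:.6f}",
                f"{r.in_resection_combined:.6f}",
            ]
            f.write("\t".join(row) + "\n")


def run_pipeline(
    cfg: PipelineConfig,
    group_specs: dict[str, _syn.GroupSpec] | None = None,
    duration: float = 60.0,
    n_channels: int = 30,
    recordings: list[tuple[_pre.Recording, str, str]] | None = None,
) -> dict:
    """Run the cohort workflow and write the feature table + group stats.

    Either pass ``recordings`` (list of (Recording, subject id, group label))
    or let the synthetic cohort generator produce ``group_specs`` subjects of
    ``duration`` seconds on ``n_channels`` channels.  Returns a summary dict
    and writes <out_dir>/features.tsv and <out_dir>/group_stats.json.
    """
    cfg.validate()
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    results: list[SubjectResult] = []
    if recordings is None:
        if group_specs is None:
            group_specs = {
                "LTLE": _syn.GroupSpec(5.4, 3),
                "MTLE": _syn.GroupSpec(9.3, 3),
                "NTLE": _syn.GroupSpec(3.5, 3),
            }
        subjects = _syn.simulate_cohort(
            group_specs, seed=cfg.seed, duration=duration, n_channels=n_channels
        )
        idx = 0
        for rec, _gt, group in subjects:
            results.append(
                analyze_subject(rec, cfg, subject=f"S{idx:03d}", group=group, preprocessed=True)
            )
            idx += 1
    else:
        for rec, subject, group in recordings:
            results.append(analyze_subject(rec, cfg, subject=subject, group=group))
    write_feature_table(results, out_dir / "features.tsv")

    summary: dict = {"n_subjects": len(results)}
    groups = sorted({r.group for r in results})
    if len(groups) >= 2 and all(
        sum(1 for r in results if r.group == g) >= 2 for g in groups
    ):
        rates = {g: np.array([r.rate_per_10min for r in results if r.group == g]) for g in groups}
        st = _scalp.cohort_stats(rates)
        summary["rate_anova"] = {
            "F": st.F,
            "p": st.p,
            "significant": st.significant,
            "group_means": {g: float(v.mean()) for g, v in rates.items()},
            "pairwise_bonferroni": {f"{a}|{b}": p for (a, b), p in st.pairwise.items()},
        }
    (out_dir / "group_stats.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    return summary
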