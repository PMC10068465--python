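"""Tucker decomposition, LCMV beamforming, and the combined pipeline."""

import warnings

import numpy as np
import pytest

from rippleloc import (
    Recording,
    RippleEvent,
    build_ripple_tensor,
    lcmv_localize,
    resection_overlap,
    tucker_decompose,
    tucker_denoise,
    tucker_lcmv,
)
from rippleloc.localize import SourceEstimate, multi_mode_product

FS = 1000.0


def random_low_rank_tensor(rng, shape=(30, 40, 8), ranks=(3, 3, 2)):
    core = rng.standard_normal(ranks)
    factors = [np.linalg.qr(rng.standard_normal((s, r)))[0] for s, r in zip(shape, ranks)]
    return multi_mode_product(core, factors)


class TestTucker:
    def test_order2_equals_truncated_svd(self, rng):
        a = rng.standard_normal((20, 30))
        m = tucker_decompose(a, ranks=(5, 5))
        u, s, vt = np.linalg.svd(a, full_matrices=False)
        svd_rec = (u[:, :5] * s[:5]) @ vt[:5]
        assert np.linalg.norm(m.reconstruct() - svd_rec) <= 1e-8

    def test_exact_multilinear_rank_recovery(self, rng):
        t = random_low_rank_tensor(rng, (10, 12, 8), (3, 4, 2))
        m = tucker_decompose(t, ranks=(3, 4, 2))
        assert np.linalg.norm(m.reconstruct() - t) <= 1e-10

    def test_energy_contract(self, rng):
        t = rng.standard_normal((20, 30, 10))
        m = tucker_decompose(t, energy_frac=0.95)
        assert m.fit >= 0.95 - 0.02

    def test_factor_orthonormality_and_shape(self, rng):
        t = rng.standard_normal((8, 9, 7))
        m = tucker_decompose(t, energy_frac=0.9)
        for u in m.factors:
            assert np.allclose(u.T @ u, np.eye(u.shape[1]), atol=1e-8)
        assert m.reconstruct().shape == t.shape

    def test_hooi_fit_nondecreasing(self, rng):
        t = random_low_rank_tensor(rng) + 0.5 * rng.standard_normal((30, 40, 8))
        m = tucker_decompose(t, ranks=(3, 3, 2))
        h = np.asarray(m.fit_history)
        assert (np.diff(h) >= -1e-10).all()

    def test_denoise_improves_mse(self):
        wins = 0
        for seed in range(20):
            r = np.random.default_rng(1000 + seed)
            clean = random_low_rank_tensor(r)
            sigma = 0.5 * np.linalg.norm(clean) / np.sqrt(clean.size)
            noisy = clean + sigma * r.standard_normal(clean.shape)
            den = tucker_denoise(noisy)
            wins += np.mean((den - clean) ** 2) < np.mean((noisy - clean) ** 2)
        assert wins >= 18

    def test_full_energy_is_identity(self, rng):
        t = rng.standard_normal((6, 7, 5))
        assert np.allclose(tucker_denoise(t, energy_frac=1.0), t, atol=1e-8)

    def test_noiseless_low_rank_passthrough(self, rng):
        # balanced core (equal mode-wise singular values) so the energy rule
        # cannot truncate below the true multilinear rank
        core = np.zeros((3, 3, 2))
        core[:, :, 0] = np.eye(3)
        core[:, :, 1] = np.roll(np.eye(3), 1, axis=1)
        factors = [np.linalg.qr(rng.standard_normal((s, r)))[0]
                   for s, r in [(30, 3), (40, 3), (8, 2)]]
        t = multi_mode_product(core, factors)
        assert np.linalg.norm(tucker_denoise(t) - t) <= 1e-8 * np.linalg.norm(t)

    def test_order_one_rejected(self):
        with pytest.raises(ValueError):
            tucker_decompose(np.arange(5.0))


class TestBuildRippleTensor:
    def _rec(self, n_ch=6, n_s=4000):
        return Recording(data=np.random.default_rng(0).standard_normal((n_ch, n_s)), fs=FS)

    def _ev(self, onset):
        return RippleEvent(channel="MEG0000", onset=onset, offset=onset + 0.05,
                           peak_times=[onset + 0.01 * i for i in range(4)],
                           peak_amplitudes=[1.0] * 4)

    def test_shape(self):
        rec = self._rec()
        t = build_ripple_tensor(rec, [self._ev(1.0 + 0.5 * k) for k in range(5)], 0.3)
        assert t.shape == (6, 300, 5)

    def test_single_event_singleton_mode(self):
        t = build_ripple_tensor(self._rec(), [self._ev(2.0)], 0.3)
        assert t.shape[2] == 1
        m = tucker_decompose(t, energy_frac=0.95)
        assert m.ranks[2] == 1

    def test_edge_event_zero_padded_with_warning(self):
        rec = self._rec()
        with pytest.warns(UserWarning, match="clipped"):
            t = build_ripple_tensor(rec, [self._ev(0.01)], 0.3)
        assert t.shape == (6, 300, 1)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            build_ripple_tensor(self._rec(), [], 0.3)


def dipole_window(source_model, src, rng=None, snr_amp=None, n=300):
    w = np.hanning(n) * np.sin(2 * np.pi * 150 * np.arange(n) / FS)
    sig = np.outer(source_model.lead_field[:, src], w)
    if snr_amp is None:
        return sig
    return sig + rng.standard_normal(sig.shape) * sig.std() / snr_amp


class TestLcmv:
    def test_noiseless_dipole_localized_exactly(self, forward_model, rng):
        for src in (5, 40, 77):
            win = dipole_window(forward_model, src)
            win = win + 1e-10 * rng.standard_normal(win.shape)
            est = lcmv_localize(win, forward_model)
            assert est.peak_index == src

    def test_identity_covariance_flat_map(self, rng):
        """With isotropic covariance and unit-norm columns the NAI map is flat."""
        import rippleloc.synthetic as syn

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sm = syn.make_toy_forward_model(16, 16, "random-orthogonal", seed=1)
        n = 512
        t = np.arange(n)
        basis = np.stack([np.sqrt(2 / n) * np.sin(2 * np.pi * (k + 1) * (t + 0.5) / n)
                          for k in range(16)])
        basis /= np.linalg.norm(basis, axis=1, keepdims=True)
        win = np.sqrt(n) * basis          # sample covariance exactly identity
        est = lcmv_localize(win, sm)
        assert np.ptp(est.power) / est.power.mean() < 1e-8

    def test_median_error_at_0db(self, forward_model):
        spacing = forward_model.grid_spacing()
        errs = []
        for seed in range(50):
            r = np.random.default_rng(seed)
            src = int(r.integers(forward_model.n_sources))
            est = lcmv_localize(dipole_window(forward_model, src, r, snr_amp=1.0),
                                forward_model)
            errs.append(np.linalg.norm(forward_model.grid_coords[est.peak_index]
                                       - forward_model.grid_coords[src]))
        assert np.median(errs) <= spacing

    def test_scale_equivariance(self, forward_model, rng):
        win = dipole_window(forward_model, 33, rng, snr_amp=2.0)
        e1 = lcmv_localize(win, forward_model)
        e2 = lcmv_localize(4.0 * win, forward_model)
        assert e2.peak_index == e1.peak_index
        assert np.allclose(e2.power, 16.0 * e1.power, rtol=1e-8)

    def test_dimension_mismatch_rejected(self, forward_model, rng):
        with pytest.raises(ValueError, match="channels"):
            lcmv_localize(rng.standard_normal((10, 100)), forward_model)

    def test_power_nonnegative(self, forward_model, rng):
        est = lcmv_localize(rng.standard_normal((64, 200)), forward_model)
        assert (est.power >= 0).all()


class TestTuckerLcmv:
    def _rec_with_events(self, forward_model, rng, n_ev=5, snr_amp=None):
        n = 4000
        data = np.zeros((64, n))
        events = []
        src = 20
        for k in range(n_ev):
            onset = 0.5 + 0.6 * k
            i0 = int(onset * FS)
            win = dipole_window(forward_model, src)
            data[:, i0 : i0 + 300] += win
            events.append(RippleEvent(channel="MEG0000", onset=onset + 0.145,
                                      offset=onset + 0.155,
                                      peak_times=[onset + 0.145 + 0.005 * i for i in range(4)],
                                      peak_amplitudes=[1.0] * 4))
        if snr_amp is not None:
            data += rng.standard_normal(data.shape) * dipole_window(forward_model, src).std() / snr_amp
        return Recording(data=data, fs=FS), events, src

    def test_noiseless_equivalent_to_plain(self, forward_model, rng):
        rec, events, src = self._rec_with_events(forward_model, rng)
        rec.data += 1e-9 * rng.standard_normal(rec.data.shape)
        plain = tucker_lcmv(rec, events, forward_model, denoise=False)
        tuck = tucker_lcmv(rec, events, forward_model, denoise=True)
        assert [e.peak_index for e in plain] == [e.peak_index for e in tuck]
        assert all(e.peak_index == src for e in tuck)

    def test_paired_error_tucker_not_worse(self, forward_model):
        spacing = forward_model.grid_spacing()
        plain_means, tuck_means = [], []
        for seed in range(20):
            r = np.random.default_rng(seed)
            rec, events, src = self._rec_with_events(forward_model, r, snr_amp=1.0)
            plain = tucker_lcmv(rec, events, forward_model, denoise=False)
            tuck = tucker_lcmv(rec, events, forward_model, denoise=True)
            true_pos = forward_model.grid_coords[src]
            plain_means.append(np.mean([np.linalg.norm(
                forward_model.grid_coords[e.peak_index] - true_pos) for e in plain]))
            tuck_means.append(np.mean([np.linalg.norm(
                forward_model.grid_coords[e.peak_index] - true_pos) for e in tuck]))
        assert np.mean(tuck_means) <= np.mean(plain_means) + 0.25 * spacing

    def test_overlap_fraction_bounded(self, forward_model, rng):
        rec, events, src = self._rec_with_events(forward_model, rng, snr_amp=2.0)
        ests = tucker_lcmv(rec, events, forward_model)
        frac = resection_overlap(ests, {int(forward_model.roi_labels[src])})
        assert 0.0 <= frac <= 1.0


class TestResectionOverlap:
    def _est(self, roi):
        return SourceEstimate(power=np.ones(3), peak_index=0, peak_roi=roi)

    def test_all_inside(self):
        assert resection_overlap([self._est(4)] * 3, {4, 5}) == 1.0

    def test_none_inside(self):
        assert resection_overlap([self._est(1)] * 3, {4, 5}) == 0.0

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            resection_overlap([self._est(1)], set())
        with pytest.raises(ValueError):
            resection_overlap([], {1})

    def test_high_snr_dipoles_in_mask(self, forward_model):
        hits = []
        for seed in range(10):
            r = np.random.default_rng(seed)
            src = int(r.integers(forward_model.n_sources))
            est = lcmv_localize(dipole_window(forward_model, src, r, snr_amp=1.78),
                                forward_model)  # ~5 dB
            hits.append(est.peak_roi == int(forward_model.roi_labels[src]))
        assert np.mean(hits) >= 0.8
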