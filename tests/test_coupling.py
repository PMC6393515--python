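"""Fisher transform, zero-lag correlation, lFDR, ITCOR and selection logic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from deepmeg.coupling import (
    exact_null_z,
    fisher_transform,
    fit_local_fdr,
    itcor,
    itcor_select,
    local_fdr_select,
    select_components,
    temporal_correlation,
    zero_lag_check,
)
from deepmeg.io import Epochs
from deepmeg.preprocessing import IcaComponent


class TestFisherTransform:
    def test_zero_maps_to_zero(self):
        assert fisher_transform(0.0) == 0.0

    def test_known_value(self):
        # 1/2 * ln(1.9 / 0.1), evaluated to high precision
        assert fisher_transform(0.9) == pytest.approx(1.4722194895832204, rel=1e-12)

    @given(st.floats(min_value=-0.999, max_value=0.999))
    @settings(max_examples=50, deadline=None)
    def test_odd_function(self, r):
        assert fisher_transform(-r) == pytest.approx(-fisher_transform(r), abs=1e-12)

    def test_strictly_increasing(self):
        r = np.linspace(-0.99, 0.99, 101)
        assert np.all(np.diff(fisher_transform(r)) > 0)

    def test_boundary_rejected_when_strict(self):
        with pytest.raises(ValueError):
            fisher_transform(1.0)
        assert np.isinf(fisher_transform(np.array([1.0]), strict=False))[0]


def _epochs_from(data_3d, fs=512.0):
    n = data_3d.shape[0]
    return Epochs(
        data_3d, data_3d.shape[2] / fs, fs, list(range(n)),
        [f"ch{i}" for i in range(data_3d.shape[1])],
    )


class TestTemporalCorrelation:
    def test_exact_copy_gives_unity(self):
        rng = np.random.default_rng(0)
        tc = rng.standard_normal((1, 20 * 100))
        r = temporal_correlation(tc, _epochs_from(tc.reshape(20, 1, 100)))
        assert r[0, 0] == pytest.approx(1.0)

    def test_noise_dilution_closed_form(self):
        # channel = component + noise with var ratio 3 -> r = 1/sqrt(1+3)
        rng = np.random.default_rng(1)
        tc = rng.standard_normal((1, 10000))
        chan = tc[0] + np.sqrt(3.0) * rng.standard_normal(10000)
        seeg = _epochs_from(chan.reshape(10, 1, 1000))
        r = temporal_correlation(tc, seeg)
        assert r[0, 0] == pytest.approx(0.5, abs=0.05)

    def test_independent_series_near_zero(self):
        rng = np.random.default_rng(2)
        inside = 0
        for _ in range(1000):
            a = rng.standard_normal((1, 10000))
            b = rng.standard_normal(10000)
            r = temporal_correlation(a, _epochs_from(b.reshape(10, 1, 1000)))
            inside += abs(r[0, 0]) < 0.05
        assert inside >= 990

    def test_symmetry_in_arguments(self):
        rng = np.random.default_rng(3)
        a = rng.standard_normal((2, 1000))
        b = rng.standard_normal((3, 1000))
        r_ab = temporal_correlation(a, _epochs_from(b[None, :, :]))
        r_ba = temporal_correlation(b, _epochs_from(a[None, :, :]))
        np.testing.assert_allclose(r_ab, r_ba.T, atol=1e-12)

    def test_zero_variance_flagged_nan(self):
        tc = np.random.default_rng(4).standard_normal((1, 1000))
        flat = np.zeros((1, 1, 1000))
        r = temporal_correlation(tc, _epochs_from(flat))
        assert np.isnan(r[0, 0])


class TestLocalFdr:
    def test_pure_null_no_discoveries(self):
        rng = np.random.default_rng(0)
        mask, _ = local_fdr_select(rng.standard_normal(10000))
        assert mask.sum() == 0

    def test_mixture_detection(self):
        rng = np.random.default_rng(1)
        z = np.concatenate(
            [rng.standard_normal(9500), rng.normal(6.0, 1.0, 500)]
        )
        mask, _ = local_fdr_select(z)
        assert mask[9500:].mean() >= 0.90
        assert mask[:9500].mean() <= 0.02

    def test_single_outlier_flagged(self):
        rng = np.random.default_rng(2)
        z = np.concatenate([rng.standard_normal(1000), [10.0]])
        mask, _ = local_fdr_select(z)
        assert mask[-1]

    def test_shift_equivariance_of_null_fit(self):
        rng = np.random.default_rng(3)
        z = np.concatenate([rng.standard_normal(5000), rng.normal(5, 1, 100)])
        mask0, fit0 = local_fdr_select(z)
        mask1, fit1 = local_fdr_select(z + 2.5)
        assert fit1.null_mean - fit0.null_mean == pytest.approx(2.5, abs=0.05)
        np.testing.assert_array_equal(mask0, mask1)

    def test_degenerate_histogram_warns_no_discoveries(self):
        with pytest.warns(UserWarning, match="degenerate"):
            mask, _ = local_fdr_select(np.full(100, 1.3))
        assert mask.sum() == 0

    def test_minimum_count_enforced(self):
        with pytest.raises(ValueError, match="50"):
            fit_local_fdr(np.random.default_rng(0).standard_normal(10))


class TestItcor:
    def test_identical_amplitudes_unity(self):
        rng = np.random.default_rng(0)
        amps = rng.uniform(0.5, 2.0, 40)
        shape = np.hanning(100)
        comp = amps[:, None] * shape[None, :]
        seeg = comp[:, None, :] * 2.0  # same amplitudes, different scale
        series = itcor(comp, _epochs_from(seeg))
        middle = series[0, 5:-5]
        np.testing.assert_allclose(middle, 1.0, atol=1e-8)

    def test_comodulation_window_detected(self):
        # one coupled channel among 19 noise channels, pooled over
        # (channel, time) as the selection stage pools per component
        fs = 512.0
        n_samples = 307
        n_channels = 20
        rel = (np.arange(n_samples) - 153) / fs
        rng = np.random.default_rng(1)
        n_trials = 60
        amps = np.exp(rng.normal(0, 0.5, n_trials))
        burst = np.exp(-(rel**2) / (2 * 0.010**2))  # +-25 ms support
        comp = amps[:, None] * burst[None, :] + 0.3 * rng.standard_normal(
            (n_trials, n_samples)
        )
        chans = 0.3 * rng.standard_normal((n_trials, n_channels, n_samples))
        chans[:, 0, :] += amps[:, None] * burst[None, :]
        series = itcor(comp, _epochs_from(chans, fs=fs))
        mask, _ = itcor_select(series, n_trials)
        sig_times = rel[mask[0]]
        assert np.any(np.abs(sig_times) <= 0.05)
        n_stray = int(np.sum(np.abs(rel[mask.any(axis=0)]) > 0.05))
        assert n_stray <= max(1, n_samples // 100)

    def test_independent_trials_rarely_significant(self):
        fs = 512.0
        rng = np.random.default_rng(2)
        n_runs, n_sig = 200, 0
        for _ in range(n_runs):
            comp = rng.standard_normal((20, 80))
            chan = rng.standard_normal((20, 10, 80))
            series = itcor(comp, _epochs_from(chan, fs=fs))
            mask, _ = itcor_select(series, 20)
            n_sig += mask.any()
        assert n_sig <= 0.05 * n_runs

    def test_trial_reordering_invariance(self):
        rng = np.random.default_rng(3)
        comp = rng.standard_normal((15, 50))
        chan = rng.standard_normal((15, 2, 50))
        base = itcor(comp, _epochs_from(chan))
        perm = rng.permutation(15)
        shuffled = itcor(comp[perm], _epochs_from(chan[perm]))
        np.testing.assert_allclose(base, shuffled, atol=1e-12)

    def test_too_few_trials_refused(self):
        with pytest.raises(ValueError, match="10"):
            itcor(np.zeros((5, 50)), _epochs_from(np.zeros((5, 1, 50))))


class TestZeroLag:
    def test_identical_averages_pass(self):
        w = np.hanning(307)
        ok, lag = zero_lag_check(w, w, 512.0)
        assert ok and lag == 0.0

    def test_30ms_delay_fails(self):
        w = np.zeros(307)
        w[150] = 1.0
        delayed = np.roll(w, int(0.030 * 512))
        ok, _ = zero_lag_check(w, delayed, 512.0, tolerance_ms=10.0)
        assert not ok

    def test_8ms_delay_passes(self):
        w = np.zeros(307)
        w[150] = 1.0
        delayed = np.roll(w, int(0.008 * 512))
        ok, lag = zero_lag_check(w, delayed, 512.0, tolerance_ms=10.0)
        assert ok and abs(lag) <= 0.010

    def test_flat_average_fails_with_warning(self):
        with pytest.warns(UserWarning, match="flat"):
            ok, _ = zero_lag_check(np.zeros(100), np.ones(100), 512.0)
        assert not ok


def _make_component(tc_epochs, index=0, n_channels=25, seed=0):
    rng = np.random.default_rng(seed + 100)
    topo = rng.standard_normal(n_channels)
    topo /= np.linalg.norm(topo)
    n_trials, n_samples = tc_epochs.shape
    return IcaComponent(
        topography=topo,
        timecourse=tc_epochs.reshape(-1),
        mode="triggered",
        band="2-60",
        seed=seed,
        index=index,
        fs=512.0,
        channel_ids=[f"m{i}" for i in range(n_channels)],
        n_trials=n_trials,
        n_epoch_samples=n_samples,
    )


class TestSelectComponents:
    """Selection on constructed toy decompositions (40 trials, 307 samples)."""

    fs = 512.0
    n_trials = 40
    n_samples = 307

    def _spike_epochs(self, rng, delay_s=0.0, amps=None):
        rel = (np.arange(self.n_samples) - 153) / self.fs
        shape = np.exp(-((rel - delay_s) ** 2) / (2 * 0.015**2))
        if amps is None:
            amps = np.exp(rng.normal(0, 0.4, self.n_trials))
        return amps[:, None] * shape[None, :], amps

    def _build(self, channel_signal, n_noise_channels=20, seed=0):
        rng = np.random.default_rng(seed)
        seeg = 0.2 * rng.standard_normal(
            (self.n_trials, n_noise_channels + 1, self.n_samples)
        )
        seeg[:, 0, :] += channel_signal
        return _epochs_from(seeg, fs=self.fs)

    def test_coupled_component_selected(self):
        rng = np.random.default_rng(0)
        spike, amps = self._spike_epochs(rng)
        comp_tc = spike + 0.2 * rng.standard_normal(spike.shape)
        chan = 2.0 * spike + 0.2 * rng.standard_normal(spike.shape)
        comps = [_make_component(comp_tc)] + [
            _make_component(rng.standard_normal(spike.shape), index=i, seed=i)
            for i in range(1, 6)
        ]
        res = select_components(comps, self._build(chan))
        assert res.components[0].selected
        assert "ch0" in res.components[0].significant_channels

    def test_delayed_channel_rejected_by_zero_lag(self):
        rng = np.random.default_rng(1)
        spike, amps = self._spike_epochs(rng)
        delayed, _ = self._spike_epochs(rng, delay_s=0.040, amps=amps)
        comp_tc = spike + 0.1 * rng.standard_normal(spike.shape)
        chan = 2.0 * delayed + 0.1 * rng.standard_normal(spike.shape)
        comps = [_make_component(comp_tc)] + [
            _make_component(rng.standard_normal(spike.shape), index=i, seed=i)
            for i in range(1, 6)
        ]
        res = select_components(comps, self._build(chan))
        assert not res.components[0].selected

    def test_amplitude_decoupled_channel_fails_itcor(self):
        # same average shape, independently drawn per-trial amplitudes:
        # temporal correlation passes, across-trial co-fluctuation does not
        rng = np.random.default_rng(2)
        spike, _ = self._spike_epochs(rng)
        other_amps = np.exp(rng.normal(0, 0.4, self.n_trials))
        chan_shape = spike / spike.max(axis=1, keepdims=True)
        comp_tc = spike + 0.05 * rng.standard_normal(spike.shape)
        chan = other_amps[:, None] * chan_shape + 0.05 * rng.standard_normal(spike.shape)
        comps = [_make_component(comp_tc)] + [
            _make_component(rng.standard_normal(spike.shape), index=i, seed=i)
            for i in range(1, 6)
        ]
        res = select_components(comps, self._build(chan))
        comp0 = res.components[0]
        if comp0.significant_temporal_channels:
            assert "ch0" not in comp0.significant_itcor_channels or not comp0.selected
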