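"""Filter design, Hilbert power, z-scoring and band envelopes."""

import numpy as np
import pytest
from scipy.signal import periodogram

from somnolearn import spectral as sp

FS = 1000.0
N = 10_501
TIMES = np.arange(-5500, 5001, 1.0)


def _single_trial(signal, factory, fs=FS):
    data = np.repeat(np.asarray(signal)[None, None, :], 2, axis=1)
    return factory(data, fs=fs)


class TestFilterDesign:
    @pytest.mark.parametrize("low, expected_transition", [
        (0.5, 2.0),      # 0.25 x 0.5 = 0.125 < 2 Hz floor
        (11.0, 2.75),    # 0.25 x 11
        (4.0, 2.0),      # 0.25 x 4 = 1 < 2 Hz floor
    ])
    def test_transition_rule(self, low, expected_transition):
        spec = sp.design_fir(low, low + 5, FS)
        assert spec.transition_hz == pytest.approx(expected_transition)

    def test_infeasible_band_rejected(self):
        with pytest.raises(ValueError):
            sp.design_fir(30.0, 60.0, 100.0)

    def test_sub_dc_band_degrades_to_lowpass(self):
        spec = sp.design_fir(0.25, 0.75, FS)
        assert spec.lowpass

    def test_stopband_attenuation_on_white_noise(self):
        """Sigma band-pass kills 7 Hz and 20 Hz by >= 20 dB (periodogram)."""
        rng = np.random.default_rng(0)
        wn = rng.standard_normal(30_000)
        filt = sp.apply_fir(wn, sp.design_fir(11.0, 16.0, FS))
        f, p_in = periodogram(wn, fs=FS)
        _, p_out = periodogram(filt, fs=FS)
        for f0 in (7.0, 20.0):
            band = (f > f0 - 0.5) & (f < f0 + 0.5)
            atten_db = 10 * np.log10(p_in[band].mean() / p_out[band].mean())
            assert atten_db >= 20.0
        pb = (f > 12.5) & (f < 14.5)
        assert abs(10 * np.log10(p_in[pb].mean() / p_out[pb].mean())) < 1.0

    def test_zero_phase_no_group_delay_on_impulse(self):
        x = np.zeros(4001)
        x[2000] = 1.0
        y = sp.apply_fir(x, sp.design_fir(4.0, 7.0, FS))
        assert np.argmax(np.abs(y)) == 2000


class TestHilbertPower:
    def test_pure_tone_power_flat_at_amplitude_squared(self, toy_epochs_factory):
        amp = 2.0
        sig = amp * np.sin(2 * np.pi * 13.0 * TIMES / 1000.0)
        ep = _single_trial(sig, toy_epochs_factory)
        power, _ = sp.hilbert_power(ep, freqs=np.array([13.0, 20.0]))
        central = slice(1250, 9250)  # central 8 s
        p13 = power[0, 0, 0, central]
        assert p13.mean() == pytest.approx(amp ** 2, rel=0.01)
        assert (p13.max() - p13.min()) / p13.mean() < 0.05
        assert power[0, 0, 1, central].mean() < 1e-3 * amp ** 2

    def test_zero_signal_gives_zero_power(self, toy_epochs_factory):
        ep = _single_trial(np.zeros(N), toy_epochs_factory)
        power, _ = sp.hilbert_power(ep, freqs=np.array([5.0]))
        assert np.allclose(power, 0.0)

    def test_am_modulator_recovered(self, toy_epochs_factory):
        """0.5 Hz AM on a 13 Hz carrier: envelope tracks the true modulator."""
        mod = 1 + 0.5 * np.sin(2 * np.pi * 0.5 * TIMES / 1000.0)
        ep = _single_trial(mod * np.sin(2 * np.pi * 13.0 * TIMES / 1000.0),
                           toy_epochs_factory)
        power, _ = sp.hilbert_power(ep, freqs=np.array([13.0]))
        env = np.sqrt(power[0, 0, 0])
        central = slice(1250, 9250)
        assert np.corrcoef(env[central], mod[central])[0, 1] > 0.95

    def test_output_independent_of_pad_length_in_interior(self, toy_epochs_factory):
        rng = np.random.default_rng(3)
        ep = _single_trial(rng.normal(0, 20, N), toy_epochs_factory)
        p1, _ = sp.hilbert_power(ep, freqs=np.array([6.0]), pad_s=1.0)
        p2, _ = sp.hilbert_power(ep, freqs=np.array([6.0]), pad_s=2.0)
        z1 = sp.zscore_trials(p1)[..., 500:-500]
        z2 = sp.zscore_trials(p2)[..., 500:-500]
        assert np.max(np.abs(z1 - z2)) < 1e-6


class TestZScore:
    def test_mean_zero_sd_one_per_bin(self, toy_epochs_factory):
        rng = np.random.default_rng(1)
        power = rng.gamma(2.0, 1.0, (3, 2, 4, 500))
        z = sp.zscore_trials(power)
        assert np.abs(z.mean(axis=-1)).max() < 1e-12
        assert np.abs(z.std(axis=-1) - 1).max() < 1e-12

    def test_toy_bin_population_convention(self):
        z = sp.zscore_trials(np.array([1.0, 2.0, 3.0, 4.0])[None, None, None, :])
        expected = (np.array([1, 2, 3, 4]) - 2.5) / np.sqrt(1.25)
        assert np.allclose(z.ravel(), expected)

    def test_toy_bin_sample_convention_switch(self):
        z = sp.zscore_trials(np.array([1.0, 2.0, 3.0, 4.0])[None, None, None, :],
                             ddof=1)
        assert np.allclose(z.ravel(), [-1.1619, -0.3873, 0.3873, 1.1619],
                           atol=1e-4)

    def test_constant_bin_maps_to_zero_with_warning(self):
        power = np.ones((1, 1, 1, 100))
        with pytest.warns(UserWarning, match="constant"):
            z = sp.zscore_trials(power)
        assert np.allclose(z, 0.0)

    def test_gain_invariance(self, toy_epochs_factory):
        """Doubling signal amplitude leaves z-scored power unchanged exactly."""
        rng = np.random.default_rng(2)
        sig = rng.normal(0, 20, N)
        p1, _ = sp.hilbert_power(_single_trial(sig, toy_epochs_factory),
                                 freqs=np.array([10.0]))
        p2, _ = sp.hilbert_power(_single_trial(2 * sig, toy_epochs_factory),
                                 freqs=np.array([10.0]))
        assert np.allclose(sp.zscore_trials(p1), sp.zscore_trials(p2),
                           atol=1e-10)

    def test_baseline_window_mode(self):
        power = np.concatenate([np.ones(50), np.full(50, 3.0)])[None, None, None, :]
        mask = np.arange(100) < 50
        with pytest.warns(UserWarning):
            z = sp.zscore_trials(power, baseline_mask=mask)
        assert np.allclose(z, 0.0)  # constant baseline -> guarded


class TestAveraging:
    def test_identical_channels_average_to_either(self, toy_epochs_factory):
        rng = np.random.default_rng(4)
        z = rng.normal(size=(4, 2, 3, 100))
        z[:, 1] = z[:, 0]
        ep = toy_epochs_factory(np.zeros((4, 2, 100)),
                                conditions=["CSu", "CSu", "CSp", "CSp"])
        ep.phase[:] = "early"
        maps = sp.average_tfr(z, ep)
        assert np.allclose(maps[("CSu", "early")], z[:2, 0].mean(axis=0))

    def test_empty_cell_is_explicit_missing(self, toy_epochs_factory):
        ep = toy_epochs_factory(np.zeros((2, 2, 50)),
                                conditions=["CSu", "CSu"])
        ep.phase[:] = "early"
        maps = sp.average_tfr(np.zeros((2, 2, 1, 50)), ep)
        assert maps[("CSp", "early")] is None
        assert maps[("CSu", "late")] is None

    def test_channel_trial_averaging_order_commutes(self, toy_epochs_factory):
        rng = np.random.default_rng(5)
        z = rng.normal(size=(6, 2, 2, 80))
        ep = toy_epochs_factory(np.zeros((6, 2, 80)))
        ep.phase[:] = "early"
        chan_then_trial = z.mean(axis=1).mean(axis=0)
        trial_then_chan = z.mean(axis=0).mean(axis=0)
        assert np.allclose(chan_then_trial, trial_then_chan)
        assert np.allclose(sp.average_tfr(z, ep)[("CSu", "early")],
                           chan_then_trial)


class TestBandEnvelope:
    def test_delta_uses_eight_bins_inclusive(self):
        assert list(sp.band_bins("delta")) == [0.5, 1.0, 1.5, 2.0, 2.5, 3.0,
                                               3.5, 4.0]
        assert len(sp.band_bins("theta")) == 7
        assert len(sp.band_bins("sigma")) == 11
        assert sp.frequency_grid().size == 80

    def test_band_outside_grid_rejected(self):
        with pytest.raises(ValueError):
            sp.band_bins((45.0, 60.0))

    def test_constant_map_has_constant_envelope(self):
        freqs = sp.frequency_grid()
        values = np.ones((3, freqs.size, 40))
        env = sp.band_envelope(values, freqs, "delta")
        assert np.allclose(env, 1.0)

    def test_variance_budget_on_white_noise(self, toy_epochs_factory):
        """Band-filtered variances can't exceed the unfiltered variance."""
        rng = np.random.default_rng(6)
        sig = rng.standard_normal(N)
        total = sig.var()
        band_var = 0.0
        for band in ("delta", "theta", "sigma"):
            spec = sp.design_fir(*sp.BANDS[band], FS)
            band_var += sp.apply_fir(sig, spec)[1000:-1000].var()
        assert band_var <= total * 1.05


class TestZScoreProperties:
    """Property-based checks of the per-trial normalization."""

    from hypothesis import given, settings, strategies as st

    @given(gain=st.floats(min_value=0.01, max_value=100.0),
           seed=st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_zscore_invariant_to_any_positive_gain(self, gain, seed):
        rng = np.random.default_rng(seed)
        power = rng.gamma(2.0, 1.0, (2, 1, 2, 200))
        assert np.allclose(sp.zscore_trials(power * gain),
                           sp.zscore_trials(power), atol=1e-9)

    @given(seed=st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_zscore_is_idempotent_up_to_affine(self, seed):
        rng = np.random.default_rng(seed)
        power = rng.gamma(2.0, 1.0, (1, 1, 1, 300))
        z = sp.zscore_trials(power)
        assert np.allclose(sp.zscore_trials(z), z, atol=1e-9)
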