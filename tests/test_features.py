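"""The 20 quantitative-EEG parameters: examples, closed forms, invariants."""

import numpy as np
import pytest

from eegcbf.features import (
    BANDS,
    FEATURE_NAMES,
    FeatureConfig,
    bcsef,
    burst_suppression_ratio,
    extract_feature_vector,
    log_band_ratio,
    magnitude,
    power_fraction,
    ratio05,
    signal_entropy,
    spectral_entropy,
    synch_fast_slow,
)
from eegcbf.preprocess import PowerSpectrum, power_spectrum
from eegcbf.records import SubEpoch
from eegcbf.synth import GeneratorConfig, synth_eeg_pause

FS = 250.0
N = 500


def tone(freq, amp=1.0, n=N, fs=FS):
    return amp * np.sin(2 * np.pi * freq * np.arange(n) / fs)


def flat_spectrum():
    freqs = np.arange(0.0, 125.5, 0.5)
    power = np.where((freqs >= 1) & (freqs < 47), 1.0, 0.0)
    return PowerSpectrum(freqs, power)


class TestTimeDomain:
    def test_magnitude_examples(self):
        assert magnitude(np.array([-3.0, 7.0, -12.0, 4.0])) == 12.0
        assert magnitude(np.zeros(10)) == 0.0

    def test_ratio05_half_and_half(self):
        x = np.array([1.0, -1.0, 10.0, -10.0])
        assert ratio05(x) == 50.0

    def test_ratio05_isoelectric_full(self):
        assert ratio05(np.full(N, 0.5)) == 100.0

    def test_ratio05_strict_boundary(self):
        # samples exactly at 5 µV are excluded by the strict inequality
        assert ratio05(np.full(10, 5.0)) == 0.0
        assert ratio05(np.full(10, np.nextafter(5.0, 0.0))) == 100.0

    def test_bsr_fully_isoelectric(self):
        assert burst_suppression_ratio(np.full(N, 1.0), FS) == 100.0

    def test_bsr_continuous_sinusoid_zero(self):
        # 20 µV at 10 Hz dips under 5 µV only briefly at zero crossings
        assert burst_suppression_ratio(tone(10.0, amp=20.0), FS) == 0.0

    def test_bsr_half_suppressed(self):
        x = np.concatenate([np.full(250, 1.0), np.full(250, 20.0)])
        assert burst_suppression_ratio(x, FS) == 50.0

    def test_bsr_short_runs_do_not_count(self):
        # 0.4-s suppressed runs are below the 0.5-s criterion
        x = np.tile(np.concatenate([np.full(100, 1.0), np.full(25, 20.0)]), 4)
        assert burst_suppression_ratio(x, FS) == 0.0


class TestBandRatiosAndFractions:
    def test_equal_band_powers_give_zero(self):
        freqs = np.arange(0.0, 125.5, 0.5)
        power = np.ones_like(freqs)
        sp = PowerSpectrum(freqs, power)
        # [1,4) holds 6 bins, [2,5) holds 6 bins
        assert log_band_ratio(sp, (1, 4), (2, 5)) == pytest.approx(0.0)

    def test_log10_convention(self):
        freqs = np.arange(0.0, 125.5, 0.5)
        power = np.where((freqs >= 1) & (freqs < 4), 10.0, 0.0)
        power += np.where((freqs >= 8) & (freqs < 11), 1.0, 0.0)
        sp = PowerSpectrum(freqs, power)
        assert log_band_ratio(sp, (1, 4), (8, 11)) == pytest.approx(1.0)

    def test_two_tone_dar(self):
        # delta tone at twice the alpha tone's amplitude: power ratio 4
        sp = power_spectrum(tone(2.0, amp=2.0) + tone(10.0, amp=1.0), FS)
        assert log_band_ratio(sp, BANDS["delta"], BANDS["alpha"]) == pytest.approx(
            np.log10(4.0), abs=0.01
        )

    def test_alpha_tone_alpha_fraction(self):
        sp = power_spectrum(tone(10.0), FS)
        assert power_fraction(sp, BANDS["alpha"]) >= 0.95

    def test_pr_partition_sums_to_one(self, rng):
        sp = power_spectrum(rng.standard_normal(N), FS)
        total = sum(
            power_fraction(sp, BANDS[b])
            for b in ("delta", "theta", "alpha", "beta", "gamma")
        )
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_zero_signal_fraction_zero(self):
        sp = power_spectrum(np.zeros(N), FS)
        with pytest.warns(UserWarning, match="zero total"):
            assert power_fraction(sp, BANDS["alpha"]) == 0.0


class TestBcSEF:
    def test_zero_at_full_suppression(self, rng):
        sp = power_spectrum(rng.standard_normal(N), FS)
        assert bcsef(sp, 100.0) == 0.0

    def test_tone_sef_without_suppression(self):
        sp = power_spectrum(tone(10.0), FS)
        assert bcsef(sp, 0.0) == pytest.approx(10.0, abs=0.5)

    def test_flat_spectrum_closed_form(self):
        # 95 % of 92 uniform bins between 1 and 47 Hz
        assert bcsef(flat_spectrum(), 0.0) == pytest.approx(44.7, abs=0.5)

    def test_monotone_in_bsr(self, rng):
        sp = power_spectrum(rng.standard_normal(N), FS)
        values = [bcsef(sp, b) for b in np.linspace(0, 100, 21)]
        assert all(a >= b for a, b in zip(values, values[1:]))

    def test_invalid_bsr(self, rng):
        sp = power_spectrum(rng.standard_normal(N), FS)
        with pytest.raises(ValueError):
            bcsef(sp, 120.0)


class TestEntropies:
    def test_uniform_closed_forms(self):
        x = np.ones(N)  # p uniform over 500 samples
        assert signal_entropy(x, "shannon") == pytest.approx(np.log(N), rel=1e-9)
        # Rényi at alpha=0.5 coincides with Shannon at the uniform point
        assert signal_entropy(x, "renyi") == pytest.approx(np.log(N), rel=1e-9)
        assert signal_entropy(x, "log_energy", "probability") == pytest.approx(
            -2 * N * np.log(N), rel=1e-9
        )

    def test_one_hot_shannon_zero(self):
        x = np.zeros(N)
        x[7] = 3.0
        assert signal_entropy(x, "shannon") == pytest.approx(0.0, abs=1e-9)

    def test_raw_energy_convention(self):
        x = np.full(N, 2.0)
        assert signal_entropy(x, "log_energy", "raw_energy") == pytest.approx(
            N * np.log(4.0), rel=1e-9
        )

    def test_unknown_kind(self):
        with pytest.raises(ValueError):
            signal_entropy(np.ones(4), "tsallis")

    def test_spectral_entropy_flat_is_one(self):
        assert spectral_entropy(flat_spectrum()) == pytest.approx(1.0, abs=1e-9)

    def test_spectral_entropy_single_bin_zero(self):
        freqs = np.arange(0.0, 125.5, 0.5)
        power = np.zeros_like(freqs)
        power[freqs == 10.0] = 5.0
        assert spectral_entropy(PowerSpectrum(freqs, power)) == pytest.approx(
            0.0, abs=1e-9
        )

    def test_spectral_entropy_zero_power(self):
        assert spectral_entropy(power_spectrum(np.zeros(N), FS)) == 0.0


class TestSynchFastSlow:
    def test_pure_tone_positive(self):
        assert synch_fast_slow(tone(10.0), FS) > 0.0

    def test_zero_signal_floored_to_zero(self):
        assert synch_fast_slow(np.zeros(N), FS) == 0.0

    def test_white_noise_stability(self, rng):
        vals = [synch_fast_slow(rng.standard_normal(N), FS) for _ in range(100)]
        assert np.std(vals) < 0.2 * abs(np.mean(vals))


class TestExtractFeatureVector:
    def test_all_fields_populated(self, rng):
        ep = SubEpoch(rng.standard_normal(N), FS)
        fv = extract_feature_vector(ep)
        assert tuple(fv) == FEATURE_NAMES
        assert all(np.isfinite(v) for v in fv.values())

    def test_isoelectric_regime_consistency(self, rng):
        eeg = synth_eeg_pause("isoelectric", 0.0, 2.0, rng, GeneratorConfig())
        fv = extract_feature_vector(SubEpoch(eeg.samples, FS))
        assert fv["BSR"] == 100.0
        assert fv["Ratio05"] == 100.0
        assert fv["BcSEF"] == 0.0
        assert fv["Magnitude"] < 5.0

    def test_baseline_regime_magnitude(self, rng):
        eeg = synth_eeg_pause("baseline", 100.0, 2.0, rng, GeneratorConfig())
        fv = extract_feature_vector(SubEpoch(eeg.samples, FS))
        assert fv["Magnitude"] > 20.0

    def test_deterministic(self, rng):
        ep = SubEpoch(rng.standard_normal(N), FS)
        assert extract_feature_vector(ep) == extract_feature_vector(ep)

    def test_amplitude_scaling_invariance(self, rng):
        x = rng.standard_normal(N)
        a = extract_feature_vector(SubEpoch(x, FS))
        b = extract_feature_vector(SubEpoch(3.0 * x, FS))
        scale_free = (
            "ExtraPR", "AlphaPR", "BetaPR", "DeltaPR", "ThetaPR", "GammaPR",
            "SpectralEntropy", "ShannonEntropy", "RenyiEntropy", "BG_AlphaPlus",
            "DeltaR", "DAR", "DTABR", "BetaR", "SynchFastSlow",
        )
        for name in scale_free:
            assert b[name] == pytest.approx(a[name], rel=1e-6, abs=1e-9), name
        assert b["Magnitude"] == pytest.approx(3.0 * a["Magnitude"], rel=1e-9)

    def test_bg_alpha_plus_partition_identity(self, rng):
        fv = extract_feature_vector(SubEpoch(rng.standard_normal(N), FS))
        assert fv["BG_AlphaPlus"] / 100.0 == pytest.approx(
            fv["AlphaPR"] + fv["BetaPR"] + fv["GammaPR"], abs=1e-9
        )

    def test_entropy_convention_switch(self, rng):
        x = rng.standard_normal(N)
        raw = extract_feature_vector(SubEpoch(x, FS), FeatureConfig())
        prob = extract_feature_vector(
            SubEpoch(x, FS), FeatureConfig(entropy_convention="probability")
        )
        assert raw["LogEnergyEntropy"] != prob["LogEnergyEntropy"]
        assert raw["ShannonEntropy"] == prob["ShannonEntropy"]
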