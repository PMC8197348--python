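"""The synthetic VF/CPR generator: protocol, regimes, determinism."""

import numpy as np
import pytest

from eegcbf.labeling import recovery_rate_from_trace, to_group
from eegcbf.preprocess import band_power, power_spectrum
from eegcbf.synth import (
    GeneratorConfig,
    assign_recovery,
    simulate_session,
    synth_cpr_artifact,
    synth_eeg_pause,
)


class TestConfigValidation:
    def test_negative_duration_rejected(self):
        with pytest.raises(ValueError, match="duration"):
            GeneratorConfig(block_duration_s=-1.0)

    def test_imbalance_outside_unit_interval(self):
        with pytest.raises(ValueError, match="imbalance"):
            GeneratorConfig(imbalance_target=1.2)

    def test_nonpositive_amplitude_rejected(self):
        with pytest.raises(ValueError, match="amplitude"):
            GeneratorConfig(isoelectric_peak_uv=0.0)


class TestProtocolStateMachine:
    def test_forced_rosc_after_bls(self):
        cfg = GeneratorConfig(seed=3, force_rosc_after_pause=1)
        s = simulate_session(cfg, 1)
        assert len(s.pauses) == 1
        kinds = [k for k, _ in s.timeline.stages]
        assert kinds == ["baseline", "untreated_vf"] + ["bls"] * 4 + ["pause", "monitoring"]
        assert s.rosc_stage == len(kinds) - 1

    def test_non_rosc_full_protocol(self):
        cfg = GeneratorConfig(seed=3, force_non_rosc=True)
        s = simulate_session(cfg, 1)
        kinds = [k for k, _ in s.timeline.stages]
        assert kinds.count("bls") == 4
        assert kinds.count("acls") == 10
        assert len(s.pauses) == 11
        assert s.rosc_stage is None

    def test_determinism(self):
        cfg = GeneratorConfig(seed=11)
        a = simulate_session(cfg, 2)
        b = simulate_session(cfg, 2)
        np.testing.assert_array_equal(a.eeg.samples, b.eeg.samples)
        np.testing.assert_array_equal(a.cbf.samples, b.cbf.samples)
        assert a.pauses == b.pauses and a.timeline.stages == b.timeline.stages

    def test_seed_changes_output(self):
        a = simulate_session(GeneratorConfig(seed=11), 2)
        b = simulate_session(GeneratorConfig(seed=12), 2)
        assert not np.array_equal(a.eeg.samples, b.eeg.samples)

    def test_signals_cover_same_span(self, cohort):
        for s in cohort:
            assert s.eeg.n_samples == s.cbf.samples.size
            assert s.eeg.fs == 250.0

    def test_pause_count_bounded(self, cohort):
        for s in cohort:
            assert 1 <= len(s.pauses) <= 11

    def test_labels_recomputed_from_flow_match_assignment(self, cohort):
        for s in cohort:
            for p in s.pauses:
                rate = recovery_rate_from_trace(s.cbf, p.start_s)
                assert to_group(rate) == p.group
                assert rate == pytest.approx(p.recovery_rate, abs=1.0)


class TestPauseEEGRegimes:
    def test_isoelectric_under_5uv(self, rng):
        for _ in range(20):
            eeg = synth_eeg_pause("isoelectric", 0.0, 3.0, rng)
            assert np.max(np.abs(eeg.samples)) < 5.0

    def test_baseline_exceeds_20uv(self, rng):
        for _ in range(20):
            eeg = synth_eeg_pause("baseline", 100.0, 3.0, rng)
            assert np.max(np.abs(eeg.samples)) > 20.0

    def test_duration_sample_arithmetic(self, rng):
        eeg = synth_eeg_pause("recovered", 50.0, 3.0, rng)
        assert eeg.n_samples == 750

    def test_too_short_pause_rejected(self, rng):
        with pytest.raises(ValueError, match="at least 2 s"):
            synth_eeg_pause("recovered", 50.0, 1.0, rng)

    def test_unknown_regime(self, rng):
        with pytest.raises(ValueError, match="unknown"):
            synth_eeg_pause("rem_sleep", 50.0, 3.0, rng)

    def test_recovery_rate_ordering(self):
        """Median Magnitude and 8-47 Hz share rise from 10 % to 100 % recovery."""
        rng = np.random.default_rng(99)
        stats = {}
        for rate in (10.0, 100.0):
            mags, bgs = [], []
            for _ in range(50):
                x = synth_eeg_pause("recovered", rate, 2.0, rng).samples
                sp = power_spectrum(x, 250.0)
                mags.append(np.max(np.abs(x)))
                bgs.append(band_power(sp, 8, 47) / max(band_power(sp, 1, 47), 1e-30))
            stats[rate] = (np.median(mags), np.median(bgs))
        assert stats[100.0][0] > stats[10.0][0]
        assert stats[100.0][1] > stats[10.0][1]


class TestCPRArtifact:
    def test_dominant_peak_at_compression_rate(self, rng):
        eeg = synth_cpr_artifact(102.0, 50.0, 10.0, rng)
        sp = power_spectrum(eeg.samples, eeg.fs)
        in_band = (sp.freqs >= 0.5) & (sp.freqs <= 47.0)
        peak = sp.freqs[in_band][np.argmax(sp.power[in_band])]
        assert peak == pytest.approx(1.7, abs=0.15)

    def test_peak_amplitude_at_least_configured(self, rng):
        eeg = synth_cpr_artifact(102.0, 50.0, 5.0, rng)
        assert np.max(np.abs(eeg.samples)) >= 50.0

    def test_seeds_change_phase_not_fundamental(self):
        a = synth_cpr_artifact(102.0, 50.0, 10.0, np.random.default_rng(1))
        b = synth_cpr_artifact(102.0, 50.0, 10.0, np.random.default_rng(2))
        assert not np.array_equal(a.samples, b.samples)
        for x in (a, b):
            sp = power_spectrum(x.samples, x.fs)
            in_band = (sp.freqs >= 0.5) & (sp.freqs <= 47.0)
            assert sp.freqs[in_band][np.argmax(sp.power[in_band])] == pytest.approx(
                1.7, abs=0.15
            )

    def test_nonpositive_rate_rejected(self, rng):
        with pytest.raises(ValueError, match="rate"):
            synth_cpr_artifact(0.0, 50.0, 5.0, rng)


class TestAssignRecovery:
    def test_marginal_imbalance(self):
        cfg = GeneratorConfig(imbalance_target=0.53)
        rng = np.random.default_rng(5)
        rates = [assign_recovery(cfg, 1, rng) for _ in range(1000)]
        frac_low = np.mean([r < 30.0 for r in rates])
        assert 0.48 <= frac_low <= 0.58

    def test_rates_nonnegative(self):
        cfg = GeneratorConfig()
        rng = np.random.default_rng(6)
        assert all(assign_recovery(cfg, 1, rng) >= 0 for _ in range(200))

    def test_forced_baseline_flow(self, rng):
        cfg = GeneratorConfig(forced_flow_fraction=1.0)
        assert assign_recovery(cfg, 1, rng) == 100.0

    def test_forced_zero_flow(self, rng):
        cfg = GeneratorConfig(forced_flow_fraction=0.0)
        assert assign_recovery(cfg, 1, rng) == 0.0


def test_subepochs_are_three_per_pause(small_cohort, small_table):
    n_pauses = sum(len(s.pauses) for s in small_cohort)
    assert len(small_table) == 3 * n_pauses
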