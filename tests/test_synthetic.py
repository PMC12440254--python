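import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pulsegrip as pg
from pulsegrip.synthetic import (
    TASK_CONDITIONS,
    ForceSignal,
    pulse_waveform,
    read_dataset,
    read_force_csv,
    write_dataset,
    write_force_csv,
)

# Group-mean PCFF presets for every condition, as printed in the comparison
# tables of the six vessel models.
PRINTED_AMPLITUDES = {
    "phantom_I": [0.162, 0.130, 0.010],
    "phantom_II": [0.223, 0.172, 0.141, 0.081, 0.050, 0.026],
    "phantom_III": [0.141, 0.100, 0.058],
    "porcine_I": [0.047, 0.022],
    "porcine_II": [0.122, 0.066, 0.046],
    "porcine_III": [0.059, 0.032],
}


class TestPresets:
    @pytest.mark.parametrize("task", sorted(TASK_CONDITIONS))
    def test_amplitudes_match_printed_group_means(self, task):
        assert [a for _, a in TASK_CONDITIONS[task]] == PRINTED_AMPLITUDES[task]

    @pytest.mark.parametrize(
        "task,cond,amp",
        [("porcine_I", "artery", 0.047), ("phantom_II", "0.5mm", 0.223)],
    )
    def test_make_preset_returns_printed_amplitude(self, task, cond, amp):
        spec = pg.make_preset(task, cond)
        assert spec.pulse_amplitude == amp
        assert spec.pulse_rate == 90.0
        assert spec.hold_duration == 15.0
        assert spec.amplitude_cv == 0.15
        assert spec.noise_sd == 0.003

    def test_unknown_condition_lists_valid_labels(self):
        with pytest.raises(KeyError, match="20A"):
            pg.make_preset("phantom_I", "99A")
        with pytest.raises(KeyError, match="phantom_I"):
            pg.make_preset("phantom_IV", "20A")

    def test_overrides_are_applied(self):
        spec = pg.make_preset("porcine_I", "vein", noise_sd=0.0, amplitude_cv=0.0)
        assert spec.noise_sd == 0.0 and spec.amplitude_cv == 0.0


class TestSimulateTrial:
    def test_length_is_duration_times_rate(self):
        spec = pg.make_preset("porcine_I", "artery")
        sig = pg.simulate_grip_trial(spec, fs=100, seed=0)
        assert sig.samples.size == 1500

    def test_noiseless_unit_peak_construction(self):
        spec = pg.make_preset(
            "porcine_I", "artery", pulse_amplitude=0.1,
            amplitude_cv=0.0, noise_sd=0.0,
        )
        sig = pg.simulate_grip_trial(spec, fs=100, seed=5)
        assert abs(sig.samples.max() - spec.baseline_force - 0.1) < 1e-9

    @pytest.mark.parametrize("seed", range(8))
    def test_pulse_count_over_15s_at_90bpm(self, seed):
        # oracle: count strict local maxima of the noiseless pulse train
        spec = pg.make_preset(
            "porcine_I", "artery", amplitude_cv=0.0, noise_sd=0.0
        )
        x = pg.simulate_grip_trial(spec, fs=100, seed=seed).samples
        interior = (x[1:-1] > x[:-2]) & (x[1:-1] >= x[2:])
        n_max = int(np.count_nonzero(interior & (x[1:-1] > x.min() + 0.5 * np.ptp(x))))
        assert n_max in (22, 23)

    def test_reproducible_bit_for_bit(self):
        spec = pg.make_preset("porcine_II", "2.0mm")
        a = pg.simulate_grip_trial(spec, fs=100, seed=11).samples
        b = pg.simulate_grip_trial(spec, fs=100, seed=11).samples
        assert np.array_equal(a, b)
        c = pg.simulate_grip_trial(spec, fs=100, seed=12).samples
        assert not np.array_equal(a, c)

    def test_undersampling_rejected(self):
        spec = pg.make_preset("porcine_I", "artery")
        with pytest.raises(ValueError, match="fs"):
            pg.simulate_grip_trial(spec, fs=5, seed=0)

    @given(
        amp=st.floats(0.01, 0.3),
        cv=st.floats(0.0, 0.5),
        noise=st.floats(0.0, 0.01),
        seed=st.integers(0, 2**31 - 1),
    )
    @settings(max_examples=25, deadline=None)
    def test_signal_always_finite_with_expected_length(self, amp, cv, noise, seed):
        spec = pg.make_preset(
            "porcine_I", "artery", pulse_amplitude=amp,
            amplitude_cv=cv, noise_sd=noise, hold_duration=5.0,
        )
        sig = pg.simulate_grip_trial(spec, fs=50, seed=seed)
        assert sig.samples.size == 250
        assert np.all(np.isfinite(sig.samples))

    def test_pulse_waveform_unit_peak_and_near_zero_tails(self):
        phi = np.linspace(0, 1, 10001)
        p = pulse_waveform(phi)
        assert p.max() == pytest.approx(1.0, abs=1e-12)
        assert pulse_waveform(np.array([0.3]))[0] == 1.0
        # tails hug zero for a majority of the cycle (keeps quantile baseline clean)
        assert np.mean(p < 1e-6) > 0.3


class TestGenerateDataset:
    def test_porcine_I_sequence_counts(self):
        ds = pg.generate_dataset("porcine_I", 80, 100, 42)
        assert len(ds.sequences) == 160
        assert ds.n_classes == 2
        assert np.bincount(ds.labels).tolist() == [80, 80]

    def test_phantom_III_three_classes(self):
        ds = pg.generate_dataset("phantom_III", 80, 100, 42)
        assert len(ds.sequences) == 240 and ds.n_classes == 3

    def test_minimal_dataset_labels_in_condition_order(self):
        ds = pg.generate_dataset("porcine_I", 1, 100, 0)
        assert ds.labels.tolist() == [0, 1]
        assert ds.class_names == ["artery", "vein"]

    def test_unknown_task_rejected(self):
        with pytest.raises(KeyError, match="porcine_I"):
            pg.generate_dataset("porcine_IV", 2, 100, 0)

    def test_master_seed_reproduces_dataset(self):
        a = pg.generate_dataset("porcine_I", 3, 50, 9)
        b = pg.generate_dataset("porcine_I", 3, 50, 9)
        for s1, s2 in zip(a.sequences, b.sequences):
            assert np.array_equal(s1.samples, s2.samples)

    def test_trials_differ_within_condition(self):
        ds = pg.generate_dataset("porcine_I", 2, 50, 9)
        assert not np.array_equal(ds.sequences[0].samples, ds.sequences[1].samples)


class TestIO:
    def test_force_csv_round_trip(self, tmp_path):
        spec = pg.make_preset("porcine_I", "artery")
        sig = pg.simulate_grip_trial(spec, fs=100, seed=1)
        path = tmp_path / "trial.csv"
        write_force_csv(sig, path)
        assert path.read_text().startswith("time_s,force_n")
        back = read_force_csv(path)
        assert back.fs == pytest.approx(sig.fs, rel=1e-6)
        np.testing.assert_allclose(back.samples, sig.samples, atol=1e-8)

    def test_dataset_manifest_round_trip(self, tmp_path):
        ds = pg.generate_dataset("porcine_III", 2, 50, 4)
        mpath = write_dataset(ds, tmp_path / "ds")
        back = read_dataset(mpath)
        assert back.class_names == ds.class_names
        assert back.labels.tolist() == ds.labels.tolist()
        np.testing.assert_allclose(
            back.sequences[0].samples, ds.sequences[0].samples, atol=1e-8
        )


class TestForceSignal:
    def test_rejects_degenerate_inputs(self):
        with pytest.raises(ValueError):
            ForceSignal(samples=np.array([1.0]), fs=10.0)
        with pytest.raises(ValueError):
            ForceSignal(samples=np.array([1.0, np.inf]), fs=10.0)
        with pytest.raises(ValueError):
            ForceSignal(samples=np.array([1.0, 2.0]), fs=0.0)
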