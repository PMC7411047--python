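"""Preprocessing, difference waves, mini-ERPs and decoding."""

import numpy as np
import pytest

from flashgrab.containers import DEFAULT_CHANNELS, EEGStudy, SubjectEpochs
from flashgrab.eeg import (
    DiffWave,
    cross_decode,
    decode_timecourse,
    intersubject_correlation,
    lateralized_difference,
    lateralized_differences,
    make_mini_erps,
    preprocess_epochs,
    select_c1_electrodes,
    subtract_background,
    window_mean_amplitude,
)
from flashgrab.synth import EEGSimConfig, simulate_eeg_study


def _bump(times, center, width):
    """Smooth in-band bump (raised cosine) for artifact injection."""
    prof = np.zeros_like(times)
    inside = np.abs(times - center) < width / 2
    prof[inside] = 0.5 * (1 + np.cos(2 * np.pi * (times[inside] - center) / width))
    return prof


class TestPreprocess:
    @pytest.fixture()
    def quiet_study(self):
        cfg = EEGSimConfig(
            n_subjects=1, n_trials_per_cell=2, conditions=("retinal",),
            noise_white_sd_uv=0.1, noise_pink_sd_uv=0.0, epoch_end_ms=600.0,
        )
        return simulate_eeg_study(cfg)

    def _inject(self, study, trial, amp, center):
        subj = study.subjects[0]
        veo = subj.channel_names.index("VEO")
        subj.data[veo, :, trial] += amp * _bump(subj.times, center, 150.0)

    def test_rejection_threshold_and_window(self, quiet_study):
        self._inject(quiet_study, 0, 80.0, 100.0)    # above 75 uV, in window
        self._inject(quiet_study, 1, 70.0, 100.0)    # below threshold
        self._inject(quiet_study, 2, 200.0, 500.0)   # outside [-100, 300] ms
        clean, log = preprocess_epochs(quiet_study)
        assert log["s00"] == 1
        assert clean.subjects[0].n_trials == quiet_study.subjects[0].n_trials - 1

    def test_bandpass_removes_dc_and_preserves_inband(self, quiet_study):
        subj = quiet_study.subjects[0]
        ch = subj.channel_names.index("O1")
        subj.data[ch, :, :] += 40.0  # DC offset
        clean, _ = preprocess_epochs(quiet_study)
        post = clean.subjects[0].data[ch]
        assert np.abs(post.mean()) < 1.0

    def test_missing_veo_rejected(self, quiet_study):
        subj = quiet_study.subjects[0]
        subj.channel_names[subj.channel_names.index("VEO")] = "XX"
        with pytest.raises(ValueError, match="VEO"):
            preprocess_epochs(quiet_study)


class TestC1Selection:
    def test_injected_channels_recovered(self):
        times = np.arange(-100.0, 300.0)
        names = list(DEFAULT_CHANNELS)
        erps = np.zeros((len(names), times.size))
        targets = ["P3", "P5", "PO5", "PO7", "O1"]
        mask = (times >= 60) & (times <= 100)
        for i, t in enumerate(targets):
            erps[names.index(t), mask] = 5.0 - 0.1 * i
        picked = select_c1_electrodes(erps, times, names, 5)
        assert sorted(picked) == sorted(targets)

    def test_tie_break_by_name_order(self):
        times = np.arange(-100.0, 300.0)
        names = list(DEFAULT_CHANNELS)
        erps = np.zeros((len(names), times.size))
        mask = (times >= 60) & (times <= 100)
        for t in ("O1", "O2", "OZ"):
            erps[names.index(t), mask] = 3.0
        picked = select_c1_electrodes(erps, times, names, 2)
        assert picked == ["O1", "O2"]

    def test_invalid_counts(self):
        times = np.arange(-100.0, 300.0)
        names = list(DEFAULT_CHANNELS)
        erps = np.zeros((len(names), times.size))
        with pytest.raises(ValueError):
            select_c1_electrodes(erps, times, names, 0)
        with pytest.raises(ValueError):
            select_c1_electrodes(erps, times, names, 99)


def _two_channel_subject(left_vals, right_vals, sides):
    """(P3, P4) pair; values are (time, trials) arrays."""
    left_vals = np.asarray(left_vals, float)
    data = np.stack([left_vals, np.asarray(right_vals, float)])
    n_t, n_tr = left_vals.shape
    return SubjectEpochs(
        data=data, times=np.arange(n_t, dtype=float), srate=1000.0,
        channel_names=["P3", "P4"],
        condition=np.array(["c"] * n_tr, dtype=object),
        side=np.array(sides, dtype=object),
    )


class TestLateralizedDifference:
    def test_symmetric_data_zero_wave(self):
        vals = np.random.default_rng(0).normal(size=(5, 4))
        subj = _two_channel_subject(vals, vals, ["left", "right"] * 2)
        wave = lateralized_difference(subj, "c", ["P3"])
        np.testing.assert_allclose(wave.amplitude, 0.0)

    def test_hand_computation(self):
        # trial 0 (left side):  contra = P4, diff = P4 - P3 = [2, 0]
        # trial 1 (right side): contra = P3, diff = P3 - P4 = [-3, 1]
        left = np.array([[1.0, 4.0], [2.0, 2.0]])   # P3: time x trials
        right = np.array([[3.0, 1.0], [2.0, 3.0]])  # P4
        subj = _two_channel_subject(left, right, ["left", "right"])
        wave = lateralized_difference(subj, "c", ["P3"])
        np.testing.assert_allclose(wave.amplitude, [(2 + 3) / 2, (0 - 1) / 2])

    def test_unpaired_electrode_rejected(self):
        subj = _two_channel_subject(np.zeros((3, 2)), np.zeros((3, 2)),
                                    ["left", "right"])
        with pytest.raises(ValueError, match="pairing"):
            lateralized_difference(subj, "c", ["CZ"])

    def test_subtract_background(self):
        t = np.arange(4.0)
        a = DiffWave(np.array([1.0, 2, 3, 4]), t, ("P3", "P4"))
        b = DiffWave(np.array([1.0, 1, 1, 1]), t, ("P3", "P4"))
        out = subtract_background(a, b)
        np.testing.assert_allclose(out.amplitude, [0, 1, 2, 3])
        assert out.correction == "background_subtracted"
        np.testing.assert_allclose(
            subtract_background(a, a).amplitude, 0.0
        )
        zero = DiffWave(np.zeros(4), t, ("P3", "P4"))
        np.testing.assert_allclose(subtract_background(a, zero).amplitude,
                                   a.amplitude)
        with pytest.raises(ValueError, match="time bases"):
            subtract_background(a, DiffWave(np.zeros(3), t[:3], ("P3", "P4")))


class TestMiniERPs:
    def test_k1_exhaustive_returns_raw_trials(self, rng):
        trials = rng.normal(size=(3, 4, 10))
        labels = np.repeat(["a", "b"], 5)
        samples, out = make_mini_erps(trials, labels, k=1, n_samples=5, seed=0)
        np.testing.assert_array_equal(samples[..., :5], trials[..., :5])
        np.testing.assert_array_equal(samples[..., 5:], trials[..., 5:])
        assert list(out) == ["a"] * 5 + ["b"] * 5

    def test_k_equals_class_size_gives_class_mean(self, rng):
        trials = rng.normal(size=(2, 3, 8))
        labels = np.repeat(["a", "b"], 4)
        samples, out = make_mini_erps(trials, labels, k=4, n_samples=6, seed=1)
        for cls, block in (("a", samples[..., :6]), ("b", samples[..., 6:])):
            mean = trials[..., labels == cls].mean(axis=-1, keepdims=True)
            np.testing.assert_allclose(block, np.broadcast_to(mean, block.shape),
                                       atol=1e-12)

    def test_snr_gain_is_sqrt_k(self, rng):
        # i.i.d. unit-variance noise: averaging k=9 trials cuts the noise SD
        # three-fold
        trials = rng.standard_normal((1, 1, 5000))
        labels = np.zeros(5000, dtype=int)
        samples, _ = make_mini_erps(trials, labels, k=9, n_samples=5000, seed=2)
        ratio = trials.std() / samples.std()
        assert ratio == pytest.approx(3.0, rel=0.05)

    def test_class_smaller_than_k_rejected(self, rng):
        trials = rng.normal(size=(2, 5))
        labels = np.array(["a", "a", "a", "b", "b"])
        with pytest.raises(ValueError, match="fewer than k"):
            make_mini_erps(trials, labels, k=3, n_samples=4, seed=0)

    def test_reproducible(self, rng):
        trials = rng.normal(size=(2, 2, 20))
        labels = np.repeat([0, 1], 10)
        a, _ = make_mini_erps(trials, labels, k=3, n_samples=7, seed=5)
        b, _ = make_mini_erps(trials, labels, k=3, n_samples=7, seed=5)
        np.testing.assert_array_equal(a, b)


def _signal_study(amp, n_subjects=1, n_trials=40, seed=0, decimate=24):
    cfg = EEGSimConfig(
        n_subjects=n_subjects, n_trials_per_cell=n_trials,
        conditions=("retinal",), retinal_amp_uv=amp, decimate=decimate,
        noise_white_sd_uv=4.0, noise_pink_sd_uv=4.0, seed=seed,
    )
    return cfg, simulate_eeg_study(cfg)


class TestDecoding:
    def test_separable_signal_reaches_ceiling_inside_component(self):
        cfg, study = _signal_study(amp=60.0, n_trials=50)
        res = decode_timecourse(study, "retinal", k=5, n_samples=100,
                                folds=5, seed=1)
        window = (res.times >= 46) & (res.times <= 98)
        assert res.accuracy[window].max() >= 0.95
        assert (res.accuracy >= 0).all() and (res.accuracy <= 1).all()

    def test_side_relabel_leaves_accuracy_unchanged(self, rng):
        # the classifier stage is exactly label-symmetric: swapping the two
        # class labels of fixed samples cannot change the accuracy
        from flashgrab.eeg import _fit_predict_time

        train_x = rng.normal(size=(60, 8))
        test_x = rng.normal(size=(20, 8))
        train_y = np.repeat(["left", "right"], 30)
        test_y = np.repeat(["left", "right"], 10)
        swap = {"left": "right", "right": "left"}
        a1 = _fit_predict_time(train_x, train_y, test_x, test_y, 1.0)
        a2 = _fit_predict_time(
            train_x, np.vectorize(swap.get)(train_y),
            test_x, np.vectorize(swap.get)(test_y), 1.0,
        )
        assert a1 == pytest.approx(a2)

    def test_k1_matches_plain_trial_cv(self):
        # with k = 1 and exhaustive sampling the mini-ERP machinery reduces
        # to ordinary trial-level cross-validation up to resampling noise
        from sklearn.model_selection import StratifiedKFold

        cfg, study = _signal_study(amp=25.0, n_trials=40, decimate=120)
        res = decode_timecourse(study, "retinal", k=1, n_samples=500,
                                folds=4, seed=3)
        subj = study.subjects[0]
        keep = [i for i, c in enumerate(subj.channel_names)
                if c not in ("VEO", "HEO")]
        mask = subj.condition == "retinal"
        data = subj.data[keep][:, :, mask].astype(float)
        y = subj.side[mask].astype(str)
        from flashgrab.eeg import _fit_predict_time

        accs = []
        for ti in range(data.shape[1]):
            skf = StratifiedKFold(4, shuffle=True, random_state=0)
            fold = [
                _fit_predict_time(data[:, ti, tr].T, y[tr],
                                  data[:, ti, te].T, y[te], 1.0)
                for tr, te in skf.split(y, y)
            ]
            accs.append(np.mean(fold))
        np.testing.assert_allclose(res.accuracy, accs, atol=0.1)

    def test_cross_decode_mirrored_signal_below_chance(self):
        cfg = EEGSimConfig(
            n_subjects=1, n_trials_per_cell=40, conditions=("retinal",),
            retinal_amp_uv=40.0, decimate=24, noise_white_sd_uv=4.0,
            noise_pink_sd_uv=0.0, seed=2,
        )
        study = simulate_eeg_study(cfg)
        subj = study.subjects[0]
        mirrored = subj.pick_trials(np.ones(subj.n_trials, dtype=bool))
        mirrored.condition = np.array(["mirrored"] * subj.n_trials, dtype=object)
        mirrored.side = np.where(mirrored.side == "left", "right", "left")
        merged = SubjectEpochs(
            data=np.concatenate([subj.data, mirrored.data], axis=2),
            times=subj.times, srate=subj.srate,
            channel_names=list(subj.channel_names),
            condition=np.concatenate([subj.condition, mirrored.condition]),
            side=np.concatenate([subj.side, mirrored.side]),
        )
        study2 = EEGStudy([merged], study.illusion_sizes[:1])
        mat = cross_decode(study2, "retinal", "mirrored", decimate=2, seed=0)
        grid = mat.time_grid
        win = (grid >= 46) & (grid <= 98)
        block = mat.accuracy[np.ix_(win, win)]
        assert np.diag(block).mean() < 0.3

    def test_cross_decode_within_condition_uses_folds(self):
        cfg, study = _signal_study(amp=40.0, n_trials=40, decimate=24)
        mat = cross_decode(study, "retinal", "retinal", decimate=1,
                           folds=4, seed=0)
        grid = mat.time_grid
        win = (grid >= 46) & (grid <= 98)
        pre = grid < 0
        assert np.diag(mat.accuracy)[win].max() > 0.9
        assert abs(np.diag(mat.accuracy)[pre].mean() - 0.5) < 0.15


class TestWindowAndCorrelation:
    def test_window_mean_constant_and_ramp(self):
        t = np.arange(0.0, 100.0)
        const = DiffWave(np.full(100, 2.5), t, ())
        assert window_mean_amplitude(const, 10, 50) == pytest.approx(2.5)
        ramp = DiffWave(t.copy(), t, ())
        assert window_mean_amplitude(ramp, 20, 40) == pytest.approx(30.0)
        with pytest.raises(ValueError, match="no samples"):
            window_mean_amplitude(const, 200, 300)

    def test_perfect_correlation(self):
        sizes = np.array([1.0, 3.0, 2.0, 5.0])
        amp = np.tile(sizes[:, None], (1, 7))
        np.testing.assert_allclose(intersubject_correlation(amp, sizes), 1.0)
        np.testing.assert_allclose(intersubject_correlation(-amp, sizes), -1.0)

    def test_zero_variance_sizes_flagged(self):
        amp = np.random.default_rng(0).normal(size=(4, 5))
        with pytest.warns(UserWarning, match="zero variance"):
            r = intersubject_correlation(amp, np.ones(4))
        assert np.isnan(r).all()

    def test_correlation_emerges_after_late_onset(self):
        # end-to-end: late-component gain couples amplitude to illusion size
        cfg = EEGSimConfig(
            n_subjects=10, n_trials_per_cell=150,
            conditions=("background", "illusory"), decimate=12,
            noise_white_sd_uv=2.0, noise_pink_sd_uv=2.0, seed=11,
        )
        study = simulate_eeg_study(cfg)
        ill = lateralized_differences(study, "illusory")
        bg = lateralized_differences(study, "background")
        r = intersubject_correlation(ill - bg, study.illusion_sizes)
        times = study.times
        late = (times >= 230) & (times <= 340)
        pre = times < 100
        assert r[late].mean() > 0.6
        assert abs(r[pre].mean()) < 0.35
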