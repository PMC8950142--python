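"""Preprocessing: filtering, epoching, baseline, rejection, selection, scaling."""

import numpy as np
import pytest
from scipy import signal as sp_signal

from erpdecode.montage import make_montage
from erpdecode.preprocess import (
    EpochSet,
    PreprocessConfig,
    bandpass_filter,
    baseline_correct,
    design_fir,
    extract_epochs,
    normalize,
    preprocess,
    reject_artifacts,
    select_channels,
)
from erpdecode.simulate import (
    ContinuousRecording,
    StimulusClass,
    SubjectProfile,
    generate_subject,
    stimulus_classes,
)
from erpdecode.training import trough_latency

FS = 250.0
CLS = StimulusClass("emotion_view", "fear/upright")


def _recording(data, events=(), fs=FS):
    mont = make_montage(64)
    if data.shape[0] != 64:
        full = np.zeros((64, data.shape[1]))
        full[: data.shape[0]] = data
        data = full
    return ContinuousRecording(SubjectProfile("t"), mont, data, fs,
                               [(s, CLS) for s in events])


class TestBandpass:
    def test_passband_sinusoid_preserved_within_5_percent(self):
        t = np.arange(10000) / FS
        x = np.sin(2 * np.pi * 10 * t)[None, :]
        out = bandpass_filter(_recording(x), PreprocessConfig()).data[0]
        mid = slice(3000, 7000)  # away from edges
        assert np.abs(out[mid]).max() == pytest.approx(1.0, rel=0.05)

    def test_stopband_1hz_attenuated_20db(self):
        # oracle: the designed filter's squared response (forward-backward)
        cfg = PreprocessConfig()
        taps = design_fir(cfg, FS)
        w, h = sp_signal.freqz(taps, worN=[1.0], fs=FS)
        atten_db = -20 * np.log10(np.abs(h[0]) ** 2)
        assert atten_db >= 20
        t = np.arange(20000) / FS
        x = np.sin(2 * np.pi * 1.0 * t)[None, :]
        out = bandpass_filter(_recording(x), PreprocessConfig()).data[0]
        assert np.abs(out[5000:15000]).max() < 0.1

    def test_dc_removed(self):
        x = np.full((1, 8000), 3.7)
        out = bandpass_filter(_recording(x), PreprocessConfig()).data[0]
        assert np.abs(out[2000:6000]).max() < 1e-3

    def test_invalid_band_edges_raise(self):
        with pytest.raises(ValueError):
            bandpass_filter(_recording(np.zeros((1, 1000))),
                            PreprocessConfig(band_low_hz=50, band_high_hz=40))
        with pytest.raises(ValueError):
            bandpass_filter(_recording(np.zeros((1, 1000))),
                            PreprocessConfig(band_high_hz=130))

    def test_zero_phase_preserves_n170_latency(self):
        """Filtering a noiseless evoked recording shifts the trough <= 1 sample."""
        prof = SubjectProfile("s", noise_scale_uv=0, artifact_rate=0)
        rec = generate_subject(prof, "emotion_view", 8, seed=0)
        cfg = PreprocessConfig()
        oz = list(rec.montage.channel_names).index("Oz")
        filt = bandpass_filter(rec, cfg)
        ep_raw = extract_epochs(rec, cfg)
        ep_fil = extract_epochs(filt, cfg)
        for k in range(4):
            lat_raw = trough_latency(ep_raw.data[k, oz], ep_raw.time_axis)
            lat_fil = trough_latency(ep_fil.data[k, oz], ep_fil.time_axis)
            assert abs(lat_fil - lat_raw) <= 1.0 / FS + 1e-9


class TestExtractEpochs:
    def test_250_samples_per_epoch(self):
        rec = _recording(np.zeros((2, 2000)), events=[1000])
        ep = extract_epochs(rec, PreprocessConfig())
        assert ep.data.shape[2] == 250
        assert len(ep.time_axis) == 250

    def test_window_spans_samples_950_to_1199(self):
        data = np.tile(np.arange(2000, dtype=float), (64, 1))
        rec = _recording(data, events=[1000])
        ep = extract_epochs(rec, PreprocessConfig())
        np.testing.assert_array_equal(ep.data[0, 0], np.arange(950, 1200))

    def test_underflow_event_skipped(self):
        rec = _recording(np.zeros((2, 2000)), events=[10, 1000])
        ep = extract_epochs(rec, PreprocessConfig())
        assert ep.n_trials == 1

    def test_no_events_empty_epochset(self):
        ep = extract_epochs(_recording(np.zeros((2, 1000))),
                            PreprocessConfig())
        assert ep.n_trials == 0
        assert ep.data.shape[2] == 250


class TestBaseline:
    def _epochs(self, data):
        t = (np.arange(data.shape[2]) - 50) / FS
        return EpochSet(data=data, labels=[CLS] * data.shape[0],
                        time_axis=t, channel_names=tuple(
                            f"C{i}" for i in range(data.shape[1])),
                        subject_id="t", fs=FS)

    def test_constant_epoch_maps_to_zero(self):
        ep = self._epochs(np.full((2, 3, 250), 4.2))
        np.testing.assert_allclose(baseline_correct(ep).data, 0.0, atol=1e-12)

    def test_prestimulus_mean_is_zero(self):
        rng = np.random.default_rng(0)
        ep = self._epochs(rng.standard_normal((5, 3, 250)))
        out = baseline_correct(ep)
        pre = out.time_axis < 0
        np.testing.assert_allclose(out.data[:, :, pre].mean(axis=-1), 0.0,
                                   atol=1e-9)

    def test_constant_offset_invariance(self):
        rng = np.random.default_rng(1)
        base = rng.standard_normal((4, 2, 250))
        a = baseline_correct(self._epochs(base)).data
        b = baseline_correct(self._epochs(base + 17.3)).data
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_no_prestimulus_raises(self):
        ep = self._epochs(np.zeros((1, 2, 250)))
        ep.time_axis = np.arange(250) / FS
        with pytest.raises(ValueError):
            baseline_correct(ep)


class TestRejection:
    def _epochs(self, data):
        t = (np.arange(data.shape[2]) - 50) / FS
        return EpochSet(data=data, labels=[CLS] * data.shape[0], time_axis=t,
                        channel_names=tuple(f"C{i}"
                                            for i in range(data.shape[1])),
                        subject_id="t", fs=FS)

    def test_constructed_outliers_rejected_in_order(self):
        rng = np.random.default_rng(2)
        data = rng.uniform(-20, 20, size=(10, 3, 250))
        for i in (1, 4, 7):
            data[i, rng.integers(0, 3), 100] = 300.0
        out, report = reject_artifacts(self._epochs(data), PreprocessConfig())
        assert report.n_rejected == 3
        assert report.rejected_indices == [1, 4, 7]
        assert out.n_trials == 7
        np.testing.assert_array_equal(out.data[0], data[0])

    def test_all_quiet_trials_survive(self):
        data = np.random.default_rng(3).uniform(-70, 70, size=(6, 2, 100))
        out, report = reject_artifacts(self._epochs(data), PreprocessConfig())
        assert report.n_rejected == 0
        assert out.n_trials == 6

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(4)
        data = rng.uniform(-90, 90, size=(40, 5, 120))
        out, report = reject_artifacts(self._epochs(data), PreprocessConfig())
        # independent per-trial loop
        expected = []
        for i in range(40):
            worst = 0.0
            for c in range(5):
                worst = max(worst, data[i, c].max() - data[i, c].min())
            if worst > 150.0:
                expected.append(i)
        assert report.rejected_indices == expected

    def test_rejection_after_normalization_refused(self):
        ep = self._epochs(np.ones((2, 2, 100)))
        ep.normalized = True
        with pytest.raises(ValueError):
            reject_artifacts(ep, PreprocessConfig())


class TestChannelSelection:
    def _epochs(self, names):
        return EpochSet(data=np.zeros((2, len(names), 10)),
                        labels=[CLS, CLS], time_axis=np.arange(10) / FS,
                        channel_names=tuple(names), subject_id="t", fs=FS)

    def test_default_montage_keeps_exactly_35(self):
        mont = make_montage(64)
        ep = self._epochs(mont.channel_names)
        out = select_channels(ep, PreprocessConfig())
        assert len(out.channel_names) == 35

    def test_fz_and_frontal_lookalikes_excluded(self):
        out = select_channels(self._epochs(["Fz", "Fp1", "FC1", "FT7", "Cz"]),
                              PreprocessConfig())
        assert out.channel_names == ("Cz",)

    def test_matches_enumeration_oracle_on_pristine_montage(self):
        import re

        mont = make_montage(64)
        ep = self._epochs(mont.channel_names)
        out = select_channels(ep, PreprocessConfig())
        oracle = []
        for lab in mont.channel_names:
            m = re.match(r"^([A-Za-z]+?)(?:z|\d+)$", lab)
            lp = m.group(1) if m else lab
            if any(lp.startswith(p)
                   for p in ("O", "PO", "P", "TP", "T", "CP", "C")):
                oracle.append(lab)
        assert list(out.channel_names) == oracle

    def test_bad_channels_removed_first(self):
        mont = make_montage(64)
        ep = self._epochs(mont.channel_names)
        out = select_channels(ep, PreprocessConfig(), bad_channels=("Oz", "P3"))
        assert len(out.channel_names) == 33
        assert "Oz" not in out.channel_names

    def test_empty_prefixes_and_empty_result_raise(self):
        ep = self._epochs(["Oz", "Pz"])
        with pytest.raises(ValueError):
            select_channels(ep, PreprocessConfig(channel_prefixes=()))
        ep2 = self._epochs(["Fz", "AFz"])
        with pytest.raises(ValueError):
            select_channels(ep2, PreprocessConfig())


class TestNormalize:
    def _epochs(self, data):
        return EpochSet(data=data, labels=[CLS] * data.shape[0],
                        time_axis=np.arange(data.shape[2]) / FS,
                        channel_names=tuple(f"C{i}"
                                            for i in range(data.shape[1])),
                        subject_id="t", fs=FS)

    def test_max_abs_is_exactly_one(self):
        rng = np.random.default_rng(5)
        out = normalize(self._epochs(rng.standard_normal((6, 3, 50)) * 40))
        for trial in out.data:
            assert np.abs(trial).max() == pytest.approx(1.0, abs=0)
        assert out.normalized

    def test_all_zero_trial_stays_zero(self):
        data = np.zeros((2, 2, 30))
        data[1, 0, 3] = 5.0
        out = normalize(self._epochs(data))
        np.testing.assert_allclose(out.data[0], 0.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(6)
        base = rng.standard_normal((3, 2, 40))
        a = normalize(self._epochs(base)).data
        b = normalize(self._epochs(2.0 * base)).data
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_double_normalization_refused(self):
        ep = normalize(self._epochs(np.ones((1, 1, 10))))
        with pytest.raises(ValueError):
            normalize(ep)


class TestFullPipeline:
    def test_clean_subject_yields_35x250_and_zero_rejections(self):
        prof = SubjectProfile("s", artifact_rate=0)
        rec = generate_subject(prof, "emotion_view", 16, seed=0)
        ep, report = preprocess(rec)
        assert report.n_rejected == 0
        assert ep.data.shape == (16, 35, 250)
        assert ep.data.min() >= -1.0 and ep.data.max() <= 1.0

    def test_saturated_recording_raises_zero_trials(self):
        prof = SubjectProfile("s", noise_scale_uv=400.0, artifact_rate=0)
        rec = generate_subject(prof, "emotion_view", 8, seed=0)
        with pytest.raises(ValueError, match="[Zz]ero trials"):
            preprocess(rec)

    def test_pipeline_is_deterministic(self):
        prof = SubjectProfile("s")
        rec = generate_subject(prof, "familiarity_view", 8, seed=4)
        a, ra = preprocess(rec)
        b, rb = preprocess(rec)
        np.testing.assert_array_equal(a.data, b.data)
        assert ra.rejected_indices == rb.rejected_indices

    def test_shape_conservation_through_stages(self):
        prof = SubjectProfile("s")
        rec = generate_subject(prof, "emotion_view", 12, seed=2)
        ep, report = preprocess(rec)
        assert ep.n_trials <= 12
        assert ep.n_trials == 12 - report.n_rejected
        assert ep.data.shape[1] == 35
        assert ep.data.shape[2] == 250


def test_epochs_roundtrip_hdf5(tmp_path):
    from erpdecode.preprocess import load_epochs, save_epochs

    prof = SubjectProfile("s", artifact_rate=0)
    rec = generate_subject(prof, "emotion_view", 8, seed=1)
    ep, _ = preprocess(rec)
    save_epochs(ep, tmp_path / "e.h5")
    back = load_epochs(tmp_path / "e.h5")
    np.testing.assert_array_equal(back.data, ep.data)
    assert back.labels == ep.labels
    assert back.channel_names == ep.channel_names
    assert back.normalized


def test_recording_roundtrip_fif(tmp_path):
    from erpdecode.simulate import load_recording, save_recording

    prof = SubjectProfile("s7", artifact_rate=0)
    rec = generate_subject(prof, "familiarity_view", 8, seed=2)
    save_recording(rec, tmp_path)
    back = load_recording(tmp_path, "s7")
    np.testing.assert_allclose(back.data, rec.data, atol=1e-6)
    assert [e[0] for e in back.events] == [e[0] for e in rec.events]
    assert back.events[3][1] == rec.events[3][1]
    assert back.subject.group == rec.subject.group
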