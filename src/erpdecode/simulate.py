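"""Synthetic face-perception EEG cohorts.

Generates continuous 64-channel recordings at 250 Hz whose stimulus-locked
structure mimics a face-perception ERP study with two 4-class paradigms
(emotion x view and familiarity x view):

* an N170 deflection whose latency is delayed ~10 ms for inverted faces
  (the face-inversion effect),
* an N250 deflection more negative for famous (familiar) faces,
* a sustained negative shift in the 310-1000 ms window for fearful faces,
* 1/f ("pink") background noise and occasional high-amplitude artifacts,
* an AD-like subject with attenuated, delayed components.

Component waveforms are Gaussian-windowed deflections (the paper-level
literature gives component timings, not shapes); amplitudes are weighted
over the scalp by region (posterior/temporal 1.0, central 0.5, frontal 0.1).
All generation is a pure function of (configuration, seed).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict, replace

import numpy as np

from .montage import ChannelMontage, STANDARD_64, make_montage, spatial_weight

EXPERIMENTS = ("emotion_view", "familiarity_view")

_CATEGORIES = {
    "emotion_view": (
        "fear/upright", "fear/upside-down", "neutral/upright", "neutral/upside-down",
    ),
    "familiarity_view": (
        "famous/upright", "famous/upside-down", "unfamous/upright",
        "unfamous/upside-down",
    ),
}


@dataclass(frozen=True)
class StimulusClass:
    """One of the four stimulus categories of an experiment."""

    experiment: str
    category: str

    def __post_init__(self):
        if self.experiment not in EXPERIMENTS:
            raise ValueError(f"unknown experiment: {self.experiment!r}")
        if self.category not in _CATEGORIES[self.experiment]:
            raise ValueError(
                f"unknown category {self.category!r} for {self.experiment}"
            )

    @property
    def view(self) -> str:
        return "inverted" if self.category.endswith("upside-down") else "upright"

    @property
    def attribute(self) -> str:
        """The non-view factor: fear/neutral or famous/unfamous."""
        return self.category.split("/")[0]

    @property
    def index(self) -> int:
        return _CATEGORIES[self.experiment].index(self.category)


def stimulus_classes(experiment: str):
    """The four categories of an experiment, in canonical label order."""
    if experiment not in EXPERIMENTS:
        raise ValueError(f"unknown experiment: {experiment!r}")
    return tuple(StimulusClass(experiment, c) for c in _CATEGORIES[experiment])


@dataclass
class SubjectProfile:
    """ERP morphology and noise parameters of one simulated subject.

    Amplitudes are in microvolts (negative = downward deflection), latencies
    in milliseconds post-stimulus.  ``component_attenuation`` scales every
    evoked component; the AD profile uses a value below 1 together with a
    longer inversion delay and a higher artifact rate.
    """

    subject_id: str
    group: str = "control"  # control | control_oldest | ad
    n170_latency_ms: float = 170.0
    inversion_delay_ms: float = 10.0
    n170_amplitude_uv: float = -8.0
    n170_width_ms: float = 18.0
    n250_latency_ms: float = 250.0
    n250_amplitude_uv: float = -4.0
    n250_familiarity_delta_uv: float = -2.0
    n250_width_ms: float = 25.0
    emotion_window_ms: tuple = (310.0, 1000.0)
    emotion_delta_uv: float = -1.5
    noise_scale_uv: float = 6.0
    artifact_rate: float = 0.02
    component_attenuation: float = 1.0
    #: steady posterior drive while the 300-ms stimulus is on screen
    stimulus_drive_uv: float = 1.0

    def __post_init__(self):
        if not 0.0 <= self.artifact_rate < 1.0:
            raise ValueError("artifact_rate must be in [0, 1)")
        if self.n170_latency_ms <= 0 or self.n250_latency_ms <= 0:
            raise ValueError("component latencies must be positive")
        lo, hi = self.emotion_window_ms
        if not 0 < lo < hi:
            raise ValueError("emotion window must satisfy 0 < start < end")
        if not 0.0 < self.component_attenuation <= 1.0:
            raise ValueError("component_attenuation must be in (0, 1]")


@dataclass
class ContinuousRecording:
    """A per-subject multichannel recording with stimulus-event annotations."""

    subject: SubjectProfile
    montage: ChannelMontage
    data: np.ndarray  # (channels, samples), microvolts
    fs: float
    events: list  # [(sample_index, StimulusClass), ...] strictly increasing

    def __post_init__(self):
        if self.data.shape[0] != len(self.montage):
            raise ValueError("data row count must equal montage size")
        idx = [s for s, _ in self.events]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("event sample indices must be strictly increasing")
        if idx and (idx[0] < 0 or idx[-1] >= self.data.shape[1]):
            raise ValueError("event sample index outside recording")


def _gauss(t, center_s, width_s):
    return np.exp(-0.5 * ((t - center_s) / width_s) ** 2)


def _plateau(t, start_s, end_s, ramp_s=0.02):
    """Raised plateau with smooth cosine ramps, 1 inside [start, end]."""
    y = np.zeros_like(t)
    rise = (t >= start_s - ramp_s) & (t < start_s + ramp_s)
    y[rise] = 0.5 * (1 + np.sin(np.pi * (t[rise] - start_s) / (2 * ramp_s)))
    y[(t >= start_s + ramp_s) & (t <= end_s - ramp_s)] = 1.0
    fall = (t > end_s - ramp_s) & (t <= end_s + ramp_s)
    y[fall] = 0.5 * (1 - np.sin(np.pi * (t[fall] - end_s) / (2 * ramp_s)))
    return y


STIM_DURATION_S = 0.3


def erp_template(cls: StimulusClass, profile: SubjectProfile, channel: str,
                 time_axis: np.ndarray) -> np.ndarray:
    """Noise-free evoked waveform for one class at one electrode (microvolts).

    The waveform is the sum of an N170 deflection (latency shifted by the
    inversion delay for inverted views), an N250 deflection (more negative by
    the familiarity delta for famous faces), and a sustained emotion-window
    shift for fearful faces, all scaled by the subject's attenuation factor
    and the electrode's region weight.
    """
    if channel not in STANDARD_64:
        raise ValueError(f"unknown channel: {channel!r}")
    t = np.asarray(time_axis, dtype=float)
    w = spatial_weight(channel)
    a = profile.component_attenuation

    n170_lat = profile.n170_latency_ms
    if cls.view == "inverted":
        n170_lat += profile.inversion_delay_ms
    y = profile.n170_amplitude_uv * _gauss(t, n170_lat / 1e3,
                                           profile.n170_width_ms / 1e3)

    n250_amp = profile.n250_amplitude_uv
    if cls.attribute == "famous":
        n250_amp += profile.n250_familiarity_delta_uv
    y = y + n250_amp * _gauss(t, profile.n250_latency_ms / 1e3,
                              profile.n250_width_ms / 1e3)

    if cls.attribute == "fear":
        lo, hi = profile.emotion_window_ms
        y = y + profile.emotion_delta_uv * _plateau(t, lo / 1e3, hi / 1e3)

    # small steady posterior drive while the stimulus is on screen
    y = y + profile.stimulus_drive_uv * _plateau(t, 0.0, STIM_DURATION_S,
                                                 ramp_s=0.01)

    return a * w * y


def pink_noise(rng: np.random.Generator, n_samples: int, n_channels: int = 1,
               exponent: float = 1.0) -> np.ndarray:
    """1/f^exponent power-law noise, unit RMS per channel."""
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_samples)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = freqs[nz] ** (-exponent / 2.0)
    scale[0] = 0.0  # no DC
    shaped = np.fft.irfft(spec * scale, n=n_samples, axis=-1)
    rms = shaped.std(axis=-1, keepdims=True)
    rms[rms == 0] = 1.0
    return shaped / rms


def _artifact_burst(rng, t, fs):
    """A high-amplitude smooth transient exceeding 150 uV peak-to-peak."""
    center = rng.uniform(t[0] + 0.05, t[-1] - 0.05)
    width = rng.uniform(0.03, 0.08)
    amp = rng.uniform(200.0, 400.0) * rng.choice([-1.0, 1.0])
    return amp * _gauss(t, center, width)


def default_time_axis(fs: float = 250.0, tmin: float = -0.2, tmax: float = 0.8):
    n = int(round((tmax - tmin) * fs))
    return (np.arange(n) + round(tmin * fs)) / fs


def simulate_trial(cls: StimulusClass, profile: SubjectProfile,
                   montage: ChannelMontage, rng: np.random.Generator,
                   time_axis: np.ndarray | None = None) -> np.ndarray:
    """One stimulus-locked epoch: template + pink noise (+ rare artifact)."""
    t = default_time_axis() if time_axis is None else np.asarray(time_axis)
    chans = montage.channel_names
    epoch = np.empty((len(chans), len(t)))
    for i, ch in enumerate(chans):
        epoch[i] = erp_template(cls, profile, ch, t)
    if profile.noise_scale_uv > 0:
        epoch += profile.noise_scale_uv * pink_noise(rng, len(t), len(chans))
    if profile.artifact_rate > 0 and rng.random() < profile.artifact_rate:
        ch = rng.integers(0, len(chans))
        epoch[ch] += _artifact_burst(rng, t, 250.0)
    return epoch


#: seconds between consecutive stimulus onsets (300 ms stimulus + 1 s pause
#: + response interval); comfortably larger than the 1-s epoch span
ISI_S = 1.5
_LEAD_IN_S = 2.0


def generate_subject(profile: SubjectProfile, experiment: str, n_trials: int,
                     seed, montage: ChannelMontage | None = None,
                     fs: float = 250.0) -> ContinuousRecording:
    """A continuous recording with balanced, shuffled 4-class events.

    Epoch-long evoked responses are placed on a continuous pink-noise
    carrier at fixed inter-stimulus spacing; event order is shuffled and
    class counts differ by at most one when ``n_trials`` is not divisible
    by four.
    """
    if montage is None:
        montage = make_montage()
    classes = stimulus_classes(experiment)
    if n_trials % 4:
        warnings.warn(
            f"n_trials={n_trials} not divisible by 4; classes balanced to +/-1",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    labels = [classes[i % 4] for i in range(n_trials)]
    rng.shuffle(labels)

    n_samples = int(round((_LEAD_IN_S + ISI_S * n_trials + 1.0) * fs))
    n_ch = len(montage)
    data = profile.noise_scale_uv * pink_noise(rng, n_samples, n_ch)

    t_epoch = np.arange(int(round(1.0 * fs))) / fs  # response 0..1 s
    templates = {}
    for cls in classes:
        tpl = np.empty((n_ch, len(t_epoch)))
        for i, ch in enumerate(montage.channel_names):
            tpl[i] = erp_template(cls, profile, ch, t_epoch)
        templates[cls] = tpl

    events = []
    for k, cls in enumerate(labels):
        onset = int(round((_LEAD_IN_S + ISI_S * k) * fs))
        sl = slice(onset, onset + len(t_epoch))
        data[:, sl] += templates[cls]
        if profile.artifact_rate > 0 and rng.random() < profile.artifact_rate:
            ch = rng.integers(0, n_ch)
            data[ch, sl] += _artifact_burst(rng, t_epoch, fs)
        events.append((onset, cls))
    return ContinuousRecording(subject=profile, montage=montage, data=data,
                               fs=fs, events=events)


@dataclass
class CohortConfig:
    """Study-level generation settings (defaults emulate the source cohort)."""

    experiment: str = "emotion_view"
    n_controls: int = 8           # one of them flagged control_oldest
    n_ad: int = 1
    n_trials: int = 576
    noise_scale_uv: float = 6.0
    artifact_rate: float = 0.02
    inversion_delay_ms: float = 10.0
    ad_component_attenuation: float = 0.6
    ad_inversion_delay_ms: float = 14.0
    ad_artifact_rate: float = 0.08


def cohort_profiles(config: CohortConfig):
    """Deterministic list of subject profiles for a cohort configuration."""
    profiles = []
    for i in range(config.n_controls):
        group = "control_oldest" if i == config.n_controls - 1 else "control"
        profiles.append(SubjectProfile(
            subject_id=f"ctl{i + 1:02d}", group=group,
            noise_scale_uv=config.noise_scale_uv,
            artifact_rate=config.artifact_rate,
            inversion_delay_ms=config.inversion_delay_ms,
        ))
    for j in range(config.n_ad):
        profiles.append(SubjectProfile(
            subject_id=f"ad{j + 1:02d}", group="ad",
            noise_scale_uv=config.noise_scale_uv,
            artifact_rate=config.ad_artifact_rate,
            inversion_delay_ms=config.ad_inversion_delay_ms,
            component_attenuation=config.ad_component_attenuation,
        ))
    return profiles


def generate_cohort(config: CohortConfig, seed) -> list:
    """Recordings for every subject; per-subject seeds spawn from the master."""
    profiles = cohort_profiles(config)
    montage = make_montage() if profiles else None
    children = np.random.SeedSequence(seed).spawn(len(profiles))
    return [
        generate_subject(p, config.experiment, config.n_trials, s, montage)
        for p, s in zip(profiles, children)
    ]


# ---------------------------------------------------------------------------
# on-disk form: FIF recording + TSV events sidecar + JSON manifest
# ---------------------------------------------------------------------------

def save_recording(rec: ContinuousRecording, out_dir):
    """Write ``<id>_raw.fif`` (volts), ``<id>_events.tsv`` and a profile JSON."""
    import mne
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sid = rec.subject.subject_id
    info = mne.create_info(list(rec.montage.channel_names), rec.fs, ch_types="eeg")
    raw = mne.io.RawArray(rec.data * 1e-6, info, verbose="error")
    raw.save(out / f"{sid}_raw.fif", overwrite=True, verbose="error")
    with open(out / f"{sid}_events.tsv", "w") as f:
        f.write("onset_sample\tonset_s\tlabel\n")
        for s, cls in rec.events:
            f.write(f"{s}\t{s / rec.fs:.6f}\t{cls.category}\n")
    meta = asdict(rec.subject)
    meta["experiment"] = rec.events[0][1].experiment if rec.events else None
    meta["bad_channels"] = list(rec.montage.bad_channels)
    with open(out / f"{sid}_profile.json", "w") as f:
        json.dump(meta, f, indent=1)


def load_recording(out_dir, subject_id) -> ContinuousRecording:
    import mne
    from pathlib import Path

    out = Path(out_dir)
    with open(out / f"{subject_id}_profile.json") as f:
        meta = json.load(f)
    experiment = meta.pop("experiment")
    bads = meta.pop("bad_channels")
    meta["emotion_window_ms"] = tuple(meta["emotion_window_ms"])
    profile = SubjectProfile(**meta)
    raw = mne.io.read_raw_fif(out / f"{subject_id}_raw.fif", preload=True,
                              verbose="error")
    data = raw.get_data() * 1e6
    montage = ChannelMontage(tuple(raw.ch_names),
                             make_montage().positions, tuple(bads))
    events = []
    with open(out / f"{subject_id}_events.tsv") as f:
        next(f)
        for line in f:
            s, _, cat = line.rstrip("\n").split("\t")
            events.append((int(s), StimulusClass(experiment, cat)))
    return ContinuousRecording(profile, montage, data, raw.info["sfreq"], events)


def save_cohort(recordings, out_dir, master_seed=None):
    """Write every recording plus a cohort manifest JSON; returns manifest."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"master_seed": master_seed, "subjects": []}
    for rec in recordings:
        save_recording(rec, out)
        manifest["subjects"].append({
            "subject_id": rec.subject.subject_id,
            "group": rec.subject.group,
            "n_events": len(rec.events),
        })
    with open(out / "cohort.json", "w") as f:
        json.dump(manifest, f, indent=1)
    return manifest
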