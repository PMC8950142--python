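"""Continuous EEG -> normalized, artifact-free, channel-selected epochs.

Pipeline order: zero-phase FIR band-pass (4-40 Hz) -> epoching (-200..+800 ms)
-> prestimulus baseline correction -> peak-to-peak artifact rejection
(150 uV) -> region-prefix channel selection -> per-trial [-1, 1] scaling.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .montage import match_prefix
from .simulate import ContinuousRecording, StimulusClass

logger = logging.getLogger(__name__)


@dataclass
class PreprocessConfig:
    band_low_hz: float = 4.0
    band_high_hz: float = 40.0
    tmin_s: float = -0.2
    tmax_s: float = 0.8
    reject_uv: float = 150.0
    channel_prefixes: tuple = ("O", "PO", "P", "TP", "T", "CP", "C")
    #: FIR transition bandwidth; sets the filter order (Hamming window design)
    transition_hz: float = 2.0

    def validate(self, fs: float):
        if not 0 < self.band_low_hz < self.band_high_hz < fs / 2:
            raise ValueError(
                f"band edges must satisfy 0 < low < high < fs/2, got "
                f"({self.band_low_hz}, {self.band_high_hz}) at fs={fs}"
            )
        if not self.tmin_s < 0 < self.tmax_s:
            raise ValueError("epoch window must satisfy tmin < 0 < tmax")
        if self.reject_uv <= 0:
            raise ValueError("reject_uv must be positive")


@dataclass
class EpochSet:
    """Trials x channels x time with labels and a time axis in seconds."""

    data: np.ndarray
    labels: list  # StimulusClass per trial
    time_axis: np.ndarray
    channel_names: tuple
    subject_id: str
    fs: float
    normalized: bool = False

    def __post_init__(self):
        if self.data.ndim != 3:
            raise ValueError("epoch data must be trials x channels x time")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("labels length must equal trial count")
        if self.data.shape[1] != len(self.channel_names):
            raise ValueError("channel axis must match channel_names")
        if self.data.shape[2] != len(self.time_axis):
            raise ValueError("time axis must match data")

    @property
    def n_trials(self):
        return self.data.shape[0]

    def class_indices(self):
        return np.array([l.index for l in self.labels])


@dataclass
class RejectionReport:
    n_input: int
    n_rejected: int
    rejected_indices: list
    threshold_uv: float

    def __post_init__(self):
        if self.n_rejected != len(self.rejected_indices):
            raise ValueError("n_rejected must equal |rejected_indices|")

    @property
    def per_subject_fraction(self):
        return self.n_rejected / self.n_input if self.n_input else 0.0


def design_fir(cfg: PreprocessConfig, fs: float) -> np.ndarray:
    """Hamming-window band-pass FIR taps (odd length, ~cfg.transition_hz)."""
    numtaps = int(round(3.3 * fs / cfg.transition_hz))
    numtaps += 1 - numtaps % 2  # odd for a type-I band-pass
    return signal.firwin(numtaps, [cfg.band_low_hz, cfg.band_high_hz],
                         pass_zero=False, window="hamming", fs=fs)


def bandpass_filter(rec: ContinuousRecording,
                    cfg: PreprocessConfig) -> ContinuousRecording:
    """Zero-phase (forward-backward) FIR band-pass, per channel."""
    cfg.validate(rec.fs)
    taps = design_fir(cfg, rec.fs)
    padlen = min(3 * len(taps), rec.data.shape[1] - 1)
    filtered = signal.filtfilt(taps, [1.0], rec.data, axis=-1, padlen=padlen)
    return replace(rec, data=filtered)


def extract_epochs(rec: ContinuousRecording, cfg: PreprocessConfig) -> EpochSet:
    """One epoch per event over the half-open window [tmin, tmax) in samples.

    Events whose window would cross the recording bounds are skipped with a
    logged warning.
    """
    fs = rec.fs
    start = int(round(cfg.tmin_s * fs))
    stop = int(round(cfg.tmax_s * fs))
    n_t = stop - start
    time_axis = (np.arange(n_t) + start) / fs
    epochs, labels = [], []
    n_samples = rec.data.shape[1]
    for s, cls in rec.events:
        lo, hi = s + start, s + stop
        if lo < 0 or hi > n_samples:
            logger.warning("event at sample %d: epoch window out of bounds, "
                           "skipped", s)
            continue
        epochs.append(rec.data[:, lo:hi])
        labels.append(cls)
    data = (np.stack(epochs) if epochs
            else np.empty((0, rec.data.shape[0], n_t)))
    return EpochSet(data=data, labels=labels, time_axis=time_axis,
                    channel_names=tuple(rec.montage.channel_names),
                    subject_id=rec.subject.subject_id, fs=fs)


def baseline_correct(ep: EpochSet) -> EpochSet:
    """Subtract the prestimulus (t < 0) mean, per trial and channel."""
    pre = ep.time_axis < 0
    if not pre.any():
        raise ValueError("no prestimulus samples: baseline undefined")
    base = ep.data[:, :, pre].mean(axis=-1, keepdims=True)
    return replace(ep, data=ep.data - base)


def peak_to_peak(ep_data: np.ndarray) -> np.ndarray:
    """Per-trial maximum over channels of the peak-to-peak range."""
    return (ep_data.max(axis=-1) - ep_data.min(axis=-1)).max(axis=-1)


def reject_artifacts(ep: EpochSet, cfg: PreprocessConfig):
    """Drop trials whose any-channel peak-to-peak range exceeds the threshold."""
    if ep.normalized:
        raise ValueError("rejection threshold is in microvolts; "
                         "apply before normalization")
    pp = peak_to_peak(ep.data)
    bad = np.nonzero(pp > cfg.reject_uv)[0]
    keep = np.setdiff1d(np.arange(ep.n_trials), bad)
    report = RejectionReport(n_input=ep.n_trials, n_rejected=len(bad),
                             rejected_indices=bad.tolist(),
                             threshold_uv=cfg.reject_uv)
    out = replace(ep, data=ep.data[keep],
                  labels=[ep.labels[i] for i in keep])
    return out, report


def select_channels(ep: EpochSet, cfg: PreprocessConfig,
                    bad_channels=()) -> EpochSet:
    """Keep channels whose 10-10 letter part matches a configured region prefix.

    Bad channels are removed first; matching is longest-prefix and case
    sensitive on the letter part, so ``Fp1`` and ``FC1`` are excluded while
    ``CP5``, ``POz`` and ``C3`` are kept.  Original channel order is
    preserved.
    """
    if not cfg.channel_prefixes:
        raise ValueError("channel prefix set is empty")
    keep = [i for i, c in enumerate(ep.channel_names)
            if c not in bad_channels
            and match_prefix(c, cfg.channel_prefixes) is not None]
    if not keep:
        raise ValueError("channel selection retained zero channels")
    return replace(ep, data=ep.data[:, keep, :],
                   channel_names=tuple(ep.channel_names[i] for i in keep))


def normalize(ep: EpochSet) -> EpochSet:
    """Scale each trial by its maximum absolute value into [-1, 1]."""
    if ep.normalized:
        raise ValueError("epoch set already normalized")
    m = np.abs(ep.data).max(axis=(1, 2), keepdims=True)
    m[m == 0] = 1.0  # all-zero trials stay zero
    return replace(ep, data=ep.data / m, normalized=True)


def preprocess(rec: ContinuousRecording, cfg: PreprocessConfig | None = None):
    """Full pipeline: filter -> epochs -> baseline -> reject -> select -> scale."""
    cfg = cfg or PreprocessConfig()
    filtered = bandpass_filter(rec, cfg)
    ep = extract_epochs(filtered, cfg)
    ep = baseline_correct(ep)
    ep, report = reject_artifacts(ep, cfg)
    logger.info("subject %s: rejected %d/%d epochs", ep.subject_id,
                report.n_rejected, report.n_input)
    ep = select_channels(ep, cfg, bad_channels=rec.montage.bad_channels)
    if ep.n_trials == 0:
        raise ValueError("zero trials survived artifact rejection")
    ep = normalize(ep)
    return ep, report


# ---------------------------------------------------------------------------
# on-disk form: HDF5 array container with JSON-serialized metadata
# ---------------------------------------------------------------------------

def save_epochs(ep: EpochSet, path):
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=ep.data)
        meta = {
            "labels": [(l.experiment, l.category) for l in ep.labels],
            "time_axis": ep.time_axis.tolist(),
            "channel_names": list(ep.channel_names),
            "subject_id": ep.subject_id,
            "fs": ep.fs,
            "normalized": ep.normalized,
        }
        f.attrs["meta"] = json.dumps(meta)


def load_epochs(path) -> EpochSet:
    import h5py

    with h5py.File(path, "r") as f:
        data = f["data"][...]
        meta = json.loads(f.attrs["meta"])
    return EpochSet(
        data=data,
        labels=[StimulusClass(e, c) for e, c in meta["labels"]],
        time_axis=np.asarray(meta["time_axis"]),
        channel_names=tuple(meta["channel_names"]),
        subject_id=meta["subject_id"],
        fs=meta["fs"],
        normalized=meta["normalized"],
    )
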