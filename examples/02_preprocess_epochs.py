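"""Preprocess a simulated recording into classifier-ready epochs.

Shows the full chain: 4-40 Hz zero-phase FIR band-pass, epoching into
-200..+800 ms windows (250 samples at 250 Hz), prestimulus baseline
correction, 150-uV peak-to-peak artifact rejection, posterior/central
channel selection (35 of 64 channels), and per-trial scaling into [-1, 1].
"""

from erpdecode.preprocess import PreprocessConfig, preprocess
from erpdecode.simulate import SubjectProfile, generate_subject

profile = SubjectProfile("demo", artifact_rate=0.05)
recording = generate_subject(profile, "familiarity_view", 96, seed=7)
print(f"continuous recording: {recording.data.shape[0]} channels x "
      f"{recording.data.shape[1]} samples, {len(recording.events)} events")

epochs, report = preprocess(recording, PreprocessConfig())
print(f"epochs: {epochs.data.shape}  (trials x channels x samples)")
print(f"rejected {report.n_rejected}/{report.n_input} trials "
      f"({100 * report.per_subject_fraction:.1f}%) at "
      f"{report.threshold_uv:.0f} uV peak-to-peak")
print(f"amplitude range after scaling: [{epochs.data.min():.3f}, "
      f"{epochs.data.max():.3f}]")
print(f"kept channels ({len(epochs.channel_names)}):",
      " ".join(epochs.channel_names))
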