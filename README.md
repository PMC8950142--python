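# erpdecode

Decoding visual face stimuli from raw EEG with compact convolutional
networks — on fully synthetic, physiologically structured data.

## The problem

When a person views a face, stimulus-locked EEG (the event-related
potential, ERP) carries small but systematic signatures: the face-sensitive
**N170** component (a negative deflection near 170 ms, delayed ~10 ms when
the face is inverted — the *face-inversion effect*), the **N250** (more
negative for familiar faces), and a sustained emotion-related shift in the
310–1000 ms window for fearful expressions. A natural question for
brain–computer interfacing and for clinical neuroscience is whether a
classifier can recover, from single trials, which of four stimulus
categories (emotion × view, or familiarity × view) a subject saw — and
whether decoding degrades in a subject with Alzheimer's-type impairment,
whose evoked components are attenuated and delayed.

`erpdecode` implements that study end to end as a tested Python library:

1. **Simulation** (`erpdecode.simulate`) — multi-subject continuous
   64-channel recordings at 250 Hz with class-dependent ERP templates,
   1/f background noise, occasional high-amplitude artifacts, and an
   AD-like subject profile, so every downstream stage is testable without
   any external download.
2. **Preprocessing** (`erpdecode.preprocess`) — zero-phase 4–40 Hz FIR
   band-pass, epoching into −200..+800 ms windows (250 samples),
   prestimulus baseline correction, 150 µV peak-to-peak artifact
   rejection, posterior/central channel selection by 10-10 region prefix
   (35 of 64 channels), per-trial scaling into [−1, 1].
3. **Architectures** (`erpdecode.architectures`) — EEGNet, DeepConvNet,
   EEGNet-SSVEP, and EEGNet-SSVEP with L1+L2 output regularization, built
   on a small self-contained NumPy layer engine (`erpdecode.nn`) with
   depthwise/separable convolutions, batch norm, max-norm constraints,
   Adam and early stopping.
4. **VAE augmentation** (`erpdecode.vae`) — one convolutional variational
   autoencoder per stimulus class, trained with the reconstruction + KL
   objective; decoding latent draws yields synthetic epochs used to
   pretrain classifiers.
5. **Training & evaluation** (`erpdecode.training`) — leave-subjects-out
   design (the oldest control and the AD subject never enter training),
   trial-level two-fold cross-validation repeated five times, accuracy,
   macro one-vs-rest AUC, ROC curves, confusion matrices, and a
   cross-view vs within-view confusion split that quantifies how well the
   model learned the inversion effect.
6. **Pipeline & CLI** (`erpdecode.pipeline`, `erpdecode.cli`) — a
   validated YAML configuration, deterministic per-stage seeds, content
   hashes in a run manifest, and an `erpdecode` command with
   `simulate / preprocess / train-vae / augment / train / evaluate /
   run-study` subcommands.

## Worked example

`examples/` contains one narrative script per capability. For instance:

```bash
python examples/02_preprocess_epochs.py
```

```
continuous recording: 64 channels x 36750 samples, 96 events
epochs: (93, 35, 250)  (trials x channels x samples)
rejected 3/96 trials (3.1%) at 150 uV peak-to-peak
amplitude range after scaling: [-1.000, 1.000]
kept channels (35): T7 C5 C3 C1 Cz C2 C4 C6 T8 TP7 CP5 ...
```

93 of 96 trials survive the 150 µV rejection, each reduced to the 35
posterior/central electrodes and 250 samples spanning −200..+800 ms around
stimulus onset. `examples/01_simulate_cohort.py` prints per-class Oz N170
latencies (inverted classes lag upright ones by ~10 ms),
`examples/03_vae_augmentation.py` trains per-class generators and shows a
classifier separating their synthetic output nearly perfectly, and
`examples/04_decode_cohort.py` runs the leave-subjects-out evaluation and
prints the mean accuracy/AUC table together with the cross-view vs
within-view confusion split.

## Notes

- Full model/parameter documentation lives in `docs/methods.md`.
- Continuous recordings are written as MNE FIF files with a tab-separated
  events sidecar and a JSON cohort manifest; epoch sets are stored as HDF5
  with JSON metadata.
- The simulator is a study-structure emulator, not a biophysical forward
  model; see the methods note for what passing tests do and do not imply
  about real recordings.
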