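"""Shared fixtures.

The expensive fixtures are session-scoped and shared across test modules:
a moderate-noise 4-subject cohort (two training controls, the held-out
oldest control and an AD-like subject), its preprocessed epoch sets, a set
of per-class VAE generators with synthetic samples, and a repeated two-fold
evaluation of the regularized EEGNet-SSVEP on that cohort.  Sizes are desk
scale: 96 trials per subject, posterior channel subset, reduced filter
counts and epochs.
"""

import numpy as np
import pytest

from erpdecode.architectures import ModelSpec, build_model
from erpdecode.montage import make_montage
from erpdecode.preprocess import PreprocessConfig, preprocess
from erpdecode.simulate import CohortConfig, SubjectProfile, generate_cohort
from erpdecode.training import (
    PretrainConfig,
    TrainConfig,
    leave_subjects_out_plan,
    pool_epoch_sets,
    pretrain,
    repeated_two_fold,
)
from erpdecode.vae import VAEConfig, sample_synthetic, train_vae_per_class

#: desk-scale preprocessing: occipital/parieto-occipital/parietal channels
PP_SMALL = PreprocessConfig(channel_prefixes=("O", "PO", "P"))

#: scaled-down regularized EEGNet-SSVEP used for cohort-level evaluations
SPEC_SMALL = dict(F1=8, F2=8)


@pytest.fixture(scope="session")
def montage64():
    return make_montage(64)


@pytest.fixture(scope="session")
def cohort():
    """Moderate-noise emotion-view cohort with a clear inversion effect."""
    cfg = CohortConfig(experiment="emotion_view", n_controls=3, n_ad=1,
                       n_trials=96, noise_scale_uv=3.0)
    return cfg, generate_cohort(cfg, 42)


@pytest.fixture(scope="session")
def cohort_epochs(cohort):
    """(pooled training EpochSet, {'control','alzheimer'} test sets, groups)."""
    _, recs = cohort
    eps = [preprocess(r, PP_SMALL)[0] for r in recs]
    groups = {r.subject.subject_id: r.subject.group for r in recs}
    plan = leave_subjects_out_plan(eps, groups)
    pooled = pool_epoch_sets(
        [e for e in eps if e.subject_id in plan.training_subjects])
    tests = {}
    for e in eps:
        if groups[e.subject_id] == "control_oldest":
            tests["control"] = e
        elif groups[e.subject_id] == "ad":
            tests["alzheimer"] = e
    return pooled, tests, groups


@pytest.fixture(scope="session")
def vae_models(cohort_epochs):
    """Per-class generators trained briefly on the pooled training epochs."""
    pooled, _, _ = cohort_epochs
    cfg = VAEConfig(epochs=15, early_stopping_epochs=5)
    models, report = train_vae_per_class(pooled, cfg, seed=12)
    return models, report


@pytest.fixture(scope="session")
def synthetic_sets(vae_models):
    """150 synthetic epochs per class from the trained generators."""
    models, _ = vae_models
    return {lab: sample_synthetic(m, 150, seed=100 + i)
            for i, (lab, m) in enumerate(models.items())}


@pytest.fixture(scope="session")
def pretrained_state(cohort_epochs, synthetic_sets):
    """Weights of a scaled EEGNet-SSVEP-reg pretrained on synthetic epochs."""
    pooled, _, _ = cohort_epochs
    spec = ModelSpec.create("eegnet_ssvep_reg", C=pooled.data.shape[1],
                            T=pooled.data.shape[2], **SPEC_SMALL)
    model = build_model(spec, seed=21)
    cfg = PretrainConfig(epochs=40, learning_rate=3e-4, patience=10, seed=22)
    pretrain(model, synthetic_sets, cfg)
    return spec, model.net.get_state(), model.pretrain_metrics


@pytest.fixture(scope="session")
def familiarity_pretrain():
    """Familiarity-paradigm pretraining path: subject -> epochs -> per-class
    VAEs -> 300 synthetic samples/class -> EEGNet trained on them.

    The familiarity classes carry a transient N250 difference that survives
    the band-pass, so VAE-generated classes are cleanly separable — the
    regime where synthetic pretraining approaches perfect accuracy.
    """
    from erpdecode.simulate import generate_subject

    prof = SubjectProfile("pre1")
    rec = generate_subject(prof, "familiarity_view", 144, seed=11)
    ep, _ = preprocess(rec, PP_SMALL)
    models, _ = train_vae_per_class(
        ep, VAEConfig(epochs=20, early_stopping_epochs=8), seed=12)
    synth = {lab: sample_synthetic(m, 300, seed=200 + i)
             for i, (lab, m) in enumerate(models.items())}
    spec = ModelSpec.create("eegnet", C=ep.data.shape[1], T=ep.data.shape[2])
    model = build_model(spec, seed=31)
    cfg = PretrainConfig(epochs=30, learning_rate=3e-4, patience=8, seed=32)
    pretrain(model, synth, cfg)
    return model


@pytest.fixture(scope="session")
def cv_report(cohort_epochs):
    """5x repeated two-fold evaluation of the scaled EEGNet-SSVEP-reg."""
    pooled, tests, _ = cohort_epochs
    spec = ModelSpec.create("eegnet_ssvep_reg", C=pooled.data.shape[1],
                            T=pooled.data.shape[2], **SPEC_SMALL)
    cfg = TrainConfig(epochs=80, early_stopping_epochs=20, seed=0)
    return repeated_two_fold(pooled, tests, spec, cfg, repeats=5, k=2, seed=7)


def toy_two_class(n=32, C=4, T=160, noise=0.05, seed=0):
    """Linearly separable two-class epoch arrays (n, C, T) and labels."""
    rng = np.random.default_rng(seed)
    pattern = np.sin(2 * np.pi * 7 * np.arange(T) / T)[None, :] * np.ones((C, 1))
    y = np.repeat([0, 1], n // 2)
    X = np.array([(1.0 if c == 0 else -1.0) * pattern
                  + noise * rng.standard_normal((C, T)) for c in y],
                 dtype=np.float32)
    order = rng.permutation(n)
    return X[order], y[order]
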