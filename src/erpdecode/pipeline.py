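"""End-to-end study orchestration with validated configuration and manifests.

``run_study`` executes simulate -> preprocess -> per-class VAE -> augment ->
pretrain -> repeated two-fold fine-tuning/evaluation for each requested
experiment and writes all reports under an output directory.  Every stage
seed derives deterministically from the master seed, and a run manifest
records the configuration snapshot, derived seeds and content hashes of the
simulation and preprocessing outputs so a re-run can be verified bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import asdict
from pathlib import Path

import numpy as np

from .architectures import ModelSpec, build_model
from .preprocess import PreprocessConfig, preprocess, save_epochs
from .simulate import CohortConfig, generate_cohort, save_cohort
from .training import (
    PretrainConfig,
    TrainConfig,
    leave_subjects_out_plan,
    pool_epoch_sets,
    pretrain,
    repeated_two_fold,
)
from .vae import VAEConfig, sample_synthetic, train_vae_per_class

logger = logging.getLogger(__name__)

#: configuration schema: section -> key -> (default, validator, message)
_POS = (lambda v: v > 0, "must be positive")
_FRAC = (lambda v: 0 < v < 1, "must be in (0, 1)")
_NONNEG = (lambda v: v >= 0, "must be non-negative")

CONFIG_SCHEMA = {
    "study": {
        "experiments": (["emotion_view", "familiarity_view"],
                        lambda v: set(v) <= {"emotion_view", "familiarity_view"},
                        "unknown experiment name"),
        "architectures": (["eegnet_ssvep_reg"],
                          lambda v: set(v) <= {"eegnet", "deepconvnet",
                                               "eegnet_ssvep",
                                               "eegnet_ssvep_reg"},
                          "unknown architecture name"),
        "n_synthetic_per_class": (500, *_POS),
    },
    "simulate": {
        "n_controls": (8, *_POS),
        "n_ad": (1, *_NONNEG),
        "n_trials": (576, *_POS),
        "noise_scale_uv": (6.0, *_NONNEG),
        "artifact_rate": (0.02, lambda v: 0 <= v < 1, "must be in [0, 1)"),
    },
    "preprocess": {
        "band_low_hz": (4.0, *_POS),
        "band_high_hz": (40.0, *_POS),
        "tmin_s": (-0.2, lambda v: v < 0, "must be negative"),
        "tmax_s": (0.8, *_POS),
        "reject_uv": (150.0, *_POS),
        "channel_prefixes": (["O", "PO", "P", "TP", "T", "CP", "C"],
                             lambda v: len(v) > 0,
                             "must list at least one region prefix"),
    },
    "vae": {
        "epochs": (1000, *_POS),
        "batch_size": (32, *_POS),
        "learning_rate": (1e-4, *_POS),
        "early_stopping_epochs": (25, *_POS),
        "latent_dim": (2, *_POS),
        "filters": (16, *_POS),
        "kernel_size": (5, *_POS),
    },
    "pretrain": {
        "epochs": (300, *_POS),
        "batch_size": (128, *_POS),
        "learning_rate": (1e-5, *_POS),
        "patience": (50, *_POS),
    },
    "train": {
        "epochs": (500, *_POS),
        "batch_size": (64, *_POS),
        "learning_rate": (1e-3, *_POS),
        "early_stopping_epochs": (20, *_POS),
    },
    "cv": {
        "repeats": (5, *_POS),
        "folds": (2, lambda v: v >= 2, "must be >= 2"),
    },
    "model": {
        # scaled-size overrides for the EEGNet-family filter counts; null
        # keeps each architecture's published defaults
        "F1": (None, lambda v: v is None or v > 0, "must be positive"),
        "F2": (None, lambda v: v is None or v > 0, "must be positive"),
    },
}


def validate_config(config) -> dict:
    """Fill defaults, check ranges, warn about unknown keys.

    ``config`` may be a mapping, a YAML file path, or None (all defaults).
    """
    import copy

    if config is None:
        raw = {}
    elif isinstance(config, (str, Path)):
        import yaml

        with open(config) as f:
            raw = yaml.safe_load(f) or {}
    else:
        # deep copy: validation pops keys and must not mutate the caller's dict
        raw = copy.deepcopy(dict(config))
    errors = []
    out = {}
    for section, keys in CONFIG_SCHEMA.items():
        given = raw.pop(section, {}) or {}
        if not isinstance(given, dict):
            errors.append(f"section {section!r} must be a mapping")
            continue
        out[section] = {}
        for key, (default, check, msg) in keys.items():
            if key in given:
                val = given.pop(key)
                if not check(val):
                    errors.append(f"{section}.{key}={val!r}: {msg}")
            else:
                val = default
            out[section][key] = val
        for unknown in given:
            warnings.warn(f"unknown config key {section}.{unknown} ignored",
                          stacklevel=2)
            logger.info("ignored unknown config key %s.%s", section, unknown)
    for unknown in raw:
        warnings.warn(f"unknown config section {unknown!r} ignored",
                      stacklevel=2)
    if errors:
        raise ValueError("invalid configuration: " + "; ".join(errors))
    if out["preprocess"]["band_low_hz"] >= out["preprocess"]["band_high_hz"]:
        raise ValueError("preprocess.band_low_hz must be < band_high_hz")
    return out


def _sha(arr) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def run_study(config=None, out_dir=None, seed: int = 0, save_artifacts=True):
    """Execute the full study; returns (manifest, reports-by-experiment).

    Stage order per experiment: cohort simulation, preprocessing, per-class
    VAE training on the pooled training-subject trials, synthetic sampling,
    classifier pretraining, repeated two-fold fine-tuning and evaluation.
    Fails fast with a stage-named error if any stage raises.
    """
    cfg = validate_config(config)
    out = Path(out_dir) if out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    manifest = {
        "config": cfg, "master_seed": seed, "stages": {},
        "version": 1, "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    reports = {}
    for exp_i, experiment in enumerate(cfg["study"]["experiments"]):
        exp_seed, = np.random.SeedSequence([seed, exp_i]).spawn(1)
        stage_seeds = {name: s for name, s in zip(
            ("simulate", "vae", "augment", "pretrain", "cv"),
            exp_seed.spawn(5))}
        mexp = manifest["stages"].setdefault(experiment, {})

        def _stage(name, fn):
            t0 = time.time()
            try:
                res = fn()
            except Exception as e:
                raise RuntimeError(f"stage {name!r} failed for "
                                   f"{experiment}: {e}") from e
            logger.info("[%s] stage %s done in %.1fs", experiment, name,
                        time.time() - t0)
            return res

        sim_cfg = CohortConfig(experiment=experiment, **cfg["simulate"])
        sim_seed = int(stage_seeds["simulate"].generate_state(1)[0] % 2 ** 31)
        recordings = _stage("simulate",
                            lambda: generate_cohort(sim_cfg, sim_seed))
        mexp["simulate"] = {
            "seed": sim_seed,
            "hashes": {r.subject.subject_id: _sha(r.data) for r in recordings},
        }
        if out and save_artifacts:
            save_cohort(recordings, out / experiment / "raw", sim_seed)

        pp_cfg = PreprocessConfig(**cfg["preprocess"])
        def _preprocess():
            pairs = [preprocess(r, pp_cfg) for r in recordings]
            return [p[0] for p in pairs], [p[1] for p in pairs]
        epoch_sets, reject_reports = _stage("preprocess", _preprocess)
        mexp["preprocess"] = {
            "hashes": {ep.subject_id: _sha(ep.data) for ep in epoch_sets},
            "rejected": {ep.subject_id: r.n_rejected
                         for ep, r in zip(epoch_sets, reject_reports)},
        }
        if out and save_artifacts:
            ep_dir = out / experiment / "epochs"
            ep_dir.mkdir(parents=True, exist_ok=True)
            for ep in epoch_sets:
                save_epochs(ep, ep_dir / f"{ep.subject_id}.h5")
            with open(ep_dir / "rejection.json", "w") as f:
                json.dump(mexp["preprocess"]["rejected"], f, indent=1)

        groups = {r.subject.subject_id: r.subject.group for r in recordings}
        plan = leave_subjects_out_plan(epoch_sets, groups)
        train_sets = [ep for ep in epoch_sets
                      if ep.subject_id in plan.training_subjects]
        pooled = pool_epoch_sets(train_sets)
        test_sets = {}
        for ep in epoch_sets:
            if groups[ep.subject_id] == "control_oldest":
                test_sets["control"] = ep
            elif groups[ep.subject_id] == "ad":
                test_sets["alzheimer"] = ep

        vae_cfg = VAEConfig(**cfg["vae"])
        vae_seed = int(stage_seeds["vae"].generate_state(1)[0] % 2 ** 31)
        generators, vae_report = _stage(
            "train_vae",
            lambda: train_vae_per_class(pooled, vae_cfg, seed=vae_seed))
        if out:
            vdir = out / experiment
            vdir.mkdir(parents=True, exist_ok=True)
            vae_report.to_csv(vdir / "vae_report.csv", index=False)

        n_syn = cfg["study"]["n_synthetic_per_class"]
        aug_seed = stage_seeds["augment"]
        def _augment():
            seeds = aug_seed.spawn(len(generators))
            return {lab: sample_synthetic(m, n_syn,
                                          int(s.generate_state(1)[0] % 2 ** 31))
                    for (lab, m), s in zip(generators.items(), seeds)}
        synthetic = _stage("augment", _augment)

        C = pooled.data.shape[1]
        T = pooled.data.shape[2]
        exp_reports = {}
        for arch_i, arch in enumerate(cfg["study"]["architectures"]):
            over = {k: v for k, v in cfg["model"].items() if v is not None}
            spec = ModelSpec.create(arch, C=C, T=T, N=4, **over)
            pre_seed = int(stage_seeds["pretrain"].generate_state(1)[0]
                           % 2 ** 31) + arch_i
            model = build_model(spec, seed=pre_seed)
            pre_cfg = PretrainConfig(seed=pre_seed, **cfg["pretrain"])
            _stage(f"pretrain[{arch}]",
                   lambda: pretrain(model, synthetic, pre_cfg))
            init_state = model.net.get_state()
            cv_seed = int(stage_seeds["cv"].generate_state(1)[0] % 2 ** 31) \
                + arch_i
            tr_cfg = TrainConfig(**cfg["train"])
            report = _stage(
                f"cv[{arch}]",
                lambda: repeated_two_fold(
                    pooled, test_sets, spec, tr_cfg,
                    repeats=cfg["cv"]["repeats"], k=cfg["cv"]["folds"],
                    init_state=init_state, seed=cv_seed))
            exp_reports[arch] = report
            if out:
                adir = out / experiment / arch
                adir.mkdir(parents=True, exist_ok=True)
                report.runs.to_csv(adir / "runs.csv", index=False)
                report.summary().to_csv(adir / "summary.csv", index=False)
                for (rep, fold, kind), cm in report.confusions.items():
                    np.savetxt(adir / f"confusion_r{rep}f{fold}_{kind}.csv",
                               cm, fmt="%d", delimiter=",")
        reports[experiment] = exp_reports
    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    if out:
        with open(out / "manifest.json", "w") as f:
            json.dump(manifest, f, indent=1, default=str)
    return manifest, reports
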