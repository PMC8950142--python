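"""The four compact CNN classifiers for raw EEG trials.

* ``eegnet`` — temporal convolution (F1 kernels of length T/2) ->
  depthwise spatial convolution over all C electrodes (depth multiplier D,
  max-norm 1) -> separable convolution (F2 kernels, length 16) with average
  pooling, dropout and ELU throughout -> dense softmax with max-norm 0.25.
* ``deepconvnet`` — four conv/max-pool blocks with 25/25-50/100/200 filters
  (temporal kernel length TC, all kernels max-norm 2) -> dense softmax with
  max-norm 0.5.
* ``eegnet_ssvep`` — EEGNet with a full-length temporal kernel (length T),
  F1 = F2 = 96, D = 1 and no max-norm bound on the dense layer; tuned for
  visually evoked responses.
* ``eegnet_ssvep_reg`` — the SSVEP variant with L1 + L2 penalties (0.001
  each) on the dense kernel.

Input tensors are single-trial planes ``(batch, 1, C, T)``; the forward pass
emits class probabilities.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, asdict, field

import numpy as np

from . import nn

ARCHITECTURES = ("eegnet", "deepconvnet", "eegnet_ssvep", "eegnet_ssvep_reg")


@dataclass
class ModelSpec:
    """Architecture hyperparameters; defaults follow the published tables."""

    architecture: str
    C: int
    T: int
    N: int = 4
    F1: int = 8
    F2: int = 16
    D: int = 2
    TC: int = 10
    dropout_rate: float = 0.5
    l1: float = 0.0
    l2: float = 0.0

    def __post_init__(self):
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"unknown architecture: {self.architecture!r}")
        if min(self.C, self.T, self.N) < 1:
            raise ValueError("C, T and N must be >= 1")
        if self.architecture == "eegnet_ssvep_reg":
            if not (self.l1 > 0 and self.l2 > 0):
                raise ValueError("eegnet_ssvep_reg requires l1, l2 > 0")
        elif self.l1 or self.l2:
            raise ValueError("l1/l2 penalties only apply to eegnet_ssvep_reg")

    @classmethod
    def create(cls, architecture, C, T, N=4, **overrides):
        """Spec with the architecture's published defaults filled in."""
        defaults = {"dropout_rate": 0.5, "TC": 10}
        if architecture == "eegnet":
            defaults.update(F1=8, D=2, F2=16)
        elif architecture in ("eegnet_ssvep", "eegnet_ssvep_reg"):
            defaults.update(F1=96, D=1, F2=96)
            if architecture == "eegnet_ssvep_reg":
                defaults.update(l1=0.001, l2=0.001)
        elif architecture == "deepconvnet":
            defaults.update(F1=8, D=2, F2=16)  # unused by this stack
        defaults.update(overrides)
        return cls(architecture=architecture, C=C, T=T, N=N, **defaults)


class ClassifierModel:
    """A built network plus its spec and (once trained) its history."""

    def __init__(self, spec: ModelSpec, net: nn.Sequential, seed=None):
        self.spec = spec
        self.net = net
        self.seed = seed
        self.history = None

    def count_params(self) -> int:
        return self.net.count_params()

    def predict_proba(self, X, batch_size=256):
        X = _as_input(X)
        return nn.predict_proba(self.net, X, batch_size=batch_size)

    def predict(self, X, batch_size=256):
        # argmax ties resolve to the lowest class index
        return self.predict_proba(X, batch_size).argmax(axis=1)

    def summary(self) -> str:
        lines = [f"{self.spec.architecture} (C={self.spec.C}, T={self.spec.T}, "
                 f"N={self.spec.N})"]
        for l in self.net.layers:
            ps = sum(p.val.size for p in l.params())
            lines.append(f"  {type(l).__name__:<24s} params={ps}")
        lines.append(f"  total trainable params: {self.count_params()}")
        return "\n".join(lines)

    def save(self, path):
        """Single-file checkpoint: JSON spec header + weights + BN stats."""
        state = self.net.get_state()
        arrays = {f"w{i:03d}": w for i, w in enumerate(state["weights"])}
        for i, (m, v) in enumerate(state["bn_stats"]):
            arrays[f"bnm{i:03d}"] = m
            arrays[f"bnv{i:03d}"] = v
        header = json.dumps({"spec": asdict(self.spec), "seed": self.seed,
                             "n_weights": len(state["weights"]),
                             "n_bn": len(state["bn_stats"])})
        np.savez(path, header=np.frombuffer(header.encode(), dtype=np.uint8),
                 **arrays)

    @classmethod
    def load(cls, path):
        with np.load(path) as z:
            header = json.loads(bytes(z["header"]).decode())
            spec = ModelSpec(**header["spec"])
            model = build_model(spec, seed=header["seed"])
            state = {
                "weights": [z[f"w{i:03d}"] for i in range(header["n_weights"])],
                "bn_stats": [(z[f"bnm{i:03d}"], z[f"bnv{i:03d}"])
                             for i in range(header["n_bn"])],
            }
        model.net.set_state(state)
        return model


def _as_input(X):
    """Accept (n, C, T) or (n, 1, C, T) trial tensors."""
    X = np.asarray(X, dtype=np.float32)
    if X.ndim == 3:
        X = X[:, None, :, :]
    return X


def _check_pool_chain(T, pools, arch):
    t = T
    trace = [t]
    for p in pools:
        t = t // p
        trace.append(t)
        if t == 0:
            raise ValueError(
                f"{arch}: time axis too short for pooling chain "
                f"{pools}; shape trace {trace} starting from T={T}"
            )
    return t


def _eegnet_stack(spec: ModelSpec, rng, drop_rng, first_kernel,
                  dense_maxnorm, l1=0.0, l2=0.0):
    C, T = spec.C, spec.T
    t_out = _check_pool_chain(T, (4, 8), spec.architecture)
    layers = [
        nn.Conv2D(1, spec.F1, (1, first_kernel), pad="same", use_bias=False,
                  rng=rng, name="conv_temporal", input_grad=False),
        nn.BatchNorm(spec.F1),
        nn.DepthwiseSpatialConv(spec.F1, spec.D, C, maxnorm=1.0, rng=rng,
                                name="conv_spatial"),
        nn.BatchNorm(spec.F1 * spec.D),
        nn.ELU(),
        nn.AvgPool(4),
        nn.Dropout(spec.dropout_rate, drop_rng),
        nn.DepthwiseTemporalConv(spec.F1 * spec.D, 16, rng=rng,
                                 name="sep_depthwise"),
        nn.PointwiseConv(spec.F1 * spec.D, spec.F2, use_bias=False, rng=rng,
                         name="sep_pointwise"),
        nn.BatchNorm(spec.F2),
        nn.ELU(),
        nn.AvgPool(8),
        nn.Dropout(spec.dropout_rate, drop_rng),
        nn.Flatten(),
        nn.Dense(spec.F2 * t_out, spec.N, maxnorm=dense_maxnorm, l1=l1, l2=l2,
                 rng=rng, name="dense"),
    ]
    return nn.Sequential(layers)


def build_eegnet(spec: ModelSpec, seed=0) -> ClassifierModel:
    """EEGNet: first temporal kernel spans half the trial (T/2 samples)."""
    if spec.architecture != "eegnet":
        raise ValueError("spec.architecture must be 'eegnet'")
    rng = np.random.default_rng(seed)
    drop_rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    net = _eegnet_stack(spec, rng, drop_rng, first_kernel=spec.T // 2,
                        dense_maxnorm=0.25)
    return ClassifierModel(spec, net, seed)


def build_eegnet_ssvep(spec: ModelSpec, seed=0) -> ClassifierModel:
    """EEGNet SSVEP: full-length temporal kernel, unconstrained dense layer."""
    if spec.architecture not in ("eegnet_ssvep", "eegnet_ssvep_reg"):
        raise ValueError("spec.architecture must be an eegnet_ssvep variant")
    rng = np.random.default_rng(seed)
    drop_rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    net = _eegnet_stack(spec, rng, drop_rng, first_kernel=spec.T,
                        dense_maxnorm=None, l1=spec.l1, l2=spec.l2)
    return ClassifierModel(spec, net, seed)


def build_deepconvnet(spec: ModelSpec, seed=0) -> ClassifierModel:
    """DeepConvNet: four conv/pool blocks with doubling filter counts."""
    if spec.architecture != "deepconvnet":
        raise ValueError("spec.architecture must be 'deepconvnet'")
    rng = np.random.default_rng(seed)
    drop_rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    C, T, TC = spec.C, spec.T, spec.TC
    # shape trace through the valid convolutions and poolings
    t = T
    trace = [t]
    for _ in range(4):
        t = t - (TC - 1)
        trace.append(t)
        if t < 1:
            raise ValueError(f"deepconvnet: T={T} too short; trace {trace}")
        t = t // 2
        trace.append(t)
        if t < 1:
            raise ValueError(f"deepconvnet: T={T} too short; trace {trace}")
    layers = [
        nn.Conv2D(1, 25, (1, TC), pad="valid", maxnorm=2.0, rng=rng,
                  name="b1_temporal", input_grad=False),
        nn.Conv2D(25, 25, (C, 1), pad="valid", maxnorm=2.0, rng=rng,
                  name="b1_spatial"),
        nn.BatchNorm(25, eps=1e-5, momentum=0.1),
        nn.ELU(),
        nn.MaxPool(2),
        nn.Dropout(spec.dropout_rate, drop_rng),
    ]
    filters = [25, 50, 100, 200]
    for k in range(1, 4):
        layers += [
            nn.Conv2D(filters[k - 1], filters[k], (1, TC), pad="valid",
                      maxnorm=2.0, rng=rng, name=f"b{k + 1}_temporal"),
            nn.BatchNorm(filters[k], eps=1e-5, momentum=0.1),
            nn.ELU(),
            nn.MaxPool(2),
            nn.Dropout(spec.dropout_rate, drop_rng),
        ]
    layers += [
        nn.Flatten(),
        nn.Dense(200 * t, spec.N, maxnorm=0.5, rng=rng, name="dense"),
    ]
    return ClassifierModel(spec, nn.Sequential(layers), seed)


_BUILDERS = {
    "eegnet": build_eegnet,
    "deepconvnet": build_deepconvnet,
    "eegnet_ssvep": build_eegnet_ssvep,
    "eegnet_ssvep_reg": build_eegnet_ssvep,
}


def build_model(spec: ModelSpec, seed=0) -> ClassifierModel:
    return _BUILDERS[spec.architecture](spec, seed=seed)


def count_params(model: ClassifierModel) -> int:
    """Total trainable parameter count of a built model."""
    return model.count_params()
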