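"""Per-class convolutional variational autoencoders for epoch augmentation.

One VAE is trained per stimulus class on that class's preprocessed epochs
(values in [-1, 1]).  The encoder is a stack of convolutions with LeakyReLU
and batch normalization followed by two dense heads for the latent mean mu
and log-variance; the decoder mirrors it (dense -> reshape -> convolutional
reconstruction).  Training minimizes squared reconstruction error plus the
Kullback-Leibler divergence of the Gaussian posterior from the standard
normal prior, with the reparameterization trick (z = mu + sigma * eps).

Sampling the trained decoder at latent draws yields synthetic epochs used to
pretrain classifiers.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from . import nn

_F32 = np.float32


@dataclass
class VAEConfig:
    kernel_size: int = 5
    filters: int = 16
    latent_dim: int = 2
    epochs: int = 1000
    batch_size: int = 32
    learning_rate: float = 1e-4
    early_stopping_epochs: int = 25
    n_conv_layers: int = 2
    conv_rank: int = 2          # 2 = kernels over (channels, time); 1 = time only
    latent_dist: str = "normal"  # or "uniform01"
    recon_reduction: str = "sum"  # per-sample reconstruction: "sum" or "mean"

    def __post_init__(self):
        for name in ("kernel_size", "filters", "latent_dim", "epochs",
                     "batch_size", "early_stopping_epochs", "n_conv_layers"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.conv_rank not in (1, 2):
            raise ValueError("conv_rank must be 1 or 2")
        if self.latent_dist not in ("normal", "uniform01"):
            raise ValueError("latent_dist must be 'normal' or 'uniform01'")


@dataclass
class LatentStats:
    """Latent posterior mean, spread and a sampled vector for one input."""

    mu: np.ndarray
    sigma: np.ndarray
    z: np.ndarray

    def __post_init__(self):
        if not (self.mu.shape == self.sigma.shape == self.z.shape):
            raise ValueError("mu, sigma and z must share a shape")
        if np.any(self.sigma <= 0):
            raise ValueError("sigma must be positive elementwise")


def vae_loss(x, x_recon, mu, log_var, reduction="mean"):
    """(total, reconstruction term, KL term), each averaged over the batch.

    The reconstruction term is the squared error between input and
    reconstruction (a Gaussian likelihood up to constants), reduced per
    sample by ``reduction`` ("mean" over elements or "sum").  The KL term is
    the closed form ``0.5 * sum(mu^2 + sigma^2 - 1 - log sigma^2)`` per
    sample, averaged over the batch.
    """
    x = np.asarray(x, dtype=float)
    x_recon = np.asarray(x_recon, dtype=float)
    mu = np.atleast_2d(np.asarray(mu, dtype=float))
    log_var = np.atleast_2d(np.asarray(log_var, dtype=float))
    for a in (x, x_recon, mu, log_var):
        if not np.all(np.isfinite(a)):
            raise ValueError("non-finite values in VAE loss inputs")
    b = x.shape[0] if x.ndim > 1 else 1
    sq = (x_recon - x) ** 2
    per_sample = sq.reshape(b, -1)
    if reduction == "mean":
        recon = float(per_sample.mean(axis=1).mean())
    elif reduction == "sum":
        recon = float(per_sample.sum(axis=1).mean())
    else:
        raise ValueError(f"unknown reduction {reduction!r}")
    kl_per = 0.5 * np.sum(mu ** 2 + np.exp(log_var) - 1.0 - log_var, axis=-1)
    kl = float(np.mean(kl_per))
    return recon + kl, recon, kl


class VAEModel:
    """Encoder/decoder pair for one stimulus class."""

    def __init__(self, C, T, config: VAEConfig, seed=0, class_label=None):
        if min(C, T) < config.kernel_size:
            raise ValueError(
                f"input plane ({C}, {T}) smaller than kernel size "
                f"{config.kernel_size}"
            )
        self.C, self.T = C, T
        self.config = config
        self.class_label = class_label
        self.seed = seed
        self.metrics = None
        rng = np.random.default_rng(seed)
        k = config.kernel_size
        kern = (k, k) if config.conv_rank == 2 else (1, k)
        f = config.filters
        enc = []
        in_ch = 1
        for i in range(config.n_conv_layers):
            enc += [
                nn.Conv2D(in_ch, f, kern, pad="same", rng=rng,
                          name=f"enc{i}", input_grad=(i > 0)),
                nn.LeakyReLU(),
                nn.BatchNorm(f),
            ]
            in_ch = f
        self.encoder = nn.Sequential(enc)
        flat = f * C * T
        self.mu_head = nn.Dense(flat, config.latent_dim, rng=rng, name="mu")
        self.logvar_head = nn.Dense(flat, config.latent_dim, rng=rng,
                                    name="logvar")
        dec = [
            nn.Dense(config.latent_dim, flat, rng=rng, name="dec_dense"),
            nn.Reshape((f, C, T)),
        ]
        for i in range(config.n_conv_layers - 1):
            dec += [
                nn.Conv2D(f, f, kern, pad="same", rng=rng, name=f"dec{i}"),
                nn.LeakyReLU(),
                nn.BatchNorm(f),
            ]
        dec += [nn.Conv2D(f, 1, kern, pad="same", rng=rng, name="dec_out")]
        self.decoder = nn.Sequential(dec)
        out_shape = self.decode(np.zeros((1, config.latent_dim))).shape
        if out_shape[1:] != (C, T):
            raise ValueError(
                f"decoder output shape {out_shape[1:]} != input plane ({C}, {T})"
            )

    # -- forward pieces ----------------------------------------------------
    def encode(self, x, train=False):
        x = np.asarray(x, dtype=_F32)
        if x.ndim == 3:
            x = x[:, None]
        feat = self.encoder.forward(x, train=train)
        flat = feat.reshape(len(x), -1)
        mu = self.mu_head.forward(flat, train=train)
        log_var = self.logvar_head.forward(flat, train=train)
        self._feat_shape = feat.shape
        return mu, log_var

    def decode(self, z, train=False):
        out = self.decoder.forward(np.asarray(z, dtype=_F32), train=train)
        return out[:, 0, :, :]

    def latent_stats(self, x, rng) -> LatentStats:
        mu, log_var = self.encode(np.asarray(x)[None] if np.asarray(x).ndim == 2
                                  else x)
        sigma = np.exp(0.5 * log_var)
        z = mu + sigma * rng.standard_normal(mu.shape)
        return LatentStats(mu=mu[0], sigma=sigma[0], z=z[0])

    def params(self):
        return (self.encoder.params() + self.mu_head.params()
                + self.logvar_head.params() + self.decoder.params())

    def reconstruct(self, x, rng=None):
        """Posterior-mean round trip (eps = 0), for inspection and testing."""
        mu, _ = self.encode(x)
        return self.decode(mu)

    def _loss_eval(self, X, batch_size=64):
        """Deterministic loss (posterior mean, no sampling noise)."""
        tot = 0.0
        for i in range(0, len(X), batch_size):
            xb = X[i : i + batch_size]
            mu, lv = self.encode(xb)
            xr = self.decode(mu)
            t, _, _ = vae_loss(xb, xr, mu, lv,
                               reduction=self.config.recon_reduction)
            tot += t * len(xb)
        return tot / len(X)

    def _train_step(self, xb, opt, rng):
        cfg = self.config
        b = len(xb)
        mu, lv = self.encode(xb, train=True)
        eps = rng.standard_normal(mu.shape).astype(_F32)
        sigma = np.exp(0.5 * lv)
        z = mu + sigma * eps
        xr_full = self.decoder.forward(z, train=True)
        xr = xr_full[:, 0]
        total, recon, kl = vae_loss(xb, xr, mu, lv,
                                    reduction=cfg.recon_reduction)
        # gradient of the reconstruction term
        scale = 2.0 / b
        if cfg.recon_reduction == "mean":
            scale /= xr[0].size
        d_xr = (scale * (xr - xb)).astype(_F32)[:, None]
        dz = self.decoder.backward(d_xr)
        d_mu = dz + (mu / b).astype(_F32)
        d_lv = (dz * eps * 0.5 * sigma
                + 0.5 * (np.exp(lv) - 1.0) / b).astype(_F32)
        d_flat = (self.mu_head.backward(d_mu)
                  + self.logvar_head.backward(d_lv))
        self.encoder.backward(d_flat.reshape(self._feat_shape))
        opt.step()
        return total

    def fit(self, X_train, X_val, seed=0, verbose=False):
        cfg = self.config
        rng = np.random.default_rng(seed)
        X_train = np.asarray(X_train, dtype=_F32)
        X_val = np.asarray(X_val, dtype=_F32)
        opt = nn.Adam(self.params(), lr=cfg.learning_rate)
        best = np.inf
        best_state = self._get_state()
        best_epoch = 0
        wait = 0
        history = {"loss": [], "val_loss": []}
        t0 = time.time()
        for epoch in range(cfg.epochs):
            order = rng.permutation(len(X_train))
            ep_loss = 0.0
            for i in range(0, len(X_train), cfg.batch_size):
                idx = order[i : i + cfg.batch_size]
                ep_loss += self._train_step(X_train[idx], opt, rng) * len(idx)
            history["loss"].append(ep_loss / len(X_train))
            vl = self._loss_eval(X_val) if len(X_val) else history["loss"][-1]
            history["val_loss"].append(vl)
            if verbose:
                print(f"vae epoch {epoch + 1}: loss={history['loss'][-1]:.3f} "
                      f"val={vl:.3f}")
            if vl < best - 1e-9:
                best, best_epoch, wait = vl, epoch, 0
                best_state = self._get_state()
            else:
                wait += 1
                if wait >= cfg.early_stopping_epochs:
                    break
        self._set_state(best_state)
        history["best_epoch"] = best_epoch
        history["train_time_s"] = time.time() - t0
        return history

    def _nets(self):
        return (self.encoder, nn.Sequential([self.mu_head]),
                nn.Sequential([self.logvar_head]), self.decoder)

    def _get_state(self):
        return [n.get_state() for n in self._nets()]

    def _set_state(self, state):
        for n, s in zip(self._nets(), state):
            n.set_state(s)

    def save(self, path):
        """Single-file checkpoint: JSON header + weights + BN statistics."""
        import json
        from dataclasses import asdict

        arrays = {}
        counts = []
        for ni, st in enumerate(self._get_state()):
            counts.append((len(st["weights"]), len(st["bn_stats"])))
            for i, w in enumerate(st["weights"]):
                arrays[f"n{ni}w{i:03d}"] = w
            for i, (m, v) in enumerate(st["bn_stats"]):
                arrays[f"n{ni}bm{i:03d}"] = m
                arrays[f"n{ni}bv{i:03d}"] = v
        lab = self.class_label
        header = json.dumps({
            "config": asdict(self.config), "C": self.C, "T": self.T,
            "class_label": ([lab.experiment, lab.category]
                            if lab is not None else None),
            "counts": counts, "metrics": self.metrics,
        })
        np.savez(path, header=np.frombuffer(header.encode(), dtype=np.uint8),
                 **arrays)

    @classmethod
    def load(cls, path):
        import json

        from .simulate import StimulusClass

        with np.load(path) as z:
            header = json.loads(bytes(z["header"]).decode())
            lab = header["class_label"]
            model = cls(header["C"], header["T"], VAEConfig(**header["config"]),
                        seed=0,
                        class_label=StimulusClass(*lab) if lab else None)
            state = []
            for ni, (nw, nb) in enumerate(header["counts"]):
                state.append({
                    "weights": [z[f"n{ni}w{i:03d}"] for i in range(nw)],
                    "bn_stats": [(z[f"n{ni}bm{i:03d}"], z[f"n{ni}bv{i:03d}"])
                                 for i in range(nb)],
                })
        model._set_state(state)
        model.metrics = header["metrics"]
        return model


@dataclass
class SyntheticSampleSet:
    """Decoded latent draws: n synthetic epochs of one class."""

    data: np.ndarray  # (n, C, T)
    class_label: object
    generator_id: str
    seed: object


def train_val_test_split(n, val_frac=0.2, test_frac=0.2, rng=None):
    """Shuffled index split; val/test sizes floor, remainder to train."""
    rng = rng or np.random.default_rng()
    idx = rng.permutation(n)
    n_val = int(np.floor(n * val_frac))
    n_test = int(np.floor(n * test_frac))
    n_train = n - n_val - n_test
    return (idx[:n_train], idx[n_train:n_train + n_val],
            idx[n_train + n_val:])


def build_vae(C, T, cfg: VAEConfig | None = None, seed=0,
              class_label=None) -> VAEModel:
    """An untrained VAE whose decoder replicates the (C, T) input plane."""
    return VAEModel(C, T, cfg or VAEConfig(), seed=seed,
                    class_label=class_label)


def _group_by_class(epochs_by_class):
    """Accept {class: array} or an EpochSet; return an ordered dict."""
    from .preprocess import EpochSet

    if isinstance(epochs_by_class, EpochSet):
        ep = epochs_by_class
        out = {}
        for i, lab in enumerate(ep.labels):
            out.setdefault(lab, []).append(i)
        return {lab: ep.data[idx] for lab, idx in out.items()}
    return dict(epochs_by_class)


def train_vae_per_class(epochs_by_class, cfg: VAEConfig | None = None,
                        seed=0, val_frac=0.2, test_frac=0.2, verbose=False):
    """One trained generator per class plus a per-class metrics table.

    Each class is split 60/20/20 (train/validation/test by default) and
    trained independently with early stopping on the validation loss.
    Returns ``(models, report)`` where ``report`` is a DataFrame with one
    row per class: training time, validation loss, test loss and split
    sizes.
    """
    import pandas as pd

    cfg = cfg or VAEConfig()
    grouped = _group_by_class(epochs_by_class)
    for lab, X in grouped.items():
        if len(X) < 10:
            raise ValueError(
                f"class {getattr(lab, 'category', lab)!r} has only "
                f"{len(X)} trials (>= 10 required)"
            )
    seeds = np.random.SeedSequence(seed).spawn(len(grouped))
    models = {}
    rows = []
    for (lab, X), ss in zip(grouped.items(), seeds):
        rng = np.random.default_rng(ss)
        tr, va, te = train_val_test_split(len(X), val_frac, test_frac, rng)
        C, T = X.shape[1], X.shape[2]
        model = VAEModel(C, T, cfg, seed=ss.spawn(1)[0], class_label=lab)
        hist = model.fit(X[tr], X[va], seed=ss.spawn(1)[0], verbose=verbose)
        model.history = hist
        test_loss = model._loss_eval(X[te]) if len(te) else np.nan
        model.metrics = {
            "class": getattr(lab, "category", str(lab)),
            "train_time_s": hist["train_time_s"],
            "val_loss": float(np.min(hist["val_loss"])),
            "test_loss": float(test_loss),
            "train_size": len(tr), "val_size": len(va), "test_size": len(te),
            "best_epoch": hist["best_epoch"],
        }
        models[lab] = model
        rows.append(model.metrics)
    return models, pd.DataFrame(rows)


def sample_synthetic(model: VAEModel, n, seed) -> SyntheticSampleSet:
    """Decode n latent draws; deterministic for a given seed.

    Latent vectors are drawn from N(0, 1) by default, or uniformly from
    [0, 1) when the model was configured with ``latent_dist='uniform01'``.
    """
    rng = np.random.default_rng(seed)
    L = model.config.latent_dim
    if model.config.latent_dist == "uniform01":
        z = rng.random((n, L))
    else:
        z = rng.standard_normal((n, L))
    if n == 0:
        data = np.empty((0, model.C, model.T), dtype=_F32)
    else:
        chunks = [model.decode(z[i : i + 256]) for i in range(0, n, 256)]
        data = np.concatenate(chunks, axis=0)
    gen_id = getattr(model.class_label, "category", str(model.class_label))
    return SyntheticSampleSet(data=data, class_label=model.class_label,
                              generator_id=f"vae:{gen_id}", seed=seed)
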