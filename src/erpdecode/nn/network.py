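"""Sequential network container, Adam optimizer and the supervised fit loop."""

from __future__ import annotations

import time

import numpy as np

_F32 = np.float32


def softmax(z):
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_xent(logits, y_onehot):
    """Mean cross-entropy and its gradient w.r.t. the logits."""
    p = softmax(logits)
    eps = 1e-12
    loss = -np.mean(np.sum(y_onehot * np.log(p + eps), axis=1))
    grad = (p - y_onehot) / logits.shape[0]
    return float(loss), grad.astype(_F32)


class Sequential:
    """A plain layer stack: forward caches activations for backward."""

    def __init__(self, layers):
        self.layers = list(layers)

    def params(self):
        out = []
        for l in self.layers:
            out.extend(l.params())
        return out

    def forward(self, x, train=False):
        for l in self.layers:
            x = l.forward(x, train=train)
        return x

    def backward(self, grad):
        for l in reversed(self.layers):
            grad = l.backward(grad)
        return grad

    def get_weights(self):
        return [p.val.copy() for p in self.params()]

    def set_weights(self, weights):
        params = self.params()
        if len(weights) != len(params):
            raise ValueError(
                f"weight list length {len(weights)} != parameter count {len(params)}"
            )
        for p, w in zip(params, weights):
            w = np.asarray(w, dtype=_F32)
            if w.shape != p.val.shape:
                raise ValueError(
                    f"shape mismatch for {p.name}: got {w.shape}, "
                    f"expected {p.val.shape}"
                )
            p.val[...] = w

    def count_params(self):
        return int(sum(p.val.size for p in self.params()))

    def get_state(self):
        """Trainable weights plus batch-norm running statistics."""
        from .layers import BatchNorm

        stats = [(l.run_mean.copy(), l.run_var.copy())
                 for l in self.layers if isinstance(l, BatchNorm)]
        return {"weights": self.get_weights(), "bn_stats": stats}

    def set_state(self, state):
        from .layers import BatchNorm

        self.set_weights(state["weights"])
        bns = [l for l in self.layers if isinstance(l, BatchNorm)]
        if len(bns) != len(state["bn_stats"]):
            raise ValueError("batch-norm layer count mismatch")
        for l, (m, v) in zip(bns, state["bn_stats"]):
            l.run_mean = np.asarray(m, dtype=_F32).copy()
            l.run_var = np.asarray(v, dtype=_F32).copy()


class Adam:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-7):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.val) for p in params]
        self.v = [np.zeros_like(p.val) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1 - self.beta1 ** self.t
        b2t = 1 - self.beta2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            if p.l1 or p.l2:
                g = g + p.penalty_grad()
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p.val -= (self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)).astype(
                _F32
            )
            p.apply_constraint()


def _penalty(net):
    return sum(p.penalty() for p in net.params())


def predict_proba(net, X, batch_size=256):
    out = []
    for i in range(0, len(X), batch_size):
        out.append(softmax(net.forward(X[i : i + batch_size], train=False)))
    return np.concatenate(out, axis=0)


def evaluate_loss_acc(net, X, y_onehot, batch_size=256):
    n = len(X)
    loss = 0.0
    correct = 0
    for i in range(0, n, batch_size):
        xb, yb = X[i : i + batch_size], y_onehot[i : i + batch_size]
        logits = net.forward(xb, train=False)
        l, _ = softmax_xent(logits, yb)
        loss += l * len(xb)
        correct += int(np.sum(logits.argmax(axis=1) == yb.argmax(axis=1)))
    return loss / n + _penalty(net), correct / n


def fit(net, X, y_onehot, *, X_val=None, y_val=None, epochs=100, batch_size=64,
        lr=1e-3, patience=None, rng=None, verbose=False):
    """Train with Adam and softmax cross-entropy.

    Early stopping monitors validation loss with the given patience and
    restores the best weights.  Returns a history dict with per-epoch train
    and validation loss/accuracy plus the (0-based) best epoch index.
    """
    rng = rng or np.random.default_rng()
    X = np.asarray(X, dtype=_F32)
    y_onehot = np.asarray(y_onehot, dtype=_F32)
    opt = Adam(net.params(), lr=lr)
    history = {"loss": [], "acc": [], "val_loss": [], "val_acc": []}
    best_loss = np.inf
    best_state = net.get_state()
    best_epoch = 0
    wait = 0
    t0 = time.time()
    n = len(X)
    for epoch in range(epochs):
        order = rng.permutation(n)
        ep_loss = 0.0
        ep_correct = 0
        for i in range(0, n, batch_size):
            idx = order[i : i + batch_size]
            xb, yb = X[idx], y_onehot[idx]
            logits = net.forward(xb, train=True)
            loss, grad = softmax_xent(logits, yb)
            net.backward(grad)
            opt.step()
            ep_loss += loss * len(idx)
            ep_correct += int(np.sum(logits.argmax(axis=1) == yb.argmax(axis=1)))
        history["loss"].append(ep_loss / n + _penalty(net))
        history["acc"].append(ep_correct / n)
        if X_val is not None and len(X_val):
            vl, va = evaluate_loss_acc(net, X_val, y_val, batch_size)
        else:
            vl, va = history["loss"][-1], history["acc"][-1]
        history["val_loss"].append(vl)
        history["val_acc"].append(va)
        if verbose:
            print(f"epoch {epoch + 1}/{epochs} loss={history['loss'][-1]:.4f} "
                  f"acc={history['acc'][-1]:.3f} val_loss={vl:.4f} val_acc={va:.3f}")
        if vl < best_loss - 1e-9:
            best_loss = vl
            best_state = net.get_state()
            best_epoch = epoch
            wait = 0
        else:
            wait += 1
            if patience is not None and wait >= patience:
                break
    net.set_state(best_state)
    history["best_epoch"] = best_epoch
    history["train_time_s"] = time.time() - t0
    return history
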