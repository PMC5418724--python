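"""One-hidden-layer perceptrons trained by scaled conjugate gradient (SCG).

The same machinery serves two very different workloads:

* motion classifiers (LNN / MLPANN): one network, wide input, softmax
  cross-entropy output, a handful of random restarts;
* the feature-ratio regression bank: thousands of tiny 3-3-1 networks
  (one per class x channel x feature x {mean, variance}) sharing the same
  13 input points.

Everything is therefore *batched over networks*: weights live in a
``(B, P)`` array and every SCG state variable is a length-``B`` vector, so
the whole bank (including restarts) trains in a single vectorised run.

SCG follows Moller (1993) in the netlab formulation: a Hessian-free
second-order batch method with no user learning rate. Early stopping
monitors a validation loss and restores the best-validation weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_SIGMA0 = 1.0e-4
_BETA_MIN = 1.0e-15
_BETA_MAX = 1.0e20


@dataclass(frozen=True)
class MLPSpec:
    """Architecture of a one-hidden-layer perceptron.

    ``n_hidden == 0`` means a direct linear map (no hidden layer), used as
    the reduced input-output model that the linear-activation network (LNN)
    is mathematically equivalent to.
    """

    n_in: int
    n_hidden: int
    n_out: int
    activation: str = "tanh"  # "tanh" | "identity"
    loss: str = "mse"  # "mse" | "softmax_ce"

    @property
    def n_params(self) -> int:
        if self.n_hidden == 0:
            return (self.n_in + 1) * self.n_out
        return (self.n_in + 1) * self.n_hidden + (self.n_hidden + 1) * self.n_out

    def init_weights(self, n_nets: int, rng: np.random.Generator) -> np.ndarray:
        """Small uniform random weights, scaled by fan-in."""
        w = np.empty((n_nets, self.n_params))
        if self.n_hidden == 0:
            r = 0.5 / np.sqrt(self.n_in + 1.0)
            w[:] = rng.uniform(-r, r, size=w.shape)
            return w
        p1 = (self.n_in + 1) * self.n_hidden
        r1 = 0.5 / np.sqrt(self.n_in + 1.0)
        r2 = 0.5 / np.sqrt(self.n_hidden + 1.0)
        w[:, :p1] = rng.uniform(-r1, r1, size=(n_nets, p1))
        w[:, p1:] = rng.uniform(-r2, r2, size=(n_nets, self.n_params - p1))
        return w

    def unpack(self, w: np.ndarray):
        """Split flat weights (B, P) into layer arrays."""
        B = w.shape[0]
        if self.n_hidden == 0:
            p = self.n_in * self.n_out
            W = w[:, :p].reshape(B, self.n_in, self.n_out)
            b = w[:, p:]
            return W, b
        h, c, d = self.n_hidden, self.n_out, self.n_in
        i = 0
        W1 = w[:, i : i + d * h].reshape(B, d, h)
        i += d * h
        b1 = w[:, i : i + h]
        i += h
        W2 = w[:, i : i + h * c].reshape(B, h, c)
        i += h * c
        b2 = w[:, i:]
        return W1, b1, W2, b2

    # ------------------------------------------------------------------ #

    def forward(self, w: np.ndarray, X: np.ndarray) -> np.ndarray:
        """Network outputs, shape (B, n, n_out). ``X`` is shared: (n, n_in)."""
        if self.n_hidden == 0:
            W, b = self.unpack(w)
            return np.einsum("nd,bdc->bnc", X, W) + b[:, None, :]
        W1, b1, W2, b2 = self.unpack(w)
        H = np.einsum("nd,bdh->bnh", X, W1) + b1[:, None, :]
        if self.activation == "tanh":
            H = np.tanh(H)
        return np.einsum("bnh,bhc->bnc", H, W2) + b2[:, None, :]

    def _output_and_hidden(self, w, X):
        if self.n_hidden == 0:
            W, b = self.unpack(w)
            return np.einsum("nd,bdc->bnc", X, W) + b[:, None, :], None
        W1, b1, W2, b2 = self.unpack(w)
        A = np.einsum("nd,bdh->bnh", X, W1) + b1[:, None, :]
        if self.activation == "tanh":
            A = np.tanh(A)
        return np.einsum("bnh,bhc->bnc", A, W2) + b2[:, None, :], A

    def loss_value(self, w: np.ndarray, X: np.ndarray, Y: np.ndarray) -> np.ndarray:
        Z, _ = self._output_and_hidden(w, X)
        return self._loss(Z, Y)

    def _loss(self, Z, Y):
        n = Z.shape[1]
        if self.loss == "softmax_ce":
            Zs = Z - Z.max(axis=2, keepdims=True)
            lse = np.log(np.exp(Zs).sum(axis=2))
            logp = Zs - lse[:, :, None]
            return -(np.broadcast_to(Y, Z.shape) * logp).sum(axis=2).mean(axis=1)
        r = Z - Y
        return 0.5 * (r * r).sum(axis=2).mean(axis=1)

    def loss_grad(self, w: np.ndarray, X: np.ndarray, Y: np.ndarray):
        """Loss and flat gradient for every network in the batch."""
        Z, A = self._output_and_hidden(w, X)
        n = Z.shape[1]
        if self.loss == "softmax_ce":
            Zs = Z - Z.max(axis=2, keepdims=True)
            E = np.exp(Zs)
            P = E / E.sum(axis=2, keepdims=True)
            logp = Zs - np.log(E.sum(axis=2))[:, :, None]
            Yb = np.broadcast_to(Y, Z.shape)
            f = -(Yb * logp).sum(axis=2).mean(axis=1)
            dZ = (P - Yb) / n
        else:
            r = Z - Y
            f = 0.5 * (r * r).sum(axis=2).mean(axis=1)
            dZ = r / n
        B = w.shape[0]
        g = np.empty_like(w)
        if self.n_hidden == 0:
            gW = np.einsum("nd,bnc->bdc", X, dZ)
            gb = dZ.sum(axis=1)
            g[:, : self.n_in * self.n_out] = gW.reshape(B, -1)
            g[:, self.n_in * self.n_out :] = gb
            return f, g
        _, _, W2, _ = self.unpack(w)
        gW2 = np.einsum("bnh,bnc->bhc", A, dZ)
        gb2 = dZ.sum(axis=1)
        dA = np.einsum("bnc,bhc->bnh", dZ, W2)
        if self.activation == "tanh":
            dA = dA * (1.0 - A * A)
        gW1 = np.einsum("nd,bnh->bdh", X, dA)
        gb1 = dA.sum(axis=1)
        d, h = self.n_in, self.n_hidden
        i = 0
        g[:, i : i + d * h] = gW1.reshape(B, -1)
        i += d * h
        g[:, i : i + h] = gb1
        i += h
        g[:, i : i + h * self.n_out] = gW2.reshape(B, -1)
        i += h * self.n_out
        g[:, i:] = gb2
        return f, g


def scg(
    loss_grad,
    w0: np.ndarray,
    *,
    max_iter: int = 300,
    grad_tol: float = 1.0e-10,
    val_loss=None,
    patience: int = 6,
):
    """Batched scaled-conjugate-gradient minimisation.

    Parameters
    ----------
    loss_grad : callable (B, P) -> ((B,), (B, P))
    w0 : initial weights, one row per network.
    val_loss : optional callable (B, P) -> (B,); when given, training keeps
        the best-validation weights per network and a network stops after
        ``patience`` consecutive non-improving successful steps.

    Returns ``(weights, info)`` where weights are the best-validation weights
    (or the final weights if no validation monitor was supplied).
    """
    w = np.array(w0, dtype=float, copy=True)
    B, P = w.shape
    f, grad = loss_grad(w)
    d = -grad
    mu = np.zeros(B)
    kappa = np.ones(B)
    theta = np.zeros(B)
    beta = np.ones(B)
    success = np.ones(B, dtype=bool)
    nsuccess = np.zeros(B, dtype=int)
    done = np.einsum("bp,bp->b", grad, grad) < grad_tol

    track_val = val_loss is not None
    if track_val:
        best_val = val_loss(w)
        prev_val = best_val.copy()
        best_w = w.copy()
        bad = np.zeros(B, dtype=int)

    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        if done.all():
            break
        act = success & ~done
        if act.any():
            mu_new = np.einsum("bp,bp->b", d, grad)
            flip = act & (mu_new >= 0)
            if flip.any():
                d = np.where(flip[:, None], -grad, d)
                mu_new = np.where(flip, np.einsum("bp,bp->b", d, grad), mu_new)
            mu = np.where(act, mu_new, mu)
            kappa = np.where(act, np.einsum("bp,bp->b", d, d), kappa)
            kappa_safe = np.maximum(kappa, 1.0e-300)
            sigma = _SIGMA0 / np.sqrt(kappa_safe)
            _, gplus = loss_grad(w + sigma[:, None] * d)
            theta = np.where(
                act, np.einsum("bp,bp->b", d, gplus - grad) / sigma, theta
            )
        kappa_safe = np.maximum(kappa, 1.0e-300)
        delta = theta + beta * kappa
        neg = delta <= 0
        beta = np.where(neg, beta - theta / kappa_safe, beta)
        delta = np.where(neg, beta * kappa, delta)
        delta = np.maximum(delta, 1.0e-300)
        alpha = -mu / delta
        wnew = w + alpha[:, None] * d
        fnew, gnew = loss_grad(wnew)
        with np.errstate(invalid="ignore", divide="ignore"):
            Delta = 2.0 * (fnew - f) / (alpha * mu)
        Delta = np.where(np.isfinite(Delta), Delta, -1.0)
        ok = (Delta >= 0) & np.isfinite(fnew) & ~done
        gradold = grad
        w = np.where(ok[:, None], wnew, w)
        grad = np.where(ok[:, None], gnew, grad)
        f = np.where(ok, fnew, f)
        nsuccess = np.where(ok, nsuccess + 1, nsuccess)
        beta = np.where(Delta < 0.25, np.minimum(4.0 * beta, _BETA_MAX), beta)
        beta = np.where(Delta > 0.75, np.maximum(0.5 * beta, _BETA_MIN), beta)
        mu_safe = np.where(mu == 0, 1.0, mu)
        gamma = np.einsum("bp,bp->b", gradold - grad, grad) / mu_safe
        dnew = gamma[:, None] * d - grad
        restart = ok & (nsuccess >= P)
        d = np.where(restart[:, None], -grad, np.where(ok[:, None], dnew, d))
        nsuccess = np.where(restart, 0, nsuccess)
        success = ok
        done = done | (np.einsum("bp,bp->b", grad, grad) < grad_tol)
        if track_val and ok.any():
            v = val_loss(w)
            better = ok & (v < best_val - 1.0e-12)
            if better.any():
                best_w = np.where(better[:, None], w, best_w)
                best_val = np.where(better, v, best_val)
            # stop after `patience` consecutive validation-error increases
            increased = ok & (v > prev_val + 1.0e-12)
            bad = np.where(increased, bad + 1, np.where(ok, 0, bad))
            prev_val = np.where(ok, v, prev_val)
            done = done | (bad >= patience)

    if track_val:
        # final weights may beat the last snapshot for nets that never improved
        v = val_loss(w)
        better = v < best_val
        best_w = np.where(better[:, None], w, best_w)
        best_val = np.where(better, v, best_val)
        return best_w, {"n_iter": n_iter, "val_loss": best_val, "train_loss": f}
    return w, {"n_iter": n_iter, "train_loss": f}


def train_networks(
    spec: MLPSpec,
    X: np.ndarray,
    Y: np.ndarray,
    *,
    seed: int,
    n_nets: int = 1,
    restarts: int = 3,
    X_val: np.ndarray | None = None,
    Y_val: np.ndarray | None = None,
    max_iter: int = 300,
    patience: int = 6,
):
    """Train ``n_nets`` networks (with ``restarts`` seeded restarts each).

    ``Y`` has shape (n, n_out) shared across nets or (n_nets, n, n_out) with
    one target set per network. Returns the per-network best weights,
    shape (n_nets, P), and an info dict.
    """
    rng = np.random.default_rng(seed)
    B = n_nets * restarts
    w0 = spec.init_weights(B, rng)

    per_net_targets = Y.ndim == 3
    if per_net_targets:
        Yb = np.repeat(Y, restarts, axis=0)
    else:
        Yb = Y

    def lg(w):
        return spec.loss_grad(w, X, Yb)

    val_fn = None
    if X_val is not None:
        Yv = np.repeat(Y_val, restarts, axis=0) if per_net_targets else Y_val

        def val_fn(w):  # noqa: F811
            return spec.loss_value(w, X_val, Yv)

    w, info = scg(
        lg, w0, max_iter=max_iter, val_loss=val_fn, patience=patience
    )
    score = info["val_loss"] if X_val is not None else info["train_loss"]
    score = np.where(np.isfinite(score), score, np.inf)
    pick = score.reshape(n_nets, restarts).argmin(axis=1)
    idx = np.arange(n_nets) * restarts + pick
    return w[idx], {
        "n_iter": info["n_iter"],
        "score": score[idx],
        "restart_chosen": pick,
    }
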