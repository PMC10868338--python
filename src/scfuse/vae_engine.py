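"""Shared variational machinery for the integration models.

All three integration models are variational autoencoders differing only in
how the decoder is conditioned; this module holds what they share: the
closed-form KL term against the standard-normal prior, the reconstruction
log-likelihoods (Gaussian on log-normalized data, negative binomial on raw
counts), reparameterized sampling, dense layers with hand-written backward
passes, an Adam optimizer, and the seeded minibatch training loop.

The engine is plain NumPy.  At the scales this package targets (thousands of
cells, hundreds of features, latent dimension ~16) a vectorized NumPy
backward pass trains in seconds, and keeping the whole computation in one
process makes the determinism contract trivial: every source of randomness —
weight initialization, minibatch shuffling, reparameterization noise — is
drawn from a single generator seeded by ``TrainingConfig.seed``, so reruns
reproduce loss traces exactly on one platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import List, Optional, Sequence

import numpy as np
import yaml
from scipy.special import gammaln

from .errors import DivergenceError, ParameterError, ValidationError

_LOG2PI = float(np.log(2.0 * np.pi))
_LOGVAR_CLIP = 8.0  # posterior log-variance clamp, keeps exp() tame


# ======================================================================
# Domain types
# ======================================================================

@dataclass
class VariationalPosterior:
    """Per-cell Gaussian posterior q(z|x) = N(mean, diag(exp(logvar)))."""

    mean: np.ndarray
    logvar: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.atleast_2d(np.asarray(self.mean, dtype=np.float64))
        self.logvar = np.atleast_2d(np.asarray(self.logvar, dtype=np.float64))
        if self.mean.shape != self.logvar.shape:
            raise ValidationError(
                f"mean shape {self.mean.shape} != logvar shape {self.logvar.shape}"
            )
        if not np.all(np.isfinite(self.logvar)) or not np.all(
            np.isfinite(self.mean)
        ):
            raise ValidationError("posterior parameters must be finite")


@dataclass
class TrainingConfig:
    """Hyper-parameters shared by all model fits.

    ``kl_weight`` is the beta multiplier on the KL term of the ELBO;
    ``adversarial_weight`` scales the reversed domain-classifier gradient and
    is only consumed by the domain-adversarial model.
    """

    latent_dim: int = 16
    hidden_sizes: List[int] = field(default_factory=lambda: [128, 64])
    epochs: int = 50
    batch_size: int = 128
    learning_rate: float = 1e-3
    seed: int = 0
    likelihood: str = "gaussian"
    kl_weight: float = 1.0
    adversarial_weight: float = 1.0

    def __post_init__(self) -> None:
        if self.latent_dim <= 0 or self.epochs <= 0 or self.batch_size <= 0:
            raise ParameterError("latent_dim, epochs and batch_size must be positive")
        if any(h <= 0 for h in self.hidden_sizes):
            raise ParameterError("hidden sizes must be positive")
        if self.learning_rate <= 0:
            raise ParameterError("learning_rate must be positive")
        if self.kl_weight < 0 or self.adversarial_weight < 0:
            raise ParameterError("kl_weight and adversarial_weight must be >= 0")
        if self.likelihood not in ("gaussian", "negative_binomial"):
            raise ParameterError(f"unknown likelihood {self.likelihood!r}")

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "TrainingConfig":
        return cls(**yaml.safe_load(text))


@dataclass
class FittedModel:
    """Opaque fitted-parameter store plus the per-epoch loss trace.

    ``loss_trace`` rows are ``(total, reconstruction, kl, adversarial)``
    epoch means; the kl and adversarial columns are recorded *unweighted* so
    a run with ``kl_weight=0`` still reports the KL it would have paid.
    """

    config: TrainingConfig
    loss_trace: np.ndarray
    model: object = None

    def trace_csv(self) -> str:
        lines = ["epoch,total,recon,kl,adv"]
        for e, row in enumerate(self.loss_trace):
            lines.append(f"{e}," + ",".join(f"{v:.10g}" for v in row))
        return "\n".join(lines) + "\n"


# ======================================================================
# Closed-form pieces
# ======================================================================

def kl_standard_normal(post: VariationalPosterior) -> np.ndarray:
    """Per-cell KL(q(z|x) || N(0, I)), closed form.

    KL = 0.5 * sum_j (mu_j^2 + exp(logvar_j) - logvar_j - 1), one value per
    cell, always >= 0.
    """
    mu, lv = post.mean, post.logvar
    kl = 0.5 * np.sum(mu**2 + np.exp(lv) - lv - 1.0, axis=1)
    # the closed form is >= 0 analytically; clip away negative round-off
    return np.maximum(kl, 0.0)


def reconstruction_loglik(x, decoded: dict, likelihood: str) -> float:
    """Log-likelihood of one observation vector under the decoder output.

    ``decoded`` holds distribution parameters: ``{"mean", "logvar"}`` for the
    Gaussian (per-feature variance), ``{"mean", "dispersion"}`` for the
    negative binomial (NB parameterized by mean m and inverse-dispersion
    theta, Var = m + m^2/theta).
    """
    x = np.asarray(x, dtype=np.float64)
    if likelihood == "gaussian":
        mu = np.asarray(decoded["mean"], dtype=np.float64)
        lv = np.asarray(decoded["logvar"], dtype=np.float64)
        return float(
            -0.5 * np.sum((x - mu) ** 2 / np.exp(lv) + lv + _LOG2PI)
        )
    if likelihood == "negative_binomial":
        if np.any(x < 0) or np.any(x != np.round(x)):
            raise ValidationError(
                "negative binomial likelihood requires non-negative integer counts"
            )
        m = np.asarray(decoded["mean"], dtype=np.float64)
        theta = np.asarray(decoded["dispersion"], dtype=np.float64)
        return float(
            np.sum(
                gammaln(x + theta)
                - gammaln(theta)
                - gammaln(x + 1.0)
                + theta * np.log(theta / (theta + m))
                + x * np.log(m / (theta + m), where=m > 0, out=np.zeros_like(m))
            )
        )
    raise ParameterError(f"unknown likelihood {likelihood!r}")


def reparameterized_sample(
    post: VariationalPosterior, seed: int, rng: Optional[np.random.Generator] = None
) -> np.ndarray:
    """Draw z = mean + exp(logvar/2) * eps with eps ~ N(0, I), seeded."""
    if rng is None:
        rng = np.random.default_rng(seed)
    eps = rng.standard_normal(post.mean.shape)
    return post.mean + np.exp(0.5 * post.logvar) * eps


# ======================================================================
# Layers and optimizer (hand-written backward passes)
# ======================================================================

class Dense:
    """Fully connected layer with cached forward pass and accumulated grads."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        bound = 1.0 / np.sqrt(n_in)  # uniform fan-in scaling
        self.W = rng.uniform(-bound, bound, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._x: Optional[np.ndarray] = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.gW += self._x.T @ g
        self.gb += g.sum(axis=0)
        return g @ self.W.T

    def params(self):
        yield self.W, self.gW
        yield self.b, self.gb


class ParamVector:
    """Free parameter vector (e.g. per-feature observation log-variance)."""

    def __init__(self, size: int, init: float = 0.0):
        self.v = np.full(size, float(init))
        self.gv = np.zeros(size)

    def params(self):
        yield self.v, self.gv


class MLP:
    """Stack of Dense layers with ReLU between (linear output)."""

    def __init__(self, sizes: Sequence[int], rng: np.random.Generator):
        self.layers = [
            Dense(sizes[i], sizes[i + 1], rng) for i in range(len(sizes) - 1)
        ]
        self._masks: List[np.ndarray] = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._masks = []
        for i, layer in enumerate(self.layers):
            x = layer.forward(x)
            if i < len(self.layers) - 1:
                mask = x > 0
                self._masks.append(mask)
                x = x * mask
        return x

    def backward(self, g: np.ndarray) -> np.ndarray:
        for i in range(len(self.layers) - 1, -1, -1):
            if i < len(self.layers) - 1:
                g = g * self._masks[i]
            g = self.layers[i].backward(g)
        return g

    def params(self):
        for layer in self.layers:
            yield from layer.params()


class Adam:
    """Adaptive-moment optimizer over a fixed list of (param, grad) pairs."""

    def __init__(self, param_grads, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.pairs = list(param_grads)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in self.pairs]
        self.v = [np.zeros_like(p) for p, _ in self.pairs]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for i, (p, g) in enumerate(self.pairs):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            p -= self.lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)

    def zero_grad(self) -> None:
        for _, g in self.pairs:
            g[:] = 0.0


def clip_logvar(lv: np.ndarray):
    """Clamp posterior log-variance; returns clipped values and pass mask."""
    mask = (lv > -_LOGVAR_CLIP) & (lv < _LOGVAR_CLIP)
    return np.clip(lv, -_LOGVAR_CLIP, _LOGVAR_CLIP), mask


def gaussian_nll_and_grad(x: np.ndarray, mu: np.ndarray, phi: np.ndarray):
    """Mean-per-cell Gaussian NLL with global per-feature log-variance phi.

    Returns (nll_per_cell_mean, grad_mu, grad_phi) where grads are of the
    *mean over the minibatch* of the summed-over-features NLL.
    """
    n = x.shape[0]
    inv = np.exp(-phi)
    resid = mu - x
    nll = 0.5 * np.sum(resid**2 * inv + phi + _LOG2PI) / n
    gmu = resid * inv / n
    gphi = 0.5 * np.sum(1.0 - resid**2 * inv, axis=0) / n
    return nll, gmu, gphi


# ======================================================================
# Training loop
# ======================================================================

def train(model, config: TrainingConfig) -> FittedModel:
    """Run seeded minibatch Adam on a model exposing ``n_obs`` and ``step``.

    ``model.step(idx, rng, ramp)`` must run forward+backward on the rows
    ``idx``, accumulate gradients into its parameters, and return a tuple
    ``(total, recon, kl, adv)`` of minibatch means.  The per-epoch trace
    averages these over minibatches (weighted by minibatch size).

    ``ramp`` linearly anneals the KL and adversarial weights from 0 to their
    configured values over the first half of training — the usual guard
    against posterior collapse; the configured weights are fully in force
    for the second half, so converged traces reflect them exactly.
    """
    rng = np.random.default_rng(config.seed)
    model.init_params(rng)
    opt = Adam(model.params(), lr=config.learning_rate)
    n = model.n_obs
    trace = np.zeros((config.epochs, 4))
    warmup = max(1, config.epochs // 2)
    for epoch in range(config.epochs):
        ramp = min(1.0, (epoch + 1) / warmup)
        order = rng.permutation(n)
        acc = np.zeros(4)
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            opt.zero_grad()
            parts = np.asarray(model.step(idx, rng, ramp), dtype=np.float64)
            if not np.all(np.isfinite(parts)):
                raise DivergenceError(
                    f"non-finite loss at epoch {epoch} "
                    f"(learning_rate={config.learning_rate})"
                )
            opt.step()
            acc += parts * len(idx)
        trace[epoch] = acc / n
    return FittedModel(config=config, loss_trace=trace, model=model)
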