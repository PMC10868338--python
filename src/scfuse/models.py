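"""Integration models: conditional, domain-adversarial, and multi-view VAEs.

Three fits share one variational backbone (see :mod:`scfuse.vae_engine`):

``fit_vipcca``
    Conditional variational model for *unpaired* batches.  One encoder maps
    expression to a posterior over a shared latent z; the decoder receives z
    concatenated with a one-hot batch code, so batch-specific effects are
    absorbed by the condition and z is free to encode shared biology.  The
    batch-corrected matrix decodes every cell under the reference batch code
    (the first dataset).

``fit_davae``
    Domain-adversarial variational model for *unpaired* batches.  The decoder
    sees z only; batch invariance of z is instead enforced by a domain
    classifier trained on z whose gradient is *reversed* (scaled by the
    adversarial weight) before flowing into the encoder — the classifier
    descends the domain cross-entropy while the encoder ascends it.

``fit_vimcca``
    Multi-view shared-latent model for *paired* modalities (e.g. RNA +
    protein, RNA + ATAC measured in the same cells).  The encoder consumes
    the concatenation of both views (early fusion), yielding one posterior
    per cell; two view-specific decoders reconstruct each modality.

Cells are canonicalized (sorted by batch then cell name) before training, so
the fitted parameters — and hence the returned embedding — do not depend on
the order in which cells arrive.  Outputs are returned in the caller's order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .core_data import OmicsDataset, concatenate
from .errors import PairingError, ParameterError, ValidationError
from .vae_engine import (
    Adam,
    Dense,
    FittedModel,
    MLP,
    ParamVector,
    TrainingConfig,
    VariationalPosterior,
    clip_logvar,
    gaussian_nll_and_grad,
    train,
)


@dataclass
class IntegrationResult:
    """Fitted model handle plus the embedding and batch-corrected expression."""

    latent: np.ndarray
    corrected: np.ndarray
    model: FittedModel
    batch: np.ndarray
    obs_names: pd.Index
    var_names: pd.Index


@dataclass
class LabelTransferResult:
    predicted: np.ndarray
    confidence: np.ndarray


# ======================================================================
# Model internals
# ======================================================================

class _EncoderDecoderBase:
    """Shared forward/backward pieces for the Gaussian-likelihood VAEs."""

    def __init__(self, X: np.ndarray, config: TrainingConfig):
        self.X = np.asarray(X, dtype=np.float64)
        self.config = config
        self.n_obs, self.n_features = self.X.shape

    # -------- encoder --------
    def _build_encoder(self, n_in: int, rng: np.random.Generator) -> None:
        cfg = self.config
        self.enc = MLP([n_in] + list(cfg.hidden_sizes), rng)
        self.head_mu = Dense(cfg.hidden_sizes[-1], cfg.latent_dim, rng)
        self.head_lv = Dense(cfg.hidden_sizes[-1], cfg.latent_dim, rng)

    def _encode(self, x: np.ndarray):
        h = self.enc.forward(x)
        mask = h > 0
        hr = h * mask
        mu = self.head_mu.forward(hr)
        lv, lvmask = clip_logvar(self.head_lv.forward(hr))
        return mu, lv, mask, lvmask

    def _encoder_backward(self, gmu, glv, hmask, lvmask) -> None:
        gh = self.head_mu.backward(gmu) + self.head_lv.backward(glv * lvmask)
        self.enc.backward(gh * hmask)

    def posterior(self, X: Optional[np.ndarray] = None) -> VariationalPosterior:
        mu, lv, _, _ = self._encode(self.X if X is None else X)
        return VariationalPosterior(mean=mu, logvar=lv)

    def _enc_params(self):
        yield from self.enc.params()
        yield from self.head_mu.params()
        yield from self.head_lv.params()


class VipccaModel(_EncoderDecoderBase):
    """Conditional VAE: decoder input is [z, one-hot batch]."""

    def __init__(self, X, B_onehot, config):
        super().__init__(X, config)
        self.B = np.asarray(B_onehot, dtype=np.float64)
        self.n_batches = self.B.shape[1]

    def init_params(self, rng: np.random.Generator) -> None:
        cfg = self.config
        self._build_encoder(self.n_features, rng)
        dec_sizes = [cfg.latent_dim + self.n_batches] + list(
            reversed(cfg.hidden_sizes)
        ) + [self.n_features]
        self.dec = MLP(dec_sizes, rng)
        self.phi = ParamVector(self.n_features)  # global per-feature log-variance

    def params(self):
        yield from self._enc_params()
        yield from self.dec.params()
        yield from self.phi.params()

    def step(self, idx, rng, ramp=1.0):
        cfg = self.config
        x, b = self.X[idx], self.B[idx]
        n = len(idx)
        mu, lv, hmask, lvmask = self._encode(x)
        kl = float(np.mean(0.5 * np.sum(mu**2 + np.exp(lv) - lv - 1.0, axis=1)))
        eps = rng.standard_normal(mu.shape)
        z = mu + np.exp(0.5 * lv) * eps
        out = self.dec.forward(np.hstack([z, b]))
        recon, gout, gphi = gaussian_nll_and_grad(x, out, self.phi.v)
        self.phi.gv += gphi
        gz = self.dec.backward(gout)[:, : cfg.latent_dim]
        beta = cfg.kl_weight * ramp
        gmu = gz + beta * mu / n
        glv = gz * eps * 0.5 * np.exp(0.5 * lv) + beta * 0.5 * (np.exp(lv) - 1.0) / n
        self._encoder_backward(gmu, glv, hmask, lvmask)
        return (recon + beta * kl, recon, kl, 0.0)

    def decode(self, z: np.ndarray, batch_code: int) -> np.ndarray:
        b = np.zeros((z.shape[0], self.n_batches))
        b[:, batch_code] = 1.0
        return self.dec.forward(np.hstack([z, b]))


class DavaeModel(_EncoderDecoderBase):
    """VAE with a gradient-reversed domain classifier on z.

    The classifier is a one-hidden-layer softmax net trained with its own
    optimizer for a few inner steps per minibatch (a "strong critic"), so the
    reversal direction fed to the encoder reflects an up-to-date estimate of
    where batch information lives in z.  The domain cross-entropy gradient is
    O(1) per cell while the reconstruction gradient sums over all features,
    so the reversed gradient is rescaled by ``DOMAIN_GRAD_SCALE`` to compete;
    the adversary is also held off until the latent has formed (it ramps in
    only after ``ADV_DELAY`` of the warm-up), which keeps the two-player game
    from collapsing the embedding early in training.
    """

    ADV_HIDDEN = 32
    N_CRITIC = 5
    CRITIC_LR = 1e-2
    DOMAIN_GRAD_SCALE = 30.0
    ADV_DELAY = 0.25

    def __init__(self, X, batch_idx, n_batches, config):
        super().__init__(X, config)
        self.batch_idx = np.asarray(batch_idx, dtype=np.intp)
        self.n_batches = int(n_batches)

    def init_params(self, rng: np.random.Generator) -> None:
        cfg = self.config
        self._build_encoder(self.n_features, rng)
        dec_sizes = [cfg.latent_dim] + list(reversed(cfg.hidden_sizes)) + [
            self.n_features
        ]
        self.dec = MLP(dec_sizes, rng)
        self.phi = ParamVector(self.n_features)
        self.adv = MLP([cfg.latent_dim, self.ADV_HIDDEN, self.n_batches], rng)
        self.adv_opt = Adam(self.adv.params(), lr=self.CRITIC_LR)

    def params(self):
        # the classifier descends via its own optimizer, not this list
        yield from self._enc_params()
        yield from self.dec.params()
        yield from self.phi.params()

    def _domain_ce(self, z: np.ndarray, b: np.ndarray):
        logits = self.adv.forward(z)
        logits = logits - logits.max(axis=1, keepdims=True)
        p = np.exp(logits)
        p /= p.sum(axis=1, keepdims=True)
        n = len(b)
        ce = float(-np.mean(np.log(p[np.arange(n), b] + 1e-12)))
        dlogits = p
        dlogits[np.arange(n), b] -= 1.0
        dlogits /= n
        return ce, dlogits

    def step(self, idx, rng, ramp=1.0):
        cfg = self.config
        x = self.X[idx]
        n = len(idx)
        mu, lv, hmask, lvmask = self._encode(x)
        kl = float(np.mean(0.5 * np.sum(mu**2 + np.exp(lv) - lv - 1.0, axis=1)))
        eps = rng.standard_normal(mu.shape)
        z = mu + np.exp(0.5 * lv) * eps
        b = self.batch_idx[idx]

        # classifier parameters descend the domain loss (inner critic steps)
        for _ in range(self.N_CRITIC):
            _, dlogits = self._domain_ce(z, b)
            self.adv_opt.zero_grad()
            self.adv.backward(dlogits)
            self.adv_opt.step()

        out = self.dec.forward(z)
        recon, gout, gphi = gaussian_nll_and_grad(x, out, self.phi.v)
        self.phi.gv += gphi

        ce, dlogits = self._domain_ce(z, b)
        gz_adv = self.adv.backward(dlogits)

        adv_ramp = max(0.0, (ramp - self.ADV_DELAY) / (1.0 - self.ADV_DELAY))
        lam = cfg.adversarial_weight * adv_ramp
        beta = cfg.kl_weight * ramp
        # encoder ascends the domain loss: reversed gradient, scaled by lambda
        gz = (
            self.dec.backward(gout)[:, : cfg.latent_dim]
            - lam * self.DOMAIN_GRAD_SCALE * gz_adv
        )
        gmu = gz + beta * mu / n
        glv = gz * eps * 0.5 * np.exp(0.5 * lv) + beta * 0.5 * (np.exp(lv) - 1.0) / n
        self._encoder_backward(gmu, glv, hmask, lvmask)
        return (recon + beta * kl + lam * ce, recon, kl, ce)

    def decode(self, z: np.ndarray) -> np.ndarray:
        return self.dec.forward(z)


class VimccaModel(_EncoderDecoderBase):
    """Early-fusion multi-view VAE: one posterior, two view decoders."""

    def __init__(self, X, Y, config):
        super().__init__(np.hstack([X, Y]), config)
        self.dx = X.shape[1]
        self.dy = Y.shape[1]

    def init_params(self, rng: np.random.Generator) -> None:
        cfg = self.config
        self._build_encoder(self.dx + self.dy, rng)
        rev = list(reversed(cfg.hidden_sizes))
        self.dec_x = MLP([cfg.latent_dim] + rev + [self.dx], rng)
        self.dec_y = MLP([cfg.latent_dim] + rev + [self.dy], rng)
        self.phi_x = ParamVector(self.dx)
        self.phi_y = ParamVector(self.dy)

    def params(self):
        yield from self._enc_params()
        yield from self.dec_x.params()
        yield from self.dec_y.params()
        yield from self.phi_x.params()
        yield from self.phi_y.params()

    def step(self, idx, rng, ramp=1.0):
        cfg = self.config
        xy = self.X[idx]
        x, y = xy[:, : self.dx], xy[:, self.dx :]
        n = len(idx)
        mu, lv, hmask, lvmask = self._encode(xy)
        kl = float(np.mean(0.5 * np.sum(mu**2 + np.exp(lv) - lv - 1.0, axis=1)))
        eps = rng.standard_normal(mu.shape)
        z = mu + np.exp(0.5 * lv) * eps
        out_x = self.dec_x.forward(z)
        out_y = self.dec_y.forward(z)
        rx, gx, gpx = gaussian_nll_and_grad(x, out_x, self.phi_x.v)
        ry, gy, gpy = gaussian_nll_and_grad(y, out_y, self.phi_y.v)
        self.phi_x.gv += gpx
        self.phi_y.gv += gpy
        recon = rx + ry
        gz = self.dec_x.backward(gx) + self.dec_y.backward(gy)
        beta = cfg.kl_weight * ramp
        gmu = gz + beta * mu / n
        glv = gz * eps * 0.5 * np.exp(0.5 * lv) + beta * 0.5 * (np.exp(lv) - 1.0) / n
        self._encoder_backward(gmu, glv, hmask, lvmask)
        return (recon + beta * kl, recon, kl, 0.0)

    def decode_x(self, z: np.ndarray) -> np.ndarray:
        return self.dec_x.forward(z)


# ======================================================================
# Fit entry points
# ======================================================================

def _canonical_order(batch: np.ndarray, obs_names: pd.Index) -> np.ndarray:
    """Sort cells by (batch, cell name) so training ignores input order."""
    return np.lexsort((obs_names.to_numpy(), batch))


class _Standardizer:
    """Per-feature z-scoring applied before encoding and undone after decoding.

    Centered, unit-variance inputs keep the Gaussian reconstruction term on a
    comparable scale across features and make the ReLU encoder well-behaved;
    constant features map to zero and come back unchanged.
    """

    def __init__(self, X: np.ndarray):
        self.mean = X.mean(axis=0)
        sd = X.std(axis=0)
        self.sd = np.where(sd > 0, sd, 1.0)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.sd

    def inverse(self, Z: np.ndarray) -> np.ndarray:
        return Z * self.sd + self.mean


def _check_unpaired_inputs(ds_list: Sequence[OmicsDataset]) -> None:
    if len(ds_list) < 2:
        raise ParameterError("integration requires at least 2 datasets")
    for d in ds_list:
        if d.layer_state != "lognorm":
            raise ValidationError(
                "integration expects log-normalized input; run normalize_log first"
            )


def fit_vipcca(
    ds_list: Sequence[OmicsDataset], config: Optional[TrainingConfig] = None
) -> IntegrationResult:
    """Fit the conditional variational model on unpaired batches.

    Returns the posterior-mean embedding and a batch-corrected matrix in
    which every cell is decoded under the first dataset's batch code.
    """
    config = config or TrainingConfig()
    _check_unpaired_inputs(ds_list)
    merged = concatenate(ds_list)
    codes, levels = pd.factorize(merged.batch, sort=True)
    order = _canonical_order(merged.batch, merged.obs_names)
    inv = np.argsort(order)
    B = np.eye(len(levels))[codes[order]]
    std = _Standardizer(merged.counts)
    model = VipccaModel(std.transform(merged.counts)[order], B, config)
    fitted = train(model, config)
    post = model.posterior()
    # reference batch for the corrected output = the first dataset's code
    ref_code = int(np.where(levels == merged.batch[0])[0][0])
    corrected = std.inverse(model.decode(post.mean, batch_code=ref_code))
    return IntegrationResult(
        latent=post.mean[inv],
        corrected=corrected[inv],
        model=fitted,
        batch=merged.batch,
        obs_names=merged.obs_names,
        var_names=merged.var_names,
    )


def fit_davae(
    ds_list: Sequence[OmicsDataset], config: Optional[TrainingConfig] = None
) -> IntegrationResult:
    """Fit the domain-adversarial variational model on unpaired batches."""
    config = config or TrainingConfig()
    _check_unpaired_inputs(ds_list)
    merged = concatenate(ds_list)
    codes, levels = pd.factorize(merged.batch, sort=True)
    order = _canonical_order(merged.batch, merged.obs_names)
    inv = np.argsort(order)
    std = _Standardizer(merged.counts)
    model = DavaeModel(
        std.transform(merged.counts)[order], codes[order], len(levels), config
    )
    fitted = train(model, config)
    post = model.posterior()
    corrected = std.inverse(model.decode(post.mean))
    return IntegrationResult(
        latent=post.mean[inv],
        corrected=corrected[inv],
        model=fitted,
        batch=merged.batch,
        obs_names=merged.obs_names,
        var_names=merged.var_names,
    )


def fit_vimcca(
    ds_x: OmicsDataset,
    ds_y: OmicsDataset,
    config: Optional[TrainingConfig] = None,
) -> IntegrationResult:
    """Fit the multi-view shared-latent model on paired modalities.

    Both views must carry the same cells in the same order; the returned
    ``corrected`` matrix is the decoded view-x reconstruction.
    """
    config = config or TrainingConfig()
    if ds_x.n_obs != ds_y.n_obs:
        raise PairingError(
            f"views have {ds_x.n_obs} and {ds_y.n_obs} cells; pairing impossible"
        )
    neq = np.nonzero(
        ds_x.obs_names.to_numpy() != ds_y.obs_names.to_numpy()
    )[0]
    if len(neq):
        i = int(neq[0])
        raise PairingError(
            f"cell name mismatch at position {i}: "
            f"{ds_x.obs_names[i]!r} vs {ds_y.obs_names[i]!r}"
        )
    for d in (ds_x, ds_y):
        if d.layer_state != "lognorm":
            raise ValidationError(
                "integration expects log-normalized input; run normalize_log first"
            )
    order = np.argsort(ds_x.obs_names.to_numpy(), kind="stable")
    inv = np.argsort(order)
    std_x = _Standardizer(ds_x.counts)
    std_y = _Standardizer(ds_y.counts)
    model = VimccaModel(
        std_x.transform(ds_x.counts)[order],
        std_y.transform(ds_y.counts)[order],
        config,
    )
    fitted = train(model, config)
    post = model.posterior()
    corrected = std_x.inverse(model.decode_x(post.mean))
    return IntegrationResult(
        latent=post.mean[inv],
        corrected=corrected[inv],
        model=fitted,
        batch=ds_x.batch,
        obs_names=ds_x.obs_names,
        var_names=ds_x.var_names,
    )


# ======================================================================
# Label transfer
# ======================================================================

def transfer_labels(
    ref_latent: np.ndarray,
    ref_labels,
    query_latent: np.ndarray,
    k_neighbors: int = 15,
) -> LabelTransferResult:
    """Majority vote among the Euclidean k nearest reference cells.

    Ties are broken by the smaller mean distance to the tied label's
    neighbors, then lexicographically.  ``confidence`` is the winning vote
    fraction.
    """
    ref_latent = np.asarray(ref_latent, dtype=np.float64)
    query_latent = np.asarray(query_latent, dtype=np.float64)
    ref_labels = np.asarray(ref_labels, dtype=object).astype(str)
    if ref_latent.shape[1] != query_latent.shape[1]:
        raise ValidationError(
            f"latent dimensions differ: {ref_latent.shape[1]} vs "
            f"{query_latent.shape[1]}"
        )
    if len(ref_labels) != ref_latent.shape[0]:
        raise ValidationError("ref_labels length must equal reference cell count")
    if k_neighbors <= 0 or k_neighbors > ref_latent.shape[0]:
        raise ParameterError(
            f"k_neighbors={k_neighbors} out of range for {ref_latent.shape[0]} "
            "reference cells"
        )
    nn = NearestNeighbors(n_neighbors=k_neighbors).fit(ref_latent)
    dist, idx = nn.kneighbors(query_latent)
    predicted = np.empty(query_latent.shape[0], dtype=object)
    confidence = np.empty(query_latent.shape[0])
    for i in range(query_latent.shape[0]):
        labs = ref_labels[idx[i]]
        uniq, counts = np.unique(labs, return_counts=True)
        top = counts.max()
        winners = uniq[counts == top]
        if len(winners) > 1:
            means = np.array(
                [dist[i][labs == w].mean() for w in winners]
            )
            winners = winners[means == means.min()]
            best = sorted(winners)[0]
        else:
            best = winners[0]
        predicted[i] = best
        confidence[i] = top / k_neighbors
    return LabelTransferResult(
        predicted=predicted.astype(str), confidence=confidence
    )
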