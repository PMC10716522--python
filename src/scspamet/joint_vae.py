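"""Dual-encoder joint protein-metabolite variational autoencoder.

Two encoder-decoder networks — a small one for the protein block and a
deeper one for the wider metabolite block — share a single latent space:
the per-modality encoder outputs (8-d each) are concatenated and passed
through a joint dense layer, from which the heads f_mu and f_sigma produce
the 16-d Gaussian latent parameters.  Training minimises the negative ELBO

    L = MSE_p + MSE_m + beta * KL( N(mu, sigma) || N(0, I) )

with the reparameterisation trick z = mu + sigma * eps.  Reconstruction is
Gaussian (mean squared error on z-scored inputs, summed over features,
averaged over the batch); the KL term has the diagonal-Gaussian closed form
sum 1/2 (mu^2 + sigma^2 - log sigma^2 - 1).

The implementation is plain numpy with hand-written backpropagation and an
Adam optimiser: the networks are tiny, run comfortably on one CPU core at
single-cell scale, and the explicit forward/backward passes make the ELBO
directly checkable against hand computations.  All randomness (weight
initialisation, minibatch shuffling, reparameterisation noise) is seeded,
so training is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from ._graph import knn_leiden
from .io_formats import CellTable

__all__ = [
    "VAEConfig",
    "JointVAEModel",
    "TrainHistory",
    "build_model",
    "elbo_loss",
    "train_vae",
    "embed_cells",
    "cluster_embedding",
]


@dataclass
class VAEConfig:
    protein_dim: int = 21
    metab_dim: int = 200
    protein_encoder_sizes: tuple = (16, 8)
    metab_encoder_sizes: tuple = (128, 64, 32)
    per_modality_latent: int = 8
    joint_dense: int = 16
    latent_dim: int = 16
    protein_decoder_sizes: tuple = (16,)
    metab_decoder_sizes: tuple = (64, 128)
    kl_weight: float = 1.0
    lr: float = 1e-3
    epochs: int = 100
    batch_size: int = 256
    seed: int = 0

    def __post_init__(self) -> None:
        if self.protein_dim <= 0 or self.metab_dim <= 0:
            raise ValueError("modality dimensions must be positive")
        if self.latent_dim != self.joint_dense:
            raise ValueError("latent_dim must equal the joint dense size")


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


class _MLP:
    """Fully connected stack; ReLU hidden layers, optional final activation."""

    def __init__(self, dims: Sequence[int], rng: np.random.Generator, final_relu: bool):
        self.dims = list(dims)
        self.final_relu = final_relu
        self.W = [
            rng.normal(0.0, np.sqrt(2.0 / dims[i]), size=(dims[i], dims[i + 1]))
            for i in range(len(dims) - 1)
        ]
        self.b = [np.zeros(dims[i + 1]) for i in range(len(dims) - 1)]
        self.gW = [np.zeros_like(w) for w in self.W]
        self.gb = [np.zeros_like(b) for b in self.b]

    def _active(self, layer: int) -> bool:
        return layer < len(self.W) - 1 or self.final_relu

    def forward(self, x: np.ndarray):
        acts, pres = [x], []
        a = x
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            z = a @ W + b
            pres.append(z)
            a = _relu(z) if self._active(i) else z
            acts.append(a)
        return a, (acts, pres)

    def backward(self, grad: np.ndarray, cache) -> np.ndarray:
        acts, pres = cache
        for i in reversed(range(len(self.W))):
            if self._active(i):
                grad = grad * (pres[i] > 0)
            self.gW[i] += acts[i].T @ grad
            self.gb[i] += grad.sum(axis=0)
            grad = grad @ self.W[i].T
        return grad

    def zero_grad(self) -> None:
        for g in self.gW:
            g[:] = 0.0
        for g in self.gb:
            g[:] = 0.0

    def params_and_grads(self):
        yield from zip(self.W, self.gW)
        yield from zip(self.b, self.gb)

    @property
    def n_parameters(self) -> int:
        return sum(w.size for w in self.W) + sum(b.size for b in self.b)


@dataclass
class TrainHistory:
    total: list = field(default_factory=list)
    recon_protein: list = field(default_factory=list)
    recon_metab: list = field(default_factory=list)
    kl: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.total)


class JointVAEModel:
    """Weights and forward pass of the dual-encoder VAE."""

    def __init__(self, config: VAEConfig, seed: Optional[int] = None):
        self.config = config
        rng = np.random.default_rng(config.seed if seed is None else seed)
        c = config
        self.enc_p = _MLP(
            [c.protein_dim, *c.protein_encoder_sizes], rng, final_relu=True
        )
        self.enc_m = _MLP(
            [c.metab_dim, *c.metab_encoder_sizes, c.per_modality_latent], rng, final_relu=True
        )
        if self.enc_p.dims[-1] != c.per_modality_latent:
            raise ValueError("protein encoder must end at the per-modality latent size")
        self.joint = _MLP([2 * c.per_modality_latent, c.joint_dense], rng, final_relu=True)
        self.f_mu = _MLP([c.joint_dense, c.latent_dim], rng, final_relu=False)
        self.f_logvar = _MLP([c.joint_dense, c.latent_dim], rng, final_relu=False)
        self.dec_p = _MLP(
            [c.latent_dim, *c.protein_decoder_sizes, c.protein_dim], rng, final_relu=False
        )
        self.dec_m = _MLP(
            [c.latent_dim, *c.metab_decoder_sizes, c.metab_dim], rng, final_relu=False
        )
        # z-score scalers, set by train_vae
        self.protein_channels: Optional[list] = None
        self.metab_channels: Optional[list] = None
        self.scaler_mean_p = np.zeros(c.protein_dim)
        self.scaler_sd_p = np.ones(c.protein_dim)
        self.scaler_mean_m = np.zeros(c.metab_dim)
        self.scaler_sd_m = np.ones(c.metab_dim)

    @property
    def _parts(self):
        return (self.enc_p, self.enc_m, self.joint, self.f_mu, self.f_logvar,
                self.dec_p, self.dec_m)

    @property
    def n_parameters(self) -> int:
        return sum(p.n_parameters for p in self._parts)

    def forward(self, x_p: np.ndarray, x_m: np.ndarray,
                eps: Optional[np.ndarray] = None, sample: bool = True):
        """Full forward pass; ``eps`` is the reparameterisation noise (zeros
        or ``sample=False`` give the deterministic mean path)."""
        e_p, c_ep = self.enc_p.forward(x_p)
        e_m, c_em = self.enc_m.forward(x_m)
        e = np.concatenate([e_p, e_m], axis=1)
        h, c_j = self.joint.forward(e)
        mu, c_mu = self.f_mu.forward(h)
        logvar, c_lv = self.f_logvar.forward(h)
        logvar = np.clip(logvar, -15.0, 15.0)
        sigma = np.exp(0.5 * logvar)
        if not sample:
            eps = np.zeros_like(mu)
        elif eps is None:
            raise ValueError("eps must be supplied when sample=True")
        z = mu + sigma * eps
        r_p, c_dp = self.dec_p.forward(z)
        r_m, c_dm = self.dec_m.forward(z)
        caches = dict(ep=c_ep, em=c_em, j=c_j, mu=c_mu, lv=c_lv, dp=c_dp, dm=c_dm)
        return dict(mu=mu, logvar=logvar, sigma=sigma, z=z, eps=eps,
                    recon_p=r_p, recon_m=r_m, caches=caches)

    def zero_grad(self) -> None:
        for p in self._parts:
            p.zero_grad()

    def params_and_grads(self):
        for p in self._parts:
            yield from p.params_and_grads()


def build_model(config: VAEConfig, seed: Optional[int] = None) -> JointVAEModel:
    """Seeded weight initialisation (He-scaled normal, zero biases)."""
    return JointVAEModel(config, seed=seed)


def _loss_terms(out, x_p, x_m, beta: float):
    B = x_p.shape[0]
    recon_p = float(np.sum((out["recon_p"] - x_p) ** 2) / B)
    recon_m = float(np.sum((out["recon_m"] - x_m) ** 2) / B)
    mu, sigma, logvar = out["mu"], out["sigma"], out["logvar"]
    kl = float(np.sum(0.5 * (mu ** 2 + sigma ** 2 - logvar - 1.0)) / B)
    total = recon_p + recon_m + beta * kl
    for name, v in (("recon_protein", recon_p), ("recon_metab", recon_m),
                    ("kl", kl), ("total", total)):
        if not np.isfinite(v):
            raise FloatingPointError(f"non-finite {name} term in ELBO")
    return total, recon_p, recon_m, kl


def elbo_loss(x_p: np.ndarray, x_m: np.ndarray, model: JointVAEModel,
              eps_sample: np.ndarray):
    """(total, recon_p, recon_m, kl) for one batch; total is the negative
    ELBO up to additive constants, the quantity minimised in training."""
    x_p = np.atleast_2d(np.asarray(x_p, dtype=float))
    x_m = np.atleast_2d(np.asarray(x_m, dtype=float))
    eps = np.atleast_2d(np.asarray(eps_sample, dtype=float))
    out = model.forward(x_p, x_m, eps=eps)
    return _loss_terms(out, x_p, x_m, model.config.kl_weight)


def _backward(model: JointVAEModel, out, x_p, x_m) -> None:
    B = x_p.shape[0]
    beta = model.config.kl_weight
    caches = out["caches"]
    d_rp = 2.0 * (out["recon_p"] - x_p) / B
    d_rm = 2.0 * (out["recon_m"] - x_m) / B
    dz = model.dec_p.backward(d_rp, caches["dp"]) + model.dec_m.backward(d_rm, caches["dm"])
    mu, sigma, eps = out["mu"], out["sigma"], out["eps"]
    dmu = dz + beta * mu / B
    dlv = dz * eps * sigma * 0.5 + beta * 0.5 * (sigma ** 2 - 1.0) / B
    dh = model.f_mu.backward(dmu, caches["mu"]) + model.f_logvar.backward(dlv, caches["lv"])
    de = model.joint.backward(dh, caches["j"])
    m = model.config.per_modality_latent
    model.enc_p.backward(de[:, :m], caches["ep"])
    model.enc_m.backward(de[:, m:], caches["em"])


class _Adam:
    def __init__(self, lr: float):
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.state: dict = {}

    def step(self, params_and_grads) -> None:
        self.t += 1
        for i, (p, g) in enumerate(params_and_grads):
            if i not in self.state:
                self.state[i] = (np.zeros_like(p), np.zeros_like(p))
            m, v = self.state[i]
            m[:] = self.b1 * m + (1 - self.b1) * g
            v[:] = self.b2 * v + (1 - self.b2) * g ** 2
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _zscore_fit(X: np.ndarray):
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return mean, sd


def train_vae(
    table: CellTable,
    protein_channels: Sequence[str],
    metab_channels: Sequence[str],
    config: Optional[VAEConfig] = None,
) -> tuple[JointVAEModel, TrainHistory]:
    """Minibatch Adam training on z-scored per-cell features.

    Deterministic given ``config.seed`` (shuffling, noise and init all draw
    from one generator).  Raises if the loss diverges to NaN, advising a
    lower learning rate.
    """
    if config is None:
        config = VAEConfig(protein_dim=len(protein_channels), metab_dim=len(metab_channels))
    if config.protein_dim != len(protein_channels) or config.metab_dim != len(metab_channels):
        raise ValueError("config dimensions do not match the channel lists")
    n = len(table)
    if n < config.batch_size:
        config = VAEConfig(**{**config.__dict__, "batch_size": n})
    Xp = table.channel_matrix(protein_channels)
    Xm = table.channel_matrix(metab_channels)
    mp, sp = _zscore_fit(Xp)
    mm, sm = _zscore_fit(Xm)
    Xp = (Xp - mp) / sp
    Xm = (Xm - mm) / sm

    rng = np.random.default_rng(config.seed)
    model = build_model(config, seed=int(rng.integers(2 ** 31)))
    model.protein_channels = list(protein_channels)
    model.metab_channels = list(metab_channels)
    model.scaler_mean_p, model.scaler_sd_p = mp, sp
    model.scaler_mean_m, model.scaler_sd_m = mm, sm

    opt = _Adam(config.lr)
    history = TrainHistory()
    for _ in range(config.epochs):
        order = rng.permutation(n)
        ep = np.zeros(4)
        n_batches = 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb_p, xb_m = Xp[idx], Xm[idx]
            eps = rng.standard_normal((len(idx), config.latent_dim))
            out = model.forward(xb_p, xb_m, eps=eps)
            try:
                terms = _loss_terms(out, xb_p, xb_m, config.kl_weight)
            except FloatingPointError as exc:
                raise FloatingPointError(
                    f"training diverged ({exc}); try a lower learning rate"
                ) from exc
            model.zero_grad()
            _backward(model, out, xb_p, xb_m)
            opt.step(model.params_and_grads())
            ep += np.asarray(terms)
            n_batches += 1
        ep /= n_batches
        history.total.append(ep[0])
        history.recon_protein.append(ep[1])
        history.recon_metab.append(ep[2])
        history.kl.append(ep[3])
    return model, history


def embed_cells(model: JointVAEModel, table: CellTable) -> np.ndarray:
    """Deterministic per-cell latent mean mu (no sampling)."""
    if model.protein_channels is None or model.metab_channels is None:
        raise ValueError("model has no channel lists; train it first")
    Xp = table.channel_matrix(model.protein_channels)
    Xm = table.channel_matrix(model.metab_channels)
    if Xp.shape[1] != model.config.protein_dim or Xm.shape[1] != model.config.metab_dim:
        raise ValueError("channel mismatch between model and table")
    Xp = (Xp - model.scaler_mean_p) / model.scaler_sd_p
    Xm = (Xm - model.scaler_mean_m) / model.scaler_sd_m
    out = model.forward(Xp, Xm, sample=False)
    return out["mu"]


def cluster_embedding(latents: np.ndarray, resolution: float = 1.0, seed: int = 0,
                      k: int = 15) -> np.ndarray:
    """Leiden clustering of the latent space (same contract as cell
    clustering on raw features)."""
    return knn_leiden(np.asarray(latents, dtype=float), k=k, resolution=resolution, seed=seed)
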