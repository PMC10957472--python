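"""Variational convolutional mesh autoencoder.

Encoder: per level, a Chebyshev graph convolution + ReLU followed by QEM
pooling; a dense layer then maps the coarsest features to the latent mean
``mu`` and log-variance. Decoder mirrors the encoder with barycentric
unpooling; the final convolution outputs the 3 coordinate channels with no
nonlinearity. During training the latent is sampled by reparameterization
(z = mu + sigma * eps) and a KL term pulls the per-subject posterior towards
N(0, I); at inference the latent representation is ``mu`` itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from ..mesh_core import TriangleMesh, graph_laplacian
from .sampling import SamplingOperators, build_sampling_operators
from .layers import ChebConv, Dense, Pool, ReLU


@dataclass
class ComaConfig:
    n_z: int = 8
    cheb_order: int = 6
    channels: tuple = (16, 16, 32)
    downsample_factors: tuple = (4, 4, 4)
    w_kl: float = 1e-3
    recon_loss: str = "L1"            # one of L1, L2, MSE
    learning_rate: float = 1e-3
    epochs: int = 100
    batch_size: int = 32
    seed_weights: int = 0
    seed_split: int = 0
    split_fractions: tuple = (0.8, 0.1, 0.1)
    laplacian_mode: str = "sym-normalized-scaled"

    def __post_init__(self):
        if self.w_kl < 0:
            raise ValueError("w_kl must be >= 0")
        if self.cheb_order < 1:
            raise ValueError("cheb_order must be >= 1")
        if len(self.channels) != len(self.downsample_factors):
            raise ValueError("channels and downsample_factors must have equal length")
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if self.recon_loss not in ("L1", "L2", "MSE"):
            raise ValueError("recon_loss must be one of L1, L2, MSE")

    def to_dict(self) -> dict:
        return asdict(self)


class ComaModel:
    """Holds sampling operators, layers and the per-coordinate standardizer."""

    def __init__(self, template: TriangleMesh, config: ComaConfig,
                 ops: SamplingOperators | None = None):
        self.config = config
        self.ops = ops or build_sampling_operators(template, list(config.downsample_factors))
        self.laplacians = [
            graph_laplacian(m, config.laplacian_mode).laplacian
            for m in self.ops.level_meshes
        ]
        rng = np.random.default_rng(config.seed_weights)
        k = config.cheb_order
        chans = list(config.channels)
        m_coarse = self.ops.level_meshes[-1].n_vertices
        self._coarse_dim = m_coarse * chans[-1]

        # encoder: conv -> relu -> pool per level
        self.enc_layers = []
        f_in = 3
        for level, f_out in enumerate(chans):
            self.enc_layers.append(ChebConv(self.laplacians[level], f_in, f_out, k, rng))
            self.enc_layers.append(ReLU())
            self.enc_layers.append(Pool(self.ops.down_maps[level]))
            f_in = f_out
        self.fc_mu = Dense(self._coarse_dim, config.n_z, rng)
        self.fc_logvar = Dense(self._coarse_dim, config.n_z, rng)

        # decoder: dense -> per level (unpool -> conv -> relu), last conv to 3
        self.fc_dec = Dense(config.n_z, self._coarse_dim, rng)
        self.dec_layers = []
        dec_out = chans[:-1][::-1] + [3]   # channels after each decoder conv
        f_in = chans[-1]
        for level in range(len(chans) - 1, -1, -1):
            f_out = dec_out[len(chans) - 1 - level]
            self.dec_layers.append(Pool(self.ops.up_maps[level]))
            self.dec_layers.append(ChebConv(self.laplacians[level], f_in, f_out, k, rng))
            if level != 0:
                self.dec_layers.append(ReLU())
            f_in = f_out

        # standardizer, set by the trainer from the train split
        self.x_mean = np.zeros((self.ops.level_meshes[0].n_vertices, 3))
        self.x_std = np.ones((self.ops.level_meshes[0].n_vertices, 3))

    # -- standardization ---------------------------------------------------

    def set_standardizer(self, train_shapes: np.ndarray) -> None:
        self.x_mean = train_shapes.mean(axis=0)
        std = train_shapes.std(axis=0)
        self.x_std = np.where(std < 1e-8, 1.0, std)

    def standardize(self, shapes: np.ndarray) -> np.ndarray:
        return (shapes - self.x_mean) / self.x_std

    def unstandardize(self, shapes: np.ndarray) -> np.ndarray:
        return shapes * self.x_std + self.x_mean

    # -- forward / backward ------------------------------------------------

    def encode(self, x_std: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """x_std: (B, M, 3) standardized coordinates -> (mu, logvar)."""
        h = x_std
        for layer in self.enc_layers:
            h = layer.forward(h)
        self._enc_flat_shape = h.shape
        hf = h.reshape(h.shape[0], -1)
        return self.fc_mu.forward(hf), self.fc_logvar.forward(hf)

    def decode(self, z: np.ndarray) -> np.ndarray:
        h = self.fc_dec.forward(z)
        h = h.reshape(z.shape[0], self.ops.level_meshes[-1].n_vertices, -1)
        for layer in self.dec_layers:
            h = layer.forward(h)
        return h

    def backward(self, d_xhat: np.ndarray, d_mu: np.ndarray, d_logvar: np.ndarray,
                 eps: np.ndarray, sigma: np.ndarray) -> None:
        """Backprop given gradients wrt the decoder output and the KL pulls.

        ``eps`` and ``sigma`` are the reparameterization draws used in the
        forward pass (z = mu + sigma * eps).
        """
        h = d_xhat
        for layer in reversed(self.dec_layers):
            h = layer.backward(h)
        dz = self.fc_dec.backward(h.reshape(h.shape[0], -1))
        # z = mu + exp(0.5 logvar) * eps
        d_mu_total = dz + d_mu
        d_logvar_total = 0.5 * dz * eps * sigma + d_logvar
        dhf = self.fc_mu.backward(d_mu_total) + self.fc_logvar.backward(d_logvar_total)
        h = dhf.reshape(self._enc_flat_shape)
        for layer in reversed(self.enc_layers):
            h = layer.backward(h)

    def all_layers(self):
        return self.enc_layers + [self.fc_mu, self.fc_logvar, self.fc_dec] + self.dec_layers
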