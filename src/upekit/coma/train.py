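"""Training, latent extraction and reconstruction-error evaluation.

A *run* is one trained autoencoder, identified by its hyperparameters and the
two seeds controlling weight initialization and the train/val/test split.
Runs whose mean test-set reconstruction RMSD is below 1 mm are later eligible
for the phenotype ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..mesh_core import ShapeCohort, TriangleMesh
from .model import ComaConfig, ComaModel
from .layers import Adam
from .sampling import SamplingOperators


def kl_term(mu: np.ndarray, sigma: np.ndarray) -> float:
    """Per-subject KL divergence from N(0, I), averaged over latent dims.

    Returns -(1/(2 n_z)) * sum_j (log sigma_j^2 - sigma_j^2 - mu_j^2 + 1),
    i.e. the mean over dimensions of KL(N(mu_j, sigma_j^2) || N(0, 1)).
    Non-negative; zero iff mu = 0 and sigma = 1.
    """
    mu = np.asarray(mu, float)
    sigma = np.asarray(sigma, float)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be positive")
    n_z = mu.size
    return float(-(1.0 / (2.0 * n_z)) * np.sum(np.log(sigma**2) - sigma**2 - mu**2 + 1.0))


@dataclass
class RunResult:
    run_id: str
    config: ComaConfig
    subject_ids: list[str]
    latents: np.ndarray               # (N, n_z) posterior means
    per_subject_rmsd: np.ndarray      # (N,) mm
    test_rmsd_mean: float             # mm, over the held-out test split
    split: dict = field(default_factory=dict)     # train/val/test index arrays
    history: list = field(default_factory=list)   # per-epoch train loss


def reconstruction_rmsd(original: ShapeCohort, reconstructed: ShapeCohort) -> np.ndarray:
    """Per-subject RMSD (mm): sqrt(mean over vertices of squared distance)."""
    if original.shapes.shape != reconstructed.shapes.shape:
        raise ValueError("cohorts must have identical shape arrays")
    d2 = np.sum((original.shapes - reconstructed.shapes) ** 2, axis=2)
    return np.sqrt(d2.mean(axis=1))


def _split_indices(n: int, fractions, seed: int) -> dict:
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    return {
        "train": np.sort(perm[:n_train]),
        "val": np.sort(perm[n_train : n_train + n_val]),
        "test": np.sort(perm[n_train + n_val :]),
    }


def _recon_loss_and_grad(xhat: np.ndarray, x: np.ndarray, kind: str):
    diff = xhat - x
    n = diff.size
    if kind == "L1":
        return float(np.abs(diff).mean()), np.sign(diff) / n
    if kind == "MSE":
        return float((diff**2).mean()), 2.0 * diff / n
    # L2: mean over subjects of the per-subject RMS deviation
    b = diff.shape[0]
    per = np.sqrt((diff.reshape(b, -1) ** 2).mean(axis=1))
    denom = np.maximum(per, 1e-12).reshape(b, 1, 1) * diff[0].size
    return float(per.mean()), diff / (b * denom)


def train_coma(
    cohort: ShapeCohort,
    config: ComaConfig,
    ops: SamplingOperators | None = None,
    run_id: str | None = None,
) -> tuple[ComaModel, RunResult]:
    """Train one autoencoder run and return latents/RMSD for ALL subjects.

    Deterministic given (seed_weights, seed_split); the template for the
    sampling hierarchy is the cohort mean shape unless ``ops`` is supplied.
    """
    if not cohort.aligned:
        raise ValueError("cohort must be Procrustes-aligned before training")
    n = cohort.n_subjects
    split = _split_indices(n, config.split_fractions, config.seed_split)
    if any(v.size == 0 for v in split.values()):
        raise ValueError("empty train/val/test split; cohort too small")

    template = cohort.template_mesh()
    model = ComaModel(template, config, ops=ops)
    model.set_standardizer(cohort.shapes[split["train"]])

    x_all = model.standardize(cohort.shapes)
    x_train = x_all[split["train"]]
    rng = np.random.default_rng(config.seed_weights + 1)
    opt = Adam(model.all_layers(), lr=config.learning_rate)
    n_z = config.n_z
    history = []

    for _ in range(config.epochs):
        order = rng.permutation(x_train.shape[0])
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, order.size, config.batch_size):
            xb = x_train[order[start : start + config.batch_size]]
            b = xb.shape[0]
            mu, logvar = model.encode(xb)
            logvar = np.clip(logvar, -10.0, 10.0)
            sigma = np.exp(0.5 * logvar)
            eps = rng.standard_normal(mu.shape)
            z = mu + sigma * eps
            xhat = model.decode(z)
            l_rec, d_xhat = _recon_loss_and_grad(xhat, xb, config.recon_loss)
            omega = float(
                -(1.0 / (2.0 * n_z))
                * np.mean(np.sum(logvar - sigma**2 - mu**2 + 1.0, axis=1))
            )
            loss = l_rec + config.w_kl * omega
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {len(history)}: rec={l_rec}, kl={omega}"
                )
            d_mu = config.w_kl * mu / (n_z * b)
            d_logvar = config.w_kl * (-(1.0 - sigma**2)) / (2.0 * n_z * b)
            model.backward(d_xhat, d_mu, d_logvar, eps, sigma)
            opt.step()
            epoch_loss += loss
            n_batches += 1
        history.append(epoch_loss / max(n_batches, 1))

    latents, recon = _encode_and_reconstruct(model, x_all)
    recon_mm = model.unstandardize(recon)
    rmsd = np.sqrt(np.sum((cohort.shapes - recon_mm) ** 2, axis=2).mean(axis=1))
    result = RunResult(
        run_id=run_id or f"coma_w{config.seed_weights}_s{config.seed_split}",
        config=config,
        subject_ids=list(cohort.subject_ids),
        latents=latents,
        per_subject_rmsd=rmsd,
        test_rmsd_mean=float(rmsd[split["test"]].mean()),
        split={k: v.tolist() for k, v in split.items()},
        history=history,
    )
    return model, result


def _encode_and_reconstruct(model: ComaModel, x_std: np.ndarray, batch: int = 256):
    mus, recons = [], []
    for start in range(0, x_std.shape[0], batch):
        xb = x_std[start : start + batch]
        mu, _ = model.encode(xb)
        mus.append(mu)
        recons.append(model.decode(mu))
    return np.concatenate(mus), np.concatenate(recons)


def encode_cohort(model: ComaModel, cohort: ShapeCohort) -> np.ndarray:
    """Posterior means mu(S) for every subject (no sampling at inference)."""
    if not cohort.aligned:
        raise ValueError("cohort must be aligned")
    x = model.standardize(cohort.shapes)
    mus = []
    for start in range(0, x.shape[0], 256):
        mu, _ = model.encode(x[start : start + 256])
        mus.append(mu)
    return np.concatenate(mus)


def reconstruct_cohort(model: ComaModel, cohort: ShapeCohort) -> ShapeCohort:
    """decode(encode(.)) round trip, back in millimetres."""
    x = model.standardize(cohort.shapes)
    _, recon = _encode_and_reconstruct(model, x)
    return ShapeCohort(
        list(cohort.subject_ids),
        model.unstandardize(recon),
        cohort.template_faces,
        aligned=cohort.aligned,
    )
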