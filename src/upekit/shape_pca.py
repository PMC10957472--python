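"""Linear shape-PCA baseline on vectorized, Procrustes-aligned shapes.

The model is the classical statistical shape model: the mean shape ``s_bar``
plus the top right-singular vectors of the centred (N, 3M) data matrix, with
eigenvalues ``sigma_i^2 / (N - 1)`` (the covariance uses the N-1 divisor).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mesh_core import ShapeCohort


@dataclass
class PcaModel:
    mean_shape: np.ndarray        # (3M,)
    components: np.ndarray        # (n_z, 3M), orthonormal rows
    eigenvalues: np.ndarray       # (n_z,), non-increasing
    total_variance: float         # trace of the full covariance

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    def explained_variance_ratio(self) -> np.ndarray:
        return self.eigenvalues / self.total_variance


def fit_shape_pca(cohort: ShapeCohort, n_components: int = 16) -> PcaModel:
    """Fit shape PCA by SVD of the centred data matrix.

    The component sign is fixed so that the largest-|loading| entry of each
    component is positive, making downstream GWAS effect signs reproducible.
    """
    if not cohort.aligned:
        raise ValueError("cohort must be Procrustes-aligned before PCA")
    n = cohort.n_subjects
    if n < 2:
        raise ValueError("shape PCA needs at least 2 subjects")
    x = cohort.vectorized()
    max_rank = min(n - 1, x.shape[1])
    if not 1 <= n_components <= max_rank:
        raise ValueError(f"n_components must be in [1, {max_rank}]")
    mean = x.mean(axis=0)
    xc = x - mean
    # full_matrices=False keeps this O(N^2 * 3M) for tall-skinny cohorts
    _, s, vt = np.linalg.svd(xc, full_matrices=False)
    comps = vt[:n_components]
    eig = (s[:n_components] ** 2) / (n - 1)
    # deterministic sign convention
    idx = np.argmax(np.abs(comps), axis=1)
    signs = np.sign(comps[np.arange(n_components), idx])
    signs[signs == 0] = 1.0
    comps = comps * signs[:, None]
    total_var = float((s ** 2).sum() / (n - 1))
    return PcaModel(mean, comps, eig, total_var)


def pca_encode(model: PcaModel, shapes: np.ndarray) -> np.ndarray:
    """Project vectorized shape(s) onto the components: z = V (s - s_bar)."""
    shapes = np.atleast_2d(np.asarray(shapes, float))
    if shapes.shape[1] != model.mean_shape.size:
        raise ValueError("shape vector length does not match the model")
    z = (shapes - model.mean_shape) @ model.components.T
    return z[0] if z.shape[0] == 1 else z


def pca_decode(model: PcaModel, latents: np.ndarray) -> np.ndarray:
    """Reconstruct: s_hat = s_bar + V^T z."""
    latents = np.atleast_2d(np.asarray(latents, float))
    if latents.shape[1] != model.n_components:
        raise ValueError("latent vector length does not match the model")
    s = model.mean_shape + latents @ model.components
    return s[0] if s.shape[0] == 1 else s


def encode_cohort_pca(model: PcaModel, cohort: ShapeCohort) -> np.ndarray:
    """Latent matrix (N, n_z) for every subject of an aligned cohort."""
    if not cohort.aligned:
        raise ValueError("cohort must be aligned")
    return np.atleast_2d(pca_encode(model, cohort.vectorized()))

def pca_mode_sweep(
    model: PcaModel,
    component: int,
    k_values=(-3.0, -1.5, 0.0, 1.5, 3.0),
) -> np.ndarray:
    """Shapes at s_bar + k * sqrt(lambda_i) * v_i for each k (figure support)."""
    if not 0 <= component < model.n_components:
        raise IndexError(f"component {component} out of range")
    sd = np.sqrt(model.eigenvalues[component])
    return np.stack(
        [model.mean_shape + k * sd * model.components[component] for k in k_values]
    )


def latent_quantile_meshes(
    shapes_vec: np.ndarray, latents: np.ndarray, bins=((0.0, 0.01), (0.095, 0.105), (0.495, 0.505), (0.895, 0.905), (0.99, 1.0))
) -> np.ndarray:
    """Average vectorized shape of subjects within latent-quantile bins.

    Reproduces the visual convention of averaging the meshes of subjects whose
    latent value falls in narrow quantile windows along one latent variable.
    """
    ranks = np.argsort(np.argsort(latents)) / (latents.size - 1)
    out = []
    for lo, hi in bins:
        mask = (ranks >= lo) & (ranks <= hi)
        if not mask.any():  # widen empty bins to the nearest subject
            mask = np.abs(ranks - (lo + hi) / 2) <= 1.0 / latents.size
        out.append(shapes_vec[mask].mean(axis=0))
    return np.stack(out)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def save_pca(model: PcaModel, path) -> None:
    np.savez_compressed(
        str(path),
        mean_shape=model.mean_shape,
        components=model.components,
        eigenvalues=model.eigenvalues,
        total_variance=model.total_variance,
    )


def load_pca(path) -> PcaModel:
    with np.load(str(path)) as z:
        return PcaModel(
            z["mean_shape"], z["components"], z["eigenvalues"], float(z["total_variance"])
        )


def latent_table(subject_ids, latents: np.ndarray, prefix: str = "PC") -> pd.DataFrame:
    cols = [f"{prefix}{i + 1}" for i in range(latents.shape[1])]
    df = pd.DataFrame(latents, columns=cols)
    df.insert(0, "subject_id", list(subject_ids))
    return df
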