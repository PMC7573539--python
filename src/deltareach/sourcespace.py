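"""Simplified distributed source imaging: sLORETA on the synthetic leadfield.

The minimum-norm kernel K = G^T (G G^T + lambda C)^-1 (C = regularized
sensor-noise covariance) is standardized per voxel by the 3x3 diagonal
blocks of the resolution matrix K G — the sLORETA standardization, which
has zero localization error for noiseless point sources. Source values
are reduced to one scalar per voxel by the Euclidean norm over the three
orientations, and normalized per subject by a resampled global-field-power
(GFP) constant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Epochs, Leadfield, Recording


def estimate_noise_covariance(
    rest: np.ndarray | Recording,
    shrink_frac: float = 0.1,
    min_duration: float = 5.0,
) -> np.ndarray:
    """Sensor-noise covariance from resting data, diagonally loaded with
    ``shrink_frac`` times the average eigenvalue."""
    if isinstance(rest, Recording):
        if rest.duration < min_duration:
            raise ValueError("rest segment shorter than required minimum")
        data = rest.data[rest.picks("eeg")]
    else:
        data = np.asarray(rest, dtype=float)
    c = np.cov(data)
    if not np.any(c):
        raise ValueError("rest data has rank 0")
    # mean eigenvalue = trace / n
    return c + shrink_frac * (np.trace(c) / c.shape[0]) * np.eye(c.shape[0])


@dataclass
class InverseOperator:
    """sLORETA inverse: standardized kernel plus regularization metadata."""

    kernel: np.ndarray        # voxels x 3 x channels (standardized)
    raw_kernel: np.ndarray    # voxels x 3 x channels (minimum norm)
    lam: float
    noise_cov: np.ndarray
    n_voxels: int

    def apply(self, data: np.ndarray) -> np.ndarray:
        """Project channel data (channels x ...) to (voxels, 3, ...)."""
        return np.tensordot(self.kernel, data, axes=(2, 0))


def compute_sloreta_operator(
    lf: Leadfield,
    noise_cov: np.ndarray,
    lam: float = 0.05,
) -> InverseOperator:
    """Build the sLORETA operator for a leadfield and noise covariance."""
    g = lf.gain
    noise_cov = np.asarray(noise_cov, dtype=float)
    if noise_cov.shape != (g.shape[0], g.shape[0]):
        raise ValueError("noise covariance does not match the channel count")
    gram = g @ g.T
    lam_eff = lam * np.trace(gram) / np.trace(noise_cov)
    k = np.linalg.solve(gram + lam_eff * noise_cov, g).T      # 3V x C
    nv = lf.n_voxels
    k3 = k.reshape(nv, 3, -1)
    g3 = g.reshape(-1, nv, 3)
    # resolution-matrix diagonal blocks R_vv = K_v G_v  (3 x 3 per voxel)
    r = np.einsum("vac,cvb->vab", k3, g3)
    r = 0.5 * (r + np.transpose(r, (0, 2, 1)))
    w, u = np.linalg.eigh(r)
    w = np.maximum(w, w.max(axis=1, keepdims=True) * 1e-12)
    inv_sqrt = np.einsum("vik,vk,vjk->vij", u, 1.0 / np.sqrt(w), u)
    kernel = np.einsum("vij,vjc->vic", inv_sqrt, k3)
    return InverseOperator(
        kernel=kernel,
        raw_kernel=k3,
        lam=lam,
        noise_cov=noise_cov,
        n_voxels=nv,
    )


def voxel_norm(src: np.ndarray, axis: int = 1) -> np.ndarray:
    """Euclidean norm over the 3 dipole orientations."""
    if src.shape[axis] != 3:
        raise ValueError("expected 3 orientation components per voxel")
    return np.sqrt(np.sum(src**2, axis=axis))


def voxel_direction_norm(
    coef_horz: np.ndarray, coef_vert: np.ndarray
) -> np.ndarray:
    """Single direction map: sum of the horizontal- and vertical-factor
    voxel norms. Inputs are ``voxels x 3 (x ...)`` coefficient arrays."""
    return voxel_norm(coef_horz) + voxel_norm(coef_vert)


def estimate_gfp(
    epochs: Epochs | np.ndarray,
    operator: InverseOperator,
    n_reps: int = 10000,
    seed: int = 0,
) -> float:
    """Resampled global field power of single-trial source activity.

    Each repetition draws one random sample per trial, averages across
    trials, projects to source space and takes the standard deviation of
    the voxel norms across voxels; the estimate is the median over
    ``n_reps`` repetitions.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    data = epochs.data if isinstance(epochs, Epochs) else np.asarray(epochs)
    n_tr, n_ch, n_t = data.shape
    rng = np.random.default_rng(seed)
    swapped = np.ascontiguousarray(data.transpose(0, 2, 1))  # tr x t x ch
    gfps = np.empty(n_reps)
    chunk = 256
    for start in range(0, n_reps, chunk):
        m = min(chunk, n_reps - start)
        idx = rng.integers(0, n_t, size=(m, n_tr))
        # average the selected one-sample-per-trial slices across trials
        sel = swapped[np.arange(n_tr)[None, :], idx]          # m x tr x ch
        avg = sel.mean(axis=1)                                # m x ch
        src = np.tensordot(operator.kernel, avg.T, axes=(2, 0))
        norms = voxel_norm(src)                               # V x m
        gfps[start : start + m] = norms.std(axis=0)
    return float(np.median(gfps))


def project_and_normalize(
    values: np.ndarray,
    operator: InverseOperator,
    gfp: float | None = None,
    epochs: Epochs | np.ndarray | None = None,
    n_reps: int = 10000,
    seed: int = 0,
) -> tuple[np.ndarray, float]:
    """Project channel-space values (activity averages or GLM coefficient
    columns, ``channels x ...``) to source space and divide by the
    subject's GFP constant.

    The same constant normalizes activity and coefficients; pass a
    precomputed ``gfp`` or the epochs to estimate it from.
    """
    if gfp is None:
        if epochs is None:
            raise ValueError("need either a gfp constant or epochs")
        gfp = estimate_gfp(epochs, operator, n_reps=n_reps, seed=seed)
    src = operator.apply(np.asarray(values, dtype=float))
    return src / gfp, gfp


def roi_average(values: np.ndarray, roi_labels: np.ndarray, roi: str) -> np.ndarray:
    """Mean over the voxels of one ROI; ``values`` has voxels first."""
    sel = np.flatnonzero(np.asarray(roi_labels) == roi)
    if sel.size == 0:
        raise ValueError(f"ROI {roi!r} has no voxels")
    return values[sel].mean(axis=0)
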