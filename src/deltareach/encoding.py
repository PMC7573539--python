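"""Per-timepoint linear encoding model (GLM) with analytic shrinkage.

At every time-point i the EEG activity X(i) (channels x trials) is
modeled as A(i) S + E(i), with a 4 x n_trials factor matrix

    S = [s_cond; s_dir_horz; s_dir_vert; 1]

(condition exe/obs = +-1; horizontal right/left = +-1; vertical up/down =
+-1; rows z-scored after trial-count equalization). The least-squares
coefficients are A = C_XS C_SS^-1 with the factor covariance C_SS
estimated by Ledoit-Wolf analytic shrinkage toward a scaled identity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from .core import Epochs

FACTORS = ("condition", "dir_horz", "dir_vert", "intercept")

_COND_CODE = {"exe": 1.0, "obs": -1.0}
_HORZ_CODE = {"right": 1.0, "left": -1.0, "up": 0.0, "down": 0.0}
_VERT_CODE = {"up": 1.0, "down": -1.0, "right": 0.0, "left": 0.0}


def ledoit_wolf_shrinkage(x: np.ndarray, assume_centered: bool = False) -> tuple[np.ndarray, float]:
    """Analytic (Ledoit-Wolf) shrinkage covariance toward scaled identity.

    Parameters
    ----------
    x
        ``n_samples x n_features`` data matrix.

    Returns
    -------
    (sigma, gamma)
        ``sigma = (1 - gamma) S + gamma (tr S / p) I`` with the shrinkage
        intensity ``gamma`` estimated from the data.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[1] == 0:
        raise ValueError("need a 2-D sample matrix with at least one feature")
    n, p = x.shape
    if n < 2:
        raise ValueError("need at least 2 samples")
    if not assume_centered:
        x = x - x.mean(axis=0)
    s = x.T @ x / n
    mu = np.trace(s) / p
    delta2 = np.sum((s - mu * np.eye(p)) ** 2) / p
    if delta2 <= 0:
        return s, 0.0
    # (1/n^2) sum_k ||x_k x_k^T - S||_F^2 = (sum_k ||x_k||^4 - n ||S||_F^2) / n^2
    norms4 = np.sum(np.sum(x**2, axis=1) ** 2)
    beta2 = (norms4 / n**2 - np.sum(s**2) / n) / p
    beta2 = min(max(beta2, 0.0), delta2)
    gamma = beta2 / delta2
    sigma = (1.0 - gamma) * s + gamma * mu * np.eye(p)
    return sigma, float(gamma)


def shrinkage_covariance(
    samples: np.ndarray,
    assume_centered: bool = False,
    shrinkage: float | None = None,
) -> tuple[np.ndarray, float]:
    """Shrunk covariance of ``n x p`` samples; ``shrinkage`` overrides the
    analytic intensity (0 = sample covariance, 1 = scaled identity)."""
    if shrinkage is None:
        return ledoit_wolf_shrinkage(samples, assume_centered)
    x = np.asarray(samples, dtype=float)
    if x.ndim != 2 or x.shape[1] == 0:
        raise ValueError("need a 2-D sample matrix with at least one feature")
    if not assume_centered:
        x = x - x.mean(axis=0)
    s = x.T @ x / x.shape[0]
    mu = np.trace(s) / x.shape[1]
    g = float(np.clip(shrinkage, 0.0, 1.0))
    return (1.0 - g) * s + g * mu * np.eye(x.shape[1]), g


@dataclass
class DesignMatrix:
    """Factor matrix S (4 x n_trials) plus equalization bookkeeping."""

    S: np.ndarray
    trial_index: np.ndarray     # positions into the source trial table
    factor_names: tuple = FACTORS
    z_mean: np.ndarray | None = None
    z_std: np.ndarray | None = None


def build_design_matrix(
    trials: pd.DataFrame,
    seed: int = 0,
    equalize: bool = True,
    factors: str = "full",
) -> DesignMatrix:
    """Build the (equalized, z-scored) design matrix from a trial table.

    Cells (condition x direction) are subsampled without replacement to
    the minimum cell count so the factors are exactly balanced;
    ``factors="direction"`` builds a 3-row design (horizontal, vertical,
    intercept) for condition-specific fits.
    """
    rng = np.random.default_rng(seed)
    groups = trials.groupby(["condition", "direction"], sort=True).indices
    if equalize:
        n_cells = 8 if factors == "full" else 4
        if len(groups) < n_cells:
            raise ValueError("empty condition x direction cell")
        if any(len(v) < 2 for v in groups.values()):
            raise ValueError("every cell needs at least 2 trials")
        n_min = min(len(v) for v in groups.values())
        keep = np.concatenate(
            [
                np.sort(rng.choice(idx, size=n_min, replace=False))
                for _, idx in sorted(groups.items())
            ]
        )
        keep = np.sort(keep)
    else:
        keep = np.arange(len(trials))
    sel = trials.iloc[keep]

    rows = []
    if factors == "full":
        rows.append(sel["condition"].map(_COND_CODE).to_numpy())
    elif factors != "direction":
        raise ValueError("factors must be 'full' or 'direction'")
    rows.append(sel["direction"].map(_HORZ_CODE).to_numpy())
    rows.append(sel["direction"].map(_VERT_CODE).to_numpy())
    s = np.vstack(rows)
    z_mean = s.mean(axis=1)
    z_std = s.std(axis=1)
    if np.any(z_std == 0):
        raise ValueError("a factor is constant; cannot z-score")
    s = (s - z_mean[:, None]) / z_std[:, None]
    s = np.vstack([s, np.ones(s.shape[1])])
    names = FACTORS if factors == "full" else ("dir_horz", "dir_vert", "intercept")
    return DesignMatrix(
        S=s, trial_index=keep, factor_names=names, z_mean=z_mean, z_std=z_std
    )


@dataclass
class GlmFit:
    """Coefficients and residual diagnostics of one time-point fit."""

    A: np.ndarray          # channels x n_factors
    Xhat: np.ndarray       # channels x trials
    E: np.ndarray          # residuals, X - Xhat (exact identity)
    C_XS: np.ndarray
    C_SS: np.ndarray
    gamma: float
    resid_stats: pd.DataFrame


def fit_glm(
    X: np.ndarray,
    design: DesignMatrix,
    shrinkage: float | None = None,
) -> GlmFit:
    """Fit the encoding model at one time-point.

    ``X`` is channels x trials; column counts of X and the design must
    match. The shrunk C_SS is always invertible for gamma > 0; a singular
    matrix (possible only at gamma = 0 with degenerate factors) raises.
    """
    X = np.asarray(X, dtype=float)
    s = design.S
    if X.shape[1] != s.shape[1]:
        raise ValueError("trial counts of X and S differ")
    n = s.shape[1]
    c_xs = X @ s.T / n
    c_ss, gamma = shrinkage_covariance(
        s.T, assume_centered=True, shrinkage=shrinkage
    )
    cond = np.linalg.cond(c_ss)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError("shrunk factor covariance is singular")
    a = np.linalg.solve(c_ss.T, c_xs.T).T
    xhat = a @ s
    e = X - xhat
    resid = pd.DataFrame(
        {
            "skewness": stats.skew(e, axis=1, bias=True),
            "excess_kurtosis": stats.kurtosis(e, axis=1, bias=True),
            "resid_var": e.var(axis=1),
        }
    )
    return GlmFit(
        A=a, Xhat=xhat, E=e, C_XS=c_xs, C_SS=c_ss, gamma=gamma, resid_stats=resid
    )


def fit_glm_epochs(
    epochs: Epochs,
    design: DesignMatrix,
    shrinkage: float | None = None,
) -> np.ndarray:
    """Fit the GLM at every time-point of (already subset) epochs.

    Returns coefficients with shape ``n_times x channels x n_factors``.
    """
    data = epochs.data
    if data.shape[0] != design.S.shape[1]:
        raise ValueError(
            "epochs must be subset to the design's trials before fitting"
        )
    out = np.empty((data.shape[2], data.shape[1], design.S.shape[0]))
    for t in range(data.shape[2]):
        out[t] = fit_glm(data[:, :, t].T, design, shrinkage).A
    return out


class ShrinkageLinearModel(RegressorMixin, BaseEstimator):
    """sklearn-style wrapper around the shrinkage-regularized encoder.

    ``fit(X, y)`` takes factors ``X`` (n_trials x n_factors, intercept
    column included) and responses ``y`` (n_trials x n_channels); fitted
    coefficients live in ``coef_`` (n_channels x n_factors).
    """

    def __init__(self, shrinkage: float | None = None):
        self.shrinkage = shrinkage

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if y.ndim == 1:
            y = y[:, None]
        if len(X) != len(y):
            raise ValueError("X and y must have matching trial counts")
        design = DesignMatrix(S=X.T, trial_index=np.arange(len(X)))
        res = fit_glm(y.T, design, shrinkage=self.shrinkage)
        self.coef_ = res.A
        self.gamma_ = res.gamma
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        return X @ self.coef_.T
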