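"""Group-level permutation statistics and multiple-testing control.

Sign-flip permutation tests for group-average maps, paired permutation
t-tests, and Benjamini-Hochberg FDR. Permutation p-values use the +1
smoothing p = (1 + #{null >= observed}) / (1 + n_perm) so p > 0 always;
when 2^n_subjects <= n_perm the null is enumerated exhaustively instead
(the identity flip makes p >= 1/2^n without smoothing).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class TestResult:
    statistic: float
    p: float
    n_perm: int
    sides: str
    exhaustive: bool = False
    degenerate: bool = False
    significant: bool | None = None
    p_critical: float | None = None


def _sign_patterns(n_subjects: int, n_perm: int, rng: np.random.Generator):
    """(signs matrix, exhaustive flag): all 2^S patterns when affordable."""
    if 2**n_subjects <= n_perm:
        bits = np.arange(2**n_subjects)[:, None] >> np.arange(n_subjects)
        return np.where(bits & 1, -1.0, 1.0), True
    return rng.choice([-1.0, 1.0], size=(n_perm, n_subjects)), False


def permutation_signflip_test(
    effects: np.ndarray,
    n_perm: int = 10000,
    seed: int = 0,
) -> np.ndarray:
    """One-sided sign-flip test of group-average effect magnitude.

    ``effects`` is ``subjects x features`` (statistic per feature:
    absolute group mean) or ``subjects x features x k`` (statistic:
    Euclidean norm of the group-mean k-vector, e.g. k = 3 dipole
    orientations). Each permutation flips every subject's sign before the
    group average and norm extraction; p is the fraction of permuted
    statistics >= the observed one.
    """
    effects = np.asarray(effects, dtype=float)
    if effects.ndim == 2:
        effects = effects[:, :, None]
    if effects.ndim != 3:
        raise ValueError("effects must be subjects x features (x k)")
    n_subj = effects.shape[0]
    if n_subj < 2:
        raise ValueError("need at least 2 subjects")
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    rng = np.random.default_rng(seed)
    obs = np.linalg.norm(effects.mean(axis=0), axis=-1)        # features
    signs, exhaustive = _sign_patterns(n_subj, n_perm, rng)
    null = np.linalg.norm(
        np.tensordot(signs, effects, axes=(1, 0)) / n_subj, axis=-1
    )                                                          # perms x features
    count = np.sum(null >= obs[None, :], axis=0)
    if exhaustive:
        return count / signs.shape[0]
    return (1.0 + count) / (1.0 + n_perm)


def permutation_paired_ttest(
    a: np.ndarray,
    b: np.ndarray,
    sides: str = "two",
    n_perm: int = 10000,
    seed: int = 0,
) -> TestResult:
    """Paired t-test with a sign-flip permutation null on the differences.

    ``sides="one"`` tests a > b. Zero-variance differences give p = 1
    with the ``degenerate`` flag set.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need two equally sized samples of length >= 2")
    if sides not in ("one", "two"):
        raise ValueError("sides must be 'one' or 'two'")
    d = a - b
    n = d.size
    sd = d.std(ddof=1)
    if sd == 0:
        return TestResult(0.0, 1.0, 0, sides, degenerate=True)

    def tstat(x, axis=-1):
        m = x.mean(axis=axis)
        s = x.std(axis=axis, ddof=1)
        return m / (s / np.sqrt(n))

    t_obs = tstat(d)
    rng = np.random.default_rng(seed)
    signs, exhaustive = _sign_patterns(n, n_perm, rng)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_null = tstat(signs * d[None, :])
    t_null = np.nan_to_num(t_null, nan=0.0, posinf=np.inf, neginf=-np.inf)
    if sides == "two":
        count = np.sum(np.abs(t_null) >= np.abs(t_obs) - 1e-12)
    else:
        count = np.sum(t_null >= t_obs - 1e-12)
    if exhaustive:
        p = count / signs.shape[0]
        return TestResult(float(t_obs), float(p), signs.shape[0], sides, exhaustive=True)
    p = (1.0 + count) / (1.0 + n_perm)
    return TestResult(float(t_obs), float(p), n_perm, sides)


def fdr_bh(p_values: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, float]:
    """Benjamini-Hochberg step-up over one family of p-values.

    Returns the rejection mask and the critical p (largest rejected
    p-value; 0.0 if nothing is rejected).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value family")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    below = ranked <= (np.arange(1, m + 1) * q / m)
    mask = np.zeros(m, dtype=bool)
    if np.any(below):
        k = int(np.max(np.flatnonzero(below)))
        mask[order[: k + 1]] = True
        crit = float(ranked[k])
    else:
        crit = 0.0
    return mask, crit
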