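"""Analytic single-sphere EEG forward model.

The head is modeled as a homogeneous conducting sphere (radius ``R``,
conductivity ``sigma``). The surface potential of a current dipole inside
an insulated sphere has the classical Legendre-series solution; we evaluate
the dipole potential as the moment-gradient of the internal monopole
Green's function

    G(r_e, r_q) = 1 / (4 pi sigma R) * sum_{n>=1} (2n+1)/n * f^n * P_n(c)

with ``f = |r_q| / R`` and ``c`` the cosine of the angle between electrode
``r_e`` (on the surface) and source ``r_q``. The series converges
geometrically for sources below the surface; we truncate at ``n_terms``.

This deliberately trades anatomical realism (3-layer BEM, template cortex)
for an exactly linear, dependency-free forward operator: every downstream
stage (inverse solution, encoding model) only relies on the linear-mixing
structure, which the sphere preserves.
"""

from __future__ import annotations

import numpy as np

from .core import Leadfield

#: head radius (m) and brain conductivity (S/m)
DEFAULT_RADIUS = 0.095
DEFAULT_SIGMA = 0.33


def _fibonacci_directions(n: int, z_min: float) -> np.ndarray:
    """Quasi-uniform unit vectors on the spherical cap ``z >= z_min``."""
    i = np.arange(n)
    z = z_min + (1.0 - z_min) * (i + 0.5) / n
    golden = (1 + np.sqrt(5)) / 2
    phi = 2 * np.pi * i / golden
    r = np.sqrt(np.clip(1 - z**2, 0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def sphere_dipole_gain(
    electrodes: np.ndarray,
    sources: np.ndarray,
    radius: float = DEFAULT_RADIUS,
    sigma: float = DEFAULT_SIGMA,
    n_terms: int = 80,
) -> np.ndarray:
    """Surface potentials of unit dipoles in a homogeneous sphere.

    Parameters
    ----------
    electrodes
        ``C x 3`` positions on the sphere surface (m).
    sources
        ``V x 3`` dipole positions strictly inside the sphere (m).
    n_terms
        Truncation order of the Legendre series.

    Returns
    -------
    ndarray of shape ``C x (3 V)``
        Potential in microvolt per nAm of dipole moment; columns are
        grouped per source (x, y, z moment components).
    """
    electrodes = np.asarray(electrodes, dtype=float)
    sources = np.asarray(sources, dtype=float)
    n_ch, n_src = len(electrodes), len(sources)

    b = np.linalg.norm(sources, axis=1)
    if np.any(b >= radius):
        raise ValueError("sources must lie strictly inside the sphere")
    b = np.maximum(b, 1e-9)
    bhat = sources / b[:, None]                       # V x 3
    f = b / radius                                    # V

    # cosine of the electrode-source angle, C x V
    c = (electrodes @ sources.T) / (radius * b[None, :])
    c = np.clip(c, -1.0, 1.0)

    # grad_c with respect to the source position, C x V x 3
    grad_c = electrodes[:, None, :] / (radius * b[None, :, None]) - (
        c[:, :, None] * bhat[None, :, :] / b[None, :, None]
    )

    # Legendre recurrences: P_n(c) and P'_n(c) (derivative w.r.t. c).
    p_prev = np.ones_like(c)       # P_0
    p_cur = c.copy()               # P_1
    dp_prev = np.zeros_like(c)     # P'_0
    dp_cur = np.ones_like(c)       # P'_1

    out = np.zeros((n_ch, n_src, 3))
    fpow = np.ones(n_src)          # f^{n-1}
    for n in range(1, n_terms + 1):
        if n > 1:
            p_next = ((2 * n - 1) * c * p_cur - (n - 1) * p_prev) / n
            dp_next = dp_prev + (2 * n - 1) * p_cur
            p_prev, p_cur = p_cur, p_next
            dp_prev, dp_cur = dp_cur, dp_next
            fpow = fpow * f
        coef = (2 * n + 1) / n
        # d/dr_q [ f^n P_n(c) ] = n f^{n-1}/R * P_n * bhat + f^n P'_n grad_c
        radial = (n / radius) * fpow[None, :, None] * (
            p_cur[:, :, None] * bhat[None, :, :]
        )
        tangential = (fpow * f)[None, :, None] * dp_cur[:, :, None] * grad_c
        out += coef * (radial + tangential)

    # 1/(4 pi sigma R); nAm -> V is 1e-9, V -> uV is 1e6
    out *= 1e-3 / (4 * np.pi * sigma * radius)
    return out.reshape(n_ch, 3 * n_src)


def assign_rois(voxel_positions: np.ndarray) -> np.ndarray:
    """Label voxels by scalp-frame sectors.

    Head frame: +x right, +y anterior, +z superior. Posterior-inferior
    voxels map to parieto-occipital cortex (PO), posterior-superior to the
    superior parietal lobule (SPL), central to primary sensorimotor cortex
    (SM1) and pre-central to premotor cortex (PM); hemisphere by the sign
    of x. Unassigned voxels get an empty label.
    """
    u = voxel_positions / np.linalg.norm(voxel_positions, axis=1, keepdims=True)
    x, y, z = u.T
    labels = np.full(len(u), "", dtype="<U8")
    po = y < -0.55
    spl = (~po) & (y < -0.2) & (z > 0.35)
    sm1 = (y >= -0.2) & (y < 0.2) & (z > 0.25)
    pm = (y >= 0.2) & (y < 0.6) & (z > 0.2)
    side = np.where(x < 0, "-L", "-R")
    for mask, name in [(po, "PO"), (spl, "SPL"), (sm1, "SM1"), (pm, "PM")]:
        labels[mask] = np.char.add(name, side[mask])
    return labels


def build_leadfield(
    n_channels: int = 64,
    n_voxels: int = 200,
    seed: int = 0,
    radius: float = DEFAULT_RADIUS,
    source_depth: float = 0.72,
    sigma: float = DEFAULT_SIGMA,
    n_terms: int = 80,
    position_jitter: float = 0.002,
) -> Leadfield:
    """Build the synthetic forward model.

    Electrodes sit quasi-uniformly on the upper scalp cap; sources sit on a
    cortical shell at ``source_depth * radius`` over the upper hemisphere.
    ``seed`` controls a small electrode-position jitter that emulates cap
    placement variability; the construction is deterministic given
    ``(n_channels, n_voxels, seed)``.
    """
    if n_channels < 4 or n_voxels < 8:
        raise ValueError("need n_channels >= 4 and n_voxels >= 8")
    rng = np.random.default_rng(seed)

    elec = _fibonacci_directions(n_channels, z_min=0.08)
    if position_jitter > 0:
        elec = elec + rng.normal(0, position_jitter, elec.shape)
        elec /= np.linalg.norm(elec, axis=1, keepdims=True)
    elec = elec * radius

    vox = _fibonacci_directions(n_voxels, z_min=0.02) * (source_depth * radius)

    gain = sphere_dipole_gain(elec, vox, radius, sigma, n_terms)
    return Leadfield(
        gain=gain,
        voxel_positions=vox,
        channel_positions=elec,
        roi_labels=assign_rois(vox),
        radius=radius,
    )


def central_channels(lf: Leadfield) -> np.ndarray:
    """Indices of medial central electrodes (over SM1), used to calibrate
    and read out the movement-related cortical potential."""
    u = lf.channel_positions / np.linalg.norm(
        lf.channel_positions, axis=1, keepdims=True
    )
    x, y, z = u.T
    sel = (np.abs(y) < 0.3) & (z > 0.55)
    if not np.any(sel):  # degenerate tiny montages
        sel = z >= np.quantile(z, 0.75)
    return np.flatnonzero(sel)
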