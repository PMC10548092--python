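"""Brute-force quadrature oracle for the 3-bead chain.

Independent of the Monte-Carlo sampler: the Boltzmann distribution of a
three-bead chain (two harmonic bonds, one end-to-end spherical well, hard
cores) is integrated numerically over the internal coordinates
(r1, r2, theta) with Jacobian r1^2 r2^2 sin(theta). Used to check both the
end-to-end distance distribution and the end-to-end contact probability of
the sampler.
"""

from __future__ import annotations

import numpy as np

__all__ = ["three_bead_distance_distribution", "three_bead_contact_probability"]


def _weights(k_b, a, eps, hardcore, well_radius, n_r=160, n_theta=400):
    r = np.linspace(hardcore, a + 0.45, n_r)
    theta = np.linspace(0.0, np.pi, n_theta)
    r1 = r[:, None, None]
    r2 = r[None, :, None]
    th = theta[None, None, :]
    d13 = np.sqrt(r1**2 + r2**2 - 2.0 * r1 * r2 * np.cos(th))
    energy = k_b * (r1 - a) ** 2 + k_b * (r2 - a) ** 2
    energy = energy + np.where(d13 < well_radius, eps, 0.0)
    w = r1**2 * r2**2 * np.sin(th) * np.exp(-energy)
    w = np.where(d13 < hardcore, 0.0, w)
    return d13.ravel(), w.ravel()


def three_bead_distance_distribution(
    k_b=100.0, a=1.0, eps=0.0, hardcore=0.6, well_radius=1.5, n_bins=400
):
    """Return (bin_edges, cdf) of the end-to-end distance by quadrature."""
    d13, w = _weights(k_b, a, eps, hardcore, well_radius)
    edges = np.linspace(0.0, 2.0 * (a + 0.45), n_bins + 1)
    hist, _ = np.histogram(d13, bins=edges, weights=w)
    cdf = np.concatenate([[0.0], np.cumsum(hist)])
    cdf /= cdf[-1]
    return edges, cdf


def three_bead_contact_probability(
    k_b=100.0, a=1.0, eps=0.0, hardcore=0.6, well_radius=1.5, contact_radius=1.5
):
    """P(end-to-end distance < contact_radius) by quadrature."""
    d13, w = _weights(k_b, a, eps, hardcore, well_radius)
    return float(w[d13 < contact_radius].sum() / w.sum())


def cdf_at(edges: np.ndarray, cdf: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Piecewise-linear CDF evaluator for scipy.stats.kstest."""
    return np.interp(x, edges, cdf)
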