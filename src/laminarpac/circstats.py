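"""Circular statistics for spike-phase analysis.

Angles are degrees throughout the public API.  The mean resultant vector,
Rayleigh test and circular mean are delegated to pingouin; the two-sample
Watson-Williams and Kuiper tests are implemented here from their standard
formulations.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.optimize import brentq
from scipy.special import i0e, i1e

__all__ = [
    "resultant",
    "rayleigh_test",
    "watson_williams",
    "kuiper_two_sample",
    "vonmises_R",
    "kappa_from_R",
]


def _rad(deg) -> np.ndarray:
    a = np.asarray(deg, dtype=float)
    if a.size == 0:
        raise ValueError("empty phase sample")
    return np.radians(a)


def resultant(phases_deg) -> tuple[float, float]:
    """Circular mean angle (degrees, [0, 360)) and mean resultant length R."""
    import pingouin as pg

    a = _rad(phases_deg)
    mean = float(np.degrees(pg.circ_mean(a))) % 360.0
    r = float(pg.circ_r(a))
    return mean, r


def rayleigh_test(phases_deg, alpha: float = 0.05) -> tuple[float, bool]:
    """Rayleigh test of circular uniformity.

    Returns (p, entrained) where ``entrained`` is ``p < alpha``.  Uses the
    small-sample corrected approximation of the Rayleigh Z = n*R^2 statistic.
    """
    import pingouin as pg

    a = _rad(phases_deg)
    _, p = pg.circ_rayleigh(a)
    return float(p), bool(p < alpha)


def vonmises_R(kappa: float) -> float:
    """Population mean resultant length A(kappa) = I1(kappa)/I0(kappa)."""
    if kappa < 0:
        raise ValueError("kappa must be non-negative")
    if kappa == 0:
        return 0.0
    return float(i1e(kappa) / i0e(kappa))


def kappa_from_R(r: float) -> float:
    """Invert A(kappa) = r numerically (von Mises concentration for a target R)."""
    if not 0.0 <= r < 1.0:
        raise ValueError("R must lie in [0, 1)")
    if r == 0.0:
        return 0.0
    hi = 2.0
    while vonmises_R(hi) < r:
        hi *= 2.0
        if hi > 1e8:  # r ~ 1
            break
    return float(brentq(lambda k: vonmises_R(k) - r, 1e-12, hi, xtol=1e-10))


def watson_williams(*groups_deg) -> tuple[float, float]:
    """Two-or-more-sample Watson-Williams test for equal circular means.

    Returns (F, p).  Follows the classical circular one-way ANOVA with the
    1 + 3/(8*kappa) correction factor.  A warning is issued when the pooled
    concentration is too low for the test's assumptions (mean R < 0.45).
    """
    from scipy.stats import f as f_dist

    if len(groups_deg) < 2:
        raise ValueError("need at least two groups")
    rads = [_rad(g) for g in groups_deg]
    ns = np.array([g.size for g in rads])
    if np.any(ns < 2):
        raise ValueError("each group needs at least 2 angles")
    k = len(rads)
    n_tot = int(ns.sum())

    Rs = np.array([np.abs(np.exp(1j * g).sum()) for g in rads])
    R_tot = float(np.abs(np.exp(1j * np.concatenate(rads)).sum()))
    rbar = float(Rs.sum() / n_tot)
    if rbar < 0.45:
        warnings.warn(
            "Watson-Williams: pooled resultant < 0.45; test may be unreliable",
            stacklevel=2,
        )
    kappa = kappa_from_R(min(rbar, 1 - 1e-12))
    correction = 1.0 + 3.0 / (8.0 * kappa) if kappa > 0 else 1.0

    num = (Rs.sum() - R_tot) / (k - 1)
    den = (n_tot - Rs.sum()) / (n_tot - k)
    if den <= 0:
        return np.inf, 0.0
    F = float(correction * num / den)
    p = float(f_dist.sf(F, k - 1, n_tot - k))
    return F, p


def kuiper_two_sample(a_deg, b_deg) -> tuple[float, float]:
    """Two-sample Kuiper test on circular samples.

    Returns (V, p) with V = max(F_a - F_b) + max(F_b - F_a) over the pooled
    support (rotation invariant) and p from the standard asymptotic series
    with Stephens' finite-sample correction of the effective sample size.
    """
    a = np.sort(_rad(a_deg) % (2 * np.pi))
    b = np.sort(_rad(b_deg) % (2 * np.pi))
    n, m = a.size, b.size
    pooled = np.concatenate([a, b])
    # Empirical CDFs evaluated just after each pooled point.
    fa = np.searchsorted(a, pooled, side="right") / n
    fb = np.searchsorted(b, pooled, side="right") / m
    d = fa - fb
    V = float(d.max() - d.min())

    ne = n * m / (n + m)
    lam = (np.sqrt(ne) + 0.155 + 0.24 / np.sqrt(ne)) * V
    if lam < 0.4:
        return V, 1.0
    j = np.arange(1, 101)
    terms = (4.0 * j**2 * lam**2 - 1.0) * np.exp(-2.0 * j**2 * lam**2)
    p = float(min(1.0, max(0.0, 2.0 * terms.sum())))
    return V, p
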