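"""Watson-distributed axis sampling and axial moments.

The Watson distribution is the antipodally symmetric distribution of axes
on the unit sphere with density proportional to ``exp(kappa * (mu . n)**2)``
for concentration ``kappa >= 0`` around a mean axis ``mu``.  ``kappa = 0``
is the uniform distribution of axes; ``kappa -> inf`` collapses onto ``mu``.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

__all__ = [
    "sample_watson",
    "cos2_moment",
    "kappa_from_cos2",
    "scatter_matrix",
]


def _as_unit(v, name: str = "mu") -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if v.shape != (3,):
        raise ValueError(f"{name} must be a 3-vector, got shape {v.shape}")
    n = float(np.linalg.norm(v))
    if abs(n - 1.0) > 1e-6:
        raise ValueError(f"{name} must be a unit vector (|{name}| = {n:.8f})")
    return v / n


def _orthonormal_frame(mu: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    helper = np.array([1.0, 0.0, 0.0]) if abs(mu[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(mu, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(mu, e1)
    return e1, e2


def sample_watson(mu, kappa: float, n: int, seed=None, rng=None) -> np.ndarray:
    """Draw ``n`` unit axes from a Watson distribution around ``mu``.

    Rejection sampling of ``t = cos(psi)`` on [0, 1] against the envelope
    ``exp(kappa * t)`` (valid since ``t**2 - t <= 0`` there, with acceptance
    rate >= ~0.43 for every ``kappa``), followed by a uniform azimuth and a
    random antipodal sign flip.

    Parameters
    ----------
    mu : (3,) array-like
        Mean axis; must have unit norm.
    kappa : float
        Concentration, >= 0.
    n : int
        Number of axes, >= 1.
    seed, rng :
        Either a seed for ``numpy.random.default_rng`` or an existing
        Generator.  ``rng`` wins when both are given.

    Returns
    -------
    (n, 3) ndarray of unit vectors (axial sample: signs are random).
    """
    mu = _as_unit(mu)
    kappa = float(kappa)
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    n = int(n)
    if n < 1:
        raise ValueError("n must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)

    ts = np.empty(0)
    while ts.size < n:
        m = max(int((n - ts.size) * 2.6) + 16, 64)
        u = rng.random(m)
        if kappa == 0.0:
            t = u
            accept = np.ones(m, dtype=bool)
        else:
            # inverse CDF of the truncated-exponential envelope ~ exp(kappa t)
            t = 1.0 + np.log(u + (1.0 - u) * np.exp(-kappa)) / kappa
            accept = rng.random(m) <= np.exp(kappa * (t * t - t))
        ts = np.concatenate([ts, t[accept]])
    ts = ts[:n]

    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    sin_psi = np.sqrt(np.clip(1.0 - ts * ts, 0.0, None))
    e1, e2 = _orthonormal_frame(mu)
    axes = (
        sin_psi[:, None] * np.cos(phi)[:, None] * e1
        + sin_psi[:, None] * np.sin(phi)[:, None] * e2
        + ts[:, None] * mu
    )
    # antipodal symmetry: random sign per axis
    signs = np.where(rng.random(n) < 0.5, -1.0, 1.0)
    return axes * signs[:, None]


def cos2_moment(kappa: float) -> float:
    """Exact axial second moment ``<(mu . n)**2>`` of the Watson distribution.

    Computed by 1D quadrature of the marginal density of ``t = mu . n``;
    stable for all ``kappa`` via the substitution ``x = kappa * (1 - t)``.
    Equals 1/3 at ``kappa = 0`` and tends to 1 as ``kappa -> inf``.
    """
    kappa = float(kappa)
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    if kappa == 0.0:
        return 1.0 / 3.0
    upper = min(kappa, 400.0)

    def weight(x):
        return np.exp(-2.0 * x + x * x / kappa)

    den = quad(weight, 0.0, upper, limit=200)[0]
    num = quad(lambda x: (1.0 - x / kappa) ** 2 * weight(x), 0.0, upper, limit=200)[0]
    return num / den


def kappa_from_cos2(t: float) -> float:
    """Invert :func:`cos2_moment` (returns 0 for ``t <= 1/3``)."""
    t = float(t)
    if t >= 1.0:
        raise ValueError("cos^2 moment must be < 1")
    if t <= 1.0 / 3.0:
        return 0.0
    return brentq(lambda k: cos2_moment(k) - t, 1e-9, 1e7, xtol=1e-12, rtol=1e-14)


def scatter_matrix(mu, kappa: float) -> np.ndarray:
    """Expected dyadic ``<n n^T>`` of Watson axes around ``mu``.

    Axially symmetric by construction: ``t`` along ``mu`` and ``(1 - t)/2``
    in the perpendicular plane, with ``t = cos2_moment(kappa)``.
    """
    mu = _as_unit(mu)
    t = cos2_moment(kappa)
    outer = np.outer(mu, mu)
    return t * outer + 0.5 * (1.0 - t) * (np.eye(3) - outer)
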