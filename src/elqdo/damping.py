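"""Short-range damping of the Coulomb kernel.

At short range the bare Coulomb coupling between the explicit electrons and
the charged members of the oscillator environment lets the electron density
collapse onto positive environment charges (the polarization catastrophe /
charge-spilling problem familiar from QM/MM embeddings).  The cure is a
multiplicative damping factor ``m(r)`` on each affected pair, so the pair
energy becomes ``q_i q_j m(r) / r`` with

* ``0 <= m(r) <= 1``,
* ``m(r)/r`` finite as ``r -> 0`` (no divergence at contact),
* ``m(r) -> 1`` for ``r >> sigma`` (bare Coulomb recovered at long range).

Four standard kernels from the polarizable-embedding literature are
provided; ``sigma = 0`` always means the bare Coulomb kernel.

========  ==============================================
kind      m(r),  with x = r / sigma
========  ==============================================
erf       erf(x)
exp2      1 - exp(-x**2)        (Gaussian charge smearing)
exp4      1 - exp(-x**4)
swave     1 - exp(-2 x) (1 + x) (Slater 1s charge smearing)
========  ==============================================
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf

from .errors import ConfigurationError, DomainError

DAMPING_KINDS = ("none", "erf", "exp2", "exp4", "swave")

_SQRT_PI = np.sqrt(np.pi)


def pair_sigma(sigma_i, sigma_j):
    """Combine two per-particle damping lengths into a pair length.

    Geometric mean ``sqrt(sigma_i * sigma_j)``: symmetric, reduces to the
    common value when both agree, and propagates a bare-Coulomb particle
    (``sigma = 0``) to bare-Coulomb pairs.
    """
    sigma_i = np.asarray(sigma_i, dtype=float)
    sigma_j = np.asarray(sigma_j, dtype=float)
    if np.any(sigma_i < 0) or np.any(sigma_j < 0):
        raise DomainError("damping lengths must be >= 0")
    return np.sqrt(sigma_i * sigma_j)


def damping_factor(kind, r, sigma_pair):
    """Dimensionless multiplier ``m(r)`` on the Coulomb kernel.

    Parameters
    ----------
    kind : str
        One of ``none``, ``erf``, ``exp2``, ``exp4``, ``swave``.
    r : array_like
        Pair distance (bohr), >= 0.
    sigma_pair : array_like
        Pair damping length (bohr), >= 0.  Zero entries give ``m = 1``.
    """
    r = np.asarray(r, dtype=float)
    sigma = np.asarray(sigma_pair, dtype=float)
    if np.any(r < 0):
        raise DomainError("distance must be >= 0")
    if np.any(sigma < 0):
        raise DomainError("sigma must be >= 0")
    if kind not in DAMPING_KINDS:
        raise ConfigurationError(f"unknown damping kind {kind!r}")
    if kind == "none":
        return np.ones(np.broadcast_shapes(r.shape, sigma.shape))

    bare = sigma == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        x = np.where(bare, np.inf, r / np.where(bare, 1.0, sigma))
    if kind == "erf":
        m = erf(x)
    elif kind == "exp2":
        m = -np.expm1(-(x**2))
    elif kind == "exp4":
        m = -np.expm1(-(x**4))
    else:  # swave
        with np.errstate(invalid="ignore"):  # x = inf gives exp(-inf)*inf
            m = 1.0 - np.exp(-2.0 * x) * (1.0 + x)
    return np.where(bare, 1.0, m)


def damped_inverse_r(kind, r, sigma_pair):
    """``m(r) / r`` evaluated stably, including the ``r -> 0`` limit.

    For ``sigma_pair = 0`` (bare Coulomb) coincident points return ``inf``
    rather than raising: the caller decides how to signal divergence.
    """
    r = np.asarray(r, dtype=float)
    sigma = np.asarray(sigma_pair, dtype=float)
    m = damping_factor(kind, r, sigma)
    small = r < 1e-12
    safe_r = np.where(small, 1.0, r)
    out = m / safe_r
    if kind in ("erf", "swave"):
        # finite contact limits: 2/(sigma sqrt(pi)) and 1/sigma
        bare = sigma == 0.0
        safe_sigma = np.where(bare, 1.0, sigma)
        if kind == "erf":
            limit = 2.0 / (_SQRT_PI * safe_sigma)
        else:
            limit = 1.0 / safe_sigma
        limit = np.where(bare, np.inf, limit)
    elif kind in ("exp2", "exp4"):
        limit = np.where(sigma == 0.0, np.inf, 0.0)
    else:  # none
        limit = np.full(np.broadcast_shapes(r.shape, sigma.shape), np.inf)
    return np.where(small, limit, out)
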