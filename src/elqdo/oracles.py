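"""Closed-form and brute-force references that anchor the stochastic code.

These deliberately share nothing with the Monte Carlo evaluation paths
(beyond the damping kernels), so they can serve as independent oracles:

* isolated-oscillator energies and polarizabilities (closed form),
* exact diagonalization of dipole-coupled oscillators (normal modes),
* finite-difference eigensolves of 1D / radial one-particle problems.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.linalg import eigh_tridiagonal

from .errors import PolarizationCatastropheError, ResolutionError
from .model import QdoSpec

__all__ = [
    "DipoleSystem",
    "isolated_qdo_energy",
    "qdo_polarizability",
    "dispersion_c6",
    "coupled_dipole_energy",
    "grid_eigensolve",
]


def isolated_qdo_energy(spec: QdoSpec) -> float:
    """Ground-state energy (3/2) omega of one isotropic 3D oscillator."""
    return 1.5 * spec.omega


def qdo_polarizability(spec: QdoSpec) -> float:
    """Static dipole polarizability alpha = q^2 / (mu omega^2)."""
    return spec.q**2 / (spec.mu * spec.omega**2)


def dispersion_c6(spec: QdoSpec) -> float:
    """Leading dispersion coefficient C6 = (3/4) alpha^2 omega for an
    identical pair of oscillators."""
    return 0.75 * qdo_polarizability(spec) ** 2 * spec.omega


@dataclass(frozen=True)
class DipoleSystem:
    """Oscillators coupled through the bare dipole tensor
    ``T_ij = (1 - 3 n n) / R^3`` between their centers."""

    qdos: tuple

    def __post_init__(self):
        object.__setattr__(self, "qdos", tuple(self.qdos))

    def dynamical_matrix(self):
        """Mass-weighted 3N x 3N matrix whose eigenvalues are the squared
        normal-mode frequencies."""
        n = len(self.qdos)
        K = np.zeros((3 * n, 3 * n))
        for i, q in enumerate(self.qdos):
            K[3 * i : 3 * i + 3, 3 * i : 3 * i + 3] = q.mu * q.omega**2 * np.eye(3)
        for i in range(n):
            for j in range(i + 1, n):
                dvec = self.qdos[j].center - self.qdos[i].center
                R = np.linalg.norm(dvec)
                nh = dvec / R
                T = (np.eye(3) - 3.0 * np.outer(nh, nh)) / R**3
                block = self.qdos[i].q * self.qdos[j].q * T
                K[3 * i : 3 * i + 3, 3 * j : 3 * j + 3] = block
                K[3 * j : 3 * j + 3, 3 * i : 3 * i + 3] = block.T
        m = np.repeat([q.mu for q in self.qdos], 3)
        return K / np.sqrt(np.outer(m, m))


def coupled_dipole_energy(system: DipoleSystem) -> float:
    """Exact ground-state energy (1/2) sum_k omega_k of the coupled modes.

    Raises :class:`PolarizationCatastropheError` when any squared frequency
    is non-positive (separation inside the dipole-model collapse radius).
    """
    lam = np.linalg.eigvalsh(system.dynamical_matrix())
    if np.any(lam <= 0):
        raise PolarizationCatastropheError(
            "non-positive normal mode: oscillators too close for the dipole model"
        )
    return float(0.5 * np.sum(np.sqrt(lam)))


def grid_eigensolve(potential: Callable[[np.ndarray], np.ndarray], mass: float,
                    x_min: float = None, x_max: float = 40.0, n_points: int = 2000,
                    n_states: int = 1, check_convergence: bool = False,
                    tol: float = 1e-6, radial: bool = False):
    """Lowest eigenvalues of ``-1/(2m) d2/dx2 + V(x)`` on a uniform grid.

    Dirichlet boundaries.  With ``radial=True`` the grid is ``x_j = j h``
    for ``j = 1..n`` so the ghost boundary sits exactly at ``r = 0``, the
    correct condition for the reduced radial function ``u(r) = r R(r)``
    (pass the effective potential including any centrifugal term).

    The second-order finite-difference eigenvalues are Richardson
    extrapolated from ``n`` and ``2n`` points, removing the leading h^2
    error.  With ``check_convergence`` the extrapolation is repeated at
    double resolution and a shift larger than ``tol`` raises
    :class:`ResolutionError`.
    """

    def solve(n):
        if radial:
            h = x_max / (n + 1)
            x = h * np.arange(1, n + 1)
        else:
            x = np.linspace(x_min, x_max, n)
            h = x[1] - x[0]
        diag = 1.0 / (mass * h * h) + potential(x)
        off = np.full(n - 1, -0.5 / (mass * h * h))
        vals = eigh_tridiagonal(diag, off, select="i",
                                select_range=(0, n_states - 1))[0]
        return vals

    def richardson(n):
        return (4.0 * solve(2 * n) - solve(n)) / 3.0

    vals = richardson(n_points)
    if check_convergence:
        vals2 = richardson(2 * n_points)
        if np.any(np.abs(vals - vals2) > tol):
            raise ResolutionError(
                f"eigenvalues shifted by {np.max(np.abs(vals - vals2)):.2e} under refinement"
            )
        vals = vals2
    return vals
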