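"""Trial wave function for the joint electron-drudon system.

The ansatz is a product of three factors,

    Psi = Psi_e(r_e) * Psi_Q(r_d) * J_eQ(r_e, r_d)

* ``Psi_e``: Slater determinants for each spin channel over molecular
  orbitals (contracted Gaussians or hydrogenic 1s functions, centered on
  the nuclei only), times a symmetric Jastrow factor with a homogeneous
  two-body part and an inhomogeneous three/four-body part.
* ``Psi_Q``: a correlated Gaussian ``exp(-1/2 d^T A d)`` in the stacked
  drudon displacements ``d = r_d - R_c`` with a symmetric positive-definite
  ``3N_Q x 3N_Q`` matrix ``A``.  It has no nodes, so drudon degrees of
  freedom carry no fixed-node error in DMC.
* ``J_eQ``: a dipolar coupling ``exp(mu(r_e)^T B d)`` where ``mu`` is the
  electronic dipole (nuclear-charge-weighted origin) and ``B`` holds
  ``3 x 3N_Q`` free parameters; strictly positive, so it deforms but never
  creates nodes.

All evaluation routines are batched over arbitrary leading axes; electron
coordinates have shape ``(..., N_e, 3)`` with the spin-up block first and
drudons ``(..., N_Q, 3)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .errors import ConfigurationError, ParameterError
from .model import ElQdoSystem, WalkerConfiguration, potential_energy

__all__ = [
    "BasisFunction",
    "MolecularOrbitals",
    "AnsatzParameters",
    "log_abs_psi",
    "slater_factor",
    "jastrow_two_body",
    "jastrow_three_body",
    "drudon_factor",
    "coupling_factor",
    "local_energy",
    "parameter_log_derivatives",
    "delta_log_psi",
    "hydrogen_1s_orbitals",
]

#: |det| below this is treated as a node.
NODE_EPS = 1e-300

CUSP_PARALLEL = 0.25
CUSP_ANTIPARALLEL = 0.5


# ----------------------------------------------------------------------
# basis functions
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class BasisFunction:
    """A contracted Cartesian Gaussian, or a hydrogenic (Slater 1s) orbital.

    ``kind="gto"``: sum_k c_k x^lx y^ly z^lz exp(-a_k s^2) about ``center``.
    ``kind="sto1s"``: exp(-zeta s); carries the exact nuclear cusp needed
    for the all-electron test atoms.
    """

    center: np.ndarray
    kind: str = "gto"
    angular: Tuple[int, int, int] = (0, 0, 0)
    exponents: Tuple[float, ...] = (1.0,)
    coefficients: Tuple[float, ...] = (1.0,)
    zeta: float = 1.0

    def __post_init__(self):
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        if self.kind not in ("gto", "sto1s"):
            raise ConfigurationError(f"unknown basis kind {self.kind!r}")
        if self.kind == "gto":
            if any(a <= 0 for a in self.exponents):
                raise ParameterError("Gaussian exponents must be > 0")
            if len(self.exponents) != len(self.coefficients):
                raise ConfigurationError("exponents/coefficients length mismatch")
            if any(l < 0 for l in self.angular):
                raise ConfigurationError("angular momenta must be >= 0")
        elif self.zeta <= 0:
            raise ParameterError("zeta must be > 0")

    def evaluate(self, points, derivatives: bool = True):
        """Value, gradient and Laplacian at ``points`` of shape (..., 3).

        Returns ``(val, grad, lap)`` with shapes ``(...,), (..., 3), (...,)``;
        with ``derivatives=False`` only the value is computed and the other
        two are ``None``.
        """
        pts = np.asarray(points, dtype=float)
        rel = pts - self.center
        if self.kind == "sto1s":
            s = np.linalg.norm(rel, axis=-1)
            val = np.exp(-self.zeta * s)
            if not derivatives:
                return val, None, None
            s_safe = np.where(s < 1e-12, 1e-12, s)
            grad = (-self.zeta / s_safe)[..., None] * rel * val[..., None]
            lap = (self.zeta**2 - 2.0 * self.zeta / s_safe) * val
            return val, grad, lap

        x, y, z = rel[..., 0], rel[..., 1], rel[..., 2]
        s2 = x * x + y * y + z * z
        lx, ly, lz = self.angular
        poly = _pow(x, lx) * _pow(y, ly) * _pow(z, lz)
        if not derivatives:
            val = np.zeros(s2.shape)
            for a, c in zip(self.exponents, self.coefficients):
                val += poly * (c * np.exp(-a * s2))
            return val, None, None
        val = np.zeros(s2.shape)
        grad = np.zeros(rel.shape)
        lap = np.zeros(s2.shape)
        for a, c in zip(self.exponents, self.coefficients):
            g = c * np.exp(-a * s2)
            val += poly * g
            # gradient & laplacian per axis (polynomial recursion)
            comps = ((x, lx), (y, ly), (z, lz))
            for ax in range(3):
                t, l = comps[ax]
                rest = np.ones_like(s2)
                for bx in range(3):
                    if bx != ax:
                        tb, lb = comps[bx]
                        rest = rest * _pow(tb, lb)
                d1 = -2.0 * a * _pow(t, l + 1)
                if l >= 1:
                    d1 = d1 + l * _pow(t, l - 1)
                grad[..., ax] += rest * d1 * g
                d2 = 4.0 * a * a * _pow(t, l + 2) - 2.0 * a * (2 * l + 1) * _pow(t, l)
                if l >= 2:
                    d2 = d2 + l * (l - 1) * _pow(t, l - 2)
                lap += rest * d2 * g
        return val, grad, lap


def _pow(x, n):
    if n == 0:
        return np.ones_like(x)
    return x**n


@dataclass(frozen=True)
class MolecularOrbitals:
    """Molecular orbitals as linear combinations of basis functions."""

    basis: Tuple[BasisFunction, ...]
    coefficients: np.ndarray  # (n_orbitals, n_basis)

    def __post_init__(self):
        object.__setattr__(self, "basis", tuple(self.basis))
        c = np.atleast_2d(np.asarray(self.coefficients, dtype=float))
        if c.shape[1] != len(self.basis):
            raise ConfigurationError("coefficient matrix does not match basis size")
        object.__setattr__(self, "coefficients", c)

    @property
    def n_orbitals(self) -> int:
        return self.coefficients.shape[0]

    def evaluate(self, points, derivatives: bool = True):
        """Orbital values/gradients/Laplacians at (..., N, 3) points.

        Returns shapes ``(..., N, M)``, ``(..., N, M, 3)``, ``(..., N, M)``;
        with ``derivatives=False`` the last two are ``None``.
        """
        vals, grads, laps = [], [], []
        for bf in self.basis:
            v, g, l = bf.evaluate(points, derivatives=derivatives)
            vals.append(v)
            grads.append(g)
            laps.append(l)
        V = np.stack(vals, axis=-1)  # (..., N, Q)
        C = self.coefficients
        mo_v = V @ C.T
        if not derivatives:
            return mo_v, None, None
        G = np.stack(grads, axis=-2)  # (..., N, Q, 3)
        L = np.stack(laps, axis=-1)
        mo_l = L @ C.T
        mo_g = np.einsum("...nqa,mq->...nma", G, C)
        return mo_v, mo_g, mo_l


def hydrogen_1s_orbitals(nucleus_position, zeta: float = 1.0) -> MolecularOrbitals:
    """A single hydrogenic 1s orbital (``zeta = 1`` is the exact H ground state)."""
    bf = BasisFunction(center=np.asarray(nucleus_position, float), kind="sto1s", zeta=zeta)
    return MolecularOrbitals(basis=(bf,), coefficients=np.array([[1.0]]))


# ----------------------------------------------------------------------
# ansatz parameters
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class AnsatzParameters:
    """All variational parameters of the three-factor ansatz.

    Orbital coefficients are fixed during optimization; the variational
    set is {b, g, zeta, gamma, A, B}.
    """

    mo: Optional[MolecularOrbitals] = None
    b_par: float = 1.0
    b_anti: float = 1.0
    g_par: np.ndarray = field(default_factory=lambda: np.zeros(0))
    zeta_par: np.ndarray = field(default_factory=lambda: np.zeros(0))
    g_anti: np.ndarray = field(default_factory=lambda: np.zeros(0))
    zeta_anti: np.ndarray = field(default_factory=lambda: np.zeros(0))
    jastrow_basis: Tuple[BasisFunction, ...] = ()
    gamma: Optional[np.ndarray] = None
    A: Optional[np.ndarray] = None
    B: Optional[np.ndarray] = None

    def __post_init__(self):
        for name in ("g_par", "zeta_par", "g_anti", "zeta_anti"):
            object.__setattr__(self, name, np.atleast_1d(np.asarray(getattr(self, name), float)))
        if self.g_par.shape != self.zeta_par.shape or self.g_anti.shape != self.zeta_anti.shape:
            raise ConfigurationError("g and zeta arrays must match in length")
        if np.any(self.zeta_par <= 0) or np.any(self.zeta_anti <= 0):
            raise ParameterError("Jastrow Gaussian exponents must be > 0")
        object.__setattr__(self, "jastrow_basis", tuple(self.jastrow_basis))
        if self.gamma is not None:
            gm = np.asarray(self.gamma, dtype=float)
            if gm.shape != (len(self.jastrow_basis),) * 2:
                raise ConfigurationError("gamma must be Q_J x Q_J")
            if not np.allclose(gm, gm.T, atol=1e-12):
                raise ParameterError("gamma must be symmetric")
            object.__setattr__(self, "gamma", gm)
        if self.A is not None:
            A = np.asarray(self.A, dtype=float)
            if A.ndim != 2 or A.shape[0] != A.shape[1] or A.shape[0] % 3:
                raise ConfigurationError("A must be square 3N_Q x 3N_Q")
            if not np.allclose(A, A.T, atol=1e-10):
                raise ParameterError("A must be symmetric")
            if np.any(np.linalg.eigvalsh(A) <= 0):
                raise ParameterError("A must be positive definite")
            object.__setattr__(self, "A", A)
        if self.B is not None:
            B = np.asarray(self.B, dtype=float)
            if B.ndim != 2 or B.shape[0] != 3:
                raise ConfigurationError("B must be 3 x 3N_Q")
            object.__setattr__(self, "B", B)

    @staticmethod
    def qdo_ground_state(system: ElQdoSystem, scale: float = 1.0) -> "AnsatzParameters":
        """Uncoupled drudon Gaussian with ``A = scale * diag(mu_i omega_i I)``.

        ``scale = 1`` is the exact ground state of non-interacting QDOs."""
        diag = np.repeat(system.qdo_mu * system.qdo_omega, 3)
        return AnsatzParameters(A=np.diag(scale * diag))

    def with_A(self, A) -> "AnsatzParameters":
        return replace(self, A=np.asarray(A, float))


def _split_spins(system: ElQdoSystem, electrons):
    up = electrons[..., : system.n_up, :]
    down = electrons[..., system.n_up :, :]
    return up, down


# ----------------------------------------------------------------------
# individual factors (log scale)
# ----------------------------------------------------------------------

def slater_factor(params: AnsatzParameters, system: ElQdoSystem, electrons):
    """log|det S_up| + log|det S_down| and the product of determinant signs.

    Returns ``(log_abs, sign)``; a singular channel gives ``-inf`` and
    sign 0 (node) rather than raising.
    """
    if system.n_electrons == 0:
        shape = np.asarray(electrons).shape[:-2] if electrons is not None else ()
        return np.zeros(shape), np.ones(shape)
    if params.mo is None:
        raise ConfigurationError("electronic system requires molecular orbitals")
    log_abs = None
    sign = None
    for block, n in zip(_split_spins(system, electrons), (system.n_up, system.n_down)):
        if n == 0:
            continue
        if params.mo.n_orbitals < n:
            raise ConfigurationError(
                f"{n} occupied orbitals requested but only {params.mo.n_orbitals} provided"
            )
        vals, _, _ = params.mo.evaluate(block, derivatives=False)
        mat = vals[..., :n]
        s, la = np.linalg.slogdet(mat)
        log_abs = la if log_abs is None else log_abs + la
        sign = s if sign is None else sign * s
    return log_abs, sign


def _pair_u(r, b, c, g, zeta, order=0):
    """Pair Jastrow u(r) = c r/(1+b r) + sum_n g_n exp(-zeta_n r^2).

    ``order`` 0/1/2 selects u, u' or u''.
    """
    br = 1.0 + b * r
    if order == 0:
        out = c * r / br
    elif order == 1:
        out = c / br**2
    else:
        out = -2.0 * b * c / br**3
    if len(g):
        r2 = r[..., None] ** 2
        e = g * np.exp(-zeta * r2)
        if order == 0:
            out = out + e.sum(axis=-1)
        elif order == 1:
            out = out + (-2.0 * zeta * r[..., None] * e).sum(axis=-1)
        else:
            out = out + ((4.0 * zeta**2 * r2 - 2.0 * zeta) * e).sum(axis=-1)
    return out


def _pair_structure(system: ElQdoSystem):
    ne = system.n_electrons
    spins = np.zeros(ne, dtype=int)
    spins[system.n_up :] = 1
    parallel = spins[:, None] == spins[None, :]
    return parallel


def jastrow_two_body(params: AnsatzParameters, system: ElQdoSystem, electrons):
    """Homogeneous two-body Jastrow log-factor sum_{i<j} u_s(r_ij)."""
    ne = system.n_electrons
    if ne < 2:
        return np.zeros(np.asarray(electrons).shape[:-2])
    e = np.asarray(electrons, dtype=float)
    diff = e[..., :, None, :] - e[..., None, :, :]
    r = np.sqrt(np.sum(diff * diff, axis=-1))
    parallel = _pair_structure(system)
    iu = np.triu_indices(ne, 1)
    rij = r[..., iu[0], iu[1]]
    par = parallel[iu]
    u_p = _pair_u(rij, params.b_par, CUSP_PARALLEL, params.g_par, params.zeta_par)
    u_a = _pair_u(rij, params.b_anti, CUSP_ANTIPARALLEL, params.g_anti, params.zeta_anti)
    return np.sum(np.where(par, u_p, u_a), axis=-1)


def jastrow_three_body(params: AnsatzParameters, system: ElQdoSystem, electrons):
    """Inhomogeneous three/four-body Jastrow log-factor.

    ``sum_{i<j} chi(r_i)^T gamma chi(r_j)``, evaluated as
    ``(V gamma) V^T`` summed over the strict upper triangle so the cost is
    O(N_e^2 Q_J) multiplications per configuration after the O(N_e Q_J)
    basis projection.
    """
    if params.gamma is None or system.n_electrons < 2:
        return np.zeros(np.asarray(electrons).shape[:-2])
    V = _jastrow_basis_values(params, electrons)  # (..., Ne, QJ)
    P = (V @ params.gamma) @ np.swapaxes(V, -1, -2)
    iu = np.triu_indices(system.n_electrons, 1)
    return np.sum(P[..., iu[0], iu[1]], axis=-1)


def _jastrow_basis_values(params, electrons, with_derivs=False):
    vals, grads, laps = [], [], []
    for bf in params.jastrow_basis:
        v, g, l = bf.evaluate(electrons, derivatives=with_derivs)
        vals.append(v)
        if with_derivs:
            grads.append(g)
            laps.append(l)
    V = np.stack(vals, axis=-1)
    if not with_derivs:
        return V
    G = np.stack(grads, axis=-2)  # (..., Ne, QJ, 3)
    L = np.stack(laps, axis=-1)
    return V, G, L


def drudon_factor(params: AnsatzParameters, system: ElQdoSystem, drudons):
    """log Psi_Q = -1/2 d^T A d over stacked displacements d = r_d - R_c."""
    if system.n_qdos == 0:
        return np.zeros(np.asarray(drudons).shape[:-2])
    if params.A is None:
        raise ConfigurationError("QDO system requires the A matrix")
    disp = np.asarray(drudons, float) - system.centers
    dflat = disp.reshape(*disp.shape[:-2], 3 * system.n_qdos)
    return -0.5 * np.einsum("...k,kl,...l->...", dflat, params.A, dflat)


def electronic_dipole(system: ElQdoSystem, electrons):
    """mu = sum_i Z_i R_i - sum_j r_j (nuclear-charge-weighted origin)."""
    nuc = (
        np.sum(system.nuclei_Z[:, None] * system.nuclei_pos, axis=0)
        if system.n_nuclei
        else np.zeros(3)
    )
    return nuc - np.sum(np.asarray(electrons, float), axis=-2)


def coupling_factor(params: AnsatzParameters, system: ElQdoSystem, electrons, drudons):
    """log J_eQ = mu(r_e)^T B d; zero when B is absent."""
    if params.B is None or system.n_qdos == 0 or system.n_electrons == 0:
        shapes = [np.asarray(a).shape[:-2] for a in (electrons, drudons) if a is not None]
        return np.zeros(np.broadcast_shapes(*shapes) if shapes else ())
    mu = electronic_dipole(system, electrons)
    disp = np.asarray(drudons, float) - system.centers
    dflat = disp.reshape(*disp.shape[:-2], 3 * system.n_qdos)
    return np.einsum("...a,ab,...b->...", mu, params.B, dflat)


# ----------------------------------------------------------------------
# full evaluation with per-particle gradients and Laplacians
# ----------------------------------------------------------------------

def _empty(system, electrons, drudons):
    shapes = []
    if electrons is not None:
        shapes.append(np.asarray(electrons).shape[:-2])
    if drudons is not None:
        shapes.append(np.asarray(drudons).shape[:-2])
    return np.broadcast_shapes(*shapes) if shapes else ()


def evaluate(params: AnsatzParameters, system: ElQdoSystem, electrons=None, drudons=None,
             derivatives: bool = True):
    """Evaluate log|Psi|, sign, and (optionally) per-particle derivatives.

    Returns a dict with keys ``log_psi``, ``sign`` and, when
    ``derivatives``, ``grad_e (..., Ne, 3)``, ``laplog_e (..., Ne)``,
    ``grad_d``, ``laplog_d`` — gradient and Laplacian of log|Psi| per
    particle, from which ``lap Psi / Psi = laplog + |grad|^2``.
    """
    ne, nq = system.n_electrons, system.n_qdos
    e = np.asarray(electrons, float) if electrons is not None else np.zeros((0, 3))
    d = np.asarray(drudons, float) if drudons is not None else np.zeros((0, 3))
    batch = np.broadcast_shapes(e.shape[:-2], d.shape[:-2])
    log_psi = np.zeros(batch)
    sign = np.ones(batch)
    out = {
        "grad_e": np.zeros(batch + (ne, 3)),
        "laplog_e": np.zeros(batch + (ne,)),
        "grad_d": np.zeros(batch + (nq, 3)),
        "laplog_d": np.zeros(batch + (nq,)),
    }

    # --- electronic Slater part
    if ne:
        if params.mo is None:
            raise ConfigurationError("electronic system requires molecular orbitals")
        col = 0
        for block_idx, n in enumerate((system.n_up, system.n_down)):
            if n == 0:
                continue
            if params.mo.n_orbitals < n:
                raise ConfigurationError(
                    f"{n} occupied orbitals requested but only "
                    f"{params.mo.n_orbitals} provided")
            sl = slice(col, col + n)
            blk = e[..., sl, :]
            vals, grads, laps = params.mo.evaluate(blk)
            mat = vals[..., :n]  # (..., n, n) rows=electrons, cols=orbitals
            s, la = np.linalg.slogdet(mat)
            log_psi = log_psi + la
            sign = sign * s
            if derivatives:
                ok = np.abs(s) > 0
                inv = np.linalg.inv(np.where(ok[..., None, None], mat, np.eye(n)))
                # grad_i logdet = sum_k inv[k, i] grad phi_k(r_i)
                g = np.einsum("...ik,...ika->...ia", np.swapaxes(inv, -1, -2), grads[..., :n, :])
                lap_over = np.einsum("...ik,...ik->...i", np.swapaxes(inv, -1, -2), laps[..., :n])
                out["grad_e"][..., sl, :] += g
                out["laplog_e"][..., sl] += lap_over - np.sum(g * g, axis=-1)
            col += n

    # --- two-body Jastrow
    if ne >= 2:
        diff = e[..., :, None, :] - e[..., None, :, :]
        r = np.sqrt(np.sum(diff * diff, axis=-1))
        off = ~np.eye(ne, dtype=bool)
        r_safe = np.where(off, r, 1.0)
        parallel = _pair_structure(system)
        args_p = (params.b_par, CUSP_PARALLEL, params.g_par, params.zeta_par)
        args_a = (params.b_anti, CUSP_ANTIPARALLEL, params.g_anti, params.zeta_anti)
        u0 = np.where(parallel, _pair_u(r_safe, *args_p, 0), _pair_u(r_safe, *args_a, 0))
        log_psi = log_psi + 0.5 * np.sum(np.where(off, u0, 0.0), axis=(-1, -2))
        if derivatives:
            u1 = np.where(parallel, _pair_u(r_safe, *args_p, 1), _pair_u(r_safe, *args_a, 1))
            u2 = np.where(parallel, _pair_u(r_safe, *args_p, 2), _pair_u(r_safe, *args_a, 2))
            unit = diff / r_safe[..., None]
            gmat = np.where(off[..., None], u1[..., None] * unit, 0.0)
            out["grad_e"] += np.sum(gmat, axis=-2)
            out["laplog_e"] += np.sum(np.where(off, u2 + 2.0 * u1 / r_safe, 0.0), axis=-1)

    # --- three/four-body Jastrow
    if params.gamma is not None and ne >= 2:
        V, G, L = _jastrow_basis_values(params, e, with_derivs=True)
        Vsum = np.sum(V, axis=-2)  # (..., QJ)
        W = (Vsum[..., None, :] - V) @ params.gamma  # (..., Ne, QJ): gamma (sum_{j!=i} v_j)
        # log J3 = 1/2 sum_i v_i . W_i
        log_psi = log_psi + 0.5 * np.einsum("...iq,...iq->...", V, W)
        if derivatives:
            out["grad_e"] += np.einsum("...iqa,...iq->...ia", G, W)
            out["laplog_e"] += np.einsum("...iq,...iq->...i", L, W)

    # --- drudon Gaussian
    if nq:
        if params.A is None:
            raise ConfigurationError("QDO system requires the A matrix")
        disp = d - system.centers
        dflat = disp.reshape(*disp.shape[:-2], 3 * nq)
        Ad = dflat @ params.A
        log_psi = log_psi - 0.5 * np.sum(dflat * Ad, axis=-1)
        if derivatives:
            out["grad_d"] += -Ad.reshape(*Ad.shape[:-1], nq, 3)
            tr = np.diag(params.A).reshape(nq, 3).sum(axis=1)
            out["laplog_d"] += -tr

    # --- electron-drudon coupling
    if params.B is not None and nq and ne:
        mu = electronic_dipole(system, e)
        disp = d - system.centers
        dflat = disp.reshape(*disp.shape[:-2], 3 * nq)
        Bd = dflat @ params.B.T  # (..., 3)
        log_psi = log_psi + np.sum(mu * Bd, axis=-1)
        if derivatives:
            out["grad_e"] += -Bd[..., None, :]
            Btmu = np.einsum("ab,...a->...b", params.B, mu)
            out["grad_d"] += Btmu.reshape(*Btmu.shape[:-1], nq, 3)

    out["log_psi"] = log_psi
    out["sign"] = sign
    return out


def log_abs_psi(params: AnsatzParameters, system: ElQdoSystem, electrons=None, drudons=None):
    """``(log|Psi|, sign)``; a node gives ``(-inf, 0)``."""
    if isinstance(electrons, WalkerConfiguration):
        w = electrons
        electrons, drudons = w.electrons, w.drudons
    res = evaluate(params, system, electrons, drudons, derivatives=False)
    return res["log_psi"], res["sign"]


def local_energy(params: AnsatzParameters, system: ElQdoSystem, electrons=None, drudons=None):
    """Local energy H Psi / Psi (hartree), batched.

    Kinetic terms are assembled per particle from the log-derivative
    identity ``lap Psi/Psi = lap log|Psi| + |grad log|Psi||^2``; drudon
    kinetic terms carry their mass ``1/(2 mu_i)``.
    """
    if isinstance(electrons, WalkerConfiguration):
        w = electrons
        electrons, drudons = w.electrons, w.drudons
    res = evaluate(params, system, electrons, drudons, derivatives=True)
    kin = 0.0
    if system.n_electrons:
        lap_over_psi = res["laplog_e"] + np.sum(res["grad_e"] ** 2, axis=-1)
        kin = kin - 0.5 * np.sum(lap_over_psi, axis=-1)
    if system.n_qdos:
        lap_over_psi = res["laplog_d"] + np.sum(res["grad_d"] ** 2, axis=-1)
        kin = kin - np.sum(lap_over_psi / (2.0 * system.qdo_mu), axis=-1)
    return kin + potential_energy(system, electrons, drudons)


# ----------------------------------------------------------------------
# single-particle move ratio (only affected factors recomputed)
# ----------------------------------------------------------------------

def delta_log_psi(params, system, electrons, drudons, species, index, new_pos):
    """log|Psi(new)| - log|Psi(old)| for a single-particle trial move.

    Only the factors that depend on the moved particle are recomputed:
    an electron move touches its Slater spin block and the Jastrow and
    coupling factors; a drudon move touches only the drudon Gaussian and
    the coupling.  Returns ``(dlog, sign_new)``.
    """
    if species == "e":
        e_new = np.array(electrons, copy=True)
        e_new[..., index, :] = new_pos
        # Slater: recompute the affected spin channel only
        n_up = system.n_up
        if index < n_up:
            sl, n = slice(0, n_up), n_up
        else:
            sl, n = slice(n_up, None), system.n_down
        dlog = np.zeros(np.asarray(e_new).shape[:-2])
        sign_new = np.ones_like(dlog)
        if params.mo is not None and n:
            v_old, _, _ = params.mo.evaluate(np.asarray(electrons)[..., sl, :],
                                             derivatives=False)
            v_new, _, _ = params.mo.evaluate(e_new[..., sl, :], derivatives=False)
            s_o, la_o = np.linalg.slogdet(v_old[..., :n])
            s_n, la_n = np.linalg.slogdet(v_new[..., :n])
            dlog += la_n - la_o
            sign_new *= s_n
        dlog += jastrow_two_body(params, system, e_new) - jastrow_two_body(
            params, system, electrons
        )
        dlog += jastrow_three_body(params, system, e_new) - jastrow_three_body(
            params, system, electrons
        )
        if params.B is not None and system.n_qdos:
            dlog += coupling_factor(params, system, e_new, drudons) - coupling_factor(
                params, system, electrons, drudons
            )
        return dlog, sign_new
    if species == "d":
        d_new = np.array(drudons, copy=True)
        d_new[..., index, :] = new_pos
        dlog = drudon_factor(params, system, d_new) - drudon_factor(params, system, drudons)
        if params.B is not None and system.n_electrons:
            dlog += coupling_factor(params, system, electrons, d_new) - coupling_factor(
                params, system, electrons, drudons
            )
        return dlog, np.ones(np.asarray(d_new).shape[:-2])
    raise ConfigurationError(f"unknown species {species!r}")


# ----------------------------------------------------------------------
# parameter derivatives for stochastic reconfiguration
# ----------------------------------------------------------------------

def parameter_labels(params: AnsatzParameters, system: ElQdoSystem):
    """Ordered labels of the variational parameter vector."""
    labels = []
    if system.n_electrons >= 2:
        labels += ["b_par", "b_anti"]
        labels += [f"g_par[{n}]" for n in range(len(params.g_par))]
        labels += [f"zeta_par[{n}]" for n in range(len(params.zeta_par))]
        labels += [f"g_anti[{n}]" for n in range(len(params.g_anti))]
        labels += [f"zeta_anti[{n}]" for n in range(len(params.zeta_anti))]
        if params.gamma is not None:
            q = params.gamma.shape[0]
            labels += [f"gamma[{a},{b}]" for a in range(q) for b in range(a, q)]
    if params.A is not None and system.n_qdos:
        m = params.A.shape[0]
        labels += [f"A[{a},{b}]" for a in range(m) for b in range(a, m)]
    if params.B is not None and system.n_qdos and system.n_electrons:
        labels += [f"B[{a},{b}]" for a in range(3) for b in range(params.B.shape[1])]
    return labels


def parameter_log_derivatives(params: AnsatzParameters, system: ElQdoSystem,
                              electrons=None, drudons=None):
    """O_k = d log|Psi| / d p_k over the variational set, batched (..., P).

    Symmetric blocks (gamma, A) are counted once per independent entry;
    orbital coefficients are excluded (the determinant is fixed).
    """
    ne, nq = system.n_electrons, system.n_qdos
    e = np.asarray(electrons, float) if electrons is not None else np.zeros((0, 3))
    d = np.asarray(drudons, float) if drudons is not None else np.zeros((0, 3))
    batch = np.broadcast_shapes(e.shape[:-2], d.shape[:-2])
    cols = []

    if ne >= 2:
        diff = e[..., :, None, :] - e[..., None, :, :]
        r = np.sqrt(np.sum(diff * diff, axis=-1))
        iu = np.triu_indices(ne, 1)
        rij = r[..., iu[0], iu[1]]
        par = _pair_structure(system)[iu]
        # d u / d b = -c r^2 / (1 + b r)^2
        for b, c, is_par in ((params.b_par, CUSP_PARALLEL, True),
                             (params.b_anti, CUSP_ANTIPARALLEL, False)):
            du = -c * rij**2 / (1.0 + b * rij) ** 2
            cols.append(np.sum(np.where(par == is_par, du, 0.0), axis=-1))
        for g, zeta, is_par in ((params.g_par, params.zeta_par, True),
                                (params.g_anti, params.zeta_anti, False)):
            for n in range(len(g)):
                eterm = np.exp(-zeta[n] * rij**2)
                cols.append(np.sum(np.where(par == is_par, eterm, 0.0), axis=-1))
            for n in range(len(g)):
                eterm = -g[n] * rij**2 * np.exp(-zeta[n] * rij**2)
                cols.append(np.sum(np.where(par == is_par, eterm, 0.0), axis=-1))
        if params.gamma is not None:
            V = _jastrow_basis_values(params, e)  # (..., Ne, QJ)
            S = np.sum(V, axis=-2)
            VV = np.einsum("...iq,...ip->...qp", V, V)
            outer = S[..., :, None] * S[..., None, :]
            full = outer - VV  # sum_{i != j} chi_q(i) chi_p(j)
            q = params.gamma.shape[0]
            for a in range(q):
                for b_ in range(a, q):
                    if a == b_:
                        cols.append(0.5 * full[..., a, a])
                    else:
                        cols.append(full[..., a, b_])
    if params.A is not None and nq:
        disp = d - system.centers
        df = disp.reshape(*disp.shape[:-2], 3 * nq)
        m = params.A.shape[0]
        for a in range(m):
            for b_ in range(a, m):
                if a == b_:
                    cols.append(-0.5 * df[..., a] ** 2)
                else:
                    cols.append(-df[..., a] * df[..., b_])
    if params.B is not None and nq and ne:
        mu = electronic_dipole(system, e)
        disp = d - system.centers
        df = disp.reshape(*disp.shape[:-2], 3 * nq)
        for a in range(3):
            for b_ in range(df.shape[-1]):
                cols.append(mu[..., a] * df[..., b_])
    if not cols:
        return np.zeros(batch + (0,))
    return np.stack([np.broadcast_to(c, batch) for c in cols], axis=-1)


def apply_parameter_update(params: AnsatzParameters, system: ElQdoSystem, delta,
                           spd_floor: float = 1e-6):
    """Return new parameters ``p + delta`` in the order of
    :func:`parameter_labels`; A is re-symmetrized and projected back to
    positive definite with an eigenvalue floor if the step breaks it."""
    delta = np.asarray(delta, float)
    k = 0
    kw = {}
    ne, nq = system.n_electrons, system.n_qdos
    if ne >= 2:
        kw["b_par"] = params.b_par + delta[k]; k += 1
        kw["b_anti"] = params.b_anti + delta[k]; k += 1
        for name in ("g_par", "zeta_par", "g_anti", "zeta_anti"):
            arr = getattr(params, name)
            kw[name] = arr + delta[k : k + len(arr)]
            k += len(arr)
        if params.gamma is not None:
            q = params.gamma.shape[0]
            gm = params.gamma.copy()
            for a in range(q):
                for b_ in range(a, q):
                    gm[a, b_] += delta[k]
                    gm[b_, a] = gm[a, b_]
                    k += 1
            kw["gamma"] = gm
    if params.A is not None and nq:
        m = params.A.shape[0]
        A = params.A.copy()
        for a in range(m):
            for b_ in range(a, m):
                A[a, b_] += delta[k]
                A[b_, a] = A[a, b_]
                k += 1
        w, v = np.linalg.eigh(A)
        if np.any(w <= spd_floor):
            A = (v * np.maximum(w, spd_floor)) @ v.T
        kw["A"] = A
    if params.B is not None and nq and ne:
        nb = params.B.size
        kw["B"] = params.B + delta[k : k + nb].reshape(params.B.shape)
        k += nb
    if k != len(delta):
        raise ConfigurationError("parameter update length mismatch")
    return replace(params, **kw)
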