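"""System definition and potential energy of the electron + Drude-oscillator model.

A quantum Drude oscillator (QDO) is a coarse-grained atom or molecule: a
fixed center of charge ``+q`` plus a light quantum particle (the *drudon*)
of charge ``-q`` and mass ``mu`` bound to the center by a harmonic well of
frequency ``omega``.  Static multipoles of polar molecules are added as
fixed point charges attached to a parental QDO.  An explicit electronic
subsystem (nuclei + electrons) couples to this environment through Coulomb
interactions that are short-range damped (see :mod:`elqdo.damping`).

Interaction rules
-----------------
* Drudons interact with every other charged particle by (damped) Coulomb,
  except their own center (harmonic well instead) and the point charges of
  their parental QDO (omitted).
* The electronic subsystem (electron-electron, electron-nucleus,
  nucleus-nucleus) is always bare Coulomb.
* Every pair with at least one environment member (drudon, center, point
  charge) is damped with the pair length ``sqrt(sigma_i sigma_j)``.
* Center interactions with their own point charges are rigid intramolecular
  constants and excluded by default (``include_center_own_pc``).

All positions and energies are in Hartree atomic units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import units
from .damping import DAMPING_KINDS, damped_inverse_r, pair_sigma
from .errors import ConfigurationError, DomainError, GeometryError

__all__ = [
    "QdoSpec",
    "PointCharge",
    "Nucleus",
    "ElQdoSystem",
    "WalkerConfiguration",
    "SPECIES_QDO_PARAMS",
    "make_qdo",
    "potential_energy",
    "coulomb_pair_count",
    "build_water_qdo",
    "deform_cage",
]

#: Drude-oscillator parameters {species: (q, omega, mu)} in atomic units.
SPECIES_QDO_PARAMS = {
    "Ar": (1.3314, 0.7272, 0.3020),
    "H2O": (1.1973, 0.6287, 0.3656),
}

# TIP4P electrostatics used by the water QDO model (atomic units / angstrom)
TIP4P_Q_H = 0.605
TIP4P_Q_M = -1.21
TIP4P_R_OM_ANGSTROM = 0.2667


def _vec3(x, name):
    v = np.asarray(x, dtype=float)
    if v.shape != (3,):
        raise ConfigurationError(f"{name} must be a 3-vector, got shape {v.shape}")
    return v


@dataclass(frozen=True)
class QdoSpec:
    """One quantum Drude oscillator: fixed center + drudon parameters."""

    center: np.ndarray
    q: float
    mu: float
    omega: float
    sigma: float = 0.5

    def __post_init__(self):
        object.__setattr__(self, "center", _vec3(self.center, "center"))
        if self.q <= 0 or self.mu <= 0 or self.omega <= 0:
            raise DomainError("q, mu, omega must be strictly positive")
        if self.sigma < 0:
            raise DomainError("sigma must be >= 0")


@dataclass(frozen=True)
class PointCharge:
    """A fixed point charge, optionally attached to a parental QDO."""

    position: np.ndarray
    charge: float
    parent: Optional[int] = None
    sigma: float = 0.5

    def __post_init__(self):
        object.__setattr__(self, "position", _vec3(self.position, "position"))
        if self.sigma < 0:
            raise DomainError("sigma must be >= 0")


@dataclass(frozen=True)
class Nucleus:
    """A fixed nucleus of the explicit electronic subsystem."""

    position: np.ndarray
    charge: int

    def __post_init__(self):
        object.__setattr__(self, "position", _vec3(self.position, "position"))
        if int(self.charge) != self.charge or self.charge < 1:
            raise DomainError("nuclear charge must be a positive integer")
        object.__setattr__(self, "charge", int(self.charge))


class ElQdoSystem:
    """Electrons + nuclei coupled to a QDO / point-charge environment.

    Parameters
    ----------
    nuclei, qdos, point_charges : sequences of the dataclasses above.
    n_up, n_down : electron counts per spin channel.
    damping_kind : one of ``none, erf, exp2, exp4, swave``.
    sigma_e : damping length assigned to electrons and nuclei for their
        pairs with environment members (bohr).
    qdo_coupling : ``"coulomb"`` (full model) or ``"dipole"`` — the
        inter-oscillator coupling truncated at the dipole tensor
        ``q_i q_j d_i . T_ij . d_j``; only valid for pure-QDO systems and
        used for comparison against the closed-form normal-mode solution.
    include_center_own_pc : include the rigid center/own-point-charge
        constants (default off; they cancel in interaction energies).
    """

    def __init__(
        self,
        nuclei: Sequence[Nucleus] = (),
        n_up: int = 0,
        n_down: int = 0,
        qdos: Sequence[QdoSpec] = (),
        point_charges: Sequence[PointCharge] = (),
        damping_kind: str = "erf",
        sigma_e: float = 0.5,
        qdo_coupling: str = "coulomb",
        include_center_own_pc: bool = False,
    ):
        if damping_kind not in DAMPING_KINDS:
            raise ConfigurationError(f"unknown damping kind {damping_kind!r}")
        if qdo_coupling not in ("coulomb", "dipole"):
            raise ConfigurationError(f"unknown qdo_coupling {qdo_coupling!r}")
        if n_up < 0 or n_down < 0:
            raise ConfigurationError("electron counts must be >= 0")
        if sigma_e < 0:
            raise DomainError("sigma_e must be >= 0")
        self.nuclei = tuple(nuclei)
        self.qdos = tuple(qdos)
        self.point_charges = tuple(point_charges)
        self.n_up = int(n_up)
        self.n_down = int(n_down)
        self.damping_kind = damping_kind
        self.sigma_e = float(sigma_e)
        self.qdo_coupling = qdo_coupling
        self.include_center_own_pc = bool(include_center_own_pc)

        if self.n_electrons == 0 and self.n_qdos == 0:
            raise ConfigurationError("system has no quantum particles")
        for pc in self.point_charges:
            if pc.parent is not None and not (0 <= pc.parent < self.n_qdos):
                raise ConfigurationError(f"point charge parent {pc.parent} out of range")
        if qdo_coupling == "dipole" and (self.n_electrons or self.point_charges):
            raise ConfigurationError(
                "dipole-truncated coupling is defined for pure-QDO systems only"
            )

        # cached arrays
        self.nuclei_pos = np.array([n.position for n in self.nuclei]).reshape(-1, 3)
        self.nuclei_Z = np.array([n.charge for n in self.nuclei], dtype=float)
        self.centers = np.array([q.center for q in self.qdos]).reshape(-1, 3)
        self.qdo_q = np.array([q.q for q in self.qdos], dtype=float)
        self.qdo_mu = np.array([q.mu for q in self.qdos], dtype=float)
        self.qdo_omega = np.array([q.omega for q in self.qdos], dtype=float)
        self.qdo_sigma = np.array([q.sigma for q in self.qdos], dtype=float)
        self.pc_pos = np.array([p.position for p in self.point_charges]).reshape(-1, 3)
        self.pc_q = np.array([p.charge for p in self.point_charges], dtype=float)
        self.pc_parent = np.array(
            [-1 if p.parent is None else p.parent for p in self.point_charges],
            dtype=int,
        )
        self.pc_sigma = np.array([p.sigma for p in self.point_charges], dtype=float)
        self._static_energy = None
        self._dipole_tensors = None

    # -- sizes ---------------------------------------------------------
    @property
    def n_electrons(self) -> int:
        return self.n_up + self.n_down

    @property
    def n_nuclei(self) -> int:
        return len(self.nuclei)

    @property
    def n_qdos(self) -> int:
        return len(self.qdos)

    @property
    def n_point_charges(self) -> int:
        return len(self.point_charges)

    # -- static (configuration-independent) energy ---------------------
    @property
    def static_energy(self) -> float:
        """Coulomb energy of all fixed charges (nuclei, centers, point
        charges).  Constant for a given geometry but essential when taking
        solvation-energy differences."""
        if self._static_energy is None:
            self._static_energy = self._compute_static_energy()
        return self._static_energy

    def _compute_static_energy(self) -> float:
        e = 0.0
        kind = self.damping_kind
        # nucleus-nucleus: bare
        if self.n_nuclei > 1:
            r = _dist(self.nuclei_pos, self.nuclei_pos)
            qq = np.outer(self.nuclei_Z, self.nuclei_Z)
            iu = np.triu_indices(self.n_nuclei, 1)
            with np.errstate(divide="ignore"):
                e += float(np.sum(qq[iu] / r[iu]))
        if self.qdo_coupling == "dipole":
            return e
        # nucleus-center, nucleus-pc: damped
        if self.n_nuclei and self.n_qdos:
            e += _damped_pair_sum(
                kind,
                self.nuclei_pos, self.nuclei_Z, np.full(self.n_nuclei, self.sigma_e),
                self.centers, self.qdo_q, self.qdo_sigma,
            )
        if self.n_nuclei and self.n_point_charges:
            e += _damped_pair_sum(
                kind,
                self.nuclei_pos, self.nuclei_Z, np.full(self.n_nuclei, self.sigma_e),
                self.pc_pos, self.pc_q, self.pc_sigma,
            )
        # center-center
        if self.n_qdos > 1:
            e += _damped_pair_sum(
                kind,
                self.centers, self.qdo_q, self.qdo_sigma,
                None, None, None,
            )
        # center-pc (optionally excluding own)
        if self.n_qdos and self.n_point_charges:
            mask = np.ones((self.n_qdos, self.n_point_charges), dtype=bool)
            if not self.include_center_own_pc:
                mask[self.pc_parent[self.pc_parent >= 0], np.nonzero(self.pc_parent >= 0)[0]] = False
            e += _damped_pair_sum(
                kind,
                self.centers, self.qdo_q, self.qdo_sigma,
                self.pc_pos, self.pc_q, self.pc_sigma,
                mask=mask,
            )
        # pc-pc
        if self.n_point_charges > 1:
            e += _damped_pair_sum(
                kind,
                self.pc_pos, self.pc_q, self.pc_sigma,
                None, None, None,
            )
        return float(e)

    # -- dipole tensors for the truncated coupling ---------------------
    @property
    def dipole_tensors(self) -> np.ndarray:
        """(N_Q, N_Q, 3, 3) array of T_ij = (1 - 3 nn)/R^3 between centers."""
        if self._dipole_tensors is None:
            nq = self.n_qdos
            T = np.zeros((nq, nq, 3, 3))
            for i in range(nq):
                for j in range(i + 1, nq):
                    dvec = self.centers[j] - self.centers[i]
                    R = np.linalg.norm(dvec)
                    n = dvec / R
                    t = (np.eye(3) - 3.0 * np.outer(n, n)) / R**3
                    T[i, j] = t
                    T[j, i] = t
            self._dipole_tensors = T
        return self._dipole_tensors

    def validate_walker(self, walker: "WalkerConfiguration") -> None:
        if walker.electrons.shape[-2] != self.n_electrons:
            raise ConfigurationError("electron count mismatch")
        if walker.drudons.shape[-2] != self.n_qdos:
            raise ConfigurationError("drudon count mismatch")


@dataclass
class WalkerConfiguration:
    """Joint coordinates of all quantum particles plus a statistical weight.

    ``electrons`` has the spin-up block first.
    """

    electrons: np.ndarray
    drudons: np.ndarray
    weight: float = 1.0

    def __post_init__(self):
        self.electrons = np.asarray(self.electrons, dtype=float).reshape(-1, 3)
        self.drudons = np.asarray(self.drudons, dtype=float).reshape(-1, 3)
        if self.weight < 0:
            raise DomainError("walker weight must be >= 0")


# ----------------------------------------------------------------------
# pairwise helpers (batched over arbitrary leading axes)
# ----------------------------------------------------------------------

def _dist(a, b):
    """Pairwise distances between (...,N,3) and (...,M,3)."""
    d = a[..., :, None, :] - b[..., None, :, :]
    return np.sqrt(np.sum(d * d, axis=-1))


def _damped_pair_sum(kind, pos_a, q_a, sig_a, pos_b, q_b, sig_b, mask=None):
    """Damped Coulomb sum between two *static* particle sets.

    With ``pos_b=None`` sums over unordered pairs within set a.
    """
    if pos_b is None:
        r = _dist(pos_a, pos_a)
        qq = np.outer(q_a, q_a)
        sig = pair_sigma(sig_a[:, None], sig_a[None, :])
        iu = np.triu_indices(len(q_a), 1)
        return float(np.sum(qq[iu] * damped_inverse_r(kind, r[iu], sig[iu])))
    r = _dist(pos_a, pos_b)
    qq = np.outer(q_a, q_b)
    sig = pair_sigma(sig_a[:, None], sig_b[None, :])
    v = qq * damped_inverse_r(kind, r, sig)
    if mask is not None:
        v = np.where(mask, v, 0.0)
    return float(np.sum(v))


def potential_energy(system: ElQdoSystem, electrons=None, drudons=None):
    """Total potential energy of walker configurations (hartree).

    ``electrons`` has shape ``(..., N_e, 3)`` and ``drudons``
    ``(..., N_Q, 3)``; the result has the broadcast leading shape.  A
    :class:`WalkerConfiguration` may be passed as ``electrons``.

    Coincident charges on an undamped pair yield ``inf`` (divergence is
    signalled, not raised).
    """
    if isinstance(electrons, WalkerConfiguration):
        walker = electrons
        system.validate_walker(walker)
        electrons, drudons = walker.electrons, walker.drudons
    e = np.asarray(electrons, dtype=float) if electrons is not None else np.zeros((0, 3))
    d = np.asarray(drudons, dtype=float) if drudons is not None else np.zeros((0, 3))
    if e.ndim == 1:
        e = e.reshape(-1, 3)
    if d.ndim == 1:
        d = d.reshape(-1, 3)
    if e.shape[-2] != system.n_electrons:
        raise ConfigurationError("electron coordinate count mismatch")
    if d.shape[-2] != system.n_qdos:
        raise ConfigurationError("drudon coordinate count mismatch")

    batch = np.broadcast_shapes(e.shape[:-2], d.shape[:-2])
    out = np.full(batch, system.static_energy, dtype=float)
    kind = system.damping_kind
    ne, nq, npc, nn = (
        system.n_electrons,
        system.n_qdos,
        system.n_point_charges,
        system.n_nuclei,
    )

    with np.errstate(divide="ignore", invalid="ignore"):
        # (a) harmonic wells
        if nq:
            disp = d - system.centers
            out = out + 0.5 * np.sum(
                system.qdo_mu * system.qdo_omega**2 * np.sum(disp * disp, axis=-1),
                axis=-1,
            )
        # (b) bare electronic subsystem
        if ne > 1:
            r = _dist(e, e)
            iu = np.triu_indices(ne, 1)
            out = out + np.sum(1.0 / r[..., iu[0], iu[1]], axis=-1)
        if ne and nn:
            r = _dist(e, system.nuclei_pos)
            out = out - np.sum(system.nuclei_Z / r, axis=(-1, -2))

        if system.qdo_coupling == "dipole":
            if nq > 1:
                T = system.dipole_tensors
                disp = d - system.centers
                qq = np.outer(system.qdo_q, system.qdo_q)
                pair = np.einsum("...ia,ijab,...jb->...ij", disp, T, disp)
                iu = np.triu_indices(nq, 1)
                out = out + np.sum(
                    qq[iu[0], iu[1]] * pair[..., iu[0], iu[1]], axis=-1
                )
            return out if out.shape else float(out)

        sig_d = system.qdo_sigma
        # (c) environment internal: drudon-drudon, drudon-other-center,
        #     drudon-non-parental point charge
        if nq > 1:
            r = _dist(d, d)
            qq = np.outer(system.qdo_q, system.qdo_q)
            sig = pair_sigma(sig_d[:, None], sig_d[None, :])
            iu = np.triu_indices(nq, 1)
            out = out + np.sum(
                qq[iu[0], iu[1]]
                * damped_inverse_r(kind, r[..., iu[0], iu[1]], sig[iu]),
                axis=-1,
            )
            # drudon_i - center_j (j != i)
            r = _dist(d, system.centers)
            qq = np.outer(-system.qdo_q, system.qdo_q)
            sig = pair_sigma(sig_d[:, None], sig_d[None, :])
            v = qq * damped_inverse_r(kind, r, sig)
            off = ~np.eye(nq, dtype=bool)
            out = out + np.sum(np.where(off, v, 0.0), axis=(-1, -2))
        if nq and npc:
            r = _dist(d, system.pc_pos)
            qq = np.outer(-system.qdo_q, system.pc_q)
            sig = pair_sigma(sig_d[:, None], system.pc_sigma[None, :])
            nonparental = np.arange(nq)[:, None] != system.pc_parent[None, :]
            v = qq * damped_inverse_r(kind, r, sig)
            out = out + np.sum(np.where(nonparental, v, 0.0), axis=(-1, -2))
        # (d) cross terms: electrons/nuclei vs drudons/centers/point charges
        if ne:
            sig_e = np.full(ne, system.sigma_e)
            if nq:
                r = _dist(e, d)
                sig = pair_sigma(sig_e[:, None], sig_d[None, :])
                out = out + np.sum(
                    system.qdo_q * damped_inverse_r(kind, r, sig), axis=(-1, -2)
                )
                r = _dist(e, system.centers)
                out = out - np.sum(
                    system.qdo_q * damped_inverse_r(kind, r, sig), axis=(-1, -2)
                )
            if npc:
                r = _dist(e, system.pc_pos)
                sig = pair_sigma(sig_e[:, None], system.pc_sigma[None, :])
                out = out - np.sum(
                    system.pc_q * damped_inverse_r(kind, r, sig), axis=(-1, -2)
                )
        if nn and nq:
            r = _dist(system.nuclei_pos, d)
            sig = pair_sigma(
                np.full(nn, system.sigma_e)[:, None], sig_d[None, :]
            )
            qq = np.outer(system.nuclei_Z, -system.qdo_q)
            out = out + np.sum(qq * damped_inverse_r(kind, r, sig), axis=(-1, -2))
    return out if out.shape else float(out)


def coulomb_pair_count(system: ElQdoSystem) -> dict:
    """Count Coulomb pair terms actually included in :func:`potential_energy`.

    Returns a dict with ``full`` (all unordered pairs of charged particles),
    ``included`` and ``excluded``; the exclusions are the N_Q drudon/own-center
    pairs, the drudon/parental-point-charge pairs and (by default) the
    center/own-point-charge pairs.
    """
    ne, nn, nq, npc = (
        system.n_electrons,
        system.n_nuclei,
        system.n_qdos,
        system.n_point_charges,
    )
    p = ne + nn + 2 * nq + npc
    full = p * (p - 1) // 2
    n_parented = int(np.sum(system.pc_parent >= 0))
    excluded = nq + n_parented
    if not system.include_center_own_pc:
        excluded += n_parented
    return {"full": full, "included": full - excluded, "excluded": excluded}


def make_qdo(species: str, center, sigma: float = 0.5) -> QdoSpec:
    """Build a QdoSpec from the built-in parameter table (center in bohr)."""
    if species not in SPECIES_QDO_PARAMS:
        raise ConfigurationError(f"no QDO parameters for species {species!r}")
    q, omega, mu = SPECIES_QDO_PARAMS[species]
    return QdoSpec(center=np.asarray(center, float), q=q, mu=mu, omega=omega, sigma=sigma)


# ----------------------------------------------------------------------
# water environment construction (TIP4P-style)
# ----------------------------------------------------------------------

def build_water_qdo(O, H1, H2, sigma: float = 0.5, center_site: str = "M",
                    parent_index: int = 0):
    """Turn one rigid water geometry into a water QDO plus its point charges.

    Parameters
    ----------
    O, H1, H2 : 3-vectors in **angstrom** (atomistic geometry).
    sigma : damping length assigned to all members (bohr).
    center_site : place the oscillator at the ``"M"`` charge site (default)
        or at ``"O"``.
    parent_index : index this QDO will occupy in the system's qdo list
        (stamped on the point charges).

    Returns ``(QdoSpec, [PointCharge, PointCharge, PointCharge])`` in bohr:
    ``+0.605`` on each hydrogen and ``-1.21`` on the M site, which lies on
    the HOH bisector 0.2667 angstrom from the oxygen; the oxygen itself
    carries no charge.
    """
    O = _vec3(O, "O") * units.ANGSTROM_TO_BOHR
    H1 = _vec3(H1, "H1") * units.ANGSTROM_TO_BOHR
    H2 = _vec3(H2, "H2") * units.ANGSTROM_TO_BOHR
    b1 = H1 - O
    b2 = H2 - O
    n1 = np.linalg.norm(b1)
    n2 = np.linalg.norm(b2)
    if n1 < 1e-8 or n2 < 1e-8 or np.linalg.norm(np.cross(b1, b2)) < 1e-8 * n1 * n2:
        raise GeometryError("degenerate water geometry (collinear or coincident atoms)")
    bis = b1 / n1 + b2 / n2
    bis /= np.linalg.norm(bis)
    M = O + TIP4P_R_OM_ANGSTROM * units.ANGSTROM_TO_BOHR * bis

    if center_site == "M":
        center = M
    elif center_site == "O":
        center = O
    else:
        raise ConfigurationError("center_site must be 'M' or 'O'")
    q, omega, mu = SPECIES_QDO_PARAMS["H2O"]
    qdo = QdoSpec(center=center, q=q, mu=mu, omega=omega, sigma=sigma)
    pcs = [
        PointCharge(position=H1, charge=TIP4P_Q_H, parent=parent_index, sigma=sigma),
        PointCharge(position=H2, charge=TIP4P_Q_H, parent=parent_index, sigma=sigma),
        PointCharge(position=M, charge=TIP4P_Q_M, parent=parent_index, sigma=sigma),
    ]
    return qdo, pcs


def deform_cage(subsystem_nuclei, waters, dR):
    """Radially expand (dR > 0) or compress (dR < 0) a cage of rigid waters.

    ``subsystem_nuclei`` is an (N,3) array of the embedded subsystem's
    nuclear positions; ``waters`` a sequence of ``(O, H1, H2)`` triplets.
    Every oxygen moves by ``dR`` along the unit vector from the geometric
    center of the subsystem nuclei to itself; both hydrogens translate
    rigidly with their oxygen, so intramolecular geometry is preserved
    exactly.  All lengths share one unit (angstrom in file workflows).
    """
    nuc = np.asarray(subsystem_nuclei, dtype=float).reshape(-1, 3)
    if nuc.shape[0] < 1:
        raise GeometryError("subsystem must contain at least one nucleus")
    center = nuc.mean(axis=0)
    out = []
    for O, H1, H2 in waters:
        O = _vec3(O, "O")
        radial = O - center
        norm = np.linalg.norm(radial)
        if norm < 1e-10:
            raise GeometryError("oxygen coincides with the subsystem center")
        shift = dR * radial / norm
        out.append((O + shift, _vec3(H1, "H1") + shift, _vec3(H2, "H2") + shift))
    return out
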