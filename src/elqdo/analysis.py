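"""Observables built from raw QMC energies: interaction energies, solvation
energies, binding-energy changes and potential-energy-surface scans.

All composite energies are supermolecular differences with independent runs
per subsystem; error bars propagate in quadrature.  Scan points whose
local-energy variance blows up relative to the rest of the scan are flagged
as overpolarization-unstable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from . import units
from .errors import ConfigurationError, GeometryError
from .model import PointCharge, QdoSpec, build_water_qdo
from .vmc import EnergyEstimate

__all__ = [
    "interaction_energy",
    "solvation_energy",
    "binding_energy_change",
    "PesPoint",
    "pes_scan",
    "generate_fixture_cage",
    "build_water_environment",
]

#: rigid TIP4P water geometry used by the fixture generator (angstrom / degrees)
TIP4P_R_OH = 0.9572
TIP4P_HOH_DEG = 104.52


def _check_consistent(estimates, key):
    tagged = [e.extra.get(key) for e in estimates if key in e.extra]
    if len(tagged) > 1 and any(t != tagged[0] for t in tagged[1:]):
        raise ConfigurationError(
            f"inconsistent runs: {key} differs across inputs: {tagged}"
        )


def _difference(minuend: EnergyEstimate, subtrahends, key="config") -> EnergyEstimate:
    ests = [minuend, *subtrahends]
    _check_consistent(ests, key)
    _check_consistent(ests, "dR")
    mean = minuend.mean - sum(e.mean for e in subtrahends)
    stderr = float(np.sqrt(sum(e.stderr**2 for e in ests)))
    return EnergyEstimate(
        mean=mean,
        stderr=stderr,
        variance=sum(e.variance for e in ests),
        n_eff=min(e.n_eff for e in ests),
        extra={k: v for e in ests for k, v in e.extra.items()
               if k in ("config", "dR", "tau")},
    )


def interaction_energy(e_ab: EnergyEstimate, e_a: EnergyEstimate,
                       e_b: EnergyEstimate) -> EnergyEstimate:
    """Supermolecular interaction energy E_AB - E_A - E_B.

    Runs must share their configuration tag (damping kind, sigma, ansatz
    family) when one is attached under ``extra['config']``.
    """
    return _difference(e_ab, (e_a, e_b))


def solvation_energy(e_sub_plus_env: EnergyEstimate, e_sub: EnergyEstimate,
                     e_env: EnergyEstimate) -> EnergyEstimate:
    """Solvation energy E(subsystem + environment) - E(subsystem) - E(environment)."""
    return _difference(e_sub_plus_env, (e_sub, e_env))


def binding_energy_change(e_solv_dimer: EnergyEstimate, e_solv_m1: EnergyEstimate,
                          e_solv_m2: EnergyEstimate) -> EnergyEstimate:
    """Environment-induced change of the dimer binding energy.

    ``dE_b = E_solv(D) - E_solv(M1) - E_solv(M2)``: zero when solvation is
    additive over the monomers.  All three inputs must carry the same cage
    deformation ``extra['dR']`` when tagged.
    """
    return _difference(e_solv_dimer, (e_solv_m1, e_solv_m2))


@dataclass
class PesPoint:
    """One point of a potential-energy scan (energies in hartree)."""

    coordinate: float
    energy: Optional[float] = None
    stderr: Optional[float] = None
    variance: Optional[float] = None
    flagged: bool = False
    error: Optional[str] = None

    @property
    def energy_mev(self):
        return None if self.energy is None else units.hartree_to_mev(self.energy)

    @property
    def stderr_mev(self):
        return None if self.stderr is None else units.hartree_to_mev(self.stderr)


def pes_scan(grid: Sequence[float], run_point: Callable[[float], EnergyEstimate],
             variance_flag_factor: float = 10.0, csv_path=None, json_path=None):
    """Run ``run_point`` over a grid and tabulate the results.

    A point is flagged as overpolarization-unstable when its local-energy
    variance exceeds ``variance_flag_factor`` times the scan median: when
    sampling collapses onto an undamped positive charge, the uncapped
    local-energy spread blows up relative to the rest of the scan.
    Failed points are recorded with their error and the scan continues.
    Returns a list of :class:`PesPoint`; optionally writes CSV and JSON.
    """
    points = []
    for x in grid:
        try:
            est = run_point(float(x))
            points.append(PesPoint(coordinate=float(x), energy=est.mean,
                                   stderr=est.stderr, variance=est.variance))
        except Exception as exc:  # record and continue
            points.append(PesPoint(coordinate=float(x), error=f"{type(exc).__name__}: {exc}"))
    variances = [p.variance for p in points if p.variance is not None]
    if variances:
        med = float(np.median(variances))
        for p in points:
            if p.variance is not None and med > 0:
                p.flagged = p.variance > variance_flag_factor * med
    df = pes_table(points)
    if csv_path is not None:
        df.to_csv(csv_path, index=False)
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump(df.to_dict(orient="records"), fh, indent=1)
    return points


def pes_table(points: Sequence[PesPoint]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "coordinate": p.coordinate,
                "energy_hartree": p.energy,
                "stderr_hartree": p.stderr,
                "energy_mev": p.energy_mev,
                "stderr_mev": p.stderr_mev,
                "variance": p.variance,
                "flagged": p.flagged,
                "error": p.error,
            }
            for p in points
        ]
    )


def generate_fixture_cage(n_waters: int, inner_radius: float, seed: int,
                          min_oo: float = 2.4, max_attempts: int = 2000):
    """Random non-overlapping rigid waters on a sphere (angstrom).

    Oxygens sit on the sphere of ``inner_radius`` around the origin with
    pairwise O-O distance above ``min_oo``; each water has the rigid TIP4P
    geometry (r_OH = 0.9572 A, HOH = 104.52 deg) in a random orientation.
    Reproducible by ``seed``.  Returns a list of ``(O, H1, H2)`` triplets.
    """
    if n_waters < 1:
        raise ConfigurationError("n_waters must be >= 1")
    rng = np.random.default_rng(seed)
    half = np.deg2rad(TIP4P_HOH_DEG) / 2.0
    local = np.array(
        [
            [0.0, 0.0, 0.0],
            [TIP4P_R_OH * np.sin(half), 0.0, TIP4P_R_OH * np.cos(half)],
            [-TIP4P_R_OH * np.sin(half), 0.0, TIP4P_R_OH * np.cos(half)],
        ]
    )
    oxygens = []
    waters = []
    for _ in range(n_waters):
        for attempt in range(max_attempts):
            direction = rng.standard_normal(3)
            direction /= np.linalg.norm(direction)
            O = inner_radius * direction
            if all(np.linalg.norm(O - o) > min_oo for o in oxygens):
                break
        else:
            raise GeometryError(
                f"could not place {n_waters} waters with O-O > {min_oo} A on a "
                f"{inner_radius} A sphere; increase the radius"
            )
        # random rotation from QR of a Gaussian matrix
        q, r = np.linalg.qr(rng.standard_normal((3, 3)))
        q *= np.sign(np.diag(r))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        rotated = local @ q.T + O
        oxygens.append(O)
        waters.append((rotated[0], rotated[1], rotated[2]))
    return waters


def build_water_environment(waters, sigma: float = 0.5, center_site: str = "M"):
    """Turn ``(O, H1, H2)`` triplets (angstrom) into QDO + point-charge lists."""
    qdos, pcs = [], []
    for k, (O, H1, H2) in enumerate(waters):
        qdo, charges = build_water_qdo(O, H1, H2, sigma=sigma,
                                       center_site=center_site, parent_index=k)
        qdos.append(qdo)
        pcs.extend(charges)
    return qdos, pcs
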