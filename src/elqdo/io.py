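"""File I/O: XYZ geometries, environment specifications, orbital files.

XYZ files are in angstrom (converted to bohr where objects require it);
environment and orbital files are YAML/JSON with explicit units noted in
each loader.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigurationError
from .model import Nucleus, PointCharge, QdoSpec, SPECIES_QDO_PARAMS, make_qdo
from .wavefunction import BasisFunction, MolecularOrbitals

__all__ = [
    "read_xyz",
    "write_xyz",
    "group_waters",
    "load_environment",
    "load_orbitals",
]


def read_xyz(path):
    """Read an XYZ file; returns ``(symbols, positions)`` with positions in
    angstrom."""
    import MDAnalysis as mda

    u = mda.Universe(str(path), topology_format="XYZ", format="XYZ")
    return [str(n) for n in u.atoms.names], np.array(u.atoms.positions, dtype=float)


def write_xyz(path, symbols, positions, comment=""):
    """Write an XYZ file (positions in angstrom)."""
    positions = np.asarray(positions, dtype=float).reshape(-1, 3)
    with open(path, "w") as fh:
        fh.write(f"{len(symbols)}\n{comment}\n")
        for s, p in zip(symbols, positions):
            fh.write(f"{s} {p[0]:.10f} {p[1]:.10f} {p[2]:.10f}\n")


def group_waters(symbols, positions):
    """Group an O,H,H-ordered atom list into ``(O, H1, H2)`` triplets."""
    if len(symbols) % 3:
        raise ConfigurationError("water geometry must contain O,H,H triplets")
    waters = []
    for k in range(0, len(symbols), 3):
        if symbols[k].upper()[0] != "O" or symbols[k + 1].upper()[0] != "H" \
                or symbols[k + 2].upper()[0] != "H":
            raise ConfigurationError(f"atoms {k}..{k+2} are not an O,H,H triplet")
        waters.append((positions[k], positions[k + 1], positions[k + 2]))
    return waters


def load_environment(path):
    """Load an explicit environment specification (YAML or JSON).

    Schema (all positions in bohr)::

        qdos:
          - {species: Ar, center: [x, y, z], sigma: 0.5}       # built-in table
          - {center: [...], q: ..., mu: ..., omega: ..., sigma: ...}
        point_charges:
          - {position: [...], charge: ..., parent: 0, sigma: 0.5}

    Returns ``(qdos, point_charges)``.
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    qdos = []
    for entry in data.get("qdos", []):
        if "species" in entry:
            qdos.append(make_qdo(entry["species"], entry["center"],
                                 sigma=entry.get("sigma", 0.5)))
        else:
            qdos.append(QdoSpec(center=np.asarray(entry["center"], float),
                                q=entry["q"], mu=entry["mu"], omega=entry["omega"],
                                sigma=entry.get("sigma", 0.5)))
    pcs = [
        PointCharge(position=np.asarray(e["position"], float), charge=e["charge"],
                    parent=e.get("parent"), sigma=e.get("sigma", 0.5))
        for e in data.get("point_charges", [])
    ]
    return qdos, pcs


def load_orbitals(path, nuclei_positions=None):
    """Load molecular orbitals from a JSON/YAML file.

    Schema::

        basis:
          - {center: [x, y, z], kind: gto, angular: [0, 0, 0],
             exponents: [...], coefficients: [...]}
          - {center: [...], kind: sto1s, zeta: 1.0}
          # or centered on a nucleus by index:
          - {center_index: 0, kind: sto1s, zeta: 1.0}
        mo_coefficients: [[...], ...]      # one row per occupied orbital

    Positions are in bohr.  To convert from a quantum-chemistry text
    output, emit one ``basis`` entry per contracted shell component
    (Cartesian ``angular`` triplet) and the occupied-orbital rows of the
    MO coefficient matrix in the same basis ordering.
    """
    data = yaml.safe_load(Path(path).read_text())
    basis = []
    for e in data["basis"]:
        if "center_index" in e:
            if nuclei_positions is None:
                raise ConfigurationError("center_index requires nuclei_positions")
            center = np.asarray(nuclei_positions, float)[e["center_index"]]
        else:
            center = np.asarray(e["center"], float)
        kind = e.get("kind", "gto")
        if kind == "sto1s":
            basis.append(BasisFunction(center=center, kind="sto1s", zeta=e["zeta"]))
        else:
            basis.append(
                BasisFunction(
                    center=center,
                    kind="gto",
                    angular=tuple(e.get("angular", (0, 0, 0))),
                    exponents=tuple(e["exponents"]),
                    coefficients=tuple(e["coefficients"]),
                )
            )
    return MolecularOrbitals(basis=tuple(basis),
                             coefficients=np.asarray(data["mo_coefficients"], float))
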