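"""Unit constants and conversions.

All internal quantities are in Hartree atomic units (hartree, bohr,
electron mass).  Geometry files are in angstrom and converted on input.
"""

ANGSTROM_TO_BOHR = 1.8897259886
BOHR_TO_ANGSTROM = 1.0 / ANGSTROM_TO_BOHR

HARTREE_TO_MEV = 27211.386245988
MEV_TO_HARTREE = 1.0 / HARTREE_TO_MEV


def angstrom_to_bohr(x):
    return x * ANGSTROM_TO_BOHR


def bohr_to_angstrom(x):
    return x * BOHR_TO_ANGSTROM


def hartree_to_mev(e):
    return e * HARTREE_TO_MEV


def mev_to_hartree(e):
    return e * MEV_TO_HARTREE
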