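"""Unit conversions used at module boundaries.

Coordinates are carried in Angstrom (the PDB convention); the mechanics layer
reports lengths in nm and forces in pN, matching how single-molecule stiffness
and MD restraint forces are usually quoted.  MD engines emit forces in
kJ mol^-1 nm^-1, hence the dedicated force converter.
"""

from __future__ import annotations

from .errors import UnitError

AVOGADRO = 6.02214076e23  # mol^-1 (exact, SI 2019)
BOLTZMANN_PN_NM = 1.380649e-2  # pN nm K^-1 (exact k_B rescaled)
ELEMENTARY_CHARGE_C = 1.602176634e-19  # C (exact)

ANGSTROM_PER_NM = 10.0

#: pN per kJ mol^-1 nm^-1 = 1e3 J mol^-1 nm^-1 / N_A, expressed in pN
KJ_MOL_NM_IN_PN = 1.0e3 / AVOGADRO / 1.0e-9 * 1.0e12  # = 1.66053906892...

_FORCE_IN_PN = {
    "pN": 1.0,
    "nN": 1.0e3,
    "N": 1.0e12,
    "kJ/mol/nm": KJ_MOL_NM_IN_PN,
    "kcal/mol/A": 4.184e3 / AVOGADRO / 1.0e-10 * 1.0e12,
}


def convert_force(value: float, from_unit: str, to_unit: str) -> float:
    """Convert a force between ``pN``, ``nN``, ``N``, ``kJ/mol/nm`` and
    ``kcal/mol/A``.

    The conversions are exact constant rescalings; in particular
    1 kJ mol^-1 nm^-1 = 1.66054 pN.
    """
    for unit in (from_unit, to_unit):
        if unit not in _FORCE_IN_PN:
            raise UnitError(
                f"unknown force unit {unit!r}; known: {sorted(_FORCE_IN_PN)}"
            )
    return value * _FORCE_IN_PN[from_unit] / _FORCE_IN_PN[to_unit]


def angstrom_to_nm(value):
    return value / ANGSTROM_PER_NM


def nm_to_angstrom(value):
    return value * ANGSTROM_PER_NM
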