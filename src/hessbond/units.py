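"""Conversions between atomic units and GROMACS units.

Gaussian checkpoint files store geometry in Bohr and the Cartesian Hessian
in Hartree/Bohr²; GROMACS bonded parameters use nm, kJ mol⁻¹ nm⁻² and
kJ mol⁻¹ rad⁻².  The two constants below (CODATA-level, 8 significant
figures) fix every conversion in the package:

* 1 Hartree = 2625.4996 kJ/mol
* 1 Bohr    = 0.052917721 nm

Emitted force constants are raw second derivatives of the energy, matching
the GROMACS harmonic forms V = ½k_b(b−b₀)² and V = ½k_θ(θ−θ₀)²; no extra
factor of two is applied for Amber-style k(b−b₀)² conventions.

Harmonic vibrational frequencies from quantum chemistry systematically
overestimate experiment; :func:`apply_frequency_scaling` applies an
empirical frequency scale factor *s* to a force constant.  Because
ω ∝ √k, scaling frequencies by *s* scales force constants by *s²*.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "HARTREE_TO_KJ_PER_MOL",
    "BOHR_TO_NM",
    "UnitConstants",
    "CONSTANTS",
    "bond_k_au_to_gromacs",
    "bond_k_gromacs_to_au",
    "angle_k_au_to_gromacs",
    "angle_k_gromacs_to_au",
    "length_bohr_to_nm",
    "length_nm_to_bohr",
    "apply_frequency_scaling",
]

HARTREE_TO_KJ_PER_MOL: float = 2625.4996
BOHR_TO_NM: float = 0.052917721


@dataclass(frozen=True)
class UnitConstants:
    """The two physical constants every conversion is built from."""

    hartree_to_kj_per_mol: float = HARTREE_TO_KJ_PER_MOL
    bohr_to_nm: float = BOHR_TO_NM


CONSTANTS = UnitConstants()


def bond_k_au_to_gromacs(k: float) -> float:
    """Convert a bond force constant from Hartree/Bohr² to kJ mol⁻¹ nm⁻²."""
    return k * HARTREE_TO_KJ_PER_MOL / BOHR_TO_NM**2


def bond_k_gromacs_to_au(k: float) -> float:
    """Convert a bond force constant from kJ mol⁻¹ nm⁻² to Hartree/Bohr²."""
    return k * BOHR_TO_NM**2 / HARTREE_TO_KJ_PER_MOL


def angle_k_au_to_gromacs(k: float) -> float:
    """Convert an angle force constant from Hartree/rad² to kJ mol⁻¹ rad⁻²."""
    return k * HARTREE_TO_KJ_PER_MOL


def angle_k_gromacs_to_au(k: float) -> float:
    """Convert an angle force constant from kJ mol⁻¹ rad⁻² to Hartree/rad²."""
    return k / HARTREE_TO_KJ_PER_MOL


def length_bohr_to_nm(d: float) -> float:
    """Convert a length from Bohr to nm."""
    return d * BOHR_TO_NM


def length_nm_to_bohr(d: float) -> float:
    """Convert a length from nm to Bohr."""
    return d / BOHR_TO_NM


def apply_frequency_scaling(k: float, s: float) -> float:
    """Scale a force constant by a vibrational-frequency scale factor.

    Parameters
    ----------
    k:
        Force constant (any unit).
    s:
        Frequency scale factor; must lie in (0, 1.5].  Typical literature
        values are 0.89–1.0 depending on the QM method and basis set.

    Returns
    -------
    float
        ``k * s**2`` — frequencies scale with √k, so a frequency factor
        *s* corresponds to a force-constant factor *s²*.
    """
    if not 0.0 < s <= 1.5:
        raise ValueError(f"frequency scale factor must be in (0, 1.5], got {s}")
    return k * (s * s)
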