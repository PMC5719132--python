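"""Seminario subblock eigen-analysis of the Cartesian Hessian.

The method extracts a harmonic force constant for an atom pair (or angle
triplet) from the 3×3 interatomic subblock of the full 3N×3N Hessian,
without ever constructing internal coordinates.  For a pair A–B the
negated off-diagonal block −∂²E/∂x_A∂x_B is diagonalised into eigenvalues
λ_i and eigenvectors v_i, and the bond stretch constant is the
projection-weighted sum

    k_AB = Σ_i λ_i |û_AB · v_i|        (û_AB: unit vector A→B)

For an angle A–B–C (vertex B) each arm contributes a stiffness measured
along the in-plane unit vector perpendicular to that arm, and the two arms
combine like springs in series:

    1/k_θ = 1/(d²_AB Σ_i λ^AB_i |û_PA·v^AB_i|)
          + 1/(d²_CB Σ_i λ^CB_i |û_PC·v^CB_i|)

with û_N = (û_CB × û_AB)/|û_CB × û_AB|, û_PA = û_N × û_AB and
û_PC = û_CB × û_N.  Equilibrium values are plain 3-D geometry.

All atom indices here are 0-based; the I/O layers convert from Gaussian's
1-based numbering.  Inputs are atomic units (Bohr, Hartree/Bohr²); bond
constants come out in Hartree/Bohr², angle constants in Hartree/rad²,
equilibrium values in nm and degrees.

Off-diagonal 3×3 blocks of a symmetric Hessian are not themselves
symmetric; the block is symmetrised as (B+Bᵀ)/2 before diagonalisation,
which preserves its quadratic form and guarantees real eigenvalues with
orthonormal eigenvectors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import (
    GeometryError,
    NoInteractionWarning,
    NonMinimumWarning,
    NonPositiveStiffnessError,
)
from .gaussian_io import HessianMatrix, Structure
from .units import BOHR_TO_NM

__all__ = [
    "InteratomicBlock",
    "BondGeometry",
    "AngleFrame",
    "interatomic_block",
    "bond_geometry",
    "angle_frame",
    "bond_force_value",
    "angle_force_value",
    "equilibrium_bond",
    "equilibrium_angle",
]

#: Two atoms closer than this (Bohr) are treated as coincident.
COINCIDENCE_TOL_BOHR = 1e-6
#: An angle frame with |û_CB × û_AB| below this is degenerate (collinear).
COLLINEARITY_TOL = 1e-6
#: Eigenvalues below -NEGATIVE_EIG_TOL mark a block as non-minimum-like.
NEGATIVE_EIG_TOL = 1e-8


@dataclass(frozen=True)
class InteratomicBlock:
    """Eigen-analysis of one negated off-diagonal Hessian subblock.

    ``block`` is the raw negated (A,B) 3×3 submatrix; the eigenvalues and
    eigenvectors (columns) belong to its symmetrised form.  ``non_minimum``
    records whether any eigenvalue is significantly negative, which is
    typical when the structure is not at a minimum (it can also occur
    legitimately for angle-dominated couplings).
    """

    atom_a: int
    atom_b: int
    block: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    non_minimum: bool


@dataclass(frozen=True)
class BondGeometry:
    """Unit vector A→B and scalar distance (Bohr) for one atom pair."""

    u_ab: np.ndarray
    d_ab: float


@dataclass(frozen=True)
class AngleFrame:
    """Orthonormal frame of an angle A–B–C (vertex B).

    ``u_n`` is the unit normal to the ABC plane; ``u_pa`` and ``u_pc`` are
    in-plane unit vectors perpendicular to arms A–B and C–B respectively.
    """

    u_n: np.ndarray
    u_pa: np.ndarray
    u_pc: np.ndarray


def _check_atom_index(n_atoms: int, idx: int) -> None:
    if not 0 <= idx < n_atoms:
        raise IndexError(f"atom index {idx} out of range for {n_atoms} atoms")


def interatomic_block(hessian: HessianMatrix, a: int, b: int) -> InteratomicBlock:
    """Extract and diagonalise the negated (A,B) Hessian subblock.

    Raises ``ValueError`` when ``a == b``: the diagonal self-block is not an
    interatomic coupling.
    """
    if a == b:
        raise ValueError("interatomic block requires two distinct atoms")
    _check_atom_index(hessian.n_atoms, a)
    _check_atom_index(hessian.n_atoms, b)
    block = -hessian.values[3 * a : 3 * a + 3, 3 * b : 3 * b + 3]
    sym = (block + block.T) / 2.0
    eigenvalues, eigenvectors = np.linalg.eigh(sym)
    non_minimum = bool(eigenvalues.min() < -NEGATIVE_EIG_TOL)
    return InteratomicBlock(
        atom_a=a,
        atom_b=b,
        block=block,
        eigenvalues=eigenvalues,
        eigenvectors=eigenvectors,
        non_minimum=non_minimum,
    )


def bond_geometry(structure: Structure, a: int, b: int) -> BondGeometry:
    """Unit vector and distance from atom ``a`` to atom ``b``."""
    if a == b:
        raise ValueError("bond geometry requires two distinct atoms")
    _check_atom_index(structure.atom_count, a)
    _check_atom_index(structure.atom_count, b)
    r = structure.coordinates[b] - structure.coordinates[a]
    d = float(np.linalg.norm(r))
    if d <= COINCIDENCE_TOL_BOHR:
        raise GeometryError(f"atoms {a} and {b} are coincident (d = {d:g} Bohr)")
    return BondGeometry(u_ab=r / d, d_ab=d)


def angle_frame(structure: Structure, a: int, b: int, c: int) -> AngleFrame:
    """Build the perpendicular unit-vector frame of angle A–B–C.

    Raises :class:`GeometryError` when the three atoms are (near-)collinear,
    in which case the plane normal û_N is undefined.
    """
    geom_ab = bond_geometry(structure, a, b)
    geom_cb = bond_geometry(structure, c, b)
    cross = np.cross(geom_cb.u_ab, geom_ab.u_ab)
    norm = float(np.linalg.norm(cross))
    if norm <= COLLINEARITY_TOL:
        raise GeometryError(
            f"atoms {a}-{b}-{c} are collinear; the angle frame is degenerate"
        )
    u_n = cross / norm
    return AngleFrame(
        u_n=u_n,
        u_pa=np.cross(u_n, geom_ab.u_ab),
        u_pc=np.cross(geom_cb.u_ab, u_n),
    )


def _projected_sum(block: InteratomicBlock, direction: np.ndarray) -> float:
    """Σ_i λ_i |direction · v_i| over the block's eigen-pairs."""
    return float(
        np.sum(block.eigenvalues * np.abs(direction @ block.eigenvectors))
    )


def bond_force_value(
    hessian: HessianMatrix, structure: Structure, a: int, b: int
) -> float:
    """Bond-stretch force constant of pair A–B, in Hartree/Bohr².

    A pair whose coupling block is exactly zero (e.g. two atoms of
    different, non-interacting fragments) returns 0 and emits a
    :class:`NoInteractionWarning`; a negative projected sum (not at a
    minimum, or an unrealistic pair) is returned as-is with a
    :class:`NonMinimumWarning` so the problem stays visible, and is
    rejected later when parameters are written out.
    """
    geom = bond_geometry(structure, a, b)
    blk = interatomic_block(hessian, a, b)
    if not np.any(blk.block):
        warnings.warn(
            f"atoms {a + 1} and {b + 1} share no Hessian coupling "
            f"(no interaction); force value set to 0",
            NoInteractionWarning,
            stacklevel=2,
        )
        return 0.0
    k = _projected_sum(blk, geom.u_ab)
    if k <= 0.0:
        warnings.warn(
            f"non-positive bond stiffness for atoms {a + 1}-{b + 1} "
            f"(k = {k:g} Hartree/Bohr²); structure may not be at a minimum "
            f"or the pair is unrealistic",
            NonMinimumWarning,
            stacklevel=2,
        )
    return k


def angle_force_value(
    hessian: HessianMatrix, structure: Structure, a: int, b: int, c: int
) -> float:
    """Angle-bend force constant of triplet A–B–C (vertex B), Hartree/rad².

    The two arm stiffnesses combine harmonically, so the result is positive
    whenever both arm terms are positive.  A non-positive arm term raises
    :class:`NonPositiveStiffnessError` naming the offending arm.
    """
    if len({a, b, c}) != 3:
        raise ValueError("angle requires three distinct atoms")
    geom_ab = bond_geometry(structure, a, b)
    geom_cb = bond_geometry(structure, c, b)
    frame = angle_frame(structure, a, b, c)

    term_a = geom_ab.d_ab**2 * _projected_sum(
        interatomic_block(hessian, a, b), frame.u_pa
    )
    term_c = geom_cb.d_ab**2 * _projected_sum(
        interatomic_block(hessian, c, b), frame.u_pc
    )
    if term_a <= 0.0:
        raise NonPositiveStiffnessError(
            f"arm {a + 1}-{b + 1} of angle {a + 1}-{b + 1}-{c + 1} has "
            f"non-positive stiffness ({term_a:g})"
        )
    if term_c <= 0.0:
        raise NonPositiveStiffnessError(
            f"arm {c + 1}-{b + 1} of angle {a + 1}-{b + 1}-{c + 1} has "
            f"non-positive stiffness ({term_c:g})"
        )
    return 1.0 / (1.0 / term_a + 1.0 / term_c)


def equilibrium_bond(structure: Structure, a: int, b: int) -> float:
    """Equilibrium bond length b₀ of pair A–B, in nm."""
    return bond_geometry(structure, a, b).d_ab * BOHR_TO_NM


def equilibrium_angle(structure: Structure, a: int, b: int, c: int) -> float:
    """Equilibrium interior angle θ₀ at vertex B, in degrees ∈ [0, 180]."""
    if len({a, b, c}) != 3:
        raise ValueError("angle requires three distinct atoms")
    geom_ab = bond_geometry(structure, a, b)
    geom_cb = bond_geometry(structure, c, b)
    cos_theta = float(np.clip(np.dot(geom_ab.u_ab, geom_cb.u_ab), -1.0, 1.0))
    return float(np.degrees(np.arccos(cos_theta)))
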