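"""Synthetic harmonic molecules with analytically known force fields.

A :class:`ToyModel` is a molecule whose energy is an explicit sum of
independent harmonic bond-stretch and angle-bend terms,

    E = Σ ½ k_b (b − b₀)²  +  Σ ½ k_θ (θ − θ₀)²,

with k_b in kJ mol⁻¹ nm⁻², k_θ in kJ mol⁻¹ rad⁻², b₀ in nm and θ₀ in
degrees — i.e. exactly the functional form the derived GROMACS parameters
feed.  Because every force constant is known by construction, these models
provide ground truth for the subblock eigen-analysis without any quantum
chemistry: a finite-difference Hessian of the toy energy stands in for the
Gaussian one.

The Hessian is built by central differences of the analytic gradient
(O(step²) accurate), evaluated at the stored equilibrium geometry and
converted to Hartree/Bohr² so it is indistinguishable, format-wise, from a
checkpoint-file Hessian.  Geometries are constructed exactly at each
model's minimum, which every constructor verifies through the analytic
gradient.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .errors import GeometryError
from .gaussian_io import HessianMatrix, QMResult, Structure, write_fchk
from .units import BOHR_TO_NM, HARTREE_TO_KJ_PER_MOL

__all__ = [
    "HarmonicBond",
    "HarmonicAngle",
    "ToyModel",
    "toy_energy",
    "toy_gradient",
    "numerical_hessian",
    "standard_fixtures",
    "Fixture",
    "random_rotation",
    "rotate_qm_result",
]

_NM_PER_BOHR = BOHR_TO_NM

#: Allowed central-difference step range, Bohr.
MIN_STEP_BOHR = 1e-6
MAX_STEP_BOHR = 1e-2
DEFAULT_STEP_BOHR = 1e-3

#: Gradient norm (kJ mol⁻¹ Bohr⁻¹) below which a geometry counts as a minimum.
GRADIENT_TOL = 1e-10


class HarmonicBond(NamedTuple):
    """One harmonic stretch term: 0-based atoms, k (kJ/mol/nm²), b0 (nm)."""

    i: int
    j: int
    k: float
    b0: float


class HarmonicAngle(NamedTuple):
    """One harmonic bend term: 0-based atoms (j = vertex), k (kJ/mol/rad²), theta0 (deg)."""

    i: int
    j: int
    k: int
    k_theta: float
    theta0: float


@dataclass(frozen=True)
class ToyModel:
    """Analytic harmonic force field anchored at an equilibrium geometry.

    Construction validates that all force constants are positive and that
    the stored geometry is a stationary point (analytic gradient norm
    below ``GRADIENT_TOL``).
    """

    structure: Structure
    bond_terms: tuple[HarmonicBond, ...] = ()
    angle_terms: tuple[HarmonicAngle, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "bond_terms", tuple(HarmonicBond(*t) for t in self.bond_terms)
        )
        object.__setattr__(
            self, "angle_terms", tuple(HarmonicAngle(*t) for t in self.angle_terms)
        )
        for t in self.bond_terms:
            if t.k <= 0 or t.b0 <= 0:
                raise ValueError(f"bond term {t} must have positive k and b0")
        for t in self.angle_terms:
            if t.k_theta <= 0 or not 0 < t.theta0 < 180:
                raise ValueError(f"angle term {t} must have k>0 and 0<theta0<180")
        grad = toy_gradient(self, self.structure.coordinates)
        gnorm = float(np.linalg.norm(grad))
        if gnorm > GRADIENT_TOL:
            raise ValueError(
                f"stored geometry is not a minimum: |gradient| = {gnorm:g} "
                f"kJ mol⁻¹ Bohr⁻¹"
            )


def _bond_length_nm(coords: np.ndarray, i: int, j: int) -> float:
    return float(np.linalg.norm(coords[j] - coords[i])) * _NM_PER_BOHR


def _angle_rad(coords: np.ndarray, i: int, j: int, k: int) -> float:
    u = coords[i] - coords[j]
    v = coords[k] - coords[j]
    nu = float(np.linalg.norm(u))
    nv = float(np.linalg.norm(v))
    if nu < 1e-10 or nv < 1e-10:
        raise GeometryError(f"zero-length arm in angle term {i}-{j}-{k}")
    cos_t = float(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))
    return float(np.arccos(cos_t))


def toy_energy(model: ToyModel, coords: np.ndarray) -> float:
    """Toy potential energy (kJ/mol) at ``coords`` (N×3, Bohr)."""
    coords = np.asarray(coords, dtype=float)
    if coords.shape != model.structure.coordinates.shape:
        raise ValueError(
            f"coords shape {coords.shape} does not match the model "
            f"({model.structure.coordinates.shape})"
        )
    e = 0.0
    for t in model.bond_terms:
        b = _bond_length_nm(coords, t.i, t.j)
        e += 0.5 * t.k * (b - t.b0) ** 2
    for t in model.angle_terms:
        theta = _angle_rad(coords, t.i, t.j, t.k)
        e += 0.5 * t.k_theta * (theta - np.deg2rad(t.theta0)) ** 2
    return float(e)


def toy_gradient(model: ToyModel, coords: np.ndarray) -> np.ndarray:
    """Analytic gradient of the toy energy, kJ mol⁻¹ Bohr⁻¹ (N×3)."""
    coords = np.asarray(coords, dtype=float)
    grad = np.zeros_like(coords)
    for t in model.bond_terms:
        r = coords[t.j] - coords[t.i]
        d = float(np.linalg.norm(r))
        if d < 1e-10:
            raise GeometryError(f"coincident atoms in bond term {t.i}-{t.j}")
        u = r / d
        # dE/db in kJ/mol/nm; db/dx carries Bohr→nm
        dedb = t.k * (d * _NM_PER_BOHR - t.b0)
        g = dedb * _NM_PER_BOHR * u
        grad[t.j] += g
        grad[t.i] -= g
    for t in model.angle_terms:
        u = coords[t.i] - coords[t.j]
        v = coords[t.k] - coords[t.j]
        nu = float(np.linalg.norm(u))
        nv = float(np.linalg.norm(v))
        if nu < 1e-10 or nv < 1e-10:
            raise GeometryError(f"zero-length arm in angle term {t.i}-{t.j}-{t.k}")
        uh, vh = u / nu, v / nv
        cos_t = float(np.clip(np.dot(uh, vh), -1.0, 1.0))
        sin_t = float(np.sqrt(max(1.0 - cos_t * cos_t, 0.0)))
        if sin_t < 1e-8:
            raise GeometryError(
                f"angle term {t.i}-{t.j}-{t.k} is degenerate (collinear arms)"
            )
        theta = float(np.arccos(cos_t))
        dedtheta = t.k_theta * (theta - np.deg2rad(t.theta0))  # kJ/mol/rad
        dtheta_di = (cos_t * uh - vh) / (nu * sin_t)
        dtheta_dk = (cos_t * vh - uh) / (nv * sin_t)
        grad[t.i] += dedtheta * dtheta_di
        grad[t.k] += dedtheta * dtheta_dk
        grad[t.j] -= dedtheta * (dtheta_di + dtheta_dk)
    return grad


def numerical_hessian(
    model: ToyModel, step: float = DEFAULT_STEP_BOHR
) -> HessianMatrix:
    """Central-difference Hessian at the equilibrium geometry, Hartree/Bohr².

    Each column is the central difference of the analytic gradient along
    one Cartesian coordinate; the result is symmetrised as (H+Hᵀ)/2.  For
    a translation-invariant model every row sums to ~0.
    """
    if not MIN_STEP_BOHR <= step <= MAX_STEP_BOHR:
        raise ValueError(
            f"step must lie in [{MIN_STEP_BOHR:g}, {MAX_STEP_BOHR:g}] Bohr, "
            f"got {step:g}"
        )
    x0 = model.structure.coordinates
    n3 = x0.size
    h = np.zeros((n3, n3))
    flat0 = x0.reshape(-1)
    for col in range(n3):
        xp = flat0.copy()
        xm = flat0.copy()
        xp[col] += step
        xm[col] -= step
        gp = toy_gradient(model, xp.reshape(x0.shape)).reshape(-1)
        gm = toy_gradient(model, xm.reshape(x0.shape)).reshape(-1)
        h[:, col] = (gp - gm) / (2.0 * step)
    h /= HARTREE_TO_KJ_PER_MOL  # kJ/mol/Bohr² → Hartree/Bohr²
    h = (h + h.T) / 2.0
    return HessianMatrix(values=h)


@dataclass(frozen=True)
class Fixture:
    """A toy model bundled with its synthetic checkpoint and term list."""

    name: str
    model: ToyModel
    qm: QMResult
    fchk_text: str
    terms_text: str


def _make_fixture(
    name: str,
    atomic_numbers,
    coords_nm: np.ndarray,
    bonds,
    angles,
    terms_text: str,
) -> Fixture:
    coords = np.asarray(coords_nm, dtype=float) / _NM_PER_BOHR
    structure = Structure(atomic_numbers=np.asarray(atomic_numbers), coordinates=coords)
    model = ToyModel(structure=structure, bond_terms=tuple(bonds), angle_terms=tuple(angles))
    qm = QMResult(
        structure=structure,
        hessian=numerical_hessian(model),
        source_path=f"synthetic:{name}",
    )
    return Fixture(
        name=name,
        model=model,
        qm=qm,
        fchk_text=write_fchk(qm, title=f"synthetic toy fixture: {name}"),
        terms_text=terms_text,
    )


def standard_fixtures() -> dict[str, Fixture]:
    """Build the named toy systems used throughout the test suite.

    diatomic
        Single C–C-like bond, k = 2.5e5 kJ mol⁻¹ nm⁻², b₀ = 0.10 nm.
    linear_triatomic
        Two collinear bonds with distinct constants (1e5 and 3e5).
    bent_triatomic
        Water-like H–O–H: bonds k = 4.0e5 at b₀ = 0.0957 nm and one angle
        k_θ = 400 kJ mol⁻¹ rad⁻² at θ₀ = 104.5°.
    disjoint
        Two identical, far-separated diatomic fragments; any cross-fragment
        pair has an exactly zero coupling block.
    ring6
        Planar six-membered carbon ring (regular hexagon, side 0.14 nm)
        with alternating bond constants 3e5/4e5 — a toluene-ring analogue
        for bond recovery in a cyclic topology.
    """
    fixtures: dict[str, Fixture] = {}

    fixtures["diatomic"] = _make_fixture(
        "diatomic",
        [6, 6],
        np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 0.10]]),
        [HarmonicBond(0, 1, 2.5e5, 0.10)],
        [],
        "1 2 CX CY\n",
    )

    fixtures["linear_triatomic"] = _make_fixture(
        "linear_triatomic",
        [8, 6, 8],
        np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 0.12], [0.0, 0.0, 0.23]]),
        [HarmonicBond(0, 1, 1.0e5, 0.12), HarmonicBond(1, 2, 3.0e5, 0.11)],
        [],
        "1 2 OX CX\n2 3 CX OY\n",
    )

    theta0 = 104.5
    b0 = 0.0957
    half = np.deg2rad(theta0) / 2.0
    fixtures["bent_triatomic"] = _make_fixture(
        "bent_triatomic",
        [1, 8, 1],
        np.array(
            [
                [b0 * np.sin(half), 0.0, b0 * np.cos(half)],
                [0.0, 0.0, 0.0],
                [-b0 * np.sin(half), 0.0, b0 * np.cos(half)],
            ]
        ),
        [HarmonicBond(0, 1, 4.0e5, b0), HarmonicBond(2, 1, 4.0e5, b0)],
        [HarmonicAngle(0, 1, 2, 400.0, theta0)],
        "1 2 HW OW\n3 2 HW OW\n1 2 3 HW OW HW\n",
    )

    fixtures["disjoint"] = _make_fixture(
        "disjoint",
        [6, 6, 6, 6],
        np.array(
            [
                [0.0, 0.0, 0.0],
                [0.0, 0.0, 0.11],
                [2.0, 0.0, 0.0],
                [2.0, 0.0, 0.11],
            ]
        ),
        [HarmonicBond(0, 1, 2.0e5, 0.11), HarmonicBond(2, 3, 2.0e5, 0.11)],
        [],
        "1 2 CA CB\n3 4 CA CB\n",
    )

    side = 0.14
    ring_coords = np.array(
        [
            [side * np.cos(np.pi / 3.0 * m), side * np.sin(np.pi / 3.0 * m), 0.0]
            for m in range(6)
        ]
    )
    ring_bonds = [
        HarmonicBond(m, (m + 1) % 6, 3.0e5 if m % 2 == 0 else 4.0e5, side)
        for m in range(6)
    ]
    ring_terms = "".join(
        f"{m + 1} {(m + 1) % 6 + 1} C{m + 1} C{(m + 1) % 6 + 1}\n" for m in range(6)
    )
    fixtures["ring6"] = _make_fixture(
        "ring6", [6] * 6, ring_coords, ring_bonds, [], ring_terms
    )

    return fixtures


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Draw a uniform proper rotation matrix via QR of a Gaussian matrix."""
    m = rng.standard_normal((3, 3))
    q, r = np.linalg.qr(m)
    q = q * np.sign(np.diag(r))  # make the decomposition unique
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def rotate_qm_result(qm: QMResult, rotation: np.ndarray) -> QMResult:
    """Apply a rigid rotation to coordinates and (blockwise) to the Hessian.

    Each 3×3 block H_ab transforms as R·H_ab·Rᵀ, which equals the full-matrix
    congruence with the block-diagonal (I ⊗ R) operator.
    """
    st = qm.structure
    coords = st.coordinates @ rotation.T
    big = np.kron(np.eye(st.atom_count), rotation)
    h = big @ qm.hessian.values @ big.T
    h = (h + h.T) / 2.0  # restore exact symmetry lost to round-off
    return QMResult(
        structure=Structure(atomic_numbers=st.atomic_numbers, coordinates=coords),
        hessian=HessianMatrix(values=h),
        source_path=qm.source_path,
    )
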