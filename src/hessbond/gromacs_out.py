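"""Term-list parsing and GROMACS bonded-parameter output.

The user supplies a plain-text term list naming which bonds and angles to
derive: whitespace-separated lines of either two 1-based atom IDs followed
by two force-field atom type names (a bond) or three IDs followed by three
names (an angle, vertex in the middle).  ``#`` starts a comment; blank
lines are skipped.  Derived parameters are written as ``[ bondtypes ]``
and ``[ angletypes ]`` blocks (harmonic function type 1) ready to paste
into a force field's ``ffbonded.itp``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .errors import (
    DuplicateTermWarning,
    NonPhysicalParameterError,
    TermListError,
    TermLookupError,
)
from .gaussian_io import QMResult
from .seminario import (
    angle_force_value,
    bond_force_value,
    equilibrium_angle,
    equilibrium_bond,
)
from .units import (
    angle_k_au_to_gromacs,
    apply_frequency_scaling,
    bond_k_au_to_gromacs,
)

__all__ = [
    "BondTerm",
    "AngleTerm",
    "TermList",
    "BondParameter",
    "AngleParameter",
    "parse_term_list",
    "write_gromacs_bonded",
    "read_gromacs_bonded",
    "derive_all",
]


@dataclass(frozen=True)
class BondTerm:
    """Requested bond: two 1-based atom IDs with their atom type names."""

    atom_i: int
    atom_j: int
    type_i: str
    type_j: str

    def __post_init__(self) -> None:
        if self.atom_i < 1 or self.atom_j < 1:
            raise ValueError("atom IDs are 1-based and must be positive")
        if self.atom_i == self.atom_j:
            raise ValueError("a bond needs two distinct atom IDs")
        for name in (self.type_i, self.type_j):
            if not name or any(ch.isspace() for ch in name):
                raise ValueError(f"invalid atom type name {name!r}")

    @property
    def label(self) -> str:
        return f"bond {self.atom_i}-{self.atom_j} ({self.type_i}-{self.type_j})"


@dataclass(frozen=True)
class AngleTerm:
    """Requested angle: three 1-based atom IDs (vertex in the middle)."""

    atom_i: int
    atom_j: int
    atom_k: int
    type_i: str
    type_j: str
    type_k: str

    def __post_init__(self) -> None:
        ids = (self.atom_i, self.atom_j, self.atom_k)
        if any(i < 1 for i in ids):
            raise ValueError("atom IDs are 1-based and must be positive")
        if len(set(ids)) != 3:
            raise ValueError("an angle needs three distinct atom IDs")
        for name in (self.type_i, self.type_j, self.type_k):
            if not name or any(ch.isspace() for ch in name):
                raise ValueError(f"invalid atom type name {name!r}")

    @property
    def label(self) -> str:
        return (
            f"angle {self.atom_i}-{self.atom_j}-{self.atom_k} "
            f"({self.type_i}-{self.type_j}-{self.type_k})"
        )


@dataclass(frozen=True)
class TermList:
    """Parsed term list; ``terms`` preserves the input line order."""

    terms: tuple[BondTerm | AngleTerm, ...]

    @property
    def bonds(self) -> tuple[BondTerm, ...]:
        return tuple(t for t in self.terms if isinstance(t, BondTerm))

    @property
    def angles(self) -> tuple[AngleTerm, ...]:
        return tuple(t for t in self.terms if isinstance(t, AngleTerm))


@dataclass(frozen=True)
class BondParameter:
    """Derived bond parameter: b₀ (nm) and k_b (kJ mol⁻¹ nm⁻²)."""

    term: BondTerm
    b0: float
    kb: float

    def __post_init__(self) -> None:
        import math

        if self.b0 <= 0:
            raise ValueError(f"{self.term.label}: b0 must be positive")
        if not math.isfinite(self.kb):
            raise ValueError(f"{self.term.label}: kb must be finite")


@dataclass(frozen=True)
class AngleParameter:
    """Derived angle parameter: θ₀ (degrees) and k_θ (kJ mol⁻¹ rad⁻²)."""

    term: AngleTerm
    theta0: float
    ktheta: float

    def __post_init__(self) -> None:
        import math

        if not 0 < self.theta0 < 180:
            raise ValueError(f"{self.term.label}: theta0 must be in (0, 180)")
        if not math.isfinite(self.ktheta):
            raise ValueError(f"{self.term.label}: ktheta must be finite")


def _parse_id(token: str, lineno: int) -> int:
    try:
        return int(token)
    except ValueError:
        raise TermListError(f"expected an integer atom ID, got {token!r}", lineno) from None


def parse_term_list(text: str) -> TermList:
    """Parse a term-list character stream.

    Lines with 2 IDs + 2 names become bonds, 3 IDs + 3 names angles; any
    other token count is a :class:`TermListError` carrying the line number.
    An identical repeated term is kept once and reported through a
    :class:`DuplicateTermWarning`.
    """
    terms: list[BondTerm | AngleTerm] = []
    seen: set[BondTerm | AngleTerm] = set()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        tok = line.split()
        try:
            if len(tok) == 4:
                term: BondTerm | AngleTerm = BondTerm(
                    _parse_id(tok[0], lineno), _parse_id(tok[1], lineno), tok[2], tok[3]
                )
            elif len(tok) == 6:
                term = AngleTerm(
                    _parse_id(tok[0], lineno),
                    _parse_id(tok[1], lineno),
                    _parse_id(tok[2], lineno),
                    tok[3],
                    tok[4],
                    tok[5],
                )
            else:
                raise TermListError(
                    f"expected 'i j type_i type_j' (bond) or "
                    f"'i j k type_i type_j type_k' (angle), got {len(tok)} fields",
                    lineno,
                )
        except ValueError as exc:
            if isinstance(exc, TermListError):
                raise
            raise TermListError(str(exc), lineno) from None
        if term in seen:
            warnings.warn(
                f"duplicate term on line {lineno} ({term.label}); kept once",
                DuplicateTermWarning,
                stacklevel=2,
            )
            continue
        seen.add(term)
        terms.append(term)
    return TermList(terms=tuple(terms))


def write_gromacs_bonded(
    bonds: tuple[BondParameter, ...] | list[BondParameter],
    angles: tuple[AngleParameter, ...] | list[AngleParameter],
) -> str:
    """Render ``[ bondtypes ]`` and ``[ angletypes ]`` blocks.

    b₀ is printed to 6 decimals, θ₀ and both force constants to 3 — the
    precision GROMACS force-field include files conventionally carry.  A
    negative force constant is refused: it cannot come from a structure at
    a minimum and would silently corrupt a topology.
    """
    for p in bonds:
        if p.kb < 0:
            raise NonPhysicalParameterError(
                f"{p.term.label}: negative force constant {p.kb:g}"
            )
    for p in angles:
        if p.ktheta < 0:
            raise NonPhysicalParameterError(
                f"{p.term.label}: negative force constant {p.ktheta:g}"
            )
    lines = ["[ bondtypes ]", "; i    j  func        b0            kb"]
    for p in bonds:
        lines.append(
            f"  {p.term.type_i:<4s} {p.term.type_j:<4s}    1  "
            f"{p.b0:10.6f}  {p.kb:14.3f}"
        )
    lines.append("")
    lines.append("[ angletypes ]")
    lines.append("; i    j    k  func      theta0        ktheta")
    for p in angles:
        lines.append(
            f"  {p.term.type_i:<4s} {p.term.type_j:<4s} {p.term.type_k:<4s}    1  "
            f"{p.theta0:10.3f}  {p.ktheta:12.3f}"
        )
    lines.append("")
    return "\n".join(lines)


def read_gromacs_bonded(
    text: str,
) -> tuple[list[tuple[str, str, int, float, float]], list[tuple[str, str, str, int, float, float]]]:
    """Strictly re-parse output of :func:`write_gromacs_bonded`.

    Returns raw ``(types..., func, value, value)`` rows for the bondtypes
    and angletypes sections.  Used to verify the write→read round trip of
    the output dialect.
    """
    bonds: list[tuple[str, str, int, float, float]] = []
    angles: list[tuple[str, str, str, int, float, float]] = []
    section = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split(";", 1)[0].strip()
        if not line:
            continue
        if line.startswith("["):
            section = line.strip("[] ").strip()
            if section not in ("bondtypes", "angletypes"):
                raise ValueError(f"line {lineno}: unknown section {section!r}")
            continue
        tok = line.split()
        if section == "bondtypes":
            if len(tok) != 5:
                raise ValueError(f"line {lineno}: bondtypes rows need 5 fields")
            bonds.append((tok[0], tok[1], int(tok[2]), float(tok[3]), float(tok[4])))
        elif section == "angletypes":
            if len(tok) != 6:
                raise ValueError(f"line {lineno}: angletypes rows need 6 fields")
            angles.append(
                (tok[0], tok[1], tok[2], int(tok[3]), float(tok[4]), float(tok[5]))
            )
        else:
            raise ValueError(f"line {lineno}: data outside any section")
    return bonds, angles


def derive_all(
    qm: QMResult,
    terms: TermList,
    scale: float = 1.0,
) -> tuple[tuple[BondParameter, ...], tuple[AngleParameter, ...], tuple[str, ...]]:
    """Derive every requested parameter from one QM result.

    For each term the equilibrium value and force constant are computed by
    the subblock eigen-analysis, converted to GROMACS units and multiplied
    by the squared frequency scale factor.  Warnings raised while deriving
    a term (no interaction, non-minimum stiffness) are captured and
    returned as strings prefixed with that term's label; output order
    matches input order and the computation is fully deterministic.
    """
    n = qm.structure.atom_count
    for term in terms.terms:
        ids = (
            (term.atom_i, term.atom_j)
            if isinstance(term, BondTerm)
            else (term.atom_i, term.atom_j, term.atom_k)
        )
        if any(i > n for i in ids):
            raise TermLookupError(
                f"{term.label}: atom ID exceeds structure size ({n} atoms)"
            )

    bonds: list[BondParameter] = []
    angles: list[AngleParameter] = []
    notes: list[str] = []
    for term in terms.terms:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            if isinstance(term, BondTerm):
                a, b = term.atom_i - 1, term.atom_j - 1
                b0 = equilibrium_bond(qm.structure, a, b)
                k_au = bond_force_value(qm.hessian, qm.structure, a, b)
                kb = apply_frequency_scaling(bond_k_au_to_gromacs(k_au), scale)
                bonds.append(BondParameter(term=term, b0=b0, kb=kb))
            else:
                a, b, c = term.atom_i - 1, term.atom_j - 1, term.atom_k - 1
                theta0 = equilibrium_angle(qm.structure, a, b, c)
                k_au = angle_force_value(qm.hessian, qm.structure, a, b, c)
                ktheta = apply_frequency_scaling(angle_k_au_to_gromacs(k_au), scale)
                angles.append(AngleParameter(term=term, theta0=theta0, ktheta=ktheta))
        for w in caught:
            notes.append(f"{term.label}: {w.message}")
    return tuple(bonds), tuple(angles), tuple(notes)
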