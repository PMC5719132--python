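"""Reading and writing Gaussian formatted-checkpoint (fchk) files.

A formatted checkpoint file is a plain-text dump of a Gaussian calculation.
Only three sections are needed to derive bonded parameters:

* ``Atomic numbers``                (integers)
* ``Current cartesian coordinates`` (reals, Bohr, 3 per atom)
* ``Cartesian Force Constants``     (reals, Hartree/Bohr², lower triangle
  of the 3N×3N Hessian in row-major order)

Section headers follow the Gaussian convention ``Label  T  N= count`` where
``T`` is ``I`` or ``R``; scalar header lines without ``N=`` are ignored.
Units are fixed by the fchk convention — the file itself carries no unit
metadata.  Atom IDs are 1-based in all user-facing text (Gaussian
numbering); arrays returned here are 0-indexed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from .errors import (
    DimensionError,
    FchkFormatError,
    FchkParseError,
    FchkTruncationError,
)

__all__ = [
    "Structure",
    "HessianMatrix",
    "QMResult",
    "parse_fchk",
    "write_fchk",
    "expand_lower_triangular",
    "ELEMENT_SYMBOLS",
]

# Element symbols indexed by atomic number (1..118).
ELEMENT_SYMBOLS: tuple[str, ...] = (
    "H", "He", "Li", "Be", "B", "C", "N", "O", "F", "Ne",
    "Na", "Mg", "Al", "Si", "P", "S", "Cl", "Ar", "K", "Ca",
    "Sc", "Ti", "V", "Cr", "Mn", "Fe", "Co", "Ni", "Cu", "Zn",
    "Ga", "Ge", "As", "Se", "Br", "Kr", "Rb", "Sr", "Y", "Zr",
    "Nb", "Mo", "Tc", "Ru", "Rh", "Pd", "Ag", "Cd", "In", "Sn",
    "Sb", "Te", "I", "Xe", "Cs", "Ba", "La", "Ce", "Pr", "Nd",
    "Pm", "Sm", "Eu", "Gd", "Tb", "Dy", "Ho", "Er", "Tm", "Yb",
    "Lu", "Hf", "Ta", "W", "Re", "Os", "Ir", "Pt", "Au", "Hg",
    "Tl", "Pb", "Bi", "Po", "At", "Rn", "Fr", "Ra", "Ac", "Th",
    "Pa", "U", "Np", "Pu", "Am", "Cm", "Bk", "Cf", "Es", "Fm",
    "Md", "No", "Lr", "Rf", "Db", "Sg", "Bh", "Hs", "Mt", "Ds",
    "Rg", "Cn", "Nh", "Fl", "Mc", "Lv", "Ts", "Og",
)


@dataclass(frozen=True)
class Structure:
    """Atom identities and Cartesian coordinates of one molecule.

    Attributes
    ----------
    atomic_numbers:
        Integer array of shape (N,), entries in [1, 118].
    coordinates:
        Float array of shape (N, 3), in Bohr.
    """

    atomic_numbers: np.ndarray
    coordinates: np.ndarray

    def __post_init__(self) -> None:
        z = np.asarray(self.atomic_numbers, dtype=int)
        xyz = np.asarray(self.coordinates, dtype=float)
        if z.ndim != 1 or z.size == 0:
            raise ValueError("atomic_numbers must be a non-empty 1-D sequence")
        if np.any(z < 1) or np.any(z > len(ELEMENT_SYMBOLS)):
            raise ValueError("atomic numbers must lie in [1, 118]")
        if xyz.shape != (z.size, 3):
            raise ValueError(
                f"coordinates must have shape ({z.size}, 3), got {xyz.shape}"
            )
        object.__setattr__(self, "atomic_numbers", z)
        object.__setattr__(self, "coordinates", xyz)

    @property
    def atom_count(self) -> int:
        return int(self.atomic_numbers.size)

    @property
    def element_symbols(self) -> tuple[str, ...]:
        return tuple(ELEMENT_SYMBOLS[z - 1] for z in self.atomic_numbers)


@dataclass(frozen=True)
class HessianMatrix:
    """Full symmetric Cartesian Hessian, 3N×3N, in Hartree/Bohr²."""

    values: np.ndarray

    def __post_init__(self) -> None:
        h = np.asarray(self.values, dtype=float)
        if h.ndim != 2 or h.shape[0] != h.shape[1]:
            raise ValueError(f"Hessian must be square, got shape {h.shape}")
        if h.shape[0] % 3 != 0 or h.shape[0] == 0:
            raise ValueError(
                f"Hessian dimension must be a positive multiple of 3, got {h.shape[0]}"
            )
        if not np.array_equal(h, h.T):
            raise ValueError("Hessian must be exactly symmetric")
        object.__setattr__(self, "values", h)

    @property
    def n_atoms(self) -> int:
        return self.values.shape[0] // 3


@dataclass(frozen=True)
class QMResult:
    """Geometry plus Hessian as loaded from one checkpoint file."""

    structure: Structure
    hessian: HessianMatrix
    source_path: str = ""

    def __post_init__(self) -> None:
        if self.hessian.n_atoms != self.structure.atom_count:
            raise ValueError(
                f"Hessian is for {self.hessian.n_atoms} atoms but structure "
                f"has {self.structure.atom_count}"
            )


def expand_lower_triangular(flat, dim: int) -> np.ndarray:
    """Expand a row-major lower-triangular sequence into a symmetric matrix.

    The input ordering is the fchk convention (1,1),(2,1),(2,2),(3,1),…
    The upper triangle is mirrored from the lower one, so the result is
    exactly symmetric elementwise.
    """
    flat = np.asarray(flat, dtype=float)
    if dim < 1:
        raise DimensionError(f"matrix dimension must be positive, got {dim}")
    expected = dim * (dim + 1) // 2
    if flat.ndim != 1 or flat.size != expected:
        raise DimensionError(
            f"lower triangle of a {dim}x{dim} matrix needs {expected} values, "
            f"got {flat.size}"
        )
    out = np.zeros((dim, dim))
    rows, cols = np.tril_indices(dim)
    out[rows, cols] = flat
    out[cols, rows] = flat
    return out


_SECTION_RE = re.compile(
    r"^(?P<label>.+?)\s+(?P<dtype>[IR])\s+N=\s*(?P<count>\d+)\s*$"
)

_REQUIRED_SECTIONS = (
    "Atomic numbers",
    "Current cartesian coordinates",
    "Cartesian Force Constants",
)


def _scan_sections(text: str) -> dict[str, np.ndarray]:
    """Collect every ``Label  T  N= count`` array section of an fchk stream."""
    lines = text.splitlines()
    sections: dict[str, np.ndarray] = {}
    i = 0
    while i < len(lines):
        m = _SECTION_RE.match(lines[i])
        i += 1
        if m is None:
            continue
        label = m.group("label").strip()
        count = int(m.group("count"))
        is_int = m.group("dtype") == "I"
        values: list[float] = []
        while i < len(lines) and len(values) < count:
            if _SECTION_RE.match(lines[i]):
                break  # next section began before enough values were read
            lineno = i + 1
            for tok in lines[i].split():
                try:
                    values.append(int(tok) if is_int else float(tok))
                except ValueError:
                    raise FchkParseError(
                        f"non-numeric token {tok!r} in section {label!r}", lineno
                    ) from None
            i += 1
        if len(values) != count:
            raise FchkTruncationError(
                f"section {label!r} declares {count} values but {len(values)} "
                f"were parsed"
            )
        sections[label] = np.asarray(
            values, dtype=int if is_int else float
        )
    return sections


def parse_fchk(text: str, source_path: str = "") -> QMResult:
    """Parse an fchk character stream into geometry and Hessian.

    Parameters
    ----------
    text:
        Full contents of a formatted checkpoint file.
    source_path:
        Optional provenance string stored on the result.

    Raises
    ------
    FchkFormatError
        If a required section is missing or the section sizes disagree.
    FchkTruncationError
        If a section holds fewer (or more) values than it declares.
    FchkParseError
        If a value token is not numeric (reported with its line number).
    """
    sections = _scan_sections(text)
    for name in _REQUIRED_SECTIONS:
        if name not in sections:
            raise FchkFormatError(f"missing required fchk section {name!r}")

    z = sections["Atomic numbers"]
    n = z.size
    xyz = sections["Current cartesian coordinates"]
    if xyz.size != 3 * n:
        raise FchkFormatError(
            f"'Current cartesian coordinates' holds {xyz.size} values; "
            f"expected {3 * n} for {n} atoms"
        )
    tri = sections["Cartesian Force Constants"]
    expected = 3 * n * (3 * n + 1) // 2
    if tri.size != expected:
        raise FchkFormatError(
            f"'Cartesian Force Constants' holds {tri.size} values; expected "
            f"{expected} (lower triangle of a {3 * n}x{3 * n} matrix)"
        )

    structure = Structure(atomic_numbers=z, coordinates=xyz.reshape(n, 3))
    hessian = HessianMatrix(values=expand_lower_triangular(tri, 3 * n))
    return QMResult(structure=structure, hessian=hessian, source_path=source_path)


def _format_block(values: np.ndarray, per_line: int, fmt: str) -> list[str]:
    out = []
    for start in range(0, values.size, per_line):
        chunk = values[start : start + per_line]
        out.append("".join(fmt % v for v in chunk))
    return out


def write_fchk(result: QMResult, title: str = "hessbond checkpoint") -> str:
    """Serialize a :class:`QMResult` to an fchk character stream.

    The emitted text parses back (:func:`parse_fchk`) to an equal result.
    Reals are written with 15 decimal digits — wider than Gaussian's own
    8-digit fields — so that write→parse round trips are lossless to well
    below 1e-12 relative; the parser accepts either width.
    """
    st = result.structure
    n = st.atom_count
    dim = 3 * n
    rows, cols = np.tril_indices(dim)
    tri = result.hessian.values[rows, cols]

    lines = [
        title,
        "Freq      SYNTH                                                       NONE",
        f"Number of atoms                            I  {n:17d}",
        f"{'Atomic numbers':<43}I   N={n:12d}",
    ]
    lines += _format_block(st.atomic_numbers, 6, "%12d")
    lines.append(f"{'Current cartesian coordinates':<43}R   N={3 * n:12d}")
    lines += _format_block(st.coordinates.reshape(-1), 5, "%24.15E")
    lines.append(f"{'Cartesian Force Constants':<43}R   N={tri.size:12d}")
    lines += _format_block(tri, 5, "%24.15E")
    return "\n".join(lines) + "\n"
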