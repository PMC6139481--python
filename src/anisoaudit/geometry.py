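"""Unit-cell and space-group geometry primitives.

All real-space coordinates are Cartesian angstroms in the standard PDB
orthogonalization frame (crystal *a* axis along Cartesian x, *b* in the
x-y plane).  Reciprocal-space vectors live in the dual of that frame, so
coordinate files and reflection data share one orientation convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np

__all__ = [
    "UnitCell",
    "SpaceGroup",
    "cell_volume",
    "scattering_vector",
    "d_spacing",
]


class GeometryError(ValueError):
    """Raised for degenerate cells or unknown symmetry."""


@dataclass(frozen=True)
class UnitCell:
    """Triclinic unit cell: edge lengths in angstrom, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise GeometryError(f"cell edges must be positive: {self}")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise GeometryError(f"cell angles must be in (0, 180): {self}")
        if self._cos_term() <= 0:
            raise GeometryError(f"cell metric is not positive definite: {self}")

    def _cos_term(self) -> float:
        ca, cb, cg = (np.cos(np.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        return 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg

    @property
    def volume(self) -> float:
        """Cell volume in cubic angstrom (closed triclinic form)."""
        return self.a * self.b * self.c * float(np.sqrt(self._cos_term()))

    @property
    def orth_matrix(self) -> np.ndarray:
        """Orthogonalization matrix M: Cartesian = M @ fractional."""
        ca, cb, cg = (np.cos(np.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        sg = np.sin(np.radians(self.gamma))
        v = self.volume
        return np.array(
            [
                [self.a, self.b * cg, self.c * cb],
                [0.0, self.b * sg, self.c * (ca - cb * cg) / sg],
                [0.0, 0.0, v / (self.a * self.b * sg)],
            ]
        )

    @property
    def frac_matrix(self) -> np.ndarray:
        """Fractionalization matrix, inverse of :attr:`orth_matrix`."""
        return np.linalg.inv(self.orth_matrix)

    @property
    def recip_matrix(self) -> np.ndarray:
        """Columns are the reciprocal basis vectors a*, b*, c* (1/angstrom)."""
        return self.frac_matrix.T

    def orthogonalize(self, frac: np.ndarray) -> np.ndarray:
        return np.asarray(frac, dtype=float) @ self.orth_matrix.T

    def fractionalize(self, xyz: np.ndarray) -> np.ndarray:
        return np.asarray(xyz, dtype=float) @ self.frac_matrix.T

    def to_gemmi(self) -> gemmi.UnitCell:
        return gemmi.UnitCell(self.a, self.b, self.c, self.alpha, self.beta, self.gamma)


def cell_volume(cell: UnitCell) -> float:
    """Unit-cell volume in cubic angstrom."""
    return cell.volume


@dataclass(frozen=True)
class SpaceGroup:
    """Crystallographic space group as an explicit operator list.

    ``ops`` holds (rotation, translation) pairs acting on fractional
    coordinates; rotations are exact integer matrices, translations are
    fractions of the cell edges.  ``z_asu`` is the number of asymmetric
    units per cell (symmetry operations times centering multiplicity).
    """

    hm_symbol: str
    ops: tuple[tuple[np.ndarray, np.ndarray], ...] = field(repr=False)
    z_asu: int

    @classmethod
    def from_symbol(cls, symbol: str) -> "SpaceGroup":
        sg = gemmi.find_spacegroup_by_name(symbol)
        if sg is None:
            raise GeometryError(f"unknown space-group symbol: {symbol!r}")
        den = float(gemmi.Op.DEN)
        ops = tuple(
            (np.array(op.rot, dtype=float) / den, np.array(op.tran, dtype=float) / den)
            for op in sg.operations()
        )
        return cls(hm_symbol=sg.hm, ops=ops, z_asu=len(ops))

    def point_group_rotations(self) -> list[np.ndarray]:
        """Unique rotation parts (fractional basis), translations stripped."""
        seen: list[np.ndarray] = []
        for rot, _ in self.ops:
            if not any(np.array_equal(rot, r) for r in seen):
                seen.append(rot)
        return seen

    def cartesian_rotations(self, cell: UnitCell) -> list[np.ndarray]:
        """Point-group rotations expressed in the Cartesian frame of ``cell``."""
        m = cell.orth_matrix
        minv = cell.frac_matrix
        return [m @ rot @ minv for rot in self.point_group_rotations()]


P1 = SpaceGroup.from_symbol("P 1")


def scattering_vector(hkl, cell: UnitCell) -> np.ndarray:
    """Cartesian reciprocal vector(s) h*a* + k*b* + l*c*, in 1/angstrom.

    The magnitude is 1/d.  Accepts a single (h,k,l) triple or an (n,3)
    array; (0,0,0) is rejected because it has no diffraction direction.
    """
    arr = np.asarray(hkl, dtype=float)
    single = arr.ndim == 1
    arr = np.atleast_2d(arr)
    if np.any(np.all(arr == 0, axis=1)):
        raise GeometryError("scattering vector undefined for hkl = (0,0,0)")
    svec = arr @ cell.recip_matrix.T
    return svec[0] if single else svec


def d_spacing(hkl, cell: UnitCell) -> np.ndarray | float:
    """Resolution d = 1/|s| in angstrom for one or many reflections."""
    svec = np.atleast_2d(scattering_vector(hkl, cell))
    d = 1.0 / np.linalg.norm(svec, axis=1)
    return float(d[0]) if d.size == 1 else d
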