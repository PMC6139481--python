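"""Real-space packing metrics: crystal contacts, Matthews coefficient, solvent.

A crystal contact is an atom pair between the deposited asymmetric unit
and any symmetry copy (space-group operation plus lattice translation)
within a distance cutoff, 4.0 A by default.  The contacts ratio divides
the pair count by the total number of atoms in the model, heteroatoms and
waters included.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import gemmi
import numpy as np
from scipy.spatial import cKDTree

from .geometry import SpaceGroup, UnitCell
from .io import StructureModel

__all__ = [
    "PackingResult",
    "expand_symmetry",
    "count_crystal_contacts",
    "contacts_ratio",
    "asu_mass",
    "matthews_solvent",
    "analyze_packing",
]

#: Reciprocal of the conventional protein partial specific volume
#: (0.74 cm^3/g) expressed in Matthews-coefficient units; solvent
#: fraction = 1 - PROTEIN_DENSITY_CONST / V_M.
PROTEIN_DENSITY_CONST = 1.23

#: Multiplier applied to summed heavy-atom mass to account for the
#: hydrogens absent from typical X-ray models (~5% of protein mass).
HYDROGEN_MASS_FACTOR = 1.05

SELF_IMAGE_TOL = 1e-6  # A; an image closer than this to its source atom is the atom itself


@dataclass
class PackingResult:
    n_contacts: int
    n_atoms_total: int
    contacts_ratio: float
    asu_mass: float
    matthews: Optional[float] = None
    solvent_pct: Optional[float] = None


def _translation_range(cell: UnitCell, cutoff: float) -> list[int]:
    """Half-width of the lattice-translation shell per axis.

    {-1,0,1} normally; widened while a cell edge is shorter than twice
    the cutoff so that all images within reach are enumerated.
    """
    out = []
    for length in (cell.a, cell.b, cell.c):
        n = max(1, int(np.ceil(2.0 * cutoff / length)))
        out.append(n)
    return out


def expand_symmetry(
    model: StructureModel,
    cell: UnitCell,
    sg: SpaceGroup,
    shell: Optional[list[int]] = None,
) -> list[np.ndarray]:
    """Cartesian coordinates of every symmetry copy in the local lattice shell.

    One copy per (space-group operation, lattice translation) pair over
    translations t in {-n..n}^3, excluding the identity with zero
    translation (that is the input model itself).
    """
    if model.n_atoms_total == 0:
        raise ValueError("empty model")
    if shell is None:
        shell = [1, 1, 1]
    frac = cell.fractionalize(model.coords())
    copies: list[np.ndarray] = []
    for rot, tran in sg.ops:
        base = frac @ rot.T + tran
        identity = np.allclose(rot, np.eye(3)) and np.allclose(np.mod(tran, 1.0), 0.0)
        for tx in range(-shell[0], shell[0] + 1):
            for ty in range(-shell[1], shell[1] + 1):
                for tz in range(-shell[2], shell[2] + 1):
                    if identity and tx == ty == tz == 0:
                        continue
                    copies.append(cell.orthogonalize(base + np.array([tx, ty, tz], float)))
    return copies


def count_crystal_contacts(
    model: StructureModel,
    cell: UnitCell,
    sg: SpaceGroup,
    cutoff: float = 4.0,
) -> int:
    """Count ordered (ASU atom, image atom) pairs within ``cutoff`` angstrom.

    Pairs at essentially zero distance (an atom meeting its own image on a
    special position) are excluded.  Intra-ASU pairs are never contacts.
    Implemented with a k-d tree over the expanded images; equals the
    exhaustive all-images scan by construction.
    """
    if min(cell.a, cell.b, cell.c) < cutoff / 2.0:
        warnings.warn("cell edge shorter than half the contact cutoff; widening image shell")
    # anchor the model near the origin cell so the translation shell is sufficient
    frac = cell.fractionalize(model.coords())
    anchor = np.floor(frac.mean(axis=0))
    xyz = cell.orthogonalize(frac - anchor)
    anchored = StructureModel(
        atoms=[
            type(a)(a.element, tuple(p), a.occupancy, a.record_kind, a.chain_id, a.name)
            for a, p in zip(model.atoms, xyz)
        ]
    )
    shell = _translation_range(cell, cutoff)
    copies = expand_symmetry(anchored, cell, sg, shell=shell)
    images = np.vstack(copies)
    tree = cKDTree(images)
    pairs = tree.query_ball_point(xyz, r=cutoff)
    n = 0
    for i, js in enumerate(pairs):
        if not js:
            continue
        dist = np.linalg.norm(images[js] - xyz[i], axis=1)
        n += int(np.sum(dist > SELF_IMAGE_TOL))
    return n


def contacts_ratio(n_contacts: int, model: StructureModel) -> float:
    """Crystal contacts divided by the total atom count (waters included)."""
    if model.n_atoms_total == 0:
        raise ValueError("empty model")
    return n_contacts / model.n_atoms_total


def asu_mass(model: StructureModel) -> float:
    """Macromolecular mass of the asymmetric unit in daltons.

    Standard atomic masses summed over polymer atoms only (heteroatoms
    and waters excluded), scaled by :data:`HYDROGEN_MASS_FACTOR` because
    hydrogens are absent from the model.
    """
    total = 0.0
    n_polymer = 0
    for at in model.atoms:
        if at.record_kind != "polymer":
            continue
        el = gemmi.Element(at.element)
        if el.atomic_number == 0:
            raise ValueError(f"unknown element symbol: {at.element!r}")
        total += el.weight
        n_polymer += 1
    if n_polymer == 0:
        warnings.warn("no polymer atoms; asymmetric-unit mass is zero")
        return 0.0
    return total * HYDROGEN_MASS_FACTOR


def matthews_solvent(cell: UnitCell, sg: SpaceGroup, mass: float) -> tuple[float, float]:
    """Matthews coefficient (A^3/Da) and solvent content (percent).

    V_M = V_cell / (z_asu * mass); solvent = 100 * (1 - 1.23 / V_M).
    A negative solvent content (over-packed hypothetical) is returned
    as-is with a warning, never clamped.
    """
    if mass <= 0:
        raise ValueError("asymmetric-unit mass must be positive")
    v_m = cell.volume / (sg.z_asu * mass)
    solvent = 100.0 * (1.0 - PROTEIN_DENSITY_CONST / v_m)
    if solvent < 0:
        warnings.warn(f"negative solvent content ({solvent:.1f}%): over-packed cell")
    return v_m, solvent


def analyze_packing(
    model: StructureModel,
    cell: UnitCell,
    sg: SpaceGroup,
    cutoff: float = 4.0,
) -> PackingResult:
    """Contacts ratio plus Matthews/solvent statistics for one entry."""
    n_contacts = count_crystal_contacts(model, cell, sg, cutoff=cutoff)
    mass = asu_mass(model)
    matthews = solvent = None
    if mass > 0:
        matthews, solvent = matthews_solvent(cell, sg, mass)
    return PackingResult(
        n_contacts=n_contacts,
        n_atoms_total=model.n_atoms_total,
        contacts_ratio=contacts_ratio(n_contacts, model),
        asu_mass=mass,
        matthews=matthews,
        solvent_pct=solvent,
    )
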