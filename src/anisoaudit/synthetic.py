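"""Synthetic diffraction data and toy crystals with known ground truth.

Reflection sets follow acentric Wilson statistics: each intensity is
exponentially distributed with mean K * exp(-2 s^2 B(n)), where s =
1/(2d) and B(n) = n' B n is the directional temperature factor imposed by
a configurable tensor.  Noise-free mode returns the mean itself, so
fitted parameters can be compared against the imposed ones exactly.
Toy crystals in small P1/P21/P212121 cells come with an exhaustively
computed contact count that serves as an independent oracle for the
grid-based implementation.
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, field_validator
from scipy.spatial.distance import cdist

from .audit import AuditRecord
from .geometry import SpaceGroup, UnitCell
from .io import Atom, EntryHeader, ReflectionSet, StructureModel
from .packing import _translation_range

__all__ = [
    "DirectionalSigma",
    "SimulationSpec",
    "gen_reflections",
    "gen_crystal",
    "gen_header",
    "gen_audit_population",
    "exhaustive_contact_count",
    "enumerate_hkl",
]

SELF_IMAGE_TOL = 1e-6


class DirectionalSigma(BaseModel):
    """Multiply sigma by ``factor`` for reflections in a resolution slab.

    With ``axis`` set, only reflections within ``cone_deg`` of that axis
    (Friedel-symmetrized) are affected; without it the inflation is
    global.  Used to plant directional F/sigF crossings at known
    resolutions for resolution-limit tests.
    """

    model_config = ConfigDict(arbitrary_types_allowed=True)

    factor: float = Field(gt=0)
    d_max: Optional[float] = None  # inflate where d < d_max
    axis: Optional[tuple[float, float, float]] = None
    cone_deg: float = 20.0

    def mask(self, d: np.ndarray, n_hat: np.ndarray) -> np.ndarray:
        m = np.ones(len(d), dtype=bool)
        if self.d_max is not None:
            m &= d < self.d_max
        if self.axis is not None:
            ax = np.asarray(self.axis, dtype=float)
            ax = ax / np.linalg.norm(ax)
            m &= np.abs(n_hat @ ax) >= np.cos(np.radians(self.cone_deg))
        return m


class SimulationSpec(BaseModel):
    """Ground-truth parameters for one synthetic reflection set.

    ``sigma_frac`` sets the reported uncertainty to that fraction of the
    model mean intensity, so the noise-free amplitude signal-to-noise is
    F/sigF = 2/sigma_frac everywhere (0.2 -> 10).
    """

    model_config = ConfigDict(arbitrary_types_allowed=True)

    cell: UnitCell = UnitCell(30.0, 30.0, 30.0)
    sg_symbol: str = "P 1"
    dmin: float = Field(default=2.0, gt=0)
    b_tensor: tuple[tuple[float, float, float], ...] = ((0.0,) * 3,) * 3
    scale: float = Field(default=100.0, gt=0)
    sigma_frac: float = Field(default=0.1, gt=0)
    directional_sigma: tuple[DirectionalSigma, ...] = ()
    wilson_noise: bool = True
    seed: int = 0

    @field_validator("b_tensor")
    @classmethod
    def _symmetric(cls, v):
        b = np.asarray(v, dtype=float)
        if b.shape != (3, 3) or not np.allclose(b, b.T):
            raise ValueError("b_tensor must be a symmetric 3x3 matrix")
        return tuple(tuple(row) for row in b)

    @property
    def b(self) -> np.ndarray:
        return np.asarray(self.b_tensor, dtype=float)


def enumerate_hkl(cell: UnitCell, dmin: float) -> np.ndarray:
    """Friedel-unique Miller indices with d >= dmin, excluding (0,0,0).

    Per-axis bounds follow from the real-space metric: the largest |h|
    on the resolution ellipsoid is cell-edge length / dmin.  One
    reflection per Friedel pair is kept (h > 0, or h = 0 and k > 0, or
    h = k = 0 and l > 0), matching what a deposited file stores.
    """
    hmax = [int(np.floor(length / dmin)) for length in (cell.a, cell.b, cell.c)]
    ax = [np.arange(-m, m + 1) for m in hmax]
    grid = np.stack(np.meshgrid(*ax, indexing="ij"), axis=-1).reshape(-1, 3)
    h, k, l = grid[:, 0], grid[:, 1], grid[:, 2]
    half = (h > 0) | ((h == 0) & (k > 0)) | ((h == 0) & (k == 0) & (l > 0))
    grid = grid[half]
    svec = grid @ cell.recip_matrix.T
    d = 1.0 / np.linalg.norm(svec, axis=1)
    return grid[d >= dmin]


def gen_reflections(spec: SimulationSpec) -> ReflectionSet:
    """Simulate a complete reflection set per the acentric Wilson model."""
    hkl = enumerate_hkl(spec.cell, spec.dmin)
    sg = SpaceGroup.from_symbol(spec.sg_symbol)
    if len(sg.ops) > 1:
        from .io import canonical_hkl

        _, first = np.unique(canonical_hkl(hkl, sg), axis=0, return_index=True)
        hkl = hkl[np.sort(first)]
    if len(hkl) < 100:
        warnings.warn(f"only {len(hkl)} reflections at dmin={spec.dmin}; results will be noisy")
    svec = hkl @ spec.cell.recip_matrix.T
    smag = np.linalg.norm(svec, axis=1)
    n_hat = svec / smag[:, None]
    d = 1.0 / smag
    s_wilson = 0.5 * smag  # sin(theta)/lambda = 1/(2d)
    b_dir = np.einsum("ij,jk,ik->i", n_hat, spec.b, n_hat)
    mean_i = spec.scale * np.exp(-2.0 * s_wilson**2 * b_dir)

    if spec.wilson_noise:
        rng = np.random.default_rng(spec.seed)
        intensity = rng.exponential(mean_i)
    else:
        intensity = mean_i.copy()

    sig_i = spec.sigma_frac * mean_i
    for infl in spec.directional_sigma:
        m = infl.mask(d, n_hat)
        sig_i[m] *= infl.factor

    f = np.sqrt(intensity)
    sig_f = sig_i / (2.0 * f)
    return ReflectionSet(
        hkl=hkl,
        cell=spec.cell,
        spacegroup=sg,
        f=f,
        sig_f=sig_f,
        i=intensity,
        sig_i=sig_i,
    )


def exhaustive_contact_count(
    model: StructureModel,
    cell: UnitCell,
    sg: SpaceGroup,
    cutoff: float = 4.0,
) -> int:
    """All-images brute-force contact count (independent oracle).

    Loops over every (operation, lattice translation) image and takes the
    full distance matrix to the input atoms; counts ordered pairs within
    the cutoff, excluding zero-distance self images.  Quadratic and
    simple on purpose.
    """
    frac = cell.fractionalize(model.coords())
    anchor = np.floor(frac.mean(axis=0))
    frac = frac - anchor
    xyz = cell.orthogonalize(frac)
    shell = _translation_range(cell, cutoff)
    n = 0
    for rot, tran in sg.ops:
        base = frac @ rot.T + tran
        is_identity = np.allclose(rot, np.eye(3)) and np.allclose(np.mod(tran, 1.0), 0.0)
        for tx in range(-shell[0], shell[0] + 1):
            for ty in range(-shell[1], shell[1] + 1):
                for tz in range(-shell[2], shell[2] + 1):
                    if is_identity and tx == ty == tz == 0:
                        continue
                    img = cell.orthogonalize(base + np.array([tx, ty, tz], float))
                    dmat = cdist(xyz, img)
                    n += int(np.sum((dmat <= cutoff) & (dmat > SELF_IMAGE_TOL)))
    return n


def gen_crystal(
    sg_symbol: str,
    cell: UnitCell,
    atom_spec: list[tuple[tuple[float, float, float], str]],
    cutoff: float = 4.0,
) -> tuple[StructureModel, int]:
    """Toy crystal from fractional atom positions, plus its contact oracle.

    ``atom_spec`` is a list of ((fx, fy, fz), element) pairs with
    fractional coordinates in [0, 1).  Atoms closer than 0.5 A within the
    asymmetric unit are rejected as overlapping.
    """
    fracs = np.array([p for p, _ in atom_spec], dtype=float).reshape(-1, 3)
    if np.any(fracs < 0) or np.any(fracs >= 1):
        raise ValueError("fractional positions must lie in [0, 1)")
    xyz = cell.orthogonalize(fracs)
    if len(xyz) > 1:
        dmat = cdist(xyz, xyz)
        np.fill_diagonal(dmat, np.inf)
        if dmat.min() < 0.5:
            raise ValueError(f"overlapping atoms: minimum separation {dmat.min():.2f} A")
    model = StructureModel(
        atoms=[
            Atom(element=el, xyz=tuple(p), record_kind="polymer")
            for (_, el), p in zip(atom_spec, xyz)
        ]
    )
    sg = SpaceGroup.from_symbol(sg_symbol)
    return model, exhaustive_contact_count(model, cell, sg, cutoff=cutoff)


def _revdat_date(year: int) -> str:
    return f"01-JAN-{year % 100:02d}"


def gen_header(
    entry_id: str = "1xyz",
    year: Optional[int] = 2010,
    resolution: Optional[float] = 2.0,
    cell: Optional[UnitCell] = None,
    sg_symbol: str = "P 1",
    temperature: Optional[float] = None,
    het_ids: tuple[str, ...] = (),
    keywords: tuple[str, ...] = (),
    solvent_content: Optional[float] = None,
    z: int = 1,
) -> str:
    """Emit a fixed-column legacy-PDB header block with the given fields.

    Round-trips through :func:`anisoaudit.io.parse_pdb_header`; omitted
    arguments produce genuinely absent records.
    """
    lines = [
        f"HEADER    SYNTHETIC ENTRY                         {_revdat_date(year or 2000)}   "
        f"{entry_id.upper():<4s}"
    ]
    if year is not None:
        lines.append(f"REVDAT   1   {_revdat_date(year)} {entry_id.upper():<4s}    0")
    if resolution is not None:
        lines.append(f"REMARK   2 RESOLUTION.    {resolution:.2f} ANGSTROMS.")
    if temperature is not None:
        lines.append(f"REMARK 200  TEMPERATURE           (KELVIN) : {temperature:g}")
    if solvent_content is not None:
        lines.append(f"REMARK 280  SOLVENT CONTENT, VS   (%): {solvent_content:.2f}")
    if keywords:
        lines.append("KEYWDS    " + ", ".join(keywords))
    for j, het in enumerate(het_ids, start=1):
        lines.append(f"HETNAM     {het:<3s} SYNTHETIC COMPOUND {j}")
    if cell is not None:
        lines.append(
            f"CRYST1{cell.a:9.3f}{cell.b:9.3f}{cell.c:9.3f}"
            f"{cell.alpha:7.2f}{cell.beta:7.2f}{cell.gamma:7.2f} {sg_symbol:<11s}{z:4d}"
        )
    return "\n".join(lines) + "\n"


_REASONS = ("year", "resolution", "aniso_b", "contacts_ratio")


def gen_audit_population(
    n: int,
    violation_fractions: Optional[dict[str, float]] = None,
    seed: int = 0,
) -> tuple[list[AuditRecord], dict[str, Optional[str]]]:
    """Audit records with planted curation ground truth.

    ``violation_fractions`` maps rule name (year, resolution, aniso_b,
    contacts_ratio) to the fraction of records violating exactly that
    rule; counts are rounded so the planted totals are exact.  Everyone
    else is drawn inside the keep region.  Returns the records and a map
    from entry id to the expected drop reason (None = kept).
    """
    violation_fractions = violation_fractions or {}
    unknown = set(violation_fractions) - set(_REASONS)
    if unknown:
        raise ValueError(f"unknown curation rules: {sorted(unknown)}")
    counts = {r: int(round(violation_fractions.get(r, 0.0) * n)) for r in _REASONS}
    if sum(counts.values()) > n:
        raise ValueError("violation fractions exceed the population size")
    rng = np.random.default_rng(seed)
    roles = []
    for r in _REASONS:
        roles += [r] * counts[r]
    roles += [None] * (n - len(roles))
    rng.shuffle(roles)

    records: list[AuditRecord] = []
    truth: dict[str, Optional[str]] = {}
    for idx, role in enumerate(roles):
        eid = np.base_repr(idx, 36).lower().rjust(4, "0")
        year = int(rng.integers(2006, 2021))
        res = float(rng.uniform(1.0, 5.0))
        aniso = float(rng.uniform(0.0, 150.0))
        ratio = float(rng.uniform(0.0, 1.0))
        if role == "year":
            year = int(rng.integers(1995, 2006))
        elif role == "resolution":
            res = float(rng.uniform(5.01, 9.0))
        elif role == "aniso_b":
            aniso = float(rng.uniform(150.1, 400.0))
        elif role == "contacts_ratio":
            ratio = float(rng.uniform(1.01, 4.0))
        records.append(
            AuditRecord(
                entry_id=eid, year=year, resolution=res,
                aniso_b_amp=aniso, contacts_ratio=ratio,
            )
        )
        truth[eid] = role
    return records, truth


def synthetic_entry_header(spec: SimulationSpec, **kwargs) -> EntryHeader:
    """EntryHeader matching a simulation spec (convenience for pipelines)."""
    return EntryHeader(cell=spec.cell, sg_symbol=spec.sg_symbol, **kwargs)
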