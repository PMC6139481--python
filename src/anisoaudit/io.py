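"""Readers and writers for legacy PDB files and mmCIF reflection data.

Header metadata (REVDAT year, resolution, cell, temperature, HET codes,
keywords, solvent content) is read off the fixed-column records directly;
coordinates go through gemmi.  Structure factors are exchanged as mmCIF
``_refln`` loops, the deposition format for reflection data.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Literal, Optional

import gemmi
import numpy as np

from .geometry import SpaceGroup, UnitCell

__all__ = [
    "EntryHeader",
    "StructureModel",
    "Atom",
    "ReflectionSet",
    "parse_pdb_header",
    "parse_structure",
    "read_sf_mmcif",
    "write_sf_mmcif",
    "write_pdb",
]


class PdbParseError(ValueError):
    """Malformed fixed-column record in a coordinate file."""


class SfFormatError(ValueError):
    """Reflection file lacks a usable _refln loop or violates basic sanity."""


_MONTHS = {
    "JAN": 1, "FEB": 2, "MAR": 3, "APR": 4, "MAY": 5, "JUN": 6,
    "JUL": 7, "AUG": 8, "SEP": 9, "OCT": 10, "NOV": 11, "DEC": 12,
}
_MONTH_NAMES = {v: k for k, v in _MONTHS.items()}


@dataclass
class EntryHeader:
    """Metadata lifted from a legacy-PDB header.

    Fields absent from the file stay ``None`` (or empty lists); absence is
    meaningful downstream and is never silently defaulted.
    """

    entry_id: Optional[str] = None
    year: Optional[int] = None
    resolution: Optional[float] = None
    cell: Optional[UnitCell] = None
    sg_symbol: Optional[str] = None
    temperature: Optional[float] = None
    het_ids: list[str] = field(default_factory=list)
    keywords: list[str] = field(default_factory=list)
    solvent_content: Optional[float] = None

    def __post_init__(self) -> None:
        if self.year is not None and not (1000 <= int(self.year) <= 9999):
            raise ValueError(f"year must be a 4-digit integer, got {self.year}")
        if self.resolution is not None and self.resolution <= 0:
            raise ValueError(f"resolution must be positive, got {self.resolution}")
        if self.solvent_content is not None and not 0 <= self.solvent_content <= 100:
            raise ValueError(f"solvent content must be a percentage, got {self.solvent_content}")


RecordKind = Literal["polymer", "hetero", "water"]


@dataclass(frozen=True)
class Atom:
    element: str
    xyz: tuple[float, float, float]
    occupancy: float = 1.0
    record_kind: RecordKind = "polymer"
    chain_id: str = "A"
    name: str = ""


@dataclass
class StructureModel:
    """Atoms of one deposited model (first model only, first altloc only)."""

    atoms: list[Atom]

    @property
    def n_atoms_total(self) -> int:
        """All atoms including heteroatoms and waters."""
        return len(self.atoms)

    def coords(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms], dtype=float).reshape(-1, 3)

    def mask(self, kind: RecordKind) -> np.ndarray:
        return np.array([a.record_kind == kind for a in self.atoms], dtype=bool)


def _revdat_year(line: str) -> Optional[int]:
    # REVDAT date field, cols 14-22: DD-MMM-YY
    m = re.search(r"(\d{2})-([A-Z]{3})-(\d{2})", line[13:22])
    if not m:
        return None
    yy = int(m.group(3))
    return 1900 + yy if yy >= 50 else 2000 + yy


def _parse_cryst1(line: str) -> tuple[UnitCell, str]:
    try:
        cell = UnitCell(
            a=float(line[6:15]), b=float(line[15:24]), c=float(line[24:33]),
            alpha=float(line[33:40]), beta=float(line[40:47]), gamma=float(line[47:54]),
        )
    except (ValueError, IndexError) as exc:
        raise PdbParseError(f"malformed CRYST1 record: {line.rstrip()!r}") from exc
    return cell, line[55:66].strip()


def parse_pdb_header(text: str) -> EntryHeader:
    """Extract audit metadata from a legacy-PDB header.

    Reads the most recent REVDAT year, REMARK 2 resolution, CRYST1 cell and
    space group, REMARK 200 collection temperature, HETNAM compound codes,
    KEYWDS terms and the REMARK 280 solvent content.  Records that are
    missing leave the corresponding field absent.
    """
    hdr = EntryHeader()
    keyword_text: list[str] = []
    het_seen: set[str] = set()
    for line in text.splitlines():
        tag = line[:6]
        if tag == "HEADER":
            code = line[62:66].strip()
            if code:
                hdr.entry_id = code.lower()
        elif tag == "REVDAT":
            y = _revdat_year(line)
            if y is not None:
                hdr.year = y if hdr.year is None else max(hdr.year, y)
        elif tag == "CRYST1":
            hdr.cell, hdr.sg_symbol = _parse_cryst1(line)
        elif tag == "REMARK":
            rest = line[6:]
            m = re.match(r"\s+2 RESOLUTION\.\s+([0-9]*\.?[0-9]+)\s+ANGSTROM", rest)
            if m:
                hdr.resolution = float(m.group(1))
                continue
            m = re.match(r"\s+200\s+TEMPERATURE\s+\(KELVIN\)\s*:\s*([0-9]*\.?[0-9]+)", rest)
            if m:
                hdr.temperature = float(m.group(1))
                continue
            m = re.match(r"\s+280\s+SOLVENT CONTENT, VS\s+\(%\)\s*:\s*([0-9]*\.?[0-9]+)", rest)
            if m:
                hdr.solvent_content = float(m.group(1))
        elif tag == "HETNAM":
            het = line[11:14].strip()
            if het and het not in het_seen:
                het_seen.add(het)
                hdr.het_ids.append(het)
        elif tag == "KEYWDS":
            keyword_text.append(line[10:].rstrip())
    if keyword_text:
        joined = " ".join(t.strip() for t in keyword_text)
        hdr.keywords = [k.strip() for k in joined.split(",") if k.strip()]
    return hdr


def parse_structure(text: str) -> StructureModel:
    """Read ATOM/HETATM records into a :class:`StructureModel`.

    First model only; for alternate conformations only the first-listed
    altloc of each atom is kept.  Waters (HOH) are flagged ``water``,
    other HETATM residues ``hetero``.
    """
    st = gemmi.read_pdb_string(text)
    if len(st) == 0:
        raise PdbParseError("no coordinate model found")
    st.remove_alternative_conformations()
    atoms: list[Atom] = []
    for chain in st[0]:
        for res in chain:
            if res.is_water():
                kind: RecordKind = "water"
            elif res.het_flag == "H":
                kind = "hetero"
            else:
                kind = "polymer"
            for at in res:
                atoms.append(
                    Atom(
                        element=at.element.name,
                        xyz=(at.pos.x, at.pos.y, at.pos.z),
                        occupancy=at.occ,
                        record_kind=kind,
                        chain_id=chain.name,
                        name=at.name,
                    )
                )
    if not atoms:
        raise PdbParseError("structure contains no atoms")
    return StructureModel(atoms=atoms)


@dataclass
class ReflectionSet:
    """Indexed reflections with amplitude and/or intensity data.

    Per-reflection missing values are stored as NaN; a whole data path
    (amplitudes or intensities) that the file lacks is ``None``.  Stored
    hkl are as read — symmetry reduction is used only to detect duplicate
    observations.
    """

    hkl: np.ndarray
    cell: UnitCell
    spacegroup: SpaceGroup
    f: Optional[np.ndarray] = None
    sig_f: Optional[np.ndarray] = None
    i: Optional[np.ndarray] = None
    sig_i: Optional[np.ndarray] = None
    qc: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.hkl = np.asarray(self.hkl, dtype=int).reshape(-1, 3)
        n = len(self.hkl)
        for name in ("f", "sig_f", "i", "sig_i"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != (n,):
                    raise ValueError(f"{name} has shape {v.shape}, expected ({n},)")
                setattr(self, name, v)
        if (self.f is None) != (self.sig_f is None) or (self.i is None) != (self.sig_i is None):
            raise ValueError("amplitudes and intensities each require their sigma column")
        if self.f is None and self.i is None:
            raise ValueError("need amplitude or intensity data")
        for sig in (self.sig_f, self.sig_i):
            if sig is not None and np.any(sig[np.isfinite(sig)] < 0):
                raise ValueError("negative sigma values")
        if np.any(np.all(self.hkl == 0, axis=1)):
            raise ValueError("(0,0,0) is not a reflection")
        canon = canonical_hkl(self.hkl, self.spacegroup)
        if len(np.unique(canon, axis=0)) != n:
            raise ValueError("duplicate reflections after symmetry reduction")
        self._d: Optional[np.ndarray] = None

    def __len__(self) -> int:
        return len(self.hkl)

    @property
    def d(self) -> np.ndarray:
        """Resolution of each reflection in angstrom."""
        if self._d is None:
            svec = self.hkl @ self.cell.recip_matrix.T
            self._d = 1.0 / np.linalg.norm(svec, axis=1)
        return self._d

    def s_vectors(self) -> np.ndarray:
        return self.hkl @ self.cell.recip_matrix.T

    def unit_directions(self) -> np.ndarray:
        s = self.s_vectors()
        return s / np.linalg.norm(s, axis=1, keepdims=True)

    def intensities(self, source: str) -> np.ndarray:
        """Working intensities: measured I, or F squared for amplitude data."""
        if source == "intensities":
            if self.i is None:
                raise ValueError("no intensity data present")
            return self.i
        if source == "amplitudes":
            if self.f is None:
                raise ValueError("no amplitude data present")
            return self.f**2
        raise ValueError(f"source must be 'amplitudes' or 'intensities', got {source!r}")

    def has_source(self, source: str) -> bool:
        return (self.f if source == "amplitudes" else self.i) is not None

    def amplitudes_for_limits(self) -> tuple[np.ndarray, np.ndarray]:
        """F and sigma-F for signal-to-noise work.

        When only intensities exist, F = sqrt(max(I,0)) with
        sigF = sigI/(2F); non-positive intensities are masked out (a full
        Bayesian intensity-to-amplitude conversion is out of scope).
        """
        if self.f is not None:
            return self.f, self.sig_f
        assert self.i is not None and self.sig_i is not None
        ok = self.i > 0
        f = np.where(ok, np.sqrt(np.clip(self.i, 0, None)), np.nan)
        sig = np.where(ok, self.sig_i / np.where(ok, 2 * f, 1.0), np.nan)
        return f, sig


def canonical_hkl(hkl: np.ndarray, sg: SpaceGroup) -> np.ndarray:
    """Map each hkl to a canonical symmetry-equivalent representative.

    Equivalents under the point group plus Friedel inversion are generated
    and the lexicographically largest triple is chosen; used for duplicate
    detection only.
    """
    hkl = np.asarray(hkl, dtype=float)
    variants = []
    for rot in sg.point_group_rotations():
        eq = hkl @ rot  # row-vector action on Miller indices
        variants.append(eq)
        variants.append(-eq)
    stack = np.stack(variants, axis=1)  # (n, n_ops, 3)
    # lexicographic max via composite key
    key = stack[..., 0] * 4_000_000 + stack[..., 1] * 2_000 + stack[..., 2]
    best = np.argmax(key, axis=1)
    out = stack[np.arange(len(hkl)), best]
    return np.round(out).astype(int)


_F_TAGS = [("F_meas_au", "F_meas_sigma_au"), ("F_meas", "F_meas_sigma")]
_I_TAGS = [("intensity_meas", "intensity_sigma")]


def _column_floats(block: gemmi.cif.Block, tag: str, n: int) -> Optional[np.ndarray]:
    col = block.find_loop(f"_refln.{tag}")
    vals = list(col)
    if len(vals) != n:
        return None
    out = np.full(n, np.nan)
    for k, v in enumerate(vals):
        if v not in ("?", "."):
            try:
                out[k] = float(v)
            except ValueError:
                pass  # non-numeric treated as missing
    return out


def read_sf_mmcif(
    text: str,
    cell: Optional[UnitCell] = None,
    spacegroup: Optional[SpaceGroup] = None,
) -> ReflectionSet:
    """Parse an mmCIF structure-factor file into a :class:`ReflectionSet`.

    Cell and symmetry are taken from the file's ``_cell``/``_symmetry``
    items when present, else from the ``cell``/``spacegroup`` arguments.
    Rows whose Miller indices are unreadable, whose values are missing on
    every available data path, or which duplicate an already-seen
    symmetry-equivalent reflection are dropped and counted in ``qc``.
    """
    doc = gemmi.cif.read_string(text)
    block = None
    for b in doc:
        if b.find_loop("_refln.index_h"):
            block = b
            break
    if block is None:
        raise SfFormatError("no _refln loop with Miller indices found")

    h = _column_floats(block, "index_h", len(block.find_loop("_refln.index_h")))
    n = len(h)
    k = _column_floats(block, "index_k", n)
    l = _column_floats(block, "index_l", n)
    if k is None or l is None:
        raise SfFormatError("incomplete Miller-index columns")

    f = sig_f = i = sig_i = None
    for ftag, stag in _F_TAGS:
        f = _column_floats(block, ftag, n)
        if f is not None:
            sig_f = _column_floats(block, stag, n)
            break
    for itag, stag in _I_TAGS:
        i = _column_floats(block, itag, n)
        if i is not None:
            sig_i = _column_floats(block, stag, n)
            break
    if f is None and i is None:
        raise SfFormatError("no amplitude or intensity columns in _refln loop")
    if f is not None and sig_f is None:
        sig_f = np.full(n, np.nan)
    if i is not None and sig_i is None:
        sig_i = np.full(n, np.nan)
    for name, sig in (("sigma(F)", sig_f), ("sigma(I)", sig_i)):
        if sig is not None and np.any(sig[np.isfinite(sig)] < 0):
            raise SfFormatError(f"negative {name} values")

    cv = block.find_value("_cell.length_a")
    if cv is not None:
        cell = UnitCell(
            a=float(block.find_value("_cell.length_a")),
            b=float(block.find_value("_cell.length_b")),
            c=float(block.find_value("_cell.length_c")),
            alpha=float(block.find_value("_cell.angle_alpha")),
            beta=float(block.find_value("_cell.angle_beta")),
            gamma=float(block.find_value("_cell.angle_gamma")),
        )
    if cell is None:
        raise SfFormatError("no unit cell in file and none supplied")
    sym = block.find_value("_symmetry.space_group_name_H-M") or block.find_value(
        "_space_group.name_H-M_alt"
    )
    if sym is not None:
        spacegroup = SpaceGroup.from_symbol(sym.strip("'\""))
    if spacegroup is None:
        spacegroup = SpaceGroup.from_symbol("P 1")

    qc = {"n_rows": n, "n_missing_f": 0, "n_missing_i": 0, "n_dropped": 0, "n_duplicates": 0}
    idx_ok = np.isfinite(h) & np.isfinite(k) & np.isfinite(l)
    hkl = np.zeros((n, 3), dtype=int)
    hkl[idx_ok] = np.round(np.column_stack([h[idx_ok], k[idx_ok], l[idx_ok]])).astype(int)
    nonzero = ~np.all(hkl == 0, axis=1)

    has_f = np.isfinite(f) if f is not None else np.zeros(n, bool)
    has_i = np.isfinite(i) if i is not None else np.zeros(n, bool)
    if f is not None:
        qc["n_missing_f"] = int(n - has_f.sum())
    if i is not None:
        qc["n_missing_i"] = int(n - has_i.sum())
    keep = idx_ok & nonzero & (has_f | has_i)
    qc["n_dropped"] = int(n - keep.sum())

    hkl = hkl[keep]
    sg_final = spacegroup
    canon = canonical_hkl(hkl, sg_final)
    _, first = np.unique(canon, axis=0, return_index=True)
    uniq = np.zeros(len(hkl), dtype=bool)
    uniq[first] = True
    qc["n_duplicates"] = int(len(hkl) - uniq.sum())

    def pick(arr):
        return arr[keep][uniq] if arr is not None else None

    return ReflectionSet(
        hkl=hkl[uniq],
        cell=cell,
        spacegroup=sg_final,
        f=pick(f),
        sig_f=pick(sig_f),
        i=pick(i),
        sig_i=pick(sig_i),
        qc=qc,
    )


def _fmt(x: float) -> str:
    return "?" if not np.isfinite(x) else repr(float(x))


def write_sf_mmcif(refl: ReflectionSet, block_name: str = "rsynthsf") -> str:
    """Serialize a ReflectionSet as an mmCIF _refln loop (returns text)."""
    doc = gemmi.cif.Document()
    block = doc.add_new_block(block_name)
    c = refl.cell
    for tag, val in [
        ("_cell.length_a", c.a), ("_cell.length_b", c.b), ("_cell.length_c", c.c),
        ("_cell.angle_alpha", c.alpha), ("_cell.angle_beta", c.beta),
        ("_cell.angle_gamma", c.gamma),
    ]:
        block.set_pair(tag, repr(float(val)))
    block.set_pair("_symmetry.space_group_name_H-M", gemmi.cif.quote(refl.spacegroup.hm_symbol))
    tags = ["index_h", "index_k", "index_l"]
    cols: list[np.ndarray] = []
    if refl.f is not None:
        tags += ["F_meas_au", "F_meas_sigma_au"]
        cols += [refl.f, refl.sig_f]
    if refl.i is not None:
        tags += ["intensity_meas", "intensity_sigma"]
        cols += [refl.i, refl.sig_i]
    loop = block.init_loop("_refln.", tags)
    for row_idx in range(len(refl)):
        row = [str(int(v)) for v in refl.hkl[row_idx]]
        row += [_fmt(col[row_idx]) for col in cols]
        loop.add_row(row)
    return doc.as_string()


def write_pdb(
    model: StructureModel,
    cell: UnitCell,
    sg_symbol: str = "P 1",
    header_text: str = "",
    z: int = 1,
) -> str:
    """Serialize a StructureModel (plus optional header block) as legacy PDB."""
    lines = [ln for ln in header_text.splitlines() if ln.strip()]
    if not any(ln.startswith("CRYST1") for ln in lines):
        lines.append(
            f"CRYST1{cell.a:9.3f}{cell.b:9.3f}{cell.c:9.3f}"
            f"{cell.alpha:7.2f}{cell.beta:7.2f}{cell.gamma:7.2f} {sg_symbol:<11s}{z:4d}"
        )
    res_names = {"polymer": "ALA", "hetero": "LIG", "water": "HOH"}
    for idx, at in enumerate(model.atoms, start=1):
        tag = "ATOM  " if at.record_kind == "polymer" else "HETATM"
        name = at.name or at.element
        x, y, zc = at.xyz
        lines.append(
            f"{tag}{idx:5d} {name:^4s} {res_names[at.record_kind]:<3s} "
            f"{at.chain_id[:1]}{idx % 10000:4d}    {x:8.3f}{y:8.3f}{zc:8.3f}"
            f"{at.occupancy:6.2f}{0.0:6.2f}          {at.element:>2s}"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"
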