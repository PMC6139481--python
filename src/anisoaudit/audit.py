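"""Per-entry audit records, curation filters, subset taxonomy, table output.

One :class:`AuditRecord` holds every metric computed for a deposited
entry.  Curation keeps well-behaved recent structures: deposited 2006 or
later, resolution <= 5 A, amplitude-based delta-B <= 150 A^2 and crystal
contacts ratio <= 1.  Entries are classified soluble vs membrane from a
user-supplied annotation table, with membrane entries further labelled by
fold, crystallization mode, function and membrane topology.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .geometry import UnitCell

__all__ = [
    "AuditRecord",
    "MembraneAnnotation",
    "CurationBounds",
    "build_record",
    "curate",
    "classify_subsets",
    "write_table",
    "read_table",
    "load_annotations",
    "DEFAULT_LCP_KEYWORDS",
]

FOLDS = {"alpha_helical", "beta_barrel", "monotopic", "none"}
CRYSTALLIZATIONS = {"detergent", "lcp", "bicelle", "unknown"}
FUNCTIONS = {"atpase", "electron_transfer", "channel", "receptor", "transporter", "other"}
TOPOLOGIES = {"embedded", "extramembranous_domains", "unknown"}

#: Keyword / heteroatom-code hints that an entry was crystallized in
#: lipidic cubic phase, used when the annotation table does not say.
#: OLC/OLB/OLA are monoolein-class lipid het codes; MPG is monopalmitolein.
DEFAULT_LCP_KEYWORDS = (
    "LIPIDIC CUBIC PHASE",
    "LCP",
    "IN MESO",
    "CUBIC PHASE",
    "OLC",
    "OLB",
    "OLA",
    "MPG",
)


@dataclass
class AuditRecord:
    """One flat row of the audit table; absent metrics stay ``None``."""

    entry_id: str
    year: Optional[int] = None
    resolution: Optional[float] = None
    sg_symbol: Optional[str] = None
    cell: Optional[UnitCell] = None
    temperature: Optional[float] = None
    het_ids: list[str] = field(default_factory=list)
    keywords: list[str] = field(default_factory=list)
    solvent_pct: Optional[float] = None
    matthews: Optional[float] = None
    n_contacts: Optional[int] = None
    n_atoms_total: Optional[int] = None
    contacts_ratio: Optional[float] = None
    aniso_b_amp: Optional[float] = None
    aniso_b_int: Optional[float] = None
    wilson_b_amp: Optional[float] = None
    wilson_b_int: Optional[float] = None
    ratio_amp: Optional[float] = None
    ratio_int: Optional[float] = None
    axis_limits: Optional[tuple[float, float, float]] = None
    delta_res: Optional[float] = None
    pct_rejected: Optional[float] = None
    n_reflections_total: Optional[int] = None
    n_rejected: Optional[int] = None
    ss_percent: Optional[dict[str, float]] = None
    subset_labels: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class MembraneAnnotation:
    """Membrane-protein classification for one entry.

    Mirrors the mpstruc-style taxonomy: fold (alpha-helical or beta-barrel
    transmembrane, or monotopic), crystallization mode (detergent, lipidic
    cubic phase, bicelle), broad function, and whether crystal packing is
    mediated by the membrane-embedded surface or by extramembranous
    domains.
    """

    entry_id: str
    is_membrane: bool = False
    fold: str = "none"
    crystallization: str = "unknown"
    function: str = "other"
    topology: str = "unknown"

    def __post_init__(self) -> None:
        for val, vocab, name in [
            (self.fold, FOLDS, "fold"),
            (self.crystallization, CRYSTALLIZATIONS, "crystallization"),
            (self.function, FUNCTIONS, "function"),
            (self.topology, TOPOLOGIES, "topology"),
        ]:
            if val not in vocab:
                raise ValueError(f"{name} label {val!r} not in {sorted(vocab)}")
        if not self.is_membrane and self.fold != "none":
            raise ValueError(
                f"{self.entry_id}: contradictory annotation, soluble with membrane fold {self.fold!r}"
            )


@dataclass(frozen=True)
class CurationBounds:
    """Keep thresholds; boundary values are kept except the year cut."""

    min_year: int = 2006  # "after 2005"
    max_resolution: float = 5.0
    max_aniso_b: float = 150.0
    max_contacts_ratio: float = 1.0


def build_record(header, aniso, packing, ss_percent=None) -> AuditRecord:
    """Join header, anisotropy and packing results into one AuditRecord.

    Solvent content from the deposited header takes precedence; the
    Matthews-based value fills in only when the header lacks it.
    """
    solvent = header.solvent_content
    if solvent is None and packing is not None:
        solvent = packing.solvent_pct
    rec = AuditRecord(
        entry_id=header.entry_id or "xxxx",
        year=header.year,
        resolution=header.resolution,
        sg_symbol=header.sg_symbol,
        cell=header.cell,
        temperature=header.temperature,
        het_ids=list(header.het_ids),
        keywords=list(header.keywords),
        solvent_pct=solvent,
        ss_percent=dict(ss_percent) if ss_percent else None,
    )
    if packing is not None:
        rec.matthews = packing.matthews
        rec.n_contacts = packing.n_contacts
        rec.n_atoms_total = packing.n_atoms_total
        rec.contacts_ratio = packing.contacts_ratio
    if aniso is not None:
        rec.aniso_b_amp = aniso.aniso_b_amp
        rec.aniso_b_int = aniso.aniso_b_int
        rec.wilson_b_amp = aniso.wilson_b_amp
        rec.wilson_b_int = aniso.wilson_b_int
        rec.ratio_amp = aniso.ratio_amp
        rec.ratio_int = aniso.ratio_int
        rec.axis_limits = aniso.axis_limits
        rec.delta_res = aniso.delta_res
        rec.pct_rejected = aniso.pct_rejected
        rec.n_reflections_total = aniso.n_reflections_total
        rec.n_rejected = aniso.n_rejected
    return rec


def curation_reason(rec: AuditRecord, bounds: CurationBounds = CurationBounds()) -> Optional[str]:
    """First failing curation rule for a record, or None if it is kept.

    Rules are checked in a fixed order: year, resolution, amplitude
    delta-B, contacts ratio.  A metric that was never computed does not
    fail its rule — the filters act on computed values, not missingness —
    but year and resolution are mandatory.
    """
    if rec.year is None or rec.year < bounds.min_year:
        return "year"
    if rec.resolution is None or rec.resolution > bounds.max_resolution:
        return "resolution"
    if rec.aniso_b_amp is not None and rec.aniso_b_amp > bounds.max_aniso_b:
        return "aniso_b"
    if rec.contacts_ratio is not None and rec.contacts_ratio > bounds.max_contacts_ratio:
        return "contacts_ratio"
    return None


def curate(
    records: list[AuditRecord], bounds: CurationBounds = CurationBounds()
) -> tuple[list[AuditRecord], list[tuple[AuditRecord, str]]]:
    """Partition records into (kept, dropped-with-reason)."""
    kept: list[AuditRecord] = []
    dropped: list[tuple[AuditRecord, str]] = []
    for rec in records:
        reason = curation_reason(rec, bounds)
        if reason is None:
            kept.append(rec)
        else:
            dropped.append((rec, reason))
    return kept, dropped


def classify_subsets(
    record: AuditRecord,
    annot: Optional[MembraneAnnotation],
    lcp_keywords=DEFAULT_LCP_KEYWORDS,
) -> list[str]:
    """Subset labels for one entry.

    Entries without a membrane annotation are soluble.  Membrane entries
    get [membrane] plus every applicable sub-label: fold, crystallization
    mode, function and topology.  When the crystallization mode is
    unknown, lipidic-cubic-phase growth is inferred from entry keywords
    and lipid heteroatom codes.
    """
    if annot is None or not annot.is_membrane:
        return ["soluble"]
    labels = ["membrane"]
    if annot.fold != "none":
        labels.append(annot.fold)
    cryst = annot.crystallization
    if cryst == "unknown" and _looks_lcp(record, lcp_keywords):
        cryst = "lcp"
    if cryst != "unknown":
        labels.append(cryst)
    if annot.function != "other":
        labels.append(annot.function)
    if annot.topology != "unknown":
        labels.append(annot.topology)
    return labels


def _looks_lcp(record: AuditRecord, lcp_keywords) -> bool:
    haystack = {k.upper() for k in record.keywords} | {h.upper() for h in record.het_ids}
    joined = " , ".join(sorted(haystack))
    return any(kw.upper() in haystack or kw.upper() in joined for kw in lcp_keywords)


# --- flat-table serialization -------------------------------------------------

_LIST_SEP = ";"
_CELL_COLS = ["cell_a", "cell_b", "cell_c", "cell_alpha", "cell_beta", "cell_gamma"]
_SS_KEYS = ["helix", "strand", "turn", "coil"]

TABLE_COLUMNS = (
    ["entry_id", "year", "resolution", "sg_symbol"]
    + _CELL_COLS
    + [
        "temperature", "het_ids", "keywords", "solvent_pct", "matthews",
        "n_contacts", "n_atoms_total", "contacts_ratio",
        "aniso_b_amp", "aniso_b_int", "wilson_b_amp", "wilson_b_int",
        "ratio_amp", "ratio_int",
        "axis_limit_1", "axis_limit_2", "axis_limit_3", "delta_res",
        "pct_rejected", "n_reflections_total", "n_rejected",
    ]
    + [f"ss_{k}" for k in _SS_KEYS]
    + ["subset_labels"]
)


def _record_to_row(rec: AuditRecord) -> dict:
    row: dict = {c: None for c in TABLE_COLUMNS}
    for name in (
        "entry_id", "year", "resolution", "sg_symbol", "temperature", "solvent_pct",
        "matthews", "n_contacts", "n_atoms_total", "contacts_ratio",
        "aniso_b_amp", "aniso_b_int", "wilson_b_amp", "wilson_b_int",
        "ratio_amp", "ratio_int", "delta_res", "pct_rejected",
        "n_reflections_total", "n_rejected",
    ):
        row[name] = getattr(rec, name)
    if rec.cell is not None:
        c = rec.cell
        for col, v in zip(_CELL_COLS, (c.a, c.b, c.c, c.alpha, c.beta, c.gamma)):
            row[col] = v
    row["het_ids"] = _LIST_SEP.join(rec.het_ids) if rec.het_ids else None
    row["keywords"] = _LIST_SEP.join(rec.keywords) if rec.keywords else None
    if rec.axis_limits is not None:
        for col, v in zip(("axis_limit_1", "axis_limit_2", "axis_limit_3"), rec.axis_limits):
            row[col] = v
    if rec.ss_percent:
        for k in _SS_KEYS:
            if k in rec.ss_percent:
                row[f"ss_{k}"] = rec.ss_percent[k]
    row["subset_labels"] = _LIST_SEP.join(rec.subset_labels) if rec.subset_labels else None
    return row


def _opt(val, cast):
    if val is None or (isinstance(val, float) and np.isnan(val)):
        return None
    return cast(val)


def _row_to_record(row: pd.Series) -> AuditRecord:
    cell = None
    if _opt(row["cell_a"], float) is not None:
        cell = UnitCell(*(float(row[c]) for c in _CELL_COLS))
    limits = tuple(_opt(row[f"axis_limit_{j}"], float) for j in (1, 2, 3))
    ss = {k: float(row[f"ss_{k}"]) for k in _SS_KEYS if _opt(row.get(f"ss_{k}"), float) is not None}
    return AuditRecord(
        entry_id=str(row["entry_id"]),
        year=_opt(row["year"], int),
        resolution=_opt(row["resolution"], float),
        sg_symbol=_opt(row["sg_symbol"], str),
        cell=cell,
        temperature=_opt(row["temperature"], float),
        het_ids=str(row["het_ids"]).split(_LIST_SEP) if _opt(row["het_ids"], str) else [],
        keywords=str(row["keywords"]).split(_LIST_SEP) if _opt(row["keywords"], str) else [],
        solvent_pct=_opt(row["solvent_pct"], float),
        matthews=_opt(row["matthews"], float),
        n_contacts=_opt(row["n_contacts"], int),
        n_atoms_total=_opt(row["n_atoms_total"], int),
        contacts_ratio=_opt(row["contacts_ratio"], float),
        aniso_b_amp=_opt(row["aniso_b_amp"], float),
        aniso_b_int=_opt(row["aniso_b_int"], float),
        wilson_b_amp=_opt(row["wilson_b_amp"], float),
        wilson_b_int=_opt(row["wilson_b_int"], float),
        ratio_amp=_opt(row["ratio_amp"], float),
        ratio_int=_opt(row["ratio_int"], float),
        axis_limits=limits if all(v is not None for v in limits) else None,
        delta_res=_opt(row["delta_res"], float),
        pct_rejected=_opt(row["pct_rejected"], float),
        n_reflections_total=_opt(row["n_reflections_total"], int),
        n_rejected=_opt(row["n_rejected"], int),
        ss_percent=ss or None,
        subset_labels=str(row["subset_labels"]).split(_LIST_SEP)
        if _opt(row["subset_labels"], str)
        else [],
    )


def to_dataframe(records: list[AuditRecord]) -> pd.DataFrame:
    rows = [_record_to_row(r) for r in sorted(records, key=lambda r: r.entry_id)]
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def write_table(records: list[AuditRecord], path) -> None:
    """Write the audit table as CSV, sorted by entry id.

    Absent values become empty fields (never 0); list-valued columns are
    joined with ';'.
    """
    if not records:
        raise ValueError("no records to write")
    df = to_dataframe(records)
    # repr round-trips float64 exactly; pandas' default formatting does not
    df = df.map(lambda v: repr(float(v)) if isinstance(v, float) else v)
    df.to_csv(path, index=False)


def read_table(path) -> list[AuditRecord]:
    """Read an audit CSV back into records (inverse of :func:`write_table`)."""
    df = pd.read_csv(path, dtype={"entry_id": str, "sg_symbol": str},
                     keep_default_na=True, float_precision="round_trip")
    df = df.replace({np.nan: None})
    return [_row_to_record(row) for _, row in df.iterrows()]


def load_annotations(path) -> dict[str, MembraneAnnotation]:
    """Load a membrane-annotation table (tab-separated with a header).

    Required column: entry_id; optional columns: is_membrane (0/1 or
    true/false), fold, crystallization, function, topology.  Returns a
    mapping from entry id to annotation.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "entry_id" not in df.columns:
        raise ValueError(f"annotation table {path} lacks an entry_id column")
    out: dict[str, MembraneAnnotation] = {}
    for _, row in df.iterrows():
        eid = row["entry_id"].strip().lower()
        is_mem = str(row.get("is_membrane", "0")).strip().lower() in ("1", "true", "yes")
        out[eid] = MembraneAnnotation(
            entry_id=eid,
            is_membrane=is_mem,
            fold=(row.get("fold") or "none").strip().lower() or "none",
            crystallization=(row.get("crystallization") or "unknown").strip().lower() or "unknown",
            function=(row.get("function") or "other").strip().lower() or "other",
            topology=(row.get("topology") or "unknown").strip().lower() or "unknown",
        )
    return out
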