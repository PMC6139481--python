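"""Per-entry pipeline: parse -> anisotropy -> packing -> audit record.

Each stage is fault-isolated: a malformed or missing input degrades the
record to absent fields with a logged reason instead of aborting, so a
batch over many entries always yields one row per entry.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional

from . import aniso as aniso_mod
from . import audit as audit_mod
from . import io as io_mod
from . import packing as packing_mod
from .config import RunConfig
from .geometry import SpaceGroup

__all__ = ["run_entry", "run_batch"]

log = logging.getLogger("anisoaudit")


def _read_text(path) -> Optional[str]:
    try:
        return Path(path).read_text()
    except OSError:
        return None


def run_entry(
    model_path,
    sf_path,
    config: RunConfig = RunConfig(),
    annotations: Optional[dict[str, audit_mod.MembraneAnnotation]] = None,
) -> audit_mod.AuditRecord:
    """Compute one audit record from a coordinate file and an SF file."""
    pdb_text = _read_text(model_path)
    sf_text = _read_text(sf_path)
    if pdb_text is None and sf_text is None:
        raise OSError(f"neither {model_path} nor {sf_path} is readable")

    header = io_mod.EntryHeader()
    model = None
    if pdb_text is not None:
        header = io_mod.parse_pdb_header(pdb_text)
        try:
            model = io_mod.parse_structure(pdb_text)
        except io_mod.PdbParseError as exc:
            log.warning("%s: structure unusable: %s", header.entry_id, exc)

    aniso_res = None
    if sf_text is not None:
        try:
            sg = SpaceGroup.from_symbol(header.sg_symbol) if header.sg_symbol else None
            refl = io_mod.read_sf_mmcif(sf_text, cell=header.cell, spacegroup=sg)
            aniso_res = aniso_mod.analyze_anisotropy(
                refl,
                n_shells=config.n_shells,
                threshold=config.fsigf_threshold,
                cone_deg=config.cone_deg,
                n_bins=config.n_limit_bins,
            )
        except (io_mod.SfFormatError, aniso_mod.AnisoFitError, ValueError) as exc:
            log.warning("%s: anisotropy stage skipped: %s", header.entry_id, exc)

    packing_res = None
    if model is not None and header.cell is not None and header.sg_symbol:
        try:
            sg = SpaceGroup.from_symbol(header.sg_symbol)
            packing_res = packing_mod.analyze_packing(
                model, header.cell, sg, cutoff=config.contact_cutoff
            )
        except ValueError as exc:
            log.warning("%s: packing stage skipped: %s", header.entry_id, exc)

    record = audit_mod.build_record(header, aniso_res, packing_res)
    annot = (annotations or {}).get(record.entry_id)
    record.subset_labels = audit_mod.classify_subsets(
        record, annot, lcp_keywords=config.lcp_keywords
    )
    return record


def run_batch(
    manifest: list[tuple],
    config: RunConfig = RunConfig(),
    annotations: Optional[dict[str, audit_mod.MembraneAnnotation]] = None,
) -> list[audit_mod.AuditRecord]:
    """Audit every (model, sf) pair in the manifest; rows sorted by entry id."""
    if not manifest:
        raise ValueError("empty manifest")
    records = []
    for model_path, sf_path in manifest:
        try:
            records.append(run_entry(model_path, sf_path, config, annotations))
        except OSError as exc:
            log.error("entry skipped entirely: %s", exc)
    return sorted(records, key=lambda r: r.entry_id)
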