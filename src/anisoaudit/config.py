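"""Run configuration: every threshold of the audit pipeline in one place."""

from __future__ import annotations

import tomllib
from pathlib import Path

from pydantic import BaseModel, Field

from .audit import DEFAULT_LCP_KEYWORDS, CurationBounds

__all__ = ["RunConfig"]


class RunConfig(BaseModel):
    """Pipeline thresholds.

    Defaults are the audit's standard operating point: 4.0 A contact
    cutoff, F/sigF = 3.0 directional limit threshold, 20 resolution
    shells, 20 degree cones, and curation bounds of year >= 2006,
    resolution <= 5 A, amplitude delta-B <= 150 A^2, contacts ratio <= 1.
    """

    contact_cutoff: float = Field(default=4.0, gt=0)
    fsigf_threshold: float = Field(default=3.0, gt=0)
    n_shells: int = Field(default=20, ge=3)
    cone_deg: float = Field(default=20.0, gt=0)
    n_limit_bins: int = Field(default=10, ge=2)
    wilson_d_max: float = Field(default=4.5, gt=0)
    min_year: int = 2006
    max_resolution: float = Field(default=5.0, gt=0)
    max_aniso_b: float = Field(default=150.0, gt=0)
    max_contacts_ratio: float = Field(default=1.0, gt=0)
    lcp_keywords: tuple[str, ...] = DEFAULT_LCP_KEYWORDS

    @property
    def bounds(self) -> CurationBounds:
        return CurationBounds(
            min_year=self.min_year,
            max_resolution=self.max_resolution,
            max_aniso_b=self.max_aniso_b,
            max_contacts_ratio=self.max_contacts_ratio,
        )

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        with open(path, "rb") as fh:
            return cls(**tomllib.load(fh))
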