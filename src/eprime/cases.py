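"""Patient-plus-scanner case descriptions shared by the estimator and cohort tools."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path


@dataclass
class ScannerSpec:
    """Acquisition and reconstruction attributes of the imaging condition.

    ``ttf_f50`` / ``nps_peak`` override the per-material defaults of the
    engine configuration when given.  Slice thickness/interval are carried as
    metadata only (the model is 2D in-plane).
    """

    rotation_time_s: float = 0.33
    n_sources: int = 1
    n_segments: int = 1
    pixel_size_mm: float = 0.45
    sigma_hu: float = 30.0
    ttf_f50: float | None = None  # mm^-1
    nps_peak: float | None = None  # mm^-1
    slice_thickness_mm: float | None = None
    slice_interval_mm: float | None = None
    model: str | None = None


@dataclass
class CaseSpec:
    """One patient-scanner-acquisition case for which e' is computed.

    ``diameter_mm`` and ``velocity_mm_s`` are optional direct overrides; when
    absent the reference diameter and vessel speed are derived from sex, AHA
    segment and heart rate via the shipped lookup tables.
    """

    case_id: str = "case"
    sex: str = "F"
    heart_rate: float = 65.0  # bpm
    heart_rate_sd: float = 0.0  # bpm, metadata
    aha_segment: str = "proximal-LAD"
    stenosis_severity_pct: float = 50.0
    plaque_material: str = "mixed"
    lumen_enhancement: float = 450.0  # HU, ascending-aorta contrast level
    scanner: ScannerSpec = field(default_factory=ScannerSpec)
    quality_label: str = "unknown"
    diameter_mm: float | None = None
    velocity_mm_s: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.stenosis_severity_pct <= 100.0:
            raise ValueError("stenosis_severity_pct must lie in [0, 100]")
        if self.scanner.sigma_hu < 0:
            raise ValueError("noise sigma must be >= 0")
        if self.quality_label not in ("high", "low", "unknown"):
            raise ValueError("quality_label must be high/low/unknown")

    @property
    def stenosis_fraction(self) -> float:
        return self.stenosis_severity_pct / 100.0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CaseSpec":
        d = dict(d)
        scanner = d.pop("scanner", {})
        if isinstance(scanner, dict):
            scanner = ScannerSpec(**scanner)
        return cls(scanner=scanner, **d)

    @classmethod
    def from_json(cls, path: str | Path) -> "CaseSpec":
        return cls.from_dict(json.loads(Path(path).read_text()))
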