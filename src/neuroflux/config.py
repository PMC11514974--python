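"""Run configuration for the end-to-end pipeline."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path


@dataclass
class RunConfig:
    """Everything the end-to-end simulate->cohort pipeline needs.

    All randomness flows from ``seed``; per-subject and per-scene seeds are
    spawned deterministically from it.  Thresholds: ``segment_threshold``
    is the region-growth fraction of the seed score, ``venous_floor`` the
    minimum measured venous mean as a fraction of the arterial mean before
    a subject's alpha is flagged, ``normality_alpha`` the Shapiro-Wilk gate
    level.
    """

    out_dir: str = "neuroflux_out"
    n_subjects: int = 3
    seed: int = 0
    grid: int | None = 64  # None = full per-plane matrix sizes (142/120/150)
    n_frames: int = 32
    noise_sd_mm_s: float = 2.0
    eddy_gradient: tuple[float, float] = (0.03, -0.02)  # mm/s per pixel
    segment_threshold: float = 0.5
    background_size: int = 60
    magnitude_floor_fraction: float = 0.3
    venous_floor: float = 0.01
    normality_alpha: float = 0.05
    detrend_csf: bool = True
    correlation_method: str | None = "spearman"
    write_series_files: bool = False
    population_means: dict = field(default_factory=dict)
    population_sds: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.eddy_gradient = tuple(self.eddy_gradient)
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if not 0.0 < self.segment_threshold < 1.0:
            raise ValueError("segment_threshold must lie in (0, 1)")
        if not 0.0 <= self.venous_floor < 1.0:
            raise ValueError("venous_floor must lie in [0, 1)")
        if not 0.0 < self.normality_alpha < 1.0:
            raise ValueError("normality_alpha must lie in (0, 1)")
        if self.noise_sd_mm_s < 0:
            raise ValueError("noise_sd_mm_s must be >= 0")

    def to_json(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["eddy_gradient"] = list(self.eddy_gradient)
        Path(path).write_text(json.dumps(d, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))
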