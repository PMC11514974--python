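"""Core containers shared by every pipeline stage.

The pipeline moves, per acquisition plane, from a :class:`CineSeries`
(magnitude + phase stacks over one averaged cardiac cycle) through
:class:`RoiMask` delineations to :class:`FlowWaveform` flow curves and
:class:`VolumeChangeCurve` volume curves, ending in per-subject coupling
metrics aggregated over a cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CineSeries",
    "RoiMask",
    "FlowWaveform",
    "VolumeChangeCurve",
    "INTRACRANIAL_ARTERIES",
    "INTRACRANIAL_VEINS",
    "EXTRACRANIAL_ARTERIES",
    "EXTRACRANIAL_VEINS",
    "CSF_LABEL",
    "PLANE_INTRA",
    "PLANE_EXTRA",
    "PLANE_CSF",
    "structure_role",
]

PLANE_INTRA = "intracranial"
PLANE_EXTRA = "extracranial"
PLANE_CSF = "csf"

# Structure inventory of the three acquisition planes: the intracranial plane
# holds both internal carotids and the basilar artery plus the straight and
# superior sagittal sinuses; the extracranial plane holds the carotids and
# vertebrals plus the two internal jugular veins; the CSF plane is the
# subarachnoid space at the C2C3 cervical level.
INTRACRANIAL_ARTERIES = ("ICAR_i", "ICAL_i", "BA")
INTRACRANIAL_VEINS = ("SSS", "SS")
EXTRACRANIAL_ARTERIES = ("ICAR_e", "ICAL_e", "VAR", "VAL")
EXTRACRANIAL_VEINS = ("IJVR", "IJVL")
CSF_LABEL = "CSF_C2C3"


def structure_role(label: str) -> str:
    """Role of a structure label: 'arterial', 'venous' or 'csf'."""
    if label in INTRACRANIAL_ARTERIES or label in EXTRACRANIAL_ARTERIES:
        return "arterial"
    if label in INTRACRANIAL_VEINS or label in EXTRACRANIAL_VEINS:
        return "venous"
    if label == CSF_LABEL:
        return "csf"
    raise KeyError(f"unknown structure label {label!r}")


@dataclass
class CineSeries:
    """One plane's cine acquisition: 32-frame magnitude and phase stacks.

    Arrays are ``(rows, cols, frames)``.  Phase is stored as real-valued
    radians in ``(-pi, pi]``; a stored phase ``p`` encodes velocity
    ``venc_mm_s * p / pi`` (cranial-positive).
    """

    magnitude: np.ndarray
    phase: np.ndarray
    venc_mm_s: float
    cycle_duration_s: float
    pixel_spacing_mm: tuple[float, float]
    slice_thickness_mm: float

    def __post_init__(self) -> None:
        self.magnitude = np.asarray(self.magnitude, dtype=float)
        self.phase = np.asarray(self.phase, dtype=float)
        if self.magnitude.shape != self.phase.shape:
            raise ValueError(
                f"magnitude shape {self.magnitude.shape} != phase shape "
                f"{self.phase.shape}"
            )
        if self.magnitude.ndim != 3:
            raise ValueError("stacks must be (rows, cols, frames)")
        if self.venc_mm_s <= 0:
            raise ValueError("venc_mm_s must be positive")
        if self.cycle_duration_s <= 0:
            raise ValueError("cycle_duration_s must be positive")

    @property
    def n_frames(self) -> int:
        return self.phase.shape[2]

    @property
    def shape(self) -> tuple[int, int]:
        return self.phase.shape[:2]

    @property
    def pixel_area_mm2(self) -> float:
        return float(self.pixel_spacing_mm[0] * self.pixel_spacing_mm[1])

    def velocity(self) -> np.ndarray:
        """Decode the full phase stack to velocities (mm/s)."""
        return self.venc_mm_s * self.phase / np.pi


@dataclass
class RoiMask:
    """Pixel set delineating one structure, constant over the cycle.

    ``direction_sign`` is the expected sign of the cycle-mean flow
    (+1 cranial for arteries, -1 for veins); oscillatory CSF uses +1 by
    convention but the sign is not enforced during extraction.
    """

    label: str
    mask: np.ndarray  # boolean (rows, cols)
    pixel_area_mm2: float
    direction_sign: int = 1

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")
        if not self.mask.any():
            raise ValueError(f"mask {self.label!r} is empty")
        if self.direction_sign not in (1, -1):
            raise ValueError("direction_sign must be +1 or -1")
        if self.pixel_area_mm2 <= 0:
            raise ValueError("pixel_area_mm2 must be positive")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())

    @property
    def area_mm2(self) -> float:
        return self.n_pixels * self.pixel_area_mm2

    @property
    def pixels(self) -> set[tuple[int, int]]:
        rr, cc = np.nonzero(self.mask)
        return {(int(r), int(c)) for r, c in zip(rr, cc)}


@dataclass
class FlowWaveform:
    """Flow curve (ml/min) over one normalized cardiac cycle."""

    label: str
    samples: np.ndarray  # ml/min, one per frame
    cycle_duration_s: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be 1-D")
        if not self.label:
            raise ValueError("label must be non-empty")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("flow samples must be finite")
        if self.cycle_duration_s <= 0:
            raise ValueError("cycle_duration_s must be positive")

    @property
    def n_frames(self) -> int:
        return self.samples.size

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.cycle_duration_s / self.n_frames

    def mean(self) -> float:
        return float(self.samples.mean())

    def amplitude(self) -> float:
        """Max minus min flow over the cycle (ml/min)."""
        return float(self.samples.max() - self.samples.min())


@dataclass
class VolumeChangeCurve:
    """Volume curve (ml), zero-anchored at frame 0.

    ``kind`` is one of CB_VC (cerebral blood), CSF_VC (spinal CSF) or
    CB&CSF_VC (their sum, the residual total volume change).
    """

    kind: str
    samples: np.ndarray  # ml
    cycle_duration_s: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be 1-D")
        if abs(self.samples[0]) > 1e-12:
            raise ValueError("volume curve must be zero-anchored at frame 0")
        if self.cycle_duration_s <= 0:
            raise ValueError("cycle_duration_s must be positive")

    @property
    def n_frames(self) -> int:
        return self.samples.size

    @property
    def stroke_volume_ml(self) -> float:
        """Curve amplitude (max - min), reported as a positive magnitude."""
        return float(self.samples.max() - self.samples.min())
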