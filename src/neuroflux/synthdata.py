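"""Synthetic cine phase-contrast MRI generator with known ground truth.

The generator emulates, per subject, the three acquisitions of a craniospinal
flow exam: an intracranial vascular plane (both internal carotids, basilar
artery, straight and superior sagittal sinuses), an extracranial vascular
plane (carotids, vertebrals, both internal jugular veins) and a spinal CSF
plane at the C2C3 level (annular subarachnoid space).  Vessels are disk
cross-sections carrying pulsatile plug-flow velocity waveforms; the phase
image encodes velocity as ``pi * v / VENC`` wrapped into ``(-pi, pi]`` so
velocities beyond the encoding limit alias, a spatially linear eddy-current
offset can be superimposed, and i.i.d. Gaussian velocity noise is added
before phase encoding.

Waveform templates are truncated Fourier series built from raised-cosine
powers ``((1 + cos) / 2)^p`` (p = 3 for the narrow arterial systolic bump,
p = 2 for the damped venous pulse), so every curve is band-limited to at
most four harmonics of the cardiac frequency.  The baseline fraction of each
template is solved in closed form from the requested pulsatility index, and
peak values from the requested cycle-mean flow, so ground-truth means and
PIs match the profile exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

import numpy as np

from . import dynamics
from .types import (
    CSF_LABEL,
    EXTRACRANIAL_ARTERIES,
    EXTRACRANIAL_VEINS,
    INTRACRANIAL_ARTERIES,
    INTRACRANIAL_VEINS,
    PLANE_CSF,
    PLANE_EXTRA,
    PLANE_INTRA,
    CineSeries,
    FlowWaveform,
    RoiMask,
)
from .units import MM3_PER_S_TO_ML_PER_MIN

__all__ = [
    "VesselSpec",
    "SceneSpec",
    "GroundTruth",
    "SubjectProfile",
    "SubjectTruth",
    "SubjectData",
    "CohortSpec",
    "make_waveform",
    "wrap_phase",
    "disk_mask",
    "annulus_mask",
    "render_series",
    "make_subject_truth",
    "make_subject",
    "make_cohort",
    "baseline_fraction_for_pi",
    "POPULATION_MEANS",
    "POPULATION_SDS",
]

WAVEFORM_KINDS = ("arterial", "venous", "csf")

#: Harmonic order of the raised-cosine template per waveform kind.
_BUMP_POWER = {"arterial": 3, "venous": 2, "csf": 2}

# Cohort study conditions: cycle-mean flows (ml/min), pulsatility indices,
# venous capture fractions (fraction of arterial inflow drained by the
# measured veins), CSF stroke volume (ml per cardiac cycle) and cycle length.
POPULATION_MEANS = {
    "mean_arterial_flow_intra_ml_min": 659.0,
    "mean_arterial_flow_extra_ml_min": 725.0,
    "pi_arterial_intra": 0.81,
    "pi_arterial_extra": 0.95,
    "pi_venous_intra": 0.25,
    "pi_venous_extra": 0.58,
    "venous_capture_intra": 450.0 / 659.0,
    "venous_capture_extra": 511.0 / 725.0,
    "csf_stroke_volume_ml": 0.59,
    "cycle_duration_s": 60.0 / 70.0,
    "ijv_right_fraction": 0.55,
}

POPULATION_SDS = {
    "mean_arterial_flow_intra_ml_min": 124.0,
    "mean_arterial_flow_extra_ml_min": 128.0,
    "pi_arterial_intra": 0.15,
    "pi_arterial_extra": 0.23,
    "pi_venous_intra": 0.07,
    "pi_venous_extra": 0.32,
    "venous_capture_intra": 0.10,
    "venous_capture_extra": 0.15,
    "csf_stroke_volume_ml": 0.16,
    "cycle_duration_s": 0.10,
    "ijv_right_fraction": 0.15,
}

#: Physiologic truncation bounds for cohort draws.
_BOUNDS = {
    "mean_arterial_flow_intra_ml_min": (200.0, 1500.0),
    "mean_arterial_flow_extra_ml_min": (200.0, 1500.0),
    "pi_arterial_intra": (0.2, 2.5),
    "pi_arterial_extra": (0.2, 2.5),
    "pi_venous_intra": (0.02, 2.0),
    "pi_venous_extra": (0.02, 2.0),
    "venous_capture_intra": (0.001, 1.5),
    "venous_capture_extra": (0.001, 1.5),
    "csf_stroke_volume_ml": (0.1, 1.5),
    "cycle_duration_s": (0.4, 1.6),
    "ijv_right_fraction": (0.0, 1.0),
}

# Arterial flow apportionment between the vessels of each plane.
_INTRA_ART_SHARES = {"ICAR_i": 0.40, "ICAL_i": 0.40, "BA": 0.20}
_EXTRA_ART_SHARES = {"ICAR_e": 0.36, "ICAL_e": 0.36, "VAR": 0.14, "VAL": 0.14}
_INTRA_VEIN_SHARES = {"SSS": 0.65, "SS": 0.35}

# Vessel layouts as (row, col) grid fractions and disk radii in pixels.
_INTRA_LAYOUT = {
    "ICAR_i": ((0.38, 0.40), 3.0),
    "ICAL_i": ((0.38, 0.60), 3.0),
    "BA": ((0.47, 0.50), 2.0),
    "SS": ((0.63, 0.50), 2.0),
    "SSS": ((0.80, 0.50), 4.0),
}
_EXTRA_LAYOUT = {
    "ICAR_e": ((0.35, 0.35), 3.0),
    "ICAL_e": ((0.35, 0.65), 3.0),
    "VAR": ((0.55, 0.40), 2.0),
    "VAL": ((0.55, 0.60), 2.0),
    "IJVR": ((0.75, 0.30), 4.0),
    "IJVL": ((0.75, 0.70), 4.0),
}
_CSF_ANNULUS_PX = (9.0, 5.0)  # outer, inner radius in pixels (0.8 mm spacing)

#: On-grid phase lags (fraction of cycle) of the systolic and venous peaks.
ARTERIAL_LAG = 4.0 / 32.0
VENOUS_LAG = 7.0 / 32.0

_DEFAULT_GRIDS = {PLANE_INTRA: 142, PLANE_EXTRA: 120, PLANE_CSF: 150}
_PLANE_VENC = {PLANE_INTRA: 600.0, PLANE_EXTRA: 600.0, PLANE_CSF: 50.0}
_PLANE_SPACING = {PLANE_INTRA: (1.0, 1.0), PLANE_EXTRA: (1.0, 1.0), PLANE_CSF: (0.8, 0.8)}
_PLANE_THICKNESS = {PLANE_INTRA: 2.0, PLANE_EXTRA: 2.0, PLANE_CSF: 3.0}


# ---------------------------------------------------------------------------
# waveform templates

def _bump(theta: np.ndarray, power: int) -> np.ndarray:
    return ((1.0 + np.cos(theta)) / 2.0) ** power


def _bump_mean(power: int) -> float:
    # cycle mean of ((1+cos)/2)^p  =  C(2p, p) / 4^p
    return math.comb(2 * power, power) / 4.0**power


def baseline_fraction_for_pi(pi: float, power: int) -> float:
    """Baseline fraction c0 such that ``c0 + (1-c0)*bump`` has the given PI.

    The template peaks at 1 and bottoms at ``c0``; its pulsatility index
    (max - min) / mean is ``(1-c0) / (c0 + (1-c0)*m)`` with ``m`` the bump's
    cycle mean, solved here for ``c0``.
    """
    if pi < 0:
        raise ValueError(f"pulsatility index must be >= 0, got {pi}")
    m = _bump_mean(power)
    c0 = (1.0 - pi * m) / (1.0 + pi * (1.0 - m))
    if c0 < 0:
        raise ValueError(
            f"pulsatility index {pi} is infeasible for this template "
            f"(maximum {1.0 / m:.2f})"
        )
    return c0


_DEFAULT_BASELINE = {
    "arterial": baseline_fraction_for_pi(
        POPULATION_MEANS["pi_arterial_intra"], _BUMP_POWER["arterial"]
    ),
    "venous": baseline_fraction_for_pi(
        POPULATION_MEANS["pi_venous_intra"], _BUMP_POWER["venous"]
    ),
}


def make_waveform(
    kind: str,
    peak_velocity: float,
    phase_lag: float,
    n_frames: int = 32,
    *,
    baseline_fraction: float | None = None,
) -> np.ndarray:
    """Velocity samples (mm/s) of one periodic template waveform.

    Arterial: positive baseline plus a narrow systolic bump peaking at
    ``peak_velocity`` at the frame nearest ``phase_lag``.  Venous: the same
    construction with a wider, damped pulse (pass a negative peak for a
    caudad vein).  CSF: a zero-mean oscillation (the bump minus its sample
    mean, normalized to peak at ``peak_velocity``).
    """
    if kind not in WAVEFORM_KINDS:
        raise ValueError(
            f"unknown waveform kind {kind!r}; allowed kinds: {WAVEFORM_KINDS}"
        )
    if n_frames < 8:
        raise ValueError("n_frames must be >= 8")
    theta = 2.0 * np.pi * (np.arange(n_frames) / n_frames - phase_lag)
    power = _BUMP_POWER[kind]
    b = _bump(theta, power)
    if kind == "csf":
        s = b - b.mean()
        peak = np.max(np.abs(s))
        return peak_velocity * s / peak
    c0 = _DEFAULT_BASELINE[kind] if baseline_fraction is None else baseline_fraction
    if not 0.0 <= c0 < 1.0:
        raise ValueError("baseline_fraction must lie in [0, 1)")
    return peak_velocity * (c0 + (1.0 - c0) * b)


# ---------------------------------------------------------------------------
# scene rendering

def wrap_phase(phi: np.ndarray) -> np.ndarray:
    """Wrap phase (radians) into ``(-pi, pi]``."""
    w = np.mod(np.asarray(phi, dtype=float) + np.pi, 2.0 * np.pi) - np.pi
    return np.where(w == -np.pi, np.pi, w)


def disk_mask(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    """Boolean disk: pixels with (r-r0)^2 + (c-c0)^2 <= radius^2."""
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def annulus_mask(
    shape: tuple[int, int],
    center: tuple[float, float],
    r_outer: float,
    r_inner: float,
    ligament_gap: bool = False,
) -> np.ndarray:
    """Annular CSF space; optional one-pixel radial gap (denticulate ligament)."""
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    d2 = (rr - center[0]) ** 2 + (cc - center[1]) ** 2
    mask = (d2 <= r_outer**2) & (d2 > r_inner**2)
    if ligament_gap:
        gap = np.zeros(shape, dtype=bool)
        gap[int(round(center[0])), : int(round(center[1]))] = True
        mask &= ~gap
    return mask


@dataclass
class VesselSpec:
    """One disk-shaped vessel cross-section in a scene."""

    label: str
    center: tuple[float, float]  # (row, col), 0-based pixels
    radius: float  # pixels
    waveform_kind: str = "arterial"
    peak_velocity: float = 0.0  # mm/s, cranial-positive
    phase_lag: float = 0.0  # fraction of cycle in [0, 1)
    baseline_fraction: float | None = None
    velocity_samples: np.ndarray | None = None  # explicit override (mm/s)

    def __post_init__(self) -> None:
        if self.radius < 1:
            raise ValueError("vessel radius must be >= 1 pixel")
        if self.waveform_kind not in WAVEFORM_KINDS:
            raise ValueError(
                f"unknown waveform kind {self.waveform_kind!r}; "
                f"allowed kinds: {WAVEFORM_KINDS}"
            )
        if self.waveform_kind == "arterial" and self.peak_velocity < 0:
            raise ValueError("arterial peak_velocity must be >= 0 (cranial)")
        if self.waveform_kind == "venous" and self.peak_velocity > 0:
            raise ValueError("venous peak_velocity must be <= 0 (caudad)")

    def waveform(self, n_frames: int) -> np.ndarray:
        if self.velocity_samples is not None:
            v = np.asarray(self.velocity_samples, dtype=float)
            if v.size != n_frames:
                raise ValueError("velocity_samples length must equal n_frames")
            return v
        return make_waveform(
            self.waveform_kind,
            self.peak_velocity,
            self.phase_lag,
            n_frames,
            baseline_fraction=self.baseline_fraction,
        )

    @property
    def direction_sign(self) -> int:
        if self.waveform_kind == "venous":
            return -1
        return 1


@dataclass
class SceneSpec:
    """Full description of one synthetic cine acquisition."""

    grid: tuple[int, int] = (64, 64)
    n_frames: int = 32
    cycle_duration_s: float = POPULATION_MEANS["cycle_duration_s"]
    venc_mm_s: float = 600.0
    pixel_spacing_mm: tuple[float, float] = (1.0, 1.0)
    slice_thickness_mm: float = 2.0
    vessels: list[VesselSpec] = field(default_factory=list)
    eddy_gradient: tuple[float, float] = (0.0, 0.0)  # mm/s per pixel (row, col)
    noise_sd_mm_s: float = 0.0
    seed: int = 0
    air_border: int = 0  # width of a low-magnitude frame emulating air
    magnitude_background: float = 100.0
    magnitude_vessel: float = 300.0
    magnitude_air: float = 5.0

    def __post_init__(self) -> None:
        if self.n_frames < 8:
            raise ValueError("n_frames must be >= 8")
        if self.venc_mm_s <= 0:
            raise ValueError("venc_mm_s must be positive")
        if self.cycle_duration_s <= 0:
            raise ValueError("cycle_duration_s must be positive")
        if self.noise_sd_mm_s < 0:
            raise ValueError("noise_sd_mm_s must be >= 0")


@dataclass
class GroundTruth:
    """Forward-model truth for one rendered scene.

    True flow of each structure is its (noise- and eddy-free) waveform times
    its discrete region area; masks are the exact rendered pixel sets.
    """

    masks: dict[str, RoiMask]
    flows: dict[str, FlowWaveform]
    velocity_waveforms: dict[str, np.ndarray]
    eddy_mm_s: np.ndarray


def _render_regions(
    regions: list[tuple[str, np.ndarray, np.ndarray, int]],
    *,
    grid: tuple[int, int],
    n_frames: int,
    cycle_duration_s: float,
    venc_mm_s: float,
    pixel_spacing_mm: tuple[float, float],
    slice_thickness_mm: float,
    eddy_gradient: tuple[float, float],
    noise_sd_mm_s: float,
    rng: np.random.Generator,
    air_border: int = 0,
    magnitude_background: float = 100.0,
    magnitude_region: float = 300.0,
    magnitude_air: float = 5.0,
) -> tuple[CineSeries, GroundTruth]:
    """Render labeled (mask, velocity waveform, sign) regions into a series."""
    rows, cols = grid
    pixel_area = pixel_spacing_mm[0] * pixel_spacing_mm[1]

    occupied = np.zeros(grid, dtype=bool)
    for label, mask, _, _ in regions:
        if (occupied & mask).any():
            raise ValueError(f"region {label!r} overlaps another region")
        occupied |= mask

    velocity = np.zeros((rows, cols, n_frames))
    masks: dict[str, RoiMask] = {}
    flows: dict[str, FlowWaveform] = {}
    waves: dict[str, np.ndarray] = {}
    for label, mask, wave, sign in regions:
        velocity[mask, :] += wave[None, :]
        masks[label] = RoiMask(label, mask, pixel_area, sign)
        area = mask.sum() * pixel_area
        flows[label] = FlowWaveform(
            label, wave * area * MM3_PER_S_TO_ML_PER_MIN, cycle_duration_s
        )
        waves[label] = wave.copy()

    rr = np.arange(rows) - (rows - 1) / 2.0
    cc = np.arange(cols) - (cols - 1) / 2.0
    eddy = eddy_gradient[0] * rr[:, None] + eddy_gradient[1] * cc[None, :]
    velocity += eddy[:, :, None]
    if noise_sd_mm_s > 0:
        velocity = velocity + rng.normal(0.0, noise_sd_mm_s, velocity.shape)

    phase = wrap_phase(np.pi * velocity / venc_mm_s)

    magnitude2d = np.full(grid, magnitude_background)
    magnitude2d[occupied] = magnitude_region
    if air_border > 0:
        border = np.zeros(grid, dtype=bool)
        border[:air_border, :] = border[-air_border:, :] = True
        border[:, :air_border] = border[:, -air_border:] = True
        magnitude2d[border & ~occupied] = magnitude_air
    magnitude = np.repeat(magnitude2d[:, :, None], n_frames, axis=2)

    series = CineSeries(
        magnitude,
        phase,
        venc_mm_s,
        cycle_duration_s,
        pixel_spacing_mm,
        slice_thickness_mm,
    )
    return series, GroundTruth(masks, flows, waves, eddy)


def render_series(scene: SceneSpec) -> tuple[CineSeries, GroundTruth]:
    """Render a scene into a cine magnitude/phase series plus ground truth.

    The phase stack stores ``wrap(pi*v/VENC)``, so any velocity beyond the
    encoding limit aliases; the eddy-current offset plane is added to the
    velocity field everywhere; Gaussian noise is applied to the velocity
    field before encoding and never to the ground truth.
    """
    rng = np.random.default_rng(scene.seed)
    regions = []
    for v in scene.vessels:
        mask = disk_mask(scene.grid, v.center, v.radius)
        regions.append((v.label, mask, v.waveform(scene.n_frames), v.direction_sign))
    return _render_regions(
        regions,
        grid=scene.grid,
        n_frames=scene.n_frames,
        cycle_duration_s=scene.cycle_duration_s,
        venc_mm_s=scene.venc_mm_s,
        pixel_spacing_mm=scene.pixel_spacing_mm,
        slice_thickness_mm=scene.slice_thickness_mm,
        eddy_gradient=scene.eddy_gradient,
        noise_sd_mm_s=scene.noise_sd_mm_s,
        rng=rng,
        air_border=scene.air_border,
        magnitude_background=scene.magnitude_background,
        magnitude_region=scene.magnitude_vessel,
        magnitude_air=scene.magnitude_air,
    )


# ---------------------------------------------------------------------------
# subjects and cohorts

@dataclass
class SubjectProfile:
    """Physiological targets defining one synthetic subject.

    Mean flows are cycle averages in ml/min, PIs are (max-min)/mean of the
    summed arterial / corrected venous curves, venous capture is the
    fraction of the arterial mean drained by the measured veins, and the CSF
    stroke volume is the amplitude of the spinal CSF volume-change curve.
    """

    mean_arterial_flow_intra_ml_min: float = POPULATION_MEANS["mean_arterial_flow_intra_ml_min"]
    mean_arterial_flow_extra_ml_min: float = POPULATION_MEANS["mean_arterial_flow_extra_ml_min"]
    pi_arterial_intra: float = POPULATION_MEANS["pi_arterial_intra"]
    pi_arterial_extra: float = POPULATION_MEANS["pi_arterial_extra"]
    pi_venous_intra: float = POPULATION_MEANS["pi_venous_intra"]
    pi_venous_extra: float = POPULATION_MEANS["pi_venous_extra"]
    venous_capture_intra: float = POPULATION_MEANS["venous_capture_intra"]
    venous_capture_extra: float = POPULATION_MEANS["venous_capture_extra"]
    csf_stroke_volume_ml: float = POPULATION_MEANS["csf_stroke_volume_ml"]
    cycle_duration_s: float = POPULATION_MEANS["cycle_duration_s"]
    ijv_right_fraction: float = POPULATION_MEANS["ijv_right_fraction"]
    #: sd of CSF measurement noise as a fraction of the CSF flow curve's sd;
    #: 0 gives a perfectly coupled (noise-free) CSF trace.
    csf_noise_frac: float = 0.15
    #: force CSF_VC = -CB_VC (intracranial) exactly, ignoring the CSF targets.
    perfect_compensation: bool = False

    def validate(self) -> None:
        if self.mean_arterial_flow_intra_ml_min <= 0 or self.mean_arterial_flow_extra_ml_min <= 0:
            raise ValueError("mean arterial flows must be positive")
        for name in ("pi_arterial_intra", "pi_arterial_extra"):
            baseline_fraction_for_pi(getattr(self, name), _BUMP_POWER["arterial"])
        for name in ("pi_venous_intra", "pi_venous_extra"):
            baseline_fraction_for_pi(getattr(self, name), _BUMP_POWER["venous"])
        if self.venous_capture_intra <= 0 or self.venous_capture_extra <= 0:
            raise ValueError("venous capture fractions must be positive")
        if self.csf_stroke_volume_ml < 0:
            raise ValueError("csf_stroke_volume_ml must be >= 0")
        if self.cycle_duration_s <= 0:
            raise ValueError("cycle_duration_s must be positive")
        if not 0.0 <= self.ijv_right_fraction <= 1.0:
            raise ValueError("ijv_right_fraction must lie in [0, 1]")
        if self.csf_noise_frac < 0:
            raise ValueError("csf_noise_frac must be >= 0")


@dataclass
class SubjectTruth:
    """Ground-truth flow waveforms (ml/min) of one subject, per plane."""

    profile: SubjectProfile
    flows: dict[str, dict[str, FlowWaveform]]  # plane -> label -> waveform

    def qa(self, plane: str) -> FlowWaveform:
        labels = INTRACRANIAL_ARTERIES if plane == PLANE_INTRA else EXTRACRANIAL_ARTERIES
        return dynamics.sum_flows([self.flows[plane][l] for l in labels], label=f"Qa_{plane}")

    def qv_measured(self, plane: str) -> FlowWaveform:
        labels = INTRACRANIAL_VEINS if plane == PLANE_INTRA else EXTRACRANIAL_VEINS
        return dynamics.sum_flows([self.flows[plane][l] for l in labels], label=f"Qv_{plane}")

    def alpha(self, plane: str) -> float:
        capture = (
            self.profile.venous_capture_intra
            if plane == PLANE_INTRA
            else self.profile.venous_capture_extra
        )
        return 1.0 / capture

    def av(self, plane: str) -> FlowWaveform:
        """True arterio-venous flow: Qa + alpha * Qv_measured (zero mean)."""
        qa = self.qa(plane)
        qv = self.qv_measured(plane)
        return FlowWaveform(
            f"AV_{plane}",
            qa.samples + self.alpha(plane) * qv.samples,
            qa.cycle_duration_s,
        )

    @property
    def csf_flow(self) -> FlowWaveform:
        return self.flows[PLANE_CSF][CSF_LABEL]


@dataclass
class SubjectData:
    """Rendered subject: one cine series per plane plus full ground truth."""

    series: dict[str, CineSeries]
    truth: SubjectTruth
    scene_truth: dict[str, GroundTruth]


def _unit_mean_template(power: int, c0: float, lag: float, n_frames: int) -> np.ndarray:
    """Positive unit-mean waveform shape with the PI fixed by ``c0``."""
    theta = 2.0 * np.pi * (np.arange(n_frames) / n_frames - lag)
    u = c0 + (1.0 - c0) * _bump(theta, power)
    return u / u.mean()


def _plane_flow_truth(
    profile: SubjectProfile, plane: str, n_frames: int
) -> dict[str, FlowWaveform]:
    """Per-vessel ground-truth flow waveforms of one vascular plane."""
    if plane == PLANE_INTRA:
        qa_mean = profile.mean_arterial_flow_intra_ml_min
        pi_a, pi_v = profile.pi_arterial_intra, profile.pi_venous_intra
        capture = profile.venous_capture_intra
        art_shares = _INTRA_ART_SHARES
        vein_shares = _INTRA_VEIN_SHARES
    else:
        qa_mean = profile.mean_arterial_flow_extra_ml_min
        pi_a, pi_v = profile.pi_arterial_extra, profile.pi_venous_extra
        capture = profile.venous_capture_extra
        art_shares = _EXTRA_ART_SHARES
        vein_shares = {
            "IJVR": profile.ijv_right_fraction,
            "IJVL": 1.0 - profile.ijv_right_fraction,
        }
    c0a = baseline_fraction_for_pi(pi_a, _BUMP_POWER["arterial"])
    c0v = baseline_fraction_for_pi(pi_v, _BUMP_POWER["venous"])
    ua = _unit_mean_template(_BUMP_POWER["arterial"], c0a, ARTERIAL_LAG, n_frames)
    uv = _unit_mean_template(_BUMP_POWER["venous"], c0v, VENOUS_LAG, n_frames)
    flows: dict[str, FlowWaveform] = {}
    for label, share in art_shares.items():
        flows[label] = FlowWaveform(label, share * qa_mean * ua, profile.cycle_duration_s)
    qv_mean = -capture * qa_mean  # caudad, hence negative
    for label, share in vein_shares.items():
        flows[label] = FlowWaveform(label, share * qv_mean * uv, profile.cycle_duration_s)
    return flows


def make_subject_truth(
    profile: SubjectProfile,
    seed: int | np.random.Generator = 0,
    n_frames: int = 32,
) -> SubjectTruth:
    """Ground-truth flow waveforms for all three planes of one subject.

    The spinal CSF flow mirrors the intracranial arterio-venous flow
    (scaled so the CSF volume-change amplitude matches the profile's CSF
    stroke volume, measured on a dense Fourier-interpolated grid), plus
    optional white measurement noise.
    """
    profile.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    flows = {
        PLANE_INTRA: _plane_flow_truth(profile, PLANE_INTRA, n_frames),
        PLANE_EXTRA: _plane_flow_truth(profile, PLANE_EXTRA, n_frames),
    }
    truth = SubjectTruth(profile, flows)
    av = truth.av(PLANE_INTRA)
    if profile.perfect_compensation:
        csf_samples = -av.samples
    else:
        sv_dense = dynamics.stroke_volume_dense(av)
        scale = profile.csf_stroke_volume_ml / sv_dense if sv_dense > 0 else 0.0
        csf_samples = -scale * av.samples
        if profile.csf_noise_frac > 0:
            sd = profile.csf_noise_frac * csf_samples.std()
            csf_samples = csf_samples + rng.normal(0.0, sd, n_frames)
    flows[PLANE_CSF] = {
        CSF_LABEL: FlowWaveform(CSF_LABEL, csf_samples, profile.cycle_duration_s)
    }
    return truth


def _scaled_layout(layout, grid: tuple[int, int]):
    return {
        label: ((frac[0] * (grid[0] - 1), frac[1] * (grid[1] - 1)), radius)
        for label, (frac, radius) in layout.items()
    }


def make_subject(
    profile: SubjectProfile | None = None,
    seed: int = 0,
    *,
    grid: int | None = None,
    n_frames: int = 32,
    eddy_gradient: tuple[float, float] = (0.0, 0.0),
    noise_sd_mm_s: float = 0.0,
    csf_ligament_gap: bool = False,
) -> SubjectData:
    """Render one subject's three cine acquisitions with ground truth.

    ``grid`` overrides the per-plane default matrix sizes (142/120/150) with
    a single square size, which the small-scene tests and examples use.
    Velocities are derived from the flow truth and the discrete region
    areas, so the rendered ground-truth flows equal the waveform-level truth
    exactly.
    """
    profile = SubjectProfile() if profile is None else profile
    rng = np.random.default_rng(seed)
    truth = make_subject_truth(profile, rng, n_frames)

    series: dict[str, CineSeries] = {}
    scene_truth: dict[str, GroundTruth] = {}
    for plane in (PLANE_INTRA, PLANE_EXTRA, PLANE_CSF):
        size = _DEFAULT_GRIDS[plane] if grid is None else grid
        shape = (size, size)
        spacing = _PLANE_SPACING[plane]
        pixel_area = spacing[0] * spacing[1]
        regions = []
        if plane == PLANE_CSF:
            center = ((size - 1) / 2.0, (size - 1) / 2.0)
            mask = annulus_mask(shape, center, *_CSF_ANNULUS_PX, ligament_gap=csf_ligament_gap)
            area = mask.sum() * pixel_area
            wave = truth.csf_flow.samples / (area * MM3_PER_S_TO_ML_PER_MIN)
            regions.append((CSF_LABEL, mask, wave, 1))
        else:
            layout = _scaled_layout(
                _INTRA_LAYOUT if plane == PLANE_INTRA else _EXTRA_LAYOUT, shape
            )
            for label, (center, radius) in layout.items():
                mask = disk_mask(shape, center, radius)
                area = mask.sum() * pixel_area
                flow = truth.flows[plane][label]
                wave = flow.samples / (area * MM3_PER_S_TO_ML_PER_MIN)
                sign = -1 if structure_role_is_venous(label) else 1
                regions.append((label, mask, wave, sign))
        s, gt = _render_regions(
            regions,
            grid=shape,
            n_frames=n_frames,
            cycle_duration_s=profile.cycle_duration_s,
            venc_mm_s=_PLANE_VENC[plane],
            pixel_spacing_mm=spacing,
            slice_thickness_mm=_PLANE_THICKNESS[plane],
            eddy_gradient=eddy_gradient,
            noise_sd_mm_s=noise_sd_mm_s,
            rng=rng,
        )
        series[plane] = s
        scene_truth[plane] = gt
    return SubjectData(series, truth, scene_truth)


def structure_role_is_venous(label: str) -> bool:
    return label in INTRACRANIAL_VEINS or label in EXTRACRANIAL_VEINS


@dataclass
class CohortSpec:
    """A cohort draw: per-subject profiles plus a truth table."""

    profiles: list[SubjectProfile]
    seed: int

    def truth_table(self):
        import pandas as pd

        rows = []
        for i, p in enumerate(self.profiles):
            row = {"subject": i}
            for f in fields(SubjectProfile):
                row[f.name] = getattr(p, f.name)
            rows.append(row)
        return pd.DataFrame(rows)


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, bounds: tuple[float, float]
) -> float:
    if sd == 0:
        return float(np.clip(mean, *bounds))
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if bounds[0] <= x <= bounds[1]:
            return float(x)
    raise RuntimeError("truncated normal rejection sampling failed")


def make_cohort(
    n_subjects: int,
    population_means: dict[str, float] | None = None,
    population_sds: dict[str, float] | None = None,
    seed: int = 0,
) -> CohortSpec:
    """Draw subject profiles from truncated normal population distributions.

    Means and sds default to the young-adult study conditions in
    :data:`POPULATION_MEANS` / :data:`POPULATION_SDS`; both dicts may
    override any subset of :class:`SubjectProfile` fields.
    """
    if n_subjects < 2:
        raise ValueError("a cohort needs at least 2 subjects")
    means = dict(POPULATION_MEANS)
    sds = dict(POPULATION_SDS)
    if population_means:
        means.update(population_means)
    if population_sds:
        sds.update(population_sds)
    if any(v < 0 for v in sds.values()):
        raise ValueError("population sds must be >= 0")
    rng = np.random.default_rng(seed)
    profiles = []
    for _ in range(n_subjects):
        kwargs = {
            name: _truncated_normal(rng, means[name], sds[name], _BOUNDS[name])
            for name in means
        }
        p = SubjectProfile(**kwargs)
        p.validate()
        profiles.append(p)
    return CohortSpec(profiles, seed)
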