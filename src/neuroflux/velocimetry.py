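"""Velocity decoding, de-aliasing, eddy-current correction, flow extraction.

The stored phase ``p`` of a pixel encodes velocity ``v = VENC * p / pi``
with ``p`` in ``(-pi, pi]``; true velocities beyond the encoding limit
alias by multiples of ``2 * VENC``.  De-aliasing operates by default on the
ROI-mean velocity series: temporal unwrapping removes inter-frame jumps
larger than VENC, and an optional expected sign of the cycle mean resolves
the remaining global ambiguity (a constant aliased series has no jumps to
key on).  The background (eddy-current) correction subtracts the average
velocity of a stationary-tissue ROI, i.e. redefines the zero-velocity
reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .types import CineSeries, FlowWaveform, RoiMask
from .units import MM3_PER_S_TO_ML_PER_MIN

__all__ = [
    "decode_velocity",
    "dealias",
    "DealiasResult",
    "background_reference",
    "background_correct",
    "extract_flow",
]


def decode_velocity(phase_value, venc: float):
    """Velocity (mm/s) from stored phase (radians): ``v = venc * phase / pi``."""
    if venc <= 0:
        raise ValueError("venc must be positive")
    return venc * np.asarray(phase_value, dtype=float) / np.pi


@dataclass
class DealiasResult:
    """Corrected velocity series plus per-sample wrap bookkeeping."""

    values: np.ndarray  # corrected velocities, mm/s
    wrap_counts: np.ndarray  # integer k per sample; correction = 2*k*venc
    unreliable: np.ndarray  # samples whose wrap count hit the search bound
    warnings: list[str] = field(default_factory=list)


def dealias(
    values: np.ndarray,
    venc: float,
    expected_sign: int | None = None,
    max_wraps: int = 3,
) -> DealiasResult:
    """Undo phase-wrapping of a velocity series by multiples of ``2*venc``.

    Sequentially shifts each sample by ``2*k*venc`` so no inter-frame jump
    exceeds VENC, then applies the smallest global shift that gives the
    cycle mean the expected sign (when one is given).  Idempotent on
    alias-free series; every correction is an exact integer multiple of
    ``2*venc``.  Samples that would need more than ``max_wraps`` wraps are
    flagged unreliable and left at their unwrapped-as-far-as-allowed value.
    """
    if venc <= 0:
        raise ValueError("venc must be positive")
    v = np.asarray(values, dtype=float)
    n = v.size
    k = np.zeros(n, dtype=int)
    notes: list[str] = []
    unreliable = np.zeros(n, dtype=bool)
    span = 2.0 * venc
    for t in range(1, n):
        prev = v[t - 1] + span * k[t - 1]
        k[t] = int(np.round((prev - v[t]) / span))
        if abs(k[t]) > max_wraps:
            k[t] = int(np.clip(k[t], -max_wraps, max_wraps))
            unreliable[t] = True
            notes.append(
                f"sample {t}: wrap count exceeds +/-{max_wraps}; left unreliable"
            )
    out = v + span * k
    if expected_sign is not None:
        mean = out.mean()
        if np.sign(mean) != np.sign(expected_sign) and mean != 0:
            # smallest uniform shift that flips the cycle-mean sign
            shift = int(np.ceil(abs(mean) / span)) * int(np.sign(expected_sign))
            if abs(shift) <= max_wraps:
                k = k + shift
                out = out + span * shift
            else:
                notes.append(
                    "could not match expected mean sign within the wrap bound"
                )
                unreliable |= True
    for msg in notes:
        warnings.warn(msg, stacklevel=2)
    return DealiasResult(out, k, unreliable, notes)


def background_reference(
    series: CineSeries, background: RoiMask, per_frame: bool = False
):
    """Mean decoded velocity of a stationary-tissue ROI.

    Returns the time-averaged scalar by default (the new zero-velocity
    reference); ``per_frame`` gives the frame-wise mean instead.
    """
    vel = series.velocity()[background.mask, :]  # (pixels, frames)
    return vel.mean(axis=0) if per_frame else float(vel.mean())


def background_correct(roi_velocity, background_mean_velocity):
    """Subtract the background zero-velocity reference from a series.

    ``background_mean_velocity`` may be a scalar (time-averaged) or a
    per-frame vector.
    """
    return np.asarray(roi_velocity, dtype=float) - background_mean_velocity


def extract_flow(
    series: CineSeries,
    mask: RoiMask,
    *,
    background: float | np.ndarray = 0.0,
    apply_dealias: bool = True,
    expected_sign: int | None = None,
    per_pixel_dealias: bool = False,
    max_wraps: int = 3,
) -> FlowWaveform:
    """Flow curve (ml/min) of one ROI: mean in-mask velocity times area.

    Per frame, the in-mask decoded velocities are averaged (after optional
    per-pixel de-aliasing), the ROI-mean series is de-aliased and the
    background reference subtracted, and the result is multiplied by the
    ROI area and converted from mm^3/s to ml/min.
    """
    rows, cols = series.shape
    rr, cc = np.nonzero(mask.mask)
    if rr.size == 0:
        raise ValueError("empty mask")
    if rr.max() >= rows or cc.max() >= cols:
        raise ValueError("mask extends outside the image")
    vel = series.velocity()[mask.mask, :]  # (pixels, frames)
    if apply_dealias and per_pixel_dealias:
        vel = np.stack(
            [dealias(vel[i], series.venc_mm_s, expected_sign, max_wraps).values
             for i in range(vel.shape[0])]
        )
    mean_vel = vel.mean(axis=0)
    if apply_dealias and not per_pixel_dealias:
        mean_vel = dealias(mean_vel, series.venc_mm_s, expected_sign, max_wraps).values
    mean_vel = background_correct(mean_vel, background)
    flow = mean_vel * mask.area_mm2 * MM3_PER_S_TO_ML_PER_MIN
    return FlowWaveform(mask.label, flow, series.cycle_duration_s)
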