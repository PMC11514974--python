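"""Plane-level flow aggregates and volume-change curves.

From per-structure flow waveforms this module builds the total arterial
(Qa) and measured venous (Qv) curves, rescales the venous curve so its
cycle mean balances the arterial mean (the alpha correction for unmeasured
drainage routes), forms the arterio-venous (AV) sum, and time-integrates
flows into volume-change curves: CB_VC (cerebral blood), CSF_VC (spinal
CSF) and their sum CB&CSF_VC, whose amplitudes are the stroke volumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.signal

from .types import FlowWaveform, VolumeChangeCurve
from .units import ML_PER_MIN_TO_ML_PER_S

__all__ = [
    "sum_flows",
    "correct_venous",
    "VenousCorrection",
    "pulsatility_index",
    "integrate_volume",
    "total_volume_change",
    "fourier_resample",
    "stroke_volume_dense",
    "csf_signed_amplitude",
    "PlaneAggregate",
    "aggregate_plane",
]


def sum_flows(waveforms: list[FlowWaveform], label: str = "sum") -> FlowWaveform:
    """Pointwise sum of flow curves sharing a time base."""
    if not waveforms:
        raise ValueError("need at least one waveform")
    first = waveforms[0]
    total = np.zeros(first.n_frames)
    for w in waveforms:
        if w.n_frames != first.n_frames:
            raise ValueError(
                f"waveform {w.label!r} has {w.n_frames} frames, "
                f"expected {first.n_frames}"
            )
        if not np.isclose(w.cycle_duration_s, first.cycle_duration_s):
            raise ValueError("waveforms must share a cycle duration")
        total += w.samples
    return FlowWaveform(label, total, first.cycle_duration_s)


@dataclass
class VenousCorrection:
    alpha: float
    qv: FlowWaveform


def correct_venous(
    qv_measured: FlowWaveform,
    qa: FlowWaveform,
    floor_fraction: float = 0.01,
) -> VenousCorrection:
    """Scale the measured venous curve so mean venous outflow balances Qa.

    ``alpha = |mean(Qa) / mean(Qv_measured)|`` compensates venous drainage
    routes outside the measured veins.  A measured venous mean below
    ``floor_fraction`` of the arterial mean (a subject whose drainage
    bypasses the measured veins almost entirely) is rejected rather than
    blown up by a huge alpha.
    """
    qa_mean = qa.mean()
    qv_mean = qv_measured.mean()
    if abs(qv_mean) < floor_fraction * abs(qa_mean):
        raise ValueError(
            "venous capture too low: measured venous mean "
            f"{qv_mean:.3g} ml/min is below {floor_fraction:.1%} of the "
            f"arterial mean {qa_mean:.3g} ml/min"
        )
    alpha = abs(qa_mean / qv_mean)
    qv = FlowWaveform(qv_measured.label, alpha * qv_measured.samples, qv_measured.cycle_duration_s)
    return VenousCorrection(alpha, qv)


def pulsatility_index(w: FlowWaveform) -> float:
    """PI = (max - min) / |mean| of a flow curve."""
    mean = w.mean()
    if mean == 0:
        raise ValueError("pulsatility index undefined for zero-mean flow")
    return w.amplitude() / abs(mean)


def integrate_volume(
    w: FlowWaveform, detrend: bool = True, kind: str = "VC"
) -> VolumeChangeCurve:
    """Cumulative trapezoidal time-integral of a flow curve, in ml.

    With ``detrend`` the cycle-mean flow is subtracted first so the volume
    curve closes periodically; this is required for the CSF curve (any net
    CSF drift over one averaged cycle is measurement offset) and is a no-op
    for an AV curve whose mean the alpha correction already zeroed.
    """
    q = w.samples - (w.samples.mean() if detrend else 0.0)
    dt_s = w.cycle_duration_s / w.n_frames
    increments = 0.5 * (q[:-1] + q[1:]) * dt_s * ML_PER_MIN_TO_ML_PER_S
    samples = np.concatenate([[0.0], np.cumsum(increments)])
    return VolumeChangeCurve(kind, samples, w.cycle_duration_s)


def total_volume_change(cb: VolumeChangeCurve, csf: VolumeChangeCurve) -> VolumeChangeCurve:
    """Pointwise sum CB_VC + CSF_VC; its own amplitude is the residual SV."""
    if cb.n_frames != csf.n_frames:
        raise ValueError("volume curves must have the same length")
    return VolumeChangeCurve("CB&CSF_VC", cb.samples + csf.samples, cb.cycle_duration_s)


def fourier_resample(w: FlowWaveform, factor: int) -> FlowWaveform:
    """Periodic (FFT) resampling of a flow curve to ``factor * n`` samples."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    dense = scipy.signal.resample(w.samples, factor * w.n_frames)
    return FlowWaveform(w.label, dense, w.cycle_duration_s)


def stroke_volume_dense(w: FlowWaveform, factor: int = 64, detrend: bool = True) -> float:
    """Stroke volume on a dense Fourier-interpolated grid (oracle-grade).

    Exact up to rounding for band-limited waveforms; used to calibrate
    generator amplitudes and as the independent check on the 32-point
    trapezoidal integration.
    """
    return integrate_volume(fourier_resample(w, factor), detrend=detrend).stroke_volume_ml


def csf_signed_amplitude(csf: VolumeChangeCurve, cb: VolumeChangeCurve) -> float:
    """CSF stroke volume signed by the CSF_VC value at the CB_VC maximum.

    Negative when spinal CSF volume is low while intracranial blood volume
    peaks, i.e. when CSF has vented caudad in response to blood inflow (the
    usual mirroring); the magnitude is the plain stroke volume.
    """
    at_cb_max = csf.samples[int(np.argmax(cb.samples))]
    sign = -1.0 if at_cb_max < 0 else 1.0
    return sign * csf.stroke_volume_ml


@dataclass
class PlaneAggregate:
    """Flow aggregates of one vascular plane."""

    plane: str
    qa: FlowWaveform
    qv_measured: FlowWaveform
    alpha: float
    qv: FlowWaveform  # alpha-corrected
    av: FlowWaveform  # Qa + Qv, zero cycle mean

    @property
    def pi_arterial(self) -> float:
        return pulsatility_index(self.qa)

    @property
    def pi_venous(self) -> float:
        return pulsatility_index(self.qv)


def aggregate_plane(
    plane: str,
    arterial: list[FlowWaveform],
    venous: list[FlowWaveform],
    floor_fraction: float = 0.01,
) -> PlaneAggregate:
    """Sum per-vessel curves and apply the venous alpha correction."""
    qa = sum_flows(arterial, label=f"Qa_{plane}")
    qv_measured = sum_flows(venous, label=f"Qv_{plane}")
    corr = correct_venous(qv_measured, qa, floor_fraction)
    av = FlowWaveform(f"AV_{plane}", qa.samples + corr.qv.samples, qa.cycle_duration_s)
    return PlaneAggregate(plane, qa, qv_measured, corr.alpha, corr.qv, av)
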