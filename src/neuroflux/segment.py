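"""Semi-automatic ROI delineation keyed to cardiac-frequency pulsatility.

Vessels and CSF spaces pulse at the cardiac frequency while stationary
tissue does not, so each pixel is scored by the magnitude of the first
temporal harmonic of its decoded velocity series (the cine series covers
exactly one averaged cardiac cycle, so the first Fourier bin *is* the
cardiac frequency).  An ROI is grown 4-connectedly from an operator seed
over pixels whose score reaches a fraction of the seed score, emulating a
seeded semi-automatic segmentation.  Background (stationary-tissue)
reference regions for eddy-current correction are picked adjacent to the
vessel ROIs among the least pulsatile, non-air pixels.
"""

from __future__ import annotations

import numpy as np
import scipy.ndimage

from .types import CineSeries, RoiMask

__all__ = [
    "cardiac_energy_map",
    "grow_roi",
    "pick_background_roi",
]

#: 4-connectivity structuring element used for region growth and dilation.
_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


def cardiac_energy_map(series: CineSeries) -> np.ndarray:
    """Per-pixel pulsatility score at the cardiac frequency.

    Score is the magnitude of the first-harmonic Fourier coefficient
    (amplitude scale: a pure cosine of amplitude A at the cardiac frequency
    scores A) of the decoded velocity time series.  Constant-in-time pixels
    score exactly 0; the score is immune to any static phase offset because
    the DC bin is not used.
    """
    if series.n_frames < 8:
        raise ValueError("need at least 8 frames")
    velocity = series.velocity()
    coeff = np.fft.fft(velocity, axis=2)[:, :, 1]
    return 2.0 * np.abs(coeff) / series.n_frames


def grow_roi(
    score_map: np.ndarray,
    seed_pixel: tuple[int, int],
    threshold_fraction: float = 0.5,
    *,
    label: str = "ROI",
    pixel_area_mm2: float = 1.0,
    direction_sign: int = 1,
) -> RoiMask:
    """Grow a 4-connected ROI from a seed over high-pulsatility pixels.

    The mask is the 4-connected component containing the seed of the level
    set ``score >= threshold_fraction * score(seed)``; pixels exactly at
    the threshold are included, making the result deterministic.
    """
    score = np.asarray(score_map, dtype=float)
    r, c = seed_pixel
    if not (0 <= r < score.shape[0] and 0 <= c < score.shape[1]):
        raise ValueError("seed outside image")
    if not 0.0 < threshold_fraction < 1.0:
        raise ValueError("threshold_fraction must lie in (0, 1)")
    seed_score = score[r, c]
    if seed_score == 0:
        raise ValueError("seed not pulsatile")
    candidates = score >= threshold_fraction * seed_score
    labels, _ = scipy.ndimage.label(candidates, structure=_CROSS)
    mask = labels == labels[r, c]
    return RoiMask(label, mask, pixel_area_mm2, direction_sign)


def pick_background_roi(
    series: CineSeries,
    vessel_masks: list[RoiMask],
    size: int,
    *,
    magnitude_floor_fraction: float = 0.3,
    exclusion_px: int = 1,
    max_band_px: int = 8,
    label: str = "background",
) -> RoiMask:
    """Stationary-tissue ROI adjacent to the vessel ROIs.

    Candidates lie in a dilation band around the union of the vessel masks
    (excluding the vessels themselves and a small margin against
    partial-volume edge pixels), must exceed a magnitude floor (a fraction
    of the median time-averaged magnitude, excluding air), and the ``size``
    least-pulsatile candidates are taken.  The band is widened until enough
    candidates exist.
    """
    if size < 1:
        raise ValueError("size must be >= 1")
    vessels = np.zeros(series.shape, dtype=bool)
    for m in vessel_masks:
        vessels |= m.mask
    excluded = scipy.ndimage.binary_dilation(vessels, _CROSS, iterations=exclusion_px)
    mean_mag = series.magnitude.mean(axis=2)
    adequate = mean_mag >= magnitude_floor_fraction * np.median(mean_mag)
    energy = cardiac_energy_map(series)

    for band in range(exclusion_px + 1, max_band_px + 1):
        ring = scipy.ndimage.binary_dilation(vessels, _CROSS, iterations=band)
        candidates = ring & ~excluded & adequate
        if candidates.sum() >= size:
            break
    else:
        raise ValueError(
            f"not enough background candidates: need {size}, "
            f"found {int(candidates.sum())} within {max_band_px} px"
        )
    rr, cc = np.nonzero(candidates)
    order = np.lexsort((cc, rr, energy[rr, cc]))  # energy, then row/col for ties
    keep = order[:size]
    mask = np.zeros(series.shape, dtype=bool)
    mask[rr[keep], cc[keep]] = True
    return RoiMask(label, mask, series.pixel_area_mm2, 1)
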