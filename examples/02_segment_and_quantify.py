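"""Segment a rendered plane and extract corrected flow curves.

Scores pixels by their first-harmonic (cardiac-frequency) velocity
pulsation, grows each vessel ROI from a seed click, picks a stationary
background region for the eddy-current zero reference, and compares
extracted flows against the simulation ground truth.
"""

import numpy as np

from neuroflux import synthdata as sd
from neuroflux.segment import cardiac_energy_map, grow_roi, pick_background_roi
from neuroflux.types import PLANE_INTRA, structure_role
from neuroflux.velocimetry import background_reference, extract_flow

subject = sd.make_subject(
    sd.SubjectProfile(), seed=7, grid=64,
    noise_sd_mm_s=3.0, eddy_gradient=(0.05, -0.04),
)
series = subject.series[PLANE_INTRA]
gt = subject.scene_truth[PLANE_INTRA]

energy = cardiac_energy_map(series)
rois = {}
for label, truth_mask in gt.masks.items():
    inside = np.where(truth_mask.mask, energy, -np.inf)
    seed = np.unravel_index(int(np.argmax(inside)), energy.shape)
    rois[label] = grow_roi(energy, seed, 0.5, label=label,
                           pixel_area_mm2=series.pixel_area_mm2)

background = pick_background_roi(series, list(rois.values()), 60)
reference = background_reference(series, background)
print(f"background eddy-current reference: {reference:+.2f} mm/s "
      f"(true offset at those pixels {gt.eddy_mm_s[background.mask].mean():+.2f})")

print(f"{'vessel':8s} {'area mm2':>9s} {'dice':>6s} {'mean flow':>10s} {'truth':>8s}")
for label, roi in rois.items():
    sign = -1 if structure_role(label) == "venous" else 1
    flow = extract_flow(series, roi, background=reference, expected_sign=sign)
    tm = gt.masks[label]
    dice = 2 * (roi.mask & tm.mask).sum() / (roi.n_pixels + tm.n_pixels)
    print(f"{label:8s} {roi.area_mm2:9.1f} {dice:6.3f} "
          f"{flow.mean():10.1f} {gt.flows[label].mean():8.1f}")
# Dice near 1 and flow means within a few ml/min of truth show the
# segmentation + correction chain works under noise and eddy offsets.
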