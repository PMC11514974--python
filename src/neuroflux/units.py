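"""Centralized unit conventions and conversions.

Conventions used throughout the package:

* velocities  : mm/s, cranial-directed flow positive
* areas       : mm^2
* flows       : ml/min
* volumes     : ml
* phase       : radians in (-pi, pi]; +pi*v/VENC encodes velocity v
"""

#: 1 mm/s over 1 mm^2 is 1 mm^3/s = 60/1000 ml/min.
MM3_PER_S_TO_ML_PER_MIN = 60.0 / 1000.0

#: Flow in ml/min times seconds integrates in ml after this factor.
ML_PER_MIN_TO_ML_PER_S = 1.0 / 60.0


def velocity_area_to_flow(mean_velocity_mm_s: float, area_mm2: float) -> float:
    """Flow (ml/min) through a cross-section from its mean velocity and area."""
    return mean_velocity_mm_s * area_mm2 * MM3_PER_S_TO_ML_PER_MIN
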