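# Methods

This note documents the models, parameter choices and numerical decisions
behind `neuroflux`, in the order the pipeline runs. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Forward model (synthetic cine PC-MRI)

**Scene.** Each acquisition plane is a `rows × cols × 32` magnitude/phase
stack over one averaged cardiac cycle. Vessels are disk cross-sections
(pixels with `(r−r0)² + (c−c0)² ≤ radius²`) carrying spatially uniform
("plug") velocity waveforms; the CSF space at C2C3 is an annulus (outer/inner
radii 9/5 px at 0.8 mm spacing, ≈112 mm²), with an optional one-pixel radial
gap imitating the denticulate ligament (off by default — the analysis treats
the whole subarachnoid ring). Phase stores `wrap(π·v/VENC)` in `(−π, π]`, so
|v| > VENC aliases exactly as in a scanner; a 12-bit scaled-integer phase
dialect is available as a writer flag but the core stays exact. A linear
eddy-current offset plane (mm/s per pixel, zero at the image centre) is added
to the velocity field, and i.i.d. Gaussian velocity noise is applied *before*
phase encoding. Ground truth (masks, per-structure flow = waveform × discrete
region area, eddy field) is never contaminated by noise.

**Waveforms.** Velocity templates are truncated Fourier series built from
raised-cosine powers `b_p(θ) = ((1+cos θ)/2)^p`: a narrow systolic bump
(p = 3) over a positive baseline for arteries, a wider damped pulse (p = 2)
for veins, and the zero-mean oscillation `b_2 − mean(b_2)` for CSF. Every
curve is therefore band-limited to ≤ 3 harmonics of the cardiac frequency,
which keeps 32-sample quadrature and Fourier-interpolation oracles sharp. The
bumps are symmetric rather than skewed; the simplification buys closed-form
calibration: the baseline fraction `c0` solves
`PI = (1−c0)/(c0 + (1−c0)·mean(b_p))` exactly, and scaling to a unit-mean
shape makes the cycle-mean flow match its target to machine precision (peak
phase lags sit on the 32-frame grid: systole at frame 4, venous peak at frame
7 — values chosen once as plausible young-adult timing; the data model is not
sensitive to them).

**Subjects.** A `SubjectProfile` fixes, per plane, the cycle-mean arterial
flow, arterial and venous PI, and the venous *capture fraction* (share of
arterial inflow drained by the measured veins; the true correction factor is
α = 1/capture). Arterial flow splits 40/40/20 % between the carotids and
basilar artery intracranially and 36/36/14/14 % with the vertebrals
extracranially; venous flow splits 65/35 % between superior sagittal and
straight sinus, and by the profile's right-jugular fraction extracranially
(1.0 emulates strictly unilateral jugular drainage). The spinal CSF flow
mirrors the intracranial arterio-venous curve: `Q_CSF = −s·AV + ε`, with `s`
set so the dense-grid CSF volume-curve amplitude equals the profile's CSF
stroke volume and `ε` white noise with sd = `csf_noise_frac` × sd(signal)
(default 0.15, a modest measurement-noise allowance; 0 gives perfect
coupling, and `perfect_compensation=True` forces `Q_CSF = −AV` exactly).

**Cohorts.** Profiles are drawn from independent truncated normal
distributions whose means and SDs are the young-adult reference conditions
the package targets: arterial mean flow 659 ± 124 (intracranial) and
725 ± 128 ml/min (extracranial), PI 0.81 ± 0.15 / 0.95 ± 0.23 (arterial) and
0.25 ± 0.07 / 0.58 ± 0.32 (venous), capture fractions 0.68 ± 0.10 /
0.70 ± 0.15 (implying venous means 450 / 511 ml/min), CSF stroke volume
0.59 ± 0.16 ml, cycle length 60/70 ± 0.10 s. Truncation bounds are loose
physiologic guards (e.g. PI in [0.2, 2.5], capture ≥ 0.001 so that
pathological drainage bypass remains expressible). Acquisition metadata
follow clinical practice: VENC 600 mm/s for blood, 50 mm/s for CSF; 1 mm and
0.8 mm pixels; 2 mm and 3 mm slices; 32 reconstructed frames.

## Segmentation

The pulsatility score of a pixel is the magnitude of the first-harmonic
discrete Fourier coefficient of its decoded velocity series (amplitude
scale: a pure cardiac-frequency cosine of amplitude A scores A). Because the
cine series spans exactly one averaged cycle, the first bin is the cardiac
frequency; the DC bin is ignored, making the score immune to static phase
offsets. Only the first harmonic is used — the point is to key on cardiac
periodicity, not to reconstruct the waveform. ROIs are the 4-connected
component containing the seed of the level set
`score ≥ threshold_fraction × score(seed)`; ties at the threshold are
included and growth is fully deterministic. The default `threshold_fraction`
of 0.5 is a package choice (exposed in config); on noiseless scenes it
recovers disks of radius 2–8 px with Dice ≥ 0.95 (in practice exactly).
Background regions take the `size` least-pulsatile pixels in a dilation band
(widened up to 8 px as needed) around the vessels, excluding a 1-px
partial-volume margin and pixels below a magnitude floor (default 30 % of the
image-median magnitude) that excludes air.

## Velocimetry

Decoding is the linear map `v = VENC·phase/π`. De-aliasing operates on the
ROI-mean series by default (CSF at VENC 50 aliases coherently across the
ROI; a per-pixel mode exists behind a flag): samples are sequentially
shifted by integer multiples of 2·VENC so no inter-frame jump exceeds VENC,
then, if an expected cycle-mean sign is supplied (cranial + for arteries,
− for veins, none for oscillatory CSF), the smallest uniform shift enforcing
it is applied — this resolves the constant-aliased case that temporal
unwrapping alone cannot. Corrections are always exact multiples of 2·VENC;
samples needing more than `max_wraps` (default 3) wraps are flagged
unreliable and left. Background correction subtracts the time-averaged mean
velocity of the background ROI (a scalar — the "new zero reference"); a
per-frame variant is provided since either convention is defensible. Flow is
mean in-mask velocity × mask area, `mm³/s → ml/min` via ×0.06; masks are
binary pixel sets with no sub-pixel weighting, and constant over the cycle.

## Volume dynamics

`α = |mean(Qa)/mean(Qv_meas)|` is computed per plane from the *summed* venous
curve, and the corrected venous curve is `α·Qv_meas`, making `AV = Qa + Qv`
zero-mean by construction. A measured venous mean below `venous_floor`
(default 1 %) of the arterial mean raises "venous capture too low"; in the
cohort pipeline the subject is kept with that plane's α flagged and excluded
from α aggregation. Volume curves are cumulative trapezoidal integrals
(`ml/min → ml/s` via ÷60) anchored to 0 at frame 0. The CSF flow is
mean-subtracted before integration so CSF_VC closes periodically (any net
drift over an averaged cycle is offset error); AV needs no detrend since α
zeroed its mean. With zero-mean input the wrap-around interval returns the
curve to 0 exactly, so stroke volume (max − min) is invariant under cyclic
shifts of the waveform. At 32 samples the trapezoid attenuates harmonic k by
`1 − x·cot x`, `x = πk/32` (0.3 % at k = 1, 1.3 % at k = 2), giving ≈ 0.5 %
SV error on default-profile AV curves against a dense Fourier-interpolated
oracle; extreme cohort draws (venous PI near 1) can reach ≈ 1 %. Stroke
volumes are reported as positive magnitudes; the CSF stroke volume also
carries a signed companion whose sign is that of CSF_VC at the frame where
CB_VC peaks (negative = the usual mirroring, CSF vented caudad at peak blood
volume) — the sign convention for a "negative CSF amplitude" is otherwise
ambiguous.

## Coupling statistics

The per-subject regression takes CSF_VC as response and CB_VC as predictor
(slope in ml CSF per ml blood; direction configurable). R² equals the
squared Pearson correlation; the p-value is the slope's two-sided t test
with n−2 df, identical to the regression F test in the simple-regression
case. The 32 cycle points are serially correlated; p-values ignore this (a
note travels with each result) and no multiple-testing correction is
applied. Plane comparisons use a paired Student t when the Shapiro–Wilk test
on the paired differences gives p ≥ 0.05 (the gate level is a package
choice, exposed as `normality_alpha`) and a Wilcoxon signed-rank test
otherwise; all-zero differences return p = 1 ("degenerate"), and constant
non-zero differences go straight to Wilcoxon. Stroke-volume correlations
default to Spearman in the cohort table (robust to the skewed SV
distributions); the gated Pearson/Spearman chooser is available and records
which method it used. CV% is 100·SD/|mean|.

## What the generator does and does not emulate

Passing tests demonstrate correctness of the measurement chain on data whose
generating process is known: plug-flow disks, band-limited waveforms, linear
eddy planes, white Gaussian noise, and a CSF curve that mirrors the
intracranial AV by construction. Real acquisitions add laminar velocity
profiles and partial-volume edges, through-plane motion, respiratory
modulation of CSF flow, gating jitter, susceptibility artefacts near air,
and genuinely nonlinear/lagged CSF responses — none of which are modelled.
Two consequences worth noting: per-subject coupling R² of simulated default
cohorts is near 1 (white flow-level noise integrates into a smooth curve),
so cohort R² spread does not emulate the physiological decoupling seen in
vivo and the R²-recovery experiment instead calibrates curve-level noise
explicitly; and segmentation Dice of 1.0 on noiseless scenes reflects the
absence of partial-volume blur, not expected in-vivo performance.

## Problem sizes

Defaults were chosen so every stage is exact or oracle-checked at modest
cost: demo grids of 48–64 px (full-size 142/120/150 px renders are supported
and used identically), cohorts of 2–8 rendered subjects in tests, and
waveform-level (non-rendered) cohorts of 20–1000 subjects for the recovery
experiments in `scripts/acceptance.py`, which complete in seconds.
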