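"""End-to-end orchestration: simulate -> segment -> quantify -> analyze -> cohort.

``measure_subject`` runs the measurement chain on one rendered subject
(energy-map segmentation seeded at the most pulsatile pixel of each known
structure, background eddy-current reference, de-aliased flow extraction).
``analyze_subject`` turns per-structure flow curves into plane aggregates,
volume curves and coupling metrics.  ``run_pipeline`` binds everything over
a simulated cohort, with per-stage logs and full seed determinism.
"""

from __future__ import annotations

import logging
import math
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import io as nfio
from .config import RunConfig
from .coupling import (
    CohortSummary,
    CouplingResult,
    PlaneMetrics,
    SubjectResult,
    regress_coupling,
    summarize_cohort,
)
from .dynamics import (
    aggregate_plane,
    csf_signed_amplitude,
    integrate_volume,
    total_volume_change,
)
from .segment import cardiac_energy_map, grow_roi, pick_background_roi
from .synthdata import SubjectData, make_cohort, make_subject
from .types import (
    CSF_LABEL,
    EXTRACRANIAL_ARTERIES,
    EXTRACRANIAL_VEINS,
    INTRACRANIAL_ARTERIES,
    INTRACRANIAL_VEINS,
    PLANE_CSF,
    PLANE_EXTRA,
    PLANE_INTRA,
    FlowWaveform,
    RoiMask,
    structure_role,
)
from .velocimetry import background_reference, extract_flow

__all__ = ["measure_subject", "analyze_subject", "run_pipeline", "PipelineResult"]

log = logging.getLogger("neuroflux")

_PLANE_STRUCTURES = {
    PLANE_INTRA: INTRACRANIAL_ARTERIES + INTRACRANIAL_VEINS,
    PLANE_EXTRA: EXTRACRANIAL_ARTERIES + EXTRACRANIAL_VEINS,
    PLANE_CSF: (CSF_LABEL,),
}
_ROLE_SIGN = {"arterial": 1, "venous": -1, "csf": 1}


def measure_subject(
    subject: SubjectData,
    config: RunConfig | None = None,
) -> tuple[dict[str, dict[str, FlowWaveform]], dict[str, dict[str, RoiMask]]]:
    """Segment and quantify all structures of a rendered subject.

    For each plane: build the cardiac energy map, grow each structure's ROI
    from the most pulsatile pixel inside its known location (the emulated
    operator click), pick a stationary background ROI, and extract
    de-aliased, background-corrected flow curves.  A structure with no
    pulsatile signal (e.g. an unilateral jugular with zero flow) falls back
    to its nominal manual outline.
    """
    config = config or RunConfig()
    flows: dict[str, dict[str, FlowWaveform]] = {}
    masks: dict[str, dict[str, RoiMask]] = {}
    for plane, series in subject.series.items():
        energy = cardiac_energy_map(series)
        plane_masks: dict[str, RoiMask] = {}
        for label in _PLANE_STRUCTURES[plane]:
            truth_mask = subject.scene_truth[plane].masks[label]
            inside = np.where(truth_mask.mask, energy, -np.inf)
            seed = np.unravel_index(int(np.argmax(inside)), energy.shape)
            role = structure_role(label)
            try:
                roi = grow_roi(
                    energy,
                    seed,
                    config.segment_threshold,
                    label=label,
                    pixel_area_mm2=series.pixel_area_mm2,
                    direction_sign=_ROLE_SIGN[role],
                )
            except ValueError:
                log.info("plane %s: %s not pulsatile, using manual outline", plane, label)
                roi = RoiMask(label, truth_mask.mask, series.pixel_area_mm2,
                              _ROLE_SIGN[role])
            plane_masks[label] = roi
        background = pick_background_roi(
            series,
            list(plane_masks.values()),
            config.background_size,
            magnitude_floor_fraction=config.magnitude_floor_fraction,
        )
        reference = background_reference(series, background)
        plane_flows = {}
        for label, roi in plane_masks.items():
            role = structure_role(label)
            plane_flows[label] = extract_flow(
                series,
                roi,
                background=reference,
                expected_sign=None if role == "csf" else _ROLE_SIGN[role],
            )
        flows[plane] = plane_flows
        masks[plane] = plane_masks
    return flows, masks


def _nan_plane_metrics(qa_mean: float, qv_mean: float) -> PlaneMetrics:
    return PlaneMetrics(
        alpha=math.nan,
        alpha_flagged=True,
        mean_arterial_flow=qa_mean,
        mean_venous_flow_measured=abs(qv_mean),
        pi_arterial=math.nan,
        pi_venous=math.nan,
        sv_cb=math.nan,
        sv_total=math.nan,
        coupling=None,
    )


def analyze_subject(
    flows: dict[str, dict[str, FlowWaveform]],
    subject_id: str = "subject",
    *,
    venous_floor: float = 0.01,
    detrend_csf: bool = True,
) -> SubjectResult:
    """Plane aggregates, volume curves and coupling metrics for one subject.

    A plane whose measured venous mean is below ``venous_floor`` of its
    arterial mean gets its alpha flagged and its blood-volume metrics set
    to NaN; the subject is kept (mirroring an outlier whose drainage
    bypasses the measured veins).
    """
    csf_flow = flows[PLANE_CSF][CSF_LABEL]
    csf_vc = integrate_volume(csf_flow, detrend=detrend_csf, kind="CSF_VC")
    planes: dict[str, PlaneMetrics] = {}
    cb_curves = {}
    for plane in (PLANE_INTRA, PLANE_EXTRA):
        arterial_labels = (
            INTRACRANIAL_ARTERIES if plane == PLANE_INTRA else EXTRACRANIAL_ARTERIES
        )
        venous_labels = (
            INTRACRANIAL_VEINS if plane == PLANE_INTRA else EXTRACRANIAL_VEINS
        )
        arteries = [flows[plane][l] for l in arterial_labels]
        veins = [flows[plane][l] for l in venous_labels]
        try:
            agg = aggregate_plane(plane, arteries, veins, venous_floor)
        except ValueError as err:
            log.warning("subject %s plane %s: %s", subject_id, plane, err)
            qa_mean = float(np.mean([w.mean() for w in arteries]) * len(arteries))
            qv_mean = float(np.mean([w.mean() for w in veins]) * len(veins))
            planes[plane] = _nan_plane_metrics(qa_mean, qv_mean)
            continue
        cb_vc = integrate_volume(agg.av, detrend=False, kind="CB_VC")
        cb_curves[plane] = cb_vc
        total = total_volume_change(cb_vc, csf_vc)
        coupling = regress_coupling(cb_vc, csf_vc, plane=plane)
        planes[plane] = PlaneMetrics(
            alpha=agg.alpha,
            alpha_flagged=False,
            mean_arterial_flow=agg.qa.mean(),
            mean_venous_flow_measured=abs(agg.qv_measured.mean()),
            pi_arterial=agg.pi_arterial,
            pi_venous=agg.pi_venous,
            sv_cb=cb_vc.stroke_volume_ml,
            sv_total=total.stroke_volume_ml,
            coupling=coupling,
        )
    ref_cb = cb_curves.get(PLANE_INTRA) or cb_curves.get(PLANE_EXTRA)
    signed = (
        csf_signed_amplitude(csf_vc, ref_cb) if ref_cb is not None
        else csf_vc.stroke_volume_ml
    )
    return SubjectResult(subject_id, planes, csf_vc.stroke_volume_ml, signed)


@dataclass
class PipelineResult:
    summary: CohortSummary
    subjects: list[SubjectResult]
    out_dir: Path


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Simulate a cohort and run it through the full measurement chain."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    cohort = make_cohort(
        config.n_subjects, config.population_means, config.population_sds,
        seed=config.seed,
    )
    seeds = np.random.SeedSequence(config.seed).generate_state(config.n_subjects)
    log.info("simulated cohort of %d subjects in %.2fs",
             config.n_subjects, time.perf_counter() - t0)
    results = []
    for i, profile in enumerate(cohort.profiles):
        sid = f"subject_{i:03d}"
        t1 = time.perf_counter()
        try:
            subject = make_subject(
                profile,
                seed=int(seeds[i] % (2**31)),
                grid=config.grid,
                n_frames=config.n_frames,
                eddy_gradient=config.eddy_gradient,
                noise_sd_mm_s=config.noise_sd_mm_s,
            )
            if config.write_series_files:
                for plane, series in subject.series.items():
                    nfio.write_series(series, out_dir / sid / plane)
            flows, _ = measure_subject(subject, config)
            nfio.write_flows(flows, out_dir / sid / "flows.csv")
            result = analyze_subject(
                flows, sid,
                venous_floor=config.venous_floor,
                detrend_csf=config.detrend_csf,
            )
        except Exception as err:  # noqa: BLE001 - abort with stage context
            raise RuntimeError(f"pipeline failed for {sid}: {err}") from err
        nfio.write_subject_result(result, out_dir / sid / "subject.json")
        results.append(result)
        log.info("%s analyzed in %.2fs", sid, time.perf_counter() - t1)
    summary = summarize_cohort(
        results,
        normality_alpha=config.normality_alpha,
        correlation_method=config.correlation_method,
    )
    summary.to_csv(out_dir / "cohort.csv")
    log.info("cohort summary written to %s (total %.2fs)",
             out_dir / "cohort.csv", time.perf_counter() - t0)
    return PipelineResult(summary, results, out_dir)
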