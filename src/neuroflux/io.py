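"""Readers and writers for the package's on-disk dialect.

A cine acquisition is stored as a NIfTI pair ``<stem>_mag.nii.gz`` /
``<stem>_pha.nii.gz`` (shape rows x cols x frames) plus a JSON sidecar with
the acquisition metadata (VENC, cycle duration, spacings, frame count).
Masks are NIfTI label images with a JSON manifest; flow curves and cohort
tables are plain CSV; per-subject results are JSON.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .coupling import CouplingResult, PlaneMetrics, SubjectResult
from .types import CineSeries, FlowWaveform, RoiMask

__all__ = [
    "write_series",
    "read_series",
    "write_masks",
    "read_masks",
    "write_flows",
    "read_flows",
    "write_subject_result",
    "read_subject_result",
]

_SIDECAR_FIELDS = ("venc_mm_s", "cycle_duration_s", "pixel_spacing_mm",
                   "slice_thickness_mm", "frames")


def _affine(series: CineSeries) -> np.ndarray:
    dr, dc = series.pixel_spacing_mm
    return np.diag([dr, dc, series.slice_thickness_mm, 1.0])


def write_series(series: CineSeries, stem: str | Path, quantize_bits: int | None = None) -> None:
    """Write a cine series as ``<stem>_mag/_pha.nii.gz`` + ``<stem>.json``.

    ``quantize_bits`` optionally rounds the stored phase to a scaled-integer
    grid over ``(-pi, pi]`` (e.g. 12 for a scanner-like 12-bit dialect); by
    default phase is stored as exact floating-point radians.
    """
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    phase = series.phase
    if quantize_bits is not None:
        levels = 2**quantize_bits
        step = 2.0 * np.pi / levels
        phase = np.round(phase / step) * step
    aff = _affine(series)
    nib.save(nib.Nifti1Image(series.magnitude.astype(np.float32), aff),
             str(stem) + "_mag.nii.gz")
    nib.save(nib.Nifti1Image(phase.astype(np.float64), aff),
             str(stem) + "_pha.nii.gz")
    sidecar = {
        "venc_mm_s": series.venc_mm_s,
        "cycle_duration_s": series.cycle_duration_s,
        "pixel_spacing_mm": list(series.pixel_spacing_mm),
        "slice_thickness_mm": series.slice_thickness_mm,
        "frames": series.n_frames,
    }
    stem.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_series(stem: str | Path) -> CineSeries:
    """Read a cine series written by :func:`write_series`."""
    stem = Path(stem)
    mag = np.asarray(nib.load(str(stem) + "_mag.nii.gz").dataobj, dtype=float)
    pha = np.asarray(nib.load(str(stem) + "_pha.nii.gz").dataobj, dtype=float)
    sidecar = json.loads(stem.with_suffix(".json").read_text())
    for key in ("venc_mm_s", "cycle_duration_s", "pixel_spacing_mm",
                "slice_thickness_mm", "frames"):
        if key not in sidecar:
            raise ValueError(f"sidecar {stem}.json is missing field {key!r}")
    if mag.shape != pha.shape:
        raise ValueError(
            f"magnitude stack {mag.shape} and phase stack {pha.shape} disagree"
        )
    if pha.shape[2] != sidecar["frames"]:
        raise ValueError(
            f"stacks have {pha.shape[2]} frames but sidecar says "
            f"{sidecar['frames']}"
        )
    return CineSeries(
        mag,
        pha,
        float(sidecar["venc_mm_s"]),
        float(sidecar["cycle_duration_s"]),
        tuple(sidecar["pixel_spacing_mm"]),
        float(sidecar["slice_thickness_mm"]),
    )


def write_masks(masks: dict[str, RoiMask], stem: str | Path,
                extra: dict[str, dict] | None = None) -> None:
    """Write masks as one NIfTI label image + a JSON manifest."""
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    first = next(iter(masks.values()))
    label_img = np.zeros(first.mask.shape, dtype=np.int16)
    manifest = []
    for idx, (name, m) in enumerate(sorted(masks.items()), start=1):
        label_img[m.mask] = idx
        entry = {
            "label": name,
            "index": idx,
            "area_mm2": m.area_mm2,
            "pixel_area_mm2": m.pixel_area_mm2,
            "direction_sign": m.direction_sign,
        }
        if extra and name in extra:
            entry.update(extra[name])
        manifest.append(entry)
    nib.save(nib.Nifti1Image(label_img, np.eye(4)), str(stem) + "_labels.nii.gz")
    stem.with_suffix(".json").write_text(json.dumps(manifest, indent=1))


def read_masks(stem: str | Path) -> dict[str, RoiMask]:
    stem = Path(stem)
    labels = np.asarray(nib.load(str(stem) + "_labels.nii.gz").dataobj)
    manifest = json.loads(stem.with_suffix(".json").read_text())
    out = {}
    for entry in manifest:
        out[entry["label"]] = RoiMask(
            entry["label"],
            labels == entry["index"],
            entry["pixel_area_mm2"],
            entry["direction_sign"],
        )
    return out


def write_flows(flows: dict[str, dict[str, FlowWaveform]], path: str | Path) -> None:
    """Write plane -> structure -> waveform as a tidy CSV."""
    rows = []
    for plane, by_label in flows.items():
        for label, w in by_label.items():
            for frame, (t, q) in enumerate(zip(w.times_s, w.samples)):
                rows.append(
                    {
                        "plane": plane,
                        "structure": label,
                        "frame": frame,
                        "time_s": t,
                        "flow_ml_min": q,
                        "cycle_duration_s": w.cycle_duration_s,
                    }
                )
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_flows(path: str | Path) -> dict[str, dict[str, FlowWaveform]]:
    df = pd.read_csv(path)
    out: dict[str, dict[str, FlowWaveform]] = {}
    for (plane, label), grp in df.groupby(["plane", "structure"], sort=True):
        grp = grp.sort_values("frame")
        out.setdefault(plane, {})[label] = FlowWaveform(
            label, grp["flow_ml_min"].to_numpy(), float(grp["cycle_duration_s"].iloc[0])
        )
    return out


def _coupling_to_dict(c: CouplingResult | None):
    return None if c is None else dataclasses.asdict(c)


def write_subject_result(result: SubjectResult, path: str | Path) -> None:
    payload = {
        "subject_id": result.subject_id,
        "sv_csf": result.sv_csf,
        "sv_csf_signed": result.sv_csf_signed,
        "planes": {
            plane: {
                **{k: v for k, v in dataclasses.asdict(m).items() if k != "coupling"},
                "coupling": _coupling_to_dict(m.coupling),
            }
            for plane, m in result.planes.items()
        },
    }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(payload, indent=1, allow_nan=True))


def read_subject_result(path: str | Path) -> SubjectResult:
    payload = json.loads(Path(path).read_text())
    planes = {}
    for plane, m in payload["planes"].items():
        coupling = m.pop("coupling")
        planes[plane] = PlaneMetrics(
            **{k: (math.nan if v is None else v) for k, v in m.items()},
            coupling=None if coupling is None else CouplingResult(**coupling),
        )
    return SubjectResult(payload["subject_id"], planes, payload["sv_csf"],
                         payload["sv_csf_signed"])
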