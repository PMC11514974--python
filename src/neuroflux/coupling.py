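"""Blood/CSF coupling regression and cohort-level statistics.

Per subject, the 32 points of the spinal CSF volume-change curve are
regressed on the 32 points of a plane's blood volume-change curve
(ordinary least squares, CSF as response); slope, R-squared and the
two-sided p-value of the slope (t test, n-2 df) quantify the mirroring of
blood expansion by spinal CSF venting.  Cohort comparisons between the
intracranial and extracranial planes use a paired Student's t-test or a
Wilcoxon signed-rank test, gated by a Shapiro-Wilk normality test on the
paired differences; correlations use Pearson or Spearman under the same
normality gate.  The 32 within-cycle samples are serially correlated;
p-values ignore this, and each result carries a note saying so.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .types import PLANE_EXTRA, PLANE_INTRA, VolumeChangeCurve

__all__ = [
    "CouplingResult",
    "PairedTestResult",
    "CorrelationResult",
    "PlaneMetrics",
    "SubjectResult",
    "CohortSummary",
    "regress_coupling",
    "choose_paired_test",
    "correlate_sv",
    "summarize_cohort",
]

_AUTOCORR_NOTE = (
    "p-value treats the 32 cycle points as independent; "
    "within-cycle autocorrelation is ignored"
)


@dataclass
class CouplingResult:
    """OLS fit of CSF_VC (response) on CB_VC (predictor) over the cycle."""

    r_squared: float
    slope: float
    intercept: float
    p_value: float
    n_points: int
    plane: str | None = None
    note: str = _AUTOCORR_NOTE


def regress_coupling(
    cb: VolumeChangeCurve | np.ndarray,
    csf: VolumeChangeCurve | np.ndarray,
    plane: str | None = None,
) -> CouplingResult:
    """Linear regression between the cycle points of two volume curves."""
    x = cb.samples if isinstance(cb, VolumeChangeCurve) else np.asarray(cb, float)
    y = csf.samples if isinstance(csf, VolumeChangeCurve) else np.asarray(csf, float)
    if x.size != y.size:
        raise ValueError("curves must have the same number of points")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("constant predictor: CB_VC curve has no variation")
    fit = scipy.stats.linregress(x, y)
    return CouplingResult(
        r_squared=float(fit.rvalue**2),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        p_value=float(fit.pvalue),
        n_points=int(x.size),
        plane=plane,
    )


@dataclass
class PairedTestResult:
    test_name: str  # "paired t" | "wilcoxon" | "degenerate"
    statistic: float
    p_value: float
    shapiro_p: float


def choose_paired_test(x, y, normality_alpha: float = 0.05) -> PairedTestResult:
    """Paired comparison with a Shapiro-Wilk gate on the differences.

    Normally distributed differences (Shapiro-Wilk p >= alpha) get a paired
    Student's t-test, otherwise a Wilcoxon signed-rank test.  All-zero
    differences are degenerate: p = 1 by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("paired samples must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    d = x - y
    if np.allclose(d, 0.0):
        return PairedTestResult("degenerate", 0.0, 1.0, 1.0)
    if np.ptp(d) == 0:
        # identical non-zero shift in every pair: normality is moot,
        # the distribution-free test still applies
        res = scipy.stats.wilcoxon(x, y)
        return PairedTestResult("wilcoxon", float(res.statistic), float(res.pvalue), 0.0)
    shapiro_p = float(scipy.stats.shapiro(d).pvalue)
    if shapiro_p >= normality_alpha:
        res = scipy.stats.ttest_rel(x, y)
        return PairedTestResult("paired t", float(res.statistic), float(res.pvalue), shapiro_p)
    res = scipy.stats.wilcoxon(x, y)
    return PairedTestResult("wilcoxon", float(res.statistic), float(res.pvalue), shapiro_p)


@dataclass
class CorrelationResult:
    coefficient: float
    p_value: float
    method: str  # "pearson" | "spearman"


def correlate_sv(
    sv_csf,
    sv_cb,
    method: str | None = None,
    normality_alpha: float = 0.05,
) -> CorrelationResult:
    """Correlation between per-subject stroke volumes.

    With ``method=None`` a Shapiro-Wilk gate on both margins picks Pearson
    (both normal) or Spearman; pass ``"pearson"`` or ``"spearman"`` to
    force a method.
    """
    x = np.asarray(sv_csf, dtype=float)
    y = np.asarray(sv_cb, dtype=float)
    if x.size != y.size:
        raise ValueError("samples must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 subjects")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: correlation undefined")
    if method is None:
        normal = (
            scipy.stats.shapiro(x).pvalue >= normality_alpha
            and scipy.stats.shapiro(y).pvalue >= normality_alpha
        )
        method = "pearson" if normal else "spearman"
    if method == "pearson":
        r, p = scipy.stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = scipy.stats.spearmanr(x, y)
    else:
        raise ValueError("method must be None, 'pearson' or 'spearman'")
    return CorrelationResult(float(r), float(p), method)


# ---------------------------------------------------------------------------
# per-subject and cohort containers

@dataclass
class PlaneMetrics:
    """Per-subject metrics of one vascular plane (NaN where unavailable)."""

    alpha: float
    alpha_flagged: bool
    mean_arterial_flow: float  # ml/min, positive
    mean_venous_flow_measured: float  # ml/min magnitude, as reported
    pi_arterial: float
    pi_venous: float
    sv_cb: float  # CB_VC amplitude, ml/CC
    sv_total: float  # CB&CSF_VC amplitude, ml/CC
    coupling: CouplingResult | None


@dataclass
class SubjectResult:
    subject_id: str
    planes: dict[str, PlaneMetrics]
    sv_csf: float  # magnitude, ml/CC
    sv_csf_signed: float  # signed by CSF_VC at the intracranial CB_VC peak


#: Table rows: attribute extractor per cohort metric.
_METRICS = {
    "Cerebral arterial mean flow (ml/min)": lambda m: m.mean_arterial_flow,
    "Measured cerebral venous mean flow (ml/min)": lambda m: m.mean_venous_flow_measured,
    "Correction factor alpha": lambda m: math.nan if m.alpha_flagged else m.alpha,
    "PI arterial": lambda m: m.pi_arterial,
    "PI venous": lambda m: m.pi_venous,
    "Amplitude CB_VC (ml/CC)": lambda m: m.sv_cb,
    "Amplitude CB&CSF_VC (ml/CC)": lambda m: m.sv_total,
    "R^2": lambda m: m.coupling.r_squared if m.coupling else math.nan,
    "Slope": lambda m: m.coupling.slope if m.coupling else math.nan,
}


@dataclass
class CohortSummary:
    """Cohort table (per-metric mean/SD/CV% per plane, paired p, test name)."""

    table: pd.DataFrame
    correlations: dict[str, CorrelationResult]
    n_subjects: int
    excluded_alpha_subjects: list[str] = field(default_factory=list)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _cv_percent(values: np.ndarray) -> float:
    mean = values.mean()
    if mean == 0:
        return math.nan
    return 100.0 * values.std(ddof=1) / abs(mean)


def summarize_cohort(
    results: list[SubjectResult],
    normality_alpha: float = 0.05,
    correlation_method: str | None = "spearman",
) -> CohortSummary:
    """Aggregate per-subject results into a cohort comparison table.

    Subjects whose venous capture failed the alpha floor are excluded from
    the alpha aggregation (and flagged) but kept everywhere their metrics
    exist.  Stroke-volume correlations between spinal CSF and each plane's
    blood use Spearman by default.
    """
    if len(results) < 2:
        raise ValueError("need at least 2 subjects")
    rows = []
    excluded = sorted(
        {r.subject_id for r in results for m in r.planes.values() if m.alpha_flagged}
    )
    for name, getter in _METRICS.items():
        values = {}
        for plane in (PLANE_INTRA, PLANE_EXTRA):
            vals = np.array([getter(r.planes[plane]) for r in results], dtype=float)
            values[plane] = vals[~np.isnan(vals)]
        paired_mask = ~np.isnan(
            [getter(r.planes[PLANE_INTRA]) for r in results]
        ) & ~np.isnan([getter(r.planes[PLANE_EXTRA]) for r in results])
        xi = np.array([getter(r.planes[PLANE_INTRA]) for r in results])[paired_mask]
        xe = np.array([getter(r.planes[PLANE_EXTRA]) for r in results])[paired_mask]
        if xi.size >= 3:
            test = choose_paired_test(xi, xe, normality_alpha)
            p, test_name = test.p_value, test.test_name
        else:
            p, test_name = math.nan, "n/a"
        def _stat(vals, fn):
            return fn(vals) if vals.size >= 2 else math.nan

        rows.append(
            {
                "metric": name,
                "intra_mean": _stat(values[PLANE_INTRA], np.mean),
                "intra_sd": _stat(values[PLANE_INTRA], lambda v: v.std(ddof=1)),
                "intra_cv_pct": _stat(values[PLANE_INTRA], _cv_percent),
                "extra_mean": _stat(values[PLANE_EXTRA], np.mean),
                "extra_sd": _stat(values[PLANE_EXTRA], lambda v: v.std(ddof=1)),
                "extra_cv_pct": _stat(values[PLANE_EXTRA], _cv_percent),
                "p_value": p,
                "test": test_name,
            }
        )
    sv_csf_signed = np.array([r.sv_csf_signed for r in results])
    rows.append(
        {
            "metric": "Amplitude CSF_VC (ml/CC)",
            "intra_mean": sv_csf_signed.mean(),
            "intra_sd": sv_csf_signed.std(ddof=1),
            "intra_cv_pct": _cv_percent(sv_csf_signed),
            "extra_mean": math.nan,
            "extra_sd": math.nan,
            "extra_cv_pct": math.nan,
            "p_value": math.nan,
            "test": "n/a",
        }
    )
    sv_csf = np.array([r.sv_csf for r in results])
    correlations = {}
    for plane in (PLANE_INTRA, PLANE_EXTRA):
        sv_cb = np.array([r.planes[plane].sv_cb for r in results])
        ok = ~np.isnan(sv_cb)
        if ok.sum() >= 3 and np.ptp(sv_cb[ok]) > 0 and np.ptp(sv_csf[ok]) > 0:
            correlations[plane] = correlate_sv(
                sv_csf[ok], sv_cb[ok], method=correlation_method,
                normality_alpha=normality_alpha,
            )
    return CohortSummary(pd.DataFrame(rows), correlations, len(results), excluded)
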