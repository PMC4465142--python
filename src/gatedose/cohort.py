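"""Paired cohort comparison of free-breathing vs gated treatment plans.

Extracts the per-patient dose/volume metrics and NTCP values compared in a
breathing-adapted planning study, runs two-sided paired Wilcoxon
signed-rank tests between the two techniques (and unpaired rank-sum tests
between plan-type strata), and assembles median [range] comparison tables.

Statistical conventions
-----------------------
* Paired test: zero differences are dropped (Wilcoxon's convention); the
  exact null distribution is used when at most 20 nonzero differences
  remain and their absolute values carry no ties, otherwise the normal
  approximation with continuity and tie correction.
* Unpaired test: exact when the combined sample size is at most 20 with no
  ties, otherwise the corrected normal approximation.
* Significance is declared at alpha = 0.01 per test, with no
  multiple-testing correction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dvh import (StructurePlan, differential_to_cumulative,
                  dose_at_volume, mean_dose, volume_at_dose,
                  volume_at_relative_dose)
from .geometry import BeamsEyeViewScene, max_heart_distance
from .ntcp import get_endpoint_params, relative_seriality_ntcp

logger = logging.getLogger(__name__)

__all__ = [
    "PatientPlanPair",
    "MetricRecord",
    "ComparisonRow",
    "CohortReport",
    "paired_wilcoxon",
    "unpaired_wilcoxon",
    "summarize_metric",
    "compute_plan_metrics",
    "build_cohort_report",
    "DEFAULT_ALPHA",
]

DEFAULT_ALPHA = 0.01

#: maximum sample size for exact null distributions
_EXACT_LIMIT = 20


@dataclass
class PatientPlanPair:
    """One patient's free-breathing and gated plans.

    ``plans`` maps ``(organ, technique)`` to a :class:`StructurePlan`;
    ``scenes`` maps technique to a beam's-eye-view scene for the MHD.
    """

    patient_id: str
    plan_type: str
    plans: dict[tuple[str, str], StructurePlan] = field(default_factory=dict)
    scenes: dict[str, BeamsEyeViewScene] = field(default_factory=dict)
    breathing_amplitude_mm: Optional[float] = None

    def plan(self, organ: str, technique: str) -> Optional[StructurePlan]:
        return self.plans.get((organ, technique))


@dataclass(frozen=True)
class MetricRecord:
    """One metric value for one (patient, technique)."""

    patient_id: str
    metric_name: str
    technique: str
    value: float


@dataclass(frozen=True)
class ComparisonRow:
    """Median [range] per technique plus the paired test p-value."""

    metric_name: str
    median_fb: float
    range_fb: tuple[float, float]
    median_eig: float
    range_eig: tuple[float, float]
    p_value: float
    n: int
    significant: bool

    def __post_init__(self) -> None:
        for med, (lo, hi) in ((self.median_fb, self.range_fb),
                              (self.median_eig, self.range_eig)):
            if not lo <= med <= hi:
                raise ValueError("range endpoints must bracket the median")


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def paired_wilcoxon(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided paired Wilcoxon signed-rank p-value.

    Zero differences are dropped.  The exact permutation null (all 2^m sign
    assignments of the m nonzero differences) is used when m <= 20 and the
    absolute differences are tie-free; otherwise the normal approximation
    with continuity and tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired samples must be 1-D and of equal length")
    if x.size < 5:
        raise ValueError("paired Wilcoxon needs at least 5 pairs")
    d = x - y
    nz = d[d != 0]
    if nz.size == 0:
        warnings.warn("all paired differences are zero; p = 1", stacklevel=2)
        return 1.0
    ties = np.unique(np.abs(nz)).size < nz.size
    exact = nz.size <= _EXACT_LIMIT and not ties
    method = "exact" if exact else "approx"
    logger.debug("paired Wilcoxon: m=%d nonzero, ties=%s -> %s",
                 nz.size, ties, method)
    res = stats.wilcoxon(x, y, zero_method="wilcox",
                         correction=not exact,
                         alternative="two-sided", method=method)
    return float(res.pvalue)


def unpaired_wilcoxon(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact for combined sample size <= 20 without ties, otherwise the
    continuity-corrected normal approximation with tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ties = np.unique(pooled).size < pooled.size
    exact = pooled.size <= _EXACT_LIMIT and not ties
    res = stats.mannwhitneyu(x, y, alternative="two-sided",
                             method="exact" if exact else "asymptotic",
                             use_continuity=True)
    return float(res.pvalue)


def summarize_metric(values: Sequence[float]) -> tuple[float, float, float]:
    """Median (midpoint convention for even n), min and max of a sample."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot summarize an empty sample")
    return float(np.median(v)), float(v.min()), float(v.max())


# ---------------------------------------------------------------------------
# metric extraction
# ---------------------------------------------------------------------------

def compute_plan_metrics(plan: StructurePlan) -> dict[str, float]:
    """All reportable metrics for one structure of one plan.

    Volumes are in cm^3 (when known), doses in Gy, V_x metrics and NTCP in
    percent.
    """
    organ = plan.organ
    ddvh = plan.dvh
    cdvh = differential_to_cumulative(ddvh)
    rx = plan.prescription_dose
    out: dict[str, float] = {}
    if ddvh.total_volume is not None:
        out[f"V_{organ} (cm3)"] = ddvh.total_volume
    if organ == "PTV":
        out["V_93%,PTV (%)"] = 100.0 * volume_at_relative_dose(cdvh, 93.0, rx)
    elif organ == "CTV-T":
        out["V_95%,CTV-T (%)"] = 100.0 * volume_at_relative_dose(cdvh, 95.0, rx)
    elif organ in ("heart", "LAD"):
        out[f"D_mean,{organ} (Gy)"] = mean_dose(ddvh)
        out[f"D_2%,{organ} (Gy)"] = dose_at_volume(cdvh, 0.02)
        out[f"V_25Gy,{organ} (%)"] = 100.0 * volume_at_dose(cdvh, 25.0)
        if organ == "heart":
            params = get_endpoint_params("cardiac_mortality", plan.plan_type)
            out["NTCP cardiac mortality (%)"] = (
                100.0 * relative_seriality_ntcp(ddvh, params))
    elif organ == "lung":
        out["D_mean,lung (Gy)"] = mean_dose(ddvh)
        out["V_20Gy,lung (%)"] = 100.0 * volume_at_dose(cdvh, 20.0)
        params = get_endpoint_params("radiation_pneumonitis", plan.plan_type)
        out["NTCP pneumonitis (%)"] = (
            100.0 * relative_seriality_ntcp(ddvh, params))
    return out


def extract_metric_records(cohort: Iterable[PatientPlanPair],
                           ) -> list[MetricRecord]:
    """Per-patient metric records for every available structure plan."""
    records: list[MetricRecord] = []
    for patient in cohort:
        for (organ, technique), plan in sorted(patient.plans.items()):
            for name, value in compute_plan_metrics(plan).items():
                records.append(MetricRecord(patient.patient_id, name,
                                            technique, value))
        for technique, scene in sorted(patient.scenes.items()):
            records.append(MetricRecord(patient.patient_id, "MHD (cm)",
                                        technique,
                                        max_heart_distance(scene)))
    return records


# Table row order mirroring the clinical comparison layout
_METRIC_ORDER = [
    "V_PTV (cm3)", "V_93%,PTV (%)", "V_CTV-T (cm3)", "V_95%,CTV-T (%)",
    "V_heart (cm3)", "D_mean,heart (Gy)", "D_2%,heart (Gy)",
    "V_25Gy,heart (%)", "MHD (cm)",
    "V_LAD (cm3)", "D_mean,LAD (Gy)", "D_2%,LAD (Gy)", "V_25Gy,LAD (%)",
    "V_lung (cm3)", "D_mean,lung (Gy)", "V_20Gy,lung (%)",
    "NTCP cardiac mortality (%)", "NTCP pneumonitis (%)",
]

_NTCP_METRICS = ("NTCP cardiac mortality (%)", "NTCP pneumonitis (%)")


@dataclass
class CohortReport:
    """Comparison rows for one plan-type stratum."""

    plan_type: str
    rows: list[ComparisonRow]
    alpha: float = DEFAULT_ALPHA

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "metric": r.metric_name,
            "median_FB": r.median_fb,
            "min_FB": r.range_fb[0], "max_FB": r.range_fb[1],
            "median_EIG": r.median_eig,
            "min_EIG": r.range_eig[0], "max_EIG": r.range_eig[1],
            "p_value": r.p_value, "n": r.n,
            "significant": r.significant,
        } for r in self.rows])

    def to_text(self) -> str:
        """Human-readable median [range] table, one metric per line."""
        def fmt(v: float, metric: str) -> str:
            nd = 2 if metric in _NTCP_METRICS else 1
            return f"{v:.{nd}f}"

        width = max((len(r.metric_name) for r in self.rows), default=10) + 2
        lines = [f"{self.plan_type} treatment (n per test varies; "
                 f"alpha={self.alpha})",
                 f"{'metric':<{width}}{'FB':>22}{'EIG':>22}{'p':>10}"]
        for r in self.rows:
            fb = (f"{fmt(r.median_fb, r.metric_name)} "
                  f"[{fmt(r.range_fb[0], r.metric_name)}-"
                  f"{fmt(r.range_fb[1], r.metric_name)}]")
            eig = (f"{fmt(r.median_eig, r.metric_name)} "
                   f"[{fmt(r.range_eig[0], r.metric_name)}-"
                   f"{fmt(r.range_eig[1], r.metric_name)}]")
            p = "<0.001" if r.p_value < 0.001 else f"{r.p_value:.3f}"
            star = "*" if r.significant else ""
            lines.append(f"{r.metric_name:<{width}}{fb:>22}{eig:>22}"
                         f"{p:>10}{star}")
        return "\n".join(lines) + "\n"


def build_cohort_report(cohort: Sequence[PatientPlanPair],
                        alpha: float = DEFAULT_ALPHA,
                        plan_type: Optional[str] = None) -> CohortReport:
    """Assemble the per-metric FB vs EIG comparison for one stratum.

    Patients missing a metric under either technique are dropped from that
    metric's paired test (logged).  ``plan_type`` defaults to the stratum
    of the first patient; mixing strata in one call is rejected — analyze
    tangential and locoregional cohorts separately.
    """
    cohort = list(cohort)
    if not cohort:
        raise ValueError("empty cohort")
    if plan_type is None:
        plan_type = cohort[0].plan_type
    if any(p.plan_type != plan_type for p in cohort):
        raise ValueError("cohort mixes plan types; analyze strata separately")
    records = extract_metric_records(cohort)
    frame = pd.DataFrame([{
        "patient": r.patient_id, "metric": r.metric_name,
        "technique": r.technique, "value": r.value} for r in records])
    rows: list[ComparisonRow] = []
    seen = [m for m in _METRIC_ORDER if m in set(frame["metric"])]
    for metric in seen:
        sub = frame[frame["metric"] == metric]
        wide = sub.pivot(index="patient", columns="technique", values="value")
        if "FB" not in wide or "EIG" not in wide:
            logger.warning("metric %s lacks one technique entirely; skipped",
                           metric)
            continue
        paired = wide.dropna()
        n_dropped = len(wide) - len(paired)
        if n_dropped:
            logger.warning("metric %s: dropped %d patient(s) missing one "
                           "technique", metric, n_dropped)
        fb = paired["FB"].to_numpy()
        eig = paired["EIG"].to_numpy()
        med_fb, lo_fb, hi_fb = summarize_metric(fb)
        med_eig, lo_eig, hi_eig = summarize_metric(eig)
        if len(paired) >= 5:
            p = paired_wilcoxon(fb, eig)
        else:
            logger.warning("metric %s: only %d pairs, too few for a "
                           "signed-rank test", metric, len(paired))
            p = float("nan")
        rows.append(ComparisonRow(
            metric_name=metric,
            median_fb=med_fb, range_fb=(lo_fb, hi_fb),
            median_eig=med_eig, range_eig=(lo_eig, hi_eig),
            p_value=p, n=len(paired), significant=p < alpha))
    return CohortReport(plan_type=plan_type, rows=rows, alpha=alpha)


def compare_strata(cohort_a: Sequence[PatientPlanPair],
                   cohort_b: Sequence[PatientPlanPair],
                   metric: str, technique: str = "FB") -> float:
    """Unpaired rank-sum p-value for one metric between two strata."""
    def values(cohort: Sequence[PatientPlanPair]) -> np.ndarray:
        recs = extract_metric_records(cohort)
        return np.array([r.value for r in recs
                         if r.metric_name == metric
                         and r.technique == technique])
    return unpaired_wilcoxon(values(cohort_a), values(cohort_b))


def plot_mean_dvhs(cohort: Sequence[PatientPlanPair], ax=None):
    """Convenience overlay of cohort-mean cumulative DVHs per organ.

    Gated plans are drawn solid, free-breathing dashed.  Returns the
    matplotlib axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 5))
    colors = {"PTV": "tab:blue", "CTV-T": "tab:purple", "heart": "tab:red",
              "LAD": "black", "lung": "tab:green"}
    organs = sorted({o for p in cohort for (o, _) in p.plans})
    for organ in organs:
        for technique, style in (("FB", "--"), ("EIG", "-")):
            curves = []
            grid = None
            for patient in cohort:
                plan = patient.plan(organ, technique)
                if plan is None:
                    continue
                c = differential_to_cumulative(plan.dvh)
                if grid is None:
                    grid = c.dose
                curves.append(np.interp(grid, c.dose,
                                        c.volume_fraction_at_or_above,
                                        left=1.0, right=0.0))
            if curves:
                ax.plot(grid, 100.0 * np.mean(curves, axis=0), style,
                        color=colors.get(organ, "gray"),
                        label=f"{organ} {technique}")
    ax.set_xlabel("dose (Gy)")
    ax.set_ylabel("volume (%)")
    ax.legend(fontsize=8)
    return ax
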