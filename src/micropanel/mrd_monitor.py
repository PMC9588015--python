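"""Molecular residual disease (MRD) monitoring and relapse calling.

A sample is ctDNA-positive when any probe-passing micro-panel variant has a
VAF strictly above 0.005% (5e-5).  Patients are first triaged for
evaluability — germline-artifact panels (a variant at ~100% blood VAF),
missing baseline or post-surgery data, and undetectable baseline signal
(< 0.05%) are excluded — then molecular relapse is called at the earliest
positive post-surgery monitoring timepoint, and lead time is the gap from
that call to clinically documented relapse.

Note on the positivity threshold: at consensus depths below 20,000 a single
alt molecule already exceeds 0.005%, so probe QC and (optionally) a
min_positive_variants of 2 carry the specificity burden; the default of 1
follows the stated rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

from .vaf_quant import PatientTimeline, Timepoint

CATEGORIES = (
    "evaluable",
    "insufficient_data",
    "low_baseline_signal",
    "germline_artifact",
)


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal round-half-up (4.25 -> 4.3), matching reported precision."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class PositivityConfig:
    """Positivity and evaluability thresholds.

    ``vaf_threshold`` is the fraction above which (strictly) a variant calls
    a sample positive (0.005% = 5e-5); ``baseline_detectability_threshold``
    is the baseline VAF below which a patient's panel is considered
    undetectable in blood (0.05% = 5e-4); ``germline_vaf_flag`` marks
    apparent germline variants (~100% blood VAF); ``relapse_window_months``
    is the maximum gap between last blood draw and clinical relapse for a
    patient to enter the sensitivity denominator.
    """

    vaf_threshold: float = 5e-5
    min_positive_variants: int = 1
    baseline_detectability_threshold: float = 5e-4
    germline_vaf_flag: float = 0.90
    relapse_window_months: float = 6.0

    def __post_init__(self) -> None:
        for name in ("vaf_threshold", "baseline_detectability_threshold",
                     "germline_vaf_flag"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1)")
        if self.relapse_window_months <= 0:
            raise ValueError("relapse_window_months must be > 0")
        if self.min_positive_variants < 1:
            raise ValueError("min_positive_variants must be >= 1")


@dataclass
class PatientClassification:
    category: str
    reason: str

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


@dataclass
class MonitoringResult:
    """Per-patient monitoring outcome."""

    patient_id: str
    classification: PatientClassification
    positivity: list[tuple[str, float, str]] = field(default_factory=list)
    molecular_relapse_month: float | None = None
    lead_time_months: float | None = None
    ever_positive_in_remission: bool = False
    in_sensitivity_denominator: bool = False
    detected: bool = False


@dataclass
class CohortSummary:
    """Cohort-level MRD monitoring summary."""

    category_counts: dict[str, int]
    results: list[MonitoringResult]
    contingency: dict[str, int]          # keys a,b,c,d (pCR x ever-positive)
    lead_times: list[float]
    mean_lead_time: float | None
    sensitivity_detected: int
    sensitivity_eligible: int

    @property
    def sensitivity(self) -> float | None:
        if self.sensitivity_eligible == 0:
            return None
        return self.sensitivity_detected / self.sensitivity_eligible


def summary_to_dict(summary: "CohortSummary") -> dict:
    """JSON-safe serialization of a cohort summary (inverse of
    :func:`summary_from_dict`)."""
    return {
        "category_counts": summary.category_counts,
        "contingency": summary.contingency,
        "lead_times": summary.lead_times,
        "mean_lead_time": summary.mean_lead_time,
        "sensitivity_detected": summary.sensitivity_detected,
        "sensitivity_eligible": summary.sensitivity_eligible,
        "results": [
            {
                "patient_id": r.patient_id,
                "category": r.classification.category,
                "reason": r.classification.reason,
                "positivity": [list(p) for p in r.positivity],
                "molecular_relapse_month": r.molecular_relapse_month,
                "lead_time_months": r.lead_time_months,
                "ever_positive_in_remission": r.ever_positive_in_remission,
                "in_sensitivity_denominator": r.in_sensitivity_denominator,
                "detected": r.detected,
            }
            for r in summary.results
        ],
    }


def summary_from_dict(d: dict) -> "CohortSummary":
    results = [
        MonitoringResult(
            patient_id=r["patient_id"],
            classification=PatientClassification(r["category"], r["reason"]),
            positivity=[tuple(p) for p in r["positivity"]],
            molecular_relapse_month=r["molecular_relapse_month"],
            lead_time_months=r["lead_time_months"],
            ever_positive_in_remission=r["ever_positive_in_remission"],
            in_sensitivity_denominator=r["in_sensitivity_denominator"],
            detected=r["detected"],
        )
        for r in d["results"]
    ]
    return CohortSummary(
        category_counts=d["category_counts"],
        results=results,
        contingency=d["contingency"],
        lead_times=d["lead_times"],
        mean_lead_time=d["mean_lead_time"],
        sensitivity_detected=d["sensitivity_detected"],
        sensitivity_eligible=d["sensitivity_eligible"],
    )


def call_positivity(
    timepoint: Timepoint, cfg: PositivityConfig | None = None
) -> str:
    """Positivity of one sample: positive iff at least
    ``min_positive_variants`` probe-passing variants have VAF strictly above
    ``vaf_threshold``; indeterminate when no probe-passing variant with a
    defined VAF exists."""
    cfg = cfg or PositivityConfig()
    evaluable = [
        m for m in timepoint.measurements if m.probe_pass and m.vaf is not None
    ]
    if not evaluable:
        return "indeterminate"
    n_pos = sum(1 for m in evaluable if m.vaf > cfg.vaf_threshold)
    return "positive" if n_pos >= cfg.min_positive_variants else "negative"


def classify_patient(
    timeline: PatientTimeline, cfg: PositivityConfig | None = None
) -> PatientClassification:
    """Evaluability triage, in precedence order:

    germline_artifact  - any panel variant at blood VAF >= germline_vaf_flag
                         at any timepoint;
    insufficient_data  - no baseline (T0) draw, or no draw at/after surgery;
    low_baseline_signal- every defined baseline VAF below
                         baseline_detectability_threshold;
    evaluable          - otherwise.
    """
    cfg = cfg or PositivityConfig()
    if not timeline.timepoints:
        raise ValueError(f"empty timeline for patient {timeline.patient_id}")

    for tp in timeline.timepoints:
        for m in tp.measurements:
            if m.vaf is not None and m.vaf >= cfg.germline_vaf_flag:
                return PatientClassification(
                    "germline_artifact",
                    f"{m.chrom}:{m.pos} at {m.vaf:.0%} blood VAF ({tp.label})",
                )

    baseline = timeline.timepoint("T0")
    surgery = timeline.surgery_month
    has_post_surgery = surgery is not None and any(
        tp.month >= surgery for tp in timeline.timepoints
    )
    if baseline is None:
        return PatientClassification("insufficient_data", "no baseline draw")
    if not has_post_surgery:
        return PatientClassification("insufficient_data", "no data post-surgery")

    baseline_vafs = [m.vaf for m in baseline.measurements if m.vaf is not None]
    if not baseline_vafs:
        return PatientClassification(
            "insufficient_data", "no evaluable baseline measurement"
        )
    if max(baseline_vafs) < cfg.baseline_detectability_threshold:
        return PatientClassification(
            "low_baseline_signal",
            f"max baseline VAF {max(baseline_vafs):.2e} < "
            f"{cfg.baseline_detectability_threshold:.2e}",
        )
    return PatientClassification("evaluable", "baseline signal detectable")


def _monitoring_timepoints(timeline: PatientTimeline):
    """Post-surgery monitoring draws: month >= surgery, T4 excluded."""
    if timeline.surgery_month is None:
        return []
    return [
        tp
        for tp in timeline.timepoints
        if tp.month >= timeline.surgery_month and tp.label != "T4"
    ]


def detect_molecular_relapse(
    timeline: PatientTimeline, cfg: PositivityConfig | None = None
) -> float | None:
    """Earliest positive monitoring timepoint at or after surgery (T2
    onward, relapse draws T4 excluded); None when no such timepoint."""
    cfg = cfg or PositivityConfig()
    for tp in _monitoring_timepoints(timeline):
        if call_positivity(tp, cfg) == "positive":
            return tp.month
    return None


def compute_lead_time(
    molecular_month: float, clinical_month: float
) -> tuple[float, bool]:
    """Lead time = clinical - molecular (months).  The flag marks negative
    lead times (molecular call after documented clinical relapse)."""
    lead = clinical_month - molecular_month
    return lead, lead < 0


def monitor_patient(
    timeline: PatientTimeline, cfg: PositivityConfig | None = None
) -> MonitoringResult:
    """Classify one patient and, when evaluable, call molecular relapse,
    remission positivity and sensitivity eligibility."""
    cfg = cfg or PositivityConfig()
    cls = classify_patient(timeline, cfg)
    res = MonitoringResult(patient_id=timeline.patient_id, classification=cls)
    res.positivity = [
        (tp.label, tp.month, call_positivity(tp, cfg))
        for tp in timeline.timepoints
    ]
    if cls.category != "evaluable":
        return res

    relapse = timeline.clinical_relapse_month
    res.molecular_relapse_month = detect_molecular_relapse(timeline, cfg)
    if res.molecular_relapse_month is not None and relapse is not None:
        res.lead_time_months, _ = compute_lead_time(
            res.molecular_relapse_month, relapse
        )

    # Remission window: [surgery, clinical relapse), never the T4 draw.
    for tp in _monitoring_timepoints(timeline):
        if relapse is not None and tp.month >= relapse:
            continue
        if call_positivity(tp, cfg) == "positive":
            res.ever_positive_in_remission = True
            break

    if relapse is not None:
        res.in_sensitivity_denominator = any(
            relapse - cfg.relapse_window_months <= tp.month <= relapse
            for tp in timeline.timepoints
            if tp.label != "T4"
        )
        res.detected = (
            res.molecular_relapse_month is not None
            and res.molecular_relapse_month <= relapse
        )
    return res


def summarize_cohort(
    timelines: list[PatientTimeline], cfg: PositivityConfig | None = None
) -> CohortSummary:
    """Cohort roll-up: evaluability counts, the pCR x ever-positive 2x2
    table over evaluable patients, detection sensitivity over
    window-eligible relapses, and the mean molecular lead time (rounded
    half-up to one decimal, as reported)."""
    cfg = cfg or PositivityConfig()
    results = [monitor_patient(t, cfg) for t in timelines]
    counts = {c: 0 for c in CATEGORIES}
    for r in results:
        counts[r.classification.category] += 1

    by_id = {t.patient_id: t for t in timelines}
    a = b = c = d = 0
    for r in results:
        if r.classification.category != "evaluable":
            continue
        t = by_id[r.patient_id]
        if t.pcr is None:
            continue
        if t.pcr:
            if r.ever_positive_in_remission:
                a += 1
            else:
                b += 1
        else:
            if r.ever_positive_in_remission:
                c += 1
            else:
                d += 1

    lead_times = [
        r.lead_time_months
        for r in results
        if r.in_sensitivity_denominator and r.detected
        and r.lead_time_months is not None
    ]
    detected = sum(1 for r in results if r.in_sensitivity_denominator and r.detected)
    eligible = sum(1 for r in results if r.in_sensitivity_denominator)
    mean_lead = round_half_up(sum(lead_times) / len(lead_times)) if lead_times else None
    return CohortSummary(
        category_counts=counts,
        results=results,
        contingency={"a": a, "b": b, "c": c, "d": d},
        lead_times=lead_times,
        mean_lead_time=mean_lead,
        sensitivity_detected=detected,
        sensitivity_eligible=eligible,
    )
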