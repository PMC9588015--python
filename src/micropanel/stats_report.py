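"""Study statistics and cohort report rendering.

Three statistics summarize a monitored cohort:

* Pearson chi-square (1 df, no continuity correction by default) on the
  2x2 table of pathological complete response (pCR) against ever-positive
  ctDNA during remission.  On the reported table (1/8 pCR vs 8/17 non-pCR
  ever-positive) the uncorrected statistic is 2.820, p = 0.093; the Yates
  correction would give p = 0.22 and is exposed as a flag only.
* Exact (Clopper-Pearson) binomial confidence bounds for detection
  sensitivity, solved by bisection on the binomial tail probabilities; at
  9/10 detected the 95% lower bound is 55%.
* Tissue/blood variant detection concordance, |tissue AND blood| over the
  assayable set.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

from scipy.stats import binom, chi2

from .mrd_monitor import CohortSummary, round_half_up


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts: rows pCR yes/no, columns ever-positive yes/no."""

    a: int  # pCR, positive
    b: int  # pCR, negative
    c: int  # non-pCR, positive
    d: int  # non-pCR, negative

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def margins(self) -> tuple[int, int, int, int]:
        return (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float
    correction_applied: bool


@dataclass(frozen=True)
class BinomialCI:
    successes: int
    trials: int
    confidence: float
    lower: float
    upper: float


class DegenerateTableError(ValueError):
    pass


def pearson_chi2(table: ContingencyTable2x2, yates: bool = False) -> ChiSquareResult:
    """Pearson chi-square test of independence on a 2x2 table.

    statistic = sum (O - E)^2 / E with expected counts from the margins;
    p from the chi-square distribution with 1 df.  ``yates`` applies the
    continuity correction (|O - E| reduced by 0.5, floored at 0).
    """
    r1, r2, c1, c2 = table.margins()
    if min(r1, r2, c1, c2) == 0:
        raise DegenerateTableError("chi-square requires positive margins")
    n = table.n
    obs = (table.a, table.b, table.c, table.d)
    exp = (r1 * c1 / n, r1 * c2 / n, r2 * c1 / n, r2 * c2 / n)
    stat = 0.0
    for o, e in zip(obs, exp):
        dev = abs(o - e)
        if yates:
            dev = max(dev - 0.5, 0.0)
        stat += dev * dev / e
    return ChiSquareResult(
        statistic=stat,
        df=1,
        p_value=float(chi2.sf(stat, 1)),
        correction_applied=yates,
    )


def clopper_pearson(x: int, n: int, conf: float = 0.95, tol: float = 1e-9) -> BinomialCI:
    """Exact binomial confidence interval by bisection on the tails.

    lower = smallest p with P(Bin(n, p) >= x) >= alpha/2 (0 when x = 0);
    upper = largest  p with P(Bin(n, p) <= x) >= alpha/2 (1 when x = n).
    Bisection runs on the exact binomial tail to |dp| < ``tol``, keeping the
    bounds oracle-checkable by direct binomial summation.
    """
    if not 0 <= x <= n or n < 1:
        raise ValueError(f"require 0 <= x <= n, n >= 1 (got x={x}, n={n})")
    if not 0 < conf < 1:
        raise ValueError("confidence must be in (0, 1)")
    alpha = 1.0 - conf

    def upper_tail(p: float) -> float:  # P(X >= x)
        return float(binom.sf(x - 1, n, p))

    def lower_tail(p: float) -> float:  # P(X <= x)
        return float(binom.cdf(x, n, p))

    if x == 0:
        lower = 0.0
    else:
        lo, hi = 0.0, 1.0
        while hi - lo > tol:
            mid = (lo + hi) / 2
            if upper_tail(mid) >= alpha / 2:
                hi = mid
            else:
                lo = mid
        lower = hi
    if x == n:
        upper = 1.0
    else:
        lo, hi = 0.0, 1.0
        while hi - lo > tol:
            mid = (lo + hi) / 2
            if lower_tail(mid) >= alpha / 2:
                lo = mid
            else:
                hi = mid
        upper = lo
    return BinomialCI(successes=x, trials=n, confidence=conf, lower=lower, upper=upper)


def concordance(
    tissue_detected: set, blood_detected: set, assayable: set
) -> dict:
    """Fraction of assayable variants detected in both tissue and blood.

    Returns the fraction, the rounded percent string, and the counts; NA
    (fraction None) with a warning flag when the assayable set is empty.
    """
    if not tissue_detected <= assayable or not blood_detected <= assayable:
        raise ValueError("detected sets must be subsets of the assayable set")
    n_assayable = len(assayable)
    n_both = len(tissue_detected & blood_detected)
    if n_assayable == 0:
        return {"fraction": None, "percent": "NA", "n_both": 0, "n_assayable": 0}
    frac = n_both / n_assayable
    return {
        "fraction": frac,
        "percent": format_percent(n_both, n_assayable),
        "n_both": n_both,
        "n_assayable": n_assayable,
    }


def format_percent(num: int, denom: int) -> str:
    """Percent with round-half-up to the nearest integer, except exact
    non-integer tenths which keep one decimal (1/8 -> '12.5%',
    8/17 -> '47%', 27/33 -> '82%')."""
    pct = 100.0 * num / denom
    tenths = pct * 10
    if abs(tenths - round(tenths)) < 1e-9 and round(tenths) % 10 != 0:
        return f"{round(tenths) / 10:.1f}%"
    return f"{int(round_half_up(pct, 0))}%"


def cohort_statistics(summary: CohortSummary, conf: float = 0.95) -> dict:
    """Compute the cohort's association test and sensitivity bound."""
    t = summary.contingency
    table = ContingencyTable2x2(t["a"], t["b"], t["c"], t["d"])
    stats: dict = {"contingency": t}
    try:
        chi = pearson_chi2(table)
        stats["chi_square"] = asdict(chi)
    except DegenerateTableError as err:
        stats["chi_square"] = {"error": str(err)}
    if summary.sensitivity_eligible > 0:
        ci = clopper_pearson(
            summary.sensitivity_detected, summary.sensitivity_eligible, conf
        )
        stats["sensitivity"] = {
            "detected": ci.successes,
            "eligible": ci.trials,
            "estimate": summary.sensitivity,
            "ci_lower": ci.lower,
            "ci_upper": ci.upper,
            "confidence": conf,
        }
    else:
        stats["sensitivity"] = {"detected": 0, "eligible": 0, "estimate": None}
    stats["mean_lead_time_months"] = summary.mean_lead_time
    stats["category_counts"] = summary.category_counts
    return stats


def render_report(
    summary: CohortSummary,
    stats: dict,
    config_echo: dict | None = None,
    seed: int | None = None,
    version: str = "0.1.0",
) -> dict:
    """Assemble the cohort report (deterministic key order, JSON-safe)."""
    pcr_n = summary.contingency["a"] + summary.contingency["b"]
    npcr_n = summary.contingency["c"] + summary.contingency["d"]
    report = {
        "software_version": version,
        "seed": seed,
        "config": config_echo or {},
        "category_counts": dict(sorted(summary.category_counts.items())),
        "contingency": summary.contingency,
        "positivity_percent": {
            "pcr": format_percent(summary.contingency["a"], pcr_n) if pcr_n else "NA",
            "non_pcr": format_percent(summary.contingency["c"], npcr_n)
            if npcr_n
            else "NA",
        },
        "statistics": stats,
        "lead_times_months": summary.lead_times,
        "mean_lead_time_months": summary.mean_lead_time,
        "positivity_matrix": [
            {
                "patient_id": r.patient_id,
                "category": r.classification.category,
                "timepoints": [
                    {"label": lab, "month": month, "status": status}
                    for lab, month, status in r.positivity
                ],
            }
            for r in summary.results
        ],
    }
    # round-trip guard: the report must be JSON-serializable as-is
    json.dumps(report)
    return report


def render_report_markdown(report: dict) -> str:
    """Short human-readable summary of a cohort report."""
    lines = ["# ctDNA micro-panel cohort report", ""]
    lines.append(f"software version: {report['software_version']}")
    lines.append(f"seed: {report['seed']}")
    lines.append("")
    lines.append("## Evaluability")
    for cat, n in report["category_counts"].items():
        lines.append(f"- {cat}: {n}")
    lines.append("")
    lines.append("## Positivity during remission")
    lines.append(f"- pCR: {report['positivity_percent']['pcr']}")
    lines.append(f"- non-pCR: {report['positivity_percent']['non_pcr']}")
    chi = report["statistics"].get("chi_square", {})
    if "p_value" in chi:
        lines.append(
            f"- chi-square = {chi['statistic']:.3f}, p = {chi['p_value']:.3f}"
        )
    sens = report["statistics"].get("sensitivity", {})
    if sens.get("estimate") is not None:
        lines.append("")
        lines.append("## Molecular relapse detection")
        lines.append(
            f"- sensitivity {sens['detected']}/{sens['eligible']} "
            f"(95% exact lower bound {sens['ci_lower']:.1%})"
        )
    if report["mean_lead_time_months"] is not None:
        lines.append(
            f"- mean lead time: {report['mean_lead_time_months']} months"
        )
    return "\n".join(lines) + "\n"
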