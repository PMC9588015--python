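"""Allele counting and longitudinal VAF quantification at panel loci.

Passing consensus reads (one per original template molecule) are counted at
each micro-panel locus into ref / alt / other / no-call bins; the variant
allele fraction is alt over the evaluable depth (no-calls excluded from the
denominator).  Per-sample measurements carry the raw assigned-read coverage
so the low-performing-probe rule (< 1,000x observed coverage excludes the
probe from positivity calling) can be applied, and measurements are
assembled into per-patient timelines keyed by draw timepoint.
"""

from __future__ import annotations


from dataclasses import dataclass, field

from .panel_design import PanelTarget
from .umi_consensus import ConsensusRead

#: Raw-coverage floor below which a probe is "low-performing" in a sample.
DEFAULT_MIN_RAW_COVERAGE = 1000


@dataclass
class LocusReadcount:
    """Allele counts from passing consensus reads at one panel locus."""

    patient_id: str
    timepoint: str
    chrom: str
    pos: int              # 1-based
    ref_allele: str
    alt_allele: str
    ref_count: int = 0
    alt_count: int = 0
    other_count: int = 0
    no_call_count: int = 0
    raw_coverage: int = 0

    @property
    def consensus_depth(self) -> int:
        return self.ref_count + self.alt_count + self.other_count + self.no_call_count


@dataclass
class VafMeasurement:
    """VAF at one locus in one sample, with probe QC."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    vaf: float | None     # None iff evaluable depth is 0
    consensus_depth: int
    raw_coverage: int
    probe_pass: bool

    @property
    def locus(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref_allele, self.alt_allele)


@dataclass
class Timepoint:
    label: str
    month: float
    measurements: list[VafMeasurement] = field(default_factory=list)


@dataclass
class PatientTimeline:
    """A patient's longitudinal VAF measurements joined to clinical fields.

    Timepoint labels follow the draw scheme T0 (baseline), T1 (Cycle 1
    Day 3), T2 (surgery), T3.k (serial follow-up) and T4 (relapse draw).
    """

    patient_id: str
    timepoints: list[Timepoint]
    pcr: bool | None = None
    surgery_month: float | None = None
    clinical_relapse_month: float | None = None
    last_followup_month: float | None = None

    def __post_init__(self) -> None:
        months = [tp.month for tp in self.timepoints]
        if any(b <= a for a, b in zip(months, months[1:])):
            raise ValueError("timepoint months must be strictly increasing")
        labels = [tp.label for tp in self.timepoints]
        if len(set(labels)) != len(labels):
            raise ValueError("timepoint labels must be unique")

    def timepoint(self, label: str) -> Timepoint | None:
        for tp in self.timepoints:
            if tp.label == label:
                return tp
        return None


def count_alleles(
    consensus_reads: list[ConsensusRead],
    target: PanelTarget,
    patient_id: str = "",
    timepoint: str = "",
    raw_coverage: int = 0,
) -> LocusReadcount:
    """Count passing consensus reads at a panel target's variant locus.

    Each passing consensus read covering the locus contributes exactly once:
    as ref or alt when its base(s) at the locus equal the respective allele,
    as no-call when any relevant base is N, as other otherwise.  Alleles are
    matched by full allele string at the locus offset; a length-changing
    (indel) allele whose consensus context matches neither full string
    counts as other.
    """
    v = target.variant
    rc = LocusReadcount(
        patient_id=patient_id,
        timepoint=timepoint,
        chrom=v.chrom,
        pos=v.pos,
        ref_allele=v.ref_allele,
        alt_allele=v.alt_allele,
        raw_coverage=raw_coverage,
    )
    offset = target.locus_offset
    if offset < 0:
        raise ValueError("variant locus outside its amplicon")
    for cons in consensus_reads:
        if not cons.passes or cons.amplicon_id != target.amplicon_id:
            continue
        ref_obs = cons.sequence[offset : offset + len(v.ref_allele)]
        alt_obs = cons.sequence[offset : offset + len(v.alt_allele)]
        if len(ref_obs) < len(v.ref_allele) and len(alt_obs) < len(v.alt_allele):
            continue  # read does not span the locus
        if "N" in ref_obs[: len(v.ref_allele)] or "N" in alt_obs[: len(v.alt_allele)]:
            rc.no_call_count += 1
        elif alt_obs == v.alt_allele and v.alt_allele != v.ref_allele:
            rc.alt_count += 1
        elif ref_obs == v.ref_allele:
            rc.ref_count += 1
        else:
            rc.other_count += 1
    return rc


def compute_vaf(
    readcount: LocusReadcount,
    min_raw_coverage: int = DEFAULT_MIN_RAW_COVERAGE,
) -> VafMeasurement:
    """VAF = alt / (ref + alt + other); undefined when that denominator is 0."""
    denom = readcount.ref_count + readcount.alt_count + readcount.other_count
    vaf = readcount.alt_count / denom if denom > 0 else None
    return VafMeasurement(
        chrom=readcount.chrom,
        pos=readcount.pos,
        ref_allele=readcount.ref_allele,
        alt_allele=readcount.alt_allele,
        vaf=vaf,
        consensus_depth=readcount.consensus_depth,
        raw_coverage=readcount.raw_coverage,
        probe_pass=probe_qc(readcount.raw_coverage, min_raw_coverage),
    )


def probe_qc(
    raw_coverage: int, min_raw_coverage: int = DEFAULT_MIN_RAW_COVERAGE
) -> bool:
    """Low-performing-probe rule: pass iff observed (raw assigned-read)
    coverage is at least ``min_raw_coverage``; below 1,000x the probe is
    excluded from positivity calling."""
    return raw_coverage >= min_raw_coverage


def assemble_timeline(
    measurements: list[tuple[str, str, float, VafMeasurement]],
    clinical: dict,
) -> PatientTimeline:
    """Assemble one patient's timeline from flat measurement rows.

    ``measurements`` rows are (patient_id, timepoint_label, month,
    VafMeasurement); ``clinical`` carries patient_id, pcr, surgery_month,
    clinical_relapse_month, last_followup_month.  Rows are grouped by
    timepoint and sorted by month; duplicate (patient, label) pairs with
    conflicting months and unknown patient ids are input errors.
    """
    patient_id = clinical["patient_id"]
    grouped: dict[str, tuple[float, list[VafMeasurement]]] = {}
    for pid, label, month, m in measurements:
        if pid != patient_id:
            raise ValueError(
                f"measurement for unknown patient {pid!r} (expected {patient_id!r})"
            )
        if label in grouped:
            if grouped[label][0] != month:
                raise ValueError(
                    f"duplicate timepoint {label!r} with conflicting months"
                )
            if any(prev.locus == m.locus for prev in grouped[label][1]):
                raise ValueError(
                    f"duplicate measurement for {m.locus} at timepoint {label!r}"
                )
            grouped[label][1].append(m)
        else:
            grouped[label] = (month, [m])
    months_seen = [month for month, _ in grouped.values()]
    if len(set(months_seen)) != len(months_seen):
        raise ValueError("two timepoint labels share one month")
    tps = [
        Timepoint(label=label, month=month, measurements=ms)
        for label, (month, ms) in grouped.items()
    ]
    tps.sort(key=lambda tp: tp.month)
    return PatientTimeline(
        patient_id=patient_id,
        timepoints=tps,
        pcr=clinical.get("pcr"),
        surgery_month=clinical.get("surgery_month"),
        clinical_relapse_month=clinical.get("clinical_relapse_month"),
        last_followup_month=clinical.get("last_followup_month"),
    )
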