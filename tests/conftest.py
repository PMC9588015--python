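"""Shared fixtures and builders for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from micropanel.panel_design import SomaticVariant
from micropanel.vaf_quant import PatientTimeline, Timepoint, VafMeasurement


def make_variant(
    patient_id="P001",
    chrom="17",
    pos=7_675_000,
    ref="C",
    alt="T",
    gene="TP53",
    consequence="missense",
    vaf=0.30,
    depth=80,
    pop_af=0.0,
    mq0=0.0,
    known=False,
    confidence="high",
) -> SomaticVariant:
    return SomaticVariant(
        patient_id=patient_id,
        chrom=chrom,
        pos=pos,
        ref_allele=ref,
        alt_allele=alt,
        gene_symbol=gene,
        consequence_class=consequence,
        tissue_vaf=vaf,
        depth=depth,
        population_af=pop_af,
        mq0_fraction=mq0,
        known_variant=known,
        confidence=confidence,
    )


def make_measurement(
    vaf, pos=100, probe_pass=True, raw_coverage=5000, depth=5000
) -> VafMeasurement:
    return VafMeasurement(
        chrom="1",
        pos=pos,
        ref_allele="A",
        alt_allele="G",
        vaf=vaf,
        consensus_depth=depth,
        raw_coverage=raw_coverage,
        probe_pass=probe_pass,
    )


def make_timeline(
    draws: list[tuple[str, float, list[float | None]]],
    patient_id="P001",
    pcr=False,
    surgery_month=5.0,
    clinical_relapse_month=None,
    probe_pass=True,
) -> PatientTimeline:
    """Build a timeline from (label, month, [vafs]) rows."""
    tps = [
        Timepoint(
            label=label,
            month=month,
            measurements=[
                make_measurement(v, pos=100 + i, probe_pass=probe_pass)
                for i, v in enumerate(vafs)
            ],
        )
        for label, month, vafs in draws
    ]
    return PatientTimeline(
        patient_id=patient_id,
        timepoints=tps,
        pcr=pcr,
        surgery_month=surgery_month,
        clinical_relapse_month=clinical_relapse_month,
        last_followup_month=max((tp.month for tp in tps), default=None),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
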