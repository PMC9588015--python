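"""Allele counting, VAF computation, probe QC and timeline assembly."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from micropanel.panel_design import PanelTarget
from micropanel.synthetic_data import (
    CohortConfig,
    ErrorModel,
    simulate_cohort,
    simulate_locus_counts,
)
from micropanel.panel_design import filter_variants, select_panel
from micropanel.umi_consensus import ConsensusRead
from micropanel.vaf_quant import (
    LocusReadcount,
    assemble_timeline,
    compute_vaf,
    count_alleles,
    probe_qc,
)

from .conftest import make_measurement, make_variant


AMP_ID = "P001:1:101:A>G"


def consensus(seq, amp=AMP_ID, status="pass"):
    return ConsensusRead(
        amplicon_id=amp,
        sequence=seq,
        position_error=np.zeros(len(seq)),
        family_size=3,
        read_error_rate=0.0,
        no_call_fraction=seq.count("N") / len(seq),
        filter_status=status,
    )


@pytest.fixture
def target():
    # variant at pos 101 (1-based) inside amplicon [50, 200); offset 50
    v = make_variant(chrom="1", pos=101, ref="A", alt="G", gene="G1")
    return PanelTarget(
        variant=v, amplicon_start=50, amplicon_end=200, primer_pair_id="pp1"
    )


def seq_with(base, offset=50, length=150):
    return "C" * offset + base + "C" * (length - offset - 1)


class TestCountAlleles:
    def test_ref_alt_split(self, target):
        reads = [consensus(seq_with("G"))] * 3 + [consensus(seq_with("A"))] * 7
        rc = count_alleles(reads, target)
        assert (rc.ref_count, rc.alt_count, rc.consensus_depth) == (7, 3, 10)

    def test_n_at_locus_counts_as_no_call(self, target):
        reads = [consensus(seq_with("N")), consensus(seq_with("A"))]
        rc = count_alleles(reads, target)
        assert rc.no_call_count == 1 and rc.ref_count == 1

    def test_third_allele_counts_as_other(self, target):
        rc = count_alleles([consensus(seq_with("T"))], target)
        assert rc.other_count == 1

    def test_zero_covering_reads(self, target):
        rc = count_alleles([], target)
        assert rc.consensus_depth == 0

    def test_failed_consensus_excluded(self, target):
        reads = [consensus(seq_with("G"), status="dropped_read_error")]
        assert count_alleles(reads, target).consensus_depth == 0

    def test_other_amplicon_excluded(self, target):
        reads = [consensus(seq_with("G"), amp="other")]
        assert count_alleles(reads, target).consensus_depth == 0

    @given(
        st.lists(st.sampled_from(["A", "G", "T", "N"]), min_size=0, max_size=60)
    )
    @settings(max_examples=100, deadline=None)
    def test_count_conservation(self, bases):
        v = make_variant(chrom="1", pos=101, ref="A", alt="G", gene="G1")
        tgt = PanelTarget(
            variant=v, amplicon_start=50, amplicon_end=200, primer_pair_id="pp1"
        )
        reads = [consensus(seq_with(b)) for b in bases]
        rc = count_alleles(reads, tgt)
        assert (
            rc.ref_count + rc.alt_count + rc.other_count + rc.no_call_count
            == rc.consensus_depth
            == len(bases)
        )


class TestComputeVaf:
    def rc(self, ref=0, alt=0, other=0, no_call=0, raw=5000):
        return LocusReadcount(
            patient_id="P", timepoint="T0", chrom="1", pos=101,
            ref_allele="A", alt_allele="G", ref_count=ref, alt_count=alt,
            other_count=other, no_call_count=no_call, raw_coverage=raw,
        )

    def test_simple_fraction(self):
        assert compute_vaf(self.rc(ref=7, alt=3)).vaf == pytest.approx(0.30)

    def test_zero_denominator_undefined(self):
        m = compute_vaf(self.rc(no_call=5))
        assert m.vaf is None

    def test_no_calls_excluded_from_denominator(self):
        m = compute_vaf(self.rc(ref=5, alt=5, no_call=10))
        assert m.vaf == pytest.approx(0.5)

    def test_boundary_for_positivity_is_exact(self):
        m = compute_vaf(self.rc(ref=19_999, alt=1))
        assert m.vaf == 1 / 20_000 == 5.0e-5

    def test_probe_flag_carried(self):
        assert compute_vaf(self.rc(ref=1, raw=999)).probe_pass is False
        assert compute_vaf(self.rc(ref=1, raw=1000)).probe_pass is True


class TestProbeQC:
    @pytest.mark.parametrize(
        "raw,expected", [(999, False), (1000, True), (0, False), (10_000, True)]
    )
    def test_thousand_x_boundary(self, raw, expected):
        assert probe_qc(raw) is expected


class TestAssembleTimeline:
    CLINICAL = {
        "patient_id": "P001", "pcr": True, "surgery_month": 5.0,
        "clinical_relapse_month": None, "last_followup_month": 24.0,
    }

    def test_rows_sorted_by_month(self):
        rows = [
            ("P001", "T2", 5.0, make_measurement(0.0)),
            ("P001", "T0", 0.0, make_measurement(0.001)),
            ("P001", "T3.1", 11.0, make_measurement(0.0)),
        ]
        tl = assemble_timeline(rows, self.CLINICAL)
        assert [tp.label for tp in tl.timepoints] == ["T0", "T2", "T3.1"]

    def test_single_timepoint(self):
        tl = assemble_timeline(
            [("P001", "T0", 0.0, make_measurement(0.001))], self.CLINICAL
        )
        assert len(tl.timepoints) == 1

    def test_duplicate_timepoint_rejected(self):
        rows = [
            ("P001", "T2", 5.0, make_measurement(0.0, pos=100)),
            ("P001", "T2", 5.0, make_measurement(0.0, pos=100)),
        ]
        with pytest.raises(ValueError):
            assemble_timeline(rows, self.CLINICAL)

    def test_unknown_patient_rejected(self):
        with pytest.raises(ValueError):
            assemble_timeline(
                [("P999", "T0", 0.0, make_measurement(0.0))], self.CLINICAL
            )

    def test_multiple_variants_per_timepoint_allowed(self):
        rows = [
            ("P001", "T0", 0.0, make_measurement(0.001, pos=100)),
            ("P001", "T0", 0.0, make_measurement(0.002, pos=200)),
        ]
        tl = assemble_timeline(rows, self.CLINICAL)
        assert len(tl.timepoints[0].measurements) == 2


class TestCalibration:
    def test_vaf_estimator_unbiased_at_study_baseline(self):
        """Mean estimated VAF over 200 replicates at true fraction 0.0033
        and 5,000 templates stays within 3 standard errors of truth."""
        truths = simulate_cohort(CohortConfig(n_patients=1, seed=8))
        truth = truths[0]
        panel = select_panel(filter_variants(truth.variant_profile))
        target = panel.targets[0]
        truth.trajectory["T0"] = 0.0033
        truth.variant_multipliers[target.variant.locus] = 1.0
        truth.germline_locus = None
        truth.transient_label = None
        em = ErrorModel(templates_per_amplicon=5000)
        rng = np.random.default_rng(21)
        est = []
        for _ in range(200):
            counts = simulate_locus_counts(truth, panel, "T0", em, rng)
            rc = next(
                c for c in counts
                if (c.chrom, c.pos) == (target.variant.chrom, target.variant.pos)
            )
            est.append(compute_vaf(rc).vaf)
        se = np.std(est, ddof=1) / np.sqrt(len(est))
        assert abs(np.mean(est) - 0.0033) <= 3 * se


class TestEndToEndZeroError:
    def test_alt_count_equals_simulated_templates(self, rng):
        """Zero-error reads -> UMI consensus -> allele counts reproduce the
        simulator's recorded alt-template counts exactly."""
        from micropanel.synthetic_data import (
            attach_amplicon_sequences, simulate_amplicon_reads,
        )
        from micropanel import umi_consensus as uc

        truths = simulate_cohort(CohortConfig(n_patients=1, seed=4))
        panel = select_panel(filter_variants(truths[0].variant_profile))
        seqs = attach_amplicon_sequences(panel, rng)
        em = ErrorModel(
            per_base_substitution_rate=0.0, no_call_rate=0.0,
            templates_per_amplicon=400,
        )
        af = {t.amplicon_id: 0.0123 for t in panel.targets}
        reads, truth_counts = simulate_amplicon_reads(panel, seqs, af, em, rng)
        anchors = {a: s[:20] for a, s in seqs.items()}
        tagged = []
        for rid, s1, q1, s2, q2 in reads:
            tr = uc.extract_umi((rid, s1, q1), (rid, s2, q2))
            amp = uc.assign_amplicon(tr, anchors)
            assert amp is not None
            tagged.append(
                uc.TaggedRead(umi=tr.umi, sequence=tr.sequence, amplicon_id=amp)
            )
        cons = uc.collapse_reads(tagged)
        assert all(c.read_error_rate == 0.0 for c in cons)
        assert all(c.passes for c in cons)
        for t in panel.targets:
            rc = count_alleles(cons, t)
            assert rc.alt_count == truth_counts[t.amplicon_id]["alt_templates"]
            assert rc.consensus_depth == truth_counts[t.amplicon_id]["templates"]
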