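"""UMI extraction, amplicon assignment, family grouping, consensus calling."""

import itertools

import numpy as np
import pytest

from micropanel.umi_consensus import (
    ConsensusFilterConfig,
    ConsensusRead,
    ManifestError,
    ReadFamily,
    TaggedRead,
    call_consensus,
    extract_umi,
    filter_consensus,
    group_families,
    hamming,
    sample_coverage_qc,
)


def tagged(umi, seq, amp="A1"):
    return TaggedRead(umi=umi, sequence=seq, amplicon_id=amp)


def family(seqs, umi="ACGTACGTAC", amp="A1"):
    return ReadFamily(umi=umi, amplicon_id=amp, members=[tagged(umi, s, amp) for s in seqs])


class TestExtractUmi:
    def test_umi_is_first_ten_bases_of_read2(self):
        r1 = ("r1", "GGGGCCCC", "IIIIIIII")
        r2 = ("r1", "ACGTACGTACTTTTGGGG", "I" * 18)
        tr = extract_umi(r1, r2)
        assert tr.umi == "ACGTACGTAC"
        assert tr.mate_remainder == "TTTTGGGG"
        assert tr.sequence == "GGGGCCCC"

    def test_short_read2_rejected(self):
        assert extract_umi(("r", "AAAA", "IIII"), ("r", "ACGTACGT", "I" * 8)) is None

    def test_custom_umi_length(self):
        tr = extract_umi(("r", "AA", "II"), ("r", "ACGTT", "IIIII"), umi_length=4)
        assert tr.umi == "ACGT" and tr.mate_remainder == "T"


class TestAssignAmplicon:
    ANCHORS = {"A1": "ACGTACGTACGTACGTACGT", "A2": "TTTTTTTTTTGGGGGGGGGG"}

    def test_exact_match(self):
        r = tagged("N" * 10, "ACGTACGTACGTACGTACGT" + "C" * 50)
        from micropanel.umi_consensus import assign_amplicon

        assert assign_amplicon(r, self.ANCHORS) == "A1"

    def test_one_mismatch_tolerated(self):
        from micropanel.umi_consensus import assign_amplicon

        r = tagged("N" * 10, "CCGTACGTACGTACGTACGT" + "C" * 50)
        assert assign_amplicon(r, self.ANCHORS, max_mismatches=1) == "A1"
        assert assign_amplicon(r, self.ANCHORS, max_mismatches=0) is None

    def test_ambiguous_match_unassigned(self):
        from micropanel.umi_consensus import assign_amplicon

        anchors = {"A1": "AAAA", "A2": "AAAT"}
        r = tagged("N" * 10, "AAAC" + "G" * 20)
        assert assign_amplicon(r, anchors, max_mismatches=1) is None

    def test_duplicate_anchors_rejected(self):
        from micropanel.umi_consensus import assign_amplicon

        with pytest.raises(ManifestError):
            assign_amplicon(tagged("N" * 10, "ACGT"), {"A1": "ACGT", "A2": "ACGT"})

    def test_hamming_matches_bruteforce(self, rng):
        for _ in range(200):
            a = "".join(rng.choice(list("ACGTN"), 10))
            b = "".join(rng.choice(list("ACGTN"), 10))
            assert hamming(a, b) == sum(
                1 for x, y in zip(a, b) if x != y
            )


def bruteforce_directional(umi_counts, max_dist):
    """Independent fixpoint oracle for directional adjacency clustering.

    Roots are taken in descending-count order; a cluster is the least fixed
    point of 'add any unassigned UMI within max_dist of a member whose count
    is at least twice the candidate's minus... (candidate <= member/2 + 1)'.
    Rescans the whole UMI set until no change.
    """
    order = sorted(umi_counts, key=lambda u: (-umi_counts[u], u))
    assigned = {}
    for root in order:
        if root in assigned:
            continue
        cluster = {root}
        changed = True
        while changed:
            changed = False
            for u in order:
                if u in assigned or u in cluster:
                    continue
                for m in cluster:
                    if (
                        hamming(u, m) <= max_dist
                        and umi_counts[u] <= umi_counts[m] / 2 + 1
                    ):
                        cluster.add(u)
                        changed = True
                        break
        for u in cluster:
            assigned[u] = root
    partition = {}
    for u, r in assigned.items():
        partition.setdefault(r, set()).add(u)
    return set(frozenset(s) for s in partition.values())


class TestGroupFamilies:
    def test_same_umi_one_family(self):
        fams = group_families([tagged("A" * 10, "ACGT"), tagged("A" * 10, "ACGT")])
        assert len(fams) == 1 and fams[0].size == 2

    def test_directional_merge_of_singleton_neighbor(self):
        reads = [tagged("A" * 10, "ACGT") for _ in range(100)]
        reads.append(tagged("A" * 9 + "C", "ACGT"))
        fams = group_families(reads)
        assert len(fams) == 1 and fams[0].size == 101
        assert fams[0].umi == "A" * 10  # representative is the abundant UMI

    def test_same_umi_different_amplicons_never_merged(self):
        fams = group_families(
            [tagged("A" * 10, "ACGT", amp="A1"), tagged("A" * 10, "ACGT", amp="A2")]
        )
        assert len(fams) == 2

    def test_edit_distance_zero_is_exact_grouping(self):
        reads = [tagged("A" * 10, "ACGT"), tagged("A" * 9 + "C", "ACGT")]
        cfg = ConsensusFilterConfig(umi_edit_distance=0)
        assert len(group_families(reads, cfg)) == 2

    def test_umis_with_n_never_merged_across_differing_n(self):
        # N differs from every base, so AN... and AA... are distance 1 but a
        # large AN family is never absorbed into an equally large AA family
        reads = [tagged("AN" + "A" * 8, "ACGT") for _ in range(10)]
        reads += [tagged("AA" + "A" * 8, "ACGT") for _ in range(10)]
        fams = group_families(reads)
        assert len(fams) == 2

    def test_partition_conservation_random(self, rng):
        umis = ["".join(rng.choice(list("ACGT"), 10)) for _ in range(50)]
        reads = [tagged(u, "ACGT") for u in rng.choice(umis, 300)]
        fams = group_families(reads)
        assert sum(f.size for f in fams) == len(reads)

    @pytest.mark.parametrize("trial", range(25))
    def test_agrees_with_bruteforce_oracle(self, trial):
        rng = np.random.default_rng(1000 + trial)
        n_umis = int(rng.integers(1, 21))
        # short UMIs over a 2-letter alphabet force plenty of adjacency
        umis = list(
            {"".join(rng.choice(list("AC"), 4)) for _ in range(n_umis)}
        )
        counts = {u: int(rng.integers(1, 40)) for u in umis}
        reads = [tagged(u, "ACGT") for u in umis for _ in range(counts[u])]
        fams = group_families(reads)
        got = set(frozenset({m.umi for m in f.members}) for f in fams)
        expected = bruteforce_directional(counts, max_dist=1)
        assert got == expected


class TestCallConsensus:
    def test_identical_reads(self):
        c = call_consensus(family(["ACGTACGT"] * 3))
        assert c.sequence == "ACGTACGT"
        assert c.read_error_rate == 0.0
        assert c.no_call_fraction == 0.0

    def test_two_to_one_majority(self):
        c = call_consensus(family(["AAAA", "AAAA", "AAAT"]))
        assert c.sequence == "AAAA"
        assert c.position_error[3] == pytest.approx(1 / 3)
        assert c.read_error_rate == pytest.approx(1 / 12)

    def test_tie_gives_no_call(self):
        c = call_consensus(family(["AAAA", "AAAT"]))
        assert c.sequence == "AAAN"

    def test_single_read_family(self):
        c = call_consensus(family(["ACGT"]))
        assert c.sequence == "ACGT" and c.read_error_rate == 0.0

    def test_n_members_excluded_from_counts(self):
        c = call_consensus(family(["AANA", "AAGA", "AAGA"]))
        assert c.sequence == "AAGA"
        assert c.position_error[2] == 0.0


class TestFilterConsensus:
    def make_consensus(self, length=150, read_error=0.0, pos_errors=()):
        pe = np.zeros(length)
        for i, e in pos_errors:
            pe[i] = e
        return ConsensusRead(
            amplicon_id="A1",
            sequence="A" * length,
            position_error=pe,
            family_size=5,
            read_error_rate=read_error,
            no_call_fraction=0.0,
        )

    def test_read_error_above_five_percent_dropped(self):
        c = filter_consensus(self.make_consensus(read_error=0.08))
        assert c.filter_status == "dropped_read_error"

    def test_read_error_exactly_five_percent_kept(self):
        c = filter_consensus(self.make_consensus(read_error=0.05))
        assert c.filter_status == "pass"

    def test_base_error_above_ten_percent_masked(self):
        c = filter_consensus(
            self.make_consensus(read_error=0.01, pos_errors=[(0, 1 / 3)])
        )
        assert c.sequence[0] == "N" and c.filter_status == "pass"

    def test_base_error_exactly_ten_percent_not_masked(self):
        c = filter_consensus(
            self.make_consensus(read_error=0.01, pos_errors=[(0, 0.10)])
        )
        assert c.sequence[0] == "A"

    def test_over_half_no_calls_dropped(self):
        # 76 of 150 positions masked -> no-call fraction 0.507 > 0.50
        c = filter_consensus(
            self.make_consensus(
                read_error=0.02, pos_errors=[(i, 0.2) for i in range(76)]
            )
        )
        assert c.no_call_fraction == pytest.approx(76 / 150)
        assert c.filter_status == "dropped_no_call"

    def test_exactly_half_no_calls_kept(self):
        c = filter_consensus(
            self.make_consensus(
                read_error=0.02, pos_errors=[(i, 0.2) for i in range(75)]
            )
        )
        assert c.filter_status == "pass"

    def test_family_level_no_call_drop(self):
        # members rich in N: masked positions have 3 informative reads with a
        # dissenter (error 1/3 > 0.10) while overall read error stays <= 5%
        length, n_members, n_bad = 150, 50, 76
        members = []
        for i in range(n_members):
            seq = ["A"] * length
            for j in range(n_bad):
                if i < 3:
                    seq[j] = "A" if i else "T"  # member 0 dissents
                else:
                    seq[j] = "N"
            members.append("".join(seq))
        c = call_consensus(family(members))
        assert c.read_error_rate <= 0.05
        c = filter_consensus(c)
        assert c.filter_status == "dropped_no_call"


class TestCoverageQC:
    def passing(self, n, amp="A1", length=10):
        return [
            ConsensusRead(
                amplicon_id=amp,
                sequence="A" * length,
                position_error=np.zeros(length),
                family_size=2,
                read_error_rate=0.0,
                no_call_fraction=0.0,
                filter_status="pass",
            )
            for _ in range(n)
        ]

    def test_mean_below_500_fails(self):
        reads = self.passing(500, "A1") + self.passing(499, "A2")
        qc = sample_coverage_qc(reads, [("A1", 0), ("A2", 0)])
        assert qc["mean_unique_coverage"] == 499.5
        assert not qc["pass"]

    def test_mean_exactly_500_passes(self):
        qc = sample_coverage_qc(self.passing(500), [("A1", 0)])
        assert qc["pass"]

    def test_zero_reads_fail(self):
        qc = sample_coverage_qc([], [("A1", 0)])
        assert qc["mean_unique_coverage"] == 0 and not qc["pass"]

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError):
            sample_coverage_qc(self.passing(10), [])

    def test_failed_consensus_not_counted(self):
        reads = self.passing(600)
        for r in reads[:200]:
            r.filter_status = "dropped_read_error"
        qc = sample_coverage_qc(reads, [("A1", 0)])
        assert qc["mean_unique_coverage"] == 400


class TestErrorSuppression:
    def test_consensus_suppresses_random_errors(self, rng):
        """Per-base error 0.02, family size 5: post-consensus mismatch rate
        must fall below 0.002 and strictly below the raw-read rate."""
        length, n_fam, fam_size, p_err = 150, 700, 5, 0.02
        bases = np.array(list("ACGT"))
        template_codes = rng.integers(0, 4, size=(n_fam, length))
        raw_mismatches = 0
        cons_mismatches = 0
        total_raw = 0
        for f in range(n_fam):
            template = "".join(bases[template_codes[f]])
            member_codes = np.tile(template_codes[f], (fam_size, 1))
            err = rng.random(member_codes.shape) < p_err
            member_codes = (member_codes + err * rng.integers(1, 4, member_codes.shape)) % 4
            members = ["".join(bases[row]) for row in member_codes]
            raw_mismatches += int(err.sum())
            total_raw += fam_size * length
            c = call_consensus(family(members))
            cons_mismatches += sum(a != b for a, b in zip(c.sequence, template))
        assert total_raw >= 100_000
        raw_rate = raw_mismatches / total_raw
        cons_rate = cons_mismatches / (n_fam * length)
        assert cons_rate < 0.002
        assert cons_rate < raw_rate
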