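"""UMI-based amplicon error correction.

Amplicon libraries tag every original single-strand template molecule with a
unique molecular identifier (UMI): the first 10 bp of read 2.  All reads
sharing a UMI (within one amplicon) are presumed PCR/sequencing copies of a
single template, so collapsing each read family to a per-position majority
consensus suppresses polymerase and sequencer errors by orders of magnitude
and lets variant allele fractions well below 0.1% be measured reliably.

Stages implemented here:

1. ``extract_umi``        - pull the UMI off read 2.
2. ``assign_amplicon``    - anchor-match reads to panel amplicons
                            (replaces genome alignment; amplicons are short
                            and uniquely identified by their 5' sequence).
3. ``group_families``     - directional-adjacency UMI grouping.
4. ``call_consensus``     - count-based majority consensus per family.
5. ``filter_consensus``   - read-error / base-error / no-call filters.
6. ``sample_coverage_qc`` - 500x mean unique (consensus) coverage gate.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass

import numpy as np

_BASES = "ACGTN"
_BASE_TO_CODE = {b: i for i, b in enumerate(_BASES)}
_N_CODE = _BASE_TO_CODE["N"]


class ManifestError(ValueError):
    """Raised for inconsistent amplicon manifests."""


@dataclass(frozen=True)
class TaggedRead:
    """A read pair after UMI extraction.

    ``sequence`` is the read-1 sequence (covering the full amplicon and used
    for consensus); ``mate_remainder`` is read 2 with the UMI removed.
    """

    umi: str
    sequence: str
    quality: str = ""
    read_id: str = ""
    mate_remainder: str = ""
    amplicon_id: str | None = None


@dataclass
class ReadFamily:
    """All reads presumed to derive from one template molecule."""

    umi: str                 # representative (highest-count) UMI of the cluster
    amplicon_id: str
    members: list[TaggedRead]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("read family must have >= 1 member")
        if any(m.amplicon_id != self.amplicon_id for m in self.members):
            raise ValueError("family members must share an amplicon")

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class ConsensusRead:
    """Majority consensus of a read family with disagreement metadata."""

    amplicon_id: str
    sequence: str
    position_error: np.ndarray        # per-position disagreement fraction
    family_size: int
    read_error_rate: float
    no_call_fraction: float
    filter_status: str = "unfiltered"

    @property
    def passes(self) -> bool:
        return self.filter_status == "pass"


@dataclass(frozen=True)
class ConsensusFilterConfig:
    """Thresholds for consensus filtering and sample QC.

    Consensus reads whose overall read error rate exceeds
    ``max_read_error_rate`` are dropped; individual consensus bases whose
    error rate exceeds ``max_base_error_rate`` are masked to N; reads left
    with more than ``max_no_call_fraction`` no-calls are dropped.  All three
    comparisons are strict (rates must *exceed* the threshold), while the
    sample-level ``min_mean_unique_coverage`` of 500 is inclusive.
    """

    max_read_error_rate: float = 0.05
    max_base_error_rate: float = 0.10
    max_no_call_fraction: float = 0.50
    min_family_size: int = 1
    umi_edit_distance: int = 1
    min_mean_unique_coverage: float = 500.0

    def __post_init__(self) -> None:
        for name in ("max_read_error_rate", "max_base_error_rate",
                     "max_no_call_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.min_family_size < 1 or self.umi_edit_distance < 0:
            raise ValueError("invalid family/edit-distance settings")


def extract_umi(read1, read2, umi_length: int = 10) -> TaggedRead | None:
    """Split a read pair into UMI + template.

    ``read1``/``read2`` are ``(read_id, sequence, quality)`` tuples.  The UMI
    is the first ``umi_length`` bases of read 2; those bases are removed from
    the read-2 template.  Returns None (caller counts it in QC) when read 2
    is not longer than the UMI.
    """
    rid1, seq1, qual1 = read1
    _, seq2, _ = read2
    if len(seq2) <= umi_length:
        return None
    return TaggedRead(
        umi=seq2[:umi_length],
        sequence=seq1,
        quality=qual1,
        read_id=rid1,
        mate_remainder=seq2[umi_length:],
    )


def hamming(a: str, b: str) -> int:
    """Hamming distance between equal-length strings.

    N is an ordinary fifth symbol: it mismatches every base (so UMIs are
    never merged across differing N positions) but matches another N.
    """
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


def assign_amplicon(
    read: TaggedRead,
    anchors: dict[str, str],
    max_mismatches: int = 1,
) -> str | None:
    """Assign a read to the amplicon whose 5' anchor it matches.

    ``anchors`` maps amplicon_id -> anchor subsequence (a prefix of the
    amplicon reference).  The read is assigned iff exactly one anchor matches
    its prefix within ``max_mismatches``; ambiguous or absent matches return
    None.
    """
    if len(set(anchors.values())) != len(anchors):
        raise ManifestError("duplicate anchor sequences in manifest")
    hits = []
    for amp_id, anchor in anchors.items():
        prefix = read.sequence[: len(anchor)]
        if len(prefix) < len(anchor):
            continue
        if hamming(prefix, anchor) <= max_mismatches:
            hits.append(amp_id)
    if len(hits) != 1:
        return None
    return hits[0]


def _directional_clusters(
    umi_counts: dict[str, int], max_dist: int
) -> dict[str, str]:
    """Directional adjacency clustering of UMIs within one amplicon.

    UMIs are visited in descending count (ties: lexicographic).  From each
    unvisited UMI a cluster grows by repeatedly absorbing unvisited UMIs
    within ``max_dist`` of any cluster member whose count is at most
    (absorbing member's count / 2) + 1.  Returns umi -> representative.
    """
    order = sorted(umi_counts, key=lambda u: (-umi_counts[u], u))
    rep: dict[str, str] = {}
    for root in order:
        if root in rep:
            continue
        rep[root] = root
        frontier = [root]
        while frontier:
            node = frontier.pop()
            for other in order:
                if other in rep:
                    continue
                if (
                    hamming(node, other) <= max_dist
                    and umi_counts[other] <= umi_counts[node] / 2 + 1
                ):
                    rep[other] = root
                    frontier.append(other)
    return rep


def group_families(
    tagged_reads: list[TaggedRead],
    cfg: ConsensusFilterConfig | None = None,
) -> list[ReadFamily]:
    """Group amplicon-assigned reads into UMI families.

    Within each amplicon, UMIs within ``umi_edit_distance`` are merged by the
    directional rule (small counts absorbed when <= larger/2 + 1), the
    standard guard against UMI collisions; distance 0 gives exact grouping.
    Families partition the assigned reads exactly.
    """
    cfg = cfg or ConsensusFilterConfig()
    by_amp: dict[str, list[TaggedRead]] = defaultdict(list)
    for r in tagged_reads:
        if r.amplicon_id is None:
            raise ValueError("reads must be amplicon-assigned before grouping")
        by_amp[r.amplicon_id].append(r)

    families: list[ReadFamily] = []
    for amp_id in sorted(by_amp):
        reads = by_amp[amp_id]
        counts = Counter(r.umi for r in reads)
        if cfg.umi_edit_distance == 0:
            rep = {u: u for u in counts}
        else:
            rep = _directional_clusters(dict(counts), cfg.umi_edit_distance)
        members: dict[str, list[TaggedRead]] = defaultdict(list)
        for r in reads:
            members[rep[r.umi]].append(r)
        for umi in sorted(members):
            families.append(
                ReadFamily(umi=umi, amplicon_id=amp_id, members=members[umi])
            )
    return families


def _encode(seqs: list[str]) -> np.ndarray:
    length = max(len(s) for s in seqs)
    arr = np.full((len(seqs), length), _N_CODE, dtype=np.uint8)
    for i, s in enumerate(seqs):
        arr[i, : len(s)] = [_BASE_TO_CODE.get(b, _N_CODE) for b in s]
    return arr


def call_consensus(family: ReadFamily) -> ConsensusRead:
    """Count-based majority consensus of one read family.

    Per position the consensus base is the strict majority among non-N member
    bases (ties and all-N positions give N).  The per-position error is the
    fraction of non-N member bases disagreeing with the consensus; the read
    error rate is total disagreeing bases over total non-N bases.
    """
    arr = _encode([m.sequence for m in family.members])
    n_reads, length = arr.shape
    # counts[b, j] = number of members with base b at position j
    counts = np.zeros((5, length), dtype=np.int64)
    for b in range(5):
        counts[b] = (arr == b).sum(axis=0)
    informative = counts[:4].sum(axis=0)
    top = counts[:4].argmax(axis=0)
    top_count = counts[:4].max(axis=0)
    # strict majority among non-N bases; ties -> N
    n_top = (counts[:4] == top_count).sum(axis=0)
    is_call = (informative > 0) & (n_top == 1) & (2 * top_count > informative)
    cons_codes = np.where(is_call, top, _N_CODE)

    disagree = np.where(is_call, informative - top_count, 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        pos_error = np.where(informative > 0, disagree / np.maximum(informative, 1), 0.0)
    total_informative = int(informative[is_call].sum())
    read_error = (
        float(disagree.sum()) / total_informative if total_informative else 0.0
    )
    seq = "".join(_BASES[c] for c in cons_codes)
    return ConsensusRead(
        amplicon_id=family.amplicon_id,
        sequence=seq,
        position_error=pos_error,
        family_size=family.size,
        read_error_rate=read_error,
        no_call_fraction=seq.count("N") / length if length else 0.0,
    )


def filter_consensus(
    consensus: ConsensusRead, cfg: ConsensusFilterConfig | None = None
) -> ConsensusRead:
    """Apply the three consensus filters, in order.

    (1) drop the read if its read error rate exceeds ``max_read_error_rate``;
    (2) mask to N every base whose error rate exceeds ``max_base_error_rate``;
    (3) drop the read if the resulting no-call fraction exceeds
    ``max_no_call_fraction``.  All comparisons strict.
    """
    cfg = cfg or ConsensusFilterConfig()
    if consensus.read_error_rate > cfg.max_read_error_rate:
        consensus.filter_status = "dropped_read_error"
        return consensus
    mask = consensus.position_error > cfg.max_base_error_rate
    if mask.any():
        seq = np.array(list(consensus.sequence))
        seq[mask] = "N"
        consensus.sequence = "".join(seq)
    length = len(consensus.sequence)
    consensus.no_call_fraction = (
        consensus.sequence.count("N") / length if length else 0.0
    )
    if consensus.no_call_fraction > cfg.max_no_call_fraction:
        consensus.filter_status = "dropped_no_call"
    else:
        consensus.filter_status = "pass"
    return consensus


def collapse_reads(
    tagged_reads: list[TaggedRead],
    cfg: ConsensusFilterConfig | None = None,
) -> list[ConsensusRead]:
    """Group, call and filter consensus reads in one pass."""
    cfg = cfg or ConsensusFilterConfig()
    out = []
    for fam in group_families(tagged_reads, cfg):
        if fam.size < cfg.min_family_size:
            continue
        out.append(filter_consensus(call_consensus(fam), cfg))
    return out


def sample_coverage_qc(
    consensus_reads: list[ConsensusRead],
    panel_loci: list[tuple[str, int]],
    cfg: ConsensusFilterConfig | None = None,
) -> dict:
    """Sample-level unique-coverage QC.

    ``panel_loci`` is a list of (amplicon_id, locus_offset).  The metric is
    the mean, over panel loci, of passing consensus reads covering the locus
    with a called (non-N) base or any base; coverage here counts passing
    consensus reads whose sequence spans the offset.  The sample passes iff
    the mean is at least ``min_mean_unique_coverage`` (inclusive).
    """
    cfg = cfg or ConsensusFilterConfig()
    if not panel_loci:
        raise ValueError("coverage QC requires a non-empty panel")
    per_amp: dict[str, int] = Counter()
    for c in consensus_reads:
        if c.passes:
            per_amp[c.amplicon_id] += 1
    cov = []
    for amp_id, offset in panel_loci:
        n = sum(
            1
            for c in consensus_reads
            if c.passes and c.amplicon_id == amp_id and offset < len(c.sequence)
        )
        cov.append(n)
    mean_cov = float(np.mean(cov))
    return {
        "mean_unique_coverage": mean_cov,
        "per_locus_coverage": dict(zip([f"{a}:{o}" for a, o in panel_loci], cov)),
        "pass": mean_cov >= cfg.min_mean_unique_coverage,
    }
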